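"""Spectrophotometric pigment quantification (96% ethanol extracts).

Chlorophylls and total carotenoids are computed from absorbances at 663,
646 and 470 nm with Lichtenthaler-type coefficients:

    Chl a = 12.21 * A663 - 2.81 * A646
    Chl b = 20.13 * A646 - 5.1  * A663
    Chl T = Chl a + Chl b
    Car   = (1000 * A470 - 3.27 * Chl a - 104 * Chl b) / 227

Concentrations are in ug per ml of extract; :func:`to_mg_per_g` converts to
mg per g fresh weight given the extraction protocol (default 2 ml of
ethanol per 25 mg of leaf tissue).

All four outputs are linear in the absorbances, which makes the mapping
(Chl a, Chl b, Car) -> (A663, A646, A470) an invertible linear system;
:func:`absorbances_for` solves it, which the synthetic-data generator uses
to fabricate absorbance panels with known pigment truth.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "chlorophyll_a",
    "chlorophyll_b",
    "total_chlorophyll",
    "carotenoids",
    "quantify",
    "absorbances_for",
    "to_mg_per_g",
]

# coefficient matrix of (chl_a, chl_b) on (A663, A646)
_CHL_COEF = np.array([[12.21, -2.81], [-5.1, 20.13]])


def _check_absorbance(name: str, a) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if np.any(a < 0):
        raise InputError(f"negative absorbance in {name}")
    return a


def chlorophyll_a(a663, a646):
    """Chlorophyll a, ug/ml: 12.21*A663 - 2.81*A646."""
    a663 = _check_absorbance("A663", a663)
    a646 = _check_absorbance("A646", a646)
    return 12.21 * a663 - 2.81 * a646


def chlorophyll_b(a663, a646):
    """Chlorophyll b, ug/ml: 20.13*A646 - 5.1*A663."""
    a663 = _check_absorbance("A663", a663)
    a646 = _check_absorbance("A646", a646)
    return 20.13 * a646 - 5.1 * a663


def total_chlorophyll(chl_a, chl_b):
    """Total chlorophyll: the exact sum Chl a + Chl b."""
    return np.asarray(chl_a, dtype=float) + np.asarray(chl_b, dtype=float)


def carotenoids(a470, chl_a, chl_b):
    """Total carotenoids, ug/ml: (1000*A470 - 3.27*Chl a - 104*Chl b) / 227.

    A negative result (possible for noisy readings of chlorophyll-rich,
    carotenoid-poor extracts) is returned as computed but flagged with a
    warning rather than rejected.
    """
    a470 = _check_absorbance("A470", a470)
    car = (1000.0 * a470 - 3.27 * np.asarray(chl_a, float) - 104.0 * np.asarray(chl_b, float)) / 227.0
    if np.any(np.asarray(car) < 0):
        warnings.warn(
            "negative carotenoid concentration computed; absorbances may be "
            "inconsistent with the chlorophyll estimates",
            stacklevel=2,
        )
    return car


def quantify(samples: pd.DataFrame, per_gram: bool = False) -> pd.DataFrame:
    """Add chl_a, chl_b, chl_total and carotenoid columns to an absorbance table.

    ``samples`` needs columns a663, a646, a470 (any identifier columns are
    passed through).  With ``per_gram=True`` concentrations are converted to
    mg/g fresh weight using the default extraction protocol.
    """
    for col in ("a663", "a646", "a470"):
        if col not in samples.columns:
            raise InputError(f"absorbance table is missing column {col!r}")
    out = samples.copy()
    chl_a = chlorophyll_a(out["a663"], out["a646"])
    chl_b = chlorophyll_b(out["a663"], out["a646"])
    out["chl_a"] = chl_a
    out["chl_b"] = chl_b
    out["chl_total"] = total_chlorophyll(chl_a, chl_b)
    out["carotenoids"] = carotenoids(out["a470"], chl_a, chl_b)
    if per_gram:
        for col in ("chl_a", "chl_b", "chl_total", "carotenoids"):
            out[col] = to_mg_per_g(out[col])
    return out


def absorbances_for(chl_a, chl_b, car):
    """Absorbances (A663, A646, A470) yielding the given pigment values.

    Inverts the quantification formulas exactly.  Raises if the target
    pigment combination would require a negative absorbance (nonphysical).
    """
    targets = np.stack(
        [np.asarray(chl_a, float), np.asarray(chl_b, float)], axis=-1
    )
    ab = np.linalg.solve(_CHL_COEF, targets[..., None])[..., 0]
    a663, a646 = ab[..., 0], ab[..., 1]
    a470 = (
        227.0 * np.asarray(car, float)
        + 3.27 * np.asarray(chl_a, float)
        + 104.0 * np.asarray(chl_b, float)
    ) / 1000.0
    if np.any(a663 < 0) or np.any(a646 < 0) or np.any(a470 < 0):
        raise InputError(
            "target pigment values require negative absorbances; "
            "not a physical sample"
        )
    return a663, a646, a470


def to_mg_per_g(
    ug_per_ml, extract_volume_ml: float = 2.0, tissue_mass_mg: float = 25.0
):
    """Convert ug/ml of extract to mg/g fresh weight.

    Defaults follow the extraction protocol: 25 mg of tissue homogenised in
    2 ml of 96% ethanol, i.e. 1 ug/ml corresponds to 0.08 mg/g.
    """
    if extract_volume_ml <= 0 or tissue_mass_mg <= 0:
        raise InputError("extract volume and tissue mass must be positive")
    ug_total = np.asarray(ug_per_ml, dtype=float) * extract_volume_ml
    return ug_total / tissue_mass_mg  # ug/mg == mg/g
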