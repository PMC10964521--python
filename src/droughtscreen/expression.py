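"""Relative qPCR quantification by the comparative-CT (Livak) method.

The cycle threshold (CT) is the PCR cycle at which a well's fluorescence
crosses the detection threshold; one extra cycle corresponds to a doubling
of template under ideal amplification.  Expression of a target gene is
quantified relative to a stably expressed reference gene and to a calibrator
condition:

    dCT  = CT(target) - CT(reference)          within a sample
    ddCT = dCT(treated) - dCT(calibrator)
    fold change = 2 ** (-ddCT)

Amplification efficiency is assumed to be exactly 2 per cycle in the fold
change; primer efficiencies estimated from dilution series are reported for
quality control only and never folded into the quantification.

The study design this module serves: targets Dhn1 (dehydrin), SOD, POD and
CAT, reference alpha-tubulin, in two wild barley genotypes under three soil
moisture levels, with two biological x two technical replicates.  Technical
replicates are collapsed by the arithmetic mean of CT before dCT; biological
replicates are preserved for downstream ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, InputError, MissingDataError

__all__ = [
    "REFERENCE_GENE",
    "CALIBRATOR_TREATMENT",
    "TREATMENTS",
    "TARGET_GENES",
    "collapse_technical",
    "delta_ct",
    "fold_change",
    "relative_expression",
    "summarize_fold_changes",
    "PrimerEfficiency",
    "primer_efficiency",
]

REFERENCE_GENE = "alpha_tubulin"
CALIBRATOR_TREATMENT = "control_90_95FC"
#: soil-moisture treatments as fractions of field capacity
TREATMENTS = ("control_90_95FC", "mild_50_55FC", "severe_25_30FC")
TARGET_GENES = ("Dhn1", "SOD", "POD", "CAT")

_CT_RANGE = (5.0, 45.0)
_CELL_KEYS = ["genotype", "treatment", "gene", "bio_rep"]


def _check_ct_range(ct: pd.Series) -> None:
    low, high = _CT_RANGE
    n_out = int(((ct < low) | (ct > high)).sum())
    if n_out:
        warnings.warn(
            f"{n_out} CT value(s) outside the plausible range [{low}, {high}]; "
            "kept, but check the raw wells",
            stacklevel=3,
        )


def collapse_technical(records: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates: mean CT per (genotype, treatment, gene, bio_rep)."""
    required = _CELL_KEYS + ["ct"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise InputError(f"CT table is missing column(s) {missing}")
    if not np.isfinite(records["ct"]).all():
        raise InputError("CT table contains non-finite CT values")
    _check_ct_range(records["ct"])
    out = (
        records.groupby(_CELL_KEYS, as_index=False, sort=False)["ct"]
        .mean()
    )
    return out


def delta_ct(target_ct, reference_ct):
    """dCT = CT(target) - CT(reference); accepts scalars or aligned arrays."""
    return np.asarray(target_ct, dtype=float) - np.asarray(reference_ct, dtype=float) \
        if np.ndim(target_ct) or np.ndim(reference_ct) \
        else float(target_ct) - float(reference_ct)


def fold_change(delta_ct_treated, delta_ct_calibrator):
    """2^-ddCT relative expression; 1.0 when treated and calibrator dCT agree."""
    ddct = np.asarray(delta_ct_treated, dtype=float) - np.asarray(
        delta_ct_calibrator, dtype=float
    )
    result = np.exp2(-ddct)
    return float(result) if result.ndim == 0 else result


def relative_expression(
    records: pd.DataFrame,
    reference_gene: str = REFERENCE_GENE,
    calibrator: str = CALIBRATOR_TREATMENT,
    collapse: bool = True,
) -> pd.DataFrame:
    """Fold-change table from a raw CT table.

    For every (genotype, gene, bio_rep) the reference gene's CT in the same
    cell is subtracted (dCT); the calibrator dCT of the same genotype and
    gene — averaged over the calibrator's biological replicates — is then
    subtracted (ddCT) and the fold change 2^-ddCT attached.  Calibrator rows
    therefore have mean ddCT exactly 0 per (genotype, gene).

    Returns columns genotype, treatment, gene, bio_rep, dct, ddct,
    fold_change, one row per biological replicate of each target gene.
    """
    table = collapse_technical(records) if collapse else records.copy()
    ref = table[table["gene"] == reference_gene]
    if ref.empty:
        raise MissingDataError(
            f"reference gene {reference_gene!r} absent from the CT table"
        )
    targets = table[table["gene"] != reference_gene].copy()
    ref_ct = ref.set_index(["genotype", "treatment", "bio_rep"])["ct"]
    idx = pd.MultiIndex.from_frame(targets[["genotype", "treatment", "bio_rep"]])
    matched = ref_ct.reindex(idx)
    if matched.isna().any():
        cells = sorted(set(idx[matched.isna().to_numpy()]))
        raise MissingDataError(
            f"reference gene {reference_gene!r} missing for cell(s) "
            f"(genotype, treatment, bio_rep): {cells}"
        )
    targets["dct"] = targets["ct"].to_numpy() - matched.to_numpy()

    cal = targets[targets["treatment"] == calibrator]
    if cal.empty:
        raise MissingDataError(f"calibrator treatment {calibrator!r} absent")
    cal_dct = cal.groupby(["genotype", "gene"])["dct"].mean()
    key = pd.MultiIndex.from_frame(targets[["genotype", "gene"]])
    cal_matched = cal_dct.reindex(key)
    if cal_matched.isna().any():
        cells = sorted(set(key[cal_matched.isna().to_numpy()]))
        raise MissingDataError(
            f"no calibrator ({calibrator!r}) dCT for (genotype, gene) cell(s): {cells}"
        )
    targets["ddct"] = targets["dct"].to_numpy() - cal_matched.to_numpy()
    targets["fold_change"] = np.exp2(-targets["ddct"])
    cols = ["genotype", "treatment", "gene", "bio_rep", "dct", "ddct", "fold_change"]
    return targets[cols].reset_index(drop=True)


def summarize_fold_changes(fold_table: pd.DataFrame) -> pd.DataFrame:
    """Geometric-mean fold change per (genotype, treatment, gene).

    The geometric mean is the natural summary on the fold-change scale (the
    arithmetic mean of ddCT back-transformed); the calibrator cell summarises
    to exactly 1.
    """
    grouped = fold_table.groupby(["genotype", "treatment", "gene"], as_index=False)
    out = grouped.agg(
        mean_ddct=("ddct", "mean"), n_reps=("fold_change", "size")
    )
    out["fold_change"] = np.exp2(-out["mean_ddct"])
    return out


@dataclass(frozen=True)
class PrimerEfficiency:
    """Standard-curve fit: CT regressed on log10 template amount."""

    slope: float
    intercept: float
    efficiency: float  # fraction: 1.0 = perfect doubling per cycle
    r_squared: float


def primer_efficiency(dilution_log10, ct) -> PrimerEfficiency:
    """Estimate amplification efficiency from a dilution series.

    ``dilution_log10`` is log10 of relative template input.  Least squares of
    CT on log10(input) gives slope m; efficiency E = 10^(-1/m) - 1, so a
    slope of -3.3219 (= -1/log10 2) corresponds to E = 1 (100%, doubling).
    """
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(ct, dtype=float)
    if x.size < 3:
        raise InputError("primer efficiency needs at least 3 dilution points")
    if np.ptp(x) == 0:
        raise InputError("all dilution points identical; cannot fit a standard curve")
    fit = stats.linregress(x, y)
    if not np.isfinite(fit.slope) or fit.slope >= 0:
        raise ComputationError(
            f"degenerate dilution series: slope {fit.slope:.4g} is not negative "
            "(CT must decrease with template input)"
        )
    eff = 10.0 ** (-1.0 / fit.slope) - 1.0
    return PrimerEfficiency(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        efficiency=float(eff),
        r_squared=float(fit.rvalue**2),
    )
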