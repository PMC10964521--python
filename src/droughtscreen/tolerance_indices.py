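"""Yield-based drought-tolerance indices and the composite STS selection score.

A multi-environment yield trial records, for every genotype, the yield under
well-watered conditions (``yp``, potential yield) and under drought stress
(``ys``).  Six classical single-trait indices summarise the contrast:

==========  =======================================  =================
index       formula                                  tolerant when
==========  =======================================  =================
TOL         Yp - Ys                                  small
MP          (Yp + Ys) / 2                            large
GMP         sqrt(Yp * Ys)                            large
HM          2 * Yp * Ys / (Yp + Ys)                  large
STI         Yp * Ys / mean(Yp)^2                     large
SSI         (1 - Ys/Yp) / SI,  SI = 1 - mean(Ys)/mean(Yp)   small
==========  =======================================  =================

The stress-tolerance score combines them with the Finlay-Wilkinson
sensitivity slope ``b`` (regression of a genotype's yields on the
environment mean yields) into a single selection criterion::

    STS = GMP + STI + HM + MP - TOL - SSI - b

Genotypes are ranked by descending STS; rank 1 is the most drought tolerant.
Ties are broken by ascending genotype identifier so the ranking is a
deterministic function of the table contents, independent of row order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ComputationError, InputError

__all__ = [
    "TrialSummary",
    "trial_summary",
    "compute_basic_indices",
    "compute_b",
    "compute_sts",
    "rank_genotypes",
    "classify_extremes",
    "score_trial",
    "BASIC_INDEX_COLUMNS",
    "STS_COMPONENTS",
]

BASIC_INDEX_COLUMNS = ("ssi", "tol", "mp", "gmp", "sti", "hm")
#: components entering STS with their sign in the sum
STS_COMPONENTS = {
    "gmp": +1.0,
    "sti": +1.0,
    "hm": +1.0,
    "mp": +1.0,
    "tol": -1.0,
    "ssi": -1.0,
    "b": -1.0,
}


@dataclass(frozen=True)
class TrialSummary:
    """Population-level summary of a two-environment trial.

    ``stress_intensity`` (SI) is ``1 - mean_ys / mean_yp``: 0 means the
    stress environment yielded as well as the control, values near 1 mean
    near-total yield loss.
    """

    mean_yp: float
    mean_ys: float

    @property
    def stress_intensity(self) -> float:
        return 1.0 - self.mean_ys / self.mean_yp


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    for col in ("genotype", "yp", "ys"):
        if col not in records.columns:
            raise InputError(f"yield table is missing required column {col!r}")
    if records["genotype"].duplicated().any():
        dupes = records.loc[records["genotype"].duplicated(), "genotype"].tolist()
        raise InputError(f"duplicate genotype id(s) in yield table: {dupes}")
    bad_yp = records.loc[~(records["yp"] > 0), "genotype"].tolist()
    if bad_yp:
        raise InputError(
            f"non-positive control yield (yp) for genotype(s) {bad_yp}; "
            "records with yp <= 0 are rejected, not dropped"
        )
    bad_ys = records.loc[records["ys"] < 0, "genotype"].tolist()
    if bad_ys:
        raise InputError(f"negative stress yield (ys) for genotype(s) {bad_ys}")
    return records


def trial_summary(records: pd.DataFrame) -> TrialSummary:
    """Population means and stress intensity over all genotypes in the trial."""
    records = _validate_records(records)
    return TrialSummary(
        mean_yp=float(records["yp"].mean()), mean_ys=float(records["ys"].mean())
    )


def compute_basic_indices(
    records: pd.DataFrame, summary: TrialSummary | None = None
) -> pd.DataFrame:
    """Compute SSI, TOL, MP, GMP, STI and HM for every genotype.

    Parameters
    ----------
    records
        Table with columns ``genotype``, ``yp``, ``ys``; one row per genotype.
    summary
        Population means used by STI and SSI.  Defaults to the means of
        ``records`` itself (the usual case: indices relative to the trial's
        own population).

    Returns the input columns plus one column per index, row order preserved.
    """
    records = _validate_records(records)
    if summary is None:
        summary = trial_summary(records)
    si = summary.stress_intensity
    if si == 0:
        raise ComputationError(
            "stress intensity SI = 1 - mean_ys/mean_yp is zero for this trial; "
            "SSI is undefined"
        )
    yp = records["yp"].to_numpy(dtype=float)
    ys = records["ys"].to_numpy(dtype=float)
    out = records[["genotype", "yp", "ys"]].copy()
    out["ssi"] = (1.0 - ys / yp) / si
    out["tol"] = yp - ys
    out["mp"] = (yp + ys) / 2.0
    out["gmp"] = np.sqrt(yp * ys)
    out["sti"] = yp * ys / summary.mean_yp**2
    out["hm"] = 2.0 * yp * ys / (yp + ys)
    return out


def compute_b(yields: pd.DataFrame) -> pd.Series:
    """Finlay-Wilkinson sensitivity slope per genotype.

    ``yields`` has a ``genotype`` column and one column per environment.
    For each genotype the least-squares slope of its yields on the
    environment mean yields is returned; with exactly two environments this
    reduces to ``(y1 - y2) / (mean1 - mean2)``.  A genotype tracking the
    environment mean one-to-one has b = 1; a flat responder has b = 0.
    """
    env_cols = [c for c in yields.columns if c != "genotype"]
    if "genotype" not in yields.columns:
        raise InputError("yield table is missing required column 'genotype'")
    if len(env_cols) < 2:
        raise InputError("compute_b needs at least two environment columns")
    y = yields[env_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise InputError("environment yields must all be finite")
    env_means = y.mean(axis=0)
    x = env_means - env_means.mean()
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ComputationError(
            "environment mean yields are all equal; the sensitivity slope b "
            "is undefined"
        )
    slopes = (y - y.mean(axis=1, keepdims=True)) @ x / sxx
    return pd.Series(slopes, index=yields["genotype"].to_numpy(), name="b")


def compute_sts(index_table: pd.DataFrame, standardize: bool = False) -> pd.DataFrame:
    """Attach the composite score STS = GMP + STI + HM + MP - TOL - SSI - b.

    The sum is taken on the raw index values.  With ``standardize=True``
    each component is z-scored across genotypes first (an optional mode;
    the raw sum is the documented default).
    """
    missing = [c for c in STS_COMPONENTS if c not in index_table.columns]
    if missing:
        raise InputError(f"index table is missing STS component column(s) {missing}")
    comp = index_table[list(STS_COMPONENTS)].astype(float)
    bad = comp.isna().any(axis=1) | ~np.isfinite(comp).all(axis=1)
    if bad.any():
        rows = index_table.loc[bad, "genotype"].tolist()
        raise InputError(f"incomplete or non-finite STS components for genotype(s) {rows}")
    if standardize:
        sd = comp.std(ddof=1)
        if (sd == 0).any():
            raise ComputationError(
                "cannot standardize: zero variance in component(s) "
                f"{sd.index[sd == 0].tolist()}"
            )
        comp = (comp - comp.mean()) / sd
    out = index_table.copy()
    out["sts"] = sum(sign * comp[name] for name, sign in STS_COMPONENTS.items())
    return out


def rank_genotypes(index_table: pd.DataFrame) -> pd.DataFrame:
    """Rank genotypes by descending STS (rank 1 = most tolerant).

    Ties are broken by ascending genotype identifier.  The genotype -> rank
    map depends only on the (genotype, sts) pairs, never on row order.
    """
    if "sts" not in index_table.columns:
        raise InputError("index table has no 'sts' column; run compute_sts first")
    out = index_table.copy()
    if len(out) == 0:
        out["rank"] = pd.Series(dtype=int)
        return out
    order = out.sort_values(
        ["sts", "genotype"], ascending=[False, True], kind="mergesort"
    ).index
    ranks = pd.Series(np.arange(1, len(out) + 1), index=order)
    out["rank"] = ranks.reindex(out.index).astype(int)
    return out


def classify_extremes(
    index_table: pd.DataFrame, k_tolerant: int = 9, k_sensitive: int = 11
) -> tuple[list, list]:
    """Top-k (tolerant) and bottom-k (sensitive) genotypes by STS rank.

    Both lists are ordered by rank: the tolerant list starts at rank 1, the
    sensitive list at rank n (the single most sensitive genotype first).
    """
    if k_tolerant < 0 or k_sensitive < 0:
        raise InputError("k_tolerant and k_sensitive must be non-negative")
    n = len(index_table)
    if k_tolerant + k_sensitive > n:
        raise InputError(
            f"k_tolerant + k_sensitive = {k_tolerant + k_sensitive} exceeds the "
            f"{n} genotypes in the table"
        )
    ranked = index_table
    if "rank" not in ranked.columns:
        ranked = rank_genotypes(ranked)
    by_rank = ranked.sort_values("rank")
    tolerant = by_rank["genotype"].head(k_tolerant).tolist()
    sensitive = by_rank["genotype"].tail(k_sensitive).tolist()[::-1]
    return tolerant, sensitive


def score_trial(records: pd.DataFrame, standardize: bool = False) -> pd.DataFrame:
    """Full scoring of a two-environment (Yp/Ys) trial.

    Convenience wrapper: basic indices, two-environment sensitivity slope,
    STS and ranks in one call.  Returns the complete index table with
    columns genotype, yp, ys, ssi, tol, mp, gmp, sti, hm, b, sts, rank.
    """
    table = compute_basic_indices(records)
    wide = records[["genotype", "yp", "ys"]]
    b = compute_b(wide)
    table["b"] = b.reindex(table["genotype"]).to_numpy()
    table = compute_sts(table, standardize=standardize)
    return rank_genotypes(table)
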