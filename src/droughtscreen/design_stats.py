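"""Two-factor completely-randomized factorial ANOVA and Duncan's range test.

The greenhouse experiments cross genotype (G) with soil-moisture stress
level (S) in a completely randomized design with r replicates per cell.
For a balanced g x s x r layout the fixed-effects decomposition is the
classical closed form

    SS_G    = s*r * sum_g (m_g.  - m)^2          df = g - 1
    SS_S    = g*r * sum_s (m_.s  - m)^2          df = s - 1
    SS_GxS  = r * sum_gs (m_gs - m_g. - m_.s + m)^2   df = (g-1)(s-1)
    SS_E    = sum (y - m_gs)^2                   df = g*s*(r-1)

with F = MS_effect / MS_error against the F distribution, plus the trial's
coefficient of variation CV% = 100 * sqrt(MSE) / grand mean.  Imbalance is
an error, not an approximation: the closed form is only valid for equal
cell sizes, and the designs served here are balanced by construction.

Duncan's multiple range test compares the (ordered) treatment means with
span-dependent least significant ranges R_p = q(alpha_p, p, df_E) *
sqrt(MSE/r), where the protection level for a span of p means is
alpha_p = 1 - (1-alpha)^(p-1) and q is the studentized-range quantile.
Means within any range whose extremes differ by less than its R_p share a
letter (the classical underlining rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, InputError

__all__ = [
    "AnovaResult",
    "anova_two_factor",
    "cv_percent",
    "DuncanGrouping",
    "duncan_groups",
    "stars",
    "format_anova",
]

ANOVA_SOURCES = ("Genotype (G)", "Stress (S)", "G x S", "Error")


@dataclass(frozen=True)
class AnovaResult:
    """ANOVA table plus the design sizes and CV% it was computed from."""

    table: pd.DataFrame  # index: ANOVA_SOURCES; columns: df, sum_sq, mean_sq, F, p
    grand_mean: float
    cv_percent: float
    n_genotypes: int
    n_stress_levels: int
    n_replicates: int

    def df_column(self) -> tuple[int, ...]:
        """Degrees of freedom in table order (G, S, GxS, Error)."""
        return tuple(int(v) for v in self.table["df"])


def anova_two_factor(
    observations: pd.DataFrame,
    value: str = "value",
    genotype: str = "genotype",
    stress: str = "stress_level",
) -> AnovaResult:
    """Balanced two-factor CRD ANOVA of one trait.

    ``observations`` is tidy: one row per experimental unit with the
    genotype, the stress level and the measured value.  Every genotype x
    stress cell must contain the same number r >= 2 of replicates.
    """
    for col in (value, genotype, stress):
        if col not in observations.columns:
            raise InputError(f"trait table is missing column {col!r}")
    y_all = observations[value].to_numpy(dtype=float)
    if not np.isfinite(y_all).all():
        raise InputError("trait values must all be finite")

    counts = observations.groupby([genotype, stress], sort=True).size()
    g_levels = observations[genotype].unique()
    s_levels = observations[stress].unique()
    g, s = len(g_levels), len(s_levels)
    if len(counts) != g * s or counts.nunique() != 1:
        raise InputError(
            "unbalanced layout: every genotype x stress cell must be present "
            f"with equal replication (cell sizes: {sorted(set(counts))})"
        )
    r = int(counts.iloc[0])
    if r < 2:
        raise InputError(
            "single-replicate design: no within-cell error term; r >= 2 required"
        )

    # sort into a g x s x r array; replicate order within a cell is irrelevant
    ordered = observations.sort_values([genotype, stress], kind="mergesort")
    y = ordered[value].to_numpy(dtype=float).reshape(g, s, r)

    m = y.mean()
    m_g = y.mean(axis=(1, 2))
    m_s = y.mean(axis=(0, 2))
    m_gs = y.mean(axis=2)

    ss_g = s * r * float(((m_g - m) ** 2).sum())
    ss_s = g * r * float(((m_s - m) ** 2).sum())
    ss_gs = r * float(
        ((m_gs - m_g[:, None] - m_s[None, :] + m) ** 2).sum()
    )
    ss_e = float(((y - m_gs[:, :, None]) ** 2).sum())

    df_ = np.array([g - 1, s - 1, (g - 1) * (s - 1), g * s * (r - 1)])
    ss = np.array([ss_g, ss_s, ss_gs, ss_e])
    ms = ss / df_
    mse = ms[3]
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = np.where(mse > 0, ms[:3] / mse, np.inf)
        f_stat = np.where((mse == 0) & (ms[:3] == 0), np.nan, f_stat)
    p = stats.f.sf(f_stat, df_[:3], df_[3])

    table = pd.DataFrame(
        {
            "df": df_,
            "sum_sq": ss,
            "mean_sq": ms,
            "F": np.append(f_stat, np.nan),
            "p": np.append(p, np.nan),
        },
        index=list(ANOVA_SOURCES),
    )
    cv = cv_percent(mse, m) if m != 0 else (0.0 if mse == 0 else np.nan)
    return AnovaResult(
        table=table,
        grand_mean=float(m),
        cv_percent=float(cv),
        n_genotypes=g,
        n_stress_levels=s,
        n_replicates=r,
    )


def cv_percent(ms_error, grand_mean) -> float:
    """Coefficient of variation of the trial: 100 * sqrt(MSE) / |grand mean|."""
    if grand_mean == 0:
        raise ComputationError("CV% is undefined for a zero grand mean")
    if ms_error < 0:
        raise InputError("error mean square cannot be negative")
    return 100.0 * float(np.sqrt(ms_error)) / abs(float(grand_mean))


@lru_cache(maxsize=4096)
def _duncan_q(alpha: float, p: int, df_error: int) -> float:
    """Studentized-range quantile at the span-p protection level.

    Cached: the quantile involves numerical integration and the same
    (alpha, p, df) triples recur across traits of one experiment.
    """
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return float(stats.studentized_range.isf(alpha_p, p, df_error))


@dataclass(frozen=True)
class DuncanGrouping:
    """Ordered means with Duncan letter labels.

    ``means`` has one row per treatment combination, sorted by descending
    mean, with a ``letters`` column; means sharing any letter are not
    significantly different at the grouping's alpha.  ``lsr`` maps each span
    p = 2..k to its least significant range R_p.
    """

    means: pd.DataFrame  # columns: label, mean, letters
    alpha: float
    lsr: dict[int, float] = field(default_factory=dict)

    def letters_for(self, label) -> str:
        row = self.means[self.means["label"] == label]
        if row.empty:
            raise KeyError(label)
        return row["letters"].iloc[0]


def duncan_groups(
    cell_means,
    ms_error: float,
    df_error: int,
    r_per_mean: int,
    alpha: float = 0.05,
) -> DuncanGrouping:
    """Duncan's multiple range test over a set of treatment means.

    Parameters
    ----------
    cell_means
        Mapping or Series of treatment-combination label -> mean.
    ms_error, df_error
        Error mean square and its degrees of freedom from the ANOVA.
    r_per_mean
        Number of observations behind each mean (r for cell means).
    alpha
        Base significance level; the span-p protection level is
        1 - (1-alpha)^(p-1).
    """
    means = pd.Series(dict(cell_means) if not isinstance(cell_means, pd.Series) else cell_means)
    if means.empty:
        raise InputError("no means to compare")
    if not np.isfinite(means.to_numpy(dtype=float)).all():
        raise InputError("treatment means must be finite")
    if ms_error <= 0:
        raise ComputationError(
            "Duncan's test needs a positive error mean square"
        )
    if df_error < 1:
        raise InputError("df_error must be at least 1")
    if r_per_mean < 1:
        raise InputError("r_per_mean must be at least 1")
    if not 0 < alpha < 1:
        raise InputError("alpha must lie in (0, 1)")

    order = means.sort_values(ascending=False, kind="mergesort")
    vals = order.to_numpy(dtype=float)
    k = len(vals)
    se = float(np.sqrt(ms_error / r_per_mean))
    lsr = {p: _duncan_q(alpha, p, df_error) * se for p in range(2, k + 1)}

    # maximal non-significant runs: extend each start as far as the whole
    # span's range stays below its R_p (containment protection is implied:
    # any sub-range of a non-significant range is covered by the same run)
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j_best = i
        for j in range(i + 1, k):
            if vals[i] - vals[j] <= lsr[j - i + 1]:
                j_best = j
        runs.append((i, j_best))
    # drop runs contained in an earlier (therefore wider-starting) run
    maximal = [
        (i, j)
        for (i, j) in runs
        if not any((a <= i and j <= b) and (a, b) != (i, j) for (a, b) in runs)
    ]
    letters = [""] * k
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter_idx, (i, j) in enumerate(sorted(maximal)):
        if letter_idx >= len(alphabet):
            raise ComputationError("more letter groups than supported (26)")
        for pos in range(i, j + 1):
            letters[pos] += alphabet[letter_idx]

    table = pd.DataFrame(
        {"label": order.index.to_list(), "mean": vals, "letters": letters}
    )
    return DuncanGrouping(means=table, alpha=alpha, lsr=lsr)


def stars(p_value: float) -> str:
    """Significance marker: '**' for p <= 0.01, '*' for p <= 0.05, else ''."""
    if not 0 <= p_value <= 1:
        raise InputError(f"p-value {p_value} outside [0, 1]")
    if p_value <= 0.01:
        return "**"
    if p_value <= 0.05:
        return "*"
    return ""


def format_anova(result: AnovaResult, trait: str = "value") -> str:
    """Plain-text ANOVA report in the journal layout (MS with stars, CV% row)."""
    lines = [
        f"Analysis of variance: {trait}",
        f"{'Source of variation':<22}{'df':>4}  {'Mean square':>14}",
    ]
    for source, row in result.table.iterrows():
        ms = f"{row['mean_sq']:.4g}"
        mark = ""
        if source != "Error" and np.isfinite(row["p"]):
            mark = stars(row["p"])
        lines.append(f"{source:<22}{int(row['df']):>4}  {ms + mark:>14}")
    lines.append(f"{'CV%':<22}{'':>4}  {result.cv_percent:>13.2f}%")
    lines.append("* and ** mark significance at the 5% and 1% levels.")
    return "\n".join(lines)
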