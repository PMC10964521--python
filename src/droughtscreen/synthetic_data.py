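"""Synthetic inputs with the study's statistical structure.

No raw measurements (field yields, CT wells, absorbances, trait values) are
published for this screening study, so every pipeline stage is exercised on
generated data that mirrors the design:

* a field trial of 114 wild barley genotypes under control and drought
  environments, with tolerant / intermediate / sensitive archetypes that
  differ in their stress yield reduction (truth labels are emitted so
  recovery tests never re-derive them from the outputs);
* a greenhouse experiment crossing the two selected genotypes (88, the
  tolerant archetype, and 72, the sensitive one) with three soil-moisture
  levels (90-95%, 50-55%, 25-30% of field capacity), three replicates for
  traits and two biological x two technical replicates for expression;
* qPCR CT tables for Dhn1/SOD/POD/CAT against a flat alpha-tubulin
  reference, shifted per treatment by the study's reported fold changes;
* absorbance panels back-computed from target pigment values by inverting
  the quantification formulas, so the pigment truth is exact.

Every generator is a pure function of its :class:`SimulationConfig`; the
mandatory seed feeds independent ``numpy`` Generator streams (one per
generator, spawned as ``default_rng([seed, stream])``), which makes reruns
byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .expression import REFERENCE_GENE, TARGET_GENES, TREATMENTS
from .pigments import absorbances_for

__all__ = [
    "SimulationConfig",
    "DEFAULT_FOLD_CHANGES",
    "gen_yield_trial",
    "gen_ct_table",
    "gen_trait_matrix",
    "gen_absorbance_panel",
]

ARCHETYPES = ("tolerant", "intermediate", "sensitive")

#: expression truth: (archetype, treatment) -> fold change vs control, per gene.
#: Stress-level values are the study's reported fold changes; the cells the
#: study does not report (mild-stress POD and SOD, the sensitive genotype's
#: CAT) are filled by the geometric midpoint between 1 and the severe value.
DEFAULT_FOLD_CHANGES: dict[str, dict[tuple[str, str], float]] = {
    "Dhn1": {
        ("tolerant", "mild_50_55FC"): 5.15,
        ("tolerant", "severe_25_30FC"): 12.51,
        ("sensitive", "mild_50_55FC"): 4.69,
        ("sensitive", "severe_25_30FC"): 2.86,
    },
    "CAT": {
        ("tolerant", "mild_50_55FC"): 3.55,
        ("tolerant", "severe_25_30FC"): 7.36,
        ("sensitive", "mild_50_55FC"): math.sqrt(2.5),
        ("sensitive", "severe_25_30FC"): 2.5,
    },
    "POD": {
        ("tolerant", "mild_50_55FC"): math.sqrt(7.07),
        ("tolerant", "severe_25_30FC"): 7.07,
        ("sensitive", "mild_50_55FC"): math.sqrt(3.89),
        ("sensitive", "severe_25_30FC"): 3.89,
    },
    "SOD": {
        ("tolerant", "mild_50_55FC"): math.sqrt(7.39),
        ("tolerant", "severe_25_30FC"): 7.39,
        ("sensitive", "mild_50_55FC"): math.sqrt(3.60),
        ("sensitive", "severe_25_30FC"): 3.60,
    },
}

_STREAM_YIELD, _STREAM_CT, _STREAM_TRAIT, _STREAM_PIGMENT = 1, 2, 3, 4


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generators, with the study design as defaults."""

    seed: int
    # --- field yield trial ---
    n_genotypes: int = 114
    frac_tolerant: float = 9 / 114
    frac_sensitive: float = 11 / 114
    mean_yp: float = 10.0  # arbitrary consistent yield units
    cv_yp: float = 0.3
    reduction_tolerant: float = 0.2
    reduction_intermediate: float = 0.45
    reduction_sensitive: float = 0.7
    ys_noise_sd: float = 0.1  # multiplicative, on ys
    # --- greenhouse design ---
    tolerant_genotype: int = 88
    sensitive_genotype: int = 72
    n_reps_trait: int = 3
    n_bio_reps: int = 2
    n_tech_reps: int = 2
    # --- trait model (additive cell means + Gaussian noise) ---
    trait_grand_mean: float = 10.0
    genotype_effect: float = 1.0  # tolerant-minus-sensitive main effect
    stress_effect: float = 2.0  # control-minus-severe main effect span
    interaction_effect: float = 1.5  # crossed G x S deflection span
    trait_noise_sd: float = 0.5
    # --- expression model ---
    ct_reference_baseline: float = 20.0
    ct_target_baselines: dict = field(
        default_factory=lambda: {"Dhn1": 24.0, "SOD": 22.0, "POD": 23.0, "CAT": 25.0}
    )
    fold_changes: dict = field(default_factory=lambda: DEFAULT_FOLD_CHANGES)
    ct_noise_sd: float = 0.15
    # --- pigment model (ug/ml of extract) ---
    pigment_base: dict = field(
        default_factory=lambda: {"chl_a": 8.0, "chl_b": 3.5, "carotenoids": 2.5}
    )
    # multiplicative retention per treatment, tolerant keeps more pigment
    pigment_retention_tolerant: tuple = (1.0, 0.88, 0.70)
    pigment_retention_sensitive: tuple = (1.0, 0.75, 0.50)
    pigment_noise_sd: float = 0.15

    def __post_init__(self):
        if self.seed is None or int(self.seed) < 0:
            raise InputError("a non-negative integer seed is mandatory")
        if self.n_genotypes < 1:
            raise InputError("n_genotypes must be positive")
        if not (0 <= self.frac_tolerant and 0 <= self.frac_sensitive):
            raise InputError("archetype fractions must be non-negative")
        if self.frac_tolerant + self.frac_sensitive > 1 + 1e-12:
            raise InputError(
                "archetype fractions exceed 1 (tolerant + sensitive must leave "
                "room for the intermediate class)"
            )
        for name in ("reduction_tolerant", "reduction_intermediate", "reduction_sensitive"):
            red = getattr(self, name)
            if not 0 <= red < 1:
                raise InputError(f"{name} must lie in [0, 1)")
        if self.mean_yp <= 0 or self.cv_yp < 0:
            raise InputError("mean_yp must be positive and cv_yp non-negative")

    @property
    def frac_intermediate(self) -> float:
        return 1.0 - self.frac_tolerant - self.frac_sensitive

    @property
    def archetype_counts(self) -> dict[str, int]:
        n_tol = round(self.frac_tolerant * self.n_genotypes)
        n_sen = round(self.frac_sensitive * self.n_genotypes)
        return {
            "tolerant": n_tol,
            "intermediate": self.n_genotypes - n_tol - n_sen,
            "sensitive": n_sen,
        }

    def reduction(self, archetype: str) -> float:
        return {
            "tolerant": self.reduction_tolerant,
            "intermediate": self.reduction_intermediate,
            "sensitive": self.reduction_sensitive,
        }[archetype]

    @property
    def greenhouse_genotypes(self) -> dict[int, str]:
        return {self.tolerant_genotype: "tolerant", self.sensitive_genotype: "sensitive"}

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise InputError(f"config file {path} is not a key: value mapping")
        data.update(overrides)
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:
            raise InputError(f"invalid config: {exc}") from exc

    def to_dict(self) -> dict:
        d = asdict(self)
        # YAML/JSON-friendly: tuple keys of the fold table -> "archetype|treatment"
        d["fold_changes"] = {
            gene: {f"{a}|{t}": v for (a, t), v in cells.items()}
            for gene, cells in self.fold_changes.items()
        }
        return d


def gen_yield_trial(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the 114-genotype field trial.

    Control yields are log-normal around ``mean_yp`` with coefficient of
    variation ``cv_yp``; stress yields apply the archetype's reduction with
    multiplicative Gaussian noise.  Returns genotype, archetype (truth
    label), yp, ys; genotype ids are 1..n with archetypes scattered at
    random over the ids.
    """
    rng = config.rng(_STREAM_YIELD)
    n = config.n_genotypes
    counts = config.archetype_counts
    labels = np.repeat(
        list(counts.keys()), list(counts.values())
    )
    labels = rng.permutation(labels)
    sigma2 = math.log1p(config.cv_yp**2)
    mu = math.log(config.mean_yp) - sigma2 / 2.0
    yp = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    reductions = np.array([config.reduction(a) for a in labels])
    noise = rng.normal(0.0, config.ys_noise_sd, size=n) if config.ys_noise_sd > 0 else np.zeros(n)
    ys = np.maximum(yp * (1.0 - reductions) * (1.0 + noise), 0.0)
    return pd.DataFrame(
        {
            "genotype": np.arange(1, n + 1),
            "archetype": labels,
            "yp": yp,
            "ys": ys,
        }
    )


def _log2_shift(config: SimulationConfig, archetype: str, treatment: str, gene: str) -> float:
    if treatment == TREATMENTS[0] or gene == REFERENCE_GENE:
        return 0.0
    fold = config.fold_changes[gene][(archetype, treatment)]
    return math.log2(fold)


def gen_ct_table(config: SimulationConfig) -> pd.DataFrame:
    """Simulate the qPCR CT table for the two selected genotypes.

    The reference gene sits at a flat baseline across treatments; each
    target gene's CT drops by log2(fold) cycles under stress, where the fold
    is the configured truth for that (archetype, treatment, gene) cell.
    Gaussian well noise is added on the CT scale.  With ``ct_noise_sd = 0``
    the expression module recovers the configured folds exactly.
    """
    rng = config.rng(_STREAM_CT)
    rows = []
    for geno, archetype in config.greenhouse_genotypes.items():
        for treatment in TREATMENTS:
            for gene in (REFERENCE_GENE, *TARGET_GENES):
                base = (
                    config.ct_reference_baseline
                    if gene == REFERENCE_GENE
                    else config.ct_target_baselines[gene]
                )
                shift = _log2_shift(config, archetype, treatment, gene)
                for bio in range(1, config.n_bio_reps + 1):
                    for tech in range(1, config.n_tech_reps + 1):
                        rows.append((geno, archetype, treatment, gene, bio, tech, base - shift))
    df = pd.DataFrame(
        rows,
        columns=["genotype", "archetype", "treatment", "gene", "bio_rep", "tech_rep", "ct"],
    )
    if config.ct_noise_sd > 0:
        df["ct"] += rng.normal(0.0, config.ct_noise_sd, size=len(df))
    return df


_STRESS_SIGN = {TREATMENTS[0]: -1.0, TREATMENTS[1]: 0.0, TREATMENTS[2]: 1.0}


def gen_trait_matrix(config: SimulationConfig, trait: str = "trait") -> pd.DataFrame:
    """Simulate one trait under the 2 x 3 x r greenhouse design.

    Cell mean = grand mean + genotype effect + stress effect + interaction;
    observations add Gaussian noise.  The genotype main effect favours the
    tolerant genotype, the stress effect declines from control to severe,
    and the interaction is the classical crossed pattern (the sensitive
    genotype loses disproportionately under severe stress).
    """
    rng = config.rng(_STREAM_TRAIT)
    rows = []
    for geno, archetype in config.greenhouse_genotypes.items():
        gsign = 1.0 if archetype == "tolerant" else -1.0
        for treatment in TREATMENTS:
            ssev = _STRESS_SIGN[treatment]
            cell_mean = (
                config.trait_grand_mean
                + gsign * config.genotype_effect / 2.0
                - ssev * config.stress_effect / 2.0
                + gsign * (-ssev) * config.interaction_effect / 2.0
            )
            for rep in range(1, config.n_reps_trait + 1):
                rows.append((geno, archetype, treatment, rep, trait, cell_mean))
    df = pd.DataFrame(
        rows,
        columns=["genotype", "archetype", "stress_level", "replicate", "trait", "value"],
    )
    if config.trait_noise_sd > 0:
        df["value"] += rng.normal(0.0, config.trait_noise_sd, size=len(df))
    return df


_RETENTION_INDEX = {t: i for i, t in enumerate(TREATMENTS)}


def gen_absorbance_panel(config: SimulationConfig) -> pd.DataFrame:
    """Simulate absorbance readings with exactly known pigment truth.

    Target pigment concentrations (ug/ml) start from healthy-leaf baselines
    and retain a treatment- and archetype-dependent fraction under stress,
    plus Gaussian noise; the absorbances are then obtained by inverting the
    quantification formulas, so running the pigment module on the returned
    a663/a646/a470 columns reproduces the *_true columns exactly.
    """
    rng = config.rng(_STREAM_PIGMENT)
    rows = []
    for geno, archetype in config.greenhouse_genotypes.items():
        retention = (
            config.pigment_retention_tolerant
            if archetype == "tolerant"
            else config.pigment_retention_sensitive
        )
        for treatment in TREATMENTS:
            keep = retention[_RETENTION_INDEX[treatment]]
            for rep in range(1, config.n_reps_trait + 1):
                chl_a = config.pigment_base["chl_a"] * keep
                chl_b = config.pigment_base["chl_b"] * keep
                car = config.pigment_base["carotenoids"] * keep
                if config.pigment_noise_sd > 0:
                    chl_a, chl_b, car = np.maximum(
                        np.array([chl_a, chl_b, car])
                        + rng.normal(0.0, config.pigment_noise_sd, size=3),
                        1e-6,
                    )
                rows.append((geno, archetype, treatment, rep, chl_a, chl_b, car))
    df = pd.DataFrame(
        rows,
        columns=[
            "genotype", "archetype", "stress_level", "replicate",
            "chl_a_true", "chl_b_true", "carotenoids_true",
        ],
    )
    a663, a646, a470 = absorbances_for(
        df["chl_a_true"].to_numpy(),
        df["chl_b_true"].to_numpy(),
        df["carotenoids_true"].to_numpy(),
    )
    df.insert(4, "a663", a663)
    df.insert(5, "a646", a646)
    df.insert(6, "a470", a470)
    df.insert(
        0,
        "sample_id",
        [f"G{g}_{t}_r{r}" for g, t, r in zip(df["genotype"], df["stress_level"], df["replicate"])],
    )
    return df
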