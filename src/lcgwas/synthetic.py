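"""Synthetic case-control cohorts with latent co-morbidity structure.

Because individual-level psychiatric genotype data are access-controlled,
every downstream stage of this package is exercised on simulated cohorts
that emulate the design of a bipolar-disorder GWAS sample: roughly 1000
cases and 1034 controls, binary lifetime co-morbidity indicators observed
for cases only, latent classes generating the indicator profiles, genotypes
in Hardy-Weinberg proportions (optionally with Balding-Nichols two-population
structure), planted class-specific rare recessive effects, and auxiliary
age/sex covariates with realistic missingness.

The generator is truth-auditable: the drawn class labels, the planted SNP
effects and any subpopulation assignment are returned alongside the data so
recovery can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import GenotypeMatrix
from .lca import IndicatorMatrix

__all__ = [
    "SNPSpec",
    "CohortSpec",
    "TruthRecord",
    "Cohort",
    "simulate_cohort",
    "simulate_genotypes",
    "simulate_auxiliary",
]

_RISK_GENOTYPE = {"recessive": 2.0, "dominant": 1.0, "additive": 2.0}


@dataclass(frozen=True)
class SNPSpec:
    """One SNP to simulate, optionally carrying a planted class-specific effect.

    ``n_forced_carriers`` individuals of ``effect_class`` are overwritten with
    the risk genotype (homozygous minor for a recessive effect) after a null
    Hardy-Weinberg draw, reproducing the observed pattern of minor-allele
    homozygotes confined to a single latent class.
    """

    snp_id: str
    chromosome: str
    position: int
    maf: float
    effect_class: int | None = None
    effect_model: str | None = None
    n_forced_carriers: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.maf <= 0.5:
            raise ValueError(f"{self.snp_id}: maf must lie in (0, 0.5]")
        if self.position < 1:
            raise ValueError(f"{self.snp_id}: positions are 1-based")
        if (self.effect_class is None) != (self.effect_model is None):
            raise ValueError(
                f"{self.snp_id}: effect_class and effect_model must be set together"
            )
        if self.effect_model is not None and self.effect_model not in _RISK_GENOTYPE:
            raise ValueError(f"{self.snp_id}: unknown effect model '{self.effect_model}'")
        if self.n_forced_carriers < 0:
            raise ValueError(f"{self.snp_id}: n_forced_carriers must be >= 0")
        if self.n_forced_carriers > 0 and self.effect_class is None:
            raise ValueError(f"{self.snp_id}: forced carriers need an effect class")


@dataclass
class CohortSpec:
    """Full generative description of a synthetic case-control cohort."""

    n_cases: int
    n_controls: int
    class_proportions: tuple[float, ...]
    endorsement_probs: np.ndarray  # K x J
    item_names: list[str]
    aux_age_means: tuple[float, ...] = ()
    aux_age_sds: tuple[float, ...] = ()
    aux_female_probs: tuple[float, ...] = ()
    control_age_mean: float = 52.5
    control_age_sd: float = 17.6
    control_female_prob: float = 0.4855
    age_missing_rate: float = 0.0
    snp_specs: list[SNPSpec] = field(default_factory=list)
    n_null_snps: int = 0
    null_maf_range: tuple[float, float] = (0.01, 0.5)
    fst: float = 0.0
    genotype_missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ValueError("cohort sizes must be non-negative")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.ndim != 1 or props.size < 1:
            raise ValueError("need at least one latent class")
        if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("class proportions must be non-negative and sum to 1")
        rho = np.atleast_2d(np.asarray(self.endorsement_probs, dtype=float))
        if rho.shape[0] != props.size:
            raise ValueError("endorsement matrix must have one row per class")
        if rho.shape[1] != len(self.item_names) or rho.shape[1] < 1:
            raise ValueError("endorsement matrix width must match item_names")
        if np.any((rho < 0) | (rho > 1)):
            raise ValueError("endorsement probabilities must lie in [0, 1]")
        for name, rate in (
            ("age_missing_rate", self.age_missing_rate),
            ("genotype_missing_rate", self.genotype_missing_rate),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.null_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("null_maf_range must be an interval within (0, 0.5]")
        if self.aux_age_means and len(self.aux_age_means) != props.size:
            raise ValueError("aux_age_means must have one entry per class")
        if self.aux_age_sds and len(self.aux_age_sds) != props.size:
            raise ValueError("aux_age_sds must have one entry per class")
        if self.aux_female_probs and len(self.aux_female_probs) != props.size:
            raise ValueError("aux_female_probs must have one entry per class")
        self.class_proportions = tuple(float(p) for p in props)
        self.endorsement_probs = rho
        self.item_names = list(self.item_names)

    @property
    def K(self) -> int:
        return len(self.class_proportions)

    @property
    def n_items(self) -> int:
        return len(self.item_names)


@dataclass
class TruthRecord:
    true_class: np.ndarray  # class index per case
    planted_snps: list[tuple[str, int, str]]  # (snp_id, effect_class, effect_model)
    subpopulation: np.ndarray | None = None  # per individual, when fst > 0


@dataclass
class Cohort:
    indicators: IndicatorMatrix
    genotypes: GenotypeMatrix
    case_flags: np.ndarray
    aux: pd.DataFrame
    truth: TruthRecord

    @property
    def n_cases(self) -> int:
        return self.indicators.n_cases

    @property
    def n_controls(self) -> int:
        return int((~self.case_flags.astype(bool)).sum())


# ---------------------------------------------------------------------------
# seeding: each stage gets an independent child stream of the spec seed so a
# stage re-run standalone reproduces its slice of simulate_cohort exactly.

_STAGES = {"classes": 0, "indicators": 1, "genotypes": 2, "auxiliary": 3}


def _stage_rng(spec: CohortSpec, stage: str) -> np.random.Generator:
    children = np.random.SeedSequence(spec.seed).spawn(len(_STAGES))
    return np.random.default_rng(children[_STAGES[stage]])


def _draw_classes(spec: CohortSpec) -> np.ndarray:
    rng = _stage_rng(spec, "classes")
    return rng.choice(spec.K, size=spec.n_cases, p=np.asarray(spec.class_proportions))


def simulate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a complete cohort: classes, indicators, genotypes and covariates.

    Case class labels follow ``class_proportions``; indicator ``j`` for a case
    of class ``k`` is Bernoulli(``endorsement_probs[k, j]``), independent
    across items given the class.  Controls carry no indicator rows.  The
    result is deterministic for a fixed ``spec.seed``.
    """
    true_class = _draw_classes(spec)

    rng = _stage_rng(spec, "indicators")
    probs = spec.endorsement_probs[true_class]
    values = (rng.random((spec.n_cases, spec.n_items)) < probs).astype(float)
    case_ids = [f"case{i:05d}" for i in range(spec.n_cases)]
    indicators = IndicatorMatrix(values, list(spec.item_names), case_ids=case_ids)

    genotypes, subpop = _simulate_genotypes_impl(spec, true_class)
    aux = simulate_auxiliary(spec, true_class)

    case_flags = np.zeros(spec.n_cases + spec.n_controls, dtype=int)
    case_flags[: spec.n_cases] = 1
    planted = [
        (s.snp_id, int(s.effect_class), str(s.effect_model))
        for s in spec.snp_specs
        if s.effect_class is not None
    ]
    truth = TruthRecord(true_class=true_class, planted_snps=planted, subpopulation=subpop)
    return Cohort(
        indicators=indicators,
        genotypes=genotypes,
        case_flags=case_flags,
        aux=aux,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# genotypes


def _balding_nichols_freqs(rng, ancestral: np.ndarray, fst: float) -> np.ndarray:
    """Per-subpopulation allele frequencies under the Balding-Nichols model."""
    a = ancestral * (1.0 - fst) / fst
    b = (1.0 - ancestral) * (1.0 - fst) / fst
    return np.column_stack([rng.beta(a, b), rng.beta(a, b)])


def simulate_genotypes(spec: CohortSpec, true_class: np.ndarray) -> GenotypeMatrix:
    """Genotypes for cases (first) and controls under the spec's SNP panel."""
    return _simulate_genotypes_impl(spec, true_class)[0]


def _simulate_genotypes_impl(spec: CohortSpec, true_class: np.ndarray):
    true_class = np.asarray(true_class)
    if true_class.shape[0] != spec.n_cases:
        raise ValueError("true_class must have one entry per case")
    rng = _stage_rng(spec, "genotypes")
    n = spec.n_cases + spec.n_controls

    # optional two-population structure, independent of case status
    subpop = None
    if spec.fst > 0.0:
        subpop = rng.integers(0, 2, size=n)

    planted = list(spec.snp_specs)
    for s in planted:
        if s.effect_class is not None and not np.any(true_class == s.effect_class):
            raise ValueError(
                f"{s.snp_id}: effect class {s.effect_class} absent from the cohort"
            )

    lo, hi = spec.null_maf_range
    null_mafs = rng.uniform(lo, hi, size=spec.n_null_snps)
    mafs = np.concatenate([[s.maf for s in planted], null_mafs])
    m = mafs.size

    if spec.fst > 0.0:
        pop_freqs = _balding_nichols_freqs(rng, mafs, spec.fst)  # m x 2
        per_ind = pop_freqs[:, subpop].T  # n x m
        counts = rng.binomial(2, per_ind).astype(float)
    else:
        counts = rng.binomial(2, mafs, size=(n, m)).astype(float)

    protected = np.zeros((n, m), dtype=bool)
    for j, s in enumerate(planted):
        if s.effect_class is None or s.n_forced_carriers == 0:
            continue
        members = np.flatnonzero(true_class == s.effect_class)  # cases only
        if s.n_forced_carriers > members.size:
            raise ValueError(
                f"{s.snp_id}: {s.n_forced_carriers} forced carriers exceed the "
                f"{members.size} members of class {s.effect_class}"
            )
        risk = _RISK_GENOTYPE[s.effect_model]
        if s.effect_model == "recessive":
            # demote chance homozygotes so the forced count is exact and confined
            stray = counts[:, j] == 2.0
            counts[stray, j] = 1.0
        chosen = rng.choice(members, size=s.n_forced_carriers, replace=False)
        counts[chosen, j] = risk
        protected[chosen, j] = True

    if spec.genotype_missing_rate > 0.0:
        miss = rng.random((n, m)) < spec.genotype_missing_rate
        miss &= ~protected  # forced genotypes are never masked
        counts[miss] = np.nan

    snp_info = _panel_info(planted, spec.n_null_snps)
    sample_ids = [f"case{i:05d}" for i in range(spec.n_cases)] + [
        f"ctrl{i:05d}" for i in range(spec.n_controls)
    ]
    gm = GenotypeMatrix(counts=counts, snp_info=snp_info, sample_ids=sample_ids)
    return gm, subpop


def _panel_info(planted: list[SNPSpec], n_null: int) -> pd.DataFrame:
    rows = [
        {"snp_id": s.snp_id, "chrom": str(s.chromosome), "pos": int(s.position)}
        for s in planted
    ]
    for i in range(n_null):
        rows.append(
            {
                "snp_id": f"null{i:06d}",
                "chrom": str(i % 22 + 1),
                "pos": 10_000 + 1_000 * (i // 22),
            }
        )
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


# ---------------------------------------------------------------------------
# auxiliary covariates


def _truncated_normal(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    dist = stats.truncnorm(a, np.inf, loc=mean, scale=sd)
    return dist.ppf(rng.random(size))


def simulate_auxiliary(spec: CohortSpec, true_class: np.ndarray) -> pd.DataFrame:
    """Age and sex per individual (cases first, then controls).

    Case ages are normal with class-specific mean/SD truncated at 17 years;
    sex is Bernoulli with a class-specific female probability.  Controls form
    a single stratum.  Ages of cases are set missing at ``age_missing_rate``.
    """
    true_class = np.asarray(true_class)
    if true_class.shape[0] != spec.n_cases:
        raise ValueError("true_class must have one entry per case")
    rng = _stage_rng(spec, "auxiliary")

    if spec.aux_age_means:
        means = np.asarray(spec.aux_age_means)[true_class]
        sds = np.asarray(spec.aux_age_sds)[true_class]
    else:
        means = np.full(spec.n_cases, 42.0)
        sds = np.full(spec.n_cases, 12.6)
    case_age = _truncated_normal(rng, means, sds, 17.0, spec.n_cases)
    if spec.aux_female_probs:
        female_p = np.asarray(spec.aux_female_probs)[true_class]
    else:
        female_p = np.full(spec.n_cases, 0.5)
    case_female = (rng.random(spec.n_cases) < female_p).astype(float)

    ctrl_age = _truncated_normal(
        rng, spec.control_age_mean, spec.control_age_sd, 18.0, spec.n_controls
    )
    ctrl_female = (rng.random(spec.n_controls) < spec.control_female_prob).astype(float)

    age = np.concatenate([case_age, ctrl_age])
    if spec.age_missing_rate > 0.0:
        miss = rng.random(spec.n_cases) < spec.age_missing_rate
        age[: spec.n_cases][miss] = np.nan

    sample_ids = [f"case{i:05d}" for i in range(spec.n_cases)] + [
        f"ctrl{i:05d}" for i in range(spec.n_controls)
    ]
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "is_case": [1] * spec.n_cases + [0] * spec.n_controls,
            "age": age,
            "female": np.concatenate([case_female, ctrl_female]).astype(int),
        }
    )
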