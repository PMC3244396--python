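"""Genotype-phenotype association with class-membership phenotypes.

Each SNP is tested for association with a quantitative phenotype (here: the
latent-class membership probability, zero for controls) under three genetic
models — dominant, additive and recessive encodings of the minor-allele
dosage — using a correlation trend test: the Pearson correlation ``r``
between encoded genotype and phenotype over complete pairs is referred to a
1-df chi-square via ``T = n * r^2``.

Population stratification is corrected EIGENSTRAT-style: genotypes are
standardised per SNP, leading principal components of the sample covariance
are extracted, and both genotype and phenotype are residualised on the
component scores before the trend statistic is formed.

Multiplicity is controlled per genetic model with Bonferroni over the
testable SNPs, and genome-wide significant hits are retested by phenotype
permutation.  Helper statistics cover minor-allele frequencies, per-genotype
phenotype summaries, carrier odds ratios, an exact Hardy-Weinberg test, and
Q-Q / genomic-inflation diagnostics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeMatrix",
    "PhenotypeVector",
    "TrendResult",
    "GenotypeSummary",
    "AssociationRun",
    "QQData",
    "GENETIC_MODELS",
    "compute_maf",
    "maf_from_genotype_counts",
    "maf_filter",
    "encode_model",
    "trend_test",
    "pca_components",
    "stratification_adjust",
    "permutation_p",
    "bonferroni_adjust",
    "genotype_summary",
    "carrier_odds_ratio",
    "hwe_exact_test",
    "hwe_exact_from_counts",
    "qq_lambda",
    "run_association",
    "class_membership_phenotype",
]

GENETIC_MODELS = ("dominant", "additive", "recessive")

_AUTOSOMES = {str(i) for i in range(1, 23)}


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs minor-allele dosages in {0, 1, 2}; NaN = missing.

    ``snp_info`` carries one row per SNP with columns ``snp_id``, ``chrom``
    (autosome label "1".."22") and ``pos`` (1-based base pairs).
    """

    counts: np.ndarray
    snp_info: pd.DataFrame
    sample_ids: list[str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.ndim != 2:
            raise ValueError("genotype matrix must be 2-dimensional")
        vals = c[~np.isnan(c)]
        if vals.size and not np.all(np.isin(vals, (0.0, 1.0, 2.0))):
            raise ValueError("genotype dosages must be 0, 1, 2 or missing")
        if len(self.snp_info) != c.shape[1]:
            raise ValueError("snp_info rows must match the number of SNPs")
        for col in ("snp_id", "chrom", "pos"):
            if col not in self.snp_info.columns:
                raise ValueError(f"snp_info is missing column '{col}'")
        if len(self.sample_ids) != c.shape[0]:
            raise ValueError("sample_ids length must match the number of rows")
        self.counts = c
        self.snp_info = self.snp_info.reset_index(drop=True)
        self.sample_ids = [str(s) for s in self.sample_ids]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def allele_freqs(self) -> np.ndarray:
        """Frequency of the counted allele per SNP (missing excluded)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.counts, axis=0) / 2.0

    def oriented(self) -> tuple["GenotypeMatrix", list[str]]:
        """Re-orient so the counted allele is the minor one (freq <= 0.5).

        Returns the oriented matrix and the ids of flipped SNPs.
        """
        freqs = self.allele_freqs()
        flip = freqs > 0.5
        counts = self.counts.copy()
        counts[:, flip] = 2.0 - counts[:, flip]
        flipped = [str(s) for s in self.snp_info.loc[flip, "snp_id"]]
        return (
            GenotypeMatrix(counts, self.snp_info.copy(), list(self.sample_ids)),
            flipped,
        )

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.counts[:, keep],
            self.snp_info.loc[np.asarray(keep)].reset_index(drop=True),
            list(self.sample_ids),
        )


@dataclass
class PhenotypeVector:
    """Per-individual quantitative phenotype in [0, 1]; controls are 0."""

    values: np.ndarray
    definition: str = "posterior_probability"
    target_class: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("phenotype must be a vector")
        if np.any((v < 0) | (v > 1)):
            raise ValueError("phenotype values must lie in [0, 1]")
        if self.definition not in ("posterior_probability", "modal_indicator"):
            raise ValueError(f"unknown phenotype definition '{self.definition}'")
        self.values = v


def class_membership_phenotype(
    posteriors,
    case_flags: np.ndarray,
    target_class: int,
    definition: str = "posterior_probability",
) -> PhenotypeVector:
    """Build the association phenotype for one latent class.

    Cases contribute their posterior membership probability for the target
    class (or a 0/1 modal-class indicator); controls are fixed at zero under
    either definition.
    """
    case_flags = np.asarray(case_flags).astype(bool)
    P = posteriors.values if hasattr(posteriors, "values") else np.asarray(posteriors)
    if P.shape[0] != int(case_flags.sum()):
        raise ValueError("posterior rows must equal the number of cases")
    vals = np.zeros(case_flags.shape[0], dtype=float)
    if definition == "posterior_probability":
        vals[case_flags] = P[:, target_class]
    elif definition == "modal_indicator":
        vals[case_flags] = (np.argmax(P, axis=1) == target_class).astype(float)
    else:
        raise ValueError(f"unknown phenotype definition '{definition}'")
    return PhenotypeVector(vals, definition=definition, target_class=target_class)


@dataclass
class TrendResult:
    statistic: float
    p: float
    n_used: int
    testable: bool


@dataclass
class GenotypeSummary:
    snp_id: str
    maf: float
    counts: tuple[int, int, int]  # (DD, Dd, dd) = (hom minor, het, hom major)
    mean_phenotype: tuple[float, float, float]
    n_used: int


@dataclass
class QQData:
    expected: np.ndarray  # -log10 expected uniform quantiles
    observed: np.ndarray  # -log10 sorted observed p-values
    lam: float


@dataclass
class AssociationRun:
    """Results table plus the bookkeeping needed for multiplicity control."""

    results: pd.DataFrame
    removal_log: dict
    untestable: dict
    n_tests: dict
    scores: np.ndarray | None = None
    flipped_snps: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-SNP statistics


def compute_maf(genotypes: np.ndarray) -> float:
    """Minor-allele frequency of the counted allele from a dosage vector.

    Equivalent to (2*n_DD + n_Dd) / (2 * n_nonmissing); NaN when every call
    is missing.
    """
    g = np.asarray(genotypes, dtype=float)
    obs = ~np.isnan(g)
    if not obs.any():
        return float("nan")
    return float(g[obs].sum() / (2.0 * obs.sum()))


def maf_from_genotype_counts(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """MAF from the genotype count triple (DD, Dd, dd)."""
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        return float("nan")
    return (2.0 * n_hom_minor + n_het) / (2.0 * n)


def maf_filter(
    genotypes: GenotypeMatrix, threshold: float
) -> tuple[GenotypeMatrix, dict]:
    """Drop SNPs with MAF strictly below ``threshold`` (boundary kept)."""
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freqs = np.nanmean(genotypes.counts, axis=0) / 2.0
    maf = np.minimum(freqs, 1.0 - freqs)
    keep = ~(maf < threshold)  # strict <, so the boundary MAF survives
    if threshold > 0:
        keep &= ~np.isnan(maf)  # all-missing SNPs cannot clear a positive bar
    removed_ids = [str(s) for s in genotypes.snp_info.loc[~keep, "snp_id"]]
    log = {
        "threshold": threshold,
        "n_input": genotypes.n_snps,
        "n_kept": int(keep.sum()),
        "n_removed": int((~keep).sum()),
        "removed_snps": removed_ids,
    }
    return genotypes.subset_snps(keep), log


def encode_model(genotypes: np.ndarray, model: str) -> np.ndarray:
    """Encode minor-allele dosages under a genetic model; missing propagates."""
    g = np.asarray(genotypes, dtype=float)
    if model == "additive":
        return g.copy()
    if model == "dominant":
        return np.where(np.isnan(g), np.nan, (g >= 1).astype(float))
    if model == "recessive":
        return np.where(np.isnan(g), np.nan, (g == 2).astype(float))
    raise ValueError(f"unknown genetic model '{model}'")


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return float("nan")
    return float(xc @ yc) / denom


def trend_test(encoded: np.ndarray, phenotype) -> TrendResult:
    """Correlation trend test: T = n * r^2 against chi-square with 1 df.

    Not testable (statistic/p reported NaN) when fewer than two distinct
    encoded genotype values or phenotype values remain among complete pairs —
    e.g. zero minor-allele homozygotes under the recessive model.
    """
    y = phenotype.values if isinstance(phenotype, PhenotypeVector) else np.asarray(phenotype, float)
    x = np.asarray(encoded, dtype=float)
    mask = ~np.isnan(x) & ~np.isnan(y)
    n = int(mask.sum())
    xs, ys = x[mask], y[mask]
    if n < 2 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return TrendResult(float("nan"), float("nan"), n, False)
    r = _pearson_r(xs, ys)
    statistic = n * r * r
    p = float(stats.chi2.sf(statistic, 1))
    return TrendResult(float(statistic), p, n, True)


def bonferroni_adjust(p: float, n_tests: int) -> float:
    """Bonferroni-corrected p-value, capped at 1."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return min(1.0, p * n_tests)


def permutation_p(
    encoded: np.ndarray,
    phenotype,
    B: int = 1000,
    seed: int | None = None,
    scores: np.ndarray | None = None,
) -> float:
    """Empirical p by permuting the phenotype: (1 + #{T_perm >= T_obs}) / (B + 1).

    A constant phenotype yields p = 1 (every permutation ties the observed
    statistic); a degenerate encoded genotype is not testable and yields NaN.
    When principal-component ``scores`` are given, both variables are
    residualised on them first and the residual phenotype is permuted.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    y = phenotype.values if isinstance(phenotype, PhenotypeVector) else np.asarray(phenotype, float)
    x = np.asarray(encoded, dtype=float)
    mask = ~np.isnan(x) & ~np.isnan(y)
    xs, ys = x[mask], y[mask]
    if xs.size < 2 or np.ptp(xs) == 0:
        return float("nan")
    if np.ptp(ys) == 0:
        return 1.0
    if scores is not None and scores.shape[1] > 0:
        design = np.column_stack([np.ones(mask.sum()), scores[mask]])
        q, _ = np.linalg.qr(design)
        xs = xs - q @ (q.T @ xs)
        ys = ys - q @ (q.T @ ys)
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    ss_x = float(xc @ xc)
    ss_y = float(yc @ yc)
    if ss_x == 0.0 or ss_y == 0.0:
        return float("nan")
    r2_obs = (float(xc @ yc) ** 2) / (ss_x * ss_y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(B):
        yp = rng.permutation(yc)
        r2 = (float(xc @ yp) ** 2) / (ss_x * ss_y)
        if r2 >= r2_obs - 1e-15:
            hits += 1
    return (1.0 + hits) / (B + 1.0)


def genotype_summary(genotypes: np.ndarray, phenotype, snp_id: str = "") -> GenotypeSummary:
    """Genotype group sizes, MAF and per-genotype mean phenotype.

    The per-genotype phenotype averages follow the convention of the class
    membership phenotype: the major-allele homozygote mean sits near
    (cases / total) x mean class probability because controls contribute 0.
    """
    y = phenotype.values if isinstance(phenotype, PhenotypeVector) else np.asarray(phenotype, float)
    g = np.asarray(genotypes, dtype=float)
    mask = ~np.isnan(g) & ~np.isnan(y)
    gs, ys = g[mask], y[mask]
    counts = []
    means = []
    for dosage in (2.0, 1.0, 0.0):  # DD, Dd, dd
        sel = gs == dosage
        counts.append(int(sel.sum()))
        means.append(float(ys[sel].mean()) if sel.any() else float("nan"))
    return GenotypeSummary(
        snp_id=snp_id,
        maf=compute_maf(gs),
        counts=tuple(counts),
        mean_phenotype=tuple(means),
        n_used=int(mask.sum()),
    )


def carrier_odds_ratio(carrier: np.ndarray, outcome: np.ndarray) -> float:
    """Cross-product odds ratio of a 2x2 carrier-by-outcome table.

    Applies the Haldane-Anscombe 0.5 continuity correction to every cell when
    any cell is zero.
    """
    carrier = np.asarray(carrier).astype(bool)
    outcome = np.asarray(outcome).astype(bool)
    if carrier.shape != outcome.shape:
        raise ValueError("carrier and outcome vectors must have equal length")
    a = float(np.sum(carrier & outcome))
    b = float(np.sum(carrier & ~outcome))
    c = float(np.sum(~carrier & outcome))
    d = float(np.sum(~carrier & ~outcome))
    if min(a, b, c, d) == 0.0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_from_counts(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg p-value by full enumeration over heterozygote counts.

    Sums the conditional probabilities (given allele counts) of every
    genotype configuration no more probable than the observed one.
    """
    n = n_hom_minor + n_het + n_hom_major
    if n == 0:
        return 1.0
    rare = 2 * n_hom_minor + n_het
    common = 2 * n - rare
    if rare > common:
        rare, common = common, rare
    if rare == 0:
        return 1.0  # monomorphic

    hets = np.arange(rare % 2, rare + 1, 2)
    hom_r = (rare - hets) // 2
    hom_c = n - hets - hom_r
    # log P(het = h | n, rare) up to a constant shared across configurations
    logp = (
        hets * math.log(2.0)
        - _lgamma_arr(hom_r + 1)
        - _lgamma_arr(hets + 1)
        - _lgamma_arr(hom_c + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def _lgamma_arr(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float))


def hwe_exact_test(genotypes: np.ndarray) -> float:
    """Exact Hardy-Weinberg p-value for a dosage vector (missing excluded)."""
    g = np.asarray(genotypes, dtype=float)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise ValueError("no non-missing genotypes")
    return hwe_exact_from_counts(
        int((g == 2).sum()), int((g == 1).sum()), int((g == 0).sum())
    )


# ---------------------------------------------------------------------------
# stratification correction


def pca_components(
    genotypes: GenotypeMatrix, n_components: int, seed: int = 0
) -> tuple[np.ndarray, list[str]]:
    """Leading principal-component scores of the standardised genotype matrix.

    Per-SNP standardisation: centre by twice the allele frequency, scale by
    the binomial standard deviation sqrt(2 p (1 - p)); missing entries are set
    to zero after centring (the mean).  Monomorphic SNPs carry no information
    and are skipped; their ids are returned as the second element.  Scores are
    the leading left singular vectors of the standardised matrix, i.e. the
    eigenvectors of the individual-by-individual sample covariance.
    """
    if n_components >= genotypes.n_samples:
        raise ValueError("n_components must be smaller than the number of samples")
    if n_components < 1:
        raise ValueError("n_components must be at least 1")
    G = genotypes.counts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_hat = np.nanmean(G, axis=0) / 2.0
    keep = (p_hat > 0) & (p_hat < 1)
    skipped = [str(s) for s in genotypes.snp_info.loc[~keep, "snp_id"]]
    if not keep.any():
        raise ValueError("every SNP is monomorphic; no components available")
    sub = G[:, keep]
    p = p_hat[keep]
    X = (sub - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    X = np.nan_to_num(X, nan=0.0)

    n, m = X.shape
    if min(n, m) <= 1000:
        u, s, _ = np.linalg.svd(X, full_matrices=False)
        scores = u[:, :n_components]
    else:
        from sklearn.utils.extmath import randomized_svd

        u, s, _ = randomized_svd(X, n_components=n_components, random_state=seed)
        scores = u
    return scores, skipped


def stratification_adjust(
    encoded: np.ndarray, phenotype, scores: np.ndarray
) -> TrendResult:
    """Trend test after residualising genotype and phenotype on PC scores.

    Both variables are regressed (least squares with intercept) on the
    ``K_pc`` component scores; the statistic is ``T = (n - K_pc - 1) * r^2``
    on the residual correlation.  With zero components this reduces to the
    plain trend test up to the ``n`` vs ``n - 1`` degrees-of-freedom factor.
    """
    y = phenotype.values if isinstance(phenotype, PhenotypeVector) else np.asarray(phenotype, float)
    x = np.asarray(encoded, dtype=float)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] != x.shape[0] and scores.shape[1] == x.shape[0]:
        scores = scores.T
    if scores.size == 0:
        scores = np.empty((x.shape[0], 0))
    k_pc = scores.shape[1]
    mask = ~np.isnan(x) & ~np.isnan(y)
    n = int(mask.sum())
    xs, ys = x[mask], y[mask]
    if n < k_pc + 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return TrendResult(float("nan"), float("nan"), n, False)
    design = np.column_stack([np.ones(n), scores[mask]])
    q, _ = np.linalg.qr(design)
    x_res = xs - q @ (q.T @ xs)
    y_res = ys - q @ (q.T @ ys)
    ss_x = float(x_res @ x_res)
    ss_y = float(y_res @ y_res)
    if ss_x <= 1e-300 or ss_y <= 1e-300:
        return TrendResult(float("nan"), float("nan"), n, False)
    r = float(x_res @ y_res) / math.sqrt(ss_x * ss_y)
    statistic = (n - k_pc - 1) * r * r
    p = float(stats.chi2.sf(statistic, 1))
    return TrendResult(float(statistic), p, n, True)


# ---------------------------------------------------------------------------
# diagnostics


def qq_lambda(p_values: np.ndarray) -> QQData:
    """Q-Q data (-log10 scale) and the genomic inflation factor lambda.

    Lambda is the median observed 1-df chi-square statistic divided by the
    null median (~0.4549); 1 indicates calibration, > 1 systematic inflation.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no testable p-values")
    m = p.size
    order = np.sort(p)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    with np.errstate(divide="ignore"):
        observed = -np.log10(order)
    chisq = stats.chi2.isf(np.clip(order, 1e-300, 1.0), 1)
    lam = float(np.median(chisq) / stats.chi2.ppf(0.5, 1))
    return QQData(expected=expected, observed=observed, lam=lam)


# ---------------------------------------------------------------------------
# vectorised engine + driver


def _column_trend_stats(X: np.ndarray, y: np.ndarray, chunk: int = 2048):
    """Nan-aware per-column correlation of X's columns with y.

    Returns (r, n_used, testable) arrays.  Used for the unadjusted test.
    """
    n_rows, m = X.shape
    r = np.full(m, np.nan)
    n_used = np.zeros(m, dtype=int)
    testable = np.zeros(m, dtype=bool)
    y_nan = np.isnan(y)
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        Xc = X[:, lo:hi]
        mask = ~np.isnan(Xc) & ~y_nan[:, None]
        Xz = np.where(mask, Xc, 0.0)
        Yz = np.where(mask, y[:, None], 0.0)
        n = mask.sum(axis=0).astype(float)
        sx = Xz.sum(axis=0)
        sy = Yz.sum(axis=0)
        sxx = np.einsum("ij,ij->j", Xz, Xz)
        syy = np.einsum("ij,ij->j", Yz, Yz)
        sxy = np.einsum("ij,ij->j", Xz, Yz)
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        ok = (n >= 2) & (vx > 1e-12) & (vy > 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = (n * sxy - sx * sy) / np.sqrt(vx * vy)
        r[lo:hi] = np.where(ok, rr, np.nan)
        n_used[lo:hi] = n.astype(int)
        testable[lo:hi] = ok
    return r, n_used, testable


def _column_adjusted_stats(X: np.ndarray, y: np.ndarray, scores: np.ndarray):
    """Per-column residual correlation after projecting out PC scores."""
    n_rows, m = X.shape
    k_pc = scores.shape[1]
    r = np.full(m, np.nan)
    n_used = np.zeros(m, dtype=int)
    testable = np.zeros(m, dtype=bool)

    design = np.column_stack([np.ones(n_rows), scores])
    q_full, _ = np.linalg.qr(design)
    y_res_full = y - q_full @ (q_full.T @ y)
    ss_y_full = float(y_res_full @ y_res_full)

    complete = ~np.isnan(X).any(axis=0)
    if complete.any():
        Xc = X[:, complete]
        X_res = Xc - q_full @ (q_full.T @ Xc)
        ss_x = np.einsum("ij,ij->j", X_res, X_res)
        sxy = X_res.T @ y_res_full
        ok = (ss_x > 1e-12) & (ss_y_full > 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            rr = sxy / np.sqrt(ss_x * ss_y_full)
        r[complete] = np.where(ok, rr, np.nan)
        n_used[complete] = n_rows
        testable[complete] = ok

    for j in np.flatnonzero(~complete):
        res = stratification_adjust(X[:, j], y, scores)
        n_used[j] = res.n_used
        testable[j] = res.testable
        if res.testable:
            denom = res.n_used - k_pc - 1
            r[j] = math.sqrt(res.statistic / denom) if denom > 0 else np.nan
    return r, n_used, testable


def run_association(
    genotypes: GenotypeMatrix,
    phenotype: PhenotypeVector,
    models: tuple[str, ...] = GENETIC_MODELS,
    K_pc: int = 0,
    maf_threshold: float = 0.001,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int | None = None,
    scores: np.ndarray | None = None,
    pca_seed: int = 0,
) -> AssociationRun:
    """Genome-wide scan of one phenotype under the requested genetic models.

    Pipeline per run: minor-allele orientation on the combined sample, MAF
    filter (strict ``<``), optional EIGENSTRAT correction with ``K_pc``
    components, correlation trend test per SNP x model, per-model Bonferroni
    over the testable SNPs, and phenotype permutation (``B`` shuffles) for
    SNPs whose Bonferroni p is at most ``alpha``.  Untestable SNPs (e.g. no
    minor-allele homozygotes under the recessive model) are excluded from the
    Bonferroni count and reported separately.
    """
    for model in models:
        if model not in GENETIC_MODELS:
            raise ValueError(f"unknown genetic model '{model}'")
    if phenotype.values.shape[0] != genotypes.n_samples:
        raise ValueError("phenotype length must match the genotype rows")

    oriented, flipped = genotypes.oriented()
    filtered, removal_log = maf_filter(oriented, maf_threshold)
    if filtered.n_snps == 0:
        raise ValueError("no SNPs remain after MAF filtering")

    if K_pc > 0 and scores is None:
        scores, _ = pca_components(filtered, K_pc, seed=pca_seed)
    if scores is not None and scores.shape[1] == 0:
        scores = None

    y = phenotype.values
    G = filtered.counts
    info = filtered.snp_info
    k_pc = scores.shape[1] if scores is not None else 0

    # per-SNP genotype count triples, reused across models
    n_dd = (G == 2.0).sum(axis=0)
    n_dh = (G == 1.0).sum(axis=0)
    n_d0 = (G == 0.0).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mafs = np.nanmean(G, axis=0) / 2.0

    frames = []
    untestable: dict[str, list[str]] = {}
    n_tests: dict[str, int] = {}
    rng = np.random.default_rng(seed)
    for model in models:
        E = encode_model(G, model)
        if scores is not None:
            r, n_used, testable = _column_adjusted_stats(E, y, scores)
            dof_n = n_used - k_pc - 1
        else:
            r, n_used, testable = _column_trend_stats(E, y)
            dof_n = n_used
        with np.errstate(invalid="ignore"):
            statistic = dof_n * r * r
        p = np.where(testable, stats.chi2.sf(statistic, 1), np.nan)
        m_tests = int(testable.sum())
        n_tests[model] = m_tests
        untestable[model] = [str(s) for s in info.loc[~testable, "snp_id"]]

        frame = pd.DataFrame(
            {
                "snp_id": info["snp_id"],
                "chrom": info["chrom"],
                "pos": info["pos"],
                "model": model,
                "maf": mafs,
                "n_DD": n_dd,
                "n_Dd": n_dh,
                "n_dd": n_d0,
                "statistic": np.where(testable, statistic, np.nan),
                "p": p,
                "n_used": n_used,
            }
        )
        frame = frame[testable].copy()
        if m_tests:
            frame["bonferroni_p"] = np.minimum(1.0, frame["p"] * m_tests)
        else:
            frame["bonferroni_p"] = np.nan

        # permutation retest of the Bonferroni-significant hits only
        perm = np.full(len(frame), np.nan)
        hit_rows = np.flatnonzero(frame["bonferroni_p"].to_numpy() <= alpha)
        col_idx = frame.index.to_numpy()
        for pos_in_frame in hit_rows:
            j = col_idx[pos_in_frame]
            perm[pos_in_frame] = permutation_p(
                E[:, j],
                y,
                B=B,
                seed=int(rng.integers(0, 2**31 - 1)),
                scores=scores,
            )
        frame["permutation_p"] = perm
        frames.append(frame)

    results = pd.concat(frames, ignore_index=True)
    results = results.sort_values("p", kind="mergesort").reset_index(drop=True)
    return AssociationRun(
        results=results,
        removal_log=removal_log,
        untestable=untestable,
        n_tests=n_tests,
        scores=scores,
        flipped_snps=flipped,
    )
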