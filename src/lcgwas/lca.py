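"""Latent class models for binary indicators, fit by multi-start EM.

The model is a finite mixture over an unobserved categorical class variable
``c`` with ``K`` levels.  Given class membership, the ``J`` binary indicators
``u_1 .. u_J`` (here: lifetime psychiatric co-morbidity diagnoses) are
independent Bernoulli variables, so the marginal likelihood of one case is

    P(u) = sum_k  pi_k * prod_j  rho_kj^u_j * (1 - rho_kj)^(1 - u_j)

with mixing proportions ``pi`` and class-conditional endorsement
probabilities ``rho``.  Missing indicator entries are assumed missing at
random and simply drop out of the per-case product, so every available
observation contributes.

The module provides maximum-likelihood estimation by EM with many random
starts, BIC-based selection of the number of classes, the relative-entropy
measure of class separation, posterior class-membership probabilities (which
downstream association testing uses as quantitative phenotypes), class
profile odds ratios, pseudo-class Wald tests for auxiliary covariates, and
co-morbidity burden summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "IndicatorMatrix",
    "LatentClassModel",
    "PosteriorMatrix",
    "FitResult",
    "ModelSelection",
    "WaldResult",
    "loglikelihood",
    "em_fit",
    "posterior",
    "entropy",
    "select_model",
    "modal_assignment",
    "profile_odds_ratios",
    "wald_auxiliary_test",
    "comorbidity_burden",
]

# EM-internal floor keeping endorsement probabilities off the boundary so the
# log-likelihood stays finite mid-fit; final estimates are reported unsmoothed.
_RHO_FLOOR = 1e-6


# ---------------------------------------------------------------------------
# containers


@dataclass
class IndicatorMatrix:
    """Cases x items binary table; NaN marks a missing entry."""

    values: np.ndarray
    item_names: list[str]
    case_ids: list[str] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("indicator table must be 2-dimensional")
        obs = ~np.isnan(v)
        vals = v[obs]
        if vals.size and not np.all((vals == 0.0) | (vals == 1.0)):
            raise ValueError("indicator entries must be 0, 1 or missing")
        if len(self.item_names) != v.shape[1]:
            raise ValueError("item_names length does not match table width")
        if v.shape[0] and not obs.any(axis=1).all():
            bad = int(np.flatnonzero(~obs.any(axis=1))[0])
            raise ValueError(f"case row {bad} has no observed indicators")
        self.values = v
        self.item_names = list(self.item_names)
        if self.case_ids is not None:
            self.case_ids = [str(c) for c in self.case_ids]
            if len(self.case_ids) != v.shape[0]:
                raise ValueError("case_ids length does not match table height")

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        idx = self.case_ids if self.case_ids is not None else None
        return pd.DataFrame(self.values, columns=self.item_names, index=idx)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "IndicatorMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            item_names=[str(c) for c in df.columns],
            case_ids=[str(i) for i in df.index],
        )


@dataclass
class LatentClassModel:
    """Mixing proportions ``pi`` (K,) and endorsement probabilities ``rho`` (K, J)."""

    pi: np.ndarray
    rho: np.ndarray
    item_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        if self.pi.ndim != 1 or self.rho.shape[0] != self.pi.shape[0]:
            raise ValueError("pi and rho shapes disagree")
        if abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("mixing proportions must sum to 1")
        if np.any(self.pi < 0):
            raise ValueError("mixing proportions must be non-negative")
        if np.any((self.rho < 0) | (self.rho > 1)):
            raise ValueError("endorsement probabilities must lie in [0, 1]")

    @property
    def K(self) -> int:
        return self.pi.shape[0]

    @property
    def n_items(self) -> int:
        return self.rho.shape[1]


@dataclass
class PosteriorMatrix:
    """Cases x classes membership probabilities; rows sum to one."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("posterior matrix must be 2-dimensional")
        if v.shape[0] and np.any(np.abs(v.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("posterior rows must sum to 1")
        if np.any(v < 0):
            raise ValueError("posterior probabilities must be non-negative")
        self.values = v

    @property
    def n_cases(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]


@dataclass
class FitResult:
    model: LatentClassModel
    loglik: float
    bic: float
    entropy: float
    posteriors: PosteriorMatrix
    n_params: int
    converged: bool
    n_starts_used: int
    best_start_seed: int
    loglik_history: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ModelSelection:
    fits: list[FitResult]
    chosen_k: int
    table: pd.DataFrame

    @property
    def best(self) -> FitResult:
        return self.fits[self.chosen_k - 1]


@dataclass
class WaldResult:
    class_means: np.ndarray
    statistic: float
    df: int
    p_value: float
    n_draws: int


# ---------------------------------------------------------------------------
# likelihood machinery


def _split_observed(values: np.ndarray):
    """Return (x_obs, c_obs, obs) with missing entries zeroed for fast matmuls."""
    obs = ~np.isnan(values)
    x = np.where(obs, values, 0.0)
    c = np.where(obs, 1.0 - values, 0.0)
    return x, c, obs.astype(float)


def _log_component_matrix(values: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """n x K matrix of log P(u_i | class k), boundary-safe (handles rho of 0/1)."""
    obs = ~np.isnan(values)
    with np.errstate(divide="ignore"):
        lr = np.log(rho)
        lc = np.log1p(-rho)
    n = values.shape[0]
    out = np.zeros((n, rho.shape[0]))
    is_one = values == 1.0  # NaN compares False, masked below anyway
    for k in range(rho.shape[0]):
        term = np.where(obs, np.where(is_one, lr[k], lc[k]), 0.0)
        out[:, k] = term.sum(axis=1)
    return out


def loglikelihood(model: LatentClassModel, data: IndicatorMatrix) -> float:
    """Sum over cases of the log mixture likelihood; missing items skipped.

    Returns ``-inf`` (with a warning) when some case has zero likelihood under
    every class, which can only happen when a ``rho`` of exactly 0 or 1
    contradicts an observation.
    """
    if model.n_items != data.n_items:
        raise ValueError("model and data disagree on the number of items")
    logb = _log_component_matrix(data.values, model.rho)
    with np.errstate(divide="ignore"):
        logpi = np.log(model.pi)
    row_ll = logsumexp(logb + logpi, axis=1)
    if np.any(np.isneginf(row_ll)):
        warnings.warn(
            "some cases have zero likelihood under every class "
            "(boundary endorsement probability contradicts an observation)",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(row_ll.sum())


def posterior(model: LatentClassModel, data: IndicatorMatrix) -> PosteriorMatrix:
    """Class-membership probabilities per case by Bayes rule.

    A case with every item missing gets the prior ``pi`` (missing-at-random).
    """
    if model.n_items != data.n_items:
        raise ValueError("model and data disagree on the number of items")
    logb = _log_component_matrix(data.values, model.rho)
    with np.errstate(divide="ignore"):
        joint = logb + np.log(model.pi)
    row_mass = logsumexp(joint, axis=1)
    if np.any(np.isneginf(row_mass)):
        bad = int(np.flatnonzero(np.isneginf(row_mass))[0])
        raise ValueError(f"case row {bad} has zero posterior mass under the model")
    post = np.exp(joint - row_mass[:, None])
    post /= post.sum(axis=1, keepdims=True)
    return PosteriorMatrix(post)


def entropy(posteriors: PosteriorMatrix, K: int | None = None) -> float:
    """Relative entropy 1 - sum(-p ln p) / (n ln K); 1 = crisp, 0 = uniform."""
    P = posteriors.values
    if K is None:
        K = P.shape[1]
    if K < 2:
        raise ValueError("relative entropy is undefined for a single class")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    value = 1.0 + plogp.sum() / (P.shape[0] * np.log(K))
    return float(min(1.0, max(0.0, value)))


# ---------------------------------------------------------------------------
# EM


def _em_single(x, c, obs, w, K, rng, max_iter, tol):
    """One EM run from a random start on pattern-collapsed data.

    ``x``, ``c``, ``obs`` hold the unique indicator patterns and ``w`` the
    number of cases carrying each pattern; collapsing duplicates leaves the
    likelihood unchanged while bounding the E-step by the number of distinct
    response patterns rather than the sample size.
    """
    n_pat, J = obs.shape
    n = float(w.sum())
    pi = rng.dirichlet(np.ones(K))
    rho_raw = rng.uniform(0.1, 0.9, size=(K, J))
    rho = np.clip(rho_raw, _RHO_FLOOR, 1.0 - _RHO_FLOOR)
    wx = w[:, None] * x
    wobs = w[:, None] * obs
    ll_old = -np.inf
    history = []
    converged = False
    post = np.full((n_pat, K), 1.0 / K)
    for _ in range(max_iter):
        # E-step
        logb = x @ np.log(rho).T + c @ np.log1p(-rho).T
        joint = logb + np.log(pi)
        row_mass = logsumexp(joint, axis=1)
        ll = float(w @ row_mass)
        post = np.exp(joint - row_mass[:, None])
        history.append(ll)
        if ll - ll_old < tol and len(history) > 1:
            converged = True
            break
        ll_old = ll
        # M-step (posterior-weighted means, missing entries excluded item-wise)
        pi = (w @ post) / n
        pi = pi / pi.sum()
        num = post.T @ wx
        den = post.T @ wobs
        with np.errstate(invalid="ignore"):
            rho_raw = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
        rho = np.clip(rho_raw, _RHO_FLOOR, 1.0 - _RHO_FLOOR)
    return ll, pi, rho_raw, post, converged, np.asarray(history)


def _canonical_order(pi: np.ndarray, rho: np.ndarray, anchor: int | None) -> np.ndarray:
    # descending anchor-item endorsement, ties broken by descending pi
    if anchor is None:
        return np.argsort(-pi, kind="stable")
    return np.lexsort((-pi, -rho[:, anchor]))


def _resolve_anchor(item_names: list[str] | None, anchor_item) -> int | None:
    if anchor_item is None:
        return None
    if isinstance(anchor_item, (int, np.integer)):
        return int(anchor_item)
    if item_names is not None and anchor_item in item_names:
        return item_names.index(anchor_item)
    return None


def em_fit(
    data: IndicatorMatrix,
    K: int,
    n_starts: int = 50,
    max_iter: int = 1000,
    tol: float = 1e-8,
    seed: int | None = None,
    anchor_item: str | int | None = "ALCDEP",
) -> FitResult:
    """Best of ``n_starts`` EM runs for a ``K``-class model.

    Starting values: ``rho ~ Uniform(0.1, 0.9)``, ``pi ~ Dirichlet(1)``.
    Classes of the winning run are canonicalized by descending endorsement of
    the anchor item (falling back to descending ``pi`` when the anchor is not
    among the items), which keeps class identities stable across seeds and
    replicates despite the label-switching symmetry of mixtures.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    if data.n_cases < K:
        raise ValueError("need at least K cases to fit K classes")
    if n_starts < 1:
        raise ValueError("n_starts must be at least 1")

    # collapse duplicate response patterns (missing encoded as its own level)
    coded = np.where(np.isnan(data.values), 2.0, data.values)
    uniq, inverse, weights = np.unique(
        coded, axis=0, return_inverse=True, return_counts=True
    )
    patterns = np.where(uniq == 2.0, np.nan, uniq)
    x, c, obs = _split_observed(patterns)
    w = weights.astype(float)

    if K == 1:
        n_starts = 1  # single-class MLE is closed form; no local optima
    children = np.random.SeedSequence(seed).spawn(n_starts)

    best = None
    best_ll = -np.inf
    best_start = -1
    any_converged = False
    for s in range(n_starts):
        rng = np.random.default_rng(children[s])
        ll, pi, rho_raw, post, conv, hist = _em_single(
            x, c, obs, w, K, rng, max_iter, tol
        )
        any_converged = any_converged or conv
        if ll > best_ll:
            best_ll = ll
            best = (pi, rho_raw, post, conv, hist)
            best_start = s

    pi, rho_raw, post, conv, hist = best
    post = post[inverse]  # expand pattern posteriors back to one row per case
    # report boundary estimates unsmoothed: values within the smoothing floor
    # of 0 or 1 are genuine boundary solutions and are printed as exact 0 / 1
    rho_raw = np.where(rho_raw < _RHO_FLOOR, 0.0, rho_raw)
    rho_raw = np.where(rho_raw > 1.0 - _RHO_FLOOR, 1.0, rho_raw)
    anchor = _resolve_anchor(data.item_names, anchor_item)
    order = _canonical_order(pi, rho_raw, anchor)
    pi = pi[order]
    rho_raw = np.clip(rho_raw[order], 0.0, 1.0)
    post = post[:, order]
    post = post / post.sum(axis=1, keepdims=True)

    n_params = (K - 1) + K * data.n_items
    bic = -2.0 * best_ll + n_params * np.log(data.n_cases)
    posteriors = PosteriorMatrix(post)
    ent = entropy(posteriors, K) if K >= 2 else float("nan")
    if not any_converged:
        warnings.warn("no EM start converged within max_iter", RuntimeWarning)
    return FitResult(
        model=LatentClassModel(pi=pi, rho=rho_raw, item_names=data.item_names),
        loglik=best_ll,
        bic=float(bic),
        entropy=ent,
        posteriors=posteriors,
        n_params=n_params,
        converged=bool(conv),
        n_starts_used=n_starts,
        best_start_seed=best_start,
        loglik_history=hist,
    )


def select_model(
    data: IndicatorMatrix,
    K_max: int,
    n_starts: int = 50,
    seed: int | None = None,
    **em_kwargs,
) -> ModelSelection:
    """Fit K = 1 .. K_max and choose the K minimising BIC."""
    if K_max < 1:
        raise ValueError("K_max must be at least 1")
    fits = []
    rows = []
    for K in range(1, K_max + 1):
        fit = em_fit(data, K, n_starts=n_starts, seed=seed, **em_kwargs)
        fits.append(fit)
        rows.append(
            {
                "K": K,
                "loglik": fit.loglik,
                "n_params": fit.n_params,
                "bic": fit.bic,
                "entropy": fit.entropy,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(rows)
    chosen_k = int(table.loc[table["bic"].idxmin(), "K"])
    return ModelSelection(fits=fits, chosen_k=chosen_k, table=table)


def modal_assignment(posteriors: PosteriorMatrix) -> np.ndarray:
    """Most likely class per case; ties broken toward the lowest class index."""
    return np.argmax(posteriors.values, axis=1)


# ---------------------------------------------------------------------------
# derived quantities


def profile_odds_ratios(
    model: LatentClassModel,
    k: int,
    l: int,
    data: IndicatorMatrix | None = None,
    posteriors: PosteriorMatrix | None = None,
) -> pd.DataFrame:
    """Per-item odds ratios contrasting the endorsement profiles of two classes.

    ``OR_j = [rho_kj / (1 - rho_kj)] / [rho_lj / (1 - rho_lj)]``.  An item whose
    endorsement probability is exactly 0 or 1 in either class has undefined
    odds and is reported as NaN (not available).  When the fitted data and
    posteriors are supplied, a delta-method standard error is attached using
    the posterior-weighted effective counts as the observed information for
    each logit, together with a two-tailed normal p-value on the log scale.
    """
    if k == l:
        raise ValueError("classes to compare must differ")
    rho = model.rho
    eps = 1e-6  # the EM smoothing floor: anything closer to 0/1 is a boundary
    items = model.item_names or [f"item{j}" for j in range(model.n_items)]

    neff = None
    if data is not None and posteriors is not None:
        obs = (~np.isnan(data.values)).astype(float)
        neff = posteriors.values.T @ obs  # K x J effective item-wise counts

    rows = []
    for j, name in enumerate(items):
        r1, r2 = rho[k, j], rho[l, j]
        if min(r1, r2) < eps or max(r1, r2) > 1 - eps:
            rows.append({"item": name, "odds_ratio": np.nan, "se": np.nan, "p_value": np.nan})
            continue
        odds_ratio = (r1 / (1 - r1)) / (r2 / (1 - r2))
        se = p_value = np.nan
        if neff is not None:
            var_logit = 1.0 / (neff[k, j] * r1 * (1 - r1)) + 1.0 / (
                neff[l, j] * r2 * (1 - r2)
            )
            se_log = np.sqrt(var_logit)
            se = odds_ratio * se_log  # delta method on the OR scale
            z = np.log(odds_ratio) / se_log
            p_value = 2.0 * stats.norm.sf(abs(z))
        rows.append({"item": name, "odds_ratio": odds_ratio, "se": se, "p_value": p_value})
    return pd.DataFrame(rows).set_index("item")


def wald_auxiliary_test(
    posteriors: PosteriorMatrix,
    aux: np.ndarray,
    n_draws: int = 20,
    seed: int | None = None,
) -> WaldResult:
    """Equality-of-means Wald chi-square test across pseudo-class draws.

    Auxiliary covariates (age, sex) never enter the class-model likelihood.
    Instead, for each of ``n_draws`` replicates a class is sampled per case
    from its posterior row; class means and squared standard errors of the
    covariate are computed per draw (missing covariate values excluded), and
    the draws are pooled multiple-imputation style: total variance = mean
    within-draw variance + (1 + 1/D) * between-draw variance.  The statistic
    tests equality of the K pooled means with K - 1 degrees of freedom.
    """
    P = posteriors.values
    n, K = P.shape
    aux = np.asarray(aux, dtype=float)
    if aux.shape[0] != n:
        raise ValueError("auxiliary vector length must match the posterior rows")
    if n_draws < 2:
        raise ValueError("need at least 2 pseudo-class draws for variance pooling")

    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    means = np.full((n_draws, K), np.nan)
    sq_se = np.full((n_draws, K), np.nan)
    aux_obs = ~np.isnan(aux)
    for d in range(n_draws):
        u = rng.random(n)
        cls = (u[:, None] > cum).sum(axis=1)
        for kk in range(K):
            vals = aux[(cls == kk) & aux_obs]
            if vals.size >= 2:
                means[d, kk] = vals.mean()
                sq_se[d, kk] = vals.var(ddof=1) / vals.size
            elif vals.size == 1:
                means[d, kk] = vals[0]

    if np.isnan(means).all(axis=0).any():
        empty = int(np.flatnonzero(np.isnan(means).all(axis=0))[0])
        raise ValueError(f"class {empty} received no cases in any pseudo-class draw")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pooled_mean = np.nanmean(means, axis=0)
        within = np.nanmean(sq_se, axis=0)
        between = np.nanvar(means, axis=0, ddof=1)
    within = np.nan_to_num(within)
    total_var = within + (1.0 + 1.0 / n_draws) * between

    contrast = np.hstack([np.eye(K - 1), -np.ones((K - 1, 1))])
    diff = contrast @ pooled_mean
    if np.linalg.norm(diff) < 1e-12:
        statistic = 0.0
    else:
        cov = contrast @ np.diag(total_var) @ contrast.T
        statistic = float(max(0.0, diff @ np.linalg.pinv(cov) @ diff))
    p_value = float(stats.chi2.sf(statistic, K - 1)) if statistic > 0 else 1.0
    return WaldResult(
        class_means=pooled_mean,
        statistic=statistic,
        df=K - 1,
        p_value=p_value,
        n_draws=n_draws,
    )


def comorbidity_burden(
    data: IndicatorMatrix,
    assignment: np.ndarray,
    burden_items: list[str] | None = None,
    thresholds: tuple[int, ...] = (2, 3, 4),
) -> pd.DataFrame:
    """Per-class fractions of cases carrying >= t of the burden diagnoses.

    ``burden_items`` selects which indicators count as co-morbid diagnoses
    (e.g. psychotic symptoms can be excluded when they are regarded as part of
    the index phenotype rather than a separate co-morbidity).  Missing item
    entries count as not endorsed.
    """
    if burden_items is None:
        burden_items = list(data.item_names)
    missing = [b for b in burden_items if b not in data.item_names]
    if missing:
        raise ValueError(f"unknown burden items: {missing}")
    cols = [data.item_names.index(b) for b in burden_items]
    counts = np.nansum(data.values[:, cols], axis=1)
    assignment = np.asarray(assignment)
    classes = np.unique(assignment)
    rows = []
    for cl in classes:
        sub = counts[assignment == cl]
        row = {"class": int(cl), "n": int(sub.size)}
        for t in thresholds:
            row[f"ge{t}"] = float((sub >= t).mean()) if sub.size else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")
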