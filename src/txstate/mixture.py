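"""Per-gene on/off mixture models for log-normal transcript abundance.

Each gene's log abundance across a catalog of cell-type samples is described
either by a two-component normal mixture (an ``off`` and an ``on`` state with
a shared standard deviation, so the posterior on-probability is monotone in
abundance) or by a single normal (unimodal). The two models are compared by
10-fold cross-validated expected log pointwise predictive density (elpd); the
bimodal model is chosen only when its elpd advantage exceeds twice its
standard error. Genes selected unimodal are classified on/off by comparing
their posterior-mean level against pooled global on/off distributions built
from confidently bimodal genes.

Priors: component means ~ N(7, 5^2) on natural-log TPM with an ordered
constraint (mu_off <= mu_on); sigma ~ Half-Normal(3); pi ~ Uniform(0, 1).
Sampling uses 4 chains x 500 iterations by default (first half warmup).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

from . import _gibbs
from ._gibbs import Draws, SamplerConfig
from .io import AbundanceMatrix, SampleMetadata

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureConfig",
    "GeneFit",
    "ModelSelection",
    "GlobalComponents",
    "InferenceResult",
    "log_transform",
    "fit_gene",
    "posterior_on_probability",
    "elpd_from_draw_likelihoods",
    "crossvalidated_elpd",
    "select_model",
    "global_components",
    "classify_unimodal",
    "augment_with_dummies",
    "assign_cv_folds",
    "infer_expression_probabilities",
]


@dataclass
class MixtureConfig:
    """Sampler, cross-validation and assembly settings.

    ``floor`` is the TPM value substituted for zeros before taking logs so
    off-state observations stay finite. ``confident_delta``, ``confident_on``
    and ``confident_off`` select the datapoints that define the global on/off
    distributions used to classify unimodal genes.
    """

    chains: int = 4
    iters: int = 500
    folds: int = 10
    floor: float = 0.01
    seed: int = 0
    mu_prior_loc: float = 7.0
    mu_prior_scale: float = 5.0
    sigma_prior_scale: float = 3.0
    sigma_floor: float = 1e-3
    prop_scale: float = 0.3
    mh_substeps: int = 2
    max_draws: int = 500
    rhat_threshold: float = 1.05
    confident_delta: float = 10.0
    confident_on: float = 0.9
    confident_off: float = 0.1
    draw_average: bool = False

    def sampler(self) -> SamplerConfig:
        return SamplerConfig(
            chains=self.chains,
            iters=self.iters,
            mu_loc=self.mu_prior_loc,
            mu_scale=self.mu_prior_scale,
            sigma_scale=self.sigma_prior_scale,
            sigma_floor=self.sigma_floor,
            prop_scale=self.prop_scale,
            mh_substeps=self.mh_substeps,
            max_draws=self.max_draws,
        )


@dataclass
class GeneFit:
    """Posterior fit of one gene under one model."""

    gene_id: str
    model: str  # "bimodal" | "unimodal"
    draws: Draws
    diagnostics: dict = field(default_factory=dict)

    @property
    def posterior_means(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.draws.means().items()}

    @property
    def posterior_sds(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.draws.sds().items()}


@dataclass
class ModelSelection:
    """Cross-validated comparison of the bimodal and unimodal models."""

    gene_id: str
    elpd_bimodal: float
    elpd_unimodal: float
    fold_elpd_bimodal: np.ndarray
    fold_elpd_unimodal: np.ndarray
    delta_elpd: float
    se_delta: float
    choice: str


@dataclass
class GlobalComponents:
    """Pooled on/off log-normal components from confidently bimodal genes."""

    mu_on_glob: float
    sigma_on_glob: float
    mu_off_glob: float
    sigma_off_glob: float
    pi_glob: float
    n_on: int = 0
    n_off: int = 0


@dataclass
class ElpdResult:
    elpd_hat: float
    fold_elpd: np.ndarray  # (k,) per-fold sums of pointwise lpd
    pointwise: np.ndarray  # (n,) lpd per held-out observation (NaN if never held out)
    folds: np.ndarray  # fold id per observation (-1 = always in training)


def log_transform(values: np.ndarray, floor: float = 0.01) -> np.ndarray:
    """Natural log of abundances, flooring zeros at ``floor`` TPM."""
    v = np.asarray(values, dtype=float)
    if (v < 0).any():
        raise ValueError("abundances must be non-negative")
    return np.log(np.maximum(v, floor))


def augment_with_dummies(
    gene_values: Sequence[float], dissected_values: Sequence[float] = ()
) -> tuple[np.ndarray, np.ndarray]:
    """Append the min and max over catalog + dissected values as dummy points.

    The dummies anchor the dynamic range of the fit (they participate in the
    likelihood) but are excluded from held-out cross-validation folds and from
    every reported probability. Returns (augmented vector, dummy mask).
    """
    cat = np.asarray(gene_values, dtype=float)
    if cat.size == 0:
        raise ValueError("catalog vector must be non-empty")
    dis = np.asarray(dissected_values, dtype=float)
    pool = np.concatenate([cat, dis]) if dis.size else cat
    augmented = np.concatenate([cat, [pool.min(), pool.max()]])
    mask = np.zeros(augmented.size, dtype=bool)
    mask[-2:] = True
    return augmented, mask


def fit_gene(
    logE: np.ndarray,
    model: str,
    config: MixtureConfig | None = None,
    gene_id: str = "gene",
    rng: np.random.Generator | None = None,
) -> GeneFit:
    """Fit one gene's log abundances under the requested model.

    Non-convergence (split-Rhat above the threshold) is flagged in
    ``diagnostics``, never fatal; genes whose observations are all identical
    are flagged degenerate under the bimodal model.
    """
    config = config or MixtureConfig()
    y = np.asarray(logE, dtype=float).reshape(1, -1)
    if y.shape[1] < 4:
        raise ValueError("need at least 4 observations")
    if not np.isfinite(y).all():
        raise ValueError("log abundances must be finite")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if model == "bimodal":
        draws = _gibbs.fit_bimodal(y, config.sampler(), rng)
    elif model == "unimodal":
        draws = _gibbs.fit_unimodal(y, config.sampler(), rng)
    else:
        raise ValueError(f"unknown model {model!r}")
    draws = Draws(
        {k: v[:, 0] for k, v in draws.params.items()},
        {k: float(v[0]) for k, v in draws.rhat.items()},
        draws.accept_rate,
    )
    max_rhat = max(v for v in draws.rhat.values())
    degenerate = bool(np.ptp(y) < 1e-9) and model == "bimodal"
    diagnostics = {
        "rhat": draws.rhat,
        "max_rhat": max_rhat,
        "converged": bool(np.isnan(max_rhat) or max_rhat <= config.rhat_threshold),
        "degenerate": degenerate,
        "accept_rate": draws.accept_rate,
        "n_draws": draws.params[next(iter(draws.params))].shape[0],
    }
    return GeneFit(gene_id=gene_id, model=model, draws=draws, diagnostics=diagnostics)


def _bimodal_logit(
    observations: np.ndarray,
    mu_off: float,
    mu_on: float,
    sigma: float,
    pi: float,
) -> float:
    y = np.asarray(observations, dtype=float).ravel()
    slope = (mu_on - mu_off) / (sigma * sigma)
    mid = 0.5 * (mu_on + mu_off)
    return float(np.log(pi) - np.log1p(-pi) + slope * np.sum(y - mid))


def posterior_on_probability(
    observations: np.ndarray,
    fit: GeneFit | None = None,
    *,
    mu_off: float | None = None,
    mu_on: float | None = None,
    sigma: float | None = None,
    pi: float | None = None,
    draw_average: bool = False,
) -> float:
    """P(z = on) given one or more replicate observations of log abundance.

    Replicates of the same unit multiply their likelihoods inside the
    posterior-odds formula: pi * prod p(E|on) / (pi * prod p(E|on) +
    (1-pi) * prod p(E|off)). Evaluated in log space; by default parameters are
    the posterior means (plug-in), with optional averaging over draws.
    """
    y = np.asarray(observations, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("need at least one observation")
    if fit is not None:
        if fit.model != "bimodal":
            raise ValueError("posterior_on_probability requires a bimodal fit")
        if draw_average:
            p = fit.draws.params
            slope = (p["mu_on"] - p["mu_off"]) / (p["sigma"] ** 2)
            mid = 0.5 * (p["mu_on"] + p["mu_off"])
            logit = (
                np.log(p["pi"])
                - np.log1p(-p["pi"])
                + slope * (y[None, :] - mid[:, None]).sum(axis=1)
            )
            return float(np.mean(expit(logit)))
        m = fit.draws.means()
        mu_off, mu_on, sigma, pi = m["mu_off"], m["mu_on"], m["sigma"], m["pi"]
    if None in (mu_off, mu_on, sigma, pi):
        raise ValueError("provide either a GeneFit or all of mu_off/mu_on/sigma/pi")
    return float(expit(_bimodal_logit(y, mu_off, mu_on, sigma, pi)))


def elpd_from_draw_likelihoods(likelihoods: np.ndarray) -> float:
    """elpd_i = log(1/S * sum_s p(y_i | theta_s)) from per-draw likelihoods."""
    lik = np.asarray(likelihoods, dtype=float).ravel()
    if lik.size == 0:
        raise ValueError("need at least one draw")
    if (lik < 0).any():
        raise ValueError("likelihoods must be non-negative")
    return float(logsumexp(np.log(lik)) - np.log(lik.size))


def _random_folds(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    order = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[order] = np.arange(n) % k
    return folds


def crossvalidated_elpd(
    logE: np.ndarray,
    model: str,
    k: int = 10,
    config: MixtureConfig | None = None,
    folds: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> ElpdResult:
    """k-fold cross-validated elpd for one gene under one model.

    ``folds`` assigns each observation to a held-out fold; entries of -1 are
    never held out (dummy points, or the sole replicate of a driver). When
    omitted, a random balanced partition is drawn. Per fold, the model is
    refit on the training observations and the held-out log pointwise
    predictive density is a log-mean-exp over the posterior draws; the total
    elpd is the sum over held-out points.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config or MixtureConfig()
    y = np.asarray(logE, dtype=float).ravel()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if folds is None:
        folds = _random_folds(y.size, k, rng)
    folds = np.asarray(folds, dtype=int)
    if folds.size != y.size:
        raise ValueError("fold assignment length must match observations")
    pointwise = np.full(y.size, np.nan)
    fold_sums = np.zeros(k)
    sampler = config.sampler()
    for f in range(k):
        test = folds == f
        if not test.any():
            continue
        train = ~test
        yt = y[train].reshape(1, -1)
        if model == "bimodal":
            draws = _gibbs.fit_bimodal(yt, sampler, rng).thinned(config.max_draws)
            lpd = _gibbs.pointwise_lpd_bimodal(draws, y[test].reshape(1, -1))[0]
        elif model == "unimodal":
            draws = _gibbs.fit_unimodal(yt, sampler, rng).thinned(config.max_draws)
            lpd = _gibbs.pointwise_lpd_unimodal(draws, y[test].reshape(1, -1))[0]
        else:
            raise ValueError(f"unknown model {model!r}")
        pointwise[test] = lpd
        fold_sums[f] = lpd.sum()
    return ElpdResult(
        elpd_hat=float(fold_sums.sum()),
        fold_elpd=fold_sums,
        pointwise=pointwise,
        folds=folds,
    )


def select_model(
    fold_elpd_bimodal: np.ndarray | pd.Series,
    fold_elpd_unimodal: np.ndarray | pd.Series,
    gene_id: str = "gene",
) -> ModelSelection:
    """Choose bimodal only when delta elpd exceeds twice its standard error.

    The standard error is computed at fold level:
    se = sqrt(K * Var_fold(delta_i)) over the K per-fold differences.
    """
    if isinstance(fold_elpd_bimodal, pd.Series) and isinstance(fold_elpd_unimodal, pd.Series):
        if not fold_elpd_bimodal.index.equals(fold_elpd_unimodal.index):
            raise ValueError("mismatched fold sets between models")
    b = np.asarray(fold_elpd_bimodal, dtype=float)
    u = np.asarray(fold_elpd_unimodal, dtype=float)
    if b.shape != u.shape:
        raise ValueError("mismatched fold sets between models")
    diffs = b - u
    k = diffs.size
    se = float(np.sqrt(k * diffs.var(ddof=1))) if k > 1 else float("inf")
    delta = float(diffs.sum())
    choice = "bimodal" if delta > 2.0 * se else "unimodal"
    return ModelSelection(
        gene_id=gene_id,
        elpd_bimodal=float(b.sum()),
        elpd_unimodal=float(u.sum()),
        fold_elpd_bimodal=b,
        fold_elpd_unimodal=u,
        delta_elpd=delta,
        se_delta=se,
        choice=choice,
    )


def global_components(
    log_abundance: np.ndarray | pd.DataFrame,
    sample_probs: np.ndarray | pd.DataFrame,
    delta_elpd: np.ndarray | pd.Series,
    min_delta: float = 10.0,
    on_prob: float = 0.9,
    off_prob: float = 0.1,
) -> GlobalComponents:
    """Pool on/off datapoints of confidently bimodal genes into two normals.

    Rows are genes fit by the bimodal model, columns catalog samples.
    Qualifying genes have delta elpd > ``min_delta``; datapoints enter the on
    pool when P(z=on) > ``on_prob`` and the off pool when P < ``off_prob``.
    The global mixing weight is the fraction of pooled points that are on.
    """
    y = np.asarray(log_abundance, dtype=float)
    p = np.asarray(sample_probs, dtype=float)
    d = np.asarray(delta_elpd, dtype=float)
    if y.shape != p.shape or y.shape[0] != d.size:
        raise ValueError("log_abundance, sample_probs and delta_elpd must align")
    confident = d > min_delta
    on_pool = y[confident][p[confident] > on_prob]
    off_pool = y[confident][p[confident] < off_prob]
    if on_pool.size == 0 or off_pool.size == 0:
        raise ValueError(
            "no confidently bimodal genes with both on and off datapoints; "
            "relax min_delta/on_prob/off_prob"
        )
    return GlobalComponents(
        mu_on_glob=float(on_pool.mean()),
        sigma_on_glob=float(max(on_pool.std(), 1e-6)),
        mu_off_glob=float(off_pool.mean()),
        sigma_off_glob=float(max(off_pool.std(), 1e-6)),
        pi_glob=float(on_pool.size / (on_pool.size + off_pool.size)),
        n_on=int(on_pool.size),
        n_off=int(off_pool.size),
    )


def classify_unimodal(
    fit: GeneFit | float | np.ndarray,
    glob: GlobalComponents,
) -> float | np.ndarray:
    """P(z = on) for a unimodal gene from its posterior-mean level.

    Evaluates pi * p(mu | on) / (pi * p(mu | on) + (1 - pi) * p(mu | off))
    with the global on/off normal densities; the result is broadcast to every
    unit for that gene.
    """
    if isinstance(fit, GeneFit):
        if fit.model != "unimodal":
            raise ValueError("classify_unimodal requires a unimodal fit")
        mu = fit.draws.means()["mu"]
    else:
        mu = np.asarray(fit, dtype=float)
    lp_on = _normal_logpdf(mu, glob.mu_on_glob, glob.sigma_on_glob) + np.log(glob.pi_glob)
    lp_off = _normal_logpdf(mu, glob.mu_off_glob, glob.sigma_off_glob) + np.log1p(-glob.pi_glob)
    out = expit(lp_on - lp_off)
    return float(out) if np.isscalar(mu) or out.ndim == 0 else out


def _normal_logpdf(x, mu, sigma):
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * np.log(2 * np.pi)


def assign_cv_folds(metadata: SampleMetadata, k: int = 10, rng: np.random.Generator | None = None) -> pd.Series:
    """One shared sample-level fold partition for all genes.

    Samples of the same driver are spread across distinct folds so every
    training set keeps at least one replicate of each driver; a driver's sole
    sample is assigned fold -1 (always in training, never held out).
    """
    rng = rng or np.random.default_rng(0)
    catalog = metadata.table[metadata.table["sample_class"] == "cell_catalog"]
    folds = pd.Series(-1, index=pd.Index(catalog["sample_id"], name="sample_id"), dtype=int)
    loads = np.zeros(k)
    drivers = catalog.groupby("driver_id")["sample_id"].apply(list)
    for driver in rng.permutation(sorted(drivers.index)):
        samples = drivers[driver]
        if len(samples) < 2:
            logger.info("driver %s has a single sample; it is never held out", driver)
            continue
        order = np.lexsort((rng.random(k), loads))
        chosen = [int(order[i % k]) for i in range(len(samples))]
        for s, f in zip(rng.permutation(samples), chosen):
            folds[s] = f
            loads[f] += 1
    return folds


@dataclass
class InferenceResult:
    """Expression probabilities at every level plus per-gene fit tables."""

    sample_probs: pd.DataFrame
    driver_probs: pd.DataFrame
    cell_probs: pd.DataFrame
    dissected_probs: pd.DataFrame | None
    fits: pd.DataFrame
    fold_elpds: dict[str, pd.DataFrame]
    global_components: GlobalComponents | None
    folds: pd.Series
    config: MixtureConfig

    def probabilities(self, level: str) -> pd.DataFrame:
        return {
            "sample": self.sample_probs,
            "driver": self.driver_probs,
            "cell": self.cell_probs,
        }[level]


def infer_expression_probabilities(
    matrix: AbundanceMatrix,
    metadata: SampleMetadata,
    config: MixtureConfig | None = None,
) -> InferenceResult:
    """Fit every gene, select its model, and assemble probability matrices.

    Orchestrates, per gene: dummy augmentation (min/max over catalog +
    dissected levels), bimodal and unimodal fits, shared-partition 10-fold
    cross-validated elpds, the 2-se selection rule, plug-in bimodal posterior
    probabilities at sample/driver/cell level (replicates multiply their
    likelihoods) or the global-component classification for unimodal genes.
    Genes are processed as one vectorized batch; a fixed seed makes the run
    reproducible, and per-gene failures yield NA rows rather than aborting.
    """
    config = config or MixtureConfig()
    metadata = metadata.reordered(matrix.samples)
    catalog = metadata.catalog_samples()
    dissected = metadata.dissected_samples()
    if not catalog:
        raise ValueError("no cell_catalog samples to fit")
    genes = matrix.genes
    g = len(genes)

    y_cat = log_transform(matrix.data[catalog].to_numpy(), config.floor)  # (G, n_cat)
    y_dis = (
        log_transform(matrix.data[dissected].to_numpy(), config.floor)
        if dissected
        else np.empty((g, 0))
    )
    pool = np.concatenate([y_cat, y_dis], axis=1)
    dummies = np.stack([pool.min(axis=1), pool.max(axis=1)], axis=1)  # (G, 2)
    y_aug = np.concatenate([y_cat, dummies], axis=1)
    n_cat = y_cat.shape[1]

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(3 + 2 * config.folds)
    fold_rng = np.random.default_rng(children[0])
    folds = assign_cv_folds(metadata, config.folds, fold_rng)
    folds = folds.reindex(catalog).to_numpy()

    sampler = config.sampler()
    full_bim = _gibbs.fit_bimodal(y_aug, sampler, np.random.default_rng(children[1]))
    full_uni = _gibbs.fit_unimodal(y_aug, sampler, np.random.default_rng(children[2]))

    # --- cross-validation (dummies always in training) -----------------------
    k = config.folds
    fold_bim = np.zeros((g, k))
    fold_uni = np.zeros((g, k))
    for f in range(k):
        test = folds == f
        if not test.any():
            continue
        train_cols = np.concatenate([np.flatnonzero(~test), [n_cat, n_cat + 1]])
        y_train = y_aug[:, train_cols]
        y_test = y_cat[:, test]
        rng_b = np.random.default_rng(children[3 + 2 * f])
        rng_u = np.random.default_rng(children[4 + 2 * f])
        d_b = _gibbs.fit_bimodal(y_train, sampler, rng_b).thinned(config.max_draws)
        d_u = _gibbs.fit_unimodal(y_train, sampler, rng_u).thinned(config.max_draws)
        fold_bim[:, f] = _gibbs.pointwise_lpd_bimodal(d_b, y_test).sum(axis=1)
        fold_uni[:, f] = _gibbs.pointwise_lpd_unimodal(d_u, y_test).sum(axis=1)

    fold_used = np.array([(folds == f).any() for f in range(k)])
    k_eff = int(fold_used.sum())
    diffs = (fold_bim - fold_uni)[:, fold_used]
    delta = diffs.sum(axis=1)
    se = np.sqrt(k_eff * diffs.var(axis=1, ddof=1))
    elpd_b = fold_bim.sum(axis=1)
    elpd_u = fold_uni.sum(axis=1)
    is_bimodal = delta > 2.0 * se

    bm = full_bim.means()
    um = full_uni.means()
    mu_off, mu_on = bm["mu_off"], bm["mu_on"]
    sigma, pi = bm["sigma"], bm["pi"]
    rhat_b = full_bim.max_rhat()
    rhat_u = full_uni.max_rhat()
    degenerate = np.ptp(y_aug, axis=1) < 1e-9

    failed = ~(
        np.isfinite(mu_off)
        & np.isfinite(mu_on)
        & np.isfinite(sigma)
        & np.isfinite(pi)
        & np.isfinite(um["mu"])
        & np.isfinite(delta)
    )
    if failed.any():
        for gi in np.flatnonzero(failed):
            logger.warning("gene %s failed to fit; reported as NA", genes[gi])

    # --- plug-in bimodal probabilities ---------------------------------------
    with np.errstate(divide="ignore"):
        slope = (mu_on - mu_off) / (sigma * sigma)
        mid = 0.5 * (mu_on + mu_off)
        prior_logit = np.log(pi) - np.log1p(-pi)
    r_cat = slope[:, None] * (y_cat - mid[:, None])  # per-sample log likelihood ratio
    sample_logit = prior_logit[:, None] + r_cat
    sample_p_bim = expit(sample_logit)

    # global components need sample-level bimodal probabilities
    glob: GlobalComponents | None = None
    uni_prob = np.full(g, np.nan)
    if (~is_bimodal & ~failed).any():
        try:
            glob = global_components(
                y_cat[is_bimodal & ~failed],
                sample_p_bim[is_bimodal & ~failed],
                delta[is_bimodal & ~failed],
                min_delta=config.confident_delta,
                on_prob=config.confident_on,
                off_prob=config.confident_off,
            )
        except ValueError:
            logger.warning(
                "no confidently bimodal genes; unimodal genes reported as NA"
            )
        if glob is not None:
            uni_idx = ~is_bimodal & ~failed
            uni_prob[uni_idx] = classify_unimodal(um["mu"][uni_idx], glob)

    driver_of = metadata.driver_of().loc[catalog]
    cell_of = metadata.cell_of().loc[catalog]
    drivers = list(dict.fromkeys(driver_of))
    cells = list(dict.fromkeys(cell_of))
    col_idx = {s: i for i, s in enumerate(catalog)}

    def _grouped(ids: list[str], mapping: pd.Series) -> np.ndarray:
        out = np.empty((g, len(ids)))
        for j, unit in enumerate(ids):
            cols = [col_idx[s] for s in mapping.index[mapping == unit]]
            out[:, j] = expit(prior_logit + r_cat[:, cols].sum(axis=1))
        return out

    driver_p_bim = _grouped(drivers, driver_of)
    cell_p_bim = _grouped(cells, cell_of)

    def _assemble(bim_vals: np.ndarray, columns: list[str]) -> pd.DataFrame:
        out = np.where(is_bimodal[:, None], bim_vals, uni_prob[:, None])
        out = np.where(failed[:, None], np.nan, out)
        return pd.DataFrame(out, index=pd.Index(genes, name="gene"), columns=columns)

    sample_probs = _assemble(sample_p_bim, catalog)
    driver_probs = _assemble(driver_p_bim, drivers)
    cell_probs = _assemble(cell_p_bim, cells)
    dissected_probs = None
    if dissected:
        r_dis = slope[:, None] * (y_dis - mid[:, None])
        dissected_probs = _assemble(expit(prior_logit[:, None] + r_dis), dissected)

    fits = pd.DataFrame(
        {
            "model": np.where(failed, "failed", np.where(is_bimodal, "bimodal", "unimodal")),
            "mu_off": mu_off,
            "mu_on": mu_on,
            "sigma": sigma,
            "pi": pi,
            "mu_unimodal": um["mu"],
            "sigma_unimodal": um["sigma"],
            "elpd_bimodal": elpd_b,
            "elpd_unimodal": elpd_u,
            "delta_elpd": delta,
            "se_delta": se,
            "rhat_bimodal": rhat_b,
            "rhat_unimodal": rhat_u,
            "degenerate": degenerate,
            "failed": failed,
            "unimodal_prob": uni_prob,
        },
        index=pd.Index(genes, name="gene"),
    )
    n_flagged = int((np.nan_to_num(rhat_b, nan=1.0) > config.rhat_threshold).sum())
    if n_flagged:
        logger.info("%d genes flagged with split-Rhat > %.2f", n_flagged, config.rhat_threshold)

    fold_cols = [f"fold_{f}" for f in range(k)]
    return InferenceResult(
        sample_probs=sample_probs,
        driver_probs=driver_probs,
        cell_probs=cell_probs,
        dissected_probs=dissected_probs,
        fits=fits,
        fold_elpds={
            "bimodal": pd.DataFrame(fold_bim, index=genes, columns=fold_cols),
            "unimodal": pd.DataFrame(fold_uni, index=genes, columns=fold_cols),
        },
        global_components=glob,
        folds=pd.Series(folds, index=catalog, name="fold"),
        config=config,
    )
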