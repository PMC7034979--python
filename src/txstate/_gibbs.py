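"""Vectorized posterior samplers for the per-gene expression models.

Both models describe natural-log abundances. The bimodal model is a
two-component normal mixture with a shared standard deviation and ordered
component means; the unimodal model is a single normal. All genes are sampled
simultaneously: parameter arrays have shape (chains, genes) and the latent
state indicator has shape (chains, genes, observations).

Updates: the component assignments, component means and mixing weight have
conjugate full conditionals (means ~ N(mu_loc, mu_scale^2), pi ~ Beta(1, 1));
the shared sigma (Half-Normal(sigma_scale) prior) uses a few
Metropolis-within-Gibbs steps on log sigma. Because both component means
carry the same prior and pi's prior is symmetric, the unconstrained posterior
is exchangeable under label swap, so draws are relabeled (mu_off <= mu_on) to
obtain the ordered-model posterior exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class SamplerConfig:
    chains: int = 4
    iters: int = 500
    mu_loc: float = 7.0
    mu_scale: float = 5.0
    sigma_scale: float = 3.0
    sigma_floor: float = 1e-3
    prop_scale: float = 0.3
    mh_substeps: int = 2
    max_draws: int = 500


@dataclass
class Draws:
    """Posterior draw ensemble; each entry is an (S, G) array."""

    params: dict[str, np.ndarray]
    rhat: dict[str, np.ndarray] = field(default_factory=dict)
    accept_rate: float = float("nan")

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[0]

    def means(self) -> dict[str, np.ndarray]:
        return {k: v.mean(axis=0) for k, v in self.params.items()}

    def sds(self) -> dict[str, np.ndarray]:
        return {k: v.std(axis=0, ddof=1) for k, v in self.params.items()}

    def max_rhat(self) -> np.ndarray:
        return np.max(np.stack(list(self.rhat.values())), axis=0)

    def thinned(self, max_draws: int) -> "Draws":
        s = self.n_draws
        if s <= max_draws:
            return self
        idx = np.linspace(0, s - 1, max_draws).round().astype(int)
        return Draws({k: v[idx] for k, v in self.params.items()}, self.rhat, self.accept_rate)


def _split_rhat(chains_draws: np.ndarray) -> np.ndarray:
    """Split-Rhat over (chains, draws, genes); returns (genes,)."""
    c, t, g = chains_draws.shape
    if t < 4:
        return np.full(g, np.nan)
    half = t // 2
    seq = np.concatenate(
        [chains_draws[:, :half, :], chains_draws[:, half : 2 * half, :]], axis=0
    )  # (2c, half, g)
    m = seq.shape[0]
    means = seq.mean(axis=1)  # (m, g)
    variances = seq.var(axis=1, ddof=1)  # (m, g)
    w = variances.mean(axis=0)
    b = half * means.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * w + b / half
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / w)
    rhat = np.where(w <= 1e-300, 1.0, rhat)
    return rhat


def fit_bimodal(
    y: np.ndarray,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> Draws:
    """Sample the two-component shared-sigma mixture for all genes at once.

    ``y`` is (genes, observations) of log abundances. Returns post-warmup
    draws of mu_off, mu_on, sigma and pi (the mixing weight of the on state).
    """
    y = np.ascontiguousarray(y, dtype=np.float64)
    g, n = y.shape
    if n < 4:
        raise ValueError("need at least 4 observations per gene")
    c = config.chains
    ysum = y.sum(axis=1)
    yss = (y * y).sum(axis=1)
    ymin = y.min(axis=1)
    ymax = y.max(axis=1)
    yrange = np.maximum(ymax - ymin, 1e-3)

    mu_off = ymin[None, :] + 0.25 * yrange[None, :] * rng.random((c, g))
    mu_on = ymax[None, :] - 0.25 * yrange[None, :] * rng.random((c, g))
    swap0 = mu_off > mu_on
    mu_off, mu_on = np.where(swap0, mu_on, mu_off), np.where(swap0, mu_off, mu_on)
    sd0 = np.maximum(y.std(axis=1), 5 * config.sigma_floor)
    sigma = sd0[None, :] * rng.uniform(0.5, 1.0, (c, g))
    pi = rng.uniform(0.3, 0.7, (c, g))

    prior_prec = 1.0 / (config.mu_scale**2)
    prior_term = config.mu_loc * prior_prec
    warm = config.iters // 2
    keep = config.iters - warm
    out = {k: np.empty((c, keep, g)) for k in ("mu_off", "mu_on", "sigma", "pi")}
    n_acc = 0
    n_prop = 0

    for t in range(config.iters):
        # --- latent states -------------------------------------------------
        inv_var = 1.0 / (sigma * sigma)  # (c, g)
        slope = (mu_on - mu_off) * inv_var
        mid = 0.5 * (mu_on + mu_off)
        logit = slope[:, :, None] * (y[None, :, :] - mid[:, :, None])
        logit += (np.log(pi) - np.log1p(-pi))[:, :, None]
        with np.errstate(over="ignore"):
            p_on = 1.0 / (1.0 + np.exp(-logit))
        z = rng.random((c, g, n)) < p_on  # (c, g, n) bool

        n1 = z.sum(axis=2, dtype=np.float64)
        n0 = n - n1
        s1 = np.einsum("cgn,gn->cg", z, y, optimize=True)
        s0 = ysum[None, :] - s1

        # --- component means (conjugate) -----------------------------------
        prec0 = n0 * inv_var + prior_prec
        prec1 = n1 * inv_var + prior_prec
        mu_off = (s0 * inv_var + prior_term) / prec0 + rng.standard_normal((c, g)) / np.sqrt(prec0)
        mu_on = (s1 * inv_var + prior_term) / prec1 + rng.standard_normal((c, g)) / np.sqrt(prec1)

        # --- relabel to the ordered representation --------------------------
        swap = mu_off > mu_on
        if swap.any():
            mu_off, mu_on = np.where(swap, mu_on, mu_off), np.where(swap, mu_off, mu_on)
            pi = np.where(swap, 1.0 - pi, pi)
            z = z ^ swap[:, :, None]
            n1 = np.where(swap, n0, n1)
            n0 = n - n1
            s1 = np.where(swap, s0, s1)
            s0 = ysum[None, :] - s1

        # --- mixing weight ---------------------------------------------------
        pi = rng.beta(1.0 + n1, 1.0 + n0)
        np.clip(pi, 1e-12, 1.0 - 1e-12, out=pi)

        # --- shared sigma (MH on log sigma) ---------------------------------
        # SSE = sum_off (y - mu_off)^2 + sum_on (y - mu_on)^2, from sufficient stats
        sse = (
            yss[None, :]
            - 2.0 * (mu_off * s0 + mu_on * s1)
            + n0 * mu_off**2
            + n1 * mu_on**2
        )
        sse = np.maximum(sse, 0.0)
        ls = np.log(sigma)
        inv_ss2 = 1.0 / (2.0 * config.sigma_scale**2)
        for _ in range(config.mh_substeps):
            prop = ls + config.prop_scale * rng.standard_normal((c, g))
            s_new = np.exp(prop)
            s_old = np.exp(ls)
            lp_new = (1.0 - n) * prop - sse / (2.0 * s_new * s_new) - s_new * s_new * inv_ss2
            lp_old = (1.0 - n) * ls - sse / (2.0 * s_old * s_old) - s_old * s_old * inv_ss2
            accept = (np.log(rng.random((c, g))) < lp_new - lp_old) & (s_new > config.sigma_floor)
            ls = np.where(accept, prop, ls)
            n_acc += int(accept.sum())
            n_prop += accept.size
        sigma = np.exp(ls)

        if t >= warm:
            k = t - warm
            out["mu_off"][:, k, :] = mu_off
            out["mu_on"][:, k, :] = mu_on
            out["sigma"][:, k, :] = sigma
            out["pi"][:, k, :] = pi

    rhat = {k: _split_rhat(v) for k, v in out.items()}
    params = {k: v.reshape(c * keep, g) for k, v in out.items()}
    return Draws(params, rhat, accept_rate=n_acc / max(n_prop, 1))


def fit_unimodal(
    y: np.ndarray,
    config: SamplerConfig,
    rng: np.random.Generator,
) -> Draws:
    """Sample the single-normal model for all genes at once."""
    y = np.ascontiguousarray(y, dtype=np.float64)
    g, n = y.shape
    if n < 4:
        raise ValueError("need at least 4 observations per gene")
    c = config.chains
    ysum = y.sum(axis=1)
    yss = (y * y).sum(axis=1)

    mu = y.mean(axis=1)[None, :] + 0.1 * rng.standard_normal((c, g))
    sigma = np.maximum(y.std(axis=1), 5 * config.sigma_floor)[None, :] * rng.uniform(0.5, 1.0, (c, g))

    prior_prec = 1.0 / (config.mu_scale**2)
    prior_term = config.mu_loc * prior_prec
    warm = config.iters // 2
    keep = config.iters - warm
    out = {k: np.empty((c, keep, g)) for k in ("mu", "sigma")}
    n_acc = 0
    n_prop = 0
    inv_ss2 = 1.0 / (2.0 * config.sigma_scale**2)

    for t in range(config.iters):
        inv_var = 1.0 / (sigma * sigma)
        prec = n * inv_var + prior_prec
        mu = (ysum[None, :] * inv_var + prior_term) / prec + rng.standard_normal((c, g)) / np.sqrt(prec)

        sse = yss[None, :] - 2.0 * mu * ysum[None, :] + n * mu * mu
        sse = np.maximum(sse, 0.0)
        ls = np.log(sigma)
        for _ in range(config.mh_substeps):
            prop = ls + config.prop_scale * rng.standard_normal((c, g))
            s_new = np.exp(prop)
            s_old = np.exp(ls)
            lp_new = (1.0 - n) * prop - sse / (2.0 * s_new * s_new) - s_new * s_new * inv_ss2
            lp_old = (1.0 - n) * ls - sse / (2.0 * s_old * s_old) - s_old * s_old * inv_ss2
            accept = (np.log(rng.random((c, g))) < lp_new - lp_old) & (s_new > config.sigma_floor)
            ls = np.where(accept, prop, ls)
            n_acc += int(accept.sum())
            n_prop += accept.size
        sigma = np.exp(ls)

        if t >= warm:
            k = t - warm
            out["mu"][:, k, :] = mu
            out["sigma"][:, k, :] = sigma

    rhat = {k: _split_rhat(v) for k, v in out.items()}
    params = {k: v.reshape(c * keep, g) for k, v in out.items()}
    return Draws(params, rhat, accept_rate=n_acc / max(n_prop, 1))


def _log_normal_pdf(y: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    z = (y - mu) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI


def pointwise_lpd_bimodal(
    draws: Draws, y_test: np.ndarray, gene_block: int = 400
) -> np.ndarray:
    """log(1/S sum_s p(y | theta_s)) per (gene, held-out point).

    ``y_test`` is (genes, m); returns (genes, m).
    """
    y_test = np.asarray(y_test, dtype=np.float64)
    g, m = y_test.shape
    s = draws.n_draws
    out = np.empty((g, m))
    p = draws.params
    for lo in range(0, g, gene_block):
        hi = min(lo + gene_block, g)
        mu_off = p["mu_off"][:, lo:hi, None]
        mu_on = p["mu_on"][:, lo:hi, None]
        sigma = p["sigma"][:, lo:hi, None]
        pi = p["pi"][:, lo:hi, None]
        yb = y_test[None, lo:hi, :]
        lp_on = np.log(pi) + _log_normal_pdf(yb, mu_on, sigma)
        lp_off = np.log1p(-pi) + _log_normal_pdf(yb, mu_off, sigma)
        lp = np.logaddexp(lp_on, lp_off)  # (s, block, m)
        out[lo:hi] = logsumexp(lp, axis=0) - np.log(s)
    return out


def pointwise_lpd_unimodal(
    draws: Draws, y_test: np.ndarray, gene_block: int = 400
) -> np.ndarray:
    y_test = np.asarray(y_test, dtype=np.float64)
    g, m = y_test.shape
    s = draws.n_draws
    out = np.empty((g, m))
    p = draws.params
    for lo in range(0, g, gene_block):
        hi = min(lo + gene_block, g)
        mu = p["mu"][:, lo:hi, None]
        sigma = p["sigma"][:, lo:hi, None]
        lp = _log_normal_pdf(y_test[None, lo:hi, :], mu, sigma)
        out[lo:hi] = logsumexp(lp, axis=0) - np.log(s)
    return out
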