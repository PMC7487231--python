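"""Bayesian stable-isotope mixing model (SIAR model class).

A consumer's blood value for element *j* is modelled as a Gaussian
mixture of K trophic-discrimination-corrected sources:

    x_ij ~ Normal( Σ_k p_k (μ_jk + λ_jk),
                   Σ_k p_k² (ω_jk² + τ_jk²) + σ_j² )

with diet proportions ``p`` on the simplex under a flat Dirichlet(1,…,1)
prior, source means/SDs (μ, ω), TDF means/SDs (λ, τ) and a per-element
residual scale σ_j with a weakly informative half-Normal(0, 5 ‰) prior.
Consumers are modelled per species (no individual random effects).

The posterior is sampled by random-walk Metropolis on additive-log-ratio
(ALR) transformed proportions and log residual scales, with the ALR
Jacobian Σ_k log p_k included so the prior on ``p`` is exactly
Dirichlet.  Several independent chains are run for split-R̂ convergence
diagnostics; step sizes adapt toward a 23% acceptance rate during
burn-in only, so the retained draws come from a fixed kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ELEMENTS,
    AnalysisConfig,
    IsotopeRecord,
    SourceGroup,
    TrophicDiscrimination,
    child_rng,
)

log = logging.getLogger("trophicniche")

HALF_NORMAL_SCALE = 5.0  # prior scale of sigma_j, in per-mil
RHAT_WARN = 1.1


def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """Delta notation (‰): the sample's isotope ratio relative to an
    international standard (VPDB for C, atmospheric air for N)."""
    if r_standard <= 0:
        raise ValueError("standard ratio must be positive")
    return (r_sample / r_standard - 1.0) * 1000.0


def correct_sources(
    sources: Iterable[SourceGroup], tdf: TrophicDiscrimination
) -> list[SourceGroup]:
    """Shift source means by the TDF and add TDF variance in quadrature."""
    out = []
    for s in sources:
        out.append(
            replace(
                s,
                mean={el: s.mean[el] + tdf.mean[el] for el in ELEMENTS},
                sd={
                    el: float(np.hypot(s.sd[el], tdf.sd[el])) for el in ELEMENTS
                },
            )
        )
    return out


def pool_source_specimens(
    records: Iterable[IsotopeRecord], guild_of: dict[str, str] | None = None
) -> list[SourceGroup]:
    """Summarise raw source specimens into per-group mean ± SD.

    Grouping itself (which specimens belong together) is an input
    decision carried by ``IsotopeRecord.group``.
    """
    by_group: dict[str, list[IsotopeRecord]] = {}
    for r in records:
        by_group.setdefault(r.group, []).append(r)
    sources = []
    for name in sorted(by_group):
        recs = by_group[name]
        c = np.array([r.d13c for r in recs])
        n = np.array([r.d15n for r in recs])
        sources.append(
            SourceGroup(
                name=name,
                guild=(guild_of or {}).get(name, name),
                mean={"d13c": float(c.mean()), "d15n": float(n.mean())},
                sd={
                    "d13c": float(c.std(ddof=1)) if c.size > 1 else 0.0,
                    "d15n": float(n.std(ddof=1)) if n.size > 1 else 0.0,
                },
                n_specimens=len(recs),
            )
        )
    return sources


@dataclass
class MixingPosterior:
    """MCMC draws of diet proportions and residual scales for one species.

    ``p`` has shape (chains, draws, K) and lies on the simplex draw by
    draw; ``sigma`` has shape (chains, draws, 2).  ``rhat`` is the
    split-R̂ per source proportion.
    """

    species: str
    sources: tuple[str, ...]
    p: np.ndarray
    sigma: np.ndarray
    acceptance: float
    rhat: np.ndarray
    converged: bool

    @property
    def draws(self) -> np.ndarray:
        """All retained proportion draws pooled over chains, (N, K)."""
        return self.p.reshape(-1, self.p.shape[-1])

    def mean(self) -> pd.Series:
        return pd.Series(self.draws.mean(axis=0), index=list(self.sources))


def _alr_inverse(z: np.ndarray) -> np.ndarray:
    """Map ALR coordinates (…, K−1) to simplex points (…, K)."""
    z = np.atleast_2d(z)
    m = np.maximum(z.max(axis=-1, keepdims=True), 0.0)
    e = np.exp(z - m)
    base = np.exp(-m)  # the reference (K-th) component
    denom = base + e.sum(axis=-1, keepdims=True)
    return np.concatenate([e / denom, base / denom], axis=-1)


def split_rhat(x: np.ndarray) -> float:
    """Gelman–Rubin split-R̂ for one scalar parameter, x of shape
    (chains, draws)."""
    c, n = x.shape
    half = n // 2
    if half < 2:
        return float("nan")
    chains = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    m, n2 = chains.shape
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n2 * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_hat = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_hat / w))


class SourceMixingModel:
    """Fits the mixing model for one consumer species.

    Parameters
    ----------
    sources:
        TDF-corrected source groups (see :func:`correct_sources`).
    config:
        MCMC settings and the run seed.
    """

    def __init__(self, sources: Sequence[SourceGroup], config: AnalysisConfig):
        if len(sources) < 2:
            raise ValueError("need at least two sources")
        self.sources = list(sources)
        self.config = config
        self.names = tuple(s.name for s in sources)
        self.mu = np.array([[s.mean[el] for el in ELEMENTS] for s in sources])
        self.omega = np.array([[s.sd[el] for el in ELEMENTS] for s in sources])

    def _log_post(self, z: np.ndarray, logsig: np.ndarray, xbar, ssq, n) -> np.ndarray:
        """Vectorised log posterior for a batch of chains."""
        p = _alr_inverse(z)  # (C, K)
        sig2 = np.exp(2 * logsig)  # (C, 2)
        m = p @ self.mu  # (C, 2)
        v = (p**2) @ (self.omega**2) + sig2  # (C, 2)
        ll = -0.5 * (
            n * np.log(2 * np.pi * v) + (ssq + n * (xbar - m) ** 2) / v
        ).sum(axis=1)
        lp = np.log(p).sum(axis=1)  # ALR Jacobian; Dirichlet(1) is flat
        lp += (-np.exp(2 * logsig) / (2 * HALF_NORMAL_SCALE**2) + logsig).sum(axis=1)
        return ll + lp

    def fit(self, consumers: Sequence[IsotopeRecord], species: str = "") -> MixingPosterior:
        """Sample the posterior for one species' consumer records."""
        cfg = self.config
        x = np.array([[r.d13c, r.d15n] for r in consumers], float)
        if x.shape[0] < 2:
            raise ValueError("need at least two consumers")
        k = len(self.sources)
        if k < x.shape[1] + 1:
            log.info("system is over-determined (K=%d sources, %d elements)",
                     k, x.shape[1])
        n = x.shape[0]
        xbar = x.mean(axis=0)
        ssq = ((x - xbar) ** 2).sum(axis=0)

        rng = child_rng(cfg.rng_seed, f"mixing:{species or 'consumer'}")
        c = cfg.mcmc_chains
        n_iter = cfg.mcmc_iterations
        burn = int(round(cfg.mcmc_burn_frac * n_iter))
        dim = (k - 1) + 2

        theta = np.concatenate(
            [rng.normal(0, 0.5, size=(c, k - 1)), rng.normal(0, 0.3, size=(c, 2))],
            axis=1,
        )
        lp = self._log_post(theta[:, : k - 1], theta[:, k - 1 :], xbar, ssq, n)
        step = np.full(c, 0.3)
        accepted = np.zeros(c)
        kept_p, kept_sig = [], []
        n_adapt_acc = np.zeros(c)
        # proposal shape: isotropic at first, then the empirical
        # posterior covariance, refreshed a few times during burn-in
        # (adaptive Metropolis) and frozen before sampling so retained
        # draws come from a fixed kernel
        chol = np.eye(dim)
        refresh_at = {burn // 4, burn // 2, (3 * burn) // 4}
        history: list[np.ndarray] = []

        for it in range(n_iter):
            noise = rng.normal(size=(c, dim)) @ chol.T
            prop = theta + noise * step[:, None]
            lp_prop = self._log_post(prop[:, : k - 1], prop[:, k - 1 :], xbar, ssq, n)
            accept = np.log(rng.random(c)) < lp_prop - lp
            theta[accept] = prop[accept]
            lp[accept] = lp_prop[accept]
            if it < burn:
                n_adapt_acc += accept
                if (it + 1) % 50 == 0:
                    rate = n_adapt_acc / 50
                    step *= np.exp((rate - 0.234) * 0.5)
                    n_adapt_acc[:] = 0
                if it % 5 == 0:
                    history.append(theta.copy())
                if it + 1 in refresh_at:
                    pooled = np.concatenate(history[len(history) // 3 :], axis=0)
                    cov = np.cov(pooled, rowvar=False) + 1e-6 * np.eye(dim)
                    chol = np.linalg.cholesky(cov)
                    step = np.full(c, 2.38 / np.sqrt(dim))
            else:
                accepted += accept
                if (it - burn) % cfg.mcmc_thin == 0:
                    kept_p.append(_alr_inverse(theta[:, : k - 1]))
                    kept_sig.append(np.exp(theta[:, k - 1 :]))

        p = np.stack(kept_p, axis=1)  # (C, T, K)
        sigma = np.stack(kept_sig, axis=1)
        acc_rate = float(accepted.sum() / (c * (n_iter - burn)))
        rhat = np.array([split_rhat(p[:, :, j]) for j in range(k)])
        converged = bool(np.all(np.nan_to_num(rhat, nan=1.0) <= RHAT_WARN))
        if not converged:
            log.warning(
                "species %s: split-R̂ above %.2f for sources %s; "
                "treat posterior with caution",
                species, RHAT_WARN,
                [self.names[j] for j in np.where(rhat > RHAT_WARN)[0]],
            )
        return MixingPosterior(
            species=species, sources=self.names, p=p, sigma=sigma,
            acceptance=acc_rate, rhat=rhat, converged=converged,
        )


def fit_mixing_model(
    consumers: Sequence[IsotopeRecord],
    sources: Sequence[SourceGroup],
    config: AnalysisConfig,
    species: str = "",
) -> MixingPosterior:
    """Convenience wrapper: fit one species against corrected sources."""
    return SourceMixingModel(sources, config).fit(consumers, species=species)


def credible_intervals(
    posterior: MixingPosterior, level: float = 0.95
) -> pd.DataFrame:
    """Equal-tailed credible intervals per source, with midpoint and
    posterior mean columns.

    Midpoints are reported because interaction networks downstream weight
    cells by the CI midpoint; note midpoints need not sum to one across
    sources (each is a marginal summary of a joint simplex posterior).
    """
    draws = posterior.draws
    if draws.shape[0] < 1000:
        raise ValueError(
            f"only {draws.shape[0]} retained draws; run longer chains "
            "(need >= 1000 for stable interval estimates)"
        )
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(draws, alpha, axis=0)
    upper = np.quantile(draws, 1.0 - alpha, axis=0)
    return pd.DataFrame(
        {
            "species": posterior.species,
            "source": list(posterior.sources),
            "lower": lower,
            "upper": upper,
            "midpoint": (lower + upper) / 2.0,
            "mean": draws.mean(axis=0),
        }
    )


def ci_table(
    posteriors: Iterable[MixingPosterior], level: float = 0.95
) -> pd.DataFrame:
    """Stack per-species credible intervals into one long table."""
    return pd.concat(
        [credible_intervals(p, level) for p in posteriors], ignore_index=True
    )
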