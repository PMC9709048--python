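"""Many-to-many Bayesian mixed stock model with size and distance covariates.

Rookery-centric destination probabilities delta[j] (over the sampled mixed
stocks plus an unsampled UNK sink) are combined with the fixed rookery sizes
S and the scaled inverse-distance matrix P into mixed-stock-centric
contributions

    theta[i, j] = S[j] * delta[j, i] * P[i, j] / sum_j' S[j'] * delta[j', i] * P[i, j']

so a rookery's expected share of a mixed stock grows with its nesting output
and shrinks with its effective distance.  Expected mixed-stock haplotype
frequencies are the theta-mixture of rookery frequencies, and both rookery
and mixed-stock samples are multinomial.  Three modes are supported:

``base``
    no distance term (the original many-to-many structure): theta ~ S * delta
``distance_weighted``
    the modified model above, with P inside the normalization
``distance_prior``
    a comparison mode placing Dirichlet(kappa * P[i]) priors directly on
    theta[i] instead of weighting inside the likelihood
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sampler as _sampler
from .data import MSADataset
from .diagnostics import psrf
from .distance import scaled_inverse_distance, uniform_matrix
from .errors import ValidationError

__all__ = [
    "ModelConfig",
    "PosteriorSamples",
    "MSAResult",
    "UNK_LABEL",
    "derive_contributions",
    "expected_mixedstock_freqs",
    "log_likelihood",
    "fit",
    "summarize",
]

UNK_LABEL = "UNK"
MODES = ("base", "distance_weighted", "distance_prior")


@dataclass(frozen=True)
class ModelConfig:
    """Sampler and prior settings for one model fit."""

    mode: str = "distance_weighted"
    n_chains: int = 3
    n_iter: int = 20_000
    n_burnin: int = 10_000
    seed: int = 0
    rookery_freq_prior: float | np.ndarray = 1.0
    destination_prior: float = 1.0
    include_unk: bool = True
    ci_level_report: float = 0.95
    psrf_threshold: float = 1.08
    kappa: float | None = None  # distance_prior concentration; default = n_rookeries
    thin: int = 1

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.n_burnin >= self.n_iter:
            raise ValidationError("n_burnin must be smaller than n_iter")
        if self.n_chains < 1:
            raise ValidationError("n_chains must be >= 1")
        if not 0 < self.ci_level_report < 1:
            raise ValidationError("ci_level_report must lie in (0, 1)")
        if self.thin < 1:
            raise ValidationError("thin must be >= 1")


@dataclass(frozen=True)
class PosteriorSamples:
    """Post-burn-in MCMC draws, indexed (chain, draw, ...).

    ``delta`` is ``None`` in distance_prior mode, which has no rookery-centric
    destination parameter.
    """

    f: np.ndarray  # (C, T, J, H)
    delta: np.ndarray | None  # (C, T, J, M[+1])
    theta: np.ndarray  # (C, T, M, J)
    rookery_labels: tuple
    mixedstock_labels: tuple
    haplotype_labels: tuple
    destination_labels: tuple

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def parameter_array(self, kind: str) -> np.ndarray | None:
        """Draws of one parameter block flattened to (C, T, n_params)."""
        if kind == "theta":
            a = self.theta
        elif kind == "delta":
            if self.delta is None:
                return None
            a = self.delta
        elif kind == "f":
            a = self.f
        else:
            raise ValidationError(f"unknown parameter kind {kind!r}")
        return a.reshape(a.shape[0], a.shape[1], -1)

    def parameter_labels(self, kind: str) -> list:
        if kind == "theta":
            return [f"theta[{i}|{j}]" for i in self.mixedstock_labels for j in self.rookery_labels]
        if kind == "delta":
            if self.delta is None:
                return []
            return [f"delta[{j}|{m}]" for j in self.rookery_labels for m in self.destination_labels]
        if kind == "f":
            return [f"f[{j}|{h}]" for j in self.rookery_labels for h in self.haplotype_labels]
        raise ValidationError(f"unknown parameter kind {kind!r}")

    def pooled(self, kind: str) -> dict:
        """Map label -> 1-D array of draws pooled across chains."""
        arr = self.parameter_array(kind)
        if arr is None:
            return {}
        flat = arr.reshape(-1, arr.shape[-1])
        return dict(zip(self.parameter_labels(kind), flat.T))


@dataclass(frozen=True)
class MSAResult:
    """Posterior summaries, convergence status and run metadata."""

    summary: pd.DataFrame  # label, kind, mean, ci_lo, ci_hi, psrf
    theta_mean: pd.DataFrame  # mixed stock x rookery
    delta_mean: pd.DataFrame | None  # rookery x destination (incl. UNK)
    psrf_max: float
    converged: bool
    metadata: dict = field(default_factory=dict)


def derive_contributions(delta_at_stock, sizes, p_row) -> np.ndarray:
    """Mixed-stock-centric contributions for one mixed stock.

    ``delta_at_stock[j]`` is delta[j, i] for the stock in question.  The
    result is invariant to rescaling ``sizes`` by any positive constant.
    """
    delta_at_stock = np.asarray(delta_at_stock, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    p_row = np.asarray(p_row, dtype=float)
    if not (delta_at_stock.shape == sizes.shape == p_row.shape):
        raise ValidationError("delta, sizes and P row must have equal length")
    num = sizes * delta_at_stock * p_row
    total = num.sum()
    if total <= 0:
        raise ValidationError("degenerate mixed stock: all contribution weights are zero")
    return num / total


def expected_mixedstock_freqs(theta_row, f) -> np.ndarray:
    """Expected haplotype frequencies of a mixed stock: q[h] = sum_j theta[j] f[j, h]."""
    theta_row = np.asarray(theta_row, dtype=float)
    f = np.asarray(f, dtype=float)
    if f.ndim != 2 or f.shape[0] != theta_row.shape[0]:
        raise ValidationError(
            f"frequency matrix shape {f.shape} incompatible with theta length {theta_row.shape}"
        )
    return theta_row @ f


def _weights_and_P(dataset: MSADataset, mode: str) -> tuple[np.ndarray, np.ndarray | None]:
    S = dataset.sizes.sizes
    M = len(dataset.mixedstock_labels)
    if mode == "base":
        return np.broadcast_to(S, (M, len(S))).astype(float), None
    P = scaled_inverse_distance(dataset.distances).P
    return S[None, :] * P, P


def log_likelihood(
    dataset: MSADataset,
    f: np.ndarray,
    delta: np.ndarray | None = None,
    mode: str = "distance_weighted",
    theta: np.ndarray | None = None,
    include_coefficient: bool = False,
) -> float:
    """Multinomial log-likelihood of all count tables at given parameter values.

    Either ``delta`` (base / distance_weighted; shape (J, M[+1])) or ``theta``
    (distance_prior; shape (M, J)) must be supplied.  The multinomial
    coefficient, constant in the parameters, is excluded by default.  Returns
    ``-inf`` when a positive count meets a zero expected frequency.
    """
    X = dataset.rookery_counts.counts
    Y = dataset.mixedstock_counts.counts
    f = np.asarray(f, dtype=float)
    if f.shape != X.shape:
        raise ValidationError(f"f shape {f.shape} does not match rookery counts {X.shape}")
    if theta is None:
        if delta is None:
            raise ValidationError("provide delta (base/distance_weighted) or theta (distance_prior)")
        W, _ = _weights_and_P(dataset, mode if mode != "distance_prior" else "base")
        delta = np.asarray(delta, dtype=float)
        M = Y.shape[0]
        theta = np.vstack(
            [derive_contributions(delta[:, i], W[i], np.ones(W.shape[1])) for i in range(M)]
        )
    else:
        theta = np.asarray(theta, dtype=float)
    q = theta @ f

    def kernel(counts, probs):
        with np.errstate(divide="ignore"):
            logp = np.log(probs)
        mask = counts > 0
        if np.any(np.isneginf(logp[mask])):
            return -np.inf
        return float((counts[mask] * logp[mask]).sum())

    ll = kernel(X, f) + kernel(Y, q)
    if include_coefficient and np.isfinite(ll):
        from scipy.special import gammaln

        for counts in (X, Y):
            n = counts.sum(axis=1)
            ll += float((gammaln(n + 1) - gammaln(counts + 1).sum(axis=1)).sum())
    return ll


def _quantile(draws: np.ndarray, q, axis=None) -> np.ndarray:
    # Median-unbiased sample quantiles (Hyndman & Fan type 8).
    return np.quantile(draws, q, axis=axis, method="median_unbiased")


def summarize(samples: PosteriorSamples, ci_level: float = 0.95) -> MSAResult:
    """Per-parameter posterior mean, equal-tailed CI and PSRF tables."""
    if samples.n_draws == 0:
        raise ValidationError("no post-burn-in draws to summarize")
    if not 0 < ci_level < 1:
        raise ValidationError("ci_level must lie in (0, 1)")
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    rows = []
    contrib_psrf = []
    for kind in ("theta", "delta", "f"):
        arr = samples.parameter_array(kind)
        if arr is None:
            continue
        labels = samples.parameter_labels(kind)
        pooled = arr.reshape(-1, arr.shape[-1])
        means = pooled.mean(axis=0)
        lo = np.atleast_1d(_quantile(pooled, lo_q, axis=0))
        hi = np.atleast_1d(_quantile(pooled, hi_q, axis=0))
        if samples.n_chains >= 2:
            r = np.atleast_1d(psrf(arr))
        else:
            r = np.full(len(labels), np.nan)
        if kind in ("theta", "delta"):
            contrib_psrf.append(r)
        for k, lab in enumerate(labels):
            rows.append((lab, kind, means[k], lo[k], hi[k], r[k]))
    summary = pd.DataFrame(rows, columns=["parameter", "kind", "mean", "ci_lo", "ci_hi", "psrf"])

    M, J = len(samples.mixedstock_labels), len(samples.rookery_labels)
    theta_mean = pd.DataFrame(
        samples.theta.reshape(-1, M, J).mean(axis=0),
        index=list(samples.mixedstock_labels),
        columns=list(samples.rookery_labels),
    )
    delta_mean = None
    if samples.delta is not None:
        delta_mean = pd.DataFrame(
            samples.delta.reshape(-1, J, len(samples.destination_labels)).mean(axis=0),
            index=list(samples.rookery_labels),
            columns=list(samples.destination_labels),
        )
    all_contrib = np.concatenate(contrib_psrf) if contrib_psrf else np.array([np.nan])
    psrf_max = float(np.nanmax(all_contrib)) if np.any(np.isfinite(all_contrib)) else float("nan")
    return MSAResult(
        summary=summary,
        theta_mean=theta_mean,
        delta_mean=delta_mean,
        psrf_max=psrf_max,
        converged=bool(psrf_max <= 1.08) if np.isfinite(psrf_max) else False,
        metadata={"ci_level": ci_level},
    )


def fit(dataset: MSADataset, config: ModelConfig) -> tuple[PosteriorSamples, MSAResult]:
    """Run the MCMC sampler for the configured mode and summarize the draws."""
    X = dataset.rookery_counts.counts
    Y = dataset.mixedstock_counts.counts
    J, H = X.shape
    M = Y.shape[0]

    alpha_f = np.asarray(config.rookery_freq_prior, dtype=float)
    if alpha_f.ndim == 0:
        alpha_f = np.full(H, float(alpha_f))
    elif alpha_f.shape != (H,):
        raise ValidationError(f"rookery_freq_prior must be scalar or length {H}")
    if np.any(alpha_f <= 0):
        raise ValidationError("rookery_freq_prior concentrations must be positive")

    if config.mode == "distance_prior":
        P = scaled_inverse_distance(dataset.distances).P
        kappa = float(config.kappa) if config.kappa is not None else float(J)
        draws = _sampler.run_distance_prior(
            X, Y, P, kappa, alpha_f,
            n_chains=config.n_chains, n_iter=config.n_iter,
            n_burnin=config.n_burnin, thin=config.thin, seed=config.seed,
        )
        dest_labels = ()
    else:
        Mp = M + 1 if config.include_unk else M
        alpha_d = np.full(Mp, float(config.destination_prior))
        if config.destination_prior <= 0:
            raise ValidationError("destination_prior must be positive")
        W, _ = _weights_and_P(dataset, config.mode)
        draws = _sampler.run_many_to_many(
            X, Y, W, alpha_f, alpha_d,
            n_chains=config.n_chains, n_iter=config.n_iter,
            n_burnin=config.n_burnin, thin=config.thin, seed=config.seed,
        )
        dest_labels = tuple(dataset.mixedstock_labels) + ((UNK_LABEL,) if config.include_unk else ())

    samples = PosteriorSamples(
        f=draws["f"],
        delta=draws["delta"],
        theta=draws["theta"],
        rookery_labels=dataset.rookery_labels,
        mixedstock_labels=dataset.mixedstock_labels,
        haplotype_labels=dataset.haplotype_universe,
        destination_labels=dest_labels,
    )
    result = summarize(samples, config.ci_level_report)
    converged = result.psrf_max <= config.psrf_threshold if np.isfinite(result.psrf_max) else False
    metadata = {
        "mode": config.mode,
        "seed": config.seed,
        "n_chains": config.n_chains,
        "n_iter": config.n_iter,
        "n_burnin": config.n_burnin,
        "thin": config.thin,
        "ci_level": config.ci_level_report,
        "psrf_threshold": config.psrf_threshold,
        "orphan_haplotypes_removed": list(dataset.orphan_report.removed_haplotypes),
    }
    result = MSAResult(
        summary=result.summary,
        theta_mean=result.theta_mean,
        delta_mean=result.delta_mean,
        psrf_max=result.psrf_max,
        converged=bool(converged),
        metadata=metadata,
    )
    return samples, result
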