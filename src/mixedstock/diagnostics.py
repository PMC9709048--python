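"""Convergence diagnostics and Monte-Carlo error estimates.

The Gelman--Rubin potential scale reduction factor (PSRF) is computed in its
classic univariate form, without the degrees-of-freedom correction:

    W     = mean within-chain variance
    B/n   = variance of chain means
    Vhat  = (n-1)/n * W + B/n
    PSRF  = sqrt(max(Vhat, W) / W)

The ratio is floored at 1: values below 1 are estimation noise, and flooring
makes identical chains report exactly 1.  Effective sample sizes (for
Monte-Carlo standard errors) are delegated to arviz.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

__all__ = ["psrf", "gelman_rubin", "effective_sample_size", "mcse_mean"]


def psrf(chains: np.ndarray) -> np.ndarray:
    """Univariate PSRF along axis 0 = chain, axis 1 = draw.

    ``chains`` has shape (C, T, ...); the result has shape ``chains.shape[2:]``
    (a scalar array for a single parameter).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim < 2 or chains.shape[0] < 2:
        raise ValidationError("PSRF requires at least 2 chains")
    n = chains.shape[1]
    if n < 10:
        raise ValidationError("PSRF requires at least 10 draws per chain")
    W = chains.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = chains.mean(axis=1).var(axis=0, ddof=1)
    Vhat = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(W > 0, np.maximum(Vhat, W) / np.where(W > 0, W, 1.0), np.inf)
    # Degenerate (constant) chains: no between-chain spread either => converged.
    ratio = np.where((W == 0) & (B_over_n == 0), 1.0, ratio)
    return np.sqrt(ratio)


def gelman_rubin(samples) -> dict:
    """Map parameter label -> PSRF for every monitored parameter of a fit.

    ``samples`` is a :class:`mixedstock.model.PosteriorSamples`; monitored
    parameters are theta, delta (when present) and f.
    """
    out = {}
    for kind in ("theta", "delta", "f"):
        arr = samples.parameter_array(kind)
        if arr is None:
            continue
        labels = samples.parameter_labels(kind)
        values = psrf(arr)
        out.update(zip(labels, np.atleast_1d(values)))
    return out


def effective_sample_size(chains: np.ndarray) -> float:
    """Autocorrelation-adjusted effective sample size of one (C, T) parameter."""
    import arviz as az

    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    ds = az.convert_to_dataset(chains)
    return float(az.ess(ds)["x"].values)


def mcse_mean(chains: np.ndarray) -> float:
    """Monte-Carlo standard error of the posterior mean of one (C, T) parameter."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    sd = chains.std(ddof=1)
    ess = max(effective_sample_size(chains), 1.0)
    return sd / np.sqrt(ess)
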