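"""Model comparison via posterior differencing and the Test of Practical Equivalence.

Two fitted models are compared parameter-by-parameter: the pooled posterior
draws are subtracted pairwise (by draw index), an 89% credible interval of
the difference is formed (HDI by default), and the proportion of that
interval falling inside a region of practical equivalence (ROPE, default
-0.05..0.05) decides the outcome:

    proportion = 1  ->  difference negligible ("accepted")
    proportion = 0  ->  difference practically meaningful ("rejected")
    otherwise       ->  undecided

The proportion is geometric interval-length overlap by default; a
draw-counting estimator is available via ``method="draws"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "EquivalenceConfig",
    "ParameterEquivalence",
    "EquivalenceResult",
    "posterior_difference",
    "hdi",
    "equal_tailed_interval",
    "equivalence_test",
]


@dataclass(frozen=True)
class EquivalenceConfig:
    ci_level: float = 0.89
    rope_low: float = -0.05
    rope_high: float = 0.05
    interval_kind: str = "HDI"  # or "equal_tailed"
    method: str = "geometric"  # or "draws"

    def __post_init__(self):
        if not self.rope_low < self.rope_high:
            raise ValidationError("rope_low must be < rope_high")
        if not 0 < self.ci_level < 1:
            raise ValidationError("ci_level must lie in (0, 1)")
        if self.interval_kind not in ("HDI", "equal_tailed"):
            raise ValidationError("interval_kind must be 'HDI' or 'equal_tailed'")
        if self.method not in ("geometric", "draws"):
            raise ValidationError("method must be 'geometric' or 'draws'")


@dataclass(frozen=True)
class ParameterEquivalence:
    proportion_in_rope: float
    decision: str  # accepted | rejected | undecided
    diff_mean: float
    diff_ci: tuple


@dataclass(frozen=True)
class EquivalenceResult:
    parameters: dict  # label -> ParameterEquivalence
    config: EquivalenceConfig

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (lab, r.diff_mean, r.diff_ci[0], r.diff_ci[1], r.proportion_in_rope, r.decision)
            for lab, r in self.parameters.items()
        ]
        return pd.DataFrame(
            rows,
            columns=["parameter", "diff_mean", "ci_lo", "ci_hi", "proportion_in_rope", "decision"],
        )


def posterior_difference(a, b, kind: str = "theta", parameters=None) -> dict:
    """Pairwise draw differences a - b for every shared parameter.

    ``a`` and ``b`` are :class:`~mixedstock.model.PosteriorSamples` (or plain
    label -> draws mappings).  Draws are pooled across chains and truncated to
    the shorter count; parameters present in only one model are skipped with
    a warning.
    """
    draws_a = a if isinstance(a, dict) else a.pooled(kind)
    draws_b = b if isinstance(b, dict) else b.pooled(kind)
    if parameters is not None:
        draws_a = {k: v for k, v in draws_a.items() if k in set(parameters)}
        draws_b = {k: v for k, v in draws_b.items() if k in set(parameters)}
    shared = [k for k in draws_a if k in draws_b]
    skipped = sorted(set(draws_a) ^ set(draws_b))
    if skipped:
        warnings.warn(f"parameters present in only one model were skipped: {skipped}")
    if not shared:
        raise ValidationError("the two models share no parameters to compare")
    out = {}
    for k in shared:
        xa, xb = np.asarray(draws_a[k], float), np.asarray(draws_b[k], float)
        n = min(xa.size, xb.size)
        if xa.size != xb.size:
            warnings.warn(f"{k}: draw counts differ ({xa.size} vs {xb.size}); truncating to {n}")
        out[k] = xa[:n] - xb[:n]
    return out


def hdi(draws, level: float) -> tuple:
    """Highest density interval: the shortest contiguous window of sorted draws
    containing ceil(level * n) of them; ties go to the smallest left endpoint."""
    draws = np.sort(np.asarray(draws, dtype=float))
    n = draws.size
    if n < 10:
        raise ValidationError("HDI requires at least 10 draws")
    if not 0 < level < 1:
        raise ValidationError("level must lie in (0, 1)")
    m = int(np.ceil(level * n))
    m = min(max(m, 1), n)
    widths = draws[m - 1 :] - draws[: n - m + 1]
    k = int(np.argmin(widths))
    return float(draws[k]), float(draws[k + m - 1])


def equal_tailed_interval(draws, level: float) -> tuple:
    draws = np.asarray(draws, dtype=float)
    lo, hi = np.quantile(draws, [(1 - level) / 2, 1 - (1 - level) / 2], method="median_unbiased")
    return float(lo), float(hi)


def _proportion_in_rope(draws, interval, cfg: EquivalenceConfig) -> float:
    lo, hi = interval
    if cfg.method == "geometric":
        width = hi - lo
        if width == 0:
            return 1.0 if cfg.rope_low <= lo <= cfg.rope_high else 0.0
        overlap = max(0.0, min(hi, cfg.rope_high) - max(lo, cfg.rope_low))
        return overlap / width
    inside_ci = (draws >= lo) & (draws <= hi)
    if not np.any(inside_ci):
        return 0.0
    in_rope = (draws >= cfg.rope_low) & (draws <= cfg.rope_high)
    return float((inside_ci & in_rope).sum() / inside_ci.sum())


def equivalence_test(diffs, config: EquivalenceConfig | None = None) -> EquivalenceResult:
    """Test of Practical Equivalence on difference draws.

    ``diffs`` is either a label -> draws mapping (as returned by
    :func:`posterior_difference`) or a single draw vector.
    """
    config = config or EquivalenceConfig()
    if not isinstance(diffs, dict):
        diffs = {"diff": np.asarray(diffs)}
    results = {}
    for label, draws in diffs.items():
        draws = np.asarray(draws, dtype=float)
        if config.interval_kind == "HDI":
            interval = hdi(draws, config.ci_level)
        else:
            interval = equal_tailed_interval(draws, config.ci_level)
        prop = _proportion_in_rope(draws, interval, config)
        if prop >= 1.0 - 1e-12:
            decision = "accepted"
        elif prop <= 1e-12:
            decision = "rejected"
        else:
            decision = "undecided"
        results[label] = ParameterEquivalence(
            proportion_in_rope=float(prop),
            decision=decision,
            diff_mean=float(draws.mean()),
            diff_ci=interval,
        )
    return EquivalenceResult(parameters=results, config=config)
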