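"""End-to-end runs: experiment presets, artifact writing, and run reports.

A "run" is a directory containing ``summary.csv`` (one row per monitored
parameter), ``draws_chain<k>.csv`` (raw post-burn-in draws, one column per
parameter), ``metadata.json`` and ``run.log``.  The six experiment presets
mirror the standard comparison grid: base vs distance-weighted model,
historical vs recent rookery sizes, and old vs new mixed-stock sampling
periods (the sampling-period split is data curation — presets only label
which input files the caller supplies).
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import MSADataset, SiteKind, load_count_table, load_distance_matrix, load_size_table
from .errors import ConvergenceError, ValidationError
from .model import ModelConfig, MSAResult, PosteriorSamples, fit

__all__ = [
    "ExperimentPreset",
    "PRESETS",
    "run_fit",
    "run_experiment",
    "write_run",
    "load_run_draws",
    "report",
]


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    mode: str
    size_period: str  # historical | recent
    dataset_tag: str  # combined | old | new

    def __post_init__(self):
        if self.size_period not in ("historical", "recent"):
            raise ValidationError("size_period must be 'historical' or 'recent'")
        if self.dataset_tag not in ("combined", "old", "new"):
            raise ValidationError("dataset_tag must be 'combined', 'old' or 'new'")


PRESETS = {
    p.name: p
    for p in (
        ExperimentPreset("MSA1", "base", "historical", "combined"),
        ExperimentPreset("MSA2", "distance_weighted", "historical", "combined"),
        ExperimentPreset("MSA3", "distance_weighted", "historical", "combined"),
        ExperimentPreset("MSA4", "distance_weighted", "recent", "combined"),
        ExperimentPreset("MSA5", "distance_weighted", "historical", "old"),
        ExperimentPreset("MSA6", "distance_weighted", "recent", "new"),
    )
}


def load_dataset(
    rookeries_path, mixed_path, sizes_path, distances_path, size_period: str | None = None
) -> MSADataset:
    rook = load_count_table(rookeries_path, SiteKind.ROOKERY)
    mixed = load_count_table(mixed_path, SiteKind.MIXED_STOCK)
    sizes = load_size_table(sizes_path, period=size_period)
    dist = load_distance_matrix(distances_path)
    return MSADataset.assemble(rook, mixed, sizes, dist)


def run_fit(
    dataset: MSADataset,
    config: ModelConfig,
    out_dir,
    *,
    allow_nonconverged: bool = False,
) -> MSAResult:
    """Fit the model, write all run artifacts, enforce the convergence contract."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"mixedstock {__version__} | mode={config.mode} seed={config.seed}"]
    if not dataset.orphan_report.empty:
        log_lines.append(
            "orphan haplotypes removed (absent from all rookeries): "
            + ", ".join(
                f"{h} (n={dataset.orphan_report.removed_counts[h]})"
                for h in dataset.orphan_report.removed_haplotypes
            )
        )
    log_lines.append(
        "scaled inverse-distance matrix computed over the rookeries present in this "
        "run (row-renormalized if any were dropped upstream)"
    )
    t0 = time.time()
    samples, result = fit(dataset, config)
    log_lines.append(f"sampling finished in {time.time() - t0:.1f} s")
    log_lines.append(
        f"max PSRF over contribution parameters = {result.psrf_max:.4f} "
        f"(threshold {config.psrf_threshold}) -> "
        + ("converged" if result.converged else "NOT CONVERGED")
    )
    write_run(out, samples, result, config)
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    if not result.converged and not allow_nonconverged:
        raise ConvergenceError(
            f"max PSRF {result.psrf_max:.4f} exceeds threshold {config.psrf_threshold}"
        )
    return result


def run_experiment(
    preset: str | ExperimentPreset,
    rookeries_path,
    mixed_path,
    sizes_path,
    distances_path,
    out_dir,
    *,
    config: ModelConfig | None = None,
    allow_nonconverged: bool = False,
) -> MSAResult:
    """Resolve a preset to concrete inputs + config and execute the pipeline."""
    if isinstance(preset, str):
        if preset not in PRESETS:
            raise ValidationError(
                f"unknown preset {preset!r}; valid presets: {', '.join(sorted(PRESETS))}"
            )
        preset = PRESETS[preset]
    base = config or ModelConfig()
    cfg = dataclasses.replace(base, mode=preset.mode)
    dataset = load_dataset(
        rookeries_path, mixed_path, sizes_path, distances_path, size_period=preset.size_period
    )
    result = run_fit(dataset, cfg, out_dir, allow_nonconverged=allow_nonconverged)
    meta_path = Path(out_dir) / "metadata.json"
    meta = json.loads(meta_path.read_text())
    meta["preset"] = dataclasses.asdict(preset)
    meta_path.write_text(json.dumps(meta, indent=2))
    return result


def write_run(out_dir, samples: PosteriorSamples, result: MSAResult, config: ModelConfig) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out / "summary.csv", index=False)
    labels = []
    blocks = []
    for kind in ("theta", "delta", "f"):
        arr = samples.parameter_array(kind)
        if arr is None:
            continue
        labels.extend(samples.parameter_labels(kind))
        blocks.append(arr)
    full = np.concatenate(blocks, axis=2)  # (C, T, n_params)
    for c in range(samples.n_chains):
        pd.DataFrame(full[c], columns=labels).to_csv(
            out / f"draws_chain{c}.csv", index=False, float_format="%.6g"
        )
    meta = dict(result.metadata)
    meta.update(
        {
            "psrf_max": result.psrf_max,
            "converged": result.converged,
            "package_version": __version__,
        }
    )
    (out / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_run_draws(run_dir) -> dict:
    """Pooled label -> draws mapping reconstructed from a run directory."""
    run = Path(run_dir)
    chain_files = sorted(run.glob("draws_chain*.csv"))
    if not chain_files:
        raise ValidationError(f"{run} contains no draws_chain*.csv files")
    frames = [pd.read_csv(f) for f in chain_files]
    cols = list(frames[0].columns)
    for f in frames[1:]:
        if list(f.columns) != cols:
            raise ValidationError(f"{run}: chains disagree on parameter columns")
    pooled = pd.concat(frames, axis=0, ignore_index=True)
    return {c: pooled[c].to_numpy() for c in cols}


def report(run_dirs) -> pd.DataFrame:
    """Merge posterior summaries of several runs into one comparison table."""
    run_dirs = [Path(r) for r in run_dirs]
    if not run_dirs:
        raise ValidationError("report needs at least one run directory")
    merged = None
    reference_params = None
    for run in run_dirs:
        summ = pd.read_csv(run / "summary.csv")
        params = set(summ["parameter"])
        if reference_params is None:
            reference_params = params
        elif params != reference_params:
            diff = sorted(params ^ reference_params)
            raise ValidationError(f"runs have incompatible parameter sets; mismatches: {diff}")
        cols = summ[["parameter", "kind", "mean", "ci_lo", "ci_hi"]].copy()
        cols = cols.rename(
            columns={c: f"{c}_{run.name}" for c in ("mean", "ci_lo", "ci_hi")}
        )
        merged = cols if merged is None else merged.merge(cols, on=["parameter", "kind"])
    return merged
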