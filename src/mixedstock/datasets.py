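"""Packaged example data.

``nest_counts`` ships the three-year average annual nest counts of nine
western North Atlantic / Greater Caribbean green turtle rookeries for the
two study periods (historical ~ late 1990s, recent ~ early 2010s).
``synthetic_example`` regenerates the package's standard simulated dataset
(4 rookeries, 2 mixed stocks, 6 haplotypes, 100 samples per site).
"""

from __future__ import annotations

from importlib import resources

from .data import SourceSizeTable, load_size_table
from .simulate import SimulationSpec, simulate_dataset

__all__ = ["nest_counts", "synthetic_example", "SYNTHETIC_EXAMPLE_SEED"]

SYNTHETIC_EXAMPLE_SEED = 20_260_101


def nest_counts(period: str) -> SourceSizeTable:
    """Rookery nest counts for ``period`` ('historical' or 'recent')."""
    ref = resources.files("mixedstock.fixtures") / "table1_nest_counts.csv"
    with resources.as_file(ref) as path:
        return load_size_table(path, period=period)


def synthetic_example(seed: int = SYNTHETIC_EXAMPLE_SEED):
    """The standard synthetic dataset with its ground truth (deterministic per seed)."""
    return simulate_dataset(SimulationSpec(seed=seed))
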