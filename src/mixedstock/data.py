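"""Domain types and CSV ingestion for mixed stock analysis.

The canonical inputs are haplotype *count* tables (sites in rows, haplotype
labels in columns), a source-size table of annual nest counts per rookery,
and an effective-distance matrix (mixed stocks x rookeries, km).  Counts,
not frequencies, are canonical: the likelihood is multinomial and the sample
size carries information, so frequency-style (non-integer) input is rejected
rather than rescaled.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "SiteKind",
    "HaplotypeCountTable",
    "SourceSizeTable",
    "EffectiveDistanceMatrix",
    "OrphanReport",
    "MSADataset",
    "load_count_table",
    "write_count_table",
    "load_size_table",
    "load_distance_matrix",
    "filter_orphan_haplotypes",
    "relative_sizes",
    "size_variation",
]


class SiteKind(str, enum.Enum):
    ROOKERY = "rookery"
    MIXED_STOCK = "mixed_stock"


def _check_unique(labels, what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what} label: {lab!r}")
        seen.add(lab)


@dataclass(frozen=True)
class HaplotypeCountTable:
    """Non-negative integer haplotype counts per site.

    Rows are sites (rookeries or mixed-stock aggregations), columns are
    haplotype labels.  Every site must have at least one sampled individual.
    """

    site_labels: tuple
    haplotype_labels: tuple
    counts: np.ndarray
    site_kind: SiteKind

    def __post_init__(self):
        object.__setattr__(self, "site_labels", tuple(self.site_labels))
        object.__setattr__(self, "haplotype_labels", tuple(self.haplotype_labels))
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape != (len(self.site_labels), len(self.haplotype_labels)):
            raise ValidationError(
                f"counts shape {c.shape} does not match "
                f"{len(self.site_labels)} sites x {len(self.haplotype_labels)} haplotypes"
            )
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(np.equal(np.mod(c, 1), 0)):
                raise ValidationError("counts must be integers (frequency input is not accepted)")
            c = c.astype(np.int64)
        if np.any(c < 0):
            i, h = np.argwhere(c < 0)[0]
            raise ValidationError(
                f"negative count at site {self.site_labels[i]!r}, "
                f"haplotype {self.haplotype_labels[h]!r}"
            )
        _check_unique(self.site_labels, "site")
        _check_unique(self.haplotype_labels, "haplotype")
        if np.any(c.sum(axis=1) < 1):
            i = int(np.argmin(c.sum(axis=1)))
            raise ValidationError(f"site {self.site_labels[i]!r} has no sampled individuals")
        object.__setattr__(self, "counts", c)

    @property
    def n_sites(self) -> int:
        return len(self.site_labels)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_labels)

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.site_labels), columns=list(self.haplotype_labels)
        )

    def restrict_haplotypes(self, labels) -> "HaplotypeCountTable":
        """Return a copy keeping only ``labels`` (in the given order).

        Labels absent from the table become zero columns.
        """
        labels = tuple(labels)
        idx = {h: k for k, h in enumerate(self.haplotype_labels)}
        new = np.zeros((self.n_sites, len(labels)), dtype=np.int64)
        for k, h in enumerate(labels):
            if h in idx:
                new[:, k] = self.counts[:, idx[h]]
        return HaplotypeCountTable(self.site_labels, labels, new, self.site_kind)

    def reorder_sites(self, site_labels) -> "HaplotypeCountTable":
        order = [self.site_labels.index(s) for s in site_labels]
        return HaplotypeCountTable(
            tuple(site_labels), self.haplotype_labels, self.counts[order], self.site_kind
        )


def load_count_table(path, site_kind: SiteKind) -> HaplotypeCountTable:
    """Read a haplotype count CSV (header = haplotype labels, first column = site).

    Blank cells are read as 0.  Non-integer or negative cells raise a
    :class:`ValidationError` naming the offending row and column.
    """
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    sites = [str(s) for s in df.index]
    haps = [str(h) for h in df.columns]
    counts = np.zeros((len(sites), len(haps)), dtype=np.int64)
    for i, site in enumerate(sites):
        for j, hap in enumerate(haps):
            cell = str(df.iat[i, j]).strip()
            if cell == "":
                continue
            try:
                value = int(cell)
            except ValueError:
                raise ValidationError(
                    f"{path}: cell at site {site!r}, haplotype {hap!r} is not an "
                    f"integer count: {cell!r}"
                ) from None
            if value < 0:
                raise ValidationError(
                    f"{path}: negative count at site {site!r}, haplotype {hap!r}: {value}"
                )
            counts[i, j] = value
    return HaplotypeCountTable(tuple(sites), tuple(haps), counts, site_kind)


def write_count_table(table: HaplotypeCountTable, path) -> None:
    table.to_dataframe().to_csv(path, index_label="site")


@dataclass(frozen=True)
class SourceSizeTable:
    """Rookery sizes: three-year average annual nest counts for one period."""

    rookery_labels: tuple
    sizes: np.ndarray
    period_label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "rookery_labels", tuple(self.rookery_labels))
        s = np.asarray(self.sizes, dtype=float)
        if s.ndim != 1 or len(s) != len(self.rookery_labels):
            raise ValidationError("sizes must be a vector matching rookery_labels")
        if len(s) == 0:
            raise ValidationError("empty source-size table")
        if np.any(~np.isfinite(s)) or np.any(s <= 0):
            i = int(np.argmin(s))
            raise ValidationError(f"non-positive size for rookery {self.rookery_labels[i]!r}")
        _check_unique(self.rookery_labels, "rookery")
        object.__setattr__(self, "sizes", s)

    def proportions(self) -> np.ndarray:
        return relative_sizes(self)

    def percentages(self, decimals: int = 2) -> np.ndarray:
        """Relative sizes as percentages, rounded half-even."""
        return np.round(100.0 * self.proportions(), decimals)

    def reorder(self, rookery_labels) -> "SourceSizeTable":
        order = [self.rookery_labels.index(r) for r in rookery_labels]
        return SourceSizeTable(tuple(rookery_labels), self.sizes[order], self.period_label)


def relative_sizes(sizes: SourceSizeTable) -> np.ndarray:
    """Proportion of the total nesting output contributed by each rookery."""
    s = sizes.sizes
    return s / s.sum()


def size_variation(historical: np.ndarray, recent: np.ndarray) -> np.ndarray:
    """Change in relative size between periods, in percentage points.

    Both arguments are proportion vectors (summing to 1) over the same
    rookery ordering; the result is ``recent% - historical%``.
    """
    historical = np.asarray(historical, dtype=float)
    recent = np.asarray(recent, dtype=float)
    if historical.shape != recent.shape:
        raise ValidationError(
            f"period proportion vectors have different lengths: "
            f"{historical.shape} vs {recent.shape}"
        )
    return 100.0 * (recent - historical)


def load_size_table(path, period: str | None = None) -> SourceSizeTable:
    """Read a size CSV with columns ``rookery,period,size``.

    When ``period`` is given, only matching rows are kept (input order
    preserved).
    """
    df = pd.read_csv(path, dtype={"rookery": str, "period": str})
    for col in ("rookery", "period", "size"):
        if col not in df.columns:
            raise ValidationError(f"{path}: size table must have columns rookery,period,size")
    if period is not None:
        df = df[df["period"] == period]
        if df.empty:
            raise ValidationError(f"{path}: no rows for period {period!r}")
    label = period if period is not None else ",".join(dict.fromkeys(df["period"]))
    return SourceSizeTable(tuple(df["rookery"]), df["size"].to_numpy(float), label)


@dataclass(frozen=True)
class EffectiveDistanceMatrix:
    """Effective distances (km) from each mixed stock (rows) to each rookery.

    Distances are measured upstream along plausible ocean-current routes;
    this type only stores and validates them.  Zero or missing entries are
    rejected: a zero distance has no inverse.
    """

    mixed_stock_labels: tuple
    rookery_labels: tuple
    D: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mixed_stock_labels", tuple(self.mixed_stock_labels))
        object.__setattr__(self, "rookery_labels", tuple(self.rookery_labels))
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.mixed_stock_labels), len(self.rookery_labels)):
            raise ValidationError("distance matrix shape does not match labels")
        bad = ~np.isfinite(D) | (D <= 0)
        if np.any(bad):
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid distance at mixed stock {self.mixed_stock_labels[i]!r}, "
                f"rookery {self.rookery_labels[j]!r}: {D[i, j]!r} (must be > 0)"
            )
        _check_unique(self.mixed_stock_labels, "mixed stock")
        _check_unique(self.rookery_labels, "rookery")
        object.__setattr__(self, "D", D)

    def reorder(self, mixed_stock_labels, rookery_labels) -> "EffectiveDistanceMatrix":
        ri = [self.mixed_stock_labels.index(m) for m in mixed_stock_labels]
        ci = [self.rookery_labels.index(r) for r in rookery_labels]
        return EffectiveDistanceMatrix(
            tuple(mixed_stock_labels), tuple(rookery_labels), self.D[np.ix_(ri, ci)]
        )


def load_distance_matrix(path) -> EffectiveDistanceMatrix:
    """Read a distance CSV: rows = mixed stocks, columns = rookeries, km."""
    df = pd.read_csv(path, index_col=0)
    return EffectiveDistanceMatrix(
        tuple(str(s) for s in df.index),
        tuple(str(r) for r in df.columns),
        df.to_numpy(float),
    )


@dataclass(frozen=True)
class OrphanReport:
    """Record of haplotypes removed because no rookery carries them."""

    removed_haplotypes: tuple
    removed_counts: dict  # haplotype -> total individuals removed
    per_site: dict  # site -> {haplotype: count removed}

    @property
    def empty(self) -> bool:
        return len(self.removed_haplotypes) == 0

    def total_removed(self) -> int:
        return int(sum(self.removed_counts.values()))


def filter_orphan_haplotypes(
    mixed: HaplotypeCountTable, rookeries: HaplotypeCountTable
) -> tuple[HaplotypeCountTable, OrphanReport]:
    """Drop mixed-stock haplotypes not yet described in any rookery.

    A haplotype observed only in mixed-stock aggregations is unassignable
    under the model (its source frequency is zero everywhere), so its column
    is removed and the discarded sample counts are reported.  A mixed-stock
    site consisting entirely of such orphans cannot be analysed and raises
    :class:`ValidationError`.
    """
    rookery_present = {
        h for h, tot in zip(rookeries.haplotype_labels, rookeries.column_sums()) if tot > 0
    }
    keep = [h for h in mixed.haplotype_labels if h in rookery_present]
    orphans = [h for h in mixed.haplotype_labels if h not in rookery_present]
    if not orphans:
        return mixed, OrphanReport((), {}, {})

    orphan_idx = [mixed.haplotype_labels.index(h) for h in orphans]
    removed_counts = {
        h: int(mixed.counts[:, k].sum()) for h, k in zip(orphans, orphan_idx)
    }
    removed_counts = {h: c for h, c in removed_counts.items()}
    per_site = {}
    for i, site in enumerate(mixed.site_labels):
        row = {h: int(mixed.counts[i, k]) for h, k in zip(orphans, orphan_idx) if mixed.counts[i, k] > 0}
        if row:
            per_site[site] = row

    keep_idx = [mixed.haplotype_labels.index(h) for h in keep]
    new_counts = mixed.counts[:, keep_idx]
    empty_rows = np.flatnonzero(new_counts.sum(axis=1) == 0)
    if empty_rows.size:
        site = mixed.site_labels[int(empty_rows[0])]
        raise ValidationError(
            f"mixed stock {site!r} is composed entirely of haplotypes absent from "
            f"all rookeries; it cannot be analysed"
        )
    filtered = HaplotypeCountTable(mixed.site_labels, tuple(keep), new_counts, mixed.site_kind)
    return filtered, OrphanReport(tuple(orphans), removed_counts, per_site)


@dataclass(frozen=True)
class MSADataset:
    """Validated bundle of everything one model fit needs.

    The haplotype universe is defined by the rookery table; after orphan
    filtering every mixed-stock haplotype occurs in at least one rookery, and
    the mixed-stock table is re-indexed onto the shared universe.
    """

    rookery_counts: HaplotypeCountTable
    mixedstock_counts: HaplotypeCountTable
    sizes: SourceSizeTable
    distances: EffectiveDistanceMatrix
    haplotype_universe: tuple
    orphan_report: OrphanReport = field(default_factory=lambda: OrphanReport((), {}, {}))

    @property
    def rookery_labels(self) -> tuple:
        return self.rookery_counts.site_labels

    @property
    def mixedstock_labels(self) -> tuple:
        return self.mixedstock_counts.site_labels

    @classmethod
    def assemble(
        cls,
        rookery_counts: HaplotypeCountTable,
        mixedstock_counts: HaplotypeCountTable,
        sizes: SourceSizeTable,
        distances: EffectiveDistanceMatrix,
    ) -> "MSADataset":
        """Align labels, filter orphans and build the shared universe."""
        if rookery_counts.site_kind is not SiteKind.ROOKERY:
            raise ValidationError("rookery_counts must have site_kind=rookery")
        if mixedstock_counts.site_kind is not SiteKind.MIXED_STOCK:
            raise ValidationError("mixedstock_counts must have site_kind=mixed_stock")
        if set(sizes.rookery_labels) != set(rookery_counts.site_labels):
            missing = set(rookery_counts.site_labels) ^ set(sizes.rookery_labels)
            raise ValidationError(f"size table rookeries do not match count table: {sorted(missing)}")
        if set(distances.rookery_labels) != set(rookery_counts.site_labels):
            missing = set(rookery_counts.site_labels) ^ set(distances.rookery_labels)
            raise ValidationError(f"distance matrix rookeries do not match count table: {sorted(missing)}")
        if set(distances.mixed_stock_labels) != set(mixedstock_counts.site_labels):
            missing = set(mixedstock_counts.site_labels) ^ set(distances.mixed_stock_labels)
            raise ValidationError(f"distance matrix mixed stocks do not match count table: {sorted(missing)}")

        sizes = sizes.reorder(rookery_counts.site_labels)
        distances = distances.reorder(mixedstock_counts.site_labels, rookery_counts.site_labels)
        filtered, report = filter_orphan_haplotypes(mixedstock_counts, rookery_counts)
        universe = tuple(
            h for h, tot in zip(rookery_counts.haplotype_labels, rookery_counts.column_sums())
            if tot > 0
        )
        rook = rookery_counts.restrict_haplotypes(universe)
        mix = filtered.restrict_haplotypes(universe)
        return cls(rook, mix, sizes, distances, universe, report)
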