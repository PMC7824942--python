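"""Clonotype calling, unambiguity/clonality filters, and clone-size binning."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from tcrsimnet.io import CellTCR

logger = logging.getLogger(__name__)

PAIRED = "paired"
BETA_ONLY = "beta_only"
WITHIN_SAMPLE = "within_sample"
GLOBAL = "global"


@dataclass
class Clonotype:
    """A unique CDR3 amino-acid key with its member cells.

    In paired mode the key is (cdr3a, cdr3b); in beta-only mode cdr3a is
    ``None`` and the key is cdr3b alone.  ``samples`` and ``groups`` are
    derived from member cells and the metadata used at call time.
    """

    clonotype_id: str
    cdr3a: str | None
    cdr3b: str
    member_cells: list[tuple[str, str]] = field(default_factory=list)
    groups: set[str] = field(default_factory=set)

    @property
    def size(self) -> int:
        return len(self.member_cells)

    @property
    def samples(self) -> set[str]:
        return {sample for sample, _ in self.member_cells}

    @property
    def sample_id(self) -> str | None:
        """The single sample of a within-sample clonotype, else None."""
        s = self.samples
        return next(iter(s)) if len(s) == 1 else None


@dataclass(frozen=True)
class CloneSizeBin:
    label: str
    lower: int
    upper: int | None  # inclusive; None = unbounded

    def contains(self, size: int) -> bool:
        return size >= self.lower and (self.upper is None or size <= self.upper)


DEFAULT_BINS = [
    CloneSizeBin("1", 1, 1),
    CloneSizeBin("2-5", 2, 5),
    CloneSizeBin(">5", 6, None),
]


def filter_unambiguous(cells: list[CellTCR], mode: str = PAIRED) -> list[CellTCR]:
    """Keep cells with unambiguous chain calls.

    Paired mode requires exactly one productive usable alpha AND one beta;
    beta-only mode requires exactly one beta (alpha count is ignored).
    """
    if mode not in (PAIRED, BETA_ONLY):
        raise ValueError(f"unknown mode {mode!r}")
    kept = []
    for cell in cells:
        if len(cell.beta_chains) != 1:
            continue
        if mode == PAIRED and len(cell.alpha_chains) != 1:
            continue
        kept.append(cell)
    logger.info("filter_unambiguous(%s): %d/%d cells retained", mode, len(kept), len(cells))
    return kept


def call_clonotypes(
    cells: list[CellTCR],
    mode: str = PAIRED,
    scope: str = WITHIN_SAMPLE,
    group_by_sample: dict[str, str] | None = None,
) -> list[Clonotype]:
    """Group unambiguous cells into clonotypes by identical CDR3 amino acids.

    The key is (cdr3a, cdr3b) in paired mode, cdr3b in beta-only mode;
    within-sample scope (default) additionally keys on sample_id so one
    clone is one subject's expansion.  Output order follows first
    appearance of each key, so calling is deterministic; the clonotype
    multiset is invariant under permutation of the input.
    """
    if scope not in (WITHIN_SAMPLE, GLOBAL):
        raise ValueError(f"unknown scope {scope!r}")
    group_by_sample = group_by_sample or {}
    buckets: dict[tuple, Clonotype] = {}
    ordered_keys: list[tuple] = []
    for cell in cells:
        cdr3b = cell.beta_chains[0].cdr3_aa
        cdr3a = cell.alpha_chains[0].cdr3_aa if mode == PAIRED else None
        key: tuple = (cdr3a, cdr3b)
        if scope == WITHIN_SAMPLE:
            key = (cell.sample_id,) + key
        if key not in buckets:
            buckets[key] = Clonotype(clonotype_id="", cdr3a=cdr3a, cdr3b=cdr3b)
            ordered_keys.append(key)
        ct = buckets[key]
        ct.member_cells.append((cell.sample_id, cell.barcode))
        if cell.sample_id in group_by_sample:
            ct.groups.add(group_by_sample[cell.sample_id])
    clonotypes = []
    # stable ids ordered by first appearance; re-sorted deterministically
    # so that permuting input cells yields the same labelled multiset
    def sort_key(k):
        return tuple("" if part is None else part for part in k)

    for i, key in enumerate(sorted(ordered_keys, key=sort_key)):
        ct = buckets[key]
        ct.clonotype_id = f"ct{i:05d}"
        clonotypes.append(ct)
    return clonotypes


def filter_clonal(clonotypes: list[Clonotype], min_size: int = 2) -> list[Clonotype]:
    """Retain clonally expanded clonotypes (size >= 2 by default)."""
    kept = [ct for ct in clonotypes if ct.size >= min_size]
    if not kept:
        logger.warning("no clonotypes of size >= %d (all singletons?)", min_size)
    logger.info("filter_clonal: %d/%d clonotypes retained", len(kept), len(clonotypes))
    return kept


def validate_bins(bins: list[CloneSizeBin], max_check: int = 10_000) -> None:
    """Bins must be disjoint and cover [1, inf)."""
    for size in range(1, max_check + 1):
        hits = [b for b in bins if b.contains(size)]
        if len(hits) > 1:
            raise ValueError(f"overlapping bins at size {size}: {[b.label for b in hits]}")
        if not hits:
            raise ValueError(f"no bin covers size {size}")
    if not any(b.upper is None for b in bins):
        raise ValueError("bins must cover [1, inf): need one unbounded bin")


def bin_clone_sizes(
    clonotypes: list[Clonotype], bins: list[CloneSizeBin] | None = None
) -> pd.DataFrame:
    """Assign each clonotype to exactly one clone-size bin.

    Default bins: {1}, {2-5}, {>5}.
    """
    bins = bins if bins is not None else DEFAULT_BINS
    validate_bins(bins)
    rows = []
    for ct in clonotypes:
        label = next(b.label for b in bins if b.contains(ct.size))
        rows.append({"clonotype_id": ct.clonotype_id, "size": ct.size, "bin": label})
    return pd.DataFrame(rows, columns=["clonotype_id", "size", "bin"])


def clonotypes_to_frame(clonotypes: list[Clonotype]) -> pd.DataFrame:
    """Export clonotypes as a table (one row per clonotype)."""
    rows = []
    for ct in clonotypes:
        rows.append(
            {
                "clonotype_id": ct.clonotype_id,
                "cdr3a": ct.cdr3a or "",
                "cdr3b": ct.cdr3b,
                "size": ct.size,
                "sample_id": ";".join(sorted(ct.samples)),
                "diagnosis_group": ";".join(sorted(ct.groups)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["clonotype_id", "cdr3a", "cdr3b", "size", "sample_id", "diagnosis_group"],
    )


def clonotypes_from_frame(df: pd.DataFrame) -> list[Clonotype]:
    """Rebuild minimal Clonotype objects from a clonotype table.

    Member barcodes are not stored in the table; sizes are preserved via
    placeholder member tuples so downstream size-based logic still holds.
    """
    clonotypes = []
    for row in df.itertuples(index=False):
        samples = [s for s in str(row.sample_id).split(";") if s]
        groups = {g for g in str(row.diagnosis_group).split(";") if g}
        size = int(row.size)
        members = [(samples[i % max(len(samples), 1)] if samples else "", f"cell{i}") for i in range(size)]
        cdr3a = str(row.cdr3a) if str(row.cdr3a) else None
        clonotypes.append(
            Clonotype(
                clonotype_id=str(row.clonotype_id),
                cdr3a=cdr3a,
                cdr3b=str(row.cdr3b),
                member_cells=members,
                groups=groups,
            )
        )
    return clonotypes
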