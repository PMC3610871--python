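"""Catalogue of the five antigenic reactive regions of sperm whale myoglobin.

The five experimentally mapped immunoreactive segments (Atassi's classical
antigenic sites) serve as the candidate linear epitopes.  Coordinates are
1-based inclusive on the mature reference protein (no initiator Met), the
classical sperm whale myoglobin numbering.

Windows extracted from an alignment carry the region core plus a
configurable flank on each side; flank residues matter because sequence
differences just outside a linear epitope can still perturb its local
structure and hence antibody binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import Alignment
from .errors import CoordinateError
from .panel import GAP

DEFAULT_FLANK_WIDTH = 3


@dataclass(frozen=True)
class AntigenicRegion:
    """One antigenic reactive region in reference coordinates (1-based, inclusive)."""

    index: int
    core_sequence: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.core_sequence):
            raise ValueError(
                f"region {self.index}: span {self.start}-{self.end} does not match "
                f"core length {len(self.core_sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.core_sequence)


REGION_CATALOG: tuple[AntigenicRegion, ...] = (
    AntigenicRegion(1, "AKVEADVA", 15, 22),
    AntigenicRegion(2, "KASEDLK", 56, 62),
    AntigenicRegion(3, "ATKHKI", 94, 99),
    AntigenicRegion(4, "HVLHSRH", 113, 119),
    AntigenicRegion(5, "KYKELGY", 145, 151),
)


def load_region_catalog() -> tuple[AntigenicRegion, ...]:
    """The five catalogued antigenic reactive regions, in index order."""
    return REGION_CATALOG


def get_region(index: int) -> AntigenicRegion:
    for region in REGION_CATALOG:
        if region.index == index:
            return region
    raise KeyError(f"no antigenic region with index {index}")


def region_catalog_table() -> pd.DataFrame:
    """BED-like 1-based table of the catalogue (region, start, end, core)."""
    return pd.DataFrame.from_records(
        [
            {
                "region": r.index,
                "start": r.start,
                "end": r.end,
                "core_sequence": r.core_sequence,
            }
            for r in REGION_CATALOG
        ]
    )


@dataclass(frozen=True)
class EpitopeWindow:
    """A record's residues over one region's columns plus flanks."""

    region: AntigenicRegion
    core_residues: str
    left_flank: str
    right_flank: str
    source_id: str

    @property
    def window(self) -> str:
        return self.left_flank + self.core_residues + self.right_flank


def region_column_spans(
    msa: Alignment, region: AntigenicRegion, flank_width: int = DEFAULT_FLANK_WIDTH
) -> tuple[list[int], list[int], list[int]]:
    """Alignment columns of a region's flanks and core.

    The core span runs from the column of the region's first reference
    residue to that of its last, inclusive — insertion columns inside the
    span are part of the core.  Flanks are the ``flank_width`` alignment
    columns on each side, truncated at the alignment ends.
    """
    if flank_width < 0:
        raise ValueError("flank_width must be nonnegative")
    ref_cols = msa.reference_columns()
    if region.end > len(ref_cols):
        raise CoordinateError(
            f"region {region.index} ({region.start}-{region.end}) extends past the "
            f"{len(ref_cols)}-residue reference"
        )
    first = ref_cols[region.start - 1]
    last = ref_cols[region.end - 1]
    core = list(range(first, last + 1))
    left = list(range(max(0, first - flank_width), first))
    right = list(range(last + 1, min(msa.length, last + 1 + flank_width)))
    return left, core, right


def window_from_row(
    msa: Alignment,
    gapped_row: str,
    region: AntigenicRegion,
    flank_width: int,
    source_id: str,
) -> EpitopeWindow:
    """Extract a window from any gapped row laid out on this alignment's columns."""
    left, core, right = region_column_spans(msa, region, flank_width)
    return EpitopeWindow(
        region=region,
        core_residues="".join(gapped_row[i] for i in core),
        left_flank="".join(gapped_row[i] for i in left),
        right_flank="".join(gapped_row[i] for i in right),
        source_id=source_id,
    )


def extract_window(
    msa: Alignment,
    record_id: str,
    region: AntigenicRegion,
    flank_width: int = DEFAULT_FLANK_WIDTH,
) -> EpitopeWindow:
    """A record's epitope window over ``region`` (gap columns appear as '-')."""
    try:
        row = msa.row(record_id)
    except KeyError:
        raise ValueError(f"record {record_id!r} not in alignment") from None
    return window_from_row(msa, row, region, flank_width, source_id=record_id)


def consensus_window(
    msa: Alignment,
    panel,
    region: AntigenicRegion,
    flank_width: int = DEFAULT_FLANK_WIDTH,
    group: str = "target",
) -> EpitopeWindow:
    """The group-consensus epitope window (the immunogen template)."""
    from .align import group_consensus

    consensus = group_consensus(msa, group, panel)
    return window_from_row(
        msa, consensus, region, flank_width, source_id=f"consensus:{group}"
    )
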