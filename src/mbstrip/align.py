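"""Alignment and conservation analysis.

Panels of myoglobin sequences are near-equal length, so a *star* multiple
alignment is used: every sequence is globally aligned to a designated
reference row (classically the sperm whale sequence, which fixes the
numbering frame) and the pairwise alignments are merged into one set of
columns.  Conservation statistics — identical-site counts within a group,
informative positions, and the per-column group consensus — are computed
on those columns.

Scoring for the pairwise step is BLOSUM62 with affine gaps (open -10,
extend -1), the conventional default for close protein homologs.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import PanelValidationError
from .panel import GAP, ReferencePanel, VALID_GROUPS

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = -10.0
DEFAULT_GAP_EXTEND = -1.0


@dataclass(frozen=True)
class Alignment:
    """A set of equal-length gapped rows keyed by record id."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise PanelValidationError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise PanelValidationError("alignment row ids must be unique")
        if self.rows:
            length = len(self.rows[0])
            if any(len(r) != length for r in self.rows):
                raise PanelValidationError("all alignment rows must share one length")
        if self.reference_id is not None and self.reference_id not in self.ids:
            raise PanelValidationError(
                f"reference id {self.reference_id!r} not among alignment rows"
            )

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, record_id: str) -> str:
        try:
            return self.rows[self.ids.index(record_id)]
        except ValueError:
            raise KeyError(record_id) from None

    def column(self, index: int) -> tuple[str, ...]:
        return tuple(row[index] for row in self.rows)

    def reference_columns(self) -> tuple[int, ...]:
        """Alignment column index of each (ungapped) reference residue."""
        if self.reference_id is None:
            raise PanelValidationError("alignment has no reference row")
        ref = self.row(self.reference_id)
        return tuple(i for i, c in enumerate(ref) if c != GAP)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Optimal global alignment of two sequences."""

    a_aligned: str
    b_aligned: str
    score: float


@lru_cache(maxsize=4)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    a: str,
    b: str,
    *,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch, affine-gap) alignment of two sequences.

    Traceback is deterministic: the first optimal alignment in Biopython's
    canonical enumeration order is returned.
    """
    if not a or not b:
        raise ValueError("global_align requires two nonempty, gap-free sequences")
    if GAP in a or GAP in b:
        raise ValueError("global_align inputs must be gap-free")
    aligner = _aligner(matrix, gap_open, gap_extend)
    best = aligner.align(a, b)[0]
    return PairwiseAlignment(a_aligned=str(best[0]), b_aligned=str(best[1]), score=best.score)


def _decompose_vs_reference(ref_gapped: str, row_gapped: str, n_ref: int):
    """Split a pairwise alignment into per-reference-residue matches/insertions.

    Returns (match, inserts): ``match[k]`` is the row character aligned to
    reference residue ``k`` and ``inserts[k]`` the row characters inserted
    immediately before reference residue ``k`` (``inserts[n_ref]`` trails).
    """
    match = [GAP] * n_ref
    inserts = [""] * (n_ref + 1)
    k = 0
    for rc, wc in zip(ref_gapped, row_gapped):
        if rc == GAP:
            inserts[k] += wc
        else:
            match[k] = wc
            k += 1
    assert k == n_ref
    return match, inserts


def build_msa(
    panel: ReferencePanel,
    reference_id: str | None = None,
    *,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> Alignment:
    """Star multiple alignment of a panel against a reference row.

    Every non-reference sequence is pairwise-aligned to the reference and
    the alignments are merged on reference coordinates; insertions relative
    to the reference open shared gap columns.  The reference row is gap-free
    whenever no sequence inserts relative to it (always the case for
    equal-length indel-free panels).
    """
    if len(panel) == 0:
        raise PanelValidationError("cannot align an empty panel")
    if reference_id is None:
        reference_id = panel.records[0].id
    try:
        ref_record = panel.get(reference_id)
    except KeyError:
        raise ValueError(f"reference id {reference_id!r} not in panel") from None

    ref = ref_record.sequence.residues
    n_ref = len(ref)

    matches: dict[str, list[str]] = {}
    inserts: dict[str, list[str]] = {}
    for record in panel.records:
        if record.id == reference_id:
            matches[record.id] = list(ref)
            inserts[record.id] = [""] * (n_ref + 1)
            continue
        pw = global_align(
            ref, record.sequence.residues,
            matrix=matrix, gap_open=gap_open, gap_extend=gap_extend,
        )
        matches[record.id], inserts[record.id] = _decompose_vs_reference(
            pw.a_aligned, pw.b_aligned, n_ref
        )

    max_ins = [
        max(len(inserts[rid][k]) for rid in panel.ids) for k in range(n_ref + 1)
    ]

    rows = []
    for rid in panel.ids:
        parts = []
        for k in range(n_ref):
            parts.append(inserts[rid][k].ljust(max_ins[k], GAP))
            parts.append(matches[rid][k])
        parts.append(inserts[rid][n_ref].ljust(max_ins[n_ref], GAP))
        rows.append("".join(parts))

    return Alignment(ids=panel.ids, rows=tuple(rows), reference_id=reference_id)


def _group_rows(msa: Alignment, group: str, panel: ReferencePanel) -> list[str]:
    if group not in VALID_GROUPS:
        raise ValueError(f"unknown group label {group!r}")
    return [msa.row(r.id) for r in panel.records if r.group == group and r.id in msa.ids]


def count_identical_sites(
    msa: Alignment, group: str, panel: ReferencePanel
) -> tuple[int, int]:
    """(identical columns, total columns) within a group.

    A column counts as identical only when every group row carries the same
    non-gap residue; columns where any group row has a gap are conservative
    non-identical calls.  The complement of the identical set is the group's
    informative positions.
    """
    rows = _group_rows(msa, group, panel)
    if len(rows) < 2:
        raise ValueError(
            f"count_identical_sites needs >=2 rows in group {group!r}, got {len(rows)}"
        )
    identical = 0
    for col in zip(*rows):
        first = col[0]
        if first != GAP and all(c == first for c in col):
            identical += 1
    return identical, msa.length


def group_consensus(msa: Alignment, group: str, panel: ReferencePanel) -> str:
    """Per-column modal residue over the group rows.

    Gaps are excluded from the vote unless a column is all-gap (then '-').
    Ties break to the alphabetically smallest modal residue, which makes
    the consensus deterministic.
    """
    rows = _group_rows(msa, group, panel)
    if not rows:
        raise ValueError(f"group {group!r} has no rows in this alignment")
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for c in col:
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        if not counts:
            out.append(GAP)
            continue
        best = max(counts.values())
        out.append(min(c for c, n in counts.items() if n == best))
    return "".join(out)


def consensus_in_reference_frame(
    msa: Alignment, group: str, panel: ReferencePanel
) -> str:
    """Group consensus restricted to reference columns (1-based frame = index+1)."""
    consensus = group_consensus(msa, group, panel)
    return "".join(consensus[i] for i in msa.reference_columns())


def conservation_profile(
    msa: Alignment, group: str, panel: ReferencePanel
) -> pd.DataFrame:
    """Per-column conservation table for one group.

    Columns: ``column`` (1-based alignment column), ``reference_position``
    (1-based reference coordinate or 0 for insertion columns), ``consensus``,
    ``identical`` (all group rows share one non-gap residue), and
    ``frequencies`` (residue:count pairs over non-gap group rows).
    """
    rows = _group_rows(msa, group, panel)
    if not rows:
        raise ValueError(f"group {group!r} has no rows in this alignment")
    consensus = group_consensus(msa, group, panel)

    ref_pos = [0] * msa.length
    if msa.reference_id is not None:
        for pos, col in enumerate(msa.reference_columns(), start=1):
            ref_pos[col] = pos

    records = []
    for i in range(msa.length):
        col = [row[i] for row in rows]
        counts: dict[str, int] = {}
        for c in col:
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        identical = col[0] != GAP and all(c == col[0] for c in col)
        freq = ",".join(f"{c}:{n}" for c, n in sorted(counts.items()))
        records.append(
            {
                "column": i + 1,
                "reference_position": ref_pos[i],
                "consensus": consensus[i],
                "identical": identical,
                "frequencies": freq,
            }
        )
    return pd.DataFrame.from_records(records)


def write_aligned_fasta(msa: Alignment, destination) -> None:
    """Export the MSA as aligned FASTA."""
    from pathlib import Path

    lines = []
    for rid, row in zip(msa.ids, msa.rows):
        lines.append(f">{rid}")
        lines.append(row)
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)
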