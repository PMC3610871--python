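"""Immunizing peptide construction.

A hapten peptide for raising an anti-epitope antibody is built from the
target-group consensus sequence around a chosen antigenic region:

* the N-terminus is extended upstream into consensus residues, but only as
  long as those residues are hydrophobic (nonpolar class) — a hydrophobic
  start stabilizes the peptide in the immunoreaction;
* the region core is extended C-terminally by a fixed number of consensus
  residues (the conserved fragment), then further downstream residues are
  appended until the design length is reached — C-terminal lengthening
  exposes the antigenic region to immunocytes;
* a terminal cysteine is appended for conjugation to a carrier protein
  (e.g. OVA).

All residues come from the group consensus, never from a single species:
the immunogen targets the conserved epitope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .binding import NONPOLAR, class_of
from .errors import DesignError
from .panel import GAP
from .regions import AntigenicRegion


@dataclass(frozen=True)
class PeptideDesignRules:
    """Tunable construction rules (defaults give 16-mers ending in Cys)."""

    design_length: int = 16
    terminal_cys: bool = True
    fragment_extension: int = 2
    max_prefix: int = 3

    def __post_init__(self) -> None:
        if self.design_length < 1 or self.fragment_extension < 0 or self.max_prefix < 0:
            raise ValueError("invalid peptide design rules")


DEFAULT_RULES = PeptideDesignRules()


@dataclass(frozen=True)
class PeptideDesign:
    """A constructed immunizing peptide."""

    region: AntigenicRegion
    sequence: str
    core_span: tuple[int, int]  # 1-based inclusive span of the core within the peptide
    has_terminal_cys: bool

    @property
    def total_length(self) -> int:
        return len(self.sequence)


def _hydrophobic_prefix(consensus: str, core_start_idx: int, max_prefix: int) -> str:
    """Longest run of nonpolar consensus residues immediately upstream of the core."""
    prefix = []
    for offset in range(1, max_prefix + 1):
        idx = core_start_idx - offset
        if idx < 0:
            break
        residue = consensus[idx]
        if residue == GAP or class_of(residue) != NONPOLAR:
            break
        prefix.append(residue)
    return "".join(reversed(prefix))


def design_peptide(
    consensus: str,
    region: AntigenicRegion,
    rules: PeptideDesignRules = DEFAULT_RULES,
) -> PeptideDesign:
    """Build the immunizing peptide for ``region`` from a full-length consensus.

    ``consensus`` is the ungapped target-group consensus in the reference
    frame (1-based coordinates = string index + 1).
    """
    if region.end > len(consensus):
        raise DesignError(
            f"region {region.index} ({region.start}-{region.end}) lies outside the "
            f"{len(consensus)}-residue consensus"
        )
    start_idx = region.start - 1
    end_idx = region.end  # exclusive

    core = consensus[start_idx:end_idx]
    if core != region.core_sequence:
        # The consensus may legitimately deviate from the catalogue core;
        # the design still uses the consensus residues.
        pass

    prefix = _hydrophobic_prefix(consensus, start_idx, rules.max_prefix)
    if not prefix:
        raise DesignError(
            f"region {region.index}: no hydrophobic N-terminal start reachable within "
            f"{rules.max_prefix} upstream residues"
        )

    # the conjugation Cys occupies the last design position; disabling it
    # shortens the peptide rather than back-filling with consensus residues
    body_length = rules.design_length - 1
    needed_downstream = body_length - len(prefix) - len(core)
    if needed_downstream < rules.fragment_extension:
        raise DesignError(
            f"region {region.index}: design_length {rules.design_length} too short for "
            f"prefix + core + fragment extension"
        )
    if end_idx + needed_downstream > len(consensus):
        raise DesignError(
            f"region {region.index}: too close to the consensus C-terminus to reach "
            f"design length {rules.design_length}"
        )
    downstream = consensus[end_idx : end_idx + needed_downstream]

    sequence = prefix + core + downstream + ("C" if rules.terminal_cys else "")
    if GAP in sequence:
        raise DesignError(
            f"region {region.index}: consensus has gap characters inside the peptide span"
        )
    core_start = len(prefix) + 1
    return PeptideDesign(
        region=region,
        sequence=sequence,
        core_span=(core_start, core_start + len(core) - 1),
        has_terminal_cys=rules.terminal_cys,
    )


def peptides_to_fasta(designs, destination) -> None:
    """Write designed peptides as FASTA with metadata headers."""
    lines = []
    for d in designs:
        lines.append(
            f">peptide_region{d.region.index} core_span={d.core_span[0]}-{d.core_span[1]} "
            f"terminal_cys={'yes' if d.has_terminal_cys else 'no'} length={d.total_length}"
        )
        lines.append(d.sequence)
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)
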