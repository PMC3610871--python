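"""Synthetic myoglobin-like panel generator.

Real myoglobin panels have a characteristic structure: ~153-residue
single-chain globins, nearly identical within cetaceans apart from a small
set of informative positions, with between-group differences concentrated
in a few diagnostic epitope positions whose substitutions either preserve
or change the side-chain property class.  The generator reproduces exactly
that structure so every pipeline stage can be exercised without any
sequence download:

* a fixed packaged 153-mer scaffold (classical sperm-whale-type myoglobin
  frame) serves as the target-group consensus;
* *planted regions* overwrite scaffold spans with a target fragment and
  per-group variant fragments (this is how seal-like, artiodactyl-like,
  or avian-like epitope patterns are planted);
* target rows vary at exactly ``n_informative_target_positions`` columns
  outside the planted spans;
* off-target rows additionally mutate at a per-group background rate.

A guard band around each planted span keeps random mutations out of the
epitope windows (core + flank), so planted binding patterns are never
corrupted by background noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import SpecError
from .panel import (
    AMINO_ACIDS,
    OFFTARGET,
    ProteinSequence,
    ReferencePanel,
    SpeciesRecord,
    TARGET,
)
from .binding import PROPERTY_CLASSES

#: Classical sperm-whale-type myoglobin scaffold, 153 residues.  All five
#: antigenic reactive regions sit at their canonical coordinates
#: (AKVEADVA 15-22, KASEDLK 56-62, ATKHKI 94-99, HVLHSRH 113-119,
#: KYKELGY 145-151).
SPERM_WHALE_SCAFFOLD = (
    "VLSEGEWQLVLHVWAKVEADVAGHGQDILIRLFKSHPETLEKFDRFKHLK"
    "TEAEMKASEDLKKHGVTVLTALGAILKKKGHHEAELKPLAQSHATKHKIP"
    "IKYLEFISEAIIHVLHSRHPGDFGADAQGAMNKALELFRKDIAAKYKELG"
    "YQG"
)

#: Cetacean-consensus scaffold: the sperm-whale-type frame with the
#: majority-cetacean residues at positions 66 (N), 121 (A) and 122 (E),
#: which carry the conserved fragments KASEDLKKH (56-64) and HVLHSRHPA
#: (113-121) and the consensus context the immunizing peptides draw from.
CONSENSUS_SCAFFOLD = (
    SPERM_WHALE_SCAFFOLD[:65]
    + "N"
    + SPERM_WHALE_SCAFFOLD[66:120]
    + "AE"
    + SPERM_WHALE_SCAFFOLD[122:]
)

_ALPHABET = sorted(AMINO_ACIDS)


@dataclass(frozen=True)
class PlantedRegion:
    """A span overwritten with a target fragment and per-group variants.

    ``start`` is 1-based on the panel coordinate frame; every variant
    fragment must have the target fragment's length (no planted indels).
    """

    start: int
    target_fragment: str
    variants: Mapping[str, str] = field(default_factory=dict)

    @property
    def end(self) -> int:
        return self.start + len(self.target_fragment) - 1

    def __post_init__(self) -> None:
        if self.start < 1 or not self.target_fragment:
            raise SpecError("planted region needs start >= 1 and a nonempty fragment")
        for group, fragment in self.variants.items():
            if len(fragment) != len(self.target_fragment):
                raise SpecError(
                    f"variant for group {group!r} must match the target fragment length"
                )


@dataclass(frozen=True)
class OffTargetGroupSpec:
    """One off-target group: name, size, and background mutation behavior."""

    name: str
    n_records: int
    mutation_rate: float = 0.0
    class_constrained: bool = True

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise SpecError(f"group {self.name!r}: n_records must be >= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise SpecError(f"group {self.name!r}: mutation_rate must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Full description of a synthetic labeled panel."""

    length: int = 153
    n_target: int = 18
    offtarget_groups: tuple[OffTargetGroupSpec, ...] = ()
    planted_regions: tuple[PlantedRegion, ...] = ()
    n_informative_target_positions: int = 0
    target_class_constrained: bool = True
    guard_band: int = 3
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SpecError("panel length must be >= 1")
        if self.n_target < 0:
            raise SpecError("n_target must be >= 0")
        if self.guard_band < 0:
            raise SpecError("guard_band must be >= 0")
        spans = []
        for region in self.planted_regions:
            if region.end > self.length:
                raise SpecError(
                    f"planted region {region.start}-{region.end} exceeds length "
                    f"{self.length}"
                )
            spans.append((region.start, region.end))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise SpecError("planted regions must not overlap")
        if self.n_informative_target_positions > len(self._mutable_columns()):
            raise SpecError(
                "n_informative_target_positions exceeds the columns available "
                "outside planted regions and guard bands"
            )

    def _mutable_columns(self) -> list[int]:
        """0-based columns open to random mutation (outside spans + guard)."""
        blocked = set()
        for region in self.planted_regions:
            lo = max(1, region.start - self.guard_band)
            hi = min(self.length, region.end + self.guard_band)
            blocked.update(range(lo - 1, hi))
        return [i for i in range(self.length) if i not in blocked]


def _scaffold(length: int, rng: np.random.Generator) -> str:
    if length == len(CONSENSUS_SCAFFOLD):
        return CONSENSUS_SCAFFOLD
    return "".join(rng.choice(_ALPHABET, size=length))


def _substitute(residue: str, class_constrained: bool, rng: np.random.Generator) -> str:
    """A residue different from ``residue``; same property class if possible."""
    if class_constrained:
        pool = [
            aa
            for aa, cls in sorted(PROPERTY_CLASSES.items())
            if cls == PROPERTY_CLASSES[residue] and aa != residue
        ]
        if pool:
            return str(rng.choice(pool))
    pool = [aa for aa in _ALPHABET if aa != residue]
    return str(rng.choice(pool))


def generate_panel(spec: SyntheticPanelSpec) -> ReferencePanel:
    """Deterministically generate a labeled panel from a spec and its seed."""
    rng = np.random.default_rng(spec.seed)
    base = list(_scaffold(spec.length, rng))

    # target base row: scaffold + target fragments
    target_base = list(base)
    for region in spec.planted_regions:
        target_base[region.start - 1 : region.end] = region.target_fragment

    records: list[SpeciesRecord] = []
    target_rows = [list(target_base) for _ in range(spec.n_target)]

    # exactly n informative columns vary within the target group
    mutable = spec._mutable_columns()
    if spec.n_informative_target_positions and spec.n_target >= 2:
        chosen = rng.choice(
            np.array(mutable), size=spec.n_informative_target_positions, replace=False
        )
        for col in sorted(int(c) for c in chosen):
            row_idx = int(rng.integers(0, spec.n_target))
            target_rows[row_idx][col] = _substitute(
                target_rows[row_idx][col], spec.target_class_constrained, rng
            )

    for i, row in enumerate(target_rows, start=1):
        seq = ProteinSequence(
            id=f"T{i:02d}",
            species=f"synthetic target {i}",
            residues="".join(row),
        )
        records.append(SpeciesRecord(sequence=seq, group=TARGET, taxon_note="synthetic"))

    for group_spec in spec.offtarget_groups:
        group_base = list(base)
        for region in spec.planted_regions:
            fragment = region.variants.get(group_spec.name, region.target_fragment)
            group_base[region.start - 1 : region.end] = fragment
        for i in range(1, group_spec.n_records + 1):
            row = list(group_base)
            if group_spec.mutation_rate > 0:
                hits = rng.random(len(mutable)) < group_spec.mutation_rate
                for col, hit in zip(mutable, hits):
                    if hit:
                        row[col] = _substitute(
                            row[col], group_spec.class_constrained, rng
                        )
            seq = ProteinSequence(
                id=f"{group_spec.name}{i:02d}",
                species=f"synthetic {group_spec.name} {i}",
                residues="".join(row),
            )
            records.append(
                SpeciesRecord(sequence=seq, group=OFFTARGET, taxon_note=group_spec.name)
            )

    return ReferencePanel(records=tuple(records), name=spec.name)


def spec_from_dict(data: Mapping) -> SyntheticPanelSpec:
    """Build a :class:`SyntheticPanelSpec` from a plain (YAML-loaded) mapping."""
    planted = tuple(
        PlantedRegion(
            start=int(p["start"]),
            target_fragment=str(p["target_fragment"]),
            variants={str(k): str(v) for k, v in dict(p.get("variants", {})).items()},
        )
        for p in data.get("planted_regions", ())
    )
    groups = tuple(
        OffTargetGroupSpec(
            name=str(g["name"]),
            n_records=int(g["n_records"]),
            mutation_rate=float(g.get("mutation_rate", 0.0)),
            class_constrained=bool(g.get("class_constrained", True)),
        )
        for g in data.get("offtarget_groups", ())
    )
    return SyntheticPanelSpec(
        length=int(data.get("length", 153)),
        n_target=int(data.get("n_target", 18)),
        offtarget_groups=groups,
        planted_regions=planted,
        n_informative_target_positions=int(
            data.get("n_informative_target_positions", 0)
        ),
        target_class_constrained=bool(data.get("target_class_constrained", True)),
        guard_band=int(data.get("guard_band", 3)),
        seed=int(data.get("seed", 0)),
        name=str(data.get("name", "synthetic")),
    )


def discriminative_spec(
    n_target: int = 6,
    n_per_offtarget: int = 2,
    seed: int = 0,
    n_informative_target_positions: int = 8,
    background_rate: float = 0.02,
) -> SyntheticPanelSpec:
    """A spec planting the canonical two-epitope discriminative pattern.

    Three off-target archetypes mirror the biology the designer must
    separate: an *artiodactyl*-like group that shares epitope 2 but breaks
    epitope 4 with a cross-class substitution, a *pinniped*-like group that
    breaks epitope 2 (one cross-class + two same-class substitutions) but
    keeps epitope 4 up to a same-class swap, and an *avian*-like group that
    breaks both.  Any such panel admits the region-2/region-4 sandwich as a
    perfect design.
    """
    region2_window = CONSENSUS_SCAFFOLD[52:65]  # AEM KASEDLK KHG (positions 53-65)
    region4_window = CONSENSUS_SCAFFOLD[109:122]  # AII HVLHSRH PAE (positions 110-122)

    def edit(fragment: str, start: int, subs: Mapping[int, str]) -> str:
        chars = list(fragment)
        for pos, res in subs.items():
            chars[pos - start] = res
        return "".join(chars)

    planted = (
        PlantedRegion(
            start=53,
            target_fragment=region2_window,
            variants={
                "pinniped": edit(region2_window, 53, {56: "R", 57: "R", 62: "R"}),
                "avian": edit(region2_window, 53, {55: "Q", 62: "R", 64: "Q"}),
            },
        ),
        PlantedRegion(
            start=110,
            target_fragment=region4_window,
            variants={
                "artiodactyl": edit(region4_window, 110, {117: "A", 118: "K"}),
                "pinniped": edit(region4_window, 110, {118: "K"}),
                "avian": edit(region4_window, 110, {113: "Q", 118: "Q"}),
            },
        ),
    )
    groups = tuple(
        OffTargetGroupSpec(name, n_per_offtarget, mutation_rate=background_rate)
        for name in ("artiodactyl", "pinniped", "avian")
    )
    return SyntheticPanelSpec(
        n_target=n_target,
        offtarget_groups=groups,
        planted_regions=planted,
        n_informative_target_positions=n_informative_target_positions,
        seed=seed,
        name="discriminative-synthetic",
    )
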