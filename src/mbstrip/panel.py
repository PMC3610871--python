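"""Labeled protein-sequence panels.

A *panel* is an ordered set of myoglobin (or other single-chain protein)
sequences, each tagged with a species name and a group label — ``target``
for the species the assay must detect (cetaceans) and ``offtarget`` for
everything else.  Optionally each record carries the myoglobin
concentration of the species' muscle (mg per g wet weight), which drives
the predicted strip signal tier, and a sample-state flag (only fresh
muscle is a valid strip input).

Sequences are read from plain FASTA; metadata comes from a YAML config
keyed by FASTA record id.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Union

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaParseError, PanelConfigError, PanelValidationError

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

TARGET = "target"
OFFTARGET = "offtarget"
VALID_GROUPS = (TARGET, OFFTARGET)

FRESH = "fresh"

PathOrStream = Union[str, Path, IO[str]]


@dataclass(frozen=True)
class ProteinSequence:
    """One amino-acid sequence with an id (accession or name) and species."""

    id: str
    species: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise PanelValidationError("sequence id must be nonempty")
        residues = self.residues.upper()
        if not residues:
            raise PanelValidationError(f"record {self.id!r}: empty sequence")
        bad = set(residues) - AMINO_ACIDS - {GAP}
        if bad:
            raise PanelValidationError(
                f"record {self.id!r}: invalid residue characters {sorted(bad)!r}"
            )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SpeciesRecord:
    """A panel member: sequence plus group label and assay metadata."""

    sequence: ProteinSequence
    group: str
    taxon_note: str = ""
    mb_concentration: float | None = None  # mg Mb per g wet muscle
    sample_state: str = FRESH

    def __post_init__(self) -> None:
        if self.group not in VALID_GROUPS:
            raise PanelValidationError(
                f"record {self.sequence.id!r}: group must be one of {VALID_GROUPS}, "
                f"got {self.group!r}"
            )
        if self.mb_concentration is not None and not self.mb_concentration > 0:
            raise PanelValidationError(
                f"record {self.sequence.id!r}: mb_concentration must be > 0"
            )

    @property
    def id(self) -> str:
        return self.sequence.id

    @property
    def species(self) -> str:
        return self.sequence.species


@dataclass(frozen=True)
class ReferencePanel:
    """Ordered collection of :class:`SpeciesRecord` with unique ids."""

    records: tuple[SpeciesRecord, ...]
    name: str = "panel"

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelValidationError(f"duplicate record ids in panel: {dupes!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def get(self, record_id: str) -> SpeciesRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def group_of(self, record_id: str) -> str:
        return self.get(record_id).group

    def subset(self, group: str) -> tuple[SpeciesRecord, ...]:
        if group not in VALID_GROUPS:
            raise ValueError(f"unknown group label {group!r}")
        return tuple(r for r in self.records if r.group == group)

    def validate_for_design(self) -> None:
        """Design operations need at least one record in each group."""
        for group in VALID_GROUPS:
            if not any(r.group == group for r in self.records):
                raise PanelValidationError(
                    f"panel {self.name!r} has no {group!r} records; "
                    "design operations need both groups"
                )


def count_group(panel: ReferencePanel, group: str) -> int:
    """Number of panel records carrying ``group`` (``target``/``offtarget``)."""
    if group not in VALID_GROUPS:
        raise ValueError(f"unknown group label {group!r}; expected one of {VALID_GROUPS}")
    return sum(1 for r in panel.records if r.group == group)


# ---------------------------------------------------------------------------
# Panel configuration (YAML, keyed by FASTA id)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelConfig:
    """Per-record metadata: species, group, optional taxon/concentration/state."""

    entries: Mapping[str, Mapping[str, object]]
    name: str = "panel"

    def __contains__(self, record_id: str) -> bool:
        return record_id in self.entries


def load_panel_config(source: PathOrStream) -> PanelConfig:
    """Read a YAML panel config: ``records: {id: {species, group, ...}}``."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise PanelConfigError(f"panel config not found: {path}")
        text = path.read_text()
    else:
        text = source.read()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise PanelConfigError(f"malformed panel config: {exc}") from exc
    if not isinstance(data, dict) or "records" not in data:
        raise PanelConfigError("panel config must be a mapping with a 'records' key")
    records = data["records"]
    if not isinstance(records, dict):
        raise PanelConfigError("'records' must map record id -> metadata")
    for rid, meta in records.items():
        if not isinstance(meta, dict):
            raise PanelConfigError(f"config entry for {rid!r} must be a mapping")
        for key in ("species", "group"):
            if key not in meta:
                raise PanelConfigError(f"config entry for {rid!r} is missing {key!r}")
    return PanelConfig(entries=records, name=str(data.get("name", "panel")))


def _record_from_config(seq: ProteinSequence, meta: Mapping[str, object]) -> SpeciesRecord:
    conc = meta.get("mb_concentration")
    return SpeciesRecord(
        sequence=seq,
        group=str(meta["group"]),
        taxon_note=str(meta.get("taxon", "")),
        mb_concentration=float(conc) if conc is not None else None,
        sample_state=str(meta.get("sample_state", FRESH)),
    )


def read_fasta_panel(fasta_source: PathOrStream, config: PanelConfig) -> ReferencePanel:
    """Build a :class:`ReferencePanel` from FASTA plus a panel config.

    Record order follows the FASTA; every FASTA id must appear in the
    config (extra config entries are allowed and ignored).
    """
    if isinstance(fasta_source, (str, Path)):
        path = Path(fasta_source)
        if not path.exists():
            raise FastaParseError(f"FASTA file not found: {path}")
        handle: IO[str] = io.StringIO(path.read_text())
    else:
        handle = fasta_source

    try:
        raw = list(SeqIO.parse(handle, "fasta"))
    except ValueError as exc:
        raise FastaParseError(f"malformed FASTA: {exc}") from exc

    if not raw:
        raise FastaParseError("no FASTA records found in input")

    records: list[SpeciesRecord] = []
    seen: set[str] = set()
    for rec in raw:
        if rec.id in seen:
            raise PanelValidationError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        if rec.id not in config:
            raise PanelConfigError(
                f"FASTA record {rec.id!r} has no entry in the panel config"
            )
        meta = config.entries[rec.id]
        if not str(rec.seq):
            raise FastaParseError(f"malformed FASTA: record {rec.id!r} has no sequence")
        seq = ProteinSequence(id=rec.id, species=str(meta["species"]), residues=str(rec.seq))
        records.append(_record_from_config(seq, meta))
    return ReferencePanel(records=tuple(records), name=config.name)


def write_fasta_panel(panel: ReferencePanel, destination: PathOrStream) -> None:
    """Write panel sequences as FASTA (id + species in the header)."""
    seqrecords = [
        SeqRecord(Seq(r.sequence.residues), id=r.id, description=r.species)
        for r in panel.records
    ]
    if isinstance(destination, (str, Path)):
        with open(destination, "w") as fh:
            SeqIO.write(seqrecords, fh, "fasta")
    else:
        SeqIO.write(seqrecords, destination, "fasta")


def panel_to_config(panel: ReferencePanel) -> dict:
    """Panel metadata as a YAML-serializable config mapping (round-trips)."""
    records = {}
    for r in panel.records:
        meta: dict[str, object] = {"species": r.species, "group": r.group}
        if r.taxon_note:
            meta["taxon"] = r.taxon_note
        if r.mb_concentration is not None:
            meta["mb_concentration"] = r.mb_concentration
        if r.sample_state != FRESH:
            meta["sample_state"] = r.sample_state
        records[r.id] = meta
    return {"name": panel.name, "records": records}


def write_panel_config(panel: ReferencePanel, destination: PathOrStream) -> None:
    data = panel_to_config(panel)
    text = yaml.safe_dump(data, sort_keys=False)
    if isinstance(destination, (str, Path)):
        Path(destination).write_text(text)
    else:
        destination.write(text)
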