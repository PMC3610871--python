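"""Packaged panels mimicking the published design and validation studies.

Two panels ship with the package:

* the *reference* panel — 18 cetacean and 9 non-cetacean myoglobin
  records matching the species/accession list of the published alignment
  study (the design input);
* the *validation* panel — the 15 cetacean + 8 non-cetacean muscle-sample
  species on which the strip was validated, with muscle myoglobin
  concentrations where published values exist.

All sequences here are SYNTHETIC stand-ins: a 153-residue cetacean
consensus scaffold carrying the documented conserved fragments at their
true coordinates, with each off-target species given exactly the
epitope-region substitution pattern described for it (seal: one
cross-class Ala->Arg plus two same-class Lys->Arg changes in epitope
region 2 and a same-class Arg->Lys in region 4; cow/goat: one Ser->Ala
class change away from seal in core region 4; chicken vs dog: identical
region-2 cores but different flanks; etc.), plus a few neutral background
substitutions for realism.  They are not the database sequences — fetch
those with ``scripts/fetch_accessions.py`` if you have network access.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .panel import (
    OFFTARGET,
    ProteinSequence,
    ReferencePanel,
    SpeciesRecord,
    TARGET,
)
from .synth import CONSENSUS_SCAFFOLD

_SYNTH = "SYNTHETIC stand-in"


def _sequence(substitutions: Mapping[int, str]) -> str:
    """Consensus scaffold with 1-based position -> residue substitutions."""
    chars = list(CONSENSUS_SCAFFOLD)
    for pos, res in substitutions.items():
        chars[pos - 1] = res
    return "".join(chars)


# Epitope-region substitution patterns shared between the two panels.
_SEAL = {56: "R", 57: "R", 62: "R", 118: "K"}
_ARTIODACTYL_R4 = {117: "A", 118: "K"}  # one class change (S->A) away from seal
_DOG = {62: "R", 65: "A", **_ARTIODACTYL_R4}
_CHICKEN = {55: "Q", 62: "R", 64: "Q", 113: "Q", 118: "Q"}
_OSTRICH = {55: "Q", 62: "R", 64: "Q", 113: "Q", 116: "A"}
_TUNA = {
    17: "D", 57: "N", 60: "G", 96: "S", 115: "D", 118: "A", 148: "Q",
    1: "A", 28: "V", 73: "S", 104: "I", 133: "Q",
}

# (id, species, taxon, group, substitutions) — reference panel, 18 + 9.
_REFERENCE_ROWS = (
    ("P02179", "Balaenoptera acutorostrata (common minke whale)", "Balaenopteridae", TARGET, {74: "G"}),
    ("Q0KIY2", "Balaenoptera edeni (pygmy Bryde's whale)", "Balaenopteridae", TARGET, {35: "G"}),
    ("P02178", "Megaptera novaeangliae (humpback whale)", "Balaenopteridae", TARGET, {}),
    ("P02177", "Eschrichtius robustus (gray whale)", "Eschrichtiidae", TARGET, {45: "N"}),
    ("P02185", "Physeter macrocephalus (sperm whale)", "Physeteridae", TARGET, {66: "V"}),
    ("Q0KIY5", "Kogia breviceps (pygmy sperm whale)", "Kogiidae", TARGET, {66: "V"}),
    ("P02184", "Kogia sima (dwarf sperm whale)", "Kogiidae", TARGET, {66: "V"}),
    ("P68276", "Delphinus delphis (short-beaked common dolphin)", "Delphinidae", TARGET, {}),
    ("P02174", "Globicephala melas (long-finned pilot whale)", "Delphinidae", TARGET, {}),
    ("P02173", "Orcinus orca (killer whale)", "Delphinidae", TARGET, {}),
    ("Q0KIY3", "Peponocephala electra (melon-headed whale)", "Delphinidae", TARGET, {}),
    ("Q0KIY6", "Stenella attenuata (pantropical spotted dolphin)", "Delphinidae", TARGET, {}),
    ("P68279", "Tursiops truncatus (bottlenose dolphin)", "Delphinidae", TARGET, {}),
    ("P68278", "Phocoena phocoena (harbor porpoise)", "Phocoenidae", TARGET, {27: "T"}),
    ("P02181", "Inia geoffrensis (Amazon river dolphin)", "Iniidae", TARGET, {31: "K"}),
    ("Q0KIY9", "Indopacetus pacificus (Longman's beaked whale)", "Ziphiidae", TARGET, {}),
    ("P02183", "Mesoplodon carlhubbsi (Hubbs' beaked whale)", "Ziphiidae", TARGET, {118: "K", 50: "S"}),
    ("P02182", "Ziphius cavirostris (Cuvier's beaked whale)", "Ziphiidae", TARGET, {118: "K"}),
    ("P68080", "Phoca vitulina (harbor seal)", "Phocidae", OFFTARGET, {**_SEAL, 3: "N", 30: "L", 87: "Q"}),
    ("P02192", "Bos taurus (cattle)", "Bovidae", OFFTARGET, {**_ARTIODACTYL_R4, 45: "K", 70: "S"}),
    ("B7U9B5.3", "Capra hircus (goat)", "Bovidae", OFFTARGET, {**_ARTIODACTYL_R4, 45: "K", 129: "S"}),
    ("P68082", "Equus caballus (horse)", "Equidae", OFFTARGET, {**_ARTIODACTYL_R4, 27: "N"}),
    ("P02189", "Sus scrofa (pig)", "Suidae", OFFTARGET, {**_ARTIODACTYL_R4, 34: "T"}),
    ("P63113", "Canis lupus familiaris (dog)", "Canidae", OFFTARGET, {**_DOG, 51: "S"}),
    ("P02197", "Gallus gallus (chicken)", "Phasianidae", OFFTARGET, {**_CHICKEN, 2: "I", 29: "F"}),
    ("P85077", "Struthio camelus (ostrich)", "Struthionidae", OFFTARGET, {**_OSTRICH, 10: "I"}),
    ("P02205", "Thunnus albacares (yellowfin tuna)", "Scombridae", OFFTARGET, _TUNA),
)

# (id, species, taxon, group, substitutions, mb mg/g) — validation panel, 15 + 8.
# Cetacean concentrations sit in the published 20-70 mg/g range; the Omura's
# whale sample came from a stranded newborn (low myoglobin); beef (8), lamb-like
# goat (6), pork (2) and poultry (2) use the published domestic-meat values;
# seal muscle runs about 40 mg/g.
_VALIDATION_ROWS = (
    ("minke_whale", "Balaenoptera acutorostrata (common minke whale)", "Balaenopteridae", TARGET, {74: "G"}, 25.0),
    ("omura_whale", "Balaenoptera omurai (Omura's whale, stranded newborn)", "Balaenopteridae", TARGET, {}, 5.0),
    ("pygmy_sperm_whale", "Kogia breviceps (pygmy sperm whale)", "Kogiidae", TARGET, {66: "V"}, 40.0),
    ("dwarf_sperm_whale", "Kogia sima (dwarf sperm whale)", "Kogiidae", TARGET, {66: "V"}, 55.0),
    ("pilot_whale", "Globicephala macrorhynchus (short-finned pilot whale)", "Delphinidae", TARGET, {}, 45.0),
    ("melon_headed_whale", "Peponocephala electra (melon-headed whale)", "Delphinidae", TARGET, {}, 40.0),
    ("pygmy_killer_whale", "Feresa attenuata (pygmy killer whale)", "Delphinidae", TARGET, {}, 40.0),
    ("spotted_dolphin", "Stenella attenuata (pantropical spotted dolphin)", "Delphinidae", TARGET, {}, 40.0),
    ("bottlenose_truncatus", "Tursiops truncatus (bottlenose dolphin)", "Delphinidae", TARGET, {}, 40.0),
    ("bottlenose_aduncus", "Tursiops aduncus (bottlenose dolphin)", "Delphinidae", TARGET, {}, 40.0),
    ("frasers_dolphin", "Lagenodelphis hosei (Fraser's dolphin)", "Delphinidae", TARGET, {}, 50.0),
    ("humpback_dolphin", "Sousa chinensis (Indo-Pacific humpback dolphin)", "Delphinidae", TARGET, {}, 40.0),
    ("rough_toothed_dolphin", "Steno bredanensis (rough-toothed dolphin)", "Delphinidae", TARGET, {}, 40.0),
    ("rissos_dolphin", "Grampus griseus (Risso's dolphin)", "Delphinidae", TARGET, {}, 40.0),
    ("finless_porpoise", "Neophocaena phocaenoides (finless porpoise)", "Phocoenidae", TARGET, {}, 35.0),
    ("cattle", "Bos taurus (cattle)", "Bovidae", OFFTARGET, {**_ARTIODACTYL_R4, 45: "K", 70: "S"}, 8.0),
    ("goat", "Capra hircus (goat)", "Bovidae", OFFTARGET, {**_ARTIODACTYL_R4, 45: "K", 129: "S"}, 6.0),
    ("pig", "Sus scrofa (pig)", "Suidae", OFFTARGET, {**_ARTIODACTYL_R4, 34: "T"}, 2.0),
    ("dog", "Canis lupus familiaris (dog)", "Canidae", OFFTARGET, {**_DOG, 51: "S"}, None),
    ("rabbit", "Oryctolagus cuniculus (rabbit)", "Leporidae", OFFTARGET, {**_ARTIODACTYL_R4, 47: "R"}, None),
    ("chicken", "Gallus gallus (chicken)", "Phasianidae", OFFTARGET, {**_CHICKEN, 2: "I", 29: "F"}, 2.0),
    ("tuna", "Thunnus albacares (yellowfin tuna)", "Scombridae", OFFTARGET, _TUNA, None),
    ("seal", "Phoca vitulina (harbor seal)", "Phocidae", OFFTARGET, {**_SEAL, 3: "N", 30: "L", 87: "Q"}, 40.0),
)


def _build_reference_panel() -> ReferencePanel:
    records = []
    for rid, species, taxon, group, subs in _REFERENCE_ROWS:
        seq = ProteinSequence(id=rid, species=f"{species} [{_SYNTH}]", residues=_sequence(subs))
        records.append(SpeciesRecord(sequence=seq, group=group, taxon_note=taxon))
    return ReferencePanel(records=tuple(records), name="reference-panel-synthetic")


def _build_validation_panel() -> ReferencePanel:
    records = []
    for rid, species, taxon, group, subs, conc in _VALIDATION_ROWS:
        seq = ProteinSequence(id=rid, species=f"{species} [{_SYNTH}]", residues=_sequence(subs))
        records.append(
            SpeciesRecord(
                sequence=seq, group=group, taxon_note=taxon, mb_concentration=conc
            )
        )
    return ReferencePanel(records=tuple(records), name="validation-panel-synthetic")


@dataclass(frozen=True)
class FixturePanel:
    """The packaged design (reference) and strip-validation panels."""

    reference: ReferencePanel
    validation: ReferencePanel
    reference_id: str  # sperm whale row: the classical numbering frame


def load_paper_fixture() -> FixturePanel:
    """Build the packaged synthetic reference and validation panels."""
    return FixturePanel(
        reference=_build_reference_panel(),
        validation=_build_validation_panel(),
        reference_id="P02185",
    )
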