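# mbstrip

Conservation-driven design of sandwich-immunoassay epitope pairs for
species-discriminating lateral-flow strips, applied to cetacean myoglobin.

## The problem

Cetacean meat is traded and consumed illegally in many regions, and
DNA-based identification is too slow and lab-bound for field inspection.
Muscle myoglobin (Mb) is an attractive immunoassay target: it is a
~153-residue single-chain globin, far more concentrated in diving mammals
(cetaceans 20–70 mg/g wet muscle; seal ~40) than in domestic meats (beef 8,
lamb 6, pork 2, poultry 1–3), and highly conserved within cetaceans.

A sandwich lateral-flow strip uses two monoclonal antibodies: a
gold-conjugated **detect** antibody and an immobilized test-line **capture**
antibody. The test line appears only when the sample antigen binds *both*
(logical AND). If the detect antibody is broad (cetaceans + several
terrestrial mammals) and the capture antibody narrow (cetaceans + seal,
say), then only cetacean Mb satisfies the AND and the strip is
cetacean-specific even though neither antibody is.

`mbstrip` implements the in-silico side of that design as a reusable
pipeline:

1. **Panel** — labeled Mb sequences (`target` = cetacean, `offtarget`
   otherwise) from FASTA + a YAML config, with optional Mb concentrations.
2. **Alignment & conservation** — star alignment to a reference row
   (classically the sperm whale sequence, BLOSUM62, affine gaps −10/−1),
   per-column identical-site counts, informative positions, and the
   target-group consensus.
3. **Epitope catalogue** — the five classical antigenic reactive regions of
   sperm whale Mb: AKVEADVA (15–22), KASEDLK (56–62), ATKHKI (94–99),
   HVLHSRH (113–119), KYKELGY (145–151).
4. **Binding model** — an antibody raised against a consensus epitope
   tolerates substitutions by side-chain property class
   (nonpolar / polar-uncharged / polar-basic / polar-acidic). Per aligned
   column: identity 0, same-class 1, cross-class 3, gap 4; total =
   1.0·core + 0.5·flank penalties; binds iff total ≤ 2.5. A deterministic
   grid calibration can re-fit these against an observed reactivity profile.
5. **Sandwich selection** — enumerate ordered region pairs, keep those
   whose AND-logic is *perfect* (every target positive, every off-target
   negative), pick the largest-margin pair, and assign the broader antibody
   to the detect role.
6. **Peptide construction** — immunizing 16-mers from the consensus:
   hydrophobic N-terminal start (≤3 residues upstream), core + 2-residue
   conserved-fragment extension, consensus fill, terminal Cys for carrier
   (OVA) conjugation.
7. **Assay evaluation** — predicted strip outcomes (control/test line,
   signal tier from Mb concentration) and panel sensitivity/specificity.
8. **Synthetic data** — a seeded generator of Mb-like panels with planted
   conserved fragments, informative positions, and class-annotated
   between-group substitutions, plus packaged reference (18 cetaceans + 9
   others) and validation (15 + 8) panels whose sequences are explicitly
   SYNTHETIC stand-ins carrying the documented epitope substitution
   patterns.

## Worked example

```bash
mbstrip synth --fixture validation -o panel/
mbstrip run-all panel/panel.fasta panel/panel.yaml -o run/
```

prints

```
detect=region2 capture=region4 peptides=MKASEDLKKHGNTVLC,AIIHVLHSRHPAEFGC sensitivity=1.00 specificity=1.00
```

meaning: the selected sandwich uses antigenic region 2 (KASEDLK) for the
broad detect antibody and region 4 (HVLHSRH) for the narrow capture
antibody; the two immunizing peptides constructed from the cetacean
consensus are the general peptide `MKASEDLKKHGNTVLC` and the specific
peptide `AIIHVLHSRHPAEFGC`; and on the 23-species validation panel
(15 cetaceans, 8 others) the predicted strip calls every cetacean positive
and every non-cetacean negative. `run/` holds the alignment
(`msa.fasta`), conservation table, species × region binding matrix, design
report (including *all* perfect pairs), peptides FASTA, per-species strip
calls, and metrics — all plain tab-delimited text or FASTA, byte-identical
across re-runs.

The same library surface is available in Python:

```python
import mbstrip as mb

fx = mb.load_paper_fixture()
msa = mb.build_msa(fx.reference, fx.reference_id)
design = mb.select_sandwich_pair(fx.reference, msa, mb.BindingModelParams())
print(design.detect_region.index, design.capture_region.index)  # 2 4
```

The packaged panels use synthetic stand-in sequences;
`scripts/fetch_accessions.py` downloads the real database entries for users
with network access.

## Layout

```
src/mbstrip/        panel, align, regions, binding, sandwich,
                    peptides, assay, synth, fixtures, pipeline, cli
tests/              pytest suite (unit, property, end-to-end)
scripts/            acceptance.py, fetch_accessions.py
docs/methods.md     model assumptions, parameters, limitations
```
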