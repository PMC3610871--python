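# Methods

## Scope and model

`mbstrip` models the *in-silico* half of designing a sandwich lateral-flow
strip that distinguishes cetacean myoglobin (Mb) from that of all other
species in a panel. Everything wet-lab — immunization, hybridoma work,
blotting, ELISA chemistry, strip lamination — is outside the model; the
package predicts which epitope pair *should* work and what the strip
*should* read, given sequences, a substitution-tolerance model, and muscle
Mb concentrations.

The core abstraction is a labeled **panel**: ordered records of
(sequence, species, group ∈ {target, offtarget}, optional Mb concentration
in mg per g wet muscle, sample state). All design statistics are computed
per group against the **target consensus**.

## Alignment and conservation

Panels of Mb orthologs are nearly equal-length, so a **star alignment**
suffices: each sequence is globally aligned to a designated reference row
and the pairwise alignments are merged on reference coordinates, with
insertions opening shared gap columns. The reference defaults to the first
record; for the packaged reference panel it is the sperm whale row, which
fixes the classical Mb numbering (1-based on the mature chain, no
initiator Met) that the five-region catalogue uses. Pairwise scoring is
BLOSUM62 with affine gaps (open −10, extend −1) via Biopython's
`PairwiseAligner`; the first optimal traceback in its canonical order is
taken, so alignment is deterministic. Tests verify scores against an
independent Gotoh dynamic program.

Conservation within a group:

* a column is **identical** when every group row carries the same non-gap
  residue; any gap makes the column non-identical (conservative choice);
* **informative positions** are exactly the non-identical columns, so
  identical + informative = total columns by construction;
* the **group consensus** is the per-column modal residue over non-gap
  rows, ties broken to the alphabetically smallest residue (deterministic);
  all-gap columns yield `-`.

## Epitope catalogue and windows

The five classical antigenic reactive regions of sperm whale Mb are the
candidate epitopes: AKVEADVA (15–22), KASEDLK (56–62), ATKHKI (94–99),
HVLHSRH (113–119), KYKELGY (145–151). No de-novo epitope scanning is done.
An **epitope window** is a record's residues over a region's alignment
columns plus a flank of `flank_width` columns on each side (default 3:
wide enough to cover the two-residue conserved-fragment extensions of
regions 2 and 4 — KASEDLK→KASEDLKKH, HVLHSRH→HVLHSRHPA — with one spare
column for flank-driven effects such as the chicken-vs-dog difference).
Coordinates always resolve through alignment columns, never raw indices,
so windows survive indels.

## Binding model

A monoclonal raised against a consensus epitope is assumed to tolerate a
species' substitutions in proportion to the side-chain chemistry change.
Residues fall into four property classes — nonpolar {G A V L I M F W P},
polar uncharged {S T C Y N Q}, polar basic {K R H}, polar acidic {D E};
His is assigned to polar basic by standard convention. Per aligned column:

| event        | penalty |
|--------------|---------|
| identity     | 0       |
| same class   | 1       |
| cross class  | 3       |
| any gap      | 4       |

Total = `core_weight`·(core sum) + `flank_weight`·(flank sum), with
defaults 1.0 and 0.5; the antibody **binds** iff total ≤ 2.5
(`binding_threshold`). These defaults encode the qualitative reference
behavior: one same-class core change (e.g. the seal-type Arg→Lys in region
4, penalty 1) binds; one cross-class plus two same-class core changes (the
seal pattern in region 2, penalty 5) does not; two cross-class flank
changes (penalty 3 after weighting) alone abolish binding, which is how
identical-core species (chicken vs dog in region 2) can still differ.
Scores are dimensionless and ordinal — this is a quantified structural
argument, not an affinity predictor.

`calibrate_params` searches a documented deterministic grid (fields in
fixed order, `itertools.product`) for the first parameter point satisfying
a set of must-bind/must-not-bind constraints, and reports infeasibility
(with the violated constraint labels at the least-violating grid point)
rather than raising. The shipped defaults satisfy the packaged reactivity
constraint set; the calibration path exists so users can re-fit against
their own observed profiles.

## Sandwich selection

All ordered (detect, capture) pairs of distinct regions are enumerated in
index order. A pair is **perfect** when every target species binds both
region epitopes (scored against the target consensus window of each
region) and every off-target fails at least one. Among perfect pairs the
selection maximizes a **margin** — per species, the distance to
misclassification: for a predicted positive, the smaller headroom
(threshold − total) of the two regions; for a predicted negative, the
largest excess (total − threshold) among its failing regions (it flips
only when all failing regions recover); the pair margin is the minimum
over species. Ties break to the lowest (detect, capture) index pair.
Roles are then assigned by breadth: the region whose antibody binds more
panel species becomes the detect (conjugate) antibody, the narrower one
the capture (test-line) antibody. The design report lists *all* perfect
pairs, since the chosen one is sufficient rather than provably unique.
When no pair is perfect the result is an explicit no-solution (CLI exit
code 4), not an exception.

## Peptide construction

Immunizing peptides are built from the target consensus only:

1. walk upstream from the region core at most `max_prefix` (3) residues,
   keeping the longest run of nonpolar-class residues — the peptide must
   start hydrophobic (region 2 takes the single Met; region 4 takes
   Ala-Ile-Ile); no such start is a design error;
2. append the core, then `fragment_extension` (2) downstream consensus
   residues (reproducing the conserved 9-mer fragments), then further
   downstream residues up to `design_length − 1` (15);
3. finish with a terminal Cys for carrier-protein conjugation
   (`design_length` 16 total). Disabling the Cys shortens the peptide to
   15 rather than back-filling, so the peptide body is identical either way.

The prefix/extension arithmetic is a reconstruction from the stated design
intent; it reproduces both reference 16-mers from one rule set and is
flagged as a modeling choice, not measured chemistry.

## Strip prediction and metrics

The control line is always positive for a well-formed run. The test line
is the AND of the two binding calls. Signal tier is ordinal, driven by
muscle Mb concentration with thresholds anchored to published
concentrations: **strong** ≥ 20 mg/g (the cetacean lower bound),
**moderate** ≥ 8 (beef), **weak** below; records without a concentration
default to strong when positive. Non-fresh samples (boiled/cured) are
reduced to a validity flag that forces the test line negative — the
underlying protein chemistry is out of scope. Replicate/operator
variability is not modeled; predictions are deterministic. Sensitivity and
specificity are computed with target as the positive class.

## Synthetic data and packaged panels

The generator emulates the structure of real Mb panels: a fixed packaged
153-mer scaffold (classical sperm-whale-type frame, with the
majority-cetacean residues at positions 66/121/122) as the target
consensus; **planted regions** that overwrite spans with per-group variant
fragments; exactly `n_informative_target_positions` randomly placed
single-row substitutions within the target group; and per-group background
substitution rates (optionally class-constrained) for off-targets. A
3-column guard band around planted spans keeps random mutations out of the
planted epitope windows, which is what makes planted-structure recovery an
unconditional property rather than a probabilistic one. One
`numpy.random.default_rng(seed)` instance per call; identical spec + seed
gives byte-identical panels.

The packaged reference (18 cetaceans + 9 others, ids = the database
accessions they stand in for) and validation (15 cetaceans + 8 others,
with Mb concentrations) panels are built from the scaffold with explicit
per-species substitution tables that encode the documented epitope
relationships: seal differs from the cetacean consensus at exactly three
region-2 fragment positions (one cross-class Ala→Arg, two same-class
Lys→Arg at the core's terminal lysines — the latter placement is a
packaged choice, the source does not print the positions) and by one
same-class Arg→Lys in region 4; cow/goat (and the other detect-positive
mammals) carry the seal-type region-4 Lys plus the cross-class Ser→Ala
that separates them from seal by one residue; chicken shares dog's
region-2 core but differs in the flanks; two beaked whales carry the
seal-type region-4 variant (same class, so they remain capture-positive).
Every fixture header is labeled SYNTHETIC; `scripts/fetch_accessions.py`
retrieves the real entries when network access is available. What passing
tests on these panels show is that the *pipeline logic* reproduces the
documented design; they do not re-verify the database sequences
themselves.

The validation panel has 8 non-cetacean species (rat is excluded): the
strip validation set is 23 samples, and the packaged panel follows that
count.

## Numerical and degenerate-input choices

* Consensus ties → alphabetically smallest residue; alignment traceback →
  first optimal path; pair ties → lowest index pair: every pipeline output
  is deterministic and re-runs are byte-identical (no timestamps in
  artifacts).
* Threshold comparisons use plain `<=` on small sums of 0/1/3/4-valued
  penalties scaled by 0.5/1.0 — exactly representable, so no tolerance
  machinery is needed.
* Gap columns in a window score the gap penalty; all-gap consensus columns
  emit `-` and poison any peptide span that touches them (design error).
* Empty groups, single-row groups for identity counts, same-region pairs,
  unknown group labels, and out-of-range regions are argument errors;
  infeasible calibration and no-solution selection are explicit results.

## Problem sizes

The packaged panels are 27 and 23 sequences of 153 residues; property
tests use generated panels of ~12 rows and the full test suite plus the
acceptance script each run in well under a minute on one CPU. These sizes
match the study design (the method is a desk-scale analysis of a
~27-sequence ortholog family, not a genomics-scale screen).

## Known limitations

* The binding model is linear-epitope, additive, and class-based; it has
  no structure, no conformational epitopes, no affinity units, and no
  cross-inhibition between the two antibodies.
* Star alignment assumes near-equal-length orthologs; it is not a general
  progressive MSA and does no iterative refinement.
* Signal tiers are ordinal anchors, not optical physics; the observed
  dilution-dependence of one antibody on minke whale samples is treated as
  a concentration effect, not a sequence effect.
* The packaged fixture encodes the documented substitution patterns, not
  the full real sequences; accession-level verification requires the fetch
  script and network access.
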