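"""Pairwise alignment, star MSA, and conservation statistics."""

import pytest
from hypothesis import given, strategies as st
from Bio.Align import substitution_matrices

import mbstrip as mb
from mbstrip.synth import CONSENSUS_SCAFFOLD

AA = "ACDEFGHIKLMNPQRSTVWY"
_BLOSUM62 = substitution_matrices.load("BLOSUM62")

residues = st.text(alphabet=AA, min_size=1, max_size=30)


def gotoh_score(a: str, b: str, gap_open: float = -10.0, gap_extend: float = -1.0) -> float:
    """Independent affine-gap global alignment DP (score only).

    A gap of length L costs gap_open + (L-1)*gap_extend; end gaps are
    penalized.  Only the BLOSUM62 constants are shared with the package.
    """
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def test_identical_sequences_align_without_gaps():
    result = mb.global_align(CONSENSUS_SCAFFOLD, CONSENSUS_SCAFFOLD)
    assert result.a_aligned == result.b_aligned == CONSENSUS_SCAFFOLD


def test_single_substitution_gives_gapless_alignment_with_152_identities():
    mutant = CONSENSUS_SCAFFOLD[:70] + "W" + CONSENSUS_SCAFFOLD[71:]
    result = mb.global_align(CONSENSUS_SCAFFOLD, mutant)
    assert "-" not in result.a_aligned and "-" not in result.b_aligned
    identities = sum(x == y for x, y in zip(result.a_aligned, result.b_aligned))
    assert identities == 152


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        mb.global_align("", "VLSEG")


@given(a=residues, b=residues)
def test_alignment_score_matches_independent_dp_oracle(a, b):
    assert mb.global_align(a, b).score == pytest.approx(gotoh_score(a, b))


@given(a=residues, b=residues)
def test_alignment_score_is_symmetric(a, b):
    assert mb.global_align(a, b).score == pytest.approx(mb.global_align(b, a).score)


def _panel(rows, groups=None):
    groups = groups or ["target"] * len(rows)
    records = tuple(
        mb.SpeciesRecord(
            sequence=mb.ProteinSequence(id=f"r{i}", species=f"r{i}", residues=row),
            group=group,
        )
        for i, (row, group) in enumerate(zip(rows, groups))
    )
    return mb.ReferencePanel(records=records)


def test_star_msa_of_equal_length_sequences_has_sequence_length_columns():
    panel = _panel([CONSENSUS_SCAFFOLD, CONSENSUS_SCAFFOLD, CONSENSUS_SCAFFOLD])
    msa = mb.build_msa(panel, "r0")
    assert msa.length == 153
    assert all("-" not in row for row in msa.rows)


def test_star_msa_places_single_deletion_as_one_gap_keeping_reference_intact():
    deleted = CONSENSUS_SCAFFOLD[:80] + CONSENSUS_SCAFFOLD[81:]
    panel = _panel([CONSENSUS_SCAFFOLD, deleted])
    msa = mb.build_msa(panel, "r0")
    assert msa.length == 153
    assert msa.row("r0") == CONSENSUS_SCAFFOLD
    assert msa.row("r1").count("-") == 1


def test_star_msa_opens_gap_columns_for_insertions():
    inserted = CONSENSUS_SCAFFOLD[:80] + "GG" + CONSENSUS_SCAFFOLD[80:]
    panel = _panel([CONSENSUS_SCAFFOLD, inserted])
    msa = mb.build_msa(panel, "r0")
    assert msa.length == 155
    assert msa.row("r0").count("-") == 2
    assert msa.row("r1").count("-") == 0
    # removing gaps recovers the input rows
    assert msa.row("r1").replace("-", "") == inserted


def test_missing_reference_is_an_argument_error():
    panel = _panel([CONSENSUS_SCAFFOLD])
    with pytest.raises(ValueError, match="reference"):
        mb.build_msa(panel, "nope")


def naive_identical_count(rows):
    count = 0
    for col in zip(*rows):
        if col[0] != "-" and all(c == col[0] for c in col):
            count += 1
    return count


def test_identical_rows_are_fully_identical():
    panel = _panel([CONSENSUS_SCAFFOLD] * 3)
    msa = mb.build_msa(panel, "r0")
    assert mb.count_identical_sites(msa, "target", panel) == (153, 153)


def test_rows_differing_everywhere_share_no_identical_sites():
    rows = ["AAAA", "CCCC"]
    panel = _panel(rows)
    msa = mb.Alignment(ids=panel.ids, rows=tuple(rows), reference_id="r0")
    assert mb.count_identical_sites(msa, "target", panel) == (0, 4)


def test_single_row_group_rejected_for_identity_count():
    panel = _panel([CONSENSUS_SCAFFOLD, CONSENSUS_SCAFFOLD], ["target", "offtarget"])
    msa = mb.build_msa(panel, "r0")
    with pytest.raises(ValueError, match=">=2"):
        mb.count_identical_sites(msa, "target", panel)


@given(
    data=st.lists(
        st.text(alphabet=AA + "-", min_size=12, max_size=12), min_size=2, max_size=8
    )
)
def test_identical_site_count_matches_naive_column_loop(data):
    panel_rows = tuple(data)
    ids = tuple(f"r{i}" for i in range(len(panel_rows)))
    records = tuple(
        mb.SpeciesRecord(
            sequence=mb.ProteinSequence(id=i, species=i, residues=row.replace("-", "") or "A"),
            group="target",
        )
        for i, row in zip(ids, panel_rows)
    )
    panel = mb.ReferencePanel(records=records)
    msa = mb.Alignment(ids=ids, rows=panel_rows)
    identical, total = mb.count_identical_sites(msa, "target", panel)
    assert total == 12
    assert identical == naive_identical_count(panel_rows)
    # informative positions are exactly the complement of the identical set
    assert identical + (total - identical) == total


def test_consensus_of_single_row_group_is_that_row():
    panel = _panel([CONSENSUS_SCAFFOLD, "A" * 153], ["target", "offtarget"])
    msa = mb.build_msa(panel, "r0")
    assert mb.group_consensus(msa, "target", panel) == CONSENSUS_SCAFFOLD


def test_consensus_tie_breaks_to_alphabetically_smallest_modal_residue():
    rows = ("KA", "RA")
    panel = _panel(list(rows))
    msa = mb.Alignment(ids=panel.ids, rows=rows)
    assert mb.group_consensus(msa, "target", panel) == "KA"


def test_cetacean_consensus_carries_the_conserved_fragments(
    reference_panel, reference_msa
):
    consensus = mb.consensus_in_reference_frame(reference_msa, "target", reference_panel)
    assert consensus[55:64] == "KASEDLKKH"  # positions 56-64
    assert consensus[112:121] == "HVLHSRHPA"  # positions 113-121


def test_conservation_profile_frequencies_sum_to_nongap_rows(
    reference_panel, reference_msa
):
    profile = mb.conservation_profile(reference_msa, "target", reference_panel)
    assert len(profile) == reference_msa.length
    n_target = mb.count_group(reference_panel, "target")
    for freq in profile["frequencies"]:
        total = sum(int(part.split(":")[1]) for part in freq.split(","))
        assert total == n_target  # fixture rows are gap-free
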