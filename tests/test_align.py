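import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from algbarcode.align import (
    Alignment,
    DistanceMatrix,
    center_star_msa,
    dedupe_genotypes,
    distance_matrix,
    global_align,
    nucleotide_diversity,
    p_distance,
    percent_identity,
)
from algbarcode.seqio import SeqRecord

from conftest import random_seq, records

dna = st.text(alphabet="ACGT", min_size=1, max_size=6)


# --- independent oracle: brute-force enumeration of all global alignments ---

def all_alignments(a: str, b: str):
    if not a and not b:
        yield "", ""
        return
    if a:
        for x, y in all_alignments(a[1:], b):
            yield a[0] + x, "-" + y
    if b:
        for x, y in all_alignments(a, b[1:]):
            yield "-" + x, b[0] + y
    if a and b:
        for x, y in all_alignments(a[1:], b[1:]):
            yield a[0] + x, b[0] + y


def brute_force_score(a: str, b: str, match=1, mismatch=-1, gap=-2) -> float:
    def score(x, y):
        total = 0
        for p, q in zip(x, y):
            if "-" in (p, q):
                total += gap
            elif p == q:
                total += match
            else:
                total += mismatch
        return total

    return max(score(x, y) for x, y in all_alignments(a, b))


def test_identical_sequences_align_without_gaps():
    aln = global_align(*records("ACGT", "ACGT"))
    assert [r.sequence for r in aln.records] == ["ACGT", "ACGT"]
    assert aln.score == 4


def test_single_gap_alignment_and_identity_policies():
    aln = global_align(*records("ACGT", "ACT"))
    assert sorted(r.sequence for r in aln.records) == ["AC-T", "ACGT"]
    assert percent_identity(aln) == 100.0  # gap column skipped: 3/3
    assert percent_identity(aln, "all_columns") == 75.0  # 3/4


@given(dna, dna)
def test_alignment_score_matches_exhaustive_enumeration(a, b):
    aln = global_align(*records(a, b))
    assert aln.score == brute_force_score(a, b)


def test_p_distance_basic_cases():
    assert p_distance("ACGT", "ACGT") == 0.0
    assert p_distance("ACGT", "ACGA") == 0.25
    # gap column skipped under pairwise deletion: 0 mismatches over 3 sites
    assert p_distance("AC-T", "ACGT") == 0.0
    # ambiguity codes excluded from compared sites
    assert p_distance("ACNT", "ACGT") == 0.0


def test_p_distance_errors():
    with pytest.raises(ValueError, match="equal length"):
        p_distance("ACGT", "ACG")
    with pytest.raises(ValueError, match="comparable"):
        p_distance("A---", "-CGT")


@given(st.lists(st.text(alphabet="ACGT-N", min_size=8, max_size=8), min_size=2, max_size=5))
def test_p_distance_symmetry_and_range(rows):
    for r1, r2 in itertools.combinations(rows, 2):
        try:
            d = p_distance(r1, r2)
        except ValueError:
            continue
        assert d == p_distance(r2, r1)
        assert 0.0 <= d <= 1.0


def test_identity_and_p_distance_are_complements_on_gapless_pairs(rng):
    for _ in range(20):
        a, b = (random_seq(rng, 30) for _ in range(2))
        aln = Alignment(records=records(a, b))
        assert percent_identity(aln) + 100 * p_distance(a, b) == pytest.approx(100.0)


def test_distance_matrix_equals_elementwise_oracle(rng):
    rows = [random_seq(rng, 40, "ACGT-N") for _ in range(5)]
    recs = records(*rows)
    dm = distance_matrix(recs)
    for i, j in itertools.combinations(range(5), 2):
        assert dm.values[i, j] == pytest.approx(p_distance(rows[i], rows[j]))
        assert dm.values[i, j] == dm.values[j, i]
    assert np.all(np.diag(dm.values) == 0)


def test_distance_matrix_cross_checked_against_skbio(rng):
    """Independent oracle: scikit-bio's hamming-based p-distance on gapless data."""
    from skbio import DistanceMatrix as SkbioDM, DNA
    from skbio.sequence.distance import hamming

    rows = [random_seq(rng, 60) for _ in range(4)]
    dm = distance_matrix(records(*rows))
    sk = SkbioDM.from_iterable([DNA(r) for r in rows], metric=hamming)
    assert np.allclose(dm.values, sk.data)


def test_zero_matrix_for_identical_rows():
    dm = distance_matrix(records("ACGT", "ACGT", "ACGT"))
    assert np.all(dm.values == 0)


def test_row_permutation_permutes_labels_consistently(rng):
    rows = [random_seq(rng, 30) for _ in range(4)]
    recs = records(*rows)
    dm = distance_matrix(recs)
    perm = [2, 0, 3, 1]
    dm_p = distance_matrix([recs[i] for i in perm])
    for a in dm.labels:
        for b in dm.labels:
            assert dm.get(a, b) == pytest.approx(dm_p.get(a, b))


def test_complete_deletion_equals_pairwise_when_gapless(rng):
    rows = [random_seq(rng, 50) for _ in range(4)]
    recs = records(*rows)
    a = distance_matrix(recs, "pairwise_deletion")
    b = distance_matrix(recs, "complete_deletion")
    assert np.allclose(a.values, b.values)
    assert (a.gap_policy, b.gap_policy) == ("pairwise_deletion", "complete_deletion")


def test_complete_deletion_drops_columns_globally():
    # gap in row 2 removes the column for every pair
    recs = records("ACGT", "ACGA", "AC-T")
    full = distance_matrix(recs, "complete_deletion")
    assert full.values[0, 1] == pytest.approx(1 / 3)  # ACT vs ACA after deletion
    pw = distance_matrix(recs, "pairwise_deletion")
    assert pw.values[0, 1] == pytest.approx(0.25)  # all four columns compared


def test_center_star_identical_records_introduce_no_gaps():
    msa = center_star_msa(records("ACGTACGT", "ACGTACGT", "ACGTACGT"))
    assert all("-" not in r.sequence for r in msa.records)


def test_center_star_single_substitutions_stay_gapless():
    msa = center_star_msa(records("ACGTACGTAC", "ACGAACGTAC", "ACGTACGTTC"))
    assert msa.length == 10
    assert all("-" not in r.sequence for r in msa.records)


def test_center_star_recovers_simulated_divergence(small_db):
    """MSA p-distances reproduce the exact simulated divergences."""
    cfg, recs, truth = small_db
    subset = [recs[i] for i in (0, 1, 3, 9)]  # two conspecifics + two other species
    msa = center_star_msa(subset)
    dm = distance_matrix(msa.records)
    direct = distance_matrix(subset)
    assert np.allclose(dm.values, direct.values, atol=0.01)


def test_center_star_handles_an_indel():
    msa = center_star_msa(records("ACGTACGT", "ACGACGT", "ACGTACGT"))
    assert msa.length == 8
    assert msa.records[1].sequence.count("-") == 1


def test_dedupe_genotypes_counts():
    assert len(dedupe_genotypes(records("ACGT", "ACGT", "ACGA"))) == 2
    assert len(dedupe_genotypes(records("ACGT", "acgu", "NACGTN"))) == 1  # normalised
    assert dedupe_genotypes([]) == []


@given(st.lists(st.text(alphabet="ACGT", min_size=4, max_size=4), min_size=1, max_size=6))
def test_genotype_count_invariant_under_duplication(seqs):
    recs = records(*seqs)
    doubled = records(*(seqs + seqs))
    assert len(dedupe_genotypes(recs)) == len(dedupe_genotypes(doubled))


def test_nucleotide_diversity_small_cases():
    ten = "ACGTACGTAC"
    mutated = "ACGTACGTAT"
    assert nucleotide_diversity(records(ten, mutated)) == pytest.approx(0.1)
    assert nucleotide_diversity(records(ten, ten, ten)) == 0.0


def test_nucleotide_diversity_equals_upper_triangle_mean(rng):
    rows = [random_seq(rng, 25) for _ in range(5)]
    recs = records(*rows)
    pi = nucleotide_diversity(recs)
    pairs = [
        p_distance(a, b) for a, b in itertools.combinations(rows, 2)
    ]
    assert pi == pytest.approx(sum(pairs) / len(pairs))


def test_nucleotide_diversity_invariant_under_row_order(rng):
    rows = [random_seq(rng, 25) for _ in range(4)]
    assert nucleotide_diversity(records(*rows)) == pytest.approx(
        nucleotide_diversity(records(*rows[::-1]))
    )


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(labels=("a", "b"), values=np.array([[0, 0.1], [0.2, 0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(labels=("a", "b"), values=np.array([[0.1, 0.2], [0.2, 0]]))
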