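import numpy as np
import pytest
from sklearn.base import clone

from algbarcode.gap import ThresholdSet
from algbarcode.identify import (
    BarcodeGapClassifier,
    BestHit,
    IdentificationDecision,
    best_hit,
    classify,
    filter_accepted_names,
    roadmap_identify,
    summarize_counts,
)
from algbarcode.seqio import SeqRecord
from algbarcode.simulate import SimConfig, simulate_reference_db
from algbarcode.structure import fold_nussinov

from conftest import records


def _refs(*pairs):
    return [SeqRecord(id=i, sequence=s, species=sp) for i, s, sp in pairs]


def test_best_hit_identical_query_scores_100():
    refs = _refs(("h1", "ACGTACGTAC", "Alpha one"), ("h2", "ACGTACGTTT", "Alpha two"))
    query = SeqRecord(id="q", sequence="ACGTACGTAC")
    hit = best_hit(query, refs)
    assert (hit.hit_id, hit.identity, hit.tie) == ("h1", 100.0, False)
    assert hit.implied_distance == 0.0


def test_best_hit_tie_broken_lexicographically_and_flagged():
    refs = _refs(("b", "ACGTACGTAA", "Beta"), ("a", "ACGTACGTTT", "Alpha"))
    query = SeqRecord(id="q", sequence="ACGTACGTAT")  # 1 mismatch to both
    hit = best_hit(query, refs)
    assert hit.hit_id == "a" and hit.tie


def test_best_hit_empty_db_rejected():
    with pytest.raises(ValueError, match="empty"):
        best_hit(SeqRecord(id="q", sequence="ACGT"), [])


def test_best_hit_recovers_generating_species(small_db):
    cfg, recs, truth = small_db
    species_of = dict(zip(truth["id"], truth["species"]))
    query = recs[0]
    refs = [r for r in recs if r.id != query.id]
    hit = best_hit(query, refs)
    assert hit.hit_species == species_of[query.id]


def _hit(identity, species="Chlorella sorokiniana"):
    return BestHit(query_id="q", hit_id="h", hit_species=species, identity=identity)


def test_classify_threshold_cases():
    its1 = ThresholdSet(marker="nuITS1", threshold=0.029)
    assert classify(_hit(100), its1)[:2] == (True, "species")
    assert classify(_hit(95), its1)[:2] == (False, "unassigned")  # d=0.05


def test_classify_genus_fallback_rescues_chlorella_hit():
    """Identity 96% fails the pooled nuITS2 threshold (0.032) but passes the
    Chlorella-specific minimum (0.076)."""
    its2 = ThresholdSet(marker="nuITS2", threshold=0.032)
    fallback = {"Chlorella": ThresholdSet(marker="nuITS2", threshold=0.076)}
    below, rank, used = classify(_hit(96), its2, fallback)
    assert (below, rank, used) == (True, "species", True)
    # a non-Chlorella hit at 96% stays unassigned
    below2, rank2, used2 = classify(_hit(96, "Desmodesmus armatus"), its2, fallback)
    assert (below2, rank2, used2) == (False, "unassigned", False)


def _decision(query_id, species, rank="species"):
    return IdentificationDecision(
        query_id=query_id,
        marker="rbcL",
        best_hit=BestHit(query_id=query_id, hit_id="h", hit_species=species, identity=99),
        below_threshold=True,
        final_rank=rank,
        rationale=("best-hit", "below-threshold"),
    )


def test_name_filter_demotes_unaccepted_names():
    decisions = [
        _decision(f"q{i}", "Chlorella pyrenoidosa") for i in range(6)
    ] + [_decision(f"s{i}", "Chlorella sorokiniana") for i in range(3)]
    kept = filter_accepted_names(decisions, {"Chlorella sorokiniana"})
    species_level = [d for d in kept if d.final_rank == "species"]
    assert len(species_level) == 3
    demoted = [d for d in kept if d.final_rank == "unassigned"]
    assert all("name-not-accepted" in d.rationale for d in demoted)
    assert all(d.name_accepted is False for d in demoted)


def test_name_filter_edge_cases():
    decisions = [_decision("q", "Chlorella sorokiniana")]
    assert filter_accepted_names(decisions, set())[0].final_rank == "unassigned"
    kept = filter_accepted_names(decisions, {"Chlorella sorokiniana"})
    assert kept[0].final_rank == "species" and kept[0].name_accepted


def test_decision_invariants_enforced():
    with pytest.raises(ValueError, match="rationale"):
        IdentificationDecision(
            query_id="q", marker="rbcL", best_hit=None, below_threshold=True,
            final_rank="unassigned", rationale=(),
        )
    with pytest.raises(ValueError, match="below-threshold"):
        IdentificationDecision(
            query_id="q", marker="rbcL", best_hit=None, below_threshold=False,
            final_rank="species", rationale=("x",),
        )
    with pytest.raises(ValueError, match="CBC"):
        IdentificationDecision(
            query_id="q", marker="nuITS2", best_hit=None, below_threshold=True,
            final_rank="species", cbc_count=2, rationale=("x",),
        )


@pytest.fixture()
def roadmap_setup():
    refs = _refs(
        ("ref_sor", "GGGCGCAAAGCGCCCAAAGGGGCCAAAGGCCCCTTT", "Chlorella sorokiniana"),
        ("ref_vul", "GGGCGCAAAGCGCCCTTTGGGGCCTTAGGCCCCAAA", "Chlorella vulgaris"),
    )
    thresholds = {"nuITS2": ThresholdSet(marker="nuITS2", threshold=0.10)}
    return refs, thresholds


def test_roadmap_perfect_hit_accepted_name_no_cbc(roadmap_setup):
    refs, thresholds = roadmap_setup
    query = SeqRecord(id="q", sequence=refs[0].sequence)
    dec = roadmap_identify(
        {"nuITS2": query},
        {"nuITS2": refs},
        thresholds,
        accepted_names={"Chlorella sorokiniana", "Chlorella vulgaris"},
        structures={"nuITS2": fold_nussinov(query.sequence)},
        ref_structures={r.id: fold_nussinov(r.sequence) for r in refs},
    )
    assert dec.final_rank == "species"
    assert dec.cbc_count == 0
    assert dec.best_hit.hit_species == "Chlorella sorokiniana"


def test_roadmap_cbc_presence_blocks_species_rank():
    from algbarcode.simulate import simulate_structure_pair

    seq = "G" * 8 + "GCGC" + "AAAA" + "GCGC" + "C" * 8
    base, other = simulate_structure_pair(seq, 1, 0, seed=2)
    refs = [SeqRecord(id="hitX", sequence=other.sequence, species="Alpha beta")]
    query = SeqRecord(id="q", sequence=base.sequence)
    dec = roadmap_identify(
        {"nuITS2": query},
        {"nuITS2": refs},
        {"nuITS2": ThresholdSet(marker="nuITS2", threshold=0.2)},
        structures={"nuITS2": base},
        ref_structures={"hitX": other},
    )
    assert dec.final_rank == "genus"
    assert dec.cbc_count == 1
    assert "cbc-present" in dec.rationale


def test_roadmap_no_marker_below_threshold_is_unassigned(roadmap_setup):
    refs, _ = roadmap_setup
    thresholds = {"nuITS2": ThresholdSet(marker="nuITS2", threshold=0.01)}
    query = SeqRecord(id="q", sequence="TTTTTTTTTTGCGCCCAAAGGGGCCAAAGGCCCCAA")
    dec = roadmap_identify({"nuITS2": query}, {"nuITS2": refs}, thresholds)
    assert dec.final_rank == "unassigned"
    assert dec.rationale


def test_roadmap_falls_back_to_secondary_marker(roadmap_setup):
    refs, _ = roadmap_setup
    thresholds = {
        "nuITS2": ThresholdSet(marker="nuITS2", threshold=0.001),  # will fail
        "rbcL": ThresholdSet(marker="rbcL", threshold=0.10),
    }
    rbcl_refs = _refs(("rb1", "ACGTACGTACGTACGTACGT", "Chlorella sorokiniana"))
    bundle = {
        "nuITS2": SeqRecord(id="q", sequence="TTTTGCAAAGCGCCCAAAGGGGCCAAAGGCCCCTTT"),
        "rbcL": SeqRecord(id="q", sequence="ACGTACGTACGTACGTACGT"),
    }
    dec = roadmap_identify(
        bundle, {"nuITS2": refs, "rbcL": rbcl_refs}, thresholds,
        accepted_names={"Chlorella sorokiniana"},
    )
    assert dec.marker == "rbcL" and dec.final_rank == "species"


def test_summarize_counts_rounding_and_empty():
    decisions = [_decision(f"q{i}", "X y") for i in range(18)]
    summary = summarize_counts(decisions, {"rbcL": 51})
    assert summary["rbcL"] == {"count": 18, "percent": 35, "denominator": 51}
    assert summarize_counts([], {"rbcL": 49})["rbcL"]["count"] == 0


def test_raising_threshold_never_decreases_species_count(small_db):
    cfg, recs, truth = small_db
    refs, queries = recs[::2], recs[1::2]
    counts = []
    for thr in (0.001, 0.02, 0.05, 0.2, 0.6):
        ts = {"unknown": ThresholdSet(marker="unknown", threshold=thr)}
        n = 0
        for q in queries:
            dec = roadmap_identify(
                {"unknown": q}, {"unknown": refs}, ts, marker_priority=("unknown",)
            )
            n += dec.final_rank == "species"
        counts.append(n)
    assert counts == sorted(counts)


# --- sklearn estimator ------------------------------------------------------

def test_classifier_is_sklearn_compatible(small_db):
    cfg, recs, truth = small_db
    clf = BarcodeGapClassifier()
    params = clf.get_params()
    assert set(params) == {"threshold", "gap_policy", "unassigned_label"}
    cloned = clone(clf).set_params(threshold=0.05)
    assert cloned.get_params()["threshold"] == 0.05


def test_classifier_fit_predict_on_simulated_data(small_db):
    cfg, recs, truth = small_db
    X = [r.sequence for r in recs]
    y = [r.species for r in recs]
    clf = BarcodeGapClassifier().fit(X, y)
    assert clf.threshold_ == pytest.approx(cfg.inter_divergence)
    # perfect self-assignment and a divergent outlier rejected
    assert list(clf.predict(X[:4])) == y[:4]
    outlier = "A" * cfg.seq_length
    assert clf.predict([outlier])[0] == "unassigned"


def test_classifier_with_no_false_assignments_under_margin(small_db):
    from algbarcode.simulate import mutate_sequence

    cfg, recs, truth = small_db
    clf = BarcodeGapClassifier().fit(
        [r.sequence for r in recs], [r.species for r in recs]
    )
    rng = np.random.default_rng(3)
    for rec in recs[::4]:
        q = mutate_sequence(rec.sequence, cfg.intra_divergence / 2, rng).sequence
        assert clf.predict([q])[0] == rec.species


def test_classifier_validates_input(small_db):
    cfg, recs, truth = small_db
    clf = BarcodeGapClassifier()
    with pytest.raises(ValueError, match="aligned"):
        clf.fit(["ACGT", "ACG"], ["a", "b"])
    with pytest.raises(ValueError, match="different lengths"):
        clf.fit(["ACGT"], ["a", "b"])
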