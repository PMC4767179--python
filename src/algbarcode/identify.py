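"""Best-hit search, threshold classification and the identification roadmap.

The decision chain for a query strain mirrors standard barcoding practice
for green microalgae:

(a) similarity search against a reference database; the best hit's implied
    distance (1 − identity/100) must fall strictly below the marker's
    barcode-gap threshold;
(b) for nuITS2, absence of compensatory base changes (CBCs) between the
    query and hit secondary structures (hemi-CBCs do not block a
    species-level call);
(c) the assigned species name must be a currently accepted binomial;
(d) if the primary marker fails, the remaining markers are evaluated in
    priority order (nuITS2 -> nuITS1 -> rbcL by default).

A query whose best hit fails the pooled threshold may be rescued by a
genus-specific threshold when one is supplied (the genus minimum
interspecific distance is never smaller than the pooled minimum).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .align import global_align, p_distance, percent_identity
from .gap import ThresholdSet, derive_threshold, gap_summaries
from .seqio import SeqRecord
from .structure import SecondaryStructure, count_cbc, make_structure_pair
from .util import round_half_up

__all__ = [
    "BestHit",
    "IdentificationDecision",
    "best_hit",
    "classify",
    "filter_accepted_names",
    "roadmap_identify",
    "summarize_counts",
    "BarcodeGapClassifier",
]

MARKER_PRIORITY = ("nuITS2", "nuITS1", "rbcL")


@dataclass(frozen=True)
class BestHit:
    """Best database match for a query, with its implied p-distance."""

    query_id: str
    hit_id: str
    hit_species: str | None
    identity: float
    tie: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 100:
            raise ValueError(f"identity out of [0, 100]: {self.identity}")

    @property
    def implied_distance(self) -> float:
        return (100.0 - self.identity) / 100.0

    @property
    def hit_genus(self) -> str | None:
        if not self.hit_species:
            return None
        return self.hit_species.split()[0]


@dataclass(frozen=True)
class IdentificationDecision:
    """Outcome of the decision roadmap for one query and marker."""

    query_id: str
    marker: str
    best_hit: BestHit | None
    below_threshold: bool
    final_rank: str  # {"species", "genus", "unassigned"}
    cbc_count: int | None = None
    hemi_cbc_count: int | None = None
    name_accepted: bool | None = None
    used_genus_fallback: bool = False
    rationale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.final_rank not in ("species", "genus", "unassigned"):
            raise ValueError(f"invalid rank {self.final_rank!r}")
        if not self.rationale:
            raise ValueError("rationale must be non-empty")
        if self.final_rank == "species":
            if not self.below_threshold:
                raise ValueError("species rank requires below-threshold distance")
            if self.cbc_count not in (None, 0):
                raise ValueError("species rank requires zero CBCs (or CBC not evaluated)")
            if self.name_accepted is False:
                raise ValueError("species rank requires an accepted name")


def best_hit(
    query: SeqRecord,
    refdb: Sequence[SeqRecord],
    *,
    identity_policy: str = "exclude_end_gaps",
) -> BestHit:
    """Exhaustive global-identity search over a local reference database.

    Ties on identity are broken by higher alignment coverage (compared
    columns), then lexicographic hit id; a tie on both is flagged.
    """
    refdb = list(refdb)
    if not refdb:
        raise ValueError("reference database is empty")
    scored = []
    for ref in refdb:
        aln = global_align(query, ref)
        ident = percent_identity(aln, policy=identity_policy)
        r1, r2 = (r.sequence for r in aln.records)
        coverage = sum(1 for x, y in zip(r1, r2) if x != "-" and y != "-")
        scored.append((ident, coverage, ref))
    best_ident = max(s[0] for s in scored)
    top = [s for s in scored if np.isclose(s[0], best_ident)]
    best_cov = max(s[1] for s in top)
    top = sorted((s for s in top if s[1] == best_cov), key=lambda s: s[2].id)
    chosen = top[0][2]
    return BestHit(
        query_id=query.id,
        hit_id=chosen.id,
        hit_species=chosen.species,
        identity=float(best_ident),
        tie=len(top) > 1,
    )


def classify(
    hit: BestHit,
    thresholds: ThresholdSet,
    genus_fallback: Mapping[str, ThresholdSet] | None = None,
) -> tuple[bool, str, bool]:
    """Apply the distance threshold to a best hit.

    Returns ``(below_threshold, provisional_rank, used_fallback)`` where
    provisional rank is "species" when the implied distance is strictly
    below the applicable threshold and "unassigned" otherwise.  When the
    pooled threshold fails and a genus-specific threshold is available for
    the hit's genus, that (larger) threshold is retried.
    """
    d = hit.implied_distance
    if thresholds.is_species_level(d):
        return True, "species", False
    if genus_fallback and hit.hit_genus and hit.hit_genus in genus_fallback:
        if genus_fallback[hit.hit_genus].is_species_level(d):
            return True, "species", True
    return False, "unassigned", False


def filter_accepted_names(
    decisions: Iterable[IdentificationDecision],
    accepted_names: set[str] | frozenset[str],
) -> list[IdentificationDecision]:
    """Demote species-level decisions whose hit name is not accepted.

    The accepted-names set is a user-supplied table of currently valid
    species names; a species-level decision pointing at a name outside it
    is demoted to unassigned with rationale "name-not-accepted".
    """
    out = []
    for dec in decisions:
        if dec.final_rank != "species":
            out.append(dec)
            continue
        name = dec.best_hit.hit_species if dec.best_hit else None
        if name in accepted_names:
            out.append(replace(dec, name_accepted=True))
        else:
            out.append(
                replace(
                    dec,
                    final_rank="unassigned",
                    name_accepted=False,
                    rationale=dec.rationale + ("name-not-accepted",),
                )
            )
    return out


def _evaluate_marker(
    marker: str,
    query: SeqRecord,
    structure: SecondaryStructure | None,
    refdb: Sequence[SeqRecord],
    ref_structures: Mapping[str, SecondaryStructure] | None,
    thresholds: ThresholdSet,
    genus_fallback: Mapping[str, ThresholdSet] | None,
) -> IdentificationDecision:
    rationale: list[str] = []
    hit = best_hit(query, refdb)
    rationale.append(
        f"best-hit:{hit.hit_id}:{hit.identity:.0f}%"
        + (":tie" if hit.tie else "")
    )
    below, rank, used_fb = classify(hit, thresholds, genus_fallback)
    if used_fb:
        rationale.append("genus-fallback-threshold")
    rationale.append("below-threshold" if below else "above-threshold")
    cbc = hemi = None
    if below and structure is not None and ref_structures and hit.hit_id in ref_structures:
        report = count_cbc(make_structure_pair(structure, ref_structures[hit.hit_id]))
        cbc, hemi = report.cbc, report.hemi_cbc
        rationale.append(f"cbc:{cbc}/{hemi}")
        if cbc > 0:
            # a CBC predicts two distinct species: demote to genus level
            return IdentificationDecision(
                query_id=query.id,
                marker=marker,
                best_hit=hit,
                below_threshold=below,
                final_rank="genus",
                cbc_count=cbc,
                hemi_cbc_count=hemi,
                used_genus_fallback=used_fb,
                rationale=tuple(rationale + ["cbc-present"]),
            )
    elif below and structure is not None:
        rationale.append("cbc:not-evaluated")
    return IdentificationDecision(
        query_id=query.id,
        marker=marker,
        best_hit=hit,
        below_threshold=below,
        final_rank="species" if below else "unassigned",
        cbc_count=cbc,
        hemi_cbc_count=hemi,
        used_genus_fallback=used_fb,
        rationale=tuple(rationale),
    )


def roadmap_identify(
    query_bundle: Mapping[str, SeqRecord],
    refdb: Mapping[str, Sequence[SeqRecord]],
    thresholds: Mapping[str, ThresholdSet],
    accepted_names: set[str] | None = None,
    *,
    structures: Mapping[str, SecondaryStructure] | None = None,
    ref_structures: Mapping[str, SecondaryStructure] | None = None,
    genus_fallback: Mapping[str, Mapping[str, ThresholdSet]] | None = None,
    marker_priority: Sequence[str] = MARKER_PRIORITY,
) -> IdentificationDecision:
    """Run the full decision roadmap for one query strain.

    ``query_bundle`` maps marker name to the query's record for that
    marker (at least one marker must be present); ``structures`` maps
    marker -> query secondary structure (nuITS2 CBC step) and
    ``ref_structures`` maps reference id -> structure.  Markers are tried
    in priority order; the first marker passing every step yields a
    species-level decision, otherwise the last evaluated marker's decision
    is returned (with its failure rationale).
    """
    if not query_bundle:
        raise ValueError("query bundle is empty")
    last: IdentificationDecision | None = None
    for marker in marker_priority:
        if marker not in query_bundle:
            continue
        if marker not in refdb or marker not in thresholds:
            continue
        dec = _evaluate_marker(
            marker,
            query_bundle[marker],
            (structures or {}).get(marker),
            refdb[marker],
            ref_structures,
            thresholds[marker],
            (genus_fallback or {}).get(marker),
        )
        if dec.final_rank == "species" and accepted_names is not None:
            dec = filter_accepted_names([dec], frozenset(accepted_names))[0]
        if dec.final_rank == "species":
            return dec
        last = dec
    if last is None:
        raise ValueError("no marker of the bundle is covered by the reference sets")
    return last


def summarize_counts(
    decisions: Iterable[IdentificationDecision],
    denominator_per_marker: Mapping[str, int],
) -> dict[str, dict[str, float]]:
    """Species-level counts and integer percentages per marker.

    ``denominator_per_marker`` gives the number of strains successfully
    sequenced for each marker (the percentage base).  Percentages use
    half-up rounding, matching printed-table style.
    """
    counts: dict[str, int] = {m: 0 for m in denominator_per_marker}
    for dec in decisions:
        if dec.final_rank == "species" and dec.marker in counts:
            counts[dec.marker] += 1
    out = {}
    for marker, denom in denominator_per_marker.items():
        pct = round_half_up(100.0 * counts[marker] / denom) if denom else 0
        out[marker] = {"count": counts[marker], "percent": pct, "denominator": denom}
    return out


# ---------------------------------------------------------------------------
# scikit-learn-style estimator over the threshold-assignment core
# ---------------------------------------------------------------------------

class BarcodeGapClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-reference species assignment under a barcode-gap threshold.

    ``fit`` takes aligned (equal-length) reference sequences ``X`` with
    species labels ``y``, computes the p-distance matrix and per-species
    barcode-gap summaries, and derives the marker threshold as the minimum
    interspecific distance (unless ``threshold`` is given).  ``predict``
    assigns each query to the species of its nearest reference when that
    distance is strictly below the threshold, else to ``unassigned_label``.

    Parameters
    ----------
    threshold : float or None
        Fixed species-level threshold; ``None`` derives it from the
        reference set at fit time.
    gap_policy : str
        Gap handling for p-distances ("pairwise_deletion" or
        "complete_deletion").
    unassigned_label : str
        Label returned for queries failing the threshold.
    """

    def __init__(
        self,
        threshold: float | None = None,
        gap_policy: str = "pairwise_deletion",
        unassigned_label: str = "unassigned",
    ):
        self.threshold = threshold
        self.gap_policy = gap_policy
        self.unassigned_label = unassigned_label

    def fit(self, X, y):
        X = [x.sequence if isinstance(x, SeqRecord) else str(x) for x in X]
        y = [str(label) for label in y]
        if len(X) != len(y):
            raise ValueError("X and y have different lengths")
        if len(set(len(s) for s in X)) != 1:
            raise ValueError("reference sequences must be aligned (equal length)")
        records = tuple(
            SeqRecord(id=f"ref{i}", sequence=s, species=sp)
            for i, (s, sp) in enumerate(zip(X, y))
        )
        from .align import distance_matrix

        dm = distance_matrix(records, gap_policy=self.gap_policy)
        species_map = {rec.id: rec.species for rec in records}
        self.gap_summaries_ = gap_summaries(dm, species_map)
        if self.threshold is None:
            self.threshold_ = derive_threshold(self.gap_summaries_, marker="unknown").threshold
        else:
            self.threshold_ = float(self.threshold)
        self.classes_ = np.array(sorted(set(y)) + [self.unassigned_label])
        self.reference_ = records
        self._ref_enc = np.stack([_encode_cached(s) for s in X])
        self._ref_species = np.array(y)
        return self

    def predict(self, X):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "threshold_")
        X = [x.sequence if isinstance(x, SeqRecord) else str(x) for x in X]
        dists, nearest = self.decision_distances(X)
        labels = np.where(
            dists < self.threshold_, self._ref_species[nearest], self.unassigned_label
        )
        return labels

    def decision_distances(self, X):
        """Distance to the nearest reference and its index, per query."""
        from .align import encode

        out_d = np.empty(len(X))
        out_i = np.empty(len(X), dtype=int)
        present_ref = self._ref_enc != 255
        for k, seq in enumerate(X):
            q = encode(seq)
            if q.shape[0] != self._ref_enc.shape[1]:
                raise ValueError("query length does not match the reference alignment")
            ok = (q != 255) & present_ref
            compared = ok.sum(axis=1)
            if (compared == 0).any():
                raise ValueError("query shares no comparable sites with a reference")
            d = ((q != self._ref_enc) & ok).sum(axis=1) / compared
            out_i[k] = int(np.argmin(d))
            out_d[k] = float(d[out_i[k]])
        return out_d, out_i


def _encode_cached(seq: str) -> np.ndarray:
    from .align import encode

    return encode(seq)
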