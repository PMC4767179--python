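"""Barcode-gap statistics and distance-threshold derivation.

A barcode gap exists for a species when its maximum intraspecific p-distance
is smaller than its minimum distance to any other species.  The identification
threshold for a marker is the smallest minimum-interspecific distance observed
across the reference taxon sampling; species-level assignment then requires a
query-to-hit distance *strictly below* the threshold.  Singleton species have
no intraspecific distance but still contribute their minimum interspecific
distance to threshold derivation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .align import DistanceMatrix

__all__ = [
    "GapSummary",
    "ThresholdSet",
    "gap_summaries",
    "derive_threshold",
    "genus_threshold",
    "summaries_to_frame",
]


@dataclass(frozen=True)
class GapSummary:
    """Per-species barcode-gap statistics.

    ``max_intra`` is ``None`` for singleton species (no within-species
    pair); for the gap predicate it is then treated as 0 and the summary is
    flagged via ``singleton``.
    """

    species: str
    n_seqs: int
    max_intra: float | None
    min_inter: float
    gap_present: bool
    singleton: bool = False

    def __post_init__(self) -> None:
        for value in (self.max_intra, self.min_inter):
            if value is not None and not 0 <= value <= 1:
                raise ValueError(f"distance out of [0, 1]: {value}")


@dataclass(frozen=True)
class ThresholdSet:
    """A marker's species-level distance threshold.

    ``comparison`` is strict: a query is species-level when its implied
    distance to the best hit is < ``threshold``.  ``source`` records the
    species (or genera) whose minimum interspecific distances were pooled.
    """

    marker: str
    threshold: float
    source: tuple[str, ...] = ()
    comparison: str = "strict-less-than"

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")

    def is_species_level(self, distance: float) -> bool:
        return distance < self.threshold


def gap_summaries(
    matrix: DistanceMatrix, species_map: Mapping[str, str]
) -> list[GapSummary]:
    """Compute per-species max-intra / min-inter statistics.

    Every matrix label must be mapped to a species and at least two species
    must be present.  Returns one summary per species, ordered by species
    name.
    """
    missing = [lab for lab in matrix.labels if lab not in species_map]
    if missing:
        raise ValueError(f"labels without a species mapping: {missing[:5]}")
    species_of = {lab: species_map[lab] for lab in matrix.labels}
    species = sorted(set(species_of.values()))
    if len(species) < 2:
        raise ValueError("barcode-gap analysis needs at least 2 species")
    idx = {lab: i for i, lab in enumerate(matrix.labels)}
    members = {
        sp: np.array([idx[lab] for lab in matrix.labels if species_of[lab] == sp])
        for sp in species
    }
    out: list[GapSummary] = []
    for sp in species:
        own = members[sp]
        others = np.array([i for i in range(len(matrix)) if i not in set(own.tolist())])
        if own.size == 0:
            raise ValueError(f"species {sp!r} has no members")
        if own.size > 1:
            sub = matrix.values[np.ix_(own, own)]
            max_intra = float(sub[np.triu_indices(own.size, k=1)].max())
        else:
            max_intra = None
        min_inter = float(matrix.values[np.ix_(own, others)].min())
        gap = (max_intra if max_intra is not None else 0.0) < min_inter
        out.append(
            GapSummary(
                species=sp,
                n_seqs=int(own.size),
                max_intra=max_intra,
                min_inter=min_inter,
                gap_present=gap,
                singleton=own.size == 1,
            )
        )
    return out


def _flatten(
    summaries: Mapping[str, Sequence[GapSummary]] | Sequence[GapSummary],
) -> list[tuple[str | None, GapSummary]]:
    if isinstance(summaries, Mapping):
        return [(genus, s) for genus, group in summaries.items() for s in group]
    return [(None, s) for s in summaries]


def derive_threshold(
    summaries: Mapping[str, Sequence[GapSummary]]
    | Sequence[GapSummary]
    | Mapping[str, float],
    marker: str,
) -> ThresholdSet:
    """Marker threshold: the global minimum of min_inter across the sampling.

    ``summaries`` is a flat sequence of :class:`GapSummary`, a mapping
    genus -> summaries (each genus analysed on its own reference matrix,
    the usual workflow), or a mapping genus -> already-computed minimum
    interspecific distance.
    """
    if isinstance(summaries, Mapping) and summaries and all(
        isinstance(v, (int, float)) for v in summaries.values()
    ):
        threshold = min(float(v) for v in summaries.values())
        return ThresholdSet(marker=marker, threshold=threshold, source=tuple(summaries))
    flat = _flatten(summaries)
    if not flat:
        raise ValueError("no gap summaries supplied")
    threshold = min(s.min_inter for _, s in flat)
    source = tuple(dict.fromkeys(g if g is not None else s.species for g, s in flat))
    return ThresholdSet(marker=marker, threshold=threshold, source=source)


def genus_threshold(
    summaries: Mapping[str, Sequence[GapSummary]], genus: str, marker: str
) -> ThresholdSet:
    """Threshold restricted to a single genus's species.

    Supports the rescue rule by which a query failing the pooled threshold
    may still be species-level under the (necessarily >=) genus-specific
    minimum interspecific distance.
    """
    if genus not in summaries:
        raise KeyError(f"genus {genus!r} not in summaries")
    group = list(summaries[genus])
    if len(group) < 2:
        raise ValueError(f"genus {genus!r} has fewer than 2 species: no interspecific pair")
    threshold = min(s.min_inter for s in group)
    return ThresholdSet(marker=marker, threshold=threshold, source=(genus,))


def summaries_to_frame(summaries: Sequence[GapSummary]) -> pd.DataFrame:
    """Tabulate summaries (distances rounded to 3 decimals for reports)."""
    return pd.DataFrame(
        {
            "species": [s.species for s in summaries],
            "n_seqs": [s.n_seqs for s in summaries],
            "max_intra": [
                None if s.max_intra is None else round(s.max_intra, 3) for s in summaries
            ],
            "min_inter": [round(s.min_inter, 3) for s in summaries],
            "gap_present": [s.gap_present for s in summaries],
            "singleton": [s.singleton for s in summaries],
        }
    )
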