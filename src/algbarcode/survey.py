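"""Worked example: the Embrapa|LBA strain survey.

The package ships a transcription of the published molecular-identification
survey of 51 freshwater green microalgae strains (Embrapa|LBA#1-51): for
each strain and marker (nuITS1, nuITS2, rbcL) the closest reference-database
match, its integer percent identity, and for nuITS2 the CBC/hemi-CBC counts
against that match.  Applying the published barcode-gap thresholds to this
table reproduces the survey's species-level identification counts without
any network access.

The published thresholds derive from per-genus reference samplings of two
species-dense genera (Chlorella and Desmodesmus); the genus minimum
interspecific distances are recorded in :data:`REFERENCE_GENUS_MINIMA`.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import pandas as pd

from .gap import ThresholdSet, derive_threshold
from .identify import (
    BestHit,
    IdentificationDecision,
    classify,
    filter_accepted_names,
    summarize_counts,
)

__all__ = [
    "REFERENCE_GENUS_MINIMA",
    "SEQUENCED_STRAINS",
    "load_strain_survey",
    "load_accepted_names",
    "survey_thresholds",
    "classify_survey",
]

#: Minimum interspecific p-distance per genus in the reference samplings,
#: as printed in the published barcode-gap figures.  The marker threshold
#: is the minimum over genera.
REFERENCE_GENUS_MINIMA: dict[str, dict[str, float]] = {
    "nuITS1": {"Chlorella": 0.058, "Desmodesmus": 0.029},
    "nuITS2": {"Chlorella": 0.076, "Desmodesmus": 0.032},
    "rbcL": {"Desmodesmus": 0.015},
}

#: Strains successfully sequenced per marker (percentage denominators).
SEQUENCED_STRAINS: dict[str, int] = {"nuITS1": 51, "nuITS2": 51, "rbcL": 49}

_COLUMNS = {
    "nuITS1": ("its1_species", "its1_identity", None, None),
    "nuITS2": ("its2_species", "its2_identity", "its2_cbc", "its2_hcbc"),
    "rbcL": ("rbcl_species", "rbcl_identity", None, None),
}


def load_strain_survey() -> pd.DataFrame:
    """Load the packaged 51-strain best-hit table."""
    with resources.files("algbarcode.data").joinpath("lba_strain_hits.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_accepted_names() -> frozenset[str]:
    """Accepted species names for the worked example.

    Contains every closest-match name of the survey except the deprecated
    binomial "Chlorella pyrenoidosa" (currently Pseudochlorella
    pyrenoidosa).
    """
    with resources.files("algbarcode.data").joinpath("accepted_names.tsv").open() as fh:
        frame = pd.read_csv(fh, sep="\t")
    return frozenset(frame["species"])


def survey_thresholds() -> dict[str, ThresholdSet]:
    """Marker thresholds derived from the reference genus minima."""
    return {
        marker: derive_threshold(minima, marker)
        for marker, minima in REFERENCE_GENUS_MINIMA.items()
    }


def _chlorella_fallback() -> dict[str, dict[str, ThresholdSet]]:
    its2 = REFERENCE_GENUS_MINIMA["nuITS2"]["Chlorella"]
    return {
        "nuITS2": {
            "Chlorella": ThresholdSet(marker="nuITS2", threshold=its2, source=("Chlorella",))
        }
    }


def classify_survey(
    table: pd.DataFrame | None = None,
    thresholds: Mapping[str, ThresholdSet] | None = None,
    *,
    genus_fallback: bool = True,
    apply_cbc: bool = True,
    accepted_names: frozenset[str] | None = None,
    denominators: Mapping[str, int] | None = None,
) -> dict:
    """Classify every surveyed strain per marker under the thresholds.

    For each marker a strain is species-level when its implied best-hit
    distance (1 − identity/100, the documented bridge from printed integer
    identities to p-distances) is strictly below the marker threshold; for
    nuITS2 a recorded CBC additionally demotes the call to genus level
    (hemi-CBCs do not).  With ``genus_fallback`` the Chlorella-specific
    nuITS2 threshold rescues Chlorella-hit strains failing the pooled
    threshold.  ``accepted_names`` (when given) demotes species-level calls
    whose hit name is not accepted.

    Returns a dict with per-marker decisions, the species-level strain
    lists, and count/percentage summaries.
    """
    table = load_strain_survey() if table is None else table
    thresholds = survey_thresholds() if thresholds is None else thresholds
    denominators = dict(SEQUENCED_STRAINS) if denominators is None else dict(denominators)
    fallback = _chlorella_fallback() if genus_fallback else {}

    decisions: dict[str, list[IdentificationDecision]] = {}
    for marker, (sp_col, id_col, cbc_col, hcbc_col) in _COLUMNS.items():
        marker_decisions = []
        for _, row in table.iterrows():
            if pd.isna(row[id_col]):
                continue
            hit = BestHit(
                query_id=row["strain"],
                hit_id=f"{row['strain']}:{marker}",
                hit_species=row[sp_col],
                identity=float(row[id_col]),
            )
            below, rank, used_fb = classify(
                hit, thresholds[marker], fallback.get(marker)
            )
            rationale = [
                f"best-hit:{hit.hit_species}:{hit.identity:.0f}%",
                "below-threshold" if below else "above-threshold",
            ]
            if used_fb:
                rationale.insert(1, "genus-fallback-threshold")
            cbc = hemi = None
            if cbc_col is not None and not pd.isna(row[cbc_col]):
                cbc, hemi = int(row[cbc_col]), int(row[hcbc_col])
            if below and apply_cbc and cbc is not None and cbc > 0:
                rank = "genus"
                rationale.append("cbc-present")
            marker_decisions.append(
                IdentificationDecision(
                    query_id=row["strain"],
                    marker=marker,
                    best_hit=hit,
                    below_threshold=below,
                    final_rank=rank,
                    cbc_count=cbc,
                    hemi_cbc_count=hemi,
                    used_genus_fallback=used_fb,
                    rationale=tuple(rationale),
                )
            )
        if accepted_names is not None:
            marker_decisions = filter_accepted_names(marker_decisions, accepted_names)
        decisions[marker] = marker_decisions

    species_strains = {
        marker: [d.query_id for d in decs if d.final_rank == "species"]
        for marker, decs in decisions.items()
    }
    all_decisions = [d for decs in decisions.values() for d in decs]
    summary = summarize_counts(all_decisions, denominators)
    return {
        "decisions": decisions,
        "species_strains": species_strains,
        "summary": summary,
        "thresholds": {m: t.threshold for m, t in thresholds.items()},
    }
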