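"""Reference-database workflows over user-downloaded sequence sets.

The barcode-gap statistics of real reference samplings depend on GenBank
accessions that are not redistributed with the package.  This module runs
the full gap/threshold/genotype chain over a local directory of downloaded
(and aligned) FASTA files, so the accession-based numbers can be reproduced
once the sequences are fetched.  Results are best-effort: alignment choices
and the distance gap policy are not uniquely determined by the published
figures, and both are therefore recorded in the output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from .align import dedupe_genotypes, distance_matrix
from .gap import derive_threshold, gap_summaries, genus_threshold
from .seqio import read_fasta

__all__ = ["genbank_reference_workflow"]


def genbank_reference_workflow(
    directory: str | Path,
    markers: Mapping[str, tuple[str, ...]] = {
        "nuITS1": ("Chlorella", "Desmodesmus"),
        "nuITS2": ("Chlorella", "Desmodesmus"),
        "rbcL": ("Desmodesmus",),
    },
    gap_policy: str = "pairwise_deletion",
) -> dict:
    """Compute gap statistics and thresholds from downloaded reference sets.

    Expects, inside ``directory``:

    - ``<marker>_<Genus>.fasta`` — an *aligned* reference set for one genus
      and marker, headers carrying species labels (``id|species``);
    - optionally ``strains_<marker>.fasta`` — query-strain sequences, used
      only for genotype counting.

    Returns a dict with per-genus minimum interspecific distances, the
    derived marker thresholds, per-genus summaries, and genotype counts.
    Raises :class:`FileNotFoundError` naming every missing reference file.
    """
    directory = Path(directory)
    missing = []
    per_marker: dict[str, dict] = {}
    for marker, genera in markers.items():
        by_genus = {}
        for genus in genera:
            path = directory / f"{marker}_{genus}.fasta"
            if not path.exists():
                missing.append(str(path))
                continue
            records = read_fasta(path, marker=marker)
            dm = distance_matrix(records, gap_policy=gap_policy)
            species_map = {r.id: r.species for r in records}
            by_genus[genus] = gap_summaries(dm, species_map)
        per_marker[marker] = by_genus
    if missing:
        raise FileNotFoundError(
            "reference accession sets not found (download and align them "
            "first): " + ", ".join(missing)
        )
    out: dict = {"gap_policy": gap_policy, "markers": {}}
    for marker, by_genus in per_marker.items():
        genus_minima = {
            genus: genus_threshold(by_genus, genus, marker).threshold
            if len(by_genus[genus]) > 1
            else min(s.min_inter for s in by_genus[genus])
            for genus in by_genus
        }
        out["markers"][marker] = {
            "genus_min_inter": genus_minima,
            "threshold": derive_threshold(by_genus, marker).threshold,
            "summaries": by_genus,
        }
        strain_path = directory / f"strains_{marker}.fasta"
        if strain_path.exists():
            strains = read_fasta(strain_path, marker=marker)
            out["markers"][marker]["n_genotypes"] = len(dedupe_genotypes(strains))
    return out
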