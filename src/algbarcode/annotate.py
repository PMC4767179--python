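"""Splitting ITS1-5.8S-ITS2 amplicons into their three subregions.

The 5.8S gene is located by a pair of conserved flanking motifs (degenerate
IUPAC strings, configurable), a deliberately lightweight heuristic in place
of profile-HMM annotation.  ITS1 is everything upstream of the 5.8S, ITS2
everything downstream; the three spans partition the amplicon.  Accuracy of
the default motifs is validated on synthetic amplicons only — for real data,
supply motifs appropriate to the clade under study.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pcr import iupac_match
from .seqio import SeqRecord

__all__ = ["MotifConfig", "ItsAnnotation", "annotate_its", "DEFAULT_MOTIFS"]


@dataclass(frozen=True)
class MotifConfig:
    """Conserved motifs delimiting the 5.8S gene.

    ``start_motif`` anchors the 5.8S 5' end (motif start == gene start);
    ``end_motif`` anchors its 3' end (motif end == gene end).  A candidate
    is accepted when the implied 5.8S length falls in
    [min_58s_len, max_58s_len].  Each motif tolerates ``max_mismatch``
    degenerate mismatches.
    """

    start_motif: str = "CGATGAAGAACGCAGC"
    end_motif: str = "GAATTGCAGAATTC"
    min_58s_len: int = 100
    max_58s_len: int = 200
    max_mismatch: int = 1


DEFAULT_MOTIFS = MotifConfig()


@dataclass(frozen=True)
class ItsAnnotation:
    """0-based half-open spans of ITS1, 5.8S and ITS2 on the amplicon."""

    its1_span: tuple[int, int]
    r58s_span: tuple[int, int]
    its2_span: tuple[int, int]

    def __post_init__(self) -> None:
        spans = (self.its1_span, self.r58s_span, self.its2_span)
        flat = [x for span in spans for x in span]
        if flat != sorted(flat) or any(a > b for a, b in spans):
            raise ValueError(f"spans must be ordered and non-overlapping: {spans}")

    def extract(self, record: SeqRecord) -> dict[str, str]:
        seq = record.sequence
        return {
            "nuITS1": seq[slice(*self.its1_span)],
            "5.8S": seq[slice(*self.r58s_span)],
            "nuITS2": seq[slice(*self.its2_span)],
        }


def _motif_sites(seq: str, motif: str, max_mismatch: int) -> list[int]:
    hits = []
    k = len(motif)
    for i in range(len(seq) - k + 1):
        mm = 0
        for p, t in zip(motif, seq[i : i + k]):
            if not iupac_match(p, t):
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            hits.append(i)
    return hits


def annotate_its(
    record: SeqRecord, motif_config: MotifConfig = DEFAULT_MOTIFS
) -> ItsAnnotation | None:
    """Locate the 5.8S gene on an ITS-full amplicon by its flanking motifs.

    Returns ``None`` when no motif pair with a plausible 5.8S length is
    found (the record is then unannotatable and subregion operations skip
    it).  The leftmost valid start motif is used; the end motif is the
    nearest one satisfying the configured length range, so the annotation
    is insensitive to extra flanking sequence around the amplicon.
    """
    seq = record.sequence
    cfg = motif_config
    starts = _motif_sites(seq, cfg.start_motif.upper(), cfg.max_mismatch)
    ends = _motif_sites(seq, cfg.end_motif.upper(), cfg.max_mismatch)
    for s in starts:
        for e in ends:
            gene_end = e + len(cfg.end_motif)
            length = gene_end - s
            if cfg.min_58s_len <= length <= cfg.max_58s_len:
                return ItsAnnotation(
                    its1_span=(0, s),
                    r58s_span=(s, gene_end),
                    its2_span=(gene_end, len(seq)),
                )
    return None
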