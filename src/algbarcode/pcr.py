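"""Degenerate-primer in-silico PCR.

Primer/template matching is fully degenerate on both sides: an IUPAC code in
the primer matches an IUPAC code in the template whenever the two encoded
nucleotide sets intersect.  Amplicon coordinates are reported 1-based, with
the printed amplicon length defined as (reverse-primer 3'-end position −
forward-primer 5'-start position), the convention under which a product
spanning positions 192 to 657 of rbcL is reported as 465 nt.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import IUPAC_SETS, SeqRecord

__all__ = [
    "PrimerPair",
    "Amplicon",
    "iupac_match",
    "reverse_complement",
    "insilico_pcr",
]

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N", "I": "N",
    "-": "-",
}


def iupac_match(pattern_base: str, seq_base: str) -> bool:
    """True iff the two IUPAC codes share at least one nucleotide.

    Both arguments may be ambiguous; matching is symmetric set intersection
    (W matches A, W matches D, W does not match C).
    """
    try:
        pa = IUPAC_SETS[pattern_base.upper()]
        pb = IUPAC_SETS[seq_base.upper()]
    except KeyError as exc:
        raise ValueError(f"not an IUPAC nucleotide code: {exc.args[0]!r}") from None
    return bool(pa & pb)


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[ch] for ch in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"not an IUPAC nucleotide code: {exc.args[0]!r}") from None


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair with optional reference coordinates.

    ``fwd_pos``/``rev_pos`` are 1-based positions on a reference sequence
    (forward 5'-start and reverse 3'-end respectively); they are metadata
    only and never used for matching.
    """

    name: str
    forward: str
    reverse: str
    fwd_pos: int | None = None
    rev_pos: int | None = None
    annealing_temp: float | None = None

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        for primer in (self.forward, self.reverse):
            for ch in primer:
                if ch.upper() not in IUPAC_SETS:
                    raise ValueError(f"primer {self.name!r}: invalid character {ch!r}")
        if self.fwd_pos is not None and self.rev_pos is not None and not self.rev_pos > self.fwd_pos:
            raise ValueError(f"primer {self.name!r}: rev_pos must exceed fwd_pos")


@dataclass(frozen=True)
class Amplicon:
    """Result of an in-silico PCR: either a predicted product or a no-hit.

    ``start``/``end`` are 1-based inclusive template coordinates of the
    product (forward 5'-start to reverse 3'-end); ``length = end - start``
    follows the printed-table convention.  ``span`` gives the 0-based
    half-open interval covering the full product.
    """

    found: bool
    start: int | None = None
    end: int | None = None
    sequence: str | None = None
    forward_hits: tuple[int, ...] = ()
    reverse_hits: tuple[int, ...] = ()
    ambiguous: bool = False

    @property
    def length(self) -> int | None:
        if not self.found:
            return None
        return self.end - self.start

    @property
    def span(self) -> tuple[int, int] | None:
        if not self.found:
            return None
        return (self.start - 1, self.end)


def _mismatches(primer: str, window: str, limit: int) -> int | None:
    """Mismatch count between primer and template window, or None if > limit."""
    count = 0
    for p, t in zip(primer, window):
        if not iupac_match(p, t):
            count += 1
            if count > limit:
                return None
    return count


def _find_sites(template: str, primer: str, max_mismatch: int) -> list[int]:
    n, k = len(template), len(primer)
    return [
        i
        for i in range(n - k + 1)
        if _mismatches(primer, template[i : i + k], max_mismatch) is not None
    ]


def insilico_pcr(
    template: SeqRecord | str,
    pair: PrimerPair,
    max_mismatch: int = 0,
) -> Amplicon:
    """Predict the PCR product of a degenerate primer pair on a template.

    The forward primer is searched on the given strand and the reverse
    primer as its reverse complement.  The leftmost forward site is paired
    with the rightmost compatible reverse site.  Absence of a compatible
    site pair yields ``Amplicon(found=False)`` rather than an exception;
    multiple forward sites are all reported and flagged as ambiguous.
    """
    seq = template.sequence if isinstance(template, SeqRecord) else template.upper()
    fwd_sites = _find_sites(seq, pair.forward.upper(), max_mismatch)
    rev_rc = reverse_complement(pair.reverse)
    rev_sites = _find_sites(seq, rev_rc, max_mismatch)
    if not fwd_sites or not rev_sites:
        return Amplicon(found=False, forward_hits=tuple(fwd_sites), reverse_hits=tuple(rev_sites))
    f = fwd_sites[0]
    compatible = [s for s in rev_sites if s >= f + len(pair.forward)]
    if not compatible:
        return Amplicon(found=False, forward_hits=tuple(fwd_sites), reverse_hits=tuple(rev_sites))
    s = compatible[-1]
    end0 = s + len(rev_rc)  # half-open end == 1-based position of the reverse 3' base
    return Amplicon(
        found=True,
        start=f + 1,
        end=end0,
        sequence=seq[f:end0],
        forward_hits=tuple(fwd_sites),
        reverse_hits=tuple(rev_sites),
        ambiguous=len(fwd_sites) > 1,
    )
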