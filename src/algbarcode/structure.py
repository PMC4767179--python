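"""ITS2 secondary structures and compensatory base changes (CBCs).

A compensatory base change is a substitution at *both* nucleotides of a
conserved structural base pair between two sequences, with pairing
maintained (e.g. G·C -> A·U); a hemi-CBC changes only one side (G·C -> G·U).
CBC presence between a query and its closest reference is an established
predictor that the two belong to different species.

Structures are represented in dot-bracket notation (nested pairs only).
For biological data, externally predicted structures read from dot-bracket
files are the recommended input; a base-pair-maximisation folder
(:func:`fold_nussinov`) and alignment-based homology transfer
(:func:`transfer_structure`) are provided as desk-scale surrogates for
thermodynamic folding and template-based modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

from .align import Alignment, global_align
from .seqio import SeqRecord

__all__ = [
    "SecondaryStructure",
    "StructurePair",
    "CbcReport",
    "parse_dotbracket",
    "pairs_to_dotbracket",
    "fold_nussinov",
    "transfer_structure",
    "make_structure_pair",
    "count_cbc",
    "read_vienna",
    "write_vienna",
]

#: Canonical pairs, DNA alphabet (GU wobble included as GT).
CANONICAL = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")})


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class SecondaryStructure:
    """A sequence with its nested base pairing.

    ``pairs`` holds 0-based (i, j) with i < j.  Non-canonical pairs are
    permitted in the representation (they are flagged and excluded from CBC
    evaluation downstream).
    """

    sequence: str
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        seen: set[int] = set()
        for i, j in self.pairs:
            if not (0 <= i < j < n):
                raise ValueError(f"pair {(i, j)} out of bounds for length {n}")
            if i in seen or j in seen:
                raise ValueError(f"position in more than one pair: {(i, j)}")
            seen.update((i, j))
        for (i, j), (k, l) in [
            (p, q) for p in self.pairs for q in self.pairs if p < q
        ]:
            if i < k < j < l or k < i < l < j:
                raise ValueError(f"crossing (pseudoknotted) pairs: {(i, j)} and {(k, l)}")

    @property
    def dotbracket(self) -> str:
        return pairs_to_dotbracket(self.pairs, len(self.sequence))

    def non_canonical(self) -> frozenset[tuple[int, int]]:
        s = _norm(self.sequence)
        return frozenset(
            (i, j) for i, j in self.pairs if (s[i], s[j]) not in CANONICAL
        )

    def n_pairs(self) -> int:
        return len(self.pairs)


def parse_dotbracket(seq: str, db_string: str) -> SecondaryStructure:
    """Build a structure from dot-bracket notation via stack matching."""
    if len(seq) != len(db_string):
        raise ValueError("sequence and dot-bracket string must have equal length")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for i, ch in enumerate(db_string):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure(sequence=seq, pairs=frozenset(pairs))


def pairs_to_dotbracket(pairs: frozenset[tuple[int, int]], length: int) -> str:
    out = ["."] * length
    for i, j in pairs:
        out[i], out[j] = "(", ")"
    return "".join(out)


def fold_nussinov(seq: str | SeqRecord, min_loop: int = 3) -> SecondaryStructure:
    """Maximum-base-pairing fold (Nussinov DP).

    A deterministic stand-in for energy-minimisation folding: it maximises
    the number of nested canonical pairs (A·T/U, G·C, G·T/U) subject to a
    minimum hairpin loop of ``min_loop`` unpaired bases.  Traceback prefers
    closing a pair over bifurcation, taking the smallest partner index.
    """
    raw = seq.sequence if isinstance(seq, SeqRecord) else seq
    s = _norm(raw)
    n = len(s)
    if n < 2:
        return SecondaryStructure(sequence=raw, pairs=frozenset())
    can = [[(s[i], s[j]) in CANONICAL for j in range(n)] for i in range(n)]
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i][j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                if can[k][j]:
                    left = N[i][k - 1] if k > i else 0
                    inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    cand = left + 1 + inner
                    if cand > best:
                        best = cand
            N[i][j] = best
    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or N[i][j] == 0:
            continue
        paired = False
        for k in range(i, j - min_loop):
            if can[k][j]:
                left = N[i][k - 1] if k > i else 0
                inner = N[k + 1][j - 1] if k + 1 <= j - 1 else 0
                if left + 1 + inner == N[i][j]:
                    pairs.add((k, j))
                    if k > i:
                        stack.append((i, k - 1))
                    if k + 1 <= j - 1:
                        stack.append((k + 1, j - 1))
                    paired = True
                    break
        if not paired:
            stack.append((i, j - 1))
    return SecondaryStructure(sequence=raw, pairs=frozenset(pairs))


def transfer_structure(
    template: SecondaryStructure, target: SeqRecord | str
) -> SecondaryStructure:
    """Homology-transfer a template structure onto a related sequence.

    The template and target sequences are globally aligned; template pairs
    whose two positions both map onto target residues are kept, all others
    are dropped.
    """
    target_seq = target.sequence if isinstance(target, SeqRecord) else target
    a = SeqRecord(id="__template__", sequence=template.sequence)
    b = SeqRecord(id="__target__", sequence=target_seq)
    aln = global_align(a, b)
    row_t, row_q = aln.records[0].sequence, aln.records[1].sequence
    # template position -> target position (None where target is gapped)
    mapping: dict[int, int | None] = {}
    ti = qi = 0
    for x, y in zip(row_t, row_q):
        if x != "-" and y != "-":
            mapping[ti] = qi
        elif x != "-":
            mapping[ti] = None
        if x != "-":
            ti += 1
        if y != "-":
            qi += 1
    pairs = set()
    for i, j in template.pairs:
        mi, mj = mapping.get(i), mapping.get(j)
        if mi is not None and mj is not None and mi < mj:
            pairs.add((mi, mj))
    return SecondaryStructure(sequence=target_seq, pairs=frozenset(pairs))


@dataclass(frozen=True)
class StructurePair:
    """Two sequence/structure pairs on a common alignment.

    ``aligned_a``/``aligned_b`` are the gapped rows; ``pairs_a``/``pairs_b``
    are the structures' pairs mapped to alignment columns; ``shared_pairs``
    is their intersection — the conserved structural pairs on which CBCs are
    evaluated.
    """

    aligned_a: str
    aligned_b: str
    pairs_a: frozenset[tuple[int, int]]
    pairs_b: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows must have equal length")

    @property
    def shared_pairs(self) -> frozenset[tuple[int, int]]:
        return self.pairs_a & self.pairs_b


def _map_to_columns(
    pairs: frozenset[tuple[int, int]], aligned_row: str
) -> frozenset[tuple[int, int]]:
    col_of: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(aligned_row):
        if ch != "-":
            col_of[pos] = col
            pos += 1
    return frozenset(
        (col_of[i], col_of[j]) for i, j in pairs if i in col_of and j in col_of
    )


def make_structure_pair(a: SecondaryStructure, b: SecondaryStructure) -> StructurePair:
    """Align two sequence/structure pairs and map their pairs to columns."""
    ra = SeqRecord(id="__a__", sequence=a.sequence)
    rb = SeqRecord(id="__b__", sequence=b.sequence)
    aln = global_align(ra, rb)
    row_a, row_b = aln.records[0].sequence, aln.records[1].sequence
    return StructurePair(
        aligned_a=row_a,
        aligned_b=row_b,
        pairs_a=_map_to_columns(a.pairs, row_a),
        pairs_b=_map_to_columns(b.pairs, row_b),
    )


@dataclass(frozen=True)
class CbcReport:
    """CBC/hemi-CBC counts with per-pair detail.

    ``detail`` rows are (column_i, column_j, bases_in_a, bases_in_b,
    category) with category in {"cbc", "hemi-cbc", "unchanged",
    "non-canonical", "gapped"}.
    """

    cbc: int
    hemi_cbc: int
    unchanged: int
    skipped_non_canonical: int
    skipped_gapped: int
    detail: tuple[tuple[int, int, str, str, str], ...] = field(default=(), repr=False)

    @property
    def evaluated(self) -> int:
        return self.cbc + self.hemi_cbc + self.unchanged


def count_cbc(pair: StructurePair) -> CbcReport:
    """Count CBCs and hemi-CBCs over the shared structural pairs.

    A shared pair is evaluated only when both alignment columns are
    ungapped in both sequences and the base pair is canonical in both:
    CBC when both sides differ between the sequences, hemi-CBC when
    exactly one side differs.  Gapped or non-canonical shared pairs are
    skipped and reported separately.
    """
    a, b = _norm(pair.aligned_a), _norm(pair.aligned_b)
    cbc = hemi = same = non_canon = gapped = 0
    detail = []
    for i, j in sorted(pair.shared_pairs):
        xa, ya = a[i], a[j]
        xb, yb = b[i], b[j]
        bases_a, bases_b = f"{xa}-{ya}", f"{xb}-{yb}"
        if "-" in (xa, ya, xb, yb):
            gapped += 1
            detail.append((i, j, bases_a, bases_b, "gapped"))
            continue
        if (xa, ya) not in CANONICAL or (xb, yb) not in CANONICAL:
            non_canon += 1
            detail.append((i, j, bases_a, bases_b, "non-canonical"))
            continue
        diff_x, diff_y = xa != xb, ya != yb
        if diff_x and diff_y:
            cbc += 1
            cat = "cbc"
        elif diff_x or diff_y:
            hemi += 1
            cat = "hemi-cbc"
        else:
            same += 1
            cat = "unchanged"
        detail.append((i, j, bases_a, bases_b, cat))
    return CbcReport(
        cbc=cbc,
        hemi_cbc=hemi,
        unchanged=same,
        skipped_non_canonical=non_canon,
        skipped_gapped=gapped,
        detail=tuple(detail),
    )


# ---------------------------------------------------------------------------
# Vienna (dot-bracket) file I/O
# ---------------------------------------------------------------------------

def read_vienna(path: str | Path) -> dict[str, SecondaryStructure]:
    """Read a Vienna-format file: >id / sequence / dot-bracket triples."""
    structures: dict[str, SecondaryStructure] = {}
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"{path}: expected '>' header at line {i + 1}")
        name = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise ValueError(f"{path}: truncated entry {name!r}")
        seq, db = lines[i + 1], lines[i + 2].split()[0]
        structures[name] = parse_dotbracket(seq, db)
        i += 3
    if not structures:
        raise ValueError(f"{path}: no structures found")
    return structures


def write_vienna(structures: dict[str, SecondaryStructure], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, st in structures.items():
            fh.write(f">{name}\n{st.sequence}\n{st.dotbracket}\n")
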