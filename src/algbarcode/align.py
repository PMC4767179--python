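"""Alignment utilities and uncorrected p-distances.

The quantitative core of barcode-gap analysis is the uncorrected pairwise
(p) distance: the proportion of differing sites among compared sites.  Two
gap policies are supported and always recorded in the output:

``pairwise_deletion``
    For each pair, columns where either row carries a gap or an ambiguity
    code are skipped.  This is the default for pairwise distances.
``complete_deletion``
    Columns carrying a gap or ambiguity in *any* row are removed once for
    the whole alignment before any pair is compared.

Ambiguity codes (N and partial codes) are excluded from compared sites
rather than counted as mismatches.

A Needleman–Wunsch global aligner with a deterministic traceback and a
center-star multiple aligner are included for desk-scale work and synthetic
fixtures; externally aligned FASTA is the expected input for real analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .seqio import SeqRecord
from .util import round_half_up

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "GapPolicy",
    "global_align",
    "percent_identity",
    "p_distance",
    "distance_matrix",
    "center_star_msa",
    "dedupe_genotypes",
    "nucleotide_diversity",
]

GapPolicy = Literal["pairwise_deletion", "complete_deletion"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MISSING = 255  # gaps and ambiguity codes: excluded from compared sites


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as uint8: A,C,G,T -> 0..3; gap/ambiguity -> 255."""
    arr = np.full(len(seq), _MISSING, dtype=np.uint8)
    for i, ch in enumerate(seq):
        arr[i] = _CODE.get(ch, _MISSING)
    return arr


@dataclass(frozen=True)
class Alignment:
    """A gapped alignment of two or more records (all rows equal length)."""

    records: tuple[SeqRecord, ...]
    score: float | None = None

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        for r in self.records:
            if not r.sequence.replace("-", ""):
                raise ValueError(f"row {r.id!r} is all gaps")

    @property
    def length(self) -> int:
        return len(self.records[0].sequence)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def row(self, rid: str) -> str:
        for r in self.records:
            if r.id == rid:
                return r.sequence
        raise KeyError(rid)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of p-distances with its gap policy recorded."""

    labels: tuple[str, ...]
    values: np.ndarray
    gap_policy: GapPolicy = "pairwise_deletion"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        if np.nanmin(v) < 0 or np.nanmax(v) > 1:
            raise ValueError("p-distances must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", float_format="%.6f")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self)}\n")
            for label, row in zip(self.labels, self.values):
                fh.write(label + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Pairwise global alignment (Needleman–Wunsch, linear gap penalty)
# ---------------------------------------------------------------------------

def global_align(
    a: SeqRecord,
    b: SeqRecord,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> Alignment:
    """Optimal global alignment of two unaligned records.

    Traceback ties are broken deterministically: substitution is preferred
    over a gap in ``a``, which is preferred over a gap in ``b``.
    """
    s1, s2 = a.sequence, b.sequence
    if not s1 or not s2:
        raise ValueError("cannot align an empty sequence")
    n, m = len(s1), len(s2)
    H = np.empty((n + 1, m + 1), dtype=float)
    H[0, :] = gap * np.arange(m + 1)
    H[:, 0] = gap * np.arange(n + 1)
    sub = np.where(
        encode_pairs_equal(s1, s2), match, mismatch
    )  # (n, m) substitution scores
    # row recurrence: H[i,j] = max(diag, up, H[i,j-1]+gap).  With a linear
    # gap penalty the left-dependency is a prefix scan:
    # H[i,j] = gap*j + cummax(c[k] - gap*k) with c = [H[i,0], max(diag, up)].
    offsets = gap * np.arange(m + 1)
    c = np.empty(m + 1)
    for i in range(1, n + 1):
        np.maximum(H[i - 1, :-1] + sub[i - 1], H[i - 1, 1:] + gap, out=c[1:])
        c[0] = H[i, 0]
        H[i] = np.maximum.accumulate(c - offsets) + offsets
    # traceback: prefer diagonal, then gap-in-a (consume b), then gap-in-b
    out1, out2 = [], []
    i, j = n, m
    while i > 0 or j > 0:
        here = H[i, j]
        if i > 0 and j > 0 and np.isclose(here, H[i - 1, j - 1] + sub[i - 1, j - 1]):
            out1.append(s1[i - 1])
            out2.append(s2[j - 1])
            i, j = i - 1, j - 1
        elif j > 0 and np.isclose(here, H[i, j - 1] + gap):
            out1.append("-")
            out2.append(s2[j - 1])
            j -= 1
        else:
            out1.append(s1[i - 1])
            out2.append("-")
            i -= 1
    row_a = replace(a, sequence="".join(reversed(out1)))
    row_b = replace(b, sequence="".join(reversed(out2)))
    return Alignment(records=(row_a, row_b), score=float(H[n, m]))


def encode_pairs_equal(s1: str, s2: str) -> np.ndarray:
    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2.encode(), dtype=np.uint8)
    return a1[:, None] == a2[None, :]


# ---------------------------------------------------------------------------
# Identity and p-distance
# ---------------------------------------------------------------------------

def _core_region(r1: str, r2: str) -> tuple[int, int]:
    """Columns inside both rows' terminal-gap trims (half-open)."""
    def span(row: str) -> tuple[int, int]:
        first = len(row) - len(row.lstrip("-"))
        last = len(row.rstrip("-"))
        return first, last

    (f1, l1), (f2, l2) = span(r1), span(r2)
    return max(f1, f2), min(l1, l2)


def percent_identity(
    alignment: Alignment,
    policy: Literal["exclude_end_gaps", "all_columns"] = "exclude_end_gaps",
) -> float:
    """Percent identity of a pairwise alignment.

    ``exclude_end_gaps`` (default) ignores terminal-gap columns and skips
    columns where either row carries an internal gap or ambiguity code, so
    identity and p-distance are exact complements on the compared sites.
    ``all_columns`` counts every alignment column, gap columns as
    mismatches.  Full precision is returned; round for printed-table
    comparisons.
    """
    if len(alignment.records) != 2:
        raise ValueError("percent_identity is defined for pairwise alignments")
    r1, r2 = (r.sequence for r in alignment.records)
    if policy == "all_columns":
        compared = len(r1)
        matches = sum(
            1 for x, y in zip(r1, r2) if x == y and x != "-"
        )
    else:
        start, stop = _core_region(r1, r2)
        compared = matches = 0
        for x, y in zip(r1[start:stop], r2[start:stop]):
            if x not in _CODE or y not in _CODE:
                continue
            compared += 1
            if x == y:
                matches += 1
    if compared == 0:
        raise ValueError("no compared columns")
    return 100.0 * matches / compared


def p_distance(
    row_a: str | SeqRecord,
    row_b: str | SeqRecord,
    gap_policy: GapPolicy = "pairwise_deletion",
) -> float:
    """Uncorrected p-distance between two equal-length aligned rows.

    Columns where either row carries a gap or an ambiguity code are
    excluded from the compared sites.  For two rows the two gap policies
    coincide; the argument is accepted for interface symmetry.
    """
    s1 = row_a.sequence if isinstance(row_a, SeqRecord) else row_a
    s2 = row_b.sequence if isinstance(row_b, SeqRecord) else row_b
    if len(s1) != len(s2):
        raise ValueError("rows must have equal length")
    e1, e2 = encode(s1), encode(s2)
    ok = (e1 != _MISSING) & (e2 != _MISSING)
    compared = int(ok.sum())
    if compared == 0:
        raise ValueError("no comparable sites between the two rows")
    mismatches = int(((e1 != e2) & ok).sum())
    return mismatches / compared


def distance_matrix(
    alignment: Alignment | Sequence[SeqRecord],
    gap_policy: GapPolicy = "pairwise_deletion",
) -> DistanceMatrix:
    """All pairwise p-distances of an alignment.

    Under ``complete_deletion`` the columns carrying any gap/ambiguity are
    removed once for all rows first.
    """
    records = alignment.records if isinstance(alignment, Alignment) else tuple(alignment)
    if len(records) < 2:
        raise ValueError("need at least 2 rows")
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise ValueError("rows must have equal length")
    enc = np.stack([encode(r.sequence) for r in records])
    if gap_policy == "complete_deletion":
        keep = (enc != _MISSING).all(axis=0)
        if not keep.any():
            raise ValueError("complete deletion removed all columns")
        enc = enc[:, keep]
    elif gap_policy != "pairwise_deletion":
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    n = len(records)
    labels = tuple(r.id for r in records)
    values = np.zeros((n, n), dtype=float)
    present = enc != _MISSING
    for i in range(n):
        ok = present[i] & present[i + 1 :]
        compared = ok.sum(axis=1)
        if (compared == 0).any():
            j = i + 1 + int(np.argmax(compared == 0))
            raise ValueError(
                f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
            )
        diff = ((enc[i] != enc[i + 1 :]) & ok).sum(axis=1)
        values[i, i + 1 :] = diff / compared
    values = values + values.T
    return DistanceMatrix(labels=labels, values=values, gap_policy=gap_policy)


# ---------------------------------------------------------------------------
# Center-star multiple alignment (fixture aligner for synthetic/toy data)
# ---------------------------------------------------------------------------

def center_star_msa(records: Sequence[SeqRecord], **align_kwargs) -> Alignment:
    """Center-star multiple alignment ("once a gap, always a gap").

    The center is the record minimising the summed pairwise alignment cost
    to all others; every other record is merged into the master alignment
    via its pairwise alignment to the center.  Intended for synthetic and
    toy data, not as a replacement for a production aligner.
    """
    records = list(records)
    if not records:
        raise ValueError("empty input")
    if len(records) == 1:
        raise ValueError("need at least 2 records for an MSA")
    pairwise: dict[tuple[int, int], Alignment] = {}
    cost = np.zeros(len(records))
    for i, j in itertools.combinations(range(len(records)), 2):
        aln = global_align(records[i], records[j], **align_kwargs)
        pairwise[(i, j)] = aln
        d = p_distance(aln.records[0].sequence, aln.records[1].sequence)
        cost[i] += d
        cost[j] += d
    c = int(np.argmin(cost))
    center = records[c]
    # master alignment: row 0 is the (progressively gapped) center
    master_rows: list[str] = [center.sequence]
    master_ids = [c]
    for idx in range(len(records)):
        if idx == c:
            continue
        key = (c, idx) if c < idx else (idx, c)
        aln = pairwise[key]
        c_row, o_row = aln.row(center.id), aln.row(records[idx].id)
        mc = master_rows[0]
        # merge the two gap patterns of the center (same ungapped content)
        merged_master: list[list[str]] = [[] for _ in master_rows]
        merged_new: list[str] = []
        i = j = 0
        while i < len(mc) or j < len(c_row):
            take_master = i < len(mc) and mc[i] == "-"
            take_pair = j < len(c_row) and c_row[j] == "-"
            if i < len(mc) and j < len(c_row) and not take_master and not take_pair:
                for k, row in enumerate(master_rows):
                    merged_master[k].append(row[i])
                merged_new.append(o_row[j])
                i += 1
                j += 1
            elif take_master or j >= len(c_row):
                for k, row in enumerate(master_rows):
                    merged_master[k].append(row[i])
                merged_new.append("-")
                i += 1
            else:
                for k in range(len(master_rows)):
                    merged_master[k].append("-")
                merged_new.append(o_row[j])
                j += 1
        master_rows = ["".join(r) for r in merged_master] + ["".join(merged_new)]
        master_ids.append(idx)
    order = sorted(range(len(master_ids)), key=lambda k: master_ids[k])
    out = tuple(
        replace(records[master_ids[k]], sequence=master_rows[k]) for k in order
    )
    return Alignment(records=out)


# ---------------------------------------------------------------------------
# Genotypes and diversity
# ---------------------------------------------------------------------------

def dedupe_genotypes(records: Iterable[SeqRecord]) -> list[list[SeqRecord]]:
    """Group records of one marker into exact-identity genotypes.

    Sequences are compared after uppercasing, U->T normalisation and
    trimming of leading/trailing N runs.  The number of distinct genotypes
    is ``len(result)``.
    """
    groups: dict[str, list[SeqRecord]] = {}
    for rec in records:
        key = rec.sequence.upper().replace("U", "T").strip("N")
        groups.setdefault(key, []).append(rec)
    return list(groups.values())


def nucleotide_diversity(
    alignment: Alignment | Sequence[SeqRecord],
    gap_policy: GapPolicy = "pairwise_deletion",
) -> float:
    """Nucleotide diversity (pi): mean p-distance over all unordered pairs."""
    dm = distance_matrix(alignment, gap_policy)
    n = len(dm)
    iu = np.triu_indices(n, k=1)
    return float(dm.values[iu].mean())
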