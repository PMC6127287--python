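"""Multiple alignment and per-column base profiles.

Conserved-window discovery needs a column-wise view of the target set.
This module either ingests a pre-computed alignment (the recommended path
for more than a few hundred sequences) or builds one with a self-contained
progressive aligner: a k-mer-distance guide tree (UPGMA, k=6) followed by
affine-gap global profile-profile alignment (Gotoh), deterministic given
inputs and parameters.

Scoring convention: ``match``/``mismatch`` per column pair; a gap run of
length L costs ``gap_open + L * gap_extend`` (i.e. the first gap column
costs ``gap_open + gap_extend``). Defaults: +1/-1/-4/-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree

from .seqio import GAP, IUPAC_BASES, SequenceError, SequenceRecord

__all__ = [
    "Alignment",
    "ColumnProfile",
    "AlignScoring",
    "align_progressive",
    "align_pair",
    "column_profiles",
    "minimal_degenerate_consensus",
    "GAP_FLAG",
]

#: Sentinel returned by :func:`minimal_degenerate_consensus` for columns
#: containing at least one gap (such columns are disqualified from primers).
GAP_FLAG = GAP

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_NEG = -1e30


@dataclass(frozen=True)
class AlignScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -4.0
    gap_extend: float = -1.0

    @property
    def first_gap_column(self) -> float:
        return self.gap_open + self.gap_extend


@dataclass
class Alignment:
    """An ordered set of equal-length gapped sequences."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise SequenceError("alignment must contain at least one record")
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) != 1:
            raise SequenceError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    @property
    def n_rows(self) -> int:
        return len(self.records)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)

    def ungapped_records(self) -> list[SequenceRecord]:
        return [r.without_gaps() for r in self.records]

    def column_to_position(self, row: int) -> np.ndarray:
        """Map alignment column -> 0-based ungapped position in *row*.

        For a gap column the value is the position of the next non-gap
        residue (so spans convert cleanly under half-open semantics).
        """
        residues = self.records[row].residues
        is_base = np.frombuffer(residues.encode(), dtype=np.uint8) != ord(GAP)
        return np.concatenate([[0], np.cumsum(is_base)])[:-1]


@dataclass(frozen=True)
class ColumnProfile:
    """Integer residue tallies for one alignment column.

    ``counts`` buckets rows into A/C/G/T/gap/other ("other" = degenerate
    input letters); ``weights`` spreads degenerate letters fractionally
    over their bases (1/|bases| each), which is what consensus calling
    consumes.
    """

    column_index: int
    counts: dict[str, int]
    weights: dict[str, float]


def column_profiles(aln: Alignment) -> list[ColumnProfile]:
    """One :class:`ColumnProfile` per column; counts sum to the row count."""
    profiles = []
    for j in range(aln.n_columns):
        counts = {"A": 0, "C": 0, "G": 0, "T": 0, "gap": 0, "other": 0}
        weights = {"A": 0.0, "C": 0.0, "G": 0.0, "T": 0.0}
        for rec in aln.records:
            letter = rec.residues[j]
            if letter == GAP:
                counts["gap"] += 1
                continue
            bases = IUPAC_BASES[letter]
            if len(bases) == 1:
                counts[letter] += 1
            else:
                counts["other"] += 1
            w = 1.0 / len(bases)
            for b in bases:
                weights[b] += w
        profiles.append(ColumnProfile(j, counts, weights))
    return profiles


def minimal_degenerate_consensus(profile: ColumnProfile, min_fraction: float = 0.0) -> str:
    """Smallest IUPAC code covering the column's observed bases.

    Bases whose fractional frequency among non-gap observations is below
    *min_fraction* are dropped (default 0: every observed base must be
    covered, i.e. the consensus primer matches all targets at this
    column). Returns :data:`GAP_FLAG` if the column contains any gap.
    """
    if not 0.0 <= min_fraction <= 0.5:
        raise ValueError("min_fraction must be in [0, 0.5]")
    if profile.counts.get("gap", 0) > 0:
        return GAP_FLAG
    total = sum(profile.weights.values())
    if total <= 0:
        raise SequenceError(f"empty column profile at column {profile.column_index}")
    kept = {b for b, w in profile.weights.items() if w > 0 and w / total >= min_fraction}
    if not kept:  # min_fraction excluded everything; keep the modal base
        kept = {max(profile.weights, key=profile.weights.get)}
    from .seqio import smallest_code_for

    return smallest_code_for(kept)


# ---------------------------------------------------------------------------
# Progressive alignment machinery


def _freq_matrix(rows: Sequence[str]) -> np.ndarray:
    """(n_cols, 4) fractional base frequencies; gaps contribute zero."""
    n_cols = len(rows[0])
    F = np.zeros((n_cols, 4))
    for row in rows:
        for j, letter in enumerate(row):
            if letter == GAP:
                continue
            bases = IUPAC_BASES[letter]
            w = 1.0 / len(bases)
            for b in bases:
                F[j, _BASE_INDEX[b]] += w
    return F / len(rows)


def _profile_gotoh(rows_a: Sequence[str], rows_b: Sequence[str],
                   scoring: AlignScoring) -> tuple[float, list[tuple[int | None, int | None]]]:
    """Affine-gap global alignment of two gapped profiles.

    Returns the optimal score and the column-pair path as a list of
    ``(i, j)`` with ``None`` marking an inserted gap column.
    Vectorized row-wise; the horizontal gap state is resolved with a
    running-maximum scan, so the whole DP is O(n*m) numpy work.
    """
    FA = _freq_matrix(rows_a)
    FB = _freq_matrix(rows_b)
    n, m = FA.shape[0], FB.shape[0]
    sub = np.full((4, 4), scoring.mismatch) + np.eye(4) * (scoring.match - scoring.mismatch)
    S = FA @ sub @ FB.T  # (n, m) expected column-pair score

    goc, ge = scoring.first_gap_column, scoring.gap_extend
    M = np.full((n + 1, m + 1), _NEG)
    Ix = np.full((n + 1, m + 1), _NEG)  # gap in B (consumes A column)
    Iy = np.full((n + 1, m + 1), _NEG)  # gap in A (consumes B column)
    M[0, 0] = 0.0
    cols = np.arange(m + 1)
    # row 0: only horizontal gaps possible
    # scan identity: Iy[i,j] = max_{k<j} (max(M,Ix)[i,k] + goc + ge*(j-1-k))
    t0 = np.maximum(M[0], Ix[0]) + goc - ge * cols
    run0 = np.maximum.accumulate(t0)
    Iy[0, 1:] = run0[:-1] + ge * cols[:-1]
    for i in range(1, n + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
        M[i, 1:] = S[i - 1, :] + prev_best[:-1]
        Ix[i] = np.maximum(np.maximum(M[i - 1], Iy[i - 1]) + goc, Ix[i - 1] + ge)
        t = np.maximum(M[i], Ix[i]) + goc - ge * cols
        run = np.maximum.accumulate(t)
        Iy[i, 1:] = run[:-1] + ge * cols[:-1]

    # traceback (tolerant float comparison: the scan computes Iy in a
    # different op order than the scalar recurrence)
    tol = 1e-6
    state = int(np.argmax([M[n, m], Ix[n, m], Iy[n, m]]))
    score = float([M[n, m], Ix[n, m], Iy[n, m]][state])
    path: list[tuple[int | None, int | None]] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:  # M
            target = M[i, j] - S[i - 1, j - 1]
            path.append((i - 1, j - 1))
            if abs(M[i - 1, j - 1] - target) <= tol:
                state = 0
            elif abs(Ix[i - 1, j - 1] - target) <= tol:
                state = 1
            else:
                state = 2
            i, j = i - 1, j - 1
        elif state == 1:  # Ix: gap in B
            path.append((i - 1, None))
            if abs(M[i - 1, j] + goc - Ix[i, j]) <= tol:
                state = 0
            elif abs(Iy[i - 1, j] + goc - Ix[i, j]) <= tol:
                state = 2
            i -= 1
        else:  # Iy: gap in A
            path.append((None, j - 1))
            if abs(M[i, j - 1] + goc - Iy[i, j]) <= tol:
                state = 0
            elif abs(Ix[i, j - 1] + goc - Iy[i, j]) <= tol:
                state = 1
            j -= 1
    path.reverse()
    return score, path


def _merge(rows_a: Sequence[str], rows_b: Sequence[str],
           path: list[tuple[int | None, int | None]]) -> tuple[list[str], list[str]]:
    out_a = ["".join(row[i] if i is not None else GAP for i, _ in path) for row in rows_a]
    out_b = ["".join(row[j] if j is not None else GAP for _, j in path) for row in rows_b]
    return out_a, out_b


def align_pair(a: str, b: str, scoring: AlignScoring = AlignScoring()) -> tuple[float, str, str]:
    """Global affine-gap alignment of two ungapped sequences."""
    score, path = _profile_gotoh([a], [b], scoring)
    (ra,), (rb,) = _merge([a], [b], path)
    return score, ra, rb


def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    if len(seq) < k:
        counts[seq] = 1
        return counts
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _kmer_distance_matrix(seqs: Sequence[str], k: int = 6) -> np.ndarray:
    profiles = [_kmer_counts(s, k) for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = profiles[i], profiles[j]
            if len(pj) < len(pi):
                pi, pj = pj, pi
            common = sum(min(c, pj.get(kmer, 0)) for kmer, c in pi.items())
            denom = min(max(len(seqs[i]) - k + 1, 1), max(len(seqs[j]) - k + 1, 1))
            D[i, j] = D[j, i] = 1.0 - common / denom
    return D


def align_progressive(records: Sequence[SequenceRecord],
                      match: float = 1.0, mismatch: float = -1.0,
                      gap_open: float = -4.0, gap_extend: float = -1.0,
                      guide_k: int = 6) -> Alignment:
    """Progressive multiple alignment.

    A UPGMA guide tree on pairwise k-mer distances (k=6 by default) fixes
    the merge order; each merge is an affine-gap global profile-profile
    alignment. Deterministic given inputs and parameters (ties broken by
    input order via the linkage implementation). Intended for desk-scale
    jobs (up to a few hundred sequences of a couple of kb); supply a
    pre-computed alignment beyond that.
    """
    records = [r.without_gaps() for r in records]
    scoring = AlignScoring(match, mismatch, gap_open, gap_extend)
    if len(records) == 1:
        warnings.warn("single sequence: returning a 1-row alignment")
        return Alignment(list(records))
    if len(records) == 2:
        _, ra, rb = align_pair(records[0].residues, records[1].residues, scoring)
        return Alignment([SequenceRecord(records[0].id, ra, records[0].description),
                          SequenceRecord(records[1].id, rb, records[1].description)])

    seqs = [r.residues for r in records]
    D = _kmer_distance_matrix(seqs, guide_k)
    condensed = D[np.triu_indices(len(seqs), k=1)]
    tree = to_tree(linkage(condensed, method="average"))

    def build(node) -> tuple[list[int], list[str]]:
        if node.is_leaf():
            return [node.id], [seqs[node.id]]
        idx_l, rows_l = build(node.left)
        idx_r, rows_r = build(node.right)
        _, path = _profile_gotoh(rows_l, rows_r, scoring)
        merged_l, merged_r = _merge(rows_l, rows_r, path)
        return idx_l + idx_r, merged_l + merged_r

    order, rows = build(tree)
    # restore input order
    by_input = sorted(range(len(order)), key=lambda p: order[p])
    out = [SequenceRecord(records[order[p]].id, rows[p], records[order[p]].description)
           for p in by_input]
    return Alignment(out)


def profiles_to_tsv(profiles: Iterable[ColumnProfile], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("column\tA\tC\tG\tT\tgap\tother\n")
        for p in profiles:
            c = p.counts
            fh.write(f"{p.column_index}\t{c['A']}\t{c['C']}\t{c['G']}\t{c['T']}"
                     f"\t{c['gap']}\t{c['other']}\n")
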