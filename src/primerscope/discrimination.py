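"""Amplicon-region discriminability: distances, thresholds, NJ trees.

A primer pair is only useful for species-level surveys if the region it
amplifies separates species. This module scores that: pairwise identity
from global affine-gap alignments, distance matrices under p-distance /
JC69 / K2P models, the fraction of sequence pairs that remain
indistinguishable at an identity threshold (98% by convention), and a
neighbor-joining tree over the amplified region.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from skbio import DistanceMatrix, TreeNode

from .msa import AlignScoring
from .seqio import GAP, SequenceRecord

__all__ = [
    "pairwise_identity",
    "pairwise_identity_matrix",
    "distance_matrix",
    "indistinguishable_fraction",
    "neighbor_joining",
    "compare_resolution",
    "ResolutionReport",
    "tree_to_newick",
    "newick_to_tree",
]


def _aligner(scoring: AlignScoring = AlignScoring()) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # first gap column costs gap_open + gap_extend, as in the msa module
    aligner.open_gap_score = scoring.first_gap_column
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def _aligned_rows(a: str, b: str, scoring: AlignScoring) -> tuple[str, str]:
    alignment = _aligner(scoring).align(a, b)[0]
    return str(alignment[0]), str(alignment[1])


def _core_bounds(ra: str, rb: str) -> tuple[int, int]:
    """[start, end) of the region between terminal-gap runs."""
    n = len(ra)
    start = 0
    while start < n and (ra[start] == GAP or rb[start] == GAP):
        start += 1
    end = n
    while end > start and (ra[end - 1] == GAP or rb[end - 1] == GAP):
        end -= 1
    return start, end


def pairwise_identity(a: str | SequenceRecord, b: str | SequenceRecord,
                      scoring: AlignScoring = AlignScoring()) -> float:
    """Fraction of identical columns in the global alignment of a and b.

    The denominator is the aligned length excluding terminal-gap columns,
    so a partial sequence nested in a longer one is not penalized for
    missing ends; internal gap columns do count as differences.
    """
    sa = a.ungapped if isinstance(a, SequenceRecord) else a
    sb = b.ungapped if isinstance(b, SequenceRecord) else b
    if not sa or not sb:
        raise ValueError("empty sequence")
    if sa == sb:
        return 1.0
    ra, rb = _aligned_rows(sa, sb, scoring)
    start, end = _core_bounds(ra, rb)
    if end <= start:
        return 0.0
    matches = sum(1 for x, y in zip(ra[start:end], rb[start:end])
                  if x == y and x != GAP)
    return matches / (end - start)


def pairwise_identity_matrix(records: list[SequenceRecord],
                             scoring: AlignScoring = AlignScoring()
                             ) -> tuple[list[str], np.ndarray]:
    """Symmetric all-vs-all identity matrix (diagonal 1)."""
    labels = [r.id for r in records]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate record ids")
    n = len(records)
    M = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = pairwise_identity(records[i], records[j], scoring)
    return labels, M


def _transition(x: str, y: str) -> bool:
    return {x, y} in ({"A", "G"}, {"C", "T"})


def distance_matrix(inserts: list[SequenceRecord], model: str = "p",
                    scoring: AlignScoring = AlignScoring(),
                    max_distance: float = 5.0) -> DistanceMatrix:
    """Pairwise evolutionary distances over the amplified region.

    Models: ``p`` (p-distance = 1 - identity), ``jc69``
    (-(3/4) ln(1 - 4p/3)), ``k2p`` (Kimura two-parameter from transition
    and transversion proportions). Saturated distances (non-positive log
    argument) are set to *max_distance* with a warning.
    """
    if model not in {"p", "jc69", "k2p"}:
        raise ValueError(f"unknown model {model!r}")
    if len(inserts) < 2:
        raise ValueError("need at least 2 sequences")
    labels = [r.id for r in inserts]
    n = len(inserts)
    D = np.zeros((n, n))
    saturated = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = inserts[i].ungapped, inserts[j].ungapped
            ra, rb = _aligned_rows(a, b, scoring)
            start, end = _core_bounds(ra, rb)
            core = [(x, y) for x, y in zip(ra[start:end], rb[start:end])]
            aligned = max(end - start, 1)
            diffs = sum(1 for x, y in core if not (x == y and x != GAP))
            p = diffs / aligned
            if model == "p":
                d = p
            elif model == "jc69":
                arg = 1.0 - 4.0 * p / 3.0
                if arg <= 0:
                    d, saturated = max_distance, saturated + 1
                else:
                    d = -0.75 * math.log(arg)
            else:  # k2p over both-base columns
                comp = [(x, y) for x, y in core if x != GAP and y != GAP]
                nc = max(len(comp), 1)
                P = sum(1 for x, y in comp if x != y and _transition(x, y)) / nc
                Q = sum(1 for x, y in comp if x != y and not _transition(x, y)) / nc
                arg1, arg2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
                if arg1 <= 0 or arg2 <= 0:
                    d, saturated = max_distance, saturated + 1
                else:
                    d = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
            D[i, j] = D[j, i] = d
    if saturated:
        warnings.warn(f"{saturated} saturated pairwise distances set to {max_distance}")
    return DistanceMatrix(D, ids=labels)


def indistinguishable_fraction(identities, threshold: float,
                               labels: list[str] | None = None,
                               species_of: dict[str, str] | None = None) -> float:
    """Share of unordered pairs at or above the identity threshold.

    *identities* is either a square identity matrix (diagonal 1) or a
    :class:`skbio.DistanceMatrix` of p-distances (identity = 1 - d).
    By default the denominator is all n(n-1)/2 pairs; with *species_of*
    (id -> species label) only pairs of distinct species are counted in
    numerator and denominator.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if isinstance(identities, DistanceMatrix):
        labels = list(identities.ids)
        M = 1.0 - identities.data
        np.fill_diagonal(M, 1.0)
    else:
        M = np.asarray(identities, dtype=float)
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least 2 sequences")
    hits = total = 0
    for i in range(n):
        for j in range(i + 1, n):
            if species_of is not None:
                if labels is None:
                    raise ValueError("species_of requires labels")
                if species_of[labels[i]] == species_of[labels[j]]:
                    continue
            total += 1
            if M[i, j] >= threshold:
                hits += 1
    if total == 0:
        raise ValueError("no eligible pairs")
    return hits / total


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Among equal-Q candidate joins the pair whose (lexicographically
    smallest leaf label, partner) is lowest is taken. Negative branch
    lengths are clamped to zero with a warning. Additive matrices are
    reproduced exactly by tree path lengths.
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("need at least 3 labels for a tree")
    D = np.array(dm.data, dtype=float)
    if np.any(D < 0):
        raise ValueError("negative distances")
    nodes = [TreeNode(name=name) for name in labels]
    reps = list(labels)  # smallest leaf label under each active node
    clamped = 0

    def attach(parent: TreeNode, child: TreeNode, length: float) -> None:
        nonlocal clamped
        if length < 0:
            clamped += 1
            length = 0.0
        child.length = float(length)
        parent.append(child)

    while len(nodes) > 3:
        r = len(nodes)
        rowsum = D.sum(axis=1)
        best = None
        for i in range(r):
            for j in range(i + 1, r):
                q = (r - 2) * D[i, j] - rowsum[i] - rowsum[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        new = TreeNode()
        attach(new, nodes[i], li)
        attach(new, nodes[j], lj)
        d_new = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        D2 = np.zeros((r - 1, r - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = d_new[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        reps = [reps[k] for k in keep] + [min(reps[i], reps[j])]

    # final three-way join at an unrooted (trifurcating) root
    root = TreeNode()
    (i, j, k) = (0, 1, 2)
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        attach(root, nodes[idx], length)
    if clamped:
        warnings.warn(f"{clamped} negative NJ branch lengths clamped to 0")
    return root


def tree_to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def newick_to_tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick), format="newick")


@dataclass(frozen=True)
class ResolutionReport:
    fraction_full: float
    fraction_insert: float
    detail: pd.DataFrame  # pairs distinguishable in one region but not the other


def compare_resolution(full_length: list[SequenceRecord],
                       inserts: list[SequenceRecord],
                       threshold: float = 0.98,
                       scoring: AlignScoring = AlignScoring()) -> ResolutionReport:
    """Indistinguishable-pair fractions of full sequences vs inserts.

    Label sets must match exactly; the detail table lists every pair
    whose distinguishability differs between the two regions.
    """
    ids_full = {r.id for r in full_length}
    ids_ins = {r.id for r in inserts}
    if ids_full != ids_ins:
        raise ValueError("label sets of full-length and insert records differ")
    order = sorted(ids_full)
    full_by = {r.id: r for r in full_length}
    ins_by = {r.id: r for r in inserts}
    labels, Mf = pairwise_identity_matrix([full_by[i] for i in order], scoring)
    _, Mi = pairwise_identity_matrix([ins_by[i] for i in order], scoring)
    rows = []
    for i in range(len(order)):
        for j in range(i + 1, len(order)):
            amb_f, amb_i = Mf[i, j] >= threshold, Mi[i, j] >= threshold
            if amb_f != amb_i:
                rows.append({"a": order[i], "b": order[j],
                             "identity_full": Mf[i, j], "identity_insert": Mi[i, j],
                             "indistinct_full": amb_f, "indistinct_insert": amb_i})
    detail = pd.DataFrame(rows, columns=["a", "b", "identity_full", "identity_insert",
                                         "indistinct_full", "indistinct_insert"])
    return ResolutionReport(indistinguishable_fraction(Mf, threshold),
                            indistinguishable_fraction(Mi, threshold), detail)


def distance_matrix_to_phylip(dm: DistanceMatrix, path: str) -> None:
    """Square PHYLIP distance-matrix format."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm.ids)}\n")
        for name in dm.ids:
            row = " ".join(f"{v:.6f}" for v in dm[name])
            fh.write(f"{name[:10]:<10} {row}\n")
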