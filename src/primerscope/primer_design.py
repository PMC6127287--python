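"""Degenerate primer design from conserved alignment windows.

The design rules mirror the common constraint system for group-specific
16S primers: candidate oligos 17-24 nt long with at most two degenerate
IUPAC positions, drawn from gap-free alignment windows whose minimal
degenerate consensus covers every observed base, paired so the predicted
product exceeds a minimum size (default >400 bp).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .msa import GAP_FLAG, Alignment, column_profiles, minimal_degenerate_consensus
from .seqio import (GAP, SequenceRecord, count_degeneracy, expand_degenerate,
                    iupac_match, reverse_complement)

__all__ = [
    "DesignConstraints",
    "PrimerCandidate",
    "PrimerPair",
    "find_conserved_windows",
    "make_candidates",
    "assemble_pairs",
    "design_primers",
    "estimate_tm",
]


@dataclass(frozen=True)
class DesignConstraints:
    min_len: int = 17
    max_len: int = 24
    max_degenerate: int = 2
    min_product: int = 400
    min_target_coverage: float = 1.0
    min_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not 0.0 <= self.min_target_coverage <= 1.0:
            raise ValueError("min_target_coverage must be in [0, 1]")


@dataclass(frozen=True)
class PrimerCandidate:
    """A degenerate oligo candidate anchored to an alignment window.

    ``sequence`` is written 5'->3' in primer orientation: for reverse
    candidates it is the reverse complement of the window consensus.
    ``window`` is [start, end) in 0-based alignment columns.
    """

    name: str
    sequence: str
    orientation: str  # "forward" | "reverse"
    window: tuple[int, int]
    n_degenerate: int
    fold_degeneracy: int
    target_coverage: float
    position_label: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: PrimerCandidate
    reverse: PrimerCandidate
    predicted_product: int


def find_conserved_windows(aln: Alignment,
                           constraints: DesignConstraints = DesignConstraints(),
                           ) -> list[tuple[tuple[int, int], str]]:
    """Enumerate primer-sized conserved windows.

    Every window with length in ``[min_len, max_len]`` whose per-column
    minimal degenerate consensus has no gap-flagged column and at most
    ``max_degenerate`` degenerate columns, in ascending (start, end)
    order; overlapping windows are allowed.
    """
    if aln.n_columns < constraints.min_len:
        warnings.warn("alignment shorter than min_len; no windows")
        return []
    profiles = column_profiles(aln)
    consensus = [minimal_degenerate_consensus(p, constraints.min_fraction) for p in profiles]
    bad = [1 if c == GAP_FLAG else 0 for c in consensus]
    deg = [0 if c == GAP_FLAG else (1 if count_degeneracy(c)[0] else 0) for c in consensus]
    # prefix sums for O(1) window checks
    import itertools
    cum_bad = [0, *itertools.accumulate(bad)]
    cum_deg = [0, *itertools.accumulate(deg)]
    out = []
    n = aln.n_columns
    for start in range(n):
        for length in range(constraints.min_len, constraints.max_len + 1):
            end = start + length
            if end > n:
                break
            if cum_bad[end] - cum_bad[start]:
                continue
            if cum_deg[end] - cum_deg[start] > constraints.max_degenerate:
                continue
            out.append(((start, end), "".join(consensus[start:end])))
    out.sort(key=lambda w: w[0])
    return out


def _coverage(consensus: str, window: tuple[int, int], aln: Alignment) -> float:
    """Fraction of rows whose window residues are fully IUPAC-covered.

    Zero-mismatch criterion: every row base must be a subset-compatible
    match of the consensus letter (no gap in the row window).
    """
    start, end = window
    hit = 0
    for rec in aln.records:
        segment = rec.residues[start:end]
        if GAP in segment:
            continue
        if all(iupac_match(c, s) for c, s in zip(consensus, segment)):
            hit += 1
    return hit / aln.n_rows


def make_candidates(windows: Sequence[tuple[tuple[int, int], str]],
                    aln: Alignment,
                    constraints: DesignConstraints = DesignConstraints(),
                    reference_id: str | None = None) -> list[PrimerCandidate]:
    """Turn conserved windows into forward and reverse primer candidates.

    Each window yields the consensus as a forward candidate and its
    reverse complement as a reverse candidate. Coverage is the fraction
    of targets matched full-length with zero mismatches at the window
    locus; candidates under ``min_target_coverage`` are dropped.
    Identical (sequence, orientation) candidates from overlapping windows
    are merged, keeping the widest window.
    """
    col2pos = None
    if reference_id is not None:
        row = _reference_row(aln, reference_id)
        col2pos = aln.column_to_position(row)

    best: dict[tuple[str, str], PrimerCandidate] = {}
    for window, consensus in windows:
        coverage = _coverage(consensus, window, aln)
        if coverage < constraints.min_target_coverage:
            continue
        n_deg, fold = count_degeneracy(consensus)
        for orientation, seq in (("forward", consensus),
                                 ("reverse", reverse_complement(consensus))):
            label = _position_label(window, orientation, col2pos)
            name = label or f"{window[0]}-{window[1]}{orientation[0]}"
            cand = PrimerCandidate(name=name, sequence=seq, orientation=orientation,
                                   window=window, n_degenerate=n_deg,
                                   fold_degeneracy=fold, target_coverage=coverage,
                                   position_label=label)
            key = (seq, orientation)
            prior = best.get(key)
            if prior is None or (cand.window[1] - cand.window[0]) > (prior.window[1] - prior.window[0]):
                best[key] = cand
    out = sorted(best.values(), key=lambda c: (c.window, c.orientation))
    for cand in out:  # design-rule postconditions
        assert constraints.min_len <= len(cand) <= constraints.max_len
        assert cand.n_degenerate <= constraints.max_degenerate
    return out


def _reference_row(aln: Alignment, reference_id: str) -> int:
    for i, rec in enumerate(aln.records):
        if rec.id == reference_id:
            return i
    raise KeyError(f"reference id {reference_id!r} not in alignment")


def _position_label(window: tuple[int, int], orientation: str, col2pos) -> str:
    """1-based start-position label on the designated reference ("15f"/"687r")."""
    if col2pos is None:
        return ""
    start, end = window
    if orientation == "forward":
        return f"{int(col2pos[start]) + 1}f"
    return f"{int(col2pos[start]) + 1}r"


def assemble_pairs(candidates: Sequence[PrimerCandidate],
                   constraints: DesignConstraints = DesignConstraints(),
                   aln: Alignment | None = None,
                   reference_id: str | None = None) -> list[PrimerPair]:
    """All forward x reverse combinations exceeding the minimum product.

    The forward window must lie entirely upstream of the reverse window.
    Product size is measured on the designated ungapped reference when
    given, else on alignment columns with majority-gap columns excluded.
    Ordered by (forward start, reverse start).
    """
    forwards = [c for c in candidates if c.orientation == "forward"]
    reverses = [c for c in candidates if c.orientation == "reverse"]
    col2pos = None
    gap_majority = None
    if aln is not None and reference_id is not None:
        col2pos = aln.column_to_position(_reference_row(aln, reference_id))
    elif aln is not None:
        profiles = column_profiles(aln)
        gap_majority = [p.counts["gap"] * 2 > aln.n_rows for p in profiles]
        import itertools
        gap_cum = [0, *itertools.accumulate(int(g) for g in gap_majority)]
        gap_majority = gap_cum  # prefix sums of majority-gap columns

    pairs = []
    for fwd in forwards:
        for rev in reverses:
            if fwd.window[1] > rev.window[0]:
                continue
            span = (fwd.window[0], rev.window[1])
            if col2pos is not None:
                end_pos = int(col2pos[span[1] - 1]) + 1  # past-the-end on reference
                product = end_pos - int(col2pos[span[0]])
            elif gap_majority is not None:
                product = (span[1] - span[0]) - (gap_majority[span[1]] - gap_majority[span[0]])
            else:
                product = span[1] - span[0]
            if product <= constraints.min_product:
                continue
            name = f"{fwd.name}/{rev.name}"
            pairs.append(PrimerPair(name, fwd, rev, product))
    if not pairs:
        warnings.warn("no primer pairs satisfy the product-size constraint")
    pairs.sort(key=lambda p: (p.forward.window[0], p.reverse.window[0]))
    return pairs


def design_primers(aln: Alignment,
                   constraints: DesignConstraints = DesignConstraints(),
                   reference_id: str | None = None,
                   ) -> tuple[list[PrimerCandidate], list[PrimerPair]]:
    """Full design pass: windows -> candidates -> pairs."""
    windows = find_conserved_windows(aln, constraints)
    candidates = make_candidates(windows, aln, constraints, reference_id)
    pairs = assemble_pairs(candidates, constraints, aln, reference_id)
    return candidates, pairs


def estimate_tm(seq: str) -> float:
    """Screening melting-temperature estimate, degrees C to one decimal.

    Wallace rule 2(A+T)+4(G+C) below 14 nt, else 64.9 + 41*(GC-16.4)/N.
    Degenerate positions contribute their expected GC content, which
    equals the mean over all concrete expansions (both formulas are
    linear in the GC count). A screening aid only; annealing temperatures
    for bench use must be determined empirically.
    """
    if GAP in seq:
        raise ValueError("gapped sequence")
    n = len(seq)
    exp_gc = 0.0
    for letter in seq:
        bases = expand_degenerate(letter)
        exp_gc += sum(1 for b in bases for ch in b if ch in "GC") / len(bases)
    if n < 14:
        tm = 2.0 * (n - exp_gc) + 4.0 * exp_gc
    else:
        tm = 64.9 + 41.0 * (exp_gc - 16.4) / n
    return round(tm, 1)


def candidates_to_tsv(candidates: Iterable[PrimerCandidate], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("name\torientation\tsequence\tposition\tlength\tn_degenerate"
                 "\tcoverage\test_tm\n")
        for c in candidates:
            fh.write(f"{c.name}\t{c.orientation}\t{c.sequence}\t{c.position_label}"
                     f"\t{len(c)}\t{c.n_degenerate}\t{c.target_coverage:.4f}"
                     f"\t{estimate_tm(c.sequence):.1f}\n")


def pairs_to_tsv(pairs: Iterable[PrimerPair], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("pair\tforward\treverse\tforward_seq\treverse_seq\tpredicted_product\n")
        for p in pairs:
            fh.write(f"{p.name}\t{p.forward.name}\t{p.reverse.name}"
                     f"\t{p.forward.sequence}\t{p.reverse.sequence}\t{p.predicted_product}\n")
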