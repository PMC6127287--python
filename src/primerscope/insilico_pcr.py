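"""IUPAC-aware in-silico PCR with a 3'-anchor mismatch policy.

Primers are placed ungapped on both strands of each template; a hit
tolerates up to ``max_mismatches`` IUPAC mismatches overall but none in
the 3'-terminal ``three_prime_anchor`` positions, reflecting that
polymerase extension fails from a mispaired 3' end. Productive
forward/reverse site combinations within a product-size window become
:class:`AmpliconHit` records carrying the inter-primer insert, which
downstream modules use for discriminability scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .primer_design import PrimerPair
from .seqio import SequenceRecord, iupac_match, reverse_complement

__all__ = [
    "MatchPolicy",
    "PrimerSite",
    "AmpliconHit",
    "match_sites",
    "amplify",
    "coverage_report",
]


@dataclass(frozen=True)
class MatchPolicy:
    """Mismatch tolerance for primer placement.

    ``three_prime_anchor`` positions at the primer 3' end must match
    exactly (default 3, the common in-silico PCR convention). Indels are
    never allowed in the primer footprint.
    """

    max_mismatches: int = 2
    three_prime_anchor: int = 3
    search_both_strands: bool = True

    def __post_init__(self) -> None:
        if self.max_mismatches < 0 or self.three_prime_anchor < 0:
            raise ValueError("policy fields must be non-negative")


@dataclass(frozen=True)
class PrimerSite:
    span: tuple[int, int]  # [start, end) on the template plus strand
    mismatches: int
    strand: str  # '+': primer as written anneals to minus strand (extends rightward)


@dataclass(frozen=True)
class AmpliconHit:
    template_id: str
    forward_span: tuple[int, int]
    reverse_span: tuple[int, int]
    strand: str
    product_length: int
    insert: str
    mismatches_fwd: int
    mismatches_rev: int
    primary: bool = False


def _scan(pattern: str, template: str, policy: MatchPolicy,
          anchor_at_start: bool) -> list[tuple[tuple[int, int], int]]:
    """All ungapped placements of *pattern* within mismatch policy.

    ``anchor_at_start`` selects which end of the pattern carries the
    3' anchor (True when the pattern is a reverse-complemented primer).
    """
    L, N = len(pattern), len(template)
    hits = []
    anchor = min(policy.three_prime_anchor, L)
    for start in range(N - L + 1):
        mism = 0
        ok = True
        for k in range(L):
            if not iupac_match(pattern[k], template[start + k]):
                in_anchor = k < anchor if anchor_at_start else k >= L - anchor
                if in_anchor:
                    ok = False
                    break
                mism += 1
                if mism > policy.max_mismatches:
                    ok = False
                    break
        if ok:
            hits.append(((start, start + L), mism))
    return hits


def match_sites(primer: str, template: SequenceRecord,
                policy: MatchPolicy = MatchPolicy()) -> list[PrimerSite]:
    """Every admissible primer placement on the template.

    Plus-strand sites are placements of the primer as written (primer 3'
    end at the right edge of the span); minus-strand sites are placements
    of its reverse complement (primer 3' end at the left edge). Spans are
    always in plus-strand coordinates, 0-based half-open.
    """
    seq = template.ungapped
    if len(primer) > len(seq):
        return []
    sites = [PrimerSite(span, mism, "+")
             for span, mism in _scan(primer, seq, policy, anchor_at_start=False)]
    if policy.search_both_strands:
        rc = reverse_complement(primer)
        sites += [PrimerSite(span, mism, "-")
                  for span, mism in _scan(rc, seq, policy, anchor_at_start=True)]
    sites.sort(key=lambda s: (s.span, s.strand))
    return sites


def amplify(pair: PrimerPair | tuple[str, str],
            templates: Sequence[SequenceRecord],
            policy: MatchPolicy = MatchPolicy(),
            product_range: tuple[int, int] = (100, 3000)) -> list[AmpliconHit]:
    """Predict amplicons for a primer pair over a template collection.

    A productive combination is a forward site and a reverse site in
    converging orientation with product length inside *product_range*.
    All hits are reported; per template, the best one (fewest total
    mismatches, then shortest product, then leftmost) is flagged
    ``primary``.
    """
    fwd, rev = _pair_sequences(pair)
    lo, hi = product_range
    if lo < len(fwd) + len(rev):
        raise ValueError("product_range minimum smaller than combined primer length")
    hits: list[AmpliconHit] = []
    for template in templates:
        seq = template.ungapped
        fwd_sites = match_sites(fwd, template, policy)
        rev_sites = match_sites(rev, template, policy)
        per_template: list[AmpliconHit] = []
        # plus-strand product: forward on '+', reverse on '-', forward upstream
        for fs in (s for s in fwd_sites if s.strand == "+"):
            for rs in (s for s in rev_sites if s.strand == "-"):
                if rs.span[0] < fs.span[1]:
                    continue
                product = rs.span[1] - fs.span[0]
                if not lo <= product <= hi:
                    continue
                insert = seq[fs.span[1] : rs.span[0]]
                per_template.append(AmpliconHit(template.id, fs.span, rs.span, "+",
                                                product, insert, fs.mismatches, rs.mismatches))
        if policy.search_both_strands:
            # minus-strand product: forward on '-', reverse on '+', reverse upstream
            for fs in (s for s in fwd_sites if s.strand == "-"):
                for rs in (s for s in rev_sites if s.strand == "+"):
                    if fs.span[0] < rs.span[1]:
                        continue
                    product = fs.span[1] - rs.span[0]
                    if not lo <= product <= hi:
                        continue
                    insert = reverse_complement(seq[rs.span[1] : fs.span[0]])
                    per_template.append(AmpliconHit(template.id, fs.span, rs.span, "-",
                                                    product, insert, fs.mismatches, rs.mismatches))
        if per_template:
            best = min(range(len(per_template)),
                       key=lambda i: (per_template[i].mismatches_fwd + per_template[i].mismatches_rev,
                                      per_template[i].product_length,
                                      per_template[i].forward_span[0]))
            per_template[best] = _flag_primary(per_template[best])
        hits.extend(per_template)
    return hits


def _flag_primary(hit: AmpliconHit) -> AmpliconHit:
    return AmpliconHit(hit.template_id, hit.forward_span, hit.reverse_span, hit.strand,
                       hit.product_length, hit.insert, hit.mismatches_fwd,
                       hit.mismatches_rev, primary=True)


def _pair_sequences(pair: PrimerPair | tuple[str, str]) -> tuple[str, str]:
    if isinstance(pair, PrimerPair):
        return pair.forward.sequence, pair.reverse.sequence
    return pair


def coverage_report(pair, targets: Sequence[SequenceRecord],
                    nontargets: Sequence[SequenceRecord] = (),
                    policy: MatchPolicy = MatchPolicy(),
                    product_range: tuple[int, int] = (100, 3000),
                    ) -> tuple[float, int, pd.DataFrame]:
    """In-silico specificity screen of one pair against two panels.

    Returns (fraction of targets amplified, number of non-target
    templates amplified, per-template table of primary hits).
    """
    if not targets:
        raise ValueError("empty target set")
    rows = []
    amplified = 0
    for group, panel in (("target", targets), ("nontarget", nontargets)):
        hits = amplify(pair, panel, policy, product_range)
        primary = {h.template_id: h for h in hits if h.primary}
        if group == "target":
            amplified = len(primary)
            nontarget_count = 0
        else:
            nontarget_count = len(primary)
        for h in primary.values():
            rows.append({"template": h.template_id, "group": group,
                         "start": h.forward_span[0], "end": h.reverse_span[1],
                         "strand": h.strand, "product": h.product_length,
                         "mismatches": h.mismatches_fwd + h.mismatches_rev})
    table = pd.DataFrame(rows, columns=["template", "group", "start", "end",
                                        "strand", "product", "mismatches"])
    return amplified / len(targets), nontarget_count, table


def hits_to_bed(hits: Iterable[AmpliconHit], path: str | Path) -> None:
    """Amplicon spans as BED (0-based half-open, strand column)."""
    with open(path, "w") as fh:
        for h in hits:
            start = min(h.forward_span[0], h.reverse_span[0])
            end = max(h.forward_span[1], h.reverse_span[1])
            fh.write(f"{h.template_id}\t{start}\t{end}\tamplicon\t{h.product_length}\t{h.strand}\n")


def inserts_to_records(hits: Iterable[AmpliconHit], primary_only: bool = True
                       ) -> list[SequenceRecord]:
    """Extracted inter-primer inserts as records (id|start-end|strand)."""
    out = []
    for h in hits:
        if primary_only and not h.primary:
            continue
        rid = f"{h.template_id}|{h.forward_span[0]}-{h.reverse_span[1]}|{h.strand}"
        out.append(SequenceRecord(rid, h.insert))
    return out
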