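"""Amplicon-survey summaries: OTUs, taxonomy, proportions, diversity.

The workflow standardizes read depth across samples by seeded random
subsampling (to the smallest sample by default), dereplicates reads into
OTUs at 100% identity (exact full-length match), assigns each OTU to the
best-matching labeled reference, and summarizes target-read proportions,
per-condition presence/absence and relative abundance, observed OTUs,
Shannon diversity and rarefaction curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discrimination import pairwise_identity
from .msa import AlignScoring
from .seqio import SequenceRecord

__all__ = [
    "OTUTable",
    "TaxonAssignment",
    "DiversityResult",
    "subsample_reads",
    "dereplicate",
    "assign_taxonomy",
    "target_proportion",
    "abundance_and_presence",
    "presence_and_richness",
    "alpha_diversity",
    "format_percent",
]


@dataclass
class OTUTable:
    """Dereplicated reads for one sample: OTU id -> (representative, count)."""

    sample_id: str
    otus: dict[str, tuple[str, int]]

    @property
    def total_reads(self) -> int:
        return sum(c for _, c in self.otus.values())

    @property
    def observed_otus(self) -> int:
        return len(self.otus)

    def counts(self) -> dict[str, int]:
        return {oid: c for oid, (_, c) in self.otus.items()}


def subsample_reads(samples: dict[str, list[SequenceRecord]],
                    depth: int | str = "auto",
                    seed: int = 0) -> dict[str, list[SequenceRecord]]:
    """Standardize read depth by uniform without-replacement subsampling.

    ``depth="auto"`` uses the smallest sample size (the convention when
    comparing samples sequenced to different depths). Seeded and
    reproducible; each output set has exactly *depth* reads.
    """
    sizes = {name: len(reads) for name, reads in samples.items()}
    if depth == "auto":
        depth = min(sizes.values())
    depth = int(depth)
    for name, size in sizes.items():
        if depth > size:
            raise ValueError(f"depth {depth} exceeds sample {name!r} size {size}")
    rng = np.random.default_rng(seed)
    out = {}
    for name in samples:  # iteration order fixed by dict insertion order
        idx = rng.choice(sizes[name], size=depth, replace=False)
        out[name] = [samples[name][i] for i in sorted(idx)]
    return out


def dereplicate(reads: list[SequenceRecord], sample_id: str = "sample") -> OTUTable:
    """Exact-string dereplication (100% identity over the full length).

    The representative of each OTU is its first-occurring read; OTU ids
    are assigned in order of first occurrence.
    """
    otus: dict[str, tuple[str, int]] = {}
    index: dict[str, str] = {}
    for rec in reads:
        seq = rec.ungapped
        oid = index.get(seq)
        if oid is None:
            oid = f"OTU{len(index) + 1}"
            index[seq] = oid
            otus[oid] = (seq, 1)
        else:
            rep, count = otus[oid]
            otus[oid] = (rep, count + 1)
    return OTUTable(sample_id, otus)


@dataclass(frozen=True)
class TaxonAssignment:
    label: str  # binomial "Genus species", or "unassigned"
    identity: float
    tie: bool = False


def _reference_label(rec: SequenceRecord) -> str:
    return rec.description if rec.description else rec.id.replace("_", " ")


def assign_taxonomy(otus: OTUTable, reference: list[SequenceRecord],
                    min_identity: float = 0.97,
                    scoring: AlignScoring = AlignScoring()
                    ) -> dict[str, TaxonAssignment]:
    """Best-match assignment of OTU representatives to a labeled reference.

    Each representative takes the binomial label of its highest-identity
    reference hit when that identity reaches *min_identity* (default
    0.97, the conventional species-level proxy), else "unassigned".
    Exact ties go to the first reference in file order, flagged.
    """
    if not reference:
        raise ValueError("empty reference collection")
    out: dict[str, TaxonAssignment] = {}
    for oid, (rep, _count) in otus.otus.items():
        best_label, best_ident, tie = "unassigned", -1.0, False
        for ref in reference:
            ident = 1.0 if rep == ref.ungapped else pairwise_identity(rep, ref.ungapped, scoring)
            if ident > best_ident:
                best_label, best_ident, tie = _reference_label(ref), ident, False
            elif ident == best_ident:
                tie = True
        if best_ident >= min_identity:
            out[oid] = TaxonAssignment(best_label, best_ident, tie)
        else:
            out[oid] = TaxonAssignment("unassigned", best_ident, tie)
    return out


def format_percent(value: float) -> str:
    """Survey-table display convention: integer when >=1%, one decimal below."""
    if value >= 1.0:
        return str(int(round(value)))
    return f"{round(value, 1):.1f}"


@dataclass(frozen=True)
class TargetProportion:
    target_reads: int
    total_reads: int
    percent: float  # raw, unrounded

    @property
    def display(self) -> str:
        return format_percent(self.percent)


def target_proportion(assignments: dict[str, TaxonAssignment],
                      otus: OTUTable,
                      target_taxa: set[str]) -> TargetProportion:
    """Reads assigned to any target taxon, as count and percentage.

    Genus-level entries in *target_taxa* (single token) match any
    binomial of that genus.
    """
    genera = {t for t in target_taxa if " " not in t}
    counts = otus.counts()
    target = 0
    for oid, assignment in assignments.items():
        label = assignment.label
        if label in target_taxa or label.split(" ")[0] in genera:
            target += counts.get(oid, 0)
    total = otus.total_reads
    percent = 100.0 * target / total if total else 0.0
    return TargetProportion(target, total, percent)


def abundance_and_presence(per_condition: dict[str, tuple[dict[str, TaxonAssignment], OTUTable]],
                           target_taxa: set[str] | None = None,
                           ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Relative-abundance, presence/absence and richness per condition.

    *per_condition* maps a condition label (e.g. "Sample 1/L5") to its
    (assignments, OTU table). Abundance is percent of the condition's
    total reads; presence is abundance > 0; richness counts target taxa
    present. "unassigned" never counts as a target.
    """
    columns = {}
    for condition, (assignments, otus) in per_condition.items():
        counts = otus.counts()
        total = otus.total_reads
        taxa: dict[str, int] = {}
        for oid, assignment in assignments.items():
            taxa[assignment.label] = taxa.get(assignment.label, 0) + counts.get(oid, 0)
        columns[condition] = {t: 100.0 * c / total for t, c in taxa.items() if total}
    abundance = pd.DataFrame(columns).fillna(0.0)
    abundance = abundance.sort_index()
    if target_taxa is not None:
        keep = [t for t in abundance.index
                if t in target_taxa or t.split(" ")[0] in {x for x in target_taxa if " " not in x}]
        abundance = abundance.loc[keep]
    presence, richness = presence_and_richness(abundance)
    return abundance, presence, richness


def presence_and_richness(abundance: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.Series]:
    """Presence/absence matrix and per-condition species richness.

    Accepts any taxa x conditions abundance table (rows: taxa, values:
    relative abundance); presence is strictly positive abundance.
    """
    presence = abundance > 0
    richness = presence.sum(axis=0)
    richness.name = "richness"
    return presence, richness


@dataclass(frozen=True)
class DiversityResult:
    observed_otus: int
    shannon: float
    rarefaction_curve: list[tuple[int, float, float]]  # (depth, mean, sd)


def shannon_index(counts, base: float = math.e) -> float:
    """Shannon entropy of OTU relative frequencies (natural log default)."""
    arr = np.asarray([c for c in counts if c > 0], dtype=float)
    if arr.size == 0:
        return 0.0
    p = arr / arr.sum()
    return float(-(p * np.log(p)).sum() / math.log(base))


def alpha_diversity(otus: OTUTable,
                    rarefaction_depths: list[int] | None = None,
                    replicates: int = 10,
                    seed: int = 0,
                    base: float = math.e) -> DiversityResult:
    """Observed OTUs, Shannon index, and a rarefaction curve.

    Each rarefaction point is the mean (and sd) of observed OTUs over
    *replicates* seeded without-replacement subsamples of the read pool.
    Depths beyond the total read count are skipped with a warning.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    counts = np.array(list(otus.counts().values()), dtype=int)
    total = int(counts.sum())
    shannon = shannon_index(counts, base)
    curve: list[tuple[int, float, float]] = []
    if rarefaction_depths:
        rng = np.random.default_rng(seed)
        pool = np.repeat(np.arange(counts.size), counts)
        for depth in rarefaction_depths:
            if depth > total:
                warnings.warn(f"rarefaction depth {depth} exceeds {total} reads; skipped")
                continue
            observed = [np.unique(rng.choice(pool, size=depth, replace=False)).size
                        for _ in range(replicates)]
            curve.append((depth, float(np.mean(observed)), float(np.std(observed, ddof=0))))
    return DiversityResult(int(counts.size), shannon, curve)


def expected_rarefaction(counts, depth: int) -> float:
    """Closed-form expected observed OTUs under hypergeometric subsampling.

    E[S_d] = sum_i 1 - C(N - n_i, d) / C(N, d); the analytic counterpart
    of the Monte-Carlo rarefaction in :func:`alpha_diversity`.
    """
    counts = [int(c) for c in counts if c > 0]
    N = sum(counts)
    if depth > N:
        raise ValueError("depth exceeds total reads")
    denom = math.comb(N, depth)
    return sum(1.0 - math.comb(N - n, depth) / denom for n in counts)
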