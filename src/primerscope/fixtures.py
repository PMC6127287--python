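"""Synthetic clades and read sets with known ground truth.

Real group-specific primer studies start from hundreds of curated 16S
genes; those cannot ship with a toolkit. Instead this module generates
data with the same structure: a target clade whose members all carry two
planted degenerate primer-binding sites (defaults: the 18-mer forward /
20-mer reverse of a published LAB-specific pair, product ~750 bp)
flanking a variable insert, non-target outgroups engineered to share no
17-mer with either site, and labeled amplicon read sets of known
composition. Every generator is deterministic given its seed, so tests
can assert exact recoveries: the design stage must re-derive the planted
degeneracies, in-silico PCR must amplify 100% of targets and no
non-target, and dereplication/assignment must recover the composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import IUPAC_BASES, SequenceRecord, reverse_complement

__all__ = [
    "CladeSpec",
    "ReadSetSpec",
    "Clade",
    "CladeTruth",
    "generate_clade",
    "generate_reads",
    "generate_insert_panel",
    "LAB_GENERA",
]

#: The seven target genera of the LAB group.
LAB_GENERA = ("Lactobacillus", "Streptococcus", "Weissella", "Lactococcus",
              "Pediococcus", "Enterococcus", "Leuconostoc")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CladeSpec:
    n_targets: int = 20
    n_nontargets: int = 5
    site_fwd: str = "GCTCAGGAYGAACGCYGG"
    site_rev: str = "CACCGCTACACATGRADTTC"  # 5'->3' as a reverse primer
    insert_length: int = 712  # total product = insert + both sites = 750
    flank_length: int = 40
    insert_divergence: float = 0.10  # expected pairwise substitution rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insert_length < 1:
            raise ValueError("insert_length must be >= 1")
        if self.n_targets < 2:
            raise ValueError("need at least 2 targets")


@dataclass(frozen=True)
class CladeTruth:
    fwd_site_span: tuple[int, int]  # identical plus-strand coords in every target
    rev_site_span: tuple[int, int]
    product_length: int
    inserts: dict[str, str]  # target id -> inter-primer region
    n_indistinguishable_pairs_98: int  # insert pairs with identity >= 0.98


@dataclass(frozen=True)
class Clade:
    targets: list[SequenceRecord]
    nontargets: list[SequenceRecord]
    truth: CladeTruth

    def taxon_labels(self) -> dict[str, str]:
        """id -> binomial label for every sequence in the clade."""
        return {r.id: (r.description or r.id.replace("_", " "))
                for r in [*self.targets, *self.nontargets]}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each position w.p. *rate* with a uniformly different base."""
    arr = np.array(list(seq))
    hit = rng.random(arr.size) < rate
    for i in np.flatnonzero(hit):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _realize_site(rng: np.random.Generator, site: str, n: int) -> list[str]:
    """Concrete per-target realizations of a degenerate site.

    Degenerate positions are sampled uniformly among their allowed bases,
    with every allowed base guaranteed to occur in at least one target
    (so the minimal degenerate consensus over the targets re-derives the
    planted code exactly).
    """
    columns = []
    for letter in site:
        bases = sorted(IUPAC_BASES[letter])
        if len(bases) == 1:
            columns.append([bases[0]] * n)
            continue
        col = [bases[i % len(bases)] for i in range(n)]
        rng.shuffle(col)
        columns.append(col)
    return ["".join(columns[j][i] for j in range(len(site))) for i in range(n)]


def _shares_kmer(seq: str, sites: list[str], k: int = 17) -> bool:
    kmers = set()
    for site in sites:
        for variant in (site, reverse_complement(site)):
            # degenerate letters in planted sites: expand column sets lazily by
            # checking concrete k-mers of the candidate against IUPAC windows
            kmers.add(variant)
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        for variant in kmers:
            for j in range(len(variant) - k + 1):
                if all(window[t] in IUPAC_BASES[variant[j + t]] for t in range(k)):
                    return True
    return False


def _hamming_identity(a: str, b: str) -> float:
    return sum(x == y for x, y in zip(a, b)) / len(a)


def generate_clade(spec: CladeSpec = CladeSpec()) -> Clade:
    """Build a target clade with planted primer sites plus outgroups.

    Targets share the layout ``flank - fwd site - insert - revcomp(rev
    site) - flank``; flanks and inserts diverge by substitutions only
    (all targets equal length, so the true alignment is ungapped), sites
    vary only at their degenerate positions. Non-targets are random
    sequences of the same length rejected until they share no 17-mer
    with either site on either strand.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_targets
    fwd_realized = _realize_site(rng, spec.site_fwd, n)
    rev_plus = reverse_complement(spec.site_rev)  # plus-strand appearance
    rev_realized = _realize_site(rng, rev_plus, n)

    ancestral_insert = _random_seq(rng, spec.insert_length)
    ancestral_flank5 = _random_seq(rng, spec.flank_length)
    ancestral_flank3 = _random_seq(rng, spec.flank_length)
    per_target_rate = spec.insert_divergence / 2.0  # pairwise ~ 2x per-branch

    targets = []
    inserts = {}
    for i in range(n):
        genus = LAB_GENERA[i % len(LAB_GENERA)]
        label = f"{genus} fictus{i + 1:02d}"
        tid = label.replace(" ", "_")
        insert = _mutate(rng, ancestral_insert, per_target_rate)
        seq = (_mutate(rng, ancestral_flank5, per_target_rate)
               + fwd_realized[i] + insert + rev_realized[i]
               + _mutate(rng, ancestral_flank3, per_target_rate))
        targets.append(SequenceRecord(tid, seq, label))
        inserts[tid] = insert

    total_len = (2 * spec.flank_length + len(spec.site_fwd)
                 + spec.insert_length + len(spec.site_rev))
    nontargets = []
    for i in range(spec.n_nontargets):
        while True:
            seq = _random_seq(rng, total_len)
            if not _shares_kmer(seq, [spec.site_fwd, rev_plus]):
                break
        label = f"Outgroupium externum{i + 1:02d}"
        nontargets.append(SequenceRecord(label.replace(" ", "_"), seq, label))

    ids = list(inserts)
    close = sum(1 for a in range(len(ids)) for b in range(a + 1, len(ids))
                if _hamming_identity(inserts[ids[a]], inserts[ids[b]]) >= 0.98)
    f0 = spec.flank_length
    truth = CladeTruth(
        fwd_site_span=(f0, f0 + len(spec.site_fwd)),
        rev_site_span=(f0 + len(spec.site_fwd) + spec.insert_length,
                       f0 + len(spec.site_fwd) + spec.insert_length + len(spec.site_rev)),
        product_length=len(spec.site_fwd) + spec.insert_length + len(spec.site_rev),
        inserts=inserts,
        n_indistinguishable_pairs_98=close,
    )
    return Clade(targets, nontargets, truth)


@dataclass(frozen=True)
class ReadSetSpec:
    composition: dict[str, float]  # taxon id -> relative abundance (sums to 1)
    depth: int = 2551  # the depth-standardization convention of LAB surveys
    error_rate: float = 0.0
    region: str = "insert"  # "insert" (pair amplicon) or "full" (universal-primer emulation)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition must sum to 1, got {total}")


def generate_reads(spec: ReadSetSpec, clade: Clade
                   ) -> tuple[list[SequenceRecord], list[tuple[str, str]]]:
    """Draw labeled amplicon reads from a clade.

    Reads are full copies of the source region (the inter-primer insert,
    or the whole sequence in the universal-primer emulation) with seeded
    per-base substitution errors. Returns (reads, truth labels) where
    truth is a sidecar list of (read id, source taxon id).
    """
    sources: dict[str, str] = {}
    by_id = {r.id: r for r in [*clade.targets, *clade.nontargets]}
    for taxon in spec.composition:
        if taxon not in by_id:
            raise KeyError(f"unknown taxon {taxon!r}")
        if spec.region == "insert" and taxon in clade.truth.inserts:
            sources[taxon] = clade.truth.inserts[taxon]
        else:
            sources[taxon] = by_id[taxon].ungapped
    rng = np.random.default_rng(spec.seed)
    taxa = list(spec.composition)
    probs = np.array([spec.composition[t] for t in taxa])
    draws = rng.choice(len(taxa), size=spec.depth, p=probs)
    reads, truth = [], []
    for i, t_idx in enumerate(draws):
        taxon = taxa[t_idx]
        seq = sources[taxon]
        if spec.error_rate > 0:
            seq = _mutate(rng, seq, spec.error_rate)
        rid = f"read{i + 1:06d}"
        reads.append(SequenceRecord(rid, seq, taxon))
        truth.append((rid, taxon))
    return reads, truth


def generate_insert_panel(n: int = 50, n_close_pairs: int = 5,
                          length: int = 300, seed: int = 0,
                          close_identity: float = 0.99) -> list[SequenceRecord]:
    """A panel engineered so exactly *n_close_pairs* pairs are near-identical.

    ``n - n_close_pairs`` mutually unrelated random sequences, of which
    the first *n_close_pairs* each get a partner at *close_identity*
    (e.g. 0.99 > the 0.98 species-resolution threshold); all other pairs
    sit near random-sequence identity, far below the threshold. Used to
    check the indistinguishable-pair fraction exactly (e.g. 5 of 1225).
    """
    if n_close_pairs * 2 > n:
        raise ValueError("too many close pairs for panel size")
    rng = np.random.default_rng(seed)
    n_sub = max(1, round(length * (1.0 - close_identity)))
    backbone = [_random_seq(rng, length) for _ in range(n - n_close_pairs)]
    records = [SequenceRecord(f"panel{i + 1:03d}", s, "") for i, s in enumerate(backbone)]
    for j in range(n_close_pairs):
        arr = np.array(list(backbone[j]))
        pos = rng.choice(length, size=n_sub, replace=False)
        for p in pos:
            choices = [b for b in "ACGT" if b != arr[p]]
            arr[p] = choices[rng.integers(3)]
        records.append(SequenceRecord(f"panel{len(records) + 1:03d}", "".join(arr),
                                      f"partner_of panel{j + 1:03d}"))
    return records
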