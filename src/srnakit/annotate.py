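"""Exact genome mapping of tags and priority-ruled annotation.

Each unique tag is located on both strands of the genome by exact string
search.  A tag overlapping features of several RNA classes is resolved
to exactly one category through the fixed priority lattice

    rRNA (Genbank) > rRNA (Rfam) > known miRNA > repeat > exon > intron

and a mapped tag overlapping no feature — or an unmapped tag — is
categorised ``unann``.  Tags resolved to a known miRNA are attributed to
a single catalog entry, which yields the known-miRNA count matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .preprocess import TagSet
from .sequtil import is_acgt, revcomp
from .simdata import GenomicFeature

#: category -> priority rank (lower wins); unann is the fallback
PRIORITY = {
    "rRNA_genbank": 0,
    "rRNA_rfam": 1,
    "known_miRNA": 2,
    "repeat": 3,
    "exon": 4,
    "intron": 5,
}
UNANN = "unann"
ALL_CATEGORIES = tuple(PRIORITY) + (UNANN,)

#: tag 5'/3' offset tolerated beyond an annotated mature arm when
#: attributing a tag to a specific mature miRNA
MATURE_OFFSET_TOLERANCE = 3


@dataclass(frozen=True)
class GenomicHit:
    seq: str
    chrom: str
    start: int  # 0-based, forward-strand coordinate of the leftmost base
    strand: str

    @property
    def end(self) -> int:
        return self.start + len(self.seq)


@dataclass
class AnnotatedTag:
    seq: str
    counts: dict[str, int]
    hits: list[GenomicHit]
    category: str = UNANN
    assigned_mirna: str | None = None


@dataclass
class CatalogEntry:
    name: str
    chrom: str
    strand: str
    precursor: tuple[int, int]
    matures: list[tuple[int, int]]


@dataclass
class MiRNACatalog:
    """Known miRNA precursors with their mature arm intervals."""

    entries: dict[str, CatalogEntry] = field(default_factory=dict)

    @classmethod
    def from_truth(cls, genome) -> "MiRNACatalog":
        cat = cls()
        for m in genome.planted("known"):
            cat.entries[m.name] = CatalogEntry(
                m.name, m.chrom, m.strand, m.precursor, [m.mature]
            )
        return cat

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# mapping


_ENC_TABLE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENC_TABLE[_b] = _i


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """Base-4 integer codes of all k-mers (uint64); N-containing = 2**63."""
    enc = _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    bad = enc == 255
    enc = np.where(bad, 0, enc).astype(np.uint64)
    n = len(seq) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = np.zeros(n, dtype=np.uint64)
    anybad = np.zeros(n, dtype=bool)
    for j in range(k):
        codes = codes * np.uint64(4) + enc[j : n + j]
        anybad |= bad[j : n + j]
    codes[anybad] = np.uint64(1) << np.uint64(63)
    return codes


def map_tags(
    tags: TagSet | Iterable[str],
    chromosomes: dict[str, str],
) -> tuple[dict[str, list[GenomicHit]], int]:
    """All exact occurrences of each tag on both strands.

    Returns (hits-per-tag, number of skipped non-ACGT tags).  A '-'
    strand hit is reported at the forward coordinate where the reverse
    complement of the tag occurs.  Candidate positions are found by a
    k-mer hash join on tag prefixes and verified by exact string
    comparison, so the result is identical to a naive scan.
    """
    seqs = list(tags.counts) if isinstance(tags, TagSet) else list(tags)
    hits: dict[str, list[GenomicHit]] = {}
    skipped = 0
    queries: dict[int, list[tuple[str, str]]] = {}  # prefix code -> (fwd form, tag, strand)
    k = 12
    for seq in seqs:
        if not is_acgt(seq):
            skipped += 1
            continue
        hits[seq] = []
        k = min(k, len(seq))
    for seq in hits:
        for fwd, strand in ((seq, "+"), (revcomp(seq), "-")):
            code = int(_kmer_codes(fwd[:k], k)[0])
            queries.setdefault(code, []).append((fwd, seq, strand))
    if queries:
        key_arr = np.fromiter(queries.keys(), dtype=np.uint64)
        for chrom, ref in chromosomes.items():
            codes = _kmer_codes(ref, k)
            cand = np.nonzero(np.isin(codes, key_arr))[0]
            for p in cand.tolist():
                for fwd, seq, strand in queries[int(codes[p])]:
                    if ref.startswith(fwd, p):
                        hits[seq].append(GenomicHit(seq, chrom, p, strand))
    for seq in hits:
        hits[seq].sort(key=lambda h: (h.chrom, h.start, h.strand))
    if skipped:
        warnings.warn(f"skipped {skipped} non-ACGT tags during mapping")
    return hits, skipped


# ---------------------------------------------------------------------------
# priority resolution


def build_feature_index(features: Iterable[GenomicFeature]) -> dict[str, IntervalTree]:
    index: dict[str, IntervalTree] = {}
    for f in features:
        index.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    return index


def resolve_category(
    hits: list[GenomicHit],
    index: dict[str, IntervalTree],
    catalog: MiRNACatalog | None = None,
) -> tuple[str, str | None]:
    """Resolve one tag to its highest-priority category.

    Non-miRNA classes overlap on either strand (a degradation fragment
    of an rRNA or exon is recognisable from both strands); a known-miRNA
    feature counts only on the strand it is annotated on.  For counting,
    a tag with several same-strand mature-arm matches goes to the miRNA
    whose mature start is closest to the tag start, ties broken by name.
    """
    if not hits:
        return UNANN, None
    best_rank = None
    mirna_candidates: list[tuple[int, str]] = []
    for h in hits:
        tree = index.get(h.chrom)
        if tree is None:
            continue
        for iv in tree.overlap(h.start, h.end):
            f: GenomicFeature = iv.data
            if f.category == "known_miRNA" and f.strand != h.strand:
                continue
            rank = PRIORITY[f.category]
            if best_rank is None or rank < best_rank:
                best_rank = rank
            if f.category == "known_miRNA" and catalog is not None:
                entry = catalog.entries.get(f.name)
                if entry is not None:
                    dist = min(
                        (abs(h.start - ms) for ms, _ in entry.matures), default=0
                    )
                    mirna_candidates.append((dist, f.name))
            elif f.category == "known_miRNA":
                mirna_candidates.append((0, f.name))
    if best_rank is None:
        return UNANN, None
    category = next(c for c, r in PRIORITY.items() if r == best_rank)
    if category == "known_miRNA":
        mirna_candidates.sort()
        return category, mirna_candidates[0][1]
    return category, None


def annotate_tags(
    tags: TagSet,
    chromosomes: dict[str, str],
    features: Iterable[GenomicFeature],
    catalog: MiRNACatalog | None = None,
) -> list[AnnotatedTag]:
    """Map and categorise every tag of a tag set."""
    hits, _ = map_tags(tags, chromosomes)
    index = build_feature_index(features)
    out = []
    for seq, counts in tags.counts.items():
        tag_hits = hits.get(seq, [])
        category, mirna = resolve_category(tag_hits, index, catalog)
        out.append(
            AnnotatedTag(seq=seq, counts=dict(counts), hits=tag_hits, category=category, assigned_mirna=mirna)
        )
    return out


# ---------------------------------------------------------------------------
# quantification and summaries


def quantify_known(annotated: Iterable[AnnotatedTag], samples: list[str]) -> pd.DataFrame:
    """Known-miRNA count matrix (miRNA x sample); all-zero rows dropped."""
    acc: dict[str, dict[str, int]] = {}
    for t in annotated:
        if t.category != "known_miRNA" or t.assigned_mirna is None:
            continue
        row = acc.setdefault(t.assigned_mirna, {s: 0 for s in samples})
        for s, n in t.counts.items():
            row[s] = row.get(s, 0) + n
    df = pd.DataFrame.from_dict(acc, orient="index").reindex(columns=samples).fillna(0).astype(int)
    df = df.loc[df.sum(axis=1) > 0].sort_index()
    return df


def category_summary(
    annotated: Iterable[AnnotatedTag], sample: str
) -> dict[str, dict[str, float]]:
    """Per-category read proportions for one sample.

    Returned over all clean reads and, separately, over mapped reads
    only (where ``unann`` means mapped but feature-free).
    """
    clean_counts = {c: 0 for c in ALL_CATEGORIES}
    mapped_counts = {c: 0 for c in ALL_CATEGORIES}
    for t in annotated:
        n = t.counts.get(sample, 0)
        if not n:
            continue
        clean_counts[t.category] += n
        if t.hits:
            mapped_counts[t.category] += n
    def _props(counts):
        total = sum(counts.values())
        if total == 0:
            return {c: 0.0 for c in counts}
        return {c: v / total for c, v in counts.items()}
    return {
        "over_clean": _props(clean_counts),
        "over_mapped": _props(mapped_counts),
        "counts": clean_counts,
    }
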