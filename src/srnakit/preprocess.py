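"""Raw reads -> clean reads -> unique sequence tags.

A small-RNA library is sequenced as fixed-length raw reads in which the
short insert is followed by the 3' sequencing adaptor.  Cleaning trims
that adaptor, discards reads with no recognizable adaptor (contaminants),
reads whose insert falls outside the retained 18-30 nt window, and reads
of low base quality.  The surviving inserts are collapsed into unique
*sequence tags*, each carrying one read count per sample.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30
DEFAULT_MIN_QUALITY = 20.0
DEFAULT_MIN_OVERLAP = 6
#: mismatches tolerated in an adaptor alignment: 1 per 10 aligned bases
MISMATCH_PER_10 = 1


def find_adaptor(seq: str, adaptor: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> int | None:
    """Locate the 3' adaptor in ``seq``.

    Scans left to right for the leftmost position ``i`` at which a prefix
    of ``adaptor`` (at least ``min_overlap`` long, i.e. everything from
    ``i`` to the end of the read) aligns with at most 1 mismatch per 10
    aligned bases.  Returns ``i`` (the insert length) or None when no
    adaptor is detectable.
    """
    if not adaptor or min_overlap < 1:
        raise ValueError("adaptor must be non-empty and min_overlap >= 1")
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        k = min(len(adaptor), n - i)
        if k < min_overlap:
            break
        allowed = (k // 10) * MISMATCH_PER_10
        mism = 0
        ok = True
        for a, b in zip(seq[i : i + k], adaptor[:k]):
            if a != b:
                mism += 1
                if mism > allowed:
                    ok = False
                    break
        if ok:
            return i
    return None


def trim_adaptor(
    seq: str,
    qual: Sequence[int] | None,
    adaptor: str,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[str, Sequence[int] | None] | None:
    """Return (insert, insert_qualities) or None for a contaminant.

    A read containing an ambiguity base (N) or no detectable adaptor is
    flagged contaminant (None).  Never raises on biological input.
    """
    if "N" in seq:
        return None
    i = find_adaptor(seq, adaptor, min_overlap)
    if i is None:
        return None
    return seq[:i], (None if qual is None else qual[:i])


@dataclass
class CleanReadSet:
    """Clean reads of one sample plus exact filter bookkeeping."""

    sample: str
    reads: list[str] = field(default_factory=list)
    counters: dict[str, int] = field(
        default_factory=lambda: {
            "raw_total": 0,
            "adaptor_trimmed": 0,
            "removed_contaminant": 0,
            "removed_too_small": 0,
            "removed_too_long": 0,
            "removed_low_quality": 0,
            "clean_total": 0,
        }
    )

    @property
    def clean_total(self) -> int:
        return self.counters["clean_total"]

    def check_conservation(self) -> bool:
        c = self.counters
        removed = (
            c["removed_contaminant"]
            + c["removed_too_small"]
            + c["removed_too_long"]
            + c["removed_low_quality"]
        )
        return c["clean_total"] == c["raw_total"] - removed


def _iter_fastq(source) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (name, sequence, phred_qualities) from a FASTQ path/handle."""
    for rec in SeqIO.parse(source, "fastq"):
        yield rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]


def make_clean_reads(
    source,
    sample: str,
    adaptor: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    min_quality: float = DEFAULT_MIN_QUALITY,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> CleanReadSet:
    """Apply adaptor trimming and the clean-read filters to a FASTQ source.

    ``source`` may be a path, an open handle, or an iterable of
    ``(name, sequence, qualities)`` triples (as produced by the simulator).
    Malformed FASTQ raises a ValueError naming the failing record index.
    """
    out = CleanReadSet(sample=sample)
    c = out.counters
    if isinstance(source, Iterable) and not isinstance(source, (str, bytes)) and not hasattr(source, "read"):
        records = iter(source)
    else:
        records = _iter_fastq(source)

    idx = -1
    while True:
        idx += 1
        try:
            item = next(records, None)
        except ValueError as exc:  # Biopython parse error
            raise ValueError(f"malformed FASTQ record at index {idx}: {exc}") from exc
        if item is None:
            break
        _, seq, qual = item
        if isinstance(qual, str):  # Phred+33 string from the simulator
            qual = [ord(ch) - 33 for ch in qual]
        c["raw_total"] += 1
        trimmed = trim_adaptor(seq, qual, adaptor, min_overlap)
        if trimmed is None:
            c["removed_contaminant"] += 1
            continue
        insert, iqual = trimmed
        c["adaptor_trimmed"] += 1
        if len(insert) < min_len:
            c["removed_too_small"] += 1
            continue
        if len(insert) > max_len:
            c["removed_too_long"] += 1
            continue
        if iqual is not None and len(iqual) and float(np.mean(iqual)) < min_quality:
            c["removed_low_quality"] += 1
            continue
        out.reads.append(insert)
        c["clean_total"] += 1
    return out


@dataclass
class TagSet:
    """Unique sequence tags with per-sample read counts."""

    counts: dict[str, dict[str, int]]
    samples: list[str]
    clean_totals: dict[str, int]

    def __len__(self) -> int:
        return len(self.counts)

    def sample_total(self, sample: str) -> int:
        if sample not in self.samples:
            raise KeyError(f"unknown sample {sample!r}")
        return sum(per.get(sample, 0) for per in self.counts.values())

    def to_rows(self):
        for seq in sorted(self.counts):
            yield seq, self.counts[seq]


def collapse_tags(*clean_sets: CleanReadSet) -> TagSet:
    """Exact multiset collapse of clean reads into unique tags."""
    if not clean_sets:
        raise ValueError("at least one sample required")
    counts: dict[str, dict[str, int]] = {}
    samples = []
    totals = {}
    for cs in clean_sets:
        samples.append(cs.sample)
        totals[cs.sample] = cs.clean_total
        for seq, n in Counter(cs.reads).items():
            counts.setdefault(seq, {})[cs.sample] = counts.get(seq, {}).get(cs.sample, 0) + n
    return TagSet(counts=counts, samples=samples, clean_totals=totals)


def length_histogram(tags: TagSet, sample: str) -> dict[int, int]:
    """Read-count-weighted insert length histogram for one sample."""
    if sample not in tags.samples:
        raise KeyError(f"unknown sample {sample!r}")
    hist: dict[int, int] = {}
    for seq, per in tags.counts.items():
        n = per.get(sample, 0)
        if n:
            hist[len(seq)] = hist.get(len(seq), 0) + n
    return hist
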