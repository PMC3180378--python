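"""Novel miRNA prediction from unannotated mapped tags.

The procedure mirrors the classic hairpin-excision approach: each
unannotated tag locus is excised with genomic flanks in two frames (tag
as putative 5' arm, tag as putative 3' arm), the window is folded, and
the locus is accepted as a novel miRNA when the fold shows a miRNA-like
hairpin: low folding score (mfe), a mature/star duplex of at least
``min_stem_pairs`` base pairs with small bulges and asymmetry, the
mature tag clear of the terminal loop, homogeneous read 5' ends (the
Dicer-processing signature) and a mature length of 18-26 nt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .annotate import AnnotatedTag
from .folding import MAX_FOLD_LEN, MIN_FOLD_LEN, FoldResult, fold_rna
from .sequtil import revcomp


@dataclass
class HairpinThresholds:
    mfe_max: float = -18.0  # declared fold-score units, not kcal/mol
    min_stem_pairs: int = 16  # mature/star duplex pairs
    max_bulge: int = 4  # largest bulge inside the duplex
    max_asymmetry: int = 5  # total length asymmetry of the duplex sides
    max_duplex_space: int = 35  # nt between the mature and star arms
    dicer_frac: float = 0.9  # reads sharing the modal 5' end
    mature_min_len: int = 18
    mature_max_len: int = 26
    min_loop_clearance: int = 2  # nt between mature and terminal loop


@dataclass
class SupportingTag:
    seq: str
    start: int  # forward-strand genome coordinate
    counts: dict[str, int]


@dataclass
class CandidateLocus:
    chrom: str
    strand: str
    start: int  # forward-strand merged tag span
    end: int
    tags: list[SupportingTag] = field(default_factory=list)

    def support(self, sample: str | None = None) -> int:
        if sample is None:
            return sum(sum(t.counts.values()) for t in self.tags)
        return sum(t.counts.get(sample, 0) for t in self.tags)


@dataclass
class HairpinCandidate:
    chrom: str
    strand: str
    precursor: tuple[int, int]  # forward-strand genome interval
    sequence: str  # sense orientation of the folded window
    structure: str
    mfe: float
    mature: tuple[int, int]  # forward-strand genome interval
    star: tuple[int, int] | None
    stem_pairs: int
    supporting: list[SupportingTag]
    accepted: bool
    reason: str  # "accepted" or the first failed criterion
    window: tuple[int, int] = (0, 0)
    clipped: bool = False


# ---------------------------------------------------------------------------
# locus extraction


def extract_candidate_loci(
    annotated: Iterable[AnnotatedTag],
    chrom_lengths: dict[str, int],
    flank_up: int = 150,
    flank_down: int = 150,
    min_reads: int = 3,
    sample: str | None = None,
) -> list[tuple[CandidateLocus, list[tuple[int, int, bool]]]]:
    """Merge unannotated mapped tag loci and excise candidate windows.

    Overlapping same-strand tag loci merge into one locus (each tag is
    placed at its first genomic hit).  For every locus two windows are
    excised — the tag treated as the 5' arm (flank added 3' of the tag
    in its own orientation) and as the 3' arm (flank added 5') — and
    clipped at chromosome edges.  Loci supported by fewer than
    ``min_reads`` reads are dropped.
    """
    if flank_up < 0 or flank_down < 0:
        raise ValueError("flanks must be >= 0")
    per_strand: dict[tuple[str, str], list[SupportingTag]] = {}
    for t in annotated:
        if t.category != "unann" or not t.hits:
            continue
        h = t.hits[0]
        per_strand.setdefault((h.chrom, h.strand), []).append(
            SupportingTag(t.seq, h.start, dict(t.counts))
        )
    out = []
    for (chrom, strand), tags in sorted(per_strand.items()):
        tags.sort(key=lambda t: t.start)
        current: CandidateLocus | None = None
        loci: list[CandidateLocus] = []
        for t in tags:
            t_end = t.start + len(t.seq)
            if current is not None and t.start < current.end:
                current.end = max(current.end, t_end)
                current.tags.append(t)
            else:
                current = CandidateLocus(chrom, strand, t.start, t_end, [t])
                loci.append(current)
        L = chrom_lengths[chrom]
        for locus in loci:
            if locus.support(sample) < min_reads:
                continue
            if strand == "+":
                raw = [
                    (locus.start, locus.end + flank_down),
                    (locus.start - flank_up, locus.end),
                ]
            else:  # sense-3' extension decreases the forward coordinate
                raw = [
                    (locus.start - flank_down, locus.end),
                    (locus.start, locus.end + flank_up),
                ]
            windows = []
            for a, b in raw:
                ca, cb = max(a, 0), min(b, L)
                windows.append((ca, cb, (ca, cb) != (a, b)))
            out.append((locus, windows))
    return out


# ---------------------------------------------------------------------------
# hairpin evaluation


def _sense_window(chrom_seq: str, a: int, b: int, strand: str) -> str:
    fwd = chrom_seq[a:b]
    return fwd if strand == "+" else revcomp(fwd)


def _sense_offset(pos: int, length: int, a: int, b: int, strand: str) -> int:
    """Sense-orientation offset of a forward interval [pos, pos+length)."""
    if strand == "+":
        return pos - a
    return b - (pos + length)


def _forward_interval(off: int, length: int, a: int, b: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return (a + off, a + off + length)
    return (b - off - length, b - off)


def _duplex(fold: FoldResult, m0: int, m1: int, max_bulge: int, max_asymmetry: int):
    """Best mature/star duplex run in a fold.

    Pairs with one end inside the mature interval are chained (sorted by
    mature position) and split wherever a bulge on either side exceeds
    ``max_bulge`` or the running asymmetry exceeds ``max_asymmetry``;
    the longest surviving run is the duplex.  This keeps a true hairpin
    intact even when the global fold adds stray long-range pairs, while
    random sequence rarely sustains a long compact run.  Returns
    (n_pairs, star_lo, star_hi, side) with side in {"right", "left"}.
    """
    left, right = [], []
    for i, j in fold.pairs:
        i_in = m0 <= i < m1
        j_in = m0 <= j < m1
        if i_in and j_in:
            continue  # mature self-pair: never part of the duplex
        if i_in:
            right.append((i, j))  # partner 3' of mature
        elif j_in:
            left.append((j, i))  # partner 5' of mature
    best = (0, None, None, "right", [])
    for chain, label in ((right, "right"), (left, "left")):
        chain.sort()
        seg: list[tuple[int, int]] = []
        asym = 0
        segments = []
        for pair in chain:
            if seg:
                gm = pair[0] - seg[-1][0] - 1
                gp = abs(seg[-1][1] - pair[1]) - 1
                if gm > max_bulge or gp > max_bulge or abs(asym + gm - gp) > max_asymmetry:
                    segments.append(seg)
                    seg = []
                    asym = 0
                else:
                    asym += gm - gp
            seg.append(pair)
        if seg:
            segments.append(seg)
        for seg in segments:
            if len(seg) > best[0]:
                parts = [p for _, p in seg]
                best = (len(seg), min(parts), max(parts) + 1, label, seg)
    return best


def evaluate_hairpin(
    window_seq: str,
    mature: tuple[int, int],
    read_start_weights: dict[int, int],
    thresholds: HairpinThresholds | None = None,
    fold: FoldResult | None = None,
) -> tuple[bool, str, FoldResult, int, tuple[int, int] | None]:
    """Apply the acceptance criteria to one excised window.

    ``mature`` is the supported mature interval in window (sense)
    coordinates; ``read_start_weights`` maps sense 5'-start offsets of
    supporting reads to their read counts.  Returns (accepted, reason,
    fold, stem_pairs, star_interval); the reason names the first failed
    criterion.
    """
    th = thresholds or HairpinThresholds()
    if fold is None:
        fold = fold_rna(window_seq)
    m0, m1 = mature

    # (a) folding score
    if fold.mfe > th.mfe_max:
        return False, "mfe", fold, 0, None

    n_pairs, s_lo, s_hi, side, segment = _duplex(fold, m0, m1, th.max_bulge, th.max_asymmetry)

    # (b) mature/star duplex strength and shape; the star must sit just
    # across the terminal loop, not in distant flanking sequence
    if n_pairs < th.min_stem_pairs:
        return False, "stem", fold, n_pairs, None
    space = (s_lo - m1) if side == "right" else (m0 - s_hi)
    if space > th.max_duplex_space:
        return False, "stem", fold, n_pairs, None

    # (c) mature clear of the terminal loop: locate the innermost pair
    # nested inside the loop-proximal duplex pair
    if side == "right":
        lo, hi = max(segment)  # innermost duplex pair (largest mature pos)
    else:
        m_in, p_in = min(segment)
        lo, hi = p_in, m_in
    loop_a, loop_b = lo, hi
    for i, j in fold.pairs:
        if lo <= i and j <= hi and i >= loop_a:
            loop_a, loop_b = i, j
    loop_start, loop_end = loop_a + 1, loop_b
    if side == "right":
        clearance = loop_start - m1
    else:
        clearance = m0 - loop_end
    if clearance < th.min_loop_clearance:
        return False, "loop", fold, n_pairs, None

    # (d) Dicer 5'-end homogeneity
    total = sum(read_start_weights.values())
    modal = max(read_start_weights.values()) if read_start_weights else 0
    if total == 0 or modal / total < th.dicer_frac:
        return False, "dicer", fold, n_pairs, None

    # (e) mature length
    if not th.mature_min_len <= (m1 - m0) <= th.mature_max_len:
        return False, "mature_length", fold, n_pairs, None

    return True, "accepted", fold, n_pairs, (s_lo, s_hi)


# ---------------------------------------------------------------------------
# per-sample calling and the shared list


def _evaluate_locus(
    locus: CandidateLocus,
    windows: list[tuple[int, int, bool]],
    chrom_seq: str,
    sample: str | None,
    th: HairpinThresholds,
    fold_cache: dict[str, FoldResult] | None = None,
) -> HairpinCandidate:
    reads = [t for t in locus.tags if (sample is None or t.counts.get(sample, 0) > 0)]
    weights: dict[int, int] = {}
    best_tag: SupportingTag | None = None
    best_n = -1
    for t in reads:
        n = t.counts.get(sample, 0) if sample else sum(t.counts.values())
        if n > best_n:
            best_n, best_tag = n, t
    last: HairpinCandidate | None = None
    for a, b, clipped in windows:
        if b - a < MIN_FOLD_LEN or b - a > MAX_FOLD_LEN:
            last = HairpinCandidate(
                locus.chrom, locus.strand, (a, b), "", "", 0.0,
                (best_tag.start, best_tag.start + len(best_tag.seq)) if best_tag else (a, a),
                None, 0, reads, False, "window_length", (a, b), clipped,
            )
            continue
        seq = _sense_window(chrom_seq, a, b, locus.strand)
        weights = {}
        for t in reads:
            off = _sense_offset(t.start, len(t.seq), a, b, locus.strand)
            n = t.counts.get(sample, 0) if sample else sum(t.counts.values())
            if n:
                weights[off] = weights.get(off, 0) + n
        m_off = _sense_offset(best_tag.start, len(best_tag.seq), a, b, locus.strand)
        if m_off < 0 or m_off + len(best_tag.seq) > b - a:
            last = HairpinCandidate(
                locus.chrom, locus.strand, (a, b), seq, "", 0.0,
                (best_tag.start, best_tag.start + len(best_tag.seq)),
                None, 0, reads, False, "mature_outside_window", (a, b), clipped,
            )
            continue
        mature = (m_off, m_off + len(best_tag.seq))
        if fold_cache is not None and seq in fold_cache:
            fold = fold_cache[seq]
        else:
            fold = fold_rna(seq)
            if fold_cache is not None:
                fold_cache[seq] = fold
        ok, reason, fold, n_pairs, star = evaluate_hairpin(seq, mature, weights, th, fold)
        mature_fwd = _forward_interval(mature[0], mature[1] - mature[0], a, b, locus.strand)
        star_fwd = (
            _forward_interval(star[0], star[1] - star[0], a, b, locus.strand) if star else None
        )
        if star_fwd:
            prec = (min(mature_fwd[0], star_fwd[0]), max(mature_fwd[1], star_fwd[1]))
        else:
            prec = mature_fwd
        cand = HairpinCandidate(
            locus.chrom, locus.strand, prec, seq, fold.structure, fold.mfe,
            mature_fwd, star_fwd, n_pairs, reads, ok, reason, (a, b), clipped,
        )
        if ok:
            return cand
        last = cand
    assert last is not None
    return last


def call_novel_mirnas(
    annotated: Iterable[AnnotatedTag],
    chromosomes: dict[str, str],
    samples: list[str],
    flank_up: int = 150,
    flank_down: int = 150,
    min_reads: int = 3,
    thresholds: HairpinThresholds | None = None,
) -> tuple[dict[str, list[HairpinCandidate]], list[HairpinCandidate]]:
    """Accepted novel-miRNA candidates per sample, plus the shared list.

    A locus enters the shared list when an accepted candidate of every
    sample overlaps it by >= 1 nt on the same strand.
    """
    th = thresholds or HairpinThresholds()
    annotated = list(annotated)
    chrom_lengths = {c: len(s) for c, s in chromosomes.items()}
    fold_cache: dict[str, FoldResult] = {}
    per_sample: dict[str, list[HairpinCandidate]] = {}
    for sample in samples:
        loci = extract_candidate_loci(
            annotated, chrom_lengths, flank_up, flank_down, min_reads, sample
        )
        accepted = []
        for locus, windows in loci:
            cand = _evaluate_locus(
                locus, windows, chromosomes[locus.chrom], sample, th, fold_cache
            )
            if cand.accepted:
                accepted.append(cand)
        per_sample[sample] = accepted

    shared: list[HairpinCandidate] = []
    if samples:
        first = per_sample[samples[0]]
        for cand in first:
            hit_all = True
            for s in samples[1:]:
                if not any(
                    c.chrom == cand.chrom
                    and c.strand == cand.strand
                    and c.precursor[0] < cand.precursor[1]
                    and cand.precursor[0] < c.precursor[1]
                    for c in per_sample[s]
                ):
                    hit_all = False
                    break
            if hit_all:
                shared.append(cand)
    return per_sample, shared
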