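"""Exact mapping and priority-rule category resolution."""

import numpy as np
import pytest

from srnakit.annotate import (
    PRIORITY,
    UNANN,
    GenomicHit,
    MiRNACatalog,
    build_feature_index,
    category_summary,
    map_tags,
    quantify_known,
    resolve_category,
    AnnotatedTag,
)
from srnakit.sequtil import random_seq, revcomp
from srnakit.simdata import GenomicFeature


def _naive_scan(tag, chromosomes):
    hits = []
    for chrom, ref in chromosomes.items():
        for fwd, strand in ((tag, "+"), (revcomp(tag), "-")):
            start = ref.find(fwd)
            while start != -1:
                hits.append((chrom, start, strand))
                start = ref.find(fwd, start + 1)
    return sorted(hits)


def test_planted_substring_is_found():
    rng = np.random.default_rng(0)
    ref = random_seq(rng, 2000)
    tag = ref[100:122]
    hits, _ = map_tags([tag], {"chr1": ref})
    assert any(h.chrom == "chr1" and h.start == 100 and h.strand == "+" for h in hits[tag])


def test_tag_and_revcomp_give_opposite_strand_hits():
    rng = np.random.default_rng(1)
    tag = random_seq(rng, 22)
    ref = random_seq(rng, 500) + tag + random_seq(rng, 500) + revcomp(tag) + random_seq(rng, 500)
    hits, _ = map_tags([tag], {"chrA": ref})
    strands = sorted(h.strand for h in hits[tag])
    assert strands == ["+", "-"]


def test_non_acgt_tags_skipped_with_warning():
    with pytest.warns(UserWarning, match="non-ACGT"):
        hits, skipped = map_tags(["ACGTNACGTNACGTNACGTN"], {"chr1": "ACGT" * 100})
    assert skipped == 1 and hits == {}


def test_mapping_equals_naive_scan_oracle():
    rng = np.random.default_rng(2)
    chromosomes = {"chr1": random_seq(rng, 60_000), "chr2": random_seq(rng, 40_000)}
    tags = []
    for _ in range(30):  # planted forward and reverse
        L = int(rng.integers(18, 31))
        c = "chr1" if rng.random() < 0.5 else "chr2"
        p = int(rng.integers(0, len(chromosomes[c]) - L))
        sub = chromosomes[c][p : p + L]
        tags.append(sub if rng.random() < 0.5 else revcomp(sub))
    tags += [random_seq(rng, 22) for _ in range(30)]  # mostly unmapped
    hits, _ = map_tags(tags, chromosomes)
    for tag in set(tags):
        got = sorted((h.chrom, h.start, h.strand) for h in hits[tag])
        assert got == _naive_scan(tag, chromosomes), tag


def _feat(chrom, start, end, cat, strand="+", name="f"):
    return GenomicFeature(chrom, start, end, strand, cat, name)


def test_priority_mirna_beats_exon():
    idx = build_feature_index(
        [_feat("c", 100, 160, "known_miRNA", name="mir-x"), _feat("c", 90, 200, "exon")]
    )
    hit = GenomicHit("A" * 22, "c", 120, "+")
    cat, mirna = resolve_category([hit], idx)
    assert cat == "known_miRNA" and mirna == "mir-x"


def test_priority_rfam_beats_mirna():
    idx = build_feature_index(
        [_feat("c", 100, 160, "known_miRNA"), _feat("c", 90, 200, "rRNA_rfam")]
    )
    cat, _ = resolve_category([GenomicHit("A" * 22, "c", 120, "+")], idx)
    assert cat == "rRNA_rfam"


def test_no_overlap_is_unann():
    idx = build_feature_index([_feat("c", 1000, 1100, "exon")])
    cat, mirna = resolve_category([GenomicHit("A" * 22, "c", 120, "+")], idx)
    assert cat == UNANN and mirna is None
    assert resolve_category([], idx) == (UNANN, None)


def test_priority_resolution_matches_rank_oracle():
    """1,000 random hit/feature fixtures against brute-force rank-max."""
    rng = np.random.default_rng(5)
    cats = list(PRIORITY)
    for _ in range(1000):
        feats = []
        for i in range(int(rng.integers(0, 6))):
            s = int(rng.integers(0, 400))
            e = s + int(rng.integers(20, 200))
            feats.append(
                _feat("c", s, e, cats[int(rng.integers(0, len(cats)))],
                      strand="+" if rng.random() < 0.5 else "-", name=f"f{i}")
            )
        idx = build_feature_index(feats)
        h_start = int(rng.integers(0, 500))
        h_strand = "+" if rng.random() < 0.5 else "-"
        hit = GenomicHit("A" * 22, "c", h_start, h_strand)
        got, _ = resolve_category([hit], idx)
        overlapping = [
            f.category
            for f in feats
            if f.start < hit.end and h_start < f.end
            and (f.category != "known_miRNA" or f.strand == h_strand)
        ]
        want = min(overlapping, key=PRIORITY.get) if overlapping else UNANN
        assert got == want


def test_quantify_sums_tag_counts():
    t1 = AnnotatedTag("A" * 22, {"S1": 3}, [], "known_miRNA", "mir-A")
    t2 = AnnotatedTag("C" * 22, {"S1": 4}, [], "known_miRNA", "mir-A")
    t3 = AnnotatedTag("G" * 22, {"S1": 0}, [], "known_miRNA", "mir-B")
    df = quantify_known([t1, t2, t3], ["S1"])
    assert int(df.loc["mir-A", "S1"]) == 7
    assert "mir-B" not in df.index  # zero in all samples -> dropped


def test_known_counts_equal_truth_in_errorfree_simulation(study):
    for name, lib in study.libraries.items():
        truth = {k: v for k, v in lib.truth_counts.items() if k.startswith("mir-")}
        got = study.matrix.counts[name]
        for mirna, n in truth.items():
            assert int(got.get(mirna, 0)) == n, (name, mirna)


def test_category_counts_conserve_clean_total(study):
    for name, cs in study.clean.items():
        counts = study.summaries[name]["counts"]
        assert sum(counts.values()) == cs.clean_total
        props = study.summaries[name]["over_clean"]
        assert abs(sum(props.values()) - 1.0) < 1e-9


def test_constructed_category_split_is_reproduced():
    """A 60/15/25 miRNA/other/unann fixture yields those proportions."""
    tags = [
        AnnotatedTag("A" * 20, {"S": 60}, [GenomicHit("A" * 20, "c", 0, "+")], "known_miRNA", "mir-A"),
        AnnotatedTag("C" * 20, {"S": 15}, [GenomicHit("C" * 20, "c", 50, "+")], "exon", None),
        AnnotatedTag("G" * 20, {"S": 25}, [GenomicHit("G" * 20, "c", 99, "+")], UNANN, None),
    ]
    props = category_summary(tags, "S")["over_clean"]
    assert props["known_miRNA"] == pytest.approx(0.60)
    assert props["exon"] == pytest.approx(0.15)
    assert props[UNANN] == pytest.approx(0.25)


def test_annotation_invariant_under_genome_reverse_complement():
    rng = np.random.default_rng(9)
    ref = random_seq(rng, 3000)
    L = len(ref)
    tag = ref[500:522]
    feats = [_feat("c", 490, 560, "known_miRNA", "+", "mir-z"), _feat("c", 1000, 1200, "exon")]
    cat = MiRNACatalog()
    idx = build_feature_index(feats)
    hits, _ = map_tags([tag], {"c": ref})
    got1 = resolve_category(hits[tag], idx)

    rc_ref = revcomp(ref)
    rc_feats = [
        GenomicFeature("c", L - f.end, L - f.start, "-" if f.strand == "+" else "+", f.category, f.name)
        for f in feats
    ]
    rc_hits, _ = map_tags([tag], {"c": rc_ref})
    got2 = resolve_category(rc_hits[tag], build_feature_index(rc_feats))
    assert got1 == got2
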