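"""Toy genomes and simulated small-RNA libraries with planted truth.

The generator builds a multi-chromosome genome (always including "chr1"
and "chrX"), plants perfect fold-back miRNA precursors (arm + loop +
reverse-complement of the arm), genomic clusters of precursors within
10 kb, non-miRNA RNA classes (rRNA-like, repeats, exons, introns), decoy
loci whose 3' "arm" is random sequence and therefore cannot form a
hairpin, and simulates per-sample sequencing libraries: mature-miRNA
reads Poisson-distributed around a true abundance, degradation fragments,
adaptor-less contaminants and low-quality reads.

X-dosage model: a female sample with two active X chromosomes expresses
X-linked miRNAs at ``xci_ratio`` (default 2.0) times the one-active-X /
male level; autosomal output is unchanged.  This is the ground truth the
X-inactivation caller is validated against.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .preprocess import find_adaptor
from .sequtil import random_seq, revcomp

CATEGORIES = ("rRNA_genbank", "rRNA_rfam", "known_miRNA", "repeat", "exon", "intron")

#: expected composition of the mappable (non-contaminant, good-quality)
#: part of a library; chosen to echo a typical stem-cell small-RNA
#: library in which known miRNAs dominate, other annotated RNA stays
#: under 15 % and roughly a quarter of reads stay unannotated.
KNOWN_SHARE = 0.60
NOVEL_SHARE = 0.08
DECOY_SHARE = 0.02
ANNOT_DEG_SHARE = 0.14
INTERGENIC_SHARE = 0.16

_SPACER_LEN = 4  # paired extension between the mature arm and the loop
_LOOP_LEN = 8

DEFAULT_MATURE_LEN_DISTRIBUTION = {
    18: 0.010,
    19: 0.020,
    20: 0.070,
    21: 0.150,
    22: 0.300,
    23: 0.250,
    24: 0.100,
    25: 0.050,
    26: 0.030,
    27: 0.012,
    28: 0.008,
}


@dataclass
class SimulationConfig:
    """Study conditions for the toy genome and libraries."""

    n_autosomes: int = 3
    chrom_length: int = 300_000
    n_mirnas_per_chrom: int = 12
    n_clustered_groups: int = 2
    n_other_rna: int = 4  # per class (rRNA_genbank, rRNA_rfam, repeat, exon, intron)
    n_novel_mirnas: int = 8
    n_decoy_loci: int = 8
    adaptor_seq: str = "TCGTATGCCGTCTTCTGCTTG"
    read_depth: int = 50_000
    raw_read_length: int = 35
    mature_len_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_MATURE_LEN_DISTRIBUTION)
    )
    frac_contaminant: float = 0.05
    frac_low_quality: float = 0.03
    xci_ratio: float = 2.0
    #: fraction of each planted class's expression carried by chrX.  Real
    #: small-RNA libraries put only a few percent of miRNA reads on the X,
    #: so doubling X output perturbs the library composition only mildly
    #: (autosomal profiles stay parallel across XCI states).
    x_expression_share: float = 0.06
    quality_threshold: float = 20.0
    min_adaptor_overlap: int = 6
    seed: int = 0

    def validate(self) -> None:
        for name in ("frac_contaminant", "frac_low_quality"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.xci_ratio <= 0:
            raise ValueError("xci_ratio must be positive")
        if not 0.0 < self.x_expression_share < 1.0:
            raise ValueError("x_expression_share must lie in (0, 1)")
        if self.n_autosomes < 1:
            raise ValueError("need at least one autosome (chr1)")
        dist = self.mature_len_distribution
        if abs(sum(dist.values()) - 1.0) > 1e-6:
            raise ValueError("mature_len_distribution must sum to 1")
        longest = max(l for l, p in dist.items() if p > 0)
        if longest > self.raw_read_length - self.min_adaptor_overlap:
            raise ValueError(
                "requested mature length exceeds raw read length minus "
                "minimum adaptor overlap"
            )
        # rough capacity check: miRNA units are separated by >10 kb
        per_chrom = self.n_mirnas_per_chrom * 11_000 + 5_000
        if per_chrom > self.chrom_length:
            raise ValueError("chrom_length too small for requested features")

    def to_yaml(self, path) -> None:
        import yaml

        d = dict(vars(self))
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class GenomicFeature:
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    category: str
    name: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError("feature interval must satisfy 0 <= start < end")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class PlantedMiRNA:
    """Truth-registry entry for one planted precursor."""

    name: str
    chrom: str
    strand: str
    precursor: tuple[int, int]  # forward-strand, 0-based half-open
    mature: tuple[int, int]
    star: tuple[int, int]
    mature_seq: str
    precursor_seq: str  # sense orientation
    kind: str  # known | novel | decoy
    base_abundance: float = 0.0  # expected clean reads at the reference depth


@dataclass
class ToyGenome:
    config: SimulationConfig
    chromosomes: dict[str, str]
    features: list[GenomicFeature]
    truth: dict[str, PlantedMiRNA]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.chromosomes.items()}

    def planted(self, kind: str) -> list[PlantedMiRNA]:
        return [m for m in self.truth.values() if m.kind == kind]

    def occupied(self, chrom: str) -> list[tuple[int, int]]:
        ivs = [(f.start, f.end) for f in self.features if f.chrom == chrom]
        ivs += [m.precursor for m in self.truth.values() if m.chrom == chrom]
        return sorted(ivs)


@dataclass(frozen=True)
class SampleSpec:
    name: str
    sex: str  # male | female
    xci_status: str  # male | one_active_X | two_active_X

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be male or female")
        if self.xci_status not in ("male", "one_active_X", "two_active_X"):
            raise ValueError("bad xci_status")
        if (self.sex == "male") != (self.xci_status == "male"):
            raise ValueError("xci_status 'male' iff sex 'male'")


class PlacementError(RuntimeError):
    """Raised when requested features cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# genome construction


def _sample_len(rng: np.random.Generator, dist: dict[int, float]) -> int:
    lens = sorted(dist)
    probs = np.array([dist[l] for l in lens], dtype=float)
    probs /= probs.sum()
    return int(rng.choice(lens, p=probs))


MATURE_MIRNA_MAX_LEN = 26  # canonical Dicer product; longer reads are degradation


def _draw_mature(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    """Random mature sequence screened against spurious adaptor matches.

    Lengths follow the configured read-length distribution truncated to
    the canonical mature-miRNA range (<= 26 nt); the longer tail of the
    distribution is reserved for degradation fragments.
    """
    dist = {
        l: p for l, p in cfg.mature_len_distribution.items() if l <= MATURE_MIRNA_MAX_LEN
    }
    for _ in range(100):
        m = random_seq(rng, _sample_len(rng, dist))
        if find_adaptor(m + cfg.adaptor_seq, cfg.adaptor_seq, cfg.min_adaptor_overlap) == len(m):
            return m
    raise PlacementError("could not draw an adaptor-free mature sequence")


def _hairpin(mature: str, rng: np.random.Generator) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Perfect-complement precursor; returns (seq, mature_off, star_off)."""
    arm = mature + random_seq(rng, _SPACER_LEN)
    loop = random_seq(rng, _LOOP_LEN)
    seq = arm + loop + revcomp(arm)
    m = (0, len(mature))
    star_start = len(arm) + _LOOP_LEN + _SPACER_LEN
    return seq, m, (star_start, star_start + len(mature))


def _decoy(mature: str, rng: np.random.Generator) -> tuple[str, tuple[int, int], tuple[int, int]]:
    """Decoy locus: mature arm plus a random, non-complementary 'arm'."""
    arm = mature + random_seq(rng, _SPACER_LEN)
    loop = random_seq(rng, _LOOP_LEN)
    other = random_seq(rng, len(arm))
    seq = arm + loop + other
    m = (0, len(mature))
    star_start = len(arm) + _LOOP_LEN + _SPACER_LEN
    return seq, m, (star_start, star_start + len(mature))


def _place_units(
    rng: np.random.Generator, chrom_len: int, widths: list[int], min_sep: int
) -> list[int]:
    """Non-overlapping left coordinates with pairwise gaps >= min_sep.

    Deterministic slot construction: the total slack is distributed
    uniformly at random among the gaps, so no rejection loop is needed.
    """
    total = sum(widths) + min_sep * (len(widths) + 1)
    if total > chrom_len:
        raise PlacementError(
            f"cannot place {len(widths)} units of total width {sum(widths)} "
            f"with separation {min_sep} on a {chrom_len} bp chromosome"
        )
    slack = chrom_len - total
    cuts = np.sort(rng.integers(0, slack + 1, size=len(widths) + 1))
    starts = []
    pos = 0
    prev_cut = 0
    for w, cut in zip(widths, cuts):
        pos += min_sep + int(cut - prev_cut)
        prev_cut = cut
        starts.append(pos)
        pos += w
    return starts


def _place_in_gaps(
    rng: np.random.Generator,
    chrom_len: int,
    occupied: list[tuple[int, int]],
    width: int,
    margin: int = 50,
    attempts: int = 2000,
) -> int:
    """Random start for a feature avoiding occupied intervals (+margin)."""
    for _ in range(attempts):
        s = int(rng.integers(0, chrom_len - width))
        e = s + width
        if all(e + margin <= a or b + margin <= s for a, b in occupied):
            occupied.append((s, e))
            occupied.sort()
            return s
    raise PlacementError("could not place feature without overlap")


def generate_toy_genome(config: SimulationConfig) -> ToyGenome:
    """Build the genome, annotation features and truth registry.

    Deterministic given ``config.seed``.  Guarantees at least one cluster
    of >=2 precursors with first nucleotides < 10 kb apart (when
    ``n_clustered_groups`` >= 1) and, on every chromosome with >= 2
    placement units, at least one precursor pair >= 10,001 bases apart.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_names = ["chr1"] + [f"chr{i}" for i in range(2, config.n_autosomes + 1)] + ["chrX"]

    chromosomes = {c: random_seq(rng, config.chrom_length) for c in chrom_names}
    features: list[GenomicFeature] = []
    truth: dict[str, PlantedMiRNA] = {}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    # --- known miRNA precursors, cluster groups assigned cyclically
    cluster_chroms = [chrom_names[i % len(chrom_names)] for i in range(config.n_clustered_groups)]
    mirna_id = 0
    weights = []
    for chrom in chrom_names:
        n_clusters_here = cluster_chroms.count(chrom)
        n_units = config.n_mirnas_per_chrom - n_clusters_here  # cluster = 2 precursors
        if n_units < n_clusters_here or n_units < 1:
            raise PlacementError("n_mirnas_per_chrom too small for requested clusters")
        unit_plans = []  # list of lists of (gap_from_unit_start, hairpin spec)
        for u in range(n_units):
            if u < n_clusters_here:
                gap = int(rng.integers(500, 8001))  # first-nt distance < 10 kb
                unit_plans.append([0, gap])
            else:
                unit_plans.append([0])
        specs = []
        widths = []
        for plan in unit_plans:
            members = []
            for off in plan:
                mature = _draw_mature(rng, config)
                seq, m_off, s_off = _hairpin(mature, rng)
                members.append((off, mature, seq, m_off, s_off))
            specs.append(members)
            widths.append(plan[-1] + len(members[-1][2]))
        # >=10,001 bp separation between units ensures non-cluster pairs
        starts = _place_units(rng, config.chrom_length, widths, min_sep=10_500)
        seq_arr = chromosomes[chrom]
        for unit_start, members, width in zip(starts, specs, widths):
            occupied[chrom].append((unit_start, unit_start + width))
            for off, mature, pseq, m_off, s_off in members:
                strand = "+" if rng.random() < 0.5 else "-"
                s = unit_start + off
                L = len(pseq)
                fwd = pseq if strand == "+" else revcomp(pseq)
                seq_arr = seq_arr[:s] + fwd + seq_arr[s + L :]

                def fwd_iv(off2: tuple[int, int]) -> tuple[int, int]:
                    if strand == "+":
                        return (s + off2[0], s + off2[1])
                    return (s + L - off2[1], s + L - off2[0])

                name = f"mir-{mirna_id:03d}"
                mirna_id += 1
                w = float(np.exp(rng.normal(0.0, 1.2)))
                weights.append((name, w))
                truth[name] = PlantedMiRNA(
                    name=name,
                    chrom=chrom,
                    strand=strand,
                    precursor=(s, s + L),
                    mature=fwd_iv(m_off),
                    star=fwd_iv(s_off),
                    mature_seq=mature,
                    precursor_seq=pseq,
                    kind="known",
                )
                features.append(
                    GenomicFeature(chrom, s, s + L, strand, "known_miRNA", name)
                )
        chromosomes[chrom] = seq_arr
        occupied[chrom].sort()

    # --- novel miRNAs and decoys (no annotation features -> unann tags)
    def plant_extra(n: int, kind: str, builder) -> None:
        for i in range(n):
            chrom = chrom_names[i % len(chrom_names)]
            mature = _draw_mature(rng, config)
            pseq, m_off, s_off = builder(mature, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            L = len(pseq)
            s = _place_in_gaps(rng, config.chrom_length, occupied[chrom], L)
            fwd = pseq if strand == "+" else revcomp(pseq)
            chromosomes[chrom] = chromosomes[chrom][:s] + fwd + chromosomes[chrom][s + L :]

            def fwd_iv(off2: tuple[int, int]) -> tuple[int, int]:
                if strand == "+":
                    return (s + off2[0], s + off2[1])
                return (s + L - off2[1], s + L - off2[0])

            name = f"{kind}-{i:03d}"
            truth[name] = PlantedMiRNA(
                name=name,
                chrom=chrom,
                strand=strand,
                precursor=(s, s + L),
                mature=fwd_iv(m_off),
                star=fwd_iv(s_off),
                mature_seq=mature,
                precursor_seq=pseq,
                kind=kind,
            )

    plant_extra(config.n_novel_mirnas, "novel", _hairpin)
    plant_extra(config.n_decoy_loci, "decoy", _decoy)

    # --- other RNA classes (degradation sources)
    for category in ("rRNA_genbank", "rRNA_rfam", "repeat", "exon", "intron"):
        for i in range(config.n_other_rna):
            chrom = chrom_names[(i + zlib.crc32(category.encode())) % len(chrom_names)]
            width = int(rng.integers(150, 401))
            s = _place_in_gaps(rng, config.chrom_length, occupied[chrom], width)
            strand = "+" if rng.random() < 0.5 else "-"
            features.append(
                GenomicFeature(chrom, s, s + width, strand, category, f"{category}_{i}")
            )

    genome = ToyGenome(config=config, chromosomes=chromosomes, features=features, truth=truth)
    _assign_abundances(genome, rng_weights=dict(weights), rng=rng)
    _check_genome(genome)
    return genome


def _assign_abundances(genome: ToyGenome, rng_weights: dict[str, float], rng: np.random.Generator) -> None:
    cfg = genome.config
    mappable = cfg.read_depth * (1.0 - cfg.frac_contaminant - cfg.frac_low_quality)
    for kind, share in (("known", KNOWN_SHARE), ("novel", NOVEL_SHARE), ("decoy", DECOY_SHARE)):
        members = genome.planted(kind)
        if not members:
            continue
        w = np.array(
            [rng_weights.get(m.name, float(np.exp(rng.normal(0.0, 1.2)))) for m in members]
        )
        on_x = np.array([m.chrom == "chrX" for m in members])
        if on_x.any() and (~on_x).any():
            xs = cfg.x_expression_share
            w[on_x] *= xs / w[on_x].sum()
            w[~on_x] *= (1.0 - xs) / w[~on_x].sum()
        w = w / w.sum()
        for m, wi in zip(members, w):
            m.base_abundance = float(share * mappable * wi)


def _check_genome(genome: ToyGenome) -> None:
    for f in genome.features:
        if f.end > len(genome.chromosomes[f.chrom]):
            raise PlacementError(f"feature {f.name} exceeds chromosome bounds")
    for m in genome.truth.values():
        p0, p1 = m.precursor
        m0, m1 = m.mature
        if not (p0 <= m0 < m1 <= p1):
            raise AssertionError("mature interval must lie within precursor")
        fwd = genome.chromosomes[m.chrom][m0:m1]
        sense = fwd if m.strand == "+" else revcomp(fwd)
        if sense != m.mature_seq:
            raise AssertionError(f"planted mature of {m.name} not found on stated strand")
    ivs: dict[str, list[tuple[int, int]]] = {}
    for m in genome.truth.values():
        ivs.setdefault(m.chrom, []).append(m.precursor)
    for chrom, lst in ivs.items():
        lst.sort()
        for (a0, a1), (b0, b1) in zip(lst, lst[1:]):
            if b0 < a1:
                raise PlacementError(f"overlapping precursors on {chrom}")


# ---------------------------------------------------------------------------
# library simulation


@dataclass
class SimulatedLibrary:
    sample: SampleSpec
    records: list[tuple[str, str, str]]  # (name, sequence, phred33 quality)
    truth_counts: dict[str, int]  # planted locus -> realized clean-read count
    class_counts: dict[str, int]


def sample_rng(config: SimulationConfig, sample_name: str) -> np.random.Generator:
    """One RNG stream per sample: adding a sample perturbs no other."""
    tag = zlib.crc32(sample_name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, tag]))


def _dosage_multiplier(m: PlantedMiRNA, sample: SampleSpec, xci_ratio: float) -> float:
    if m.chrom == "chrX" and sample.xci_status == "two_active_X":
        return xci_ratio
    return 1.0


def simulate_counts(
    genome: ToyGenome,
    sample: SampleSpec,
    depth: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Poisson-realized clean-read counts for every planted locus.

    X-linked loci are scaled by ``xci_ratio`` for two-active-X samples.
    """
    cfg = genome.config
    if depth is None:
        depth = cfg.read_depth
    if rng is None:
        rng = sample_rng(cfg, sample.name)
    scale = depth / cfg.read_depth
    out = {}
    for m in genome.truth.values():
        lam = m.base_abundance * scale * _dosage_multiplier(m, sample, cfg.xci_ratio)
        out[m.name] = int(rng.poisson(lam)) if lam > 0 else 0
    return out


def _qual_string(rng: np.random.Generator, n: int, low: bool) -> str:
    if low:
        q = rng.integers(5, 15, size=n)
    else:
        q = rng.integers(35, 41, size=n)
    return "".join(chr(33 + int(x)) for x in q)


def _raw_read(insert: str, cfg: SimulationConfig) -> str:
    raw = (insert + cfg.adaptor_seq)[: cfg.raw_read_length]
    if len(raw) < cfg.raw_read_length:  # pad with adaptor-cycle filler
        raw = raw + ("A" * (cfg.raw_read_length - len(raw)))
    return raw


def _degradation_insert(
    rng: np.random.Generator,
    genome: ToyGenome,
    intervals: list[tuple[str, int, int, str]],
    cfg: SimulationConfig,
) -> str:
    for _ in range(60):
        chrom, s, e, strand = intervals[int(rng.integers(0, len(intervals)))]
        ln = min(_sample_len(rng, cfg.mature_len_distribution), e - s)
        start = int(rng.integers(s, e - ln + 1))
        frag = genome.chromosomes[chrom][start : start + ln]
        if strand == "-" or (strand == "." and rng.random() < 0.5):
            frag = revcomp(frag)
        if "N" not in frag and find_adaptor(
            frag + cfg.adaptor_seq, cfg.adaptor_seq, cfg.min_adaptor_overlap
        ) == len(frag):
            return frag
    raise PlacementError("could not draw an adaptor-free degradation fragment")


def _intergenic_intervals(genome: ToyGenome) -> list[tuple[str, int, int, str]]:
    out = []
    for chrom, seq in genome.chromosomes.items():
        occ = genome.occupied(chrom)
        pos = 0
        for a, b in occ:
            if a - pos >= 60:
                out.append((chrom, pos, a, "."))
            pos = max(pos, b)
        if len(seq) - pos >= 60:
            out.append((chrom, pos, len(seq), "."))
    return out


def _contaminant(rng: np.random.Generator, cfg: SimulationConfig) -> str:
    for _ in range(100):
        s = random_seq(rng, cfg.raw_read_length)
        if find_adaptor(s, cfg.adaptor_seq, cfg.min_adaptor_overlap) is None:
            return s
    raise PlacementError("could not draw an adaptor-free contaminant")


def simulate_library(
    genome: ToyGenome,
    sample: SampleSpec,
    depth: int | None = None,
) -> SimulatedLibrary:
    """Simulate one sequencing library (raw 35 nt reads with 3' adaptor).

    Composition: planted-locus reads with Poisson counts (X-dosage
    scaled), degradation fragments from annotated features and from
    intergenic space, ``frac_contaminant`` adaptor-less reads, and
    ``frac_low_quality`` reads with mean quality below the threshold.
    Deterministic given config seed and sample name.
    """
    cfg = genome.config
    if depth is None:
        depth = cfg.read_depth
    rng = sample_rng(cfg, sample.name)
    records: list[tuple[str, str, str]] = []
    truth_counts = simulate_counts(genome, sample, depth=depth, rng=rng)
    if depth == 0:
        return SimulatedLibrary(sample, [], {k: 0 for k in truth_counts}, {})

    rest = depth * (1.0 - cfg.frac_contaminant - cfg.frac_low_quality)

    inserts: list[str] = []
    # planted loci
    for m in genome.truth.values():
        inserts.extend([m.mature_seq] * truth_counts[m.name])
    class_counts = {"planted": len(inserts)}

    # degradation from annotated features and intergenic space
    feat_ivs = [
        (f.chrom, f.start, f.end, f.strand)
        for f in genome.features
        if f.category != "known_miRNA"
    ]
    inter_ivs = _intergenic_intervals(genome)
    n_deg = int(round(ANNOT_DEG_SHARE * rest))
    n_inter = int(round(INTERGENIC_SHARE * rest))
    for _ in range(n_deg):
        inserts.append(_degradation_insert(rng, genome, feat_ivs, cfg))
    for _ in range(n_inter):
        inserts.append(_degradation_insert(rng, genome, inter_ivs, cfg))
    class_counts["degradation"] = n_deg
    class_counts["intergenic"] = n_inter

    # contaminant / low-quality fractions are of the *realized* library,
    # so the recovered removal fractions match the configured rates
    mappable = len(inserts)
    total_est = mappable / (1.0 - cfg.frac_contaminant - cfg.frac_low_quality)
    n_cont = int(round(cfg.frac_contaminant * total_est))
    n_lowq = int(round(cfg.frac_low_quality * total_est))
    class_counts["contaminant"] = n_cont
    class_counts["low_quality"] = n_lowq

    for i, ins in enumerate(inserts):
        raw = _raw_read(ins, cfg)
        records.append((f"read{i:07d}", raw, _qual_string(rng, len(raw), low=False)))

    base = len(records)
    for i in range(n_lowq):
        ins = _degradation_insert(rng, genome, inter_ivs, cfg)
        raw = _raw_read(ins, cfg)
        records.append((f"read{base + i:07d}", raw, _qual_string(rng, len(raw), low=True)))
    base = len(records)
    for i in range(n_cont):
        raw = _contaminant(rng, cfg)
        records.append((f"read{base + i:07d}", raw, _qual_string(rng, len(raw), low=False)))

    # fixed shuffle so read order carries no class signal
    order = rng.permutation(len(records))
    records = [records[int(k)] for k in order]
    return SimulatedLibrary(sample, records, truth_counts, class_counts)


# ---------------------------------------------------------------------------
# positions-level simulation for the Poisson noise-filter regime


@dataclass
class FilterStudy:
    """Counts + mapped positions at a sparse, genome-wide regime."""

    counts: dict[str, dict[str, int]]  # locus -> {sample: count}
    positions: dict[str, dict[str, np.ndarray]]  # sample -> chrom -> starts
    loci: dict[str, tuple[str, int]]  # locus -> (chrom, first nucleotide)
    clean_totals: dict[str, int]
    is_noise: dict[str, bool]


def simulate_filter_study(
    samples: list[str],
    n_chroms: int = 4,
    chrom_length: int = 12_500_000,
    clean_total: int = 1_000_000,
    n_planted: int = 48,
    n_noise: int = 200,
    planted_tpm_low: float = 15.0,
    planted_tpm_high: float = 5_000.0,
    rng: np.random.Generator | None = None,
) -> FilterStudy:
    """Sparse mapped-read landscape for exercising the noise filter.

    Emulates the published regime in proportion (reads per genome base
    ~0.02): planted miRNA loci with expression >= ~10 TPM, noise loci
    with 1-2 sporadic reads, and a uniform background of mapped
    degradation reads over the whole genome.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    loci: dict[str, tuple[str, int]] = {}
    counts: dict[str, dict[str, int]] = {}
    is_noise: dict[str, bool] = {}
    lam_planted = np.exp(
        rng.uniform(np.log(planted_tpm_low), np.log(planted_tpm_high), size=n_planted)
    ) * (clean_total / 1e6)
    for i in range(n_planted):
        name = f"planted-{i:03d}"
        loci[name] = (chroms[i % n_chroms], int(rng.integers(0, chrom_length)))
        counts[name] = {s: int(rng.poisson(lam_planted[i])) for s in samples}
        is_noise[name] = False
    for i in range(n_noise):
        name = f"noise-{i:03d}"
        loci[name] = (chroms[i % n_chroms], int(rng.integers(0, chrom_length)))
        counts[name] = {s: int(rng.integers(1, 3)) for s in samples}
        is_noise[name] = True

    positions: dict[str, dict[str, np.ndarray]] = {}
    clean_totals = {}
    for s in samples:
        locus_reads = sum(counts[n][s] for n in counts)
        n_bg = max(clean_total - locus_reads, 0)
        per_chrom: dict[str, list[np.ndarray]] = {c: [] for c in chroms}
        bg_chrom = rng.integers(0, n_chroms, size=n_bg)
        bg_pos = rng.integers(0, chrom_length, size=n_bg)
        for ci, c in enumerate(chroms):
            per_chrom[c].append(bg_pos[bg_chrom == ci])
        for name, (chrom, pos) in loci.items():
            k = counts[name][s]
            if k:
                per_chrom[chrom].append(np.full(k, pos, dtype=np.int64))
        positions[s] = {c: np.sort(np.concatenate(v)) if v else np.array([], dtype=np.int64) for c, v in per_chrom.items()}
        clean_totals[s] = n_bg + locus_reads
    return FilterStudy(counts, positions, loci, clean_totals, is_noise)


# ---------------------------------------------------------------------------
# on-disk outputs


def write_genome(genome: ToyGenome, outdir: str | Path) -> None:
    """Write genome FASTA, features GFF3 + BED6, and the truth table TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in genome.chromosomes.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(outdir / "features.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for f in genome.features:
            # GFF is 1-based closed
            fh.write(
                f"{f.chrom}\tsrnakit\t{f.category}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\tID={f.name}\n"
            )
    with open(outdir / "features.bed", "w") as fh:
        for f in genome.features:
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{f.name}\t0\t{f.strand}\n")
    with open(outdir / "truth_mirnas.tsv", "w") as fh:
        fh.write(
            "name\tkind\tchrom\tstrand\tprec_start\tprec_end\tmat_start\tmat_end\t"
            "star_start\tstar_end\tbase_abundance\tmature_seq\n"
        )
        for m in genome.truth.values():
            fh.write(
                f"{m.name}\t{m.kind}\t{m.chrom}\t{m.strand}\t{m.precursor[0]}\t"
                f"{m.precursor[1]}\t{m.mature[0]}\t{m.mature[1]}\t{m.star[0]}\t"
                f"{m.star[1]}\t{m.base_abundance:.4f}\t{m.mature_seq}\n"
            )


def write_fastq(library: SimulatedLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in library.records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
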