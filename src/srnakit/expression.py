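"""TPM normalisation, Poisson noise filtering, genomic clusters and
differential expression for two unreplicated libraries.

Normalisation is tags-per-million clean reads:

    TPM = count / clean_total * 1e6

The noise filter draws random 50-bp bins across every chromosome,
estimates the background rate lambda as the mean number of mapped read
starts per bin, and converts the smallest count whose upper-tail Poisson
probability falls below ``p_crit`` into a per-sample TPM threshold; a
miRNA survives when its TPM reaches max(tpm_floor, that threshold) in at
least one sample.  Genomic clusters chain precursors whose first
nucleotides lie within 10 kb.  Differential expression between two
libraries without replicates uses the Audic-Claverie count test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage


@dataclass
class ExpressionMatrix:
    counts: pd.DataFrame  # miRNA x sample, integer counts
    clean_totals: dict[str, int]
    loci: pd.DataFrame | None = None  # index=miRNA: chrom, strand, position
    tpm: pd.DataFrame = field(init=False)

    def __post_init__(self):
        for s in self.counts.columns:
            if self.clean_totals.get(s, 0) <= 0:
                raise ValueError(f"clean_total for sample {s!r} must be > 0")
        totals = pd.Series(self.clean_totals).reindex(self.counts.columns)
        self.tpm = self.counts / totals * 1e6

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset(self, names) -> "ExpressionMatrix":
        loci = self.loci.loc[self.loci.index.intersection(names)] if self.loci is not None else None
        return ExpressionMatrix(self.counts.loc[names], dict(self.clean_totals), loci)


def normalize_tpm(
    counts: pd.DataFrame,
    clean_totals: dict[str, int],
    loci: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Wrap a count matrix with exact per-cell TPM normalisation."""
    return ExpressionMatrix(counts.astype(int), dict(clean_totals), loci)


# ---------------------------------------------------------------------------
# Poisson background filter


def poisson_count_threshold(lam: float, p_crit: float = 1e-4, max_c: int = 100_000) -> int:
    """Smallest count c with P(X >= c) < p_crit for X ~ Poisson(lam)."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    c = 1
    while stats.poisson.sf(c - 1, lam) >= p_crit:
        c += 1
        if c > max_c:
            raise RuntimeError("no Poisson threshold below max_c")
    return c


@dataclass
class NoiseFilterReport:
    per_sample: dict[str, dict[str, float]]  # lambda, c_star, tpm_threshold, effective
    n_bins_per_chrom: int
    bin_len: int
    p_crit: float
    tpm_floor: float


def poisson_noise_filter(
    matrix: ExpressionMatrix,
    chrom_lengths: dict[str, int],
    positions: dict[str, dict[str, np.ndarray]],
    n_bins_per_chrom: int = 10_000,
    bin_len: int = 50,
    p_crit: float = 1e-4,
    tpm_floor: float = 3.0,
    rng: np.random.Generator | None = None,
) -> tuple[ExpressionMatrix, NoiseFilterReport]:
    """Remove rows indistinguishable from sporadic background reads.

    ``positions[sample][chrom]`` holds the mapped read start coordinates
    of that sample.  For each sample, ``n_bins_per_chrom`` random
    ``bin_len``-bp bins per chromosome estimate the background rate; a
    row is retained when its TPM reaches the effective threshold
    max(tpm_floor, TPM-equivalent of c*) in at least one sample.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    for chrom, L in chrom_lengths.items():
        if L < bin_len:
            raise ValueError(f"chromosome {chrom} shorter than bin_len")
    report: dict[str, dict[str, float]] = {}
    keep = pd.Series(False, index=matrix.counts.index)
    for s in matrix.samples:
        counts = []
        for chrom, L in chrom_lengths.items():
            starts = np.sort(np.asarray(positions.get(s, {}).get(chrom, []), dtype=np.int64))
            bins = rng.integers(0, L - bin_len + 1, size=n_bins_per_chrom)
            hi = np.searchsorted(starts, bins + bin_len, side="left")
            lo = np.searchsorted(starts, bins, side="left")
            counts.append(hi - lo)
        lam = float(np.mean(np.concatenate(counts)))
        c_star = poisson_count_threshold(lam, p_crit)
        tpm_eq = c_star / matrix.clean_totals[s] * 1e6
        effective = max(tpm_floor, tpm_eq)
        report[s] = {
            "lambda": lam,
            "c_star": float(c_star),
            "tpm_threshold": tpm_eq,
            "effective_threshold": effective,
        }
        keep |= matrix.tpm[s] >= effective
    filtered = matrix.subset(matrix.counts.index[keep])
    return filtered, NoiseFilterReport(report, n_bins_per_chrom, bin_len, p_crit, tpm_floor)


# ---------------------------------------------------------------------------
# 10-kb genomic clusters


@dataclass
class ClusterGroup:
    cluster_id: int
    chrom: str | None
    members: list[str]  # ordered by first-nucleotide position
    span: tuple[int, int] | None
    summed_tpm: dict[str, float]
    positioned: bool = True


def group_clusters(
    matrix: ExpressionMatrix,
    max_gap: int = 10_000,
) -> list[ClusterGroup]:
    """Chain miRNAs whose first nucleotides are within ``max_gap`` bases.

    Single-linkage chaining along each chromosome: sort by position and
    join consecutive rows at distance <= max_gap (inclusive).  Rows
    without genomic position become flagged singletons.  Clusters are
    returned ranked by total summed TPM (descending), ties by members.
    """
    loci = matrix.loci
    groups: list[ClusterGroup] = []
    cid = 0
    positioned = loci.dropna(subset=["position"]) if loci is not None else pd.DataFrame()
    known_rows = matrix.counts.index.intersection(positioned.index) if len(positioned) else []
    for chrom in sorted(positioned["chrom"].unique()) if len(positioned) else []:
        rows = positioned.loc[[r for r in known_rows if positioned.loc[r, "chrom"] == chrom]]
        rows = rows.sort_values("position")
        chain: list[str] = []
        last = None
        for name, row in rows.iterrows():
            pos = int(row["position"])
            if last is not None and pos - last > max_gap:
                groups.append(_make_group(cid, chrom, chain, positioned, matrix))
                cid += 1
                chain = []
            chain.append(name)
            last = pos
        if chain:
            groups.append(_make_group(cid, chrom, chain, positioned, matrix))
            cid += 1
    in_groups = {m for g in groups for m in g.members}
    for name in matrix.counts.index:
        if name not in in_groups:
            groups.append(
                ClusterGroup(
                    cid, None, [name], None,
                    {s: float(matrix.tpm.loc[name, s]) for s in matrix.samples},
                    positioned=False,
                )
            )
            cid += 1
    groups.sort(key=lambda g: (-sum(g.summed_tpm.values()), g.members))
    return groups


def _make_group(cid, chrom, chain, loci, matrix) -> ClusterGroup:
    pos = [int(loci.loc[m, "position"]) for m in chain]
    tpm = {s: float(matrix.tpm.loc[chain, s].sum()) for s in matrix.samples}
    return ClusterGroup(cid, chrom, list(chain), (min(pos), max(pos) + 1), tpm)


# ---------------------------------------------------------------------------
# differential expression (Audic-Claverie)


def audic_claverie_p(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie p-value for counts x (library size n1)
    and y (library size n2).

    Under the AC model the predictive distribution of y given x is
    negative binomial with r = x + 1 and success probability
    n1 / (n1 + n2); the two-sided p doubles the smaller tail (capped at
    1).  The conditioning direction is fixed by the caller so that the
    value is invariant under swapping the two libraries.
    """
    p = n1 / (n1 + n2)
    lo = stats.nbinom.cdf(y, x + 1, p)
    hi = stats.nbinom.sf(y - 1, x + 1, p)
    return float(min(1.0, 2.0 * min(lo, hi)))


@dataclass
class DifferentialResult:
    mirna: str
    count_a: int
    count_b: int
    tpm_a: float
    tpm_b: float
    log2_ratio: float
    p_value: float
    flag: str  # up | down | ns


def differential_expression(
    matrix: ExpressionMatrix,
    sample_a: str,
    sample_b: str,
    min_tpm: float = 3.0,
    fc_threshold: float = 2.0,
    alpha: float = 0.05,
    pseudocount: float = 0.5,
) -> list[DifferentialResult]:
    """Audic-Claverie differential expression of A vs B.

    Rows must exceed ``min_tpm`` in at least one of the two samples.
    log2_ratio = log2((TPM_A + pc) / (TPM_B + pc)); a row is flagged
    up/down when |log2_ratio| > log2(fc_threshold) and p < alpha.  The
    AC conditioning is canonicalised on the lexicographically smaller
    sample name, making results antisymmetric under swapping A and B.
    """
    for s in (sample_a, sample_b):
        if s not in matrix.samples:
            raise KeyError(f"unknown sample {s!r}")
    na, nb = matrix.clean_totals[sample_a], matrix.clean_totals[sample_b]
    lr_cut = np.log2(fc_threshold)
    out = []
    for name in matrix.counts.index:
        ta, tb = float(matrix.tpm.loc[name, sample_a]), float(matrix.tpm.loc[name, sample_b])
        if max(ta, tb) <= min_tpm:
            continue
        ca, cb = int(matrix.counts.loc[name, sample_a]), int(matrix.counts.loc[name, sample_b])
        lr = float(np.log2((ta + pseudocount) / (tb + pseudocount)))
        if sample_a <= sample_b:
            p = audic_claverie_p(ca, cb, na, nb)
        else:
            p = audic_claverie_p(cb, ca, nb, na)
        if p < alpha and lr > lr_cut:
            flag = "up"
        elif p < alpha and lr < -lr_cut:
            flag = "down"
        else:
            flag = "ns"
        out.append(DifferentialResult(name, ca, cb, ta, tb, lr, p, flag))
    return out


# ---------------------------------------------------------------------------
# hierarchical clustering of samples


def hierarchical_clustering(matrix: ExpressionMatrix, samples: list[str] | None = None):
    """Average-linkage clustering on 1 - Pearson r of log2(TPM+1) profiles.

    Returns (linkage matrix, sample order).  Deterministic: the distance
    ties are broken by sample order as given.
    """
    samples = samples or matrix.samples
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    X = np.log2(matrix.tpm[samples].to_numpy(dtype=float) + 1.0)
    corr = np.corrcoef(X.T)
    d = 1.0 - corr
    iu = np.triu_indices(len(samples), k=1)
    condensed = np.clip(d[iu], 0.0, None)
    Z = linkage(condensed, method="average")
    return Z, list(samples)
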