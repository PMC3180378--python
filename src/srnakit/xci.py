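"""X-chromosome activity inference from chromosome-wise miRNA dosage.

A female cell line with two active X chromosomes expresses X-linked
miRNAs at roughly twice the level of a one-active-X line, while
autosomal output is unchanged.  The caller builds a per-miRNA baseline
(the median TPM across male reference samples), expresses every sample
as position-ordered log2 ratios against that baseline, smooths them
with a centred moving average for visualisation, and compares each test
sample's X-linked ratios with the pooled reference ratios by a
two-sided Mann-Whitney test, with chromosome 1 as a within-genome
control against global library-size artefacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_WINDOW = 5


def collect_chromosome_mirnas(matrix: ExpressionMatrix, chrom: str) -> pd.DataFrame:
    """Rows of one chromosome, ordered by first-nucleotide position.

    Rows with zero counts in every sample are excluded.
    """
    if matrix.loci is None:
        raise ValueError("matrix has no genomic positions")
    if chrom not in set(matrix.loci["chrom"].dropna()):
        raise KeyError(f"unknown chromosome {chrom!r}")
    rows = matrix.loci[matrix.loci["chrom"] == chrom].sort_values("position")
    rows = rows.loc[matrix.counts.loc[rows.index].sum(axis=1) > 0]
    return rows


def male_baseline(
    matrix: ExpressionMatrix, male_samples: list[str], chrom: str
) -> tuple[pd.Series, list[str]]:
    """Per-miRNA baseline: median TPM over male samples.

    Returns (baseline over the chromosome's expressed rows, flagged
    names excluded for a zero baseline).
    """
    if not male_samples:
        raise ValueError("at least one male sample required")
    rows = collect_chromosome_mirnas(matrix, chrom)
    base = matrix.tpm.loc[rows.index, male_samples].median(axis=1)
    flagged = list(base.index[base == 0])
    return base[base > 0], flagged


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average, window truncated at the series ends."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd and >= 1")
    h = window // 2
    n = len(x)
    return np.array([np.mean(x[max(0, i - h) : min(n, i + h + 1)]) for i in range(n)])


@dataclass
class ChromosomeProfile:
    sample: str
    chrom: str
    mirnas: list[str]  # ordered by position
    positions: np.ndarray
    log2_ratio: np.ndarray
    moving_avg: np.ndarray


def relative_profile(
    matrix: ExpressionMatrix,
    sample: str,
    baseline: pd.Series,
    chrom: str,
    window: int = DEFAULT_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ChromosomeProfile:
    """Position-ordered log2(TPM / baseline) series with moving average."""
    rows = collect_chromosome_mirnas(matrix, chrom)
    rows = rows.loc[rows.index.intersection(baseline.index)]
    names = list(rows.index)
    tpm = matrix.tpm.loc[names, sample].to_numpy(dtype=float)
    base = baseline.loc[names].to_numpy(dtype=float)
    ratios = np.log2((tpm + pseudocount) / (base + pseudocount))
    if window > len(ratios):
        warnings.warn("moving-average window larger than series; shrinking")
        window = len(ratios) if len(ratios) % 2 else max(1, len(ratios) - 1)
    ma = moving_average(ratios, window) if len(ratios) else ratios.copy()
    return ChromosomeProfile(
        sample, chrom, names, rows["position"].to_numpy(), ratios, ma
    )


@dataclass
class XCICall:
    sample: str
    elevation: float  # median X log2-ratio minus median control log2-ratio
    p_value: float  # X-linked comparison vs pooled reference
    control_p_value: float
    control_shift: float  # |median control log2-ratio|
    call: str  # one_active_X | two_active_X | indeterminate
    reason: str


@dataclass
class XCIReport:
    calls: dict[str, XCICall]
    reference_samples: list[str]
    alpha: float
    elevation_min: float


def _mwu(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return 1.0
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0  # fully tied
    return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def call_xci(
    profiles: dict[str, dict[str, ChromosomeProfile]],
    reference: list[str],
    alpha: float = 0.05,
    elevation_min: float = 0.5,
    min_x_mirnas: int = 3,
) -> XCIReport:
    """Call X activity for every non-reference sample.

    ``profiles[sample]`` maps ``"X"`` and ``"control"`` to that sample's
    chromosome profiles; ``reference`` names the baseline pool (the male
    plus any females of known one-active-X status).  A sample is called
    two_active_X when its X-linked log2 ratios are significantly above
    the pooled reference (Mann-Whitney, two-sided) with an elevation
    above ``elevation_min``, and one_active_X when the elevation is
    consistent with the reference; a shifted control chromosome (a
    global, non-X artefact) makes the sample indeterminate.
    """
    ref_x = np.concatenate(
        [profiles[r]["X"].log2_ratio for r in reference]
    ) if reference else np.array([])
    ref_c = np.concatenate(
        [profiles[r]["control"].log2_ratio for r in reference]
    ) if reference else np.array([])
    calls: dict[str, XCICall] = {}
    for sample, prof in profiles.items():
        if sample in reference:
            continue
        x = prof["X"].log2_ratio
        c = prof["control"].log2_ratio
        med_c = float(np.median(c)) if len(c) else 0.0
        elevation = (float(np.median(x)) if len(x) else 0.0) - med_c
        p_x = _mwu(x, ref_x)
        p_c = _mwu(c, ref_c)
        ctrl_shift = abs(med_c)
        if len(x) < min_x_mirnas:
            call, reason = "indeterminate", "fewer than %d X-linked miRNAs" % min_x_mirnas
        elif p_c < alpha and ctrl_shift > elevation_min:
            call, reason = "indeterminate", "control chromosome shifted"
        elif p_x < alpha and elevation > elevation_min:
            call, reason = "two_active_X", "X-linked elevation significant"
        elif elevation <= elevation_min:
            call, reason = "one_active_X", "X dosage consistent with reference"
        else:
            call, reason = "indeterminate", "elevated X but not significant"
        calls[sample] = XCICall(sample, elevation, p_x, p_c, ctrl_shift, call, reason)
    return XCIReport(calls, list(reference), alpha, elevation_min)


def build_profiles(
    matrix: ExpressionMatrix,
    male_samples: list[str],
    samples: list[str] | None = None,
    x_chrom: str = "chrX",
    control_chrom: str = "chr1",
    window: int = DEFAULT_WINDOW,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, dict[str, ChromosomeProfile]]:
    """Convenience: baseline + X/control profiles for every sample."""
    base_x, _ = male_baseline(matrix, male_samples, x_chrom)
    base_c, _ = male_baseline(matrix, male_samples, control_chrom)
    out = {}
    for s in samples or matrix.samples:
        out[s] = {
            "X": relative_profile(matrix, s, base_x, x_chrom, window, pseudocount),
            "control": relative_profile(matrix, s, base_c, control_chrom, window, pseudocount),
        }
    return out
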