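"""Chromosome profiles, male baseline and X-activity calls."""

import numpy as np
import pandas as pd
import pytest

from srnakit.expression import normalize_tpm
from srnakit.xci import (
    build_profiles,
    call_xci,
    collect_chromosome_mirnas,
    male_baseline,
    moving_average,
    relative_profile,
)


def _matrix(counts, totals, rows):
    loci = pd.DataFrame(
        {n: {"chrom": c, "strand": "+", "position": p} for n, (c, p) in rows.items()}
    ).T
    return normalize_tpm(pd.DataFrame(counts), totals, loci)


def _simple_matrix(x_tpms, c_tpms, samples):
    """Matrix with X-linked and chr1-linked rows at the given TPMs."""
    rows, counts = {}, {s: {} for s in samples}
    total = 1_000_000
    for i, _ in enumerate(x_tpms[samples[0]]):
        rows[f"x{i}"] = ("chrX", 1000 * (i + 1))
        for s in samples:
            counts[s][f"x{i}"] = int(x_tpms[s][i])
    for i, _ in enumerate(c_tpms[samples[0]]):
        rows[f"c{i}"] = ("chr1", 1000 * (i + 1))
        for s in samples:
            counts[s][f"c{i}"] = int(c_tpms[s][i])
    return _matrix(counts, {s: total for s in samples}, rows)


def test_collect_rows_sorted_and_zero_rows_excluded():
    em = _matrix(
        {"S": {"a": 5, "b": 0, "c": 9}},
        {"S": 100},
        {"a": ("chrX", 500), "b": ("chrX", 100), "c": ("chrX", 200)},
    )
    rows = collect_chromosome_mirnas(em, "chrX")
    assert list(rows.index) == ["c", "a"]  # position order, b dropped (zero)
    with pytest.raises(KeyError):
        collect_chromosome_mirnas(em, "chr99")


def test_collect_is_input_order_invariant():
    counts = {"S": {f"m{i}": i + 1 for i in range(10)}}
    rows = {f"m{i}": ("chrX", int(p)) for i, p in enumerate([900, 100, 500, 300, 800, 200, 700, 400, 600, 50])}
    em1 = _matrix(counts, {"S": 100}, rows)
    order = list(np.random.default_rng(0).permutation(list(counts["S"])))
    em2 = _matrix({"S": {k: counts["S"][k] for k in order}}, {"S": 100}, {k: rows[k] for k in order})
    assert list(collect_chromosome_mirnas(em1, "chrX").index) == list(
        collect_chromosome_mirnas(em2, "chrX").index
    )


def test_male_baseline_median_and_zero_exclusion():
    em = _matrix(
        {"M1": {"a": 2, "b": 0}, "M2": {"a": 4, "b": 0}, "M3": {"a": 6, "b": 0}},
        {"M1": 1_000_000, "M2": 1_000_000, "M3": 1_000_000},
        {"a": ("chrX", 100), "b": ("chrX", 200)},
    )
    base, flagged = male_baseline(em, ["M1", "M2", "M3"], "chrX")
    assert float(base["a"]) == 4.0
    assert "b" not in base.index and flagged == []  # b has zero counts everywhere
    with pytest.raises(ValueError):
        male_baseline(em, [], "chrX")


def test_single_male_baseline_is_its_own_vector():
    em = _matrix(
        {"M": {"a": 7, "b": 3}},
        {"M": 1_000_000},
        {"a": ("chrX", 100), "b": ("chrX", 200)},
    )
    base, _ = male_baseline(em, ["M"], "chrX")
    assert float(base["a"]) == 7.0 and float(base["b"]) == 3.0


def test_profile_identity_and_doubling():
    em = _matrix(
        {"M": {"a": 8, "b": 20}, "F": {"a": 16, "b": 40}},
        {"M": 1_000_000, "F": 1_000_000},
        {"a": ("chrX", 100), "b": ("chrX", 200)},
    )
    base, _ = male_baseline(em, ["M"], "chrX")
    p_m = relative_profile(em, "M", base, "chrX", window=1, pseudocount=0.0)
    assert np.allclose(p_m.log2_ratio, 0.0) and np.allclose(p_m.moving_avg, 0.0)
    p_f = relative_profile(em, "F", base, "chrX", window=1, pseudocount=0.0)
    assert np.allclose(p_f.log2_ratio, 1.0)
    assert np.allclose(p_f.moving_avg, p_f.log2_ratio)  # window=1 is the raw series


def test_profile_scale_equivariance():
    rng = np.random.default_rng(3)
    tpms = rng.integers(10, 500, size=8)
    em = _matrix(
        {"M": {f"m{i}": int(t) for i, t in enumerate(tpms)},
         "F": {f"m{i}": int(t) * 8 for i, t in enumerate(tpms)}},
        {"M": 1_000_000, "F": 1_000_000},
        {f"m{i}": ("chrX", 100 * (i + 1)) for i in range(8)},
    )
    base, _ = male_baseline(em, ["M"], "chrX")
    prof = relative_profile(em, "F", base, "chrX", window=1, pseudocount=0.0)
    assert np.allclose(prof.log2_ratio, 3.0)  # log2 8


def test_moving_average_window_rules():
    x = np.arange(10, dtype=float)
    full = moving_average(x, 9)
    assert full[4] == pytest.approx(np.mean(x[0:9]))
    with pytest.raises(ValueError):
        moving_average(x, 4)  # even window


def test_moving_average_preserves_mean_at_full_window():
    x = np.array([1.0, 4.0, -2.0, 0.5, 3.5])
    ma = moving_average(x, 5)
    assert ma[2] == pytest.approx(np.mean(x))


def test_window_larger_than_series_shrinks_with_warning():
    em = _matrix(
        {"M": {"a": 8, "b": 20}, "F": {"a": 16, "b": 40}},
        {"M": 1_000_000, "F": 1_000_000},
        {"a": ("chrX", 100), "b": ("chrX", 200)},
    )
    base, _ = male_baseline(em, ["M"], "chrX")
    with pytest.warns(UserWarning, match="window"):
        prof = relative_profile(em, "F", base, "chrX", window=11)
    assert len(prof.moving_avg) == 2


def test_global_scaling_artifact_never_called_two_active():
    """A library-size artefact doubles every chromosome: the chr1 control
    catches it, so the sample is never called two_active_X."""
    rng = np.random.default_rng(5)
    base = rng.integers(50, 400, size=12)
    samples = ["M", "F"]
    x_tpms = {"M": base, "F": base * 2}
    c_tpms = {"M": base, "F": base * 2}
    em = _simple_matrix(x_tpms, c_tpms, samples)
    profiles = build_profiles(em, ["M"])
    report = call_xci(profiles, ["M"])
    assert report.calls["F"].call != "two_active_X"


def test_true_dosage_difference_called_two_active():
    rng = np.random.default_rng(6)
    base = rng.integers(100, 800, size=12)
    x_tpms = {"M": base, "F": base * 2}
    c_tpms = {"M": base, "F": base}
    em = _simple_matrix(x_tpms, c_tpms, ["M", "F"])
    report = call_xci(build_profiles(em, ["M"]), ["M"])
    call = report.calls["F"]
    assert call.call == "two_active_X"
    assert call.elevation > 0.5 and call.p_value < 0.05


def test_matched_dosage_called_one_active():
    rng = np.random.default_rng(7)
    base = rng.integers(100, 800, size=12)
    noisy = np.maximum(1, (base * np.exp(rng.normal(0, 0.05, size=12)))).astype(int)
    em = _simple_matrix({"M": base, "F": noisy}, {"M": base, "F": base}, ["M", "F"])
    report = call_xci(build_profiles(em, ["M"]), ["M"])
    assert report.calls["F"].call == "one_active_X"


def test_control_chromosome_profiles_run_parallel():
    """chr1 log2-ratio curves of simulated samples stay parallel across
    XCI states (pairwise median absolute difference < 0.25)."""
    from srnakit.benchmarks import chr1_profiles_parallel

    assert chr1_profiles_parallel(seed=41) < 0.25


def test_too_few_x_mirnas_indeterminate():
    em = _simple_matrix({"M": [100, 200], "F": [200, 400]}, {"M": [100] * 6, "F": [100] * 6}, ["M", "F"])
    report = call_xci(build_profiles(em, ["M"]), ["M"])
    assert report.calls["F"].call == "indeterminate"
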