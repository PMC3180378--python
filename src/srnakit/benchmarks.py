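"""Simulation-based recovery studies over the pipeline's planted truth.

These procedures define the package's headline verification runs: novel
hairpin recall against decoys, noise-filter retention, differential-
expression error rates, and X-inactivation call accuracy.  They are used
both by the test suite and by the reproduction script, so the numbers
reported in either place come from the same computations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotate import MiRNACatalog
from .expression import (
    differential_expression,
    normalize_tpm,
    poisson_noise_filter,
)
from .novel import call_novel_mirnas
from .pipeline import known_loci_frame, run_pipeline
from .simdata import (
    DECOY_SHARE,
    KNOWN_SHARE,
    NOVEL_SHARE,
    SampleSpec,
    SimulationConfig,
    generate_toy_genome,
    simulate_counts,
    simulate_filter_study,
)
from .xci import build_profiles, call_xci


def _overlaps(cand, planted) -> bool:
    return (
        cand.chrom == planted.chrom
        and cand.precursor[0] < planted.precursor[1]
        and planted.precursor[0] < cand.precursor[1]
    )


def novel_recovery(
    seeds=(101, 102, 103), n_novel: int = 20, n_decoy: int = 20
) -> dict[str, float]:
    """Recall of planted novel hairpins and decoy acceptance rate.

    Two samples per seed; a planted hairpin counts as recovered when a
    shared accepted locus overlaps it, a decoy as falsely accepted when
    any sample's accepted list overlaps it.
    """
    n_rec = n_tot = n_dec_hit = n_dec_tot = 0
    for seed in seeds:
        cfg = SimulationConfig(seed=seed, n_novel_mirnas=n_novel, n_decoy_loci=n_decoy)
        samples = [
            SampleSpec("S1", "female", "one_active_X"),
            SampleSpec("S2", "female", "one_active_X"),
        ]
        res = run_pipeline(cfg, samples)
        per_sample, shared = call_novel_mirnas(
            res.annotated, res.genome.chromosomes, res.tags.samples
        )
        novel = res.genome.planted("novel")
        decoys = res.genome.planted("decoy")
        n_tot += len(novel)
        n_rec += sum(1 for m in novel if any(_overlaps(c, m) for c in shared))
        n_dec_tot += len(decoys)
        n_dec_hit += sum(
            1
            for m in decoys
            if any(_overlaps(c, m) for cands in per_sample.values() for c in cands)
        )
    return {
        "recall": n_rec / n_tot,
        "decoy_acceptance": n_dec_hit / n_dec_tot,
        "n_novel": n_tot,
        "n_decoy": n_dec_tot,
    }


def noise_filter_recovery(seeds=(11, 12, 13)) -> dict[str, float]:
    """Retention of well-expressed planted loci vs removal of noise loci."""
    kept_planted = tot_planted = removed_noise = tot_noise = 0
    lams = []
    for seed in seeds:
        study = simulate_filter_study(["A", "B"], rng=np.random.default_rng(seed))
        counts = pd.DataFrame(study.counts).T
        loci = pd.DataFrame(
            {n: {"chrom": c, "strand": "+", "position": p} for n, (c, p) in study.loci.items()}
        ).T
        em = normalize_tpm(counts, study.clean_totals, loci)
        chrom_lengths = {f"chr{i + 1}": 12_500_000 for i in range(4)}
        filtered, report = poisson_noise_filter(
            em, chrom_lengths, study.positions, rng=np.random.default_rng(seed + 1000)
        )
        kept = set(filtered.counts.index)
        for name, noise in study.is_noise.items():
            if noise:
                tot_noise += 1
                removed_noise += name not in kept
            elif float(em.tpm.loc[name].max()) >= 10.0:
                tot_planted += 1
                kept_planted += name in kept
        lams += [report.per_sample[s]["lambda"] for s in ("A", "B")]
    return {
        "planted_retained": kept_planted / tot_planted,
        "noise_removed": removed_noise / tot_noise,
        "n_planted": tot_planted,
        "n_noise": tot_noise,
        "mean_lambda": float(np.mean(lams)),
    }


def de_error_rates(
    seeds=(21, 22, 23), n_null: int = 500, n_effect: int = 60
) -> dict[str, float]:
    """Type-I rate under the null and power for 4-fold effects >= 50 counts."""
    flagged_null = tot_null = flagged_eff = tot_eff = 0
    for seed in seeds:
        rng = np.random.default_rng(seed)
        lam_null = rng.uniform(50, 1000, size=n_null)
        lam_b = rng.uniform(50, 500, size=n_effect)
        counts = {"A": {}, "B": {}}
        for i, lam in enumerate(lam_null):
            counts["A"][f"null{i}"] = int(rng.poisson(lam))
            counts["B"][f"null{i}"] = int(rng.poisson(lam))
        for i, lam in enumerate(lam_b):
            counts["A"][f"eff{i}"] = int(rng.poisson(4.0 * lam))
            counts["B"][f"eff{i}"] = int(rng.poisson(lam))
        total = 2_000_000  # equal library sizes
        em = normalize_tpm(pd.DataFrame(counts), {"A": total, "B": total})
        res = {r.mirna: r for r in differential_expression(em, "A", "B")}
        for i in range(n_null):
            r = res.get(f"null{i}")
            if r is not None:
                tot_null += 1
                flagged_null += r.flag != "ns"
        for i in range(n_effect):
            r = res.get(f"eff{i}")
            if r is not None and r.count_b >= 50:
                tot_eff += 1
                flagged_eff += r.flag == "up"
    return {
        "null_flag_rate": flagged_null / tot_null,
        "null_se": float(np.sqrt(0.05 * 0.95 / tot_null)),
        "power_4fold": flagged_eff / tot_eff,
        "n_null": tot_null,
        "n_effect": tot_eff,
    }


def xci_recovery(seed: int = 31, n_replicates: int = 20) -> dict[str, float]:
    """Call accuracy for simulated two-active-X and one-active-X females
    against a male reference, with the chromosome-1 control.

    Counts-level replicates at the default depth; the clean total is the
    planted total scaled up by the expected mappable fraction.
    """
    cfg = SimulationConfig(seed=seed)
    genome = generate_toy_genome(cfg)
    catalog = MiRNACatalog.from_truth(genome)
    loci = known_loci_frame(catalog)
    planted_share = KNOWN_SHARE + NOVEL_SHARE + DECOY_SHARE
    rng = np.random.default_rng(seed)
    correct = {"two_active_X": 0, "one_active_X": 0}
    control_triggered = 0
    for rep in range(n_replicates):
        for status in ("two_active_X", "one_active_X"):
            male = SampleSpec(f"M{rep}", "male", "male")
            fem = SampleSpec(f"F{rep}", "female", status)
            counts, totals = {}, {}
            for s in (male, fem):
                c = simulate_counts(
                    genome, s, rng=np.random.default_rng(int(rng.integers(2**31)))
                )
                counts[s.name] = {k: v for k, v in c.items() if k.startswith("mir-")}
                totals[s.name] = max(int(sum(c.values()) / planted_share), 1)
            df = pd.DataFrame(counts).fillna(0).astype(int)
            em = normalize_tpm(df, totals, loci.reindex(df.index))
            report = call_xci(build_profiles(em, [male.name]), [male.name])
            call = report.calls[fem.name]
            correct[status] += call.call == status
            control_triggered += call.reason == "control chromosome shifted"
    return {
        "two_active_correct": correct["two_active_X"],
        "one_active_correct": correct["one_active_X"],
        "n_replicates": n_replicates,
        "control_triggered": control_triggered,
    }


def chr1_profiles_parallel(seed: int = 41, n_samples: int = 4) -> float:
    """Max pairwise median absolute difference of chr1 log2 ratios.

    Mirrors the expectation that control-chromosome moving-average plots
    of all samples run parallel regardless of X status.
    """
    cfg = SimulationConfig(seed=seed)
    genome = generate_toy_genome(cfg)
    catalog = MiRNACatalog.from_truth(genome)
    loci = known_loci_frame(catalog)
    planted_share = KNOWN_SHARE + NOVEL_SHARE + DECOY_SHARE
    statuses = ["male", "one_active_X", "two_active_X", "one_active_X"]
    specs = [
        SampleSpec(f"S{i}", "male" if st == "male" else "female", st)
        for i, st in enumerate(statuses[:n_samples])
    ]
    counts, totals = {}, {}
    for s in specs:
        c = simulate_counts(genome, s)
        counts[s.name] = {k: v for k, v in c.items() if k.startswith("mir-")}
        totals[s.name] = max(int(sum(c.values()) / planted_share), 1)
    df = pd.DataFrame(counts).fillna(0).astype(int)
    em = normalize_tpm(df, totals, loci.reindex(df.index))
    profiles = build_profiles(em, [specs[0].name])
    series = [profiles[s.name]["control"].log2_ratio for s in specs]
    worst = 0.0
    for i in range(len(series)):
        for j in range(i + 1, len(series)):
            worst = max(worst, float(np.median(np.abs(series[i] - series[j]))))
    return worst
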