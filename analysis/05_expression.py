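#!/usr/bin/env python
"""Quantify known miRNAs: TPM, noise filter, 10-kb clusters, DE.

Normalises counts to tags-per-million clean reads, removes rows that are
indistinguishable from sporadic background by the random-bin Poisson
filter, chains precursors into 10-kb genomic clusters ranked by summed
TPM, compares the test lines against the female reference line with the
Audic-Claverie test, and exports the average-linkage sample dendrogram.
"""

import json
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, study

from srnakit.expression import (
    differential_expression,
    group_clusters,
    hierarchical_clustering,
    poisson_noise_filter,
)


def main() -> None:
    res = study()
    RESULTS.mkdir(exist_ok=True)

    filtered, report = poisson_noise_filter(
        res.matrix,
        res.genome.chrom_lengths,
        res.positions,
        rng=np.random.default_rng(res.genome.config.seed),
    )
    (RESULTS / "05_filter_report.json").write_text(
        json.dumps(report.per_sample, indent=2)
    )
    filtered.tpm.round(2).to_csv(RESULTS / "05_tpm.tsv", sep="\t")

    groups = group_clusters(filtered)
    rows = ["cluster\tchrom\tspan\tmembers\tsummed_tpm_total"]
    for g in groups[:10]:
        span = f"{g.span[0]}-{g.span[1]}" if g.span else "."
        rows.append(
            f"{g.cluster_id}\t{g.chrom or '.'}\t{span}\t{','.join(g.members)}\t"
            f"{sum(g.summed_tpm.values()):.0f}"
        )
    (RESULTS / "05_clusters_top10.tsv").write_text("\n".join(rows) + "\n")

    de_rows = ["comparison\tmirna\tcount_a\tcount_b\ttpm_a\ttpm_b\tlog2_ratio\tp_value\tflag"]
    flag_counts = {}
    for a, b in (("pESC1", "ivfF"), ("pESC2", "ivfF")):
        for r in differential_expression(filtered, a, b):
            de_rows.append(
                f"{a}_vs_{b}\t{r.mirna}\t{r.count_a}\t{r.count_b}\t{r.tpm_a:.1f}\t"
                f"{r.tpm_b:.1f}\t{r.log2_ratio:.3f}\t{r.p_value:.3g}\t{r.flag}"
            )
            key = (f"{a}_vs_{b}", r.flag)
            flag_counts[key] = flag_counts.get(key, 0) + 1
    (RESULTS / "05_differential_expression.tsv").write_text("\n".join(de_rows) + "\n")

    Z, order = hierarchical_clustering(filtered)
    (RESULTS / "05_linkage.json").write_text(
        json.dumps({"samples": order, "linkage": Z.tolist()}, indent=2)
    )

    kept = len(filtered.counts)
    thr = {s: round(v["effective_threshold"], 1) for s, v in report.per_sample.items()}
    print(f"noise filter: {kept}/{len(res.matrix.counts)} known miRNAs retained "
          f"(effective TPM thresholds {thr})")
    multi = [g for g in groups if len(g.members) > 1]
    print(f"clusters: {len(multi)} multi-member clusters of {len(groups)} groups")
    if multi:
        top = multi[0]
        print(f"top enriched cluster: {top.chrom}:{top.span[0]}-{top.span[1]} "
              f"{top.members} ({sum(top.summed_tpm.values()):.0f} summed TPM)")
    for (cmp_, flag), n in sorted(flag_counts.items()):
        if flag != "ns":
            print(f"DE {cmp_}: {n} miRNAs {flag}")
    print(f"dendrogram sample order: {order}")


if __name__ == "__main__":
    main()
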