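#!/usr/bin/env python
"""Infer the X-activity status of the test lines from miRNA dosage.

Builds the per-miRNA male-median baseline, expresses every sample as
position-ordered log2 ratios on chrX and on chr1 (the control), smooths
them with a centred 5-point moving average, and calls each test line
one_active_X / two_active_X / indeterminate against the pooled reference
(male + known one-active-X female).
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import REFERENCE_SAMPLES, RESULTS, study

from srnakit.xci import build_profiles, call_xci


def main() -> None:
    res = study()
    RESULTS.mkdir(exist_ok=True)
    profiles = build_profiles(res.matrix, ["ivfM"])
    report = call_xci(profiles, REFERENCE_SAMPLES)

    rows = ["sample\tchrom\tmirna\tposition\tlog2_ratio\tmoving_average"]
    for sample, prof in profiles.items():
        for label, p in prof.items():
            chrom = "chrX" if label == "X" else "chr1"
            for name, pos, lr, ma in zip(p.mirnas, p.positions, p.log2_ratio, p.moving_avg):
                rows.append(f"{sample}\t{chrom}\t{name}\t{pos}\t{lr:.3f}\t{ma:.3f}")
    (RESULTS / "06_profiles.tsv").write_text("\n".join(rows) + "\n")

    out = {
        s: {
            "call": c.call,
            "reason": c.reason,
            "elevation": round(c.elevation, 3),
            "p_value": float(f"{c.p_value:.3g}"),
            "control_p_value": float(f"{c.control_p_value:.3g}"),
            "control_shift": round(c.control_shift, 3),
        }
        for s, c in report.calls.items()
    }
    (RESULTS / "06_xci_report.json").write_text(json.dumps(out, indent=2))

    for s, c in report.calls.items():
        print(
            f"{s}: {c.call} (X elevation {c.elevation:+.2f} log2, p={c.p_value:.2g}; "
            f"chr1 shift {c.control_shift:.2f}, p={c.control_p_value:.2g})"
        )


if __name__ == "__main__":
    main()
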