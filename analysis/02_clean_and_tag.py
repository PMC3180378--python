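#!/usr/bin/env python
"""Clean the raw reads and collapse them into unique sequence tags.

Reports the exact filter bookkeeping per library (adaptor trimming,
contaminant / too-small / too-long / low-quality removal) and the
read-length histogram of the clean reads, which should peak at 22-23 nt
if the libraries are miRNA-dominated.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SCRATCH, study

from srnakit.preprocess import length_histogram


def main() -> None:
    res = study()
    RESULTS.mkdir(exist_ok=True)

    counters = {name: cs.counters for name, cs in res.clean.items()}
    (RESULTS / "02_clean_counters.json").write_text(json.dumps(counters, indent=2))

    lines = ["length\t" + "\t".join(res.tags.samples)]
    hists = {s: length_histogram(res.tags, s) for s in res.tags.samples}
    for L in range(18, 31):
        lines.append(f"{L}\t" + "\t".join(str(hists[s].get(L, 0)) for s in res.tags.samples))
    (RESULTS / "02_length_histogram.tsv").write_text("\n".join(lines) + "\n")

    tag_dir = SCRATCH / "tags"
    tag_dir.mkdir(parents=True, exist_ok=True)
    with open(tag_dir / "tags.tsv", "w") as fh:
        fh.write("sequence\t" + "\t".join(res.tags.samples) + "\n")
        for seq, per in res.tags.to_rows():
            fh.write(seq + "\t" + "\t".join(str(per.get(s, 0)) for s in res.tags.samples) + "\n")

    for name, cs in res.clean.items():
        c = cs.counters
        print(
            f"{name}: {c['raw_total']} raw -> {c['clean_total']} clean "
            f"(contaminant {c['removed_contaminant']}, <18nt {c['removed_too_small']}, "
            f">30nt {c['removed_too_long']}, low-quality {c['removed_low_quality']})"
        )
        assert cs.check_conservation()
    for s in res.tags.samples:
        mode = max(hists[s], key=hists[s].get)
        print(f"{s}: {len(res.tags)} unique tags overall; length mode {mode} nt")


if __name__ == "__main__":
    main()
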