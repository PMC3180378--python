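#!/usr/bin/env python
"""Map tags to the genome and resolve each to one RNA category.

Applies the priority lattice rRNA(Genbank) > rRNA(Rfam) > known miRNA >
repeat > exon > intron (mapped but feature-free tags are 'unann') and
quantifies the known miRNAs.  In a miRNA-rich library roughly 60 % of
mapped reads land on known miRNAs, under 15 % on other annotated RNA and
about a quarter stay unannotated.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SCRATCH, study


def main() -> None:
    res = study()
    RESULTS.mkdir(exist_ok=True)

    (RESULTS / "03_category_summary.json").write_text(
        json.dumps(res.summaries, indent=2)
    )
    res.matrix.counts.to_csv(RESULTS / "03_known_counts.tsv", sep="\t")

    ann_dir = SCRATCH / "annotation"
    ann_dir.mkdir(parents=True, exist_ok=True)
    with open(ann_dir / "annotated_tags.tsv", "w") as fh:
        fh.write("sequence\tcategory\tassigned_mirna\tn_hits\t"
                 + "\t".join(res.tags.samples) + "\n")
        for t in res.annotated:
            fh.write(
                f"{t.seq}\t{t.category}\t{t.assigned_mirna or '.'}\t{len(t.hits)}\t"
                + "\t".join(str(t.counts.get(s, 0)) for s in res.tags.samples)
                + "\n"
            )

    detected = (res.matrix.counts > 0).sum(axis=0)
    print(f"known-miRNA catalog: {len(res.catalog)} precursors")
    for s in res.tags.samples:
        p = res.summaries[s]["over_mapped"]
        other = sum(p[c] for c in ("rRNA_genbank", "rRNA_rfam", "repeat", "exon", "intron"))
        print(
            f"{s}: {int(detected[s])} known miRNAs detected; of mapped reads "
            f"{100 * p['known_miRNA']:.1f}% known miRNA, {100 * other:.1f}% other "
            f"annotated, {100 * p['unann']:.1f}% unann"
        )


if __name__ == "__main__":
    main()
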