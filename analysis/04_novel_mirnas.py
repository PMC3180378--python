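#!/usr/bin/env python
"""Predict novel miRNAs from the unannotated mapped tags.

Excises each unannotated tag locus with 150-nt flanks, folds the
windows, and accepts hairpins passing the folding-score, mature/star
duplex, terminal-loop, Dicer 5'-homogeneity and mature-length criteria.
Writes the per-sample candidate table, the accepted precursor FASTA with
dot-bracket structures, a BED of accepted loci and the shared list.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, study

from srnakit.novel import call_novel_mirnas


def main() -> None:
    res = study()
    RESULTS.mkdir(exist_ok=True)
    per_sample, shared = call_novel_mirnas(
        res.annotated, res.genome.chromosomes, res.tags.samples
    )

    shared_keys = {(c.chrom, c.strand, c.precursor) for c in shared}
    rows = ["sample\tchrom\tstart\tend\tstrand\tmfe\tstem_pairs\tshared"]
    fasta, bed = [], []
    for s, cands in per_sample.items():
        for i, c in enumerate(cands):
            is_shared = (c.chrom, c.strand, c.precursor) in shared_keys
            rows.append(
                f"{s}\t{c.chrom}\t{c.precursor[0]}\t{c.precursor[1]}\t{c.strand}\t"
                f"{c.mfe:.1f}\t{c.stem_pairs}\t{int(is_shared)}"
            )
            name = f"{s}_novel_{i:03d}"
            fasta.append(f">{name} {c.chrom}:{c.precursor[0]}-{c.precursor[1]}({c.strand})")
            fasta.append(c.sequence)
            fasta.append(c.structure)
            bed.append(
                f"{c.chrom}\t{c.precursor[0]}\t{c.precursor[1]}\t{name}\t0\t{c.strand}"
            )
    (RESULTS / "04_novel_candidates.tsv").write_text("\n".join(rows) + "\n")
    (RESULTS / "04_novel_precursors.fa").write_text("\n".join(fasta) + "\n")
    (RESULTS / "04_novel_loci.bed").write_text("\n".join(bed) + "\n")

    truth = res.genome.planted("novel")
    def hits_truth(c):
        return any(
            c.chrom == m.chrom and c.precursor[0] < m.precursor[1] and m.precursor[0] < c.precursor[1]
            for m in truth
        )
    for s, cands in per_sample.items():
        print(f"{s}: {len(cands)} accepted novel hairpins")
    n_true = sum(1 for c in shared if hits_truth(c))
    print(
        f"shared by all samples: {len(shared)} loci "
        f"({n_true} overlap a planted novel hairpin of {len(truth)} planted)"
    )


if __name__ == "__main__":
    main()
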