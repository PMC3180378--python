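#!/usr/bin/env python
"""Build the toy genome and simulate the four small-RNA libraries.

Writes the genome FASTA, the annotation tracks (GFF3 + BED6), the truth
registry and the per-sample FASTQ files.  The bulky sequence files go to
scratch/simulation/; the small truth table and the config are copied to
results/ for the downstream scripts' readers.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _common import RESULTS, SCRATCH, study

from srnakit.simdata import write_fastq, write_genome


def main() -> None:
    res = study()
    outdir = SCRATCH / "simulation"
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome(res.genome, outdir)
    res.genome.config.to_yaml(outdir / "config.yaml")
    for name, lib in res.libraries.items():
        write_fastq(lib, outdir / f"{name}.fastq")
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "01_truth_mirnas.tsv").write_text(
        (outdir / "truth_mirnas.tsv").read_text()
    )

    g = res.genome
    print(f"genome: {len(g.chromosomes)} chromosomes x {g.config.chrom_length} bp")
    print(
        f"planted: {len(g.planted('known'))} known miRNAs, "
        f"{len(g.planted('novel'))} novel hairpins, {len(g.planted('decoy'))} decoys"
    )
    for name, lib in res.libraries.items():
        print(f"library {name}: {len(lib.records)} raw reads -> {outdir / (name + '.fastq')}")


if __name__ == "__main__":
    main()
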