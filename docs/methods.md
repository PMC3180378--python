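# Methods

`srnakit` implements, as a tested pipeline over simulated data, the
computational analysis chain of a bulk small-RNA sequencing study of
embryonic stem cell lines: read cleaning, priority-ruled tag annotation,
novel miRNA hairpin calling, TPM quantification with a Poisson
background filter, 10-kb genomic cluster grouping, two-library
differential expression, and an X-chromosome-inactivation (XCI) caller
based on chromosome-wide miRNA dosage. This note records the models,
the parameters that matter, and the design choices made where the
procedure was genuinely open.

## The simulated study

The deposited sequencing data of the original study are not consumed;
instead a synthetic-data module generates toy genomes and libraries in
which every downstream claim is checkable against planted truth.

**Genome.** Four chromosomes (chr1, chr2, chr3, chrX) of 300 kb of
uniform random sequence. Each chromosome carries 12 known miRNA
precursors planted as perfect fold-back hairpins: a stem arm (mature +
4 nt spacer), an 8 nt loop, and the reverse complement of the arm, so
acceptance by the hairpin criteria is guaranteed by construction.
Cluster groups (default 2 genome-wide) place two precursors with first
nucleotides 0.5–8 kb apart; all other precursor units are separated by
more than 10.5 kb, so both sides of the 10-kb cluster boundary occur.
Novel hairpins (same construction, but absent from the annotation
tracks) and decoy loci (mature arm plus a *random* 3' arm that cannot
base-pair) are planted in intergenic space, together with rRNA-like
(Genbank and Rfam tiers), repeat, exon and intron features. Coordinates
are 0-based half-open internally and converted at the GFF boundary
(1-based closed).

**Libraries.** Raw reads are 35 nt: the insert followed by the 3'
adaptor (default `TCGTATGCCGTCTTCTGCTTG`), truncated at 35 nt. Each
planted locus draws a Poisson count around its true abundance;
abundances are log-normal (σ = 1.2) within each class, with the class
shares of the mappable library fixed at 60 % known miRNA, 8 % novel,
2 % decoy, 14 % degradation of annotated features and 16 % intergenic
degradation — the composition of a miRNA-dominated stem-cell library,
in which ~60 % of mapped reads are known miRNA, under 15 % other
annotated RNA and about a quarter unannotated. Insert lengths follow a categorical distribution
over 18–28 nt peaked at 22–23 nt; planted mature arms use the same
distribution truncated at 26 nt (the canonical Dicer product range),
the longer tail being degradation only. Contaminants (5 %) are random
35-mers screened to contain no adaptor match; low-quality reads (3 %)
carry mean Phred < 20. Every insert is screened so the adaptor's
leftmost detectable occurrence is the true junction, which makes
error-free trimming recovery exact. One RNG stream per sample, seeded
from (config seed, CRC32 of the sample name), so adding a sample
perturbs no other.

**X-dosage model.** A female sample with two active X chromosomes
expresses X-linked loci at `xci_ratio` (default 2.0) times the
one-active-X/male level; autosomal output is unchanged, so the library
total grows slightly. chrX carries `x_expression_share` = 6 % of each
class's expression — the realistic share; giving the X a uniform 25 %
share would let X reactivation inflate the library total by ~40 % and
shift every autosomal log-ratio by up to −0.5, which contradicts the
observed parallelism of control-chromosome profiles across XCI states.

**What the generator does not emulate:** sequencing errors and isomiRs
(so count recovery is exact, and the mapper can be an exact matcher),
5' adaptors, UMIs, multi-mapping families of near-identical paralogs,
imprinting, and any chromatin-level mechanism of XCI. Passing tests
therefore demonstrate the *algorithms* recover planted structure, not
that the pipeline is robust to real-data artefacts.

## Read cleaning and tags

Adaptor trimming scans left-to-right for the leftmost position where a
prefix of the adaptor (≥ 6 nt, i.e. everything to the read's 3' end)
aligns with at most 1 mismatch per 10 aligned bases. Reads with an N or
no detectable adaptor are contaminants; inserts shorter than 18 nt or
longer than 30 nt, and inserts with mean Phred < 20, are removed, each
with its own counter, so `raw = clean + Σ removed` holds exactly.
Clean reads collapse into unique sequence tags with per-sample counts;
count conservation (`clean_total = Σ tag counts`) is asserted at every
stage.

## Mapping and priority annotation

Tags are located on both genome strands by exact string search (a
12-mer hash join verified by string comparison; equivalent to a naive
scan, which the tests assert). A tag overlapping features of several
classes resolves to exactly one category through the priority lattice
rRNA(Genbank) > rRNA(Rfam) > known miRNA > repeat > exon > intron, with
mapped feature-free (and unmapped) tags as `unann`. Known-miRNA
features count only on their annotated strand; the other classes
overlap strand-agnostically (a degradation fragment is recognisable
from either strand). A multi-hit tag contributes its whole count to its
single resolved category; for known-miRNA counting it is attributed to
the precursor whose mature start is nearest the tag start (ties broken
by name), tolerating 5'/3' offsets of ≤ 3 nt beyond the mature arm.

## Novel miRNA calling

Unannotated mapped tag loci (merged when overlapping on a strand, and
requiring ≥ 3 supporting reads — a copy-number gate that also keeps
singleton degradation fragments out of the fold stage) are excised in
two frames: tag as 5' arm (150 nt flank added 3' of the tag in its own
orientation) and tag as 3' arm (flank added 5'), clipped at chromosome
edges.

**Folding** is Nussinov-style weighted base-pair maximisation with pair
scores GC −3, AU −2, GU −1 (declared units, *not* kcal/mol — scores are
not comparable to thermodynamic folders), minimum loop 3 nt, no
pseudoknots. Tie-breaks are deterministic: the closing pair is
preferred, then the smallest bifurcation point. The DP agrees with an
exhaustive structure-enumeration oracle on short sequences (tested at
n ≤ 25).

**Acceptance criteria** for a candidate window, checked in order with
the first failure recorded: (a) fold score ≤ −18; (b) a mature/star
duplex of ≥ 16 base pairs — computed as the longest compact nested run
of mature-position pairs, split wherever a bulge exceeds 4 nt or
cumulative asymmetry exceeds 5, with the star at most 35 nt beyond the
mature (Mireap's documented duplex geometry); counting every
mature-touching pair of the global fold instead would let random
windows pass and stray long-range pairs fail true hairpins; (c) mature
entirely on one arm, ≥ 2 nt clear of the terminal loop; (d) ≥ 90 % of
supporting reads sharing the modal 5' start (the Dicer-processing
signature); (e) mature length 18–26 nt. A locus is accepted if either
excision frame passes; the shared list contains loci accepted in every
sample with ≥ 1 nt same-strand overlap. Under the default study this
recovers ≥ 90 % of planted novel hairpins with ≤ 5 % decoy acceptance
(measured: ~97 % and ~2 % over three seeds).

## Quantification, noise filter, clusters, differential expression

TPM is `count / clean_total × 1e6`, exact per cell. The noise filter
draws 10,000 random 50-bp bins per chromosome, takes λ = mean mapped
read starts per bin, computes the smallest count c* with Poisson upper
tail < 1e-4, and keeps a row if its TPM reaches max(3 TPM,
TPM-equivalent of c*) in ≥ 1 sample. The 3-TPM floor and the Poisson
threshold are independent knobs; the effective cutoff is their maximum.
On the 300-kb toy genome the read density is ~10⁴× that of a
genome-scale experiment, so λ and hence the effective threshold are
much higher than 3 TPM there; the filter's recovery properties are
therefore exercised on a positions-level simulation at genome-scale
sparsity (10⁶ reads over
5×10⁷ bp, λ ≈ 1, c* = 7), where all planted loci ≥ 10 TPM survive and
all 1–2-read noise loci are removed.

Genomic clusters chain precursors along a chromosome whose first
nucleotides are ≤ 10,000 bases apart (inclusive boundary; single
linkage, the conventional delimitation), and are ranked by summed TPM.
Rows without positions become flagged singletons.

Differential expression between two unreplicated libraries uses the
Audic–Claverie count test — the standard choice for that design — via
its negative-binomial identity: given count x
in a library of size N₁, the predictive law of the other count is
NB(x+1, N₁/(N₁+N₂)); the two-sided p doubles the smaller tail. The
conditioning direction is canonicalised on the lexicographically
smaller sample name, making results exactly antisymmetric under
swapping the samples. A row is flagged up/down when |log2 ratio| >
log2(2) and p < 0.05, with a 0.5-TPM pseudocount in the ratio.
Simulated error rates: null flag rate 0 % (the fold-change gate makes
the test conservative), power 100 % for 4-fold effects at ≥ 50 counts.
Sample dendrograms use average linkage on 1 − Pearson r of log2(TPM+1)
profiles.

## X-inactivation calling

The baseline is the per-miRNA median TPM across male reference samples
(zero-baseline rows are excluded and flagged). Every sample is
expressed as position-ordered log2((TPM+0.5)/(baseline+0.5)) on chrX
and on chr1 (the control), smoothed for visualisation by a centred
moving average (default window 5, truncated at the ends; the window is
a configurable default — no canonical value exists).

Each test sample's X ratios are compared with the pooled reference
ratios by a two-sided Mann–Whitney test. With a single male reference
the male's own ratios are identically zero, and a rank test against a
tied block is anti-conservative — chance significance at the nominal
5 % level occurs in ~15 % of null replicates. The call logic therefore
uses the *elevation* (median X log2 ratio minus median chr1 log2 ratio,
which also cancels compositional shifts) as co-primary evidence:

- `two_active_X`: X comparison significant (α = 0.05) **and** elevation
  > 0.5 (≈1.4×), with the control gate clear;
- `one_active_X`: elevation ≤ 0.5 and the control gate clear,
  regardless of chance significance;
- `indeterminate`: fewer than 3 X-linked miRNAs, a shifted control
  chromosome (control comparison significant **and** |median chr1
  ratio| > 0.5 — the signature of a global, non-X artefact such as a
  mis-scaled library), or an elevated-but-not-significant X.

Raw p-values for both chromosomes are always reported. Under the
default study conditions the caller recovers 20/20 simulated
two-active-X and 20/20 one-active-X females, and control-chromosome
profiles of all samples are parallel (pairwise median absolute
difference of chr1 ratios ≈ 0.1, bound 0.25).

## Problem sizes and determinism

Default sizes — 4 × 300 kb genome, 48 known + 8 novel + 8 decoy loci,
50,000 reads per library — were chosen so that a full study simulates
and analyses in seconds while every statistical property above is
measurable; the recovery studies use 20 planted novel hairpins and 20
decoys per seed over three seeds, 20 XCI replicates per regime, and
500 null + 60 effect miRNAs per DE seed. All randomness flows from
explicit seeds (NumPy `default_rng`); identical config and seed give
byte-identical genomes and libraries.

## Known limitations

- The exact mapper requires error-free reads; it is adequate for the
  toy genomes it is specified for, not for real sequencing data.
- The fold score is a weighted pair count; thresholds calibrated to it
  (e.g. −18) do not transfer to thermodynamic folders.
- The Audic–Claverie test models Poisson sampling only; biological
  replicate variance is out of scope (two-library design).
- The XCI caller needs ≥ 3 expressed X-linked miRNAs and a male (or
  known one-active-X) reference; it reports dosage, not the silencing
  mechanism.
- No multiple-testing correction is applied to the DE p-values (the
  flagged lists are screening output, not confirmatory claims);
  downstream users should treat them accordingly.
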