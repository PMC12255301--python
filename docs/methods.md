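# Methods

This note documents the models and procedures `tadedit` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was open. It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The discovery model

A-to-I editing is observed as A>G mismatches between RNA-seq reads and the
genomic reference (inosine is read as guanosine). The pipeline treats editing
detection as RNA–DNA difference calling under heavy filtering:

1. **Trimming.** Reads are trimmed by the modified-Mott criterion: with
   per-base error probability `p_i = 10^(-Q_i/10)` each base scores
   `(limit − p_i)` (default limit 0.05) and the maximal-sum contiguous
   segment is retained. Reads with more than 2 ambiguous bases or shorter
   than 50 nt after trimming are dropped. This is the standard realization of
   an error-probability-limit trimmer; where several segments tie, the
   leftmost maximal segment is kept (an arbitrary but deterministic
   tie-break).
2. **Mapping.** The built-in mapper reports full-length ungapped placements
   with identity ≥ 0.95 (aligned fraction is 1 by construction); reads with
   two or more equal-best placements are discarded entirely, so repeats
   cannot fake variants. Exact 14-mer seeds sampled every 2 bases are
   guaranteed by pigeonhole to hit every qualifying placement for reads
   ≥ 50 nt at ≥ 95% identity, which is why the mapper provably equals a
   brute-force scan over all (position, strand) pairs — a property the test
   suite checks directly. Gapped, externally produced alignments enter
   through the SAM reader; the simulator emits no indels, so the built-in
   path never needs gap handling. Samples with < 50% of input reads mapped
   (inclusive threshold) are excluded entirely.
3. **Pileup and calling.** A read base counts toward a position only if its
   own quality is ≥ 30 and every base within ±2 positions on the read
   (truncated at read ends) is ≥ 30. Coverage counts qualified bases only,
   so `100 × count / coverage` doubles as the editing level. Substitution
   calls require coverage in [20, 10^6], alt count ≥ 3 and frequency ≥ 1%.
4. **Cascade.** Per sample: unique supporting-read start and end coordinates
   ≥ 3 each (PCR/positional-artifact guard), frequency within [5, 98]%
   inclusive (the 98% ceiling removes strain-specific DNA variants, which sit
   at ~100%), and at most two alleles with calling-level support
   (hyper-allelic positions are artifacts; the allele count uses the same
   min-count support threshold as calling so that stray error reads at deep
   coverage cannot inflate it). Variants must then be shared by all
   replicates of an experiment (or k of n for the strain-comparison profile);
   keys surviving in any experiment are unioned per species. Only variants
   inside annotated genes (CDS, tRNA, rRNA) are kept, oriented to the coding
   strand: a forward T>C inside a minus-strand gene is a coding A>G;
   everything not A>G on the coding strand is discarded. Sites inside genes
   overlapping on both strands are ambiguous and dropped with a logged
   warning. Optional stages: strand-specific support filtering (stranded
   libraries; sites whose alt support is entirely antisense are dropped, and
   levels count sense reads only) and subtraction of DNA-seq variants.
5. **Rescue.** For every final site, the level and coverage are re-extracted
   in *all* samples with no thresholds, so replicates where the site fell
   below the calling floor still report their observed (possibly < 1%)
   level. Zero-coverage samples report a missing level, never zero. A site's
   single summary level is the unweighted mean over non-missing samples —
   one of several defensible weightings; it is used only in reports.

Two profiles bundle the thresholds: `cross_species` (≥ 5%, all replicates)
and `abaylyi` (≥ 1%, 3-of-4 replicates, stranded filtering, DNA subtraction).

## Motif and recoding statistics

The 4-mer statistic uses the category `(−1, A, +1, +2)` around the edited A
on the coding strand — 64 `XAYZ` categories. The null is genome-sampled: per
species, the frequency of each category over **both strands** of its genome
(genes lie on either strand), combined across species weighted by observed
site counts so expected totals equal N. Enrichment is a chi-square goodness
of fit, `Σ(O−E)²/E` with df = 63; categories with expected < 1 would be
pooled into a rest class (whole-genome nulls never trigger this).

7-mers are classified by Hamming distance to the consensus `YTACGAA`
(Y ∈ {C,T}; edited A at position 3), binned 0 / 1 / ≥2. The logo matrix is a
position frequency matrix over the 21-base contexts with information content
`IC_i = 2 − H_i − 3/(2·ln2·n)` (small-sample corrected).

Codon effects translate the reference and A→G-edited codons with the
bacterial genetic code (identical to the standard code for internal codons)
and classify synonymous / nonsynonymous / stop gain / stop loss
mechanically, with no special-casing of stop codons. Note that editing the
third position of `TTA`/`CTA` is synonymous for **leucine** under the
standard code (these are sometimes mislabelled lysine codons in the
literature). The expected codon-position and effect distributions condition
on the TACG context — the null is all CDS adenosines inside `TACG` on the
coding strand, per species, weighted by site counts — because the deaminase
requires that context; an unconditioned all-adenosine null would conflate
motif preference with positional preference.

## Secondary structure

Windows are 17 nt (the length of the tRNA-Arg2 anticodon arm) with the
edited A at 1-based position 8 (`NNNNNYT[A]CGAANNNNN`); offset d slides the
window d bases downstream along the coding strand in 1-nt steps. The profile
reports per-offset mean MFE, standard error and n (windows running off a
contig are skipped and excluded from n). The offset range (−30..+30 by
default, narrower in tests for speed) is configurable.

Folding goes through an engine adapter: ViennaRNA's nearest-neighbor
thermodynamic model at 37 °C with default parameters, or a built-in Nussinov
base-pair-maximization scorer (−1 per pair, minimum hairpin loop 3) that is
explicitly non-thermodynamic and exists so relative comparisons work without
ViennaRNA. All structure conclusions use only relative comparisons (sites vs
controls, offset vs offset), so the engine choice cannot flip them.

Control sites are all other `YTACGAA` occurrences on either genome strand
(real sites removed), anchored at the would-be edited A — on the reverse
strand the anchor is the complementary A's forward coordinate. The
site-vs-control comparison at offset 0 uses Welch's unequal-variance t with
Welch–Satterthwaite df. (`YTACGAA` is used for controls; a 6-mer variant of
the pattern circulating in the literature is internally inconsistent in
length and is not used.)

## Differential editing and conservation

Per-site strain comparisons use the classic pooled-variance Student's t on
per-replicate levels (two-sided), with p = 1 by convention when both groups
are identical constants, followed by Benjamini–Hochberg step-up correction
across sites: `q_i = min_{j≥rank(i)} p_(j)·m/j`, capped at 1. Relative
change is `(mean_b − mean_a)/mean_a`, reported missing when the baseline
mean is 0 (the formula is a package decision; an absolute-difference variant
is trivially derived from the reported means). Comparisons of per-site mean
levels between two *site sets* use Welch's t.

Conservation classes partition events grouped by a normalized protein key
(supplied in the input table; homology search is out of scope): *conserved*
if ≥ 2 species share the same (position, substitution) on the same protein,
*partially conserved* if the protein is edited in ≥ 2 species but not at
this exact position/substitution, *unique* otherwise. Alignment-column
extraction maps an ungapped reference position to its MSA column and
tabulates residue frequencies over sequences passing the exclusion flags.

## The synthetic-data generator

The generator is the package's ground-truth instrument, not a fixture. It
emulates: a random bacterial-like genome (GC content configurable, default
0.5) with non-overlapping, stop-free CDS on both strands (ATG … stop);
editing sites rewritten into `YTACGAA` on the coding strand, one per gene,
optionally embedded in a stem-loop (the 3′ flank of the 17-nt window is the
reverse complement of the 5-base 5′ flank, leaving the 7-mer in the loop, so
the planted structure matches the anticodon-arm geometry; the 5′ stem is
GC-biased, ≥ 60% G/C, so the stem is thermodynamically stable); per-read
independent Bernoulli editing at the site's designed level; strain SNPs at
non-edited in-gene coding-strand adenosines, present in every read (~100%
frequency) to exercise the 98% ceiling; uniform substitution errors applied
after editing; constant Q37 qualities with an optional low-quality 3′ tail
to exercise trimming; stranded (transcript-orientation) or unstranded
single-end reads; and per-replicate RNG streams derived from one master seed
by fixed offsets, making every output bitwise deterministic.

Reference conditions (the defaults): 50 kb genome, 40 CDS of 300–900 nt,
30 editing sites at levels ~U(0.10, 0.60), 50× coverage, 100-nt reads,
3 replicates, error rate 10⁻³, 5 strain SNPs, stranded. Planted sites keep a
margin of one read length from gene ends so site coverage ≈ mean coverage
and the recovery statistics measure the cascade rather than edge-coverage
artifacts. Gene expression is uniform across genes (the statistics under
test do not depend on expression heterogeneity).

Deliberately **not** emulated: indels, PCR duplicates, paired-end inserts,
quality miscalibration, expression heterogeneity, operon structure and real
codon usage. Passing recovery tests therefore demonstrates the correctness
of the cascade's logic and thresholds under the stated noise model — not
robustness to alignment artifacts around indels or to duplicate-driven
coordinate clustering, which the unique-start/end filters can only be
exercised against, not proven on.

## Acceptance quantities and simulation sizes

`scripts/acceptance.py` recomputes, from fresh seeded simulations:

* **Parameter recovery** under the reference conditions above: sensitivity,
  false positives, the fraction of recovered sites whose pooled level
  estimate falls inside the designed level's 95% binomial interval, and
  strain-SNP leakage.
* **Motif statistics** of the recovered sites (TACG fraction, chi-square
  df) and **null calibration**: 200 draws of 500 sites from the genomic
  A-centred 4-mer distribution of a 40 kb genome (expected counts ≈ 8 per
  category, comfortably inside the chi-square approximation's validity),
  tested for uniformity of p-values by Kolmogorov–Smirnov. Sampling from
  the A-centred 4-mer population — the test's own null — is the correct
  calibration for the 64-category test; sampling only TACG adenosines
  calibrates the codon-position null instead.
* **Structure discrimination**: 20 independent simulations of 50 planted
  hairpin sites on 60 kb genomes vs 10× shuffled-flank controls
  (motif-preserving flank permutations), Welch p at offset 0, plus the
  location of the profile minimum over offsets −10..+10.
* **Differential power**: 100 simulations of 10 sites at WT 30% vs mutant
  3%, binomial noise at 500×, 4+4 replicates; and the q ≤ 0.05 rate over
  200 global-null simulations.

Problem sizes are chosen to make each quantity statistically stable at desk
scale; all are configurable upward through the same APIs. Two published
summary statistics suites exist in the tests: the self-contained checks
above, and a recomputation over the cross-species editing-site table
published as supplementary material of the originating study, which cannot
be redistributed here — to run it, place that table at
`data/supplementary_sites.tsv` with columns `CONTEXT21`, `RNA_CLASS`,
`CODON_REF`, `CODON_POSITION`.

## Known limitations

* The built-in mapper is ungapped and single-end by design; real data
  should arrive pre-aligned through the SAM reader.
* Neighborhood quality semantics at read ends vary between callers and are
  rarely documented; this implementation truncates the neighborhood at read
  boundaries.
* Whether the 50%-mapped QC threshold is inclusive is unspecified upstream;
  inclusive (≥) comparisons are used throughout, matching "at least"
  phrasing.
* The hyper-allelic filter counts alleles at calling-level support
  (count ≥ 3); a literal "any observed base" reading would break on deep
  data with sequencing errors.
* Conservation grouping trusts the supplied protein keys; no homology
  search or phylogenetic correction is performed.
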