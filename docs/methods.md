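# Methods

`mitosoma` analyses catalogues of somatic mitochondrial DNA (mtDNA)
mutations that were mapped jointly in tumor genomes (WGS) and
transcriptomes (polyA+ RNA-seq).  One catalogue row is one mutation in one
tumor with its variant allele frequencies (VAFs) in tumor DNA, matched
normal DNA and tumor RNA.  The analysis has five parts: variant-effect
annotation on the circular mitochondrial genome, heteroplasmy-based
selection statistics, strand-resolved mutational-signature enrichment,
DNA-vs-RNA allelic-imbalance detection of tRNA processing defects, and
structural-impact scoring of mt-tRNA variants.  A synthetic-catalogue
generator supplies fully labelled inputs so that every stage is testable
without sequencing data.

## Coordinates, strands and the reference fixture

Coordinates are 1-based inclusive on a circular 16,569-nt genome.  The
reference plus strand is designated the light (L) strand (it is the
cytosine-rich strand); the heavy (H) strand is its reverse complement.
Features may wrap the replication origin; the control region (D-loop) is
fixed to the conventional 16,024–576 interval.  Thirty-seven genes tile
the genome — 13 protein-coding, 22 tRNAs, 2 rRNAs — at the standard human
coordinates, with protein-gene ends adjusted by one or two bases so every
gene is a whole number of codons (the real genome ends several genes on
incomplete stop codons completed by polyadenylation; modelling that adds
nothing here).  ND6 and eight tRNAs are H-strand genes and are evaluated
on the reverse complement.

The packaged genome is **synthetic**: the real reference sequence is not
redistributed with the package.  `scripts/build_reference.py` generates it
deterministically with the statistical structure that the analyses depend
on:

* overall base composition matching the real plus strand
  (A 0.32, C 0.30, G 0.13, T 0.25);
* protein genes sampled codon-by-codon from position-specific base
  frequencies with mammalian-mtDNA-like third-position G depletion
  (pos-3 G = 0.04, A = 0.44), with no in-frame stops and a terminal stop
  codon.  This calibration matters: it sets the neutral expectation for
  the synonymous:nonsynonymous test (below) to ~0.75, the value the real
  genome must have given the published test outcome;
* the three indel-hotspot homopolymer runs (polyC 10,947–52 and 11,867–72
  in ND4; polyA 12,418–25 in ND5), with flanking bases pinned so each
  annotated run is maximal;
* designed cloverleaf tRNA genes (acceptor stem 7 bp, D-arm 4 bp,
  anticodon and T arms 5 bp; the Ser-AGY homolog lacks the D-arm), each
  verified during the build to fold into its annotated structure under
  the package's own energy model.  Gene-local sequence, dot-bracket
  structure and per-position domain labels ship as text fixtures.

## Effect annotation

Regions are assigned by feature lookup with priority
protein > tRNA > rRNA > D-loop; overlapping protein genes (ATP8/ATP6,
ND4L/ND4) resolve to "coding" and the most severe effect across the
overlapping reading frames is reported (severity: nonsense > frameshift >
missense > inframe > synonymous).  SNVs are translated under the
vertebrate mitochondrial code (AGA/AGG stops, ATA Met, TGA Trp) on the
gene's own strand.  Indels are frameshift iff the length change is not a
multiple of 3, and are left-aligned within homopolymer runs so recurrent
slippage events collapse onto one canonical position.  Padded allele
representations are trimmed before classification, making annotation
invariant to the caller's spelling of an SNV.

Strand-resolved substitution classes follow the pyrimidine convention:
each SNV is reported as the change of the pyrimidine of the mutated base
pair, on the strand that carries the pyrimidine.  A reference G>A is a
C>T change on the H strand.  The 12 classes (6 pyrimidine changes × 2
strands) partition all SNVs.

## Selection statistics

Heteroplasmy is the tumor-DNA VAF; summaries (mean, max, fraction above a
threshold such as the 0.95 near-homoplasmy cut) are over mutations, not
tumors.  Category distributions are compared with the two-sample
Kolmogorov–Smirnov test (exact null below 10 observations per group,
asymptotic otherwise — SciPy's implementation behind the module surface).

The synonymous:nonsynonymous selection test compares the observed coding
split against a spectrum-matched neutral expectation with a Yates
continuity-corrected one-degree-of-freedom goodness-of-fit statistic,
Σ (|O−E|−0.5)²/E.  The neutral expectation enumerates every possible SNV
at every protein-coding position, classifies each with the same effect
annotator, and combines per-class nonsynonymous fractions with weights
equal to the catalogue's observed class frequencies.  Each class's total
mass equals its observed frequency (uniform within the class): the
observed spectrum already reflects per-class target abundance, so
weighting sites directly would count availability twice and — on this
genome — depress the expectation from ~0.75 to ~0.70, an expectation no
transition-dominated mammalian mtDNA catalogue could match.

## Mutational signature

Expected class fractions assume each position mutates with equal
probability to the three alternatives, scaled by single-base composition:
class (P>Q, S) expects freq(source base)/3, where the source base is P
for L-strand classes and its complement for H-strand classes (no
trinucleotide normalisation).  Enrichment is observed/expected per class;
a pooled statistic reports mutations at G:C reference pairs against the
composition expectation.  Segment densities partition the circle into 50
near-equal segments from position 1 (floor length 331 nt, the remainder
added one base each to the final segments).  A separate descriptive
statistic reports the fraction of C>T events with a 5′ pyrimidine
neighbour on the mutated strand (UV-signature check); D-loop exclusion is
available as a switch.

## DNA/RNA allelic imbalance

Concordance is the Pearson correlation of (DNA VAF, RNA VAF) on
untransformed frequencies.  Processing-defect candidates are records with
RNA − DNA VAF strictly above a threshold (default 0.3; RNA-deficit and
two-sided variants available).  Regional enrichment of the imbalanced set
uses the two-sided Fisher exact test on the 2×2 table (in-region ×
imbalanced).  Coverage profiles are normalised by each sample's total
mitochondrial read count; case-versus-control fold change divides the
normalised case depth by the per-base median of normalised controls, with
a 1e-9 pseudocount in normalised units keeping zero-coverage positions
finite.

## tRNA structural impact

Ensemble base-pair probability matrices are computed with McCaskill-style
inside–outside partition-function recursions over all non-crossing
structures with Watson–Crick and GU pairs and hairpin loops of ≥3 bases.
The energy model is deliberately simple — per-pair formation energies
(GC −1.2, AU −0.6, GU −0.3 kT) plus additive stacking energies for
adjacent pairs (per-pair strengths 1.5/0.9/0.5 kT), no dangles or special
loops, β = 1.  The implementation is verified against exhaustive
enumeration of all structures for sequences up to 12 nt.  Absolute
energies are not comparable to full Turner-model engines; every score is
used only relative to a matched null (below), so group-level conclusions,
not per-variant p-values, are the supported output.

The impact score `d` of a substitution is the maximal Euclidean distance
between wild-type and mutant matrices restricted to a sequence window
(default 100 nt, i.e. the whole tRNA), maximised over subintervals with
ties resolved toward the longest interval.  The null distribution pools
scores from dinucleotide-preserving shuffles (Altschul–Erickson Eulerian
walks, preserving exact dinucleotide counts and terminal bases) of the 22
tRNA sequences, each shuffle receiving one uniform random substitution.
The empirical p-value is (1 + #{null ≥ d})/(1 + N), never zero, and is
verified to be uniform for null variants.  tRNAs whose wild type fails a
native-fold check (fewer than 70% of reference cloverleaf pairs at
ensemble probability ≥ 0.5) are excluded from group comparisons; on the
designed fixtures all 22 pass, so the synthetic analysis retains all
variants where the original tool-dependent analysis retained a subset.
Stem/loop localisation is read from the reference cloverleaf (stem iff
paired).  Processing-defect and remaining tRNA variants are compared with
a two-sided Wilcoxon rank-sum test with midrank ties, exact by
enumeration up to 10 per group and tie-corrected normal approximation
above.

## Synthetic data

`simulate_catalogue` draws catalogues generatively: per-tumor Poisson
counts (default rate 1.17/tumor); SNVs sampled class-first from the
12-class probabilities and then positionally among matching reference
bases with D-loop density multiplied by 3.3; indels as single-base slips
in mononucleotide runs (default 8.4% of mutations); DNA VAFs from
effect-conditional Beta mixtures; RNA VAF = clip(DNA + Gaussian noise,
σ = 0.05, clipped at ±0.25); and 15 injected processing-defect mutations
(12 in tRNAs) with DNA VAF ≤ 0.55 and an RNA excess drawn uniformly from
[0.35, 0.55] — above the 0.3 detection threshold by more than the noise
bound, so recovery is exact by construction.

Heteroplasmy models are mixtures of a Beta component (α+β = 4, truncated
to [0.15, 1] to respect the somatic-calling VAF floor, raw mean solved so
truncation does not bias the target mean) and a near-homoplasmic uniform
on (0.951, 1] whose weight is solved so each class's P(VAF > 0.95) is
0.0837 — giving a catalogue-wide near-homoplasmy fraction of 8.0% once
~4% of mutations are frameshifts.  Class means: 0.58 by default, 0.396
for frameshifts (hard ceiling 0.85), 0.488 for nonsense, 0.658 for
D-loop.  The default class probabilities put (C>T, H) at 10.6× its
composition expectation and 65% of total mass on G:C-pair classes, with
(T>C, H) = 0.22 as the secondary heavy-strand excess.

`study_catalogue` is the package's stand-in for the study's deposited
mutation table.  It fixes the marginals the study reports — per-cancer
tumor/mutation/indel counts (14 types, 527 tumors, 616 confirmed of 644
sequenced), 564 SNVs + 52 indels, 335 mutated tumors, 363 coding
mutations split 251/69/27/16 missense/synonymous/frameshift/nonsense,
45 tRNA SNVs of which 12 imbalanced (all at pair-breaking internal stem
positions) and 33 background (23 stem, 10 loop), the three indel
hotspots, 15 imbalanced records total against a 601-record background —
and draws everything underneath (positions, alleles, VAFs, tumor
assignment) from the generative model.  tRNA variants are drawn first and
the remaining SNV class counts are allocated by largest remainder so the
catalogue-wide spectrum hits the configured probabilities up to rounding;
the per-type mutated-tumor allocation scales the Poisson expectation to
the fixed total of 335.  Injected defect mutations break Watson–Crick
pairs (G→A against C, etc.); background stem variants prefer GU-creating
transitions (C→T, A→G), encoding the structure–processing relationship
the analysis is designed to detect.

`simulate_coverage` produces control profiles as Poisson noise around a
smooth baseline (200 reads/base modulated ±30%) and a case profile whose
expected depth is multiplied by the accumulation fold across the mutated
tRNA window; totals vary ±15% per sample to exercise normalisation.

### What the generator does and does not emulate

It reproduces the marginal structure of the study data (burden, spectrum,
VAF distributions by effect class, imbalance geometry) but not read-level
artefacts (alignment error, nuclear mitochondrial pseudogene
contamination, coverage-dependent VAF noise), linkage between mutations
in the same tumor, or real tRNA sequences.  Passing tests therefore show
the pipeline recovers known structure of this kind, not that it is robust
to upstream calling artefacts, which are out of scope.

## Problem sizes and numerical choices

Default analysis runs use 50 shuffles per tRNA for the structure null
(1,100 null scores, ~1 minute); the test suite uses 20.  Folding is exact
(no sampling); distances use 2-D prefix sums.  Random streams derive from
a single user seed via `numpy.random.default_rng` with fixed stream
offsets; identical inputs and seed give byte-identical outputs.
Truncated-Beta and mixture-weight calibrations use `brentq`/fixed-point
solves at construction time.  Fisher, KS and Wilcoxon routines are exact
on small inputs and are tested against brute-force enumeration.

## Known limitations

* The structural energy model ranks variants reliably (verified against
  enumeration and the shuffle null) but its absolute scores and p-values
  are not comparable to published Turner-model tools.
* Indels receive no structural score (length-changing folding comparison
  is undefined in the fixed-window distance mode).
* The synthetic reference cannot reproduce position-specific biology of
  the real genome (e.g. true hypervariable sites); analyses that depend
  only on composition, gene layout and codon structure are faithful,
  position-level lookups are not.
* The catalogue model treats mutations as independent across tumors;
  recurrence arises only through hotspot placement.
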