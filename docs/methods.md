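# Methods

## Scope and model

karyoscope infers whole-chromosome karyotype state — chromosome count,
per-chromosome copy-number folds, strain-level euploid/aneuploid verdicts,
nuclear composition, and predicted offspring ploidy classes — for fungal
genomes where strains can be homokaryotic or heterokaryotic. The unit of
analysis is the whole chromosome throughout; sub-chromosomal CNV
segmentation is out of scope by design.

## Telomere scanning

Telomeric arrays are tandem repeats of a 7 bp unit (`CCCCTAA` on the 5'
strand; its reverse complement `TTAGGGG` marks the 3' end). The scanner
seeds at exact unit occurrences and grows arrays one unit at a time in both
directions, accepting a candidate unit if (a) its own mismatches do not
exceed a per-unit cap of `max(1, floor(f·k))` bases (k = unit length,
f = `max_mismatch_fraction`, default 0.1) and (b) the cumulative mismatches
stay within `f` of the array length. The per-unit cap is what prevents
arbitrary flanking sequence (which mismatches a 7-mer by ~75% on average)
from riding a long array's accumulated budget. Indels inside arrays are not
modelled: terminal telomere arrays are unit-phased in practice, and the
frame-preserving search keeps coordinates exact, which the generator-truth
tests exploit.

An array is *terminal* (side `left`/`right`) when it starts/ends within
`end_window` (default 1,000 bp) of the contig end; interior arrays are
reported as `interstitial` and excluded from accounting. The minimum copy
number for reporting defaults to 5. None of these three values is dictated
by the underlying biology; they are package defaults chosen so that a
5-copy terminal array is unambiguous against random sequence (an exact 7-mer
occurs every ~16 kb by chance, but 5 consecutive near-exact units are
vanishingly unlikely) while short degenerate arrays are still found.

## rDNA detection

Ribosomal DNA arrays are located by infix alignment (edit distance) of an
rRNA reference against each contig, both strands, iteratively masking each
match until none reaches `min_identity` (default 0.80) at
`min_match_length` (default 500 bp). Overlapping or abutting matches —
consecutive copies of a tandem array — are merged into one locus; the locus
is *terminal* when it lies within `end_window` of a contig end. A bundled
synthetic rRNA-like unit (3 kb, GC 0.55, generated from a fixed seed;
synthetic, with no biological sequence content) serves as the default
query so fixtures need no downloads; any real rRNA FASTA (e.g. 18S/5.8S/28S
records) is accepted.

## Chromosome accounting

Contigs are classed by their terminal features: `complete_two_telomeres`
(telomere on both ends), `complete_telomere_plus_rdna` (one telomere and a
terminal rDNA locus on the opposite end — rDNA can occupy a chromosome end
in these species, so such contigs are complete), else `partial`. Two counts
are reported because practice is genuinely split: the *strict* chromosome
count (double-telomere contigs only) and the *extended* count (strict plus
telomere+rDNA contigs). The extended count is the headline, since a terminal
rDNA array is positive evidence that the assembly reached the chromosome
end. Contigs with more than two terminal arrays are flagged anomalous
(a signature of a false join) but not corrected.

## Depth profiling

Coverage is computed over fixed windows (default 10,000 bp) tiling each
sequence, as aligned bases overlapping the bin divided by bin width;
secondary/supplementary/duplicate/unmapped records are excluded and a MAPQ
floor (default 0) applies. Alternatively a per-bin table is ingested
(native or Sambamba-style window format). Robust per-chromosome depth is a
two-sided trimmed mean (default 10% per tail) after masking bins beyond 5
scaled MADs of the chromosome median; terminal short bins are excluded from
summaries. The trimming + masking combination is the substitute for visual
inspection of depth tracks: it tolerates the sporadic repeat-driven depth
spikes real assemblies show without biasing the chromosome mean. Optional
GC correction (bin GC deciles, divide by stratum median) is off by default.

## Fold estimation and classification

The baseline (1× level) is the median of per-chromosome robust depths —
valid because duplicated chromosomes are a minority (at most 3 of 15 in the
screened strains); a kernel-density mode estimator is available for
assemblies where that assumption is doubtful. Folds are assigned to the
nearest value of the grid {1, 1.5, 2, 2.5, 3, 3.5, 4} when the relative
deviation is ≤ 0.12, else left unassigned and the strain verdict becomes
*ambiguous* — near-miss folds are never silently rounded. The grid is the
union of multiples observed for one- and two-nucleus duplications plus
half-integer midpoints so that, e.g., a true 1.25 lands on "unassigned"
rather than on 1 or 1.5. The 0.12 tolerance is a package decision rule (no
published rule separates 1.5× from noisy 1×/2×): at 50× base depth with
NB dispersion 0.1 and ≥ 200 bins per chromosome, the fold standard error is
≈ 0.03, so 0.12 is ≈ 4 SE — wide enough for realistic noise, narrow enough
that adjacent grid points (gap 0.5 relative ≥ 0.17 at 2×) stay separated.
Assignment confidence is the fraction of 200 bin-level bootstrap resamples
(chromosome-wise resampling, baseline recomputed each replicate) that
reproduce the point assignment.

## Nuclear composition

With `n` nuclei and an assigned multiple `m`, the chromosome's total copy
target is `m·n` (each nucleus contributes one baseline copy). Integer
targets are enumerated as all splits into `n` positive parts; joint
assignments across duplicated chromosomes are deduplicated up to nucleus
relabelling and ordered by parsimony — fewest distinct nucleus genotypes,
then smallest maximum copy number. Parsimony ordering is a package
convention: for a dikaryon at 1.5× it ranks the balanced explanation
(one euploid and one duplicated nucleus) first, which is the classical
interpretation. Non-integer targets (a 1.5× fold in a nominally
single-nucleus strain, as protoplast-derived isolates can show when they
carry more than one nucleus of the same mating type) are representable only
as a mixture of two nucleus populations; with `allow_mixture` the solver
returns the floor/ceil two-population mixture whose weights reproduce the
fold exactly. Infeasible targets raise an explicit typed error rather than
returning an approximation. The enumeration guard (200,000 joint
assignments) is far above any realistic case (≤ 4 nuclei, ≤ 3 duplicated
chromosomes).

## Meiosis model

The classical verbal reasoning about offspring of an aneuploid parent — a
duplicated chromosome yields balanced and duplicated spores, while losses
are lethal — is made mechanistic as chromatid allocation: karyogamy sums the two parental copy vectors into
`K`; each chromosome replicates to `2K` chromatids; the four spores receive
`floor(2K/4)` each with the remainder given to a uniformly random spore
subset (*faithful* mode). *Disordered* mode then moves, with probability
`p_nd` per chromosome, one chromatid from a random non-empty donor spore to
a random recipient — the simplest abstraction that gives a nondisjunction
rate a concrete meaning. Spores with any chromosome at zero are inviable;
offspring are i.i.d. viable spores (single-spore isolates), not constrained
tetrads. Chromatid conservation (spore copies sum to `2K` per chromosome)
is asserted on every draw.

For the trisomic dikaryon case (`K = 3` for one chromosome: 6 chromatids →
2,2,1,1) faithful allocation yields exactly two viable classes at equal
frequency, matching the observed mix of euploid and duplicated offspring.
Whether a 3× parent means (3,3) nuclei or an unequal split is not decidable
from fold data; the simulator takes the parental nucleus pair as input
rather than inferring it. Goodness of fit of observed cohorts uses the
exact binomial test (two classes), the exact multinomial test (small
expected counts), or chi-square (all expected counts ≥ 5).

## Synthetic-data generator

The generator is first-class, tested code and defines the conditions under
which the pipeline is validated:

* **Assemblies** — contigs of i.i.d. bases at a target GC with planted
  terminal telomere arrays and tandem rDNA arrays, plus a truth table of
  all planted features (0-based half-open). Plans that do not fit the
  contig are rejected.
* **Coverage** — per-bin depth from a negative binomial with mean
  `base_depth × (nucleus-weighted copies)` and variance `m + α·m²`
  (dispersion `α = 0` collapses to the exact mean); a fraction of bins
  (default 2%) is multiplied by a factor uniform on [0.2, 5] to emulate
  repeat-driven spikes. No published noise model exists for these depth
  tracks; the NB choice is the standard overdispersed-count stand-in and is
  configurable. Defaults (50× base depth, dispersion 0.1, 2% outliers)
  represent a typical long-read genome run.
* **Reads** — optional uniform error-free read origins with per-chromosome
  rate ∝ length × weighted copies, plus a writer that materialises the
  truth alignment as a sorted BAM so the alignment-ingestion path is
  exercised without an external aligner.
* **Cohorts** — per-offspring copy configurations with truth labels
  (euploid/aneuploid, duplicated chromosomes, folds).

Preset strain configurations encode the screened karyotype states (a 2×
homokaryon; 1.5× dikaryons; a 3× strain; protoplast strains mixing nucleus
populations; the eight- and twenty-offspring cohorts) over 15 chromosomes
with lengths spaced 5.46–2.15 Mb, chromosome 15 smallest. The generator
does not emulate mappability structure, GC bias, read errors or reference
bias — so passing tests demonstrate correctness of the inference given
binned coverage, not robustness to alignment artefacts on real data.

## Problem sizes and determinism

Simulated depth uses the full Mb-scale chromosome set (≈ 5,700 full 10 kb
bins per strain); assembly-scan fixtures use 60 kb contigs, since
completeness accounting depends only on contig ends. Recovery properties
are evaluated over 100 seeded strains. All randomness flows through numpy
`SeedSequence([seed, stream...])` so one user seed fans out to independent,
individually reproducible stage streams; identical seeds give byte-identical
outputs.

## Known limitations

* Whole-chromosome resolution only; partial duplications would dilute the
  fold toward 1 and typically land "unassigned".
* The baseline assumes fewer than half the chromosomes are duplicated.
* Telomere arrays with internal indels, or unit variants other than the
  configured motif set, are not chained across frame shifts.
* The meiosis model ignores recombination, mating-type constraints and
  spore germination bias; `p_nd` is a phenomenological rate, not a measured
  one.
* Nucleus-mixture inference is a representational device: fold data alone
  cannot distinguish a true population mixture from intermediate-coverage
  artefacts.
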