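# Methods

This note records the models behind each stage of `nucmir`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical conventions used throughout.

## Enrichment calling

The data model is a probe × sample matrix of non-negative raw array
intensities with each sample annotated by compartment (nuclear or
cytoplasmic) and replicate. Three calling rules are implemented because
cross-sample normalization rests on the assumption that most probes do not
change — an assumption that nucleo-cytoplasmic fractionation violates by
design. Candidates robust across rules are the interesting ones.

**Raw nuclear percentage.** Probes with raw signal below the detection floor
(`signal_floor`, 30 raw units) in *every* sample are removed; requiring only
one detected sample is deliberate, since a strongly compartmentalized probe
can legitimately be near zero in half the samples. Signals are averaged over
replicates per compartment and pct = 100·N̄/(N̄+C̄) computed. The call is
strictly greater than `nuclear_pct_threshold` (70%), so a probe at exactly
70.00 is not called. Probes expressed in only one compartment give 100 or 0
(well-defined); probes at zero in both are reported undefined (NaN) and never
called. Percentages are invariant to any global rescaling of the matrix.

**In-sample rank.** Within each sample, probes are sorted descending and
ordinal positions 1..N assigned, ties receiving the average position; the
score is (N+1)/2 − position, so the median probe scores 0 and larger signal
means a larger score. "Distance from the median" is realized in rank units
rather than raw-signal units: this makes the method a pure rank rule,
invariant to any strictly monotone within-sample transform, which is the
point of in-sample normalization (raw-signal distance is available via
`rank_scores(..., distance="signal")`). A probe is called enriched only when
its score in every nuclear sample strictly exceeds its score in every
cytoplasmic sample; any tie breaks the call. Note that this is a *relative*
rule: in a population whose background nuclear fractions vary, probes with
above-typical (but sub-threshold) nuclear share are rightfully called by the
rank rule while the percentage rule rejects them. The two rules provably
coincide on the planted set only when the background shares a single nuclear
fraction, which is how the noiseless-agreement calibration is run.

**Quantile normalization + moderated t.** Every sample is forced onto the
mean-of-sorted-columns reference distribution (ties receive the mean of the
reference values they span), signals are log2(x+1)-transformed, and a
two-group empirical-Bayes t-test applied. The per-probe pooled variance s²
(d = n₁+n₂−2 df) is shrunk toward a prior, s²ᵖᵒˢᵗ = (d₀s₀² + d·s²)/(d₀+d).
The prior (d₀, s₀²) is fitted by moment-matching on the log scale: with
e = log s² − ψ(d/2) + log(d/2), solving ψ′(d₀/2) = Var(e) − ψ′(d/2) by
Newton inversion of the trigamma function and recovering s₀² from the mean.
Zero sample variances are offset to 10⁻⁵ × median rather than dropped; when
the observed log-variance spread does not exceed its sampling floor the
prior is degenerate (d₀ = ∞) and s₀² is the arithmetic mean of the
variances; the total degrees of freedom are capped at n_probes × d. These
conventions were cross-checked against an independent Bioconductor
implementation of the same hierarchical model, with agreement to ~10⁻¹⁵ in
both prior branches (the comparison is kept as a test). Multiple testing is
Benjamini–Hochberg. Setting `prior_df=0` recovers the ordinary two-sample
t-test exactly. Full probe-level array preprocessing (background correction,
probe-set summarization) is out of scope: the pipeline starts from one row
per miRNA, already summarized.

## Motif discovery and the exact test

Motif presence is binary per sequence ("contains"), not occurrence-weighted,
matching how the contingency table is constructed. `find_recurrent_motif`
reports k-mers supported by at least ⌈min_support_frac · n⌉ of the enriched
sequences, sorted by support then lexicographically; `divergent_members`
names the sequences lacking the top motif. The default motif length is 4 nt.

Fisher's exact test is computed by explicit summation of the hypergeometric
distribution over all tables with the observed margins, accumulating
log-probabilities (log-gamma binomials + log-sum-exp) so that tails of
order 10⁻¹⁰ and smaller are stable. The one-sided (enrichment-direction)
test is the default — the direction of the hypothesis is given by the
design — with the two-sided version (point-probability criterion, with a
1+10⁻⁹ multiplicative tolerance for floating-point ties) available. On the
observed 13-vs-30 design (12/13 carriers vs 0/30) the one-sided p equals
31/C(43,13) ≈ 8.5 × 10⁻¹⁰.

Whether the appropriate comparison group is the 30 least-nuclear miRNAs or
the genome-wide ~25% motif prevalence is genuinely open; the 13-vs-30 table
is the default and the generator accepts any background prevalence.

## GA-box (MAZ consensus) scanning

The scanner reports, for each adenosine whose flanks are runs of G, the
maximal arm length n ∈ [`maz_n_min`, `maz_n_max`] = [2, 6] (maximal munch
per center); every shorter arm is necessarily contained in the match, so
nested reporting would only inflate hit counts (it is available via
`nested=True`). Overlapping centers are all reported. U and T are treated
identically, so DNA and RNA scan the same. A plain exact-substring utility
(`scan_element`) is provided for checking candidate localization elements
such as the hexanucleotide reported to direct miR-29b nuclear import.

## RIP targets

The read-count floor (`count_floor`, 10 reads) applies to a gene's total
across the table's samples within one pull-down — the data do not determine
a per-sample convention, and totals are the more stable choice at the low
depths typical of nuclear RIP. The filter is idempotent and monotone in the
floor. Seed sites follow the canonical taxonomy (8mer, 7mer-m8, 7mer-A1,
6mer) on the reverse complement of miRNA positions 2–7, reporting the single
strongest class per matched locus; G:U wobble in the seed is off by default
(`allow_wobble=True` to enable). External target-prediction databases and
their context scores are deliberately not consulted: the site classes are
computed from sequence alone. Genes without a UTR sequence are skipped with
a logged count rather than failing the run. The partition of two pull-downs'
target sets into unique/shared is plain set algebra, with sizes logged.

## Splicing screen

Gene-level signal is defined as the mean of the transcript's exon signals —
self-contained from the exon table, at the cost of the gene estimate being
perturbed by the differential exon itself (see the generator note below).
The splicing index uses replicate-averaged values; zero denominators are
undefined and excluded, and single-exon transcripts are excluded with a
warning.

Significance: per transcript, a two-way fixed-effects ANOVA on log2(x+1)
signals with factors exon and compartment, fitted as the cell-means model.
Each exon's p-value is the F-test (1 numerator df, within-cell residual df)
of its single-exon-vs-rest interaction contrast on the cell means,
c = (m̄ⱼ,ₙ − m̄ⱼ,c) − mean over i≠j of (m̄ᵢ,ₙ − m̄ᵢ,c), with
Var(c) = σ²(1/rₙ + 1/r_c)(1 + 1/(E−1)). The contrast is computed against
the *full* model's residual; collapsing the non-focal exons into one cell
before fitting would pour exon main effects into the residual and make the
null p-values conservative rather than uniform. Under multiplicative
log-normal noise the log-scale normality assumption holds exactly, and the
null p-values are verified uniform by a KS check. In the noiseless
degenerate case (zero residual) a zero contrast is reported as p = 1 and a
non-zero contrast as p = 0. Balanced designs are permutation-invariant
within compartments by construction.

An exon is flagged when q < `fdr_alpha` (0.01) and its linear
gene-normalized fold exceeds `si_threshold` (2) in either direction, i.e.
|si| > 1 on the log2 scale; the splicing-index convention is not uniquely
determined by the screen's definition, and a stricter |si| > 2 reading is
available via the same parameter. FDR control is applied per exon, with
transcripts flagged when any exon passes — the alternative (per-transcript
correction) is a coarser screen and was not adopted. Flagged transcripts
are crossed with the RIP target map to produce (miRNA, transcript) pairings.

## Synthetic data

The generators define the study conditions for every calibration and test.
All are deterministic in their seed, and truth fields that chance events can
contaminate (motif copies created by random sequence, accidental seed sites)
are recomputed by scanning after generation.

- **Arrays** (`gen_expression`): 847 probes, triplicate per compartment.
  Total abundance is log-normal (meanlog 7, sdlog 1.5 on the natural-log
  scale of raw units), which places a realistic few percent of probes under
  the detection floor so the low-signal filter is exercised. 13 planted
  probes draw their nuclear fraction from U[0.75, 0.95]; background from
  U[0.2, 0.6], reflecting that most miRNAs show some nuclear signal without
  approaching the 70% threshold. Planted probes' abundance is resampled
  above 100 raw units: a probe that is undetectable cannot meaningfully be
  nucleus-enriched, and the planted set emulates candidates that were by
  construction detected. Replicate noise is multiplicative log-normal with
  unit mean and CV `noise_cv` (default 0.1); at CV 0 the compartment means
  are exact.
- **Mature sets** (`gen_mirna_set`): 13 enriched vs 30 background sequences,
  18–24 nt, uniform base composition. By default 12/13 enriched sequences
  carry the motif (inserted at a random position) and 0/30 background do
  (rejection-sampled, capped at 10,000 attempts); the genome-wide ~25%
  background prevalence is available as a parameter. Designated carrier
  counts are deterministic (rounded fraction of the group), not Bernoulli.
- **Hairpins** (`gen_premir`): 5′ arm + loop + reverse-complement 3′ arm,
  total ≤ 80 nt (the modeled binding-assay oligo limit), with an optional
  planted GⁿAGⁿ in the 5′ arm or rejection-sampled GA-box-free.
- **RIP** (`gen_rip_dataset`): disjoint planted unique-Ago1 / unique-Ago2 /
  shared gene sets (defaults 19/44/66 out of 400 genes — the modeled
  189/435/657 partition scaled by ten for desk-scale runs). Counts are
  negative-binomial (dispersion 0.3), mean 50 for a gene in its planted
  pull-down and 2 otherwise, redrawn so planted genes always reach the
  count floor and others never do; each planted gene carries one planted
  8mer site for a random supplied miRNA in its 200-nt UTR.
- **Exons** (`gen_exon_table`): 100 transcripts × 8 exons × triplicates,
  log-normal gene abundance with mild exon-baseline variation. A planted
  exon is scaled by u in the nucleus and 1/u in the cytoplasm, u solved in
  closed form (u² + wu(1−M) − M = 0, w = eⱼ/(S−eⱼ)) so the *measured*
  gene-normalized ratio equals `si_magnitude` (default 4) exactly in the
  noiseless limit. Exact planting necessarily perturbs the sibling exons —
  with gene = mean of exons it is impossible for the planted ratio to be
  exactly M while all siblings stay exactly at 1 — but the symmetric split
  keeps the siblings' common counter-shift well below the flagging cutoff
  (|si| ≈ 0.3 at the defaults), and this is asserted by test. At most one
  exon per transcript is planted.

What the generators do **not** emulate: probe cross-hybridization, array
spatial artifacts, batch effects, sequencing biases upstream of the count
table, UTR base composition, or any correlation between a miRNA's abundance
and its sequence. Passing recovery tests therefore demonstrates that the
implementations invert their own generative assumptions at realistic noise —
not that those assumptions exhaust real arrays or libraries.

## Problem sizes and calibrations

The recovery and calibration checks run at the generator defaults: the
percentage-method recovery averages sensitivity and false-positive rate over
100 seeds of the 847-probe design (target: sensitivity ≥ 0.95, FPR ≤ 0.01);
the splicing null calibration runs 100 seeds of the 100 × 8 exon design with
nothing planted (flagged-transcript rate ≤ 2% at FDR 0.01); the exact-test
oracle comparison enumerates every 2×2 table with n ≤ 20; the scanner
oracles run on 1,000 random inputs each; and the RIP end-to-end recovery
runs the full 400-gene default design once. These sizes keep the whole
suite in the tens of seconds while leaving the Monte-Carlo margins wide.

## Known limitations

- The enrichment stage assumes one row per mature miRNA; probe-set
  summarization from probe-level array data is out of scope.
- The moderated-t stage presumes log-scale signals are approximately normal
  with probe-specific variances exchangeable under one inverse-chi-square
  prior; strongly bimodal variance structure would violate the fit.
- Seed-site scanning is sequence-only; no accessibility, conservation or
  context scoring.
- The splicing screen tests exon-by-compartment interaction per transcript
  independently; shared splicing factors across transcripts are not modeled.
- RNA secondary structure is not predicted anywhere; hairpin "arms" in the
  generator are exact reverse complements, which real precursors are not.
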