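# Methods

This note documents the models and procedures implemented in `wgdkit`,
the assumptions behind them, and the design choices made where the
methodology is genuinely open.  All numerical claims below are computed
by the test suite or by `scripts/acceptance.py`; nothing here is quoted
from elsewhere.

## Duplicate-pair detection

The paranome (the set of duplicated genes within one genome) is built
from an all-against-all protein comparison.  `wgdkit` replaces heuristic
seeded search with exact affine-gap dynamic programming (BLOSUM62, gap
cost 11 + L for a gap of length L, local mode), which at desk scale
(up to a few thousand proteins) is tractable and fully deterministic.
A pair is retained when all three classic filters pass strictly:

* sequence similarity > 70 % — similarity means BLASTP-style
  *positives*: aligned columns with a positive BLOSUM62 score, divided
  by the alignment length (gap columns included).  Percent identity is
  reported alongside so users can re-filter under identity semantics;
* mutual protein coverage > 80 % — each sequence's aligned (non-gap)
  residue count over its full length; *both* must exceed the threshold;
* protein length > 30 amino acids.

For proteomes above 500 sequences, a candidate prefilter first indexes
amino-acid 5-mers and keeps only pairs sharing at least five distinct
5-mers (k-mers seen in more than 100 proteins are ignored as
low-complexity).  At the divergence the similarity filter can accept
(roughly ≥ 50 % identity over a near-full-length alignment), homologous
pairs share dozens of 5-mers, so the prefilter does not change the
retained set — the exact aligner still decides every candidate — while
reducing the quadratic sweep to the candidate list.  `prefilter="none"`
forces the exhaustive sweep; a unit test checks the two modes agree on a
mixed family/background fixture.

Within a multigene family every qualifying pair is kept (no family
collapsing or node weighting); the resulting Ks histograms are therefore
pair-based.

## Codon-aware alignment

Coding sequences are aligned by globally aligning their translations and
back-translating the gapped proteins, so gaps land on codon boundaries
and the frame is preserved.  Inputs must be clean ORFs — in-frame,
stop-free, unambiguous; the I/O layer enforces this and can optionally
drop offending records.  Frameshift- or stop-tolerant alignment is
deliberately out of scope: the intended inputs are predicted gene
models, and columns with a gap in either sequence are excluded from all
site counting downstream (pairwise deletion).

## Ka/Ks estimation

Two estimators are implemented; every output row carries its method tag.

**NG86 (default).**  Nei–Gojobori counting with a Jukes–Cantor
correction.  A position's synonymous-site fraction is the number of
synonymous single-nucleotide changes over the number of changes that do
not create a stop codon, so S + N = 3 × codon columns exactly.  Codon
pairs differing at several positions average their synonymous and
non-synonymous differences over all minimal mutational pathways, with
equal weights; pathways through stop codons are excluded (if every
pathway hits a stop — possible only for rare codon pairs — all pathways
are used with stop steps counted as non-synonymous).  Proportions are
corrected with d = −(3/4)·ln(1 − (4/3)p); p ≥ 3/4 yields an `undefined`
status rather than an exception.  The whole counting layer is verified
exhaustively (all 61 × 61 sense codon pairs) against an independently
written pathway-enumeration oracle.

**LPB_kappa.**  A transition/transversion-aware Li–Pamilo–Bianchi
estimator.  Codon positions are classified by degeneracy (0-, 2-,
4-fold; 3-fold isoleucine sites count as 2-fold; changes to stop codons
count as non-synonymous for classification).  Transitional and
transversional difference proportions per class are corrected with the
Kimura two-parameter model, and

    Ks = (L2·A2 + L4·A4)/(L2 + L4) + B4
    Ka = A0 + (L0·B0 + L2·B2)/(L0 + L2)

where A and B are the K2P transitional and transversional distances per
class.  Kappa (the ts/tv rate ratio α/β) is estimated from third
positions that are fourfold degenerate in both sequences; when fewer
than 10 such sites exist or the K2P logs are undefined, a fixed fallback
of κ = 2 (typical for nuclear genes) is used with a logged warning.
The supplied or estimated kappa also weights the mutational pathways of
multi-hit codons (weight κ per transition step), which is how ambiguous
differences are apportioned between degeneracy classes.  The exact
likelihood formulation of "maximum-likelihood LPB" variants in external
calculators is not reproduced; this estimator is the package's
documented surrogate.

**A normalization caveat users should know.**  NG86 and LPB express
"per synonymous site" in different currencies: NG86 counts fractional
sites (a 2-fold site contributes 1/3 of a synonymous site), while the
LPB assembly estimates the synonymous rate of a fourfold-equivalent
site.  Under transition bias (κ ≈ 2) LPB Ks runs ≈ 10 % below NG86 Ks on
the same data, and LPB omega correspondingly higher.  This is a
between-estimator convention difference, not an error; pipelines should
not mix the two methods within one analysis.  The synthetic-data
generator defines its planted ground truth in NG86 currency (events per
NG86 site), which is why the recovery experiments and the pipeline
default use NG86.

Omega is reported as missing (never 0 or ∞) when Ks is zero or either
rate is unestimable; downstream classification treats missingness
explicitly.

## Ks distributions and mixture dating

Retained pairs with `ok` status and Ks in (0.01, 5.0] form the age
distribution.  The upper bound excludes saturated synonymous sites; the
lower bound (exposed as a flag) drops allelic or essentially identical
artifacts.  Exclusion counts are kept by reason.

Mixtures of Gaussians on ln Ks (log-normal components on Ks) are fitted
by EM: random initialisation from data points, 10 restarts by default,
convergence when the log-likelihood improvement falls below a relative
tolerance of 1e-6, at most 500 iterations.  The implementation asserts
log-likelihood monotonicity and responsibility normalisation at every
iteration.  A component collapsing below σ = 1e-3 aborts the restart
(except for a single component owning all data, a legitimate point
mass, whose scale is floored instead).  The component count is chosen by
BIC over k = 1..5 with 3k − 1 free parameters; the full model table is
part of every report.  Components with weight ≥ 0.05 are reported as
peaks, ascending by median Ks = exp(μ).  Every stochastic call takes an
explicit seed that is recorded in the output.

**What plain mixtures can and cannot say.**  A whole-genome duplication
leaves a burst of similarly aged pairs; the fitted component medians
date those bursts, and the planted-peak recovery experiment (below)
shows the medians are recovered within a few percent.  The *component
count*, however, is not a WGD count: the small-scale-duplication
background is quasi-exponential, which in log space is left-skewed and
decidedly non-Gaussian, so BIC assigns it one or two components of its
own.  In a background-only simulation the selected k is typically 2–3,
not 1 — with ~1300 retained pairs the likelihood gain of a second
component over the skewed background is an order of magnitude larger
than the BIC penalty, for any background rate (the exponential family is
a scale family, so its log-space shape is rate-invariant).  Peak calling
should therefore rest on which components match, not how many exist; an
optional uniform-background component exists behind a flag but is off by
default to keep the default model the plain mixture.

## Ortholog selection scans

1:1:1 ortholog clusters across three species are built from pairwise
reciprocal best hits (unique top local-alignment score in both
directions; ties disqualify) closed into triangles.  For a species pair,
each cluster's omega is computed from the inter-species codon alignment.
Two orientations are offered:

* `symmetric` (default): the single pairwise omega is reported on both
  species axes.  It is the directly measurable quantity but averages the
  two lineages.
* `outgroup`: per-branch rates from the three pairwise distances,
  ka₁ = (ka₁₂ + ka₁ₒ − ka₂ₒ)/2 and likewise for Ks, with a third species
  as outgroup.  This is required to detect species-divergent selection;
  negative or zero apportioned rates yield a missing omega.

Clusters are classified from their two omegas with thresholds that are
flags recorded in every output: positive selection in both species
(both ≥ 1.0), species-divergent (one ≥ 1.0, the other ≤ 0.7 — the 0.7
operationalises "intense purifying selection"; no published cutoff
exists, only exemplar value pairs like 1.7 vs 0.2), conserved in both
(both < 1.0), otherwise mixed; missing omegas give a missing label.
The classifier is a total pure function and species-permutation
equivariant.

A user-supplied genes-of-interest table (reference protein, category —
e.g. immunity, stress response, shell formation) is joined by local
alignment: a cluster is tagged when any member reaches ≥ 80 % similarity
to a reference, the best similarity winning and exact ties resolved by
category name.

## K-mer genome profiling

Canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement under the 2-bit A<C<G<T encoding) are counted with a 1 bp
sliding window, vectorised in memory; k must be odd and within
[11, 31], and windows containing non-ACGT characters are skipped.  The
two-column `depth count` histogram dialect of the common k-mer counters
is read and written, so externally counted spectra from full sequencing
runs drop into the same fit.

The depth histogram is modelled in the GenomeScope tradition: an error
region below the first local minimum of the lightly smoothed histogram
(override by flag); a heterozygous peak at depth λ (per-haplotype
coverage) and a homozygous peak constrained at 2λ, both negative
binomial with a shared dispersion, fitted by weighted least squares; and
a repeat tail above 2.5 × 2λ (flag).  Because the histogram mode may be
either peak (the heterozygous peak overtakes the homozygous one around
r ≈ 2–3 % at k = 17), both placements are fitted and the lower-cost one
wins, with near-ties (within 5 % plus a small absolute slack for
exact-fit cases) resolved toward the lower-heterozygosity reading.
With fitted distinct-k-mer areas a (het) and b (hom):

    genome size      = Σ depth·count (non-error bins) / (2λ)
    het fraction f   = a / (a + 2b),   r = 1 − (1 − f)^(1/k)
    repeat fraction  = mass above 2.5·2λ / non-error mass

The f ↔ r relation follows because a k-mer is homozygous exactly when it
spans no heterozygous site, probability (1 − r)^k, and each heterozygous
column contributes two haplotype-private k-mers.  Genome size includes
repeats (their extra copies add mass proportionally).  When two k values
are surveyed (the conventional 17 and 23), the per-k profiles are
reported side by side, never averaged — the two can legitimately
disagree, as the error- and repeat-sensitivity of the spectrum changes
with k.

## Synthetic data

The generator produces every input the pipelines consume, as pure
functions of a scenario (seed included); truth tables accompany all
outputs and suffice to score every downstream stage.

**Forward codon evolution.**  Point mutations are proposed uniformly
over sites with within-site weights κ for the transition and 1 per
transversion (every site's total proposal rate is then equal, so uniform
position choice is exact).  Stop-codon mutants are always rejected;
synonymous changes accept with probability 1/max(1, ω) and
non-synonymous with ω/max(1, ω).  Each branch carries two Poisson event
quotas — synonymous with mean (Ks/2)·S and non-synonymous with mean
ω·(Ks/2)·N, where S and N are the ancestor's NG86 site counts — and
evolves until both are met, the classes interleaving at the ω-paced
acceptance rates.  The planted Ks and ω are therefore realised event
counts per site, exact in NG86 currency by construction.  Above Ks ≈ 3
repeated hits make any counting-based ground truth soft; such pairs fall
beyond the analysis truncation anyway.  This is an accept/reject scheme,
not a full codon rate-matrix simulation: it controls the quantities the
estimators measure at a fraction of the machinery.

**Paranome scenario.**  Pair ages mix an exponential
small-scale-duplication background (rate 1.0 — young duplicates
dominate, as in real paranomes) with log-normal WGD bursts; the defaults
plant two bursts of 800 pairs (ln-scale σ = 0.25) at median Ks 0.6132
and 1.8196 over 1500 background pairs, 300 codons per gene (a typical
CDS), ω = 0.1 (retained duplicates evolve under strong purifying
selection) and κ = 2.  Burst ages are drawn log-normally — the same
family the mixture fits — so median recovery is a well-posed
parameter-recovery experiment.

**Ortholog scenario.**  Each cluster descends from a random ancestor:
species 1 and 2 sit Ks/2 from the ancestor (default total divergence
0.3, appropriate for congeneric species and small enough that estimator
saturation does not erode the planted regimes), the outgroup species
sits a further branch of the same total length away under ω = 0.2.
Regimes default to equal thirds of (0.2, 0.2), (1.5, 1.5) and
(1.5, 0.2) at 500 codons, apportioned by largest remainder and shuffled.

**Sequencing scenario.**  Haplotype 1 is uniform random sequence,
optionally with a tail segment repeated `repeat_copy_number` times to
occupy `repeat_fraction` of the genome; haplotype 2 differs at the
heterozygosity rate.  Reads of fixed length are drawn uniformly from
both haplotypes with per-base substitution errors (default 0.2 %,
Illumina-like).  Defaults: 1 Mb, r = 1 %, 40× total coverage, 150 bp
reads.  FASTQ output is byte-identical for a fixed scenario.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: gene structure (introns, UTRs, isoforms),
codon-usage and GC bias, rate variation across sites and genes, gene
conversion between duplicates, indel evolution inside the simulated
pairs, non-uniform read coverage and quality profiles, and sequencing
of genomes with gigabase-scale repeat landscapes.  Recovery results
certify the estimators and fits under their own model assumptions, not
performance on any particular real genome.

## Problem sizes and determinism

The recovery experiments run at the scale the analyses are designed
for: paranomes of ~3,100 pairs (6,200 genes × 300 codons), 200 ortholog
clusters × 500 codons, and 1 Mb diploid genomes at 40×; 20 seeded
replicates for the dating experiments and 10 for the genome survey.
EM restarts are reduced from 10 to 5 inside the replicated experiments
(the likelihood surface at these sample sizes is benign; single-fit
results are unchanged).  All randomness flows from explicit seeds;
reruns are bit-reproducible, and every pipeline writes a manifest
echoing its parameters and seeds.

## Known limitations

* The MLPB-style estimator is a surrogate (see above), and its Ks
  normalization differs from NG86's by design.
* Plain BIC mixtures over-segment quasi-exponential backgrounds; the
  component count is not a WGD count (see the dating section).
* The symmetric selection-scan orientation cannot detect
  species-divergent selection; use the outgroup orientation when a third
  species is available.
* Counting-based Ka/Ks saturates: estimates above Ks ≈ 3 are
  increasingly biased and pairs beyond 5 are excluded outright.
* In-memory k-mer counting is for desk-scale inputs; count full
  sequencing runs externally and import the histogram.
* No statistical test of peak "compatibility" across species is
  offered; peak tables are reported side by side only.
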