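# Methods

## Signal model and orientation

Direct RNA sequencing reads translocate 3′→5′, so an event aligner
reports each reference 5-mer (written 5′→3′) with its raw current
samples in 3′→5′ order. Track assembly therefore reverses every
per-position sample list before anything downstream sees it; all
vectors in the package are 5′→3′. When an aligner emits several rows
for one (read, position) — re-segmentation artifacts — their sample
lists are concatenated in row order before the flip, which preserves
every raw sample. Rows whose reference 5-mer contains characters
outside ACGT are dropped with a logged count, because the pore-model
lookup is undefined for them. Serialized floats carry six decimals, so
write→read round-trips are exact at that precision and repeated writes
are byte-identical.

## Per-read features

A candidate site is an A (m6A mode) or C (m5C mode) at the centre of a
9-mer; the five overlapping 5-mers starting at offsets −4…0 from the
centre all carry its signal. Each 5-mer's variable-dwell sample list is
compressed to 20 order-preserving segment medians: with n ≥ 20 samples
the boundaries sit at ⌊i·n/20⌋ (deterministic near-equal partition; the
median of an even segment is the mean of the two central values); with
n < 20 the original values are kept and padded to 20 with copies of
their overall median. Candidates inside base runs (AA, AAA…) each get
their own window; windows missing any of the five 5-mers (read ends)
are skipped. The classifier input is the 100-length observed vector
paired with the elementwise absolute distance to the pore-model
expectation (each 5-mer level repeated 20×), as two channels. The
sequence itself is never an input, which keeps the model abstracted
from sequence context.

## Per-read classifier

A compact residual 1-D CNN: a stem convolution (kernel 7) with batch
normalisation and ReLU, followed by configurable residual blocks
(conv–BN–ReLU–conv–BN plus identity or 1×1-projected skip, kernel 5),
global average pooling and a sigmoid head. Default width is 16 channels
per block; the engine (convolutions, batch-norm, backpropagation,
AMSGrad) is implemented in NumPy and is fully deterministic given the
construction seed and data order. Training minimises binary
cross-entropy reported in bits, −(1/N)Σ[y log₂ p + (1−y) log₂(1−p)],
with probabilities clamped at 1e-7 in the metric; the training gradient
is computed from logits, which is algebraically equivalent and
numerically safe. Validation metrics (accuracy, precision, recall, AUC
by the rank statistic, loss) are recorded every `eval_every` examples
and the best-validation-loss parameters are restored at the end.
Defaults: 10 epochs, AMSGrad at learning rate 1e-4, batch 64,
`eval_every` 200 000. The desk-scale configuration used by the tests
and the acceptance script shrinks this to 12-channel blocks, 4 epochs,
learning rate 1e-3 and `eval_every` 2000 — chosen as the smallest
schedule that saturates on the generator's default conditions. Class
balance is enforced by constructing balanced training data rather than
by loss weighting.

Read-level calls use a double cutoff: probability > 0.7 is modified,
< 0.3 unmodified, and the closed band [0.3, 0.7] is discarded as
unreliable; under a uniform probability distribution this retains 60%
of reads (the observed retention on real data depends on how
concentrated the probabilities are).

## Site classifier and stoichiometry

The site model classifies the distribution of per-read probabilities at
a transcript position. The distribution is encoded as a length-100
sorted-quantile vector (inverted-CDF quantiles at levels (i+0.5)/100),
which is invariant to read order and to duplication of the whole read
multiset — so pooling replicates is exactly concatenation of their read
sets. A 20-bin histogram encoding would be a reasonable alternative;
quantiles were chosen because they normalise coverage without binning
loss. The network is the same CNN family with one input channel.

Training sites are controlled mixtures from pools of per-read
probabilities of known state (never reads used to train the read
model): a site is modified with probability 0.5; coverage (1–100) and,
if modified, stoichiometry (1–100%) are drawn with linearly decaying
weights (10 − v)·0.01 + 0.9 = 1 − 0.01·v, clamped at zero, so
low-coverage and low-stoichiometry sites dominate as they do in real
transcriptomes; a modified site receives round(stoichiometry × coverage)
modified-pool reads. The split is 9:1 train/test. About 6–7% of
"modified" training sites receive zero modified reads by construction
(very low stoichiometry × coverage); they are kept, as honest label
noise, and bound the attainable site-level AUC slightly below 1.

Stoichiometry is not regressed: it is n_mod / (n_mod + n_unmod) under
the double cutoff, with discarded reads excluded from both counts, and
is reported as missing when every read is discarded.

## Transcriptome-scale calling and FDR

The site model only runs on positions with more than 20 reads
(coverage ≥ 21, strict inequality). A site is significant when its
probability strictly exceeds the cutoff (default 0.9999). The cutoff is
calibrated by shuffling all per-read probabilities across tested sites
while preserving the site count and each site's coverage, re-running
the site model, and taking the fraction of shuffled sites passing each
cutoff as the FDR estimate; the shuffling unit is the per-read
probability rather than the raw signal, which is equivalent because the
site model's input is exactly the probability multiset. Ten shuffling
rounds are averaged by default. The enrichment test for an external
candidate list counts high-probability (> 0.99) candidates and compares
against 1000 equally sized random draws from the tested sites, with the
+1-corrected empirical p-value (1 + #{rounds ≥ observed}) / (rounds + 1),
so p is never exactly zero.

## Differential methylation

Sites with > 20 reads in both conditions and an absolute stoichiometry
difference ≥ 0.1 (double-cutoff estimates) are tested with a two-tailed
Mann–Whitney U-test on the per-read probabilities: exact enumeration
when min(n_A, n_B) ≤ 8 with no ties, otherwise the normal approximation
with mid-ranks and tie-corrected variance (probabilities cluster near 0
and 1, so ties are common). A perfectly central statistic
(U = n_A·n_B/2, e.g. identical samples) reports p = 1.
Benjamini–Hochberg runs over exactly the tested set — the stoichiometry
filter is part of the procedure, applied before testing — and
significance is adjusted p ≤ α.

## Co-occurrence

For two sites on one transcript, reads covering both are labelled by
the double cutoff; reads discarded at either site are dropped from both
numerator and denominator (the same denominator convention as
stoichiometry). Co-occurrence is the fraction of retained reads with
equal states; both-unmodified molecules count as co-occurring. Distance
is the difference of centre-base positions, with orientation recorded
(A-upstream vs C-upstream). Two nulls: per-site independent
permutation of the state vectors (preserves marginals exactly; for
independent sites with modified fractions p, q the null mean converges
to pq + (1−p)(1−q)), and random pairs of modified sites from different
transcripts, aligned by random index after truncation to the smaller
coverage, which preserves each site's state composition while
destroying molecular linkage. The distance-stratified test compares
observed per-pair co-occurrences with pooled permutation nulls by a
one-sided (greater) Mann–Whitney test per (orientation, distance ∈
1–15 nt) bucket. The transcript-level test partitions transcripts with
at least two tested sites into both/one/none categories — cross-type
site pairs closer than 5 nt are mutually discarded first, since
adjacent modifications interfere with each other's signal — and applies
a two-tailed Fisher exact test; rRNA contigs can be excluded by a
deny-list.

## Synthetic data generator

The generator stands in for in-vitro transcribed (IVT) ground-truth
material. Per reference 5-mer it draws a dwell of
`dwell_min + Poisson(dwell_mean − dwell_min)` raw samples (default mean
8, minimum 2 — an overdispersed positive law reproducing the variable
number of samples per 5-mer) and Gaussian noise (default 2 pA) around
the pore-model level. A modified base adds a per-offset level shift to
each of the five 5-mers overlapping it (default 4 pA at every offset);
the shift acts on the 5-mer mean, matching the level-shift abstraction
of pore physics. Per-read site states are Bernoulli with the configured
stoichiometry; designated pairs are coupled through a Gaussian copula
whose latent correlation is solved by bisection to reach the target
state correlation, with Fréchet-bound infeasibility reported as an
error. Events are serialized 3′→5′ per 5-mer, exactly as an event
aligner would emit them. Pore-model levels are drawn uniformly in
80–130 pA.

What the generator does *not* emulate: sequence-dependent noise
heterogeneity, dwell–sequence coupling, alignment and segmentation
errors, pore-to-pore drift, other modification types with their own
signatures, and multiple modified bases inside one 9-mer. Passing tests
therefore demonstrate that the machinery is correct and calibrated
under its stated signal model — a 4 pA shift at 2 pA noise is
deliberately well-separated — not that the default-trained models
transfer to real flow-cell data, which requires training on real IVT
material.

## Numerical and design choices

- Coordinates are 0-based 5-mer start positions; the centre of a 9-mer
  at position p uses the five 5-mers starting at p−4 … p.
- The quantile encoding uses the inverted CDF (not interpolation)
  precisely so that replicate pooling is exact concatenation.
- The mixture-weight formula goes negative above coverage 100; weights
  are clamped at 0 and coverage capped at 100.
- Empirical permutation p-values always carry the +1 correction.
- Batch-norm inference uses running statistics (momentum 0.1); training
  and prediction are deterministic at fixed thread count.
- Desk-scale problem sizes (tests and acceptance script): 40 training
  transcripts × 60 reads for the read model, 3000 mixture sites for the
  site model, 5–10 seeds × ~30 sites for the null calibrations, 200
  reads × 1000 permutations for the co-occurrence null. These sizes were
  chosen as the smallest at which the statistical checks have adequate
  power.

## Known limitations

- The exact site-level input encoding and the exact convolutional
  topology are this package's own design within the stated family; a
  desk-scale network cannot be expected to reproduce accuracies
  reported for large trained models on real data.
- Positional isomers (e.g. m1A vs m6A) shift the signal similarly and
  are not separable by this signal model.
- Sites closer than ~5 nt interfere through the shared 9-mer window
  (visible in the README example); site-level significance largely
  suppresses the bleed, but read-level probabilities at adjacent
  positions are inflated.
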