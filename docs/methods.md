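# Methods

## Problem and model

Absence of heterozygosity (AOH) is a long contiguous run of homozygous
alleles, typically arising from uniparental isodisomy, parental
consanguinity or complex rearrangement. At ultra-low sequencing depth
(0.05–1×) almost no site is covered twice, so genotype- or B-allele-based
detectors fail. `aohscan` instead asks, for each small genomic bin, whether
the few reads it contains look like draws from **one** latent haplotype or
**two**, using the joint haplotype frequencies of a phased population
reference panel as the prior over local haplotypes.

### Ploidy likelihood ratio

Let a bin contain reads r = 1..R, each observing alleles at a few panel
SNPs, and let the panel, restricted to those SNPs, collapse to distinct
allele patterns j with frequencies f_j. With per-base error ε, the emission
probability of read r from pattern j is

    e(r, j) = Π_sites (1−ε if observed allele matches pattern else ε).

The two hypotheses are:

* haploid (AOH-like): one latent haplotype drawn from the panel generated
  all reads — `L_hap = Σ_j f_j Π_r e(r, j)`;
* diploid: two latent haplotypes drawn independently; each read comes from
  one of them with probability ½ —
  `L_dip = Σ_j Σ_k f_j f_k Π_r [e(r,j) + e(r,k)] / 2`.

The statistic is `LLR = ln L_hap − ln L_dip` (natural log). Two identities
anchor the implementation and are enforced in tests: a single read carries
no information (`LLR = 0` exactly, because Σ_k f_k = 1 factors out), and
ε = ½ makes every read uninformative. Pattern collapsing is exact, not an
approximation: pattern frequencies are summed haplotype weights, so the
collapsed sums equal the full sums over all H haplotypes; the test suite
verifies this to 1e-12 against brute-force nested summation.

### Per-SNP anchoring and bin features

One LLR is computed per observed SNP ("anchor"): the read set is every read
covering the anchor plus the nearest other SNP-bearing reads in the same
10 kb bin (distance of their leftmost SNP to the anchor, read-name
tie-break), capped at `max_reads_per_anchor` (default 12) reads. The bin
feature is the mean and the population variance (divisor n) of its anchor
LLRs. At ultra-low depth most bins hold fewer reads than the cap, so all
anchors share one read set and one LLR — the variance is then genuinely 0.
Bins with fewer than `min_reads_per_bin` (default 2) SNP-bearing reads are
invalid ("no data"): a single read is provably uninformative here, so
nothing is lost. An alternative resampling mode (D random read subsets per
bin) is available behind `EmissionConfig.resample_draws` for sensitivity
analysis; it is off by default.

### Windows and classification

Valid bins form a sequence per chromosome; a sliding window takes exactly N
consecutive valid bins (skipping invalid ones so every window is full),
advancing one valid bin per step. N follows the depth tier: 100 bins below
0.25× (the midpoint between the tested 0.1× and 0.5× tiers), else 250. The
window's checkpoint is the midpoint of its central valid bin (offset
⌊N/2⌋); its label is half-open membership of the checkpoint in a truth
interval.

The classifier over the 2×N feature matrix (per-bin LLR mean; per-bin LLR
variance) is a bidirectional GRU:

    Z_t = σ(W_xz X_t + W_hz H_{t−1} + b_z)
    R_t = σ(W_xr X_t + W_hr H_{t−1} + b_r)
    N_t = tanh(W_xn X_t + W_hn (R_t ⊗ H_{t−1}) + b_n)
    H_t = (1 − Z_t) ⊗ N_t + Z_t ⊗ H_{t−1}

run forward and backward with independent parameters and merged by
concatenation, followed by single-head scaled dot-product self-attention
over the merged states, mean-pooling, a 64-neuron tanh dense layer and a
logistic output: the probability that the checkpoint lies in an AOH region.
The network, backpropagation (through time and attention) and the Adam
optimiser are implemented directly in numpy; the analytic gradients are
checked against central finite differences in the test suite, and the GRU
cell against an independent scalar transcription of the four equations.

Training minimises binary cross-entropy for at most 300 epochs with early
stopping once training accuracy reaches 99.5%, returning the checkpoint
with the best observed training accuracy. Features are z-scored per channel
with statistics frozen from the training set. Everything is seeded:
initialisation, shuffling, subsampling.

### Calling

Checkpoint probabilities become regions by taking maximal runs strictly
above 0.6 (probability exactly 0.6 does not call), anchored at the central
bins of the run's first and last checkpoints; runs separated by at most
500 kb are merged; assembly-gap (N-region) intervals are subtracted after
merging, splitting calls they interrupt; fragments under 1 Mb are dropped.
Calls of at least 10 Mb carry a "reportable" flag, the conventional
threshold for raising uniparental disomy. Scoring uses the
coverage-of-truth rule: a truth region counts as detected when calls cover
at least 50% of its length; calls touching no truth are "additional".

### Gaussian-HMM baseline

For comparison, a 5-state hidden Markov model with full-covariance Gaussian
emissions (hmmlearn) is fit, unsupervised, to the genome-ordered sequence
of per-checkpoint 2-vectors (window mean of bin LLR means, window mean of
bin LLR variances). The state whose emission mean has the largest LLR-mean
component is taken as the AOH state; its posterior is thresholded by the
same caller. Degenerate covariance triggers one jittered retry.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| bin size | 10 kb | LLR aggregation unit |
| ε (emission error) | 0.002 | typical sequencer substitution rate; the source method states no value |
| max reads per anchor | 12 | caps read count (never truncates a read's own observations) |
| min reads per bin | 2 | one read is provably uninformative |
| N (window bins) | 100 / 250 | depth tier, cutover 0.25× |
| threshold | 0.6 | strict inequality on checkpoint probability |
| merge gap | 500 kb | quantifies "adjacent" candidate merging |
| min call size | 1 Mb | calling floor; 10 Mb flags "reportable" |
| concordance overlap | 50% | detection rule against truth intervals |
| GRU hidden width | 32 | free choice (only the 64-unit dense head is fixed); 32 keeps desk-scale training cheap with no measured loss of recovery |
| Adam lr / batch | 0.01 / 128 | chosen for convergence speed on the synthetic benchmark |

## Synthetic generator

The generator emulates the study regime on one chromosome: a panel of H
haplotypes (default 60) built from K founders (default 12) whose allele
frequencies are Beta(0.5, 0.5) truncated to [0.02, 0.98] at 2 SNPs/kb, the
remaining H−K haplotypes Li–Stephens copies of founders with a per-bp
switch rate of 1e-5 (≈ the 4Ne·r/H copying rate for Ne = 1e4, r = 1e-8)
and per-site copying mismatch 1e-4 — giving block LD on the 10 kb scale the
likelihood needs. Individuals draw two panel haplotypes; inside implanted
intervals the second haplotype is overwritten by the first (iso-disomy:
exactly zero heterozygous panel sites inside; outside, heterozygosity
matches panel expectation). Reads are uniform 35 bp single-end at the
requested fold-coverage; each comes from either haplotype with probability
½ and flips each observed allele with probability ε_seq = 0.002.

What it does **not** model: mosaic AOH, heterodisomy with recombination
interspersion, X-chromosome hemizygosity, non-uniform coverage (GC bias,
mappability), duplicates, indels, alignment error, panel/sample ancestry
mismatch, and the SNP density of real population panels (tens of thousands
of sites per Mb; the default 2/kb keeps desk-scale runs minutes long). Passing the benchmark therefore shows
that the method recovers iso-disomic tracts under idealized sparse
sampling with realistic LD — not that it matches the operating
characteristics reported on real cohorts.

## Benchmark problem sizes

The reference benchmark (`aohscan.benchmark.run_full_benchmark`, also used
by `scripts/acceptance.py`) uses: 100 Mb chromosome, 60-haplotype panel at
2 SNPs/kb, 8 training + 8 test individuals each with one 10–20 Mb tract,
0.1× depth, N = 100, training pool subsampled to at most 3000 windows
(balanced: all positives kept, negatives filled in, seeded). The depth
trend re-sequences the first 3 test individuals at 0.05× and 0.5× with
three read seeds each, reusing the 0.1×-trained model (windows are built
over valid bins, so the same N applies across depths). These sizes are the
package's reference configuration; all are arguments.

## Numerical and design choices

* Natural log for LLR; population variance (divisor n) for bin variance —
  fixed for reproducibility where the source method is silent.
* The likelihood formulas are the standard one-vs-two latent haplotype
  formalization of "reads from the same haplotype are likelier under fewer
  haplotypes"; the emission model is the symmetric ε-error channel.
* "Uniquely aligned" is proxied by MAPQ ≥ 30 (configurable); "quality
  value of more than 20 per base" is operationalized as mean base quality
  > 20 plus a per-site check at each used SNP (strict per-base mode
  available); N-base fraction ≤ 5%. Adapter content is assumed trimmed.
* Down-sampling is Bernoulli per read (whole reads kept or dropped
  together); an exact-count mode exists.
* Panel positions are 1-based (VCF convention); every other interval is
  0-based half-open; conversion only at I/O boundaries.
* Sites with missing or unphased genotypes are dropped, not imputed.
* Haplotype weights are uniform empirical panel proportions (no
  shrinkage); subsetting renormalizes.
* Attention is placed after the BGRU (simplest faithful reading of
  "self-attention over the matrix"); merge = concatenation.
* The HMM state→AOH mapping (largest LLR-mean emission) is a deliberate
  simple rule; with five states the AOH regime may be shared among states,
  which depresses the baseline — the comparison uses identical windows and
  caller for both methods.
* Checkpoint-to-region anchoring uses central bins, not full window spans:
  windows overlap heavily, and central bins make the caller's geometry
  independent of N.
* Region endpoints, merging and masking are closed under the half-open,
  sorted, non-overlapping convention; `merge_and_mask` is idempotent.

## Known limitations

* Mosaic AOH is out of scope (a fractional-haploid mixture model would be
  required).
* The per-anchor read-set rule is a documented choice; the source method
  does not state which reads enter each SNP's LLR.
* Sensitivity at a given depth depends strongly on panel SNP density and
  LD scale; desk-scale defaults are sparser than real panels.
* hmmlearn's EM may oscillate on near-degenerate sequences (it logs
  convergence warnings); the baseline uses a fixed iteration cap and seed.
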