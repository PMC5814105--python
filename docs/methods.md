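# Methods

## Model

Each chromosome is binned at a fixed size (default 10 kbp) and every bin
carries a spin σ_k ∈ {−1, +1}: +1 for active/euchromatic chromatin, −1 for
inactive/heterochromatic. For a pair of bins (i, j) at separation
d = j − i the *sequence neighborhood* **σ** is the ordered spin vector of
the W bins windowed around each site (W = 10 by default): positions
i−(W/2−1) … i+W/2 around i and the mirror j−W/2 … j+(W/2−1) around j. For
d ≤ W the two windows merge into one contiguous stretch of N = d + W − 1
bins; for d > W the neighborhood is the disjoint union with N = 2W. With
W = 10 this gives N = d + 9 at short range and N = 20 otherwise.

At every distance two conditional distributions over neighborhoods are
modelled: P(σ | c, d), the distribution of neighborhoods *given* that
their pair is in contact, and the background P(σ | d) irrespective of
contact. Both are maximum-entropy distributions constrained to first and
second spin moments, i.e. Ising models at kT = 1 with fields h_k and
pairwise couplings J_kl. By Bayes' rule their ratio equals the
distance-normalized contact probability P(c|σ,d)/P(c|d), which is the
quantity compared with observed-over-expected Hi-C counts n_ij/⟨n(d)⟩.

## Ensembles and fitting

Ensembles are built by scrolling all pairs (i, i+d) within the chosen
regions. A neighborhood is skipped entirely if it leaves the chromosome or
touches a bin with no state annotation — padding would inject fabricated
states into the fitted moments. Contact-conditioned ensembles weight each
neighborhood by its pair's count n_ij (real-valued weights are accepted,
e.g. after ICE); background ensembles use unit weights. Every accepted
vector is also added mirror-reversed with the same weight, since genomic
orientation cannot influence contact formation; this forces exactly
palindromic moments, and therefore palindromic fitted parameters.

Fitting is plain Boltzmann learning: enumerate all 2^N states, compute
model moments, step h_k by α(⟨σ_k⟩_data − ⟨σ_k⟩_model) and J_kl likewise,
until *every* constrained moment is within ε. Defaults α = 0.025 and
ε = 1e-4. The objective is convex, so the solution is unique and the
initialization (uniform in ±0.1, seeded) affects only the iteration count;
the seed is recorded in the model bank. The convergence check is the
max-norm over constraints, equivalent to the per-constraint criterion.
`max_iter` defaults to 50000 plain gradient steps — no acceleration, for
simplicity and an exact correspondence with the published scheme.
Enumeration is capped at N = 20 by default (hard cap 23); the state table
and pair-product table are cached per N so repeated fits never
re-allocate them. Neighborhood-size note: one description of the
construction puts the contiguous/split boundary at d < 12, but with W = 10
the windows overlap only for d ≤ 10, so the geometric rule "contiguous iff
d ≤ W" is used.

First-order (fields-only) models are available for comparison; on
correlated data they cannot reproduce pairwise statistics, which the test
suite demonstrates quantitatively.

## Contact maps

Input maps are intra-chromosomal COO TSV counts; mirrored duplicates are
summed into the upper triangle. ICE balancing is implemented as sequential
row-sum equalization — divide n_ij by b_i b_j with b_i the row sum over
its mean, iterate to tolerance (default 1e-5, 200 iterations), leave empty
rows zero and restore the mean row sum at the end. This is deliberately
the simple row-equalization variant, not the published variance-stabilized
algorithm. One practical caveat: row balancing is diffusion-like, so on
maps whose populated band is narrow relative to the matrix (e.g. only
d ≤ 15 of a 20000-bin chromosome) it converges impractically slowly. It is
intended for maps with full distance coverage, where the band is a sizable
fraction of the matrix; the acceptance script therefore measures it on a
300-bin map with a d ≤ 15 band.

The distance profile ⟨n(d)⟩ and ζ²(d) are the mean and population variance
of counts over *all* eligible pairs at separation d (zero counts included
as observations), pooled over sequences. The profile is computed over the
whole chromosome by default; restricting it to training regions changes it
negligibly for the synthetic genomes used here and is configurable.

## Forward prediction and mutation scan

Predicted ratios are computed in the log domain: the energy difference
Σ Δh_k σ_k + Σ ΔJ_kl σ_k σ_l plus the log-partition-function difference,
cached per distance. Correlations with experiment are pooled over all
pairs and distances by default (per-distance correlations are exposed as
an option, since either pooling convention is defensible). The mutation
scan selects sites whose *local* contact map — the pairs whose
neighborhood contains the site — correlates with experiment above a
threshold (default c > 0.6), flips the site's spin, recomputes only the
affected pairs, and reports Δc = c′ − c on the same pair set. The caller's
state vector is never modified. Sites are assigned to non-overlapping
categories promoter > gene body > no gene from BED annotations.

## Inverse inference

The posterior of one site's state given all counts multiplies, over the M
pairs whose neighborhood contains the site, the marginal
Σ_{σ: σ_k′ = s} P(n_ij | σ, d) P(σ | d), and corrects for the M-fold
over-counting of the prior with the exponent (1 − M). The count likelihood
is Gaussian with mean λ_{σ,d} = ⟨n(d)⟩ · P(c|σ,d)/P(c|d) — normalized so
the background-average of λ is exactly ⟨n(d)⟩ — and variance either pooled
per distance from the data (default) or set to λ (Poisson-matched); a
floor of 1e-6 keeps it positive. All accumulation is in the log domain
with per-pair log-sum-exp, so underflow cannot occur. Each pair's
2^N-state sum is shared among its N sites, which makes whole-chromosome
inference one (pairs × 2^N) table per distance; the default demonstrations
use W = 4 (N ≤ 8), where this is seconds per chromosome, while W = 10 is
supported but much heavier. Posterior ties (p = 0.5) call +1 at the
default threshold, documented as the ≥ rule. The prior defaults to flat;
supplying the genome-wide spin-up frequency is recommended and is what the
pipeline commands do when truth/training states are available. Note the
consistency requirement: when contact and background models coincide the
posterior reduces to the prior only if the prior equals the background's
single-site marginal — a self-consistency the planted generator satisfies
by construction.

## Synthetic data

The generator emulates both experimental inputs under exactly the model's
assumptions. The chromatin track is a stationary two-state Markov chain
with persistence probability 0.9 (geometric domains, mean run ≈ 10 bins ≈
100 kbp, a realistic chromatin-domain scale). The planted background model
at each distance is the *exact* marginal of that chain on the neighborhood
positions: restricting a Markov chain to an ordered subset of sites yields
a nearest-neighbour Ising chain with coupling atanh((2p−1)^g) across each
genomic gap g. The planted contact model adds fields +0.6 at the two
contacting positions and ±0.2 couplings on consecutive interior positions,
ferromagnetic below d* = 8 bins and antiferromagnetic above — a sign
transition with distance mirroring what fitted parameters show on real
data. Counts are Poisson with mean ⟨n(d)⟩ · ratio(σ) under a power-law
depth profile ⟨n(d)⟩ = depth · d^−0.75, depth 100 by default. Poisson
generation (not Gaussian) keeps counts non-negative integers as in real
Hi-C, so the inverse module's Gaussian likelihood is exercised under mild,
realistic model mismatch.

Because the background matches the true sequence law, the count-weighted
ensemble converges in depth to the planted contact distribution, making
end-to-end parameter recovery well-posed. What the generator does *not*
emulate: polymer physics (no excluded volume, no loop extrusion), mapping
biases, unmappable regions, inter-chromosomal contacts, or disagreement
between the cell populations assayed for states and for contacts. Passing
tests therefore demonstrate correctness of the inference machinery, not
that real genomes satisfy the model's assumptions.

## Problem sizes and test design

The acceptance-level checks run on a 20000-bin chromosome with W = 4,
d = 1..15 and depth 100 — models of N ≤ 8 spins, where exact enumeration
makes whole-pipeline runs take a couple of minutes; W = 10/N = 20 behaves
identically in structure but each fit enumerates 2^20 states. Sampled-
ensemble recovery uses 2·10^5 draws (moment standard errors ≈ 0.002,
recovered-parameter RMSE ≈ 0.005–0.03). The held-out forward correlation
against the generative ratios exceeds 0.99, against the noisy simulated
counts ≈ 0.97; inverse agreement is ≈ 94% at depth 100, degrading with
depth toward the prior. These are computed fresh by `tests/` and
`scripts/acceptance.py` on every run.

## Known limitations

* Exact enumeration limits neighborhoods to ~20–23 spins; no Monte Carlo
  fallback is provided (out of scope by design).
* The learning rate is fixed; very strongly correlated targets (|C| → 1)
  converge slowly and boundary moments (|m| = 1) are rejected as
  unrealizable rather than fitted with infinite fields.
* ICE here is row-sum equalization only, and is ill-conditioned on
  narrow-band maps (above).
* The inverse posterior is per-site marginal with the (1 − M) prior
  correction — not a joint MAP over the whole sequence.
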