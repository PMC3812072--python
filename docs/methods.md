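# Methods

## The biological model

Fission yeast (*Schizosaccharomyces pombe*) switches mating type by gene
conversion of the expressed *mat1* locus, using one of two
heterochromatic donor cassettes: *mat2* and *mat3*.  Switching is
replication-coupled: a strand-specific imprint deposited during
lagging-strand synthesis marks a cell as *switchable*; at the next
division, leading-strand replication through the imprinted *mat1*
generates a one-ended recombinogenic break that is healed by copying a
donor cassette.  Two structural rules follow directly from strand
segregation and are reproduced exactly by the package's division rules:

* **one-in-four** — exactly one of the four granddaughters of a newly
  switched (unimprinted) cell switches;
* **recurrent switching** — the switchable lineage switches at every
  division.

Donor choice is directional.  Two portable cis-acting recombination
enhancers, SRE2 (next to *mat2*) and SRE3 (next to *mat3*), promote the
use of their adjacent cassette; P cells mostly engage SRE3 and M cells
mostly SRE2, with the bias set by cell-type-specific chromatin (more
Swi6/Swi2 across the region in M cells).  The package's **competition
model** encodes this as a weight table
`w[enhancer][cell type][chromatin]`; the probability that the
mat2-adjacent enhancer captures the break is `w2/(w2+w3)`.  A conversion
attempt only changes the mating type when the chosen cassette's content
differs from the cell's (heterologous conversion); a homologous choice
is a futile cycle.  The per-division switching rate of an imprinted
cell's leading daughter is therefore

    h_X = s_eff * sum over slots p(slot) * [slot heterologous for X]

with `s_eff` the compound probability that an attempt completes.

The **2004 spreading model** is implemented as an alternative variant
for model discrimination: the Swi2/Swi5 recombination-promoting complex
(RPC) nucleates at SRE3, stays there in P cells (preferring the
SRE3-adjacent slot) and spreads to *mat2* via Swi6 in M cells
(preferring *mat2*); when SRE3 or RPC is absent, *mat2* is preferred by
default.  The rule's preferred donor is taken with probability `q`.
The published description of this rule does not cover one genotype
combination (M cells, Swi6 absent, SRE3 and RPC present); we resolve it
by the model's own logic — spreading requires Swi6, so RPC remains at
SRE3 and the SRE3 slot is preferred, as in P cells.

## Parameters, defaults, units

| parameter | default | meaning |
|---|---|---|
| `w[SRE2][P][swi6+]` (= e_P) | 0.2 | P cells engage SRE2 ("wrong" enhancer) in 20% of attempts |
| `w[SRE3][P][swi6+]` | 0.8 | complement of e_P |
| `w[SRE3][M][swi6+]` (= e_M) | 0.1 | M cells engage SRE3 in 10% of attempts |
| `w[SRE2][M][swi6+]` | 0.9 | complement of e_M |
| `w[SRE3][*][swi6Δ]` / `w[SRE2][*][swi6Δ]` | 0.85 / 0.15 | **calibrated constants**, chosen so wild-type architecture without Swi6 settles near 15% P (the observed strong M bias); not measured |
| `w[NONE][*][*]` | 0.02 | invented residual activity of an enhancer-less slot: deletion strains still switch, very inefficiently |
| `attempt_success` (s) | 0.85 | probability an imprinted division completes a conversion; places compound switching in the observed 80–90% band |
| `rpc_loss_success` | 0.02 | replaces s in swi2Δ/swi5Δ genotypes; RPC loss cripples, but does not abolish, conversion |
| `imprint_efficiency` (β) | 1.0 | lagging-strand imprinting probability; directional efficiency is carried by s |
| `spreading_preference` (q) | 0.9 | 2004-rule preference strength (invented; no published value exists) |

All are dimensionless probabilities or relative weights.  The 20%/10%
error rates are interpreted as *per attempted switch*, with attempt
success s applied separately.

## The analytic oracle

Following a uniformly random daughter at each division yields a 4-state
Markov chain over (allele × imprint): from `Xu` the lineage imprints
with probability β/2; from `Xs` it switches allele with probability
`h_X/2`.  Under neutral synchronous growth the population's expected
composition follows this chain.  With both rates positive the
stationary P fraction has the closed form

    fraction_P = h_M / (h_M + h_P)

independent of β and s (both scale the two fluxes equally); the
implementation computes the stationary vector from the linear system
and asserts agreement with the closed form to 1e-10 on every call.  The
stationary switchable (imprinted) fraction is β/2 — with β=1, half of
all dividing cells, reproducing the "every other cell" switching
frequency.  One-way switching gives an absorbing composition; no
switching leaves the composition founder-dependent, and the result
carries an explicit flag for each case.

**Convergence caveat.** The chain relaxes at rate ≈ (h_P+h_M)/4 per
generation.  Slow-switching architectures (content-swapped cassettes
with native enhancers: h_P+h_M ≈ 0.26) are still visibly off
stationarity after 30 generations; simulator/oracle agreement is
therefore checked against the chain's *transient* at the matched
generation (`project_fractions`), and stationarity of the chain itself
is verified analytically at large t.  Quoted "steady" simulated values
use 150 generations.

## Culture simulation

Synchronous generations with a carrying capacity: every cell divides
(the population exactly doubles), then the population is uniformly
subsampled without replacement back to the capacity — a
Wright–Fisher-style scheme chosen because the quantities of interest
are per-culture ratios, not timing.  Because cells of a given state are
exchangeable, the update acts on the four state counts with exact
binomial/multinomial draws and multivariate-hypergeometric subsampling;
this is distributionally identical to dividing cells one by one and
keeps a 10⁴-cell, 30-generation culture at sub-millisecond cost.
Per-cell division (`divide`) and explicit pedigrees remain available
and are tested against the count-based simulator through the chain
oracle.  Failed conversion attempts heal without switching by default
(`lethal_on_failure=False`); the fate of unhealed breaks is not
established, so the lethal variant is provided as a flag.  Each
simulation uses a single seeded NumPy generator, recorded in the
trajectory for bit-reproducibility.

## Synthetic observations

The generator emulates the statistical structure of three readouts:

* **microscopy** — per-replicate P-cell counts,
  Binomial(n_cells, f_true); defaults of 9 replicates × 500 cells
  mirror the nine-independent-culture panels and typical fluorescence
  tallies of the emulated study design.
* **southern** — intensity pairs `f·exp(ε₁)`, `(1−f)·exp(ε₂)` with
  lognormal noise at CV 0.15.  The noise scale is invented (no
  measurement-error model is published); consequently Southern-type
  data are used for display and fraction estimates only, never in
  likelihoods.
* **variegated cultures** — full culture simulations founded by single
  cells of random type; with RPC loss (attempt success 0.02) founder
  effects dominate and replicate fractions are bimodal near 0 and 1,
  the statistical signature of colonies staining at their junctions.

What passing tests on these data do **not** show: robustness to real
microscopy miscounting, blot saturation or loading artifacts,
non-binomial clumping of cells, or growth-rate differences between
mating types — none of which are modeled.

## Inference

* **Fraction estimates**: pooled binomial + Wilson 95% interval
  (microscopy); replicate-mean of intensity ratios + seeded percentile
  bootstrap (southern).
* **Phenotype classes** operationalize the qualitative iodine/Southern
  readouts: *variegated* if the binomial dispersion statistic
  `D = Σ(xᵢ−nᵢp̂)²/(nᵢp̂(1−p̂))` exceeds its parametric-bootstrap null at
  p < 0.01; otherwise *balanced* when the Wilson interval reaches the
  equivalence band 0.5 ± 0.1, else *biased* toward the majority type.
  The band (configurable `balance_margin`; 0 recovers a strict
  "interval contains ½" rule) was set from the published strain labels:
  populations at 48–56% P are called balanced, 72% M and beyond are
  called biased.  At the default steady state the wild-type
  architecture sits at 9/17 ≈ 52.9% P, so a strict rule would misclassify
  wild type given enough cells — an equivalence band is the correct
  formalization of "balanced".
* **Error-rate fitting** (`DonorChoiceModel.fit`): each culture's count
  is Binomial(n, f(strain, θ)) with f the closed-form steady state;
  the likelihood is maximized on an (e_P, e_M) grid at resolution 0.005
  with a 10× local refinement (the steady-state likelihood is used
  because cultures are sampled after many generations; trajectory-based
  fitting is out of scope).  Identifiability is diagnosed from the rank
  of the Fisher information of the strain→fraction map: a single
  steady-state strain constrains only e_M/(e_P+e_M), in which case the
  ratio and its CI are reported instead of the pair.  Confidence
  intervals are percentile bootstrap over replicate cultures, with
  Hesterberg's expanded-percentile small-sample correction (plain
  percentile intervals are systematically narrow at 9 replicates).
* **Model comparison**: both variants are optimized over their free
  parameters with the same grid discipline; the signed log-likelihood
  difference (competition − spreading) is reported.  A single strain's
  steady fraction can be fit perfectly by either model, so
  discrimination requires a panel; on the swapped-cassette panel the
  spreading rule pins wild-type-like strains at f = ½ and misses the
  content-swapped strains entirely, while the competition model fits
  all four architectures with two parameters.  Flat likelihoods (e.g.
  the spreading model on wild type alone, where f = ½ for every q) are
  tolerated in comparisons and flagged non-identifiable.

## Numerical choices

* Stationary vectors: least-squares solve of π(T−I)=0 with
  normalization; power-iteration fallback; closed-form cross-check at
  1e-10.
* Likelihood grids: parameters at cell midpoints (res/2, …, 1−res/2),
  avoiding the 0/1 boundary; fractions clipped at 1e-9 inside logs;
  grid cells with undefined fractions get −∞.
* Dispersion bootstrap: p-value (1+#{D* ≥ D})/(B+1); degenerate pooled
  estimates (p̂ ∈ {0,1}) short-circuit to a biased call with an
  undefined p-value.
* Deterministic mode (pedigrees): divisions without an RNG require all
  branch probabilities forced to 0/1 and raise otherwise.
* Pedigree depth is capped at 20 generations (2²⁰ nodes).

## Problem sizes used in the shipped tests and acceptance script

Culture checks use capacity 10⁴, 30 generations, 5 seeds per
architecture (150 generations where a stationary simulated value is
quoted).  Recovery and classification checks use 100 synthetic datasets
per scenario of 9 replicates × 500 cells, bootstraps of 500–1000
resamples, and a 0.005 fitting grid.  These sizes make every
Monte-Carlo margin comfortable while the full suite runs in about a
minute.

## Known limitations

* Donor competition is conditional on an attempt: deleting both
  enhancers leaves the residual weights to normalize to 50:50 at full
  attempt rate, so the double-deletion strain switches efficiently in
  the model, whereas it is observed to switch very poorly and
  variegate.  Capturing this would require coupling enhancer weights to
  the attempt rate, which the current parameterization deliberately
  separates.
* The swi6Δ weight column is a calibrated constant, not an estimate;
  inference can re-estimate it from swi6Δ panels but the defaults
  should not be read as measurements.
* No cell-cycle timing, death/selection differences between P and M
  cells, or mating/sporulation dynamics; "generation" is a synchronous
  doubling.
* The content-dependent donor bonus hinted at for the M-content/SRE2
  combination is not modeled.
* Chromatin mutants other than Swi6 loss (clr4, clr7, clr8) are not
  modeled separately; `swi6_present` is the only chromatin switch.
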