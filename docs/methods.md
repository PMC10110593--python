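# Methods

`dragtrace` analyzes clonal lineage-tracing data from an in situ VDJ-style
barcoding cassette ("Diversity through RAG"): a genomic locus carrying one
synthetic V, D and J segment that, upon Cre induction, undergoes
RAG-mediated recombination.  Trimming at the four junction ends,
TdT-mediated untemplated insertions at the two junctions, and occasional
incorporation of the D segment in reverse-complement orientation make the
recombined sequence a heritable, heavily diversified DNA barcode.  This
note records the models, the numerical choices, and what the synthetic data
do and do not establish.

## Generative recombination model

A recombination *scenario* is the tuple
(inverted, del_v, del_d5, del_d3, del_j, ins_vd, ins_dj).  Its probability
is the product of independent factors:

    P(scenario) = P(inv) · P_delV(del_v) · P_delD5(del_d5) · P_delD3(del_d3)
                  · P_delJ(del_j) · P_insVD(|ins_vd|) · Π p_nt(b)
                  · P_insDJ(|ins_dj|) · Π p_nt(b)

with categorical trim/insertion-length distributions, an i.i.d. nucleotide
composition for inserted bases, and a Bernoulli for D inversion.  D trims
are counted in the post-orientation frame.  P-nucleotides are not modeled
and the insertion composition has no Markov dependence (first-order
extensions would need junction-resolved data that the assay's published
summaries do not provide).

The generation probability of a barcode is

    P_gen(s) = Σ_{scenario : realize(scenario) = s} P(scenario),

summed over *all* consistent scenarios — junctions are ambiguous because
inserted bases may coincide with germline ends, so no single "best
annotation" is used inside the probability.

**Defaults.** Trim supports are 0–32 per site, capped at segment length;
insertion supports 0–15 per junction; D inversion probability 0.12.  The
two D-site supports partition the 17-nt D length (0–8 and 0–9): because the
scenario probability is a plain product of independent per-site factors,
every in-support (del_d5, del_d3) pair must be jointly feasible, otherwise
the model would not normalize over sequence space and forward sampling
could produce invalid scenarios.  Full D deletion remains reachable.
Trim-count and insertion-length profiles decay geometrically (decay 0.82
for V/J trims, 0.70 for D trims, 0.72 for insertions), giving means of a
few nucleotides while keeping the observed extremes (15-nt junction
insertions, 32-nt site deletions) attainable at realistic frequency.
Inserted bases use p_nt = (0.20, 0.30, 0.30, 0.20) for A,C,G,T — a mild
G/C bias typical of TdT additions; the exact composition is re-estimable
from data.

**Exact P_gen by junction factorization.**  Explicit scenario enumeration
is exponential in the junction ambiguity (10^4–10^5 scenarios for a
realistic barcode), so the engine factorizes the sum.  For each placement
of a trimmed (possibly inverted) D core inside the sequence, the V-side
choices (V trim and left insertion) and J-side choices are conditionally
independent; pre-summing per-position V-side and J-side weights reduces
P_gen to a sum over D-core placements.  The result is exact: tests verify
agreement with brute-force scenario iteration to 1e-12 on micro cassettes,
and that P_gen sums to 1 over the full producible sequence space.  Kernels
are numba-compiled; one full-length barcode scores in well under a
millisecond.

**EM fitting.**  `fit_model` is MAP-EM under symmetric Dirichlet priors
(pseudo-count 0.5 per category; tolerance 1e-6 on the max parameter change;
at most 200 iterations; uniform initialization with p_inv = 0.5).  The
E-step computes exact expected trim/insertion/composition counts through
the same factorization, weighting every consistent scenario by its
normalized probability.  The penalized objective is guaranteed
non-decreasing; the data log-likelihood is recorded per iteration and is
asserted non-decreasing (relative tolerance 1e-7) in tests.  Unproducible
sequences are excluded with a logged warning and reported count.  Note an
identifiability caveat: some scenario sets are observationally equivalent
(e.g. a V trim plus insertion versus a D-end shift); EM then converges to
the correct *posterior mixture* over the equivalence class, which is why
degenerate (point-mass) recovery tests first verify the realized sequence
is uniquely decodable.

## Synthetic data

The simulator emulates the structure of the deposited raw data: clones
with heavy-tailed sizes, three bone-marrow compartments (HSPC, MP, M) with
barcode-sharing fate classes, technical PCR duplicates, UMI-tagged reads
with PCR/sequencing noise, and longitudinal low-capture blood samples.

* **Clone sizes**: log-normal per compartment, median 1000 cells,
  sd 0.5 log10 units — spanning roughly 100–10,000 cells, the observed
  myeloid range.  The distributional family is a modeling choice; only the
  range is constrained by observation.
* **Fate classes**: multinomial over the seven nonempty subsets of
  {HSPC, MP, M}; defaults put 13.7% on the triple-positive class (the
  observed sharing), 0 on HSPC+M (never observed), and plausible masses on
  the rest (HSPC 0.20, MP 0.08, M 0.15, HSPC+MP 0.10, MP+M 0.333).
  Compartment cell counts are zero exactly outside a clone's class.
* **Labeling**: Bernoulli(labeling efficiency, default 0.5) per clone,
  independent of fate — induction is treated as neutral.
* **Reads**: cells are drawn without replacement (multivariate
  hypergeometric on clone sizes) from the GFP+ clones of the sorted
  compartment; each cell's molecules go to one of the PCR duplicates
  (emulating splitting of sheared gDNA); each cell yields Poisson(1)+1
  UMIs (8 nt), each UMI Poisson(3)+1 reads; substitution errors at 1e-3
  per base.  A read is UMI + 12-nt constant anchor + the full recombined
  region (~135 nt total for the default cassette — the region itself is
  117 nt in germline configuration, so reads are emitted at full barcode
  length rather than truncated to a fixed machine read length).  Every
  emitted read is accounted for in a truth table.
* **Time course**: expected blood diversity follows
  log mu_it = 5.8 + u_i − 0.15·t + 0.25·(t−7)₊ with u_i ~ N(0, 0.3²) and
  gamma observation noise of shape 50 — a decline to roughly half by month
  7 followed by a linear rise, matching the qualitative trajectory the
  assay revealed.  Blood replicates capture each active clone with
  probability 0.05 by default, which reproduces the observed contrast
  between poor blood duplicate overlap and good bone-marrow duplicate
  overlap.

Not modeled: PCR chimeras and amplification jackpots, base-quality
structure, clone-size correlations between compartments, cassette
deletion/silencing, and real oligo architecture.  Passing tests therefore
demonstrate correctness of the algorithms under the stated noise model,
not robustness to every artifact of real libraries.

## Barcode calling

UMI = first 8 bases; the following 12 bases must match the constant anchor
(≤1 mismatch).  Per-UMI consensus is a position-wise majority vote over
reads of the group's modal length; groups with <2 reads or a tied vote are
discarded — ties are *not* resolved to N because barcode identity must be
exact.  Consensus sequences are annotated by the most parsimonious
scenario: maximal germline retention, ties broken by fewer insertions,
then lexicographically (verified against enumerate-and-minimize).
Detection filtering keeps a (barcode, biological sample) entry only if it
has ≥3 UMIs in *every* PCR replicate, then sums replicates.  These
thresholds are configuration-first defaults — the study's exact numeric
thresholds are not published.  Replicate concordance reports Jaccard
overlap of detected sets and Pearson correlation of arcsinh-transformed
fractions (cofactor 1, the same transform used for heatmaps); the study
does not state its overlap formula or correlation scale.

## Recurrence filtering

Barcodes are retained when P_gen < 1e-4 (strict, matching the published
cutoff).  The recurrence probability of a barcode across n independent
recombination events is the binomial tail 1 − (1−p)ⁿ − np(1−p)ⁿ⁻¹.
Cross-mouse uniqueness is exact sequence identity over the union of
retained barcodes.

## Diversity estimation

chao2 uses the PCR duplicates as the m = 2 incidence units:
classic form S_obs + ((m−1)/m)·Q1²/(2Q2) when doubletons exist, the
bias-corrected form S_obs + ((m−1)/m)·Q1(Q1−1)/(2(Q2+1)) when Q2 = 0; both
forms are exposed, and a counts-level entry point accepts (S_obs, Q1, Q2,
m) directly.  Labeling correction divides estimated richness by the GFP+
fraction — valid because Bernoulli labeling is an unbiased thinning of
clones under neutrality.  Renyi entropies use natural logs; the reported
default Simpson variant is the inverse Simpson (positive and continuous,
hence compatible with a gamma response model); identities
exp(H₂)·λ = 1 and monotonicity of H_q in q are property-tested.

## Breakpoint gamma GLMM

Diversity observations y_itr > 0 are modeled as Gamma(shape ν, mean μ_it),
log μ_it = β₀ + u_i + β₁t + β₂(t−t_b)₊, u_i ~ N(0, σ_u²).  Continuity of
log μ at t_b holds by construction.  The per-mouse random intercept is
integrated by adaptive Gauss–Hermite quadrature (9 nodes; the mode and
curvature of each mouse's integrand are found by a damped Newton
iteration, which is safe because the integrand is strictly log-concave in
u).  Fixed effects, log σ_u and log ν are maximized by Nelder-Mead with a
polish restart; log σ_u and log ν are clamped to a broad box
(σ_u ≤ e⁵, ν ≤ e²⁰) so that exactly-noiseless data — where the gamma MLE
diverges — remain numerically finite.  t_b is estimated by profiling over
a grid (default 5–10 months, step 0.5; small samples of 4 mice do not
support joint gradient estimation of a kink location), warm-starting each
grid point from the previous solution.  Random effects are
intercept-only: 4 mice cannot identify random slopes.  Sampling noise is
accounted for by fitting the per-replicate observations rather than
replicate means.

AIC counts k = (fixed effects) + 2 variance parameters, plus 1 for the
profiled breakpoint (intercept 3, linear 4, breakpoint 6); the selection
table breaks AIC ties toward fewer parameters.  Predicted trajectories
report the conditional mean at u_i = 0 (the median mouse — stated in the
output metadata; a marginal adjustment would multiply by E[e^u]) with a
delta-method 95% band on the log scale from the inverse observed
information (central finite differences).  Predictions beyond ±20% of the
training time range warn about extrapolation.

## Problem sizes used in the shipped checks

Oracle comparisons use micro cassettes (segments ≤6 nt, trims ≤2,
insertions ≤2) whose whole scenario space is enumerable; EM recovery uses
50,000 simulated barcodes (total-variation error <0.05 per categorical,
observed ≈0.01); simulator profile checks use 100,000 sampled events;
pipeline recovery uses mixtures of 7–150 clones at 2,000–25,000 sampled
cells; GLMM operating characteristics use 100 seeded replicates of the
4-mice × 9-months × duplicates design.

## Known limitations

* The synthetic cassette sequences are stand-ins with realistic lengths,
  not the deposited construct; real cassette FASTA and fitted model JSON
  are drop-in replacements.
* P_gen assumes the recombination model family is correct; model
  misspecification (e.g. sequence-dependent trimming) biases both P_gen
  and EM estimates.
* chao2 is a lower-bound-style estimator; with only m = 2 units its
  variance is substantial, and the labeling correction inherits any
  non-neutrality of induction.
* The breakpoint is restricted to the profiling grid; uncertainty in t_b
  is visible in the stored profile but not propagated into the prediction
  band or the fixed-effect covariance.  A consequence worth knowing: when
  the true trajectory has *no* breakpoint, the conditional-on-t_b interval
  for the slope change β₂ is mildly anticonservative (empirical coverage
  ≈80–85% rather than 95% in simulation), because profiling places t_b
  where the apparent kink is largest.  The supported way to decide whether
  a breakpoint exists is the AIC comparison against the log-linear null,
  not the β₂ interval.
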