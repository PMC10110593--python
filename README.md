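# dragtrace

Analysis toolkit for **in situ VDJ-style DNA barcoding** of hematopoiesis.
A genomic cassette carrying synthetic V, D and J segments recombines upon
Cre induction — nucleotide trimming at the junctions, TdT-mediated
untemplated insertions, and occasional D-segment inversion turn each
recombination event into a heritable clonal barcode (and switch on GFP).
Sequencing the recombined locus from sorted cell populations then reads out
which stem/progenitor clones produced which cells, over months, in the
unperturbed animal.

`dragtrace` implements the full quantitative pipeline around that assay,
for researchers doing clonal lineage tracing in blood (or any tissue with
a recombination-based barcode):

1. **Generative recombination model & P_gen** — the probability that one
   recombination event produces a given barcode,

   `P_gen(s) = Σ_scenarios P(inv) · Π P_del(d_site) · Π P_ins(ℓ_junction) · Π p_nt(b)`,

   summed *exactly* over every scenario consistent with the sequence
   (junction ambiguity included) via a junction-factorized engine, with
   model parameters fitted from observed barcodes by EM.  Barcodes likely
   to recur independently in different cells (high P_gen) are filtered at
   the `P_gen < 1e-4` cutoff before clonal interpretation.
2. **Synthetic data with ground truth** — clone populations with fate
   classes and 100–10,000-cell log-normal sizes, UMI-tagged reads with PCR
   duplicates and sequencing errors, and longitudinal blood samples whose
   diversity follows a programmed breakpoint trajectory.
3. **UMI barcode calling** — UMI extraction, per-UMI majority-vote
   consensus, parsimony annotation against the cassette, detection
   filtering across PCR replicates, arcsinh-transformed fractions,
   replicate concordance.
4. **Clonal analysis** — fate classes over {HSPC, MP, M}, cells-per-clone,
   chao2 richness with labeling-efficiency correction (`Ŝ = S_obs +
   ((m−1)/m)·Q1²/(2Q2)`, bias-corrected form when Q2 = 0), Simpson and
   Renyi diversity profiles.
5. **Diversity dynamics** — a gamma generalized linear mixed model with a
   breakpoint, `log μ_it = β₀ + u_i + β₁t + β₂(t−t_b)₊`,
   `u_i ~ N(0, σ_u²)`, fitted by adaptive Gauss–Hermite marginal likelihood
   with t_b profiled over a grid, compared against intercept-only and
   log-linear null models by AIC.

See `docs/methods.md` for model details, defaults and limitations.

## Worked example

```python
import numpy as np
from dragtrace import *
from dragtrace.simulate import sample_metadata

rng = np.random.default_rng(1)
ref = default_reference()
model = default_model(ref)

# simulate a clone population and one sorted myeloid sample (2 PCR replicates)
pop = simulate_clone_population(200, model, ref, rng, labeling_efficiency=0.5)
spec = SampleSpec("m1_M", "m1", "M", timepoint_months=15.0, cells_sampled=10_000)
reads, truth = simulate_reads(pop, spec, ReadLayout(), rng)

# call barcodes and apply detection + recurrence filters
layout, bounds = ReadLayout(), Bounds.default(ref)
meta = sample_metadata(spec, gfp_fraction=0.5)
calls = {rid: call_sample(reads[rid], layout, ref, bounds)[0] for rid in meta.index}
matrix = build_matrix(calls, meta)
filtered, _ = filter_matrix(matrix)
retained, rep = filter_by_pgen(annotate_pgen(filtered, model, ref), threshold=1e-4)

# diversity dynamics on longitudinal blood samples
obs = simulate_diversity_observations(BreakpointDynamics(), 4, np.arange(4, 13), 2, rng)
fit = fit_breakpoint_glmm(obs)
nulls = fit_null_models(obs)
print(compare_models([fit, nulls["linear"], nulls["intercept"]]))
```

Output:

```
reads per replicate: {'m1_M_R1': 40193, 'm1_M_R2': 39507}
barcodes detected: 68 | retained after filtering: 65
P_gen filter: kept 64/65 (fraction 0.985)
largest clone (cells): 990
inverse Simpson: 24.21
      kind  k      loglik        aic  delta_aic
breakpoint  6 -335.470012 682.940023   0.000000
    linear  4 -358.090279 724.180559  41.240535
 intercept  3 -359.455706 724.911411  41.971388
estimated breakpoint: 6.5 | slopes: -0.177 0.083
```

Reading this: 80k reads collapse to 68 detected barcodes; 65 survive the
"≥3 UMIs in both PCR replicates" detection filter, and one more is removed
as a likely recurrent (high-P_gen) barcode.  Clone sizes are fractions ×
sorted cells.  On the longitudinal data, AIC decisively prefers the
breakpoint model (ΔAIC ≈ 41 vs the log-linear null); the fitted trajectory
declines at −0.18/month before a breakpoint near month 6.5 and rises at
+0.08/month afterwards — the signature of late-recruited long-term
repopulating clones.

A command-line interface mirrors the library:
`dragtrace sim|call|pgen|fit|pgen-filter|analyze|fit-dynamics --help`.

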