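# Methods

## Model

The transmission model is the standard order-of-acquisition NBDA one.
Given a symmetric association network with weights `a_ij ∈ [0, 1]` and an
informed set I, each naive individual i learns at rate

    R_i = s · Σ_{j ∈ I} a_ij + 1,

where the baseline asocial rate is normalized to 1 and `s ≥ 0` scales the
social transmission rate per unit of association. Only the order of
acquisition is modelled: the probability that i is the next learner is
`R_i / Σ_j R_j` over the current naive set. The log-likelihood of an
observed order is the sum of the log of these probabilities over events;
the first event, with all rates equal, contributes `log(1/N)` to both the
social and the asocial (`s = 0`) model and therefore cancels from every
comparison. Key assumptions: a static undirected network, a single
diffusion, homogeneous asocial rates (no individual-level variables), and
association as the pathway of transmission.

## Observational error

Association strengths are estimated with the simple ratio index from
per-dyad counts of sampling periods together (x) and apart
(failures; under the group-by-individual representation the
"both identified but not associated" term is identically zero, because
co-presence in a row *is* association). Treating the periods as
independent Bernoulli trials, uncertainty about a dyad's true association
is the conjugate Beta posterior `Beta(α + x, β + n − x)`; the default
prior `α = β = 1` is uniform. One noisy network is drawn per replicate —
one independent draw per unordered dyad, mirrored, zero diagonal. A
never-sampled dyad has SRI 0 in the point-estimate network by convention
but a full uniform posterior in the noise model; the asymmetry is
deliberate (the point estimate must be defined everywhere, the noise
model must represent ignorance honestly).

## Fitting and inference

- The social model is fitted by bounded 1-D maximization of the
  log-likelihood over `s ∈ [0, S_MAX]` on a `log1p(s)` axis
  (Brent-style; `xatol = 1e-8` in transformed units). `S_MAX = 1e7`.
- Diffusions that follow the network closely produce likelihoods that
  rise and plateau as `s → ∞`. An optimum whose likelihood is within
  `1e-9` of the value at `S_MAX` is reported as `s_hat = S_MAX` with
  `bounded_above = True` and an infinite CI upper limit. Such estimates
  enter summary means as-is, which biases mean `s` estimates far above
  the generating value — a known reporting artifact of OADA; the mean
  scales with `S_MAX` and should not be interpreted as an effect size.
  The CI, in particular its lower bound, is the quantity to report.
- A numerically flat likelihood (e.g. an equal-weight network) is
  reported as `s_hat = 0` with CI `[0, ∞)`: ties break toward the null,
  keeping false positives conservative.
- The 95% CI is the profile-likelihood set
  `{s : logL(s) ≥ logL(ŝ) − 1.92}` (half the χ²₁ 0.95 quantile), with
  finite endpoints located by bisection on the transformed axis.
- Model selection uses AICc with `n` = number of acquisition events,
  `k = 1` (social) vs `k = 0` (asocial); a model is selected only when
  |ΔAICc| strictly exceeds the threshold (default 2). Fits with fewer
  than three events raise a degenerate-fit error, since the AICc
  small-sample correction for the one-parameter model is undefined at
  `n = 2`.
- The likelihood-ratio p-value uses the plain χ²₁ upper tail, which is
  conservative at the `s = 0` boundary; a 50:50 χ²₀/χ²₁ mixture is
  available via `lrt_pvalue(..., boundary_correction=True)`. The
  pipeline's decisions rest on ΔAICc, so this choice affects only the
  reported p.

## Sensitivity sweep

Per cut-off N and replicate: simulate a diffusion on the error-free SRI
network (fresh each replicate by default; a fixed-diffusion mode exists
for analyzing one observed diffusion), draw a noisy network, drop
individuals with fewer than N sightings (retain-learners mode keeps
informed individuals regardless), restrict the order, fit, compare.
Dropped learners are removed entirely — they are not counted as informed
for the remaining individuals' rates. Summaries per cut-off: proportion
of conclusive comparisons, the proportion of conclusive comparisons won
by the social model (power when `s > 0`, false-positive rate when
`s = 0`; an all-replicates-denominator variant is emitted as
`power_all_reps`), mean/SD of `ŝ`, 95% CI coverage of the true `s`, and
the over/under-estimation split. Replicates where the cut-off leaves
fewer than two learners (or fewer than three fittable events) are tallied
as degenerate and excluded from every denominator. Per-replicate RNG
streams are derived from `(base_seed, cutoff_index, replicate_index)`, so
results are byte-identical regardless of execution order.

## Synthetic data generator

The generator emulates a field data set of 60 individuals over 331
sampling periods: group sizes are drawn from a zero-truncated geometric
reshaped to a maximum of 10 and calibrated (single ratio parameter, solved
by root-finding) so the expected mean group size is 1.92; a core third of
individuals carries a 6× sighting propensity; individuals are partitioned
into 15 latent social units assigned block-wise by propensity (frequently
sighted individuals form frequently sighted units, as when some units
range mostly inside a study area); each observation seeds one individual
propensity-weighted and fills remaining slots from the seed's unit with
probability 0.95. These defaults reproduce the structural features the
procedure needs: a realized mean group size of 1.92 ± 0.09 across seeds,
roughly 42 of 60 individuals with ≥ 4 sightings, the core third holding
about three-quarters of all presence records, and enough social
differentiation that diffusions at `s = 8` yield power in a
discriminating range (~0.3–0.8 across cut-offs) rather than pinned at 0
or 100%.

What the generator does **not** emulate: temporal autocorrelation between
sampling periods (rows are exchangeable, consistent with the
independent-trials assumption of the Beta updating), spatial structure,
demographic turnover, and observer-specific identification error. Passing
tests therefore show the procedure behaves correctly under its own
assumptions, not that those assumptions hold for any particular field
data set.

## Problem sizes

The default test and acceptance runs use reduced Monte-Carlo sizes —
hundreds to 1,000 replicates per cut-off rather than 10,000 — chosen so
proportions carry ~1–3 percentage points of Monte-Carlo error, which is
adequate for locating a power peak; `RunConfig.n_reps` restores any
larger budget.

## Known limitations

- Single static network; no dynamic-network or time-of-acquisition
  (TADA) variants, and no individual-level variables.
- Association-index error model only (Beta-binomial on SRI counts);
  interaction-rate data would need a different error expression.
- Mean `ŝ` summaries depend on `S_MAX` whenever plateau fits occur and
  are reported for completeness, not interpretation.
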