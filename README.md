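# nbdacutoff

Choosing a sighting cut-off point for network-based diffusion analysis
(NBDA) by simulation.

## The problem

NBDA infers social learning when the spread of a novel behavior follows an
association network. Field data sets rarely sample every individual well,
so researchers usually include only individuals seen at least *N* times
when building the network. A high cut-off reduces uncertainty in the
included edges but throws away linking individuals; a low cut-off keeps
everyone but floods the network with poorly estimated edges. `nbdacutoff`
resolves this trade-off for a specific data set by measuring, per cut-off,
the statistical power and the false-positive rate of the analysis under a
principled model of observational error.

## Method

Starting from a binary group-by-individual observation matrix (rows =
sampling periods, columns = individuals), the tool:

1. builds the **simple ratio index** network,
   `SRI = x / (y_a + y_b + y_ab + x)`, from per-dyad counts of periods
   together (x) and apart (the y terms);
2. simulates a diffusion under the NBDA transmission model: a naive
   individual's learning rate is `R_i = s * Σ_j a_ij + 1` (sum over
   informed j), and the next learner is drawn with probability
   `R_i / Σ_j R_j`; the innovator is uniform and the process stops at a
   fixed number of learners (default 20);
3. injects observational error by redrawing each dyad's weight from its
   conjugate posterior `a_ij | data ~ Beta(1 + x, 1 + n − x)` under a
   uniform `Beta(1, 1)` prior — well-sampled dyads stay close to their
   SRI, poorly sampled dyads vary widely;
4. drops every individual seen fewer than *N* times (optionally retaining
   learners) from the noisy network and the acquisition order;
5. fits social and asocial **order-of-acquisition diffusion analysis**
   (OADA) models by maximum likelihood, with a 95% profile-likelihood CI
   for `s`, and compares them by AICc (selection threshold ΔAICc > 2).

Steps 2–5 are repeated (default 10,000 replicates) per cut-off, for `s > 0`
(power) and `s = 0` (false positives). The recommended cut-off maximizes
power subject to an acceptable false-positive rate. Because a diffusion
that tracks the network closely makes the likelihood plateau as
`s → ∞`, some fits sit at the optimizer bound with an infinite CI upper
limit; the lower CI bound then remains the interpretable quantity.

A synthetic-data generator produces observation matrices with realistic
structure (60 individuals, 331 sampling periods, group sizes 1–10 with
mean 1.92, a core third of individuals accounting for most sightings,
latent social units) for testing and demonstration.

## Worked example

```bash
nbda-cutoff generate-data --seed 1 -o obs.csv
nbda-cutoff network -i obs.csv -o sri.csv
nbda-cutoff power -i obs.csv --s 8 --reps 1000 --cutoffs 1,2,3,4,5,6,7,8 \
    --retain-learners false --seed 7 -o power.csv
nbda-cutoff falsepos -i obs.csv --reps 1000 --cutoffs 1,2,3,4,5,6,7,8 \
    --seed 7 -o fpr.csv
```

The two sweeps print:

```
wrote 8 cut-off summaries to power.csv
max power/fpr 0.4952 at cut-off 3 (57 individuals included)
wrote 8 cut-off summaries to fpr.csv
max power/fpr 0.0391 at cut-off 2 (60 individuals included)
```

meaning that of the model comparisons that were conclusive
(|ΔAICc| > 2), 50% selected the social model when the diffusion was truly
social (s = 8) — peaking when individuals with fewer than three sightings
were excluded — while with s = 0 the social model was never selected in
more than 3.9% of conclusive comparisons, so every cut-off in the grid
keeps false positives below the conventional 5%. `power.csv` holds one row per
cut-off with the number of included individuals, the proportion of
conclusive comparisons, power, the mean and SD of the `s` estimates, 95%
CI coverage of the true `s`, and the over/under-estimation split. The
same columns from the `falsepos` run give the false-positive rate; a
cut-off is trustworthy when that rate stays below 5%.

The same pipeline is available as a library (`generate_observations`,
`sri_matrix`, `sample_noisy_network`, `simulate_diffusion`, `fit_oada`,
`run_sweep`), which is the better entry point for scripting or for real
observation matrices.

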