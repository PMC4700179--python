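# timbrekit

Tools for studying how listeners judge the dissimilarity of musical timbres,
combining three things that usually live in separate codebases:

1. **Stimulus synthesis** — a 24-band ERB-spaced Gammatone filterbank with
   auditory *chimera* generation (impose one sound's per-band amplitude
   envelopes on another sound's temporal fine structure), *filterband
   scrambling* (build a sound from four donors, six bands each), harmonic
   tone complexes at f0 = 311 Hz, and stimulus conditioning (500 ms, 20-ms
   raised-cosine fade, peak normalization).
2. **Acoustic description** — a fixed registry of 34 scalar timbre
   descriptors: 12 temporal measures of the Hilbert amplitude envelope
   (attack/decay/release durations, log-attack time, slopes, temporal
   centroid, effective duration, energy modulation, RMS-envelope summaries)
   and 11 spectral measures per 25-ms Gammatone frame (centroid, spread,
   skew, kurtosis, slope, decrease, rolloff, spectrotemporal variation,
   frame energy, flatness, crest), each summarized by median and IQR.
3. **Rating analysis and modelling** — dissimilarity-rating matrices on a
   1–9 scale with order-asymmetry statistics (lower-minus-upper triangular
   differences, Shapiro–Wilk + Bonferroni-corrected one-sample t-tests),
   Fisher-averaged inter-rater correlations with percentile-bootstrap CIs,
   complete-linkage clustering with cophenetic correlation, and a partial
   least-squares (SIMPLS) regression of mean ratings on absolute descriptor
   differences plus binary categorical predictors (instrument family,
   excitation, resonator, and recording/transformation indicators).

The model at the core is

```
y ≈ X β,     X = [ |d_i(A) − d_i(B)| ;  1{cat_c(A) ≠ cat_c(B)} ],
β = W (P′W)⁻¹ q
```

where `y` holds mean pairwise dissimilarities, the latent decomposition
`X = T P′ + E`, `y = T q′ + F` maximizes predictor–response covariance
(SIMPLS), the number of components is chosen by seeded 6-fold
cross-validation, and coefficient significance comes from a percentile
bootstrap (a coefficient is significant when its 95 % CI excludes zero).
Model fits are compared with a two-correlation Fisher z test on r = √R².

Because the original audio corpus and rating data of such studies are
typically proprietary, the package ships a first-class synthetic-data
module: seeded instrument-like tones organized in the canonical
14-instrument category grid, chimera/FBS transformations of them, and a
generative rating model (descriptor deltas + categorical effects + an
order-dependent asymmetry for transformation-then-recording presentations +
rater noise, clipped to the 1–9 scale) with known ground truth, so every
stage of the pipeline can be validated end to end.

## Worked example

```python
import numpy as np
from timbrekit import synth, descriptors, model, ratings

# 1. synthesize a bank of 14 instrument-like tones + category table
bank, categories = synth.make_stimulus_bank(n_recordings=14, seed=7)

# 2. acoustic descriptors (14 stimuli x 34 descriptors)
table = descriptors.descriptor_table(bank)

# 3. simulate a 24-subject dissimilarity-rating study
classes = {s.label: "recording" for s in bank}
config = synth.RatingGenConfig(seed=7, n_subjects=24)
study = synth.simulate_ratings(table, classes, config, categories)

# 4. order-averaged mean matrix -> 105-pair design -> SIMPLS fit
mean = ratings.mean_matrix(study, average_order=True)
order = list(study.stimuli)
design = model.build_design(table.loc[order], categories=categories,
                            classes=classes, y_matrix=mean.values,
                            stimuli_order=order)
k = model.select_components(design, folds=6, seed=7)
fit = model.simpls_fit(design, k)
print(f"selected k = {k}, R^2 = {fit.r2:.3f}")

# 5. bootstrap coefficient significance
boot = model.bootstrap_beta(design, k, n_boot=1000, seed=7)

# 6. clustering of the mean matrix
tree = ratings.cluster_tree(mean.values, study.stimuli)
print(f"{tree['n_clusters']} clusters, cophenetic r = {tree['cophenetic_r']:.2f}")
```

This prints

```
selected k = 8, R^2 = 0.994
2 clusters, cophenetic r = 0.83
```

and `boot` lists, per descriptor, the standardized coefficient with its
bootstrap CI — here the generator's dominant decay-duration effect comes
out on top (β = 0.55, CI [0.48, 0.60]), the injected negative
RMS-envelope-IQR effect is recovered with the right sign (β = −0.18), and
the high R² reflects the low simulated rater noise relative to 24 averaged
subjects.  The two flat clusters at the 70 % linkage cutoff separate the
impulsively excited (plucked/struck) tones from the sustained (blown/bowed)
ones.

A command-line interface wraps the same pipeline:

```bash
timbrekit synth --n 14 --seed 7 --out stimuli/
timbrekit chimera make --source stimuli/PNO.wav --filter stimuli/FLT.wav --out chimera.wav
timbrekit describe --dir stimuli/ --out descriptors.csv
timbrekit run --config run.yaml --out report/     # full pipeline + figures
```

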