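# cmlstate

State-transition modeling of blood transcriptomes for inducible chronic
myeloid leukemia (CML).  The package treats a bulk RNA-seq time series as
the trajectory of a particle in a one-dimensional potential landscape: a
disease *state-space* is constructed from the transcriptome by singular
value decomposition, the landscape over that coordinate is derived both
mechanistically (from a double-negative-feedback gene circuit driven by
the oncogenic BCR::ABL signal) and empirically (from the kernel density
of observed samples), and disease progression, time-to-disease and
treatment response are predicted by Langevin / Fokker–Planck dynamics on
the landscape.  It is written for computational biologists who want to
fit, simulate and interrogate such models on their own cohort data; a
synthetic-cohort generator reproduces the statistical structure of the
motivating experiment so every stage is testable without a download.

## The model

Each sample's log-normalized, gene-centered expression is mapped to a
coordinate `x` (a rotated principal component; *health high, disease
low*).  Disease dynamics follow the overdamped Langevin equation

    dX_t = (−dU/dx + F(x, t)) dt + sqrt(2 R(t)) dB_t

with the landscape gradient stored in quintic-root form

    dU/dx = a (x − c1)(x − c2)(x − c3)(x − c4)(x − c5),

where the stable critical points `c1, c3, c5` are the observable early,
transition and late disease states and the unstable `c2, c4` are the
basin boundaries.  `F` is a treatment force (signal silencing or kinase
inhibition, with a Heaviside onset and an exponential post-dosing
decay), and `R` the piecewise-constant diffusion coefficient.  The
matching Fokker–Planck equation is solved with a conservative
Chang–Cooper (Scharfetter–Gummel) finite-volume scheme; the probability
mass absorbed beyond `c5` is the time-to-disease curve `P(t)`.
Gene-level structure comes from the *eigengene* loadings of the disease
axis: a differentially expressed gene with loading `v2` and fold change
`log2FC` contributes `−v2·log2FC` toward disease (positive = pro-CML).

## Worked example

```sh
python examples/predict_time_to_disease.py
```

generates a 12-subject synthetic disease cohort, solves the
Fokker–Planck equation from each subject's week-0 state, and compares
predicted with simulated-observed first crossings of the late-disease
point.  It prints a per-subject table and then

```
log-rank p = 0.36 (large p: predicted and observed event curves are compatible)
concordance index = 0.82 (fraction of subject pairs whose predicted ordering
matches the observed ordering; 0.5 is chance)
```

meaning the predicted time-to-disease distribution is statistically
indistinguishable from the observed one and the model orders subjects by
risk far better than chance.  The other scripts under `examples/` cover
the circuit bifurcation analysis, state-space construction, empirical
landscapes, diffusion calibration and the gene-level analyses, each
printing a few numbers with a line on what they mean.

The end-to-end pipeline is also available from the shell:

```sh
cmlstate run-all --outdir out --seed 1
```

which writes the dataset, state-space model, landscape, survival
comparison, circuit treatment analysis, calibration surface and gene
tables under `out/` together with a hashed manifest.

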