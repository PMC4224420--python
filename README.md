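# camdce

Unsupervised deconvolution of dynamic contrast-enhanced (DCE) imaging by
convex analysis of mixtures, with multi-compartment pharmacokinetic
estimation.

Advanced tumors intermingle vascular compartments with distinct
pharmacokinetics — leaky angiogenic vessels on the rim, sluggish flow in a
hypoxic core — at a spatial scale below imaging resolution. A single pixel
therefore mixes the tracer kinetics of several compartments, and standard
one-compartment fits of DCE-MRI average away exactly the heterogeneity of
interest. `camdce` resolves the compartments without any prior knowledge of
their number, location, or kinetics, for researchers analyzing DCE-MRI or
other dynamic tracer series (dynamic PET, dynamic fluorescence).

## Model

Each tissue compartment j exchanges tracer with plasma through a
first-order (Tofts-type) model driven by the plasma input C_p(t):

    dC_j/dt = Ktrans_j C_p(t) − kep_j C_j(t)
    ⇒  C_j(t) = Ktrans_j · (C_p ⊛ e^{−kep_j t})

A pixel time-course is a nonnegative mixture with local volume transfer
constants K_{i,j} and local plasma volume v_{p,i}:

    x_i(t) = Σ_j K_{i,j} (C_p ⊛ e^{−kep_j t}) + v_{p,i} C_p(t)

After sum normalization, the pixel time-courses occupy a convex set whose
**vertices are the compartment curves** — provided the curves are linearly
independent and every compartment has at least one pure-volume pixel. The
pipeline therefore:

1. **Preprocesses** — masks the tumor, drops pre-uptake frames, removes
   pixels with mean or temporal variation below 5% of the respective
   maximum, and sum-normalizes each pixel curve.
2. **Clusters** the normalized curves by affinity propagation (message
   passing on similarities s(i,m) = −‖x_i − x_m‖²) with EM refinement, to
   denoise the scatter simplex into M representative centers.
3. **Finds the vertices** by exhaustive search over all C(M, J) subsets of
   centers, minimizing the summed margin of error (Euclidean distance to
   the candidate convex hull) of the remaining centers.
4. **Selects the compartment count J** by minimum description length over
   J ∈ {2..6}.
5. **Estimates kinetics** — the earliest-peaking vertex is the plasma
   input; each tissue vertex is deconvolved through a Toeplitz
   discretization of the convolution to recover (Ktrans, kep); per-pixel
   nonnegative least squares against the vertex basis yields the local
   transfer-constant maps and the partial-volume fraction.

Because curves are sum-normalized, Ktrans values are relative (shape-only);
kep is an absolute rate in /min.

## Worked example

Simulate a rim/core tumor phantom (two tissue pools, kep = 1.5 and
0.15 /min, plus a plasma input; 30 dB noise) and run the full pipeline:

```
$ camdce simulate --out study.csv --truth-out truth --seed 3
wrote 19x576 series to study.csv
wrote ground-truth sidecars with prefix truth

$ camdce fit study.csv --outdir run --mask truth_mask.txt
J=3, M=8, kep=[0.2153, 1.5094] /min, partial-volume fraction=0.289
outputs in run
```

Reading the output: clustering found M=8 representative centers; MDL
selected J=3 compartments (two tissue pools + plasma input, the generative
truth); the fast pool's flux rate constant is recovered as 1.509 /min
(truth 1.5) and the slow pool as 0.215 /min (truth 0.15 — the slow-pool
vertex carries some partial-volume contamination at this noise level, see
`docs/methods.md`); 28.9% of pixels are partial-volume mixtures. The
directory `run/` holds the MDL curve, the vertex (compartment) curves, the
pharmacokinetic table `pk_parameters.csv`, per-pixel transfer-constant
maps, a convexity-preserving scatter-simplex plot, and a `manifest.json`
with the seed and configuration hash.

The same steps are available as a library (`generate_synthetic_study`,
`preprocess`, `cluster_series`, `em_refine`, `select_num_compartments`,
`fit_flux_rate`, `fit_local_transfer_maps`, `run_pipeline`); `camdce
report` compares fitted runs across timepoints for longitudinal studies.

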