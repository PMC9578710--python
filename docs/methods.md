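# Methods

## The shuttling models

Both topologies describe one effector (YAP or TAZ) as two species on a 2D
pixel grid: unphosphorylated `U` and phosphorylated `P`. All reactions are
first order; concentrations are areal densities (the model plane is a single
confocal slice), lengths are µm, times are s.

Reactions and transport:

| process | canonical | alternative |
|---|---|---|
| phosphorylation U→P (`k_phos`, 1/s) | cytoplasm | nucleus |
| dephosphorylation P→U | cytoplasm (`k_dephos_cyt`) | nucleus (`k_dephos_nuc`) and cytoplasm (`k_dephos_cyt`) |
| nuclear import (`k_import`, µm/s) | U | U |
| nuclear export (`k_export`, µm/s) | U | P |
| synthesis (`k_syn`, conc/s) | U, cytoplasm | U, cytoplasm |
| degradation (`k_deg`, 1/s) | U and P, cytoplasm | U and P, cytoplasm |

The cell is closed (no plasma-membrane flux). Membrane transport is a
permeability flux density: `J = k × c(source side)` per unit membrane
length. Synthesis and degradation are included so that an open system with a
unique nontrivial steady state exists and so that the steady state can show
a gradient of protein disseminating from the nucleus through a diffusing,
degrading cytoplasm. Cytoplasmic dephosphorylation closes the
phosphorylation cycle in the alternative model (exported P is recycled to U
rather than only degraded). Whether degradation acts on U, P or both, and
whether transports are bidirectional, are config-exposed choices; the
defaults above are the ones used throughout.

The nuclear phosphorylation/dephosphorylation ratio
`r = k_phos / k_dephos_nuc` is the quantity the ratio studies scan: in the
alternative topology the well-mixed nuclear/cytoplasmic ratio (NCR) is
strictly non-increasing in `r`, so low `r` produces nuclear enrichment and
high `r` nuclear exclusion.

### Default parameters

`KineticParameters()` defaults: `k_phos = 0.17`, `k_dephos_nuc = 1.0`,
`k_dephos_cyt = 0.02`, `k_deg = 0.05`, `k_syn = 0.05` (1/s or conc/s),
`k_import = 0.8`, `k_export = 2.0` µm/s (export fast: P leaves the nucleus
rapidly), `D_U = D_P = 2` µm²/s. They were chosen once, from the well-mixed
closed form on the reference single-cell geometry, so that the two study
ratios fall on opposite sides of NCR = 1 (r = 0.17 → NCR ≈ 2.5, r = 0.75 →
NCR ≈ 0.8 well-mixed) while staying inside the default bounds:
rate constants 1e-4–1 s⁻¹, permeabilities 1e-3–10 µm/s, diffusion
0.1–30 µm²/s. The bounds are spans covering published estimates of YAP
diffusion and transport and are user-overridable in every fitting call.

### Well-mixed oracle

Removing diffusion collapses each topology to ≤ 4 linear ODEs over
(species, compartment) with transport scaled by membrane area over
compartment volume. For `k_deg > 0` the steady state is the unique solution
of a linear system; for the closed system (`k_syn = k_deg = 0`) it is the
one-dimensional nullspace ray scaled to the initial total amount. A
singular matrix with a nonzero source (e.g. synthesis without degradation)
has no finite steady state and raises. This oracle is independent of the
spatial solver and anchors its well-mixed limit.

## The FTCS solver

Geometry is a per-pixel label map (0 exterior, 1 cytoplasm, 2 nucleus) with
physical pixel size `h`. Diffusion uses the 4-neighbour Laplacian restricted
to each compartment (pairwise conservative fluxes; zero-flux at every
compartment boundary), membrane transport acts on the two pixels of each
nuclear-membrane face with rate `k/h` (face length `h` over pixel area
`h²`), and reactions act pointwise. Because every term is linear the update
is assembled once as a sparse operator `dc/dt = M c + s` and the explicit
step is `c ← c + dt (M c + s)` — arithmetically identical to the stencil
loop, executed as one sparse matrix–vector product per step.

* **Time step.** `dt = safety · min(h²/(4 D_max), 1/k_max)` where `k_max`
  is the largest total first-order loss on any species/compartment
  (permeabilities counted as `k/h`). Default `safety = 0.5` keeps the update
  matrix non-negative even when both bounds are active, so concentrations
  stay ≥ 0.
* **Steady state.** The solver marches until
  `max |∂c/∂t| ≤ tol`, default `tol = 1e-6 ×` mean initial concentration
  per second (configurable, reported in the result). Reaching `t_max`
  without convergence sets a flag rather than raising — the fitting layer
  penalizes such simulations. Default initial condition: all protein as U,
  uniform in the cytoplasm; the steady state of the linear system is
  initialization-independent (asserted by test).
* **Accuracy.** The scheme is first order in `dt` and second order in `h`
  in compartment interiors; the membrane source term is first order in `h`,
  so steady-state compartment means carry an O(h) membrane error that is
  largest when membrane boundary layers are steep (slow diffusion, fast
  transport). Grid-refinement consistency (< 2 % on halving `h`) therefore
  holds in smooth regimes (D ≳ 10 µm²/s at h ≈ 1 µm for the default cell);
  at the default D = 2 the spatial NCR sits a few percent below the
  well-mixed value, which is physical (gradients), plus an O(h)
  discretization bias of order 1 %. The well-mixed oracle comparison uses
  the discrete membrane length (face count × h), which the operator
  reproduces exactly in the large-D limit.

## Fitting

The observable is the total-effector image U + P (the fluorescent tag labels
both forms), max-normalized exactly like the experimental targets. The cost
is

```
cost = w_img · mean_cell_px (target − model)²  +  w_ss · (max|∂c/∂t| / mean c)²
```

Both terms are per-pixel/relative so costs are comparable across geometries,
and with the default `w_img = w_ss = 1` a residual drift of 1 %/s
contributes like a 1 % image mismatch. The second term penalizes
non-converged simulations even when their snapshot happens to resemble the
target; simulation failure maps to +inf. The per-pixel averaging (rather
than summing) is a monotone rescaling at fixed geometry and does not change
any optimum.

"Summarized residual" is the mean of squared residuals over cell pixels,
consistent with the image term of the cost.

Max-normalization of a *noisy* image is biased: the maximum pixel is
noise-inflated, so the normalized target is systematically deflated relative
to a normalized (smooth) model image, which shifts the cost optimum away
from the generating parameters. `fit_cost` and `ratio_scan` therefore take a
`preprocess` hook (typically a σ = 1 px Gaussian denoiser) that is applied
*identically* to the simulated observable as was applied to the target
before normalization — compare like with like. The two-point ratio
discrimination is robust to the raw normalization; quantitative parameter
recovery is not.

Particle swarm: global-best, inertia 0.729, cognitive = social = 1.49445
(standard constriction values), reflecting bound handling, optimization in
log10 parameter space because rates span orders of magnitude. Runs are
deterministic given the seed; ensembles (e.g. 200 parametrizations) are
produced by looping over seeds, and that multi-start workflow is also the
recommended way to fit: single swarms at reduced budgets can stall on the
near-degenerate valley that links `k_phos` and `k_dephos_nuc` (a single
normalized steady-state image constrains their ratio far better than either
rate), so fits should be run from several seeds and the lowest-cost
parametrization selected. The full reference budget is 20 particles × 200
iterations; the test suite uses 20 × 50 on a 64×64 grid with two starts,
which recovers the generating ratio `r` well within 25 % on a noiseless
self-target — absolute rates are structurally non-identifiable from a
single normalized steady-state image, the ratio is the recoverable
quantity.

## Image quantification

The trained interactive classifiers used on real data are replaced by a
pluggable pixel-classifier contract (image → per-pixel foreground
probability). The deterministic baseline is Gaussian smoothing (σ = 1 px)
rescaled to [0, 1], thresholded by Otsu unless a threshold is given; an
optional random-forest backend on smoothing/gradient features is provided
for labelled data. Consequences: NCR values on real micrographs would be
comparable in trend, not absolutely, since the published thresholds are
unknown.

* **NCR**: mean nuclear / mean cytoplasmic effector intensity per FOV; cell
  count = labelled nuclear objects; FOVs split at the mean cell count
  (strictly below → low density, at-or-above → high). Minimum nucleus size
  20 px at the live-cell scale.
* **PLA**: pseudo-cytoplasm = nuclear mask dilated 30 iterations (3×3
  square, one pass per iteration) minus nuclei. Dots: classify, threshold,
  connected components; touching dots are split at local maxima (one peak =
  one dot) and the 1–50 px area range applies per split dot; assignment by
  centroid (nucleus / ring / unassigned — whether boundary dots were
  assigned by centroid or overlap in the original pipelines is unstated).
* **IHC**: tiles (1 mm², 400×400 px contract) with tissue fraction from a
  smoothed intensity mask; tiles < 50 % tissue are flagged excluded;
  positive nuclei = thresholded probability map (default 0.6) ∩ tissue,
  counted and divided by tissue area. Optional block-mean binning before
  classification; densities are invariant to it within ~10 %.
* An optional variance-of-Laplacian focus score stands in for the manual
  prescreening of out-of-focus images.

## Signature index

Per-gene z-scores are computed across *all* samples (sd with n−1; the
alternative — across time-point means — is config-exposed). Zero-variance
genes are zeroed and flagged. The activity index at time t sums the z-scores
of signature genes exceeding 0.5 (strict) and divides by the signature size;
replicate z values are averaged per (gene, time) before thresholding
(threshold-then-average is exposed as an option). Large signatures are first
restricted to genes with |fold change| > 2 versus the control mean (values
declared log2; linear input supported). Peak time is the arg-max over time
points, ties to the earliest with a flag. The shipped ROS/AKT/YAP lists are
synthetic placeholders of the published sizes (23/28/23); real lists are
user-supplied text files.

## Synthetic data

The generators are pure functions of (spec, seed). The confocal renderer
uses 512×512 px at 1.24 µm/px by default (0.4 mm² FOV) with Poisson shot
noise on gain-scaled intensities, Gaussian read noise and constant
background; PLA scenes default to 0.18 µm/px optics with diffraction-limited
Gaussian dots; IHC tiles are 400×400 px ≡ 1 mm² with a random-blob tissue
region thresholded at the quantile matching the requested tissue fraction;
expression time courses put a Gaussian bump in log-time (default peaks 8 h /
18 h / 36 h for ROS/AKT/YAP, amplitude 3 log2 units, noise sd 0.5, 4
replicates, grid 6 h–16 d) on gene-specific baselines. The density–NCR
coupling used for stratification fixtures is a logistic map from cell count
to true NCR — a fixture device, not a mechanistic claim. What these
generators do *not* emulate: PSF blur, uneven illumination, histology colour
variation, probe-level microarray noise; tests passing on them show the
pipelines are correct on their stated contracts, not that they are robust to
every real-data artefact.

Study problem sizes: ratio discrimination runs on a 128×128 single-cell
domain; fitting studies use 64×64 and 20 particles × 50 iterations; the
full 20 × 200 budget is available behind a flag (`analysis/03 --full`).

## Known limitations

* The membrane flux discretization is first order in pixel size (see
  above); published mesh/step sizes are unknown, so comparisons are
  qualitative and oracle-based, not bit-wise.
* Single-cell fitting only; multi-cell joint fitting is a driver-level loop.
* No implicit or adaptive time stepping; very fast permeabilities near the
  bound edge make the explicit step small and, combined with synthesis and
  negligible export, can produce physically unbounded accumulation that is
  reported as non-convergence and penalized, not raised.
* SBML export is not provided; model interchange uses the YAML
  serialization.
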