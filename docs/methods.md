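# Methods

This note documents the models, numerical choices and limitations behind
`bofem`. It is written for someone who wants to know exactly what the
simulations emulate and what a passing test suite does (and does not)
demonstrate about real micrographs.

## Image model and simulator

A noiseless micrograph is a sum of 2D projections of a 3D phantom placed
at uniform-random, non-overlapping positions (rejection sampling, minimum
center separation 0.8 × box, at most 10⁴ draws per particle) with
uniform-random in-plane rotation (bilinear interpolation about the box
center). The micrograph is then multiplied in Fourier space by a
weak-phase CTF and i.i.d. Gaussian noise is added.

**Phantoms.** Two synthetic structures are built from 3D Gaussian lobes
plus ~220 "pseudo-atoms" (small Gaussians, σ 3–5 Å, scattered inside the
lobes with a fixed seed so each phantom is a deterministic object):

* a compact three-fold-symmetric *trimer* (~100 Å wide, ~110 Å tall) —
  the imaged particle;
* a mushroom-shaped *decoy* (broad cap, stalk, three feet) — the
  "unrelated structure" used as a deliberately wrong picking template.

The pseudo-atom texture matters: smooth lobes alone have almost no
spectral power in the 20–50 Å band where real protein projections (and
the reference-bias effect measured there) live. Projections are rendered
by rotating the voxel grid (uniform random orientations via random
rotation matrices) and summing along z; projection orientation is exact
to bilinear interpolation, and line-integral mass is conserved to
interpolation tolerance.

**CTF.** CTF(k) = −[√(1−A²)·sin γ(k) + A·cos γ(k)]·E(k) with
γ(k) = −π λ k² Δf − (π/2) Cs λ³ k⁴, relativistic λ at the stated
voltage, and Gaussian envelope E(k) = exp(−k²/(2b²)). Defaults: 200 kV,
Δf = −1 μm (underfocus), Cs = 2.0 mm, A = 0.10, b = 0.333 Å⁻¹. The sign
convention is chosen so that a stated negative (under)focus yields a
transfer function that is negative from DC through its first zero
(≈ 0.062 Å⁻¹ at these settings): particles appear dark on a bright
background across their entire shape band, which is the contrast regime
in which single-template picking is coherent. Feeding the stated defocus
into γ with the opposite sign (available as `defocus_sign=+1`) splits
the low-frequency band into opposite-contrast halves at ≈ 89 Å and makes
envelope-scale template matching nearly blind; we treat the single-sign
convention as the physically intended reading. The envelope "half width"
is interpreted as the Gaussian σ of E(k); it is configurable and isolated
in one function.

**Noise and SNR.** SNR is the variance ratio σ²_signal/σ²_noise. For a
micrograph, σ²_signal is the variance of the full noiseless (CTF-applied)
micrograph; noise is i.i.d. Gaussian with variance σ²_signal/SNR. The
realized ratio matches the target within 1% on ≥10⁶-pixel fields.
Because empty background dilutes the variance, micrograph SNR
understates single-particle SNR by the area factor
(micrograph area)/(n · box²) — ×1.6 at the reference density, so
micrograph SNR 0.005 ≈ single-particle SNR 0.008.

**Scales.** The reference geometry is 4096² at 1.0 Å/pixel with 323
particles in 180-pixel boxes. The desk geometry (2048², 2.0 Å/pixel,
box 90, 323 particles) is exactly the 2×-binned frame of the reference:
density, physical particle size and CTF are unchanged. SNR labels are
always quoted at the reference scale; when noise is added at desk
resolution the target is multiplied by the binning factor squared
(`binned_snr`), because decimating white noise raises the variance-ratio
SNR by f² while leaving the smooth signal nearly unchanged. This is what
makes desk-scale false-positive and drop-off measurements comparable to
reference-scale ones.

## Picking templates

Three template choices are emulated: a *Gaussian circle* (radial
Gaussian, σ = 0.15 × box — about half the particle radius), a projection
of the *imaged phantom*, and a projection of the *decoy*. Projection
templates are low-passed to 30 Å with a gentle 10-Fourier-pixel cosine
edge (imitating the Gaussian rolloff of classic template preparation) and
contrast-matched to the data: the simulation CTF is applied when the data
carry a CTF, otherwise the template is negated (pure-noise controls).
The Gaussian-circle template is used dark (negative amplitude) for the
same reason. Without contrast matching, the mixed CTF signs across the
template band largely cancel the correlation.

## FLC numerics

The three sliding sums are evaluated with FFT convolutions in float64
(so the Cauchy–Schwarz bound |C_L| ≤ 1 survives rounding on 16-Mpixel
maps); σ²_MT is clamped at 0 before the square root, and positions with
σ_MT below max(10⁻⁶ × global std, tiny) are flagged invalid and set to 0.
Only footprint positions fully inside the micrograph are evaluated
("valid" mode). The mask defaults to a filled disk of diameter
0.9 × box. Peaks are 3×3 local maxima visited in descending value
(row-major on ties, logged) with greedy euclidean suppression at radius
0.5 × box. FFT evaluation is verified against a brute-force double loop
to 10⁻⁸ on random instances.

## EM alignment

* **Grid.** Rotations every 5° and integer shifts within ±3 pixels by
  default (`TransformGrid.make`); the desk pipeline uses 10–12° and ±2 at
  box 45–64 to keep a 5-class, 2000-particle run in minutes. The grid is
  a declared discretization, not a claim about any external
  implementation.
* **Priors.** Uniform over rotations and classes (mixing weights
  learned); isotropic Gaussian over shifts with width ξ normalized over
  the shift grid, updated as the responsibility-weighted RMS shift and
  floored at 0.3 px; ξ = ∞ gives a uniform shift prior.
* **σ model.** One scalar σ shared by all classes and pixels. The M-step
  updates σ from the E-step's expected residual (coordinate ascent on the
  EM objective: first σ given the old averages, then the averages given
  the data — each step increases the bound, so the log-likelihood is
  non-decreasing up to interpolation error; the suite asserts
  ΔL ≥ −10⁻⁶|L|).
* **E-step.** Log weights via a single particles × transformed-references
  matrix product, normalized per particle with log-sum-exp;
  responsibilities below 10⁻¹² truncated and renormalized. Computation
  follows the input dtype: float64 in the small oracle tests (equality to
  enumeration within 10⁻¹⁰), float32 in the pipeline.
* **M-step.** Class averages by back-transforming the
  responsibility-weighted image sums (shifts combined before the single
  inverse rotation per class/rotation — mathematically identical,
  ~25× fewer interpolations).
* **Starts.** `random_noise_image` (K stack members), `gaussian_circle`
  (K copies of a radial Gaussian scaled to the data std, each perturbed
  by 1% seeded noise so classes can diverge), `unaligned_average`
  (averages of K random disjoint subsets — this start deliberately
  carries whatever bias picking imprinted).
* **Empty classes** (total responsibility < 10⁻⁶ N) are reseeded from the
  worst-explained particle and the event recorded in the trace.
* Convergence at |ΔL| < 10⁻⁷|L| or `max_iter`; milestone class averages
  are snapshotted for the iteration-history figures/curves.
* Mirror latent variables are not modeled.

## Evaluation

* **Matching**: greedy one-to-one in descending rank; a pick is a true
  positive if an unmatched truth center lies within d_max = box/4.
* **Drop-off**: moving median (window 5, edge-replicated) then the argmax
  single-step drop; a drop that does not exceed 3× the mean remaining
  step is flagged low-confidence.
* **FRC**: single-Fourier-pixel rings; a soft circular mask (cosine edge,
  radius 0.45 × box) is applied first (switchable) to suppress box-edge
  cross terms. FRC-0.5 is the first low-to-high crossing, linearly
  interpolated; never-≥0.5 curves report 0 and never-<0.5 curves report
  Nyquist (logged). `aligned_frc` maximizes the masked inner product over
  rotation/shift before comparing — needed when a class average's
  in-plane orientation is arbitrary relative to a reference projection.
* **Power spectra**: |F|²/J ring means excluding DC, satisfying Parseval
  over the Nyquist disk; SSNR is the ring-power ratio of the noiseless
  micrograph to the recovered noise realization.

## What the tests show — and what they do not

The pure-noise controls reproduce the reference-bias phenomenology at
desk scale: the unaligned average of noise picks correlates with the
picking template above 0.5 throughout the 20–50 Å band, EM started from a
Gaussian circle drives the correlation below 0.5 everywhere above
0.02 Å⁻¹, and EM started from the unaligned average retains the replica
with a slowly decaying FRC-0.5 crossing. The signal experiments show
recovery of true structure (not the decoy template) from micrograph SNR
0.005 with ~2000 particles. The control geometry matters: the strength of
per-particle selection bias scales like 1/(mask area), so a faithful
scale-down keeps the box large (128 px) and the pick density low
(~12 per 1-Mpixel noise field); shrinking the box or picking more densely
produces a bias strong enough that *any* optimizer, including EM, will
lock onto the replica — a regime the reference conditions avoid.

The simulator emulates: projection imaging with a single CTF, white
Gaussian noise, isolated particles, exhaustively known ground truth. It
does **not** emulate structured ice/carbon background, contamination,
detector MTF, dose/motion effects, defocus variation within or between
micrographs, particle overlap or aggregation, or conformational
heterogeneity. Passing tests therefore demonstrate the internal
consistency and the noise-robustness mechanism of the two objective
functions, not end-to-end performance on real data.

Observed deviations from the reference behavior are recorded where they
occur: at micrograph SNR 0.002 the measured false-positive rate of the
Gaussian-circle template (≲1%) is well below the ≈7% reference value;
our picker at full template resolution is more specific than the
original SPIDER-based workflow (which was typically run on 2–4× binned
micrographs, reducing the matched-filter gain). The corresponding
acceptance check is left failing rather than degrading the picker to
match.

## Problem sizes used in the automated runs

Module tests run on toy instances (≤ 64² images). The acceptance-level
tests use: 3 desk micrographs per picking condition; 250 noise fields of
1024² for the controls (≈3000 picks, EM on 2000 at box 64); 7 desk
micrographs (≈2000 particles, EM at box 45, K=5, 25 iterations) for the
recovery experiment. `scripts/acceptance.py` uses the full reference
micrograph size (4096²), three seeded micrographs per condition.
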