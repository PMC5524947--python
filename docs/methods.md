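# Methods

## Model and procedure

`alignval` scores each particle image of an SPA dataset for alignment
precision and accuracy against the map reconstructed from it.  Three steps
run per particle:

1. **Global search.**  The map is projected on a near-uniform angular grid
   (equal-area spiral lattice filtered to one asymmetric unit, sampling rate
   Δ).  Each grid projection is distorted by the particle's own CTF, then the
   particle is aligned against every projection by exhaustive in-plane
   rotation (step = Δ by default) with an FFT translational search per
   rotation, under a circular mask.  The ξ best-scoring projections form the
   particle's match set: directions `p_k` with NCC weights `w_k`.
2. **Statistics.**  Precision statistic α = weighted mean pairwise geodesic
   distance among the `p_k` (symmetry-aware: distances are minimized over the
   point-group operators).  Accuracy statistic χ = weighted mean geodesic
   distance from the recorded direction `p̂` to the `p_k`.
3. **Calibration.**  α maps linearly to a score `q_p` with the Monte-Carlo
   noise clusterability `α̂_NOISE` at 0 and the perfect-reference `α_m,good`
   at 1 (χ likewise for `q_a`).  The perfect reference is the map projected
   at the particle's recorded orientation and shift, CTF-applied, no noise,
   pushed through the *same, independent* global search.  Q is the percentage
   with both scores ≥ τ; pruning keeps that subset.

Assumptions: particles are independent projections of a single structure
plus noise; the CTF is the standard weak-phase model
`−√(1−A²)·sin γ − A·cos γ` with
`γ = πλΔz(θ)f² − (π/2)C_s λ³f⁴ + phase shift`; projection directions `p` and
`−p` are distinct (no mirror search).  The check is one-sided: low scores
refute an alignment, high scores cannot prove it.

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| ξ | 7 | matches kept per particle; on a near-hexagonal grid each node has ~6 neighbours, so a well-aligned particle can fill its match set from one grid cell |
| Δ | 5° | angular sampling of the grid (and default in-plane step); the standard rate for global searches |
| M | 500 | Monte-Carlo repeats for the noise references; the standard error of `α̂_NOISE` is ≈ 0.19/√M rad ≈ 0.5° at M=500 |
| τ | 0.5 | pass threshold, the midpoint between the noise (0) and perfect (1) references; inclusive (≥) |
| max shift | box/8 px | translational search bound; generous vs. typical residual shifts |
| mask radius | 0.45·N px | NCC mask; excludes rotation corner artifacts |
| symmetry | C1 | point group (C*n*/D*n*/T/O/I); defines the asymmetric unit for grids, random draws and distances |

Noise references use **unit weights** (the NCC weighting in α/χ comes from
real matches; random angular draws have no similarity value).  `χ̂_NOISE` is
computed per particle at its own `p̂` — for non-trivial symmetry the
distance-to-uniform distribution depends on where in the asymmetric unit the
particle sits; for C1 it collapses to the constant π/2 in expectation.  All
Monte-Carlo draws derive from a single run seed with per-particle
substreams, so reports are deterministic and independent of evaluation
order.

In **precision-only mode** (no recorded orientations, e.g. ranking ab initio
maps) the perfect counterpart is built at the particle's rank-1 match
orientation — the natural stand-in given that no refined orientation exists —
and only `q_p` is reported; Q then reduces to the percentage of precise
particles.

## Numerical choices

* Euler convention ZYZ `(rot, tilt, psi)`, degrees in metadata, radians
  internally; the viewing direction is `(sin t cos r, sin t sin r, cos t)`;
  image origin at the center pixel `N//2`.
* Projection is real-space: trilinear resampling of the volume on the
  rotated ray grid, summed along the ray (one-voxel step, so pixel values
  carry density·Å).  Linear in the volume by construction; bilinear/trilinear
  interpolation everywhere for determinism and speed.
* `arccos` arguments are clipped to [−1, 1]; coincident directions give
  exactly 0.
* The asymmetric-unit representative of a direction is its symmetry image
  with lexicographically largest `(z, x, y)`; sampling draws uniformly on
  the sphere and canonicalizes (the canonical map is a piecewise rotation,
  so area-uniformity is preserved).
* The grid is an equal-area spiral lattice sized so neighbours sit ≈ Δ
  apart (hexagonal-packing estimate), filtered to the asymmetric unit and
  de-duplicated under the symmetry-aware distance at Δ/4.
* The translational search evaluates the cross-correlation only at the
  offsets inside the shift bound, via a direct window DFT (two small matrix
  products per rotation) rather than full inverse FFTs; both images are
  mask-normalized and zeroed outside the mask, which bounds NCC in [−1, 1]
  exactly (Cauchy–Schwarz).
* Scores are **not clamped**; values beyond [0, 1] are genuine (discrete
  grid + small ξ make the experimental search occasionally beat or trail its
  reference) and are reported as-is.
* Degenerate cases flag the particle as failing instead of aborting:
  references closer than 1e-9 (`degenerate-reference`), all-zero weight
  products (`degenerate-input`), constant images raise a dedicated error.
* Ties in the top-ξ selection break toward the lower grid index; the
  in-plane/shift argmax takes the first maximum in scan order.

## Synthetic data

`alignval.synthetic` generates the study datasets: a phantom volume (sum of
isotropic Gaussian blobs) and particle stacks with ground-truth labels.
Signal particles are projections at uniform random directions (uniform
in-plane angle, shifts up to box/10), CTF-distorted at defocus drawn from
0.8–2.5 µm, plus additive white Gaussian noise scaled to a target SNR
defined as the masked signal/noise variance ratio — measurable directly on
the output.  Contaminant classes mirror the failure modes the scores are
meant to catch: pure-noise images (should fail precision), bright-spot
artifact images (one Gaussian spot at 5× signal RMS) and wrong-conformation
particles from a perturbed phantom (should keep precision but lose
accuracy), plus optional deliberate randomization of recorded orientations
(misassignments a refinement could have committed).

The default phantom is a 48-box (voxel 1.5 Å) with 32 small blobs
(σ 0.9–1.8 voxels) packed inside a 15-voxel radius.  The dense texture is
deliberate: real particles present enough structural detail that NCC falls
off with angular distance, which is the property the clusterability
statistic exploits.  A phantom of a few large blobs projects nearly alike in
every direction and misrepresents the method's operating regime (its match
sets are spread even for noiseless images).  `default_phantom_spec(box)`
rescales the same geometry; tests use the 32-box variant where speed
matters.

What the generator does *not* emulate: colored/structured noise, per-pixel
detector statistics, beam-induced motion, partial CTF correction errors,
crowded or overlapping picks.  Passing tests therefore demonstrate the
method's behaviour under its own assumptions (white noise, single structure,
correct CTFs), not performance on every real-data pathology.

## Problem sizes used by the test suite

The shipped tests and the acceptance script run desk-scale versions of the
method's experiments: 32-box datasets at Δ = 15° for the noiseless
self-consistency and orientation-corruption checks (200 particles), the
48-box phantom at Δ = 10° for the SNR 0.1 signal-vs-noise discrimination
(200 + 200 particles), and Δ = 15°, SNR 2, 60 particles for the
precision-only map ranking.  M = 500 throughout.  These sizes keep a full
run in minutes on one CPU while leaving the per-particle checks far from
their margins (the map-ranking experiment is the exception discussed
above).

## What precision-only ranking can and cannot see

The precision score is calibrated *per map*, between that map's own noise and
perfect references.  It therefore measures whether particles align
consistently **with respect to the candidate map**, not the map's absolute
quality.  Two consequences, both measured on the phantom datasets:

* Pure low-pass degradation of a map does not lower its precision
  aggregates: a blurred map still aligns particles consistently against
  itself (at low SNR, smooth references are actually *more* noise-robust
  matched filters, and the blurred map scores higher).  Ranking a sharp map
  above a smoothed copy of itself by mean precision score is outside what
  the statistic resolves at desk scale; the corresponding check in the test
  suite documents this and currently fails by design of the experiment.
* The mean of the unclamped scores is heavy-tailed: particles whose
  reference clusterability lands near the noise reference produce
  ratio-type outliers (observed |q_p| up to ~50 in 60-particle runs).  The
  per-map fraction of precise particles (q_p ≥ τ) is the stabler aggregate
  and is always reported alongside the mean.

Ranking is informative when candidate maps differ *structurally* (a wrong
map cannot cluster particles that do not belong to it), which is the
good-vs-bad contrast the mode is intended for.

## Limitations

* NCC under a fixed circular mask, no low-pass weighting: very low SNR data
  (≲ 0.05 at small box sizes) loses angular contrast before the scores
  degrade gracefully.
* No mirror/handedness search; maps with near-mirror-symmetric projections
  can place antipodal directions in a match set, inflating α for both the
  particle and its reference (the calibration absorbs most of this).
* The perfect reference shares the discrete grid with the experimental
  search, so scores slightly beyond 1 / below 0 are expected; they carry no
  extra meaning.
* Runtime is dominated by the per-particle search, O(grid × rotations);
  per-particle CTF filtering of the reference stack is cached only across
  consecutive identical CTFs.
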