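# Methods

This note documents the physics models, parameter choices and numerical
decisions behind ccbrachy, and what its verification does and does not
establish.

## Successive-scattering decomposition

The dose around a photon source separates by scatter generation: primary
photons deposit collision kerma where they first interact; the energy
they scatter (the first-scatter scerma S1sc) is transported by a
first-scatter kernel; the energy scattered *again* (second-scatter scerma
S2sc) is transported by a multiple-scatter kernel that covers all
generations ≥ 2 at once, closing the Neumann series.  All doses are
collision kerma in MeV/g per emitted source photon — the engine and the
Monte Carlo reference share this surrogate (electron transport disabled;
the secondary-electron ranges at ¹⁹²Ir energies are below the voxel
size), and they share the same interaction-coefficient tables, so their
comparison isolates the transport algorithm.

Stages:

1. **Primary**: exact per-line raytracing.  For spectral line i,
   Ψ_i(v) = w_i E_i exp(−Σ_m t_m (μ/ρ)_{m,i})/(4π d²), with t_m the
   density-weighted mass thickness of medium m between source and voxel
   center (Siddon-style grid traversal) and d the source distance;
   D_prim = Σ_i Ψ_i (μen/ρ)_i.  The source voxel uses the analytic
   finite-volume mean of 1/d² over a cube (≈ 15.35/h² for voxel side h).
2. **S1sc** = Σ_i Ψ_i [(μ−μen)/ρ]_i — everything removed from the primary
   beam that is not locally absorbed, including coherently scattered
   energy.
3. **First-scatter dose**: collapsed-cone superposition (below) with the
   water 1sc kernel; attenuation scaled by η_1sc and absorption by
   χ_1sc/η_1sc per voxel (both scalings are part of the baseline
   algorithm for this generation).
4. **S2sc** = D_1sc (μ̄−μ̄_en)/μ̄_en with 1sc-spectrum averages of the
   local medium.
5. **Multiple-scatter dose**: the two-term line recursion in `original`
   (η only) or `corrected` (χ/η with the transported-energy re-balance
   R̂_corr) mode.

## Collapsed-cone transport

Space is partitioned into M equal-solid-angle cones (zenith-uniform
rings; M = 1620/240 for 1sc/msc in the high-accuracy profile, 320/72 in
the desk-scale profile).  For each direction, parallel transport lines
seeded on a perpendicular lattice of spacing h/√2 traverse the grid
(this spacing guarantees every voxel is crossed: every voxel's projected
shadow contains a disc of diameter h).  Δl_max is the per-voxel,
per-direction total crossing length; with line cross-section A and
κ = V/(A Δl_max) the per-line release σ_j Δl_j reproduces each voxel's
released energy exactly on the finite lattice.  The recursion conserves
energy identically (released = deposited + boundary exit, to float
precision, in both modes) — verified per step, per line and globally.

Kernel cones are indexed by the polar angle between the transport
direction and the local *incident* direction, approximated by the radial
unit vector from the source (exact for primary→1sc; an approximation for
1sc→msc, where the 1sc fluence is only predominantly radial).  The
source voxel, where the radial direction is undefined, releases with
4π-averaged kernel amplitudes.

## Kernels and scatter spectra

Forced-interaction Monte Carlo in infinite water generates the kernels:

* **1sc kernel**: vertex energies sampled ∝ w_i E_i μ_i (a primary line
  feeds first-scatter release in proportion to its energy fluence times
  its interaction probability); the generation-1 photon's expected
  collision kerma E·μen/μ is tallied at its first interaction site in 48
  polar cones × 72 log-radial bins to 40 cm.  Its integral (≈ 0.26) is
  the fraction of released 1sc energy deposited as 1sc kerma.
* **msc kernel**: vertex energies from the 1sc spectrum; all deposition
  by generation ≥ 2 descendants is tallied.  The kernel integral is
  normalized to exactly 1 (in infinite water all released multiple-
  scatter energy is eventually absorbed), which also makes the global
  balance ∫S2sc ρ dV = ∫D_msc ρ dV + boundary exit hold by construction.

Each cone's r²-weighted radial profile is fitted with
C e^{−cr} + F e^{−fr}.  Two deliberate deviations from a naive per-cone
positive bi-exponential:

* **Negative F (build-up pair)**: the multiple-scatter profile *rises*
  to a peak near 7 cm (diffusion build-up); a sum of positive decaying
  exponentials is completely monotone and cannot represent it.  A
  difference C e^{−cr} − |F| e^{−fr} with |F| ≤ C, f > c captures the
  build-up while the kernel value stays non-negative.  In the transport
  the F-term then carries a negative partial fluence and is never
  clamped; only the net deposit is physical (transient negative voxels,
  clamped to zero, are counted in the diagnostics and are absent in the
  benchmark runs).
* **Shared exponents across cones**: (c, f) are fitted globally
  (minimizing the summed per-cone cost) with per-cone amplitudes.  With
  per-cone exponents, fluence carried along a line would be attenuated
  with the wrong coefficient whenever the line's polar bin changes along
  its path; with shared exponents the recursion reproduces the fitted
  kernel exactly (validated by point-release transport tests, agreement
  within a few percent at all radii).

Scatter spectra: the 1sc spectrum is the energy spectrum of photons
leaving the forced vertex; the msc spectrum is the energy-fluence
spectrum of generation ≥ 2 photons within 12 cm of the vertex.  The η/χ
factors rescale energy transport and absorption, so energy-fluence
weighting is the consistent average; the radius restriction excludes the
soft diffuse bath that accumulates at radii beyond any phantom of
interest and would otherwise dominate the average (number-fluence,
volume-integrated weighting yields χ_msc/η_msc ≈ 2.3 for cortical bone —
the conversion factor of a field that is nowhere present at the
benchmark distances — versus 1.40 with the energy-fluence, phantom-scale
definition).

## Interaction coefficients

No cross-section compendium ships with the runtime environment, so the
per-element tables (H, C, N, O, Na, Mg, P, S, Ar, Ca; 1 keV–1.5 MeV) are
generated from a semi-analytic model anchored on embedded water values:
exact Klein-Nishina incoherent cross sections (free stationary
electrons) with numerically integrated energy-transfer moments; a
photoelectric term τ/ρ = C(E) Z^p(E)/A with p ramping 4.15→4.45
(10 keV→1 MeV) and C(E) solved so the water mixture reproduces the water
μen/ρ anchor exactly; and a coherent term from the water μ/ρ residual,
distributed ∝ Z³/A.  Water is exact by construction; bone-to-water
coefficient ratios agree with published compendium values within ~3 %
above 100 keV and ~5–13 % at 40–80 keV.  Because engine and reference
share these tables, table errors cancel to first order in the Δ
comparison.  Pair production (< 0.3 % of μ below 1.4 MeV for low-Z
media) and post-photoelectric fluorescence (K yields < 0.2, sub-4 keV
photons) are neglected.

The ¹⁹²Ir source is a bare point emitting a 29-line spectrum (Pt/Os K
x-rays and γ lines, 61 keV–1.38 MeV, mean 0.354 MeV); no encapsulation
or self-absorption.  `fit_coeffs_over_distance` provides
hardening-corrected effective coefficients (least-squares single-
exponential match of the exact spectral attenuation over a 0–10 cm
range, 1 cm sampling, unweighted); the engine's primary raytrace is
per-line exact, so the fitted coefficients serve analysis rather than
the dose chain.

## Monte Carlo reference

Photon random walks on the voxel grid with exact per-voxel free paths;
Compton via free-electron Klein-Nishina sampling (composition-rejection),
terminal photoelectric absorption, Thomson-angle Rayleigh (form-factor
free) that by default increments the bookkeeping number like any photon
interaction — matching the engine's bookkeeping, which counts coherently
scattered energy as next-generation.  Photon cutoff 1 keV (local
deposit).  Kerma is scored by a track-length estimator per generation
class.  Interaction forcing (within a 12 cm radius) splits each flight
into an analytically scored escape branch and a collision branch drawn
from the truncated free-path distribution — the simple track-length
tally stays unbiased, verified against the analog estimator.  Russian
roulette below weight 0.02 (survival 0.25).  Type A uncertainties use
history-by-history accumulators per voxel and, exactly, for a run-time
region mask; post-hoc regions fall back to an independent-voxel
approximation that ignores intra-history correlations.

## Benchmark geometry and the desk-scale profile

Benchmarks: a 30.1 cm water cube, 0.1 cm voxels (301³), with a
2.1×2.1×3.1 cm³ box of cortical bone (center 6 cm or 3 cm from the
source) or air (3 cm); box faces lie exactly on voxel boundaries, and the
full-resolution box contains 13 671 voxels.  The desk-scale profile used
for verification runs scales this world down: 0.2 cm voxels on a 16.2 cm
phantom (81³; an odd voxel count keeps the source on a voxel center),
box faces snapped to the nearest boundaries (2.2×2.2×3.0 cm³, 1815
voxels), 320/72 directions, ≥ 2×10⁶ forced histories.

What a green desk-scale comparison establishes: the engine's generation-
resolved agreement with an independent Monte Carlo on the same world, the
bone under-dosage of the original msc transport, and its removal by the
χ correction.  What it does not establish: absolute agreement with
published production-scale figures.  In the 16.2 cm phantom the
multiple-scatter share of the total dose at the 6 cm box is ≈ 0.29
versus ≈ 0.4 in a 30.1 cm phantom, which proportionally shrinks every
Δ̄; the point-source approximation, the semi-analytic coefficient tables
and the reduced resolution add further scale differences of a few
percentage points.

## Known limitations

* The bi-exponential (even with the build-up pair) redistributes ≈ 7 %
  of in-range multiple-scatter deposition into the tail once the kernel
  integral is closed to 1; the engine correspondingly runs a few percent
  below the reference in near-source water and slightly over near the
  phantom boundary (where the infinite-water kernel counts "leave and
  re-enter" paths a truncated phantom cannot return).
* χ/η are spatially constant per medium, derived from the water scatter
  spectra; inside a bone insert the real msc spectrum hardens, so the
  corrected mode residually misses at interfaces (the same limitation
  the full-scale algorithm exhibits).
* The collapsed-cone discretization leaves the familiar spiky
  first-scatter artifacts; the Δ_1sc distributions are positively skewed
  while their means stay near zero.
* The media-scaling architecture is not meant for high-Z shields (media-
  specific kernels would be required).
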