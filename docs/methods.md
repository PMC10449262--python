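# Methods

## Signal model

An OCT A-scan is modelled in the single-scattering regime. The irradiance
decays per Lambert–Beer,

    L(z) = L(0) · exp(−2 ∫₀^z μ(u) du),

with μ(z) the attenuation coefficient (1/mm; the factor 2 is the round
trip), and the digitised intensity is the locally backscattered portion of
the attenuated light,

    I(z) = −β R(z) dL/dz = 2 β R(z) μ(z) L(z),

where R(z) ∈ (0, 1) is the backscattering fraction (the part of the
attenuated light scattered into the detection aperture) and β the
detection conversion factor. Only the product βL is observable; the
incident level βL(0) is an instrument constant measured from a strong
reflector. For an ideal sphere suspension R follows from the volume
scattering function γ(θ): the implementation integrates γ(θ)·sinθ over
the *backward* cone [π − arcsin(NA), π] against the full sphere
(`phase_R`), and the anisotropy g is the γ-weighted mean cosine
(`phase_g`); both use 512-node Gauss–Legendre quadrature. The backward
cone is used because light collected by an objective of acceptance
half-angle arcsin(NA) is backscattered light; a forward-cone bound would
contradict the θ > 90° regime the quantity describes.

Depth is in millimetres everywhere, sample *i* of a grid sits at
`z0 + i·dz`, depth windows are half-open index ranges, and dB values are
`10·log10(I/db_ref)` with a configurable reference (default 1 A.U.,
since the floor thresholds are conventionally quoted without one).

## Baseline estimator and its bias

The depth-resolved baseline is `μ₀(z) = I(z) / (2 ∫_z^∞ I)`. It is exact
when R is constant and biased otherwise: dividing the model equations
shows the error at z is controlled by ∫_z^∞ R′(u) L(u) du — only R
variation *below* the evaluation depth matters, and the bias is largest
just above each interface. Conversely, the pointwise inversion

    R(z) = I(z) / (2 βL(0) μ(z)) · exp(+2 ∫₀^z μ)

is exact given the true μ. Composing the two is an exact identity: for
*any* input, `init_R(vermeer_mu(I))` is constant and equal to the
sample-average backscattering `R̃ = ∫₀^∞ I / βL(0)`. The coupled system is
underdetermined — both equations derive from the same intensity model —
so a naive alternation between them is the identity map and never leaves
its starting point. Any working scheme must inject independent
information; here that is the local decay of I inside homogeneous
segments (below).

## The constrained stationary iteration

`solve` alternates two half-steps under constraints:

1. **μ update** (`update_mu`, default mode `ratio`): apply the baseline
   formula to I/R_k. Since I/R = −β dL/dz, this is exact whenever the
   piecewise-constant R_k is exact. The alternative mode `correction`
   evaluates the explicit bracketed correction factor with the
   distributional derivative of R_k (one impulse ΔR per breakpoint) and
   the previous iterate μ_k in the exponentials; the two modes agree to a
   few percent at interior depths for moderate R contrast, and `ratio` is
   the default because it needs no derivative of R.
2. **R refresh**: the raw profile `init_R(I, μ)` is *fuzzily processed* —
   its derivative is thresholded at `deriv_factor` (default 4.5) times its
   mean absolute value; contiguous low-derivative runs become segments
   replaced by their mean, above-threshold pixels join the adjacent
   *deeper* segment (attenuation bias only propagates upward, so boundary
   pixels must not contaminate the shallower mean). Each segment is then
   *anchored*: its local attenuation is re-fitted from its own
   exponential decay (log-linear least squares inside the segment,
   trimming the absorbed boundary pixels) and the pointwise inversion with
   this anchored μ, averaged per segment, gives the segment's R. Anchoring
   is what breaks the degeneracy: the within-segment decay is information
   the global inversion never uses, and it makes the true profile an
   attracting fixed point. On the noise-free four-layer phantom the loop
   converges in 2–3 iterations with per-layer errors below 0.5%.

Numerical details that matter:

* the derivative used by the fuzzy processing is a *backward* difference
  of ln R. Backward, because it flags exactly the sample where a step
  occurs, so the segmentation of the solver's own piecewise output is
  stationary from loop to loop (a centred difference smears steps over two
  pixels and the regenerated breakpoint creeps one pixel per pass).
  Logarithmic, because structural changes of R are multiplicative and the
  effective R of layered tissue spans decades; an absolute-derivative
  threshold is set by the noisiest bright region and misses every step
  elsewhere, while the log derivative treats each decade alike (and is
  equivalent on profiles confined to one decade);
* re-segmentation across loops is hierarchical: the fuzzy threshold is
  recomputed *per segment* each loop, adapting the scale to the local
  range of R; sub-segments shorter than 5 pixels merge into their deeper
  neighbour. Re-segmentation always runs on the data-anchored raw
  inversion, never on the fed-back staircase;
* cumulative attenuation integrals use the left-Riemann rule (exact for
  staircase profiles whose jumps sit on samples — the trapezoid rule
  charges half a pixel of the deeper layer to the interval above every
  jump and the error compounds exponentially); semi-infinite intensity
  integrals use the trapezoid rule plus the analytic tail, with the
  half-pixel above the surface jump removed;
* the first 2 pixels below the detected surface are excluded from R
  estimation (edge effects of the discrete integrals).

**Constraints.** R must lie in (0, 1) and every segment mean inside
(A·R̃, B·R̃); μ_k/μ₀ is clamped to [C, D]; at most E loops; the loop stops
once the largest relative change of μ (at its own argmax depth) falls
below `rel_tol` = 1%. Defaults {A, B, C, D, E} = {0.1, 10, 0.2, 5, 10}
are loose enough never to bind on the phantoms while preventing runaway
compensation. The R-band constraints are enforced by *projection*
(clipping segment values into the band at every refresh), exactly like
the μ clamp: aborting on first violation would end the loop at k = 1 on
noisy data because of a single outlier segment, whereas projection keeps
every emitted state feasible. For the 13-layer retinal scene the band is
opened to (1e−4, 100)·R̃ (`retina_iteration_config`), a choice made a
priori from the scene itself: the backward phase-function density alone
varies ~10× between its g = 0.84 and g = 0.98 layers, with the
scattering-coefficient contrast on top.

## Preprocessing

* **Averaging**: elementwise mean over a temporal window (default 5
  B-scans), cutting fully developed speckle variance by ~1/N.
* **Axial PSF**: Lorentzian confocal factor
  `H(z) = ((z − z_f)/z_R)² + 1)⁻¹`; correction divides it out.
  Sensitivity roll-off defaults to identity (negligible for a 12 mm
  coherence-length swept source) but any per-depth vector is accepted.
* **PSF calibration**: two images of one reflector shifted by a measured
  Δz; (z_R, z_f) minimise the L1 norm of the H-normalised difference over
  the depth overlap, summed over all A-scans, by exhaustive search over
  Cartesian grids (defaults z_R ∈ [0.01, 2] mm, z_f ∈ [−1, 3] mm, step
  0.01; ties break toward the smallest z_R then z_f).
* **Noise floor**: on the median-filtered dB trace (window 5, to avoid
  speckle-triggered early crossings) the first depths beyond the peak
  where the trace falls to `start_db` (58) and `floor_db` (50) bound the
  distal fit window; a trace sitting exactly on the floor approaches it
  from above, so arrival within 1 dB counts as crossing. The decay is
  fitted log-linearly on the floor-subtracted intensity (the floor level
  estimated from the flat region beyond the crossing) and then refined by
  a three-parameter fit `a·exp(−2μz) + c`, because the initial floor
  estimate is residual-signal-contaminated and over-steepens the slope.
  Values beyond the crossing are replaced by the fitted exponential and
  the profile carries the closed-form tail, so every ∫_z^∞ includes the
  exact analytic remainder — without this the baseline underestimates μ
  at mid-depth (the package reproduces both the bias and its removal).
  Whether the thresholds apply before or after averaging is a free
  choice; they are applied after, matching the processing order.

## Monte Carlo model

Weighted-photon transport through plane-parallel layers in the classic
multi-layer scheme: dimensionless exponential step sampling with carry-over
across boundaries, Henyey–Greenstein scattering, absorption by weight
deposition, unpolarised Fresnel reflection/refraction at mismatched
interfaces, Russian roulette below weight 1e−4 with survival 0.1. Roulette
is implemented as an exchange with the absorbed pool (a kill deposits the
weight, a survival withdraws the boost), so the launched weight is
conserved exactly per run — an assertable invariant rather than an
expectation. The packaged retinal scene has 13 layers (inner limiting
membrane through sclera) with tabulated thickness (µm), index,
absorption and scattering (1/cm) and anisotropy, air above (specular entry
reflex bookkept as reflected weight), an index-matched half-space below,
detection NA 0.05, detector radius one lateral step (10 µm), 5 µm
coherence gate.

**Detection.** A photon is detected when it leaves the top surface within
the detector radius and inside the acceptance cone `sin θ_air ≤ NA`. The
analog estimator records those exits directly, but at NA 0.05 the yield is
a few photons per 10⁵ launched — unusable at desk scale. The default
estimator is therefore next-event estimation: at every scattering vertex
of a still-descending photon within the detector radius, the photon
tallies `weight × HG density toward vertical × cone solid angle ×
exp(−τ_up) × top-interface transmission`, binned by round-trip optical
path (0.5 µm bins, far below the coherence gate). The expectation matches
analog detection for that channel; redirects of already-ascending photons
are not tallied (their near-forward phase density makes the point estimate
a rare O(weight) spike rather than a smooth tally), which slightly
underestimates the diffuse multiple-scattering background. All layer-fit
comparisons are made against profiles from the same estimator, so the
comparison is self-consistent.

**A-line synthesis.** Each detected photon becomes a Gaussian gate of 1/e
half-width l_coh in optical-path coordinates, centred at its round-trip
path; geometric depth is path/(2n). Envelope summation (speckle-free mean
intensity) is the default; a fringe mode with an explicit carrier and
squared-magnitude demodulation exists for completeness (the carrier
wavenumber defaults to the 1060 nm source). B-scans repeat transport with
independent child seeds per lateral position and are bit-reproducible.

## Synthetic data: what it does and does not emulate

The fixture generator composes, in acquisition order: closed-form
single-scattering signal → axial PSF → multiplicative unit-mean
exponential speckle (fully developed) → additive constant noise floor,
all seeded. The Monte Carlo scene adds multiple scattering, NA-gated
detection and coherence gating. Not emulated: sensitivity roll-off
(negligible by design), axial/lateral PSF in the Monte Carlo scene,
shot noise of the detector, motion, dispersion, and real-tissue
heterogeneity within layers. Passing tests therefore demonstrate
correctness of the estimators under the stated models and their
robustness to these specific degradations — not performance on clinical
data.

## Problem sizes and the known limitation

The phantom validations use a 3 mm, 1 µm-pitch grid (3000 samples) and
run in well under a second. The retinal Monte Carlo validation uses 10⁵
photons per A-line × 20 A-lines; all A-lines are averaged (the scene is
laterally homogeneous), the analysis is truncated 100 µm below the
deepest evaluable layer, an analytic tail is fitted on the distal 18% of
the kept range, and the per-layer ground truth is the exponential-decay
fit on the same averaged profile over the five thick layers (windows
shrunk 20% per side to stay clear of gate bleed). A simulated B-scan has
no calibrated βL(0); it is normalised so that R̃ = 10⁻³, which leaves
every attenuation metric unchanged.

At this photon budget the averaged A-line carries ~30–40% per-pixel
noise, and the derivative-threshold segmentation cannot resolve the
weakly contrasted inner-retina boundaries (steps of order one noise
standard deviation per pixel). Layers left merged absorb their internal R
steps into the segment decay fit, which mis-anchors R and propagates into
μ elsewhere; with an oracle 13-layer segmentation the same data yields a
~15% mean layer error, and the phantom scenes recover to ~0.1%. This is
the known hard regime of fuzzy processing on tissue with weakly
distinguishable layers; resolving it would need either more photons or a
change-point detector with better noise averaging than a single-pixel
derivative threshold, which is deliberately out of scope here.

## Design choices on genuinely open points

* The four-layer validation phantom fixes its R values but not its μ
  values; the latter are overridable fixture parameters with defaults
  (1, 2, 3, 1.5) mm⁻¹ — R recovery is insensitive to the choice.
  Its βL(0) is quoted per pixel (2.07e−2 A.U.·px at 1 µm pitch) and
  stored as 2.07e−5 A.U.·mm.
* The layer-resolved R formula is often written with a leading factor 2
  that, under this intensity convention, returns twice the generating R
  (shown in closed form); the default convention omits it so
  single-scattering fixtures round-trip, and `convention="literal"` keeps
  it.
* "Average derivative" is read as the mean of |d/dz|; the derivative of
  the piecewise-constant R in correction mode is a sum of breakpoint
  impulses; R is refreshed from the inversion with the updated μ each
  loop.
* μ below the detected sample bottom (where the signal is extrapolated)
  is set to zero in reported maps.
* Degenerate inputs: an all-zero A-line yields zero μ with a warning;
  zero-denominator depths are zeroed; data gaps inside the support are
  nearest-filled before segmentation; per-column failures in B-scan
  solving fall back to the baseline for that column and are recorded in
  the state.
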