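# Methods

This note documents the models behind each analysis stage, the synthetic
data they are validated against, the tunable parameters, and the numerical
choices made where the design was genuinely open.

## Coordinate conventions and the trajectory dialect

All internal lengths are nm, times ns, temperatures K; area per lipid is
reported in Å² (×100) to match the units the field quotes. The z axis is
the membrane normal; the membrane center of a frame is the midpoint between
the per-leaflet mean phosphorus z, so every depth statistic is invariant
under rigid z translations. Distances use the minimum-image convention in
all three dimensions.

Trajectories are stored in a GRO-style fixed-column dialect, one block per
frame, with six-decimal coordinate columns so that a write→read round trip
is the identity to 1e-6 nm. Atom names encode structure: `P` for lipid
phosphorus, `C<k>A`/`H<k>A1..2` and `C<k>B/...` for the sn-1/sn-2 chain
carbons and their hydrogens (ordered glycerol → terminal methyl), `OW`/
`HW1`/`HW2` for water, and probe anchors `HEAD`, `OCB` (carbonyl O), `NAM`
(amino N), plus `TDMX`/`AXSX` dummy atoms placed 1 nm from `HEAD` along the
transition dipole and long molecular axis. The dipole anchors are never
wrapped, so unit vectors survive the round trip; C–H unit vectors are
reconstructed from hydrogen positions before any wrapping. A YAML sidecar
carries temperature, conformer label, frame spacing `dt`, and the
`excitation_time` at which the probe is considered switched to its S1
charge distribution. Leaflets are assigned at read time from the sign of
the phosphorus z against the midplane.

## Synthetic data: what it emulates and what it does not

The generator fabricates the statistical structure the analyses consume,
each feature with a closed-form or constructed ground truth:

* **Lipids** sit on an n_x × n_y lattice with ±20% cell jitter; the lateral
  box is built as `n_lipids_per_leaflet × apl_target` *exactly*, so the APL
  analysis must return the target to machine precision. Default 64 lipids
  per leaflet at 52.3 Å² — a gel-region bilayer at the X-ray reference
  area.
* **Leaflet sheets** at ±(half_thickness + A·sin(2πx/λ)) with Gaussian
  positional noise (default 0.02 nm). The two leaflets are displaced in
  opposite z directions at the same lateral phase, so the thickness field
  carries the ripple at amplitude 2A (peak-to-trough 4A).
* **Chain C–H vectors** are drawn per frame with cos²θ ~ Beta with mean
  (2S+1)/3 (concentration 30), random azimuth and cosθ sign, making the
  *expected* S_CD of each carbon exactly its profile value. Plateau carbons
  3–10 carry `scd_plateau_target`; disorder grows toward the terminal
  methyl (the profile tapers by up to 70%), mimicking the canonical chain
  profile. Orientations, not torsional dynamics, are generated — the
  analyses only consume vectors.
* **The probe dipole** performs discrete-step rotational diffusion:
  tangent-plane Gaussian steps of mean squared angle 4·D·dt
  (D = `tdm_wobble_rate`), rejected when they leave the cone of semiangle
  θ_c about the reference axis. The rejection walk is Metropolis with a
  symmetric proposal, so its stationary law is uniform on the spherical
  cap, for which the anisotropy plateau has the closed form
  r∞/r₀ = [cos θ_c(1 + cos θ_c)/2]². With the cone removed the walk is free
  isotropic rotational diffusion with ⟨P₂⟩ = exp(−6Dt). Step-size bias is
  O(D·dt); defaults keep 6·D·dt ≲ 0.01.
* **Waters** fill two solvent slabs (1.8 nm each side) uniformly, with
  TIP3P-like geometry (O–H 0.0957 nm, H–O–H 104.52°). After
  `excitation_time` each water's orientation statistic relaxes as
  μ(t) = m_eq·(1 − exp(−(t − t_exc)/τ)) toward
  `equilibrated_orientation_mean`, with per-water Gaussian scatter 0.25 on
  cos θ. Oxygen positions are frozen across frames (frames emulate
  *uncorrelated* snapshots, not continuous dynamics).
* **Emission records** draw wavelengths from N(mean, σ) truncated above
  200 nm and oscillator strengths uniform in (0.2, 0.6); a `mixed` table
  alternates conformers with the Conf-II mean red-shifted 15 nm, the
  separation that makes the second conformer appear as a spectral shoulder.

Randomness is split into per-component child streams of the master seed
(lipids / probe / waters / emission), so resizing one component does not
shift another's draws.

What passing tests on this data do **not** show: real bilayers couple chain
order, thickness, APL and hydration self-consistently; here each feature is
independently prescribed. There is no force field, no water–lipid
interaction, and no attempt to reproduce trajectory-specific published
numbers (head-group depths, Table-style orientation sums) that depend on
unpublished 400 ns production runs.

## Probe geometry

Tilt angles are arccos of the dot product with the normal, reported over
the full [0°, 180°] — a dipole at ~80° (just above the membrane plane) is
physically distinct from ~100° (just below), so no folding is applied by
default; a `fold` option exists for comparison with symmetric conventions.
Distributions use 5° histogram bins centered on multiples of the bin width;
the mode is the maximal bin center (ties → smaller angle) and the HWHM is
linearly interpolated at half the modal count, the error-bar convention
used for such distributions. A windowed mode-drift diagnostic (largest
deviation of quarter-trajectory modes from the global mode) is emitted with
each distribution, mirroring the convergence requirement that orientational
fluctuations stay below ~5°.

## Hydration

g(r) is normalized by the ideal-gas count at a reference water density —
N/V_box by default, the solvent-slab density when the caller provides it
(the meaningful choice for membrane systems). Coordination numbers are
exact cumulative per-frame pair counts, tested bin-by-bin against a brute
force enumeration.

Hydrogen bonds use the common geometric criterion (donor–acceptor
≤ 0.35 nm, H–donor–acceptor angle ≤ 30°), counted per (water, acceptor)
pair over the probe's carbonyl O and amino N, restricted to waters within
0.5 nm of the head COM.

The cumulative solvent orientation sums s·cos θ over waters with O inside
the radius (default 1 nm), θ between head→O and O→(H1+H2)/2, with the
overall sign fixed to s = −1 so that an oxygen facing the probe — the
arrangement that stabilizes the enlarged S1 dipole — contributes
negatively. Two deliberate choices: the statistic is a *sum*, not a mean
(equilibrated-shell magnitudes of several units require population
weighting), and window values are time-averages of the per-frame statistic
over each window. Both the sign and the windows (defaults 0–1, 3–4, 6–7,
9–10, 12–13, 20–21 ns after excitation) are configurable. The relaxation
fit C(t) = A·exp(−t/τ) + C∞ is a Levenberg–Marquardt least-squares fit
(lmfit); constant or non-convergent series are returned flagged, never
raised.

## Membrane phase

APL divides the lateral box area by lipids per leaflet; the probe is not
counted as a lipid by default (a switch adds it to its leaflet's count,
since a 1-per-128 amphiphile is on the boundary of either convention).
S_CD is computed from explicit C–H unit vectors; united-atom H
reconstruction is out of scope because the generator (and the dialect)
carry explicit vectors. Thickness maps difference per-cell leaflet-mean
phosphorus heights; empty cells are filled by periodic nearest-neighbour
interpolation and flagged. Ripple metrics take the RMS about the mean and
the dominant wavelength from the 2-D FFT power spectrum with the zero mode
removed; a flat map is flagged rather than given a spurious wavelength (the
wavelength is quantized to the spectral bins L/k of the finite box).

Phase labels are advisory, rule-based fingerprints with thresholds exposed
in config and echoed in the call: APL ≥ 55 Å² with plateau |S_CD| < 0.15 →
L_α; APL ≤ 51.5 Å² with high order → L_c; otherwise gel, promoted to P_β′
when the thickness RMS exceeds 0.15 nm. The same features are what one
reads off by inspection; the defaults bracket the ~51 / ~52 / 57 Å²
progression of DPPC across its phases.

## Photophysics

**Spectra.** Each emission record contributes a Gaussian at its wavelength,
σ = FWHM/2.3548, weighted by oscillator strength (or uniformly — whether
snapshot spectra should be f-weighted is a genuinely open choice, so both
modes exist). Default FWHM 15 nm: with conformer components ~15 nm apart
this renders the weaker conformer as a shoulder rather than a resolved
peak, which is the regime of interest. Shoulder detection reports secondary
local maxima and, on monotonic flanks, dips of the Savitzky–Golay-smoothed
second derivative (extra negative curvature flanked by zero crossings);
ties at the global maximum resolve to the shorter wavelength.

**Radiative lifetimes** use k_r = f·ν̃²/1.499 (ν̃ in cm⁻¹, k_r in s⁻¹), the
standard oscillator-strength relation. How published computed decay times
were obtained from excited-state output is not stated in the source
experiments this package mirrors; this estimator is *a* defensible choice,
documented here rather than asserted as theirs.

**Anisotropy.** r(t) = (2/5)⟨P₂(μ̂(t₀)·μ̂(t₀+t))⟩ over all time origins
(spacing configurable; overlapping origins trade variance for bias-free
means). Absorption and emission dipoles are taken collinear, so r(0) = 0.4
exactly. The plateau is the mean over the final 20% of lags; the time
constant comes from a single-exponential-plus-offset least-squares fit.

**TCSPC.** The simulator draws each photon's component with probability
equal to its integrated-intensity fraction (integrated intensity *is*
photon share), samples an exponential arrival, adds Gaussian IRF jitter,
and histograms; a finite time window discards out-of-range photons exactly
as an acquisition window would. The fitting engine minimizes the Poisson
negative log-likelihood Σ(m_j − c_j·log m_j) with bin expectations
m_j = Σ_i A_i·[F_i(e_{j+1}) − F_i(e_j)], where F_i is the exponential CDF
or, with an IRF, the exponentially-modified-Gaussian CDF
(`scipy.stats.exponnorm`) — the exact exponential⊗Gaussian convolution, so
reconvolution is analytic and truncated histograms need no renormalization.
Poisson MLE rather than least squares because photon counting is Poisson;
the amplitude parameters are free, so the fit is equivariant under count
rescaling. Optimization runs deterministic multi-starts around the moment
lifetime estimate (Nelder–Mead polish then BFGS); uncertainties come from
the observed information matrix (finite-difference Hessian in log
parameters, delta method for lifetimes and fractions). Intensity fractions
are reported as f_i = α_iτ_i/Σα_jτ_j × 100 and always sum to 100.

**Two-population anisotropy** mixes component anisotropies with
intensity weights w_i(t) = (f_i/τ_i)·exp(−t/τ_i). A slow population with
persistently high r plus a fast population whose r decays reproduces the
non-monotonic "turn-up": as the fast emitters die out, the mixture
anisotropy rises back toward the slow population's value. Grid points where
all weights underflow are truncated and flagged.

**Steady-state anisotropy** is trapezoidal quadrature of
∫r·I dt / ∫I dt, which reproduces the Perrin form r₀/(1 + τ/θ) in the
mono-exponential limit to the quadrature error.

## Problem sizes and tolerances

The validation suites run at deliberately modest scale: 64 lipids × 60–100
frames for order-parameter and APL recovery (plateau tolerance ±0.02),
8–20 × 10³ steps for dipole-diffusion closed forms (plateau ±0.03, free
rate ±5% with 12 walkers averaged), 600 waters × 100 frames for the
solvent-relaxation recovery (±15%), and 10⁵–5×10⁵ photons for lifetime
recovery (within 3× the experimental uncertainties for the two-component
case, 2% for mono-exponential fits). Degenerate inputs — flat spectra,
constant series, frozen dipoles, empty maps — return flagged results or
precise errors rather than NaNs.

## Known limitations

* The coordinate dialect is text-only; binary trajectory formats
  (XTC/TRR/DCD) are out of scope.
* The IRF model is a single Gaussian; measured (tabulated) IRFs are only
  used through their first two moments.
* Phase labels are threshold heuristics, not a thermodynamic assignment.
* The generator's frames are temporally uncorrelated except for the probe
  dipole and the water-orientation trend; autocorrelation-based analyses
  other than the dipole anisotropy would see white noise.
* The long molecular axis of the probe is generated about a fixed 40°
  reference tilt; which atom pair spans that axis in real coordinates is
  configurable, with the naphthalene long-axis anchors as the default.
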