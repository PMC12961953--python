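# Methods

`memspt` analyses the two-dimensional diffusion of micron-scale particles at
a phospholipid-covered air–water interface. It has five stages: synthetic
data generation, particle detection and linking, drift-corrected MSD
analysis, membrane-hydrodynamic prediction, and experiment-vs-theory
comparison. This note records the models, the parameters that matter, the
numerical choices, and the limitations.

## Observation model and synthetic data

All positions are in micrometres in a frame whose origin is the centre of
the top-left pixel (x rightward along columns, y downward along rows);
frame indices are 0-based. One convention end-to-end avoids
pixel-centre/off-by-one bugs between rendering, detection and analysis.

`simulate_tracks` draws, for each particle, per-axis frame increments

    dx ~ N(v_drift * dt, 2 D dt)

independent across particles, axes and frames (2D Brownian motion with a
global drift shared by every particle). Static localization noise —
apparent centroid motion caused by frame-to-frame pixel-intensity variation
— is modelled as i.i.d. Gaussian noise of standard deviation
`localization_sigma` per axis per frame added to the observed positions
(white, uncorrelated between frames). Its MSD signature is a
lag-independent floor of `4 sigma^2` in 2D; the default sigma = 0.05 um
reproduces the ~0.01 um^2 floor characteristic of IRM imaging of
immobilized particles at high frame rate.

Defaults mirror the experimental acquisition this package is built around:
83.3 frames/s, 10,001 frames (~120 s), and a mixed ensemble of five 10-um
disks (D = 0.035 um^2/s) and twenty 1-um spheres (D = 0.15 um^2/s) — the
two particle classes, at the measured diffusivities for a 2.5 mg/m^2 DPPC
monolayer. Global drift is optional; `DriftModel.paper_like()` gives a
constant 0.75 um/s, i.e. ~90 um of drift over 120 s. A piecewise-constant
drift mode is also available (the time course of real interfacial drift is
generally unknown; constant is the default).

Initial positions are rejection-sampled so no two rendered particles start
closer than the sum of their rendered radii plus 1 um. Tracks may leave the
field of view; rendering clips and tracking naturally truncates such
tracks.

`render_frames` draws each particle as a uniform dark disk (linear
edge antialiasing) of its population's `rendered_radius` on a grey
background, blurs the frame with a Gaussian PSF (`psf_sigma`, default
0.3 um), and adds Gaussian camera noise — a minimal imitation of IRM
contrast (dark particles on grey). Stacks are 16-bit multi-page TIFF.

What the generator does **not** emulate: interference fringes and
illumination gradients of real IRM, LE/LC domain texture, particle
aggregation dynamics, inter-particle hydrodynamic coupling, anisotropic or
rotating disk images, and detector nonlinearities. Tests passing on this
synthetic data therefore validate the analysis chain (detection, linking,
drift correction, MSD statistics), not the microscope model.

## Detection and linking

The classic bandpass + centroid-refinement + nearest-neighbour scheme for
colloid tracking. Dark-on-grey images are inverted first so features are
maxima (one bright-spot code path). The bandpass is a Gaussian smooth at
`noise_length` (default 1 px) minus a boxcar background over
`feature_diameter`, clipped at zero. Candidates are local maxima within a
`feature_diameter` neighbourhood above a percentile threshold of the
filtered image; each is refined to the intensity-weighted centroid inside a
circular mask of radius `feature_diameter/2`, re-centred while the estimate
moves by more than half a pixel. Candidates whose mask would cross the
image border are dropped; near-duplicate refinements are merged. An
optional `min_mass` cut suppresses weak spurious maxima (useful on very
clean images where faint PSF-tail ripples survive the percentile
threshold). On noiseless synthetic renders the RMS centroid error is below
0.1 px; error grows monotonically with camera noise.

Linking ranks all (track, detection) pairs within `max_displacement` by
distance and assigns greedily from the smallest, each side used once;
unmatched detections open new tracks; tracks unmatched for more than
`memory` frames close (`memory=0` by default — the acquisitions this
mimics yield uninterrupted tracks). At the dilute coverages simulated
(tens of particles per field) greedy assignment coincides with globally
optimal assignment in practice; no probabilistic linking is attempted.

Detection diameter and threshold are exposed as configuration; the
defaults (9 px, 99th percentile, 1 px noise length) were chosen on the
synthetic fixtures with 0.2 um pixels and 1-um spheres. A single-pass
detection of a *mixed* field uses one feature diameter sized for the
largest particles; small particles inside a large particle's bandpass halo
are then masked — the package's tests document this, and the two size
classes are best tracked in separate passes (as the experiments themselves
did). Recovered tracks are split into size classes by median estimated
spot radius (uniform-disk-equivalent radius from the radius of gyration),
cut at 3 um by default.

## Drift correction

The mean displacement of all tracked particles at each frame transition is
subtracted from every particle's displacement at that transition, and each
corrected track is rebuilt by cumulative summation from its starting
point. By construction the ensemble-mean corrected displacement at every
fully co-observed transition is exactly zero. Transitions with no
co-observed particle receive zero correction and are counted as gaps.
Drift is estimated from all tracked particles jointly by default (a
`population` flag restricts it to one class).

Two summaries of the estimated drift path are reported. The *arc length*
(sum of per-transition magnitudes) is the literal path length, but with N
co-observed particles each per-transition estimate carries the Brownian
noise of the N-particle mean, and summing magnitudes of noisy vectors
inflates the arc length substantially when the per-frame drift step is
smaller than that noise (E|v + xi| >> |v|). The *net displacement*
(straight-line span of the cumulative path) cancels this noise and is the
robust measure for near-constant drift; it is the quantity the acceptance
benchmark uses for drift recovery.

Because the subtracted mean includes the particle itself, corrected
increments have their variance shrunk by (1 − 1/N); diffusivities
estimated after correction are biased low by 1/N. With the ~20-particle
ensembles used here that bias is ~5%, well inside the quoted dispersions;
it is inherent to the average-displacement correction, not removed, and is
visible in the tests.

## MSD, scaling exponent, diffusivity

For 2D Brownian motion ⟨Δr²(τ)⟩ = 2 d D τ^α with d = 2 and α = 1.
`compute_msd` pools every squared displacement over each integer frame lag
from every start time of every track (time-and-ensemble average,
observation-weighted; for equal-length tracks this equals the per-particle
mean exactly). A per-particle MSD matrix is kept for dispersion estimates.
The default maximum lag is a quarter of the longest track — the usual
guard against the statistics-poor tail.

α is the weighted least-squares slope of log(MSD) vs log(τ) over a lag
window, default 0.5–5 s: below ~0.5 s the static-noise floor biases the
apparent exponent down, above ~5–10 s the time-averaged MSD becomes
noisy. Weights are 1/τ, because the sampling variance of a time-averaged
MSD grows roughly linearly with lag (displacement pairs overlap more and
more); an equal-weight fit over-trusts the noisy tail. For exact power-law
curves the weighted and unweighted fits coincide.

D is a point estimate at the single available lag nearest 1 s (ties to the
smaller lag): D = MSD/(2 d τ). One second sits above the noise floor and
below the statistics-limited regime. The quoted dispersion is one standard
deviation of the per-particle MSD at that lag, propagated through the same
division — the spread of individual particles' time-averaged behaviour,
not a standard error of the mean.

The static-noise floor is measured exactly as in the lab protocol: MSD of
immobilized particles under the same observation model, averaged over lags,
with a warning if the curve has material lag dependence.

## Membrane hydrodynamics

A disk of radius a embedded in a membrane of interfacial viscosity η
[Pa·s·m] between bulk phases μ1 (air, 1.8×10⁻⁵ Pa·s) and μ2 (water at
21 °C, 9.8×10⁻⁴ Pa·s) has reduced radius ε = a(μ1+μ2)/η. The package
implements the explicit Petrov–Schwille approximation to the HPW theory,

    D(ε) = kBT/(4πη) · [ln(2/ε) − γ + 4ε/π − (ε²/2)ln(2/ε)]
                      / [1 − (ε³/π)ln(2/ε) + c1·ε^b1/(1 + c2·ε^b2)],

with the published fitted constants c1 = 0.73761, b1 = 2.74819,
c2 = 0.52119, b2 = 0.51465, and the Saffman–Delbrück small-ε law
D = kBT/(4πη)(ln(2/ε) − γ) for cross-checking (the two agree to 0.02% at
ε = 10⁻³). Some transcriptions render the logarithms as ln(2ε); only
ln(2/ε) yields the positive Saffman–Delbrück limit at small ε, and that
reading is implemented. The formula is evaluated in double precision and
is pinned in the tests against an independent 50-digit symbolic
evaluation. A validity envelope ε ∈ [10⁻⁶, 10⁶] is enforced; outside it a
clear error names the envelope. The full HPW dual-integral-equation
solution, finite-thickness and slip-boundary extensions are out of scope.

Interfacial viscosities are user inputs (`predict_curve` takes a CSV of
(Γ, η) rows): DPPC monolayer surface viscosities vary over orders of
magnitude with surface concentration and are measured, not modelled, here.

## Monolayer coverage

With DPPC insoluble in the subphase, deposited mass fixes the mean
molecular area: area = M/(Γ·N_A) (M = 734.04 g/mol, overridable). Phase
labels follow the standard DPPC ranges: gas above 90 Å²/molecule,
LE/LE–LC coexistence in (58, 90] (a single label — the LE/coexistence
boundary is not resolved here), LC in [48, 58], and a `beyond_LC` flag
below 48 Å². Boundaries are half-open with membership assigned to the
denser phase, deterministic by construction. Reported Γ is taken at face
value; residual interfacial impurities would make true coverage higher
than nominal.

## Comparison

`compare` joins measured and predicted D on Γ (nearest match within
0.05 mg/m², a tenth of the usual 0.5 mg/m² grid) and reports
D_exp/D_pred and its log10; |log10| ≥ 1 — an order of magnitude or more —
is flagged as regime disagreement, the signature that the embedded-disk
assumption of the hydrodynamic model does not describe the particle's
actual arrangement at the interface.

## Reproducibility and problem sizes

Every stochastic stage takes an explicit seed; a run is reproducible
byte-for-byte from its config + seed, and outputs carry a config hash.
The benchmark script (`scripts/acceptance.py`) derives independent
sub-seeds from one master seed and recomputes: the noise floor from 20
immobile particles × 2,000 frames; α from 5 Brownian tracks × 10,001
frames; and the drift path from 4 tracks × 10,001 frames — the ensemble
sizes of the experiments being emulated. The full image-based pipeline
test uses 20 spheres × 2,500 frames at 256×256 px, a field large enough
for 1-s-lag diffusivity estimation at D = 0.1 um²/s while keeping the
whole suite fast.

Known limitations: α and D estimates at the experimental ensemble sizes
(4–7 disks) are dominated by the heavy-tailed fluctuations of
time-averaged MSDs — the per-particle dispersion quoted alongside D is
large because the underlying spread is large, not because the estimator is
poor; the drift-corrected D carries the (1 − 1/N) centering bias; joint
detection of strongly size-disparate particle classes in one pass masks
small particles near large ones; and the renderer's IRM imitation is
deliberately minimal.
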