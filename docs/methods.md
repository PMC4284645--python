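# Methods

`clamptrace` quantifies the DNA-bound population of the bacterial replication
sliding clamp (the β₂ homodimer, DnaN) in live *E. coli* from two kinds of
single-molecule fluorescence experiments, and ties both to a minimal kinetic
model.  Every analysis stage can be exercised against a synthetic microscopy
generator that records exact ground truth, so the whole pipeline is testable
without any experimental data.

## Kinetic model

The bound-clamp count `N(t)` is modelled as an immigration–death chain:
clamps are loaded at a constant effective rate `k_p` (primer formation on the
lagging strand is rate limiting — every new primer consumes one clamp from
the cytoplasmic pool), and each bound clamp is unloaded independently with
time constant `t_unload`:

    N → N + 1   at rate k_p              (while t ≤ t_rep)
    N → N − 1   at rate N / t_unload

Consequences used throughout:

* stationary distribution Poisson with mean `N_ss = k_p · t_unload`;
* steady-state balance: the total unloading flux `N_ss / t_unload` equals
  the loading flux, so the effective per-clamp loading interval is
  `t_load = t_unload / N_ss`;
* mean trajectory `N̄(t) = N_ss (1 − e^{−t/τ}) + N_0 e^{−t/τ}` with
  `τ = t_unload`, decaying as a pure exponential after loading stops at
  termination (`t_rep`).

Two samplers are implemented: the fixed-step scheme (per step of length
`dt`, a birth fires with probability `dt·k_p` and a death with probability
`N·dt/t_unload`, drawn from independent uniforms so both may fire in one
step) and an exact event-driven sampler used as an independent cross-check.
`dt` must satisfy `dt·k_p < 0.1` and `dt·N_max/t_unload < 0.1` for a
conservative reachable maximum `N_max = N_ss + 6√N_ss + 10`; invalid steps
are refused, not clipped.  Defaults: `k_p = 46/195 s⁻¹` (one loading every
≈4.24 s), `t_unload = 195 s`, `t_rep = 4080 s`, `N_0 = 0`,
`dt = min(1/k_p, t_unload)/1000` when unspecified.

## Synthetic microscopy generator

The generator emulates a mother-machine acquisition: dead-end growth
channels (along image rows) each holding a mother cell, imaged every 2.5 min
at 80 ms exposure, 160 nm pixels, Gaussian PSF σ = 1.3 px.

Cell cycles.  Each cycle draws a replication duration
`t_rep ~ N(68, 10) min` (truncated to ±40%) and a slack
`B + D ~ N(16, 5) min` (truncated at ≥ 12 min), with 30% of the slack before
initiation (B period) and 70% after termination (D period); the doubling
time is their sum (mean ≈ 85.8 min, sd ≈ 11 min).  The two periods are
drawn jointly rather than independently so that termination always precedes
division — independent draws of doubling and replication times at the
configured spreads would make roughly a third of all cycles physically
impossible.  This narrows the doubling-time spread relative to a free draw;
population means are unaffected.  At division the mother keeps the dead-end
half of everything (length, content, residual bound clamps binomially).

Content and foci.  Total clamp content grows exponentially from 60 to 120
dimers per cycle; each dimer carries two fluorophore fusions, so a cell's
fluorescence is `2 × dimers × unit_intensity` counts.  The bound count
follows the exact kinetic sampler (pure decay outside the replication
period).  Bound clamps render as one mid-cell diffraction-limited focus
before a configurable sister-separation fraction (0.4) of replication and as
two foci (binomial split) moving apart afterwards; the remaining content is
spread uniformly over the PSF-blurred cell footprint.  Rendering uses
closed-form pixel-integrated Gaussians and blurred rectangles, so photometry
is exact: with noise off and a flat beam, the summed image minus background
equals `unit_intensity ×` the intact fluorophore count to machine precision
(the sub-0.1% PSF tail that would leave the detector is folded back in).

Instrument effects.  Multiplicative Gaussian beam shading; additive offset
plus linear gradient; linear stage drift applied to cells and to a bright
fiducial marker in the PDMS margin; Poisson shot noise at an effective
camera gain (20 counts/photon, folding EM excess noise into the gain) plus
Gaussian read noise; optional per-exposure photobleaching as independent
per-fluorophore Bernoulli survival (default 1.0 — at a 2.5-min frame
interval and 80 ms exposures the bleached fraction per cycle is negligible,
and the calibration module's correction is exercised on dedicated
fixtures).  The default unit intensity (2000 counts ≈ 100 detected photons
per fluorophore per 80 ms frame) puts single fluorophores at peak SNR ≈ 4,
comparable to a bright YFP under EMCCD detection.

PALM movies place at most one activated molecule per cell; a molecule
disappears at the earlier of an exponential unloading time and a
photobleaching time that accrues only during the illumination window of
each frame.  Calibration fields place isolated single fluorophores on a
jittered grid (≥ 18 px pitch) with optional single-step bleaching.

What the generator does not emulate: phase-contrast optics (the brightfield
proxy is a dark rectangle per cell), cell-shape fluctuations and pole
curvature, chromosome organisation (focus positions are geometric, not a
replication-fork model), fluorophore blinking and maturation (dark
fraction 0), and cell-to-cell variability of the kinetic parameters
themselves.  Passing recovery tests therefore demonstrates correctness of
the measurement chain under the model's assumptions, not robustness to
every property of real data — in particular the cell-to-cell spread of the
recovered plateau (sd ≈ 3) is far below the measured biological spread
(sd ≈ 12), so population s.e.m. values from synthetic runs are optimistic.

## Time-lapse quantification

Preprocessing: rolling-ball background subtraction (radius 15 px ≈ 11 PSF σ,
clipped at zero), flat-fielding by the normalized beam profile, and
integer-pixel drift correction tracking the fiducial (subpixel centroid,
shifts rounded; residual ≤ 1 px).  Per channel, a kymograph sums each frame
perpendicular to the channel over a band 2 px wider than the channel so the
PSF-blurred sides of the cell are integrated with it.

Cycle segmentation: mother-cell poles come from isodata thresholding of the
brightfield row profiles (isodata places the threshold midway between the
dark and bright class means, which is robust where Otsu can collapse onto
the dark-class edge); a division is a >25% single-frame drop in mother
length.

Decomposition: per cell-frame, the summed line profile (padded 3 px past
the poles to capture the blurred cell edge) is split into background
(median per-pixel level outside the cell), cytoplasm and foci with exact
conservation.  Candidate focus runs are contiguous positions above a robust
threshold — `level + max(3·noise, 0.2·(peak − level))` where the level and
noise are seeded from the lower quantiles of the interior profile (pole
roll-off rows excluded).  The focal intensity is then measured by
non-negative least squares of a flat cytoplasm floor plus up to two
Gaussian components of fixed PSF width (each paired with a 1.6 σ companion
so just-merged sister foci read as one broadened spot) at peak positions
found on a lightly smoothed profile.  The fit is used instead of a
median-floor run sum because in a short cell with two separated foci the
focal PSF tails reach every remaining row: no row subset yields an
uncontaminated cytoplasm level, and the run-sum estimator loses 7–26% of
the focal flux exactly in the plateau phase that matters.  Fitted
components below 10× the profile noise are discarded as noise excursions.

Initiation and termination are the half-maximum crossings of the
foci-intensity trace (≥ 2 consecutive frames), with the replication time
counted inclusively over both crossing frames.  Half-maximum crossings
cancel the asymmetric detection lags of a presence rule: after termination
the exponential decay lingers above any detection floor for several frames,
while the rise after initiation crosses the same floor almost immediately.

Selection flags (all four required): birth length within [0.5, 2]× the
expected birth length; relative elongation ≥ 1.4; a complete cycle not
clipped by the movie ends; and a diffuse start *and* end — focal intensity
below 20% of the cycle's plateau in the first and last two frames.  The
diffuse criterion is intensity-based because a few bound dimers necessarily
remain at division (≈ 10 min of unloading decay leaves 2–4 of 46) and would
otherwise fail essentially every healthy cell.

## Calibration

The unit intensity is the 10%-trimmed mean of aperture-photometry sums
(±5 px box, local background from the surrounding annulus *mean* — the
annulus median is biased low under skewed shot noise) over ≥ 10 isolated
single-fluorophore spots; it scales linearly with exposure.  Counts are
`intensity / i1`, halved in dimer mode; bleaching is undone by multiplying
frame *n* by `survival⁻ⁿ`.  A dark (immature) fluorophore fraction is
assumed zero; the generator can inject one to quantify the induced
proportional undercount, which is documented but not corrected.

Population averaging resamples each selected cell onto a normalized
replication phase (0 = initiation, 1 = termination) by linear
interpolation; the bound fraction is computed per cell before averaging;
plateau statistics (mean, sd, s.e.m.) are per-cell means over the phase
window [0.3, 0.9], following the observation that the steady state spans
roughly the middle two-thirds of replication.

## PALM dwell-time estimation

Spots are detected per frame with an à-trous B3-spline wavelet transform:
the detection mask is the intersection of detail planes 2..3 thresholded at
3 robust standard deviations (plane MAD), connected regions under 5 px
discarded (false positives < 0.1 per 128² noise frame, detection > 95% at
peak SNR 5).  Traces link detections by nearest position within 3 px; a
trace ends after 2 consecutive missed frames (bridging short blinks);
out-of-cell spots are rejected; traces reaching the last frame are
right-censored.  A fixed-position photometry pass extends each trace a few
frames past disappearance so the single-step filter (piecewise-constant
1-step vs 2-step least squares, F-ratio ≤ 3, floor < 25% of the plateau)
can verify a single downward step; censored traces are exempt from the
filter since their step is unobserved.

On-times are fitted with an interval/right-censored exponential: an
uncensored on-time of `k` frames places the event in `((k−1)Δ, kΔ]`.  With
a common frame interval the likelihood is geometric and the MLE is closed
form, `τ = Δ / log(1 + n_u/S)` with `S = Σ(k_i − 1) + Σ t_cens/Δ`; it
reduces to the sample mean in the fine-frame uncensored limit.  A
brute-force grid maximization is kept as a test oracle.

Unloading and bleaching are treated as independent exponential competing
risks: `1/t_obs = 1/t_unload + 1/t_bleach_wall`.  The bleaching constant is
measured in the exposure-time domain from a fast movie (frames back to
back, unloading negligible) and converted to the slow movie's wall clock by
the duty cycle (`exposure/frame interval`, 0.4/5 at defaults).  Confidence
intervals are percentile bootstrap over case-resampled on-time sets
(default 10⁴ replicates; the closed-form refit makes this vectorizable),
refitting and re-correcting each resample.  The point estimate inherits a
small (+1–2%) convexity bias from inverting the rate difference at n = 84;
it is reported as computed.  Estimation is refused when
`t_obs ≥ t_bleach_wall` (bleaching-dominated data cannot resolve
unloading).

## Numerical and scale choices

Problem sizes were chosen to keep a full run on one CPU in well under a
minute while leaving sampling error small against every tolerance asserted:
the reproduction script uses 240-frame movies with 18 channels (~85
selected cells) for cycle timing and content and 24 channels (~120 cells)
for the plateau; the test fixture uses 200 frames × 8 channels.  All
randomness flows from explicit integer seeds; identical configuration and
seed reproduce stacks bit for bit.  Coordinates are 0-based with half-open
intervals, axis order (frame, row, column), channels along rows.

Known limitations: integer-pixel drift correction only; no lineage tracking
beyond the mother cell; the brightfield proxy sidesteps real segmentation
difficulty; the focal decomposition assumes at most two foci of known PSF
width; and the competing-risks bleach correction assumes memoryless
bleaching, which real fluorophores only approximate.
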