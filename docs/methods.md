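# Methods

This note records the models, conventions and design choices behind
`texchange`, in the order the pipeline runs.

## Stimulus surface model

The rough texture is a zero-mean, isotropic Gaussian random field with the
piecewise height power spectral density

    φ(q) = C                       for q0 ≤ q ≤ qr
    φ(q) = C (q/qr)^(−2(1+H))      for qr < q ≤ q1
    φ(q) = 0                       otherwise

with q the wavenumber magnitude (rad/m). Defaults: q0 = 1200, qr = 2400,
q1 = 3600 rad/m, so the plateau band spans wavelengths 2π/qr…2π/q0 =
2.62–5.24 mm and the self-affine tail extends down to 2π/q1 ≈ 1.75 mm.
The Hurst exponent of the printed stimulus is not known; the default
H = 0.8 is typical for real engineering surfaces and is configurable. The
variance convention is the isotropic Parseval integral
σ² = (1/2π)∫ φ(q) q dq.

Synthesis is spectral: white Gaussian noise is filtered in the 2D Fourier
domain by √(φ(q)/(dx·dy)), which gives a real field whose expected
periodogram equals φ and whose realized RMS matches the closed-form
integral to a few percent on the 100 × 50 mm default extent. The
amplitude constant is then fixed by rescaling the realization to an
*exact* RMS roughness (0.15 mm default) — C is a free scale, so
calibrating the realization is equivalent to calibrating C. Grid spacing
defaults to 0.1 mm (≥ 17 samples per shortest retained wavelength);
synthesis refuses spacings coarser than a quarter wavelength of q1.

The tile is composed as 40 mm smooth + 10 mm transition + 40 mm rough.
Those segments cover only 90 of the 100 mm, so 5 mm margins at each end
continue the adjacent texture. The transition is a linear cross-fade of
the rough heights from 0 to 1 across the central band — the simplest
monotone merge with no step discontinuity; the actual blend used for the
printed stimulus is not documented, and any monotone ramp would satisfy
the same tests. Coordinates put x = 0 at the middle of the transition
band, positive toward the rough end; every downstream position rule uses
this frame.

## Contact estimation and trial bookkeeping

The tile sits on a six-axis load cell. For a single planar contact at
(x, y, 0) with force F (z up, compression Fz < 0), the torque is
T = r × F, so the centre of pressure is x = −Ty/Fz, y = Tx/Fz —
independent of the tangential friction components. Wrench streams are
block-averaged from 1 kHz to 100 Hz before inversion (missing samples are
excluded from each block mean; a fully missing block stays missing), and
samples below 5 gf load or off the tile are flagged invalid rather than
erroring: 5 gf is far below the 30–50 g contact loads, and guards the
division by Fz. Load is |Fz|·1000/9.81 gram-force; whether the study used
|Fz| or the total force magnitude is not stated, and |Fz| is assumed (the
difference is second order in the friction angle).

A texture transition is a completed traversal of the ±5 mm band around
the tile centre. Which instant within the band serves as the event time
is ambiguous; the default is the far-edge exit (the finger has fully
crossed the 10 mm transition region), with `entry` and `centre` rules
available as alternatives. At 2.5 cm/s the far-edge exit falls 2.2 s into
a 4 s sweep. Trials are epoched at the visual onset cues and accepted
when fewer than 25% of trajectory samples are missing *and* exactly one
transition falls in the window.

## EEG preprocessing and time-frequency power

Zero-phase (forward-backward) 4th-order Butterworth filters: 0.5–100 Hz
band-pass and a 48–52 Hz notch; the study names the cutoffs but not the
filter family, and zero-phase IIR avoids latency distortion of the 0 ms
transition alignment. Signals are resampled to 256 Hz and re-referenced
to the common average. Ocular/cardiac decomposition is out of scope; a
peak-to-peak amplitude threshold per epoch is available as a crude
artifact screen.

Epochs span −2…2 s around each transition (1024 samples). Power is a
sliding Hanning-tapered periodogram: a 1 s window centred on each point
of the half-open 0.01 s grid {−2.00, −1.99, …, +1.99}, which yields
exactly 400 time bins; a naive interior-only slide would give 301, so the
centred-with-truncation convention is what reproduces the 400-point
series. Near the epoch edges the window is truncated and the estimate
renormalised by the truncated taper's Σw², keeping it unbiased for
stationary signals (verified by simulation). At 256 samples per window
the frequency grid is exactly 1 Hz; bins 1–80 Hz are kept, one-sided
density normalisation (µV²/Hz). A single full-length taper is used per
window: 1 Hz resolution from a 1 s window leaves no room to average
shorter sub-segments without losing resolution.

### Robust z-scoring

Power is z-scored with the median and *unscaled* MAD (no 1.4826
consistency factor — the 5-MAD outlier rule then reads in raw MAD units)
pooled over all trials of both conditions, per channel and frequency.
The pooling deliberately includes the epoch's time bins: normalising
each time bin by its own across-trial median and MAD would cancel,
exactly, any multiplicative power change shared by all trials — an
event-locked ERD is such a change, so a per-bin normalisation makes the
pre-vs-transition contrast identically zero by construction. Pooling the
epoch keeps event-locked structure in z while still cancelling
per-channel power scale. The per-bin variant is available
(`robust_z(..., pooling="per_bin")`) and satisfies median 0 / MAD 1 at
every bin, but is not used in the analysis path. Because band power is
right-skewed, the *mean* z carries a positive offset relative to the
median; all contrasts are window differences, which cancel it. Bins with
MAD = 0 are flagged undefined and excluded by NaN-aware averaging.

Band × window values are means of z over the band's 1 Hz bins (theta
4–7 → 4 bins, alpha 8–12 → 5, beta 16–24 → 9; inclusive) and the
window's time bins (pre −650…−200 ms and transition 0…450 ms, half-open
→ 45 bins each). The pre-transition window follows the Methods text
(−650 ms); the −600 ms variant that appears in one figure caption is
treated as a typo and is configurable. Trial-level values with |z| > 5
are excluded before averaging (strict "exceeds": exactly 5 is kept).

Note an inherent property of the 1 s window: power at bin t mixes
signal from t ± 0.5 s, so a short ERD bleeds into the pre-transition
window and the measured contrast is diluted relative to the injected
power change. This is a property of the method, not of the simulation,
and it is why recovery is asserted statistically across participants
rather than as a point estimate of the injected magnitude.

## Statistics

The exploratory stage tests each of the 128 electrodes (the vertex
reference is excluded) separately: paired t on the within-participant
condition difference against a sign-flip permutation null (random swap of
the two condition values within each participant), 5,000 resamples,
two-sided, with the add-one estimator p = (b+1)/(n_perm+1) so p is never
exactly 0. Sign-flipping leaves Σd² invariant, so the permuted t is a
function of the permuted mean alone — the null is computed by one matrix
product. Ties between permuted and observed |t| (guaranteed by the
identity pattern) are counted with a 1e-8 relative tolerance. All-zero
differences give t = 0, p = 1; zero-variance differences around a
non-zero mean are flagged undefined. The exploratory stage is left
uncorrected by design; this is verified to hold its 5% level by
simulation.

Electrodes with p < 0.05 are grouped into connected components of a
spatial adjacency graph; singletons are legitimate clusters. The
neighbour criterion is not documented for the original net, so adjacency
is angular distance below a threshold chosen such that the median
neighbour count is ≈ 6 (typical for a 129-channel geodesic layout), and
is configurable. Each cluster's electrode-mean values then get a paired
two-sided follow-up t-test (df = n−1), Bonferroni-corrected over the
number of clusters in that band × contrast family; the three bands are
separate families and no cross-band correction is applied. Two contrasts
are built from the band/window table: `pre_vs_transition` (pooled trials,
pre window vs transition window) and `s2r_vs_r2s` (transition window,
smooth→rough vs rough→smooth trials). Mean loads over the same two
windows are compared with an ordinary paired t-test.

"Flagged by the pipeline" — the quantity used for parameter-recovery
metrics — means membership in a cluster whose Bonferroni-corrected
follow-up test is significant, i.e. what a study report would list as a
finding. The raw exploratory stage is an exact level-α test, so its
false-positive rate fluctuates around α by construction; the reported
two-stage finding is what is meaningfully held below α.

## Synthetic sessions

The generator's defaults are the study conditions: 4 blocks × 30
back-to-back 4 s sweeps (120 trials, 60 per direction), 2.5 cm/s over the
100 mm tile, blocks counterbalanced by starting texture, contact load
40 ± 10 g (between-trial SD) with slow within-trial modulation, wrench at
1 kHz with white sensor noise (2 mN force, 2·10⁻⁵ N·m torque — ~0.1 mm
position noise at typical loads), friction µ = 0.4 opposing the motion.
Speed jitter (±10%, low-pass filtered) perturbs the instantaneous speed
within a sweep while the paced traversal still spans the tile in 4 s.
Dropouts, when enabled, arrive as whole 10 ms acquisition frames in short
bursts (mean 2 frames), as buffered-DAQ glitches do — i.i.d. sample
losses would vanish under block averaging and never exercise the 25%
rule.

EEG (129 channels, 1 kHz) is phenomenological, per channel: 1/f^γ
background (γ = 1, 9 µV RMS), 10 Hz and 20 Hz narrow-band rhythms with
Gaussian spatial profiles (σ = 0.55 rad) over left/right sensorimotor
sites — half from shared left/right sources, half channel-local — plus
1.5 µV white sensor noise. The reference channel records zeros, as a
physical reference does. The sensor layout is an idealized Fibonacci cap
(synthetic; it reproduces coverage, not any vendor's numbering).
Per-participant log-normal scaling of rhythm amplitude (σ = 0.2) and ERD
magnitude (σ = 0.1) makes the group t-test non-degenerate.

An ERD is injected by scaling a target channel's band rhythm by
√(1 + Δ) between onset and offset relative to each matching trial's true
transition time, with 50 ms raised-cosine ramps against spectral
splatter; the injected relative band-power change of the rhythm equals Δ
exactly, at exactly the target electrodes. Defaults mirror the analysis
transition window (0–450 ms) and Δ = −40%. What the generator does *not*
emulate: volume-conducted topographic spread of the ERD itself (gating is
per-channel, so neighbouring electrodes are clean nulls), ocular/cardiac
artifacts, non-stationary drift, or any texture-to-vibration
transduction into the EEG. Passing recovery tests therefore demonstrate
that the pipeline detects electrode-resolved, event-locked band-power
changes of the stated size under realistic noise — not that it would
reproduce any particular human topography.

## Problem sizes

The parameter-recovery experiment runs 30 simulated participants with 12
sweeps each (2 blocks × 6 — a reduced session; the per-participant z
statistics pool all 12 trials, comfortably above the ≥ 8 required) and
5,000 permutations; sensitivity and false-positive rate are computed
against the 3 injected electrodes nearest the left sensorimotor site.
The type-I calibration uses 3,000 independent null electrodes at n = 30.
These sizes were chosen to make the whole acceptance run a ~10-minute,
single-CPU computation while keeping every statistical claim at the
study's n.

## Known limitations

- The per-bin z-scoring variant and the epoch-pooled default bracket an
  ambiguity in the source description of the normalisation; only the
  pooled reading supports event-locked contrasts (see above).
- The Hurst exponent, ERD time course, adjacency criterion and
  transition-instant rule are undocumented for the original study; each
  is a configurable parameter with a defensible default rather than a
  reconstruction.
- Clock fusion between sensor and EEG streams is assumed exact (the
  simulation shares one clock); a constant-offset correction hook exists
  but no synchronisation error model is provided.
- STL export triangulates the grid directly; it is for inspection and
  printing workflows, not a validated manufacturing pipeline.
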