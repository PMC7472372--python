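# Methods

## System overview

`fixmon` models an instrumented external fixator for monitoring bone
regeneration: four load cells on the fixator bars stream force samples over
a framed binary protocol; after static-rest baseline normalization, the
forces feed two stiffness estimators (one per clinical phase) whose
uncertainty is budgeted from an in vitro spring-bench calibration. A
synthetic bench generates every input with planted ground truth so each
estimator can be validated against the value the generator injected.

## Telemetry format and resynchronization

One frame is 15 bytes: a 3-byte sync mark (`AA 55 A5`), four signed 16-bit
little-endian ADC counts, and an unsigned 32-bit little-endian timestamp in
milliseconds since session start. Ten frames form the 150-byte transmission
block. The hardware contract fixes only the mark width and the block size;
the field order and endianness are this package's own convention,
documented byte-exact in `fixmon.telemetry` and frozen by round-trip tests.
Wall-clock anchoring is a single session-level value in the JSON metadata
sidecar, not a per-frame field.

The decoder walks frame by frame while the sync mark appears at the
expected offset. After a mismatch it scans forward; an off-grid candidate
is accepted only if the *next* 15-byte slot also begins with the sync mark
(or the stream ends there). We chose this double-mark lookahead over a
timestamp-monotonicity gate deliberately: a corrupted timestamp that parses
as a large integer would poison a monotonicity gate and reject every
subsequent genuine frame, whereas an accidental 3-byte payload match
followed by a second aligned match 15 bytes later has probability ~2⁻⁴⁸
per position. Under any single contiguous corruption at most two frames are
lost and all later frames are recovered bit-exactly; the decode report
lists every resynchronization event and the bytes skipped, so
`frames_in ≈ frames_decoded + frames_lost` is always checkable.

The ADC transfer is affine per cell (`force = count·scale + offset`,
compression negative, traction positive); the default scale maps the full
signed 16-bit range onto the ±1 kN sensor range (≈0.0305 N/count).
Baseline normalization subtracts the per-cell arithmetic mean of a
static-rest window (default 10 s at the configured rate, 5–50 Hz). It is a
pure per-cell shift: variances and force differences are untouched.

## Stiffness estimators

**Distraction.** Each daily 1 mm displacement produces a near-instantaneous
force peak followed by viscoelastic relaxation. The peak callus stiffness
is `max |Ff| / Δd`, with the peak searched over the first 60 s after onset
— the peak is effectively instantaneous, and 60 s comfortably brackets
trigger-time jitter while excluding the relaxation tail, which is retained
on the event for inspection but never enters the statistic. Traces shorter
than the search window raise an insufficient-data error.

**Consolidation.** Stance is detected as GRF above 5 % of its maximum; the
estimator evaluates `Kc = Kf(Fa − Ff)/Ff` at the single stance-peak instant
(no whole-trace regression), using magnitudes since fixator traces are
stored compression-negative. Multiple steps aggregate by mean with the SD
reported. A step whose fixator force at the peak is below a 1 N guard is
flagged and counted (`n_degenerate`), never dropped silently; only when
*every* step is degenerate does the estimator raise — that condition means
the callus carries essentially the whole load, i.e. consolidation beyond
the measurable range, not a data defect. `Fa/GRF` is held constant at 3.22
throughout consolidation; body weight converts to force with g = 9.81 m/s².

`E = Kc·L/A` exposes the modulus conversion as a formula (linear in both
`Kc` and gap length `L`); no specific endpoint values are asserted because
the gap lengths behind published endpoint moduli are not part of the data
this package ships.

## Uncertainty budget

Three relative standard uncertainty sources are combined in quadrature and
expanded with coverage factor k = 2 (standard GUM practice, ≈95 % coverage
under approximately normal errors):

- `u_ref = SD/(√5·Ksr)` from the 5 direct reference-spring tests;
- `u_repl = SD(assembly means)/(√4·Ks)` — replication across 4 independent
  fixator re-assemblies;
- `u_rept = pooled within-assembly SD/(√5·Ks)` — repetition across the 5
  estimates per assembly.

This budget is a reconstruction from the three named sources and standard
metrology practice; because the coverage convention behind the published
per-spring `U` values is not fully specified, individual `U` values are
treated as order-of-magnitude checks, while the published *column averages*
(7.50 % distraction, 14.04 % consolidation) are reproduced exactly from the
bundled table and serve as the default uncertainty tags on in vivo
estimates. Relative error is `e = 100·|Ks − Ksr|/Ksr`; for tabulated
reports per-row values are rounded to 2 decimals before phase averaging,
which reproduces the published averages (6.73 % / 4.90 %) exactly. Both
error estimators (error-of-means and mean-of-per-estimate-errors) are
provided, since published per-row values are consistent with either
depending on the row.

Relative-error traces against a reference instrument mask samples where the
reference magnitude is below 5 % of full scale (50 N) to avoid
divide-by-near-zero at test start.

## Synthetic bench

The generator emulates the study conditions, not idealized data:

- **Rest streams**: independent Gaussian noise per cell, SD 0.18 N (the in
  vitro empty-signal level), optional linear drift (default 0 N/h — the
  empty-signal characterization is drift-free by construction; drift is
  exercised explicitly in tests). Four independent cells give a summed-
  channel SD of 2 × 0.18 = 0.36 N by quadrature.
- **Distraction events**: force response `peak·(r + (1−r)·e^(−t/τ))` — a
  single-exponential standard-linear-solid relaxation with τ = 300 s and
  residual ratio r = 0.6, chosen as the simplest viscoelastic form
  consistent with an instantaneous peak and a plateau; the published traces
  constrain the shape only qualitatively. The planted stiffness schedule
  ramps linearly to 250 N/mm over the 15-day, 1 mm/day protocol, matching
  the reported late-phase peak stiffness; in vivo noise (3.01 N SD) applies
  to the summed channel.
- **Gait steps**: the stance GRF is two raised-cosine humps (stance 0.6 s,
  hump ratio 1.1, peak 205 N ≈ 661 N internal force / 3.22); no standard
  ovine GRF waveform is published, so the double-hump shape is chosen for
  its two locatable extrema. The fixator force follows parallel-spring
  sharing `Ff = Fa·Kf/(Kf + Kc)` exactly, so the consolidation estimator
  inverts it to machine precision on noise-free steps — this is the
  inversion oracle.
- **Calibration bench**: assembly-to-assembly variability is modeled as a
  Gaussian force-transmission factor `Kf_a/Kf` with `Kf_a ~ N(593, 21)` N/mm
  applied in both phases. The distraction estimator (Ff/Δd) contains no Kf,
  so a literal Kf perturbation would leave it untouched; physically the
  dispersion originates in the pin–bone fixation, which perturbs how much
  load the instrumented bars see — hence the multiplicative factor.
  Repetition error is sensor noise (0.36 N) on the measured force, and the
  reference stiffness is the mean of 5 direct tests with 0.5 % relative SD.
  Gaussianity of the inter-assembly variability is an assumption; only its
  SD is constrained.

All generators are deterministic under a fixed scenario seed, with
per-generator substreams so outputs do not depend on call order.

## What passing tests do and do not show

The synthetic bench reproduces the *structure* of the real system (load
sharing, relaxation, framing, noise levels, variance components), not its
physiology: gait variability, callus heterogeneity (explicitly a
homogeneous-callus model), bending/torsion load paths, temperature drift
dynamics and soft-tissue force storage are not modeled. Exact recovery of
planted stiffness therefore validates the estimators and codec, not the
biological fidelity of any particular in vivo number. Published in vivo
magnitudes (0.53→1.85 kN/mm consolidation stiffening, modulus endpoints,
the 3.66 % physical-calibration error) depend on unpublished raw inputs and
are covered qualitatively: monotone stiffening trends, formula linearity,
and a synthetic gain-error trace that recovers an injected ~3.5 % error.

## Problem sizes and numerical choices

Noise-quadrature checks use 10⁵ samples (SD of the SD ≈ 0.1 %); variance-
component Monte Carlo uses 1000 grids of 4 × 5 with unbiased ANOVA moment
estimators as the oracle; bench-dispersion recovery averages 300 seeds and
compares against the c₄(4)-corrected SD expectation. Ties in peak
detection resolve to the earliest index (`argmax`). Degenerate inputs
(empty windows, all-zero GRF, incomplete grids, non-positive references)
raise typed exceptions rather than propagating NaNs.
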