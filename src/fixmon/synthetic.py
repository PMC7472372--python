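"""Synthetic bench: generates every input the pipeline consumes.

Emulates the instrumented-fixator platform end to end with planted ground
truth, so every estimator can be checked against the value the generator
injected:

- zero-load telemetry streams with per-cell Gaussian sensor noise
  (0.18 N in vitro) and optional slow drift;
- distraction force responses: an instantaneous peak (planted stiffness x
  applied displacement) followed by single-exponential viscoelastic
  relaxation, standard-linear-solid style;
- gait steps: a double-hump stance GRF, skeletal force via the constant
  Fa/GRF ratio, and fixator force from parallel-spring load sharing
  ``Ff = Fa * Kf / (Kf + Kc)``, with in vivo noise (3.01 N on the summed
  channel) added on top;
- spring-bench calibration grids with assembly-level (replication) and
  repeat-level (repetition) error sources.

Everything is deterministic under a fixed scenario seed; each generator
draws from its own seeded substream so outputs are independent of call
order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolError
from .fixator import DistractionEvent, FixatorParams, StepRecord
from .telemetry import AcquisitionConfig, SampleFrame, make_frames

#: in vitro per-cell empty-signal noise SD, N
IN_VITRO_NOISE_SD_N = 0.18
#: in vivo noise SD of the summed four-cell force, N
IN_VIVO_SUM_NOISE_SD_N = 3.01


@dataclass(frozen=True)
class CallusModel:
    """Viscoelastic callus response to a distraction increment.

    ``k_end`` is the peak callus stiffness reached on the last distraction
    day; the daily stiffness schedule ramps linearly up to it, matching the
    observed rise to ~250 N/mm by the end of a 15-day, 1 mm/day protocol.
    After the near-instantaneous force peak the tissue relaxes toward a
    residual plateau: ``Ff(t) = peak * (residual + (1 - residual) e^{-t/tau})``.
    """

    k_end: float = 250.0  # N/mm on the last distraction day
    peak_overshoot_ratio: float = 1.0
    relaxation_tau_s: float = 300.0
    residual_ratio: float = 0.6  # long-time force fraction of the peak

    def __post_init__(self) -> None:
        if self.k_end <= 0:
            raise ValueError("k_end must be positive")
        if not 0.0 <= self.residual_ratio <= 1.0:
            raise ValueError("residual_ratio must lie in [0, 1]")


@dataclass(frozen=True)
class GaitModel:
    """Double-hump stance profile of a walking sheep on a load platform."""

    grf_peak: float = 205.0  # N, taller hump; ~661 N internal force / 3.22
    stance_s: float = 0.6
    hump_ratio: float = 1.1  # first hump height / second hump height


@dataclass(frozen=True)
class Protocol:
    """Clinical timeline: latency, daily distraction, then consolidation."""

    latency_days: int = 7
    distraction_days: int = 15
    rate_mm_per_day: float = 1.0

    def __post_init__(self) -> None:
        if self.latency_days < 0 or self.distraction_days < 0:
            raise ValueError("protocol day counts must be non-negative")


@dataclass(frozen=True)
class SyntheticScenario:
    """Generative parameters for the whole synthetic study."""

    seed: int = 0
    noise_sd_per_cell: float = IN_VITRO_NOISE_SD_N  # N
    noise_sd_in_vivo_sum: float = IN_VIVO_SUM_NOISE_SD_N  # N
    drift_rate_n_per_hour: float = 0.0  # per cell; rest streams at zero load
    callus: CallusModel = field(default_factory=CallusModel)
    gait: GaitModel = field(default_factory=GaitModel)
    fixator: FixatorParams = field(default_factory=FixatorParams)
    protocol: Protocol = field(default_factory=Protocol)

    def __post_init__(self) -> None:
        if self.noise_sd_per_cell < 0 or self.noise_sd_in_vivo_sum < 0:
            raise ValueError("noise SDs must be non-negative")

    def rng(self, salt: int) -> np.random.Generator:
        """Seeded substream; distinct salts decorrelate the generators."""
        return np.random.default_rng([self.seed, salt])


_SALT_REST, _SALT_DISTRACTION, _SALT_STEP, _SALT_BENCH = 11, 23, 37, 53


# ---------------------------------------------------------------------------
# Telemetry streams
# ---------------------------------------------------------------------------

def simulate_rest_forces(
    scenario: SyntheticScenario, n_samples: int, sample_rate: float = 10.0
) -> np.ndarray:
    """Zero-load four-cell force matrix ``(n, 4)``: Gaussian noise + drift."""
    rng = scenario.rng(_SALT_REST)
    forces = rng.normal(0.0, scenario.noise_sd_per_cell, size=(n_samples, 4))
    if scenario.drift_rate_n_per_hour:
        t_h = np.arange(n_samples) / sample_rate / 3600.0
        forces += scenario.drift_rate_n_per_hour * t_h[:, None]
    return forces


def simulate_rest_stream(
    scenario: SyntheticScenario,
    duration_s: float,
    config: AcquisitionConfig | None = None,
) -> list[SampleFrame]:
    """Empty-signal telemetry at rest, quantized through the ADC transfer."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    config = config or AcquisitionConfig()
    n = int(round(duration_s * config.sample_rate))
    forces = simulate_rest_forces(scenario, n, config.sample_rate)
    return make_frames(forces, config)


# ---------------------------------------------------------------------------
# Distraction events
# ---------------------------------------------------------------------------

def planted_stiffness_schedule(scenario: SyntheticScenario, day_index: int) -> float:
    """Planted callus stiffness on a distraction day: linear ramp to k_end."""
    p = scenario.protocol
    if not 1 <= day_index <= p.distraction_days:
        raise ProtocolError(
            f"day {day_index} outside the distraction phase (1..{p.distraction_days})"
        )
    return scenario.callus.k_end * day_index / p.distraction_days


def simulate_distraction_event(
    scenario: SyntheticScenario,
    day_index: int,
    sample_rate: float = 10.0,
    duration_s: float = 1200.0,
) -> tuple[DistractionEvent, dict]:
    """One daily distraction with its viscoelastic relaxation and ground truth.

    Returns ``(event, truth)`` where ``truth['pcs_true']`` is the planted
    peak callus stiffness (N/mm) before noise.
    """
    cm = scenario.callus
    delta_d = scenario.protocol.rate_mm_per_day
    kc_day = planted_stiffness_schedule(scenario, day_index)
    peak = cm.peak_overshoot_ratio * kc_day * delta_d
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    with np.errstate(over="ignore"):
        decay = np.exp(-t / cm.relaxation_tau_s) if np.isfinite(cm.relaxation_tau_s) else 1.0
    ff = peak * (cm.residual_ratio + (1.0 - cm.residual_ratio) * decay)
    rng = scenario.rng(_SALT_DISTRACTION + day_index)
    ff = ff + rng.normal(0.0, scenario.noise_sd_in_vivo_sum, size=t.shape)
    event = DistractionEvent(delta_d_mm=delta_d, time_s=t, ff_N=ff, day_index=day_index)
    truth = {"pcs_true": peak / delta_d, "kc_day": kc_day, "peak_N": peak}
    return event, truth


# ---------------------------------------------------------------------------
# Gait steps
# ---------------------------------------------------------------------------

def _raised_cosine(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height raised-cosine bump supported on |t - center| <= width/2."""
    x = (t - center) / (width / 2.0)
    bump = 0.5 * (1.0 + np.cos(np.pi * np.clip(x, -1.0, 1.0)))
    return np.where(np.abs(x) <= 1.0, bump, 0.0)


def simulate_step(
    scenario: SyntheticScenario,
    kc_true: float,
    sample_rate: float = 100.0,
    step_index: int = 0,
) -> tuple[StepRecord, dict]:
    """One stance with planted callus stiffness and parallel-spring split.

    The GRF is two raised-cosine humps (heel-strike taller by
    ``hump_ratio``); the fixator trace is stored compression-negative with
    in vivo noise whose four-cell sum has SD ``noise_sd_in_vivo_sum``.
    """
    if kc_true < 0:
        raise ValueError("planted callus stiffness must be non-negative")
    g = scenario.gait
    kf = scenario.fixator.kf
    lead = 0.2  # unloaded samples before/after stance, s
    t = np.arange(int(round((g.stance_s + 2 * lead) * sample_rate))) / sample_rate
    c1, c2 = lead + 0.3 * g.stance_s, lead + 0.7 * g.stance_s
    width = 0.6 * g.stance_s
    grf = g.grf_peak * _raised_cosine(t, c1, width) + (
        g.grf_peak / g.hump_ratio
    ) * _raised_cosine(t, c2, width)
    fa = scenario.fixator.fa_grf_ratio * grf
    share = kf / (kf + kc_true)  # fixator fraction of the skeletal load
    ff = -fa * share  # compression negative
    rng = scenario.rng(_SALT_STEP + step_index)
    ff = ff + rng.normal(0.0, scenario.noise_sd_in_vivo_sum, size=t.shape)
    record = StepRecord(time_s=t, grf_N=grf, ff_N=ff)
    truth = {"kc_true": kc_true, "ff_over_fa": share}
    return record, truth


# ---------------------------------------------------------------------------
# Calibration bench
# ---------------------------------------------------------------------------

def draw_bench_grid(
    rng: np.random.Generator,
    mean: float,
    sd_between: float,
    sd_within: float,
    n_assemblies: int = 4,
    n_repeats: int = 5,
) -> np.ndarray:
    """Two-level Gaussian grid with known variance components (oracle input)."""
    assembly_means = mean + rng.normal(0.0, sd_between, size=n_assemblies)
    return assembly_means[:, None] + rng.normal(0.0, sd_within, size=(n_assemblies, n_repeats))


def simulate_bench(
    scenario: SyntheticScenario,
    ksr: float,
    phase: str,
    n_assemblies: int = 4,
    n_repeats: int = 5,
    delta_d_mm: float = 1.0,
    fa_load_n: float = 661.0,
    ref_rel_sd: float = 0.005,
    bench_index: int = 0,
):
    """Spring-bench campaign for one reference spring, with logged draws.

    Replication error is modeled as an assembly-level force-transmission
    factor ``Kf_a / Kf`` with ``Kf_a ~ N(Kf, kf_sd)`` — the physical source
    is the pin-bone fixation, which perturbs how much load the instrumented
    bars actually see.  Repetition error comes from sensor noise on the
    measured fixator force (summed-channel SD ``2 x per-cell SD`` in vitro).
    The reference stiffness is the mean of 5 direct machine tests with
    relative SD ``ref_rel_sd``; ``u_ref`` follows as SD/(sqrt(5) * Ksr).

    Returns ``(record, truth)``.
    """
    from .calibration import SpringBenchRecord  # local import avoids a cycle

    if ksr <= 0:
        raise ValueError("reference stiffness must be positive")
    rng = scenario.rng(_SALT_BENCH + bench_index)
    kf = scenario.fixator.kf
    force_noise_sd = 2.0 * scenario.noise_sd_per_cell  # four cells in quadrature

    ref_tests = ksr * (1.0 + rng.normal(0.0, ref_rel_sd, size=5))
    ksr_ref = float(ref_tests.mean())
    ksr_u_pct = (
        100.0 * float(ref_tests.std(ddof=1)) / (np.sqrt(5.0) * ksr_ref)
        if ref_rel_sd > 0
        else 0.0
    )

    kf_assemblies = kf + rng.normal(0.0, scenario.fixator.kf_sd, size=n_assemblies)
    grid = np.empty((n_assemblies, n_repeats))
    for a, kf_a in enumerate(kf_assemblies):
        for r in range(n_repeats):
            noise = rng.normal(0.0, force_noise_sd)
            if phase == "distraction":
                # spring decompressed by delta_d; measured force scaled by the
                # assembly transmission factor
                ff_meas = ksr_ref * delta_d_mm * (kf_a / kf) + noise
                grid[a, r] = ff_meas / delta_d_mm
            elif phase == "consolidation":
                # machine applies Fa; true split uses the as-built Kf_a, the
                # estimator inverts with the nominal Kf
                ff_true = fa_load_n * kf_a / (kf_a + ksr_ref)
                ff_meas = ff_true + noise
                grid[a, r] = kf * (fa_load_n - ff_meas) / ff_meas
            else:
                raise ValueError(f"unknown phase {phase!r}")

    record = SpringBenchRecord(
        ksr=ksr_ref, ksr_u_pct=ksr_u_pct, phase=phase, estimates=grid,
        spring_id=f"{phase[:4]}-{bench_index}",
    )
    truth = {
        "ksr_nominal": ksr,
        "ksr_ref": ksr_ref,
        "kf_assemblies": kf_assemblies.tolist(),
        "force_noise_sd": force_noise_sd,
        "ref_tests": ref_tests.tolist(),
    }
    return record, truth
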