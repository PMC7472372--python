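"""Bone-fixator mechanical model and callus stiffness estimation.

During limb reconstruction the external fixator and the regenerating bone
callus carry the skeletal load in parallel.  Writing ``Fa`` for the internal
(skeletal) force, ``Ff`` for the force through the fixator bars and ``Fc``
for the force through the callus:

    Fc = Fa - Ff                                   (force partition)

Two estimation regimes follow from the clinical protocol:

*Distraction phase* — after each controlled 1 mm displacement of the bony
fragment the limb is at rest (``Fa = 0``), so the monitored fixator force
equals the callus traction force and the instantaneous peak callus stiffness
(PCS) is ``max Ff / delta_d`` before viscoelastic relaxation sets in.

*Consolidation phase* — during gait, load sharing between the two parallel
paths gives

    Kc = Kf * Fc / Ff = Kf * (Fa - Ff) / Ff

with ``Kf`` the fixator's axial stiffness and ``Fa`` obtained from the
ground reaction force via a constant anatomical ratio ``Fa/GRF``.

An axial Young's modulus follows from ``E = Kc * L / A`` with ``L`` the
distraction gap and ``A`` the bone cross-section.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import calibration
from .errors import DegenerateStepError, InsufficientDataError, NoStanceError

#: standard gravity used to convert body mass to weight, m/s^2
GRAVITY = 9.81


@dataclass(frozen=True)
class FixatorParams:
    """Mechanical parameters of the instrumented fixator assembly.

    ``kf`` is the axial stiffness of the complete frame (bars, frames and
    pin flexion), measured by compression testing; its between-assembly SD
    ``kf_sd`` is dominated by the pin-bone fixation.  ``fa_grf_ratio`` maps
    platform ground reaction force to skeletal internal force and exceeds 1
    because muscles and soft tissues carry part of the internal load that
    the platform never sees.
    """

    kf: float = 593.0  # N/mm
    kf_sd: float = 21.0  # N/mm, between-assembly
    n_cells: int = 4
    fa_grf_ratio: float = 3.22
    per_cell_range: tuple[float, float] = (0.0, 1000.0)  # N

    def __post_init__(self) -> None:
        if self.kf <= 0:
            raise ValueError("fixator stiffness kf must be positive")
        if self.fa_grf_ratio <= 1:
            raise ValueError("fa_grf_ratio must exceed 1")
        if self.n_cells != 4:
            raise ValueError("the fixator carries exactly 4 load cells")


@dataclass(frozen=True)
class CallusGeometry:
    """Geometry converting axial stiffness to a Young's modulus."""

    cross_section_area_mm2: float = 147.8  # metatarsal cortical bone + marrow
    gap_length_mm: float = 15.0  # cumulative distraction

    def __post_init__(self) -> None:
        if self.cross_section_area_mm2 <= 0 or self.gap_length_mm <= 0:
            raise ValueError("geometry dimensions must be positive")


@dataclass(frozen=True)
class StiffnessEstimate:
    """Phase-tagged callus stiffness with its expanded relative uncertainty."""

    kc: float  # N/mm
    phase: str  # "distraction" | "consolidation"
    timepoint: int | None  # protocol day
    relative_uncertainty_pct: float
    n: int  # events or steps aggregated
    kc_sd: float = 0.0  # dispersion over aggregated steps
    n_degenerate: int = 0  # steps flagged by the division guard, not dropped silently

    def __post_init__(self) -> None:
        if self.kc < 0:
            raise ValueError("stiffness must be non-negative")
        if self.relative_uncertainty_pct < 0:
            raise ValueError("relative uncertainty must be non-negative")


@dataclass
class DistractionEvent:
    """One daily distraction: applied displacement plus the force response.

    ``ff_N`` is the baseline-normalized fixator-sum force (traction
    positive) monitored from distraction onset, typically for 20 minutes to
    capture both the instantaneous peak and the viscoelastic relaxation.
    """

    delta_d_mm: float
    time_s: np.ndarray
    ff_N: np.ndarray
    day_index: int = 0

    def __post_init__(self) -> None:
        if self.delta_d_mm <= 0:
            raise ValueError("applied displacement must be positive")
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.ff_N = np.asarray(self.ff_N, dtype=float)
        if self.time_s.shape != self.ff_N.shape:
            raise ValueError("time and force traces must have equal length")


@dataclass
class StepRecord:
    """One stance: synchronized GRF and fixator-sum force traces."""

    time_s: np.ndarray
    grf_N: np.ndarray
    ff_N: np.ndarray  # signed, compression negative
    stance_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.grf_N = np.asarray(self.grf_N, dtype=float)
        self.ff_N = np.asarray(self.ff_N, dtype=float)
        if not (self.time_s.shape == self.grf_N.shape == self.ff_N.shape):
            raise ValueError("traces must be synchronized (equal length)")
        if self.stance_mask is not None:
            self.stance_mask = np.asarray(self.stance_mask, dtype=bool)
            if self.stance_mask.shape != self.time_s.shape:
                raise ValueError("stance_mask must match trace length")


# ---------------------------------------------------------------------------
# Core relations
# ---------------------------------------------------------------------------

def partition_force(fa, ff):
    """Callus force from the parallel load paths: ``Fc = Fa - Ff``.

    Accepts scalars or arrays; conservation ``Fa = Ff + Fc`` holds exactly.
    """
    return np.subtract(fa, ff)


def skeletal_force_from_grf(grf, params: FixatorParams = FixatorParams()):
    """Internal skeletal force from platform GRF: ``Fa = ratio * GRF``."""
    grf = np.asarray(grf, dtype=float)
    if np.any(grf < 0):
        raise ValueError("GRF must be non-negative during stance")
    fa = params.fa_grf_ratio * grf
    return float(fa) if fa.ndim == 0 else fa


def peak_skeletal_load(
    body_mass_kg: float = 53.5, load_factor: float = 1.26, g: float = GRAVITY
) -> float:
    """Design bound on the internal force during gait, in N.

    The highest metatarsal internal forces reported for sheep reach about
    1.26 x body weight; for an average 53.5 kg animal this bounds the load
    shared by the four cells at roughly 661 N, well inside the 0-1 kN
    per-cell sensor range.
    """
    return load_factor * body_mass_kg * g


def young_modulus(
    kc: float | StiffnessEstimate, geom: CallusGeometry = CallusGeometry()
) -> float:
    """Axial Young's modulus of the callus, MPa: ``E = Kc * L / A``.

    Units work out directly: (N/mm x mm) / mm^2 = N/mm^2 = MPa.  Linear in
    both the stiffness and the gap length.
    """
    kc_val = kc.kc if isinstance(kc, StiffnessEstimate) else float(kc)
    return kc_val * geom.gap_length_mm / geom.cross_section_area_mm2


# ---------------------------------------------------------------------------
# Distraction phase
# ---------------------------------------------------------------------------

#: peak-search window after distraction onset, seconds.  The force peak is
#: effectively instantaneous; 60 s comfortably brackets it while excluding
#: the relaxation tail from the PCS statistic.
PCS_PEAK_WINDOW_S = 60.0


def distraction_stiffness(
    event: DistractionEvent,
    peak_window_s: float = PCS_PEAK_WINDOW_S,
    relative_uncertainty_pct: float | None = None,
) -> StiffnessEstimate:
    """Peak callus stiffness (PCS) from one distraction event.

    ``PCS = max |Ff| over the post-onset window / delta_d``.  The relaxation
    tail stays in the event for inspection but does not enter the statistic.
    The default uncertainty tag is the in vitro distraction-phase expanded
    uncertainty from the bundled calibration campaign.
    """
    t = event.time_s - event.time_s[0]
    if t.size == 0 or t[-1] < peak_window_s:
        raise InsufficientDataError(
            f"trace shorter than the {peak_window_s:.0f} s peak-search window"
        )
    window = t <= peak_window_s
    pcs = float(np.max(np.abs(event.ff_N[window])) / event.delta_d_mm)
    if relative_uncertainty_pct is None:
        relative_uncertainty_pct = calibration.DISTRACTION_EXPANDED_U_PCT
    return StiffnessEstimate(
        kc=pcs,
        phase="distraction",
        timepoint=event.day_index,
        relative_uncertainty_pct=relative_uncertainty_pct,
        n=1,
    )


# ---------------------------------------------------------------------------
# Consolidation phase
# ---------------------------------------------------------------------------

def gait_peak_detect(step: StepRecord, threshold_fraction: float = 0.05) -> int:
    """Index of the stance-phase GRF maximum.

    Stance is defined as ``GRF > threshold_fraction * max(GRF)``; with a
    double-hump ovine stance profile this lands on the taller hump.
    """
    grf = step.grf_N
    peak = float(np.max(grf)) if grf.size else 0.0
    if peak <= 0:
        raise NoStanceError("GRF trace contains no loading (all zero)")
    mask = grf > threshold_fraction * peak
    if step.stance_mask is not None:
        mask &= step.stance_mask
    if not mask.any():
        raise NoStanceError("no samples above the stance threshold")
    idx = np.flatnonzero(mask)
    return int(idx[np.argmax(grf[idx])])


#: minimum fixator force at the stance peak, N; below it the load share of
#: the fixator is within noise and Eq.-style inversion is ill-conditioned.
FF_FLOOR_N = 1.0


def consolidation_stiffness(
    steps: StepRecord | Iterable[StepRecord],
    params: FixatorParams = FixatorParams(),
    ff_floor: float = FF_FLOOR_N,
    threshold_fraction: float = 0.05,
    timepoint: int | None = None,
    relative_uncertainty_pct: float | None = None,
) -> StiffnessEstimate:
    """Callus stiffness from gait steps via parallel-springs load sharing.

    Evaluated at the stance-peak instant of each step:
    ``Kc = Kf * (Fa - Ff) / Ff`` with ``Fa = ratio * GRF`` and magnitudes
    taken at that instant (fixator traces are stored compression-negative).
    Multiple steps aggregate by mean with the dispersion reported.  A step
    whose fixator force falls below ``ff_floor`` is flagged — counted in
    ``n_degenerate``, never silently dropped — and
    :class:`DegenerateStepError` is raised only when no valid step remains
    (near-zero fixator load share, i.e. a callus consolidated beyond the
    measurable range).
    """
    if isinstance(steps, StepRecord):
        steps = [steps]
    kcs = []
    n_degenerate = 0
    n_seen = 0
    for step in steps:
        n_seen += 1
        i = gait_peak_detect(step, threshold_fraction)
        fa = params.fa_grf_ratio * float(step.grf_N[i])
        ff = abs(float(step.ff_N[i]))
        if ff < ff_floor:
            n_degenerate += 1
            continue
        kcs.append(params.kf * (fa - ff) / ff)
    if n_seen == 0:
        raise InsufficientDataError("no steps provided")
    if not kcs:
        raise DegenerateStepError(
            f"all {n_degenerate} steps below the {ff_floor} N fixator-force guard"
        )
    kcs = np.asarray(kcs)
    if relative_uncertainty_pct is None:
        relative_uncertainty_pct = calibration.CONSOLIDATION_EXPANDED_U_PCT
    return StiffnessEstimate(
        kc=float(np.mean(kcs)),
        phase="consolidation",
        timepoint=timepoint,
        relative_uncertainty_pct=relative_uncertainty_pct,
        n=len(kcs),
        kc_sd=float(np.std(kcs, ddof=1)) if len(kcs) > 1 else 0.0,
        n_degenerate=n_degenerate,
    )


def estimates_to_records(estimates: Sequence[StiffnessEstimate]) -> "pd.DataFrame":
    """Tabulate estimates with columns phase, day, Kc_N_per_mm, U_percent, n."""
    import pandas as pd

    return pd.DataFrame(
        {
            "phase": [e.phase for e in estimates],
            "day": [e.timepoint for e in estimates],
            "Kc_N_per_mm": [e.kc for e in estimates],
            "U_percent": [e.relative_uncertainty_pct for e in estimates],
            "n": [e.n for e in estimates],
        }
    )
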