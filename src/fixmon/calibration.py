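"""In vitro calibration analysis: relative error and the uncertainty budget.

The stiffness-estimation models are validated on a spring bench: an elastic
spring of known reference stiffness ``Ksr`` stands in for the bone callus,
and the instrumented fixator estimates that stiffness through the same
equations used in vivo.  For each spring the bench campaign performs 4
independent fixator re-assemblies with 5 repeated estimates each (a 4 x 5
grid), from which three relative uncertainty sources are budgeted:

- ``u_ref``  — uncertainty of the reference stiffness itself, from 5 direct
  spring tests: ``SD / (sqrt(5) * Ksr)``;
- ``u_repl`` — replication (between re-assemblies): SD of the 4 assembly
  means divided by ``sqrt(4) * Ks``;
- ``u_rept`` — repetition (within one assembly): pooled within-assembly SD
  divided by ``sqrt(5) * Ks``.

They combine in quadrature and are expanded with a coverage factor ``k = 2``
(GUM practice, ~95 % coverage for roughly normal errors):

    U = k * sqrt(u_ref**2 + u_repl**2 + u_rept**2)

The published bench results for this platform (six springs per clinical
phase) are bundled as :data:`REFERENCE_BENCH` and serve as regression
fixtures and as the default report layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError

PHASES = ("distraction", "consolidation")

#: Spring-bench validation results for the platform.  Columns per row:
#: (Ksr N/mm, Ks N/mm, sigma_s N/mm, e %, U %); six springs per phase,
#: spanning the callus stiffness expected over each clinical phase.
REFERENCE_BENCH: dict[str, list[tuple[float, float, float, float, float]]] = {
    "distraction": [
        (16.75, 17.25, 1.20, 3.01, 8.91),
        (39.93, 35.65, 2.86, 10.72, 10.74),
        (65.45, 62.88, 4.03, 3.93, 8.29),
        (102.77, 92.15, 3.21, 10.33, 5.01),
        (175.01, 167.09, 4.90, 4.52, 3.81),
        (208.83, 192.39, 9.03, 7.87, 8.26),
    ],
    "consolidation": [
        (103.01, 98.79, 16.52, 4.09, 21.92),
        (208.83, 194.29, 14.62, 6.96, 9.65),
        (416.37, 398.33, 31.86, 4.33, 14.22),
        (1979.03, 1960.38, 148.25, 0.94, 12.15),
        (5050.13, 4572.29, 539.96, 9.46, 16.02),
        (7448.78, 7716.09, 567.94, 3.59, 10.28),
    ],
}

#: Reference-spring stiffness values used on the bench, per phase (N/mm).
BENCH_SPRINGS = {phase: [row[0] for row in rows] for phase, rows in REFERENCE_BENCH.items()}


@dataclass(frozen=True)
class UncertaintyBudget:
    """Three-source relative uncertainty budget, all components in percent."""

    u_ref_pct: float
    u_repl_pct: float
    u_rept_pct: float
    k: float = 2.0

    def __post_init__(self) -> None:
        if min(self.u_ref_pct, self.u_repl_pct, self.u_rept_pct) < 0:
            raise ValueError("uncertainty components must be non-negative")

    @property
    def expanded_pct(self) -> float:
        """Expanded relative uncertainty U = k * quadrature sum, percent."""
        return self.k * math.sqrt(
            self.u_ref_pct**2 + self.u_repl_pct**2 + self.u_rept_pct**2
        )


@dataclass
class SpringBenchRecord:
    """One spring's bench campaign: reference value plus the estimate grid."""

    ksr: float  # reference stiffness, N/mm (mean of 5 direct tests)
    ksr_u_pct: float  # relative standard uncertainty of the reference, %
    phase: str
    estimates: np.ndarray  # shape (n_assemblies, n_repeats)
    spring_id: str = ""

    def __post_init__(self) -> None:
        if self.ksr <= 0:
            raise DomainError("reference stiffness Ksr must be positive")
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        est = np.asarray(self.estimates, dtype=float)
        if est.ndim != 2 or est.shape[0] < 2 or est.shape[1] < 2:
            raise InsufficientDataError(
                "estimate grid must be 2-D with >=2 assemblies and >=2 repeats"
            )
        if not np.all(np.isfinite(est)):
            raise InsufficientDataError("estimate grid is incomplete (non-finite entries)")
        if np.any(est <= 0):
            raise ValueError("all stiffness estimates must be positive")
        self.estimates = est


@dataclass(frozen=True)
class CalibrationRow:
    """One summarized bench row: Ksr, Ks, sigma_s, e (%), U (%)."""

    ksr: float
    ks: float
    sigma_s: float
    e_pct: float
    u_pct: float
    budget: UncertaintyBudget | None = None
    spring_id: str = ""
    phase: str = ""


def relative_error(ksr: float, ks: float, ndigits: int | None = None) -> float:
    """Relative stiffness-estimation error, percent: 100 |Ks - Ksr| / Ksr."""
    if ksr <= 0:
        raise DomainError("Ksr must be positive")
    e = 100.0 * abs(ks - ksr) / ksr
    return round(e, ndigits) if ndigits is not None else e


def summarize_bench(record: SpringBenchRecord) -> CalibrationRow:
    """Collapse a 4 x 5 estimate grid into one calibration-report row.

    ``Ks`` is the grand mean, ``sigma_s`` the SD over all estimates, and the
    replication/repetition components follow the budget defined in the module
    docstring.  ``e`` is the error of the mean estimate (the alternative
    mean-of-per-estimate-errors statistic is :func:`mean_per_estimate_error`).
    """
    est = record.estimates
    n_assemblies, n_repeats = est.shape
    ks = float(est.mean())
    sigma_s = float(est.std(ddof=1))
    assembly_means = est.mean(axis=1)
    sd_between = float(assembly_means.std(ddof=1))
    pooled_within = float(np.sqrt(est.var(axis=1, ddof=1).mean()))
    budget = UncertaintyBudget(
        u_ref_pct=record.ksr_u_pct,
        u_repl_pct=100.0 * sd_between / (math.sqrt(n_assemblies) * ks),
        u_rept_pct=100.0 * pooled_within / (math.sqrt(n_repeats) * ks),
    )
    return CalibrationRow(
        ksr=record.ksr,
        ks=ks,
        sigma_s=sigma_s,
        e_pct=relative_error(record.ksr, ks),
        u_pct=budget.expanded_pct,
        budget=budget,
        spring_id=record.spring_id,
        phase=record.phase,
    )


def mean_per_estimate_error(record: SpringBenchRecord) -> float:
    """Mean of the 20 per-estimate relative errors, percent."""
    return float(
        np.mean([relative_error(record.ksr, ks) for ks in record.estimates.ravel()])
    )


def phase_average(rows: Sequence[CalibrationRow]) -> tuple[float, float]:
    """Phase-level (mean e %, mean U %), per-row values rounded to 2 decimals.

    Per-row rounding before averaging mirrors how tabulated calibration
    reports are conventionally printed.
    """
    if len(rows) == 0:
        raise InsufficientDataError("phase_average needs at least one row")
    mean_e = float(np.mean([round(r.e_pct, 2) for r in rows]))
    mean_u = float(np.mean([round(r.u_pct, 2) for r in rows]))
    return round(mean_e, 2), round(mean_u, 2)


def reference_rows(phase: str) -> list[CalibrationRow]:
    """Bundled bench results as :class:`CalibrationRow` objects."""
    return [
        CalibrationRow(
            ksr=ksr, ks=ks, sigma_s=sg, e_pct=e, u_pct=u,
            spring_id=f"{phase[:4]}-{i + 1}", phase=phase,
        )
        for i, (ksr, ks, sg, e, u) in enumerate(REFERENCE_BENCH[phase])
    ]


# In vitro phase-level expanded uncertainties, computed from the bundled
# bench table at import time; used as default uncertainty tags on in vivo
# stiffness estimates.
DISTRACTION_EXPANDED_U_PCT = phase_average(reference_rows("distraction"))[1]
CONSOLIDATION_EXPANDED_U_PCT = phase_average(reference_rows("consolidation"))[1]


# ---------------------------------------------------------------------------
# Force-acquisition error traces
# ---------------------------------------------------------------------------

def force_acquisition_error(
    measured: np.ndarray,
    reference: np.ndarray,
    floor: float = 0.05 * 1000.0,
) -> tuple[np.ndarray, float]:
    """Pointwise relative force error against a reference instrument.

    Returns ``(error_pct, mean_pct)``.  Samples where the reference magnitude
    is below ``floor`` (default 5 % of the 1 kN full scale) are masked NaN to
    avoid divide-by-near-zero at test start; the summary mean covers unmasked
    samples only.
    """
    measured = np.asarray(measured, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if measured.shape != reference.shape:
        raise ValueError("measured and reference traces must be synchronized")
    err = np.full(measured.shape, np.nan)
    mask = np.abs(reference) >= floor
    if not mask.any():
        raise InsufficientDataError("all samples below the reference floor")
    err[mask] = 100.0 * np.abs(measured[mask] - reference[mask]) / np.abs(reference[mask])
    return err, float(np.nanmean(err))


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------

BENCH_CSV_COLUMNS = ["spring_id", "phase", "Ksr", "Ksr_u_pct", "assembly", "repeat", "Ks_est"]


def read_bench_csv(path) -> list[SpringBenchRecord]:
    """Load bench grids from long-format CSV (columns :data:`BENCH_CSV_COLUMNS`)."""
    df = pd.read_csv(path)
    missing = set(BENCH_CSV_COLUMNS) - {"Ksr_u_pct"} - set(df.columns)
    if missing:
        raise ValueError(f"bench CSV missing columns: {sorted(missing)}")
    records = []
    for (spring_id, phase), grp in df.groupby(["spring_id", "phase"], sort=False):
        grid = grp.pivot(index="assembly", columns="repeat", values="Ks_est")
        records.append(
            SpringBenchRecord(
                ksr=float(grp["Ksr"].iloc[0]),
                ksr_u_pct=float(grp["Ksr_u_pct"].iloc[0]) if "Ksr_u_pct" in grp else 0.0,
                phase=str(phase),
                estimates=grid.to_numpy(),
                spring_id=str(spring_id),
            )
        )
    return records


def calibration_report(records: Iterable[SpringBenchRecord]) -> pd.DataFrame:
    """Summarize bench records into a report table with phase-average footers.

    Columns: spring_id, phase, Ksr_N_per_mm, Ks_N_per_mm, sigma_s_N_per_mm,
    e_pct, U_pct; one footer row per phase carries the phase averages.
    """
    rows = [summarize_bench(r) for r in records]
    if not rows:
        raise InsufficientDataError("no bench records to report")
    out = []
    for r in rows:
        out.append(
            {
                "spring_id": r.spring_id,
                "phase": r.phase,
                "Ksr_N_per_mm": round(r.ksr, 2),
                "Ks_N_per_mm": round(r.ks, 2),
                "sigma_s_N_per_mm": round(r.sigma_s, 2),
                "e_pct": round(r.e_pct, 2),
                "U_pct": round(r.u_pct, 2),
            }
        )
    for phase in PHASES:
        phase_rows = [r for r in rows if r.phase == phase]
        if phase_rows:
            mean_e, mean_u = phase_average(phase_rows)
            out.append(
                {
                    "spring_id": "average",
                    "phase": phase,
                    "Ksr_N_per_mm": np.nan,
                    "Ks_N_per_mm": np.nan,
                    "sigma_s_N_per_mm": np.nan,
                    "e_pct": mean_e,
                    "U_pct": mean_u,
                }
            )
    return pd.DataFrame(out)
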