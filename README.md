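# fixmon

Telemetry processing and bone-callus stiffness estimation for instrumented
external fixators.

## The problem

During distraction osteogenesis (bone lengthening) and related regeneration
treatments, an external fixator stabilizes the osteotomized bone while new
callus tissue bridges the gap. Instrumenting the fixator bars with load
cells lets clinicians and researchers follow the mechanical maturation of
the callus *in vivo*, without radiography or sacrifice: as the callus
stiffens, it takes over an increasing share of the skeletal load and the
fixator reads less. `fixmon` implements the computational side of such a
platform — the binary telemetry format with resynchronization, baseline
normalization, the bone–fixator mechanical model, the calibration
uncertainty budget, and a synthetic bench that emulates the whole system
with planted ground truth.

## The model

Writing `Fa` for the internal skeletal force, `Ff` for the force through the
fixator and `Fc` for the force through the callus, the two parallel load
paths satisfy

```
Fc = Fa − Ff
```

**Distraction phase** — after each controlled displacement `Δd` (1 mm/day)
the limb is at rest, so the fixator reads the callus traction directly and
the instantaneous *peak callus stiffness* before viscoelastic relaxation is

```
PCS = max Ff / Δd
```

**Consolidation phase** — during gait, with `Kf` the fixator's axial
stiffness (593 ± 21 N/mm) and `Fa = 3.22 × GRF` from a floor-platform
ground-reaction-force measurement, parallel-spring load sharing gives

```
Kc = Kf (Fa − Ff) / Ff
```

evaluated at the stance peak. An axial Young's modulus follows from
`E = Kc·L/A` with `L` the distraction gap and `A` the bone cross-section
(147.8 mm² for the ovine metatarsus).

Estimates carry an expanded relative uncertainty from an in vitro spring
bench campaign (reference, replication and repetition sources combined in
quadrature, coverage factor k = 2): 7.50 % for distraction and 14.04 % for
consolidation on average.

## Worked example

```python
import numpy as np
from fixmon import (
    SyntheticScenario, simulate_distraction_event, simulate_step,
    distraction_stiffness, consolidation_stiffness, young_modulus,
    CallusGeometry,
)

scenario = SyntheticScenario(seed=42)

event, truth = simulate_distraction_event(scenario, day_index=9)
pcs = distraction_stiffness(event)
print(f"day {event.day_index} distraction: PCS = {pcs.kc:.1f} N/mm "
      f"(planted {truth['pcs_true']:.1f}), U = {pcs.relative_uncertainty_pct:.2f} %")

steps = [simulate_step(scenario, kc_true=1850.0, step_index=i)[0] for i in range(6)]
est = consolidation_stiffness(steps, timepoint=12)
print(f"consolidation day {est.timepoint}: Kc = {est.kc:.0f} +- {est.kc_sd:.0f} N/mm "
      f"over {est.n} steps, U = {est.relative_uncertainty_pct:.2f} %")

geom = CallusGeometry(cross_section_area_mm2=147.8, gap_length_mm=15.0)
print(f"Young's modulus: E = {young_modulus(est, geom):.1f} MPa")
```

prints

```
day 9 distraction: PCS = 159.2 N/mm (planted 150.0), U = 7.50 %
consolidation day 12: Kc = 1864 +- 46 N/mm over 6 steps, U = 14.04 %
Young's modulus: E = 189.2 MPa
```

The day-9 peak callus stiffness lands ~6 % above the planted 150 N/mm
because the peak search rides on in vivo measurement noise (3.01 N SD on
the summed channel); the consolidation estimate inverts the load-sharing
model over six noisy gait steps and recovers the planted 1850 N/mm within
1 %, and converting it over a 15 mm gap gives a woven-bone-range modulus.

## Command line

```
fixmon simulate --kind rest --seed 1 --out session/          # telemetry binary
fixmon decode session/stream.bin --out traces.csv            # normalize + resync log
fixmon simulate --kind distraction --days 1,6,9,12 --out session/
fixmon estimate --phase distraction --in session/events.csv --out stiffness.csv
fixmon simulate --kind bench --phase consolidation --out session/
fixmon calibrate-report --in session/bench.csv --out report.csv
```

Every `simulate` output ships with a `truth.json` sidecar holding the
planted ground truth, so any downstream estimate can be checked against the
value the generator injected.

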