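# agderm

Mass-balance modelling of consumer exposure to silver nanoparticles (Ag NPs)
released from antimicrobial coated textiles: first-order release-rate
estimation from release experiments, simulation of textile → skin →
stratum-corneum / oral mass flows over wear scenarios, and REACH-style risk
characterization against a DNEL.

The package is aimed at exposure scientists and risk assessors who need
transparent, reproducible intake estimates for nanoparticle-coated consumer
products (face masks, clothing, gloves) from bench-scale release data.

## Model

The Ag mass `m(t)` (ng) on the skin surface obeys a single-compartment
balance with a first-order source and first-order losses:

```
dm/dt = S_p(t) − (k_sc + k_o + k_ww) · m(t)
S_p(t) = k_p · m_p(t),    m_p(t) = m_p,0 · e^(−k_p t)
```

where `m_p,0 = areal load × contact area × f_a` is the Ag initially on the
textile, `k_p` (1/min) the textile→skin release constant, and `k_sc`, `k_o`,
`k_ww` the net loss rates to stratum corneum, (peri-)oral region, and
wear/washing.  Receiving compartments are absorbing; total mass is conserved.

Two kinds of measurements parameterize the model:

- **Release experiments** (abrasion, sweat immersion, washing).  When only one
  removal process acts, one (donor, receptor) mass pair inverts to
  `k_x = −(1/t)·ln(1 − m_x/m_0)`.  Applied to 10-second sweaty-abrasion data
  this yields family-average release constants of 0.086, 0.12 and 0.15 1/min
  for the AgCur, AgHEC6.4 and AgHEC coatings.
- **Franz-cell permeation fluxes.**  Dividing the median penetration flux J
  (ng/cm²/h) by the donor load gives `k_sc` per skin condition:
  1.8×10⁻⁶ 1/h (fresh skin), 2.7×10⁻⁶ (cryopreserved), 34×10⁻⁶
  (glycerolized, a necrotic-skin surrogate).

Intake accumulated over a wear day, normalized by body weight (60 kg default)
and divided by the lowest general-population DNEL (0.01 mg/kg-bw/day), gives
the risk characterization ratio RCR; RCR > 1 flags inadequately controlled
risk.

## Worked example

Eight hours of face-mask wear (contact area 555 cm², AgCur coating,
1530 ng-Ag/cm²) on fresh, healthy skin:

```python
from agderm import face_mask_scenario, simulate, rcr

scenario = face_mask_scenario("AgCur", "fresh", wear_hours=8.0)
trajectory = simulate(scenario, dt=0.1)
released = trajectory.m_p0 - trajectory.m_textile[-1]
print(f"initial Ag on mask     : {trajectory.m_p0 / 1e3:.1f} ug")
print(f"released during wear   : {100 * released / trajectory.m_p0:.1f} %")
print(f"stratum-corneum intake : {trajectory.sc_intake:.2f} ng "
      f"({100 * trajectory.sc_intake / trajectory.m_p0:.4f} % of the load)")
result = rcr(trajectory.sc_intake, scenario.subject)
print(f"intake per body weight : {result.intake_ng_per_kg_day:.3f} ng/kg-bw/day")
print(f"risk characterization  : RCR = {result.rcr:.1e}")
```

prints

```
initial Ag on mask     : 849.1 ug
released during wear   : 100.0 %
stratum-corneum intake : 11.93 ng (0.0014 % of the load)
intake per body weight : 0.199 ng/kg-bw/day
risk characterization  : RCR = 2.0e-05
```

The textile empties almost completely within the first hour of wear
(99% released at 60 min), yet only 0.0014% of the silver crosses into the
stratum corneum in 8 h on healthy skin — dermal intake is release-limited at
first, then permeation-limited.  On glycerolized (necrotic-surrogate) skin the
same scenario yields ~225 ng, 19× more.

A command-line interface mirrors the library:

```sh
agderm simulate --config examples/face_mask_fresh.yaml --out out/
agderm fit-k release_data.csv --out estimates.csv
agderm risk-table --out risk.csv
agderm generate-synthetic --out synthetic.csv --true-k 0.086 --seed 1
agderm reproduce-paper --out report/
```

`agderm reproduce-paper` recomputes every published desk-scale quantity
(permeation-constant conversions, abrasion release constants, the 8-h intake
table, skin-type ratios, wear-time effects, the RCR chain) from the bundled
parameter tables and writes a side-by-side comparison with pass/fail flags,
including the documented unit caveats.

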