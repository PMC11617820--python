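# Methods

## Model

`agderm` implements a compartmental mass balance for dermal and inadvertent
oral exposure to nanoparticles released from a coated textile worn on skin.
Five compartments are tracked: the textile donor, the skin surface, and three
absorbing sinks — stratum corneum, oral, and wear/wash.  The skin-surface mass
`m(t)` follows

    dm/dt = S_p(t) − (k_sc + k_o + k_ww) · m(t),

with all transfers first-order and net (no back-transfer from a receiving
compartment).  The source is a standard first-order donor: the textile mass
decays as `m_p(t) = m_p,0 · e^(−k_p t)` during wear and the emission rate is
`S_p(t) = k_p · m_p(t)`, so the cumulative emission is
`m_p,0 · (1 − e^(−k_p t))`.  This form has the property that the emission rate
integrates exactly to the donor depletion, which is what makes the
whole-system mass balance closeable; it reproduces the characteristic
behaviour of the abrasion-parameterized textiles (essentially complete release
within the first hour at k_p ≈ 0.09–0.15 1/min).

Key modelling assumptions:

- **Intake = stratum corneum.**  Mass reaching the stratum corneum is counted
  as dermal intake and conservatively assumed fully systemically available.
- **Absorbing sinks.**  Particles in the stratum corneum, mouth, or removed by
  washing never return to the skin surface.
- **Lag times ignored by default.**  Franz-cell lag times (6–11 h) would
  suppress essentially all 8-h absorption; the reference results are computed
  with zero lag, which is the conservative choice and the only one consistent
  with the published 8-h intakes.  A per-scenario `sc_lag_min` switch delays
  `k_sc` activation when a lag is wanted.
- **Wear end ≠ washing.**  When a wear interval ends, the garment (with its
  residual silver) leaves the skin, but the deposit already on the skin
  remains and keeps feeding the stratum corneum until the simulation horizon.
  This is the only reading under which shortening wear from 8 h to 2 h changes
  the intake by well under 1% while 30-minute wear loses about 1 ng — both
  behaviours the test suite verifies.  Washing, when scheduled, moves the
  entire skin-surface deposit to the wear/wash sink at the stated time.
- **Mouthing as discrete events.**  Finger/hand-to-mouth contact is an
  instantaneous fractional transfer of the skin load on the contacted area
  (`load × area × TF × n × F_ret`), not a continuous rate: the reference
  glove scenario describes a single mouthing episode with effectively complete
  transfer at the end of wear, which a continuous `k_o` cannot represent
  without an arbitrary duration.  Retention defaults to 1 (complete
  ingestion), the worst case.

## Units

Internal computation uses ng, cm² and minutes.  The stratum-corneum constant
is measured in 1/h and stored in that native unit; it is converted by the
exact factor 60 exactly once, when a simulation is assembled.  This avoids the
recurrent 1/h-vs-1/min confusion that this parameter invites (the source
literature itself mixes the two).

## Parameters

| parameter | unit | default | origin |
|---|---|---|---|
| k_p (AgCur / AgHEC6.4 / AgHEC) | 1/min | 0.086 / 0.12 / 0.15 | mean of per-sample 10-s abrasion inversions |
| k_sc (fresh / cryo / glycerolized) | 1/h | 1.8e-6 / 2.7e-6 / 34e-6 | flux ÷ donor load, rounded as published |
| areal load (AgCur / AgHEC6.4 / AgHEC) | ng/cm² | 1530 / 1658 / 1430 | family means of coated-sample ICP-MS loads |
| contact area: face mask / full body / hands | cm² | 555 / 20 000 / 900 | scenario geometry |
| fingertip mouthing area | cm² | 11.5 | three adult fingertips |
| mouthing transfer efficiency TF | – | 0.1 | inferred calibration, see below |
| body weight | kg | 60 | general-population default |
| DNEL | mg/kg-bw/day | 0.01 | lowest general-population systemic DNEL |

The scenario builders use the *rounded, published* permeation constants
(1.8/2.7/34 ×10⁻⁶ 1/h) rather than the unrounded flux/load quotients
(1.770/2.655/33.63 ×10⁻⁶): the reference intake tabulations are
self-consistent only under the rounded values, and the difference (≤1.7%) is
far below the uncertainty of the underlying flux medians.
`flux_to_rate_constant` always returns the unrounded quotient.

The mouthing transfer efficiency of 0.1 is not a measured value: it is the
value that reconciles the quoted 1.8 µg fingertip ingestion with
11.5 cm² × 1530 ng/cm², and it is exposed as an ordinary argument rather than
buried as a constant.

## Numerics

- **Integrator.**  Fixed-step classical Runge–Kutta (RK4), default
  `dt = 0.1 min`.  The system is linear and non-stiff at these rates
  (fastest time constant ≈ 1/k_p ≈ 7–12 min), so a stiff solver is
  unnecessary; a fixed step makes the conservation audit trivial.  Because the
  right-hand side sums to zero across compartments, every RK4 step conserves
  total mass to round-off; the trajectory validator enforces a 10⁻⁶ relative
  tolerance end to end.
- **Piecewise regimes.**  The time axis is split at wear-interval edges, oral
  events, washing and lag times; each piece is integrated with a constant
  right-hand side and a step shrunk to divide the piece exactly, so schedule
  boundaries are hit exactly rather than straddled.  `dt` larger than the
  shortest wear interval is rejected.
- **Closed-form cross-check.**  For a donor feeding a skin surface whose only
  loss is `k_sc`, the intake has the first-order-in-`k_sc` form
  `k_sc · m_p,0 · [T − (1 − e^(−k_p'T))/k_p']` (`k_p'` in 1/h).  In the
  textile regime `k_sc·T ≈ 10⁻⁵–10⁻³` its error (≈ `k_sc·T/2`) is well below
  the 0.1% agreement the tests demand of the ODE; outside `k_sc·T < 0.01` the
  implementation switches to the exact two-exponential solution (with the
  confluent `k_p' = k_sc` case handled separately).
- **Degenerate inputs.**  Zero load, zero area or zero wear time produce valid
  all-zero trajectories, not errors.  A zero simulation horizon is an error in
  the library; the CLI intercepts it and writes an empty trajectory with a
  warning.
- **Estimator edge cases.**  The log-decay inversion is undefined at complete
  release (`m_x ≥ m_0`), which is rejected at construction.  The replicate
  standard deviation is the sample (n−1) form; a single replicate reports
  sd = 0 by convention.  Replicate aggregation averages per-sample rate
  constants, not release fractions (matching how the reference group averages
  are formed).

## Synthetic data

`agderm.synthetic` emulates the statistical structure of a short-contact
release campaign: per-sample initial loads lognormal around a family nominal
(default CV 0.3, the observed between-sample spread), exact first-order
release over the contact time, and multiplicative lognormal measurement noise
(default CV 0.1, since replicate scatter in the ICP-MS data is proportional to
level).  All randomness flows through an explicit integer seed
(`numpy.random.default_rng`); a fixed seed reproduces the dataset
byte-for-byte through the CSV writer.

What it does *not* emulate: instrument calibration drift, censoring at the
detection limit, spatial non-uniformity of the coating, or any dependence of
release on mechanical parameters (force, cycle count).  Passing recovery tests
therefore demonstrates estimator correctness and bias behaviour under
idealized noise, not robustness to real ICP-MS artefacts.

Recovery performance is itself under test: over 200 seeded campaigns of 50
samples at 10% noise, the median estimated constant must sit within 5% of
truth.

## Known discrepancies in the reference values

These are recomputed and flagged (not silently matched) by
`agderm reproduce-paper`:

1. **Intake unit label.**  The published 8-h intake column is headed "[µg]"
   but its numerals are consistent only with ng (12 ng is 0.0014% of the
   849 µg face-mask load, matching the quoted penetration percentage; 12 µg
   would be 1.4%).  The engine reports ng throughout.
2. **RCR columns.**  The published scenario RCRs (0.001–0.9) cannot be derived
   from the printed intakes with the stated normalization (÷60 kg,
   ÷0.01 mg/kg-bw/day) under either unit reading.  The RCR column computed
   here follows strictly from the stated formula; only the independently
   consistent 60-min comparison chain (2.6 ng → 0.043 ng/kg-bw → RCR 4.3×10⁻⁶)
   is asserted.
3. **Two face-mask intake cells.**  Sixteen of the eighteen intake numerals
   reproduce within 2%; the AgHEC6.4/cryopreserved (19) and AgHEC/fresh (11)
   face-mask cells land at 2.8% and 2.4%.  Both carry only two significant
   figures, and the matching full-body cells (702, 405), which carry more
   digits, agree within 0.4% — the model is consistent and the printed
   integers are display-precision artefacts.  The corresponding per-cell
   checks are left failing rather than widened.
4. **Intact-skin permeation row.**  0.02 ng/cm²/h over 70 µg/cm² gives
   0.29×10⁻⁶ 1/h, not the published 0.27×10⁻⁶; the conversion check flags it.
5. **T-shirt immersion mean.**  Inverting 6.8% and 5.0% releases over 30 min
   gives 0.0020 1/min, not the published 0.0017 (the trousers value, 0.0050,
   does reproduce).  How the published mean was formed is not recoverable from
   the printed fractions; the estimator is asserted against its own algebra.

## Problem sizes

Reference results use `dt = 0.1 min` (4 800 steps over an 8-h wear), at which
the integrator sits ~10⁻⁴ relative from the analytic solution — far inside
every tolerance used; the convergence test demonstrates the expected
order-of-accuracy collapse between dt = 4, 2 and 1 min.  Synthetic recovery
uses 200 campaigns × 50 samples.  The entire reproduction (estimation + 18
scenario integrations + report) runs in seconds on one core.

## Limitations

- The sport-comparison scenario needs garment masses that are only available
  in the study's supplementary material; the builder accepts them via config
  and refuses (with a pointer) when absent.  Its published dermal-exposure
  total is therefore supported but not asserted in the no-download test suite.
- No dissolution/ionic-silver kinetics, no diffusion-based (Fick/Potts–Guy)
  permeation, no size-dependent penetration rules, no inhalation route, no
  probabilistic population modelling.
- Continuous mouthing (`k_o`) and wear loss (`k_ww`) rates are supported by
  the engine but default to zero for lack of measured constants.
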