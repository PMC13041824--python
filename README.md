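# batflight

Wingbeat-resolved analysis of motor cortical activity during bat flight.

Bats steer highly reproducible 3D flight paths by adjusting individual
~8 Hz wingbeat cycles, and motor cortical units participate sparsely and
selectively in this control: some lock to the wingbeat phase, some encode
per-cycle kinematics, some fire only on specific wingbeats with
millisecond precision.  This package provides, for anyone analyzing (or
simulating) such recordings:

* **flight kinematics** — flight segmentation, direction-sensitive path
  clustering, speed / g-force / angular-velocity / flight-path-angle
  derivation, flight-to-flight reproducibility;
* **wingbeat analysis** — cycle detection from the dorsoventral
  accelerometer (band-pass + analytic-signal phase), stroke envelopes and
  left–right asymmetries, per-cycle adaptation vectors, ordinal-preserving
  wingbeat grouping;
* **unit statistics** — circular-shift permutation tests for flight
  modulation (BH-FDR q = 0.01), silent-wingbeat fractions, resultant
  vector length R = |Σₖ e^{iθₖ}|/n with per-path permutation nulls
  (q = 0.05), and cross-path wingbeat-phase decoding via sine/cosine
  regression;
* **recruitment decoding** — binary wingbeat "barcodes", linear-SVM
  decoding of wingbeat group with band accuracy and label-shuffle nulls,
  population similarity-versus-lag curves, cross-path divergence traces;
* **kinematic encoding** — per-unit Poisson GLMs on 17 per-cycle features
  with elastic-net selection, cross-validated deviance pseudo-R²
  (1 − D(model)/D(null)) and the normalized participation ratio
  (Σwᵢ²)²/Σwᵢ⁴ of the fitted weights;
* **population dimensionality** — PCA spectra with n90 and core/extended
  participation ratios, demixed PCA splitting condition-specific
  (wingbeat group) from condition-invariant (time-only) variance, and
  GPFA with per-factor Gaussian-process timescales and
  leave-one-neuron-out dimensionality selection;
* **a synthetic session generator** whose planted ground truth (paths,
  phases, groups, tuning parameters, latent factors) lets every stage be
  scored quantitatively.

## Worked example

```python
import numpy as np
from batflight import GeneratorConfig, generate_session
from batflight import wingbeats as wbm, unitstats as us
from batflight.core import resultant_vector

cfg = GeneratorConfig(seed=7, flights_per_path=6)
session, truth = generate_session(cfg)

table, theta = wbm.detect_wingbeats(session.t, session.accel[:, 2],
                                    session.sample_rate, truth.flights)
stats = wbm.period_statistics(table)
print(f"flights: {len(truth.flights)}  wingbeats: {stats['n']}  "
      f"period median {stats['median_ms']:.1f} ms  IQR {stats['iqr_ms']:.1f} ms")

uid = 0  # a phase-locked unit
phases = us.spike_phases(session.spikes[uid], session.t, theta)
rvl, pref = resultant_vector(phases[~np.isnan(phases)])
frac = us.silent_wingbeat_fraction(session.spikes[uid], table)
print(f"unit {uid}: RVL {rvl:.2f}  preferred phase {pref:.2f} rad  "
      f"silent-wingbeat fraction {frac:.2f}")
```

Output:

```
flights: 12  wingbeats: 201  period median 124.9 ms  IQR 3.2 ms
unit 0: RVL 0.88  preferred phase 5.54 rad  silent-wingbeat fraction 0.27
```

Twelve flights over two paths yield 201 detected cycles whose median
period (124.9 ms) matches the planted 8 Hz rhythm, with the small IQR
coming from the planted 3 ms period jitter.  Unit 0 is a tonic
phase-locked unit: its resultant vector length of 0.88 means its spikes
concentrate tightly around one wingbeat phase (0 = uniform, 1 = perfect
locking), and it fires in most cycles (27% silent), unlike the sparse
group-selective units whose silent fractions exceed 0.9.

The same analyses are scriptable from the shell:

```bash
batflight simulate --out session_dir --seed 7
batflight run-all session_dir --out report_dir --seed 7
```

which writes `flights.csv`, `wingbeats.csv`, `unit_stats.csv`,
`phase_pairs.csv`, `glm_fits.csv`, `decode_report.json`,
`dim_report.json` and a consolidated `report.json` (content fully
determined by the seed).

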