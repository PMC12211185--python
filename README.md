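# cardionano

Quantitative analysis of cardiomyocyte nanostructure and physiology:

* **Spatial statistics of single-molecule localization microscopy (SMLM)
  point clouds** — Ripley's K/L functions with the centered-curve peak that
  summarizes cluster organization, CSR-normalized pairwise-distance
  frequency curves, and nearest-neighbor distance analysis (NNA).
* **Persistent homology** of localization patterns — barcodes of connected
  components (H0) and holes (H1) under an expanding-circle (radius-
  parameterized Vietoris–Rips) filtration, with hole-size histograms of bar
  endpoints.
* **Localization extraction** — converting blinking-emitter acquisition
  stacks into a localization table (the "Orte-Matrix") by consecutive-frame
  difference detection, dark-state bridging and intensity-weighted
  barycenters.
* **Kinetics of paced calcium transients and contraction recordings** —
  per-beat diastolic/systolic levels, 10–90 % rise time, release rate,
  reuptake time constant τ from a single-exponential fit to the descending
  phase, and beating frequency / amplitude / contraction and relaxation
  velocities from motion traces.
* **Synthetic data generation** for all of the above (Thomas cluster
  processes, blinking-emitter stacks, paced transients, contracting texture
  stacks) with retained ground truth, plus a two-condition comparison
  pipeline using means ± SEM and two-tailed Student's t-tests.

The intended users are microscopists and cardiac physiologists who need a
reproducible, testable version of these analyses without proprietary
acquisition software.

## The statistics at the core

For a point pattern of n molecules in a window W, Ripley's K is estimated
as

    K̂(r) = |W| / (n(n−1)) · Σ_{i≠j} 1(0 < d_ij ≤ r),

optionally with toroidal edge correction. Its variance-stabilized form
L(r) = √(K(r)/π) satisfies L(r) − r ≈ 0 under complete spatial randomness
(CSR); clustering raises the curve, and the **peak of L(r) − r** (its value
and radius) is the per-cell organization summary compared across
conditions.

Persistent homology grows a disc of radius r around every localization: an
edge between two points appears at r = d/2 (when their circles touch).
Components merge (H0 bars end) at the halved minimum-spanning-tree edge
lengths; cycles of points enclose holes (H1 bars) that die when triangles
fill them, so the distribution of H1 death radii measures hole sizes in nm.

Calcium reuptake is quantified by fitting y(t) = B + A·exp(−(t−t₀)/τ) to
the descending phase of each paced transient; 1/τ is the reuptake rate.

## Worked example

```python
import numpy as np
from cardionano.core import Window
from cardionano.synthgen import ClusterModel, gen_clustered
from cardionano.pointstats import ripley_k

window = Window.square(2000.0)  # 2 x 2 um field, coordinates in nm
model = ClusterModel(window, n_parents=20, offspring_mean=25,
                     cluster_sigma=20.0, background_rate=5e-6,
                     loc_precision_sigma=10.0, seed=1)
pattern = gen_clustered(model)
print(pattern.n)                       # 535 localizations
res = ripley_k(pattern, np.arange(0, 505, 5.0), edge_mode="torus")
print(res.peak_radius, res.peak_value) # 75.0  172.74565517410232
```

The pattern has 535 localizations in ~20 clusters of 20 nm spread (plus
10 nm localization jitter); the centered Ripley curve peaks at 75 nm with a
value of ≈173 nm — far above the ≈0 expected under CSR, quantifying the
clustering at its characteristic scale.

The shipped two-condition demo compares this "control" regime against a
loosened-cluster regime with faster calcium kinetics:

```bash
cardionano run configs/demo.yaml --out demo_report
```

`demo_report/summary.json` then contains, for the Ripley peak value
(4 replicates per condition): control mean 168.82 ± 3.32 (SEM) nm versus
treated 115.07 ± 8.97 nm, t = 5.62 on 6 degrees of freedom, p = 0.00135
(`**`) — loosening clusters from 20 nm to 60 nm lowers the organization
peak, the direction-of-effect the spatial statistics are designed to
resolve. Rerunning with the same master seed reproduces the file byte for
byte.

The same CLI exposes every stage individually
(`cardionano simulate|localize|ripley|nna|persistence|transients|contract|compare`).

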