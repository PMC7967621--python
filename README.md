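# ecopattern

Three-layer analysis of ecosystem-pattern evolution from categorical
land-cover rasters, for landscape ecologists studying regional change — in
particular abrupt change such as a major natural disturbance — across several
mapped epochs.

**Layer 1 — what changed.** Inter-class area transfer matrices between
epochs (the Markov cross-tabulation A, with A[i][j] the area moving from
class *i* to class *j*) and six class-level landscape pattern indices
computed from first principles by patch labeling:

| index | definition | unit |
|---|---|---|
| CA | total class area | ha |
| NP | number of patches | count |
| PD | patch density, NP per 100 ha of landscape | /100 ha |
| PLAND | 100·CA / landscape area | % |
| LPI | 100·(largest patch area) / landscape area | % |
| MPS | CA / NP | ha |

**Layer 2 — why it changed.** Deng-type grey relational degrees
ξ(m,n) = (Δmin + ρΔmax)/(Δ(m,n) + ρΔmax), R = mean ξ, between a reference
series (total landscape area) and the composition/pattern indicators; and an
entropy-weighted coupling–coordination diagnosis between the ecosystem
subsystem (class areas) and the landscape-pattern subsystem (NP, PD, LPI,
MPS): coupling degree C = n·[ΠU/(ΣU)ⁿ]^(1/n), coordination index T = Σβ·U,
coordination degree D = √(C·T) graded into ten labelled levels, plus the
relative priority P = U_eco/U_land (lag / synchronous / lead).

**Layer 3 — how good the outcome is.** Interval-entropy-weight TOPSIS:
min-max normalisation with polarity, entropy weights, Euclidean distances d±
to the per-indicator ideal/anti-ideal, relative closeness
C = d⁻/(d⁺ + d⁻), competition ranking.

A seeded synthetic-landscape generator (smoothed-field neutral landscapes
with Markov epoch transitions) makes every stage runnable and testable with
no external data.

## Worked example

Two synthetic epochs, 200×200 cells of 100 m (400 km²), half forest, with a
known transition schedule (forest loses 10 % to farmland and 5 % to
grassland per epoch):

```python
import numpy as np
from ecopattern import (LandscapeSpec, TransitionSpec, generate_epoch_series,
                        compute_class_metrics, compute_transfer, transfer_to_table)

spec = LandscapeSpec(shape=(200, 200), cell_size_m=100.0,
                     class_proportions={"forest": 0.5, "grassland": 0.2,
                                        "farmland": 0.3},
                     patch_scale=3.0, seed=42)
t = TransitionSpec(classes=("forest", "grassland", "farmland"),
                   rate_matrix=np.array([[0.85, 0.05, 0.10],
                                         [0.05, 0.90, 0.05],
                                         [0.10, 0.00, 0.90]]),
                   spatial_mode="iid", seed=43)
g2000, g2010 = generate_epoch_series(spec, [t], labels=["2000", "2010"])

print(compute_class_metrics(g2000).round(3).loc[["forest", "grassland", "farmland"]])
T = compute_transfer(g2000, g2010)
print(transfer_to_table(T, display_classes=["forest", "grassland", "farmland"]))
```

prints (metrics first):

```
                CA  NP     PD  PLAND     LPI      MPS
class
forest     20000.0  32  0.080   50.0  19.405  625.000
grassland   8000.0  63  0.158   20.0  12.118  126.984
farmland   12000.0  70  0.175   30.0   8.042  171.429
```

Forest covers exactly half the 40 000 ha landscape (CA = 20 000 ha,
PLAND = 50 %), in 32 patches (PD = 0.08 per 100 ha, MPS = 625 ha), and the
largest single forest patch holds 19.4 % of the landscape.

```
              forest  grassland  farmland   Total  Change  Roll-In (%)
Type
forest        170.12       4.23     12.16  186.51   16.39        32.67
grassland       9.74      71.87      0.00   81.61    9.74        19.41
farmland       20.14       3.90    107.84  131.88   24.04        47.92
Total         200.00      80.00    120.00  400.00     NaN          NaN
Change         29.88       8.13     12.16     NaN   50.17          NaN
Roll-Out (%)   59.56      16.20     24.24     NaN     NaN       100.00
```

The transfer report (km²; rows are the destination epoch, as these tables
are conventionally printed): of forest's initial 200 km², 29.88 km² left it
(a 14.9 % empirical exit rate against the specified 15 %), which is 59.56 %
of all area that changed class (50.17 km²); farmland gained 24.04 km² net of
its own diagonal, 47.92 % of total change.

The same objects feed layer 2 (`grey_relational`, `couple_subsystems`) and
layer 3 (`run_topsis`); `ecopattern run --config config.yaml` drives all
three layers from rasters on disk, and `ecopattern synth | metrics |
transfer | grey | couple | topsis` expose each stage on the shell.

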