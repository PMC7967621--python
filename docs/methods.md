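# Methods

This note records the models implemented, the defaults and why, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Rasters and areas

A `ClassGrid` is a row-major 2-D integer raster (origin top-left) with a
cell size in metres, a nodata code and a legend of (code, class-name)
entries. No reprojection or resampling is performed anywhere; epochs must be
supplied co-registered, and `check_coregistered` verifies shape, cell size
and (when known) origin to an absolute tolerance of 1e-6 m. Nodata cells are
excluded from every area total; a grid that is entirely nodata is rejected
rather than yielding empty results. Areas are carried internally in m² and
converted only at reporting: km² for transfer matrices, hectares for CA and
MPS — the units these tables are conventionally printed in.

Supported formats: ESRI ASCII grid (plain text, parsed here) and TIFF via
tifffile, with cell size, origin and nodata carried in the ImageDescription
tag as JSON. A `strict` flag controls whether codes absent from the legend
abort the read or are mapped to nodata with a logged count.

## Landscape metrics (layer 1)

Patches are maximal same-class connected components labelled with
`scipy.ndimage.label`. Default connectivity is 8 (queen adjacency), the
FRAGSTATS default; 4 is available because published analyses rarely state
the choice and the two differ exactly on diagonal-only contact. Metric
definitions are as in the README table. Three choices worth stating:

- **PD unit** defaults to patches per 100 ha (the FRAGSTATS convention) and
  is configurable (`per_ha`, `per_km2`) because small printed PD increments
  do not disambiguate the unit.
- **MPS of an absent class** is reported as missing (NaN), not 0, so that
  MPS·NP = CA remains a testable identity for every class with NP ≥ 1.
- **Denominators** (PLAND, LPI, PD) use the non-nodata landscape area.

The suite checks all six metrics exactly (to 1e-12 relative) against an
independent flood-fill recomputation on seeded random grids, plus the
conservation (ΣCA = landscape area, ΣPLAND = 100) and bridging-cell
monotonicity invariants.

## Transfer matrices (layer 1)

`compute_transfer` cross-tabulates two epochs into A[i][j] = area moving
from class i to class j (km²), dropping cells that are nodata in *either*
epoch (intersection analysis; the dropped area is logged). Change
statistics: loss = row total − diagonal, gain = column total − diagonal,
total change = grand total − trace, and roll-out/roll-in percentages share
that single all-class denominator, so each percentage column sums to 100.
Display restriction (e.g. hiding an "other/unused" class) affects only which
rows are shown — totals and the percentage denominator always keep every
class, matching how such tables are printed.

The report writer emits the conventional layout with the *destination* epoch
on rows; `matrix_from_printed_table` inverts that layout, reconstructing a
hidden class's row, column and diagonal from the printed totals by
difference (clamping small negative residuals that arise from 2-decimal
rounding).

Markov chaining of transfer matrices across epochs holds only for spatially
independent transitions; it is exercised on the generator's "iid" mode
within sampling error and is not asserted in general.

## Grey relational analysis (layer 2)

Deng's formulation with Δmin and Δmax taken globally over all comparison
series and time points — the only reading under which ξ ∈ (0, 1] and the
resolution coefficient ρ (default 0.5, valid range (0, 1]) acts as a
damping constant. Series are first made dimensionless by dividing by the
series mean (default) or the first value; both modes are exposed because
conventions differ and the choice changes R. R is the plain arithmetic mean
of ξ over time points. Degrees are graded into six lower-inclusive bins
(0–0.25 very low … 0.85–1.00 very high, top bin closed).

Degenerate input: when Δmax is at floating-point noise level (every series
numerically coincides with the reference) all coefficients are set to 1
instead of amplifying the noise; the cutoff is 1e-12 relative to the
reference scale.

The pipeline wires the total landscape area as the reference series and the
class areas plus the focal class's NP/PD/LPI/MPS as comparisons. For a
full-coverage raster the reference is constant — it becomes an all-ones
series after mean scaling and the analysis measures how steadily each
indicator holds its own mean, which is the intended reading for a fixed
study region.

## Coupling–coordination and relative priority (layer 2)

Each subsystem panel (ecosystem = class areas; landscape pattern = NP, PD,
LPI, MPS) is min-max normalised (polarity applied; optional floor ε for
implementations that keep values strictly positive, default 0), entropy
weighted, and collapsed to a composite U = ΣW·y per epoch. Then

- C = n·[ΠU/(ΣU)ⁿ]^(1/n), computed in logs for stability; C = 0 when any
  subsystem value is 0, and an all-zero epoch is defined as C = 0 with a
  warning rather than an error;
- T = Σβ·U with β = (0.5, 0.5) by default — no published basis for an
  asymmetric weighting was found, and equal weights are the neutral choice;
- D = √(C·T) by default. The alternative literal product D = C·T is kept
  selectable (`model_form="literal"`), but the published worked-example
  table is only consistent with the square-root form (the literal form
  misses its first row by more than 0.1; a regression test pins this), and
  the square-root form is also the standard "modified" coupling-coordination
  model in the literature.

D is graded into ten half-open bins of width 0.1 (level 1 "Extreme
imbalance" … level 10 "Best coordination"; D = 1 maps into level 10). A
1e-9 epsilon guards the bin edges against float representation of values
like 0.7.

Relative priority is the plain ratio P = U_eco/U_land with thresholds
(1, 100): P < 1 ecosystem lag, 1 ≤ P ≤ 100 synchronous, P > 100 ecosystem
lead. The strikingly wide synchronous band is kept as the method defines it
and is configurable (`priority_thresholds`) for users who want a tighter
symmetric band such as (1, 1.5).

## TOPSIS (layer 3)

Interval (min-max) normalisation with polarity → entropy weights → weighted
matrix r = W·z → ideal best/worst as column max/min (valid because polarity
is already folded in) → Euclidean distances → closeness C = d⁻/(d⁺+d⁻) →
competition ranking ("1224", ties share the better rank, stable input
order). The degenerate single-point case d⁺ = d⁻ = 0 is defined as C = 0.5
with a warning. Entropy weighting means a constant indicator receives weight
0; if every indicator is constant the weights fall back to equal, with a
warning.

## Synthetic landscapes

`generate_landscape` builds neutral landscapes: a standard-normal field
smoothed by a Gaussian kernel of radius `patch_scale` (cells) and sliced at
the ranked-cell quantiles of the target class proportions. Realised
proportions are exact to within one cell; mean patch size grows with
`patch_scale`. Classes are assigned in legend order along the field's value
axis, so adjacent-valued classes share most boundaries — acceptable because
all metrics here are per class.

`evolve_landscape` applies a k×k row-stochastic transition matrix per epoch.
"iid" mode draws each cell independently (empirical rates converge to the
specified matrix; the suite checks a 0.3 rate to ±0.03 on 200×200 grids).
"frontier" mode moves the same expected number of cells per class but picks
them from class-boundary cells first, giving spatially clustered change
fronts; per-class exit totals are then deterministic given the seed, at the
cost of iid-ness. Nodata cells never change, so the non-nodata cell count is
conserved.

What the generator does **not** emulate: topography or any covariate-driven
change, anisotropy, class-adjacency preferences beyond the shared-threshold
artefact, temporal autocorrelation of rates, or the area distributions of
any real region. Green tests therefore demonstrate the correctness of the
arithmetic and its invariants under controlled conditions, not the realism
of any particular landscape.

Default study conditions used by the tests and examples: 200×200 cells of
100 m (400 km²) for rate-recovery checks (chosen so a ±0.03 tolerance on a
0.3 rate is comfortably above sampling noise), 50 random grids ≤30×30 for
exact oracle equivalence, and five epochs for pipeline runs, mirroring the
five-epoch mapping cadence typical of decadal land-cover products.

## Pipeline and CLI

`PipelineConfig` (YAML) drives the layers: layer 1 writes per-epoch metric
tables and transfer reports for consecutive pairs plus first↔last; layer 2
builds its indicator panel from layer 1 automatically (focal class = largest
class at the first epoch unless configured) or accepts an explicit panel;
layer 3 ranks any objects × indicators CSV. All numeric-affecting events —
dropped nodata area, constant-indicator warnings, weight fallbacks — are
logged at INFO/WARNING. Validation failures exit the CLI with code 2.

## Known limitations

- Only class-level indices are implemented; landscape-level diversity,
  shape, core-area and contagion metrics are out of scope.
- No multi-step Markov projection of future land cover.
- The grey "comprehensive correlation degree" is the plain time-average of
  coefficients; no additional aggregation across objects is applied.
- TIFF georeferencing is minimal (cell size/origin metadata), not full
  GeoTIFF tag support; ESRI ASCII is the lossless interchange format here.
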