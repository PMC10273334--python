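# Methods

`paleoneuro` implements a quantitative comparative-paleoneurology workflow
for crocodyliform endocasts and endosseous labyrinths: proportion panels,
sensory-acuity estimators, the reptile encephalisation quotient (REQ) chain,
rostral-proportion ecomorph classification, and semilandmark
Procrustes/PCA morphospace analysis. This note records the models, the
defaults, and the design decisions taken where the workflow admitted more
than one defensible choice.

## Data model and units

Measurements follow fixed per-column units: lengths and diameters in mm,
flexure angles in degrees, semicircular-canal enclosed areas in mm²,
endocast/optic volumes in mm³, brain volumes in cm³, body masses in g.
Missing values are `None` in memory and `?` in CSV (empty cells also parse
as missing). Tables are one specimen per row with canonical snake_case
headers; published tables in this field are usually printed transposed
(specimen per column), so the packaged example tables ship already
transposed. The reader accepts only the row-per-specimen layout to avoid
orientation ambiguity. Endocast volumes given in cm³ (the `table6` schema)
are converted to mm³ on read (×1000) so a single canonical field carries
them internally.

The packaged example tables reproduce a published nine/eight/22-specimen
crocodyliform dataset: 15 endocast/labyrinth measurements for 8 specimens
(14 cells unmeasurable, marked `?`), the derived proportion table, PCA
specimen metadata with ecology and skull classes, olfactory-bulb and
cerebral-hemisphere diameters, optic-lobe and endocast volumes, and
endocast/brain volumes with body masses for nine taxa.

## Proportion panel and ecomorph classes

`compute_ratio_panel` derives eleven dimensionless ratios from the raw
measurements (e.g. ASC:PSC enclosed area, cochlear duct length : labyrinth
height). One ratio uses a compound denominator: pituitary length over the
*hindcast* length, endocast length minus olfactory tract length. Ratios are
kept unrounded; display rounding is half-away-from-zero to 2 decimals,
matching how such tables are printed. Because the source measurements are
printed as integers, recomputed ratios can differ from the printed
proportion table in the last digit; the reproduction report therefore
flags each cell as `match` (equal at 2 dp), `tolerance-match` (±0.01),
`mismatch`, or `unverifiable` (a missing operand).

Skull classes follow rostrum-length : skull-length thresholds:
brevirostrine < 0.55, mesorostrine on the closed interval [0.55, 0.70],
longirostrine > 0.70. The boundary values go to mesorostrine because the
middle class is conventionally stated as a range while its neighbours are
strict inequalities. `classify_dataset` computes the class whenever a
ratio is present and passes through an asserted class (flagged `inferred`)
when it is not. Published assignments occasionally weigh snout *width* as
well as length (a long but broad snout may be called brevirostrine); when a
computed class disagrees with an asserted one, the result is flagged
`consistent_with_asserted=False` rather than silently overridden — in the
packaged 22-specimen metadata table this affects three taxa. The snout
width ratio is carried as metadata only; its operational definition varies
between sources, so it never enters classification.

## Sensory acuity

**Olfactory ratio.** The greatest olfactory-bulb diameter relative to the
greatest cerebral-hemisphere diameter, log-transformed as
`log10(100 · bulb/hemisphere)`. The percentage-log form is adopted because
it reproduces the published worked examples exactly (17.59/29.19 → 1.78;
19.13/28.89 → 1.82) and makes equal diameters read exactly 2.0. Both the
base and the ×100 factor are keyword-configurable.

**Optic fraction.** Optic-lobe volume as a percentage of the whole
endocast volume, displayed at integer percent. One cell of the published
nine-taxon panel (Lohuecosuchus, printed 15%) recomputes to 14% from its
printed volumes and is treated as unverifiable.

## The REQ chain

1. **Body mass** from total skull length via the crocodylian allometry
   `ln(TL) = 0.32·ln(M) + 2.05` (TL mm, M g), applied in its rearranged
   form `M = (TL·e^−2.05)^(1/0.32)`; the slope/intercept are parameters.
   When a source supplies body mass directly, it is used as given.
2. **Brain volume** from endocast volume by ordinary least squares. The
   regression originally cited for this step is not printed anywhere with
   its coefficients, so the package default is refit from the packaged
   nine-taxon (endocast, brain) panel: slope 0.246 cm³/cm³, intercept
   2.350 cm³, r² = 0.997. Any `BrainRegression` can be substituted.
3. **Brain mass** at density 1 g/cm³ (parameter).
4. **REQ** = MBr / (0.0155 · MBd^0.553), observed brain mass over the
   expected reptilian brain mass at the same body mass. The scale and
   exponent are parameters with the published defaults.

The REQ values printed alongside the nine-taxon panel are *not* recoverable
by applying this formula to the printed masses (most columns are a uniform
≈1.26× larger, but not all), so the chain carries no exact reproduction
test; it is instead verified by identities — REQ ≡ 1 when MBr equals the
expected brain mass, equivariance under joint rescaling of MBr and the
scale coefficient, and exact round-tripping of the body-mass allometry.

## Morphometrics

**GPA.** Standard iterative Generalized Procrustes Analysis: centre each
configuration, scale to unit centroid size, rotate onto the evolving
consensus by proper orthogonal Procrustes (determinant +1 — labyrinths are
chirally consistent, so reflections are excluded), re-estimate the
consensus, and repeat until the consensus RMS change falls below `tol`
(default 1e-10; `max_iter` 100; non-convergence is reported in the result,
not raised). Because a GPA solution is unique only up to a global
rotation, the aligned set is finally rotated into a canonical frame
(consensus inertia axes aligned with the coordinate axes, descending
variance, signs fixed by the largest-magnitude consensus coordinate,
determinant +1). This makes downstream PCA scores — including their signs —
reproducible under arbitrary rigid motions and rescalings of the inputs,
verified to ≤ 1e-6 end to end.

**Sliding.** Semilandmark positions along a curve are not individually
homologous, so an optional sliding step (`procrustes_distance` mode) moves
each interior semilandmark along its discrete tangent (central differences
within its curve) by the tangential component of its residual to the
consensus — the 1D minimiser of squared distance along that direction —
then re-runs GPA. Curve endpoints and non-semilandmarks are fixed. The
slid result is accepted only if it does not increase the total Procrustes
sum of squares; otherwise the input is returned unchanged, making the
documented monotonicity property hold unconditionally. Bending-energy
(thin-plate-spline) sliding is deliberately out of scope; the
Procrustes-distance criterion is the minimal-assumption choice for curve
semilandmarks.

**Shape PCA.** Covariance PCA (never correlation) of the flattened aligned
coordinates about the consensus, computed by SVD of the centred data
matrix; eigenvalues are s²/(n−1), identical to an explicit covariance
eigen-decomposition (tested to 1e-8). Scores are computed in the linear
tangent space at the consensus without an additional orthogonal
projection, adequate at the small shape variances analysed here.
Eigenvector signs follow a deterministic convention (largest-magnitude
entry positive). At most min(n−1, 3k−7) eigenvalues are non-zero after the
removal of translation (3), scale (1), and rotation (3).

**Morphospace summaries.** Per-group centroids and score ranges on the
first three PCs, pairwise centroid distances, and a 1D overlap fraction
per PC computed as intersection length over union length of the two
groups' score intervals (0 for disjoint groups).

## Synthetic data

No landmark compilation is distributed with the comparative data this
package targets, so the generators provide inputs with known truth.

The synthetic labyrinth is built from three planar circular arcs — anterior
and posterior canals in near-vertical, mutually orthogonal planes sharing a
common-crus point, the lateral canal near-horizontal — plus a short common
crus and a gently bowed cochlear-duct curve. Three controls mirror the main
axes of labyrinth shape variation in crocodyliforms: `height_width_ratio`
(dorsoventral compression; tall/short vs. low/long labyrinths),
`asc_psc_size_ratio` (anterior vs. posterior canal linear size; enclosed
areas scale as its square, verified against a shoelace-on-best-fit-plane
oracle), and `cochlear_angle_deg` (anteriorly vs. ventrally directed
cochlear duct). The default landmark budget is 82 semilandmarks,
partitioned ASC 22 / PSC 20 / LSC 20 / common crus 6 / cochlear duct 14 —
the total matches the published design, the partition is a configurable
package default. Landmark noise is isotropic Gaussian with standard
deviation `noise_sd` × centroid size. The default anterior:posterior size
ratio (1.5) sits in the range implied by published area ratios (2.1–3.4,
i.e. linear 1.45–1.84). All randomness flows from `numpy.random.default_rng`
with explicit seeds; population generators spawn per-specimen child seeds
from a `SeedSequence`, so outputs are pure functions of (params, seed).

What the generator does **not** emulate: canal torsion and non-planarity,
cross-sectional canal thickness, digitisation error correlated along
curves, allometric shape change, and phylogenetic covariance among
specimens. Passing tests therefore demonstrate the correctness of the
estimators under the stated model, not the anatomical realism of any
reconstruction.

The allometry generator draws endocast volumes log-uniformly (default
5–40 cm³, the span of the packaged comparative panel), brain volumes on a
known line plus Gaussian noise (default σ 0.5 cm³), body masses
log-uniformly (5×10³–2×10⁵ g), and skull lengths satisfying the log-linear
allometry exactly before a small lognormal perturbation (σ 0.02). Recovery
is validated by a 200-replicate Monte-Carlo check that the OLS estimates
fall within 3 standard errors of truth in ≥95% of replicates (n = 50).

## Problem sizes and numerical choices

Simulation-based tests use 10–20 specimens per group at 82 landmarks, and
200 Monte-Carlo replicates at n = 50 for regression calibration — large
enough for the parameter-recovery bounds stated above while keeping the
whole suite fast. GPA convergence tolerance 1e-10 (RMS consensus change);
aligned sets satisfy zero-centroid and unit-centroid-size to 1e-9 or
better. Degenerate inputs (coincident landmarks, collinear configurations,
all-equal regression abscissae) raise `ValidationError` rather than
returning garbage. Display rounding is half-away-from-zero; all
computation uses unrounded values.

## Known limitations

* The published morphospace variance percentages cannot be reproduced:
  the underlying 20-specimen landmark compilation is not distributed.
  The PCA is instead validated by oracle equivalence, normalisation
  invariants, and known-truth cluster separation on synthetic data.
* The printed REQ column is internally inconsistent with its own formula
  and inputs (see above); the package computes the formula as printed.
* Sliding uses a single Procrustes-distance pass with tangents from the
  current shapes; it is not iterated to a joint fixed point.
* The skull width ratio is metadata only and never enters classification.
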