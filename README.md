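# paleoneuro

Quantitative comparative paleoneurology for crocodyliforms (and other
fossil archosaurs measured the same way): turn endocast and endosseous
labyrinth measurements into proportion panels, sensory-acuity estimates,
reptile encephalisation quotients, rostral-proportion ecomorph classes, and
semilandmark Procrustes/PCA morphospaces — with seeded synthetic-data
generators so every stage is testable without CT-derived inputs.

Intended users: paleoneurologists and evolutionary morphologists who have
measured digital endocasts and inner ears (from CT segmentation or the
literature) and want the downstream numbers computed reproducibly.

## What it computes

**Proportion panel.** Eleven dimensionless ratios from 15 standard
endocast/labyrinth measurements (e.g. ASC:PSC enclosed canal area,
cochlear duct length : labyrinth height), with missing values propagated
and 2-decimal display rounding.

**Ecomorph classes.** Rostrum-length : skull-length thresholds —
brevirostrine < 0.55 ≤ mesorostrine ≤ 0.70 < longirostrine.

**Sensory acuity.** Olfactory ratio `log10(100 · bulb ⌀ / hemisphere ⌀)`
and relative optic-lobe volume `100 · V_optic / V_endocast` (%).

**Encephalisation.** The REQ chain:

    ln(TL) = 0.32 ln(MBd) + 2.05        (body mass from skull length)
    V_brain = a·V_endocast + b          (OLS; default refit a=0.246, b=2.350, r²=0.997)
    MBr = V_brain · 1 g/cm³
    REQ = MBr / (0.0155 · MBd^0.553)

All coefficients are parameters with these published defaults.

**Morphometrics.** Generalized Procrustes Analysis (translation, unit
centroid size, proper rotations, canonical final orientation), optional
Procrustes-distance semilandmark sliding along curve tangents, covariance
shape PCA, and per-group morphospace summaries (centroids, ranges,
overlaps).

**Synthetic data.** Seeded generators for labyrinth semilandmark
configurations (82 landmarks over ASC/PSC/LSC/common crus/cochlear duct,
with controllable height:width, canal-size, and cochlear-angle axes) and
for allometry tables with known ground truth.

## Worked example

The package ships the published nine-taxon crocodyliform panels as example
data:

```python
from paleoneuro import load_example_table, sensory_report
from paleoneuro.panels import display_round

volumes = (
    load_example_table("table4")   # bulb / hemisphere diameters
    .merge(load_example_table("table5"))   # optic & endocast volumes
    .merge(load_example_table("table6"))   # brain volumes & body masses
)
rep = sensory_report(volumes.volumes["NHMUK_PV_R_4769"])  # fossil gavialoid
print(display_round(rep.olfactory_ratio))        # 1.78
print(round(rep.optic_fraction_percent))         # 12
print(rep.brain_volume_cm3, rep.body_mass_g)     # 8.19 cm^3, 168653.9 g
print(round(rep.req, 2))                         # 0.68
```

The olfactory ratio 1.78 and optic fraction 12 % match the published
estimates for this specimen exactly. The REQ of 0.68 is the printed formula
applied to the printed masses; see `docs/methods.md` for why the originally
printed REQ column differs from its own formula.

From the shell, the same stages run as:

```sh
paleoneuro panel ratios --in table1.csv --out ratios.csv
paleoneuro panel classify --in table3.csv --out classes.csv
paleoneuro sensory --volumes table6.csv --acuity table4.csv --optic table5.csv --out report.csv
paleoneuro synth labyrinths --seed 42 --out lm.csv
paleoneuro morpho --landmarks lm.csv --out scores.csv --report variance.csv
paleoneuro run --config run.yaml     # full pipeline + manifest.json
```

## Layout

| module | contents |
| --- | --- |
| `paleoneuro.core_model` | domain types, validation, CSV/TPS readers and writers |
| `paleoneuro.panels` | ratio panel, skull-class thresholds |
| `paleoneuro.sensory_metrics` | olfactory/optic acuity, allometry, REQ |
| `paleoneuro.morphometrics` | GPA, sliding, shape PCA, morphospace summaries |
| `paleoneuro.synthetic_data` | seeded labyrinth and allometry generators |
| `paleoneuro.cli_report` | `paleoneuro` CLI and YAML-configured pipeline |

See `docs/methods.md` for the models, defaults, and design decisions.
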