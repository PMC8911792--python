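# marcex

Chemometric analysis of bioactive-compound extraction from grape marc
(wine pomace), for food scientists and natural-product chemists who optimize
solid–liquid extractions over a factorial design.

A typical experiment varies extraction temperature *t* (30, 45, 65 °C) and
ethanol concentration *C* (0–96 % v/v) and measures four yield responses per
condition: total polyphenols (TPC, mg GAE/g DW), flavonoids (TFC, mg GAE/g
DW), tannins (TC, mg TAE/g DW) and anthocyanins (TAC, mg ME/g DW). `marcex`
provides:

- **Dataset model and reference tables** — a validated full-factorial
  container (`ExtractionDataset`) with the 15-condition grape-marc yield
  table, the extract composition/antioxidant/CIELab table and the
  antimicrobial (inhibition zone, MIC/MBC) table packaged as fixtures;
  argmax/argmin, fold-change, two-fold dilution series and composition
  summaries.
- **Parametric spline curve model** — an interpolating space curve through
  all *n* experimental points. With knots ξ₁ < … < ξₙ, each coordinate
  direction (t, C, response) is a piecewise polynomial

  P<sub>i</sub>(s) = Σ<sub>j=1…k+1</sub> c<sub>ji</sub> (s − ξ<sub>i</sub>)<sup>k+1−j</sup>,  i = 1 … n−1,

  so a cubic fit (k = 3) of 15 points carries (15−1) × 3 × 4 = **168
  coefficients** and reproduces every measured point with virtually zero
  modeling error.
- **Mutual-information dependency analysis** — plug-in Shannon entropy and
  MI(X,Y) = H(X) + H(Y) − H(X,Y) in bits, on discretized condition means,
  with a sensitivity sweep over binnings and DOT/JSON graph export.
- **Optimization report** — per-response optima/minima, fold-changes,
  consensus optimum, optional dense spline-curve refinement.
- **CIELab chromatics** — chroma C\* = √(a\*² + b\*²) and hue angle
  H\* = atan2(b\*, a\*) with quadrant classification.
- **Synthetic-data generator** — factorial datasets from a unimodal
  concentration ridge with linear temperature gain, Gaussian noise and a
  latent-factor cross-response coupling ρ, with ground truth for recovery
  studies.

## Worked example

```python
from marcex import SplineCurveModel, MutualInformationModel, load_fixture, optimize, report

ds = load_fixture("table1")          # 15-condition factorial yield table

print(SplineCurveModel(ds, "TPC").fit().summary())
```

```
Parametric spline curve fit
===========================
response:          TPC
points (n):        15
order (k):         3
ordering:          lexicographic
parameterization:  index
boundary:          natural
intervals:         14
coefficients:      168  ((n-1) x 3 x (k+1) = 14 x 3 x 4)
max knot residual: 1.858e-16 (relative)
```

The curve interpolates all 15 points (knot residual at machine precision)
and exports the 168 per-interval coefficients
(`.coefficients`, long format: direction, interval, j, c_ji).

```python
rep = optimize(ds)
rep.consensus                        # Condition(temperature=65.0, concentration=60.0)
rep.fold_changes["(65,60)/(30,60)"]  # {'TPC': 1.47, 'TFC': 1.59, 'TC': 1.63, 'TAC': 1.45}
```

All four responses peak at 65 °C / 60 % v/v (TPC 11.02, TFC 7.76, TC 1.37,
TAC 0.97); heating from 30 to 65 °C at 60 % ethanol multiplies the yields by
1.45–1.63. `report(rep, format="markdown")` renders the table with the
optimum flagged.

```python
print(MutualInformationModel(ds).fit().summary())
```

```
Mutual-information dependency analysis (plug-in estimator, bits)
================================================================
observations:   15 condition means
discretization: {'temperature': 'distinct_levels', 'TPC': 'equal_width/3', ...}

edge                     MI (bits)
TFC -- TPC                   1.306
TC -- TFC                    1.289
TC -- TPC                    1.163
TAC -- TC                    0.966
TAC -- TPC                   0.844
TAC -- TFC                   0.761
TC -- temperature            0.376
TPC -- temperature           0.278
TFC -- temperature           0.278
TAC -- temperature           0.113
```

The response–response interdependencies (e.g. TPC–TAC, TPC–TFC) carry far
more information than any temperature–response pair — temperature influences
the yields, but the yields co-vary much more strongly with one another.
`mi_sensitivity(ds, (2, 3, 4, 5))` confirms this ordering for every response
binning from 2 to 5 bins.

A CLI mirrors the library: `marcex optimize`, `marcex fit-spline`,
`marcex mi`, `marcex chroma`, `marcex simulate`.

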