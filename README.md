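# bufcomp

Street-network buffers are the standard way to define the "neighborhood"
around a participant's home in built-environment and physical-activity
research: every spatial feature reachable within a network distance (here
1 km, a 10–15 minute walk) of the home counts as exposure. But GIS platforms
construct these buffer polygons differently, and the choice of construction
changes the measured environment. `bufcomp` implements three constructions —

* **sausage** — a fixed-radius (trim) disk swept along every reached street
  segment; fully reproducible across software;
* **detailed-trimmed** — a service-area polygon wrapping the reached streets
  at the trim distance, closing only slivers between nearby streets;
* **detailed** — a looser service-area polygon that also annexes street
  blocks enclosed by the reach;

and asks the question that matters for study comparability: *do the eleven
standard built-environment measures (BEMs) differ between buffer methods,
and do those differences propagate into the associations between the
environment and physical-activity outcomes?*

The package is exercised entirely on synthetic cities (pruned street grids
with parcels, transit stops, parks and a participant cohort whose outcomes
are drawn from a known latent model), so every stage is testable without
proprietary data.

## Methods in brief

For each participant the home is snapped to the nearest walkable street
(limited-access highways and ramps are excluded), and a single-source
Dijkstra expansion finds every full or partial edge segment within the 1 km
cutoff, with mid-edge origins and exact partial-edge intervals. The three
polygon constructions are applied to the same reached segments. Eleven BEMs
are computed per buffer: net residential density (units per residential
km²), intersection count and density, transit stop and private recreation
count and density (points optionally snapped to the network first), park
count and total park area, land-use mix

LUM = −Σᵢ pᵢ ln pᵢ / ln k,  pᵢ = share of category i's land area (k = 4),

and a walkability index = z(residential density) + z(land-use mix) +
z(intersection density).

Method comparison runs at two levels:

1. **values** — paired *t* tests and mean squared error between two methods'
   BEM vectors;
2. **associations** — each standardized BEM enters a linear mixed model
   (maximum likelihood) for each of five self-reported outcomes, with
   socio-demographic covariates and a recruitment-cluster random intercept;
   coefficient pairs from two methods are compared with
   z = (b₁ − b₂)/√(se₁² + se₂²) and tabulated by whether each member is
   significant at α = 0.05.

## Worked example

```sh
bufcomp run --config configs/demo.yaml
```

runs the full pipeline on a packaged demo city (200 participants, seed 7)
and writes `bem.csv`, `bem_comparisons.csv`, `association_fits.csv`,
`coef_comparisons.csv`, `agreement.csv/json` and a `manifest.json` into
`bufcomp_out/`. On this demo the three methods produce mean buffer areas of

| method           | mean area (km²) |
|------------------|-----------------|
| sausage          | 0.65            |
| detailed-trimmed | 0.68            |
| detailed         | 1.13            |

— the expected ordering, with the detailed polygons annexing enclosed
blocks. 59% of the paired BEM value comparisons are significant at α = 0.05
(82% for sausage vs detailed, where the area gap is largest; density
measures differ most because their denominator is the buffer area itself).
Yet of the 110 association-model coefficient pairs, 0% (sausage vs
detailed-trimmed) and 1.8% (sausage vs detailed) differ in statistical
significance: the *values* of the measures depend on the buffer
construction, but the *associations* they support largely do not.

The same can be driven from Python:

```python
from bufcomp import RunConfig, run
manifest = run(RunConfig(synth_n=200, synth_clusters=15, seed=7,
                         out_dir="bufcomp_out"))
```

Other subcommands: `bufcomp synth` (write a synthetic city dataset),
`bufcomp buffers` (polygons only), `bufcomp compare` (value-level comparison
of an existing BEM table).

## Layout

```
src/bufcomp/
  geodata.py        data model + GeoJSON/CSV I/O (planar meters contract)
  service_area.py   snapping and network-distance reach
  buffers.py        the three buffer constructions
  bem.py            the eleven built-environment measures
  synthetic_city.py city, feature and cohort generator
  comparison.py     t/MSE, mixed models, coefficient z tests, agreement
  pipeline.py       config-driven orchestration + manifest
  cli.py            `bufcomp` command-line interface
docs/methods.md     model assumptions, parameter choices, limitations
```
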