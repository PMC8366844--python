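# Data dictionary

## Record CSV (`records.csv`)

One row per study-record. UTF-8, comma-separated, header required.

| column | type | meaning |
|---|---|---|
| `record_id` | string | unique record identifier |
| `species_id` | string | species key; must appear in the species CSV and the tree |
| `N` | int ≥ 1 | number of diet samples examined |
| `y` | int or empty | samples containing plant material; **empty cell = not reported** |
| `mentioned` | 0/1 | plants mentioned but count not given (only valid when `y` is empty) |
| `sample_type` | 0/1 | 0 = scat, 1 = digestive tract |
| `island` | 0/1 | sampling site on an island (< 10,000 km²) |
| `spring` … `winter`, `dry`, `wet` | 0/1 | season dummies; all zero = whole-year study; mutually exclusive in generated data |
| `precip` | float | mean monthly precipitation, mm (min-max normalized before fitting) |
| `tmax` | float | mean daily maximum temperature, °C |
| `tmin` | float | mean daily minimum temperature, °C |
| `ndvi` | float | mean monthly NDVI, unitless in [−1, 1] |

Invariants enforced on load: `0 ≤ y ≤ N` when reported; `mentioned` implies
unreported; unknown species rejected with the row index.

## Species CSV (`species.csv`)

| column | type | meaning |
|---|---|---|
| `species_id` | string | species key |
| `body_mass` | float > 0 | adult body mass, kg (log-transformed before fitting) |

PV axis scores are computed from the tree at run time; a `pv_design.csv`
(species × PV1..PVk) is written alongside the results for reference.

## Tree (`tree.nwk`)

Newick with branch lengths on every edge; leaf labels are `species_id`
values.

## Truth sidecar (`truth.json`, synthetic bundles only)

Generative ground truth: `psi`, `global_intercept`, `env_coefficients`
(12, in the record-CSV column order island…sample_type),
`species_coefficients` (log body mass first, then PV axes), `omega`,
`theta` (per species), `mentioned_prob`, `seed`, and the realized
`species_intercepts` (α_j) and `record_effects` (τ_i).

## Draw table (`*_draws.csv`, optional)

Long format: `chain`, `iteration`, `parameter`, `value`. Vector parameters
are flattened as `name[k]` in design order. A `*.diagnostics.json` sidecar
carries the run config, Rhat per parameter block, divergence counts and
metadata.
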