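# psomcs

Growth-coupled strain design for constraint-based metabolic models.
`psomcs` couples two pieces:

* **Dual-system cut sets** — constrained minimal cut sets (cMCS) are
  extracted directly from the stoichiometric matrix: a Farkas-type
  certificate of infeasibility for an *undesired* flux region is solved as
  a MILP whose binary indicators mark knocked-out reactions, while an
  embedded primal block keeps a *desired* flux region feasible. Each solve
  returns one minimum-cardinality knockout set.
* **Particle swarm search** — the design itself (e.g. "guaranteed product
  yield at least x₁ with growth yield x₂ attainable") is parameterized by
  a threshold vector. A constriction-coefficient swarm with a ring-plus-
  random informant topology searches the threshold space, scoring each
  position by `(1 − |cMCS|/n) · ∏ xᵢ/xᵢ(max)`.

The result is the best achievable design together with a minimal knockout
set that enforces it, plus the FVA production envelope of the knockout
strain.

## Command line

```sh
# full pipeline: reduce -> compress -> exclude -> yield bounds -> swarm
psomcs run --model examples/toy_network.tsv --design examples/toy_design.json \
           --particles 4 --iterations 10 --max-cuts 5 --seed 1 --out out/

# FVA production envelope of a knockout strain
psomcs envelope --model examples/toy_network.tsv --knockouts R2,R9 \
                --product R4 --growth R7 --reference R1,R2,R3 --out env.csv

# random consistent test network in the tabular dialect
psomcs synth --metabolites 6 --reactions 10 --seed 7 --out net.tsv

# re-check a cut-set TSV against a design at a given threshold
psomcs validate --model examples/toy_network.tsv --design examples/toy_design.json \
                --x 1.0 --cutsets cuts.tsv
```

`run` writes `result.json` (best position, fitness, cut set, trace),
`cutsets.tsv` (one knockout set per line, decompressed to original
reaction ids), `trace.csv`, `envelope.csv` and `config.json` into the
output directory. Exit codes: 2 = configuration error, 3 = model error,
4 = solver error.

## Model formats

SBML Level 3 (FBC) via cobrapy, plus a plain-text tabular dialect for
fixtures — one whitespace-separated row per reaction:

```
# id  rev|irr  met:coef[,met:coef...]  [lb ub]
R9  irr  A:-1,B:1
```

Exchange reactions are detected structurally (single nonzero
stoichiometric entry). Spontaneous reactions are an explicit annotation
list in the design JSON (`"spontaneous": [...]`), since SBML has no
standard flag for them.

## Design JSON

```json
{
  "reference": ["R1", "R2", "R3"],
  "objectives": [
    {"name": "product", "numerator": "R4", "role": "product_min_yield"},
    {"name": "growth",  "numerator": "R7", "role": "growth_min_yield"}
  ]
}
```

`reference` names the denominator reactions whose summed flux is
normalized to 1; each objective contributes one swarm dimension. Optional
keys: `knockout_excluded`, `protect_essential_for`, `spontaneous`,
`exclude_exchanges`, `include_product_in_desired`.

## Library use

```python
from psomcs import PSOConfig, run_pso
from psomcs.synth import toy_network, toy_design

net, spec = toy_network(), toy_design()
result = run_pso(net, spec, PSOConfig(n_particles=4, max_iterations=30, seed=7))
print(result.g, result.best_cutset.sorted())   # [1.0] ['R2', 'R9']
```

Module map: `network` (loading, condition reduction, subset compression,
knockout exclusions), `lp` (FBA/FVA/yield bounds/regions/envelopes),
`design` (thresholds → target/desired regions), `dual` (the cut-set MILP,
validation, minimality, enumeration), `pso` (the swarm), `synth`
(toy fixture, random network generator, brute-force oracles), `cli`.

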