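# periltools

Trait-based intrinsic extinction vulnerability for exploited marine
bivalves: assemble species traits from occurrences and sea-surface
temperature, estimate clade volatility from the fossil record, combine them
into the PERIL score, test the phylogenetic structure of exploitation, model
exploitation as a function of traits, and map vulnerable exploited species
on an equal-area shelf grid.

## Who this is for

Conservation macroecologists working with under-assessed marine
invertebrates, where direct population data are scarce but traits,
occurrences and a rich fossil record are available. The package treats
vulnerability as *relative and intrinsic* — what a species' own biology and
its clade's history imply about sensitivity to perturbation — and is meant
to prioritize species and regions for formal assessment, not to replace it.

## The score

For each species with family extinction rate q̂ (per Myr), geographic range
r (km², convex hull of point occurrences, floored at 100 km² for
single-occurrence species) and thermal range T (°C, spread of SST across
occupied 50 × 50 km cells):

    PERIL ∝ q̂ + 1/ln r + 1/T

with each component min–max rescaled to [0, 1] over the analyzed species
set and averaged, so scores live in [0, 1]. Range and thermal breadth are
inverted: widespread, eurythermal species in low-turnover families score
low. q̂ is the boundary-crosser per-capita extinction rate of the family's
genera through the Cenozoic, q = −ln(Nbt/Nb)/Δt per stage,
duration-weighted across stages. Species above the global (or regional)
median are "vulnerable"; above the 80% quantile, "highly vulnerable".
See `docs/methods.md` for every convention.

## Worked example

Everything is runnable end to end on synthetic data with known ground
truth:

```sh
periltools simulate --seed 7 --n-species 120 --n-families 15 --out demo/
periltools score --species demo/species.csv --out demo/scored.csv
periltools map --species demo/scored.csv --grid demo/grid.geojson \
    --occurrences demo/occurrences_cells.csv \
    --threshold 0.8 --scope global --out demo/layer.geojson
```

which prints

```
wrote fixture set for 120 species to demo/
scored 120 of 120 species -> demo/scored.csv
wrote vulnerability layer for 772 cells to demo/layer.geojson
```

`scored.csv` gains the three rescaled components and the `peril` column;
`layer.geojson` carries, per cell, the species / exploited / vulnerable /
vulnerable-and-exploited counts and proportions under the stated threshold
rule, with the rule and quantile convention in a `.meta.json` sidecar.
Library use mirrors the CLI:

```python
from periltools import io, peril
from periltools.types import ThresholdRule

records = io.read_species_table("demo/species.csv")
components = peril.peril_scores(records)          # writes .peril back
labels = peril.classify({r.species_id: r.peril for r in records},
                        ThresholdRule(quantile=0.8))
```

The other subcommands: `rates` (family q̂ from fossil first/last stage
occurrences), `signal` (phylo-D for presence of exploited species; Pagel's
λ and Blomberg's K for the proportion), `assoc` (per-trait KS tests and the
maximum-likelihood fit of `exploited ~ traits + (1 | family)`).

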