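# lifespan-epistasis

A library and command-line tool (`epi`) for classifying **lifespan
epistasis** between longevity-associated genes in animal models
(*C. elegans*, *D. melanogaster*, *M. musculus*), and for building the
wild-type → n-mutant **intervention network** from curated lifespan
records.

Interventional gerontology routinely combines gene perturbations —
loss-of-function mutations, knockouts, RNAi, overexpression — and asks
whether the combined effect on lifespan is more or less than the parts.
This package answers that question computably: given per-experiment
cohort lifespans for the wild type (WT), single mutants and higher-order
n-mutants, it classifies every gene combination, scores "full" and
"simple" synergism for n ≥ 2, evaluates monotonic epistasis along
assayed intervention paths, and exports the strain network for
visualization.

## The classification model

All effects are percent lifespan changes relative to the
same-experiment wild type:

```
ΔG = (LS(G) − LS(WT)) · 100 / LS(WT)
```

For a double mutant whose single effects ΔG1, ΔG2 share a direction,
the interaction is one of five categories, compared on absolute values:

| category          | rule                                              |
|-------------------|---------------------------------------------------|
| synergistic       | \|Δ(G1,G2)\| > \|ΔG1\| + \|ΔG2\|                  |
| additive          | \|Δ(G1,G2)\| = \|ΔG1\| + \|ΔG2\|  (within ε)      |
| almost additive   | max(\|ΔG1\|,\|ΔG2\|) < \|Δ(G1,G2)\| < \|ΔG1\|+\|ΔG2\| |
| dependent         | min(\|ΔG1\|,\|ΔG2\|) ≤ \|Δ(G1,G2)\| ≤ max(\|ΔG1\|,\|ΔG2\|) |
| antagonistic      | \|Δ(G1,G2)\| < min(\|ΔG1\|,\|ΔG2\|)               |

A double mutant shifted in the *opposite* direction from both singles is
antagonistic; singles with opposite or zero effects are not directly
assessable.

For n-mutants, **full synergism** requires the combination's Δ to exceed
the summed Δ of *every* disjoint bipartition of its genes into a
k-mutant and an (n−k)-mutant, all intermediaries assayed in the same
experiment (a strict recursive variant, requiring synergy at every
sub-level, is available behind a flag). **Simple synergism** compares
only against the summed single effects — cheap, but falsifiable: missing
intermediaries can mask a dependency. **Partially-known monotony**
checks that lifespan strictly increases (or decreases) along every
assayed WT → n-mutant path; a fully assayed n-mutant has n! such paths.

## Worked example

WT lives 20 days; a `daf-2` mutant 40 days (+100%); an `rsks-1` mutant
24 days (+20%); the double mutant 70 days (+250%):

```python
from lifespan_epistasis import (classify_pair, full_synergy, monotony,
                                group_observations, GeneIntervention,
                                LifespanObservation, MutantModel)

def obs(genes, days):
    ivs = frozenset(GeneIntervention(g, "loss-of-function mutation") for g in genes)
    return LifespanObservation(model=MutantModel("C. elegans", ivs),
                               lifespan_days=days, temperature_c=20.0,
                               diet="NGM", study_id="PMID-example")

group, = group_observations([obs((), 20.0), obs(("daf-2",), 40.0),
                             obs(("rsks-1",), 24.0), obs(("daf-2", "rsks-1"), 70.0)])
double = MutantModel("C. elegans", frozenset(
    GeneIntervention(g, "loss-of-function mutation") for g in ("daf-2", "rsks-1")))
call = full_synergy(group, double)
print(f"category:  {call.category} ({call.phenotype_direction})")
res = monotony(group, double)
print(f"monotony:  {res.verdict} ({res.paths_known}/{res.paths_total} paths known)")
```

prints

```
category:  synergistic (long-lived)
monotony:  monotonic_positive (2/2 paths known)
```

+250% exceeds 100% + 20%, so the pair is fully synergistic, and both
single-step construction paths (via `daf-2` and via `rsks-1`) increase
lifespan at every step.

The same pipeline from the shell, on simulated data with known ground
truth (10% lifespan noise, three independent experiments):

```
$ epi simulate --config cfg.json --seed 1 --out data.csv --truth truth.json
wrote 12 observations to data.csv
$ epi classify --input data.csv --mode full --out calls.csv
wrote 3 calls to calls.csv
```

Each row of `calls.csv` is one (combination, experiment) call with its
evidence deltas, e.g.

```
C. elegans,daf-2;rsks-1,2,full,synergistic,long-lived,SIM-1-0|20|standard,"{""daf-2"": 109.7261, ...}"
```

Other subcommands: `epi load` (validation + row accounting), `epi qc`
(per-strain lifespan distributions), `epi network` (Cytoscape.js JSON /
GraphML export, green = long-lived, red = short-lived), `epi summarize`
(record counts, epistasis cross-tabulations, evaluability).

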