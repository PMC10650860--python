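# stresskit

Stress-tolerance analysis for multi-environment crop trials: tolerance
indices from paired normal/stress yields, correlation and PCA summaries
of those indices, Ward clustering of genotypes into tolerance classes,
and the classical trial statistics around them (two-way ANOVA,
entry-mean broad-sense heritability, LSD/Duncan mean separation).

## The problem

Breeders screening a germplasm collection under terminal heat or
combined heat-drought stress need to separate genotypes that *yield
well and hold their yield under stress* from those that merely yield
well under optimal conditions. The standard approach grows the same
genotypes under a normal sowing and one or more late (stressed)
sowings, takes per-genotype replicate-mean yields Ypᵢ (normal) and Ysᵢ
(stress), and computes a panel of selection indices:

| index | formula | reads as |
|---|---|---|
| SI | 1 − Ȳs/Ȳp | stress intensity of the episode (population level) |
| STI | Ypᵢ·Ysᵢ / Ȳp² | joint performance under both regimes |
| TOL | Ypᵢ − Ysᵢ | absolute yield loss (g/plot) |
| MP, GMP, HARM | arithmetic / geometric / harmonic mean of (Ypᵢ, Ysᵢ) | average productivity |
| SSI | (1 − Ysᵢ/Ypᵢ)/SI | Fischer–Maurer susceptibility |
| YSI | Ysᵢ/Ypᵢ | yield stability (retained fraction) |

Genotypes are then z-standardized on the nine columns (Ys, Yp and the
seven indices), summarized by correlation-matrix PCA with per-variable
contributions, clustered by Ward's minimum-variance criterion, and the
four resulting clusters labelled tolerant → susceptible from their mean
GMP, SSI and YSI. `stresskit` implements that whole chain, plus a
synthetic-data module that emulates a 43-genotype, four-environment
(N1/N2 normal, SI heat, SNI combined heat-drought), two-replicate trial
so the pipeline is testable end to end without any field data.

## Worked example

```python
import pandas as pd, stresskit as sk

pairs = sk.YieldPairTable(pd.DataFrame({
    "genotype": ["FLIP-a", "FLIP-b", "FLIP-c"],
    "Yp": [100.0, 60.0, 80.0],   # g/plot, normal sowing
    "Ys": [50.0, 46.0, 48.0],    # g/plot, late (heat) sowing
}), stress="heat")
idx = sk.compute_indices(pairs)
print(f"SI = {idx.si:.3f}")
print(idx.data.round(4).to_string(index=False))
```

prints

```
SI = 0.400
genotype   Ys    Yp    STI  TOL     GMP   MP    HARM    SSI    YSI
  FLIP-a 50.0 100.0 0.7812 50.0 70.7107 75.0 66.6667 1.2500 0.5000
  FLIP-b 46.0  60.0 0.4312 14.0 52.5357 53.0 52.0755 0.5833 0.7667
  FLIP-c 48.0  80.0 0.6000 32.0 61.9677 64.0 60.0000 1.0000 0.6000
```

The episode removed 40 % of the population's mean yield (SI = 0.40).
FLIP-a loses half its own yield (YSI 0.50, SSI 1.25 — more susceptible
than average) but from a high base, so STI and GMP still rank it first;
FLIP-b is the most stable (YSI 0.77) but unproductive.

The classification chain on the simulated 43-genotype combined-stress
collection (`python examples/03_tolerance_classification.py`):

```
Cluster sizes by tolerance label:
moderately_susceptible    12
moderately_tolerant        2
susceptible                7
tolerant                  22
```

The first two PCA dimensions carry 99.35 % of the index variance — as
expected, since all nine columns are functions of the two-dimensional
(Yp, Ys) input. See `examples/` for one narrative script per
capability, and the `stresskit` CLI (`simulate | indices | corr |
classify | anova | report`) for shell use:

```sh
stresskit simulate --preset paper_heat_clusters --seed 1 -o pairs.csv
stresskit indices --pairs pairs.csv -o indices.csv
stresskit classify --indices indices.csv --k 4 -o clusters.csv --pca pca.csv
```

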