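# magflux

Genome-resolved immigration analysis for full-scale aerobic granular
sludge (AGS) wastewater treatment plants.

Continuous inoculation with sewage biomass means that detecting an
organism in a reactor says nothing about whether it actually grows
there. `magflux` separates growers from immigrants: from
metagenome-assembled-genome (MAG) relative-abundance and
relative-expression profiles of the influent, the reactor, the excess
sludge and the effluent, it computes a per-population steady-state
mass balance, classifies every MAG by growth, dominance and relative
activity, and quantifies how much of the community is sustained by
immigration rather than by growth — overall and separately for flocs
(FL), small granules (SG) and large granules (LG). It is written for
environmental-biotechnology and microbiome researchers working with
CoverM-style MAG tables from activated or granular sludge systems.

## The mass balance

At steady state, a MAG *x* with relative abundance (or relative
expression) *p* in each compartment has a population-specific solids
retention time and net growth rate

```
θ_x = p_x,AGS · M_AGS / (p_x,ES · J_ES + p_x,EF · J_EF)                    [d]
μ_x = (p_x,ES · J_ES + p_x,EF · J_EF − p_x,WW · J_WW) / (p_x,AGS · M_AGS) [1/d]
```

where `M_AGS` is the reactor biomass (kg TSS) and `J_ES`, `J_EF`,
`J_WW` the daily TSS fluxes of excess sludge, effluent and influent.
`μ_x < 0` marks populations that decay in the reactor and persist only
through immigration; the *immigration rate* is their cumulative
reactor abundance. The same balance applies per aggregate size class
using the class composition of the MLSS, the excess sludge and the
effluent. Because expression and abundance are compositional, the
RNA/DNA ratio ("relative activity") is the per-unit-biomass activity
proxy, with a data-driven cutoff (regression slope of RNA on DNA
shares through the origin) separating higher from lower relative
activity. A transparent count-based differential-expression test
(median-of-ratios normalization, pooled t on log2 normalized counts,
|log2FC| ≥ 1 and/or P < 5% tiers) classifies MAGs as active or
inactive in the reactor relative to the influent.

A forward simulator (`magflux.synthdata`) generates complete synthetic
plant datasets — guild-structured communities with known growth rates
and activity factors, triplicate sampling, multinomial read noise —
in which the steady-state identity holds exactly, so the entire
pipeline is testable against ground truth.

## Worked example

Simulate a plant and run the full analysis:

```
magflux simulate --seed 17 --depth 100000 --outdir data/
magflux all --plant data/plant.yaml --dna data/profiles_dna.tsv \
    --rna data/profiles_rna.tsv --counts data/counts_rna.tsv \
    --mags data/mags.tsv --seed 17 --outdir out/
```

which prints (abridged):

```
daily influent biomass load: 7.2% of reactor inventory (7.0% at 0.5% rounding)
whole-system growth groups (n = 3 replicates): positive 119 ± 3 (79 dominant), negative 181 ± 3 (77 dominant)
cumulative reactor share: positive 41.3 ± 0.3%, negative 28.8 ± 0.3% (immigration rate)
RNA/DNA cutoff (slope): 0.755; 191 MAGs at higher relative activity
positive group relative activity: 0.68 (27.4/40.2)
negative group relative activity: 1.09 (32.6/29.8)
growth x activity quadrants (classified n = 300): positive/active: 109, positive/inactive: 11, negative/active: 43, negative/inactive: 137
ANOSIM by sample type: R = 0.938, p = 0.0010 (999 permutations)
```

Read it as: the simulated influent delivers 7.2% of the reactor's
biomass inventory per day; 181 of 300 simulated populations decay in
the reactor yet make up 29% of its biomass — they persist purely
through immigration — and most of those decayers are
transcriptionally inactive in the reactor, while the declining group
as a whole still shows higher activity per unit biomass (1.09) than
the growing group (0.68). Output tables (`growth_whole.tsv`, `growth_by_class.tsv`,
`immigration_summary.tsv`, `relative_activity.tsv`, `de_results.tsv`,
`bray_curtis.tsv`, `pcoa_coordinates.tsv`, `dendrogram.nwk`) carry the
per-MAG detail.

The same computations are available as a library:

```python
from magflux import reference_plant, daily_load_ratio, compute_srt

plant = reference_plant()        # the full-scale plant's printed design data
daily_load_ratio(plant)          # 7.37  (% of reactor biomass per day)
compute_srt(0.01, 0.01, 0.01, plant)  # 16.30 d: system SRT when proportions cancel
```

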