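# Methods

## The steady-state mass balance

The model treats the reactor as a single well-mixed biomass inventory
`M_AGS` (kg TSS) at steady state: no net accumulation, so everything a
population gains by growth and immigration it loses with the two
wastage streams. For MAG *x*, with `p` the relative abundance (or
relative expression) in a compartment,

```
θ_x = p_x,AGS·M_AGS / (p_x,ES·J_ES + p_x,EF·J_EF)
μ_x = (p_x,ES·J_ES + p_x,EF·J_EF − p_x,WW·J_WW) / (p_x,AGS·M_AGS)
    = 1/θ_x − p_x,WW·J_WW / (p_x,AGS·M_AGS)
```

Assumptions worth keeping in mind:

- **Steady state.** Weekly triplicate sampling of a stable full-scale
  plant justifies it; transients (seasonal shifts, washout events)
  violate it and bias μ.
- **Relative abundances proxy biomass shares.** Any per-MAG factor
  shared across compartments (genome size, extraction and mapping
  efficiency) cancels because every term is linear in `p`; factors
  that *differ* between compartments do not cancel.
- **One conversion currency.** Fluxes are TSS; the model never
  converts to cell counts or absolute abundances.

The whole-reactor profile `p_AGS` is either a measured mixed sample or
reconstructed as the MLSS-weighted sum of per-class profiles
`Σ_a f_a·p_x,a`. For metatranscriptomes the reactor is sampled in an
anaerobic and an aerobic phase; per-class values are the equal-weight
mean of the two phase means before mixing.

### Per-aggregate-class balance

For size class *a* (flocs FL, small granules SG, large granules LG)
the terms become `p_x,a·f_a·M_AGS` (inventory),
`p_x,ES·g_a·J_ES + p_x,EF·h_a·J_EF` (wastage, with `g`/`h` the class
composition of excess sludge and effluent) and `p_x,WW·s_a·J_WW`
(influent). The apportionment `s_a` of incoming biomass over classes
is not observable from the data; three conventions are provided:

- `mlss` (default): `s_a = f_a` — immigrants meet reactor biomass in
  proportion to its mass;
- `all-to-FL`: all influent biomass joins the flocs, the class
  physically closest to incoming suspended solids;
- `uniform`: equal thirds.

The choice materially changes per-class immigration rates (e.g. under
`mlss`, large granules receive a full influent share but shed almost
nothing via wastage, driving most class-level μ negative), so
per-class results should always be reported with the convention used.
The whole-system balance is unaffected.

### Zero handling and flags

A MAG absent from the reactor but present in the influent is kept,
flagged `washed_out`, with θ and μ undefined — never silently
dropped. A MAG absent from the influent is flagged `resident_only`
and has μ = 1/θ > 0 by construction; immigration summaries cover only
MAGs shared between influent and reactor ("immigrants"). Empty
wastage gives the +∞ SRT sentinel.

### Defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| dominance threshold | 0.1 | % mean reactor abundance | the conventional dominant/rare split, boundary inclusive |
| MAG screen | completeness > 50, contamination < 10 | % | medium-quality draft genomes (MIMAG), strict inequalities |
| replicate spread | sample sd (n−1) | — | three weekly replicates are a sample, not a population |
| influent split | mlss | — | see above |
| effluent class composition | all FL | — | flocs escape over the effluent weir; granules settle |

## Relative activity

Relative expression over relative abundance (RNA/DNA) measures
activity per unit biomass. Ratios are computed from replicate-mean
(and phase-mean) profiles because per-replicate ratios are dominated
by count noise at low abundance; ratios built on DNA means below 1e−5
are flagged low-confidence but retained. The classification cutoff is
estimated from the data: the default `slope` method is the
least-squares slope through the origin of RNA on DNA shares
(equivalently the abundance-weighted mean ratio); `mean_ratio` is the
unweighted mean, and the two coincide exactly on any ray through the
origin. A fixed cutoff of 1 ("expression tracks abundance") is also
supported. Group-level relative activity is cumulative expression
over cumulative abundance, which equals the abundance-weighted mean
of member ratios.

Because both profiles are compositional, only *relative* activity
differences are identifiable: multiplying every activity factor by a
constant changes nothing observable, and the overall scale of the
ratio reflects the two assays' mapped-read fractions. This is why the
simulator's recovery test for the cutoff targets the RNA/DNA
mapped-fraction ratio rather than the raw activity factors.

## Differential expression

The DE step exists to give a sign (more expressed in the reactor than
the influent = active) and a significance tier (|log2FC| ≥ 1 and/or
P < 0.05) per MAG. It uses median-of-ratios size factors (geometric
mean normalized to 1), a pseudocount of 0.5 on normalized counts,
log2 fold change of group means, and by default a pooled-variance
Student t on log2 normalized counts. The pooled test was chosen over
Welch because at the n = 3 + 3 design it is calibrated (~5% type-I
error on null count data) while Welch is conservative (~4%); an exact
label-permutation option exists but is pointless at this design — the
70-odd distinct label splits bound p from below at ~0.1. Raw
p-values drive the tiers; BH q-values are emitted alongside. No
dispersion shrinkage is attempted: downstream classification consumes
only sign and tier, and both sign-only and tier-filtered quadrant
counts are reported because the activity definition is a judgement
call.

## Community statistics

Bray–Curtis dissimilarity, PCoA (Gower double-centering +
eigendecomposition, coordinates scaled by √λ), rank-based ANOSIM with
an add-one permutation p-value, and UPGMA clustering are implemented
from their definitions; the test suite cross-checks each against
scipy/scikit-bio. Negative PCoA eigenvalues are reported unchanged
(no Cailliez/Lingoes correction) and explained variance is over
positive eigenvalues only. UPGMA breaks ties toward the
lexicographically smallest cluster-label pair so merge order is
deterministic; Newick branch lengths place tips at height 0 and each
node at half its merge height, so tip-to-tip path lengths reproduce
cophenetic distances.

## The synthetic plant

The generator emulates the sampled structure of a full-scale AGS
plant — influent, a reactor fractionated into FL/SG/LG, excess
sludge, effluent; weekly triplicates; DNA and RNA tables with
unmapped-read pools (30%/40%) and multinomial or
Dirichlet-multinomial count noise — with the plant template fixed at
the full-scale design values (55,972 kg TSS; 2177/1256/4122.5 kg
TSS d⁻¹).

Construction guarantees the steady-state identity *exactly*: reactor
inventories follow `m_x = p_WW,x·J_WW/((J_ES+J_EF)/M_AGS − μ_x)`, and
J_WW is calibrated (rather than renormalizing masses) to the unique
scalar making `Σ m_x = M_AGS`. Class partitioning by per-MAG affinity
weights, rescaled to the MLSS composition, redistributes biomass, so
the stored ground-truth μ/θ are recomputed from the final compartment
profiles — still exact, but shifted from the drawn guild targets
(floc-affine MAGs lose more via the floc-rich wastage streams). Guild
defaults (sewage-derived fermenters decaying at −0.30 to −0.01 d⁻¹
and dominating the influent; PAOs/GAOs growing at up to 0.055 d⁻¹,
just under the washout bound (J_ES+J_EF)/M_AGS ≈ 0.061 d⁻¹;
slow-growing nitrifiers; activity factors centred at 2.1 for the
decayers and 0.78 for the growers) mirror the guild structure of
municipal AGS plants; the names are labels on parameter ranges, no
metabolism is simulated.

What passing recovery tests shows — and what it does not: the
pipeline inverts the generative model exactly (machine precision on
noise-free data, through the TSV round trip) and is robust to
multinomial sampling at 10⁶ reads (≥95%, in practice ~100%, correct
growth signs at |μ| ≥ 0.05 d⁻¹ over 3 replicates × 5 plants). Real
data additionally violate steady state, have compartment-dependent
extraction biases and non-multinomial overdispersion; the
Dirichlet-multinomial noise model probes the latter but the recovery
guarantees do not extend to the former.

## Numerical choices

- Internal unit is the fraction [0, 1]; files are percent. Fraction
  maps must sum to 1 within 1e−9.
- μ and θ are exact ratios of sums — no optimization, no iteration;
  degenerate denominators yield sentinels (∞, NaN) rather than
  exceptions once a record exists.
- Permutation p-values use the add-one convention; exact enumeration
  replaces sampling when the label-split count is ≤ 20,000.
- Problem sizes in tests and the acceptance script (300 MAGs, 3
  replicates, depth 10⁶, 5 seeds; 1000 null MAGs for DE calibration;
  ≤ 10 samples for ordination oracles) were chosen as the smallest
  sizes at which the statistical claims are sharp.

## Known limitations

- No absolute abundances: everything is per unit TSS, and TSS-to-cell
  conversion is out of scope.
- The influent-apportionment convention for per-class balances is a
  modelling choice, not an inference; report it with results.
- The DE stand-in does not shrink dispersions; at very low counts its
  fold changes are pseudocount-dominated.
- Immigration summaries treat replicate weeks as exchangeable; slow
  trends across weeks inflate the reported sd.
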