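"""Relative activity (RNA/DNA) of MAGs and growth × activity classes.

A MAG's relative expression measures its share of community activity;
its relative abundance measures its share of community biomass.  Their
ratio — the relative activity — is activity per unit biomass, so a
declining (negative net growth) population can still be among the most
active per cell.  The classification threshold between "higher" and
"lower" relative activity is estimated from the data, either as the
slope through the origin of RNA vs DNA shares across MAGs or as the
mean per-MAG ratio; both equal 1 when expression simply tracks
abundance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iodata import ProfileMatrix, ProfileError

__all__ = [
    "relative_activity",
    "estimate_cutoff",
    "classify_relative_activity",
    "group_activity_ratio",
    "cumulative_activity_ratio",
    "classify_quadrants",
    "LOW_CONFIDENCE_FLOOR",
]

#: DNA mean fractions below this are flagged low-confidence: at such
#: abundances read-count noise dominates the ratio.
LOW_CONFIDENCE_FLOOR = 1e-5

_CUTOFF_METHODS = ("slope", "mean_ratio")


def _scope_means(profiles: ProfileMatrix, scope: str) -> pd.Series:
    sub = profiles.select(compartment=scope)
    if sub.shape[1] == 0:
        raise ProfileError(f"no {scope!r} columns in profile table")
    return sub.mean(axis=1)


def relative_activity(
    dna: ProfileMatrix,
    rna: ProfileMatrix,
    scope: str = "AGS",
    low_conf_floor: float = LOW_CONFIDENCE_FLOOR,
) -> pd.DataFrame:
    """Per-MAG RNA/DNA ratio from replicate-mean profiles in one
    compartment.

    Returns a frame indexed by MAG id with the mean DNA and RNA
    fractions, the ratio (NaN where the DNA mean is zero), and a
    low-confidence flag for ratios built on DNA means below
    ``low_conf_floor``.  Ratios use means across replicates (and phases)
    rather than per-replicate ratios, which are unstable at low
    abundance.
    """
    common = dna.mag_ids.intersection(rna.mag_ids)
    if len(common) == 0:
        raise ProfileError("DNA and RNA tables share no MAG ids")
    d = _scope_means(dna, scope).loc[common]
    r = _scope_means(rna, scope).loc[common]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d > 0, r / d, np.nan)
    return pd.DataFrame(
        {
            "dna_mean": d,
            "rna_mean": r,
            "rna_dna_ratio": ratio,
            "low_confidence": d < low_conf_floor,
        },
        index=common,
    )


def estimate_cutoff(
    dna: ProfileMatrix,
    rna: ProfileMatrix,
    method: str = "slope",
    scope: str = "AGS",
) -> float:
    """Data-driven relative-activity threshold.

    ``slope``: least-squares slope through the origin of RNA vs DNA
    across MAGs, Σ(d·r)/Σd² — an abundance-weighted mean ratio.
    ``mean_ratio``: unweighted arithmetic mean of per-MAG ratios.
    The two agree exactly when all MAGs lie on a line through the
    origin.  A fixed cutoff of 1 is the "expression tracks abundance"
    alternative.
    """
    if method not in _CUTOFF_METHODS:
        raise ValueError(f"method must be one of {_CUTOFF_METHODS}")
    table = relative_activity(dna, rna, scope=scope)
    d = table["dna_mean"].to_numpy()
    r = table["rna_mean"].to_numpy()
    pos = d > 0
    if pos.sum() == 0:
        raise ProfileError("cannot estimate a cutoff: all DNA means are zero")
    if method == "slope":
        return float((d[pos] * r[pos]).sum() / (d[pos] ** 2).sum())
    return float((r[pos] / d[pos]).mean())


def classify_relative_activity(
    ratios: pd.DataFrame | pd.Series, cutoff: float
) -> pd.Series:
    """``higher`` iff RNA/DNA ≥ cutoff, ``lower`` otherwise; MAGs with an
    undefined ratio are excluded."""
    r = ratios["rna_dna_ratio"] if isinstance(ratios, pd.DataFrame) else ratios
    defined = r.dropna()
    return pd.Series(
        np.where(defined >= cutoff, "higher", "lower"), index=defined.index
    )


def cumulative_activity_ratio(
    cumulative_expression_pct: float, cumulative_abundance_pct: float
) -> float:
    """Group-level relative activity: the group's cumulative relative
    expression over its cumulative relative abundance (both percent).

    Equals the abundance-weighted mean of the member RNA/DNA ratios.
    """
    if cumulative_abundance_pct <= 0:
        raise ValueError("cumulative abundance must be positive")
    return cumulative_expression_pct / cumulative_abundance_pct


def group_activity_ratio(
    records: pd.DataFrame,
    dna: ProfileMatrix,
    rna: ProfileMatrix,
    scope: str = "AGS",
) -> pd.DataFrame:
    """Cumulative RNA and DNA reactor shares and their ratio per growth
    group (positive / negative net growth).

    Group membership is by the sign of each MAG's replicate-mean μ from
    the whole-system records.
    """
    whole = records[records["scope"] == "whole"]
    mean_mu = whole.groupby("mag_id")["mu_per_day"].mean()
    act = relative_activity(dna, rna, scope=scope)
    rows = []
    for group, sign in (("positive", 1), ("negative", -1)):
        ids = mean_mu.index[np.sign(mean_mu) == sign]
        ids = act.index.intersection(ids)
        cum_dna = 100.0 * float(act.loc[ids, "dna_mean"].sum())
        cum_rna = 100.0 * float(act.loc[ids, "rna_mean"].sum())
        rows.append(
            {
                "group": group,
                "n_mags": len(ids),
                "cumulative_dna_pct": cum_dna,
                "cumulative_rna_pct": cum_rna,
                "relative_activity": (
                    cumulative_activity_ratio(cum_rna, cum_dna) if cum_dna > 0 else np.nan
                ),
            }
        )
    return pd.DataFrame(rows).set_index("group")


@dataclass
class QuadrantCounts:
    """2×2 growth × activity classification with significance tiers."""

    table: pd.DataFrame  # index (growth, activity), columns tiers + total

    @property
    def n_classified(self) -> int:
        return int(self.table["total"].sum())


_TIERS = ("NS", "fc_only", "p_only", "both")


def classify_quadrants(
    growth: pd.DataFrame,
    de: pd.DataFrame,
    mag_ids: set[str] | None = None,
) -> QuadrantCounts:
    """Count MAGs per growth class (positive/negative net growth) ×
    activity class (active iff expressed more in the reactor than in the
    influent, i.e. log2FC > 0), split by significance tier.

    ``mag_ids`` optionally restricts the classification, e.g. to MAGs
    passing the completeness/contamination screen.
    """
    whole = growth[growth["scope"] == "whole"]
    mean_mu = whole.groupby("mag_id")["mu_per_day"].mean().dropna()
    de_idx = de.set_index("mag_id") if "mag_id" in de.columns else de
    ids = mean_mu.index.intersection(de_idx.index)
    if mag_ids is not None:
        ids = ids.intersection(pd.Index(sorted(mag_ids)))
    counts = pd.DataFrame(
        0,
        index=pd.MultiIndex.from_product(
            [("positive", "negative"), ("active", "inactive")],
            names=["growth_class", "activity_class"],
        ),
        columns=list(_TIERS),
    )
    for mag in ids:
        mu = mean_mu[mag]
        if mu == 0:
            continue
        g = "positive" if mu > 0 else "negative"
        lfc = float(de_idx.loc[mag, "log2fc"])
        a = "active" if lfc > 0 else "inactive"
        counts.loc[(g, a), str(de_idx.loc[mag, "tier"])] += 1
    counts["total"] = counts[list(_TIERS)].sum(axis=1)
    return QuadrantCounts(counts)
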