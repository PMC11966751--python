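"""Per-MAG steady-state mass balance: SRT and net growth rate.

At steady state the reactor inventory of every population is constant,
so whatever a MAG gains by growth and immigration it loses with the
excess sludge and the effluent.  For MAG *x* with relative abundance
(or relative expression) ``p`` in each compartment:

    θ_x = p_AGS · M_AGS / (p_ES · J_ES + p_EF · J_EF)            [d]
    μ_x = (p_ES · J_ES + p_EF · J_EF − p_WW · J_WW) / (p_AGS · M_AGS)

θ_x is the population-specific solids retention time (biomass in the
system over biomass leaving per day) and μ_x the net growth rate.
μ_x < 0 identifies populations that decay in the reactor and persist
only through continuous immigration with the influent; μ_x > 0
identifies populations that grow in the reactor.  Because relative
abundances enter every term linearly, any per-MAG scale factor (e.g.
genome size or mapping efficiency, as long as it is shared across
compartments) cancels.

The same balance applies separately to each aggregate size class
(flocs, small granules, large granules) with the class share of the
reactor inventory, of the wastage streams and of the influent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .iodata import (
    ConfigError,
    PlantParameters,
    ProfileMatrix,
    SIZE_CLASSES,
)

__all__ = [
    "MassBalanceError",
    "compute_srt",
    "compute_net_growth",
    "run_mass_balance",
    "run_mass_balance_by_class",
    "classify_dominance",
    "summarize_immigration",
    "daily_load_ratio",
    "ImmigrationSummary",
    "DOMINANCE_THRESHOLD",
    "INFLUENT_SPLITS",
]

#: Mean reactor relative abundance at or above which a MAG counts as
#: dominant (0.1% of total reads); below it the MAG is rare.
DOMINANCE_THRESHOLD = 0.001

#: How the influent biomass flux is apportioned over size classes in the
#: per-class balance: proportional to the MLSS composition (immigrants
#: meet reactor biomass in proportion to its mass), all to the flocs, or
#: uniformly.
INFLUENT_SPLITS = ("mlss", "all-to-FL", "uniform")


class MassBalanceError(ValueError):
    """Invalid input to a mass-balance computation."""


# --------------------------------------------------------------------------
# scalar balances
# --------------------------------------------------------------------------


def compute_srt(p_ags: float, p_es: float, p_ef: float, plant: PlantParameters) -> float:
    """Population SRT in days; ``inf`` when nothing leaves the system."""
    if not p_ags > 0:
        raise MassBalanceError("p_ags must be positive to define an SRT")
    if p_es < 0 or p_ef < 0:
        raise MassBalanceError("compartment fractions must be non-negative")
    out = p_es * plant.j_es + p_ef * plant.j_ef
    if out == 0:
        return math.inf
    return p_ags * plant.m_ags / out


def compute_net_growth(
    p_ags: float, p_es: float, p_ef: float, p_ww: float, plant: PlantParameters
) -> float:
    """Net growth rate μ in d⁻¹ (equivalently 1/θ − immigration term)."""
    if not p_ags > 0:
        raise MassBalanceError("p_ags must be positive to define a growth rate")
    if min(p_es, p_ef, p_ww) < 0:
        raise MassBalanceError("compartment fractions must be non-negative")
    leaving = p_es * plant.j_es + p_ef * plant.j_ef
    entering = p_ww * plant.j_ww
    return (leaving - entering) / (p_ags * plant.m_ags)


def daily_load_ratio(plant: PlantParameters) -> float:
    """Daily influent biomass load as percent of the reactor inventory,
    100·J_WW/M_AGS."""
    return 100.0 * plant.j_ww / plant.m_ags


# --------------------------------------------------------------------------
# compartment vectors
# --------------------------------------------------------------------------


def _single_column(
    profiles: ProfileMatrix, compartment: str, replicate: int
) -> pd.Series:
    sub = profiles.select(compartment=compartment, replicate=replicate)
    if sub.shape[1] == 0:
        raise ConfigError(
            f"no {compartment} column for replicate {replicate}"
        )
    # ES may be reported whole ('none'/'mixed'); average duplicates.
    return sub.mean(axis=1)


def _ags_class_vector(
    profiles: ProfileMatrix, cls: str, replicate: int
) -> pd.Series:
    """Reactor profile of one size class, averaged over redox phases.

    Metatranscriptomic reactor samples come in an anaerobic and an
    aerobic version; the balance uses their per-phase means averaged
    with equal weight.
    """
    sub = profiles.select(
        compartment="AGS", aggregate_class=cls, replicate=replicate
    )
    if sub.shape[1] == 0:
        raise ConfigError(f"no AGS.{cls} column for replicate {replicate}")
    phases = {k.phase for k in sub.columns}
    if phases == {"none"} or len(sub.columns) == 1:
        return sub.mean(axis=1)
    per_phase = [
        profiles.select(
            compartment="AGS", aggregate_class=cls, phase=ph, replicate=replicate
        ).mean(axis=1)
        for ph in sorted(phases)
    ]
    return sum(per_phase) / len(per_phase)


def ags_mixed_vector(
    profiles: ProfileMatrix, replicate: int, plant: PlantParameters | None
) -> pd.Series:
    """Whole-reactor profile: the ``mixed`` column if present, otherwise
    the MLSS-weighted sum of the per-class profiles Σ_a f_a·p_x,a."""
    mixed = profiles.select(compartment="AGS", aggregate_class="mixed", replicate=replicate)
    if mixed.shape[1] > 0:
        return _ags_class_vector(profiles, "mixed", replicate)
    if plant is None:
        raise ConfigError(
            "per-class AGS profiles require plant MLSS fractions to "
            "reconstruct the whole-reactor profile"
        )
    f = plant.mlss_fractions
    parts = [f[cls] * _ags_class_vector(profiles, cls, replicate) for cls in SIZE_CLASSES]
    return sum(parts)


# --------------------------------------------------------------------------
# table-level balances
# --------------------------------------------------------------------------


def _growth_class(mu: float) -> str:
    if math.isnan(mu):
        return "undefined"
    if mu > 0:
        return "positive"
    if mu < 0:
        return "negative"
    return "zero"


def _balance_rows(
    mag_ids: pd.Index,
    replicate: int,
    scope: str,
    biomass: pd.Series,
    leaving: pd.Series,
    entering: pd.Series,
    m_scale: float,
) -> list[dict]:
    """Rows of the growth-record table for one replicate and scope.

    ``biomass`` is p_AGS·(scope biomass, kg); ``leaving``/``entering``
    are kg d⁻¹ per MAG.  MAGs absent from the reactor are kept with an
    undefined class (flag ``washed_out`` when present in the influent);
    MAGs absent from the influent are flagged ``resident_only``.
    """
    rows = []
    for mag in mag_ids:
        b = float(biomass[mag])
        out_flux = float(leaving[mag])
        in_flux = float(entering[mag])
        flags = []
        if b > 0:
            theta = b / out_flux if out_flux > 0 else math.inf
            mu = (out_flux - in_flux) / b
            if in_flux == 0:
                flags.append("resident_only")
        else:
            theta = math.nan
            mu = math.nan
            if in_flux > 0:
                flags.append("washed_out")
        rows.append(
            {
                "mag_id": mag,
                "replicate": replicate,
                "scope": scope,
                "theta_days": theta,
                "mu_per_day": mu,
                "growth_class": _growth_class(mu),
                "flags": ",".join(flags),
                "p_ags": b / m_scale,
                "p_ww": in_flux,  # rescaled by caller
            }
        )
    return rows


def _finalize(rows: list[dict], j_ww_scope: pd.Series | float, dominance: pd.Series) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    df["p_ww"] = df["p_ww"] / j_ww_scope
    df["dominance"] = df["mag_id"].map(dominance)
    cols = [
        "mag_id",
        "replicate",
        "scope",
        "theta_days",
        "mu_per_day",
        "growth_class",
        "dominance",
        "flags",
        "p_ags",
        "p_ww",
    ]
    return df[cols]


def run_mass_balance(
    profiles: ProfileMatrix,
    plant: PlantParameters,
    kind: str | None = None,
) -> pd.DataFrame:
    """Whole-system growth records, one row per MAG and replicate.

    Requires influent, effluent and excess-sludge columns plus either a
    mixed reactor column or all three per-class reactor columns for each
    replicate.  Returns a table with θ (days), μ (d⁻¹), growth class,
    dominance, flags, and the reactor/influent fractions used.
    """
    if kind is not None and kind != profiles.kind:
        raise ConfigError(
            f"profile kind mismatch: table is {profiles.kind!r}, requested {kind!r}"
        )
    reps = profiles.replicates("influent")
    if not reps:
        raise ConfigError("no influent columns in profile table")
    dominance = classify_dominance(profiles, plant=plant)
    rows: list[dict] = []
    for rep in reps:
        p_ww = _single_column(profiles, "influent", rep)
        p_es = _single_column(profiles, "excess_sludge", rep)
        p_ef = _single_column(profiles, "effluent", rep)
        p_ags = ags_mixed_vector(profiles, rep, plant)
        biomass = p_ags * plant.m_ags
        leaving = p_es * plant.j_es + p_ef * plant.j_ef
        entering = p_ww * plant.j_ww
        rows.extend(
            _balance_rows(profiles.mag_ids, rep, "whole", biomass, leaving, entering, plant.m_ags)
        )
    return _finalize(rows, plant.j_ww, dominance)


def run_mass_balance_by_class(
    profiles: ProfileMatrix,
    plant: PlantParameters,
    kind: str | None = None,
    influent_split: str = "mlss",
) -> pd.DataFrame:
    """Per-size-class growth records (scopes FL, SG, LG).

    For class *a* the biomass term is p_x,a·f_a·M_AGS, the wastage term
    p_x,ES·g_a·J_ES + p_x,EF·h_a·J_EF with g/h the class composition of
    the excess sludge and effluent, and the influent term
    p_x,WW·s_a·J_WW with s_a set by ``influent_split``.
    """
    if kind is not None and kind != profiles.kind:
        raise ConfigError(
            f"profile kind mismatch: table is {profiles.kind!r}, requested {kind!r}"
        )
    if influent_split not in INFLUENT_SPLITS:
        raise ConfigError(
            f"influent_split must be one of {INFLUENT_SPLITS}, got {influent_split!r}"
        )
    if influent_split == "mlss":
        s = dict(plant.mlss_fractions)
    elif influent_split == "all-to-FL":
        s = {"FL": 1.0, "SG": 0.0, "LG": 0.0}
    else:
        s = {cls: 1.0 / 3.0 for cls in SIZE_CLASSES}

    reps = profiles.replicates("influent")
    if not reps:
        raise ConfigError("no influent columns in profile table")
    dominance = classify_dominance(profiles, plant=plant)
    rows: list[dict] = []
    for rep in reps:
        p_ww = _single_column(profiles, "influent", rep)
        p_es = _single_column(profiles, "excess_sludge", rep)
        p_ef = _single_column(profiles, "effluent", rep)
        for cls in SIZE_CLASSES:
            p_cls = _ags_class_vector(profiles, cls, rep)
            f_a = plant.mlss_fractions[cls]
            biomass = p_cls * f_a * plant.m_ags
            leaving = (
                p_es * plant.es_fractions[cls] * plant.j_es
                + p_ef * plant.ef_fractions[cls] * plant.j_ef
            )
            entering = p_ww * s[cls] * plant.j_ww
            m_scale = f_a * plant.m_ags if f_a > 0 else plant.m_ags
            rows.extend(
                _balance_rows(profiles.mag_ids, rep, cls, biomass, leaving, entering, m_scale)
            )
    j_scope = pd.Series(
        [s[r["scope"]] * plant.j_ww if s[r["scope"]] > 0 else plant.j_ww for r in rows]
    )
    df = _finalize(rows, j_scope.to_numpy(), dominance)
    return df


def classify_dominance(
    profiles: ProfileMatrix,
    threshold: float = DOMINANCE_THRESHOLD,
    plant: PlantParameters | None = None,
) -> pd.Series:
    """Label each MAG dominant (mean whole-reactor abundance ≥ threshold,
    boundary inclusive) or rare.

    The whole-reactor profile is the mixed column when present, else the
    MLSS-weighted class sum (``plant`` required in that case).
    """
    if not 0 < threshold < 1:
        raise ConfigError("dominance threshold must lie in (0, 1)")
    reps = profiles.replicates("AGS")
    if not reps:
        raise ConfigError("no AGS columns in profile table")
    means = sum(ags_mixed_vector(profiles, rep, plant) for rep in reps) / len(reps)
    return pd.Series(
        np.where(means >= threshold, "dominant", "rare"), index=profiles.mag_ids
    )


# --------------------------------------------------------------------------
# immigration summaries
# --------------------------------------------------------------------------


@dataclass
class ImmigrationSummary:
    """Replicate-level summary of growth groups in one scope.

    ``table`` is indexed by growth group (positive/negative) with
    mean ± sd (sample sd, n−1) of the species counts — split into
    dominant and rare — and of the cumulative relative abundance (or
    expression) of the group in the reactor and in the influent, in
    percent.  ``immigration_rate_pct`` is the negative group's
    cumulative reactor share: the fraction of the community sustained
    by immigration rather than growth.
    """

    scope: str
    kind: str
    n_replicates: int
    table: pd.DataFrame
    immigration_rate_pct: float
    immigration_rate_sd_pct: float


def _nan_sd(values: list[float]) -> float:
    if len(values) < 2:
        return float("nan")
    return float(np.std(values, ddof=1))


def summarize_immigration(
    records: pd.DataFrame, kind: str = "metagenomics"
) -> dict[str, ImmigrationSummary]:
    """Summaries per scope from a growth-record table.

    Only immigrants — MAGs shared between influent and reactor — enter
    the summary: resident-only and washed-out MAGs are excluded.
    """
    out: dict[str, ImmigrationSummary] = {}
    for scope, scoped in records.groupby("scope", sort=False):
        immigrants = scoped[
            (scoped["p_ags"] > 0) & (scoped["p_ww"] > 0)
        ]
        reps = sorted(immigrants["replicate"].unique())
        stats: dict[str, dict[str, list[float]]] = {
            g: {
                "n": [],
                "n_dominant": [],
                "n_rare": [],
                "ags_pct": [],
                "influent_pct": [],
            }
            for g in ("positive", "negative")
        }
        for rep in reps:
            sub = immigrants[immigrants["replicate"] == rep]
            for group in ("positive", "negative"):
                grp = sub[sub["growth_class"] == group]
                stats[group]["n"].append(float(len(grp)))
                stats[group]["n_dominant"].append(
                    float((grp["dominance"] == "dominant").sum())
                )
                stats[group]["n_rare"].append(float((grp["dominance"] == "rare").sum()))
                stats[group]["ags_pct"].append(100.0 * float(grp["p_ags"].sum()))
                stats[group]["influent_pct"].append(100.0 * float(grp["p_ww"].sum()))
        rows = {}
        for group, vals in stats.items():
            rows[group] = {
                "n_mean": float(np.mean(vals["n"])) if reps else 0.0,
                "n_sd": _nan_sd(vals["n"]),
                "n_dominant_mean": float(np.mean(vals["n_dominant"])) if reps else 0.0,
                "n_dominant_sd": _nan_sd(vals["n_dominant"]),
                "n_rare_mean": float(np.mean(vals["n_rare"])) if reps else 0.0,
                "n_rare_sd": _nan_sd(vals["n_rare"]),
                "ags_pct_mean": float(np.mean(vals["ags_pct"])) if reps else 0.0,
                "ags_pct_sd": _nan_sd(vals["ags_pct"]),
                "influent_pct_mean": float(np.mean(vals["influent_pct"])) if reps else 0.0,
                "influent_pct_sd": _nan_sd(vals["influent_pct"]),
            }
        table = pd.DataFrame(rows).T
        out[scope] = ImmigrationSummary(
            scope=scope,
            kind=kind,
            n_replicates=len(reps),
            table=table,
            immigration_rate_pct=float(table.loc["negative", "ags_pct_mean"]),
            immigration_rate_sd_pct=float(table.loc["negative", "ags_pct_sd"]),
        )
    return out


def growth_records_to_tsv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, lineterminator="\n")
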