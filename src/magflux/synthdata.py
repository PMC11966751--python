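"""Forward simulator of a steady-state AGS plant community.

The generator draws an influent community and per-MAG net growth
rates, then solves the steady-state mass balance *exactly* so that the
emitted compartment profiles satisfy

    p_ES·J_ES + p_EF·J_EF − p_WW·J_WW = μ_x · p_AGS · M_AGS

for every MAG.  This makes parameter recovery a sharp test: running
the mass balance on noise-free emitted tables must return the stored
ground truth to machine precision, and any discrepancy is a defect in
the pipeline, not in the data.

Construction
------------
Each MAG's reactor inventory follows from its influent loading and
growth rate, m_x = p_WW,x·J_WW / ((J_ES+J_EF)/M_AGS − μ_x); the
influent flux J_WW is then calibrated by the unique scalar that makes
Σ m_x = M_AGS, so reactor fractions are consistent with the plant
inventory without breaking the balance.  Inventories are partitioned
over flocs / small granules / large granules by per-MAG affinity
weights and rescaled so class totals match the plant's MLSS
composition; the excess-sludge and effluent profiles are the
class-composition-weighted mixtures.  Because the class partition
redistributes biomass, each MAG's *stored* μ and θ are recomputed from
the final compartment profiles — they remain exact by construction but
can differ from the guild's drawn target rate.

Expression tables scale each MAG's abundance by an activity factor α
(RNA/DNA ratio at equal mapped depth) and renormalize per sample;
reactor expression is emitted for an aerobic and an anaerobic phase
(identical by default).  An explicit "unmapped" read pool keeps column
sums below 100% as in real profiles (30% of DNA and 40% of RNA reads
unmapped by default).  Count noise is multinomial or
Dirichlet-multinomial at a configurable depth.

Default community
-----------------
Three hundred MAGs in four guilds chosen to mirror a municipal AGS
plant: sewage-derived fermenters and sulfate reducers (decaying in the
reactor, abundant in the influent, floc-associated, high relative
activity), PAOs and GAOs (growing, granule-associated), and nitrifiers
(slow-growing, large-granule-associated).  Guild names are labels for
realistic parameter combinations; no metabolism is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .iodata import (
    ConfigError,
    PlantParameters,
    ProfileMatrix,
    SampleKey,
    SIZE_CLASSES,
    reference_plant,
    write_plant_config,
    write_profile_table,
)

__all__ = [
    "GuildSpec",
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "default_config",
    "three_guild_config",
    "generate_truth",
    "emit_profiles",
    "write_dataset",
]

NOISE_MODELS = ("none", "multinomial", "dirichlet_multinomial")


@dataclass(frozen=True)
class GuildSpec:
    """Parameter ranges for one functional guild.

    ``mu_range`` bounds the drawn net growth rates (d⁻¹, uniform);
    ``alpha_log_mean``/``alpha_log_sd`` parameterize the lognormal
    activity factor; ``influent_share`` is the guild's share of the
    influent community (shares are normalized across guilds);
    ``influent_log_sd`` spreads member abundances lognormally within
    the guild; ``affinity`` gives mean FL/SG/LG partitioning weights,
    jittered per MAG by a Dirichlet draw with ``affinity_concentration``.
    """

    name: str
    n: int
    mu_range: tuple[float, float]
    influent_share: float
    affinity: Mapping[str, float]
    alpha_log_mean: float = 0.0
    alpha_log_sd: float = 0.25
    influent_log_sd: float = 1.0
    affinity_concentration: float = 50.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"guild {self.name}: n must be >= 1")
        if self.mu_range[0] > self.mu_range[1]:
            raise ConfigError(f"guild {self.name}: empty mu range")
        if self.influent_share <= 0:
            raise ConfigError(f"guild {self.name}: influent share must be positive")
        if any(v < 0 for v in self.affinity.values()) or sum(self.affinity.values()) <= 0:
            raise ConfigError(f"guild {self.name}: invalid affinity weights")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full specification of a synthetic plant dataset."""

    guilds: tuple[GuildSpec, ...]
    plant: PlantParameters = field(default_factory=reference_plant)
    n_replicates: int = 3
    depth: int = 1_000_000
    noise: str = "multinomial"
    overdispersion: float = 200.0
    unmapped_dna: float = 0.30
    unmapped_rna: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in NOISE_MODELS:
            raise ConfigError(f"noise must be one of {NOISE_MODELS}")
        bound = self.plant.washout_rate
        for g in self.guilds:
            if g.mu_range[1] >= bound:
                raise ConfigError(
                    f"guild {g.name}: mu upper bound {g.mu_range[1]:.4g} reaches the "
                    f"washout bound (J_ES+J_EF)/M_AGS = {bound:.4g} d^-1"
                )
        if not 0 <= self.unmapped_dna < 1 or not 0 <= self.unmapped_rna < 1:
            raise ConfigError("unmapped fractions must lie in [0, 1)")
        if self.n_replicates < 1 or self.depth < 1:
            raise ConfigError("n_replicates and depth must be positive")

    @property
    def n_mags(self) -> int:
        return sum(g.n for g in self.guilds)


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The standard 300-MAG, four-guild plant community."""
    guilds = (
        GuildSpec(
            name="fermenter",
            n=150,
            mu_range=(-0.30, -0.01),
            influent_share=0.70,
            affinity={"FL": 0.6, "SG": 0.3, "LG": 0.1},
            alpha_log_mean=float(np.log(2.1)),
            alpha_log_sd=0.3,
        ),
        GuildSpec(
            name="PAO",
            n=60,
            mu_range=(0.005, 0.055),
            influent_share=0.05,
            affinity={"FL": 0.15, "SG": 0.5, "LG": 0.35},
            alpha_log_mean=float(np.log(0.78)),
            alpha_log_sd=0.3,
        ),
        GuildSpec(
            name="GAO",
            n=60,
            mu_range=(0.005, 0.055),
            influent_share=0.15,
            affinity={"FL": 0.2, "SG": 0.5, "LG": 0.3},
            alpha_log_mean=float(np.log(0.78)),
            alpha_log_sd=0.3,
        ),
        GuildSpec(
            name="nitrifier",
            n=30,
            mu_range=(0.001, 0.03),
            influent_share=0.10,
            affinity={"FL": 0.1, "SG": 0.4, "LG": 0.5},
            alpha_log_mean=0.0,
            alpha_log_sd=0.25,
        ),
    )
    return SyntheticConfig(guilds=guilds, seed=seed, **overrides)


def three_guild_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A 300-MAG, three-guild plant: sewage-derived decayers, growing
    heterotrophs (PAO/GAO-like) and nitrifiers.  Used for parameter-
    recovery exercises; defaults to noise-free emission."""
    guilds = (
        GuildSpec(
            name="fermenter",
            n=150,
            mu_range=(-0.30, -0.01),
            influent_share=0.70,
            affinity={"FL": 0.6, "SG": 0.3, "LG": 0.1},
            alpha_log_mean=float(np.log(2.1)),
        ),
        GuildSpec(
            name="heterotroph",
            n=100,
            mu_range=(0.005, 0.055),
            influent_share=0.20,
            affinity={"FL": 0.2, "SG": 0.5, "LG": 0.3},
            alpha_log_mean=float(np.log(0.78)),
        ),
        GuildSpec(
            name="nitrifier",
            n=50,
            mu_range=(0.001, 0.03),
            influent_share=0.10,
            affinity={"FL": 0.1, "SG": 0.4, "LG": 0.5},
        ),
    )
    overrides.setdefault("noise", "none")
    return SyntheticConfig(guilds=guilds, seed=seed, **overrides)


@dataclass
class SyntheticTruth:
    """Ground truth behind one synthetic dataset.

    ``table`` is indexed by MAG id with the guild, influent fraction
    (of mapped reads), activity factor α, per-class reactor fractions,
    derived compartment fractions, and the exact whole-system μ (d⁻¹)
    and θ (days).  ``plant`` carries the calibrated J_WW.
    """

    table: pd.DataFrame
    plant: PlantParameters
    seed: int


def _mag_ids(cfg: SyntheticConfig) -> list[str]:
    ids = []
    for g in cfg.guilds:
        ids.extend(f"MAG_{g.name}_{i:03d}" for i in range(1, g.n + 1))
    return ids


def generate_truth(cfg: SyntheticConfig) -> SyntheticTruth:
    """Draw a community and solve the steady-state plant exactly."""
    rng = np.random.default_rng(cfg.seed)
    plant = cfg.plant
    r = plant.washout_rate

    guild_names, mu, alpha, w, aff = [], [], [], [], []
    for g in cfg.guilds:
        guild_names.extend([g.name] * g.n)
        mu.append(rng.uniform(g.mu_range[0], g.mu_range[1], g.n))
        alpha.append(rng.lognormal(g.alpha_log_mean, g.alpha_log_sd, g.n))
        raw = rng.lognormal(0.0, g.influent_log_sd, g.n)
        w.append(g.influent_share * raw / raw.sum())
        base = np.array([g.affinity.get(c, 0.0) for c in SIZE_CLASSES], dtype=float)
        base = base / base.sum()
        if np.isfinite(g.affinity_concentration):
            aff.append(rng.dirichlet(g.affinity_concentration * base, g.n))
        else:  # infinite concentration: every member at the guild mean
            aff.append(np.tile(base, (g.n, 1)))
    mu = np.concatenate(mu)
    alpha = np.concatenate(alpha)
    w = np.concatenate(w)
    w = w / w.sum()  # influent fractions of mapped reads
    aff = np.vstack(aff)

    # reactor inventory per unit influent flux, then calibrate J_WW
    inv_per_flux = w / (r - mu)  # kg per (kg/d): all mu < r by config
    j_ww = plant.m_ags / inv_per_flux.sum()
    plant = plant.with_j_ww(j_ww)
    m = inv_per_flux * j_ww  # per-MAG reactor biomass, sums to M_AGS

    # partition over size classes by affinity, rescale to MLSS composition
    m_cls = m[:, None] * aff
    totals = m_cls.sum(axis=0)
    if np.any(totals <= 0):
        raise ConfigError("a size class received no biomass; adjust affinities")
    f = np.array([plant.mlss_fractions[c] for c in SIZE_CLASSES])
    m_cls = m_cls * (f * plant.m_ags / totals)
    p_cls = m_cls / (f * plant.m_ags)  # class profiles, columns sum to 1

    p_ags = m_cls.sum(axis=1) / plant.m_ags
    g_frac = np.array([plant.es_fractions[c] for c in SIZE_CLASSES])
    h_frac = np.array([plant.ef_fractions[c] for c in SIZE_CLASSES])
    p_es = p_cls @ g_frac
    p_ef = p_cls @ h_frac

    leaving = p_es * plant.j_es + p_ef * plant.j_ef
    mu_true = (leaving - w * plant.j_ww) / (p_ags * plant.m_ags)
    with np.errstate(divide="ignore"):
        theta_true = np.where(leaving > 0, p_ags * plant.m_ags / leaving, np.inf)

    table = pd.DataFrame(
        {
            "guild": guild_names,
            "mu_target": mu,
            "mu_true": mu_true,
            "theta_true": theta_true,
            "alpha": alpha,
            "influent_fraction": w,
            "p_ags": p_ags,
            "p_es": p_es,
            "p_ef": p_ef,
            **{f"p_{c}": p_cls[:, i] for i, c in enumerate(SIZE_CLASSES)},
        },
        index=pd.Index(_mag_ids(cfg), name="mag_id"),
    )
    return SyntheticTruth(table=table, plant=plant, seed=cfg.seed)


@dataclass
class SyntheticDataset:
    """Every table the pipeline consumes, for one simulated plant."""

    dna: ProfileMatrix
    rna: ProfileMatrix
    dna_counts: pd.DataFrame
    rna_counts: pd.DataFrame
    mag_metadata: pd.DataFrame
    truth: SyntheticTruth
    config: SyntheticConfig


def _sample_keys(cfg: SyntheticConfig, kind: str) -> list[SampleKey]:
    keys = []
    for rep in range(1, cfg.n_replicates + 1):
        keys.append(SampleKey("influent", replicate=rep))
        keys.append(SampleKey("excess_sludge", replicate=rep))
        keys.append(SampleKey("effluent", replicate=rep))
        for cls in SIZE_CLASSES:
            if kind == "metatranscriptomics":
                keys.append(SampleKey("AGS", cls, "aerobic", rep))
                keys.append(SampleKey("AGS", cls, "anaerobic", rep))
            else:
                keys.append(SampleKey("AGS", cls, replicate=rep))
    return keys


def _noise_free_column(truth: SyntheticTruth, key: SampleKey, alpha: np.ndarray | None) -> np.ndarray:
    t = truth.table
    if key.compartment == "influent":
        p = t["influent_fraction"].to_numpy()
    elif key.compartment == "excess_sludge":
        p = t["p_es"].to_numpy()
    elif key.compartment == "effluent":
        p = t["p_ef"].to_numpy()
    elif key.aggregate_class == "mixed":
        p = t["p_ags"].to_numpy()
    else:
        p = t[f"p_{key.aggregate_class}"].to_numpy()
    if alpha is not None:
        p = p * alpha
        p = p / p.sum()
    return p


def _draw_fractions(
    p_mapped: np.ndarray, mapped: float, depth: int, noise: str, over: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """(fractions of total reads, integer counts) for one sample.

    Noise-free output keeps the exact fractions (counts are rounded for
    the count table only); noisy output derives fractions from the
    sampled counts.
    """
    probs = np.append(p_mapped * mapped, 1.0 - mapped)
    probs = probs / probs.sum()
    if noise == "none":
        frac = p_mapped * mapped
        return frac, np.round(frac * depth)
    if noise == "dirichlet_multinomial":
        probs = rng.dirichlet(probs * over)
    c = rng.multinomial(depth, probs)
    return c[:-1] / depth, c[:-1].astype(float)


def emit_profiles(truth: SyntheticTruth, cfg: SyntheticConfig) -> SyntheticDataset:
    """Emit DNA and RNA profile matrices and count tables.

    Fractions are of *total* reads (an unmapped pool absorbs
    ``unmapped_dna`` / ``unmapped_rna`` of each sample); expression
    scales abundance by each MAG's α and renormalizes per sample; the
    reactor expression is emitted for both redox phases.  The same seed
    always yields the same dataset.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2_000_003]))
    alpha = truth.table["alpha"].to_numpy()
    frames = {}
    counts = {}
    for kind, mapped, act in (
        ("metagenomics", 1.0 - cfg.unmapped_dna, None),
        ("metatranscriptomics", 1.0 - cfg.unmapped_rna, alpha),
    ):
        keys = _sample_keys(cfg, kind)
        cols = {}
        cnt_cols = {}
        for key in keys:
            p = _noise_free_column(truth, key, act)
            frac, c = _draw_fractions(
                p, mapped, cfg.depth, cfg.noise, cfg.overdispersion, rng
            )
            cols[key] = frac
            cnt_cols[key] = c.astype(int)
        frames[kind] = ProfileMatrix(
            pd.DataFrame(cols, index=truth.table.index), kind
        )
        counts[kind] = pd.DataFrame(cnt_cols, index=truth.table.index)

    meta = pd.DataFrame(
        {
            "taxonomy": [
                f"d__Bacteria;g__synthetic_{g}" for g in truth.table["guild"]
            ],
            "completeness": 90.0,
            "contamination": 2.0,
            "guild": truth.table["guild"],
        },
        index=truth.table.index,
    )
    return SyntheticDataset(
        dna=frames["metagenomics"],
        rna=frames["metatranscriptomics"],
        dna_counts=counts["metagenomics"],
        rna_counts=counts["metatranscriptomics"],
        mag_metadata=meta,
        truth=truth,
        config=cfg,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a complete dataset directory in the pipeline's file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "dna": outdir / "profiles_dna.tsv",
        "rna": outdir / "profiles_rna.tsv",
        "dna_counts": outdir / "counts_dna.tsv",
        "rna_counts": outdir / "counts_rna.tsv",
        "mags": outdir / "mags.tsv",
        "plant": outdir / "plant.yaml",
        "truth": outdir / "truth.tsv",
    }
    write_profile_table(dataset.dna, paths["dna"])
    write_profile_table(dataset.rna, paths["rna"])
    for name in ("dna_counts", "rna_counts"):
        df = getattr(dataset, name).copy()
        df.columns = [str(c) for c in df.columns]
        df.to_csv(paths[name], sep="\t", index_label="mag_id", lineterminator="\n")
    dataset.mag_metadata.to_csv(
        paths["mags"], sep="\t", index_label="mag_id", lineterminator="\n"
    )
    write_plant_config(dataset.truth.plant, paths["plant"])
    dataset.truth.table.to_csv(paths["truth"], sep="\t", lineterminator="\n")
    return paths
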