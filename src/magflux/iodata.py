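"""Tabular input/output for the immigration mass-balance pipeline.

The pipeline consumes three kinds of tables, all plain TSV:

* MAG-by-sample relative abundance / relative expression profiles
  (CoverM-style, values in percent of *total* reads),
* MAG metadata (taxonomy, completeness, contamination, optional guild),
* a plant-parameter YAML with biomass, daily fluxes and the aggregate
  size-class composition of the mixed liquor, excess sludge and effluent.

Internally every profile value is a fraction in [0, 1]; percent appears
only at the file boundary.  Sample columns are addressed through
:class:`SampleKey`, a dot-separated grammar
``compartment[.class][.phase].repN`` (case-insensitive), e.g.
``AGS.FL.anaerobic.rep2`` or ``influent.rep1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SampleKey",
    "PlantParameters",
    "ProfileMatrix",
    "ProfileError",
    "ConfigError",
    "reference_plant",
    "read_profile_table",
    "write_profile_table",
    "renormalize_to_mapped",
    "read_plant_config",
    "write_plant_config",
    "read_mag_metadata",
    "filter_mags",
]

COMPARTMENTS = ("influent", "AGS", "effluent", "excess_sludge")
AGGREGATE_CLASSES = ("FL", "SG", "LG", "mixed", "none")
PHASES = ("aerobic", "anaerobic", "none")
PROFILE_KINDS = ("metagenomics", "metatranscriptomics")

#: Size classes that partition the reactor biomass: flocs (< 0.2 mm),
#: small granules (0.2–1 mm) and large granules (> 1 mm).
SIZE_CLASSES = ("FL", "SG", "LG")

_FRACTION_TOL = 1e-9


class ProfileError(ValueError):
    """Malformed or inconsistent profile table."""


class ConfigError(ValueError):
    """Invalid plant or run configuration."""


# --------------------------------------------------------------------------
# sample keys
# --------------------------------------------------------------------------

_REP_RE = re.compile(r"^rep(\d+)$", re.IGNORECASE)

_COMPARTMENT_ALIASES = {
    "influent": "influent",
    "ags": "AGS",
    "effluent": "effluent",
    "excess_sludge": "excess_sludge",
}
_CLASS_ALIASES = {"fl": "FL", "sg": "SG", "lg": "LG", "mixed": "mixed"}
_PHASE_ALIASES = {"aerobic": "aerobic", "anaerobic": "anaerobic"}


@dataclass(frozen=True, order=True)
class SampleKey:
    """Identity of one sample column.

    ``aggregate_class`` is meaningful only for reactor (AGS) and
    excess-sludge-derived samples; ``phase`` only for reactor
    metatranscriptomic samples.  ``mixed`` denotes the reconstructed
    whole-reactor profile.  Replicates pair samples across compartments
    by week of sampling.
    """

    compartment: str
    aggregate_class: str = "none"
    phase: str = "none"
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ProfileError(f"unknown compartment {self.compartment!r}")
        if self.aggregate_class not in AGGREGATE_CLASSES:
            raise ProfileError(f"unknown aggregate class {self.aggregate_class!r}")
        if self.phase not in PHASES:
            raise ProfileError(f"unknown phase {self.phase!r}")
        if self.aggregate_class != "none" and self.compartment not in (
            "AGS",
            "excess_sludge",
        ):
            raise ProfileError(
                f"aggregate class {self.aggregate_class!r} not allowed for "
                f"compartment {self.compartment!r}"
            )
        if self.phase != "none" and self.compartment != "AGS":
            raise ProfileError(
                f"phase {self.phase!r} only allowed for AGS samples"
            )
        if self.replicate < 1:
            raise ProfileError("replicate index must be a positive integer")

    @classmethod
    def parse(cls, token: str) -> "SampleKey":
        """Parse a dot-separated column header token."""
        parts = token.strip().split(".")
        if len(parts) < 2:
            raise ProfileError(f"malformed sample key {token!r}: need compartment.repN")
        m = _REP_RE.match(parts[-1])
        if m is None:
            raise ProfileError(
                f"malformed sample key {token!r}: last field must be repN"
            )
        replicate = int(m.group(1))
        comp = _COMPARTMENT_ALIASES.get(parts[0].lower())
        if comp is None:
            raise ProfileError(
                f"malformed sample key {token!r}: unknown compartment {parts[0]!r}"
            )
        agg, phase = "none", "none"
        for mid in parts[1:-1]:
            low = mid.lower()
            if low in _CLASS_ALIASES and agg == "none":
                agg = _CLASS_ALIASES[low]
            elif low in _PHASE_ALIASES and phase == "none":
                phase = _PHASE_ALIASES[low]
            else:
                raise ProfileError(
                    f"malformed sample key {token!r}: unexpected field {mid!r}"
                )
        return cls(comp, agg, phase, replicate)

    def __str__(self) -> str:
        parts = [self.compartment]
        if self.aggregate_class != "none":
            parts.append(self.aggregate_class)
        if self.phase != "none":
            parts.append(self.phase)
        parts.append(f"rep{self.replicate}")
        return ".".join(parts)


# --------------------------------------------------------------------------
# plant parameters
# --------------------------------------------------------------------------


def _validate_fractions(name: str, fractions: Mapping[str, float]) -> dict:
    out = {}
    for cls in SIZE_CLASSES:
        if cls not in fractions:
            raise ConfigError(f"{name} missing size class {cls!r}")
        v = float(fractions[cls])
        if v < 0:
            raise ConfigError(f"{name}[{cls}] is negative")
        out[cls] = v
    extra = set(fractions) - set(SIZE_CLASSES)
    if extra:
        raise ConfigError(f"{name} has unknown size classes {sorted(extra)}")
    if abs(sum(out.values()) - 1.0) > _FRACTION_TOL:
        raise ConfigError(f"{name} must sum to 1, got {sum(out.values()):.12g}")
    return out


@dataclass(frozen=True)
class PlantParameters:
    """Steady-state biomass inventory and fluxes of the plant.

    Attributes
    ----------
    m_ags : float
        Total reactor biomass, kg TSS.
    j_es, j_ef, j_ww : float
        Daily TSS biomass fluxes (kg d⁻¹) of the excess sludge, the
        effluent, and the influent wastewater respectively.
    mlss_fractions : dict
        Mass fraction of the reactor biomass in each size class
        (FL/SG/LG), summing to 1.
    es_fractions, ef_fractions : dict
        Size-class composition of the excess sludge and of the biomass
        escaping with the effluent.
    """

    m_ags: float
    j_es: float
    j_ef: float
    j_ww: float
    mlss_fractions: Mapping[str, float]
    es_fractions: Mapping[str, float]
    ef_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"FL": 1.0, "SG": 0.0, "LG": 0.0}
    )

    def __post_init__(self) -> None:
        for name in ("m_ags", "j_es", "j_ef", "j_ww"):
            if not float(getattr(self, name)) > 0:
                raise ConfigError(f"{name} must be positive")
        object.__setattr__(
            self, "mlss_fractions", _validate_fractions("mlss_fractions", self.mlss_fractions)
        )
        object.__setattr__(
            self, "es_fractions", _validate_fractions("es_fractions", self.es_fractions)
        )
        object.__setattr__(
            self, "ef_fractions", _validate_fractions("ef_fractions", self.ef_fractions)
        )

    @property
    def washout_rate(self) -> float:
        """(J_ES + J_EF) / M_AGS, d⁻¹ — the system-wide dilution rate.

        No population can sustain a net growth rate at or above this
        bound at steady state.
        """
        return (self.j_es + self.j_ef) / self.m_ags

    def with_j_ww(self, j_ww: float) -> "PlantParameters":
        return replace(self, j_ww=j_ww)


def reference_plant() -> PlantParameters:
    """Design parameters of the full-scale AGS plant used throughout.

    55,972 kg TSS reactor inventory; 2177 / 1256 / 4122.5 kg TSS d⁻¹
    excess-sludge, effluent and influent fluxes; aerobic well-mixed MLSS
    of 25% flocs, 53% small and 22% large granules; excess sludge of
    50% FL / 45% SG / 5% LG; effluent biomass treated as all flocs.
    """
    return PlantParameters(
        m_ags=55972.0,
        j_es=2177.0,
        j_ef=1256.0,
        j_ww=4122.5,
        mlss_fractions={"FL": 0.25, "SG": 0.53, "LG": 0.22},
        es_fractions={"FL": 0.50, "SG": 0.45, "LG": 0.05},
        ef_fractions={"FL": 1.0, "SG": 0.0, "LG": 0.0},
    )


# --------------------------------------------------------------------------
# profile matrices
# --------------------------------------------------------------------------


@dataclass
class ProfileMatrix:
    """MAG × sample matrix of read fractions.

    ``data`` is indexed by MAG id; its columns are :class:`SampleKey`
    objects; values are fractions of total reads in [0, 1].  Column sums
    below 1 reflect unmapped reads; the per-column sum is recorded as
    ``mapped_fraction`` when the table provides no explicit value.
    """

    data: pd.DataFrame
    kind: str
    mapped_fraction: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ProfileError(f"unknown profile kind {self.kind!r}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ProfileError(f"duplicate MAG id {dup!r}")
        vals = self.data.to_numpy(dtype=float)
        if np.any(vals < 0):
            raise ProfileError("negative profile values")
        sums = vals.sum(axis=0)
        if np.any(sums > 1 + _FRACTION_TOL):
            bad = self.data.columns[int(np.argmax(sums))]
            raise ProfileError(f"column {bad} sums to {sums.max():.6g} > 1")
        if self.mapped_fraction is None:
            self.mapped_fraction = pd.Series(sums, index=self.data.columns)

    # -- introspection -----------------------------------------------------

    @property
    def mag_ids(self) -> pd.Index:
        return self.data.index

    @property
    def columns(self) -> list[SampleKey]:
        return list(self.data.columns)

    def replicates(self, compartment: str | None = None) -> list[int]:
        keys = self.columns
        if compartment is not None:
            keys = [k for k in keys if k.compartment == compartment]
        return sorted({k.replicate for k in keys})

    def select(
        self,
        compartment: str | None = None,
        aggregate_class: str | None = None,
        phase: str | None = None,
        replicate: int | None = None,
    ) -> pd.DataFrame:
        """Sub-matrix of columns matching every given criterion."""
        cols = [
            k
            for k in self.columns
            if (compartment is None or k.compartment == compartment)
            and (aggregate_class is None or k.aggregate_class == aggregate_class)
            and (phase is None or k.phase == phase)
            and (replicate is None or k.replicate == replicate)
        ]
        return self.data[cols]

    def sorted_by_mag(self) -> "ProfileMatrix":
        order = self.data.sort_index()
        return ProfileMatrix(order, self.kind, self.mapped_fraction)


def read_profile_table(path: str | Path, kind: str) -> ProfileMatrix:
    """Read a percent-valued profile TSV into fractional form.

    The first column holds MAG ids; every other header token is parsed
    as a :class:`SampleKey`.  Values are percent of total reads (0–100)
    and are divided by 100 on the way in.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ProfileError(f"duplicate MAG id {dup!r} in {path}")
    try:
        keys = [SampleKey.parse(c) for c in df.columns]
    except ProfileError as exc:
        raise ProfileError(f"{path}: {exc}") from exc
    vals = df.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ProfileError(f"{path}: negative value in profile table")
    if np.any(vals.sum(axis=0) > 100 * (1 + _FRACTION_TOL)):
        raise ProfileError(f"{path}: a column sums to more than 100%")
    out = pd.DataFrame(vals / 100.0, index=df.index, columns=keys)
    return ProfileMatrix(out, kind)


def write_profile_table(profiles: ProfileMatrix, path: str | Path) -> None:
    """Write a ProfileMatrix back to percent-valued TSV."""
    df = profiles.data.copy()
    df.columns = [str(k) for k in df.columns]
    (df * 100.0).to_csv(path, sep="\t", index_label="mag_id", lineterminator="\n")


def renormalize_to_mapped(profiles: ProfileMatrix) -> ProfileMatrix:
    """Rescale each column so fractions are of *mapped* reads.

    Per-column division by the mapped fraction; columns with no mapped
    reads are left untouched.
    """
    sums = profiles.data.sum(axis=0)
    safe = sums.where(sums > 0, 1.0)
    data = profiles.data.div(safe, axis=1)
    return ProfileMatrix(
        data, profiles.kind, pd.Series(1.0, index=profiles.data.columns)
    )


# --------------------------------------------------------------------------
# MAG metadata
# --------------------------------------------------------------------------

_META_COLUMNS = ("taxonomy", "completeness", "contamination")


def read_mag_metadata(path: str | Path) -> pd.DataFrame:
    """Read the MAG metadata TSV (taxonomy, completeness %, contamination %)."""
    df = pd.read_csv(path, sep="\t", index_col="mag_id")
    df.index = df.index.astype(str)
    for col in _META_COLUMNS:
        if col not in df.columns:
            raise ProfileError(f"{path}: missing metadata column {col!r}")
    comp = df["completeness"].astype(float)
    cont = df["contamination"].astype(float)
    if ((comp < 0) | (comp > 100)).any():
        raise ProfileError(f"{path}: completeness outside [0, 100]")
    if (cont < 0).any():
        raise ProfileError(f"{path}: negative contamination")
    if "guild" not in df.columns:
        df["guild"] = ""
    return df


def filter_mags(
    meta: pd.DataFrame,
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> set[str]:
    """MAGs with completeness strictly above and contamination strictly
    below the thresholds (the usual medium-quality draft-genome screen)."""
    for thr in (min_completeness, max_contamination):
        if not 0 <= thr <= 100:
            raise ConfigError("thresholds must lie in [0, 100]")
    keep = (meta["completeness"].astype(float) > min_completeness) & (
        meta["contamination"].astype(float) < max_contamination
    )
    return set(meta.index[keep])


# --------------------------------------------------------------------------
# plant config YAML
# --------------------------------------------------------------------------

_PLANT_KEYS = {"M_AGS": "m_ags", "J_ES": "j_es", "J_EF": "j_ef", "J_WW": "j_ww"}


def read_plant_config(path: str | Path) -> PlantParameters:
    """Read plant parameters from YAML.

    Expected keys: ``M_AGS``, ``J_ES``, ``J_EF``, ``J_WW``,
    ``mlss_fractions``, ``es_fractions`` and optionally
    ``ef_fractions`` (defaults to all-flocs effluent).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: plant config must be a mapping")
    kwargs: dict = {}
    for yaml_key, attr in _PLANT_KEYS.items():
        if yaml_key not in raw:
            raise ConfigError(f"{path}: missing key {yaml_key!r}")
        kwargs[attr] = float(raw[yaml_key])
    for name in ("mlss_fractions", "es_fractions"):
        if name not in raw:
            raise ConfigError(f"{path}: missing key {name!r}")
        kwargs[name] = raw[name]
    if "ef_fractions" in raw:
        kwargs["ef_fractions"] = raw["ef_fractions"]
    return PlantParameters(**kwargs)


def write_plant_config(plant: PlantParameters, path: str | Path) -> None:
    doc = {
        "M_AGS": float(plant.m_ags),
        "J_ES": float(plant.j_es),
        "J_EF": float(plant.j_ef),
        "J_WW": float(plant.j_ww),
        "mlss_fractions": {k: float(v) for k, v in plant.mlss_fractions.items()},
        "es_fractions": {k: float(v) for k, v in plant.es_fractions.items()},
        "ef_fractions": {k: float(v) for k, v in plant.ef_fractions.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def profiles_from_frame(
    df: pd.DataFrame, kind: str, mapped_fraction: pd.Series | None = None
) -> ProfileMatrix:
    """Build a ProfileMatrix from an in-memory fractional DataFrame whose
    column labels are SampleKeys or parseable key strings."""
    cols = [c if isinstance(c, SampleKey) else SampleKey.parse(str(c)) for c in df.columns]
    out = df.copy()
    out.columns = cols
    return ProfileMatrix(out, kind, mapped_fraction)
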