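"""Synthetic morphometry cohorts with a donor → kidney → slide hierarchy.

Emulates the structure of a repeat-biopsy study on deceased-donor kidneys:
each kidney is biopsied with several retrieval techniques (punch, core,
wedge), each biopsy repeated several times, a fixed number of biopsies
excluded for tissue quality, and each retained biopsy sectioned once per
stain (H&E, PAS).  Every continuous variable is generated from a three-level
random-effects model (donor + kidney + slide); counts are rounded products
of a latent per-area density and the latent cortex area, so that variance
fractions configured at generation time are recoverable downstream.

The glomerular-density distribution is lognormal and anchored by its 10th
percentile (default 1.5 glomeruli per area unit), which drives the cortex
area recommendation of the adequacy stage.  Units are deliberately abstract
("area units" / "length units"): the generator models relative variability,
not absolute physical scale.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: Column order of a cohort table; one row per slide (or per excluded biopsy).
COLUMNS = [
    "donor_id",
    "kidney_id",
    "biopsy_id",
    "technique",
    "stain",
    "excluded",
    "medulla_present",
    "cortex_area",
    "biopsy_depth",
    "biopsy_width",
    "glomeruli_total",
    "glomeruli_sclerotic",
    "artery_count",
    "arteriole_count",
    "vessel_count",
    "if_area",
    "ta_area",
    "artery_wall_thickness",
    "artery_lumen_diameter",
    "artery_full_diameter",
    "artery_puncture",
]

_STRING_COLS = ["donor_id", "kidney_id", "biopsy_id", "technique", "stain"]
_BOOL_COLS = ["excluded", "medulla_present"]
_NULLABLE_BOOL_COLS = ["artery_puncture"]
_FLOAT_COLS = [c for c in COLUMNS if c not in _STRING_COLS + _BOOL_COLS + _NULLABLE_BOOL_COLS]

# Latent variables and their default (donor, kidney, slide) variance
# components.  "log_*" variables act multiplicatively (effects additive on
# the log scale), "logit_*" on the log-odds scale, the rest additively.
DEFAULT_VARIANCE_COMPONENTS: dict[str, tuple[float, float, float]] = {
    "log_cortex_area": (0.02, 0.01, 0.03),
    "biopsy_depth": (0.40, 0.20, 0.40),
    "biopsy_width": (0.30, 0.15, 0.30),
    "log_glomerular_density": (0.0625, 0.0225, 0.04),
    "logit_gs_propensity": (0.60, 0.20, 0.0),
    "logit_if_frac": (0.50, 0.20, 0.30),
    "logit_ta_frac": (0.50, 0.20, 0.30),
    "log_artery_density": (0.05, 0.02, 0.08),
    "log_arteriole_density": (0.05, 0.02, 0.08),
    "log_wall_thickness": (0.04, 0.01, 0.03),
    "log_lumen_diameter": (0.05, 0.015, 0.03),
}

# Baseline levels of the latent variables (natural scale).
_BASELINES = {
    "gs_frac": 0.12,        # sclerotic fraction at the logit origin
    "if_frac": 0.10,
    "ta_frac": 0.08,
    "artery_density": 0.12,     # arteries per area unit
    "arteriole_density": 0.30,
    "wall_thickness": 12.0,     # length units
    "lumen_diameter": 18.0,
    "puncture_prob": 0.05,
}

DEFAULT_DEPTH_MEANS = {"punch": 4.0, "core": 12.0, "wedge": 6.0}
DEFAULT_WIDTH_MEANS = {"punch": 3.0, "core": 2.0, "wedge": 15.0}


def _default_kidney_map(n_donors: int) -> dict[str, int]:
    """First four donors contribute both kidneys, the rest one each."""
    return {f"D{i + 1:02d}": (2 if i < 4 else 1) for i in range(n_donors)}


@dataclass
class SimConfig:
    """Study design and generative parameters of a synthetic cohort.

    Defaults reproduce the reference design: 12 donors contributing 16
    kidneys, 3 techniques x 3 replicates = 144 biopsies, 19 excluded,
    2 stains per retained biopsy (250 slides), 27 medulla-bearing biopsies
    (54 slides with unavailable cortex area), and a glomerular density whose
    0.10 quantile is 1.5 per area unit.
    """

    n_donors: int = 12
    kidneys_per_donor: Mapping[str, int] | None = None
    techniques: Sequence[str] = ("punch", "core", "wedge")
    replicates_per_technique: int = 3
    n_excluded: int = 19
    stains: Sequence[str] = ("H&E", "PAS")
    n_medulla_biopsies: int = 27
    variance_components: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_VARIANCE_COMPONENTS)
    )
    #: additive shift (percentage points) of IF% and TA% on PAS slides
    stain_effect_ifta_pct: float = 3.0
    #: mean cortex area per technique; default strictly ordered wedge > core > punch
    technique_area_means: Mapping[str, float] = field(
        default_factory=lambda: {"punch": 10.0, "core": 25.0, "wedge": 60.0}
    )
    #: mean biopsy depth / width per technique
    technique_depth_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_MEANS)
    )
    technique_width_means: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WIDTH_MEANS)
    )
    #: 0.10 quantile of the marginal glomerular density (per area unit)
    density_q10: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kidneys_per_donor is None:
            self.kidneys_per_donor = _default_kidney_map(self.n_donors)

    # -- derived sizes ----------------------------------------------------
    @property
    def n_kidneys(self) -> int:
        return sum(self.kidneys_per_donor.values())

    @property
    def n_biopsies(self) -> int:
        return self.n_kidneys * len(self.techniques) * self.replicates_per_technique

    def validate(self) -> None:
        if self.n_donors < 1:
            raise ConfigError("n_donors must be >= 1")
        if len(self.kidneys_per_donor) != self.n_donors:
            raise ConfigError("kidneys_per_donor must map exactly n_donors donors")
        if any(k not in (1, 2) for k in self.kidneys_per_donor.values()):
            raise ConfigError("kidneys_per_donor values must be 1 or 2")
        if not self.techniques or len(set(self.techniques)) != len(self.techniques):
            raise ConfigError("techniques must be a non-empty set of distinct labels")
        if self.replicates_per_technique < 1:
            raise ConfigError("replicates_per_technique must be >= 1")
        if not (0 <= self.n_excluded < self.n_biopsies):
            raise ConfigError("n_excluded must satisfy 0 <= n_excluded < total biopsies")
        if not self.stains or len(set(self.stains)) != len(self.stains):
            raise ConfigError("stains must be a non-empty set of distinct labels")
        if not (0 <= self.n_medulla_biopsies <= self.n_biopsies - self.n_excluded):
            raise ConfigError(
                "n_medulla_biopsies must not exceed the number of retained biopsies"
            )
        for name, comps in self.variance_components.items():
            if len(comps) != 3 or any(v < 0 for v in comps):
                raise ConfigError(
                    f"variance_components[{name!r}] must be three non-negative variances"
                )
        missing = [t for t in self.techniques if t not in self.technique_area_means]
        if missing:
            raise ConfigError(f"technique_area_means missing entries for {missing}")
        means = [self.technique_area_means[t] for t in self.techniques]
        if any(m <= 0 for m in means):
            raise ConfigError("technique_area_means must be positive")
        if self.density_q10 <= 0:
            raise ConfigError("density_q10 must be > 0")


def null_config(seed: int = 0, **overrides) -> SimConfig:
    """A cohort configuration with no biopsy-processing effects.

    Technique means are equalized and the stain shift removed, so every
    processing-vs-morphometry null hypothesis is true; used to calibrate the
    dependence battery's Type 1 behaviour.
    """
    cfg = SimConfig(
        technique_area_means={"punch": 25.0, "core": 25.0, "wedge": 25.0},
        technique_depth_means={"punch": 8.0, "core": 8.0, "wedge": 8.0},
        technique_width_means={"punch": 5.0, "core": 5.0, "wedge": 5.0},
        stain_effect_ifta_pct=0.0,
        seed=seed,
        **overrides,
    )
    return cfg


def _components(config: SimConfig, name: str) -> tuple[float, float, float]:
    return tuple(config.variance_components.get(name, (0.0, 0.0, 0.0)))


class _Effects:
    """Per-variable hierarchical effects d_i + k_j + s_l, drawn in a fixed order."""

    def __init__(self, rng, config, donor_idx, kidney_idx, n_slides):
        self.rng = rng
        self.config = config
        self.donor_idx = donor_idx
        self.kidney_idx = kidney_idx
        self.n_slides = n_slides
        self.n_donors = donor_idx.max() + 1
        self.n_kidneys = kidney_idx.max() + 1

    def draw(self, name: str) -> np.ndarray:
        vd, vk, vs = _components(self.config, name)
        d = self.rng.normal(0.0, np.sqrt(vd), self.n_donors)
        k = self.rng.normal(0.0, np.sqrt(vk), self.n_kidneys)
        s = self.rng.normal(0.0, np.sqrt(vs), self.n_slides)
        return d[self.donor_idx] + k[self.kidney_idx] + s


def simulate_cohort(config: SimConfig | None = None) -> pd.DataFrame:
    """Generate a cohort table, one row per slide plus one per excluded biopsy.

    Excluded biopsies were never sectioned or stained, so they appear as a
    single row with ``excluded=True`` and all morphometry missing; this keeps
    the full biopsy accounting visible in one table.  Deterministic given
    ``config.seed``.
    """
    config = config or SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    # ---- design frame: donors -> kidneys -> biopsies --------------------
    donors, kidneys, kidney_donor = [], [], []
    for donor, n_k in config.kidneys_per_donor.items():
        donors.append(donor)
        sides = ["L", "R"][:n_k]
        for side in sides:
            kidneys.append(f"{donor}-{side}")
            kidney_donor.append(donor)

    biopsies = []  # (donor, kidney, biopsy_id, technique)
    for kid, don in zip(kidneys, kidney_donor):
        for tech in config.techniques:
            for rep in range(1, config.replicates_per_technique + 1):
                biopsies.append((don, kid, f"{kid}-{tech}-{rep}", tech))
    n_biopsies = len(biopsies)

    excluded_pos = rng.choice(n_biopsies, size=config.n_excluded, replace=False)
    excluded_mask = np.zeros(n_biopsies, dtype=bool)
    excluded_mask[excluded_pos] = True
    retained_pos = np.flatnonzero(~excluded_mask)
    medulla_pos = rng.choice(retained_pos, size=config.n_medulla_biopsies, replace=False)
    medulla_mask = np.zeros(n_biopsies, dtype=bool)
    medulla_mask[medulla_pos] = True

    # ---- slide frame: one row per retained biopsy x stain ---------------
    rows = []
    for pos, (don, kid, bid, tech) in enumerate(biopsies):
        if excluded_mask[pos]:
            continue
        for stain in config.stains:
            rows.append((don, kid, bid, tech, stain, medulla_mask[pos]))
    slides = pd.DataFrame(
        rows, columns=["donor_id", "kidney_id", "biopsy_id", "technique", "stain", "medulla_present"]
    )
    n_slides = len(slides)

    donor_codes = {d: i for i, d in enumerate(donors)}
    kidney_codes = {k: i for i, k in enumerate(kidneys)}
    donor_idx = slides["donor_id"].map(donor_codes).to_numpy()
    kidney_idx = slides["kidney_id"].map(kidney_codes).to_numpy()
    eff = _Effects(rng, config, donor_idx, kidney_idx, n_slides)

    tech_area = slides["technique"].map(config.technique_area_means).to_numpy(float)
    cortex_area = tech_area * np.exp(eff.draw("log_cortex_area"))

    depth = slides["technique"].map(config.technique_depth_means).fillna(5.0).to_numpy(float)
    depth = np.clip(depth + eff.draw("biopsy_depth"), 0.1, None)
    width = slides["technique"].map(config.technique_width_means).fillna(3.0).to_numpy(float)
    width = np.clip(width + eff.draw("biopsy_width"), 0.1, None)

    # glomerular density: lognormal anchored at its 0.10 quantile
    sigma_tot = np.sqrt(sum(_components(config, "log_glomerular_density")))
    mu = np.log(config.density_q10) + norm.ppf(0.9) * sigma_tot
    density = np.exp(mu + eff.draw("log_glomerular_density"))
    glomeruli_total = np.maximum(0, np.rint(density * cortex_area))

    # sclerotic glomeruli: binomial with a logit-scale donor/kidney propensity;
    # a fully degenerate propensity (all three components zero) switches to
    # the rounded expectation, so a no-noise config yields identical slides
    # within each kidney.
    gs_logit = logit(_BASELINES["gs_frac"]) + eff.draw("logit_gs_propensity")
    p_gs = expit(gs_logit)
    if sum(_components(config, "logit_gs_propensity")) > 0:
        sclerotic = rng.binomial(glomeruli_total.astype(int), p_gs).astype(float)
    else:
        sclerotic = np.rint(glomeruli_total * p_gs)

    pas = (slides["stain"] == "PAS").to_numpy()
    if_pct = 100.0 * expit(logit(_BASELINES["if_frac"]) + eff.draw("logit_if_frac"))
    ta_pct = 100.0 * expit(logit(_BASELINES["ta_frac"]) + eff.draw("logit_ta_frac"))
    if_pct = np.clip(if_pct + np.where(pas, config.stain_effect_ifta_pct, 0.0), 0.0, 100.0)
    ta_pct = np.clip(ta_pct + np.where(pas, config.stain_effect_ifta_pct, 0.0), 0.0, 100.0)
    if_area = if_pct / 100.0 * cortex_area
    ta_area = ta_pct / 100.0 * cortex_area

    artery_density = _BASELINES["artery_density"] * np.exp(eff.draw("log_artery_density"))
    arteriole_density = _BASELINES["arteriole_density"] * np.exp(eff.draw("log_arteriole_density"))
    artery_count = np.maximum(0, np.rint(artery_density * cortex_area))
    arteriole_count = np.maximum(0, np.rint(arteriole_density * cortex_area))

    wall = _BASELINES["wall_thickness"] * np.exp(eff.draw("log_wall_thickness"))
    lumen = _BASELINES["lumen_diameter"] * np.exp(eff.draw("log_lumen_diameter"))
    full = lumen + 2.0 * wall

    puncture = rng.random(n_slides) < _BASELINES["puncture_prob"]

    slide_df = pd.DataFrame(
        {
            "donor_id": slides["donor_id"],
            "kidney_id": slides["kidney_id"],
            "biopsy_id": slides["biopsy_id"],
            "technique": slides["technique"],
            "stain": slides["stain"],
            "excluded": False,
            "medulla_present": slides["medulla_present"].to_numpy(),
            # medulla slides: cortex area could not be delineated separately
            "cortex_area": np.where(slides["medulla_present"], np.nan, cortex_area),
            "biopsy_depth": depth,
            "biopsy_width": width,
            "glomeruli_total": glomeruli_total,
            "glomeruli_sclerotic": sclerotic,
            "artery_count": artery_count,
            "arteriole_count": arteriole_count,
            "vessel_count": artery_count + arteriole_count,
            "if_area": if_area,
            "ta_area": ta_area,
            "artery_wall_thickness": wall,
            "artery_lumen_diameter": lumen,
            "artery_full_diameter": full,
            "artery_puncture": puncture,
        }
    )

    excl_rows = [
        {
            "donor_id": don,
            "kidney_id": kid,
            "biopsy_id": bid,
            "technique": tech,
            "stain": pd.NA,
            "excluded": True,
            "medulla_present": False,
        }
        for pos, (don, kid, bid, tech) in enumerate(biopsies)
        if excluded_mask[pos]
    ]
    if excl_rows:
        excl_df = pd.DataFrame(excl_rows)
        for c in _FLOAT_COLS:
            excl_df[c] = np.nan
        excl_df["artery_puncture"] = pd.NA
        df = pd.concat([slide_df, excl_df], ignore_index=True)
    else:
        df = slide_df

    df = df[COLUMNS]
    df = df.sort_values(["biopsy_id", "stain"], kind="stable", na_position="last")
    df = df.reset_index(drop=True)
    return _apply_schema(df)


def _apply_schema(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for c in _STRING_COLS:
        df[c] = df[c].astype("string")
    for c in _BOOL_COLS:
        df[c] = df[c].astype(bool)
    for c in _NULLABLE_BOOL_COLS:
        df[c] = df[c].astype("boolean")
    for c in _FLOAT_COLS:
        df[c] = df[c].astype(float)
    return df


def validate_cohort(df: pd.DataFrame) -> None:
    """Check slide-level invariants; raise :class:`DataError` naming the row."""
    missing_cols = [c for c in COLUMNS if c not in df.columns]
    if missing_cols:
        raise DataError(f"cohort table missing columns: {missing_cols}")
    live = ~df["excluded"].to_numpy(bool)
    for col in ("cortex_area", "biopsy_depth", "biopsy_width", "if_area", "ta_area",
                "artery_wall_thickness", "artery_lumen_diameter", "artery_full_diameter"):
        vals = df[col].to_numpy(float)
        bad = live & ~np.isnan(vals) & (vals <= 0)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise DataError(f"row {row}: {col} must be > 0 on non-excluded records")
    tot = df["glomeruli_total"].to_numpy(float)
    scl = df["glomeruli_sclerotic"].to_numpy(float)
    both = ~np.isnan(tot) & ~np.isnan(scl)
    bad = both & ((scl < 0) | (scl > tot))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise DataError(f"row {row}: glomeruli_sclerotic must be in [0, glomeruli_total]")
    lum = df["artery_lumen_diameter"].to_numpy(float)
    ful = df["artery_full_diameter"].to_numpy(float)
    bad = ~np.isnan(lum) & ~np.isnan(ful) & (lum >= ful)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise DataError(f"row {row}: artery_lumen_diameter must be < artery_full_diameter")
    medulla = df["medulla_present"].to_numpy(bool)
    area = df["cortex_area"].to_numpy(float)
    bad = medulla & live & ~np.isnan(area)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise DataError(f"row {row}: medulla_present slides must have cortex_area missing")


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table to CSV (missing values as empty fields)."""
    validate_cohort(df)
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV back into the canonical schema; lossless round trip."""
    try:
        raw = pd.read_csv(path, dtype="string")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise DataError(f"cannot parse cohort CSV {path}: {exc}") from exc
    missing_cols = [c for c in COLUMNS if c not in raw.columns]
    if missing_cols:
        raise DataError(f"{path}: missing columns {missing_cols}")
    df = pd.DataFrame(index=raw.index)
    for c in _STRING_COLS:
        df[c] = raw[c]
    bool_map = {"True": True, "False": False}
    for c in _BOOL_COLS + _NULLABLE_BOOL_COLS:
        col = raw[c].map(bool_map)
        invalid = raw[c].notna() & col.isna()
        if invalid.any():
            row = int(np.flatnonzero(invalid.to_numpy())[0])
            raise DataError(f"row {row}: column {c} must be True/False")
        df[c] = col
    for c in _FLOAT_COLS:
        try:
            df[c] = raw[c].astype(float)
        except ValueError as exc:
            raise DataError(f"column {c}: non-numeric value ({exc})") from exc
    df = _apply_schema(df[COLUMNS])
    validate_cohort(df)
    return df


def cohort_sha256(df: pd.DataFrame) -> str:
    """Stable content hash of a cohort table (used by the pipeline manifest)."""
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()
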