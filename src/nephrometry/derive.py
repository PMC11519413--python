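"""Derived and intensive morphometric variables and Remuzzi scoring.

Extensive measurements (counts, areas) depend on how much tissue the biopsy
happened to capture; dividing by the cortex area delineated on the slide
yields intensive "per unit area" variables that are comparable across
biopsies.  Slides containing medulla have no separate cortex-area
measurement, so every intensive variable is missing there.

The Remuzzi score sums four 0-3 sub-scores (glomerulosclerosis %, IF %,
TA %, arterial wall/lumen ratio); the total (0-12) drives the transplant
decision: 0-3 single kidney, 4-6 dual transplant, >=7 discard.  The interval
boundaries are closed on the right (a GS of exactly 50% scores 2, not 3).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import DataError
from .simulate import validate_cohort

logger = logging.getLogger(__name__)

#: intensive (per-area) variables, missing whenever medulla is present
PER_AREA_FIELDS = [
    "glomeruli_per_area",
    "healthy_per_area",
    "sclerotic_per_area",
    "artery_per_area",
    "arteriole_per_area",
    "vessel_per_area",
]

#: columns appended by :func:`derive_variables`
DERIVED_FIELDS = [
    "healthy_glomeruli",
    "gs_pct",
    "if_pct",
    "ta_pct",
    *PER_AREA_FIELDS,
    "wall_lumen_ratio",
    "sub_g",
    "sub_if",
    "sub_ta",
    "sub_a",
    "total_score",
    "decision",
]

# Right-closed interval edges; score = number of edges strictly below value.
_GS_EDGES = (2.0, 20.0, 50.0)
_IFTA_EDGES = (6.0, 20.0, 50.0)
_ARTERY_EDGES = (0.5, 0.8, 1.2)


def _score_intervals(x: float, edges: tuple[float, ...]) -> int:
    s = 0
    for e in edges:
        if x > e:
            s += 1
    return s


def remuzzi_subscore_gs(gs_pct: float) -> int:
    """Glomerulosclerosis sub-score: [0,2]→0, (2,20]→1, (20,50]→2, (50,100]→3."""
    if not 0 <= gs_pct <= 100:
        raise DataError(f"gs_pct must be in [0, 100], got {gs_pct}")
    return _score_intervals(gs_pct, _GS_EDGES)


def remuzzi_subscore_ifta(pct: float) -> int:
    """IF or TA sub-score (identical thresholds): [0,6]→0, (6,20]→1, (20,50]→2, (50,100]→3."""
    if not 0 <= pct <= 100:
        raise DataError(f"IF/TA percentage must be in [0, 100], got {pct}")
    return _score_intervals(pct, _IFTA_EDGES)


def remuzzi_subscore_artery(ratio: float) -> int:
    """Arterial wall/lumen sub-score: [0,0.5]→0, (0.5,0.8]→1, (0.8,1.2]→2, (1.2,∞)→3."""
    if ratio < 0 or not np.isfinite(ratio):
        raise DataError(f"wall/lumen ratio must be finite and >= 0, got {ratio}")
    return _score_intervals(ratio, _ARTERY_EDGES)


def transplant_decision(total_score: int) -> str:
    """Map a total Remuzzi score to single / dual / discard.

    The conventional rule is used: 0-3 single, 4-6 dual, >=7 discard.
    """
    if not float(total_score).is_integer():
        raise DataError(f"total_score must be an integer, got {total_score}")
    total_score = int(total_score)
    if not 0 <= total_score <= 12:
        raise DataError(f"total_score must be in [0, 12], got {total_score}")
    if total_score <= 3:
        return "single"
    if total_score <= 6:
        return "dual"
    return "discard"


def _vector_score(values: np.ndarray, edges: tuple[float, ...]) -> np.ndarray:
    out = np.full(values.shape, np.nan)
    ok = ~np.isnan(values)
    out[ok] = np.searchsorted(np.asarray(edges), values[ok], side="left")
    return out


def derive_variables(records: pd.DataFrame, validate: bool = True) -> pd.DataFrame:
    """Append all derived and intensive variables to the non-excluded slides.

    Returns one row per non-excluded input slide with the original columns
    plus :data:`DERIVED_FIELDS`.  Intensive variables are set missing on
    medulla-bearing slides; a glomerulosclerosis percentage with zero total
    glomeruli is missing (0/0 carries no information); a zero lumen diameter
    makes the wall/lumen ratio missing with a warning.
    """
    if validate:
        validate_cohort(records)
    df = records.loc[~records["excluded"].astype(bool)].reset_index(drop=True).copy()

    area = df["cortex_area"].to_numpy(float)
    medulla = df["medulla_present"].to_numpy(bool)
    if np.any(~medulla & (np.nan_to_num(area, nan=1.0) <= 0)):
        row = int(np.flatnonzero(~medulla & (np.nan_to_num(area, nan=1.0) <= 0))[0])
        raise DataError(f"row {row}: zero cortex_area on a cortex-only slide")

    total = df["glomeruli_total"].to_numpy(float)
    sclerotic = df["glomeruli_sclerotic"].to_numpy(float)
    df["healthy_glomeruli"] = total - sclerotic

    with np.errstate(invalid="ignore", divide="ignore"):
        gs = np.where(total > 0, 100.0 * sclerotic / total, np.nan)
        df["gs_pct"] = gs

        # intensive variables: count (or area) divided by cortex area
        norm_area = np.where(medulla, np.nan, area)
        df["if_pct"] = 100.0 * df["if_area"].to_numpy(float) / norm_area
        df["ta_pct"] = 100.0 * df["ta_area"].to_numpy(float) / norm_area
        df["glomeruli_per_area"] = total / norm_area
        df["healthy_per_area"] = df["healthy_glomeruli"].to_numpy(float) / norm_area
        df["sclerotic_per_area"] = sclerotic / norm_area
        df["artery_per_area"] = df["artery_count"].to_numpy(float) / norm_area
        df["arteriole_per_area"] = df["arteriole_count"].to_numpy(float) / norm_area
        df["vessel_per_area"] = df["vessel_count"].to_numpy(float) / norm_area

        lumen = df["artery_lumen_diameter"].to_numpy(float)
        wall = df["artery_wall_thickness"].to_numpy(float)
        zero_lumen = ~np.isnan(lumen) & (lumen == 0)
        if zero_lumen.any():
            warnings.warn(
                f"{int(zero_lumen.sum())} slide(s) with zero lumen diameter; "
                "wall/lumen ratio set missing",
                stacklevel=2,
            )
        df["wall_lumen_ratio"] = np.where(zero_lumen, np.nan, wall / lumen)

    df["sub_g"] = _vector_score(df["gs_pct"].to_numpy(float), _GS_EDGES)
    df["sub_if"] = _vector_score(df["if_pct"].to_numpy(float), _IFTA_EDGES)
    df["sub_ta"] = _vector_score(df["ta_pct"].to_numpy(float), _IFTA_EDGES)
    df["sub_a"] = _vector_score(df["wall_lumen_ratio"].to_numpy(float), _ARTERY_EDGES)
    df["total_score"] = df["sub_g"] + df["sub_if"] + df["sub_ta"] + df["sub_a"]

    score = df["total_score"].to_numpy(float)
    decision = np.where(
        np.isnan(score),
        None,
        np.where(score <= 3, "single", np.where(score <= 6, "dual", "discard")),
    )
    df["decision"] = pd.array(decision, dtype="string")
    return df


def write_derived(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_derived(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("donor_id", "kidney_id", "biopsy_id", "technique", "stain", "decision"):
        if c in df.columns:
            df[c] = df[c].astype("string")
    return df
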