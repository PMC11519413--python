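"""Inter- vs intra-donor variance decomposition ("discriminating power").

With no functional outcome data available, inter-donor variability serves as
a proxy for graft-health signal: a morphometric variable is a useful health
indicator when most of its variance separates donors rather than repeats
within a donor.  The decomposition is the one-way sum-of-squares ratio
(eta squared): pct_inter = 100 * SS_between / SS_total with donors as
groups, and pct_intra its complement.  Vessel-related variables are
evaluated on PAS-stained slides only, mirroring clinical practice.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

#: variables measured on the worst artery / vessels: PAS slides only
PAS_ONLY_VARIABLES = frozenset(
    {
        "artery_count",
        "arteriole_count",
        "vessel_count",
        "artery_per_area",
        "arteriole_per_area",
        "vessel_per_area",
        "artery_wall_thickness",
        "artery_lumen_diameter",
        "artery_full_diameter",
        "wall_lumen_ratio",
        "sub_a",
    }
)

#: default variable list for the sensitivity table
DEFAULT_VARIABLES = [
    "cortex_area",
    "biopsy_depth",
    "biopsy_width",
    "glomeruli_total",
    "glomeruli_sclerotic",
    "healthy_glomeruli",
    "gs_pct",
    "glomeruli_per_area",
    "healthy_per_area",
    "sclerotic_per_area",
    "if_area",
    "ta_area",
    "if_pct",
    "ta_pct",
    "artery_count",
    "arteriole_count",
    "vessel_count",
    "artery_wall_thickness",
    "artery_lumen_diameter",
    "artery_full_diameter",
    "wall_lumen_ratio",
    "sub_g",
    "sub_if",
    "sub_ta",
    "sub_a",
    "total_score",
]


def variance_fraction(values, donor_labels) -> tuple[float, float]:
    """Percent of variance explained between vs within donors.

    Missing values are dropped (available-case).  Returns
    ``(pct_inter, pct_intra)`` summing to 100.  A constant variable has no
    variance to attribute: returns ``(nan, nan)`` with a warning.  Fewer
    than two donors is an error.
    """
    values = np.asarray(values, dtype=float)
    donor_labels = np.asarray(donor_labels)
    if values.shape != donor_labels.shape:
        raise DataError("values and donor_labels must have equal length")
    ok = ~np.isnan(values)
    values, donor_labels = values[ok], donor_labels[ok]
    groups = pd.Series(values).groupby(pd.Series(donor_labels), observed=True)
    if groups.ngroups < 2:
        raise DataError("variance decomposition needs >= 2 donors with data")
    grand = values.mean()
    ss_total = float(np.sum((values - grand) ** 2))
    if ss_total == 0.0:
        warnings.warn("all values identical; variance fraction undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    counts = groups.size().to_numpy()
    means = groups.mean().to_numpy()
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    pct_inter = 100.0 * ss_between / ss_total
    return (pct_inter, 100.0 - pct_inter)


def sensitivity_table(
    derived: pd.DataFrame,
    variables=None,
    unit: str = "slide",
    donor_col: str = "donor_id",
) -> pd.DataFrame:
    """Per-variable inter/intra-donor variance fractions, Table-3 style.

    Parameters
    ----------
    derived
        Output of :func:`nephrometry.derive.derive_variables`.
    variables
        Variable names to decompose; defaults to :data:`DEFAULT_VARIABLES`
        intersected with the available columns.
    unit
        ``"slide"`` (default) uses one observation per slide; ``"biopsy"``
        averages the stained sections of each biopsy first.
    """
    if derived.empty:
        raise DataError("derived table is empty")
    if unit not in ("slide", "biopsy"):
        raise ConfigError(f"unit must be 'slide' or 'biopsy', got {unit!r}")
    if variables is None:
        variables = [v for v in DEFAULT_VARIABLES if v in derived.columns]
    unknown = [v for v in variables if v not in derived.columns]
    if unknown:
        raise ConfigError(f"unknown variable name(s): {unknown}")

    rows = []
    for var in variables:
        pas_only = var in PAS_ONLY_VARIABLES
        sub = derived[derived["stain"] == "PAS"] if pas_only else derived
        if unit == "biopsy":
            sub = (
                sub.groupby(["donor_id", "biopsy_id"], observed=True)[var]
                .mean()
                .reset_index()
                .rename(columns={"donor_id": donor_col})
            )
        vals = sub[var].to_numpy(float)
        labels = sub[donor_col].to_numpy()
        n_used = int(np.sum(~np.isnan(vals)))
        pct_inter, pct_intra = variance_fraction(vals, labels)
        rows.append(
            {
                "variable": var,
                "pct_intra_donor": pct_intra,
                "pct_inter_donor": pct_inter,
                "n_used": n_used,
                "restricted_to_pas": pas_only,
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("pct_inter_donor", ascending=False, ignore_index=True)


def write_sensitivity(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
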