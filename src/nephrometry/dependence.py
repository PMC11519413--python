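"""Dependence of morphometric variables on biopsy processing.

Biopsy processing (retrieval technique, stain, medulla content) should not
change what a slide measures; this module tests whether it does.  Because
kidneys differ greatly from each other, raw values are first rank-normalized
*within each kidney* (midranks divided by the kidney's observation count),
so inter-kidney variability cannot mask a processing effect.  Pairs of
categorical variables use Pearson's chi-squared test; continuous-vs-
categorical pairs use the k-sample Anderson-Darling test in its tie-adjusted
(midrank) form, which tolerates the heavy ties that rank normalization
creates.  The battery's p-values are controlled with the Benjamini-Hochberg
step-up procedure at a false-discovery rate of 1.5% by default.

The Anderson-Darling statistic is computed here directly (it is also the
permutation engine's inner loop); the asymptotic p-value uses scipy's
interpolation of the published critical values.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from importlib import resources

import numpy as np
import pandas as pd
import scipy.stats
import yaml
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)

DEFAULT_FDR_Q = 0.015
DEFAULT_N_PERM = 9999

#: processing variables tested against the morphometric battery
PROCESSING_VARIABLES = ["technique", "stain", "medulla_present"]


# ---------------------------------------------------------------------------
# rank normalization
# ---------------------------------------------------------------------------

def rank_within_kidney(values, kidney_labels) -> np.ndarray:
    """Normalized midranks in (0, 1], computed separately per kidney.

    Within each kidney the non-missing values are ranked (ties receive the
    average of the adjacent ranks) and divided by that kidney's number of
    observations.  Missing values stay missing.
    """
    values = np.asarray(values, dtype=float)
    kidney_labels = np.asarray(kidney_labels)
    if values.shape != kidney_labels.shape:
        raise DataError("values and kidney_labels must have equal length")
    out = np.full(values.shape, np.nan)
    for kidney in pd.unique(kidney_labels):
        sel = (kidney_labels == kidney) & ~np.isnan(values)
        m = int(sel.sum())
        if m == 0:
            warnings.warn(f"kidney {kidney!r} has no observations; skipped", stacklevel=2)
            continue
        out[sel] = scipy.stats.rankdata(values[sel], method="average") / m
    return out


# ---------------------------------------------------------------------------
# chi-squared test for categorical pairs
# ---------------------------------------------------------------------------

def chi2_independence(counts, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a two-way table.

    Zero-margin rows/columns are dropped with a warning.  Yates' continuity
    correction is off by default.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2:
        raise DataError("contingency table must be two-dimensional")
    if (table < 0).any() or not np.allclose(table, np.rint(table)):
        raise DataError("contingency table must hold non-negative integers")
    rows = table.sum(axis=1) > 0
    cols = table.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        warnings.warn("dropping zero-margin rows/columns before chi-squared test",
                      stacklevel=2)
        table = table[rows][:, cols]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise DataError("contingency table needs >= 2 rows and >= 2 columns with data")
    stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# Anderson-Darling k-sample test (tie-adjusted A2akN, Scholz & Stephens 1987)
# ---------------------------------------------------------------------------

class _ADWorkspace:
    """Tie structure of a sample, shared by all label permutations."""

    def __init__(self, values: np.ndarray, sizes: np.ndarray):
        order = np.argsort(values, kind="stable")
        z = values[order]
        # value-class index per observation (in original order)
        is_new = np.empty(len(z), dtype=bool)
        is_new[0] = True
        is_new[1:] = z[1:] != z[:-1]
        class_sorted = np.cumsum(is_new) - 1
        self.vclass = np.empty(len(z), dtype=np.int64)
        self.vclass[order] = class_sorted
        self.L = int(class_sorted[-1]) + 1
        self.lj = np.bincount(class_sorted, minlength=self.L).astype(float)
        self.Bj = np.cumsum(self.lj)
        self.N = len(z)
        self.sizes = sizes.astype(float)
        self.k = len(sizes)
        Bbar = self.Bj - self.lj / 2.0
        denom = Bbar * (self.N - Bbar) - self.N * self.lj / 4.0
        self.Bbar = Bbar
        # denom is zero only when a single class spans the whole sample
        self.valid = denom > 0
        self.denom = np.where(self.valid, denom, 1.0)
        self.weight = np.where(self.valid, self.lj / self.N, 0.0)

    def a2akn(self, labels: np.ndarray) -> float:
        """Tie-adjusted statistic for one labelling (groups coded 0..k-1)."""
        f = np.zeros((self.k, self.L))
        np.add.at(f, (labels, self.vclass), 1.0)
        M = np.cumsum(f, axis=1) - f / 2.0
        num = (self.N * M - np.outer(self.sizes, self.Bbar)) ** 2
        inner = (self.weight * num / self.denom).sum(axis=1)
        return float((self.N - 1) / self.N * (inner / self.sizes).sum())

    def a2akn_batch(self, labels_matrix: np.ndarray) -> np.ndarray:
        """Statistic for many labellings at once; labels_matrix is (R, N)."""
        R = labels_matrix.shape[0]
        flat = labels_matrix * self.L + self.vclass[None, :]
        offsets = (np.arange(R) * (self.k * self.L))[:, None]
        counts = np.bincount(
            (flat + offsets).ravel(), minlength=R * self.k * self.L
        ).reshape(R, self.k, self.L).astype(float)
        M = np.cumsum(counts, axis=2) - counts / 2.0
        num = (self.N * M - self.sizes[None, :, None] * self.Bbar[None, None, :]) ** 2
        inner = (self.weight[None, None, :] * num / self.denom[None, None, :]).sum(axis=2)
        return (self.N - 1) / self.N * (inner / self.sizes[None, :]).sum(axis=1)


def _ad_null_sd(sizes: np.ndarray) -> float:
    """Null standard deviation of A2akN (exact finite-N formula)."""
    N = int(sizes.sum())
    k = len(sizes)
    H = float(np.sum(1.0 / sizes))
    i = np.arange(1, N)
    h = float(np.sum(1.0 / i))
    # g = sum_{i=1}^{N-2} sum_{j=i+1}^{N-1} 1/((N-i) j)
    inner = np.cumsum(1.0 / i[::-1])[::-1]  # inner[t] = sum_{j=t+1}^{N-1} 1/j at t=i
    g = float(np.sum((1.0 / (N - i[:-1])) * inner[1:]))
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    var = (a * N**3 + b * N**2 + c * N + d) / ((N - 1.0) * (N - 2.0) * (N - 3.0))
    return math.sqrt(var)


def _groups_to_codes(group_labels) -> tuple[np.ndarray, np.ndarray]:
    codes, uniques = pd.factorize(np.asarray(group_labels))
    sizes = np.bincount(codes, minlength=len(uniques))
    return codes.astype(np.int64), sizes


def ad_ksample(
    values,
    group_labels,
    method: str = "permutation",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> tuple[float, float]:
    """k-sample Anderson-Darling test (tie-adjusted, midrank version).

    Returns the standardized statistic ``(A2akN - (k-1)) / sigma_N`` and a
    p-value.  ``method``:

    - ``"permutation"`` (default): Monte-Carlo relabelling with a fixed
      seed; p = (1 + #{perm >= observed}) / (1 + n_perm).
    - ``"asymptotic"``: interpolation of the published critical values
      (via scipy); fast, but the p-value is clipped to [0.001, 0.25].
    - ``"exact"``: exhaustive enumeration of all distinct relabellings
      (small samples only); p = #{relabelling >= observed} / #relabellings.
    """
    values = np.asarray(values, dtype=float)
    codes, sizes = _groups_to_codes(group_labels)
    if values.shape != codes.shape:
        raise DataError("values and group_labels must have equal length")
    if np.isnan(values).any():
        raise DataError("ad_ksample requires non-missing values; drop NaNs first")
    if len(sizes) < 2 or (sizes == 0).any():
        raise DataError("ad_ksample needs >= 2 groups with >= 1 observation each")
    if np.all(values == values[0]):
        return 0.0, 1.0

    ws = _ADWorkspace(values, sizes)
    obs = ws.a2akn(codes)
    sd = _ad_null_sd(sizes)
    k = len(sizes)
    stat = (obs - (k - 1)) / sd

    if method == "asymptotic":
        samples = [values[codes == i] for i in range(k)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # scipy warns when p is clipped
            res = scipy.stats.anderson_ksamp(samples, midrank=True)
        return stat, float(res.pvalue)

    tol = 1e-9 * max(1.0, abs(obs))
    if method == "permutation":
        if n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        n_ge = 0
        block = max(1, min(n_perm, 2000))
        done = 0
        while done < n_perm:
            r = min(block, n_perm - done)
            perms = np.empty((r, ws.N), dtype=np.int64)
            for i in range(r):
                perms[i] = rng.permutation(codes)
            n_ge += int(np.sum(ws.a2akn_batch(perms) >= obs - tol))
            done += r
        return stat, (1 + n_ge) / (1 + n_perm)

    if method == "exact":
        total = math.factorial(ws.N)
        for n_i in sizes:
            total //= math.factorial(int(n_i))
        if total > 500_000:
            raise ConfigError(
                f"exact enumeration infeasible: {total} distinct relabellings"
            )
        n_ge = 0
        positions = list(range(ws.N))
        lab = np.empty(ws.N, dtype=np.int64)

        def _assign(remaining, group):
            nonlocal n_ge
            if group == k - 1:
                lab[remaining] = group
                if ws.a2akn(lab) >= obs - tol:
                    n_ge += 1
                return
            for combo in itertools.combinations(remaining, int(sizes[group])):
                lab[list(combo)] = group
                rest = [p for p in remaining if p not in combo]
                _assign(rest, group + 1)

        _assign(positions, 0)
        return stat, n_ge / total

    raise ConfigError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values, q: float = DEFAULT_FDR_Q) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise DataError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ConfigError("q must lie in (0, 1)")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def fdr_bound(m: int, k: int, p_max: float) -> float:
    """Plug-in bound m * p_max / k on the expected FDR when all k rejected
    p-values are at most ``p_max`` among m tests."""
    if k == 0:
        raise DataError("fdr_bound undefined for zero rejections")
    if not 1 <= k <= m:
        raise DataError("need 1 <= k <= m")
    if not 0 <= p_max <= 1:
        raise DataError("p_max must lie in [0, 1]")
    return m * p_max / k


# ---------------------------------------------------------------------------
# the battery
# ---------------------------------------------------------------------------

def default_pairs() -> list[dict]:
    """The shipped processing-vs-morphometry pair list (user-editable YAML)."""
    text = resources.files("nephrometry.data").joinpath("default_pairs.yaml").read_text()
    return load_pairs_config(text)


def load_pairs_config(text: str) -> list[dict]:
    cfg = yaml.safe_load(text)
    processing = cfg["processing_variables"]
    pairs = []
    for entry in cfg["morphometric_variables"]:
        name, vtype = entry["name"], entry.get("type", "continuous")
        if vtype not in ("continuous", "categorical"):
            raise ConfigError(f"variable {name!r}: unknown type {vtype!r}")
        for proc in processing:
            pairs.append(
                {"processing": proc, "morphometric": name, "morphometric_type": vtype}
            )
    return pairs


def run_dependence_battery(
    derived: pd.DataFrame,
    pairs: list[dict] | None = None,
    q: float = DEFAULT_FDR_Q,
    method: str = "permutation",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    kidney_col: str = "kidney_id",
) -> pd.DataFrame:
    """Run every processing-vs-morphometric test and apply BH at level ``q``.

    Continuous morphometric variables are rank-normalized per kidney before
    the Anderson-Darling test; categorical ones are cross-tabulated against
    the processing variable for a chi-squared test.  Missing values are
    dropped per pair; a pair with fewer than two observed processing groups
    is reported as untestable (p missing, never rejected).
    """
    if pairs is None:
        pairs = default_pairs()
    for pair in pairs:
        for col in (pair["processing"], pair["morphometric"]):
            if col not in derived.columns:
                raise ConfigError(f"pair references unknown column {col!r}")

    seeds = np.random.SeedSequence(seed).generate_state(len(pairs)) % (2**31)
    rows = []
    for i, pair in enumerate(pairs):
        proc, morpho = pair["processing"], pair["morphometric"]
        sub = derived[[proc, morpho, kidney_col]].dropna()
        groups = sub[proc].astype(str).to_numpy()
        untestable = len(pd.unique(groups)) < 2 or len(sub) < 3
        stat = p = float("nan")
        test = "ad_ksample" if pair["morphometric_type"] == "continuous" else "chi2"
        if not untestable:
            if test == "chi2":
                table = pd.crosstab(sub[proc], sub[morpho]).to_numpy()
                try:
                    stat, p = chi2_independence(table)
                except DataError:
                    untestable = True
            else:
                ranks = rank_within_kidney(
                    sub[morpho].to_numpy(float), sub[kidney_col].to_numpy()
                )
                stat, p = ad_ksample(
                    ranks, groups, method=method, n_perm=n_perm, seed=int(seeds[i])
                )
        rows.append(
            {
                "processing_variable": proc,
                "morphometric_variable": morpho,
                "test": test,
                "statistic": stat,
                "p_value": p,
                "untestable": untestable,
            }
        )
    out = pd.DataFrame(rows)
    out["rejected"] = False
    testable = ~out["untestable"]
    if testable.any():
        out.loc[testable, "rejected"] = bh_adjust(out.loc[testable, "p_value"], q)
    n_rej = int(out["rejected"].sum())
    logger.info("dependence battery: %d pairs, %d testable, %d rejected at q=%g",
                len(out), int(testable.sum()), n_rej, q)
    return out


def write_dependence(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
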