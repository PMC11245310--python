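"""Native-holdup mass-spectrometry depletion statistics.

A native holdup (nHU) experiment incubates bait-saturated resin with a dilute
total cell extract and quantifies, by label-free MS, how much of each
endogenous full-length protein is depleted from the supernatant relative to a
control resin. This module implements the proteomic stage: median
normalization of XIC intensity tables, imputation of missing values from the
low-intensity pool, per-protein equal-variance t-tests on log2 intensities,
conversion of depletion to binding intensity and apparent affinity, binder
calling, and cross-experiment / cross-bait comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .affinity import BaitConcentration, BindingIntensity, censor_affinity

__all__ = [
    "IntensityTable",
    "ExperimentComparison",
    "DEFAULT_P_CAP",
    "DEFAULT_BI_THRESHOLD",
    "normalize_median",
    "impute_missing",
    "test_depletion",
    "depletion_to_bi",
    "analyze_depletion",
    "call_significant",
    "compare_experiments",
    "interactome_similarity",
]

#: Raw p-value cap of the conjunctive significance gate.
DEFAULT_P_CAP = 0.05
#: BI detection gate of the conjunctive significance gate (Kd ~ 68 uM at 10 uM bait).
DEFAULT_BI_THRESHOLD = 0.128

_ROLES = ("bait", "control")

# smallest positive double; p-values that underflow are floored here so a
# zero-variance separation still yields a representable positive number
_TINY_P = np.nextafter(0.0, 1.0)


@dataclass
class IntensityTable:
    """Proteins x samples matrix of XIC-style intensities with missing values.

    ``values`` is indexed by unique protein ids with one column per sample;
    missing measurements are NaN. ``samples`` annotates each column with a
    role (``bait`` or ``control``) and a replicate index.
    """

    values: pd.DataFrame
    samples: pd.DataFrame  # columns: sample_id, role, replicate

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("protein ids must be unique")
        required = {"sample_id", "role", "replicate"}
        if not required.issubset(self.samples.columns):
            raise ValueError(f"sample sheet must have columns {sorted(required)}")
        bad = set(self.samples["role"]) - set(_ROLES)
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        for role in _ROLES:
            if not (self.samples["role"] == role).any():
                raise ValueError(f"need at least one {role} sample")
        sheet_ids = list(self.samples["sample_id"])
        if sorted(sheet_ids) != sorted(self.values.columns):
            raise ValueError("sample sheet ids do not match table columns")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0.0:
            raise ValueError("intensities must be nonnegative")

    def columns_for(self, role: str) -> list:
        return list(self.samples.loc[self.samples["role"] == role, "sample_id"])

    def copy(self) -> "IntensityTable":
        return IntensityTable(self.values.copy(), self.samples.copy())


def normalize_median(table: IntensityTable) -> IntensityTable:
    """Rescale each sample so its detected-value median equals the grand median.

    Corrects minor loading differences between injections. Missing entries
    are untouched; a sample with no detected values is an error.
    """
    values = table.values.copy()
    arr = values.to_numpy(dtype=float)
    detected = arr[~np.isnan(arr)]
    if detected.size == 0:
        raise ValueError("table has no detected values")
    grand = float(np.median(detected))
    for j, col in enumerate(values.columns):
        colvals = arr[:, j]
        colvals = colvals[~np.isnan(colvals)]
        if colvals.size == 0:
            raise ValueError(f"sample {col!r} has no detected values")
        med = float(np.median(colvals))
        if med <= 0:
            raise ValueError(f"sample {col!r} has nonpositive median intensity")
        values[col] = values[col] * (grand / med)
    return IntensityTable(values, table.samples.copy())


def impute_missing(
    table: IntensityTable,
    low_fraction: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> IntensityTable:
    """Replace missing entries with random draws from the low-intensity pool.

    The pool is the set of detected intensities at or below the
    ``low_fraction`` quantile of the *entire* dataset (not per sample),
    emulating the missing-not-at-random behaviour of label-free MS where
    low-abundance proteins drop below the detection limit. Detected cells
    are left bit-identical; output is deterministic given ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = table.values.copy()
    arr = values.to_numpy(dtype=float)
    mask = np.isnan(arr)
    detected = arr[~mask]
    if detected.size == 0:
        raise ValueError("cannot impute: no detected values")
    cutoff = float(np.quantile(detected, low_fraction))
    pool = detected[detected <= cutoff]
    if pool.size == 0:  # pathological quantile; fall back to the minimum
        pool = np.array([detected.min()])
    arr[mask] = rng.choice(pool, size=int(mask.sum()), replace=True)
    out = pd.DataFrame(arr, index=values.index, columns=values.columns)
    return IntensityTable(out, table.samples.copy())


def test_depletion(bait_values, control_values) -> tuple[float, float]:
    """Equal-variance two-sided t-test on log2 intensities.

    Returns ``(log2fc, pvalue)`` where log2fc = mean(log2 bait) -
    mean(log2 control). Degenerate cases: identical groups with zero pooled
    variance give p = 1; zero pooled variance with distinct means gives the
    smallest positive double rather than 0.
    """
    b = np.asarray(bait_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if b.size < 2 or c.size < 2:
        raise ValueError("need at least two values per group")
    if np.any(b <= 0) or np.any(c <= 0):
        raise ValueError("intensities must be positive for log2 transform")
    lb, lc = np.log2(b), np.log2(c)
    log2fc = float(lb.mean() - lc.mean())
    if lb.var(ddof=1) == 0.0 and lc.var(ddof=1) == 0.0:
        return log2fc, 1.0 if log2fc == 0.0 else _TINY_P
    t, p = stats.ttest_ind(lb, lc, equal_var=True)
    p = float(p)
    if p <= 0.0:
        p = _TINY_P
    return log2fc, p


def depletion_to_bi(log2fc: float) -> BindingIntensity:
    """BI = 1 - 2^log2fc, clamped (and flagged) at 0 for enrichment."""
    raw = 1.0 - 2.0**log2fc
    return BindingIntensity.from_raw(raw)


def analyze_depletion(
    table: IntensityTable,
    bait: BaitConcentration,
    p_cap: float = DEFAULT_P_CAP,
    bi_threshold: float = DEFAULT_BI_THRESHOLD,
    low_fraction: float = 0.10,
    seed: int = 0,
    normalize: bool = True,
) -> pd.DataFrame:
    """Full per-protein depletion pipeline on one intensity table.

    Median-normalizes, imputes missing values, tests depletion per protein,
    converts to BI and censored apparent affinity, and applies the
    conjunctive (p, BI) significance gate. Returns a DataFrame with columns
    ``log2fc, pvalue, bi, pk, censored, significant`` indexed by protein id;
    the thresholds used are recorded in ``DataFrame.attrs``.
    """
    if normalize:
        table = normalize_median(table)
    table = impute_missing(table, low_fraction=low_fraction, seed=seed)
    bait_cols = table.columns_for("bait")
    ctrl_cols = table.columns_for("control")
    rows = []
    for pid, row in table.values.iterrows():
        log2fc, p = test_depletion(row[bait_cols].to_numpy(), row[ctrl_cols].to_numpy())
        bi = depletion_to_bi(log2fc)
        aff = censor_affinity(bi, bi_threshold, bait)
        rows.append((pid, log2fc, p, bi.bi, aff.pk, aff.censored))
    out = pd.DataFrame(
        rows, columns=["protein_id", "log2fc", "pvalue", "bi", "pk", "censored"]
    ).set_index("protein_id")
    out.attrs["bait_conc_molar"] = bait.conc
    return call_significant(out, p_cap=p_cap, bi_threshold=bi_threshold)


def call_significant(
    results: pd.DataFrame,
    p_cap: float = DEFAULT_P_CAP,
    bi_threshold: float = DEFAULT_BI_THRESHOLD,
) -> pd.DataFrame:
    """Conjunctive significance gate: p <= p_cap AND BI >= bi_threshold."""
    out = results.copy()
    out.attrs.update(results.attrs)
    out["significant"] = (out["pvalue"] <= p_cap) & (out["bi"] >= bi_threshold)
    out.attrs["p_cap"] = p_cap
    out.attrs["bi_threshold"] = bi_threshold
    return out


@dataclass
class ExperimentComparison:
    """Cross-experiment recall and affinity-correlation summary."""

    recall_ab: float
    recall_ba: float
    pcc: float
    fit_slope: float
    fit_intercept: float
    correlation_pvalue: float
    n_shared_significant: int
    correlation_defined: bool
    # pointwise 95% confidence band of the OLS fit, evaluated on a pk grid
    band_x: np.ndarray = field(default_factory=lambda: np.empty(0))
    band_lower: np.ndarray = field(default_factory=lambda: np.empty(0))
    band_upper: np.ndarray = field(default_factory=lambda: np.empty(0))


def _recall(
    frm: pd.DataFrame,
    to: pd.DataFrame,
    bi_threshold: float,
    recovered: str,
) -> float:
    """Fraction of ``frm``'s significant set recovered in ``to``.

    ``recovered='depleted'`` also counts sub-significant partners whose
    depletion in ``to`` clears the BI threshold, treating their measured
    depletion as true; ``'significant'`` requires the gate in both.
    """
    shared = frm.index.intersection(to.index)
    sig = frm.loc[shared]
    sig = sig[sig["significant"]]
    if len(sig) == 0:
        return math.nan
    other = to.loc[sig.index]
    if recovered == "depleted":
        hit = other["significant"] | (other["bi"] >= bi_threshold)
    elif recovered == "significant":
        hit = other["significant"]
    else:
        raise ValueError(f"unknown recovered mode {recovered!r}")
    return float(hit.mean())


def _pearson_with_fit(x: np.ndarray, y: np.ndarray):
    """Pearson r with its t-based two-sided p, OLS fit and 95% band."""
    import statsmodels.api as sm

    n = x.size
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0:
        p = 0.0 if n > 2 else 1.0
    else:
        t = r * math.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    grid = np.linspace(x.min(), x.max(), 50)
    pred = fit.get_prediction(sm.add_constant(grid)).conf_int(alpha=0.05)
    return r, float(p), float(fit.params[1]), float(fit.params[0]), grid, pred


def compare_experiments(
    a: pd.DataFrame,
    b: pd.DataFrame,
    bi_threshold: float = DEFAULT_BI_THRESHOLD,
    recovered: str = "depleted",
) -> ExperimentComparison:
    """Recall in both directions plus affinity correlation over shared binders.

    The correlation uses apparent pK of partners significant in *both*
    experiments, with an OLS linear fit, a pointwise 95% confidence band and
    a two-sided t-test on the correlation coefficient. Fewer than 3 shared
    significant partners leaves the correlation undefined (flagged).
    """
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("experiments share no protein ids")
    recall_ab = _recall(a, b, bi_threshold, recovered)
    recall_ba = _recall(b, a, bi_threshold, recovered)
    both = shared[(a.loc[shared, "significant"]) & (b.loc[shared, "significant"])]
    if len(both) < 3:
        return ExperimentComparison(
            recall_ab, recall_ba, math.nan, math.nan, math.nan, math.nan,
            len(both), correlation_defined=False,
        )
    x = a.loc[both, "pk"].to_numpy(dtype=float)
    y = b.loc[both, "pk"].to_numpy(dtype=float)
    r, p, slope, intercept, grid, band = _pearson_with_fit(x, y)
    return ExperimentComparison(
        recall_ab, recall_ba, r, slope, intercept, p, len(both),
        correlation_defined=True,
        band_x=grid, band_lower=band[:, 0], band_upper=band[:, 1],
    )


def interactome_similarity(profiles: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Pearson correlation of apparent pK over shared binders.

    ``profiles`` maps bait id -> depletion results (as from
    :func:`analyze_depletion`). Returns a long-form DataFrame with one row
    per ordered pair carrying ``pcc``, ``n`` and ``pvalue``; pairs with
    fewer than 3 shared significant partners are flagged undefined
    (NaN pcc). The implied matrix is symmetric with unit diagonal.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two baits")
    baits = list(profiles)
    rows = []
    for i, bi_ in enumerate(baits):
        for j, bj in enumerate(baits):
            if i == j:
                rows.append((bi_, bj, 1.0, int(profiles[bi_]["significant"].sum()), 0.0, True))
                continue
            a, b = profiles[bi_], profiles[bj]
            shared = a.index.intersection(b.index)
            both = shared[a.loc[shared, "significant"] & b.loc[shared, "significant"]]
            n = len(both)
            if n < 3:
                rows.append((bi_, bj, math.nan, n, math.nan, False))
                continue
            x = a.loc[both, "pk"].to_numpy(dtype=float)
            y = b.loc[both, "pk"].to_numpy(dtype=float)
            if np.std(x) == 0.0 or np.std(y) == 0.0:
                rows.append((bi_, bj, math.nan, n, math.nan, False))
                continue
            r, p, *_ = _pearson_with_fit(x, y)
            rows.append((bi_, bj, r, n, p, True))
    return pd.DataFrame(
        rows, columns=["bait_a", "bait_b", "pcc", "n", "pvalue", "defined"]
    )
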