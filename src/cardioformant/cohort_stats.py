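"""Group comparison statistics: pooled t-tests, Holm-Bonferroni correction,
site/formant ranking, window-length sweeps, and the sample-size calculation.

Feature tables are tidy pandas DataFrames with columns
``subject_id, group, site, formant, window_length_s, value`` (a subset of the
columns is accepted where the operation fixes the remaining cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import MissingCellError, ParameterError
from .pcg_io import SITES

PAH_MPAP_THRESHOLD = 25.0
PAH_PAWP_THRESHOLD = 15.0


def label_group(mPAp: float, PAWp: float) -> str | None:
    """Pure grouping rule: PAH iff mPAp >= 25 and PAWp <= 15; normal iff mPAp < 25.

    Subjects with an elevated wedge pressure fall outside both printed
    definitions and return None (callers exclude them with a warning).
    """
    if PAWp > PAH_PAWP_THRESHOLD:
        return None
    return "PAH" if mPAp >= PAH_MPAP_THRESHOLD else "normal"


def assign_groups(metadata: pd.DataFrame) -> pd.DataFrame:
    """Add a ``group`` column from (mPAp_mmHg, PAWp_mmHg); drop unlabeled rows."""
    out = metadata.copy()
    out["group"] = [
        label_group(m, w) for m, w in zip(out["mPAp_mmHg"], out["PAWp_mmHg"])
    ]
    dropped = out["group"].isna()
    if dropped.any():
        warnings.warn(
            f"excluding {sorted(out.loc[dropped, 'subject_id'].unique())}: "
            "wedge pressure > 15 mmHg falls outside both group definitions",
            stacklevel=2,
        )
    return out[~dropped].reset_index(drop=True)


@dataclass
class TestResult:
    """One two-sample comparison for a (site, formant, window length) cell."""

    site: str
    formant: int
    window_length: float
    t: float
    df: float
    p_raw: float
    p_corrected: float | None = None


def _validate_group(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ParameterError(f"group {name!r} needs >= 2 values, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ParameterError(f"group {name!r} contains non-finite values")
    return values


def two_sample_ttest(xs, ys) -> tuple[float, float, float]:
    """Pooled-variance (Student's) two-sided two-sample t-test.

    Returns (t, df, p) with df = n1 + n2 - 2.
    """
    xs = _validate_group(xs, "x")
    ys = _validate_group(ys, "y")
    if np.var(xs, ddof=1) + np.var(ys, ddof=1) == 0.0:
        raise ParameterError("both groups have zero variance; t-test is undefined")
    res = stats.ttest_ind(xs, ys, equal_var=True)
    return float(res.statistic), float(xs.size + ys.size - 2), float(res.pvalue)


def ttest_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float, float]:
    """Pooled-variance two-sided t-test from summary statistics only."""
    if n1 < 2 or n2 < 2:
        raise ParameterError("each group needs n >= 2")
    if s1 < 0 or s2 < 0:
        raise ParameterError("standard deviations must be >= 0")
    if s1 == 0 and s2 == 0:
        raise ParameterError("zero pooled variance; t-test is undefined")
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(res.statistic), float(n1 + n2 - 2), float(res.pvalue)


def holm_bonferroni(p_raw) -> np.ndarray:
    """Holm's step-down adjusted p-values, returned in the input order.

    Sort ascending, multiply the i-th smallest by (m - i), take the running
    maximum, cap at 1.
    """
    p = np.asarray(p_raw, dtype=np.float64)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("p_raw must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def rank_sites_formants(
    features: pd.DataFrame, alpha: float = 0.05, correct: bool = True
) -> list[TestResult]:
    """Test PAH vs normal means in every (site, formant) cell; rank by p.

    ``features`` must contain one value per subject for each of the 16 cells
    (columns: subject_id, group, site, formant, value, and optionally
    window_length_s).  Returns the 16 results sorted ascending by raw p-value;
    the first element is the selected (site, formant).
    """
    required = {"subject_id", "group", "site", "formant", "value"}
    missing_cols = required - set(features.columns)
    if missing_cols:
        raise ParameterError(f"feature table is missing columns: {sorted(missing_cols)}")
    cells = [(site, f) for site in SITES for f in (1, 2, 3, 4)]
    missing = [
        c
        for c in cells
        if features[(features["site"] == c[0]) & (features["formant"] == c[1])].empty
    ]
    if missing:
        raise MissingCellError(f"feature table lacks cells: {missing}")
    L = float(features["window_length_s"].iloc[0]) if "window_length_s" in features else np.nan
    results = []
    for site, f in cells:
        cell = features[(features["site"] == site) & (features["formant"] == f)]
        pah = cell.loc[cell["group"] == "PAH", "value"].to_numpy()
        normal = cell.loc[cell["group"] == "normal", "value"].to_numpy()
        t, df, p = two_sample_ttest(pah, normal)
        results.append(TestResult(site=site, formant=f, window_length=L, t=t, df=df, p_raw=p))
    if correct:
        corrected = holm_bonferroni([r.p_raw for r in results])
        for r, pc in zip(results, corrected):
            r.p_corrected = float(pc)
    results.sort(key=lambda r: r.p_raw)
    return results


def sweep_window_lengths(features: pd.DataFrame) -> list[TestResult]:
    """Test PAH vs normal at every window length; Holm-correct across lengths.

    ``features`` holds one (site, formant) cell with columns subject_id,
    group, window_length_s, value.  Returns one TestResult per length, in
    ascending length order, with ``p_corrected`` filled; the optimum is the
    length minimizing the corrected p-value (see :func:`optimal_window`).
    """
    required = {"subject_id", "group", "window_length_s", "value"}
    missing_cols = required - set(features.columns)
    if missing_cols:
        raise ParameterError(f"feature table is missing columns: {sorted(missing_cols)}")
    site = str(features["site"].iloc[0]) if "site" in features else "unknown"
    formant = int(features["formant"].iloc[0]) if "formant" in features else 0
    results = []
    for L in sorted(features["window_length_s"].unique()):
        cell = features[features["window_length_s"] == L]
        pah = cell.loc[cell["group"] == "PAH", "value"].to_numpy()
        normal = cell.loc[cell["group"] == "normal", "value"].to_numpy()
        t, df, p = two_sample_ttest(pah, normal)
        results.append(
            TestResult(site=site, formant=formant, window_length=float(L), t=t, df=df, p_raw=p)
        )
    corrected = holm_bonferroni([r.p_raw for r in results])
    for r, pc in zip(results, corrected):
        r.p_corrected = float(pc)
    return results


def optimal_window(results: list[TestResult]) -> TestResult:
    """The sweep result with the smallest corrected p (ties: smallest raw p)."""
    if not results:
        raise ParameterError("empty sweep")
    return min(results, key=lambda r: (r.p_corrected, r.p_raw))


@dataclass
class PowerSpec:
    """Inputs and outputs of the post-hoc sample-size calculation."""

    mean_null: float
    mean_alt: float
    sd_null: float
    alpha: float = 0.05
    power: float = 0.90
    n_required: int | None = None


def required_sample_size(
    mean_null: float,
    mean_alt: float,
    sd_null: float,
    alpha: float = 0.05,
    power: float = 0.90,
    method: str = "normal",
) -> int:
    """Per-group n for a two-sided two-sample comparison at the given power.

    ``method="normal"`` uses n = 2 (z_{1-a/2} + z_power)^2 sigma^2 / delta^2
    with ceiling rounding (floored at 2).  ``method="noncentral_t"`` inverts
    the noncentral-t power function instead (typically one subject larger).
    The alternative group's sd is taken equal to ``sd_null``.
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ParameterError("alpha and power must lie in (0, 1)")
    if sd_null <= 0:
        raise ParameterError("sd_null must be > 0")
    delta = abs(mean_alt - mean_null)
    if delta == 0:
        raise ParameterError("zero effect size implies an infinite sample size")
    if method == "normal":
        z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
        n = 2.0 * (z * sd_null / delta) ** 2
        return max(int(np.ceil(n - 1e-12)), 2)
    if method == "noncentral_t":
        for n in range(2, 1_000_000):
            if _nct_power(n, delta / sd_null, alpha) >= power:
                return n
        raise ParameterError("sample size exceeds the search limit")
    raise ParameterError(f"unknown method {method!r}")


def _nct_power(n: int, effect: float, alpha: float) -> float:
    """Exact two-sided power of the pooled t-test at per-group size n."""
    df = 2 * n - 2
    nc = effect * np.sqrt(n / 2.0)
    crit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(crit, df, nc) + stats.nct.cdf(-crit, df, nc))
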