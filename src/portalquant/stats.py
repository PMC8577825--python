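"""Census, ratio, efficiency and hypothesis-test statistics.

These are the figure-level summaries computed from pipeline tables (or any
user CSV of counts): the per-field census of ductal (DC) and mesenchymal
(Msc) cells with the Msc:DC ratio and contacted percentage, organoid
formation efficiency, fold-change normalization to a monoculture reference,
Tukey box summaries (median, quartiles, 1.5·IQR whiskers, explicit
outliers) and a Mann-Whitney U test with an exact small-sample null.

Conventions: quartiles use linear interpolation between order statistics;
an undefined ratio (no DCs in the field) propagates as NaN, never as 0 or
infinity; all tests are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError

EXACT_MW_LIMIT = 24  # enumeration cap: C(24,12) ≈ 2.7e6 assignments


# ---------------------------------------------------------------------------
# census and simple ratios


@dataclass
class FOVCensus:
    """Per-field counts of ductal and mesenchymal cells."""

    fov_id: str
    n_dc: int
    n_msc_sca1_pos: int
    n_msc_sca1_neg: int
    ratio_msc_dc: float          # NaN when n_dc == 0
    pct_contacted: float         # NaN when n_dc == 0

    def to_row(self) -> dict:
        return vars(self).copy()


def fov_census(objects: pd.DataFrame, fov_id: str = "fov0") -> FOVCensus:
    """Census from a per-object table.

    ``objects`` needs columns ``obj_class`` ('dc' or 'msc'), boolean/int
    ``sca1``, and boolean/int ``contacted`` (meaningful for DC rows).  The
    Msc:DC ratio counts SCA1+ mesenchymal cells relative to DCs and is NaN
    (undefined, excluded from group summaries) when the field has no DCs.
    """
    dc = objects[objects.obj_class == "dc"]
    msc = objects[objects.obj_class == "msc"]
    n_dc = len(dc)
    n_pos = int(msc.sca1.astype(bool).sum())
    n_neg = len(msc) - n_pos
    if n_dc > 0:
        ratio = n_pos / n_dc
        pct = 100.0 * float(dc.contacted.astype(bool).mean())
    else:
        ratio = float("nan")
        pct = float("nan")
    return FOVCensus(fov_id, n_dc, n_pos, n_neg, ratio, pct)


def organoid_formation_efficiency(n_organoids: int, n_seeded: int) -> float:
    """Percent of seeded epithelial cells that formed a cystic organoid."""
    if n_seeded <= 0:
        raise ConfigError("n_seeded must be positive")
    if n_organoids < 0:
        raise ConfigError("n_organoids must be non-negative")
    return 100.0 * n_organoids / n_seeded


def normalize_to_reference(value: float, reference: float) -> float:
    """Fold-change relative to a (positive) monoculture reference."""
    if reference <= 0:
        raise ConfigError("reference must be positive for fold-change normalization")
    return value / reference


def positive_fraction(n_pos: int, n_total: int) -> float:
    """Percent positive (e.g. EdU+ DCs among all DCs)."""
    if n_total <= 0:
        raise ConfigError("n_total must be positive")
    if not 0 <= n_pos <= n_total:
        raise ConfigError("n_pos must be within [0, n_total]")
    return 100.0 * n_pos / n_total


# ---------------------------------------------------------------------------
# Tukey box summary


@dataclass
class TukeySummary:
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: list

    def to_row(self) -> dict:
        d = vars(self).copy()
        d["n_outliers"] = len(d.pop("outliers"))
        return d


def tukey_summary(x) -> TukeySummary:
    """Median, quartiles, 1.5·IQR whiskers and explicit outliers.

    Whiskers are the most extreme data points inside
    ``[q1 − 1.5·IQR, q3 + 1.5·IQR]``; points outside are listed as outliers.
    """
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ConfigError("tukey_summary requires at least one value")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = sorted(arr[(arr < lo_fence) | (arr > hi_fence)].tolist())
    return TukeySummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass
class TestResult:
    statistic: float     # U of the first sample
    n1: int
    n2: int
    p_two_sided: float
    method: str


def _midranks(values: np.ndarray) -> np.ndarray:
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values), dtype=float)
    sv = values[order]
    i = 0
    while i < len(sv):
        j = i
        while j + 1 < len(sv) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _u_statistic(ranks: np.ndarray, idx1, n1: int) -> float:
    return float(ranks[idx1].sum()) - n1 * (n1 + 1) / 2.0


def mann_whitney_u(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode='auto'`` uses the exact permutation null when ``n1 + n2 <= 20``
    and the data are tie-free, otherwise a tie-corrected normal
    approximation with continuity correction.  ``mode='exact'`` forces full
    enumeration of rank assignments (valid with ties; capped at
    ``n1 + n2 <= 24``); ``mode='approx'`` forces the normal approximation.
    The exact two-sided p-value is the null probability of a U at least as
    far from n1·n2/2 as observed.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ConfigError("both samples must be non-empty")
    if mode not in ("auto", "exact", "approx"):
        raise ConfigError(f"unknown mode {mode!r}")
    combined = np.concatenate([x, y])
    ranks = _midranks(combined)
    u1 = _u_statistic(ranks, np.arange(n1), n1)
    has_ties = len(np.unique(combined)) < n1 + n2

    if mode == "exact" or (mode == "auto" and n1 + n2 <= 20 and not has_ties):
        if n1 + n2 > EXACT_MW_LIMIT:
            raise ConfigError(
                f"exact enumeration limited to n1+n2 <= {EXACT_MW_LIMIT}"
            )
        p = _exact_two_sided_p(ranks, n1, n2, u1)
        return TestResult(u1, n1, n2, p, "exact")
    p = _approx_two_sided_p(ranks, n1, n2, u1)
    return TestResult(u1, n1, n2, p, "normal-approx, tie-corrected")


def _exact_two_sided_p(ranks: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    n = n1 + n2
    center = n1 * n2 / 2.0
    dev = abs(u_obs - center) - 1e-12
    combos = np.fromiter(
        itertools.chain.from_iterable(itertools.combinations(range(n), n1)),
        dtype=np.intp,
    ).reshape(-1, n1)
    u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2.0
    extreme = np.abs(u_all - center) >= dev
    return float(extreme.mean())


def _approx_two_sided_p(ranks: np.ndarray, n1: int, n2: int, u_obs: float) -> float:
    n = n1 + n2
    mu = n1 * n2 / 2.0
    # tie correction on the rank variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    sigma_sq = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if sigma_sq <= 0:
        return 1.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(sigma_sq)
    z = max(z, 0.0)
    p = math.erfc(z / math.sqrt(2.0))
    return float(min(p, 1.0))


def welch_t_test(x, y) -> TestResult:
    """Welch's unequal-variance t test (two-sided); thin convenience wrapper."""
    from scipy import stats as sps

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigError("welch_t_test needs >= 2 observations per group")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TestResult(float(res.statistic), len(x), len(y), float(res.pvalue), "welch-t")
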