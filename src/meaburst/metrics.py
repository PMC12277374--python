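"""Per-period activity statistics and stimulation-change metrics.

Covers firing rates per period, the bounded normalized rate change
(b - a)/(b + a), cluster presence patterns, burst-frequency fold changes,
per-burst collective activity strength, binned pairwise Pearson
synchrony, and paired Wilcoxon signed-rank comparisons with optional
Bonferroni correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Burst, PERIOD_NAMES, Periods, WaveformCluster


@dataclass(frozen=True)
class SummaryStat:
    """Mean +/- sample standard deviation (ddof = 1) of a value set."""

    mean: float
    sd: float
    n: int

    @classmethod
    def of(cls, values: Sequence[float]) -> "SummaryStat":
        v = np.asarray(values, dtype=np.float64)
        sd = float(np.std(v, ddof=1)) if len(v) >= 2 else float("nan")
        return cls(mean=float(np.mean(v)), sd=sd, n=len(v))

    def __str__(self) -> str:
        return f"{self.mean:.3g} ± {self.sd:.3g} (n={self.n})"


def rates_by_period(cluster_times: Mapping[int, np.ndarray],
                    periods: Periods) -> pd.DataFrame:
    """Spike counts and firing rates (count / period duration, Hz) per
    cluster per period."""
    rows = []
    for cid in sorted(cluster_times):
        t = np.asarray(cluster_times[cid])
        row = {"cluster_id": cid}
        for name in PERIOD_NAMES:
            dur = periods.duration(name)
            if dur <= 0:
                raise ValueError("zero-duration period")
            n = int(periods.mask(t, name).sum())
            row[f"n_{name}"] = n
            row[f"rate_{name}"] = n / dur
        rows.append(row)
    cols = ["cluster_id"] + [f"n_{p}" for p in PERIOD_NAMES] \
        + [f"rate_{p}" for p in PERIOD_NAMES]
    return pd.DataFrame(rows, columns=cols)


def normalized_change(rate_a, rate_b):
    """Bounded rate-change score (b - a) / (b + a) in [-1, 1].

    ``a`` is the baseline (pre-stimulation) rate. Newly active clusters
    (a = 0, b > 0) score exactly 1, unchanged clusters 0, silenced ones
    -1; both rates zero is undefined (NaN, excluded from histograms).
    Antisymmetric under swapping the two rates.
    """
    a = np.asarray(rate_a, dtype=np.float64)
    b = np.asarray(rate_b, dtype=np.float64)
    if np.any(a < 0) or np.any(b < 0):
        raise ValueError("rates must be >= 0")
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(tot > 0, (b - a) / np.where(tot > 0, tot, 1.0),
                       np.nan)
    return out if out.ndim else float(out)


def change_scores(rates: pd.DataFrame) -> pd.DataFrame:
    """Normalized in-vs-pre and post-vs-pre change per cluster."""
    out = rates[["cluster_id"]].copy()
    out["delta_in"] = normalized_change(rates["rate_pre"], rates["rate_in"])
    out["delta_post"] = normalized_change(rates["rate_pre"], rates["rate_post"])
    return out


def presence_pattern(counts: Sequence[int]) -> tuple[int, int, int]:
    return tuple(int(c > 0) for c in counts)


def presence_distribution(cluster_times: Mapping[int, np.ndarray],
                          periods: Periods) -> Dict[tuple, float]:
    """Fraction of clusters per presence pattern (pre, in, post).

    A cluster is present in a period if it has at least one spike there;
    the 2^3 - 1 nonempty patterns partition the clusters, so the returned
    fractions sum to 1.
    """
    if not cluster_times:
        return {}
    rates = rates_by_period(cluster_times, periods)
    pats = [presence_pattern(row) for row in
            rates[[f"n_{p}" for p in PERIOD_NAMES]].to_numpy()]
    n = len(pats)
    out: Dict[tuple, float] = {}
    for p in pats:
        if p == (0, 0, 0):
            raise ValueError("cluster with no spikes in any period")
        out[p] = out.get(p, 0.0) + 1.0 / n
    return out


def fraction_not_present_before(dist: Mapping[tuple, float]) -> float:
    return sum(f for p, f in dist.items() if p[0] == 0)


def fraction_all_periods(dist: Mapping[tuple, float]) -> float:
    return dist.get((1, 1, 1), 0.0)


@dataclass(frozen=True)
class BurstFrequencyChange:
    rate_pre: float      # bursts / min
    rate_in: float
    rate_post: float
    fold_in: float       # inf (flagged) when the pre rate is zero
    fold_post: float
    pre_rate_zero: bool


def burst_frequency_change(bursts: Sequence[Burst], periods: Periods
                           ) -> BurstFrequencyChange:
    """Burst rate per minute per period and in/pre, post/pre fold changes.

    A zero pre-stimulation burst rate makes the folds infinite; they are
    reported as ``inf`` with ``pre_rate_zero`` set rather than dropped,
    since control sessions may genuinely lack baseline bursts.
    """
    onsets = np.array([b.onset for b in bursts])
    rates = {}
    for name in PERIOD_NAMES:
        rates[name] = periods.mask(onsets, name).sum() / periods.duration(name) * 60.0
    zero = rates["pre"] == 0
    fold = (lambda r: math.inf if zero else r / rates["pre"])
    return BurstFrequencyChange(rate_pre=rates["pre"], rate_in=rates["in"],
                                rate_post=rates["post"],
                                fold_in=fold(rates["in"]),
                                fold_post=fold(rates["post"]),
                                pre_rate_zero=bool(zero))


def collective_activity_strength(bursts: Sequence[Burst], n_clusters: int,
                                 periods: Periods) -> Dict[str, float]:
    """Mean per-burst participation percentage per period.

    Each burst contributes 100 * (participating clusters / retained
    clusters); periods without bursts are NaN (undefined, excluded).
    """
    if n_clusters <= 0:
        raise ValueError("n_clusters must be > 0")
    per_burst: Dict[str, list] = {p: [] for p in PERIOD_NAMES}
    for b in bursts:
        per_burst[periods.which(b.onset)].append(
            100.0 * len(b.participants) / n_clusters)
    return {p: (float(np.mean(v)) if v else float("nan"))
            for p, v in per_burst.items()}


@dataclass(frozen=True)
class SynchronyReport:
    bin_width: float
    mean_r: Dict[str, float]          # mean pairwise Pearson r per period
    n_pairs: Dict[str, int]
    ratio_in_pre: float               # % of the pre-period mean r
    ratio_post_pre: float


def binned_counts(times: np.ndarray, span: tuple[float, float],
                  bin_width: float) -> np.ndarray:
    a, b = span
    edges = np.arange(a, b + bin_width * 0.5, bin_width)
    if edges[-1] < b:
        edges = np.append(edges, b)
    return np.histogram(np.asarray(times), bins=edges)[0]


def pairwise_synchrony(cluster_times: Mapping[int, np.ndarray],
                       periods: Periods, bin_width: float = 0.100
                       ) -> SynchronyReport:
    """Binned pairwise Pearson synchrony per period.

    Spike trains are binned per period (default 100 ms, the burst-window
    scale); Pearson r is computed for every pair of clusters with nonzero
    count variance, averaged per period, and the stimulation/post means
    are expressed as percentages of the pre-stimulation mean.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mean_r: Dict[str, float] = {}
    n_pairs: Dict[str, int] = {}
    for name in PERIOD_NAMES:
        span = periods.span(name)
        mat = np.array([binned_counts(t, span, bin_width)
                        for _, t in sorted(cluster_times.items())])
        valid = mat[mat.std(axis=1) > 0]
        if len(valid) < 2:
            mean_r[name], n_pairs[name] = float("nan"), 0
            continue
        r = np.corrcoef(valid)
        iu = np.triu_indices(len(valid), k=1)
        mean_r[name] = float(np.mean(r[iu]))
        n_pairs[name] = len(iu[0])

    def ratio(x, base):
        return float("nan") if (not np.isfinite(base) or base == 0) \
            else 100.0 * x / base

    return SynchronyReport(bin_width=bin_width, mean_r=mean_r,
                           n_pairs=n_pairs,
                           ratio_in_pre=ratio(mean_r["in"], mean_r["pre"]),
                           ratio_post_pre=ratio(mean_r["post"], mean_r["pre"]))


@dataclass(frozen=True)
class PairedTestResult:
    p_raw: float
    p_corrected: float
    n: int
    n_nonzero: int
    statistic: float
    undefined: bool
    method: str


def compare_conditions(before: Sequence[float], after: Sequence[float],
                       correction: str = "none", n_comparisons: int = 1
                       ) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded (standard signed-rank convention); the
    exact permutation null is used for fewer than 20 nonzero pairs, the
    tie-corrected normal approximation otherwise. ``correction``
    "bonferroni" multiplies p by ``n_comparisons`` (capped at 1).
    """
    x = np.asarray(before, dtype=np.float64)
    y = np.asarray(after, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-D vectors")
    if len(x) < 5:
        raise ValueError("need at least 5 pairs")
    if correction not in ("none", "bonferroni"):
        raise ValueError("correction must be 'none' or 'bonferroni'")
    d = y - x
    nz = int(np.count_nonzero(d))
    if nz == 0:
        return PairedTestResult(p_raw=float("nan"), p_corrected=float("nan"),
                                n=len(x), n_nonzero=0, statistic=float("nan"),
                                undefined=True, method="none")
    method = "exact" if nz < 20 else "approx"
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                         method=method)
    p = float(res.pvalue)
    p_corr = p
    if correction == "bonferroni":
        p_corr = min(1.0, p * n_comparisons)
    return PairedTestResult(p_raw=p, p_corrected=p_corr, n=len(x),
                            n_nonzero=nz, statistic=float(res.statistic),
                            undefined=False, method=method)
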