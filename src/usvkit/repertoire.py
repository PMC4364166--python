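"""Call-repertoire density grids and sequential (lagged-duration) analysis.

The repertoire view bins every call into a 2-D histogram over call duration
and frequency modulation ("density plot"), each cell expressed as a
percentage of all calls, which makes call clusters visible and comparable
across groups.  The sequential view asks whether call emission order is
random: within each subject, call durations are correlated with the
durations one, two and three calls back (N-1, N-2, N-3), and the resulting
per-subject Pearson coefficients are tested against chance at the group
level.  Subjects contribute only if they emitted more than three calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DensityGrid",
    "density_grid",
    "lagged_duration_correlations",
    "group_sequential_test",
    "SequentialResult",
    "sequential_analysis",
    "MIN_CALLS_FOR_SEQUENTIAL",
]

MIN_CALLS_FOR_SEQUENTIAL = 3  # subjects must have emitted > this many calls


@dataclass
class DensityGrid:
    """2-D histogram over (duration ms, FM kHz), cells in percent of calls.

    The last row/column is an overflow bin catching calls beyond the final
    edge.  ``empty`` flags an all-zero grid from an empty call list.
    """

    duration_edges: np.ndarray  # ms, includes +inf overflow edge
    fm_edges: np.ndarray  # kHz, includes +inf overflow edge
    percent: np.ndarray  # shape (n_dur_bins, n_fm_bins)
    n_calls: int

    @property
    def empty(self) -> bool:
        return self.n_calls == 0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.percent.shape[0]):
            for j in range(self.percent.shape[1]):
                rows.append({"duration_bin_ms": self.duration_edges[i],
                             "fm_bin_khz": self.fm_edges[j],
                             "percent": self.percent[i, j]})
        return pd.DataFrame(rows)


def density_grid(durations_ms: np.ndarray, fm_khz: np.ndarray,
                 duration_bin_ms: float = 5.0, fm_bin_khz: float = 5.0,
                 duration_max_ms: float = 100.0,
                 fm_max_khz: float = 80.0) -> DensityGrid:
    """Bin calls into the duration x FM grid, normalized to percentages.

    Cells sum to 100% whenever any calls exist; calls beyond the last edge
    land in an overflow bin so nothing is dropped.
    """
    if duration_bin_ms <= 0 or fm_bin_khz <= 0:
        raise ValueError("bin widths must be positive")
    d = np.asarray(durations_ms, dtype=float)
    f = np.asarray(fm_khz, dtype=float)
    if d.shape != f.shape:
        raise ValueError("durations and FM values must align")
    d_edges = np.append(np.arange(0.0, duration_max_ms + duration_bin_ms / 2,
                                  duration_bin_ms), np.inf)
    f_edges = np.append(np.arange(0.0, fm_max_khz + fm_bin_khz / 2,
                                  fm_bin_khz), np.inf)
    counts, _, _ = np.histogram2d(d, f, bins=(d_edges, f_edges))
    n = d.size
    if n == 0:
        warnings.warn("density grid computed from an empty call list",
                      stacklevel=2)
        percent = counts
    else:
        percent = counts / n * 100.0
    return DensityGrid(duration_edges=d_edges, fm_edges=f_edges,
                       percent=percent, n_calls=int(n))


def lagged_duration_correlations(durations_ms: np.ndarray,
                                 max_lag: int = 3) -> dict[int, float]:
    """Pearson r between call durations and the durations k calls back.

    For lag k the overlapping subsequences are (x_k..x_{n-1}) vs.
    (x_0..x_{n-1-k}).  A lag whose subsequences have zero variance yields
    NaN with a warning rather than an error: real subjects occasionally emit
    runs of identical (quantized) durations.
    """
    x = np.asarray(durations_ms, dtype=float)
    n = x.size
    if n <= max_lag + 1:
        raise ValueError(
            f"need more than max_lag + 1 = {max_lag + 1} calls, got {n}")
    out: dict[int, float] = {}
    for k in range(1, max_lag + 1):
        a, b = x[k:], x[:-k]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            warnings.warn(f"constant duration subsequence at lag {k}; "
                          "correlation undefined", stacklevel=2)
            out[k] = np.nan
        else:
            out[k] = float(sps.pearsonr(a, b).statistic)
    return out


def group_sequential_test(r_values: np.ndarray, chance: float = 0.0
                          ) -> tuple[float, int, float]:
    """Test subject-level correlation coefficients against chance level.

    One-sample t-test of the per-subject r's against ``chance`` (default 0);
    df = n_subjects - 1.  Requires at least two usable (non-NaN) subjects and
    nonzero spread.
    """
    r = np.asarray(r_values, dtype=float)
    r = r[~np.isnan(r)]
    if r.size < 2:
        raise ValueError("need >= 2 subjects with defined correlations")
    if np.ptp(r) == 0:
        if np.allclose(r, chance):
            return 0.0, r.size - 1, 1.0
        raise ValueError("zero variance across subjects; t undefined")
    res = sps.ttest_1samp(r, popmean=chance)
    return float(res.statistic), int(res.df), float(res.pvalue)


@dataclass
class SequentialResult:
    """Per-subject lagged correlations and the group-level tests."""

    per_subject: pd.DataFrame  # subject, n_calls, r_lag1..r_lag{max_lag}
    group_tests: pd.DataFrame  # lag, n_subjects, t, df, p
    excluded_subjects: list[str] = field(default_factory=list)


def sequential_analysis(durations_by_subject: dict[str, np.ndarray],
                        max_lag: int = 3, chance: float = 0.0,
                        min_calls: int = MIN_CALLS_FOR_SEQUENTIAL,
                        n_permutations: int = 0,
                        rng: np.random.Generator | None = None
                        ) -> SequentialResult:
    """Full sequential analysis over a set of subjects.

    Subjects with ``min_calls`` or fewer calls (default 3, i.e. the > 3-call
    inclusion rule) are excluded.  With ``n_permutations > 0``, each
    subject's chance level is its mean r over that many within-subject
    shuffles instead of the constant ``chance``; the group test then compares
    observed minus permuted-chance coefficients against zero, which is the
    permutation-null reading of "against chance level".
    """
    if n_permutations > 0 and rng is None:
        rng = np.random.default_rng(0)
    rows, excluded = [], []
    null_rows = []
    for subject, durs in durations_by_subject.items():
        durs = np.asarray(durs, dtype=float)
        if durs.size <= max(min_calls, max_lag + 1):
            excluded.append(subject)
            continue
        rs = lagged_duration_correlations(durs, max_lag=max_lag)
        row = {"subject": subject, "n_calls": durs.size}
        row.update({f"r_lag{k}": v for k, v in rs.items()})
        rows.append(row)
        if n_permutations > 0:
            acc = {k: [] for k in range(1, max_lag + 1)}
            for _ in range(n_permutations):
                perm = rng.permutation(durs)
                pr = lagged_duration_correlations(perm, max_lag=max_lag)
                for k, v in pr.items():
                    acc[k].append(v)
            null_rows.append({f"r_lag{k}": float(np.nanmean(acc[k]))
                              for k in range(1, max_lag + 1)})
    per_subject = pd.DataFrame(
        rows, columns=["subject", "n_calls"]
        + [f"r_lag{k}" for k in range(1, max_lag + 1)])
    tests = []
    for k in range(1, max_lag + 1):
        col = per_subject[f"r_lag{k}"].to_numpy(dtype=float)
        if n_permutations > 0 and null_rows:
            null = np.array([nr[f"r_lag{k}"] for nr in null_rows])
            col = col - null
        ok = ~np.isnan(col)
        if ok.sum() >= 2 and np.ptp(col[ok]) > 0:
            t, df, p = group_sequential_test(col[ok],
                                             0.0 if n_permutations else chance)
        else:
            t, df, p = np.nan, int(ok.sum()) - 1, np.nan
        tests.append({"lag": k, "n_subjects": int(ok.sum()),
                      "t": t, "df": df, "p": p})
    return SequentialResult(per_subject=per_subject,
                            group_tests=pd.DataFrame(tests),
                            excluded_subjects=excluded)
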