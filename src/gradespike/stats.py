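"""Per-cell and population statistics.

The central instrument is the Jarque-Bera (JB) statistic with Monte-Carlo
critical values: spike-amplitude distributions that depart from normality
(here, bimodal small/large mixtures) push JB far above the critical value
simulated from normal samples of the same size, flagging the cell as
multimodal.  The rest of the module covers firing rate and ISI coefficient of
variation (≈1 for Poisson activity), per-cell amplitude normalization for
pooled histograms, ordinary least-squares coupling between ∫EAP and Ca²⁺
amplitude, an activity index, and the paired/unpaired/distribution tests used
for condition comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sst

__all__ = [
    "CellResult",
    "NullTable",
    "rate_and_cv",
    "jarque_bera",
    "jb_critical_value",
    "multimodality_flag",
    "normalize_amplitudes",
    "paired_regression",
    "activity_index",
    "compare_conditions",
]


@dataclass
class CellResult:
    """Per-cell summary row."""

    cell_id: str
    rate: float                    # Hz
    isi_cv: float                  # nan when < 3 events
    amplitudes: np.ndarray         # ΔF/F
    jb_stat: float = float("nan")
    jb_crit: float = float("nan")
    multimodal: bool | None = None
    mean_snr: float = float("nan")
    activity_index: float = float("nan")
    animal_id: str = ""


def rate_and_cv(event_times: np.ndarray, duration: float) -> tuple[float, float]:
    """Firing rate (count/duration) and ISI coefficient of variation.

    The CV uses the sample SD (n−1 denominator) over mean of the inter-spike
    intervals and is NaN (flagged undefined) for fewer than 3 events.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    t = np.asarray(event_times, dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("event times must be strictly increasing")
    rate = t.size / duration
    if t.size < 3:
        return rate, float("nan")
    isis = np.diff(t)
    return rate, float(np.std(isis, ddof=1) / np.mean(isis))


def _skew_kurt(x: np.ndarray, axis: int = -1) -> tuple[np.ndarray, np.ndarray]:
    """Biased (population) moment estimators of skewness and kurtosis."""
    m = x.mean(axis=axis, keepdims=True)
    c = x - m
    m2 = np.mean(c**2, axis=axis)
    m3 = np.mean(c**3, axis=axis)
    m4 = np.mean(c**4, axis=axis)
    return m3 / m2**1.5, m4 / m2**2


def jarque_bera(samples: np.ndarray) -> float:
    """Classical JB statistic, (n/6)·(S² + (K − 3)²/4), biased moments."""
    x = np.asarray(samples, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError(f"jarque_bera needs n >= 8 samples, got {n}")
    if np.var(x) == 0:
        raise ValueError("jarque_bera is undefined for zero-variance samples")
    s, k = _skew_kurt(x)
    return float(n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0))


@dataclass
class NullTable:
    """Cache of Monte-Carlo JB critical values, one per sample size.

    For each requested ``n`` the critical value is the empirical (1 − alpha)
    quantile of JB over ``replicates`` samples of ``n`` i.i.d. standard-normal
    draws.  Each ``n`` derives its own child generator from ``seed`` so the
    table is reproducible and order-independent.
    """

    alpha: float = 0.05
    replicates: int = 100_000
    seed: int = 0
    values: dict[int, float] = field(default_factory=dict)

    def critical(self, n: int) -> float:
        n = int(n)
        if n < 8:
            raise ValueError(f"critical value undefined for n = {n} < 8")
        if n not in self.values:
            self.values[n] = jb_critical_value(n, self.alpha, self.replicates, self.seed)
        return self.values[n]


def jb_critical_value(
    n: int, alpha: float = 0.05, replicates: int = 100_000, seed: int = 0
) -> float:
    """Empirical (1 − alpha) quantile of JB under the normal null at size n."""
    if n < 8:
        raise ValueError(f"n must be >= 8, got {n}")
    if replicates < 100:
        raise ValueError("need at least 100 replicates")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(n),)))
    # Chunked so tables for many n stay within memory.
    jbs = np.empty(replicates)
    done = 0
    chunk = max(1, min(replicates, int(2e7) // max(n, 1)))
    while done < replicates:
        m = min(chunk, replicates - done)
        x = rng.standard_normal((m, n))
        s, k = _skew_kurt(x, axis=1)
        jbs[done:done + m] = n / 6.0 * (s**2 + (k - 3.0) ** 2 / 4.0)
        done += m
    return float(np.quantile(jbs, 1.0 - alpha))


def multimodality_flag(amplitudes: np.ndarray, null: NullTable) -> bool | None:
    """True iff JB of the amplitudes exceeds the simulated critical value.

    Returns None (indeterminate) when the sample is too small for JB.
    """
    x = np.asarray(amplitudes, dtype=float)
    if x.size < 8:
        return None
    return bool(jarque_bera(x) > null.critical(x.size))


def normalize_amplitudes(
    cells: dict[str, dict[str, np.ndarray]], control_condition: str = "control"
) -> dict[str, np.ndarray]:
    """Pool per-condition amplitudes after dividing by each cell's control mean.

    ``cells`` maps cell_id → {condition → amplitude array}.  Every amplitude
    (control and treated) is divided by that cell's mean control amplitude, so
    cell-to-cell amplitude differences do not bias the pooled histograms.
    Cells lacking the control condition (or with non-positive control mean)
    are excluded with a warning.
    """
    import logging

    pooled: dict[str, list[np.ndarray]] = {}
    for cell_id, by_cond in cells.items():
        if control_condition not in by_cond:
            logging.getLogger(__name__).warning(
                "cell %s has no %r condition; excluded from pooled histograms",
                cell_id, control_condition,
            )
            continue
        ctrl_mean = float(np.mean(by_cond[control_condition]))
        if not ctrl_mean > 0:
            logging.getLogger(__name__).warning(
                "cell %s control mean %.3g is not positive; excluded", cell_id, ctrl_mean
            )
            continue
        for cond, amps in by_cond.items():
            pooled.setdefault(cond, []).append(np.asarray(amps, dtype=float) / ctrl_mean)
    return {cond: np.concatenate(parts) for cond, parts in pooled.items()}


def paired_regression(
    integral_peaks: np.ndarray, ca_amplitudes: np.ndarray
) -> tuple[float, float, float]:
    """OLS of Ca²⁺ amplitude on ∫EAP peak: ``(slope, intercept, r_squared)``."""
    x = np.asarray(integral_peaks, dtype=float)
    y = np.asarray(ca_amplitudes, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("paired_regression needs at least 3 matched pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("paired_regression is undefined with zero variance")
    res = sst.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def activity_index(
    amplitudes: np.ndarray, duration: float, mode: str = "amplitude_sum",
    dff_trace=None,
) -> float:
    """Ca²⁺ activity in ΔF/F·s⁻¹.

    Default ``"amplitude_sum"``: sum of detected spike amplitudes over the
    recording duration (reads the unit literally).  Alternative
    ``"positive_derivative"``: mean positive first derivative of the ΔF/F
    trace (pass ``dff_trace``) — provided because the quantity's definition is
    not pinned down by its unit alone.
    """
    if duration <= 0:
        raise ValueError(f"duration must be > 0, got {duration}")
    if mode == "amplitude_sum":
        return float(np.sum(amplitudes) / duration)
    if mode == "positive_derivative":
        if dff_trace is None:
            raise ValueError("positive_derivative mode needs the ΔF/F trace")
        d = np.diff(dff_trace.samples) * dff_trace.sample_rate
        return float(np.mean(np.clip(d, 0.0, None)))
    raise ValueError(f"unknown activity_index mode {mode!r}")


def compare_conditions(
    per_cell_pre: np.ndarray,
    per_cell_post: np.ndarray,
    design: str = "paired",
) -> dict:
    """Condition comparison: Wilcoxon signed-rank, Mann-Whitney U, or KS.

    ``paired``   — signed-rank on matched per-cell values;
    ``unpaired`` — rank-sum on two independent groups;
    ``distribution`` — two-sample KS on pooled (normalized) amplitudes.
    Returns statistic, two-sided p-value and per-group median ± IQR.
    """
    a = np.asarray(per_cell_pre, dtype=float)
    b = np.asarray(per_cell_post, dtype=float)
    if design == "paired":
        if a.size != b.size:
            raise ValueError(f"paired design needs matched vectors, got {a.size} vs {b.size}")
        if a.size < 5:
            raise ValueError("paired design needs >= 5 cells")
        if np.all(a == b):
            stat, p = 0.0, 1.0  # no differences: maximal attainable p
        else:
            stat, p = sst.wilcoxon(a, b)
    elif design == "unpaired":
        if min(a.size, b.size) < 5:
            raise ValueError("unpaired design needs >= 5 cells per group")
        stat, p = sst.mannwhitneyu(a, b, alternative="two-sided")
    elif design == "distribution":
        stat, p = sst.ks_2samp(a, b)
    else:
        raise ValueError(f"unknown design {design!r}; use paired, unpaired or distribution")

    def _summ(x: np.ndarray) -> str:
        med = np.median(x)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        return f"{med:.3g} ±{iqr:.3g} (median ±IQR)"

    return {
        "design": design,
        "statistic": float(stat),
        "p_value": float(p),
        "pre_summary": _summ(a),
        "post_summary": _summ(b),
        "pre_median": float(np.median(a)),
        "post_median": float(np.median(b)),
    }
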