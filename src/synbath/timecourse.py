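"""EFS time-course analysis.

Twelve-hour electrical-field-stimulation (EFS) experiments follow the
neurogenic contractile tone of isolated bronchi at a 5-min stimulation
cadence. Contraction amplitudes are normalised to the pre-treatment control
EFS response, giving relaxation as a percentage of control; a polynomial
trend (degree chosen by AICc, capped at 4) smooths each trace, from which the
maximal relaxation (E_max), the onset of action (t1/2, earliest time the
trend reaches half its maximum) and the plateau level are read off.

Synergism over time is the observed-minus-expected (Bliss) delta curve with
per-time significance; its summaries are the interval AUCs (trapezoidal,
%*h), the duration of synergism (hours after treatment for which the delta
stays significantly positive) and a head-to-head comparison table between
two combinations.

Internally effects are fractions; deltas and AUCs are reported on the %
scale, times in minutes (converted to hours for AUC and duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .bliss import _validate_and_clip
from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "normalize_efs",
    "fit_trend",
    "compute_metrics",
    "synergism_curve",
    "auc_intervals",
    "duration_of_synergism",
    "compare_combinations",
    "PolynomialTrend",
    "TimeCourseMetrics",
    "DeltaCurve",
    "CombinationMetrics",
    "DEFAULT_INTERVALS",
]

# Standard reporting intervals, hours post-treatment.
DEFAULT_INTERVALS = ((0, 1), (0, 3), (0, 6), (0, 9), (0, 12))


def normalize_efs(raw_amplitudes, pre_treatment_reference):
    """Relaxation (%) relative to the pre-treatment control EFS contraction.

    relaxation = 100 * (1 - amplitude / reference); invariant to rescaling
    amplitudes and reference by a common factor.
    """
    ref = float(pre_treatment_reference)
    if ref <= 0:
        raise InvalidInputError("pre-treatment EFS reference must be positive")
    amp = np.asarray(raw_amplitudes, dtype=float)
    out = 100.0 * (1.0 - amp / ref)
    return float(out) if np.isscalar(raw_amplitudes) else out


@dataclass
class PolynomialTrend:
    """Least-squares polynomial trend of a time course."""

    poly: np.polynomial.Polynomial
    degree: int
    rss: float
    n_points: int

    def predict(self, t):
        return self.poly(np.asarray(t, dtype=float))

    __call__ = predict


def _aicc(rss: float, n: int, k: int) -> float:
    # Gaussian log-likelihood AIC with small-sample correction; k counts the
    # polynomial coefficients plus the noise variance.
    if n - k - 1 <= 0:
        return np.inf
    return n * np.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_trend(times, values, max_degree: int = 4) -> PolynomialTrend:
    """Polynomial trend with degree selected by corrected AIC (capped).

    Near-interpolating fits (rss ~ 0) short-circuit to the smallest such
    degree so that exactly-polynomial data recover their true degree.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size != y.size:
        raise InvalidInputError("times and values must be the same length")
    if t.size < max_degree + 2:
        raise InvalidInputError(
            f"need >= {max_degree + 2} points for a degree-{max_degree} trend"
        )
    candidates = []
    for d in range(max_degree + 1):
        poly = np.polynomial.Polynomial.fit(t, y, d)
        rss = float(np.sum((poly(t) - y) ** 2))
        candidates.append((d, poly, rss))
    # exact-fit short circuit
    scale = max(float(np.sum(y * y)), 1.0)
    for d, poly, rss in candidates:
        if rss <= 1e-18 * scale:
            return PolynomialTrend(poly, d, rss, t.size)
    best = min(candidates, key=lambda c: _aicc(c[2], t.size, c[0] + 2))
    return PolynomialTrend(best[1], best[0], best[2], t.size)


@dataclass
class TimeCourseMetrics:
    """Scalar summaries of one (relaxation or synergism) time course."""

    e_max: float
    t_half: float | None          # min; None when the trend starts above half-max
    e_max_plateau: float
    auc: dict = field(default_factory=dict)   # interval label -> %*h
    duration_of_synergism: float | None = None  # h

    def to_dict(self) -> dict:
        return {
            "e_max": self.e_max,
            "t_half_min": self.t_half,
            "e_max_plateau": self.e_max_plateau,
            "auc_pct_h": dict(self.auc),
            "duration_of_synergism_h": self.duration_of_synergism,
        }


def _eval_trend(trend, t):
    f = getattr(trend, "predict", trend)
    return np.asarray(f(np.asarray(t, dtype=float)), dtype=float)


def compute_metrics(
    trend,
    times,
    values=None,
    *,
    plateau_window_h: float = 3.0,
    plateau_decline_fraction: float = 0.9,
) -> TimeCourseMetrics:
    """E_max, onset t1/2 and plateau level from a fitted trend.

    ``trend`` is any callable (or object with ``.predict``) mapping time (min)
    to effect; t1/2 is found by root-bracketing the earliest crossing of
    E_max/2. The plateau is the mean of the trend over the final
    ``plateau_window_h`` hours, truncated where a terminal decline drops the
    trend below ``plateau_decline_fraction`` of the window maximum.
    """
    t = np.asarray(times, dtype=float)
    if t.size < 2:
        raise InvalidInputError("need at least two time points")
    dense = np.linspace(t.min(), t.max(), max(20 * t.size, 2000))
    yd = _eval_trend(trend, dense)
    i_max = int(np.argmax(yd))
    e_max = float(yd[i_max])
    half = e_max / 2.0

    t_half: float | None
    rising = np.nonzero(yd[: i_max + 1] >= half)[0]
    if rising.size == 0:  # pragma: no cover - flat trend edge case
        t_half = None
    elif rising[0] == 0:
        # trend already above half-max at the first observed time
        t_half = float(dense[0]) if yd[0] <= half + 1e-12 else None
    else:
        j = rising[0]
        t_half = float(
            optimize.brentq(
                lambda x: _eval_trend(trend, x) - half, dense[j - 1], dense[j]
            )
        )

    # plateau: mean trend over the trailing window, excluding terminal decline
    w0 = t.max() - plateau_window_h * 60.0
    win = dense[dense >= w0]
    yw = _eval_trend(trend, win)
    cutoff = plateau_decline_fraction * float(yw.max())
    below = np.nonzero(yw < cutoff)[0]
    # drop only a *terminal* declining segment (contiguous run ending at t_end)
    end = win.size
    while end > 1 and yw[end - 1] < cutoff:
        end -= 1
    plateau = float(yw[:end].mean())

    auc: dict = {}
    if values is not None:
        y = np.asarray(values, dtype=float)
        t_end_h = t.max() / 60.0
        usable = [iv for iv in DEFAULT_INTERVALS if iv[1] <= t_end_h + 1e-9]
        if usable:
            auc = auc_intervals((t, y), intervals=usable, scale=1.0)

    return TimeCourseMetrics(
        e_max=e_max, t_half=t_half, e_max_plateau=plateau, auc=auc
    )


@dataclass
class DeltaCurve:
    """Observed-minus-expected synergism curve with per-time significance.

    ``delta``/``sem`` are fractions of E_max (multiply by 100 for % points);
    ``times`` are minutes post-treatment.
    """

    times: np.ndarray
    delta: np.ndarray
    sem: np.ndarray
    p_values: np.ndarray
    overall_p: float | None = None
    interpolated: bool = False
    n: int = 0

    @property
    def delta_percent(self) -> np.ndarray:
        return 100.0 * self.delta

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "delta_percent": self.delta_percent,
                "sem_percent": 100.0 * self.sem,
                "p_value": self.p_values,
            }
        )


def synergism_curve(
    observed,
    single_agent_traces,
    times,
    *,
    expected_times=None,
    alpha: float = 0.05,
    test: str = "welch",
    overall_test: bool = True,
) -> DeltaCurve:
    """Delta(t) = observed combination - BI expectation, with significance.

    Parameters
    ----------
    observed : (n_subjects, n_times) fractions for the combination.
    single_agent_traces : dict label -> (n_subjects, n_times) fractions, one
        entry per drug; the BI expectation is computed within each subject.
    times : shared time grid (min). If the single-agent traces live on
        ``expected_times`` instead, they are linearly interpolated onto
        ``times`` (recorded via ``interpolated``); disjoint grids raise.
    test : 'welch' (default; higher power at n = 3) or 'paired'.
    overall_test : also run a treatment x time two-way ANOVA over the whole
        curve (observed vs expected as the treatment factor).
    """
    t = np.asarray(times, dtype=float)
    obs = np.atleast_2d(np.asarray(observed, dtype=float))
    if obs.shape[1] != t.size:
        raise InvalidInputError("observed traces do not match the time grid")
    if obs.shape[0] < 2:
        raise InsufficientDataError("need >=2 subject replicates")

    singles = {k: np.atleast_2d(np.asarray(v, dtype=float))
               for k, v in single_agent_traces.items()}
    if len(singles) < 2:
        raise InvalidInputError("need single-agent traces for >=2 drugs")

    interpolated = False
    if expected_times is not None:
        te = np.asarray(expected_times, dtype=float)
        if te.max() < t.min() or te.min() > t.max():
            raise InvalidInputError("observed and expected time grids are disjoint")
        if te.shape != t.shape or not np.allclose(te, t):
            inside = (t >= te.min()) & (t <= te.max())
            if not inside.all():
                raise InvalidInputError(
                    "expected traces do not cover the observed time grid"
                )
            singles = {
                k: np.vstack([np.interp(t, te, row) for row in v])
                for k, v in singles.items()
            }
            interpolated = True

    survival = np.ones_like(obs)
    for k, v in singles.items():
        if v.shape != obs.shape:
            raise InvalidInputError(f"trace shape mismatch for {k!r}")
        vc, _ = _validate_and_clip(v, k)
        survival *= 1.0 - vc
    expected = 1.0 - survival
    obs_c, _ = _validate_and_clip(obs, "observed")

    if test == "paired":
        _, p = stats.ttest_rel(obs_c, expected, axis=0)
    elif test == "welch":
        _, p = stats.ttest_ind(obs_c, expected, axis=0, equal_var=False)
    else:
        raise InvalidInputError(f"unknown test: {test!r}")

    diff = obs_c - expected
    n = obs.shape[0]
    delta = diff.mean(axis=0)
    sem = diff.std(axis=0, ddof=1) / np.sqrt(n)

    overall_p = None
    if overall_test:
        overall_p = _two_way_anova_p(obs_c, expected, t)

    return DeltaCurve(
        times=t, delta=delta, sem=sem, p_values=np.asarray(p),
        overall_p=overall_p, interpolated=interpolated, n=n,
    )


def _two_way_anova_p(observed, expected, times) -> float:
    """Treatment (observed vs expected) x time two-way ANOVA, treatment p."""
    import statsmodels.api as sm

    n, m = observed.shape
    y = np.concatenate([observed.ravel(), expected.ravel()])
    group = np.repeat([1.0, 0.0], n * m)
    time_idx = np.tile(np.repeat(np.arange(m), 1), 2 * n)
    time_idx = np.concatenate([np.tile(np.arange(m), n)] * 2)
    time_dummies = np.eye(m)[time_idx][:, 1:]  # drop reference level
    X = sm.add_constant(np.column_stack([group, time_dummies]))
    fit = sm.OLS(y, X).fit()
    return float(fit.pvalues[1])


def auc_intervals(
    delta_curve,
    intervals=DEFAULT_INTERVALS,
    *,
    scale: float = 100.0,
) -> dict:
    """Trapezoidal AUC of the synergism curve per interval, in % * h.

    ``delta_curve`` is a :class:`DeltaCurve` (fractions; converted to %) or a
    ``(times_min, values)`` pair with ``scale`` applied to the values (use
    ``scale=1.0`` when the values are already on the % scale). Interval
    bounds are hours; bounds falling between grid points are handled by
    linear interpolation; intervals beyond the data range raise.
    """
    if isinstance(delta_curve, DeltaCurve):
        t_min, y = delta_curve.times, delta_curve.delta_percent
    else:
        t_min, y = delta_curve
        y = np.asarray(y, dtype=float) * scale
    t_h = np.asarray(t_min, dtype=float) / 60.0
    out = {}
    for a, b in intervals:
        if a < t_h.min() - 1e-9 or b > t_h.max() + 1e-9:
            raise InvalidInputError(
                f"interval {a}-{b} h outside the data range "
                f"[{t_h.min():.2f}, {t_h.max():.2f}] h"
            )
        grid = np.unique(np.clip(np.concatenate([[a], t_h, [b]]), a, b))
        vals = np.interp(grid, t_h, y)
        out[f"{a:g}-{b:g}"] = float(np.trapezoid(vals, grid))
    return out


def duration_of_synergism(
    delta_curve: DeltaCurve,
    alpha: float = 0.05,
    *,
    gap_tolerance: int = 1,
) -> float:
    """Hours after treatment for which synergism remains significant.

    A time point counts when delta > 0 and its two-sided p < alpha. Runs of
    such points are merged across at most ``gap_tolerance`` consecutive
    non-significant points (5-min sampling at n = 3 makes isolated dropouts
    likely); the duration is the end time of the longest merged run,
    i.e. the clock time post-treatment up to which synergism persists.
    Returns 0.0 when no point is significant.
    """
    sig = (delta_curve.delta > 0) & (delta_curve.p_values < alpha)
    idx = np.nonzero(sig)[0]
    if idx.size == 0:
        return 0.0
    segments = []
    start = prev = idx[0]
    for j in idx[1:]:
        if j - prev <= gap_tolerance + 1:
            prev = j
        else:
            segments.append((start, prev))
            start = prev = j
    segments.append((start, prev))
    lengths = [delta_curve.times[b] - delta_curve.times[a] for a, b in segments]
    a, b = segments[int(np.argmax(lengths))]
    return float(delta_curve.times[b] / 60.0)


@dataclass
class CombinationMetrics:
    """Synergism summaries for one drug combination, with uncertainty.

    Means and SEMs as printed in reports: AUCs in % * h per interval label,
    onset in min, plateau in %, duration in h; ``n`` subjects. Optional
    per-subject AUC replicates enable a two-way ANOVA in comparisons.
    """

    label: str
    auc: dict                      # interval -> (mean, sem)
    t_half: tuple[float, float]    # (mean, sem) min
    e_max_plateau: tuple[float, float]  # (mean, sem) %
    duration_h: tuple[float, float]     # (mean, sem) h
    n: int = 3
    auc_replicates: dict | None = None  # interval -> per-subject array


def _welch_p(mean_a, sem_a, n_a, mean_b, sem_b, n_b) -> float:
    if not (np.isfinite(sem_a) and np.isfinite(sem_b)) or (sem_a == sem_b == 0):
        return float("nan")
    _, p = stats.ttest_ind_from_stats(
        mean_a, sem_a * np.sqrt(n_a), n_a,
        mean_b, sem_b * np.sqrt(n_b), n_b,
        equal_var=False,
    )
    return float(p)


def compare_combinations(
    metrics_a: CombinationMetrics,
    metrics_b: CombinationMetrics,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Head-to-head difference table between two combinations.

    One row per AUC interval plus onset (t1/2), E_max plateau and duration;
    ``difference`` is ``a - b``. Scalar rows are tested by Welch t from the
    summary statistics; when both metrics carry per-subject AUC replicates a
    combination x interval two-way ANOVA p-value is attached to the AUC rows
    instead of per-interval t-tests being the only evidence.
    """
    if set(metrics_a.auc) != set(metrics_b.auc):
        raise InvalidInputError(
            "combinations report different AUC intervals; align them first"
        )
    rows = []
    for interval in metrics_a.auc:
        (ma, sa), (mb, sb) = metrics_a.auc[interval], metrics_b.auc[interval]
        rows.append(
            {
                "metric": f"auc_{interval}_h",
                "a_mean": ma, "a_sem": sa, "b_mean": mb, "b_sem": sb,
                "difference": ma - mb,
                "p_value": _welch_p(ma, sa, metrics_a.n, mb, sb, metrics_b.n),
            }
        )
    for name, (va, sa), (vb, sb) in (
        ("t_half_min", metrics_a.t_half, metrics_b.t_half),
        ("e_max_plateau_pct", metrics_a.e_max_plateau, metrics_b.e_max_plateau),
        ("duration_h", metrics_a.duration_h, metrics_b.duration_h),
    ):
        rows.append(
            {
                "metric": name,
                "a_mean": va, "a_sem": sa, "b_mean": vb, "b_sem": sb,
                "difference": va - vb,
                "p_value": _welch_p(va, sa, metrics_a.n, vb, sb, metrics_b.n),
            }
        )
    table = pd.DataFrame(rows)
    table["significant"] = table["p_value"] < alpha

    if metrics_a.auc_replicates and metrics_b.auc_replicates:
        table.attrs["auc_anova_p"] = _auc_two_way_anova(
            metrics_a.auc_replicates, metrics_b.auc_replicates
        )
    return table


def _auc_two_way_anova(reps_a: dict, reps_b: dict) -> float:
    """Combination x interval two-way ANOVA on per-subject AUCs (combo p)."""
    import statsmodels.api as sm

    ys, combos, intervals = [], [], []
    for which, reps in (("a", reps_a), ("b", reps_b)):
        for interval, arr in reps.items():
            for v in np.asarray(arr, dtype=float):
                ys.append(v)
                combos.append(which)
                intervals.append(interval)
    df = pd.DataFrame({"y": ys, "combo": combos, "interval": intervals})
    combo = (df["combo"] == "a").astype(float).to_numpy()
    dummies = pd.get_dummies(df["interval"], drop_first=True, dtype=float).to_numpy()
    X = sm.add_constant(np.column_stack([combo, dummies]))
    fit = sm.OLS(df["y"].to_numpy(), X).fit()
    return float(fit.pvalues[1])
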