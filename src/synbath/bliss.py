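"""Bliss Independence (BI) interaction analysis.

The BI reference model assumes the combined drugs act independently, so the
expected fractional effect of a combination is

    2 agents:  E(x,y)   = Ex + Ey - Ex*Ey
    3 agents:  E(x,y,z) = Ex + Ey + Ez - Ex*Ey - Ex*Ez - Ey*Ez + ... ,

both identical to the complement-product form 1 - prod(1 - Ei). An observed
combination effect above the expectation is synergistic, below it is
antagonistic, and otherwise the drugs are merely additive; significance of
the departure is judged by a two-sided t-test on replicates.

All effects entering BI are fractions in [0, 1]. Fitted maxima occasionally
exceed 1 slightly (e.g. PCLS E_max just above the papaverine level); such
inputs are clipped to [0, 1] for the probabilistic model and the clipping is
recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    PairingError,
    UndefinedCorrelationError,
)

__all__ = [
    "bliss_expected_2",
    "bliss_expected_3",
    "bliss_expected",
    "expected_with_uncertainty",
    "assess_interaction",
    "correlate",
    "ExpectedEffect",
    "BlissAssessment",
    "CorrelationResult",
    "ADMISSIBLE_RANGE",
]

# Raw normalised effects may legitimately stray slightly outside [0, 1]
# (noise below the plateau, E_max above papaverine); anything further out is
# treated as a data error rather than silently clipped.
ADMISSIBLE_RANGE = (-0.05, 1.10)


def _validate_and_clip(e, name):
    e = np.asarray(e, dtype=float)
    if np.any(~np.isfinite(e)):
        raise InvalidInputError(f"{name}: effects must be finite")
    lo, hi = ADMISSIBLE_RANGE
    tol = 1e-9  # absorb float round-trip error at the truncation boundaries
    if np.any(e < lo - tol) or np.any(e > hi + tol):
        raise InvalidInputError(
            f"{name}: effect outside admissible range [{lo}, {hi}]"
        )
    clipped = bool(np.any(e < 0.0) or np.any(e > 1.0))
    return np.clip(e, 0.0, 1.0), clipped


def bliss_expected_2(e_x, e_y):
    """Expected fractional effect of two independent agents, Ex + Ey - Ex*Ey."""
    ex, _ = _validate_and_clip(e_x, "e_x")
    ey, _ = _validate_and_clip(e_y, "e_y")
    out = np.clip(ex + ey - ex * ey, 0.0, 1.0)
    return float(out) if np.isscalar(e_x) and np.isscalar(e_y) else out


def bliss_expected_3(e_x, e_y, e_z):
    """Expected fractional effect of three independent agents.

    Inclusion-exclusion form Ex + Ey + Ez - ExEy - ExEz - EyEz + ExEyEz,
    equal to 1 - (1-Ex)(1-Ey)(1-Ez); reduces to the 2-agent formula when any
    input is 0.
    """
    ex, _ = _validate_and_clip(e_x, "e_x")
    ey, _ = _validate_and_clip(e_y, "e_y")
    ez, _ = _validate_and_clip(e_z, "e_z")
    out = np.clip(ex + ey + ez - ex * ey - ex * ez - ey * ez + ex * ey * ez,
                  0.0, 1.0)
    scalar = np.isscalar(e_x) and np.isscalar(e_y) and np.isscalar(e_z)
    return float(out) if scalar else out


def bliss_expected(effects):
    """Complement-product BI expectation 1 - prod(1 - Ei) for 2+ agents."""
    effects = [np.asarray(e, dtype=float) for e in effects]
    if len(effects) < 2:
        raise InvalidInputError("BI expectation needs at least two agents")
    clipped = False
    survival = 1.0
    for i, e in enumerate(effects):
        e, c = _validate_and_clip(e, f"effect[{i}]")
        clipped |= c
        survival = survival * (1.0 - e)
    return 1.0 - survival


@dataclass
class ExpectedEffect:
    """BI-expected effect with replicate uncertainty."""

    mean: float
    sem: float
    per_subject: np.ndarray | None = None
    pairing: str = "by_subject"
    clipped_inputs: bool = False

    @property
    def n(self) -> int:
        return 0 if self.per_subject is None else int(len(self.per_subject))


def _as_replicate_matrix(single_agent_replicates):
    """dict label -> array, or 2D array (n_drugs, n_subjects) -> 2D float array."""
    if isinstance(single_agent_replicates, dict):
        arrays = [np.asarray(v, dtype=float) for v in single_agent_replicates.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in single_agent_replicates]
    if len(arrays) < 2:
        raise InvalidInputError("need replicates for at least two drugs")
    return arrays


def expected_with_uncertainty(
    single_agent_replicates, pairing: str = "by_subject"
) -> ExpectedEffect:
    """BI-expected effect mean +/- SEM from single-agent replicates.

    ``by_subject`` (default) computes the BI expectation within each matched
    subject and summarises those as mean +/- SEM (n = subjects), mirroring the
    subject-level mean +/- SEM reporting of organ-bath studies.
    ``delta_method`` propagates first-order variance of the per-drug means
    through the BI formula; use it when subjects cannot be matched.
    """
    arrays = _as_replicate_matrix(single_agent_replicates)
    for a in arrays:
        if a.size < 2:
            raise InsufficientDataError("need >=2 replicates per drug")

    if pairing == "by_subject":
        n = {a.size for a in arrays}
        if len(n) != 1:
            raise PairingError(
                "by_subject pairing needs the same matched subjects for every drug"
            )
        clipped = False
        survival = np.ones(arrays[0].size)
        for i, a in enumerate(arrays):
            a, c = _validate_and_clip(a, f"drug[{i}]")
            clipped |= c
            survival *= 1.0 - a
        per_subject = 1.0 - survival
        m = per_subject.size
        return ExpectedEffect(
            mean=float(per_subject.mean()),
            sem=float(per_subject.std(ddof=1) / np.sqrt(m)),
            per_subject=per_subject,
            pairing="by_subject",
            clipped_inputs=clipped,
        )

    if pairing == "delta_method":
        clipped = False
        means, sems = [], []
        for i, a in enumerate(arrays):
            a, c = _validate_and_clip(a, f"drug[{i}]")
            clipped |= c
            means.append(a.mean())
            sems.append(a.std(ddof=1) / np.sqrt(a.size))
        means = np.asarray(means)
        sems = np.asarray(sems)
        expected = 1.0 - np.prod(1.0 - means)
        # dE/dm_i = prod_{j != i} (1 - m_j); first-order variance propagation.
        var = 0.0
        for i in range(means.size):
            grad = np.prod(np.delete(1.0 - means, i))
            var += (grad * sems[i]) ** 2
        return ExpectedEffect(
            mean=float(expected),
            sem=float(np.sqrt(var)),
            per_subject=None,
            pairing="delta_method",
            clipped_inputs=clipped,
        )

    raise InvalidInputError(f"unknown pairing scheme: {pairing!r}")


@dataclass
class BlissAssessment:
    """Observed vs BI-expected effect at one condition (level or time)."""

    condition: float
    observed_mean: float
    observed_sem: float
    expected_mean: float
    expected_sem: float
    delta: float            # observed - expected, in percentage points
    p_value: float
    classification: str     # synergistic | additive | antagonistic
    clipped_inputs: bool = False
    n: int = 0
    test: str = "paired"

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "observed_mean": self.observed_mean,
            "observed_sem": self.observed_sem,
            "expected_mean": self.expected_mean,
            "expected_sem": self.expected_sem,
            "delta": self.delta,
            "p_value": self.p_value,
            "classification": self.classification,
            "clipped_inputs": self.clipped_inputs,
        }


def classify(delta: float, p_value: float, alpha: float) -> str:
    """Directional interaction call: significant positive delta is synergy.

    ``delta`` is in percentage points; departures below numerical noise
    (1e-10 points) are additive regardless of the test, so that observed ==
    expected data cannot be flagged through a zero-variance t statistic.
    """
    if abs(delta) < 1e-10:
        return "additive"
    if np.isfinite(p_value) and p_value < alpha:
        if delta > 0:
            return "synergistic"
        if delta < 0:
            return "antagonistic"
    return "additive"


def assess_interaction(
    observed,
    expected,
    *,
    alpha: float = 0.05,
    test: str | None = None,
    condition: float = float("nan"),
) -> BlissAssessment:
    """Compare observed combination replicates with the BI expectation.

    ``expected`` is either an :class:`ExpectedEffect` or the single-agent
    replicates (dict / 2D array), in which case ``expected_with_uncertainty``
    is applied with by-subject pairing.

    The test is a two-sided t-test: paired on matched subjects when the
    expectation carries per-subject values (default, exact at small n),
    otherwise Welch's unequal-variance test. Delta is reported in percentage
    points on the % scale.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise InsufficientDataError("need >=2 observed replicates")
    obs, obs_clipped = _validate_and_clip(obs, "observed")

    if not isinstance(expected, ExpectedEffect):
        expected = expected_with_uncertainty(expected, pairing="by_subject")

    if test is None:
        test = "paired" if expected.per_subject is not None else "welch"
    if test == "paired":
        if expected.per_subject is None or expected.per_subject.size != obs.size:
            raise PairingError(
                "paired test needs per-subject expected values matching the "
                "observed replicates"
            )
        tstat, p = stats.ttest_rel(obs, expected.per_subject)
    elif test == "welch":
        if expected.per_subject is not None:
            tstat, p = stats.ttest_ind(obs, expected.per_subject, equal_var=False)
        else:
            # Summary-statistics Welch test against the propagated expectation.
            tstat, p = stats.ttest_ind_from_stats(
                obs.mean(), obs.std(ddof=1), obs.size,
                expected.mean, expected.sem * np.sqrt(obs.size), obs.size,
                equal_var=False,
            )
    else:
        raise InvalidInputError(f"unknown test: {test!r}")

    delta_pct = 100.0 * (obs.mean() - expected.mean)
    return BlissAssessment(
        condition=float(condition),
        observed_mean=float(obs.mean()),
        observed_sem=float(obs.std(ddof=1) / np.sqrt(obs.size)),
        expected_mean=expected.mean,
        expected_sem=expected.sem,
        delta=float(delta_pct),
        p_value=float(p),
        classification=classify(delta_pct, float(p), alpha),
        clipped_inputs=obs_clipped or expected.clipped_inputs,
        n=int(obs.size),
        test=test,
    )


@dataclass
class CorrelationResult:
    pearson_r: float
    r_squared: float
    p_value: float


def correlate(x_values, y_values) -> CorrelationResult:
    """Pearson correlation with R^2 (= r**2 exactly) and two-sided p-value."""
    x = np.asarray(x_values, dtype=float)
    y = np.asarray(y_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise UndefinedCorrelationError("need >=3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise UndefinedCorrelationError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(pearson_r=r, r_squared=r * r, p_value=float(res.pvalue))
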