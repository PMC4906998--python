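"""Concentration-response curve (CRC) analysis.

Fits the variable-slope four-parameter logistic (4PL) model

    Y = Bottom + (Top - Bottom) / (1 + 10**((LogEC50 - X) * HillSlope))

to relaxation data normalised to the papaverine (100 uM) maximum, and derives
the potency and efficacy summaries used throughout airway pharmacology:
pEC50 (= -LogEC50), E_max (fitted Top), EC_n (the concentration producing n%
of maximal effect) and isoeffective concentration pairings used to design
combination experiments.

Responses are fractions of the papaverine E_max (0 = precontraction plateau,
1 = papaverine level); concentrations are mol/L, handled internally as log10.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    ConvergenceError,
    DegenerateNormalizationError,
    InvalidInputError,
    NoFitError,
)

__all__ = [
    "four_pl",
    "normalize_responses",
    "fit_4pl",
    "ec_n",
    "isoeffective_grid",
    "ConcentrationResponseCurve",
    "FourPLFit",
    "IsoeffectivePair",
    "PHYSIOLOGICAL_BOUNDS",
]

# Default parameter box on the normalised-effect scale: the plateau anchors 0,
# papaverine anchors 1, so Bottom near 0 and Top near 1 are physiological.
# Order: (bottom, top, log_ec50, hill_slope); log_ec50 bounds are grid-derived.
PHYSIOLOGICAL_BOUNDS = {
    "bottom": (-0.05, 0.2),
    "top": (0.5, 1.1),
    "hill_slope": (1e-3, 5.0),
}

# Responses flatter than this fraction of E_max carry no fittable signal.
_FLAT_RANGE = 0.02


def four_pl(x, bottom, top, log_ec50, hill_slope):
    """Variable-slope sigmoid; ``x`` is log10 molar concentration."""
    x = np.asarray(x, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - x) * hill_slope))


def normalize_responses(raw, papaverine_reference, precontraction_plateau):
    """Map raw tension (or luminal area) onto the fraction-of-papaverine scale.

    The precontraction plateau maps to 0, the papaverine level to 1; the map
    is linear, so values beyond either anchor are preserved (not clipped).
    """
    raw = np.asarray(raw, dtype=float)
    pap = float(papaverine_reference)
    plateau = float(precontraction_plateau)
    span = pap - plateau
    if span == 0.0 or abs(span) < 1e-12 * max(abs(pap), abs(plateau), 1.0):
        raise DegenerateNormalizationError(
            "papaverine reference equals the precontraction plateau; "
            "normalisation is undefined"
        )
    return (raw - plateau) / span


@dataclass
class ConcentrationResponseCurve:
    """One replicate CRC: normalised responses on a log10 concentration grid."""

    drug_labels: tuple[str, ...]
    log_conc: np.ndarray
    response: np.ndarray
    subject_id: str = ""
    tissue: str = "segmental_bronchus"
    precontraction: str = "acetylcholine"

    def __post_init__(self):
        self.drug_labels = tuple(self.drug_labels)
        self.log_conc = np.asarray(self.log_conc, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.log_conc.shape != self.response.shape:
            raise InvalidInputError("log_conc and response must be the same length")
        if not np.all(np.isfinite(self.response)):
            raise InvalidInputError("responses must be finite")


@dataclass
class FourPLFit:
    """Fitted 4PL parameters with standard errors and fit quality."""

    bottom: float
    top: float
    log_ec50: float
    hill_slope: float
    standard_errors: dict = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0
    drug_label: str = ""
    subject_id: str = ""

    @property
    def pec50(self) -> float:
        return -self.log_ec50

    @property
    def e_max(self) -> float:
        return self.top

    def predict(self, x):
        return four_pl(x, self.bottom, self.top, self.log_ec50, self.hill_slope)

    def to_dict(self) -> dict:
        return {
            "drug_label": self.drug_label,
            "subject_id": self.subject_id,
            "bottom": self.bottom,
            "top": self.top,
            "log_ec50": self.log_ec50,
            "hill_slope": self.hill_slope,
            "pec50": self.pec50,
            "e_max": self.e_max,
            "rss": self.rss,
            "n_points": self.n_points,
            "standard_errors": dict(self.standard_errors),
        }


@dataclass
class IsoeffectivePair:
    """Concentrations of each drug producing the same single-agent effect."""

    effect_level: float
    conc_per_drug: dict[str, float]
    attainable: bool = True
    unattainable_drugs: tuple[str, ...] = ()


def _starting_values(x, y, bounds_lo, bounds_hi):
    # Deterministic starting rule: extremes of the data for the asymptotes,
    # the grid point nearest half-range for LogEC50, unit Hill slope.
    b0 = float(np.min(y))
    t0 = float(np.max(y))
    half = 0.5 * (b0 + t0)
    lec0 = float(x[np.argmin(np.abs(y - half))])
    p0 = np.array([b0, t0, lec0, 1.0])
    return np.minimum(np.maximum(p0, bounds_lo + 1e-9), bounds_hi - 1e-9)


def fit_4pl(
    log_conc,
    response=None,
    *,
    constrained: bool = True,
    drug_label: str = "",
    subject_id: str = "",
) -> FourPLFit:
    """Least-squares 4PL fit of normalised responses vs log10 concentration.

    Accepts either a :class:`ConcentrationResponseCurve` or two arrays.
    ``constrained=True`` (default) applies the physiological parameter box
    (Bottom in [-0.05, 0.2], Top in [0.5, 1.1], Hill in (0, 5]); pass
    ``constrained=False`` for an unconstrained fit (Hill kept positive).

    Raises
    ------
    InvalidInputError : fewer than 5 distinct concentrations.
    NoFitError : response range below 2% of E_max (flat data).
    ConvergenceError : optimiser failure, with diagnostics.
    """
    if isinstance(log_conc, ConcentrationResponseCurve):
        curve = log_conc
        x, y = curve.log_conc, curve.response
        drug_label = drug_label or ";".join(curve.drug_labels)
        subject_id = subject_id or curve.subject_id
    else:
        x = np.asarray(log_conc, dtype=float)
        y = np.asarray(response, dtype=float)

    if x.size == 0:
        raise InvalidInputError("empty concentration grid")
    if np.unique(x).size < 5:
        raise InvalidInputError(
            f"need >=5 distinct concentrations, got {np.unique(x).size}"
        )
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InvalidInputError("concentrations and responses must be finite")
    if np.ptp(y) < _FLAT_RANGE:
        raise NoFitError(
            f"response range {np.ptp(y):.4f} below the {_FLAT_RANGE} noise floor; "
            "no concentration dependence to fit"
        )

    if constrained:
        lo = np.array([
            PHYSIOLOGICAL_BOUNDS["bottom"][0],
            PHYSIOLOGICAL_BOUNDS["top"][0],
            x.min() - 2.0,
            PHYSIOLOGICAL_BOUNDS["hill_slope"][0],
        ])
        hi = np.array([
            PHYSIOLOGICAL_BOUNDS["bottom"][1],
            PHYSIOLOGICAL_BOUNDS["top"][1],
            x.max() + 2.0,
            PHYSIOLOGICAL_BOUNDS["hill_slope"][1],
        ])
    else:
        lo = np.array([-np.inf, -np.inf, x.min() - 6.0, 1e-6])
        hi = np.array([np.inf, np.inf, x.max() + 6.0, np.inf])

    p0 = _starting_values(x, y, lo, hi)
    try:
        popt, pcov = curve_fit(
            four_pl, x, y, p0=p0, bounds=(lo, hi), maxfev=20000, method="trf"
        )
    except RuntimeError as exc:  # pragma: no cover - rare optimiser failure
        raise ConvergenceError(
            "4PL fit did not converge",
            diagnostics={"p0": p0.tolist(), "n": int(x.size), "error": str(exc)},
        ) from exc

    resid = y - four_pl(x, *popt)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    names = ("bottom", "top", "log_ec50", "hill_slope")
    return FourPLFit(
        bottom=float(popt[0]),
        top=float(popt[1]),
        log_ec50=float(popt[2]),
        hill_slope=float(popt[3]),
        standard_errors={n: float(s) for n, s in zip(names, se)},
        rss=float(resid @ resid),
        n_points=int(x.size),
        drug_label=drug_label,
        subject_id=subject_id,
    )


def ec_n(fit, n_percent: float) -> float:
    """Concentration (mol/L) producing ``n_percent`` % of maximal effect.

    Closed form: EC_n = 10**log_ec50 * (f / (1 - f))**(1 / hill) with
    f = (n/100 - bottom) / (top - bottom). Requires bottom < n/100 < top.

    Works on any object with bottom/top/log_ec50/hill_slope attributes
    (a fitted curve or a generator ground truth).
    """
    level = float(n_percent) / 100.0
    if not (fit.bottom < level < fit.top):
        raise InvalidInputError(
            f"effect level {n_percent}% outside the attainable range "
            f"({fit.bottom:.3f}, {fit.top:.3f})"
        )
    f = (level - fit.bottom) / (fit.top - fit.bottom)
    return float(10.0 ** fit.log_ec50 * (f / (1.0 - f)) ** (1.0 / fit.hill_slope))


def isoeffective_grid(fits, levels_percent) -> list[IsoeffectivePair]:
    """Isoeffective concentration pairs across 2-3 fitted drugs.

    One pair per requested level (in % of maximal effect). Levels outside a
    drug's attainable (bottom, top) window are flagged ``attainable=False``
    rather than dropped; if no level is attainable by every drug an
    InvalidInputError is raised.
    """
    fits = list(fits)
    if not 2 <= len(fits) <= 3:
        raise InvalidInputError("isoeffective design needs 2 or 3 fitted drugs")
    labels = [f.drug_label or f"drug_{i}" for i, f in enumerate(fits)]
    pairs: list[IsoeffectivePair] = []
    any_ok = False
    for n in levels_percent:
        level = float(n) / 100.0
        missing = tuple(
            lab for lab, f in zip(labels, fits) if not (f.bottom < level < f.top)
        )
        if missing:
            pairs.append(
                IsoeffectivePair(level, {}, attainable=False, unattainable_drugs=missing)
            )
            continue
        conc = {lab: ec_n(f, n) for lab, f in zip(labels, fits)}
        pairs.append(IsoeffectivePair(level, conc))
        any_ok = True
    if not any_ok:
        raise InvalidInputError(
            "no requested effect level is attainable by every drug"
        )
    return pairs
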