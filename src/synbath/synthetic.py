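"""Synthetic organ-bath data generator.

Emulates the two experimental designs the analysis consumes, with a known
ground truth so every downstream estimator can be validated end to end:

* concentration-response curves (CRCs): per-subject variable-slope sigmoid
  relaxation with additive Gaussian noise on the normalised-effect scale,
  including combination curves built on the Bliss surface at isoeffective
  concentrations with a configurable injected synergy deviation;
* 12-h EFS time courses at a 5-min stimulation cadence: single agents
  plateauing at their EC-level effect, the combination following the Bliss
  expectation plus an injected synergy term over a configurable window
  (saturating-exponential onset, fast decay outside the window), a drug wash
  at 60 min, and a zero-mean time-control trace.

The generator is phenomenological — no receptor kinetics or cAMP dynamics —
and writes the tidy bath-table schema (raw tensions plus the papaverine and
pre-treatment EFS references) so that the normalisation steps are exercised
too. Every function is fully determined by ``SyntheticConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import crc as _crc
from .errors import InvalidInputError

__all__ = [
    "DrugTruth",
    "SyntheticConfig",
    "GLYCOPYRRONIUM",
    "INDACATEROL",
    "FORSKOLIN",
    "default_grid",
    "simulate_crc",
    "simulate_combination_crc",
    "simulate_efs_timecourse",
]

# Raw-signal encoding constants: per-subject precontraction plateau tension
# drawn uniformly from this range (g); papaverine relaxes to this fraction of
# the plateau. Purely presentational — normalisation inverts them exactly.
_PLATEAU_TENSION_RANGE = (1.5, 3.0)
_PAPAVERINE_FRACTION = 0.1

# Noisy responses are truncated to the physically plausible window on the
# normalised scale (slight undershoot below the plateau, E_max above 1).
_TRUNCATION = (-0.05, 1.10)


@dataclass
class DrugTruth:
    """Ground-truth 4PL parameters of one drug on the fraction-of-E_max scale."""

    label: str
    bottom: float
    top: float
    log_ec50: float
    hill_slope: float

    def __post_init__(self):
        if not self.top > self.bottom:
            raise InvalidInputError("top must exceed bottom")
        if not self.hill_slope > 0:
            raise InvalidInputError("hill_slope must be positive")
        if not -0.05 <= self.bottom <= 1.0 or not 0.0 < self.top <= 1.05:
            raise InvalidInputError("asymptotes outside the normalised-effect scale")

    @property
    def pec50(self) -> float:
        return -self.log_ec50

    def predict(self, log_conc):
        return _crc.four_pl(log_conc, self.bottom, self.top,
                            self.log_ec50, self.hill_slope)

    def ec(self, level: float) -> float:
        """Molar concentration producing the given fractional effect."""
        return _crc.ec_n(self, 100.0 * level)


# Reported potencies vs the acetylcholine EC70 tone in segmental bronchi:
# pEC50 8.44 (glycopyrronium) and 7.39 (indacaterol); E_max 99.68% and 92.28%.
GLYCOPYRRONIUM = DrugTruth("glycopyrronium", 0.0, 0.9968, -8.44, 1.0)
INDACATEROL = DrugTruth("indacaterol", 0.0, 0.9228, -7.39, 1.0)
# Forskolin is characterised in the triple design only by its isoeffective
# EC30 (56.2 nM); its log EC50 is back-derived assuming hill 1 and full range:
# EC50 = EC30 * (0.7 / 0.3).
FORSKOLIN = DrugTruth("forskolin", 0.0, 1.0, float(np.log10(56.2e-9 * 7 / 3)), 1.0)


@dataclass
class SyntheticConfig:
    """Generative truth shared by all fixtures; the seed fixes every draw."""

    drugs: list = field(default_factory=lambda: [GLYCOPYRRONIUM, INDACATEROL])
    n_subjects: int = 3
    noise_sd: float = 0.05            # fraction of E_max, per measurement
    synergy_delta: float = 0.0        # injected deviation from the Bliss surface
    synergy_window: tuple = (0.0, 540.0)   # min (EFS mode)
    concentration_grid: np.ndarray | None = None  # log10 mol/L
    efs_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 725.0, 5.0)
    )
    wash_time: float = 60.0           # min
    include_time_control: bool = True
    onset_half_time: float = 18.3     # min, saturating-exponential onset
    decay_half_time: float = 2.0      # min, synergy decay outside the window
    subject_effect_sd: float = 0.0    # per-subject shared offset (default off)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise InvalidInputError("n_subjects must be >= 2")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if not -1.0 <= self.synergy_delta <= 1.0:
            raise InvalidInputError("synergy_delta must lie in [-1, 1]")
        self.efs_grid = np.asarray(self.efs_grid, dtype=float)
        if self.efs_grid.size < 2 or np.any(np.diff(self.efs_grid) <= 0):
            raise InvalidInputError("efs_grid must be strictly increasing")
        if self.concentration_grid is not None:
            self.concentration_grid = np.asarray(self.concentration_grid, float)
            if self.concentration_grid.size == 0:
                raise InvalidInputError("empty concentration grid")
        w0, w1 = self.synergy_window
        if not (0.0 <= w0 < w1 <= float(self.efs_grid.max())):
            raise InvalidInputError("synergy_window must lie within the EFS grid")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["drugs"] = [asdict(t) for t in self.drugs]
        d["efs_grid"] = self.efs_grid.tolist()
        if self.concentration_grid is not None:
            d["concentration_grid"] = self.concentration_grid.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["drugs"] = [DrugTruth(**t) for t in d.get("drugs", [])]
        if d.get("efs_grid") is not None:
            d["efs_grid"] = np.asarray(d["efs_grid"], float)
        if d.get("concentration_grid") is not None:
            d["concentration_grid"] = np.asarray(d["concentration_grid"], float)
        d["synergy_window"] = tuple(d.get("synergy_window", (0.0, 540.0)))
        return cls(**d)


def default_grid(truth: DrugTruth, n_points: int = 8) -> np.ndarray:
    """Semi-logarithmic grid centred on the drug's log EC50 (one-decade steps)."""
    return truth.log_ec50 + np.linspace(-3.5, 3.5, n_points)


def _subject_ids(n: int) -> list[str]:
    return [f"S{i + 1}" for i in range(n)]


def _raw_from_fraction(resp, plateau):
    pap = _PAPAVERINE_FRACTION * plateau
    return plateau + resp * (pap - plateau), pap


def _efs_amplitude(relax, reference):
    return reference * (1.0 - relax)


def simulate_crc(truth: DrugTruth, cfg: SyntheticConfig) -> pd.DataFrame:
    """Per-subject single-agent CRC replicates in the tidy bath-table schema.

    response = 4PL(truth, x) + N(0, noise_sd), truncated to [-0.05, 1.10],
    encoded as raw tension against a per-subject plateau and papaverine
    reference. Zero noise reproduces the generating sigmoid exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    grid = cfg.concentration_grid
    if grid is None:
        grid = default_grid(truth)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidInputError("empty concentration grid")

    subjects = _subject_ids(cfg.n_subjects)
    plateaus = rng.uniform(*_PLATEAU_TENSION_RANGE, size=cfg.n_subjects)
    offsets = rng.normal(0.0, cfg.subject_effect_sd, size=cfg.n_subjects) \
        if cfg.subject_effect_sd > 0 else np.zeros(cfg.n_subjects)

    rows = []
    for s, subj in enumerate(subjects):
        resp = truth.predict(grid) + offsets[s]
        resp = resp + rng.normal(0.0, cfg.noise_sd, size=grid.size)
        resp = np.clip(resp, *_TRUNCATION)
        raw, pap = _raw_from_fraction(resp, plateaus[s])
        for x, r in zip(grid, raw):
            rows.append(
                {
                    "subject_id": subj,
                    "tissue": "bronchus",
                    "precontraction": "acetylcholine",
                    "drug_labels": truth.label,
                    "mode": "crc",
                    "concentration_molar": 10.0 ** x,
                    "time_min": np.nan,
                    "response_raw": r,
                    "papaverine_reference": pap,
                    "pretreatment_efs_reference": np.nan,
                }
            )
    return pd.DataFrame(rows)


def simulate_combination_crc(
    truth_a: DrugTruth,
    truth_b: DrugTruth,
    truth_c: DrugTruth | None = None,
    *,
    synergy_delta: float | None = None,
    cfg: SyntheticConfig,
    levels=tuple(np.round(np.arange(0.1, 0.91, 0.1), 10)),
):
    """Isoeffective combination design: singles and combination at each level.

    At each fractional effect level f every drug is dosed at its own EC_f, so
    each single agent contributes effect f and the Bliss expectation is
    1 - (1-f)**k. The combination response is
    clip(BI + synergy_delta, 0, 1) + noise; with ``synergy_delta = 0`` the
    combination lies on the Bliss surface in expectation.

    Returns ``(table, unattainable_levels)``; levels outside any drug's
    attainable range are flagged and skipped, not silently dropped.
    """
    truths = [t for t in (truth_a, truth_b, truth_c) if t is not None]
    delta = cfg.synergy_delta if synergy_delta is None else float(synergy_delta)
    if not -1.0 <= delta <= 1.0:
        raise InvalidInputError("synergy_delta must lie in [-1, 1]")
    rng = np.random.default_rng(cfg.seed)
    subjects = _subject_ids(cfg.n_subjects)
    plateaus = rng.uniform(*_PLATEAU_TENSION_RANGE, size=cfg.n_subjects)

    rows = []
    unattainable = []
    combo_label = ";".join(t.label for t in truths)
    for f in levels:
        f = float(f)
        if any(not (t.bottom < f < t.top) for t in truths):
            unattainable.append(f)
            continue
        concs = [t.ec(f) for t in truths]
        expected = 1.0 - (1.0 - f) ** len(truths)
        target = float(np.clip(expected + delta, 0.0, 1.0))
        for s, subj in enumerate(subjects):
            for t, c in zip(truths, concs):
                r = np.clip(f + rng.normal(0.0, cfg.noise_sd), *_TRUNCATION)
                raw, pap = _raw_from_fraction(r, plateaus[s])
                rows.append(
                    {
                        "subject_id": subj,
                        "tissue": "bronchus",
                        "precontraction": "acetylcholine",
                        "drug_labels": t.label,
                        "mode": "crc",
                        "concentration_molar": c,
                        "time_min": np.nan,
                        "response_raw": raw,
                        "papaverine_reference": pap,
                        "pretreatment_efs_reference": np.nan,
                    }
                )
            r = np.clip(target + rng.normal(0.0, cfg.noise_sd), *_TRUNCATION)
            raw, pap = _raw_from_fraction(r, plateaus[s])
            rows.append(
                {
                    "subject_id": subj,
                    "tissue": "bronchus",
                    "precontraction": "acetylcholine",
                    "drug_labels": combo_label,
                    "mode": "combination_crc",
                    "concentration_molar": ";".join(repr(float(c)) for c in concs),
                    "time_min": np.nan,
                    "response_raw": raw,
                    "papaverine_reference": pap,
                    "pretreatment_efs_reference": np.nan,
                }
            )
    return pd.DataFrame(rows), unattainable


def _onset(t, half_time):
    return 1.0 - 2.0 ** (-np.maximum(t, 0.0) / half_time)


def _synergy_profile(t, delta, window, onset_half, decay_half):
    w0, w1 = window
    rise = delta * _onset(t - w0, onset_half)
    peak = delta * _onset(w1 - w0, onset_half)
    out = np.where(t < w0, 0.0, np.where(t <= w1, rise,
                                         peak * 2.0 ** (-(t - w1) / decay_half)))
    return out


def simulate_efs_timecourse(
    truths,
    per_drug_effect: float = 0.2,
    *,
    synergy_delta: float | None = None,
    cfg: SyntheticConfig,
) -> pd.DataFrame:
    """Per-subject EFS traces: single agents, combination, and time control.

    Single agents rise with the onset half-time to ``per_drug_effect`` and
    plateau there; the combination follows the Bliss expectation of those
    traces plus the injected synergy term inside ``cfg.synergy_window``
    (decaying with ``cfg.decay_half_time`` outside). The time control
    fluctuates around zero relaxation. Raw EFS amplitudes are encoded
    against a per-subject pre-treatment reference contraction.
    """
    truths = list(truths)
    if not 0.0 < per_drug_effect < 1.0:
        raise InvalidInputError("per_drug_effect must lie in (0, 1)")
    delta = cfg.synergy_delta if synergy_delta is None else float(synergy_delta)
    t = cfg.efs_grid
    if cfg.wash_time >= float(t.max()):
        raise InvalidInputError("wash_time must precede the end of the EFS grid")

    rng = np.random.default_rng(cfg.seed)
    subjects = _subject_ids(cfg.n_subjects)
    references = rng.uniform(*_PLATEAU_TENSION_RANGE, size=cfg.n_subjects)
    offsets = rng.normal(0.0, cfg.subject_effect_sd, size=cfg.n_subjects) \
        if cfg.subject_effect_sd > 0 else np.zeros(cfg.n_subjects)

    single = per_drug_effect * _onset(t, cfg.onset_half_time)
    base = 1.0 - (1.0 - single) ** len(truths)
    syn = _synergy_profile(t, delta, cfg.synergy_window,
                           cfg.onset_half_time, cfg.decay_half_time)
    combo = np.clip(base + syn, 0.0, 1.0)
    combo_label = ";".join(tr.label for tr in truths)

    conditions = [(tr.label, "efs", single) for tr in truths]
    conditions.append((combo_label, "efs", combo))
    if cfg.include_time_control:
        conditions.append(("vehicle", "time_control", np.zeros_like(t)))

    rows = []
    for s, subj in enumerate(subjects):
        for label, mode, mean_trace in conditions:
            relax = mean_trace + (offsets[s] if mode == "efs" else 0.0)
            relax = relax + rng.normal(0.0, cfg.noise_sd, size=t.size)
            relax = np.clip(relax, *_TRUNCATION)
            amp = _efs_amplitude(relax, references[s])
            for ti, a in zip(t, amp):
                rows.append(
                    {
                        "subject_id": subj,
                        "tissue": "bronchus",
                        "precontraction": "EFS",
                        "drug_labels": label,
                        "mode": mode,
                        "concentration_molar": np.nan,
                        "time_min": ti,
                        "response_raw": a,
                        "papaverine_reference": np.nan,
                        "pretreatment_efs_reference": references[s],
                    }
                )
    return pd.DataFrame(rows)
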