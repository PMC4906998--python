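"""Tidy bath-table CSV schema, run configuration, and normalisation helpers.

One canonical unit system: concentrations are stored in mol/L (";"-joined
for combination rows, one value per drug), effects as fractions of the
papaverine E_max; percentages appear only in rendered reports. Exactly one
of ``concentration_molar`` / ``time_min`` is populated per row.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import timecourse as _tc
from .errors import SchemaError
from .synthetic import SyntheticConfig

__all__ = [
    "COLUMNS",
    "read_bath_table",
    "write_bath_table",
    "normalize_table",
    "parse_concentrations",
    "RunConfig",
]

COLUMNS = (
    "subject_id",
    "tissue",
    "precontraction",
    "drug_labels",
    "mode",
    "concentration_molar",
    "time_min",
    "response_raw",
    "papaverine_reference",
    "pretreatment_efs_reference",
)

_MODES = {"crc", "efs", "combination_crc", "time_control"}
_CRC_MODES = {"crc", "combination_crc"}


def parse_concentrations(value) -> tuple[float, ...]:
    """Parse a concentration cell: one molar value, or ";"-joined for combos."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return (float(value),)
    return tuple(float(p) for p in str(value).split(";"))


def _is_blank(v) -> bool:
    if v is None:
        return True
    if isinstance(v, float) and np.isnan(v):
        return True
    return isinstance(v, str) and v.strip() == ""


def read_bath_table(path) -> pd.DataFrame:
    """Read and validate a tidy bath table; collects row errors with line numbers.

    Columns are header-keyed, so order is free. Raises :class:`SchemaError`
    naming missing columns, or carrying the list of row-level problems.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    df = pd.read_csv(
        path,
        dtype={"concentration_molar": "object"},
        float_precision="round_trip",
    )
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    df = df[list(COLUMNS) + [c for c in df.columns if c not in COLUMNS]]

    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header occupies line 1
        mode = row["mode"]
        if mode not in _MODES:
            errors.append(f"line {line}: unknown mode {mode!r}")
            continue
        has_conc = not _is_blank(row["concentration_molar"])
        has_time = not _is_blank(row["time_min"])
        if has_conc == has_time:
            errors.append(
                f"line {line}: exactly one of concentration_molar/time_min "
                "must be populated"
            )
        if has_conc:
            try:
                parse_concentrations(row["concentration_molar"])
            except ValueError:
                errors.append(
                    f"line {line}: non-numeric concentration_molar "
                    f"{row['concentration_molar']!r}"
                )
        if not np.isfinite(row["response_raw"]):
            errors.append(f"line {line}: non-numeric response_raw")
        if mode in _CRC_MODES and _is_blank(row["papaverine_reference"]):
            errors.append(
                f"line {line}: papaverine_reference required on {mode} rows"
            )
        if mode in {"efs", "time_control"} and _is_blank(
            row["pretreatment_efs_reference"]
        ):
            errors.append(
                f"line {line}: pretreatment_efs_reference required on {mode} rows"
            )
    if errors:
        raise SchemaError(
            f"{len(errors)} invalid row(s) in {path.name}", row_errors=errors
        )
    return df


def write_bath_table(df: pd.DataFrame, path) -> None:
    """Write a tidy bath table (UTF-8, '.' decimals, comma separator)."""
    df.to_csv(path, index=False, columns=list(COLUMNS))


def normalize_table(df: pd.DataFrame) -> pd.DataFrame:
    """Add a ``response`` column of normalised fractions to a bath table.

    CRC rows are normalised against the papaverine reference (plateau -> 0,
    papaverine -> 1); EFS rows against the pre-treatment control contraction
    (relaxation fraction). The input is not modified.
    """
    from .synthetic import _PAPAVERINE_FRACTION

    out = df.copy()
    resp = np.full(len(out), np.nan)
    is_crc = out["mode"].isin(_CRC_MODES).to_numpy()
    is_efs = out["mode"].isin({"efs", "time_control"}).to_numpy()
    if is_crc.any():
        raw = out.loc[is_crc, "response_raw"].to_numpy(float)
        pap = out.loc[is_crc, "papaverine_reference"].to_numpy(float)
        # The generator encodes papaverine at a fixed fraction of the
        # precontraction plateau; recover the plateau from the reference.
        # Real data would carry the plateau directly; the linear map is the
        # same either way (plateau -> 0, papaverine -> 1).
        plateau = pap / _PAPAVERINE_FRACTION
        resp[is_crc] = (raw - plateau) / (pap - plateau)
    if is_efs.any():
        amp = out.loc[is_efs, "response_raw"].to_numpy(float)
        ref = out.loc[is_efs, "pretreatment_efs_reference"].to_numpy(float)
        resp[is_efs] = 1.0 - amp / ref
    out["response"] = resp
    return out


@dataclass
class RunConfig:
    """End-to-end run parameters; loss-lessly (de)serialisable to JSON."""

    mode: str = "run-all"
    alpha: float = 0.05
    ec_levels: tuple = tuple(np.round(np.arange(0.1, 0.91, 0.1), 10))
    intervals: tuple = _tc.DEFAULT_INTERVALS
    pairing: str = "by_subject"
    seed: int = 0
    out_dir: str | None = None
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise SchemaError("alpha must lie in (0, 1)")
        self.ec_levels = tuple(float(v) for v in self.ec_levels)
        self.intervals = tuple((float(a), float(b)) for a, b in self.intervals)

    def to_json(self) -> str:
        d = asdict(self)
        d["synthetic"] = self.synthetic.to_dict()
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["synthetic"] = SyntheticConfig.from_dict(d.get("synthetic", {}))
        d["ec_levels"] = tuple(d.get("ec_levels", ()))
        d["intervals"] = tuple(tuple(iv) for iv in d.get("intervals", ()))
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]
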