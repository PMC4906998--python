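import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import synbath as sb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def quiet_cfg():
    """Noise-free generator configuration."""
    return sb.SyntheticConfig(noise_sd=0.0, seed=0)


@pytest.fixture
def default_cfg():
    return sb.SyntheticConfig(seed=0)


@pytest.fixture
def unit_gly():
    """Glycopyrronium-like truth with full 0-1 range (hill 1)."""
    return sb.DrugTruth("glycopyrronium", 0.0, 1.0, -8.44, 1.0)


@pytest.fixture
def unit_ind():
    """Indacaterol-like truth with full 0-1 range (hill 1)."""
    return sb.DrugTruth("indacaterol", 0.0, 1.0, -7.39, 1.0)


@pytest.fixture
def full_range_fit():
    def make(log_ec50=-8.0, hill=1.0, bottom=0.0, top=1.0, label="drug"):
        return sb.FourPLFit(
            bottom=bottom, top=top, log_ec50=log_ec50, hill_slope=hill,
            drug_label=label,
        )

    return make


def subject_mean_pec50(table):
    """Per-subject 4PL fits of a single-drug CRC table; mean pEC50."""
    from synbath import io as _io

    norm = _io.normalize_table(table)
    vals = []
    for _, grp in norm.groupby("subject_id"):
        fit = sb.fit_4pl(
            np.log10(grp["concentration_molar"].astype(float).to_numpy()),
            grp["response"].to_numpy(float),
        )
        vals.append(fit.pec50)
    return float(np.mean(vals))
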