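"""Generator contracts: determinism, zero-noise identities, injected truth."""

import numpy as np
import pytest

import synbath as sb
from synbath import io as _io
from synbath.errors import InvalidInputError


def normalized(table):
    return _io.normalize_table(table)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 1},
            {"noise_sd": -0.1},
            {"synergy_delta": 1.5},
            {"efs_grid": np.array([0.0, 10.0, 10.0])},
            {"synergy_window": (0.0, 2000.0)},
            {"concentration_grid": np.array([])},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(InvalidInputError):
            sb.SyntheticConfig(**kwargs)

    def test_drug_truth_invariants(self):
        with pytest.raises(InvalidInputError):
            sb.DrugTruth("x", 0.5, 0.4, -8.0, 1.0)
        with pytest.raises(InvalidInputError):
            sb.DrugTruth("x", 0.0, 1.0, -8.0, -1.0)


class TestSimulateCrc:
    def test_zero_noise_reproduces_the_sigmoid(self, unit_gly, quiet_cfg):
        table = sb.simulate_crc(unit_gly, quiet_cfg)
        norm = normalized(table)
        x = np.log10(norm["concentration_molar"].astype(float).to_numpy())
        assert np.allclose(
            norm["response"].to_numpy(), unit_gly.predict(x), atol=1e-12
        )

    def test_seeded_determinism_is_byte_identical(self, unit_gly):
        cfg = sb.SyntheticConfig(seed=42)
        a = sb.simulate_crc(unit_gly, cfg).to_csv(index=False)
        b = sb.simulate_crc(unit_gly, sb.SyntheticConfig(seed=42)).to_csv(index=False)
        assert a == b
        c = sb.simulate_crc(unit_gly, sb.SyntheticConfig(seed=43)).to_csv(index=False)
        assert a != c

    def test_ensemble_mean_converges_to_generating_curve(self, unit_gly):
        # mean of subject means over many simulations approaches the truth
        # away from the truncation boundaries (interior of the response range)
        n_sims = 1000
        grid = unit_gly.log_ec50 + np.linspace(-1.0, 1.0, 5)  # responses 0.09-0.91
        acc = np.zeros(grid.size)
        for s in range(n_sims):
            cfg = sb.SyntheticConfig(seed=s, concentration_grid=grid)
            norm = normalized(sb.simulate_crc(unit_gly, cfg))
            acc += norm.groupby("concentration_molar")["response"].mean().to_numpy()
        mean_curve = acc / n_sims
        truth = unit_gly.predict(np.sort(grid))
        se = 0.05 / np.sqrt(3 * n_sims)
        assert np.all(np.abs(mean_curve - truth) <= 3 * se + 1e-12)


class TestSimulateCombination:
    def test_null_surface_zero_noise(self, unit_gly, unit_ind, quiet_cfg):
        table, missing = sb.simulate_combination_crc(
            unit_gly, unit_ind, cfg=quiet_cfg
        )
        assert missing == []
        norm = normalized(table)
        combos = norm[norm["mode"] == "combination_crc"]
        singles = norm[norm["mode"] == "crc"]
        for key, grp in combos.groupby("concentration_molar"):
            conc = _io.parse_concentrations(key)
            f = unit_gly.predict(np.log10(conc[0]))
            assert np.allclose(grp["response"], 1 - (1 - f) ** 2, atol=1e-9)
        # single agents measured exactly at their isoeffective effect level
        for _, row in singles.iterrows():
            truth = unit_gly if row["drug_labels"] == "glycopyrronium" else unit_ind
            f = truth.predict(np.log10(float(row["concentration_molar"])))
            assert abs(row["response"] - f) < 1e-9

    def test_injected_delta_recovered_exactly_without_noise(
        self, unit_gly, unit_ind, quiet_cfg
    ):
        table, _ = sb.simulate_combination_crc(
            unit_gly, unit_ind, synergy_delta=0.30, cfg=quiet_cfg, levels=(0.2, 0.3)
        )
        from synbath.pipeline import assess_combination_table

        out = assess_combination_table(table)
        assert np.allclose(out["delta"], 30.0, atol=1e-9)  # percentage points

    def test_unattainable_levels_are_flagged(self, unit_gly, quiet_cfg):
        low_top = sb.DrugTruth("ind", 0.0, 0.9228, -7.39, 1.0)
        _, missing = sb.simulate_combination_crc(
            unit_gly, low_top, cfg=quiet_cfg, levels=(0.5, 0.95)
        )
        assert missing == [0.95]

    def test_mean_recovered_delta_under_noise(self, unit_gly, unit_ind):
        # Monte-Carlo: the delta estimator is unbiased for the injected truth
        from synbath.pipeline import assess_combination_table

        deltas = []
        for s in range(200):
            cfg = sb.SyntheticConfig(seed=s, noise_sd=0.05)
            table, _ = sb.simulate_combination_crc(
                unit_gly, unit_ind, synergy_delta=0.30, cfg=cfg, levels=(0.3,)
            )
            deltas.append(assess_combination_table(table)["delta"].iloc[0])
        deltas = np.asarray(deltas)
        ci = 3 * deltas.std(ddof=1) / np.sqrt(deltas.size)
        assert abs(deltas.mean() - 30.0) <= ci


class TestSimulateEfs:
    def test_bliss_null_plateau(self, unit_gly, unit_ind, quiet_cfg):
        table = sb.simulate_efs_timecourse(
            [unit_gly, unit_ind], per_drug_effect=0.2, cfg=quiet_cfg
        )
        norm = normalized(table)
        combo = norm[norm["drug_labels"].str.contains(";")]
        late = combo[combo["time_min"] == 720.0]
        assert np.allclose(late["response"], 0.36, atol=1e-6)

    def test_time_control_is_exactly_zero_without_noise(self, quiet_cfg, unit_gly, unit_ind):
        table = sb.simulate_efs_timecourse([unit_gly, unit_ind], cfg=quiet_cfg)
        tc = normalized(table)
        tc = tc[tc["mode"] == "time_control"]
        assert np.allclose(tc["response"], 0.0, atol=1e-12)

    def test_invalid_wash_time(self, unit_gly, unit_ind):
        cfg = sb.SyntheticConfig(wash_time=800.0)
        with pytest.raises(InvalidInputError):
            sb.simulate_efs_timecourse([unit_gly, unit_ind], cfg=cfg)

    def test_per_drug_effect_domain(self, unit_gly, unit_ind, quiet_cfg):
        with pytest.raises(InvalidInputError):
            sb.simulate_efs_timecourse(
                [unit_gly, unit_ind], per_drug_effect=1.2, cfg=quiet_cfg
            )

    def test_synergy_confined_to_window(self, unit_gly, unit_ind):
        cfg = sb.SyntheticConfig(
            noise_sd=0.0, synergy_delta=0.30, synergy_window=(0.0, 300.0)
        )
        norm = normalized(sb.simulate_efs_timecourse([unit_gly, unit_ind], cfg=cfg))
        combo = norm[norm["drug_labels"].str.contains(";")]
        s1 = combo[combo["time_min"] == 295.0]["response"].iloc[0]
        s2 = combo[combo["time_min"] == 400.0]["response"].iloc[0]
        assert s1 > 0.6          # base 0.36 + injected 0.30
        # well past the window the injected synergy has decayed away and only
        # the (nearly saturated) Bliss base remains
        assert abs(s2 - 0.36) < 1e-6
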