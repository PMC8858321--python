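"""Panel normalization, log-dose trend test and responder calling."""

import numpy as np
import pandas as pd
import pytest

import senescreen as ss
from senescreen.panel import normalize_panel, trend_test

DOSES = (0.25, 1.0, 5.0)


def panel_frame(rows):
    return pd.DataFrame(
        rows, columns=["cell_line", "drug", "dose_uM", "replicate", "absorbance"]
    )


def flat_panel(lines=("L1",), drugs=("d1",), value=0.8, n_reps=3):
    rows = []
    for line in lines:
        for drug in drugs:
            for dose in (0.0,) + DOSES:
                for rep in range(1, n_reps + 1):
                    rows.append((line, drug, dose, rep, value))
    return panel_frame(rows)


class TestNormalizePanel:
    def test_forced_arithmetic(self):
        rows = [("L", "d", 0.0, 1, 0.8), ("L", "d", 1.0, 1, 0.4)]
        norm = normalize_panel(panel_frame(rows))
        assert norm.loc[norm.dose_uM == 1.0, "norm"].iloc[0] == pytest.approx(0.5)

    def test_vehicle_mean_normalizes_to_one(self):
        rows = [("L", "d", 0.0, 1, 0.6), ("L", "d", 0.0, 2, 1.0)]
        norm = normalize_panel(panel_frame(rows))
        assert norm["norm"].mean() == pytest.approx(1.0)

    def test_scale_invariance(self):
        panel = flat_panel(value=0.8)
        scaled = panel.assign(absorbance=panel["absorbance"] * 7.3)
        assert np.allclose(
            normalize_panel(panel)["norm"], normalize_panel(scaled)["norm"]
        )

    def test_per_condition_vehicle(self):
        """Each (line, drug) pair uses its own vehicle wells."""
        rows = [
            ("L", "a", 0.0, 1, 1.0),
            ("L", "a", 1.0, 1, 0.5),
            ("L", "b", 0.0, 1, 2.0),
            ("L", "b", 1.0, 1, 0.5),
        ]
        norm = normalize_panel(panel_frame(rows)).set_index(["drug", "dose_uM"])
        assert norm.loc[("a", 1.0), "norm"] == pytest.approx(0.5)
        assert norm.loc[("b", 1.0), "norm"] == pytest.approx(0.25)

    def test_missing_vehicle_rejected(self):
        with pytest.raises(ValueError, match="vehicle"):
            normalize_panel(panel_frame([("L", "d", 1.0, 1, 0.5)]))

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            normalize_panel(pd.DataFrame({"cell_line": ["L"]}))


class TestTrendTest:
    def doses_vec(self, n_reps=3):
        return np.repeat(DOSES, n_reps)

    def test_flat_data(self):
        doses = self.doses_vec()
        slope, p = trend_test(np.full_like(doses, 0.9), doses)
        assert slope == pytest.approx(0.0)
        assert p == pytest.approx(0.5)

    def test_noiseless_decreasing_highly_significant(self):
        doses = self.doses_vec()
        values = 1.0 - 0.2 * np.log10(doses) + np.tile([-0.001, 0.0, 0.001], 3)
        slope, p = trend_test(values, doses)
        assert slope < 0 and p < 1e-4

    def test_direction_flip_complements_p(self):
        rng = np.random.default_rng(0)
        doses = self.doses_vec()
        values = 1.0 - 0.1 * np.log10(doses) + rng.normal(0, 0.05, len(doses))
        slope_dn, p_dn = trend_test(values, doses)
        slope_up, p_up = trend_test(2.0 - values, doses)
        assert slope_up == pytest.approx(-slope_dn)
        assert p_up == pytest.approx(1.0 - p_dn)

    def test_vehicle_rows_ignored(self):
        doses = np.concatenate([[0.0, 0.0], self.doses_vec()])
        values = np.concatenate([[5.0, 5.0], 1.0 - 0.2 * np.log10(self.doses_vec())])
        with_veh = trend_test(values, doses)
        without = trend_test(values[2:], doses[2:])
        assert with_veh == pytest.approx(without)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError, match="dose"):
            trend_test([1.0, 0.9, 1.0, 0.9], [0.25, 0.25, 1.0, 1.0])

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            trend_test([1.0, 0.9, 0.8], [0.25, 1.0, 5.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            trend_test([1.0], [0.25, 1.0])


class TestCallResponders:
    def test_noiseless_responsive_called(self):
        truth = {("L1", d): 0.6 for d in ss.DRUGS}
        panel = ss.simulate_panel(truth, noise_sd=0.0, seed=1)
        summary, details = ss.call_responders(panel)
        assert summary.loc["L1", "is_responder"]
        assert summary.loc["L1", "n_drugs_responsive"] == 3
        assert details["reason"].eq("").all()

    def test_noiseless_non_responsive_never_called(self):
        truth = {("L1", d): 0.0 for d in ss.DRUGS}
        panel = ss.simulate_panel(truth, noise_sd=0.0, seed=1)
        for alpha in (0.01, 0.05, 0.2, 0.49):
            summary, _ = ss.call_responders(panel, alpha=alpha)
            assert not summary.loc["L1", "is_responder"]

    def test_min_drugs_rule(self):
        truth = {("L1", d): 0.6 for d in ss.DRUGS[:2]}
        truth[("L1", ss.DRUGS[2])] = 0.0
        panel = ss.simulate_panel(truth, noise_sd=0.0, seed=1)
        s2, _ = ss.call_responders(panel, min_drugs=2)
        s3, _ = ss.call_responders(panel, min_drugs=3)
        assert s2.loc["L1", "is_responder"] and not s3.loc["L1", "is_responder"]

    def test_monotone_in_min_drugs_and_alpha(self):
        panel = ss.simulate_panel(ss.primary_panel_truth(), seed=11)
        base = ss.call_responders(panel, alpha=0.05, min_drugs=2)[0]["is_responder"]
        stricter = ss.call_responders(panel, alpha=0.01, min_drugs=2)[0]["is_responder"]
        fewer = ss.call_responders(panel, alpha=0.05, min_drugs=3)[0]["is_responder"]
        assert (stricter <= base).all() and (fewer <= base).all()

    def test_untestable_condition_recorded_not_raised(self):
        rows = [("L1", "d1", dose, rep, 0.9) for dose in (0.0, 0.25, 1.0) for rep in (1, 2)]
        summary, details = ss.call_responders(panel_frame(rows))
        assert not summary.loc["L1", "is_responder"]
        assert "dose" in details.loc[0, "reason"]

    def test_invalid_parameters_rejected(self):
        panel = flat_panel()
        with pytest.raises(ValueError):
            ss.call_responders(panel, alpha=0.0)
        with pytest.raises(ValueError):
            ss.call_responders(panel, min_drugs=0)

    def test_sensitivity_and_specificity_across_seeds(self):
        """At the declared design (effect 0.6, noise 0.05, 3 doses x 3 reps),
        per-line classification accuracy exceeds 95% on both classes."""
        truth = ss.primary_panel_truth()
        should = set(ss.PRIMARY_RESPONDER_LINES)
        tp = fn = tn = fp = 0
        for seed in range(50):
            panel = ss.simulate_panel(truth, seed=seed)
            called = set(ss.responder_lines(ss.call_responders(panel)[0]))
            tp += len(called & should)
            fn += len(should - called)
            fp += len(called - should)
            tn += len(set(ss.PANEL_LINES) - should - called)
        assert tp / (tp + fn) >= 0.95
        assert tn / (tn + fp) >= 0.95


class TestSecondaryConfirmation:
    def test_confirmed_subset_of_primary(self):
        primary = ss.simulate_panel(ss.primary_panel_truth(), seed=21)
        summary, _ = ss.call_responders(primary)
        secondary = ss.simulate_panel(ss.secondary_panel_truth(), seed=22)
        secondary = secondary[secondary["cell_line"].isin(ss.responder_lines(summary))]
        confirmed, _ = ss.secondary_confirmation(summary, secondary)
        assert set(confirmed) <= set(ss.responder_lines(summary))

    def test_idempotent_when_secondary_identical(self):
        panel = ss.simulate_panel(ss.primary_panel_truth(), seed=23)
        summary, _ = ss.call_responders(panel)
        responders = ss.responder_lines(summary)
        same = panel[panel["cell_line"].isin(responders)]
        confirmed, _ = ss.secondary_confirmation(summary, same)
        assert sorted(confirmed) == sorted(responders)

    def test_extra_lines_warned_and_ignored(self):
        primary = ss.simulate_panel(ss.primary_panel_truth(), noise_sd=0.0, seed=1)
        summary, _ = ss.call_responders(primary)
        # a secondary panel over all 22 lines includes non-responders
        secondary = ss.simulate_panel(ss.primary_panel_truth(), seed=24)
        with pytest.warns(UserWarning, match="ignored"):
            confirmed, sec_summary = ss.secondary_confirmation(summary, secondary)
        assert set(sec_summary.index) <= set(ss.responder_lines(summary))

    def test_no_primary_responders_returns_empty(self):
        flat = flat_panel(lines=("L1", "L2"), drugs=ss.DRUGS)
        summary, _ = ss.call_responders(flat)
        confirmed, sec = ss.secondary_confirmation(summary, flat.iloc[0:0])
        assert confirmed == [] and sec.empty
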