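"""ROC construction, outlet binning, flow-rate selection, sorting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spiralsort import populations as pop
from spiralsort import sorter
from spiralsort.errors import ConfigError, InputError, MissingModelEntryError


class TestRocCurve:
    def test_identical_samples_auc_half(self, rng):
        x = rng.normal(100.0, 10.0, 20_000)
        assert sorter.roc_curve(x, x.copy()).auc == pytest.approx(0.5, abs=0.01)

    def test_perfect_separation(self):
        t = np.linspace(0, 40, 100)
        c = np.linspace(100, 170, 100)
        assert sorter.roc_curve(t, c).auc == pytest.approx(1.0)

    def test_endpoints_and_monotonicity(self, rng):
        r = sorter.roc_curve(rng.normal(36, 21, 1_000), rng.normal(103, 32, 1_000))
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(r.tpr) >= 0).all() and (np.diff(r.fpr) >= 0).all()

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            sorter.roc_curve(np.array([]), np.array([1.0]))

    def test_antisymmetry(self, rng):
        a = rng.normal(50, 10, 5_000)
        b = rng.normal(70, 15, 5_000)
        assert sorter.roc_curve(a, b).auc == pytest.approx(
            1.0 - sorter.roc_curve(b, a).auc, abs=1e-9
        )


class TestGaussianAuc:
    def test_equal_means(self):
        assert sorter.gaussian_auc(50, 10, 50, 10) == 0.5

    def test_printed_high_rate_pairs(self):
        assert sorter.gaussian_auc(36, 21, 103, 32) == pytest.approx(0.960, abs=0.001)
        assert sorter.gaussian_auc(36, 21, 154, 18) > 0.999

    def test_matches_normal_cdf_oracle(self):
        assert sorter.gaussian_auc(100, 24, 110, 20) == pytest.approx(
            float(stats.norm.cdf(10 / np.hypot(24, 20))), abs=1e-12
        )

    @pytest.mark.parametrize(
        "pair",
        [
            ((36, 21), (103, 32)),
            ((36, 21), (154, 18)),
            ((100, 24), (110, 20)),
            ((131, 23), (134, 11)),
        ],
    )
    def test_empirical_converges_to_closed_form(self, pair):
        """Trapezoid AUC agrees with the Gaussian closed form at 1e5 draws."""
        (m1, s1), (m2, s2) = pair
        rng = np.random.default_rng(np.random.SeedSequence(404))
        emp = sorter.roc_curve(
            rng.normal(m1, s1, 100_000), rng.normal(m2, s2, 100_000)
        ).auc
        assert emp == pytest.approx(sorter.gaussian_auc(m1, s1, m2, s2), abs=0.005)


class TestFitPositionModel:
    def test_plain_sample_statistics(self, rng):
        x = rng.normal(36, 21, 50_000)
        mu, sd = sorter.fit_position_model(x)
        assert mu == pytest.approx(x.mean()) and sd == pytest.approx(x.std(ddof=1))

    def test_truncation_aware_mle_removes_bias(self):
        rng = np.random.default_rng(np.random.SeedSequence(11))
        a, b = (0 - 36) / 21, (170 - 36) / 21
        x = stats.truncnorm.rvs(a, b, loc=36, scale=21, size=20_000, random_state=rng)
        naive_mu = x.mean()
        mu, sd = sorter.fit_position_model(x, lower=0.0, upper=170.0)
        assert abs(mu - 36.0) < abs(naive_mu - 36.0)
        assert mu == pytest.approx(36.0, abs=1.0)
        assert sd == pytest.approx(21.0, abs=1.0)


class TestOutletBins:
    def test_default_quarters(self):
        bins = sorter.OutletBins()
        assert bins.labels == ("A", "B", "C", "D")
        assert bins.width_um == 170.0

    def test_edges_must_increase(self):
        with pytest.raises(ConfigError):
            sorter.OutletBins(edges_um=(0.0, 85.0, 42.5, 170.0))

    def test_all_low_positions_in_a(self):
        counts = sorter.positions_to_outlets(np.array([1.0, 20.0, 42.4]))
        assert counts["A"] == 3 and counts.sum() == 3

    def test_boundary_half_open(self):
        assert sorter.outlet_of(42.5) == "B"
        assert sorter.outlet_of(170.0) == "D"  # last bin closed

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            sorter.positions_to_outlets(np.array([-0.1]))

    def test_conservation(self, rng):
        pos = rng.uniform(0, 170, 1_234)
        assert sorter.positions_to_outlets(pos).sum() == 1_234


class TestSelectFlowRate:
    def test_highest_rate_wins_with_printed_model(self, model):
        sel = sorter.select_flow_rate(model, [0.2, 0.4, 0.6, 0.8, 1.0], seed=1)
        assert sel.flow_rate_ml_min == 1.0

    def test_low_rate_auc_matches_printed_overlap(self, model):
        sel = sorter.select_flow_rate(model, [0.2, 0.4, 0.6, 0.8, 1.0], seed=1)
        row = sel.auc_table.set_index("flow_rate_ml_min").loc[0.2]
        assert row["auc_vs_nucleated"] == pytest.approx(0.62, abs=0.015)
        assert np.isnan(row["auc_vs_nucleus"])  # no nuclei data at 0.2

    def test_high_rate_dominates_for_nuclei(self, model):
        sel = sorter.select_flow_rate(model, [0.4, 0.6, 0.8, 1.0], seed=2)
        t = sel.auc_table.set_index("flow_rate_ml_min")["auc_vs_nucleus"]
        assert t.loc[1.0] == t.max()

    def test_single_candidate(self, model):
        sel = sorter.select_flow_rate(model, [0.4], seed=3)
        assert sel.flow_rate_ml_min == 0.4

    def test_deterministic_per_seed(self, model):
        a = sorter.select_flow_rate(model, [0.4, 1.0], seed=9)
        b = sorter.select_flow_rate(model, [0.4, 1.0], seed=9)
        pd.testing.assert_frame_equal(a.auc_table, b.auc_table)

    def test_no_usable_candidate_rejected(self, model):
        with pytest.raises(InputError):
            sorter.select_flow_rate(model, [0.05], seed=1)


class TestSimulateSort:
    @pytest.fixture()
    def small_table(self, presets):
        table = pop.generate_events(presets["I"], 3_000, seed=6)
        return table[table["true_class"] != pop.DEBRIS].reset_index(drop=True)

    def test_event_conservation(self, small_table, model):
        outlets = sorter.simulate_sort(small_table, model, 1.0, seed=4)
        assert sum(len(t) for t in outlets.values()) == len(small_table)

    def test_nuclei_concentrate_inner_wall(self, small_table, model):
        """At 1 ml/min nuclei (154 ± 18 µm) are overwhelmingly in outlet D."""
        outlets = sorter.simulate_sort(small_table, model, 1.0, seed=4)
        n_nuc = {
            k: (t["true_class"] == "nucleus").sum() for k, t in outlets.items()
        }
        total = sum(n_nuc.values())
        assert n_nuc["D"] / total > 0.85

    def test_zero_sd_model_is_deterministic(self, small_table):
        m = sorter.FocusingModel(
            entries={
                ("enucleated", 1.0): (20.0, 0.0),
                ("nucleated", 1.0): (100.0, 0.0),
                ("nucleus", 1.0): (150.0, 0.0),
            }
        )
        outlets = sorter.simulate_sort(small_table, m, 1.0, seed=4)
        assert set(outlets["A"]["true_class"]) == {"enucleated"}
        assert set(outlets["C"]["true_class"]) == {"nucleated"}
        assert set(outlets["D"]["true_class"]) == {"nucleus"}

    def test_missing_class_entry_named(self, small_table, model):
        with pytest.raises(MissingModelEntryError, match="nucleus"):
            sorter.simulate_sort(small_table, model, 0.2, seed=4)


class TestFocusingModelIO:
    def test_yaml_round_trip(self, model, tmp_path):
        path = tmp_path / "model.yaml"
        model.to_yaml(path)
        back = sorter.FocusingModel.from_yaml(path)
        assert back.entries == model.entries
        assert back.channel_width_um == model.channel_width_um

    def test_default_contains_printed_high_rate_entry(self, model):
        assert model.get("enucleated", 1.0) == (36.0, 21.0)

    def test_mean_outside_channel_rejected(self):
        with pytest.raises(ConfigError):
            sorter.FocusingModel(entries={("enucleated", 1.0): (200.0, 5.0)})
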