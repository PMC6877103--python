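"""Gating: ploidy anchors, debris/viability/cycle classes, threshold rules
and the cleaved-PARP 2D boundary."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hypercyte import cytogate, synthdata
from hypercyte.cytogate import (
    BimodalityError,
    GateSet,
    GatingError,
    PloidyAnchors,
    fit_ploidy_anchors,
    threshold_bimodal_midpoint,
    threshold_control_percentile,
)


def _basic_gates(anchor=300.0, cv=0.06, k=2.5):
    a = PloidyAnchors(anchor_3n=anchor, cv_est=cv)
    return GateSet(
        anchors=a,
        debris_threshold=0.25 * anchor,
        pi_threshold=60.0,
        caspase_threshold=50.0,
        edu_threshold=50.0,
        g1_window=(anchor * (1 - k * cv), anchor * (1 + k * cv)),
        g2_window=(2 * anchor * (1 - k * cv), 2 * anchor * (1 + k * cv)),
    )


class TestPloidyAnchors:
    def test_gaussian_mode_recovered(self):
        rng = np.random.default_rng(0)
        v = rng.normal(300.0, 15.0, 5000)
        anchors = fit_ploidy_anchors(v)
        # independent oracle: fine-histogram mode
        hist, edges = np.histogram(v, bins=200)
        oracle = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
        assert anchors.anchor_3n == pytest.approx(300.0, rel=0.02)
        assert anchors.anchor_3n == pytest.approx(oracle, rel=0.02)
        assert anchors.anchor_6n == pytest.approx(600.0, rel=0.02)
        assert anchors.cv_est == pytest.approx(0.05, abs=0.02)

    def test_dominant_mode_of_mixture(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(300, 15, 3500), rng.normal(600, 30, 1500)])
        anchors = fit_ploidy_anchors(v)
        assert anchors.anchor_3n == pytest.approx(300.0, rel=0.03)

    def test_scale_equivariance_exact(self):
        rng = np.random.default_rng(2)
        v = np.concatenate([rng.normal(300, 18, 3000), rng.normal(600, 36, 1000)])
        a1 = fit_ploidy_anchors(v)
        a2 = fit_ploidy_anchors(2.0 * v)
        assert a2.anchor_3n == pytest.approx(2.0 * a1.anchor_3n, rel=1e-9)
        assert a2.cv_est == pytest.approx(a1.cv_est, rel=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(GatingError, match="100"):
            fit_ploidy_anchors(np.ones(50) * 300)

    def test_anchor_6n_is_twice_3n(self):
        a = PloidyAnchors(anchor_3n=123.0, cv_est=0.05)
        assert a.anchor_6n == 246.0


class TestThresholdRules:
    def test_bimodal_midpoint_point_masses(self):
        v = np.array([10.0] * 100 + [20.0] * 100)
        assert threshold_bimodal_midpoint(v) == pytest.approx(15.0, abs=0.1)

    def test_bimodal_midpoint_gaussians(self):
        rng = np.random.default_rng(3)
        v = np.concatenate([rng.normal(10, 1, 1000), rng.normal(20, 1, 1000)])
        thr = threshold_bimodal_midpoint(v)
        assert thr == pytest.approx(15.0, abs=0.5)
        # density-minimum oracle: the valley between the modes
        grid = np.linspace(5, 25, 400)
        from scipy.stats import gaussian_kde
        dens = gaussian_kde(v)(grid)
        valley = grid[(grid > 12) & (grid < 18)][
            np.argmin(dens[(grid > 12) & (grid < 18)])
        ]
        assert abs(thr - valley) < 1.0

    def test_unimodal_input_raises(self):
        rng = np.random.default_rng(4)
        with pytest.raises(BimodalityError):
            threshold_bimodal_midpoint(rng.normal(10, 1, 2000))

    def test_percentile_linear_interpolation_convention(self):
        assert threshold_control_percentile(np.arange(1, 1001), 99.5) == pytest.approx(
            995.005
        )

    def test_percentile_normal_quantile(self):
        rng = np.random.default_rng(5)
        thr = threshold_control_percentile(rng.standard_normal(100_000), 99.5)
        assert thr == pytest.approx(2.576, abs=0.03)

    def test_percentile_self_consistency(self):
        rng = np.random.default_rng(6)
        v = rng.normal(30, 8, 10_000)
        thr = threshold_control_percentile(v, 99.5)
        assert (v > thr).mean() == pytest.approx(0.005, abs=0.001)

    def test_empty_control_rejected(self):
        with pytest.raises(GatingError):
            threshold_control_percentile([], 99.5)


class TestCleavedParpGate:
    def test_control_self_positivity_near_two_percent(self, mixed_population):
        _, truth, records = mixed_population
        viable = records[truth.true_viability.values == "VIABLE"]
        flags = cytogate.gate_cleaved_parp(viable, viable)
        assert flags.mean() == pytest.approx(0.02, abs=0.005)

    def test_shifted_positive_population_flagged(self, mixed_population):
        _, truth, records = mixed_population
        viable = records[truth.true_viability.values == "VIABLE"].reset_index(drop=True)
        rule = cytogate.fit_cparp_rule(viable)
        treated = viable.copy()
        pos = np.arange(len(treated)) < int(0.3 * len(treated))
        treated.loc[pos, "mean_cparp"] = np.random.default_rng(7).normal(
            25 + 5 * 6, 6, int(pos.sum())
        )
        treated.loc[pos, "nc_ratio_cparp"] = 3.0
        flags = cytogate.apply_cparp_rule(treated, rule)
        assert flags[pos].mean() >= 0.95

    def test_degenerate_control_rejected(self):
        control = pd.DataFrame(
            {"mean_cparp": np.full(200, 25.0), "nc_ratio_cparp": np.full(200, 1.0)}
        )
        with pytest.raises(GatingError, match="degenerate|variance"):
            cytogate.fit_cparp_rule(control)


class TestRecordGates:
    def test_debris_rule(self):
        gates = _basic_gates()
        rec = pd.DataFrame({"integrated_hoechst": [0.1 * 300, 300.0]})
        flags = cytogate.gate_debris(rec, gates)
        assert list(flags) == [True, False]

    def test_synthetic_fragments_all_flagged(self):
        spec = synthdata.PopulationSpec(n_cells=3000, fragment_fraction=0.1, seed=21)
        truth, records = synthdata.generate_population(spec)
        gates = cytogate.fit_gateset(records)
        flags = cytogate.gate_debris(records, gates)
        frag = truth.true_class.values == "DEBRIS"
        assert flags[frag].all()

    def test_viability_truth_table(self):
        gates = _basic_gates()
        rec = pd.DataFrame(
            {
                "mean_pi": [10.0, 10.0, 200.0, 200.0],
                "mean_caspase": [10.0, 150.0, 150.0, 10.0],
            }
        )
        out = list(cytogate.classify_viability(rec, gates))
        assert out == ["VIABLE", "EARLY_APOPTOTIC", "LATE_APOPTOTIC", "NECROTIC"]

    def test_missing_viability_channel_warns_unassigned(self):
        gates = _basic_gates()
        rec = pd.DataFrame({"mean_pi": [10.0]})
        with pytest.warns(UserWarning, match="missing"):
            out = cytogate.classify_viability(rec, gates)
        assert (out == "UNASSIGNED").all()

    def test_cell_cycle_examples(self):
        gates = _basic_gates()
        rec = pd.DataFrame(
            {
                "integrated_hoechst": [450.0, 300.0, 900.0, 400.0],
                "mean_edu": [120.0, 10.0, 10.0, 10.0],
            }
        )
        out = list(cytogate.classify_cell_cycle(rec, gates))
        # EdU+ mid-DNA -> S; 3N EdU- -> G1; 9N -> HYPER; between windows -> UNASSIGNED
        assert out == ["S", "G1", "HYPER", "UNASSIGNED"]

    def test_gate_ordering_validated(self):
        gates = _basic_gates()
        gates.g1_window = (500.0, 700.0)  # overlaps G2
        with pytest.raises(GatingError, match="ordering"):
            gates.validate()


class TestApplyGateset:
    def test_empty_table(self, fitted_gates):
        labels = cytogate.apply_gateset(
            pd.DataFrame(columns=["integrated_hoechst", "mean_pi", "mean_caspase",
                                  "mean_edu"]),
            fitted_gates,
        )
        assert len(labels) == 0

    def test_partition_property(self, mixed_labels):
        assert set(mixed_labels.cycle.unique()) <= {
            "G1", "S", "G2", "HYPER", "UNASSIGNED"
        }
        # debris never carries a cycle class
        assert (mixed_labels.loc[mixed_labels.is_debris, "cycle"] == "UNASSIGNED").all()

    def test_known_fractions_recovered(self, mixed_population, mixed_labels):
        _, truth, _ = mixed_population
        est = cytogate.class_fractions(mixed_labels)
        tru = truth.true_class.value_counts(normalize=True)
        for c in ("G1", "S", "G2", "HYPER"):
            assert est[c] == pytest.approx(tru[c], abs=0.03)

    def test_scale_equivariance_of_labels(self, mixed_population, mixed_labels):
        _, _, records = mixed_population
        scaled = records.copy()
        for col in ("integrated_hoechst", "mean_hoechst"):
            scaled[col] = 3.7 * scaled[col]
        gates = cytogate.fit_gateset(scaled)
        labels2 = cytogate.apply_gateset(scaled, gates)
        assert (labels2.cycle.values == mixed_labels.cycle.values).mean() > 0.999

    def test_hyper_estimate_monotone_in_true_fraction(self):
        est = []
        for h in (0.05, 0.15, 0.30):
            fr = {"G1": 0.70 - h, "S": 0.15, "G2": 0.15, "HYPER": h}
            spec = synthdata.PopulationSpec(n_cells=4000, class_fractions=fr, seed=5)
            _, records = synthdata.generate_population(spec)
            gates = cytogate.fit_gateset(records)
            labels = cytogate.apply_gateset(records, gates)
            est.append(cytogate.class_fractions(labels)["HYPER"])
        assert est[0] < est[1] < est[2]

    def test_gateset_roundtrip_serialization(self, fitted_gates):
        d = fitted_gates.to_dict()
        back = GateSet.from_dict(d)
        assert back.anchors.anchor_3n == fitted_gates.anchors.anchor_3n
        assert back.suprag2_threshold == fitted_gates.suprag2_threshold
        assert back.marker_thresholds == fitted_gates.marker_thresholds


@settings(max_examples=25, derandomize=True, deadline=None)
@given(q=st.floats(min_value=80.0, max_value=99.5))
def test_percentile_rule_flags_expected_tail(q):
    """Applying a q-percentile threshold back to its own control flags
    about (100-q)% of it, for any q."""
    rng = np.random.default_rng(17)
    v = rng.normal(50, 10, 5000)
    thr = threshold_control_percentile(v, q)
    frac = (v > thr).mean()
    assert frac == pytest.approx((100 - q) / 100, abs=0.005)
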