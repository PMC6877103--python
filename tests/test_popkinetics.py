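"""Per-well endpoints: suppression rules, survival normalization, the
checkpoint ratio, mitotic metrics, 4PL dose-response and regrowth."""

import numpy as np
import pandas as pd
import pytest

from hypercyte import cytogate, synthdata
from hypercyte.popkinetics import (
    KineticsError,
    chk1_damage_ratio,
    fit_dose_response,
    mitotic_metrics,
    normalize_survival,
    quantify_regrowth,
    summarize_well,
    summarize_wells,
)


def _well(n_viable, n_other=0, condition=0.0, well="A01", day=1, area=400.0):
    """Minimal labeled well: n_viable viable G1 cells plus dead extras."""
    n = n_viable + n_other
    records = pd.DataFrame(
        {
            "well": well, "day": day, "condition": condition,
            "area": np.full(n, area),
            "integrated_hoechst": np.full(n, 300.0),
            "centroid_x": np.linspace(0, 100, n),
            "centroid_y": np.linspace(0, 100, n),
            "mean_pchk1": np.full(n, 50.0),
            "mean_ph2ax": np.full(n, 30.0),
        }
    )
    labels = pd.DataFrame(
        {
            "is_debris": False,
            "viability": ["VIABLE"] * n_viable + ["NECROTIC"] * n_other,
            "cycle": ["G1"] * n_viable + ["UNASSIGNED"] * n_other,
        },
        index=records.index,
    )
    return records, labels


class TestSummarizeWell:
    @pytest.mark.parametrize("n,suppressed", [(4, True), (5, False)])
    def test_min_cell_suppression_boundary(self, n, suppressed):
        records, labels = _well(n)
        out = summarize_well(records, labels)
        assert out["suppressed"] is suppressed

    def test_fractions_sum_to_one(self):
        records, labels = _well(20)
        labels.loc[:5, "cycle"] = "G2"
        out = summarize_well(records, labels)
        total = sum(out[f"frac_{c}"] for c in ("G1", "S", "G2", "HYPER", "UNASSIGNED"))
        assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("n_class,reported", [(4, False), (5, True)])
    def test_median_area_min_class_boundary(self, n_class, reported):
        records, labels = _well(20)
        labels.loc[: n_class - 1, "cycle"] = "HYPER"
        labels.loc[n_class:, "cycle"] = "G1"
        out = summarize_well(records, labels)
        assert bool(np.isfinite(out["median_area_HYPER"])) is reported

    def test_median_areas_match_truth(self, mixed_population, mixed_labels):
        _, truth, records = mixed_population
        out = summarize_well(records, mixed_labels)
        viable = truth.true_viability.values == "VIABLE"
        for c in ("G1", "G2", "HYPER"):
            true_med = truth.true_area[(truth.true_class.values == c) & viable].median()
            assert out[f"median_area_{c}"] == pytest.approx(true_med, rel=0.05)


class TestNormalizeSurvival:
    def _summaries(self):
        rows = []
        for well, cond, n in [("A01", 0.0, 100), ("A02", 0.0, 120),
                              ("B01", 5.0, 55), ("B02", 10.0, 20)]:
            rows.append({"well": well, "day": 1, "condition": cond, "n_viable": n})
        return pd.DataFrame(rows)

    def test_reference_wells_average_to_one(self):
        out = normalize_survival(self._summaries())
        ref = out[out.condition == 0.0]
        assert ref.survival.mean() == pytest.approx(1.0)

    def test_half_reference_gives_half_survival(self):
        out = normalize_survival(self._summaries())
        assert out.loc[out.well == "B01", "survival"].iloc[0] == pytest.approx(0.5)

    def test_zero_reference_rejected(self):
        s = self._summaries()
        s.loc[s.condition == 0.0, "n_viable"] = 0
        with pytest.raises(KineticsError):
            normalize_survival(s)


class TestChk1DamageRatio:
    def test_self_ratio_is_exactly_one(self):
        # G2 means equal to bulk means by construction
        records, labels = _well(50)
        labels["cycle"] = "G2"
        assert chk1_damage_ratio(records, labels, records) == 1.0

    def test_direct_formula(self):
        records, labels = _well(50)
        labels["cycle"] = "G2"
        bulk = records.copy()
        records = records.assign(
            mean_pchk1=records.mean_pchk1 * 2.0, mean_ph2ax=records.mean_ph2ax * 2.6
        )
        ratio = chk1_damage_ratio(records, labels, bulk)
        assert ratio == pytest.approx(2.0 / 2.6)

    @pytest.mark.parametrize("n_g2,finite", [(4, False), (5, True)])
    def test_min_g2_suppression_boundary(self, n_g2, finite):
        records, labels = _well(20)
        labels.loc[: n_g2 - 1, "cycle"] = "G2"
        ratio = chk1_damage_ratio(records, labels, records)
        assert bool(np.isfinite(ratio)) is finite


class TestMitoticMetrics:
    def test_mitotic_fraction_recovered(self):
        spec = synthdata.PopulationSpec(n_cells=6000, mitotic_fraction=0.03, seed=9)
        truth, records = synthdata.generate_population(spec)
        gates = cytogate.fit_gateset(records)
        labels = cytogate.apply_gateset(records, gates)
        out = mitotic_metrics(records, labels)
        true_frac = truth.state_ph3[truth.true_viability == "VIABLE"].mean()
        assert out["mitotic_fraction"] == pytest.approx(true_frac, abs=0.01)

    def test_no_hyper_mitoses_when_all_mitotic_at_6n(self):
        records, labels = _well(100)
        labels["pos_ph3"] = [True] * 10 + [False] * 90
        labels.loc[:9, "cycle"] = "G2"  # mitotic nuclei at exactly 6N
        out = mitotic_metrics(records, labels)
        assert out["hyper_fraction_of_mitotic"] == 0.0

    @pytest.mark.parametrize("n_mit,finite", [(4, False), (5, True)])
    def test_min_mitotic_suppression_boundary(self, n_mit, finite):
        records, labels = _well(100)
        labels["pos_ph3"] = [True] * n_mit + [False] * (100 - n_mit)
        labels["pos_ph2ax"] = False
        out = mitotic_metrics(records, labels)
        assert bool(np.isfinite(out["hyper_fraction_of_mitotic"])) is finite


class TestDoseResponse:
    DOSES = np.array([0, 0.625, 1.25, 2.5, 5, 10, 20, 40])

    @staticmethod
    def _curve(d, top=1.0, bottom=0.05, hill=1.5, ic50=5.0):
        d = np.asarray(d, float)
        return bottom + (top - bottom) / (
            1 + np.where(d > 0, (d / ic50) ** hill, 0.0)
        )

    def test_noiseless_recovery_exact(self):
        fit = fit_dose_response(self.DOSES, self._curve(self.DOSES))
        assert fit.ic50 == pytest.approx(5.0, abs=1e-6)
        assert fit.hill == pytest.approx(1.5, abs=1e-6)

    def test_icq_closed_form(self):
        fit = fit_dose_response(self.DOSES, self._curve(self.DOSES))
        assert fit.icq(80) == pytest.approx(fit.ic50 * (80 / 20) ** (1 / fit.hill))

    def test_noisy_replicates_median_error(self):
        rng = np.random.default_rng(12)
        y = self._curve(self.DOSES)
        errs = []
        for _ in range(100):
            fit = fit_dose_response(self.DOSES, y * rng.normal(1, 0.05, len(y)))
            errs.append(abs(fit.ic50 - 5.0) / 5.0)
        assert np.median(errs) <= 0.10

    def test_requires_vehicle_and_four_doses(self):
        with pytest.raises(KineticsError):
            fit_dose_response([1, 2, 4, 8], [1, 0.8, 0.5, 0.2])


class TestRegrowth:
    def test_covered_fraction_and_normalization(self):
        def well(n, area):
            records, labels = _well(n, area=area)
            return records, labels

        tables = {"A01": well(0, 400.0), "B01": well(50, 100.0), "C01": well(10, 500.0)}
        out = quantify_regrowth(tables, well_area=1_000_000.0)
        out = out.set_index("well")
        assert out.loc["A01", "covered_fraction"] == 0.0
        assert out.loc["B01", "covered_fraction"] == pytest.approx(0.005)
        assert out.loc["B01", "normalized_growth"] == 1.0

    def test_zero_well_area_rejected(self):
        with pytest.raises(KineticsError):
            quantify_regrowth({}, well_area=0.0)


def test_summaries_over_plate(mixed_population, mixed_labels):
    _, _, records = mixed_population
    out = summarize_wells(records, mixed_labels)
    assert len(out) == 1
    assert out.iloc[0].n_viable > 4000
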