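"""Kappa/F1, stratum fractions, zonal confusion and scenario selection."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from coverwise.classify import LABEL_NODATA, ClassifiedMap
from coverwise.evaluate import (ConfusionAreas, ConfusionCounts,
                                EvaluationError, EvaluationReport,
                                confusion_from_labels, confusion_percentages,
                                criterion_winners, f1, kappa,
                                majority_winner, map_area_percent,
                                select_best_scenario, stratum_tp_fraction,
                                zonal_confusion)
from coverwise.sampling import ReferencePolygon


class TestKappaF1:
    def test_perfect_agreement(self):
        assert kappa(ConfusionCounts(tp=50, fp=0, tn=50, fn=0)) == 1.0

    def test_hand_worked_case(self):
        # p_o = 0.7, p_e = 0.5 -> kappa 0.4
        assert kappa(ConfusionCounts(tp=40, fn=10, fp=20, tn=30)) == \
            pytest.approx(0.4)

    def test_chance_level_counts(self):
        # counts proportional to independent marginals
        assert kappa(ConfusionCounts(tp=12, fp=28, fn=18, tn=42)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_f1_examples(self):
        assert f1(ConfusionCounts(10, 0, 0, 0)) == 1.0
        assert f1(ConfusionCounts(0, 5, 3, 0)) == 0.0
        assert f1(ConfusionCounts(tp=40, fp=20, tn=0, fn=10)) == \
            pytest.approx(80 / 110)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(EvaluationError):
            kappa(ConfusionCounts(0, 0, 0, 0))
        with pytest.raises(EvaluationError):
            f1(ConfusionCounts(0, 0, 7, 0))

    def test_matches_sklearn_on_random_labels(self, rng):
        from sklearn.metrics import cohen_kappa_score, f1_score

        for _ in range(10):
            y_true = rng.integers(0, 2, size=300)
            y_pred = rng.integers(0, 2, size=300)
            counts = confusion_from_labels(y_true, y_pred)
            assert kappa(counts) == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-12)
            if counts.tp + counts.fp + counts.fn:
                assert f1(counts) == pytest.approx(
                    f1_score(y_true, y_pred), abs=1e-12)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(tp=st.integers(0, 500), fp=st.integers(0, 500),
           tn=st.integers(0, 500), fn=st.integers(0, 500))
    def test_bounds(self, tp, fp, tn, fn):
        counts = ConfusionCounts(tp, fp, tn, fn)
        if counts.total:
            assert -1.0 <= kappa(counts) <= 1.0
        if tp + fp + fn:
            assert 0.0 <= f1(counts) <= 1.0


def _map_from_labels(labels):
    labels = np.asarray(labels, dtype=np.uint8)
    prob = np.where(labels == LABEL_NODATA, np.nan,
                    labels.astype(np.float32))
    return ClassifiedMap(labels=labels, probability=prob)


def _val_poly(pid, klass, stratum, pixels):
    return ReferencePolygon(id=pid, center=(0.0, 0.0), radius=2.0,
                            klass=klass, cover_pct=0, stratum=stratum,
                            pixels=pixels, role="validation")


class TestStratumFractions:
    @pytest.fixture
    def validation(self):
        return [
            _val_poly(0, "target", "20-40", [(0, 0), (0, 1)]),
            _val_poly(1, "target", "50-70", [(1, 0), (1, 1)]),
            _val_poly(2, "target", "80-100", [(2, 0), (2, 1)]),
            _val_poly(3, "background", None, [(3, 0), (3, 1), (3, 2)]),
        ]

    def test_all_target_map(self, validation):
        cmap = _map_from_labels(np.ones((4, 4)))
        strata, bg = stratum_tp_fraction(cmap, validation)
        assert strata == {"20-40": 100.0, "50-70": 100.0, "80-100": 100.0}
        assert bg == 100.0

    def test_all_background_map(self, validation):
        cmap = _map_from_labels(np.zeros((4, 4)))
        strata, bg = stratum_tp_fraction(cmap, validation)
        assert set(strata.values()) == {0.0}
        assert bg == 0.0

    def test_mixed_map_recount_oracle(self, validation, rng):
        labels = rng.integers(0, 2, size=(4, 4))
        cmap = _map_from_labels(labels)
        strata, bg = stratum_tp_fraction(cmap, validation)
        for p in validation[:3]:
            expected = 100.0 * np.mean([labels[r, c] for r, c in p.pixels])
            assert strata[p.stratum] == pytest.approx(expected)
        assert bg == pytest.approx(
            100.0 * np.mean([labels[r, c] for r, c in validation[3].pixels]))

    def test_missing_stratum_absent_not_zero(self, validation):
        cmap = _map_from_labels(np.ones((4, 4)))
        strata, _ = stratum_tp_fraction(cmap, validation[1:])
        assert "20-40" not in strata


class TestMapArea:
    def test_extremes_and_oracle(self, rng):
        assert map_area_percent(_map_from_labels(np.ones((5, 5)))) == 100.0
        checker = np.indices((6, 6)).sum(axis=0) % 2
        assert map_area_percent(_map_from_labels(checker)) == 50.0
        labels = rng.integers(0, 2, size=(9, 9))
        assert map_area_percent(_map_from_labels(labels)) == \
            pytest.approx(100.0 * labels.mean())

    def test_all_nodata_rejected(self):
        with pytest.raises(EvaluationError):
            map_area_percent(_map_from_labels(
                np.full((3, 3), LABEL_NODATA)))


class TestZonalConfusion:
    def test_toy_raster_matches_enumeration(self, rng):
        labels = rng.integers(0, 2, size=(10, 10))
        cmap = _map_from_labels(labels)
        patch = box(3.0, -7.0, 5.0, -5.0)           # pixels (5..6, 3..4)
        control = box(0.0, -10.0, 10.0, 0.0)
        areas = zonal_confusion(cmap, [patch], control)
        inside = np.zeros((10, 10), dtype=bool)
        inside[5:7, 3:5] = True
        tp = int(np.sum(inside & (labels == 1)))
        fp = int(np.sum(~inside & (labels == 1)))
        assert areas.control_species_area == 4.0
        assert areas.control_background_area == 96.0
        assert areas.tp_area == tp
        assert areas.fp_area == fp
        assert areas.tp_area + areas.fn_area == areas.control_species_area
        assert areas.fp_area + areas.tn_area == areas.control_background_area

    def test_perfect_and_empty_maps(self):
        inside = np.zeros((10, 10))
        inside[5:7, 3:5] = 1
        patch = box(3.0, -7.0, 5.0, -5.0)
        control = box(0.0, -10.0, 10.0, 0.0)
        perfect = zonal_confusion(_map_from_labels(inside), [patch], control)
        assert perfect.fp_area == perfect.fn_area == 0.0
        empty = zonal_confusion(_map_from_labels(np.zeros((10, 10))),
                                [patch], control)
        assert empty.tp_area == empty.fp_area == 0.0
        assert empty.fn_area == empty.control_species_area

    def test_no_patches_means_no_species_zone(self):
        cmap = _map_from_labels(np.zeros((5, 5)))
        areas = zonal_confusion(cmap, [], box(0.0, -5.0, 5.0, 0.0))
        assert areas.control_species_area == 0.0
        assert areas.control_background_area == 25.0


class TestPercentageConvention:
    def test_integer_columns_asymmetric_normalization(self):
        areas = confusion_percentages(ConfusionAreas(
            control_species_area=14189, control_background_area=85667,
            tp_area=9784, fp_area=1946, tn_area=83739, fn_area=4387))
        assert (areas.tp_pct, areas.fp_pct, areas.tn_pct, areas.fn_pct) == \
            (69, 14, 98, 31)

    def test_one_decimal_variant(self):
        areas = confusion_percentages(ConfusionAreas(
            control_species_area=10797, control_background_area=89203,
            tp_area=8134, fp_area=5910, tn_area=83149, fn_area=2663))
        assert areas.fp_pct_1dp == 54.7

    def test_extremes_and_errors(self):
        areas = confusion_percentages(ConfusionAreas(
            control_species_area=50, control_background_area=50,
            tp_area=50, fp_area=0, tn_area=50, fn_area=0))
        assert (areas.tp_pct, areas.fp_pct) == (100, 0)
        with pytest.raises(EvaluationError):
            confusion_percentages(ConfusionAreas(0, 10, 0, 0, 10, 0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(species=st.integers(1, 10000), tp=st.integers(0, 10000))
    def test_tp_fn_complementarity(self, species, tp):
        tp = min(tp, species)
        areas = confusion_percentages(ConfusionAreas(
            control_species_area=species, control_background_area=100,
            tp_area=tp, fp_area=0, tn_area=100, fn_area=species - tp))
        # consistent areas keep the half-up-rounded shares complementary
        assert areas.tp_pct + areas.fn_pct in (99, 100, 101)
        assert abs(areas.tp_pct_1dp + areas.fn_pct_1dp - 100.0) <= 0.1 + 1e-9


def _report(name, kappa_, f1_, strata, bg_fp, tp_pct, fp_pct):
    areas = ConfusionAreas(100, 100, tp_pct, fp_pct, 100 - fp_pct,
                           100 - tp_pct, tp_pct=tp_pct, fp_pct=fp_pct)
    return EvaluationReport(scenario=name, kappa=kappa_, f1=f1_,
                            stratum_tp_pct=strata, background_fp_pct=bg_fp,
                            confusion_areas=areas)


class TestScenarioSelection:
    def test_dominating_report_wins_unanimously(self):
        a = _report("A", 0.9, 0.9, {"20-40": 90.0}, 1.0, 90, 2)
        b = _report("B", 0.5, 0.5, {"20-40": 50.0}, 20.0, 50, 30)
        best, winners = select_best_scenario([a, b])
        assert best == "A"
        assert set(winners.values()) == {"A"}

    def test_majority_vote_patterns(self):
        assert majority_winner({"accuracy": "SC1_30", "stratum": "SC1_40",
                                "field": "SC1_30"}) == "SC1_30"
        assert majority_winner({"accuracy": "SC1_30", "stratum": "SC1_40",
                                "field": "SC1_40"}) == "SC1_40"

    def test_three_way_disagreement_field_decides(self):
        assert majority_winner({"accuracy": "A", "stratum": "B",
                                "field": "C"}) == "C"

    def test_field_tie_broken_by_lower_fp(self):
        a = _report("A", 0.1, 0.1, {}, 0.0, 80, 30)
        b = _report("B", 0.2, 0.2, {}, 0.0, 80, 10)
        winners = criterion_winners([a, b])
        assert winners["field"] == "B"

    def test_too_few_reports_rejected(self):
        with pytest.raises(EvaluationError):
            select_best_scenario([_report("A", 1, 1, {}, 0, 50, 0)])
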