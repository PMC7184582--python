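import math

import numpy as np
import pytest

from perioprp import (
    CDC_AAP_2012,
    EFP_AAP_2018,
    ConfusionCounts,
    binary_auc_from_labels,
    confusion,
    counts_from_rates,
    crosstab_to_edges,
    dor_ci,
    evaluate_protocols,
    indicators,
    multiclass_auc,
    reclassification_table,
    tidy_indicator_table,
)
from _oracles import brute_pairwise_auc


def random_tables(rng, n, max_cell=200):
    for _ in range(n):
        tp, fp, tn, fn = (int(v) for v in rng.integers(0, max_cell + 1, size=4))
        if tp + fp + tn + fn == 0:
            tp = 1
        yield ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


class TestConfusion:
    def test_enumeration_example(self):
        c = confusion([1, 1, 0, 0], [1, 0, 0, 1])
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 1, 1)

    def test_perfect_agreement_has_no_errors(self):
        c = confusion([1, 0, 1], [1, 0, 1])
        assert c.fp == c.fn == 0

    def test_all_negative(self):
        c = confusion([0] * 10, [0] * 10)
        assert (c.tn, c.tp, c.fp, c.fn) == (10, 0, 0, 0)

    def test_errors(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])
        with pytest.raises(ValueError):
            confusion([1, 2], [1, 0])
        with pytest.raises(ValueError):
            confusion([], [])


class TestIndicators:
    def test_perfect_classifier(self):
        ind = indicators(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        for name in ("sensitivity", "specificity", "accuracy", "precision",
                     "f1", "mcc", "auc"):
            assert getattr(ind, name).value == pytest.approx(1.0)
        assert ind.youden.value == pytest.approx(1.0)

    def test_worked_arithmetic_example(self):
        ind = indicators(ConfusionCounts(tp=50, fn=50, tn=90, fp=10))
        assert ind.sensitivity.value == pytest.approx(0.5)
        assert ind.specificity.value == pytest.approx(0.9)
        assert ind.youden.value == pytest.approx(0.4)
        assert ind.accuracy.value == pytest.approx(0.7)
        assert ind.precision.value == pytest.approx(50 / 60)
        assert ind.auc.value == pytest.approx(0.7)

    def test_literal_formula_agreement_on_random_tables(self):
        """Every indicator matches its textbook formula to 1e-12 on 1,000
        random contingency tables (NA exactly when a denominator is 0)."""
        rng = np.random.default_rng(2024)
        for c in random_tables(rng, 1000):
            ind = indicators(c)
            tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
            checks = {
                "sensitivity": (tp, tp + fn),
                "specificity": (tn, tn + fp),
                "accuracy": (tp + tn, tp + fp + tn + fn),
                "precision": (tp, tp + fp),
                "f1": (2 * tp, 2 * tp + fp + fn),
            }
            for name, (num, den) in checks.items():
                got = getattr(ind, name).value
                if den == 0:
                    assert math.isnan(got)
                else:
                    assert got == pytest.approx(num / den, abs=1e-12)
            den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            if den == 0:
                assert math.isnan(ind.mcc.value)
            else:
                expected = (tp * tn - fp * fn) / math.sqrt(den)
                assert ind.mcc.value == pytest.approx(expected, abs=1e-12)
                assert -1.0 - 1e-12 <= ind.mcc.value <= 1.0 + 1e-12

    def test_auc_identities_exact(self):
        rng = np.random.default_rng(31)
        for c in random_tables(rng, 200):
            ind = indicators(c)
            auc = binary_auc_from_labels(c)
            if math.isnan(auc):
                assert math.isnan(ind.auc.value)
                continue
            assert auc == (ind.sensitivity.value + ind.specificity.value) / 2
            # equal up to float rounding of the re-association
            assert auc == pytest.approx((ind.youden.value + 1) / 2, abs=1e-12)

    def test_mcc_one_only_for_perfect_tables(self):
        assert indicators(ConfusionCounts(tp=3, tn=7, fp=0, fn=0)).mcc.value == 1.0
        nearly = indicators(ConfusionCounts(tp=3, tn=7, fp=1, fn=0))
        assert nearly.mcc.value < 1.0

    def test_f1_is_harmonic_mean(self):
        c = ConfusionCounts(tp=30, fp=10, fn=20, tn=40)
        ind = indicators(c)
        p, s = ind.precision.value, ind.sensitivity.value
        assert ind.f1.value == pytest.approx(2 * p * s / (p + s), abs=1e-12)

    def test_prevalence_invariance_under_negative_duplication(self):
        """Duplicating the negative class leaves sens/spec/DOR/AUC unchanged
        but shifts the prevalence-dependent indicators."""
        base = ConfusionCounts(tp=40, fn=10, tn=60, fp=20)
        k = 5
        dup = ConfusionCounts(tp=40, fn=10, tn=60 * k, fp=20 * k)
        a, b = indicators(base), indicators(dup)
        assert a.sensitivity.value == b.sensitivity.value
        assert a.specificity.value == b.specificity.value
        assert a.auc.value == b.auc.value
        assert a.dor.value == pytest.approx(b.dor.value)
        for name in ("accuracy", "precision", "f1", "mcc"):
            assert getattr(a, name).value != getattr(b, name).value

    def test_wilson_interval_brackets_estimate(self):
        rng = np.random.default_rng(8)
        for c in random_tables(rng, 100):
            ind = indicators(c)
            for name in ("sensitivity", "specificity", "accuracy", "precision"):
                est = getattr(ind, name)
                if not math.isnan(est.value):
                    assert est.ci_low <= est.value <= est.ci_high
                    assert 0.0 <= est.ci_low and est.ci_high <= 1.0


class TestDOR:
    def test_balanced_table_symmetric_about_one(self):
        r = dor_ci(ConfusionCounts(tp=25, tn=25, fp=25, fn=25))
        assert r.dor == pytest.approx(1.0)
        assert r.ci_low == pytest.approx(1.0 / r.ci_high)
        assert r.log10_dor == pytest.approx(0.0)

    def test_arithmetic_oracle(self):
        # (90/10)/(10/90) = 81; SE = sqrt(2/90 + 2/10)
        r = dor_ci(ConfusionCounts(tp=90, fn=10, fp=10, tn=90))
        assert r.dor == pytest.approx(81.0)
        se = math.sqrt(1 / 90 + 1 / 10 + 1 / 10 + 1 / 90)
        assert se == pytest.approx(0.4714, abs=1e-4)
        assert r.ci_low == pytest.approx(math.exp(math.log(81) - 1.96 * se))
        assert r.ci_high == pytest.approx(math.exp(math.log(81) + 1.96 * se))
        assert not r.corrected

    def test_zero_cell_haldane_anscombe(self):
        r = dor_ci(ConfusionCounts(tp=10, fn=5, fp=0, tn=20))
        assert r.corrected
        expected = (10.5 / 5.5) / (0.5 / 20.5)
        assert r.dor == pytest.approx(expected)
        assert math.isfinite(r.ci_low) and math.isfinite(r.ci_high)

    def test_rate_reconstruction_reaches_printed_scale(self):
        c = counts_from_rates(0.871, 0.785, 100000, 100000)
        assert c.tp / (c.tp + c.fn) == pytest.approx(0.871)
        assert c.tn / (c.tn + c.fp) == pytest.approx(0.785)
        assert dor_ci(c).log10_dor == pytest.approx(1.392, abs=1e-3)


class TestBinaryAUC:
    def test_boundary_values(self):
        assert binary_auc_from_labels(ConfusionCounts(tp=5, tn=5, fp=0, fn=0)) == 1.0
        chance = ConfusionCounts(tp=5, fn=5, tn=5, fp=5)
        assert binary_auc_from_labels(chance) == 0.5

    def test_undefined_without_both_classes(self):
        assert math.isnan(binary_auc_from_labels(ConfusionCounts(tp=5, fn=5, tn=0, fp=0)))


class TestMulticlassAUC:
    def test_perfect_agreement(self):
        stages = [0, 1, 2, 3] * 3
        assert multiclass_auc(stages, stages) == pytest.approx(1.0)

    def test_two_class_reduction_to_binary(self):
        rng = np.random.default_rng(55)
        ref = rng.integers(0, 2, size=60)
        test = rng.integers(0, 2, size=60)
        expected = binary_auc_from_labels(confusion(ref, test))
        assert multiclass_auc(ref, test) == pytest.approx(expected)

    def test_small_instance_matches_brute_force(self):
        ref = [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2]
        test = [0, 1, 0, 2, 1, 1, 0, 2, 2, 2, 1, 0]
        assert multiclass_auc(ref, test) == pytest.approx(
            brute_pairwise_auc(ref, test)
        )

    def test_matches_sklearn_one_vs_one(self):
        """Cross-check against scikit-learn's pairwise one-vs-one AUC with
        one-hot scores for the hard labels."""
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(77)
        for _ in range(10):
            ref = rng.integers(0, 4, size=200)
            if len(np.unique(ref)) < 4:
                continue
            test = np.clip(ref + rng.integers(-1, 2, size=200), 0, 3)
            onehot = np.zeros((200, 4))
            onehot[np.arange(200), test] = 1.0
            expected = roc_auc_score(ref, onehot, multi_class="ovo",
                                     average="macro", labels=[0, 1, 2, 3])
            assert multiclass_auc(ref, test) == pytest.approx(expected, abs=1e-12)

    def test_relabelling_invariance(self):
        rng = np.random.default_rng(3)
        ref = rng.integers(0, 4, size=100)
        test = rng.integers(0, 4, size=100)
        perm = np.array([2, 0, 3, 1])
        assert multiclass_auc(perm[ref], perm[test]) == pytest.approx(
            multiclass_auc(ref, test)
        )

    def test_single_class_reference_rejected(self):
        with pytest.raises(ValueError):
            multiclass_auc([1, 1, 1], [0, 1, 2])


class TestReclassification:
    def test_identical_vectors_are_diagonal(self):
        stages = [0, 1, 2, 3, 2, 1]
        table = reclassification_table(stages, stages)
        assert table.sum() == 6
        assert (table == np.diag(np.diag(table))).all()

    def test_downgrade_pattern(self):
        table = reclassification_table([2, 1], [0, 0])
        assert table[2, 0] == 1 and table[1, 0] == 1
        assert table.sum() == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            reclassification_table([], [])

    def test_edge_list_preserves_counts(self):
        table = reclassification_table([0, 1, 2, 3, 3], [1, 1, 0, 3, 2])
        edges = crosstab_to_edges(table)
        assert edges["count"].sum() == 5
        assert len(edges) == 16


@pytest.fixture(scope="module")
def small_population():
    from perioprp import SyntheticConfig, generate_population

    cfg = SyntheticConfig(n_participants=150)
    charts, _ = generate_population(cfg, seed=12)
    return charts


class TestEvaluateProtocols:
    def test_output_shape(self, small_population):
        table = evaluate_protocols(
            small_population,
            definitions=(EFP_AAP_2018, CDC_AAP_2012),
            protocols=("FULL_MOUTH", "RAMFJORD", "MB_B"),
        )
        assert len(table) == 2 * 3
        assert set(table["definition"]) == {EFP_AAP_2018, CDC_AAP_2012}

    def test_full_mouth_rows_are_perfect(self, small_population):
        table = evaluate_protocols(
            small_population, protocols=("FULL_MOUTH",)
        )
        for _, row in table.iterrows():
            for name in ("sensitivity", "specificity", "accuracy", "mcc",
                         "auc", "staging_auc"):
                assert row[name] == pytest.approx(1.0)

    def test_prp_rows_have_no_false_positives(self, small_population):
        table = evaluate_protocols(
            small_population,
            protocols=("RAMFJORD", "CPITN", "MB_B", "MB_B_DB", "MB_B_DL"),
        )
        assert (table["fp"] == 0).all()
        assert (table["specificity"] == 1.0).all()

    def test_tidy_table_melts_all_indicators(self, small_population):
        wide = evaluate_protocols(small_population, protocols=("FULL_MOUTH",))
        tidy = tidy_indicator_table(wide)
        assert {"definition", "protocol", "indicator", "estimate",
                "ci_lo", "ci_hi"} <= set(tidy.columns)
        assert len(tidy) == len(wide) * 15

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate_protocols([], protocols=("FULL_MOUTH",))
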