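import numpy as np
import pytest

from ramandx.chemometrics import lda_fit, lda_predict, make_task, pca_fit, pca_project
from ramandx.evaluation import (
    ConfusionMatrix,
    CVConfig,
    PCCurve,
    accuracy_vs_pcs,
    compute_metrics,
    difference_spectra,
    kfold_split,
    run_cv,
    select_n_pcs,
    subrange_analysis,
    DEFAULT_SUBRANGES,
)
from ramandx.preprocess import preprocess_manifest
from ramandx.spectra_io import DatabaseEntry, DatabaseSpec, Spectrum, build_database
from ramandx.synthetic import ClassEffect, SimConfig, generate_dataset
from tests.conftest import SMALL_KW


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(tp=50, fn=0, fp=0, tn=50))
        assert (m.acc, m.se, m.sp, m.ppv, m.npv) == (100.0,) * 5

    def test_hand_arithmetic(self):
        m = compute_metrics(ConfusionMatrix(tp=30, fn=10, fp=5, tn=55))
        assert m.acc == pytest.approx(85.0)
        assert m.se == pytest.approx(75.0)
        assert m.sp == pytest.approx(91.667, abs=1e-3)
        assert m.ppv == pytest.approx(85.714, abs=1e-3)
        assert m.npv == pytest.approx(84.615, abs=1e-3)

    def test_undefined_flags(self):
        # empty positive truth: SE = 0/0 undefined; PPV = 0/5 is defined (0)
        m = compute_metrics(ConfusionMatrix(tp=0, fn=0, fp=5, tn=95))
        assert m.se is None
        assert m.ppv == 0.0
        assert m.sp == pytest.approx(95.0)
        # no predicted positives: PPV = 0/0 undefined
        m = compute_metrics(ConfusionMatrix(tp=0, fn=5, fp=0, tn=95))
        assert m.ppv is None and m.sp == pytest.approx(100.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1)

    def test_random_matrices_vs_oracle(self, rng):
        for _ in range(300):
            tp, fn, fp, tn = (int(v) for v in rng.integers(0, 40, 4))
            if tp + fn + fp + tn == 0:
                continue
            m = compute_metrics(ConfusionMatrix(tp, fn, fp, tn))
            assert m.acc == pytest.approx(100 * (tp + tn) / (tp + fn + fp + tn))
            for val, num, den in [(m.se, tp, tp + fn), (m.sp, tn, tn + fp),
                                  (m.ppv, tp, tp + fp), (m.npv, tn, tn + fn)]:
                if den == 0:
                    assert val is None
                else:
                    assert val == pytest.approx(100 * num / den)

    def test_accuracy_identity(self, rng):
        for _ in range(100):
            tp, fn, fp, tn = (int(v) for v in rng.integers(1, 30, 4))
            m = compute_metrics(ConfusionMatrix(tp, fn, fp, tn))
            lhs = m.acc * (tp + fn + fp + tn)
            rhs = m.se * (tp + fn) + m.sp * (fp + tn)
            assert lhs == pytest.approx(rhs)


def _pairs(n_a, n_b):
    return [(f"a{i}", 0) for i in range(n_a)] + [(f"b{i}", 1) for i in range(n_b)]


class TestKFoldSplit:
    def test_partition_457(self):
        entries = _pairs(169, 288)
        folds = kfold_split(entries, CVConfig(seed=3))
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {91, 92}
        flat = sorted(i for f in folds for i in f)
        assert flat == list(range(457))

    def test_determinism(self):
        entries = _pairs(30, 40)
        a = kfold_split(entries, CVConfig(seed=11))
        b = kfold_split(entries, CVConfig(seed=11))
        c = kfold_split(entries, CVConfig(seed=12))
        assert a == b
        assert a != c

    def test_stratified_ratio(self):
        entries = _pairs(169, 288)
        folds = kfold_split(entries, CVConfig(seed=5))
        for f in folds:
            n_neg = sum(1 for i in f if i < 169)
            assert abs(n_neg - 169 / 5) < 1.0 + 1e-9
            assert abs((len(f) - n_neg) - 288 / 5) < 1.0 + 1e-9

    def test_group_by_cell(self):
        # two entries per cell must land in the same fold
        entries = [(f"cell{i // 2}", i % 3 == 0) for i in range(40)]
        folds = kfold_split(
            entries, CVConfig(seed=0, stratified=False, group_by_cell=True)
        )
        for f in folds:
            cells = [entries[i][0] for i in f]
            for c in set(cells):
                assert cells.count(c) == 2

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="stratified"):
            kfold_split(_pairs(3, 40), CVConfig(seed=0, k=5))


def _separable_entries(n=40, dim=30, noise=0.01, seed=0):
    g = np.random.default_rng(seed)
    w = np.arange(float(dim))
    entries = []
    for i in range(n):
        label = "NFC" if i < n // 2 else "MBM-T"
        base = np.zeros(dim)
        base[5 if label == "NFC" else 20] = 1.0
        y = base + g.normal(0, noise, dim)
        entries.append(DatabaseEntry(f"c{i}", label, Spectrum(w, y)))
    return entries


class TestRunCV:
    def test_separable_limit(self):
        entries = _separable_entries()
        res = run_cv(entries, make_task("NFC-vs-MBM-T"), n_pcs=2, cv=CVConfig(seed=1))
        assert res.metrics.acc == 100.0
        assert res.metrics.acc_std == 0.0

    def test_each_entry_tested_once(self):
        entries = _separable_entries(n=37)
        res = run_cv(entries, make_task("NFC-vs-MBM-T"), 2, CVConfig(seed=2))
        assert res.confusion.total == 37

    def test_fold_models_reproducible_by_hand(self):
        entries = _separable_entries(n=30, noise=0.3, seed=5)
        task = make_task("NFC-vs-MBM-T")
        cv = CVConfig(seed=9)
        res = run_cv(entries, task, 3, cv)
        X = np.stack([e.spectrum.intensities for e in entries])
        y = np.array([task.membership(e.class_label) for e in entries])
        folds = kfold_split([(e.cell_id, ym) for e, ym in zip(entries, y)], cv)
        test = np.asarray(folds[0])
        train = np.setdiff1d(np.arange(30), test)
        basis = pca_fit(X[train])
        model = lda_fit(pca_project(basis, X[train], 3), y[train])
        pred, _ = lda_predict(model, pca_project(basis, X[test], 3))
        cm = res.fold_confusions[0]
        assert cm.tp == int(np.sum((y[test] == 1) & (pred == 1)))
        assert cm.tn == int(np.sum((y[test] == 0) & (pred == 0)))


class TestAccuracyVsPCs:
    def test_rank_one_signal(self):
        entries = _separable_entries(n=60, dim=25, noise=0.05, seed=3)
        curve = accuracy_vs_pcs(
            entries, make_task("NFC-vs-MBM-T"), CVConfig(seed=4), max_pcs=10
        )
        assert len(curve.n_pcs_values) == 10
        assert np.all((curve.mean_accuracy >= 0) & (curve.mean_accuracy <= 100))
        assert abs(curve.mean_accuracy[0] - curve.mean_accuracy[-1]) <= 1.0

    def test_fold_hash_matches_run_cv(self):
        entries = _separable_entries(n=40, noise=0.2)
        cv = CVConfig(seed=8)
        task = make_task("NFC-vs-MBM-T")
        curve = accuracy_vs_pcs(entries, task, cv, max_pcs=5)
        res = run_cv(entries, task, 3, cv)
        assert curve.fold_hash == res.fold_hash
        # curve value at n=3 equals the pooled run_cv accuracy
        assert curve.mean_accuracy[2] == pytest.approx(res.metrics.acc)

    def test_max_pcs_capped_by_training_size(self):
        entries = _separable_entries(n=20)
        with pytest.raises(ValueError, match="max_pcs"):
            accuracy_vs_pcs(entries, make_task("NFC-vs-MBM-T"),
                            CVConfig(seed=0), max_pcs=15)


class TestSelectNPcs:
    def test_documented_example(self):
        curve = PCCurve(np.arange(1, 7), np.array([80, 90, 93, 93.1, 93.0, 93.05]),
                        np.zeros(6))
        assert select_n_pcs(curve, 0.5) == 3

    def test_strictly_increasing(self):
        acc = np.linspace(50, 90, 8)
        curve = PCCurve(np.arange(1, 9), acc, np.zeros(8))
        assert select_n_pcs(curve, 0.5) == 8

    def test_constant_curve(self):
        curve = PCCurve(np.arange(1, 6), np.full(5, 88.0), np.zeros(5))
        assert select_n_pcs(curve, 0.5) == 1

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(200):
            acc = rng.uniform(50, 100, int(rng.integers(1, 30)))
            tol = float(rng.uniform(0, 5))
            curve = PCCurve(np.arange(1, acc.size + 1), acc, np.zeros_like(acc))
            best = max(acc)
            oracle = next(i + 1 for i, a in enumerate(acc) if a >= best - tol)
            assert select_n_pcs(curve, tol) == oracle

    def test_monotone_in_tolerance(self, rng):
        acc = rng.uniform(70, 95, 25)
        curve = PCCurve(np.arange(1, 26), acc, np.zeros(25))
        sel = [select_n_pcs(curve, t) for t in (0.1, 0.5, 1.0, 2.0, 5.0)]
        assert all(a >= b for a, b in zip(sel, sel[1:]))

    def test_empty_curve(self):
        with pytest.raises(ValueError):
            select_n_pcs(PCCurve(np.array([]), np.array([]), np.array([])))


@pytest.fixture(scope="module")
def small_db(small_preprocessed):
    return build_database(small_preprocessed, DatabaseSpec("I"))


class TestSubrangeAnalysis:
    def test_degenerate_full_range_reproduces_full_run(self, small_db):
        from ramandx.evaluation import SubrangeSpec

        task = make_task("normal-vs-abnormal")
        cv = CVConfig(seed=21)
        full = subrange_analysis(
            small_db, [task], [SubrangeSpec("full", 600.0, 1800.0)],
            cv, max_pcs=6,
        )
        curve = accuracy_vs_pcs(small_db, task, cv, max_pcs=6)
        n = select_n_pcs(curve)
        direct = run_cv(small_db, task, n, cv)
        row = full.iloc[0]
        assert row["n_pcs"] == n
        assert (row["tp"], row["fn"], row["fp"], row["tn"]) == (
            direct.confusion.tp, direct.confusion.fn,
            direct.confusion.fp, direct.confusion.tn,
        )
        assert row["acc"] == direct.metrics.acc

    def test_output_shape_four_by_four(self, small_db):
        tasks = [make_task(t) for t in
                 ["normal-vs-abnormal", "NIH/3T3-vs-MBM-T",
                  "NFC-vs-NIH/3T3", "NFC-vs-MBM-T"]]
        table = subrange_analysis(small_db, tasks, DEFAULT_SUBRANGES,
                                  CVConfig(seed=2), max_pcs=5)
        assert len(table) == 16
        assert set(table["task"]) == {t.task_id for t in tasks}
        assert set(table["range"]) == {r.name for r in DEFAULT_SUBRANGES}

    def test_localized_signal_favours_its_range(self):
        # class effect confined to 700-800/cm: the carbohydrate range
        # (600-1195) must beat the amide range (1521-1728)
        effects = {
            "NFC": ClassEffect("NFC", {}, 0.0),
            "MBM-T": ClassEffect("MBM-T", {750.0: 0.8, 781.0: 0.8}, 1.0),
        }
        cfg = SimConfig(
            seed=11,
            n_cells={"NFC": 40, "MBM-T": 40},
            site_counts={
                "center": {"NFC": 40, "MBM-T": 40},
                "cytoplasm": {"NFC": 0, "MBM-T": 0},
                "membrane": {"NFC": 0, "MBM-T": 0},
            },
            class_effects=effects,
            effect_axis={750.0: 0.4, 781.0: 0.4},
            contrast_sd=0.0,
        )
        pp = preprocess_manifest(generate_dataset(cfg))
        db = build_database(pp, DatabaseSpec("I"))
        task = make_task("NFC-vs-MBM-T")
        table = subrange_analysis(db, [task], DEFAULT_SUBRANGES,
                                  CVConfig(seed=5), max_pcs=6)
        acc = dict(zip(table["range"], table["acc"]))
        assert acc["carbohydrates"] > acc["proteins(amideI+II)"]


class TestDifferenceSpectra:
    def test_antisymmetry_and_shapes(self, small_preprocessed):
        out = difference_spectra(small_preprocessed)
        for site, d in out.items():
            assert set(d["mean"]) == {"NFC", "NIH/3T3", "MBM-T"}
            for (a, b), delta in d["diff"].items():
                assert np.array_equal(delta, -d["diff"][(b, a)])

    def test_null_distributions_give_near_zero_delta(self):
        effects = {c: ClassEffect(c, {}, 0.0) for c in ("NFC", "NIH/3T3", "MBM-T")}
        cfg = SimConfig(seed=3, class_effects=effects, **SMALL_KW)
        pp = preprocess_manifest(generate_dataset(cfg))
        out = difference_spectra(pp)
        d = out["center"]
        delta = d["diff"][("NFC", "MBM-T")]
        n_a, n_b = d["n"]["NFC"], d["n"]["MBM-T"]
        sem = np.sqrt(d["std"]["NFC"] ** 2 / n_a + d["std"]["MBM-T"] ** 2 / n_b)
        assert np.mean(np.abs(delta) < 3 * sem) > 0.95

    def test_injected_effect_located(self):
        effects = {
            "NFC": ClassEffect("NFC", {}, 0.0),
            "NIH/3T3": ClassEffect("NIH/3T3", {}, 0.0),
            "MBM-T": ClassEffect("MBM-T", {1443.0: 1.0}, 1.0),
        }
        cfg = SimConfig(seed=6, class_effects=effects,
                        effect_axis={1443.0: 0.3}, contrast_sd=0.0, **SMALL_KW)
        pp = preprocess_manifest(generate_dataset(cfg))
        out = difference_spectra(pp)
        delta = out["center"]["diff"][("MBM-T", "NFC")]
        grid = pp.grid
        peak = grid[np.argmax(np.abs(delta))]
        assert abs(peak - 1443.0) <= 5.0

    def test_missing_class_rejected(self):
        cfg = SimConfig(
            seed=1,
            n_cells={"NFC": 5, "NIH/3T3": 5, "MBM-T": 0},
            site_counts={
                "center": {"NFC": 5, "NIH/3T3": 5},
                "cytoplasm": {"NFC": 3, "NIH/3T3": 3},
                "membrane": {"NFC": 3, "NIH/3T3": 3},
            },
        )
        pp = preprocess_manifest(generate_dataset(cfg))
        with pytest.raises(ValueError, match="missing class"):
            difference_spectra(pp)
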