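import numpy as np
import pytest

import bmhnet as B
from bmhnet.exceptions import SingleClassError, UndefinedMetricError


def toy_dataset(n=20, nc=12, nb=36, seed=0, separable=False):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    Xc = rng.normal(size=(n, nc))
    Xb = rng.normal(size=(n, nb))
    if separable:
        Xb[y == 1, :8] += 3.0
    return Xc, Xb, y


class TestForward:
    def test_inference_is_deterministic(self):
        Xc, Xb, _ = toy_dataset()
        model = B.BMHNet(12, 36, B.NetConfig(backbone_hidden=8, seed=3))
        s1 = model.predict_proba(Xc, Xb)
        s2 = model.predict_proba(Xc, Xb)
        assert np.array_equal(s1, s2)

    def test_zero_inputs_give_finite_open_interval_score(self):
        model = B.BMHNet(10, 18, B.NetConfig(backbone_hidden=4, seed=0))
        score = model.predict_proba(np.zeros((1, 10)), np.zeros((1, 18)))[0]
        assert 0.0 < score < 1.0

    def test_shape_mismatch_names_offending_input(self):
        model = B.BMHNet(10, 18, B.NetConfig(backbone_hidden=4, seed=0))
        with pytest.raises(ValueError, match="x_connectome"):
            model.predict_proba(np.zeros((1, 9)), np.zeros((1, 18)))
        with pytest.raises(ValueError, match="x_betti"):
            model.predict_proba(np.zeros((1, 10)), np.zeros((1, 17)))

    def test_separable_classes_get_separated_scores(self):
        Xc, Xb, y = toy_dataset(n=40, separable=True, seed=1)
        cfg = B.NetConfig(backbone_hidden=16, learning_rate=1e-3,
                          epochs=100, seed=2)
        model = B.train((Xc, Xb, y), cfg)
        scores = model.predict_proba(Xc, Xb)
        assert scores[y == 1].mean() > scores[y == 0].mean()


class TestTraining:
    def test_loss_decreases(self):
        cfg = B.NetConfig(backbone_hidden=16, learning_rate=1e-3,
                          epochs=50, seed=0)
        model = B.train(toy_dataset(seed=4, separable=True), cfg)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_same_seed_identical_parameters(self):
        data = toy_dataset(seed=5)
        cfg = B.NetConfig(backbone_hidden=8, learning_rate=1e-3, epochs=10, seed=9)
        m1, m2 = B.train(data, cfg), B.train(data, cfg)
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k])

    def test_single_class_rejected(self):
        Xc, Xb, _ = toy_dataset()
        with pytest.raises(SingleClassError):
            B.train((Xc, Xb, np.zeros(20, dtype=int)), B.NetConfig(seed=0))

    def test_checkpoint_roundtrip(self, tmp_path):
        Xc, Xb, y = toy_dataset(seed=6)
        cfg = B.NetConfig(backbone_hidden=8, epochs=5, learning_rate=1e-3, seed=1)
        model = B.train((Xc, Xb, y), cfg)
        p = tmp_path / "model.npz"
        model.save(p)
        back = B.BMHNet.load(p)
        assert np.array_equal(
            back.predict_proba(Xc, Xb), model.predict_proba(Xc, Xb)
        )


class TestEvaluate:
    def test_perfect_separation(self):
        report = B.evaluate([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert (report.f_score, report.accuracy,
                report.precision, report.sensitivity) == (1, 1, 1, 1)

    def test_all_equal_scores_degenerate_to_all_positive(self):
        report = B.evaluate([0.5] * 6, [0, 0, 0, 1, 1, 1])
        # forced all-positive: precision 1/2, recall 1
        assert report.f_score == pytest.approx(2 / 3)
        assert report.sensitivity == 1.0

    def test_hand_computed_eight_subject_example(self):
        scores = [0.1, 0.2, 0.35, 0.4, 0.6, 0.65, 0.8, 0.9]
        labels = [0, 0, 1, 0, 1, 0, 1, 1]
        report = B.evaluate(scores, labels)
        # best cut at (0.2+0.35)/2: TP=4 FP=2 FN=0 TN=2
        assert report.binarization_threshold == pytest.approx(0.275)
        assert report.f_score == pytest.approx(0.8)
        assert report.accuracy == pytest.approx(0.75)
        assert report.precision == pytest.approx(2 / 3)
        assert report.sensitivity == pytest.approx(1.0)

    def test_invariant_to_monotone_score_transform(self):
        rng = np.random.default_rng(11)
        scores = rng.random(30)
        labels = (rng.random(30) < 0.4).astype(int)
        base = B.evaluate(scores, labels)
        warped = B.evaluate(scores**3, labels)
        for m in ("f_score", "accuracy", "precision", "sensitivity"):
            assert getattr(base, m) == pytest.approx(getattr(warped, m))

    def test_no_positive_labels_flagged(self):
        with pytest.raises(UndefinedMetricError):
            B.evaluate([0.2, 0.8], [0, 0])


class TestImportance:
    def _model(self, seed=0):
        return B.BMHNet(6, 36, B.NetConfig(backbone_hidden=8, seed=seed))

    def test_zero_betti_backbone_gives_zero_importance(self):
        model = self._model()
        model.params["emb_b_W"][:] = 0.0
        rng = np.random.default_rng(0)
        imp = B.subnetwork_importance(model, rng.normal(size=(5, 6)),
                                      rng.normal(size=(5, 36)))
        assert all(v == 0.0 for v in imp.values())

    def test_single_subnetwork_mask_isolates_importance(self):
        model = self._model(seed=1)
        # keep only DMN's inputs (block 3 of beta0 and of beta1, T=2)
        T, half = 2, 18
        keep = np.zeros(36, dtype=bool)
        j = B.SUBNETWORKS.index("DMN")
        keep[j * T:(j + 1) * T] = True
        keep[half + j * T: half + (j + 1) * T] = True
        model.params["emb_b_W"][~keep, :] = 0.0
        rng = np.random.default_rng(2)
        imp = B.subnetwork_importance(model, rng.normal(size=(8, 6)),
                                      rng.normal(size=(8, 36)))
        assert imp["DMN"] > 0
        assert all(v == 0.0 for s, v in imp.items() if s != "DMN")

    def test_invariant_to_duplicated_validation_subject(self):
        model = self._model(seed=3)
        rng = np.random.default_rng(4)
        Xc, Xb = rng.normal(size=(4, 6)), rng.normal(size=(4, 36))
        base = B.subnetwork_importance(model, Xc, Xb)
        dup = B.subnetwork_importance(
            model, np.vstack([Xc, Xc]), np.vstack([Xb, Xb])
        )
        for s in base:
            assert dup[s] == pytest.approx(base[s])

    def test_aggregate_mean_sd(self):
        splits = [{s: 1.0 for s in B.SUBNETWORKS},
                  {s: 3.0 for s in B.SUBNETWORKS}]
        agg = B.aggregate_importance(splits)
        assert agg["VN"] == (2.0, 1.0)


class TestGroupCurveTest:
    def test_identical_groups_yield_no_flags(self):
        g = np.tile(np.arange(36.0), (4, 1))
        df = B.group_curve_test(g, g)
        assert not df["significant"].any()
        assert df["undefined"].all()

    def test_large_shift_at_one_grid_point_flagged(self):
        rng = np.random.default_rng(0)
        g0 = rng.normal(size=(10, 36))
        g1 = rng.normal(size=(10, 36))
        g1[:, 7] += 100.0
        df = B.group_curve_test(g0, g1)
        assert bool(df.loc[7, "significant"])

    def test_holm_dominates_raw_pvalues(self):
        rng = np.random.default_rng(1)
        g0 = rng.normal(size=(8, 36))
        g1 = rng.normal(size=(8, 36)) + 0.5
        df = B.group_curve_test(g0, g1)
        ok = ~df["undefined"]
        assert np.all(df.loc[ok, "p_holm"] >= df.loc[ok, "p_raw"] - 1e-12)
        adj_sig = set(df.index[df["significant"]])
        raw_sig = set(df.index[ok & (df["p_raw"] <= 0.05)])
        assert adj_sig <= raw_sig

    def test_layout_annotation(self):
        rng = np.random.default_rng(2)
        df = B.group_curve_test(rng.normal(size=(3, 36)), rng.normal(size=(3, 36)))
        # 36 = 18 curves x T=2
        assert list(df["subnetwork"][:2]) == ["BGN", "BGN"]
        assert df["n"].iloc[0] == 0 and df["n"].iloc[-1] == 1
        assert df["grid_index"].max() == 1
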