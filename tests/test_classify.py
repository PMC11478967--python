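"""Box-Cox regularization and LDA classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import spikequad as sq


@pytest.fixture(scope="module")
def separable_table():
    rng = np.random.default_rng(20)
    n = 20
    return pd.DataFrame({
        "species": ["A"] * n + ["B"] * n,
        "SL": np.concatenate([rng.uniform(10, 20, n), rng.uniform(40, 50, n)]),
        "SFW": rng.normal(5, 1, 2 * n),
    })


class TestBoxCox:
    def test_lognormal_lambda_near_zero(self):
        rng = np.random.default_rng(21)
        t = pd.DataFrame({"SL": np.exp(rng.normal(2, 0.7, 200))})
        _, tf = sq.boxcox_fit_transform(t, ["SL"])
        assert -0.3 <= tf.lambdas["SL"] <= 0.3
        # independent check: grid-search profile log-likelihood peaks nearby
        x = t["SL"].to_numpy()
        grid = np.linspace(-2, 2, 161)
        ll = [sps.boxcox_llf(l, x) for l in grid]
        assert abs(grid[int(np.argmax(ll))] - tf.lambdas["SL"]) < 0.05

    def test_normalizes_lognormal_data(self):
        rng = np.random.default_rng(22)
        t = pd.DataFrame({"SL": np.exp(rng.normal(0, 0.8, 150))})
        out, _ = sq.boxcox_fit_transform(t, ["SL"])
        assert sps.shapiro(out["SL"]).pvalue > 0.01

    def test_nonpositive_values_shifted(self):
        t = pd.DataFrame({"q_S3S": [-0.5, 0.0, 0.3, 0.8, 1.2, 0.1]})
        out, tf = sq.boxcox_fit_transform(t, ["q_S3S"])
        assert tf.shifts["q_S3S"] == pytest.approx(1.5)
        assert np.isfinite(out["q_S3S"]).all()

    def test_constant_trait_skipped(self):
        t = pd.DataFrame({"SL": [3.0] * 10})
        out, tf = sq.boxcox_fit_transform(t, ["SL"])
        assert "SL" in tf.skipped
        assert (out["SL"] == 3.0).all()


class TestLda:
    def test_perfectly_separable(self, separable_table):
        res = sq.lda_classify(separable_table, "species", ["SL", "SFW"])
        assert res.accuracy == 100.0

    def test_confusion_row_sums_are_class_sizes(self, population_table):
        res = sq.lda_classify(population_table, "species",
                              sq.DIGITAL_TRAIT_NAMES)
        counts = population_table["species"].value_counts()
        for cls in res.classes:
            assert res.confusion.loc[cls].sum() == counts[cls]
        assert res.accuracy == pytest.approx(
            100.0 * np.trace(res.confusion.to_numpy())
            / res.confusion.to_numpy().sum())

    def test_permuted_labels_near_chance(self, population_table):
        rng = np.random.default_rng(23)
        t = population_table.copy()
        t["species"] = rng.permutation(t["species"].to_numpy())
        res = sq.lda_classify(
            t, "species",
            list(sq.MANUAL_TRAIT_NAMES) + list(sq.MODEL_TRAIT_NAMES))
        assert res.accuracy < 35.0

    def test_combined_beats_manual(self, population_table):
        manual = sq.lda_classify(population_table, "species",
                                 sq.MANUAL_TRAIT_NAMES)
        combined = sq.lda_classify(population_table, "species",
                                   sq.ALL_TRAIT_NAMES)
        assert combined.accuracy > manual.accuracy
        assert combined.accuracy > 60.0

    def test_affine_rescaling_invariance(self, population_table):
        traits = list(sq.MANUAL_TRAIT_NAMES) + list(sq.MODEL_TRAIT_NAMES)
        base = sq.lda_classify(population_table, "species", traits)
        t = population_table.copy()
        t["SL"] = t["SL"] * 1000.0 + 7.0
        scaled = sq.lda_classify(t, "species", traits)
        assert scaled.accuracy == pytest.approx(base.accuracy, abs=1.0)

    def test_loo_not_above_resubstitution(self, population_table):
        traits = list(sq.MODEL_TRAIT_NAMES)
        resub = sq.lda_classify(population_table, "species", traits,
                                evaluation="resubstitution")
        loo = sq.lda_classify(population_table, "species", traits,
                              evaluation="leave-one-out")
        assert loo.accuracy <= resub.accuracy + 5.0

    def test_biplot_hulls(self, population_table):
        res = sq.lda_classify(population_table, "species",
                              sq.DIGITAL_TRAIT_NAMES)
        hulls = res.class_hulls()
        assert set(hulls) == set(res.classes)
        for pts in hulls.values():
            assert pts.shape[1] == 2

    def test_single_class_rejected(self):
        t = pd.DataFrame({"species": ["A"] * 5, "SL": np.arange(5.0)})
        with pytest.raises(ValueError):
            sq.lda_classify(t, "species", ["SL"])


class TestClassificationReport:
    def test_six_row_grid(self, population_table):
        grid, results = sq.classification_report(population_table, "species")
        assert len(grid) == 6
        assert set(grid["features"]) == {"manual", "digital", "combined"}
        assert set(grid["transform"]) == {"raw", "boxcox"}
        assert ((grid["accuracy_percent"] >= 0)
                & (grid["accuracy_percent"] <= 100)).all()

    def test_boxcox_no_large_regression(self, population_table):
        # Box-Cox should not cost more than a few accuracy points
        grid, _ = sq.classification_report(population_table, "species")
        g = grid.set_index(["features", "transform"])["accuracy_percent"]
        for f in ("manual", "digital", "combined"):
            assert g[(f, "boxcox")] >= g[(f, "raw")] - 5.0

    def test_spike_type_labels(self, population_table):
        grid, _ = sq.classification_report(population_table, "spike_type")
        assert (grid["accuracy_percent"] > 33.4).all()

    def test_lambda_one_is_affine_identity(self, separable_table):
        # lambda = 1 Box-Cox is affine; LDA accuracy must match raw
        tf = sq.BoxCoxTransform(lambdas={"SL": 1.0}, shifts={"SL": 0.0})
        transformed = tf.transform(separable_table)
        raw = sq.lda_classify(separable_table, "species", ["SL", "SFW"])
        aff = sq.lda_classify(transformed, "species", ["SL", "SFW"])
        assert aff.accuracy == pytest.approx(raw.accuracy)
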