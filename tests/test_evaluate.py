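"""Evaluation statistics: ROC/AUC, confusion, inconclusive band, per-patient
and per-grade summaries, probability maps and boundary estimation."""

import numpy as np
import pandas as pd
import pytest

import oracles
from mptexture import evaluate as ev
from mptexture.evaluate import EvaluationError


def results_frame(posteriors, truths, patients=None, samples=None):
    posteriors = np.asarray(posteriors, dtype=float)
    df = pd.DataFrame(
        {
            "posterior_tumor": posteriors,
            "true_label": truths,
            "predicted": np.where(posteriors > 0.5, "tumor", "liver"),
            "inconclusive": (posteriors >= 0.3) & (posteriors <= 0.7),
        }
    )
    if patients is not None:
        df["patient_id"] = patients
    if samples is not None:
        df["sample"] = samples
    return df


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = ev.roc_auc([0.9, 0.8, 0.4, 0.2], ["tumor", "tumor", "liver", "liver"])
        assert auc == 1.0

    def test_inverted_scores_complement(self, rng):
        scores = rng.random(100)
        truths = rng.integers(0, 2, 100)
        truths[:2] = [0, 1]
        _, auc = ev.roc_auc(scores, truths)
        _, auc_inv = ev.roc_auc(1 - scores, truths)
        assert auc_inv == pytest.approx(1 - auc, abs=1e-12)

    def test_matches_mann_whitney_oracle_with_ties(self, rng):
        scores = np.round(rng.random(300), 1)  # heavy ties
        truths = rng.integers(0, 2, 300)
        truths[:2] = [0, 1]
        _, auc = ev.roc_auc(scores, truths)
        assert auc == pytest.approx(oracles.auc_mannwhitney(scores, truths), abs=1e-10)

    def test_independent_scores_near_half(self):
        in_band = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            scores = rng.random(2000)
            truths = np.repeat([0, 1], 1000)
            _, auc = ev.roc_auc(scores, truths)
            in_band += 0.45 <= auc <= 0.55
        assert in_band >= 19

    def test_roc_points_monotone(self, rng):
        scores = rng.random(50)
        truths = rng.integers(0, 2, 50)
        truths[:2] = [0, 1]
        points, _ = ev.roc_auc(scores, truths)
        assert np.all(np.diff(points[:, 0]) >= 0) and np.all(np.diff(points[:, 1]) >= 0)

    def test_single_class_errors(self):
        with pytest.raises(EvaluationError):
            ev.roc_auc([0.1, 0.9], ["tumor", "tumor"])


class TestConfusion:
    def test_correct_rate(self):
        truths = ["tumor"] * 5 + ["liver"] * 5
        predicted = ["tumor"] * 4 + ["liver"] + ["liver"] * 4 + ["tumor"]
        summary = ev.confusion_and_rates(predicted, truths)
        assert summary.correct_rate == pytest.approx(0.8)
        assert summary.confusion.sum() == 10

    def test_degenerate_specificity_flagged(self):
        summary = ev.confusion_and_rates(["tumor", "tumor"], ["tumor", "tumor"])
        assert summary.sensitivity == 1.0
        assert summary.specificity is None

    def test_unknown_label_errors(self):
        with pytest.raises(EvaluationError):
            ev.confusion_and_rates(["tumor"], ["stroma"])

    def test_correct_rate_complements_off_diagonal(self, rng):
        truths = rng.integers(0, 2, 200)
        predicted = rng.integers(0, 2, 200)
        summary = ev.confusion_and_rates(predicted, truths)
        off = summary.confusion[0, 1] + summary.confusion[1, 0]
        assert summary.correct_rate == pytest.approx(1 - off / 200)


class TestInconclusiveRate:
    @pytest.mark.parametrize(
        "posteriors, expected",
        [([0.1, 0.5, 0.8, 0.31], 0.5), ([0.99, 0.99], 0.0), ([0.5, 0.5, 0.5], 1.0)],
    )
    def test_band_fraction(self, posteriors, expected):
        assert ev.inconclusive_rate(posteriors) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(EvaluationError):
            ev.inconclusive_rate([])


class TestPerPatient:
    def test_misclassified_fraction(self):
        df = results_frame(
            posteriors=[0.9] * 8 + [0.2] * 2,
            truths=["tumor"] * 10,
            patients=["P1"] * 10,
            samples=["tumor"] * 10,
        )
        out = ev.per_patient_summary(df)
        assert len(out) == 1
        assert out.loc[0, "misclassified_fraction"] == pytest.approx(0.2)
        assert out.loc[0, "n_images"] == 10

    def test_all_correct_patient(self):
        df = results_frame([0.95] * 5, ["tumor"] * 5, ["P2"] * 5, ["tumor"] * 5)
        out = ev.per_patient_summary(df)
        assert out.loc[0, "misclassified_fraction"] == 0.0
        assert out.loc[0, "mean_true_class_posterior"] >= 0.5

    def test_image_counts_conserved(self, rng):
        n = 60
        df = results_frame(
            rng.random(n),
            rng.choice(["liver", "tumor"], n),
            rng.choice(["P1", "P2", "P3"], n),
            rng.choice(["liver", "tumor"], n),
        )
        out = ev.per_patient_summary(df)
        assert out["n_images"].sum() == n


class TestPerGrade:
    def test_rates_by_grade_and_ungraded(self):
        df = results_frame(
            [0.9, 0.9, 0.2, 0.9, 0.4, 0.8],
            ["tumor"] * 6,
            ["A", "A", "A", "B", "B", "C"],
            ["tumor"] * 6,
        )
        out = ev.per_grade_rates(df, {"A": "G1", "B": "G2"})
        rates = dict(zip(out["grade"], out["correct_rate"]))
        assert rates["G1"] == pytest.approx(2 / 3)
        assert rates["G2"] == pytest.approx(0.5)
        assert rates["ungraded"] == pytest.approx(1.0)
        assert out["correct_rate"].between(0, 1).all()

    def test_single_grade_single_row(self):
        df = results_frame([0.9], ["tumor"], ["A"], ["tumor"])
        assert len(ev.per_grade_rates(df, {"A": "G2"})) == 1

    def test_difficulty_tiers_order_correct_rates(self):
        """Grade-proxy simulation: patients generated at smaller class
        separation (harder) are classified no better than well-separated ones."""
        from mptexture import experiments as ex
        from mptexture import classify, features, fov_io, synthetic

        shape = (56, 112)
        model = next(
            iter(
                ex.run_cohort_experiment(
                    seed=11, n_patients=6, n_train_patients=3, n_fov=8,
                    combos=[("TPEF", "SHG")], n_search_steps=2, image_shape=shape,
                ).models.values()
            )
        )
        rows = []
        grades = {}
        for grade, delta, base_seed in (("easy", 1.2, 500), ("hard", 0.15, 600)):
            spec = synthetic.CohortSpec(
                n_patients=3, class_separation=delta, image_shape=shape,
                n_fov_liver=6, n_fov_tumor=6,
            )
            table = ex.featurize_cohort(spec, seed=base_seed)
            table = table[table["qc_accepted"]]
            table["patient_id"] = grade + "_" + table["patient_id"]
            grades.update({p: grade for p in table["patient_id"]})
            rows.append(table)
        preds = classify.predict(model, pd.concat(rows, ignore_index=True))
        out = ev.per_grade_rates(preds, grades)
        rates = dict(zip(out["grade"], out["correct_rate"]))
        assert rates["hard"] <= rates["easy"]
        assert rates["easy"] >= 0.9


class TestProbabilityMap:
    def make_results(self, grid=(2, 3), drop=None):
        rows = []
        for r in range(grid[0]):
            for c in range(grid[1]):
                if drop and (r, c) in drop:
                    continue
                rows.append({"row": r, "col": c, "posterior_tumor": 0.1 + 0.2 * c})
        return pd.DataFrame(rows)

    def test_grid_filled(self):
        pmap = ev.build_probability_map(self.make_results(), grid=(2, 3))
        assert pmap.values.shape == (2, 3)
        assert pmap.present.all()

    def test_missing_tile_masked(self):
        pmap = ev.build_probability_map(self.make_results(drop={(1, 1)}), grid=(2, 3))
        assert not pmap.present[1, 1]
        assert np.isnan(pmap.values[1, 1])
        assert pmap.present.sum() == 5

    def test_duplicate_tiles_error(self):
        df = self.make_results()
        df = pd.concat([df, df.iloc[[0]]], ignore_index=True)
        with pytest.raises(EvaluationError):
            ev.build_probability_map(df, grid=(2, 3))

    def test_inconclusive_mask(self):
        df = pd.DataFrame({"row": [0, 0], "col": [0, 1], "posterior_tumor": [0.5, 0.95]})
        pmap = ev.build_probability_map(df, grid=(1, 2))
        assert pmap.inconclusive[0, 0] and not pmap.inconclusive[0, 1]

    @pytest.mark.parametrize(
        "col_medians, expected",
        [
            ([0.1, 0.2, 0.3, 0.9, 0.9], 3),
            ([0.9, 0.9, 0.9], 0),       # all tumor
            ([0.1, 0.1, 0.1], 3),       # all liver -> boundary past the last column
        ],
    )
    def test_boundary_estimation(self, col_medians, expected):
        values = np.tile(col_medians, (4, 1)).astype(float)
        pmap = ev.ProbabilityMap(
            values=values,
            present=np.ones_like(values, dtype=bool),
            inconclusive=np.zeros_like(values, dtype=bool),
            sample_id="t",
        )
        assert ev.estimate_boundary_col(pmap) == expected

    def test_render_writes_png(self, tmp_path):
        pmap = ev.build_probability_map(self.make_results(drop={(0, 2)}), grid=(2, 3))
        ev.render_probability_map(pmap, tmp_path / "map.png")
        assert (tmp_path / "map.png").stat().st_size > 0


class TestEvaluateModel:
    def test_report_bundle(self, rng):
        n = 40
        truths = np.repeat(["liver", "tumor"], n // 2)
        posteriors = np.where(truths == "tumor", 0.8, 0.2) + rng.normal(0, 0.05, n)
        df = results_frame(np.clip(posteriors, 0, 1), truths, ["P1"] * n, ["liver"] * (n // 2) + ["tumor"] * (n // 2))
        report = ev.evaluate_model(df, "TPEF-SHG")
        assert report.auc > 0.95
        assert report.confusion.sum() == n
        assert 0 <= report.inconclusive_rate <= 1

    def test_report_serialization(self, tmp_path, rng):
        df = results_frame([0.9, 0.1], ["tumor", "liver"], ["P1", "P1"], ["tumor", "liver"])
        report = ev.evaluate_model(df, "TPEF")
        ev.write_report(report, tmp_path)
        assert (tmp_path / "report_tpef.json").exists()
        assert (tmp_path / "roc_tpef.csv").exists()
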