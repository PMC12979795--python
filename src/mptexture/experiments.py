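"""In-memory cohort experiments: generate → QC → featurize → train → evaluate.

These drivers realize the standard study conditions on synthetic cohorts
without touching the filesystem, and are shared by the test suite, the
acceptance script and the pipeline's building blocks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import classify, evaluate, features, fov_io, synthetic

#: Compact search space used for cohort experiments: single hidden layer,
#: two width options, two activations. Keeps the search honest (several
#: genuinely different candidates) at desk-scale runtimes.
FAST_SEARCH = classify.SearchSpace(
    n_layers=(1,),
    widths=(10, 25),
    activations=("relu", "tanh"),
    l2_range=(1e-5, 1e-2),
)

MULTI_CHANNEL_COMBOS: tuple[tuple[str, ...], ...] = (
    ("CARS", "TPEF"),
    ("CARS", "SHG"),
    ("TPEF", "SHG"),
    ("CARS", "TPEF", "SHG"),
)


def _subseed(seed: int, key: int) -> int:
    return int(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(key),)).generate_state(1)[0] % (2**31))


def featurize_cohort(
    spec: synthetic.CohortSpec,
    seed: int,
    tau_bg: float = 0.25,
    tau_sat: float = 0.05,
    levels: int = features.DEFAULT_LEVELS,
    distances_px: Sequence[int] = features.DEFAULT_DISTANCES,
    symmetric: bool = False,
) -> pd.DataFrame:
    """Generate a cohort in memory, QC every FoV and featurize the accepted
    ones. Returns one row per FoV: metadata, QC outcome and (for accepted
    FoVs) the 51 feature columns."""
    names = features.fov_feature_names()
    rows = []
    for pspec, fov in synthetic.generate_cohort(spec, seed):
        qc = fov_io.qc_filter(fov, tau_bg=tau_bg, tau_sat=tau_sat)
        r, c = fov.tile if fov.tile is not None else (0, 0)
        row = {
            "patient_id": fov.patient_id,
            "sample": fov.sample_kind,
            "row": r,
            "col": c,
            "true_label": fov.true_label,
            "qc_accepted": qc.accepted,
            "qc_reason": qc.reason,
        }
        if qc.accepted:
            vec = features.featurize_fov(
                fov, distances_px=distances_px, levels=levels, symmetric=symmetric
            )
            row.update(dict(zip(names, vec)))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortExperiment:
    """Everything produced by one separated-cohort classification run."""

    feature_table: pd.DataFrame
    split: classify.SplitPlan
    models: dict[str, classify.TrainedModel]
    reports: dict[str, evaluate.EvalReport]
    predictions: dict[str, pd.DataFrame]


def run_cohort_experiment(
    seed: int,
    n_patients: int = 40,
    n_train_patients: int = 20,
    n_fov: int = 50,
    class_separation: float = 1.0,
    combos: Sequence[Sequence[str]] = classify.CHANNEL_COMBOS,
    n_search_steps: int = 4,
    max_epochs: int = 1000,
    image_shape: tuple[int, int] = synthetic.DEFAULT_SHAPE,
    n_border_patients: int = 0,
) -> CohortExperiment:
    """Full classification experiment on one synthetic cohort.

    Defaults follow the standard evaluation conditions: 40 patients (20
    train + 20 patient-disjoint test), 50 FoVs per class per patient at the
    nominal 152×302 px geometry, full class separation.
    """
    spec = synthetic.CohortSpec(
        n_patients=n_patients,
        class_separation=class_separation,
        image_shape=image_shape,
        n_fov_liver=n_fov,
        n_fov_tumor=n_fov,
        n_border_patients=n_border_patients,
    )
    table = featurize_cohort(spec, seed=_subseed(seed, 0))
    accepted = table[table["qc_accepted"]].reset_index(drop=True)
    split = classify.make_split(accepted, n_train_patients, seed=_subseed(seed, 1))
    config = classify.TrainConfig(
        max_epochs=max_epochs,
        n_search_steps=n_search_steps,
        search_space=FAST_SEARCH,
        seed=_subseed(seed, 2),
    )
    models = classify.train_channel_models(accepted, split, config, combos=combos)
    test_rows = accepted[
        accepted["patient_id"].isin(split.test_patients)
        & accepted["sample"].isin(["liver", "tumor"])
    ].reset_index(drop=True)
    predictions = {}
    reports = {}
    for name, model in models.items():
        preds = classify.predict(model, test_rows)
        predictions[name] = preds
        reports[name] = evaluate.evaluate_model(preds, model_name=name)
    return CohortExperiment(
        feature_table=table, split=split, models=models, reports=reports, predictions=predictions
    )


def run_null_experiment(
    seed: int,
    n_patients: int = 20,
    n_fov: int = 50,
    image_shape: tuple[int, int] = synthetic.DEFAULT_SHAPE,
    combo: Sequence[str] = ("TPEF", "SHG"),
) -> float:
    """Null-control AUC: a δ=0 cohort (liver and tumor drawn from identical
    parameter distributions) split patient-wise in half; returns the test AUC
    of one model, which should hover near 0.5."""
    experiment = run_cohort_experiment(
        seed,
        n_patients=n_patients,
        n_train_patients=n_patients // 2,
        n_fov=n_fov,
        class_separation=0.0,
        combos=[tuple(combo)],
        n_search_steps=2,
        image_shape=image_shape,
    )
    report = next(iter(experiment.reports.values()))
    return report.auc


def run_border_replicates(
    model: classify.TrainedModel,
    liver: synthetic.TissueParams,
    tumor: synthetic.TissueParams,
    seeds: Sequence[int],
    grid: tuple[int, int] = (4, 10),
    boundary_col: int = 5,
    image_shape: tuple[int, int] = synthetic.DEFAULT_SHAPE,
) -> tuple[float, list[int]]:
    """Boundary localization over seeded synthetic border samples.

    For each seed a border sample is rendered, its tiles are QC'd and
    featurized with the model's channel set, the posterior map is built and
    the boundary column estimated (first 0.5-crossing of the column-wise
    median). Returns the fraction of replicates within ±1 column of the true
    boundary, plus the per-replicate estimates.
    """
    names = list(model.feature_names)
    estimates = []
    for seed in seeds:
        fovs = synthetic.render_border_sample(
            liver, tumor, grid=grid, boundary_col=boundary_col,
            rng=np.random.default_rng(int(seed)), shape=image_shape,
        )
        rows = []
        for fov in fovs:
            if not fov_io.qc_filter(fov).accepted:
                continue
            vec = features.featurize_fov(fov, channel_set=model.channel_set)
            rows.append({"row": fov.tile[0], "col": fov.tile[1], **dict(zip(names, vec))})
        tile_table = pd.DataFrame(rows)
        preds = classify.predict(model, tile_table)
        pmap = evaluate.build_probability_map(preds, grid=grid, sample_id=f"border_seed{seed}")
        estimates.append(evaluate.estimate_boundary_col(pmap))
    hits = sum(abs(est - boundary_col) <= 1 for est in estimates)
    return hits / len(estimates), estimates


def default_class_params(
    class_separation: float = 1.0,
) -> tuple[synthetic.TissueParams, synthetic.TissueParams]:
    """Class-mean liver/tumor parameters at a given separation (no patient
    random effect) — the canonical inputs for border-sample rendering."""
    spec = synthetic.CohortSpec(n_patients=1, class_separation=class_separation)
    return spec.class_means()
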