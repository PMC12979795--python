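"""End-to-end pipeline orchestration with full seed provenance.

One :class:`RunConfig` drives the whole chain — simulate → qc → featurize →
train (seven channel-combination models) → evaluate → map — writing every
stage artifact into a run directory. Stages can be run individually (each
reads the previous stage's artifacts from the run directory) or chained with
:meth:`PipelineRun.run_all`. Re-running with an identical config and seed
reproduces byte-identical feature tables; each artifact records the config
hash and global seed it came from. A JSON-lines log captures per-stage wall
time and item counts, including the QC-discard tally and the split audit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, evaluate, features, fov_io, synthetic


class ConfigError(ValueError):
    """Raised for invalid run configurations (before any compute)."""


@dataclass
class RunConfig:
    """Single source of truth for one pipeline run."""

    out_dir: str = "run"
    seed: int = 0
    # cohort
    n_patients: int = 8
    class_separation: float = 1.0
    patient_sd: float = 0.15
    image_shape: tuple[int, int] = synthetic.DEFAULT_SHAPE
    pixel_size: float = synthetic.DEFAULT_PIXEL_SIZE
    n_fov_liver: int = 8
    n_fov_tumor: int = 8
    n_border_patients: int = 1
    border_grid: tuple[int, int] = (4, 10)
    boundary_col: int = 5
    # qc
    tau_bg: float = 0.25
    tau_sat: float = 0.05
    # features
    levels: int = features.DEFAULT_LEVELS
    distances_px: tuple[int, ...] = features.DEFAULT_DISTANCES
    symmetric: bool = False
    # training
    n_train_patients: int = 4
    max_epochs: int = 1000
    n_search_steps: int = 4
    hidden_widths: tuple[int, ...] = (10, 25)
    hidden_layer_counts: tuple[int, ...] = (1,)
    activations: tuple[str, ...] = ("relu", "tanh")
    l2_range: tuple[float, float] = (1e-5, 1e-2)
    channels: tuple[tuple[str, ...], ...] = classify.CHANNEL_COMBOS
    map_model: str = "TPEF-SHG"

    def __post_init__(self) -> None:
        if not self.channels or any(len(c) == 0 for c in self.channels):
            raise ConfigError("channel combination list must be non-empty")
        for combo in self.channels:
            unknown = set(combo) - set(fov_io.CHANNEL_ORDER)
            if unknown:
                raise ConfigError(f"unknown channels {sorted(unknown)}")

    def cohort_spec(self) -> synthetic.CohortSpec:
        return synthetic.CohortSpec(
            n_patients=self.n_patients,
            class_separation=self.class_separation,
            patient_sd=self.patient_sd,
            image_shape=tuple(self.image_shape),
            pixel_size=self.pixel_size,
            n_fov_liver=self.n_fov_liver,
            n_fov_tumor=self.n_fov_tumor,
            n_border_patients=self.n_border_patients,
            border_grid=tuple(self.border_grid),
            boundary_col=self.boundary_col,
        )

    def train_config(self, seed_offset: int = 0) -> classify.TrainConfig:
        return classify.TrainConfig(
            max_epochs=self.max_epochs,
            n_search_steps=self.n_search_steps,
            search_space=classify.SearchSpace(
                n_layers=tuple(self.hidden_layer_counts),
                widths=tuple(self.hidden_widths),
                activations=tuple(self.activations),
                l2_range=tuple(self.l2_range),
            ),
            seed=_subseed(self.seed, 20 + seed_offset),
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["channels"] = [list(c) for c in self.channels]
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key in ("image_shape", "distances_px", "border_grid", "hidden_widths",
                    "hidden_layer_counts", "activations", "l2_range"):
            if key in data:
                data[key] = tuple(data[key])
        if "channels" in data:
            data["channels"] = tuple(tuple(c) for c in data["channels"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


def _subseed(seed: int, key: int) -> int:
    return int(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(key),)).generate_state(1)[0] % (2**31))


class PipelineRun:
    """Stage-wise executor over one run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out_dir = Path(config.out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(self.out_dir / "config.yaml")

    # -- logging ------------------------------------------------------------

    def _log(self, stage: str, **payload) -> None:
        record = {
            "stage": stage,
            "time": time.time(),
            "config_hash": self.config.config_hash(),
            "seed": self.config.seed,
            **payload,
        }
        with open(self.out_dir / "run.log", "a") as fh:
            fh.write(json.dumps(record) + "\n")

    def _timed(self, stage: str):
        pipeline = self

        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    pipeline._log(stage, status="failed", error=str(exc))
                    return False
                pipeline._log(stage, status="ok", wall_s=round(time.perf_counter() - self.t0, 3), **getattr(self, "counts", {}))
                return False

        return _Timer()

    # -- stages -------------------------------------------------------------

    def simulate(self) -> pd.DataFrame:
        """Generate the synthetic cohort: TIFFs + manifest.csv."""
        with self._timed("simulate") as t:
            manifest = synthetic.write_cohort(
                self.config.cohort_spec(), _subseed(self.config.seed, 0), self.out_dir / "images"
            )
            manifest.to_csv(self.out_dir / "manifest.csv", index=False)
            t.counts = {"n_fov": len(manifest), "n_patients": manifest["patient_id"].nunique()}
        return manifest

    def _read_fov(self, row: pd.Series) -> fov_io.FovImage:
        return fov_io.read_fov(
            self.out_dir / "images" / row["path"],
            patient_id=row["patient_id"],
            sample_kind=row["sample"],
            tile=(int(row["row"]), int(row["col"])),
            true_label=row["true_label"],
            pixel_size=self.config.pixel_size,
        )

    def qc(self) -> pd.DataFrame:
        """Apply the QC rule to every FoV; extend the manifest."""
        manifest = pd.read_csv(self.out_dir / "manifest.csv")
        with self._timed("qc") as t:
            reports = [
                fov_io.qc_filter(self._read_fov(row), self.config.tau_bg, self.config.tau_sat)
                for _, row in manifest.iterrows()
            ]
            manifest["qc_accepted"] = [r.accepted for r in reports]
            manifest["qc_reason"] = [r.reason for r in reports]
            manifest["background_fraction"] = [r.background_fraction for r in reports]
            manifest["saturated_fraction"] = [r.saturated_fraction for r in reports]
            manifest.to_csv(self.out_dir / "manifest_qc.csv", index=False)
            t.counts = {"n_fov": len(manifest), "n_rejected": int((~manifest["qc_accepted"]).sum())}
        return manifest

    def featurize(self) -> pd.DataFrame:
        """Compute the 51-column feature table for QC-accepted FoVs."""
        manifest = pd.read_csv(self.out_dir / "manifest_qc.csv")
        names = features.fov_feature_names(distances=self.config.distances_px)
        with self._timed("featurize") as t:
            rows = []
            for _, row in manifest[manifest["qc_accepted"]].iterrows():
                fov = self._read_fov(row)
                vec = features.featurize_fov(
                    fov,
                    distances_px=self.config.distances_px,
                    levels=self.config.levels,
                    symmetric=self.config.symmetric,
                )
                rows.append(
                    {
                        "patient_id": row["patient_id"],
                        "sample": row["sample"],
                        "row": int(row["row"]),
                        "col": int(row["col"]),
                        "true_label": row["true_label"],
                        **dict(zip(names, vec)),
                    }
                )
            table = pd.DataFrame(rows)
            table.to_csv(self.out_dir / "features.csv", index=False)
            json.dump(
                {
                    "levels": self.config.levels,
                    "distances_px": list(self.config.distances_px),
                    "symmetric": self.config.symmetric,
                    "config_hash": self.config.config_hash(),
                    "seed": self.config.seed,
                },
                open(self.out_dir / "features_config.json", "w"),
                indent=2,
            )
            t.counts = {"n_fov": len(table)}
        return table

    def train(self) -> dict[str, classify.TrainedModel]:
        """Patient-level split + one model per channel combination."""
        table = pd.read_csv(self.out_dir / "features.csv")
        with self._timed("train") as t:
            split = classify.make_split(table, self.config.n_train_patients, _subseed(self.config.seed, 10))
            models = classify.train_channel_models(table, split, self.config.train_config(), combos=self.config.channels)
            models_dir = self.out_dir / "models"
            models_dir.mkdir(exist_ok=True)
            for name, model in models.items():
                _save_model(model, models_dir / f"{name.lower().replace('-', '_')}.json")
            # split audit: training rows must come only from train patients
            train_rows = table[table["patient_id"].isin(split.train_patients)]
            audit = {
                "train_patients": list(split.train_patients),
                "test_patients": list(split.test_patients),
                "n_train_rows": len(train_rows),
                "overlap": sorted(set(split.train_patients) & set(split.test_patients)),
            }
            json.dump(audit, open(self.out_dir / "split_audit.json", "w"), indent=2)
            t.counts = {"n_models": len(models), "n_train_patients": len(split.train_patients)}
        return models

    def evaluate(self) -> dict[str, evaluate.EvalReport]:
        """Test-set reports + prediction tables for every trained model."""
        table = pd.read_csv(self.out_dir / "features.csv")
        split_audit = json.load(open(self.out_dir / "split_audit.json"))
        test_rows = table[
            table["patient_id"].isin(split_audit["test_patients"]) & table["sample"].isin(["liver", "tumor"])
        ].reset_index(drop=True)
        reports = {}
        with self._timed("evaluate") as t:
            predictions_all = []
            for path in sorted((self.out_dir / "models").glob("*.json")):
                model = _load_model(path)
                name = classify.combo_name(model.channel_set)
                preds = classify.predict(model, test_rows)
                preds.insert(0, "model", name)
                predictions_all.append(preds[["model", "patient_id", "sample", "row", "col",
                                              "true_label", "posterior_tumor", "predicted", "inconclusive"]])
                report = evaluate.evaluate_model(preds, model_name=name)
                evaluate.write_report(report, self.out_dir / "reports")
                reports[name] = report
            pd.concat(predictions_all, ignore_index=True).to_csv(self.out_dir / "predictions.csv", index=False)
            t.counts = {"n_models": len(reports), "n_test_fov": len(test_rows)}
        return reports

    def map(self) -> list[evaluate.ProbabilityMap]:
        """Posterior-probability maps of every border sample."""
        table = pd.read_csv(self.out_dir / "features.csv")
        border = table[table["sample"] == "border"]
        model_path = self.out_dir / "models" / f"{self.config.map_model.lower().replace('-', '_')}.json"
        maps: list[evaluate.ProbabilityMap] = []
        with self._timed("map") as t:
            if len(border) and model_path.exists():
                model = _load_model(model_path)
                for patient_id, group in border.groupby("patient_id"):
                    preds = classify.predict(model, group.reset_index(drop=True))
                    pmap = evaluate.build_probability_map(
                        preds, grid=tuple(self.config.border_grid), sample_id=str(patient_id)
                    )
                    maps_dir = self.out_dir / "maps"
                    maps_dir.mkdir(exist_ok=True)
                    evaluate.render_probability_map(pmap, maps_dir / f"{patient_id}.png")
                    pd.DataFrame(pmap.values).to_csv(maps_dir / f"{patient_id}_grid.csv", index=False)
                    maps.append(pmap)
            t.counts = {"n_maps": len(maps)}
        return maps

    def run_all(self) -> dict[str, evaluate.EvalReport]:
        """Execute every stage in order; returns the evaluation reports."""
        self.simulate()
        self.qc()
        self.featurize()
        self.train()
        reports = self.evaluate()
        self.map()
        return reports


def run_pipeline(config: RunConfig) -> dict[str, evaluate.EvalReport]:
    """One-call end-to-end run (see :class:`PipelineRun`)."""
    return PipelineRun(config).run_all()


# ---------------------------------------------------------------------------
# Model serialization (architecture + weights as JSON — text-only artifacts)
# ---------------------------------------------------------------------------


def _save_model(model: classify.TrainedModel, path: Path) -> None:
    payload = {
        "channel_set": list(model.channel_set),
        "feature_names": list(model.feature_names),
        "layer_widths": list(model.layer_widths),
        "activation": model.activation,
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_sd": model.scaler_sd.tolist(),
        "candidate": {
            "hidden_layers": list(model.candidate.hidden_layers),
            "activation": model.candidate.activation,
            "l2": model.candidate.l2,
            "standardize": model.candidate.standardize,
        },
        "loss_trace": model.loss_trace,
        "hit_iteration_cap": model.hit_iteration_cap,
        "n_iterations": model.n_iterations,
    }
    path.write_text(json.dumps(payload))


def _load_model(path: Path) -> classify.TrainedModel:
    payload = json.loads(path.read_text())
    return classify.TrainedModel(
        channel_set=tuple(payload["channel_set"]),
        feature_names=tuple(payload["feature_names"]),
        layer_widths=tuple(payload["layer_widths"]),
        activation=payload["activation"],
        weights=[np.asarray(w) for w in payload["weights"]],
        biases=[np.asarray(b) for b in payload["biases"]],
        scaler_mean=np.asarray(payload["scaler_mean"]),
        scaler_sd=np.asarray(payload["scaler_sd"]),
        candidate=classify.Candidate(
            hidden_layers=tuple(payload["candidate"]["hidden_layers"]),
            activation=payload["candidate"]["activation"],
            l2=payload["candidate"]["l2"],
            standardize=payload["candidate"]["standardize"],
        ),
        loss_trace=list(payload["loss_trace"]),
        hit_iteration_cap=payload["hit_iteration_cap"],
        n_iterations=payload["n_iterations"],
    )
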