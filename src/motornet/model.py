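"""Model/Results facade over the full motor-network pipeline.

:class:`MotorNetworkAnalysis` is built from a set of recordings plus a
subject-metadata table (or from the synthetic cohort generator), and its
:meth:`~MotorNetworkAnalysis.fit` runs preprocessing, connectivity, the
threshold sweep, graph metrics, group statistics and (optionally)
classification, returning a :class:`MotorNetworkResults` that carries every
table and a human-readable :meth:`~MotorNetworkResults.summary`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification as clf
from . import connectivity, graph_metrics, group_stats, preprocessing, synthetic
from .recording import HemodynamicRecording, read_recording_csv

__all__ = ["MotorNetworkAnalysis", "MotorNetworkResults"]


@dataclass
class MotorNetworkResults:
    """Estimates and diagnostics from one fitted pipeline run."""

    feature_table: pd.DataFrame  # subject metadata + 8 AUC features
    per_threshold: pd.DataFrame  # long: subject_id, metric, threshold, value
    profiles: dict  # subject_id → MetricProfile
    stats: group_stats.GroupStatsReport | None
    classification: clf.ClassificationResult | None
    preprocess_logs: list[dict]
    config: dict = field(default_factory=dict)

    def group_mean_curves(self, metric: str) -> pd.DataFrame:
        """Group-mean metric values per threshold (columns = groups)."""
        sub = self.per_threshold[self.per_threshold["metric"] == metric]
        merged = sub.merge(
            self.feature_table[["subject_id", "group"]], on="subject_id"
        )
        return merged.pivot_table(
            index="threshold", columns="group", values="value", aggfunc="mean"
        )

    def summary(self) -> str:
        lines = ["Motor-network analysis summary", "=" * 34]
        counts = self.feature_table["group"].value_counts()
        lines.append(
            "Subjects: "
            + ", ".join(f"{g}={int(counts.get(g, 0))}" for g in synthetic.GROUPS)
        )
        logs = self.preprocess_logs
        if logs:
            n_fb = sum(1 for l in logs if l.get("fallback"))
            lines.append(
                f"Preprocessing: {len(logs)} recordings, {n_fb} fell back to the 180-s window"
            )
        if self.stats is not None:
            lines.append("")
            lines.append("ANCOVA group effect (feature ~ group + age + gender):")
            for _, row in self.stats.anova.iterrows():
                lines.append(
                    f"  {row['feature']:<11} F = {row['F']:7.2f}   p = {row['p']:.3g}"
                )
            lines.append("")
            lines.append("Partial correlation with FMA (patients; age, gender controlled):")
            for _, row in self.stats.fma_correlations.iterrows():
                lines.append(
                    f"  {row['feature']:<11} r = {row['r']:+.3f}   p = {row['p']:.3g}"
                )
        if self.classification is not None:
            c = self.classification
            lines.append("")
            lines.append(f"Nested LOOCV OVR linear SVM accuracy: {100 * c.accuracy:.1f}%")
            for _, row in c.rates.iterrows():
                auc = c.roc[row["class"]]["auc"]
                lines.append(
                    f"  {row['class']:<8} sensitivity = {100 * row['sensitivity']:5.1f}%  "
                    f"specificity = {100 * row['specificity']:5.1f}%  ROC-AUC = {100 * auc:.0f}%"
                )
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> Path:
        """Write all result tables plus a manifest with content hashes."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: dict[str, str] = {}

        def _write(name: str, text: str) -> None:
            path = out_dir / name
            path.write_text(text)
            written[name] = hashlib.sha256(text.encode()).hexdigest()

        _write("features.csv", self.feature_table.to_csv(index=False))
        _write("per_threshold.csv", self.per_threshold.to_csv(index=False))
        if self.stats is not None:
            _write("report.json", self.stats.to_json())
        if self.classification is not None:
            c = self.classification
            payload = {
                "accuracy": c.accuracy,
                "classes": c.classes,
                "confusion": c.confusion.to_dict(),
                "rates": c.rates.to_dict(orient="records"),
                "roc_auc": {k: v["auc"] for k, v in c.roc.items()},
                "roc_points": {
                    k: {"fpr": v["fpr"].tolist(), "tpr": v["tpr"].tolist()}
                    for k, v in c.roc.items()
                },
                "rfe_full": c.rfe_full.to_dict(orient="records"),
                "fold_log": c.fold_log,
            }
            _write("classification.json", json.dumps(payload, indent=2))
        manifest = {
            "config": self.config,
            "files": written,
            "preprocess_logs": self.preprocess_logs,
        }
        _write("manifest.json", json.dumps(manifest, indent=2, default=str))
        return out_dir

    def plot_metric_curves(self, metrics=graph_metrics.ALL_METRICS, ax=None):
        """Group-mean metric curves over the sweep (requires matplotlib)."""
        import matplotlib.pyplot as plt

        metrics = [m for m in metrics if m in set(self.per_threshold["metric"])]
        if ax is None:
            n = len(metrics)
            ncols = min(n, 4)
            nrows = int(np.ceil(n / ncols))
            fig, axes = plt.subplots(
                nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False
            )
            axes = axes.ravel()
        else:
            axes = [ax] * len(metrics)
        for a, m in zip(axes, metrics):
            self.group_mean_curves(m).plot(ax=a, legend=(m == metrics[0]))
            a.set_title(m)
            a.set_xlabel("threshold")
        return axes[0].figure


class MotorNetworkAnalysis:
    """Resting-state motor-network model for a cohort of recordings.

    Parameters
    ----------
    recordings : list of HemodynamicRecording
    metadata : DataFrame
        One row per subject with columns ``subject_id, group, age, gender``
        and, for patients, ``FMA``.
    preprocess_params : PreprocessParams, optional
    sweep : (lo, hi, step)
        Proportional-threshold grid, default (0.3, 0.7, 0.01).
    n_random : int
        Random-reference ensemble size for γ/λ/δ (default 100; 0 skips the
        normalized metrics).
    classifier_config : ClassifierConfig, optional
    seed : int
        Master seed; per-subject ensemble seeds are spawned from it.
    """

    def __init__(
        self,
        recordings: list[HemodynamicRecording],
        metadata: pd.DataFrame,
        preprocess_params: preprocessing.PreprocessParams | None = None,
        sweep: tuple[float, float, float] = (0.3, 0.7, 0.01),
        n_random: int = 100,
        swaps_per_edge: int = 10,
        classifier_config: clf.ClassifierConfig | None = None,
        seed: int = 0,
    ) -> None:
        known = {r.subject_id for r in recordings}
        missing = known - set(metadata["subject_id"])
        if missing:
            raise ValueError(f"metadata missing subjects: {sorted(missing)}")
        self.recordings = recordings
        self.metadata = metadata.reset_index(drop=True)
        self.preprocess_params = preprocess_params
        self.sweep = sweep
        self.n_random = n_random
        self.swaps_per_edge = swaps_per_edge
        self.classifier_config = classifier_config
        self.seed = seed
        self.ground_truth: dict[str, synthetic.GroundTruth] = {}

    # ------------------------------------------------------------------ #
    @classmethod
    def from_synthetic(
        cls, config: synthetic.CohortConfig | None = None, **kwargs
    ) -> "MotorNetworkAnalysis":
        """Build the model from a freshly generated synthetic cohort."""
        cfg = config if config is not None else synthetic.CohortConfig()
        subjects = synthetic.generate_cohort(cfg)
        model = cls(
            recordings=[s.recording for s in subjects],
            metadata=synthetic.metadata_frame(subjects),
            seed=kwargs.pop("seed", cfg.seed),
            **kwargs,
        )
        model.ground_truth = {s.meta.subject_id: s.truth for s in subjects}
        return model

    @classmethod
    def from_csv_dir(
        cls,
        signals_dir: str | Path,
        metadata_csv: str | Path | None = None,
        fs: float = 10.0,
        **kwargs,
    ) -> "MotorNetworkAnalysis":
        """Load per-subject signal CSVs plus the cohort metadata table."""
        signals_dir = Path(signals_dir)
        if metadata_csv is None:
            metadata_csv = signals_dir / "metadata.csv"
        metadata = synthetic.read_metadata_csv(metadata_csv)
        recordings = []
        for sid in metadata["subject_id"]:
            path = signals_dir / f"{sid}.csv"
            if not path.exists():
                raise FileNotFoundError(path)
            recordings.append(read_recording_csv(path, fs=fs, subject_id=sid))
        return cls(recordings=recordings, metadata=metadata, **kwargs)

    # ------------------------------------------------------------------ #
    def fit(
        self,
        classify: bool = True,
        run_stats: bool = True,
        n_random: int | None = None,
    ) -> MotorNetworkResults:
        """Run the full pipeline and return the results object."""
        n_random = self.n_random if n_random is None else n_random
        lo, hi, step = self.sweep
        logs: list[dict] = []
        profiles: dict[str, graph_metrics.MetricProfile] = {}
        long_rows = []
        for idx, rec in enumerate(self.recordings):
            processed, log = preprocessing.preprocess(rec, self.preprocess_params)
            logs.append(log)
            zmat = connectivity.zmatrix_from_recording(processed)
            nets = connectivity.threshold_sweep(zmat, lo, hi, step)
            sub_seed = int(
                np.random.SeedSequence(self.seed, spawn_key=(idx,)).generate_state(1)[0]
                % (2**31)
            )
            profile = graph_metrics.subject_profile(
                nets,
                n_random=n_random,
                seed=sub_seed,
                subject_id=rec.subject_id,
                swaps_per_edge=self.swaps_per_edge,
            )
            profiles[rec.subject_id] = profile
            melted = profile.curves.reset_index().melt(
                id_vars="threshold", var_name="metric", value_name="value"
            )
            melted.insert(0, "subject_id", rec.subject_id)
            long_rows.append(melted)

        per_threshold = pd.concat(long_rows, ignore_index=True)
        features = pd.DataFrame([p.feature_row() for p in profiles.values()])
        feature_table = self.metadata.merge(features, on="subject_id")

        stats = None
        if run_stats:
            stats = group_stats.run_group_analysis(feature_table, per_threshold)

        classification = None
        if classify:
            feat_cols = ["subject_id"] + [
                c for c in features.columns if c.endswith("_AUC")
            ]
            cfg = self.classifier_config or clf.ClassifierConfig(seed=self.seed)
            classification = clf.nested_cv(
                feature_table[feat_cols],
                feature_table["group"].to_numpy(),
                cfg,
            )

        return MotorNetworkResults(
            feature_table=feature_table,
            per_threshold=per_threshold,
            profiles=profiles,
            stats=stats,
            classification=classification,
            preprocess_logs=logs,
            config={
                "sweep": list(self.sweep),
                "n_random": n_random,
                "swaps_per_edge": self.swaps_per_edge,
                "seed": self.seed,
                "n_subjects": len(self.recordings),
            },
        )
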