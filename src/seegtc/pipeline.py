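"""File-based pipeline behind the command-line interface.

A run is driven by a YAML :class:`RunConfig`; the configuration is
serialized into the output directory before any computation so a run can be
reproduced from its own copy. Each stage writes a JSON manifest recording
its inputs (with SHA-256 hashes), parameters and seed; a stage whose inputs
are missing aborts with an error naming the offending path, which also
catches stage-order violations.

Stage order: simulate (optional) -> features -> stats -> predict -> report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as seeg_io
from .features import ApEnParams, contact_average, zscore_within_subject
from .predict import OutcomeModel, SplitPlan
from .preprocess import TOTAL_S_DEFAULT, WINDOW_S_DEFAULT
from .simulate import SimConfig, generate_cohort, scaled_config
from .stats import run_comparisons
from .workflow import cohort_features

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "run_stage"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "features", "stats", "predict", "report")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Serializable configuration of a pipeline run."""

    output_dir: str = "seegtc_run"
    seed: int = 0
    simulate: bool = True
    #: "scaled" (reduced cohort for desk runs) or "full" (study-scale)
    cohort: str = "scaled"
    sim_overrides: dict = field(default_factory=dict)
    #: directory of input EDFs named <patient>_<period>.edf when simulate=False
    recordings_dir: str | None = None
    contacts_path: str | None = None
    outcomes_path: str | None = None
    artifact_spans_path: str | None = None
    window_s: float = WINDOW_S_DEFAULT
    total_s: float = TOTAL_S_DEFAULT
    apen_m: int = 2
    apen_r_factor: float = 0.2
    test_fraction: float = 1.0 / 6.0
    subsets_k: int = 5
    folds: int = 25
    figures: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def sim_config(self) -> SimConfig:
        if self.cohort == "scaled":
            return scaled_config(seed=self.seed, **self.sim_overrides)
        return SimConfig(seed=self.seed, **self.sim_overrides)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(out: Path, stage: str, inputs: list[Path],
                    params: dict) -> None:
    manifest = {
        "stage": stage,
        "inputs": {str(p): _sha256(p) for p in inputs},
        "params": params,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / f"manifest_{stage}.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def _require(stage: str, paths: list[Path]) -> None:
    for p in paths:
        if not p.exists():
            raise PipelineError(
                f"stage {stage!r}: required input {p} is missing "
                "(run the earlier stages first)")


def _load_cohort(config: RunConfig, out: Path):
    bundle = out / "cohort.npz"
    if bundle.exists():
        return seeg_io.load_cohort_bundle(bundle)
    # assemble from EDF + TSV inputs
    contacts_path = Path(config.contacts_path or out / "contacts.tsv")
    outcomes_path = Path(config.outcomes_path or out / "outcomes.tsv")
    rec_dir = Path(config.recordings_dir or out / "recordings")
    _require("features", [contacts_path, outcomes_path, rec_dir])
    contacts = seeg_io.read_contacts_tsv(contacts_path)
    outcomes = seeg_io.read_outcomes_tsv(outcomes_path)
    recordings = {}
    for pid in outcomes.index:
        for period in ("pre", "post"):
            path = rec_dir / f"{pid}_{period}.edf"
            _require("features", [path])
            recordings[(pid, period)] = seeg_io.read_edf(path, pid, period)
    from .simulate import SyntheticCohort

    return SyntheticCohort(recordings=recordings, contacts=contacts,
                           outcomes=outcomes, truth=pd.DataFrame(),
                           config=None)


def run_stage(stage: str, config: RunConfig) -> Path:
    """Run one pipeline stage against the run's output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_copy = out / "run_config.yaml"
    if not config_copy.exists():
        config.to_yaml(config_copy)

    if stage == "simulate":
        if not config.simulate:
            logger.info("simulate disabled in config; skipping")
            return out
        cohort = generate_cohort(config.sim_config())
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for (pid, period), rec in sorted(cohort.recordings.items()):
            seeg_io.write_edf(rec, rec_dir / f"{pid}_{period}.edf")
        seeg_io.write_contacts_tsv(cohort.contacts, out / "contacts.tsv")
        seeg_io.write_outcomes_tsv(cohort.outcomes, out / "outcomes.tsv")
        seeg_io.save_cohort_bundle(cohort, out / "cohort.npz")
        cohort.truth.to_csv(out / "truth.csv", index=False)
        _write_manifest(out, "simulate", [config_copy],
                        {"seed": config.seed, "cohort": config.cohort})
        return out

    if stage == "features":
        cohort = _load_cohort(config, out)
        spans = None
        if config.artifact_spans_path:
            span_list = seeg_io.read_artifact_spans_tsv(
                config.artifact_spans_path)
            spans = {key: span_list for key in cohort.recordings}
        raw = cohort_features(
            cohort, window_s=config.window_s, total_s=config.total_s,
            apen_params=ApEnParams(config.apen_m, config.apen_r_factor),
            bad_spans=spans)
        normalized = zscore_within_subject(raw)
        means = contact_average(normalized)
        seeg_io.write_features_csv(normalized, out / "features.csv")
        seeg_io.write_features_csv(means, out / "contact_means.csv")
        _write_manifest(out, "features",
                        [config_copy, out / "contacts.tsv",
                         out / "outcomes.tsv"],
                        {"window_s": config.window_s,
                         "total_s": config.total_s})
        return out

    if stage == "stats":
        _require("stats", [out / "contact_means.csv", out / "contacts.tsv",
                           out / "outcomes.tsv"])
        means = seeg_io.read_features_csv(out / "contact_means.csv")
        contacts = seeg_io.read_contacts_tsv(out / "contacts.tsv")
        outcomes = seeg_io.read_outcomes_tsv(out / "outcomes.tsv")
        comparisons = run_comparisons(means, contacts, outcomes)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        if config.figures:
            from .plotting import plot_group_comparisons

            plot_group_comparisons(means, contacts, outcomes, comparisons,
                                   path=out / "comparisons.png")
        _write_manifest(out, "stats", [out / "contact_means.csv"], {})
        return out

    if stage == "predict":
        _require("predict", [out / "contact_means.csv", out / "contacts.tsv",
                             out / "outcomes.tsv"])
        means = seeg_io.read_features_csv(out / "contact_means.csv")
        contacts = seeg_io.read_contacts_tsv(out / "contacts.tsv")
        outcomes = seeg_io.read_outcomes_tsv(out / "outcomes.tsv")
        model = OutcomeModel.from_contact_means(
            means, contacts, outcomes,
            plan=SplitPlan(test_fraction=config.test_fraction,
                           subsets_k=config.subsets_k, seed=config.seed),
            folds=config.folds)
        res = model.fit(seed=config.seed)
        res.selection["grid_scores"].to_csv(out / "model_selection.csv",
                                            index=False)
        res.patient_table.to_csv(out / "predictions.csv", index=False)
        pd.Series(res.sensor_metrics).rename("value").to_csv(
            out / "sensor_metrics.csv")
        (out / "prediction_summary.txt").write_text(res.summary())
        _write_manifest(out, "predict", [out / "contact_means.csv"],
                        {"seed": config.seed,
                         "chosen_subset":
                             int(res.selection["chosen_subset_index"]),
                         "chosen_params":
                             {k: str(v) for k, v in
                              res.selection["chosen_params"].items()}})
        return out

    if stage == "report":
        _require("report", [out / "comparisons.csv",
                            out / "prediction_summary.txt"])
        comparisons = pd.read_csv(out / "comparisons.csv")
        lines = ["SEEG RF-TC biomarker analysis report", "=" * 40, ""]
        lines.append("Significant group comparisons "
                     "(Bonferroni-corrected, alpha=0.05):")
        sig = comparisons[comparisons.significant]
        if sig.empty:
            lines.append("  none")
        else:
            for _, r in sig.iterrows():
                lines.append(
                    f"  {r['group']:<15s} {r['design']:<15s} {r['band']:<10s} "
                    f"{r['feature']:<5s} tail={r['tail']:<5s} "
                    f"p_adj={r['p_adjusted']:.2e}")
        lines.append("")
        lines.append((out / "prediction_summary.txt").read_text())
        (out / "report.txt").write_text("\n".join(lines))
        _write_manifest(out, "report", [out / "comparisons.csv"], {})
        return out

    raise PipelineError(f"unknown stage {stage!r}")


def run_pipeline(config: RunConfig) -> Path:
    """Run all stages in order; returns the output directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    for stage in STAGES:
        run_stage(stage, config)
    return out
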