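"""End-to-end orchestration: simulate -> extract -> clean -> classify ->
resolve -> report, with stable on-disk formats.

Every stage is a pure function of (inputs, config); rerunning a stage with
the same inputs reproduces its outputs byte for byte.  Outputs per stage:

* simulate  -> ``audio/`` (WAV + metadata.csv)
* extract   -> ``features.csv``
* clean     -> ``features_clean.csv``, ``hygiene_report.json``
* classify  -> ``confusion.csv``, ``chance_test.json``, ``importance.csv``
* resolve   -> ``mapping.json``, ``summary.json``, ``summary.txt``
* report    -> ``tsne.png``, ``calltype_stats.csv``, spectrogram PNGs
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .classify import RFConfig, chance_test, fit_weighted_forest, oob_confusion, variable_importance
from .confusion import ConfusionMatrix
from .features import FeatureConfig, build_feature_table
from .hygiene import HygieneConfig, replace_outliers
from .repertoire import apply_mapping, resolve_repertoire, summarize
from .synthetic import CallArchetype, SyntheticDatasetSpec
from .viz import VizConfig, plot_tsne, render_spectrogram, tsne_embed

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "extract", "clean", "classify", "resolve", "report")

_ARCHETYPE_BANKS = {
    "default": synthetic.default_archetypes,
    "bonobo": synthetic.bonobo_like_archetypes,
}


@dataclass(frozen=True)
class DatasetConfig:
    archetypes: str | list = "default"  # bank name or explicit list of dicts
    n_per_class: tuple[int, ...] | None = None  # None -> 20 per class
    gradedness: float = 0.0
    individual_effects: float = 0.08
    snr_db: float = 20.0
    sample_rate: int = 44100

    def to_spec(self, seed: int) -> SyntheticDatasetSpec:
        if isinstance(self.archetypes, str):
            arch = _ARCHETYPE_BANKS[self.archetypes]()
        else:
            arch = tuple(CallArchetype(**a) for a in self.archetypes)
        npc = self.n_per_class or tuple(20 for _ in arch)
        if isinstance(self.archetypes, str) and len(npc) < len(arch):
            arch = arch[: len(npc)]  # named bank: use its first len(npc) types
        return SyntheticDatasetSpec(
            archetypes=arch,
            n_per_class=tuple(int(x) for x in npc),
            gradedness=self.gradedness,
            individual_effects=self.individual_effects,
            snr_db=self.snr_db,
            sample_rate=self.sample_rate,
            seed=seed,
        )


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    hygiene: HygieneConfig = field(default_factory=HygieneConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    viz: VizConfig = field(default_factory=VizConfig)
    stated_total: int | None = None  # override for summary percentages
    n_spectrograms: int = 3  # example spectrograms per final call type

    def to_dict(self) -> dict:
        # JSON/YAML-canonical form (tuples become lists)
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sub = {
            "dataset": DatasetConfig,
            "features": FeatureConfig,
            "hygiene": HygieneConfig,
            "rf": RFConfig,
            "viz": VizConfig,
        }
        kwargs: dict = {}
        for key, val in d.items():
            if key in sub and isinstance(val, dict):
                kwargs[key] = sub[key](**val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _write_json(path: Path, obj: dict) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def stage_simulate(cfg: PipelineConfig, out: Path) -> Path:
    spec = cfg.dataset.to_spec(cfg.seed)
    recs, table = synthetic.generate_dataset(spec)
    audio = out / "audio"
    synthetic.write_dataset(recs, table, audio)
    logger.info("simulate: wrote %d calls to %s", len(recs), audio)
    return audio


def stage_extract(cfg: PipelineConfig, out: Path, audio_dir: Path) -> pd.DataFrame:
    recs = synthetic.load_dataset(audio_dir)
    table = build_feature_table(recs, cfg.features)
    table.to_csv(out / "features.csv", index=False)
    logger.info("extract: %d calls x %d feature columns", len(table), table.shape[1] - 2)
    return table


def stage_clean(cfg: PipelineConfig, out: Path, table: pd.DataFrame) -> pd.DataFrame:
    clean, report = replace_outliers(table, cfg.hygiene)
    clean.to_csv(out / "features_clean.csv", index=False)
    _write_json(out / "hygiene_report.json", report.to_dict())
    logger.info(
        "clean: replaced %d values in %d calls", report.n_values_replaced, report.n_calls_affected
    )
    return clean


def stage_classify(cfg: PipelineConfig, out: Path, table: pd.DataFrame) -> ConfusionMatrix:
    model, preds = fit_weighted_forest(table, cfg.rf)
    cm = oob_confusion(preds, table["original_label"].to_numpy())
    cm.to_csv(out / "confusion.csv")
    _write_json(out / "chance_test.json", chance_test(cm).to_dict())
    imp = variable_importance(model, seed=cfg.rf.seed)
    imp.sort_values(ascending=False).to_csv(out / "importance.csv", header=True)
    logger.info("classify: OOB accuracy %.3f over %d calls", model.oob_accuracy, cm.total)
    return cm


def stage_resolve(cfg: PipelineConfig, out: Path, cm: ConfusionMatrix) -> dict:
    mapping = resolve_repertoire(cm)
    mapping.to_json(out / "mapping.json")
    summary = summarize(cm, mapping, n_total=cfg.stated_total)
    _write_json(out / "summary.json", summary)
    lines = [
        f"calls: {summary['n_calls']}   putative types: {summary['n_call_types']}",
        f"OOB agreement: {summary['agreement_pct']}%  (error {summary['oob_error_pct']}%)",
        f"chance level: {summary['chance_level_pct']}%  binomial p = {summary['binomial_p_value']:.3g}",
        f"retained call types ({summary['n_retained']}): {', '.join(summary['retained'])}",
    ]
    if summary["merges"]:
        lines.append("merged: " + ", ".join(f"{a} -> {b}" for a, b in summary["merges"].items()))
    else:
        lines.append("merged: none")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    logger.info("resolve: %d retained, %d merged", summary["n_retained"], len(summary["merges"]))
    return summary


def stage_report(cfg: PipelineConfig, out: Path, table: pd.DataFrame, audio_dir: Path | None) -> None:
    mapping_path = out / "mapping.json"
    if mapping_path.exists():
        from .repertoire import RepertoireMapping

        table = apply_mapping(table, RepertoireMapping.from_json(mapping_path))
    coords = tsne_embed(table, cfg.viz)
    plot_tsne(table, coords, out / "tsne.png")
    stats_rows = []
    if audio_dir is not None and audio_dir.exists():
        recs = {r.call_id: r for r in synthetic.load_dataset(audio_dir)}
        fig_dir = out / "spectrograms"
        fig_dir.mkdir(exist_ok=True)
        for lab, grp in table.groupby("original_label"):
            for cid in grp["call_id"].head(cfg.n_spectrograms):
                st = render_spectrogram(
                    recs[cid], cfg.viz, cfg.features, fig_dir / f"{lab}_{cid}.png"
                )
                st["call_type"] = lab
                stats_rows.append(st)
    if stats_rows:
        pd.DataFrame(stats_rows).to_csv(out / "calltype_stats.csv", index=False)
    logger.info("report: t-SNE over %d calls", len(table))


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path, stages=STAGES) -> Path:
    """Run the requested stages into ``out_dir``; returns the run directory.

    Later stages read earlier stages' files, so a partial run can resume
    from an existing directory.  Any stage error aborts the run with the
    stage named; partial outputs are left in place for debugging.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "effective_config.yaml")
    audio_dir = out / "audio"
    table: pd.DataFrame | None = None
    cm: ConfusionMatrix | None = None
    for stage in stages:
        try:
            if stage == "simulate":
                audio_dir = stage_simulate(cfg, out)
            elif stage == "extract":
                table = stage_extract(cfg, out, audio_dir)
            elif stage == "clean":
                if table is None:
                    table = pd.read_csv(out / "features.csv")
                table = stage_clean(cfg, out, table)
            elif stage == "classify":
                if table is None:
                    table = pd.read_csv(out / "features_clean.csv")
                cm = stage_classify(cfg, out, table)
            elif stage == "resolve":
                if cm is None:
                    cm = ConfusionMatrix.from_csv(out / "confusion.csv")
                stage_resolve(cfg, out, cm)
            elif stage == "report":
                if table is None:
                    table = pd.read_csv(out / "features_clean.csv")
                stage_report(cfg, out, table, audio_dir)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as e:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    return out
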