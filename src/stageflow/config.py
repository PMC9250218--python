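"""Reproducible end-to-end pipeline: ingest -> fit -> simulate -> report.

A RunConfig bundles every knob of the toolchain; its defaults are the
study settings of the reference analysis (K=5 stages, W=12 complication
categories, a 30-occurrence code filter, 1-year slices, 5000 generated
patients).  Every stochastic step takes its seed from the config; a
manifest written next to the artifacts records the package version, the
seeds, and SHA-256 digests of the inputs so a run can be audited and
resumed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .analytics import pattern_table, single_complication_table, stage_summary
from .ingest import (
    FindingVocabulary,
    build_time_slices,
    encounter_stats,
    filter_codes,
    read_events,
    read_histories_jsonl,
    write_histories_jsonl,
)
from .learning import FitConfig, fit
from .model import AnchorSet, ProgressionModel, default_anchor_set
from .simulate import generate_cohort, read_cohort_jsonl, write_cohort_jsonl

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    events_path: str = ""
    anchors_path: str | None = None  # None -> bundled diabetes anchors
    K: int = 5
    W: int = 12
    min_count: int = 30
    granularity_years: float = 1.0
    fit: FitConfig = field(default_factory=FitConfig)
    n_patients: int = 5000
    horizon_years: float = 60.0
    patterns: list = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.K < 2:
            raise ValueError(f"K={self.K} must be >= 2")
        if self.W < 1:
            raise ValueError(f"W={self.W} must be >= 1")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.granularity_years <= 0:
            raise ValueError("granularity_years must be > 0")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.horizon_years <= 0:
            raise ValueError("horizon_years must be > 0")
        self.fit.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        fitdoc = doc.pop("fit", {})
        fit_known = {f.name for f in dataclasses.fields(FitConfig)}
        bad = set(fitdoc) - fit_known
        if bad:
            raise ValueError(f"unknown fit config keys: {sorted(bad)}")
        for key in ("beta_prior", "gamma_prior", "init_beta"):
            if key in fitdoc:
                fitdoc[key] = tuple(fitdoc[key])
        cfg = cls(**doc, fit=FitConfig(**fitdoc))
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_anchors(config: RunConfig) -> AnchorSet:
    if config.anchors_path:
        return AnchorSet.from_yaml(config.anchors_path)
    return default_anchor_set()


def run_pipeline(config: RunConfig, outdir, force: bool = False) -> dict:
    """Run ingest -> fit -> simulate -> report, resumable from intermediates.

    Returns the manifest dict (also written to ``outdir/manifest.json``).
    Existing intermediates are reused unless ``force`` is set.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events_path = Path(config.events_path)
    if not events_path.exists():
        raise FileNotFoundError(f"input events not found: {events_path}")
    anchors = load_anchors(config)

    vocab_path = outdir / "vocabulary.txt"
    hist_path = outdir / "histories.jsonl"
    model_path = outdir / "model.json"
    cohort_path = outdir / "cohort.jsonl"
    report_dir = outdir / "reports"
    steps = {}

    # ingest
    if force or not (vocab_path.exists() and hist_path.exists()):
        events = read_events(events_path)
        vocabulary, kept = filter_codes(events, config.min_count)
        histories = build_time_slices(kept, vocabulary, config.granularity_years)
        vocabulary.to_file(vocab_path)
        write_histories_jsonl(histories, vocabulary, hist_path)
        steps["ingest"] = "computed"
    else:
        vocabulary = FindingVocabulary.from_file(vocab_path)
        histories = read_histories_jsonl(hist_path, vocabulary)
        steps["ingest"] = "reused"
    n_enc, n_pos = encounter_stats(histories)
    logger.info("ingest: %d patients, %d codes, %d encounters, %d positives",
                len(histories), len(vocabulary), n_enc, n_pos)
    if not histories:
        raise ValueError("no patients survive preprocessing")

    # fit
    fit_cfg = dataclasses.replace(config.fit, random_seed=config.seed)
    if force or not model_path.exists():
        model, diagnostics = fit(histories, fit_cfg, anchors, vocabulary,
                                 K=config.K, W=config.W)
        model.save(model_path)
        with open(outdir / "fit_diagnostics.json", "w", encoding="utf-8") as fh:
            json.dump(diagnostics, fh, indent=1)
        steps["fit"] = "computed"
    else:
        model = ProgressionModel.load(model_path)
        steps["fit"] = "reused"

    # simulate
    if force or not cohort_path.exists():
        cohort = generate_cohort(model, config.n_patients, seed=config.seed + 1,
                                 horizon_years=config.horizon_years)
        write_cohort_jsonl(cohort, cohort_path)
        steps["simulate"] = "computed"
    else:
        cohort = read_cohort_jsonl(cohort_path)
        steps["simulate"] = "reused"

    # report
    report_dir.mkdir(exist_ok=True)
    labels = anchors.names or {}
    summary = stage_summary(cohort)
    summary.to_frame().to_csv(report_dir / "stage_summary.csv", index=False)
    single_complication_table(cohort, labels=labels).to_csv(
        report_dir / "single_complication_table.csv")
    patterns = config.patterns or []
    for i, (label, df) in enumerate(
            pattern_table(cohort, patterns, labels=labels).items()):
        out = df.copy()
        out.loc["n_V"] = df.attrs["n_V"]
        out.loc["pct_V"] = df.attrs["pct_V"]
        out.to_csv(report_dir / f"pattern_table_{i}.csv")
    steps["report"] = "computed"

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "inputs": {str(events_path): _sha256(events_path)},
        "derived": {
            "n_patients_ingested": len(histories),
            "n_codes": len(vocabulary),
            "n_encounters": n_enc,
            "n_positive_observations": n_pos,
            "n_generated": len(cohort),
        },
        "steps": steps,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
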