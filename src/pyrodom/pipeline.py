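"""End-to-end orchestration: simulate -> filter -> recalibrate -> align ->
assign -> metrics -> Kendrick -> severity comparison.

``run_pipeline`` executes every stage on a directory of peak-list CSVs,
writes each intermediate artifact, and returns a manifest recording the
configuration hash, seed, and per-stage peak accounting.  The accounting
is conserved: every input peak ends up exactly one of kept / window-
filtered / isotopologue-removed / alignment-unresolved.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .assign import AssignmentConfig, assign_table
from .compare import SeverityComparison, build_presence
from .io import read_metadata, read_peaklists
from .kendrick import (
    KendrickConfig,
    annotate_series_conditions,
    detect_series,
    kendrick_transform,
    series_frame,
)
from .metrics import annotate_table
from .peaks import align_peaks, filter_mz_window, recalibrate, remove_isotopologues
from .synthetic import SyntheticDesign, design_metadata, generate_formula_pool, \
    synthesize_peaklists, write_dataset

__all__ = ["PipelineConfig", "run_pipeline", "simulate"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs."""

    peaklist_dir: str
    metadata_path: str
    output_dir: str
    mz_window: tuple[float, float] = (200.0, 900.0)
    isotopologue_tol_ppm: float = 1.0
    do_recalibrate: bool = True
    alignment_tol_ppm: float = 0.5
    assignment: AssignmentConfig = field(default_factory=AssignmentConfig)
    strict_assignment: bool = False
    kendrick: KendrickConfig = field(default_factory=KendrickConfig)
    grouping: Mapping[str, str] | None = None
    severity_order: Sequence[str] = ("control", "low", "moderate", "high")
    ai_metric: str = "ai_standard"
    nosc_metric: str = "nosc_standard"
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.metadata_path).exists():
            raise FileNotFoundError(f"metadata file not found: {self.metadata_path}")
        if not Path(self.peaklist_dir).is_dir():
            raise FileNotFoundError(f"peak-list directory not found: {self.peaklist_dir}")
        if self.mz_window[0] >= self.mz_window[1]:
            raise ValueError("mz_window must be (lo, hi) with lo < hi")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "assignment" in raw:
            a = raw["assignment"]
            if "bounds" in a:
                a["bounds"] = tuple((el, tuple(b)) for el, b in a["bounds"].items())
            raw["assignment"] = AssignmentConfig(**a)
        if "kendrick" in raw:
            k = raw["kendrick"]
            if "require_conditions" in k:
                k["require_conditions"] = frozenset(k["require_conditions"])
            raw["kendrick"] = KendrickConfig(**k)
        if "mz_window" in raw:
            raw["mz_window"] = tuple(raw["mz_window"])
        return cls(**raw)

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, frozenset):
                return sorted(o)
            return str(o)
        d = asdict(self)
        d.pop("output_dir", None)  # hash identifies the analysis, not its destination
        blob = json.dumps(d, sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest (also written as
    ``manifest.json`` in the output directory)."""
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    metadata = read_metadata(cfg.metadata_path)
    raw = read_peaklists(cfg.peaklist_dir, metadata)
    counts = {"input_peaks": sum(len(pl) for pl in raw)}

    stage = "mz_window_filter"
    try:
        filtered, logs = [], []
        for pl in raw:
            res = filter_mz_window(pl, *cfg.mz_window)
            filtered.append(res.peaklist)
            logs.append(res.removed)
        counts["window_filtered"] = sum(len(l) for l in logs)

        stage = "isotopologue_removal"
        cleaned = []
        for pl in filtered:
            res = remove_isotopologues(pl, tol_ppm=cfg.isotopologue_tol_ppm)
            cleaned.append(res.peaklist)
            logs.append(res.removed)
        counts["isotopologue_removed"] = sum(
            len(l) for l in logs if len(l) and (l["reason"] == "isotopologue").all()
        )
        pd.concat(logs, ignore_index=True).to_csv(
            out / "filter_log.csv", index=False, float_format="%.8f"
        )

        stage = "recalibration"
        calibs = []
        if cfg.do_recalibrate:
            recal = []
            for pl in cleaned:
                res = recalibrate(pl)
                recal.append(res.peaklist)
                calibs.append(
                    {"sample_id": pl.sample_id, **vars(res.model)}
                )
            cleaned = recal
            pd.DataFrame(calibs).to_csv(out / "calibration.csv", index=False)

        stage = "alignment"
        apt = align_peaks(cleaned, tol_ppm=cfg.alignment_tol_ppm)
        counts["alignment_unresolved"] = len(apt.unresolved)
        counts["aligned_clusters"] = len(apt.consensus_mz)
        counts["kept_peaks"] = len(apt.members)
        apt.to_frame().to_csv(out / "aligned.csv", index=False, float_format="%.8f")

        stage = "formula_assignment"
        aft = assign_table(apt, cfg.assignment, strict=cfg.strict_assignment)
        counts["assigned_formulas"] = int(aft.table["formula"].notna().sum())
        aft.to_csv(out / "assigned.csv")

        stage = "metrics"
        annotated = annotate_table(aft)
        annotated.to_csv(out / "metrics.csv", index=False, float_format="%.8f")

        stage = "presence"
        pm = build_presence(aft, metadata)
        pm.detected.to_csv(out / "presence.csv")

        stage = "kendrick"
        assigned = annotated[annotated["formula"].notna()]
        masses = (
            assigned["consensus_mz"]
            if cfg.kendrick.mass_mode == "ion"
            else assigned["neutral_mass"]
        )
        records = kendrick_transform(
            masses.to_numpy(), cfg.kendrick, formulas=assigned["formula"]
        )
        records.to_csv(out / "kendrick_records.csv", index=False, float_format="%.8f")
        series = detect_series(records, cfg.kendrick)
        series = annotate_series_conditions(series, pm.occupancy(), cfg.kendrick)
        counts["kendrick_series"] = len(series)
        counts["kendrick_series_retained"] = sum(bool(s.retained) for s in series)
        series_frame(series).to_csv(out / "kendrick_series.csv", index=False)

        stage = "comparison"
        model = SeverityComparison(
            pm, annotated, grouping=cfg.grouping,
            severity_order=cfg.severity_order,
            ai_metric=cfg.ai_metric, nosc_metric=cfg.nosc_metric,
        )
        results = model.fit()
        results.ai_tests.to_csv(out / "ai_tests.csv", index=False)
        results.nosc_tests.to_csv(out / "nosc_tests.csv", index=False)
        results.nosc_density.to_csv(out / "nosc_density.csv", index=False)
        pd.DataFrame(
            {"group": list(results.unique_sets),
             "n_unique": [len(v) for v in results.unique_sets.values()]}
        ).to_csv(out / "unique_counts.csv", index=False)
        pd.DataFrame(
            [(g, f) for g in sorted(results.unique_sets)
             for f in sorted(results.unique_sets[g])],
            columns=["group", "formula"],
        ).to_csv(out / "unique_formulas.csv", index=False)
        (out / "comparison.txt").write_text(results.summary() + "\n")
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    conserved = (
        counts["input_peaks"]
        == counts["window_filtered"]
        + counts["isotopologue_removed"]
        + counts["alignment_unresolved"]
        + counts["kept_peaks"]
    )
    manifest = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_samples": len(raw),
        "counts": counts,
        "conservation_ok": bool(conserved),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def simulate(design: SyntheticDesign, outdir: str | Path) -> dict:
    """Generate a synthetic dataset on disk (thin wrapper over synthetic_data)."""
    pools = generate_formula_pool(design)
    peaklists, gt = synthesize_peaklists(pools, design)
    paths = write_dataset(peaklists, gt, design_metadata(design), outdir)
    return {
        "seed": design.seed,
        "n_samples": len(peaklists),
        "n_peaks": int(sum(len(pl) for pl in peaklists)),
        "paths": paths,
    }
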