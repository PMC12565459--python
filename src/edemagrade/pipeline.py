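"""End-to-end orchestration: simulate -> fuse -> quality -> extract ->
select -> train, as a configured, resumable run.

Each stage writes its artifacts under the run directory and records a
content hash of its configuration in ``run_state.json``; re-running with
an unchanged configuration skips completed stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fusion import FUSION_PAIRS, FusionConfig, lrd_fuse_volume
from .grading import MODEL_MENU, ModelReport, model_search
from .phantom import PhantomParams, generate_cohort, load_cohort, write_cohort
from .quality import compute_quality, normalize_metrics
from .radiomics import EmptyROIError, RadiomicsConfig, extract_table
from .selection import boruta_select, minmax_scale
from .types import MODALITIES, SubjectRecord, VolumeImage

__all__ = ["RunConfig", "run_all", "image_type_name"]

log = logging.getLogger("edemagrade")


def image_type_name(pair: tuple[str, str]) -> str:
    """Canonical fused-type name ``A+B`` (A = first-named weight)."""
    return f"{pair[0]}+{pair[1]}"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "run"
    phantom: PhantomParams = field(default_factory=PhantomParams)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    radiomics: RadiomicsConfig = field(default_factory=RadiomicsConfig)
    pairs: tuple[tuple[str, str], ...] = FUSION_PAIRS
    boruta_max_iter: int = 50
    boruta_alpha: float = 0.05
    search_budget: int = 8
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a not in MODALITIES or b not in MODALITIES or a == b:
                raise ValueError(f"invalid fusion pair ({a}, {b})")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        if "phantom" in kwargs:
            kwargs["phantom"] = PhantomParams(**kwargs["phantom"])
        if "fusion" in kwargs:
            kwargs["fusion"] = FusionConfig(**kwargs["fusion"])
        if "radiomics" in kwargs:
            kwargs["radiomics"] = RadiomicsConfig(**kwargs["radiomics"])
        if "pairs" in kwargs:
            kwargs["pairs"] = tuple(tuple(p) for p in kwargs["pairs"])
        return cls(**kwargs)


def _config_hash(cfg: RunConfig, stage: str) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    payload = json.dumps({"stage": stage, "cfg": dataclasses.asdict(cfg)},
                         sort_keys=True, default=default)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


class _RunState:
    def __init__(self, out_dir: Path):
        self.path = out_dir / "run_state.json"
        self.state = json.loads(self.path.read_text()) if self.path.exists() else {}

    def done(self, stage: str, h: str) -> bool:
        return self.state.get(stage) == h

    def mark(self, stage: str, h: str) -> None:
        self.state[stage] = h
        self.path.write_text(json.dumps(self.state, indent=2))


def _stage(cfg: RunConfig, state: _RunState, name: str):
    """Decorator-ish helper: returns True when the stage must run."""
    h = _config_hash(cfg, name)
    if state.done(name, h):
        log.info("stage %s: up to date, skipping", name)
        return None
    return h


def run_all(cfg: RunConfig) -> dict:
    """Execute the full chain; returns a summary dict.

    Produces one feature table, selection result and model report per
    image type (4 original weights + the configured fused pairs), plus a
    cross-image-type performance matrix.  Subjects whose edema ROI is
    empty are excluded with a logged reason.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = _RunState(out)

    # ---- simulate -------------------------------------------------------
    t0 = time.time()
    h = _stage(cfg, state, "simulate")
    cohort_dir = out / "phantom"
    if h:
        records, manifest = generate_cohort(cfg.phantom)
        write_cohort(records, manifest, cohort_dir)
        state.mark("simulate", h)
        log.info("stage simulate: %d subjects in %.1fs", len(records), time.time() - t0)
    records, manifest = load_cohort(cohort_dir)

    image_types = list(MODALITIES) + [image_type_name(p) for p in cfg.pairs]

    # ---- fuse -----------------------------------------------------------
    h = _stage(cfg, state, "fuse")
    fused_dir = out / "fused"
    if h:
        fused_dir.mkdir(exist_ok=True)
        for rec in records:
            for pair in cfg.pairs:
                a, b = pair
                if a not in rec.modalities or b not in rec.modalities:
                    log.warning("subject %s: missing %s or %s; pair skipped",
                                rec.subject_id, a, b)
                    continue
                t = time.time()
                fused = lrd_fuse_volume(rec.modalities[a], rec.modalities[b], cfg.fusion)
                sub = fused_dir / rec.subject_id
                sub.mkdir(exist_ok=True)
                fused.to_nifti().to_filename(
                    str(sub / f"{rec.subject_id}_{image_type_name(pair)}.nii.gz"))
                log.info("fuse %s %s: %.2fs", rec.subject_id, image_type_name(pair),
                         time.time() - t)
        state.mark("fuse", h)

    def fused_volume(rec: SubjectRecord, pair: tuple[str, str]) -> VolumeImage:
        p = fused_dir / rec.subject_id / f"{rec.subject_id}_{image_type_name(pair)}.nii.gz"
        return VolumeImage.from_nifti(p)

    # ---- quality --------------------------------------------------------
    h = _stage(cfg, state, "quality")
    if h:
        rows = []
        type_means: dict[str, dict[str, float]] = {}
        for pair in cfg.pairs:
            ft = image_type_name(pair)
            per_metric: dict[str, list[float]] = {}
            for rec in records:
                from .fusion import _rescale_255

                fused = fused_volume(rec, pair)
                report = compute_quality(
                    fused.data,
                    {m: _rescale_255(rec.modalities[m].data) for m in pair},
                )
                for r in report.as_rows(rec.subject_id, ft):
                    rows.append(r)
                    # key PSNR/SSIM by reference position so the metric
                    # set is common across fused types
                    if r["reference"]:
                        pos = "first" if r["reference"] == pair[0] else "second"
                        key = f"{r['metric']}_vs_{pos}"
                    else:
                        key = r["metric"]
                    per_metric.setdefault(key, []).append(r["value"])
            type_means[ft] = {
                k: float(np.mean([v for v in vals if np.isfinite(v)]))
                for k, vals in per_metric.items()
            }
        pd.DataFrame(rows).to_csv(out / "quality.csv", index=False)
        if len(type_means) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normalized = normalize_metrics(type_means)
            pd.DataFrame(normalized).T.to_csv(out / "quality_normalized.csv")
        state.mark("quality", h)

    # ---- extract --------------------------------------------------------
    h = _stage(cfg, state, "extract")
    feat_dir = out / "features"
    if h:
        feat_dir.mkdir(exist_ok=True)
        for ft in image_types:
            t = time.time()
            usable = []
            for rec in records:
                if (rec.mask.data == cfg.radiomics.roi.label).sum() == 0:
                    log.warning("subject %s: empty ROI, excluded", rec.subject_id)
                    continue
                usable.append(rec)
            if ft in MODALITIES:
                getter = lambda rec, m=ft: rec.modalities[m]
            else:
                pair = next(p for p in cfg.pairs if image_type_name(p) == ft)
                getter = lambda rec, p=pair: fused_volume(rec, p)
            try:
                table = extract_table(usable, getter, ft, cfg.radiomics)
            except EmptyROIError as exc:  # pragma: no cover - guarded above
                log.warning("image type %s: %s", ft, exc)
                continue
            table.to_csv(feat_dir / f"features_{ft.replace('+', '_')}.csv", index=False)
            log.info("extract %s: %d subjects, %.1fs", ft, len(table), time.time() - t)
        state.mark("extract", h)

    # ---- select + train -------------------------------------------------
    h_sel = _stage(cfg, state, "select")
    h_train = _stage(cfg, state, "train")
    summary_rows = []
    reports: dict[str, ModelReport] = {}
    for ft in image_types:
        path = feat_dir / f"features_{ft.replace('+', '_')}.csv"
        if not path.exists():
            continue
        table = pd.read_csv(path)
        y = table["grade"].to_numpy()
        Xdf = table.drop(columns=["subject_id", "image_type", "grade"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scaled, _bounds = minmax_scale(Xdf)
        sel_path = out / f"selection_{ft.replace('+', '_')}.json"
        if h_sel or not sel_path.exists():
            result = boruta_select(scaled, y, max_iter=cfg.boruta_max_iter,
                                   alpha=cfg.boruta_alpha, seed=cfg.seed)
            sel_path.write_text(json.dumps(result.to_dict(), indent=2))
            log.info("select %s: %d confirmed / %d tentative / %d rejected",
                     ft, len(result.confirmed), len(result.tentative), len(result.rejected))
        selection = json.loads(sel_path.read_text())
        chosen = selection["confirmed"] or list(scaled.columns)
        report_path = out / f"report_{ft.replace('+', '_')}.json"
        if h_train is None and report_path.exists():
            payload = json.loads(report_path.read_text())
            summary_rows.append({"image_type": ft, "classifier": payload["classifier"],
                                 **payload["mean_metrics"]})
            continue
        X = scaled[chosen].to_numpy()
        spec, report = model_search(X, y, menu=MODEL_MENU[:4], budget=max(cfg.search_budget, 4),
                                    seed=cfg.seed, k=cfg.cv_folds)
        reports[ft] = report
        report_path = out / f"report_{ft.replace('+', '_')}.json"
        report_payload = {
            "image_type": ft,
            "classifier": spec.name,
            "hyperparameters": spec.hyperparameters,
            "n_features": len(chosen),
            "mean_metrics": report.mean_metrics,
            "pooled_metrics": report.pooled_metrics,
            "confusion": report.confusion.tolist(),
            "k": report.k,
            "cv_seed": report.cv_seed,
        }
        report_path.write_text(json.dumps(report_payload, indent=2))
        summary_rows.append({"image_type": ft, "classifier": spec.name,
                             **report.mean_metrics})
    if h_sel:
        state.mark("select", h_sel)
    if h_train:
        state.mark("train", h_train)

    summary = pd.DataFrame(summary_rows)
    summary.to_csv(out / "performance_matrix.csv", index=False)
    return {"summary": summary, "reports": reports, "out_dir": str(out)}
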