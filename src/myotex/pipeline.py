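"""End-to-end orchestration: simulate -> extract -> screen -> compare.

Stages exchange plain CSV tables (wide, keyed by subject_id / roi_label /
phase) so every intermediate is diff-able and language-portable.  Each
stage writes a provenance sidecar (JSON) recording the configuration hash,
master seed and catalog version, and is idempotent for a fixed
configuration: re-running produces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synth
from .features import CATALOG_NAMES, extract_all, feature_catalog
from .groupstats import compare
from .quantize import normalize_mu3sigma, read_gray, read_mask, write_gray, write_mask
from .screening import repeatability_screen, size_screen

__all__ = [
    "PipelineConfig",
    "run_stage",
    "full_run",
    "summarize",
    "extract_cohort_features",
    "extract_repeatability_features",
    "CATALOG_VERSION",
]

CATALOG_VERSION = "1.0"

STAGES = ("simulate", "extract", "screen-size", "screen-repeat", "compare")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; YAML round-trips losslessly."""

    n_levels: int = 64
    glcm_distances: tuple[int, ...] = (2, 5)
    sector_span_deg: float = 120.0

    # screens
    r_threshold: float = 0.80
    cov_max: float = 10.0
    rsd_max: float = 30.0   # Methods criterion; 20.0 is the stricter preset

    # statistics
    normality_alpha: float = 0.05
    posthoc: str = "bonferroni"
    welch: bool = False

    # cohort sizes (population is desk-scale by default; the generator's
    # own default of 600 represents the full design)
    size_n_per_group: int = 10
    size_area_ratios: tuple[float, ...] = (0.6, 1.0, 1.5)
    repeat_n: int = 30
    repeat_perturb_radius_px: float = 0.5
    repeat_angle_jitter_deg: float = 5.0
    population_n: int = 120

    seed: int = 0
    out_dir: str = "out"

    def __post_init__(self) -> None:
        if not (0 < self.r_threshold <= 1):
            raise ValueError("r_threshold must be in (0, 1]")
        if self.cov_max <= 0 or self.rsd_max <= 0:
            raise ValueError("screen thresholds must be positive")

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        d["glcm_distances"] = list(d["glcm_distances"])
        d["size_area_ratios"] = list(d["size_area_ratios"])
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, src) -> "PipelineConfig":
        text = Path(src).read_text() if isinstance(src, (str, Path)) and "\n" not in str(src) else str(src)
        d = yaml.safe_load(text)
        d["glcm_distances"] = tuple(d["glcm_distances"])
        d["size_area_ratios"] = tuple(d["size_area_ratios"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _provenance(cfg: PipelineConfig, stage: str, extra=None) -> dict:
    rec = {
        "stage": stage,
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "catalog_version": CATALOG_VERSION,
    }
    if extra:
        rec.update(extra)
    return rec


def _write_provenance(path: Path, rec: dict) -> None:
    path.write_text(json.dumps(rec, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# in-memory extraction helpers (also used by the tests / acceptance script)

def extract_cohort_features(
    subjects,
    roi_label: str = "whole_wall",
    n_levels: int = 64,
) -> tuple[pd.DataFrame, pd.Series]:
    """Wide 50-feature table (one row per subject) plus ROI pixel counts."""
    rows, areas = {}, {}
    for s in subjects:
        q = normalize_mu3sigma(s.image, s.masks[roi_label], n_levels)
        rows[s.subject_id] = extract_all(q)
        areas[s.subject_id] = s.masks[roi_label].area
    table = pd.DataFrame(rows).T
    table.index.name = "subject_id"
    return table, pd.Series(areas, name="area")


def extract_repeatability_features(
    subjects,
    phase: str = "ED",
    roi_label: str = "whole_wall",
    n_levels: int = 64,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Intra- and inter-observer paired feature tables for one phase.

    Returns ``(intra, inter)`` with a (feature, reading) column MultiIndex:
    intra pairs observer 1's two readings, inter pairs the two observers'
    first readings.
    """
    intra_rows, inter_rows = [], []
    idx = []
    for s in subjects:
        image, bundle = s.phases[phase][0], s.phases[phase][1]
        readings = bundle["readings"]
        vecs = {}
        for key in ((1, 1), (1, 2), (2, 1)):
            q = normalize_mu3sigma(image, readings[key][roi_label], n_levels)
            vecs[key] = extract_all(q)
        idx.append(s.subject_id)
        intra_rows.append(np.concatenate([[vecs[1, 1][f], vecs[1, 2][f]]
                                          for f in CATALOG_NAMES]))
        inter_rows.append(np.concatenate([[vecs[1, 1][f], vecs[2, 1][f]]
                                          for f in CATALOG_NAMES]))
    cols = pd.MultiIndex.from_product([CATALOG_NAMES, [0, 1]],
                                      names=["feature", "reading"])
    intra = pd.DataFrame(intra_rows, index=idx, columns=cols)
    inter = pd.DataFrame(inter_rows, index=idx, columns=cols)
    intra.index.name = inter.index.name = "subject_id"
    return intra, inter


def _long_form(wide: pd.DataFrame, roi_label: str, phase: str) -> pd.DataFrame:
    long = wide.stack().rename("value").reset_index()
    long.columns = ["subject_id", "feature", "value"]
    long.insert(1, "roi_label", roi_label)
    long.insert(2, "phase", phase)
    return long


# ---------------------------------------------------------------------------
# stages

def _stage_dir(cfg: PipelineConfig, stage: str) -> Path:
    p = Path(cfg.out_dir) / stage
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run the '{producer}' stage first"
        )
    return path


def _simulate(cfg: PipelineConfig) -> dict:
    out = _stage_dir(cfg, "simulate")
    ss = np.random.SeedSequence(cfg.seed).generate_state(3) % (2**31)

    size_subjects = synth.generate_size_cohort(
        n_per_group=cfg.size_n_per_group,
        area_ratios=cfg.size_area_ratios,
        seed=int(ss[0]),
    )
    rows = []
    for s in size_subjects:
        img_path = out / f"{s.subject_id}.tiff"
        write_gray(img_path, s.image)
        mask_paths = {}
        for label, m in s.masks.items():
            mp = out / f"{s.subject_id}_{label}.png"
            write_mask(mp, m)
            mask_paths[label] = mp.name
        rows.append({"subject_id": s.subject_id, **s.meta,
                     "image": img_path.name, **{f"mask_{k}": v
                                                for k, v in mask_paths.items()}})
    pd.DataFrame(rows).to_csv(out / "size_cohort.csv", index=False)

    catalog = feature_catalog()
    catalog.to_csv(out / "feature_catalog.csv", index=False)
    _write_provenance(out / "provenance.json", _provenance(
        cfg, "simulate", {"n_size_subjects": len(size_subjects)}))
    return {"size_cohort": out / "size_cohort.csv"}


def _extract(cfg: PipelineConfig) -> dict:
    sim = _stage_dir(cfg, "simulate")
    out = _stage_dir(cfg, "extract")
    manifest = pd.read_csv(_require(sim / "size_cohort.csv", "simulate"))

    rows, areas = {}, {}
    for _, rec in manifest.iterrows():
        image = read_gray(sim / rec["image"])
        mask = read_mask(sim / rec["mask_whole_wall"])
        q = normalize_mu3sigma(image, mask, cfg.n_levels)
        rows[rec["subject_id"]] = extract_all(q)
        areas[rec["subject_id"]] = mask.area
    wide = pd.DataFrame(rows).T
    wide.index.name = "subject_id"
    wide.insert(0, "area", pd.Series(areas))
    wide.to_csv(out / "size_features.csv")
    _long_form(wide.drop(columns="area"), "whole_wall", "ED").to_csv(
        out / "size_features_long.csv", index=False)
    _write_provenance(out / "provenance.json", _provenance(cfg, "extract"))
    return {"size_features": out / "size_features.csv"}


def _screen_size(cfg: PipelineConfig) -> dict:
    ext = _stage_dir(cfg, "extract")
    out = _stage_dir(cfg, "screen-size")
    wide = pd.read_csv(_require(ext / "size_features.csv", "extract"),
                       index_col="subject_id")
    areas = wide.pop("area")
    report = size_screen(wide, areas, r_threshold=cfg.r_threshold)
    report.to_csv(out / "size_screen.csv")
    _write_provenance(out / "provenance.json", _provenance(
        cfg, "screen-size",
        {"n_excluded": int(report["excluded"].sum()),
         "n_retained": int((~report["excluded"]).sum())}))
    return {"size_screen": out / "size_screen.csv"}


def _screen_repeat(cfg: PipelineConfig) -> dict:
    out = _stage_dir(cfg, "screen-repeat")
    subjects = synth.generate_repeatability_cohort(
        n=cfg.repeat_n,
        observer_model=synth.ObserverModel(cfg.repeat_perturb_radius_px,
                                           cfg.repeat_angle_jitter_deg),
        seed=int(np.random.SeedSequence(cfg.seed).generate_state(3)[1] % (2**31)),
    )
    paths = {}
    for phase in ("ED", "ES"):
        intra, inter = extract_repeatability_features(subjects, phase=phase)
        rep = repeatability_screen(intra, inter,
                                   cov_max=cfg.cov_max, rsd_max=cfg.rsd_max)
        p = out / f"repeatability_{phase}.csv"
        rep.to_csv(p)
        paths[phase] = p
    _write_provenance(out / "provenance.json", _provenance(cfg, "screen-repeat"))
    return paths


def _compare(cfg: PipelineConfig) -> dict:
    out = _stage_dir(cfg, "compare")
    subjects = synth.generate_population(
        n=cfg.population_n,
        seed=int(np.random.SeedSequence(cfg.seed).generate_state(3)[2] % (2**31)),
    )
    # phase contrast (paired within subject, whole wall)
    rows = []
    for s in subjects:
        for phase, (img, masks) in s.phases.items():
            q = normalize_mu3sigma(img, masks["whole_wall"], cfg.n_levels)
            vec = extract_all(q)
            rec = {"subject_id": s.subject_id, "phase": phase,
                   "sex": s.meta["sex"], "age_band": s.meta["age_band"]}
            rec.update(vec.to_dict())
            rows.append(rec)
    table = pd.DataFrame(rows)
    feats = list(CATALOG_NAMES)

    phase_rep = compare(table, "phase", "paired", features=feats,
                        welch=cfg.welch)
    ed = table[table["phase"] == "ED"]
    sex_rep = compare(ed, "sex", "independent", features=feats, welch=cfg.welch)
    age_rep = compare(ed, "age_band", "k_groups", features=feats,
                      welch=cfg.welch)

    phase_rep.to_csv(out / "compare_phase.csv")
    sex_rep.to_csv(out / "compare_sex_ED.csv")
    age_rep.to_csv(out / "compare_age_ED.csv")
    _write_provenance(out / "provenance.json", _provenance(cfg, "compare"))
    return {"phase": out / "compare_phase.csv",
            "sex": out / "compare_sex_ED.csv",
            "age": out / "compare_age_ED.csv"}


_STAGE_FUNCS = {
    "simulate": _simulate,
    "extract": _extract,
    "screen-size": _screen_size,
    "screen-repeat": _screen_repeat,
    "compare": _compare,
}


def run_stage(stage: str, cfg: PipelineConfig) -> dict:
    """Run one named stage; returns the paths of its primary outputs."""
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; one of {STAGES}")
    return _STAGE_FUNCS[stage](cfg)


def full_run(cfg: PipelineConfig) -> dict:
    """Run every stage in dependency order; returns all output paths."""
    outputs = {}
    for stage in STAGES:
        outputs[stage] = run_stage(stage, cfg)
    return outputs


def summarize(cfg: PipelineConfig) -> str:
    """Human-readable digest of whichever stage reports exist."""
    base = Path(cfg.out_dir)
    lines = []
    p = base / "screen-size" / "size_screen.csv"
    if p.exists():
        rep = pd.read_csv(p, index_col="feature")
        excluded = rep.index[rep["excluded"]].tolist()
        lines.append(f"size screen: {len(excluded)} excluded, "
                     f"{int((~rep['excluded']).sum())} retained")
        for f in excluded:
            lines.append(f"  excluded: {f} (r = {rep.loc[f, 'spearman_r']:+.3f})")
    for phase in ("ED", "ES"):
        p = base / "screen-repeat" / f"repeatability_{phase}.csv"
        if p.exists():
            rep = pd.read_csv(p, index_col="feature")
            lines.append(f"repeatability screen [{phase}]: "
                         f"{int(rep['pass'].sum())}/{len(rep)} features pass")
    for name, fn in (("phase", "compare_phase.csv"),
                     ("sex (ED)", "compare_sex_ED.csv"),
                     ("age (ED)", "compare_age_ED.csv")):
        p = base / "compare" / fn
        if p.exists():
            rep = pd.read_csv(p, index_col="feature")
            lines.append(f"comparison [{name}]: "
                         f"{int(rep['significant'].sum())}/{len(rep)} "
                         f"features significant at p < 0.05")
    return "\n".join(lines)
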