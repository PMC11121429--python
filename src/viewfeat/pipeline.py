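"""Stage orchestration: simulate -> extract -> score -> analyze.

Each stage is a plain function over paths/frames so it can be driven by
the CLI, the numbered analysis scripts, or tests.  Every random stage
consumes a seed derived from the master seed and the stage label, so
stages can be rerun independently and reproducibly; a manifest records
the configuration hash, seeds, and row counts (including exclusion
bookkeeping) of each completed stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavioral, stats, synthetic
from .config import ExtractionConfig
from .image_features import (
    FEATURE_FIELDS,
    FeatureVector,
    aggregate_participant,
    extract_features,
)

log = logging.getLogger("viewfeat")


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive an independent, reproducible per-stage seed (< 2**31)."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


def config_hash(obj) -> str:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# simulate


def run_simulate(spec: synthetic.CohortSpec, out_dir: str | Path) -> dict:
    cohort = synthetic.simulate_cohort(spec)
    synthetic.write_cohort(cohort, out_dir)
    n_images = sum(len(p.images) for p in cohort.participants)
    log.info("simulated %d participants, %d images", len(cohort.participants), n_images)
    return {
        "stage": "simulate",
        "config_hash": config_hash(spec),
        "seed": spec.seed,
        "n_participants": len(cohort.participants),
        "n_images": n_images,
    }


# ---------------------------------------------------------------------------
# extract


def iter_dataset_images(dataset_dir: str | Path):
    """Yield ``(participant_id, image_path, mask_path_or_None)`` over a
    cohort directory in sorted order."""
    root = Path(dataset_dir)
    for pdir in sorted(d for d in root.iterdir() if d.is_dir()):
        for img_path in sorted(pdir.glob("window_*.png")):
            if img_path.stem.endswith("_skymask"):
                continue
            mask_path = img_path.with_name(img_path.stem + "_skymask.png")
            yield pdir.name, img_path, mask_path if mask_path.exists() else None


def extract_dataset(
    dataset_dir: str | Path, cfg: ExtractionConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Extract LLVFs for every image in an on-disk cohort.

    Returns ``(per_image, per_participant)`` frames.  A missing sky
    mask is a warning, not an error: that image's sky ratio is NaN and
    the per-participant average skips it.
    """
    import imageio.v3 as iio

    cfg = cfg or ExtractionConfig()
    per_image: dict[str, FeatureVector] = {}
    groups: dict[str, list[FeatureVector]] = {}
    found = False
    for pid, img_path, mask_path in iter_dataset_images(dataset_dir):
        found = True
        img = np.asarray(iio.imread(img_path))[..., :3]
        masked = None
        if mask_path is None:
            log.warning("no sky mask for %s; sky_ratio flagged absent", img_path)
        else:
            masked = np.asarray(iio.imread(mask_path))[..., :3]
        fv = extract_features(img, masked, cfg)
        per_image[f"{pid}/{img_path.stem}"] = fv
        groups.setdefault(pid, []).append(fv)
    if not found:
        raise FileNotFoundError(f"no window images found under {dataset_dir}")
    img_df = pd.DataFrame({k: fv.as_dict() for k, fv in per_image.items()}).T
    img_df = img_df[list(FEATURE_FIELDS)]
    img_df.index.name = "image_id"
    part_df = extract_cohort_features_from_groups(groups)
    return img_df, part_df


def extract_cohort_features_from_groups(groups: dict) -> pd.DataFrame:
    rows = {}
    for pid, fvs in groups.items():
        rows[pid] = aggregate_participant(fvs).as_dict()
    df = pd.DataFrame(rows).T[list(FEATURE_FIELDS)]
    df.index.name = "participant_id"
    return df


def extract_cohort_features(
    cohort: synthetic.Cohort, cfg: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Per-participant averaged features of an in-memory cohort."""
    cfg = cfg or ExtractionConfig()
    groups = {
        p.participant_id: [
            extract_features(img, mask, cfg)
            for img, mask in zip(p.images, p.masks)
        ]
        for p in cohort.participants
    }
    return extract_cohort_features_from_groups(groups)


# ---------------------------------------------------------------------------
# score


def score_dataset(dataset_dir: str | Path) -> pd.DataFrame:
    """Score STADI items and choice logs into per-participant outcomes."""
    root = Path(dataset_dir)
    stadi = pd.read_csv(root / "stadi_items.csv")
    choices = pd.read_csv(root / "choices.csv")
    return score_frames(stadi, choices)


def score_frames(stadi: pd.DataFrame, choices: pd.DataFrame) -> pd.DataFrame:
    na = behavioral.score_stadi_table(stadi)
    dd = behavioral.score_choice_log(choices)
    return na.merge(dd, on="participant_id", how="outer")


# ---------------------------------------------------------------------------
# analyze


def build_analysis_table(
    features: pd.DataFrame,
    ratings: pd.DataFrame,
    demographics: pd.DataFrame,
    outcomes: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the one-row-per-participant analysis table.

    Left-joins on the demographics roster so participants with missing
    outcomes stay present (as NaN) for per-analysis listwise deletion.
    """
    feats = features.reset_index()
    table = (
        demographics.merge(ratings, on="participant_id", how="left")
        .merge(feats, on="participant_id", how="left")
        .merge(outcomes, on="participant_id", how="left")
    )
    pct = table[["pct_nature", "pct_manmade", "pct_sky"]].sum(axis=1)
    if not np.allclose(pct.dropna(), 100):
        raise ValueError("percentage estimates do not sum to 100")
    return table


def run_analysis(table: pd.DataFrame) -> dict:
    """Run the full inference battery on an analysis table.

    Returns correlation matrix, the three feature->rating designs (two
    stages each) and the two outcome designs, plus exclusion counts.
    """
    n_total = len(table)
    after_diverse = stats.exclude_participants(table)
    corr_vars = list(stats.RATING_VARS) + ["pct_sky"] + list(stats.LLVF_USABLE)
    corr = stats.spearman_matrix(after_diverse, corr_vars)
    design_a = stats.design_A_feature_models(table)
    design_b = stats.design_B_outcome_models(table)
    return {
        "n_total": n_total,
        "n_after_diverse_exclusion": len(after_diverse),
        "n_per_model": {
            **{k: v[1].fit.n for k, v in design_a.items()},
            **{k: v.fit.n for k, v in design_b.items()},
        },
        "correlations": corr,
        "design_a": design_a,
        "design_b": design_b,
    }


def model_table_frame(result: stats.StepwiseResult) -> pd.DataFrame:
    """A model's coefficient table in the study's reporting layout."""
    df = result.fit.table.copy()
    df["adj_r2"] = [result.fit.adj_r2] + [np.nan] * (len(df) - 1)
    return df


def write_analysis(results: dict, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corr = results["correlations"]
    corr.rho.to_csv(out / "correlations_rho.csv")
    corr.p.to_csv(out / "correlations_p.csv")
    traces = {}
    for outcome, (stage1, stage2) in results["design_a"].items():
        model_table_frame(stage2).to_csv(
            out / f"model_{outcome}.csv", index=False
        )
        traces[outcome] = {
            "stage1": stage1.trace,
            "stage2": stage2.trace,
            "selected": list(stage2.terms),
        }
    for outcome, res in results["design_b"].items():
        model_table_frame(res).to_csv(out / f"model_{outcome}.csv", index=False)
        traces[outcome] = {"trace": res.trace, "selected": list(res.selected)}
    with open(out / "selection_traces.json", "w") as fh:
        json.dump(traces, fh, indent=1)


def write_manifest(out_dir: str | Path, entries: list[dict]) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=1)
    return path
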