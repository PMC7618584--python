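"""Batch orchestration: points -> measurements -> agreement report.

These functions are the library form of the command-line workflow: measure
every file in a manifest, compare two measurement tables, and run the fully
synthetic end-to-end experiment (simulate -> train detector -> detect ->
measure both point sources -> agreement).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import agreement as agr
from .detector import RegressionVotingDetector
from .landmarks import SchemaId, flip_horizontal, read_pts
from .measurement import (
    MeasurementDefinition,
    builtin_definitions,
    compute_aFTA,
    definitions_for_schema,
)
from .synthetic import (
    SimulationConfig,
    degrade,
    inject_alignment,
    make_template,
    render,
)

logger = logging.getLogger("kneealign")

__all__ = ["measure_manifest", "agree_tables", "run_end_to_end"]


def _resolve_definitions(names: "Sequence[str] | None",
                         ) -> "dict[str, MeasurementDefinition] | None":
    if names is None:
        return None
    table = builtin_definitions()
    unknown = [n for n in names if n not in table]
    if unknown:
        raise ValueError(
            f"unknown definition(s) {unknown}; valid names: {sorted(table)}")
    return {n: table[n] for n in names}


def measure_manifest(manifest_path: "str | Path",
                     definition_names: "Sequence[str] | None" = None,
                     ) -> pd.DataFrame:
    """Measure every pts file listed in a manifest CSV.

    The manifest has columns image_id, pts_path, schema_id, flipped and
    (when any file needs flipping) image_width.  Rows marked ``flipped``
    are mirrored to left-knee orientation before measurement.  Per-file
    failures are logged and recorded in the ``error`` column; the run
    continues.
    """
    manifest_path = Path(manifest_path)
    man = pd.read_csv(manifest_path)
    chosen = _resolve_definitions(definition_names)
    rows = []
    for rec in man.itertuples(index=False):
        flipped = bool(getattr(rec, "flipped", False))
        try:
            ls = read_pts(manifest_path.parent / rec.pts_path, rec.schema_id,
                          image_id=str(rec.image_id))
            if flipped:
                ls = flip_horizontal(ls, float(rec.image_width))
            defs = (chosen.values() if chosen is not None
                    else definitions_for_schema(ls.schema_id).values())
            applicable = [d for d in defs if d.schema_id == ls.schema_id]
            for d in applicable:
                r = compute_aFTA(ls, d)
                rows.append(dict(
                    image_id=str(rec.image_id), schema_id=ls.schema_id.value,
                    definition_name=r.definition_name,
                    aFTA_deg=round(r.aFTA_deg, 4),
                    theta_fem_deg=r.theta_fem_deg, theta_tib_deg=r.theta_tib_deg,
                    classification=r.classification,
                    in_acceptable_range=r.in_acceptable_range,
                    flipped=flipped, error=""))
        except Exception as exc:  # per-file failure: record and continue
            logger.warning("measurement failed for %s: %s", rec.image_id, exc)
            rows.append(dict(image_id=str(rec.image_id),
                             schema_id=str(rec.schema_id), definition_name="",
                             aFTA_deg=np.nan, theta_fem_deg=np.nan,
                             theta_tib_deg=np.nan, classification="",
                             in_acceptable_range=False, flipped=flipped,
                             error=str(exc)))
    cols = ["image_id", "schema_id", "definition_name", "aFTA_deg",
            "theta_fem_deg", "theta_tib_deg", "classification",
            "in_acceptable_range", "flipped", "error"]
    return pd.DataFrame(rows, columns=cols)


def agree_tables(df_a: pd.DataFrame, df_b: pd.DataFrame,
                 acceptable_range: tuple[float, float] = (2.4, 7.2),
                 ci_level: float = 0.95, icc_form: str = "icc2",
                 direction: str = "a_minus_b",
                 ) -> tuple[dict[str, agr.AgreementReport], pd.DataFrame]:
    """Agreement reports per definition for two measurement tables.

    Tables are joined on (image_id, definition_name); each definition with
    at least 3 shared images yields an AgreementReport.  Also returns the
    per-pair Bland-Altman table (means and differences) for plotting.
    """
    a = df_a[df_a["error"].fillna("") == ""][
        ["image_id", "definition_name", "aFTA_deg"]]
    b = df_b[df_b["error"].fillna("") == ""][
        ["image_id", "definition_name", "aFTA_deg"]]
    merged = a.merge(b, on=["image_id", "definition_name"],
                     suffixes=("_a", "_b"))
    if merged["image_id"].nunique() < 3:
        raise ValueError("need at least 3 shared image_ids")
    reports: dict[str, agr.AgreementReport] = {}
    ba_rows = []
    for name, grp in merged.groupby("definition_name", sort=True):
        if len(grp) < 3:
            logger.warning("definition %s: only %d shared pairs, skipped",
                           name, len(grp))
            continue
        p = agr.PairedMeasurements(grp["image_id"].tolist(),
                                   grp["aFTA_deg_a"].to_numpy(),
                                   grp["aFTA_deg_b"].to_numpy())
        reports[name] = agr.build_report(p, acceptable_range=acceptable_range,
                                         ci_level=ci_level, icc_form=icc_form,
                                         direction=direction)
        ba = agr.bland_altman(p, direction=direction)
        for iid, m, d in zip(p.ids, ba.means, ba.diffs):
            ba_rows.append(dict(image_id=iid, definition_name=name,
                                mean_deg=m, diff_deg=d))
    return reports, pd.DataFrame(ba_rows)


def run_end_to_end(seed: int = 0, schema_id: "SchemaId | str" = SchemaId.PRE_EXTENDED,
                   n_train: int = 40, n_test: int = 50, size: int = 320,
                   definition_name: str = "PreX-fem-notch-tib-shafts",
                   true_mean_deg: float = 2.0, true_sd_deg: float = 4.0,
                   point_noise_sd_px: float = 0.5, rotation_sd_deg: float = 2.0,
                   render_blur_sd: float = 1.5, render_noise_sd: float = 2.0,
                   bbox_jitter_px: float = 10.0,
                   detector: "RegressionVotingDetector | None" = None,
                   skip_detector: bool = False) -> dict:
    """The full synthetic experiment, deterministic per seed.

    Renders ``n_train`` + ``n_test`` pseudo-radiographs with known true
    aFTA, trains the regression-voting detector on the training renders,
    detects landmarks on the held-out renders from a jittered bounding-box
    initialisation, measures aFTA from both detected and ground-truth
    points, and summarises their agreement.

    With ``skip_detector=True`` the "automatic" measurements come from the
    ground-truth points re-jittered by 0.5 px instead of the detector
    (a fast pipeline check).

    Returns a dict with the agreement report, the per-image angle table
    and the median point-to-point detection error.
    """
    sid = SchemaId(schema_id)
    d = builtin_definitions()[definition_name]
    if d.schema_id != sid:
        raise ValueError(f"definition {definition_name} targets {d.schema_id}, "
                         f"not {sid}")
    rng = np.random.default_rng(seed)
    tpl = make_template(sid, size=float(size))

    def make_batch(n: int) -> tuple[list[np.ndarray], list]:
        imgs, sets = [], []
        for _ in range(n):
            t = float(rng.normal(true_mean_deg, true_sd_deg))
            sub = int(rng.integers(0, 2**31 - 1))
            cfg = SimulationConfig(
                true_aFTA_deg=t, point_noise_sd_px=point_noise_sd_px,
                global_rotation_deg=float(rng.normal(0.0, rotation_sd_deg)),
                seed=sub)
            ls = degrade(inject_alignment(tpl, t), cfg)
            imgs.append(render(ls, size, blur_sd=render_blur_sd,
                               noise_sd=render_noise_sd, seed=sub))
            sets.append(ls)
        return imgs, sets

    tr_imgs, tr_sets = make_batch(n_train)
    te_imgs, te_sets = make_batch(n_test)

    if skip_detector:
        jr = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        pred = [ls.copy(points=ls.points + jr.normal(0, 0.5, ls.points.shape),
                        source="automatic") for ls in te_sets]
        med_err = float(np.median([
            np.linalg.norm(p.points - s.points, axis=1).mean()
            for p, s in zip(pred, te_sets)]))
    else:
        det = detector or RegressionVotingDetector(random_state=int(
            rng.integers(0, 2**31 - 1)))
        logger.info("training detector on %d renders", n_train)
        det.fit(tr_imgs, tr_sets)
        bboxes = []
        for ls in te_sets:
            x0, y0 = ls.points.min(axis=0)
            x1, y1 = ls.points.max(axis=0)
            j = rng.uniform(-bbox_jitter_px, bbox_jitter_px, 4)
            bboxes.append((x0 + j[0], y0 + j[1], x1 + j[2], y1 + j[3]))
        logger.info("detecting landmarks on %d held-out renders", n_test)
        pred = det.predict(te_imgs, bboxes=bboxes)
        med_err = float(np.median([
            np.median(np.linalg.norm(p.points - s.points, axis=1))
            for p, s in zip(pred, te_sets)]))

    ids = [f"test_{i:04d}" for i in range(n_test)]
    auto = [compute_aFTA(p, d).aFTA_deg for p in pred]
    manual = [compute_aFTA(s, d).aFTA_deg for s in te_sets]
    p = agr.PairedMeasurements(ids, auto, manual)
    report = agr.build_report(p)
    table = pd.DataFrame(dict(image_id=ids, aFTA_auto_deg=auto,
                              aFTA_truth_points_deg=manual))
    return dict(report=report, table=table, median_point_error_px=med_err,
                definition_name=definition_name, schema_id=sid.value)
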