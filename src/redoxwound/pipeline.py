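"""End-to-end processing: images in, cohort marker table and statistics out.

The in-vivo arm mirrors the acquisition protocol: white-light segmentation
-> cuvette calibration of NADH/FAD -> masking -> pixel-wise ratio ->
surface RR and normalized wound area.  The cryo arm: flat-field correction
-> background zeroing -> voxel-wise ratio -> volumetric RR.  Cryo stacks
are background-corrected *after* flat-fielding (configurable), since the
illumination pattern otherwise distorts the intensity cutoff.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io_calibration as io
from . import metrics as mx
from . import segmentation as seg
from . import stats as st
from .errors import RedoxWoundError
from .frames import ChannelFrame, SurfaceMetrics, VolumetricMetrics, WoundMask
from .synthetic import CohortSimulator, CohortParams

log = logging.getLogger("redoxwound")


@dataclass
class AnalysisConfig:
    """Tunable knobs of the analysis stage (not the generator)."""

    fad_floor: Optional[float] = None          # None -> 1% of masked median FAD
    threshold_fraction: float = 0.10           # cryo background cutoff fraction
    zero_before_flat: bool = False             # order of the two cryo steps
    hist_bins: int = 100
    hist_range: Tuple[float, float] = (0.0, 4.0)
    segmentation: str = "auto"                 # auto | manual
    manual_mask_dir: Optional[str] = None


def process_session(white: ChannelFrame, nadh: ChannelFrame, fad: ChannelFrame,
                    refs: Dict[str, "io.CuvetteReference"],
                    config: AnalysisConfig = AnalysisConfig(),
                    mask: Optional[WoundMask] = None
                    ) -> Tuple[SurfaceMetrics, WoundMask]:
    """Process one in-vivo session into surface metrics and its wound mask."""
    if mask is None:
        mask = seg.segment_wound(white)
    nadh_c = io.calibrate_frame(nadh, refs["NADH"])
    fad_c = io.calibrate_frame(fad, refs["FAD"])
    nadh_m = seg.apply_mask(nadh_c, mask)
    fad_m = seg.apply_mask(fad_c, mask)
    rmap = mx.redox_map(nadh_m, fad_m, mask, fad_floor=config.fad_floor)
    metrics = mx.surface_rr(rmap, subject=nadh.subject, group=nadh.group, day=nadh.day)
    return metrics, mask


def process_biopsy(stacks: Dict[str, "io.CryoStack"],
                   config: AnalysisConfig = AnalysisConfig()) -> VolumetricMetrics:
    """Process one biopsy's NADH/FAD stacks into a volumetric redox ratio."""
    corrected, backgrounds = {}, []
    for ch in ("NADH", "FAD"):
        stack = stacks[ch]
        if config.zero_before_flat:
            stack, bg = io.zero_background(stack, config.threshold_fraction)
            stack = io.flat_field_correct(stack)
        else:
            stack = io.flat_field_correct(stack)
            stack, bg = io.zero_background(stack, config.threshold_fraction)
        corrected[ch] = stack
        backgrounds.append(bg)
    fg = seg.cryo_foreground_mask(backgrounds)
    rmap = mx.redox_map(corrected["NADH"].voxels, corrected["FAD"].voxels, fg,
                        fad_floor=config.fad_floor)
    s = stacks["NADH"]
    return mx.volumetric_rr(rmap, subject=s.subject, group=s.group, day=s.day)


# ---- cohort-level drivers ---------------------------------------------------

def _assemble_table(surface_rows: List[dict], volumetric_rows: List[dict]) -> pd.DataFrame:
    sdf = pd.DataFrame(surface_rows)
    vdf = pd.DataFrame(volumetric_rows)
    if sdf.empty and vdf.empty:
        return pd.DataFrame(
            columns=["subject", "group", "day", "surface_rr", "normalized_area",
                     "n_pixels", "volumetric_rr", "n_voxels"])
    if sdf.empty:
        return vdf
    if vdf.empty:
        return sdf
    return sdf.merge(vdf, on=["subject", "group", "day"], how="outer")


def _add_normalized_area(rows: List[dict]) -> None:
    """Fill normalized_area = N(t)/N(0) per subject, in place."""
    by_subject: Dict[str, Dict[int, dict]] = {}
    for r in rows:
        by_subject.setdefault(r["subject"], {})[r["day"]] = r
    for subj, days in by_subject.items():
        day0 = min(days)
        n0 = days[day0]["n_pixels"]
        for day, r in days.items():
            r["normalized_area"] = mx.normalized_area(r["n_pixels"], n0)


def analyze_cohort_in_memory(sim: CohortSimulator,
                             config: AnalysisConfig = AnalysisConfig(),
                             include_cryo: bool = True) -> pd.DataFrame:
    """Run the full pipeline on a simulator without touching disk."""
    surface_rows: List[dict] = []
    for subject, days in sorted(sim.truth.in_vivo.items()):
        for day in sorted(days):
            white, nadh, fad, cuv, _ = sim.session(subject, day)
            refs = {ch: io.CuvetteReference(ch, float(f.pixels.mean()), day=day)
                    for ch, f in cuv.items()}
            m, mask = process_session(white, nadh, fad, refs, config)
            surface_rows.append({
                "subject": subject, "group": m.group, "day": day,
                "surface_rr": m.surface_rr, "n_pixels": mask.n_pixels,
                "n_valid": m.n_valid})
    _add_normalized_area(surface_rows)

    volumetric_rows: List[dict] = []
    if include_cryo:
        for subject, days in sorted(sim.truth.cryo.items()):
            for day in sorted(days):
                nadh_vol, fad_vol, _, _ = sim.cryo_stack(subject, day)
                vm = process_biopsy({"NADH": nadh_vol, "FAD": fad_vol}, config)
                volumetric_rows.append({
                    "subject": subject, "group": vm.group, "day": day,
                    "volumetric_rr": vm.volumetric_rr, "n_voxels": vm.n_voxels})
    return _assemble_table(surface_rows, volumetric_rows)


def analyze_manifest(manifest_path, config: AnalysisConfig = AnalysisConfig()
                     ) -> Tuple[pd.DataFrame, List[dict]]:
    """Run the pipeline over an on-disk dataset; failures are isolated per session."""
    manifest = io.read_manifest(manifest_path)
    root = Path(manifest_path).parent
    failures: List[dict] = []

    surface_rows: List[dict] = []
    sessions = (manifest[manifest["kind"] == "frame"]
                [["subject", "group", "day"]].drop_duplicates())
    for _, srow in sessions.sort_values(["subject", "day"]).iterrows():
        subject, group, day = srow["subject"], srow["group"], int(srow["day"])
        try:
            frames, refs = io.load_session(manifest, subject, day, root=root)
            mask = None
            if config.segmentation == "manual" and config.manual_mask_dir:
                mask_path = Path(config.manual_mask_dir) / f"{subject}_day{day}.tif"
                mask = seg.load_manual_mask(mask_path, frames["WHITE"])
            m, wmask = process_session(
                frames["WHITE"], frames["NADH"], frames["FAD"], refs, config, mask)
            surface_rows.append({
                "subject": subject, "group": group, "day": day,
                "surface_rr": m.surface_rr, "n_pixels": wmask.n_pixels,
                "n_valid": m.n_valid})
        except (RedoxWoundError, OSError) as exc:
            log.error("session %s/day%s failed: %s", subject, day, exc)
            failures.append({"subject": subject, "day": day, "stage": "in_vivo",
                             "error": str(exc)})
    _add_normalized_area(surface_rows)

    volumetric_rows: List[dict] = []
    biopsies = (manifest[manifest["kind"] == "stack"]
                [["subject", "group", "day"]].drop_duplicates())
    for _, brow in biopsies.sort_values(["subject", "day"]).iterrows():
        subject, group, day = brow["subject"], brow["group"], int(brow["day"])
        try:
            stacks = io.load_cryo(manifest, subject, day, root=root)
            vm = process_biopsy(stacks, config)
            volumetric_rows.append({
                "subject": subject, "group": group, "day": day,
                "volumetric_rr": vm.volumetric_rr, "n_voxels": vm.n_voxels})
        except (RedoxWoundError, OSError) as exc:
            log.error("biopsy %s/day%s failed: %s", subject, day, exc)
            failures.append({"subject": subject, "day": day, "stage": "cryo",
                             "error": str(exc)})
    return _assemble_table(surface_rows, volumetric_rows), failures


# ---- cohort statistics -------------------------------------------------------

def cohort_statistics(table: pd.DataFrame) -> dict:
    """The full statistical layer on an analyzed cohort table."""
    out: dict = {"anova": {}, "tukey": {}, "summary": None,
                 "pearson": {}, "percent_difference": {}}
    in_vivo = table.dropna(subset=["surface_rr"]) if "surface_rr" in table else pd.DataFrame()

    for marker in ("surface_rr", "normalized_area"):
        if marker in in_vivo.columns and not in_vivo.empty:
            try:
                out["anova"][marker] = st.repeated_anova(in_vivo, marker)
            except RedoxWoundError as exc:
                log.warning("ANOVA on %s skipped: %s", marker, exc)
            try:
                out["tukey"][marker] = st.tukey_posthoc(in_vivo, marker)
            except RedoxWoundError as exc:
                log.warning("Tukey on %s skipped: %s", marker, exc)

    has_vol = "volumetric_rr" in table.columns and table["volumetric_rr"].notna().any()
    if has_vol:
        vol = table.dropna(subset=["volumetric_rr"])
        try:
            out["tukey"]["volumetric_rr"] = st.tukey_posthoc(vol, "volumetric_rr")
        except RedoxWoundError as exc:
            log.warning("Tukey on volumetric_rr skipped: %s", exc)

    out["summary"] = st.summarize_cohort(table)

    if not in_vivo.empty and in_vivo["normalized_area"].notna().sum() >= 3:
        rows = in_vivo.dropna(subset=["normalized_area", "surface_rr"])
        out["pearson"]["surface_rr_vs_area"] = st.pearson(
            rows["normalized_area"], rows["surface_rr"])
    if has_vol and not in_vivo.empty:
        both = table.dropna(subset=["surface_rr", "volumetric_rr"])
        if len(both) >= 3:
            out["pearson"]["surface_vs_volumetric"] = st.pearson(
                both["surface_rr"], both["volumetric_rr"])

    # headline effect sizes
    if not in_vivo.empty:
        diab = in_vivo[in_vivo["group"] == "diabetic"]
        if not diab.empty:
            d0, d6 = diab["day"].min(), diab["day"].max()
            m0 = diab.loc[diab["day"] == d0, "surface_rr"].mean()
            m6 = diab.loc[diab["day"] == d6, "surface_rr"].mean()
            if d6 > d0 and np.isfinite(m0) and m0 != 0:
                out["percent_difference"]["diabetic_surface_rr_drop"] = \
                    st.percent_difference(m0, m6)
    if has_vol:
        vol = table.dropna(subset=["volumetric_rr"])
        d_end = vol["day"].max()
        ctrl = vol[(vol["group"] == "control") & (vol["day"] == d_end)]["volumetric_rr"].mean()
        diab = vol[(vol["group"] == "diabetic") & (vol["day"] == d_end)]["volumetric_rr"].mean()
        if np.isfinite(ctrl) and np.isfinite(diab) and ctrl != 0:
            out["percent_difference"]["volumetric_rr_group_difference_final_day"] = \
                st.percent_difference(ctrl, diab)
    return out


def run_default_cohort(seed: int = 1, frame_shape=(256, 256),
                       include_cryo: bool = True, **param_overrides) -> dict:
    """Simulate the default cohort in memory and analyze it; returns table + stats."""
    params = CohortParams(seed=seed, frame_shape=frame_shape, **param_overrides)
    sim = CohortSimulator(params)
    table = analyze_cohort_in_memory(sim, include_cryo=include_cryo)
    return {"params": params, "simulator": sim, "table": table,
            "stats": cohort_statistics(table)}
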