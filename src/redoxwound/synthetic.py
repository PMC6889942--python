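"""Synthetic cohort generator for the wound redox-imaging pipeline.

Emulates a longitudinal mouse wound-healing experiment: a 10 mm circular
full-thickness dorsal wound imaged at 40 µm/pixel on days 0/2/4/6 with a
14-bit camera in three channels (white light, NADH, FAD), plus 3D cryo-imaged
wound biopsies at the endpoint days.  Every generated dataset carries a
machine-readable ground truth (wound geometry, per-subject redox ratios)
so downstream stages can be validated against a known answer.

The generative model, in brief:

* wound geometry — a filled disk whose radius follows a per-group healing
  schedule (controls close, diabetics do not); the true normalized area is
  the exact lattice pixel-count ratio N(t)/N(0);
* redox trajectories — group/day mean redox ratios (diabetic surface RR
  declining 61% by day 6; diabetic volumetric RR 66% below control at
  day 6) plus a per-subject random effect, an RR–area coupling term
  b·(A − 1), and per-observation noise whose variance is tied to a target
  pooled R² of 0.72 between surface RR and normalized area;
* acquisition physics — per-day per-channel lognormal excitation-lamp
  drift applied identically to tissue and cuvette frames (which is what
  makes cuvette calibration meaningful), a smooth multiplicative flat-field
  pattern on cryo slices, and Poisson–Gaussian camera noise clipped to the
  14-bit range.

By default subject effects and observation noise are re-centred within
their (group, day) cell so that cohort group means equal the configured
trajectories exactly ("exact planting"); set ``center_effects=False`` for
i.i.d. draws, e.g. in statistical calibration studies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import ScheduleError
from .frames import ChannelFrame, CryoStack, MAX_DN

GROUPS = ("control", "diabetic")

_DEF_CONTROL_RADII = {0: 5.0, 2: 4.0, 4: 3.0, 6: 2.2}
_DEF_DIABETIC_RADII = {0: 5.0, 2: 5.0, 4: 5.0, 6: 5.0}
_DEF_RR_CONTROL = {0: 1.2, 2: 1.2, 4: 1.2, 6: 1.2}
_DEF_RR_DIABETIC = {0: 1.2, 2: 0.80, 4: 0.60, 6: 0.468}
# volumetric truth: groups equal at day 0; diabetic 66% below control at day 6
_DEF_VOL_RR = {
    ("control", 0): 1.2,
    ("diabetic", 0): 1.2,
    ("control", 6): 1.2,
    ("diabetic", 6): 0.408,
}

# internal stream tags for independent RNG substreams (all < 2**16)
_STREAM_TRUTH = 101
_STREAM_DAY = 211
_STREAM_SESSION = 307
_STREAM_CRYO = 401


@dataclass
class CohortParams:
    """Stated world of the synthetic experiment.

    The defaults encode the experimental design: n = 6/group imaged in vivo
    on days 0/2/4/6, n = 4/group day-0 biopsies plus n = 6/group day-6
    biopsies, 40 µm pixels, a 5 mm wound radius, and group redox
    trajectories anchored to the reported effect sizes.
    """

    n_per_group: int = 6
    days: Tuple[int, ...] = (0, 2, 4, 6)
    frame_shape: Tuple[int, int] = (256, 256)
    pixel_size_um: float = 40.0
    wound_radius_mm_day0: float = 5.0
    control_radius_schedule: Dict[int, float] = field(
        default_factory=lambda: dict(_DEF_CONTROL_RADII))
    diabetic_radius_schedule: Dict[int, float] = field(
        default_factory=lambda: dict(_DEF_DIABETIC_RADII))
    rr_true: Dict[Tuple[str, int], float] = field(default_factory=dict)
    volumetric_rr_true: Dict[Tuple[str, int], float] = field(
        default_factory=lambda: dict(_DEF_VOL_RR))
    n_biopsy_day0: int = 4
    biopsy_days: Tuple[int, int] = (0, 6)
    # acquisition physics
    lamp_drift_sigma: float = 0.15
    noise_gain: float = 4.0
    read_noise_sd: float = 10.0
    bit_depth: int = 14
    # subject-level variation and RR<->area coupling
    subject_sd: float = 0.03
    coupling_slope_b: Optional[float] = None     # solved if None
    coupling_noise_sd: Optional[float] = None    # closed form if None
    target_r_squared: float = 0.72
    center_effects: bool = True
    equalize_groups: bool = False
    # intensity levels (DN before drift/noise); the instrument paper fixes
    # cuvette solution concentrations but not DN levels
    fad_level_dn: float = 1000.0
    cuvette_level_dn: float = 1000.0
    skin_white_dn: float = 8000.0
    wound_white_dn: float = 3000.0
    skin_nadh_dn: float = 400.0
    skin_fad_dn: float = 500.0
    center_jitter_px: int = 3
    # cryo phantom
    stack_shape: Tuple[int, int, int] = (40, 128, 128)
    voxel_size_um: Tuple[float, float, float] = (50.0, 40.0, 40.0)
    cryo_background_dn: float = 30.0
    cyl_radius_frac: float = 0.35
    cyl_depth_frac: float = 0.6
    flat_falloff: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.bit_depth != 14:
            raise ValueError("bit_depth is fixed at 14 by the camera")
        if not self.rr_true:
            self.rr_true = {("control", d): _DEF_RR_CONTROL[d] for d in (0, 2, 4, 6)}
            self.rr_true.update(
                {("diabetic", d): _DEF_RR_DIABETIC[d] for d in (0, 2, 4, 6)})
        if self.equalize_groups:
            # identical data-generating process in both groups: a true null
            self.diabetic_radius_schedule = dict(self.control_radius_schedule)
            self.rr_true = {
                (g, d): self.rr_true[("control", d)] for g in GROUPS for d in self.days}
        for d in self.days:
            for g in GROUPS:
                if (g, d) not in self.rr_true:
                    raise ValueError(f"rr_true missing ({g}, {d})")
                if self.rr_true[(g, d)] <= 0:
                    raise ValueError("rr_true values must be positive")
            for sched in (self.control_radius_schedule, self.diabetic_radius_schedule):
                if d not in sched:
                    raise ValueError(f"radius schedule missing day {d}")
        for g in GROUPS:
            for d in self.biopsy_days:
                if (g, d) not in self.volumetric_rr_true:
                    raise ValueError(f"volumetric_rr_true missing ({g}, {d})")
        ctrl = [self.control_radius_schedule[d] for d in sorted(self.days)]
        if any(b > a for a, b in zip(ctrl, ctrl[1:])):
            raise ValueError("control radius schedule must be non-increasing")
        half_extent_mm = min(self.frame_shape) / 2 * self.pixel_size_um / 1000.0
        for sched in (self.control_radius_schedule, self.diabetic_radius_schedule):
            for r in sched.values():
                if not 0 < r:
                    raise ValueError("radii must be positive")
                if r * self.geometry_scale > half_extent_mm:
                    raise ValueError("scheduled radius exceeds frame half-extent")
        if self.lamp_drift_sigma < 0 or self.noise_gain < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if not 0 <= self.seed < 2**31:
            raise ValueError("seed must be in [0, 2**31)")

    # ---- geometry -------------------------------------------------------
    @property
    def geometry_scale(self) -> float:
        """Shrink factor applied to wound radii so the disk fits the frame.

        Full-scale geometry (5 mm -> 125 px at 40 µm) needs ~512² frames;
        smaller frames use power-of-two reduced geometry, flagged in truth.
        """
        r0_px = self.wound_radius_mm_day0 * 1000.0 / self.pixel_size_um
        s = 1.0
        while r0_px * s > 0.45 * min(self.frame_shape):
            s /= 2.0
            if s < 1 / 64:
                raise ValueError("frame too small for any usable geometry")
        return s

    def radius_px(self, group: str, day: int) -> float:
        sched = (self.control_radius_schedule if group == "control"
                 else self.diabetic_radius_schedule)
        return sched[day] * 1000.0 / self.pixel_size_um * self.geometry_scale

    @property
    def noise_enabled(self) -> bool:
        return self.noise_gain > 0 or self.read_noise_sd > 0

    def subjects(self, group: str) -> List[str]:
        tag = "C" if group == "control" else "D"
        return [f"{tag}{i + 1:02d}" for i in range(self.n_per_group)]

    def biopsy_day0_subjects(self, group: str) -> List[str]:
        tag = "C" if group == "control" else "D"
        return [f"{tag}0B{i + 1}" for i in range(self.n_biopsy_day0)]


# ---- geometry primitives -------------------------------------------------

def disk_mask(shape: Tuple[int, int], center: Tuple[int, int], radius_px: float) -> np.ndarray:
    """Boolean filled disk: pixels whose centre is within ``radius_px``."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def disk_pixel_count(radius_px: float) -> int:
    """Exact lattice count of a filled disk at an integer-pixel centre."""
    n = int(np.ceil(radius_px)) + 1
    rr, cc = np.ogrid[-n : n + 1, -n : n + 1]
    return int((rr**2 + cc**2 <= radius_px**2).sum())


def cryo_phantom_mask(params: CohortParams) -> np.ndarray:
    """Cylinder-plus-spherical-cap wound phantom inside the tissue block."""
    nz, ny, nx = params.stack_shape
    rc = params.cyl_radius_frac * min(ny, nx)
    z0 = int(round(params.cyl_depth_frac * nz))
    cy, cx = ny // 2, nx // 2
    z, y, x = np.ogrid[:nz, :ny, :nx]
    r2 = (y - cy) ** 2 + (x - cx) ** 2
    # cap curvature expressed in voxel units via the z anisotropy
    z_aspect = params.voxel_size_um[0] / params.voxel_size_um[1]
    cyl = (z < z0) & (r2 <= rc**2)
    cap = (z >= z0) & (r2 + ((z - z0) * z_aspect) ** 2 <= rc**2)
    return cyl | cap


def flat_field_pattern(shape: Tuple[int, int], falloff: float) -> np.ndarray:
    """Smooth radial illumination pattern, 1 at centre, 1-falloff at the corner."""
    ny, nx = shape
    y, x = np.mgrid[:ny, :nx]
    cy, cx = (ny - 1) / 2, (nx - 1) / 2
    d2 = ((y - cy) / cy) ** 2 + ((x - cx) / cx) ** 2
    return 1.0 - falloff * d2 / 2.0


# ---- RR<->area coupling calibration --------------------------------------

def schedule_areas(params: CohortParams) -> Dict[Tuple[str, int], float]:
    """Analytic normalized areas (r_d / r_0)² per group and day."""
    out = {}
    for g in GROUPS:
        sched = (params.control_radius_schedule if g == "control"
                 else params.diabetic_radius_schedule)
        r0 = sched[min(params.days)]
        for d in params.days:
            out[(g, d)] = (sched[d] / r0) ** 2
    return out


def solve_area_coupling(params: CohortParams) -> Tuple[float, float]:
    """Solve the coupling slope b (< 0) and noise sd from the stated world.

    The observation-noise variance is tied to b by the closed form
    sigma² = b²·Var(A)·(1 − R²)/R² at the target R²; b is then the root at
    which the expected pooled regression R² of true surface RR on true
    normalized area equals the target, accounting for the planted group
    trajectories (which are themselves correlated with area) and the
    subject random effect.
    """
    if params.coupling_slope_b is not None and params.coupling_noise_sd is not None:
        return params.coupling_slope_b, params.coupling_noise_sd
    areas = schedule_areas(params)
    A = np.array([areas[(g, d)] for g in GROUPS for d in params.days])
    mu = np.array([params.rr_true[(g, d)] for g in GROUPS for d in params.days])
    V = A.var()
    rho = params.target_r_squared
    # centring removes 1/n of the within-cell variance from the pooled sample
    c = (params.n_per_group - 1) / params.n_per_group if params.center_effects else 1.0
    if V == 0:
        return 0.0, 0.0

    def sigma_eps(b: float) -> float:
        return abs(b) * np.sqrt(V * (1 - rho) / rho)

    def expected_r2(b: float) -> float:
        m = mu + b * (A - 1.0)
        cov = np.mean((A - A.mean()) * (m - m.mean()))
        var_rr = m.var() + c * (params.subject_sd**2 + sigma_eps(b) ** 2)
        return cov**2 / (V * var_rr)

    if params.coupling_slope_b is not None:
        b = params.coupling_slope_b
    else:
        lo, hi = -8.0, -1e-6
        if expected_r2(lo) < rho or expected_r2(hi) > rho:
            # target unreachable for this world; fall back to the flattest
            # slope maximising R² (documented behaviour for custom worlds)
            bs = np.linspace(lo, hi, 4001)
            b = float(bs[np.argmax([expected_r2(x) for x in bs])])
        else:
            b = float(brentq(lambda x: expected_r2(x) - rho, lo, hi, xtol=1e-12))
    se = params.coupling_noise_sd if params.coupling_noise_sd is not None else sigma_eps(b)
    return b, float(se)


# ---- ground truth ---------------------------------------------------------

@dataclass
class GroundTruth:
    """Machine-readable sidecar of planted truth for one cohort."""

    geometry_scale: float
    pixel_size_um: float
    frame_shape: Tuple[int, int]
    groups: Dict[str, str]                       # subject -> group
    in_vivo: Dict[str, Dict[int, dict]]          # subject -> day -> record
    cryo: Dict[str, Dict[int, dict]]             # subject -> day -> record
    coupling_slope_b: float
    coupling_noise_sd: float

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["in_vivo"] = {
            s: {str(d): rec for d, rec in days.items()} for s, days in self.in_vivo.items()}
        payload["cryo"] = {
            s: {str(d): rec for d, rec in days.items()} for s, days in self.cryo.items()}
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        payload["in_vivo"] = {
            s: {int(d): rec for d, rec in days.items()}
            for s, days in payload["in_vivo"].items()}
        payload["cryo"] = {
            s: {int(d): rec for d, rec in days.items()}
            for s, days in payload["cryo"].items()}
        payload["frame_shape"] = tuple(payload["frame_shape"])
        return cls(**payload)

    def surface_table(self) -> pd.DataFrame:
        rows = []
        for subj, days in self.in_vivo.items():
            for day, rec in sorted(days.items()):
                rows.append({
                    "subject": subj, "group": self.groups[subj], "day": day,
                    "surface_rr": rec["true_surface_rr"],
                    "normalized_area": rec["true_normalized_area"],
                })
        return pd.DataFrame(rows)

    def volumetric_table(self) -> pd.DataFrame:
        rows = []
        for subj, days in self.cryo.items():
            for day, rec in sorted(days.items()):
                rows.append({
                    "subject": subj, "group": self.groups[subj], "day": day,
                    "volumetric_rr": rec["true_volumetric_rr"],
                    "n_voxels": rec["n_voxels"],
                })
        return pd.DataFrame(rows)


def _centered_normal(rng, sd, shape, center: bool) -> np.ndarray:
    x = rng.normal(0.0, sd, shape) if sd > 0 else np.zeros(shape)
    if center and x.ndim and x.shape[0] > 1:
        x = x - x.mean(axis=0, keepdims=True)
    return x


def generate_truth(params: CohortParams) -> GroundTruth:
    """Plant per-subject ground truth for a whole cohort (no images)."""
    rng = np.random.default_rng([params.seed, _STREAM_TRUTH])
    b, sigma_eps = solve_area_coupling(params)
    day0 = min(params.days)
    rr_floor = 0.02

    groups: Dict[str, str] = {}
    in_vivo: Dict[str, Dict[int, dict]] = {}
    cryo: Dict[str, Dict[int, dict]] = {}

    n_vox = int(cryo_phantom_mask(params).sum())
    jit = params.center_jitter_px
    c0 = (params.frame_shape[0] // 2, params.frame_shape[1] // 2)

    for g in GROUPS:
        subs = params.subjects(g)
        for s in subs:
            groups[s] = g
        counts = {d: disk_pixel_count(params.radius_px(g, d)) for d in params.days}
        areas = {d: counts[d] / counts[day0] for d in params.days}
        u = _centered_normal(rng, params.subject_sd, (len(subs),), params.center_effects)
        for di, d in enumerate(sorted(params.days)):
            mean_rr = params.rr_true[(g, d)] + b * (areas[d] - 1.0)
            # redraw the cell if any planted RR would be non-positive
            for _ in range(1000):
                eps = _centered_normal(
                    rng, sigma_eps, (len(subs),), params.center_effects)
                rr = mean_rr + u + eps
                if np.all(rr > rr_floor):
                    break
            else:
                raise RuntimeError("could not plant positive redox ratios")
            jitters = rng.integers(-jit, jit + 1, size=(len(subs), 2))
            for si, s in enumerate(subs):
                in_vivo.setdefault(s, {})[d] = {
                    "center": [int(c0[0] + jitters[si, 0]), int(c0[1] + jitters[si, 1])],
                    "radius_px": params.radius_px(g, d),
                    "n_pixels": counts[d],
                    "true_surface_rr": float(rr[si]),
                    "true_normalized_area": float(areas[d]),
                }
        # cryo biopsies: separate mice at day 0, the in-vivo mice at day 6
        d0, d_end = params.biopsy_days
        for day, subjects in ((d0, params.biopsy_day0_subjects(g)), (d_end, subs)):
            for s in subjects:
                groups.setdefault(s, g)
            vol_mu = params.volumetric_rr_true[(g, day)]
            w = _centered_normal(
                rng, params.subject_sd, (len(subjects),), params.center_effects)
            for si, s in enumerate(subjects):
                cryo.setdefault(s, {})[day] = {
                    "n_voxels": n_vox,
                    "true_volumetric_rr": float(max(vol_mu + w[si], rr_floor)),
                }

    return GroundTruth(
        geometry_scale=params.geometry_scale,
        pixel_size_um=params.pixel_size_um,
        frame_shape=tuple(params.frame_shape),
        groups=groups, in_vivo=in_vivo, cryo=cryo,
        coupling_slope_b=b, coupling_noise_sd=sigma_eps,
    )


def simulate_truth_table(params: CohortParams) -> pd.DataFrame:
    """Fast path: the cohort's true marker table without rendering images."""
    return generate_truth(params).surface_table()


# ---- image rendering ------------------------------------------------------

def _apply_camera_noise(mean: np.ndarray, params: CohortParams, rng) -> np.ndarray:
    """Standard CCD model: scaled Poisson shot noise plus Gaussian read noise."""
    if not params.noise_enabled:
        return mean
    x = mean.astype(np.float64)
    if params.noise_gain > 0:
        x = rng.poisson(x / params.noise_gain).astype(np.float64) * params.noise_gain
    if params.read_noise_sd > 0:
        x = x + rng.normal(0.0, params.read_noise_sd, x.shape)
    return np.clip(np.rint(x), 0, MAX_DN)


class CohortSimulator:
    """Renders sessions, cuvettes and cryo stacks for one planted cohort."""

    def __init__(self, params: CohortParams, truth: Optional[GroundTruth] = None):
        self.params = params
        self.truth = truth if truth is not None else generate_truth(params)
        self._subject_index = {
            s: i for i, s in enumerate(sorted(self.truth.groups))}

    # drift factors are a property of the acquisition day, shared by all
    # subjects imaged that day and by the day's cuvette frames
    def drift_factors(self, day: int) -> Dict[str, float]:
        p = self.params
        if p.lamp_drift_sigma <= 0:
            return {c: 1.0 for c in ("WHITE", "NADH", "FAD")}
        rng = np.random.default_rng([p.seed, _STREAM_DAY, day])
        return {c: float(rng.lognormal(0.0, p.lamp_drift_sigma))
                for c in ("WHITE", "NADH", "FAD")}

    def cuvette_frames(self, day: int) -> Dict[str, ChannelFrame]:
        p = self.params
        drift = self.drift_factors(day)
        rng = np.random.default_rng([p.seed, _STREAM_DAY, day, 1])
        out = {}
        for ch in ("NADH", "FAD"):
            mean = np.full(p.frame_shape, p.cuvette_level_dn * drift[ch])
            pix = _apply_camera_noise(mean, p, rng)
            out[ch] = ChannelFrame(pix, ch, p.pixel_size_um, subject="-", day=day)
        return out

    def session(self, subject: str, day: int):
        """Render one in-vivo imaging session (white + NADH + FAD + cuvettes)."""
        p = self.params
        if subject not in self.truth.in_vivo:
            raise ScheduleError(f"subject {subject!r} has no in-vivo sessions")
        if day not in self.truth.in_vivo[subject]:
            raise ScheduleError(
                f"day {day} not in the imaging schedule for {subject!r}")
        rec = self.truth.in_vivo[subject][day]
        group = self.truth.groups[subject]
        drift = self.drift_factors(day)
        rng = np.random.default_rng(
            [p.seed, _STREAM_SESSION, self._subject_index[subject], day])

        wound = disk_mask(p.frame_shape, tuple(rec["center"]), rec["radius_px"])
        rr = rec["true_surface_rr"]

        white_mean = np.where(wound, p.wound_white_dn, p.skin_white_dn) * drift["WHITE"]
        nadh_mean = np.where(wound, p.fad_level_dn * rr, p.skin_nadh_dn) * drift["NADH"]
        fad_mean = np.where(wound, p.fad_level_dn, p.skin_fad_dn) * drift["FAD"]

        meta = dict(subject=subject, group=group, day=day)
        frames = {}
        for ch, mean in (("WHITE", white_mean), ("NADH", nadh_mean), ("FAD", fad_mean)):
            pix = _apply_camera_noise(np.minimum(mean, MAX_DN), p, rng)
            frames[ch] = ChannelFrame(pix, ch, p.pixel_size_um, **meta)
        return frames["WHITE"], frames["NADH"], frames["FAD"], self.cuvette_frames(day), rec

    def cryo_stack(self, subject: str, day: int):
        """Render one biopsy's NADH/FAD cryo volumes plus flat-field frames."""
        p = self.params
        if day not in p.biopsy_days:
            raise ScheduleError(
                f"biopsies exist only at days {p.biopsy_days}, not day {day}")
        if subject not in self.truth.cryo or day not in self.truth.cryo[subject]:
            raise ScheduleError(f"no biopsy planted for {subject!r} at day {day}")
        rec = self.truth.cryo[subject][day]
        group = self.truth.groups[subject]
        rng = np.random.default_rng(
            [p.seed, _STREAM_CRYO, self._subject_index[subject], day])

        phantom = cryo_phantom_mask(p)
        flat = flat_field_pattern(p.stack_shape[1:], p.flat_falloff)
        rr = rec["true_volumetric_rr"]
        nadh_mean = np.where(phantom, p.fad_level_dn * rr, p.cryo_background_dn) * flat
        fad_mean = np.where(phantom, p.fad_level_dn, p.cryo_background_dn) * flat

        meta = dict(subject=subject, group=group, day=day)
        # flat frames are emitted as an averaged, effectively noise-free
        # reference (labs average many flat exposures); tissue slices carry
        # the full camera-noise model
        flat_dn = flat * p.cuvette_level_dn
        stacks = {}
        for ch, mean in (("NADH", nadh_mean), ("FAD", fad_mean)):
            vox = _apply_camera_noise(np.minimum(mean, MAX_DN), p, rng)
            stacks[ch] = CryoStack(vox, ch, p.voxel_size_um, flat_dn, **meta)
        flats = {"NADH": flat_dn, "FAD": flat_dn.copy()}
        return stacks["NADH"], stacks["FAD"], flats, rec

    # ---- on-disk dataset ------------------------------------------------
    def write_cohort(self, outdir) -> Path:
        """Write frames, stacks, manifest CSV and truth JSON; return manifest path."""
        from . import io_calibration as io

        p = self.params
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rows = []

        for day in sorted(p.days):
            cuv = self.cuvette_frames(day)
            for ch, frame in cuv.items():
                rel = f"cuvettes/day{day}_{ch.lower()}.tif"
                io.write_tiff(outdir / rel, frame.pixels)
                rows.append(("-", "-", day, ch, "cuvette", rel))

        for g in GROUPS:
            for subject in params_subjects(p, g):
                for day in sorted(p.days):
                    white, nadh, fad, _, _ = self.session(subject, day)
                    base = f"invivo/{subject}/day{day}"
                    for ch, frame in (("WHITE", white), ("NADH", nadh), ("FAD", fad)):
                        rel = f"{base}/{ch.lower()}.tif"
                        io.write_tiff(outdir / rel, frame.pixels)
                        rows.append((subject, g, day, ch, "frame", rel))

        for subject, days in sorted(self.truth.cryo.items()):
            g = self.truth.groups[subject]
            for day in sorted(days):
                nadh_vol, fad_vol, flats, _ = self.cryo_stack(subject, day)
                base = f"cryo/{subject}/day{day}"
                for ch, stack in (("NADH", nadh_vol), ("FAD", fad_vol)):
                    rel = f"{base}/{ch.lower()}_stack.tif"
                    io.write_tiff(outdir / rel, stack.voxels)
                    rows.append((subject, g, day, ch, "stack", rel))
                    rel_f = f"{base}/{ch.lower()}_flat.tif"
                    io.write_tiff(outdir / rel_f, flats[ch])
                    rows.append((subject, g, day, ch, "flat", rel_f))

        manifest = pd.DataFrame(
            rows, columns=["subject", "group", "day", "channel", "kind", "path"])
        manifest_path = outdir / "manifest.csv"
        manifest.to_csv(manifest_path, index=False)
        self.truth.to_json(outdir / "truth.json")
        return manifest_path


def params_subjects(params: CohortParams, group: str) -> List[str]:
    return params.subjects(group)


# ---- functional wrappers (module-level API) -------------------------------

def simulate_session(params: CohortParams, subject: str, day: int):
    """One in-vivo session: (white, nadh, fad, cuvette frames, truth slice)."""
    return CohortSimulator(params).session(subject, day)


def simulate_cryo_stack(params: CohortParams, subject: str, day: int):
    """One biopsy: (nadh stack, fad stack, flat frames, truth slice)."""
    return CohortSimulator(params).cryo_stack(subject, day)


def simulate_cohort(params: CohortParams, outdir) -> Path:
    """Write a full cohort dataset to disk; returns the manifest path."""
    return CohortSimulator(params).write_cohort(outdir)
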