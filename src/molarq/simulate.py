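"""Seeded synthetic multi-rater landmark cohorts.

The study data (423 panoramic radiographs, two raters, one rater reading
twice) are not publicly deposited, so this module generates landmark
datasets with the same statistical structure, letting the whole analysis
pipeline run end to end and letting its operating characteristics be
checked against known ground truth.

Generative model, per subject and side:

* Eruption is a latent logistic trajectory.  With per-subject, per-side
  midpoint t0 (Gaussian across subjects, correlated between the left and
  right side of one subject) and slope beta, the eruption fraction at age a
  is s = 1 / (1 + exp(-beta * (a - t0))).
* The second molar CEJ sits a fixed per-tooth distance d_m2 below the
  occlusal plane (Gaussian across teeth); the third molar CEJ starts an
  additional ``initial_depth`` below and is carried up linearly with s:
  d_m3 = d_m2 + (1 - s) * initial_depth.  The true quotient d_m2/d_m3 thus
  rises from roughly d_m2/(d_m2 + depth) toward 1 as the tooth erupts.
* Landmarks are laid out on a canonical millimetre template in which the
  occlusal plane is the x-axis, so the perpendicular distances of the CEJ
  points equal d_m2 and d_m3 by construction.
* Rendering to an image applies, per radiograph, one random occlusal tilt
  (rotation), one magnification factor and one translation — shared by all
  raters and sessions, who read the same image — followed by independent
  Gaussian pixel jitter per rater x session on every landmark.
* Third molar angulation is drawn per side (half-normal magnitude; distal
  with probability ``p_distal``) so the eligibility filter has real work.

Rater 1 contributes sessions 1 and 2 (repeatability); every further rater
contributes session 1 only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmarks import CohortTable, Landmark, RadiographRecord, table1_cohort

__all__ = [
    "SimulatorParams",
    "sample_subjects",
    "true_geometry",
    "render_observations",
    "simulate_cohort",
]

# canonical template (millimetres, occlusal plane = x axis, apical = +y),
# laid out for side 48 where mesial is increasing x; side 38 mirrors x.
_TEMPLATE_X = {
    "M1_MESIAL_CUSP": 21.0,   # most mesial anchor
    "M2_DISTAL_CUSP": 0.0,
    "M2_MESIAL_CEJ": 9.0,
    "M3_MESIAL_CEJ": -2.0,    # distal to the anchor segment, as on real DPRs
}
_M2_AXIS_X = 4.0
_M3_AXIS_X = -7.0
_AXIS_CORONAL_Y = 1.0
_AXIS_APICAL_Y = 15.0


@dataclass(frozen=True)
class SimulatorParams:
    """Full generative-model parameterisation of a synthetic cohort.

    Defaults emulate the study design: the packaged age-by-sex cohort
    (423 series), eruption centred at 19.5 y with population spread 2.5 y,
    ~0.1 mm/px detector pitch with ~1.25x panoramic magnification, and
    1.5 px landmark placement noise per rater and session.
    """

    cohort: CohortTable = field(default_factory=table1_cohort)
    eruption_midpoint_mean: dict = field(
        default_factory=lambda: {"female": 19.5, "male": 19.5})
    eruption_midpoint_sd: float = 2.5
    eruption_slope: float = 0.8          # 1/years
    d_m2_mean: float = 4.5               # mm
    d_m2_sd: float = 0.6
    initial_depth_mean: float = 12.0     # mm, unerupted M3 CEJ below M2 CEJ
    initial_depth_sd: float = 2.0
    side_correlation: float = 0.8        # of t0 between sides 38 and 48
    magnification_mean: float = 1.25
    magnification_sd: float = 0.05
    occlusal_tilt_sd: float = 4.0        # degrees
    landmark_noise_sd: float = 1.5       # px, per rater x session
    mm_per_px_true: float = 0.1          # detector pixel pitch, mm
    mesial_angle_sd: float = 8.0         # degrees (half-normal magnitude)
    p_distal: float = 0.05
    raters: tuple = ("R1", "R2")
    sessions_for_rater_1: int = 2
    emit_mm_per_px: bool = True

    def __post_init__(self) -> None:
        for name in ("eruption_midpoint_sd", "d_m2_sd", "initial_depth_sd",
                     "magnification_sd", "occlusal_tilt_sd",
                     "landmark_noise_sd", "mesial_angle_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.side_correlation <= 1.0:
            raise ValueError("side_correlation must be in [0, 1]")
        if not 0.0 <= self.p_distal <= 1.0:
            raise ValueError("p_distal must be in [0, 1]")
        if self.mm_per_px_true <= 0:
            raise ValueError("mm_per_px_true must be positive")
        if len(self.raters) < 1:
            raise ValueError("need at least one rater")


def sample_subjects(params: SimulatorParams, seed: int) -> list[tuple[str, float, str]]:
    """Draw (subject_id, exact age, sex) for every cohort cell.

    Each cell (age year x sex) contributes exactly its cohort count; exact
    ages are uniform within [year, year + 1).  Deterministic given seed.
    """
    rng = np.random.default_rng(seed)
    subjects: list[tuple[str, float, str]] = []
    i = 0
    for sex in ("female", "male"):
        for year in CohortTable.AGES:
            for _ in range(params.cohort.cell(year, sex)):
                age = year + float(rng.uniform())
                subjects.append((f"S{i:04d}", age, sex))
                i += 1
    return subjects


@dataclass(frozen=True)
class TrueGeometry:
    """Latent state and noiseless canonical landmarks for one subject-side."""

    subject_id: str
    age: float
    sex: str
    side: int
    s: float                   # latent eruption fraction in (0, 1)
    d_m2: float                # mm, true perpendicular distance
    d_m3: float
    quotient: float            # d_m2 / d_m3
    angulation: float          # signed degrees, mesial positive
    landmarks_mm: dict         # label -> (x, y) on the canonical template


def _template_landmarks(side: int, d_m2: float, d_m3: float,
                        angulation_deg: float) -> dict[str, tuple[float, float]]:
    """Place the eight landmarks on the canonical template for one side."""
    mirror = -1.0 if side == 38 else 1.0  # side 38 mirrors the 48 layout
    pts: dict[str, tuple[float, float]] = {}
    for lbl, x in _TEMPLATE_X.items():
        y = {"M2_MESIAL_CEJ": d_m2, "M3_MESIAL_CEJ": d_m3}.get(lbl, 0.0)
        pts[lbl] = (mirror * x, y)
    pts["M2_AXIS_CORONAL"] = (mirror * _M2_AXIS_X, _AXIS_CORONAL_Y)
    pts["M2_AXIS_APICAL"] = (mirror * _M2_AXIS_X, _AXIS_APICAL_Y)
    # M3 axis: rotate the crown about the apical point, mesially for
    # positive angles.  On the template, mesial is +x for 48; the mirror
    # then maps it to -x for 38, matching the standard image orientation.
    theta = math.radians(angulation_deg)
    apical = (mirror * _M3_AXIS_X, _AXIS_APICAL_Y)
    length = _AXIS_APICAL_Y - _AXIS_CORONAL_Y
    pts["M3_AXIS_APICAL"] = apical
    pts["M3_AXIS_CORONAL"] = (
        apical[0] + mirror * length * math.sin(theta),
        apical[1] - length * math.cos(theta),
    )
    return pts


def true_geometry(subjects: list[tuple[str, float, str]],
                  params: SimulatorParams, seed: int) -> list[TrueGeometry]:
    """Draw latent eruption state and noiseless landmarks for every subject-side.

    The per-side eruption midpoints t0 of one subject are bivariate normal
    with correlation ``side_correlation``; tooth-level depths and
    angulations are independent across sides.
    """
    rng = np.random.default_rng(seed)
    rho = params.side_correlation
    cov = np.array([[1.0, rho], [rho, 1.0]]) * params.eruption_midpoint_sd ** 2
    chol = np.linalg.cholesky(cov) if params.eruption_midpoint_sd > 0 else np.zeros((2, 2))
    out: list[TrueGeometry] = []
    for subject_id, age, sex in subjects:
        mu = params.eruption_midpoint_mean[sex]
        t0_pair = mu + chol @ rng.standard_normal(2)
        for side, t0 in zip((38, 48), t0_pair):
            x = params.eruption_slope * (age - t0)
            # overflow-safe logistic
            s = 1.0 / (1.0 + math.exp(-x)) if x >= 0 else math.exp(x) / (1.0 + math.exp(x))
            d_m2 = max(1.0, rng.normal(params.d_m2_mean, params.d_m2_sd))
            depth = max(0.0, rng.normal(params.initial_depth_mean,
                                        params.initial_depth_sd))
            d_m3 = d_m2 + (1.0 - s) * depth
            magnitude = abs(rng.normal(0.0, params.mesial_angle_sd))
            sign = -1.0 if rng.uniform() < params.p_distal else 1.0
            ang = sign * magnitude
            out.append(TrueGeometry(
                subject_id=subject_id, age=age, sex=sex, side=side,
                s=s, d_m2=d_m2, d_m3=d_m3, quotient=d_m2 / d_m3,
                angulation=ang,
                landmarks_mm=_template_landmarks(side, d_m2, d_m3, ang),
            ))
    return out


def render_observations(truths: list[TrueGeometry], params: SimulatorParams,
                        seed: int) -> list[RadiographRecord]:
    """Project canonical landmarks into image pixels and add rater noise.

    One tilt, magnification and offset per radiograph (all raters read the
    same image); iid Gaussian jitter per rater x session on every landmark.
    When ``emit_mm_per_px`` is set, the records carry the calibration
    mm_per_px_true / magnification that maps pixels back to anatomical
    millimetres.
    """
    rng = np.random.default_rng(seed)
    records: list[RadiographRecord] = []
    for truth in truths:
        tilt = math.radians(rng.normal(0.0, params.occlusal_tilt_sd))
        mag = max(0.5, rng.normal(params.magnification_mean,
                                  params.magnification_sd))
        offset = rng.uniform(200.0, 2000.0, size=2)
        scale = mag / params.mm_per_px_true  # px per anatomical mm
        cos_t, sin_t = math.cos(tilt), math.sin(tilt)
        projected = {}
        for lbl, (x, y) in truth.landmarks_mm.items():
            xr = cos_t * x - sin_t * y
            yr = sin_t * x + cos_t * y
            projected[lbl] = (xr * scale + offset[0], yr * scale + offset[1])
        mm_per_px = params.mm_per_px_true / mag if params.emit_mm_per_px else None

        observer_sessions = []
        for r, rater in enumerate(params.raters):
            n_sessions = params.sessions_for_rater_1 if r == 0 else 1
            for sess in range(1, n_sessions + 1):
                observer_sessions.append((rater, sess))
        for rater, sess in observer_sessions:
            noise = rng.normal(0.0, params.landmark_noise_sd,
                               size=(len(projected), 2))
            landmarks = {}
            for (lbl, (px, py)), (nx, ny) in zip(projected.items(), noise):
                landmarks[lbl] = Landmark(label=lbl, x=px + nx, y=py + ny)
            records.append(RadiographRecord(
                subject_id=truth.subject_id, age=truth.age, sex=truth.sex,
                side=truth.side, rater_id=rater, session=sess,
                landmarks=landmarks, mm_per_px=mm_per_px,
            ))
    return records


def simulate_cohort(params: SimulatorParams | None = None, seed: int = 0,
                    ) -> tuple[list[RadiographRecord], pd.DataFrame]:
    """Generate a full synthetic multi-rater cohort.

    Returns the annotation records and a ground-truth table (one row per
    subject-side) with the latent eruption fraction, true distances, true
    quotient and true angulation, for parameter-recovery checks.
    Deterministic given (params, seed).
    """
    params = params or SimulatorParams()
    # independent streams per stage, all derived from the one seed
    ss = np.random.SeedSequence(seed)
    s_subj, s_geom, s_render = (int(c.generate_state(1)[0] % (2 ** 31))
                                for c in ss.spawn(3))
    subjects = sample_subjects(params, s_subj)
    truths = true_geometry(subjects, params, s_geom)
    records = render_observations(truths, params, s_render)
    truth_df = pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in truths],
            "age": [t.age for t in truths],
            "sex": [t.sex for t in truths],
            "side": [t.side for t in truths],
            "eruption_fraction": [t.s for t in truths],
            "d_m2_true_mm": [t.d_m2 for t in truths],
            "d_m3_true_mm": [t.d_m3 for t in truths],
            "quotient_true": [t.quotient for t in truths],
            "angulation_true_deg": [t.angulation for t in truths],
        }
    )
    return records, truth_df
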