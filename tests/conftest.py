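import math

import numpy as np
import pytest

from molarq.landmarks import Landmark, RadiographRecord


def make_record(points: dict[str, tuple[float, float]], *,
                subject_id: str = "S1", age: float = 20.0, sex: str = "male",
                side: int = 38, rater_id: str = "R1", session: int = 1,
                mm_per_px: float | None = None) -> RadiographRecord:
    """Build a record from a label -> (x, y) mapping."""
    return RadiographRecord(
        subject_id=subject_id, age=age, sex=sex, side=side,
        rater_id=rater_id, session=session,
        landmarks={lbl: Landmark(label=lbl, x=float(x), y=float(y))
                   for lbl, (x, y) in points.items()},
        mm_per_px=mm_per_px,
    )


@pytest.fixture
def simple_points() -> dict[str, tuple[float, float]]:
    """Horizontal occlusal plane; CEJ distances 4 px (M2) and 16 px (M3)."""
    return {
        "M1_MESIAL_CUSP": (0.0, 0.0),
        "M2_DISTAL_CUSP": (100.0, 0.0),
        "M2_MESIAL_CEJ": (50.0, 4.0),
        "M3_MESIAL_CEJ": (120.0, 16.0),
    }


@pytest.fixture
def simple_record(simple_points) -> RadiographRecord:
    return make_record(simple_points)


def transform_points(points, *, angle_deg: float = 0.0, scale: float = 1.0,
                     dx: float = 0.0, dy: float = 0.0, mirror_x: bool = False):
    """Apply mirror -> rotation -> scaling -> translation to every point."""
    theta = math.radians(angle_deg)
    c, s = math.cos(theta), math.sin(theta)
    out = {}
    for lbl, (x, y) in points.items():
        if mirror_x:
            x = -x
        xr = scale * (c * x - s * y) + dx
        yr = scale * (s * x + c * y) + dy
        out[lbl] = (xr, yr)
    return out


def alpha_enumeration_oracle(values: np.ndarray, metric: str = "interval") -> float:
    """Krippendorff's alpha by literal enumeration of every ordered pair.

    Independent of the package implementation: loops over units and over
    ordered pairs of pairable values, accumulating observed and expected
    squared differences term by term.
    """
    rows = []
    for row in np.asarray(values, dtype=float):
        vals = [v for v in row if not math.isnan(v)]
        if len(vals) >= 2:
            rows.append(vals)
    pooled = [v for row in rows for v in row]
    n = len(pooled)
    if n < 2 or len(rows) < 2:
        raise ValueError("not enough pairable values")

    def delta2(c, k):
        if metric == "interval":
            return (c - k) ** 2
        if metric == "ratio":
            return ((c - k) / (c + k)) ** 2
        raise ValueError(metric)

    d_o = 0.0
    for row in rows:
        m_u = len(row)
        unit_sum = 0.0
        for i in range(m_u):
            for j in range(m_u):
                if i != j:
                    unit_sum += delta2(row[i], row[j])
        d_o += unit_sum / (m_u - 1)
    d_o /= n

    d_e = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                d_e += delta2(pooled[i], pooled[j])
    d_e /= n * (n - 1)
    if d_e == 0.0:
        raise ValueError("zero expected disagreement")
    return 1.0 - d_o / d_e
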