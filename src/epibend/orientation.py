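"""Cell-division orientation angles in a local tissue frame.

Each division event carries the 3D positions of the two daughter nuclei
(3 h after mitosis), the mother cell's luminal and basal edge points, and the
local apex-base direction of the layer. The event is transformed into a local
right-handed frame O′ with origin at the daughters' midpoint:

* x′ — apex-base axis (supplied direction, orthonormalized against y′),
* y′ — luminal→basal axis (surface normal of the layer),
* z′ — roof-floor axis, z′ = x′ × y′.

The daughter-separation direction u is axial (a division has no intrinsic
direction), so the two angles are

* φ — elevation of u from the surface plane x′–z′, in [0°, 90°]; φ = 0 means
  the division is parallel to the luminal surface,
* θ — azimuth of u's projection in the x′–z′ plane measured from x′, folded
  to [0°, 180°); θ = 0 means division along the apex-base axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DivisionEvent",
    "LocalFrame",
    "OrientationAngles",
    "build_local_frame",
    "division_angles",
    "angles_for_events",
    "read_events_csv",
    "write_events_csv",
    "write_angles_csv",
]

_EPS = 1e-12


@dataclass
class DivisionEvent:
    daughter1: np.ndarray  # (3,) µm
    daughter2: np.ndarray  # (3,) µm
    mother_luminal: np.ndarray  # (3,) µm
    mother_basal: np.ndarray  # (3,) µm
    apex_base_direction: np.ndarray  # (3,) unit-ish vector, local layer tangent
    label: str = ""

    def __post_init__(self) -> None:
        for name in (
            "daughter1",
            "daughter2",
            "mother_luminal",
            "mother_basal",
            "apex_base_direction",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.linalg.norm(self.daughter1 - self.daughter2) < _EPS:
            raise ValueError(f"daughter positions coincide (event {self.label!r})")
        lb = self.mother_basal - self.mother_luminal
        if np.linalg.norm(lb) < _EPS:
            raise ValueError(f"mother edge points coincide (event {self.label!r})")
        y = lb / np.linalg.norm(lb)
        x = self.apex_base_direction
        if np.linalg.norm(x) < _EPS:
            raise ValueError(f"apex-base direction is zero (event {self.label!r})")
        x = x / np.linalg.norm(x)
        if np.linalg.norm(np.cross(x, y)) < 1e-8:
            raise ValueError(
                f"apex-base direction is parallel to the luminal-basal axis "
                f"(event {self.label!r})"
            )


@dataclass
class LocalFrame:
    origin: np.ndarray
    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray

    def __post_init__(self) -> None:
        for a, b in (("x_axis", "y_axis"), ("y_axis", "z_axis"), ("x_axis", "z_axis")):
            if abs(np.dot(getattr(self, a), getattr(self, b))) > 1e-8:
                raise ValueError(f"{a} and {b} are not orthogonal")
        if np.dot(np.cross(self.x_axis, self.y_axis), self.z_axis) < 0:
            raise ValueError("frame is not right-handed with z = x × y")

    def to_local(self, point: np.ndarray) -> np.ndarray:
        d = np.asarray(point, dtype=float) - self.origin
        return np.array(
            [np.dot(d, self.x_axis), np.dot(d, self.y_axis), np.dot(d, self.z_axis)]
        )


@dataclass
class OrientationAngles:
    phi: float  # degrees in [0, 90]
    theta: float  # degrees in [0, 180)
    theta_defined: bool = True  # False when u ∥ y′ (azimuth undefined)


def build_local_frame(event: DivisionEvent) -> LocalFrame:
    """O′ frame: origin at the daughters' midpoint, y′ luminal→basal, x′ the
    apex-base direction Gram-Schmidt-orthonormalized against y′, z′ = x′ × y′."""
    origin = 0.5 * (event.daughter1 + event.daughter2)
    y = event.mother_basal - event.mother_luminal
    y = y / np.linalg.norm(y)
    x = event.apex_base_direction / np.linalg.norm(event.apex_base_direction)
    x = x - np.dot(x, y) * y
    nx = np.linalg.norm(x)
    if nx < 1e-8:
        raise ValueError("degenerate geometry: apex-base axis parallel to y′")
    x = x / nx
    z = np.cross(x, y)
    return LocalFrame(origin=origin, x_axis=x, y_axis=y, z_axis=z)


def division_angles(event: DivisionEvent, frame: LocalFrame) -> OrientationAngles:
    """Angles (φ, θ) of the daughter-separation axis in the O′ frame."""
    u = frame.to_local(event.daughter1) - frame.to_local(event.daughter2)
    norm = np.linalg.norm(u)
    if norm < _EPS:
        raise ValueError("zero daughter separation")
    u = u / norm
    ux, uy, uz = u
    phi = float(np.degrees(np.arcsin(min(1.0, abs(uy)))))
    planar = np.hypot(ux, uz)
    if planar < 1e-9:
        # separation along y′: azimuth undefined, reported as 0 with a flag
        return OrientationAngles(phi=phi, theta=0.0, theta_defined=False)
    theta = float(np.degrees(np.arctan2(uz, ux))) % 180.0
    return OrientationAngles(phi=phi, theta=theta)


def angles_for_events(events: list[DivisionEvent]) -> pd.DataFrame:
    """Compute (φ, θ) for a batch of events; columns id, phi_deg, theta_deg,
    theta_defined."""
    rows = []
    for ev in events:
        ang = division_angles(ev, build_local_frame(ev))
        rows.append(
            {
                "id": ev.label,
                "phi_deg": ang.phi,
                "theta_deg": ang.theta,
                "theta_defined": ang.theta_defined,
            }
        )
    return pd.DataFrame(rows)


_EVENT_COLS = [
    ("daughter1", ("d1x", "d1y", "d1z")),
    ("daughter2", ("d2x", "d2y", "d2z")),
    ("mother_luminal", ("mlx", "mly", "mlz")),
    ("mother_basal", ("mbx", "mby", "mbz")),
    ("apex_base_direction", ("abx", "aby", "abz")),
]


def read_events_csv(path) -> list[DivisionEvent]:
    df = pd.read_csv(path)
    events = []
    for _, r in df.iterrows():
        kwargs = {
            field: np.array([r[c] for c in cols]) for field, cols in _EVENT_COLS
        }
        events.append(DivisionEvent(label=str(r["id"]), **kwargs))
    return events


def write_events_csv(events: list[DivisionEvent], path) -> None:
    rows = []
    for ev in events:
        row = {"id": ev.label}
        for field, cols in _EVENT_COLS:
            for c, v in zip(cols, getattr(ev, field)):
                row[c] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_angles_csv(angles: pd.DataFrame, path) -> None:
    angles.to_csv(path, index=False)
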