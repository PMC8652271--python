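"""Synthetic inputs with known ground truth for the measurement pipeline.

The study's raw microscopy traces are not deposited, so every measurement
stage is exercised on generated data instead: layer traces with
piecewise-prescribed curvature (a flat region joined to a curved one, as in
the real duct), nuclear trajectories following the piecewise-linear
interkinetic-migration law d(τ), and 3D division events with prescribed
(φ, θ) distributions. Noise is i.i.d. isotropic Gaussian on point
coordinates — a model of manual-tracing error, not of microscope optics.

Time bookkeeping: one cell cycle τ_div = 432 simulation-time units
corresponds to 24 h, so 1 h = 18 units (a "3 h after division" observation
is τ = 54).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import nuclear_depth
from .morphometrics import CurvatureProfile, LayerTrace, NuclearObservation
from .orientation import DivisionEvent

__all__ = [
    "LayerSpec",
    "TrackSpec",
    "make_layer_trace",
    "make_nuclear_tracks",
    "make_division_events",
    "estimate_gamma",
    "SIM_UNITS_PER_HOUR",
]

SIM_UNITS_PER_HOUR = 432.0 / 24.0  # τ_div = 432 ⇔ 24 h


# ---------------------------------------------------------------------------
# layer traces
# ---------------------------------------------------------------------------


@dataclass
class LayerSpec:
    """Piecewise-constant-curvature layer: ``segments`` is a list of
    (arc length µm, signed curvature µm⁻¹) pairs, apex at the start of the
    first segment. ``thickness`` is a constant or a (start, end) pair for a
    linear gradient. Curvature sign follows the lumen convention (positive =
    convex toward the lumen)."""

    segments: list[tuple[float, float]]
    thickness: float | tuple[float, float] = 50.0
    trace_noise_sd: float = 0.0  # µm
    point_spacing: float = 1.0  # µm, raw trace sampling

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("need at least one segment")
        for length, kappa in self.segments:
            if length <= 0:
                raise ValueError("segment lengths must be positive")
            if abs(kappa) * self._max_thickness() >= 2.0:
                raise ValueError("offset curves invalid: |κ|·thickness must be < 2")

    def _max_thickness(self) -> float:
        t = self.thickness
        return float(max(t)) if isinstance(t, (tuple, list)) else float(t)

    def thickness_at(self, s: np.ndarray, total: float) -> np.ndarray:
        t = self.thickness
        if isinstance(t, (tuple, list)):
            return t[0] + (t[1] - t[0]) * s / total
        return np.full_like(s, float(t))


def make_layer_trace(
    spec: LayerSpec, seed: int = 0
) -> tuple[LayerTrace, CurvatureProfile]:
    """Generate a noisy LayerTrace plus its noise-free ground-truth profile.

    The midline is integrated from the prescribed curvature; the luminal and
    basal traces are ± thickness/2 offset curves. The luminal offset is
    placed on the left of the travel direction and the turning rate is set to
    −κ_signed, so positive prescribed curvature puts the center of curvature
    on the basal side (convex to lumen).
    """
    rng = np.random.default_rng(seed)
    total = sum(length for length, _ in spec.segments)
    ds = spec.point_spacing
    n = int(np.floor(total / ds)) + 1
    s = np.arange(n) * ds

    kappa_signed = np.empty(n)
    edges = np.cumsum([length for length, _ in spec.segments])
    seg_idx = np.searchsorted(edges, s, side="right").clip(max=len(spec.segments) - 1)
    for i, (_, k) in enumerate(spec.segments):
        kappa_signed[seg_idx == i] = k

    # heading: luminal on the left normal ⇒ turning rate −κ_signed; each step
    # uses the exact circular-arc chord (length ds·sinc(κds/2), heading at
    # the half-turn) so constant-curvature segments lie exactly on circles
    dpsi = -kappa_signed[:-1] * ds
    psi = np.concatenate([[0.0], np.cumsum(dpsi)])
    chord = ds * np.sinc(dpsi / (2.0 * np.pi))
    half_psi = psi[:-1] + 0.5 * dpsi
    steps = chord[:, None] * np.column_stack([np.cos(half_psi), np.sin(half_psi)])
    mid = np.concatenate([[[0.0, 0.0]], np.cumsum(steps, axis=0)])
    tang = np.column_stack([np.cos(psi), np.sin(psi)])
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])  # left normal

    thick = spec.thickness_at(s, total)
    luminal = mid + 0.5 * thick[:, None] * normal
    basal = mid - 0.5 * thick[:, None] * normal
    if spec.trace_noise_sd > 0:
        luminal = luminal + rng.normal(0.0, spec.trace_noise_sd, luminal.shape)
        basal = basal + rng.normal(0.0, spec.trace_noise_sd, basal.shape)

    trace = LayerTrace(luminal=luminal, basal=basal, apex_tip=mid[0], side_label="simulated")
    truth = CurvatureProfile(arc_length=s, curvature=kappa_signed, thickness=thick)
    return trace, truth


# ---------------------------------------------------------------------------
# nuclear tracks
# ---------------------------------------------------------------------------


@dataclass
class TrackSpec:
    """Nuclear-trajectory generator settings (a flat layer of ``n_cells``
    columns, thickness in µm, times in hours)."""

    gamma: float = 0.9
    tau_div: float = 432.0  # sim units (24 h)
    thickness: float = 50.0  # µm
    n_cells: int = 50
    duration_h: float = 24.0
    interval_h: float = 0.5
    noise_sd: float = 0.0  # µm
    cell_spacing: float = 5.0  # µm along the layer

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if min(self.tau_div, self.thickness, self.duration_h, self.interval_h) <= 0:
            raise ValueError("tau_div, thickness, duration and interval must be positive")


def make_nuclear_tracks(
    spec: TrackSpec, seed: int = 0
) -> tuple[list[NuclearObservation], pd.DataFrame, pd.DataFrame]:
    """Nuclear observations following d(τ) with independent phase offsets.

    Returns ``(observations, table, division_times)``: the observation
    objects, a tidy table (columns id, t_h, t_since_division_h, nx, ny, lx,
    ly, bx, by, d_true) and per-cell division times in hours.
    """
    rng = np.random.default_rng(seed)
    t_h = np.arange(0.0, spec.duration_h + 1e-9, spec.interval_h)
    tau0 = rng.uniform(0.0, spec.tau_div, spec.n_cells)
    obs: list[NuclearObservation] = []
    rows = []
    div_rows = []
    for c in range(spec.n_cells):
        x = c * spec.cell_spacing
        lum = np.array([x, 0.0])
        bas = np.array([x, spec.thickness])
        tau = (tau0[c] + t_h * SIM_UNITS_PER_HOUR) % spec.tau_div
        d = nuclear_depth(tau, spec.tau_div, spec.gamma)
        # division happens when the timer wraps
        wraps = np.flatnonzero(np.diff(tau) < 0)
        for w in wraps:
            frac = (spec.tau_div - tau[w]) / SIM_UNITS_PER_HOUR
            div_rows.append({"id": f"cell{c:03d}", "division_t_h": t_h[w] + frac})
        for k, (t, dk) in enumerate(zip(t_h, d)):
            pos = lum + dk * (bas - lum)
            if spec.noise_sd > 0:
                pos = pos + rng.normal(0.0, spec.noise_sd, 2)
            label = f"cell{c:03d}"
            ob = NuclearObservation(
                nucleus=pos,
                luminal_edge=lum,
                basal_edge=bas,
                time_since_division=float(tau[k] / SIM_UNITS_PER_HOUR),
                label=label,
            )
            obs.append(ob)
            rows.append(
                {
                    "id": label,
                    "t_h": t,
                    "t_since_division_h": ob.time_since_division,
                    "nx": pos[0],
                    "ny": pos[1],
                    "lx": lum[0],
                    "ly": lum[1],
                    "bx": bas[0],
                    "by": bas[1],
                    "d_true": dk,
                }
            )
    return obs, pd.DataFrame(rows), pd.DataFrame(div_rows)


def estimate_gamma(table: pd.DataFrame, thickness: float) -> float:
    """Recover γ from tracks as the mean, over cells, of the maximal basal
    excursion (max nucleus–luminal-edge distance over the track, divided by
    the layer thickness). The excursion peaks at d = γ mid-cycle."""
    dist = np.hypot(table["nx"] - table["lx"], table["ny"] - table["ly"])
    per_cell = dist.groupby(table["id"]).max() / thickness
    return float(per_cell.mean())


# ---------------------------------------------------------------------------
# division events
# ---------------------------------------------------------------------------


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3D rotation matrix (normalized random quaternion)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_division_events(
    n: int,
    phi_spread_deg: float = 15.0,
    theta_concentration: float = 2.0,
    seed: int = 0,
    separation: float = 10.0,
    layer_height: float = 50.0,
    jitter_sd: float = 0.0,
) -> tuple[list[DivisionEvent], pd.DataFrame]:
    """Division events in randomly oriented frames from sampled true angles.

    φ ~ |N(0, spread)| clipped to [0, 90] (0 ⇒ surface-parallel divisions);
    θ ~ axial von Mises with the given concentration (0 ⇒ uniform on
    [0, 180)). With ``jitter_sd = 0`` the orientation module must recover
    the true angles to machine precision. Returns the events and a table of
    true (φ, θ).
    """
    if n < 1:
        raise ValueError("need at least one event")
    rng = np.random.default_rng(seed)
    events = []
    rows = []
    for i in range(n):
        phi = abs(rng.normal(0.0, phi_spread_deg)) if phi_spread_deg > 0 else 0.0
        phi = min(phi, 90.0)
        if np.isinf(theta_concentration):
            theta = 0.0
        elif theta_concentration > 0:
            theta = (np.degrees(rng.vonmises(0.0, theta_concentration)) / 2.0) % 180.0
        else:
            theta = rng.uniform(0.0, 180.0)
        pr, tr = np.radians(phi), np.radians(theta)
        u_local = np.array([np.cos(pr) * np.cos(tr), np.sin(pr), np.cos(pr) * np.sin(tr)])
        if rng.random() < 0.5:  # axial: either representative
            u_local = -u_local
        rot = _random_rotation(rng)
        origin = rng.uniform(-100.0, 100.0, 3)
        u_world = rot @ u_local
        d1 = origin + 0.5 * separation * u_world
        d2 = origin - 0.5 * separation * u_world
        y_world = rot @ np.array([0.0, 1.0, 0.0])
        x_world = rot @ np.array([1.0, 0.0, 0.0])
        lum = origin - 0.5 * layer_height * y_world
        bas = origin + 0.5 * layer_height * y_world
        if jitter_sd > 0:
            d1 = d1 + rng.normal(0.0, jitter_sd, 3)
            d2 = d2 + rng.normal(0.0, jitter_sd, 3)
        events.append(
            DivisionEvent(
                daughter1=d1,
                daughter2=d2,
                mother_luminal=lum,
                mother_basal=bas,
                apex_base_direction=x_world,
                label=f"event{i:03d}",
            )
        )
        rows.append({"id": f"event{i:03d}", "phi_deg": phi, "theta_deg": theta})
    return events, pd.DataFrame(rows)
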