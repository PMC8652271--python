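"""Two-dimensional vertex dynamics model of a growing pseudostratified
epithelial layer.

Cells are quadrilaterals in a single row sharing a luminal and a basal
vertex chain. Vertex positions r_i evolve by the overdamped equation of
motion η(ṙ_i − v_i) = −∇_i U, where v_i is the local velocity (the mean of
the centroid velocities of the cells containing vertex i, lagged one step)
and the potential U sums, per cell, harmonic penalties on the luminal edge
length a, basal edge length b, mean lateral length l and polygon area A
around their targets, plus a bending energy k_θ/2·θ_i² at every interior
vertex of each chain (θ_i = deviation from straight).

Each cell carries a cell-cycle timer τ ∈ [0, τ_div] (phases G1:S:G2:M in
ratio 11:8:4:1). The timer sets the nuclear depth d(τ) — a piecewise-linear
interkinetic-nuclear-migration law with basalward-return degree γ — and d in
turn sets the luminal/basal target lengths a* and b* linearly between ξ_max
and ξ_min, so luminally-stalled nuclei (d ≈ 0) demand long luminal and short
basal edges, the differential growth that bends the layer. At τ = τ_div the
cell divides at its edge midpoints; one daughter restarts at τ = 0, the
other at a uniform offset in [0, 0.1·τ_div] to desynchronize neighbours.

Virtual-experiment machinery (luminal-stalling region near the apex,
stochastic τ_div redraws, mitomycin-C-style cycle arrest) is switched on per
run; see :class:`Simulation`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field, replace

import numpy as np
from shapely.geometry import LineString

from . import _kernels

__all__ = [
    "SimParams",
    "Tissue",
    "SimulationError",
    "Simulation",
    "nuclear_depth",
    "target_lengths",
    "cycle_phase",
    "potential_energy",
    "forces",
    "step",
    "step_implicit",
    "divide_cell",
    "apply_mmc_arrest",
]


class SimulationError(RuntimeError):
    """Raised when the tissue geometry degenerates (e.g. a chain
    self-intersects)."""


@dataclass
class SimParams:
    """Model parameters. Defaults are the standard set: η=1, k_A=0.01,
    A*=125 µm², k_a=k_b=k_l=1, k_θ=30, l*=50 µm, τ_div=432, γ=0.9,
    ξ_max=5 µm, ξ_min=1 µm, dt=0.01."""

    eta: float = 1.0
    k_a: float = 1.0
    k_b: float = 1.0
    k_l: float = 1.0
    k_A: float = 0.01
    k_theta: float = 30.0
    area_target: float = 125.0  # µm²
    lateral_target: float = 50.0  # µm
    tau_div: float = 432.0
    gamma: float = 0.9
    xi_max: float = 5.0  # µm
    xi_min: float = 1.0  # µm
    dt: float = 0.01
    phase_ratio: tuple[float, float, float, float] = (11.0, 8.0, 4.0, 1.0)
    tau_offset_frac: float = 0.1  # daughter timer offset ~ U(0, frac·τ_div)
    stall_region_length: float = 20.0  # µm arc length from the apex end
    tau_div_range: tuple[float, float] = (216.0, 864.0)
    mmc_window: tuple[float, float] = (0.25, 0.8)  # fractions of τ_div
    mmc_onset_time: float = 700.0

    def __post_init__(self) -> None:
        for name in ("eta", "k_a", "k_b", "k_l", "k_A", "k_theta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if self.xi_min >= self.xi_max:
            raise ValueError("xi_min must be < xi_max")
        if self.tau_div <= 0 or self.dt <= 0:
            raise ValueError("tau_div and dt must be positive")
        if self.tau_div_range[0] <= 0 or self.tau_div_range[1] <= self.tau_div_range[0]:
            raise ValueError("tau_div_range must be positive and increasing")

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "SimParams":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            data = json.loads(source)
        else:
            with open(source) as fh:
                data = json.load(fh)
        for key in ("phase_ratio", "tau_div_range", "mmc_window"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def with_(self, **kwargs) -> "SimParams":
        return replace(self, **kwargs)


@dataclass
class Tissue:
    """Shared vertex chains plus per-cell cycle state.

    With n cells there are n+1 luminal and n+1 basal vertices; cell j owns
    luminal vertices (j, j+1) and basal vertices (j, j+1), ordered from the
    apex-side end."""

    luminal: np.ndarray  # (n+1, 2) µm
    basal: np.ndarray  # (n+1, 2) µm
    tau: np.ndarray  # (n,)
    tau_div: np.ndarray  # (n,)
    stalled: np.ndarray  # (n,) bool — daughters of stalling-region cells
    arrested: np.ndarray  # (n,) bool — MMC-style cycle arrest
    cent_vel: np.ndarray  # (n, 2) previous-step centroid velocities
    time: float = 0.0

    @property
    def n_cells(self) -> int:
        return len(self.tau)

    @property
    def frozen(self) -> np.ndarray:
        return self.stalled | self.arrested

    @classmethod
    def initial(
        cls,
        n_cells: int = 20,
        width: float = 2.5,
        height: float = 50.0,
        params: SimParams | None = None,
        rng: np.random.Generator | None = None,
    ) -> "Tissue":
        """Initial condition: ``n_cells`` rectangles of width × height µm in
        a horizontal row, luminal chain on top (the lumen is above the
        layer). Cycle timers are drawn uniformly on [0, τ_div) ("initial cell
        phase chosen at random")."""
        params = params or SimParams()
        x = np.arange(n_cells + 1) * width
        luminal = np.column_stack([x, np.full(n_cells + 1, height)])
        basal = np.column_stack([x, np.zeros(n_cells + 1)])
        if rng is None:
            tau = np.zeros(n_cells)
        else:
            tau = rng.uniform(0.0, params.tau_div, n_cells)
        return cls(
            luminal=luminal,
            basal=basal,
            tau=tau,
            tau_div=np.full(n_cells, params.tau_div),
            stalled=np.zeros(n_cells, dtype=bool),
            arrested=np.zeros(n_cells, dtype=bool),
            cent_vel=np.zeros((n_cells, 2)),
            time=0.0,
        )

    def copy(self) -> "Tissue":
        return Tissue(
            luminal=self.luminal.copy(),
            basal=self.basal.copy(),
            tau=self.tau.copy(),
            tau_div=self.tau_div.copy(),
            stalled=self.stalled.copy(),
            arrested=self.arrested.copy(),
            cent_vel=self.cent_vel.copy(),
            time=self.time,
        )

    # -- per-cell geometry -------------------------------------------------

    def luminal_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.luminal, axis=0), axis=1)

    def basal_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.basal, axis=0), axis=1)

    def lateral_lengths(self) -> np.ndarray:
        """Length of every lateral edge (n+1 of them)."""
        return np.linalg.norm(self.luminal - self.basal, axis=1)

    def mean_lateral_lengths(self) -> np.ndarray:
        lat = self.lateral_lengths()
        return 0.5 * (lat[:-1] + lat[1:])

    def areas(self) -> np.ndarray:
        """Unsigned shoelace areas of the cell quadrilaterals."""
        L, B = self.luminal, self.basal
        x = np.stack([L[:-1, 0], L[1:, 0], B[1:, 0], B[:-1, 0]])
        y = np.stack([L[:-1, 1], L[1:, 1], B[1:, 1], B[:-1, 1]])
        signed = 0.5 * np.sum(x * np.roll(y, -1, axis=0) - np.roll(x, -1, axis=0) * y, axis=0)
        return np.abs(signed)

    def centroids(self) -> np.ndarray:
        return 0.25 * (
            self.luminal[:-1] + self.luminal[1:] + self.basal[:-1] + self.basal[1:]
        )

    def nuclear_depths(self, params: SimParams) -> np.ndarray:
        return nuclear_depth(self.tau, self.tau_div, params.gamma)

    def luminal_arc_of_cells(self) -> np.ndarray:
        """Arc length along the luminal chain, from the apex-side end, of
        each cell's luminal-edge midpoint (stalling-region membership)."""
        seg = self.luminal_lengths()
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        return cum[:-1] + 0.5 * seg

    def check_chains_simple(self) -> None:
        for name, chain in (("luminal", self.luminal), ("basal", self.basal)):
            if not LineString(chain).is_simple:
                raise SimulationError(
                    f"{name} vertex chain self-intersects at t={self.time:.2f} "
                    f"({self.n_cells} cells)"
                )


# ---------------------------------------------------------------------------
# cell-cycle laws
# ---------------------------------------------------------------------------


def nuclear_depth(tau, tau_div, gamma: float):
    """Nuclear depth d(τ) ∈ [0, 1] (0 = luminal side).

    d = 2γτ/τ_div on (0, 0.5·τ_div], (−τ/τ_div + 0.95)·γ/0.45 on
    (0.5, 0.95]·τ_div, and 0 on (0.95, 1]·τ_div; continuous at the breaks.
    Accepts scalars or arrays (tau_div may be an array of per-cell lengths).
    """
    tau = np.asarray(tau, dtype=float)
    tau_div = np.asarray(tau_div, dtype=float)
    if np.any(tau < 0) or np.any(tau > tau_div):
        raise ValueError("tau outside [0, tau_div]")
    r = tau / tau_div
    d = np.where(r <= 0.5, 2.0 * gamma * r, np.where(r <= 0.95, (0.95 - r) * gamma / 0.45, 0.0))
    return float(d) if d.ndim == 0 else d


def target_lengths(d, xi_max: float, xi_min: float):
    """Luminal/basal target edge lengths, linear in the nuclear depth:
    a* = (ξ_min−ξ_max)·d + ξ_max, b* = (ξ_max−ξ_min)·d + ξ_min (their sum is
    always ξ_min+ξ_max)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d > 1):
        raise ValueError("nuclear depth must lie in [0, 1]")
    a = (xi_min - xi_max) * d + xi_max
    b = (xi_max - xi_min) * d + xi_min
    if a.ndim == 0:
        return float(a), float(b)
    return a, b


_PHASES = ("G1", "S", "G2", "M")


def cycle_phase(tau: float, tau_div: float, phase_ratio=(11.0, 8.0, 4.0, 1.0)) -> str:
    """Cycle phase at timer τ; boundaries at cumulative fractions of the
    11:8:4:1 partition (11/24, 19/24, 23/24 by default)."""
    if not 0 <= tau <= tau_div:
        raise ValueError("tau outside [0, tau_div]")
    fr = np.cumsum(phase_ratio) / np.sum(phase_ratio)
    r = tau / tau_div
    for phase, edge in zip(_PHASES[:-1], fr[:-1]):
        if r < edge:
            return phase
    return _PHASES[-1]


# ---------------------------------------------------------------------------
# energy, forces, stepping
# ---------------------------------------------------------------------------


def _targets(tissue: Tissue, params: SimParams) -> tuple[np.ndarray, np.ndarray]:
    d = tissue.nuclear_depths(params)
    return target_lengths(d, params.xi_max, params.xi_min)


def _turning_angles(chain: np.ndarray) -> np.ndarray:
    u = np.diff(chain, axis=0)
    a, b = u[:-1], u[1:]
    cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    dot = np.sum(a * b, axis=1)
    return np.arctan2(cross, dot)


def potential_energy(tissue: Tissue, params: SimParams) -> float:
    """The five-term potential U (edge springs on a, b, mean lateral l, area
    preservation, chain bending). Plain-numpy reference implementation; the
    stepping kernels use analytic gradients checked against this by central
    differences."""
    areas = tissue.areas()
    if np.any(areas <= 0):
        raise SimulationError("degenerate cell polygon with non-positive area")
    a_t, b_t = _targets(tissue, params)
    a = tissue.luminal_lengths()
    b = tissue.basal_lengths()
    lmean = tissue.mean_lateral_lengths()
    u = (
        0.5 * params.k_a * np.sum((a - a_t) ** 2)
        + 0.5 * params.k_b * np.sum((b - b_t) ** 2)
        + 0.5 * params.k_l * np.sum((lmean - params.lateral_target) ** 2)
        + 0.5 * params.k_A * np.sum((areas - params.area_target) ** 2)
    )
    for chain in (tissue.luminal, tissue.basal):
        u += 0.5 * params.k_theta * np.sum(_turning_angles(chain) ** 2)
    return float(u)


def forces(tissue: Tissue, params: SimParams) -> tuple[np.ndarray, np.ndarray]:
    """Analytic −∇U per vertex; returns (luminal forces, basal forces)."""
    a_t, b_t = _targets(tissue, params)
    n = tissue.n_cells
    FL = np.empty((n + 1, 2))
    FB = np.empty((n + 1, 2))
    _kernels.compute_forces(
        tissue.luminal,
        tissue.basal,
        np.asarray(a_t, dtype=float),
        np.asarray(b_t, dtype=float),
        params.k_a,
        params.k_b,
        params.k_l,
        params.k_A,
        params.k_theta,
        params.area_target,
        params.lateral_target,
        FL,
        FB,
    )
    return FL, FB


def step(
    tissue: Tissue,
    params: SimParams,
    n_steps: int = 1,
    use_local_velocity: bool = True,
    advance_timers: bool = True,
) -> Tissue:
    """Advance ``n_steps`` forward-Euler steps in place and return the
    tissue. ``use_local_velocity=False`` gives pure gradient flow (v_i ≡ 0);
    ``advance_timers=False`` freezes the cell cycle (mechanics only)."""
    frozen = tissue.frozen if advance_timers else np.ones(tissue.n_cells, dtype=bool)
    _kernels.run_steps(
        tissue.luminal,
        tissue.basal,
        tissue.cent_vel,
        tissue.tau,
        tissue.tau_div,
        frozen,
        int(n_steps),
        params.dt,
        params.eta,
        params.k_a,
        params.k_b,
        params.k_l,
        params.k_A,
        params.k_theta,
        params.area_target,
        params.lateral_target,
        params.xi_max,
        params.xi_min,
        params.gamma,
        use_local_velocity,
    )
    tissue.time += n_steps * params.dt
    return tissue


def step_implicit(
    tissue: Tissue,
    params: SimParams,
    n_steps: int = 1,
    max_iter: int = 60,
    tol: float = 1e-12,
) -> Tissue:
    """Validation-mode stepping that solves the velocity self-consistency.

    The local velocity v_i (mean centroid velocity of the cells containing
    vertex i) makes the equation of motion implicit: velocities appear on
    both sides. The implicit system is singular along rigid translation (a
    uniform velocity satisfies v(ṙ) = ṙ), so the self-consistent solve pins
    the mean vertex velocity to the force-driven value while the fixed-point
    iteration resolves the non-uniform components. The production scheme
    instead lags v_i one step (carrying translation history); the two agree
    on the shape evolution, which is what this Python-level validation mode
    is used to check.
    """
    n = tissue.n_cells
    for _ in range(int(n_steps)):
        FL, FB = forces(tissue, params)
        gl = FL / params.eta
        gb = FB / params.eta
        mean_g = 0.5 * (gl.mean(axis=0) + gb.mean(axis=0))
        rdot_l = gl.copy()
        rdot_b = gb.copy()
        for _ in range(max_iter):
            cvel = 0.25 * (rdot_l[:-1] + rdot_l[1:] + rdot_b[:-1] + rdot_b[1:])
            v = np.empty((n + 1, 2))
            v[0] = cvel[0]
            v[-1] = cvel[-1]
            if n > 1:
                v[1:-1] = 0.5 * (cvel[:-1] + cvel[1:])
            new_l = v + gl
            new_b = v + gb
            drift = 0.5 * (new_l.mean(axis=0) + new_b.mean(axis=0)) - mean_g
            new_l -= drift
            new_b -= drift
            delta = max(
                np.abs(new_l - rdot_l).max(), np.abs(new_b - rdot_b).max()
            )
            rdot_l, rdot_b = new_l, new_b
            if delta < tol:
                break
        tissue.luminal = tissue.luminal + params.dt * rdot_l
        tissue.basal = tissue.basal + params.dt * rdot_b
        tissue.cent_vel = 0.25 * (
            rdot_l[:-1] + rdot_l[1:] + rdot_b[:-1] + rdot_b[1:]
        )
        active = ~tissue.frozen
        tissue.tau[active] += params.dt
        tissue.time += params.dt
    return tissue


# ---------------------------------------------------------------------------
# division and arrest
# ---------------------------------------------------------------------------


def divide_cell(
    tissue: Tissue,
    cell_index: int,
    rng: np.random.Generator,
    params: SimParams,
    mother_stalling: bool = False,
    redraw_tau_div: bool = False,
) -> Tissue:
    """Split cell ``cell_index`` at the midpoints of its luminal and basal
    edges. One daughter restarts its timer at 0, the other at
    U(0, 0.1·τ_div) (assigned to a random side); daughters inherit all other
    state. With ``mother_stalling`` both daughters are flagged stalled (their
    timers never advance again); with ``redraw_tau_div`` each non-stalled
    daughter draws a fresh cycle length from U(216, 864)."""
    j = int(cell_index)
    if tissue.stalled[j] or tissue.arrested[j]:
        raise SimulationError("cannot divide a stalled or arrested cell")
    mid_l = 0.5 * (tissue.luminal[j] + tissue.luminal[j + 1])
    mid_b = 0.5 * (tissue.basal[j] + tissue.basal[j + 1])
    tissue.luminal = np.insert(tissue.luminal, j + 1, mid_l, axis=0)
    tissue.basal = np.insert(tissue.basal, j + 1, mid_b, axis=0)

    offset = rng.uniform(0.0, params.tau_offset_frac * tissue.tau_div[j])
    taus = np.array([0.0, offset])
    if rng.random() < 0.5:
        taus = taus[::-1]

    stalled_flag = bool(mother_stalling)
    if redraw_tau_div and not stalled_flag:
        new_tau_div = rng.uniform(*params.tau_div_range, size=2)
    else:
        new_tau_div = np.full(2, tissue.tau_div[j])

    tissue.tau = np.concatenate([tissue.tau[:j], taus, tissue.tau[j + 1 :]])
    tissue.tau_div = np.concatenate(
        [tissue.tau_div[:j], new_tau_div, tissue.tau_div[j + 1 :]]
    )
    tissue.stalled = np.concatenate(
        [tissue.stalled[:j], [stalled_flag, stalled_flag], tissue.stalled[j + 1 :]]
    )
    tissue.arrested = np.concatenate(
        [tissue.arrested[:j], [False, False], tissue.arrested[j + 1 :]]
    )
    tissue.cent_vel = np.insert(tissue.cent_vel, j, tissue.cent_vel[j], axis=0)
    return tissue


def apply_mmc_arrest(tissue: Tissue, params: SimParams) -> Tissue:
    """Flag as arrested every cycling cell whose timer fraction lies in the
    MMC window [0.25, 0.8]·τ_div. Only meaningful after the onset time; the
    caller gates on ``tissue.time > params.mmc_onset_time``."""
    lo, hi = params.mmc_window
    r = tissue.tau / tissue.tau_div
    tissue.arrested |= (~tissue.stalled) & (r >= lo) & (r <= hi)
    return tissue


# ---------------------------------------------------------------------------
# event-driven simulation driver
# ---------------------------------------------------------------------------


@dataclass
class Simulation:
    """Event-driven driver around the stepping kernel.

    Timers advance deterministically between divisions, so the driver
    computes the step count to the next cell-cycle event (a division, an
    MMC-window entry, or the arrest onset), integrates the mechanics in one
    compiled chunk, then handles the event in Python. Every stochastic draw
    (initial phases, daughter offsets, τ_div redraws) passes through the
    single seeded generator.
    """

    params: SimParams = field(default_factory=SimParams)
    seed: int = 0
    n_initial: int = 20
    stalling: bool = False  # luminal-stalling region near the apex
    redraw_tau_div: bool = False  # daughters draw τ_div ~ U(216, 864)
    mmc: bool = False  # cycle arrest after the onset time

    def __post_init__(self) -> None:
        self.rng = np.random.default_rng(self.seed)
        self.tissue = Tissue.initial(self.n_initial, params=self.params, rng=self.rng)
        self.stop_time: float | None = None
        self.aborted = False

    # steps until a cycling cell's τ reaches a threshold fraction of τ_div
    def _steps_to(self, target_tau: np.ndarray, mask: np.ndarray) -> int | None:
        if not np.any(mask):
            return None
        gap = target_tau[mask] - self.tissue.tau[mask]
        k = int(np.ceil(gap.min() / self.params.dt - 1e-9))
        return max(k, 1)

    def _arrest_due(self) -> np.ndarray:
        lo, hi = self.params.mmc_window
        r = self.tissue.tau / self.tissue.tau_div
        return (~self.tissue.frozen) & (r >= lo) & (r <= hi)

    def _handle_divisions(self) -> None:
        t = self.tissue
        due = np.flatnonzero(
            (~t.frozen) & (t.tau >= t.tau_div - 0.5 * self.params.dt)
        )
        if due.size == 0:
            return
        arcs = t.luminal_arc_of_cells()
        stall_members = (
            arcs < self.params.stall_region_length if self.stalling else np.zeros(t.n_cells, bool)
        )
        # process from the right so earlier indices stay valid
        for j in sorted(due.tolist(), reverse=True):
            divide_cell(
                t,
                j,
                self.rng,
                self.params,
                mother_stalling=bool(stall_members[j]),
                redraw_tau_div=self.redraw_tau_div,
            )

    def run(
        self,
        until_cells: int | None = None,
        until_time: float | None = None,
        time_cap: float = 5000.0,
        check_interval: float = 50.0,
    ) -> Tissue:
        """Run until the cell count reaches ``until_cells`` or the clock
        reaches ``until_time``, whichever is given (at least one required).
        A run hitting ``time_cap`` first is flagged ``aborted`` rather than
        silently dropped. Chain self-intersection aborts with a diagnostic.
        """
        if until_cells is None and until_time is None:
            raise ValueError("provide until_cells and/or until_time")
        p = self.params
        hard_stop = min(until_time, time_cap) if until_time is not None else time_cap
        next_check = self.tissue.time + check_interval
        while True:
            t = self.tissue
            if until_cells is not None and t.n_cells >= until_cells:
                self.stop_time = t.time
                break
            if until_time is not None and t.time >= until_time - 0.5 * p.dt:
                self.stop_time = t.time
                break
            if t.time >= time_cap - 0.5 * p.dt:
                self.stop_time = t.time
                self.aborted = True
                warnings.warn(
                    f"run hit the time cap {time_cap} before its stop condition",
                    stacklevel=2,
                )
                break

            mmc_active = self.mmc and t.time > p.mmc_onset_time
            if mmc_active:
                apply_mmc_arrest(t, p)

            # next division among cycling cells
            cycling = ~t.frozen
            k_div = self._steps_to(t.tau_div, cycling)
            candidates = []
            if k_div is not None:
                candidates.append(k_div)
            if mmc_active:
                # next entry into the arrest window
                lo = p.mmc_window[0]
                below = cycling & (t.tau / t.tau_div < lo)
                k_arr = self._steps_to(lo * t.tau_div, below)
                if k_arr is not None:
                    candidates.append(k_arr)
            elif self.mmc and t.time <= p.mmc_onset_time:
                candidates.append(
                    max(1, int(np.ceil((p.mmc_onset_time - t.time) / p.dt)))
                )
            candidates.append(max(1, int(np.ceil((hard_stop - t.time) / p.dt))))
            candidates.append(max(1, int(np.ceil((next_check - t.time) / p.dt))))
            k = min(candidates)

            step(t, p, n_steps=k)
            if t.time >= next_check:
                t.check_chains_simple()
                next_check = t.time + check_interval
            self._handle_divisions()
        self.tissue.check_chains_simple()
        return self.tissue
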