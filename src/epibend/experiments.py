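"""Virtual experiments on the vertex-dynamics layer and their curvature
readouts.

Three protocols:

* γ sweep — uniform cycling (every cell τ_div = 432, no stalling region, no
  arrest), run to a fixed cell count per γ; the replicate-mean signed
  curvature quantifies how basalward nuclear return flattens the layer.
* control — the developmental protocol: a luminal-stalling region of arc
  length L at the apex end (daughters born there never cycle again),
  non-stalled daughters redraw τ_div ~ U(216, 864); run from 20 cells until
  the count reaches 100.
* MMC arrest — identical to control, plus cycle arrest of every cell whose
  timer sits in [0.25, 0.8]·τ_div once the clock passes 700; evaluated at
  time 1300.

Simulated tissues are measured with the same midline-spline pipeline (15 µm
sampling) as experimental traces.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SimParams, Simulation, Tissue
from .morphometrics import (
    CurvatureProfile,
    LayerTrace,
    curvature_profile,
    midline_from_trace,
)
from .stats import TestResult, mann_whitney_u

__all__ = [
    "ExperimentResult",
    "ProfileComparison",
    "measure_virtual_curvature",
    "mean_signed_curvature",
    "run_gamma_sweep",
    "run_control",
    "run_mmc",
    "compare_profiles",
    "arrest_vs_control_test",
]

DEFAULT_SPACING = 15.0  # µm, same sampling as experimental profiles
EDGE_TRIM = 2  # boundary samples excluded from the scalar summary


def measure_virtual_curvature(
    tissue: Tissue, spacing: float = DEFAULT_SPACING, window: int = 7
) -> CurvatureProfile:
    """Curvature/thickness profile of a simulated tissue: the vertex chains
    become a LayerTrace (apex tip = apex-side end of the midline) and go
    through the standard measurement pipeline."""
    if tissue.n_cells < 5:
        raise ValueError("need at least 5 cells to measure a profile")
    apex = 0.5 * (tissue.luminal[0] + tissue.basal[0])
    trace = LayerTrace(
        luminal=tissue.luminal.copy(),
        basal=tissue.basal.copy(),
        apex_tip=apex,
        side_label="simulated",
    )
    midline = midline_from_trace(trace, spacing=spacing)
    return curvature_profile(midline, trace, window=window)


def mean_signed_curvature(profile: CurvatureProfile, trim: int = EDGE_TRIM) -> float:
    """Scalar curvature summary: mean signed κ over interior samples
    (``trim`` boundary samples dropped at each end)."""
    k = profile.curvature
    if len(k) <= 2 * trim:
        raise ValueError("profile too short for the requested edge trim")
    inner = k[trim : len(k) - trim] if trim else k
    return float(np.mean(inner))


@dataclass
class ExperimentResult:
    """Replicate outcomes of one virtual-experiment condition."""

    condition: str
    seeds: list  # per-replicate seed material
    profiles: list[CurvatureProfile]
    summaries: np.ndarray  # per-replicate mean signed curvature (µm⁻¹)
    stop_times: np.ndarray
    cell_counts: np.ndarray
    aborted: np.ndarray  # per-replicate time-cap flag
    params: SimParams = field(default_factory=SimParams)

    @property
    def mean_stop_time(self) -> float:
        return float(np.mean(self.stop_times))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate": np.arange(len(self.summaries)),
                "mean_curvature_per_um": self.summaries,
                "stop_time": self.stop_times,
                "n_cells": self.cell_counts,
                "aborted": self.aborted,
            }
        )

    def to_csv(self, path) -> None:
        self.summary_frame().to_csv(path, index=False)

    def metadata(self) -> dict:
        return {
            "condition": self.condition,
            "seeds": [list(np.atleast_1d(s).tolist()) for s in self.seeds],
            "stall_region_length_um": self.params.stall_region_length,
            "gamma": self.params.gamma,
            "stop_times": self.stop_times.tolist(),
            "mean_stop_time": self.mean_stop_time,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.metadata(), fh, indent=2, sort_keys=True)


def _replicate_seed(master_seed: int, stream: int, rep: int) -> list[int]:
    """Fixed counter scheme: replicates are independent and order-free given
    the master seed."""
    return [int(master_seed), int(stream), int(rep)]


def _run_condition(
    condition: str,
    params: SimParams,
    replicates: int,
    master_seed: int,
    stream: int,
    *,
    stalling: bool,
    redraw: bool,
    mmc: bool,
    until_cells: int | None,
    until_time: float | None,
    time_cap: float,
) -> ExperimentResult:
    seeds, profiles, summaries, stop_times, counts, aborted = [], [], [], [], [], []
    for rep in range(replicates):
        seed = _replicate_seed(master_seed, stream, rep)
        sim = Simulation(
            params=params,
            seed=seed,
            stalling=stalling,
            redraw_tau_div=redraw,
            mmc=mmc,
        )
        sim.run(until_cells=until_cells, until_time=until_time, time_cap=time_cap)
        prof = measure_virtual_curvature(sim.tissue)
        seeds.append(seed)
        profiles.append(prof)
        summaries.append(mean_signed_curvature(prof))
        stop_times.append(sim.stop_time)
        counts.append(sim.tissue.n_cells)
        aborted.append(sim.aborted)
    return ExperimentResult(
        condition=condition,
        seeds=seeds,
        profiles=profiles,
        summaries=np.array(summaries),
        stop_times=np.array(stop_times, dtype=float),
        cell_counts=np.array(counts),
        aborted=np.array(aborted, dtype=bool),
        params=params,
    )


def run_gamma_sweep(
    gammas,
    replicates: int = 10,
    seed: int = 0,
    params: SimParams | None = None,
    stop_cells: int = 80,
    time_cap: float = 5000.0,
) -> dict[float, ExperimentResult]:
    """Curvature vs basalward-return degree γ, uniform-cycling configuration
    (equal τ_div, no stalling, no arrest), each replicate run to
    ``stop_cells`` cells (≈ two cycles, enough for interior curvature to
    develop)."""
    base = params or SimParams()
    out: dict[float, ExperimentResult] = {}
    for gi, gamma in enumerate(gammas):
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("gamma values must lie in [0, 1]")
        out[float(gamma)] = _run_condition(
            condition=f"gamma={gamma}",
            params=base.with_(gamma=float(gamma)),
            replicates=replicates,
            master_seed=seed,
            stream=100 + gi,
            stalling=False,
            redraw=False,
            mmc=False,
            until_cells=stop_cells,
            until_time=None,
            time_cap=time_cap,
        )
    return out


def run_control(
    replicates: int = 10,
    seed: int = 0,
    params: SimParams | None = None,
    stop_cells: int = 100,
    time_cap: float = 5000.0,
) -> ExperimentResult:
    """Developmental control: stalling region active, τ_div redraws on, run
    until the cell count reaches ``stop_cells`` (100)."""
    return _run_condition(
        condition="control",
        params=params or SimParams(),
        replicates=replicates,
        master_seed=seed,
        stream=1,
        stalling=True,
        redraw=True,
        mmc=False,
        until_cells=stop_cells,
        until_time=None,
        time_cap=time_cap,
    )


def run_mmc(
    replicates: int = 10,
    seed: int = 0,
    params: SimParams | None = None,
    eval_time: float = 1300.0,
    time_cap: float = 5000.0,
) -> ExperimentResult:
    """MMC arm: same protocol as the control plus cycle arrest after the
    onset time; evaluated at ``eval_time`` (1300)."""
    return _run_condition(
        condition="mmc",
        params=params or SimParams(),
        replicates=replicates,
        master_seed=seed,
        stream=2,
        stalling=True,
        redraw=True,
        mmc=True,
        until_cells=None,
        until_time=eval_time,
        time_cap=max(time_cap, eval_time),
    )


def arrest_vs_control_test(
    control: ExperimentResult, mmc: ExperimentResult
) -> TestResult:
    """Two-sided Mann–Whitney U on replicate mean curvatures, control vs
    arrest."""
    return mann_whitney_u(control.summaries, mmc.summaries)


@dataclass
class ProfileComparison:
    experimental: CurvatureProfile
    simulated_mean: CurvatureProfile
    rmse: float


def _mean_profile(profiles: list[CurvatureProfile]) -> CurvatureProfile:
    """Average replicate profiles on the shortest common arc grid."""
    n = min(len(p.arc_length) for p in profiles)
    arc = profiles[0].arc_length[:n]
    kappa = np.mean([p.curvature[:n] for p in profiles], axis=0)
    thick = np.mean([p.thickness[:n] for p in profiles], axis=0)
    return CurvatureProfile(arc_length=arc, curvature=kappa, thickness=thick)


def compare_profiles(
    experimental: CurvatureProfile, simulated: ExperimentResult | CurvatureProfile
) -> ProfileComparison:
    """RMSE between an experimental curvature profile and the (replicate-
    mean) simulated profile, after linear interpolation of the simulated
    curve onto the overlapping part of the experimental arc grid."""
    if isinstance(simulated, ExperimentResult):
        sim = _mean_profile(simulated.profiles)
    else:
        sim = simulated
    lo = max(experimental.arc_length[0], sim.arc_length[0])
    hi = min(experimental.arc_length[-1], sim.arc_length[-1])
    mask = (experimental.arc_length >= lo) & (experimental.arc_length <= hi)
    if not np.any(mask):
        raise ValueError("profiles have no overlapping arc-length range")
    s = experimental.arc_length[mask]
    sim_k = np.interp(s, sim.arc_length, sim.curvature)
    rmse = float(np.sqrt(np.mean((experimental.curvature[mask] - sim_k) ** 2)))
    return ProfileComparison(experimental=experimental, simulated_mean=sim, rmse=rmse)
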