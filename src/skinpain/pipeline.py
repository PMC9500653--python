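"""End-to-end experiment driver: compression load -> stress -> spikes -> pain.

Chains the three model stages for a given load and nociceptor site and runs
the two sweep experiments:

* amplitude sweep — fixed geometry, varying pressure amplitude q;
* depth sweep — fixed load, nociceptor at increasing on-axis depth.

Each scenario produces one tidy :class:`SweepResult` row: the transduction
stress at the nociceptor, the membrane firing frequency, the T-cell output
statistic, and the pain decision.  Results export to CSV with a JSON
sidecar recording every resolved parameter so runs are reproducible without
re-execution.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .gct import FiberInput, GCTParams, pain_decision, simulate_gct, t_cell_output
from .mechanics import (
    CompressionLoad,
    PlanePoint,
    StressState,
    stress_axis_closed,
    stress_quadrature,
    surface_limit,
    transduction_stress,
)
from .transduction import HHParams, firing_frequency, simulate_membrane

__all__ = [
    "SolverSettings",
    "ScenarioConfig",
    "SweepResult",
    "run_scenario",
    "sweep_amplitude",
    "sweep_depth",
    "results_to_frame",
]

log = logging.getLogger("skinpain")

RESULT_COLUMNS = [
    "q_kPa",
    "depth_mm",
    "sigma_kPa",
    "frequency_Hz",
    "V_t_out_mV",
    "oscillatory_flag",
    "pain",
]


@dataclass(frozen=True)
class SolverSettings:
    """Integration settings for the two ODE stages.

    Membrane: 1200 ms at dt = 0.01 ms with the first 200 ms discarded
    before frequency analysis.  Gate circuit: 50 model time units at
    dt = 0.005, output taken over the final half.
    """

    membrane_duration_ms: float = 1200.0
    membrane_dt_ms: float = 0.01
    transient_ms: float = 200.0
    gct_duration: float = 50.0
    gct_dt: float = 0.005
    frequency_method: str = "fft"


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of one compression-pain experiment.

    Defaults reproduce the reference scenario: a = 10 mm strip, nociceptor
    on-axis at 1.6 mm depth (approximate epidermis thickness), amplitude
    grid {15, 25, 35} kPa and depth grid {1, 10, 50} mm at q = 25 kPa.
    The seed is recorded for provenance only; the model is deterministic.
    """

    q: float = 25.0
    a: float = 10.0
    depth: float = 1.6
    lateral: float = 0.0
    hh: HHParams = field(default_factory=HHParams)
    gct: GCTParams = field(default_factory=GCTParams)
    solver: SolverSettings = field(default_factory=SolverSettings)
    q_grid: tuple[float, ...] = (15.0, 25.0, 35.0)
    depth_grid: tuple[float, ...] = (1.0, 10.0, 50.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        self.load()  # validates q and a
        if self.depth < 0:
            raise ValueError(f"nociceptor depth must be >= 0, got {self.depth}")
        if not self.q_grid or not self.depth_grid:
            raise ValueError("sweep grids must be non-empty")
        if any(q <= 0 for q in self.q_grid) or any(d < 0 for d in self.depth_grid):
            raise ValueError("sweep grids must contain positive amplitudes and depths >= 0")

    def load(self) -> CompressionLoad:
        return CompressionLoad(q=self.q, a=self.a)

    def replace(self, **kw) -> "ScenarioConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "ScenarioConfig":
        """Build a config from namespaced keys (load.*, nociceptor.*, hh.*,
        gct.*, solver.*, sweep.*), as read from a YAML/JSON config file."""
        load = raw.get("load", {})
        noci = raw.get("nociceptor", {})
        sweep = raw.get("sweep", {})
        kw: dict = {}
        if "q" in load:
            kw["q"] = float(load["q"])
        if "a" in load:
            kw["a"] = float(load["a"])
        if "depth" in noci:
            kw["depth"] = float(noci["depth"])
        if "lateral" in noci:
            kw["lateral"] = float(noci["lateral"])
        if raw.get("hh"):
            kw["hh"] = HHParams(**raw["hh"])
        if raw.get("gct"):
            kw["gct"] = GCTParams(**raw["gct"])
        if raw.get("solver"):
            kw["solver"] = SolverSettings(**raw["solver"])
        if "q_grid" in sweep:
            kw["q_grid"] = tuple(float(v) for v in sweep["q_grid"])
        if "depth_grid" in sweep:
            kw["depth_grid"] = tuple(float(v) for v in sweep["depth_grid"])
        if "seed" in raw:
            kw["seed"] = raw["seed"]
        return cls(**kw)

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)  # YAML superset also accepts JSON
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(raw)


@dataclass(frozen=True)
class SweepResult:
    """One scenario outcome: stress, firing rate, T-cell output, pain flag."""

    q_kPa: float
    depth_mm: float
    sigma_kPa: float
    frequency_Hz: float
    V_t_out_mV: float
    oscillatory_flag: bool
    pain: bool


def _stress_at(config: ScenarioConfig) -> StressState:
    load = config.load()
    if config.depth == 0.0:
        return surface_limit(load, config.lateral)
    if config.lateral == 0.0:
        return stress_axis_closed(load, config.depth)
    return stress_quadrature(load, PlanePoint(x=config.depth, y=config.lateral))


def run_scenario(config: ScenarioConfig) -> SweepResult:
    """Run the three-stage pipeline for a single load/site combination.

    Stage order: contact stress at the nociceptor -> |sigma_x| ->
    membrane simulation -> firing frequency -> gate circuit with
    x_l = 0, x_s = frequency -> T-cell output -> pain decision.
    """
    t0 = time.perf_counter()
    log.info(
        "scenario q=%.3g kPa a=%.3g mm depth=%.3g mm lateral=%.3g mm "
        "(kappa_L=%.3g mS/cm^2, I_shift=%.3g uA/cm^2)",
        config.q, config.a, config.depth, config.lateral,
        config.hh.kappa_L, config.hh.I_shift,
    )
    try:
        sigma = transduction_stress(_stress_at(config))
    except Exception as exc:
        raise RuntimeError(f"mechanics stage failed: {exc}") from exc

    s = config.solver
    try:
        trace = simulate_membrane(
            sigma, config.hh, duration=s.membrane_duration_ms, dt=s.membrane_dt_ms
        )
        summary = firing_frequency(trace, method=s.frequency_method, transient=s.transient_ms)
    except Exception as exc:
        raise RuntimeError(f"transduction stage failed: {exc}") from exc

    try:
        traj = simulate_gct(
            FiberInput(x_l=0.0, x_s=summary.frequency),
            config.gct,
            duration=s.gct_duration,
            dt=s.gct_dt,
        )
        out = t_cell_output(traj)
    except Exception as exc:
        raise RuntimeError(f"gct stage failed: {exc}") from exc

    log.info(
        "scenario done in %.2f s: sigma=%.3f kPa, f=%.2f Hz, V_t=%.3f mV",
        time.perf_counter() - t0, sigma, summary.frequency, out.value,
    )
    return SweepResult(
        q_kPa=config.q,
        depth_mm=config.depth,
        sigma_kPa=sigma,
        frequency_Hz=summary.frequency,
        V_t_out_mV=out.value,
        oscillatory_flag=out.oscillatory,
        pain=pain_decision(out.value, config.gct),
    )


def sweep_amplitude(config: ScenarioConfig) -> list[SweepResult]:
    """One pipeline run per pressure amplitude in ``config.q_grid`` (ascending)."""
    grid = config.q_grid
    if not grid:
        raise ValueError("q_grid must be non-empty")
    if list(grid) != sorted(grid):
        raise ValueError("q_grid must be sorted ascending")
    return [run_scenario(config.replace(q=q)) for q in grid]


def sweep_depth(config: ScenarioConfig) -> list[SweepResult]:
    """One pipeline run per on-axis nociceptor depth in ``config.depth_grid``."""
    grid = config.depth_grid
    if not grid:
        raise ValueError("depth_grid must be non-empty")
    if list(grid) != sorted(grid):
        raise ValueError("depth_grid must be sorted ascending")
    return [run_scenario(config.replace(depth=d)) for d in grid]


def results_to_frame(results: list[SweepResult]) -> pd.DataFrame:
    """Tidy table (one row per scenario) with the documented column order."""
    return pd.DataFrame([dataclasses.asdict(r) for r in results])[RESULT_COLUMNS]


def write_outputs(results: list[SweepResult], config: ScenarioConfig, out_prefix) -> None:
    """Write <prefix>.csv plus a <prefix>.params.json sidecar of resolved parameters."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    results_to_frame(results).to_csv(prefix.with_suffix(".csv"), index=False)
    with open(prefix.with_suffix(".params.json"), "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
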