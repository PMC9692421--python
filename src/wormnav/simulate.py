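"""Closed-loop episode execution and benchmark orchestration.

An episode couples environment -> sensor -> circuit -> steering -> motion at
a fixed 0.01 s step: the head-tip concentration is sampled, the ASEL/ASER
sensors respond, the circuit produces the Joint-1 angle, the heading and
position advance, and arrival within the scenario's 1 mm radius is tested.
A 10 s in-place warm-up (zero sensory input, body frozen) precedes motion so
the rhythm is established and the dC history starts clean.

Strategy ablations operate on the parameter set: the klinotaxis-only variant
severs the SMDV->VM0 klinokinesis path (w_m0_smdv = 0) and the
klinokinesis-only variant severs the sensory gating of the SMB neurons
(w_smb_asel = w_smb_aser = 0).  Episodes contain no randomness and are fully
deterministic given their configuration.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _kernels as K
from .environment import BenchmarkSuite, Scenario, make_benchmark_suite
from .params import ModelParams, default_params

__all__ = [
    "VARIANTS",
    "SimConfig",
    "EpisodeResult",
    "apply_ablation",
    "run_episode",
    "run_benchmark",
    "summarize_benchmark",
]

VARIANTS = ("parallel", "klinokinesis_only", "klinotaxis_only")


@dataclass
class SimConfig:
    """Configuration of a single episode."""

    scenario: Scenario = field(default_factory=Scenario)
    initial_xy: tuple[float, float] = (20.0, -10.0)
    initial_psi: float = 0.0
    variant: str = "parallel"
    adaptive: bool = True
    a_coefficient: float | None = None   # overrides ase.a (non-adaptive runs)
    dt: float | None = None              # default: params.sim.dt
    max_duration: float | None = None    # default: 10x shortest-path time
    record: bool = False
    record_stride: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")


@dataclass
class EpisodeResult:
    """Outcome of one episode."""

    arrived: bool
    arrival_time: float          # s, NaN if not arrived
    ssr: float                   # search-time / shortest-path time, NaN if not arrived
    min_distance: float          # mm, closest approach to the peak
    shortest_time: float         # s, straight-line distance / speed
    trajectory: pd.DataFrame | None
    metadata: dict


def apply_ablation(params: ModelParams, variant: str) -> ModelParams:
    """Return a parameter copy with one steering pathway severed."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; one of {VARIANTS}")
    out = copy.deepcopy(params)
    if variant == "klinotaxis_only":
        # remove klinokinesis: no SMDV drive onto VM0
        out.head.w_m0_smdv = 0.0
    elif variant == "klinokinesis_only":
        # remove klinotaxis: no sensory gating of the SMB neurons
        out.head.w_smb_asel = 0.0
        out.head.w_smb_aser = 0.0
    return out


def run_episode(cfg: SimConfig, params: ModelParams | None = None) -> EpisodeResult:
    """Run one closed-loop episode; fully deterministic given ``cfg``."""
    params = params if params is not None else default_params()
    p = apply_ablation(params, cfg.variant)
    if cfg.a_coefficient is not None:
        p.ase.a = float(cfg.a_coefficient)
    dt = cfg.dt if cfg.dt is not None else p.sim.dt
    sc = cfg.scenario
    x0, y0 = cfg.initial_xy
    d0 = float(np.hypot(x0 - sc.peak_xy[0], y0 - sc.peak_xy[1]))
    shortest_time = d0 / p.body.speed
    max_duration = cfg.max_duration if cfg.max_duration is not None \
        else 10.0 * shortest_time
    warmup_steps = int(round(p.sim.warmup / dt))
    max_steps = int(round(max_duration / dt))

    tau, w, e_rest, bias, head, vnc, ase = K.pack_params(p)
    state = K.init_state_vector(p)
    ase_state, buf = K.init_ase_state(p)
    stride = cfg.record_stride if cfg.record else 0
    n_rows = (max_steps // max(stride, 1) + 2) if stride else 1
    rec = np.zeros((n_rows, K.NREC))

    arrived, arrival_time, min_dist, nrec = K.run_episode(
        state, ase_state, buf, tau, w, e_rest, bias, head, vnc, ase,
        p.body.speed, p.body.steer_tau,
        sc.peak_xy[0], sc.peak_xy[1], sc.c_max, sc.sigma,
        x0, y0, cfg.initial_psi,
        dt, warmup_steps, max_steps, cfg.adaptive, sc.arrival_radius,
        rec, stride)

    if not np.all(np.isfinite(state)):
        raise FloatingPointError(
            "numeric blow-up during episode integration; "
            f"config: {cfg!r}")

    traj = pd.DataFrame(rec[:nrec], columns=K.REC_COLUMNS) if stride else None
    ssr = arrival_time / shortest_time if arrived else float("nan")
    meta = {
        "variant": cfg.variant, "adaptive": cfg.adaptive,
        "a_coefficient": cfg.a_coefficient,
        "c_max": sc.c_max, "sigma": sc.sigma,
        "x0": x0, "y0": y0, "psi0": cfg.initial_psi,
        "dt": dt, "max_duration": max_duration, "warmup": p.sim.warmup,
        "seed": cfg.seed,
    }
    return EpisodeResult(arrived=bool(arrived), arrival_time=float(arrival_time),
                         ssr=float(ssr), min_distance=float(min_dist),
                         shortest_time=shortest_time, trajectory=traj,
                         metadata=meta)


def run_benchmark(suite: BenchmarkSuite | None = None,
                  variants: Sequence[str] = ("parallel",),
                  params: ModelParams | None = None,
                  adaptive: bool = True,
                  a_coefficient: float | None = None,
                  episode_filter=None,
                  record: bool = False) -> pd.DataFrame:
    """Run the benchmark suite for each variant; one row per episode.

    ``episode_filter`` optionally receives (scenario_index, position,
    orientation) and may return False to skip an episode (used for reduced
    subsets).  Episode failures are recorded as non-arrivals, not raised.
    """
    suite = suite or make_benchmark_suite()
    params = params if params is not None else default_params()
    rows = []
    for variant in variants:
        for si, sc, pos, psi in suite.episodes():
            if episode_filter is not None and not episode_filter(si, pos, psi):
                continue
            cfg = SimConfig(scenario=sc, initial_xy=pos, initial_psi=psi,
                            variant=variant, adaptive=adaptive,
                            a_coefficient=a_coefficient, record=record)
            try:
                res = run_episode(cfg, params)
                err = ""
            except FloatingPointError as exc:  # pragma: no cover - defensive
                res = None
                err = str(exc)
            rows.append({
                "variant": variant, "adaptive": adaptive,
                "a_coefficient": a_coefficient,
                "scenario": si, "c_max": sc.c_max, "sigma": sc.sigma,
                "x0": pos[0], "y0": pos[1], "psi0": psi,
                "arrived": res.arrived if res else False,
                "arrival_time": res.arrival_time if res else float("nan"),
                "ssr": res.ssr if res else float("nan"),
                "min_distance": res.min_distance if res else float("nan"),
                "error": err,
            })
    return pd.DataFrame(rows)


def summarize_benchmark(episodes: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per variant: arrival rate and pooled mean +- s.d. SSR
    (SSR pooled over arrived episodes only, as in the benchmark metrics)."""
    groups = []
    for (variant, adaptive, a_c), grp in episodes.groupby(
            ["variant", "adaptive", "a_coefficient"], dropna=False):
        arrived = grp["arrived"]
        ssr = grp.loc[arrived, "ssr"]
        groups.append({
            "variant": variant, "adaptive": adaptive, "a_coefficient": a_c,
            "n_episodes": len(grp),
            "arrival_rate": float(arrived.mean()),
            "mean_ssr": float(ssr.mean()) if len(ssr) else float("nan"),
            "sd_ssr": float(ssr.std(ddof=1)) if len(ssr) > 1 else float("nan"),
        })
    return pd.DataFrame(groups)
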