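"""World-frame kinematics of the 12-rod body.

The body is kinematic, not dynamic: the head tip moves at constant speed
``v`` along the heading ``psi``, and the heading turns at a rate proportional
to the commanded Joint-1 angle (``psi_dot = theta1 / steer_tau``).  A
symmetric theta1 oscillation therefore integrates to a straight sinusoidal
trajectory, while any cumulative dorsal-ventral output asymmetry becomes a
permanent heading change -- exactly the cumulative output difference the
steering analysis measures.  The remaining twelve nodes are reconstructed by
chaining rods tail-ward from the head with the eleven joint angles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import BodyConfig

__all__ = [
    "BodyState",
    "update_heading",
    "advance_head",
    "reconstruct_body",
    "measure_wavelength",
]


@dataclass
class BodyState:
    """Head position (mm), heading (rad) and the 13 node positions."""

    head_xy: np.ndarray
    heading: float
    node_xy: np.ndarray  # (13, 2)


def update_heading(psi: float, theta1: float, cfg: BodyConfig, dt: float) -> float:
    """Heading rate proportional to the commanded bend: psi += theta1/steer_tau*dt."""
    return psi + (theta1 / cfg.steer_tau) * dt


def advance_head(p1, psi: float, cfg: BodyConfig, dt: float) -> np.ndarray:
    """Constant-speed propulsion of the head tip along the heading."""
    p1 = np.asarray(p1, dtype=float)
    return p1 + cfg.speed * dt * np.array([np.cos(psi), np.sin(psi)])


def reconstruct_body(p1, psi: float, theta: np.ndarray,
                     cfg: BodyConfig) -> np.ndarray:
    """Chain the rods tail-ward from the head tip.

    Rod 1 points along ``psi``; each joint angle rotates the next rod
    clockwise relative to its anterior neighbour (alpha_{k+1} = alpha_k -
    theta_k, so a positive theta bends the anterior rod counterclockwise
    relative to the posterior one).  Returns the (n_rods + 1, 2) node array,
    node 0 = head tip.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (cfg.n_joints,):
        raise ValueError(f"expected {cfg.n_joints} joint angles, got {theta.shape}")
    alphas = psi - np.concatenate(([0.0], np.cumsum(theta)))
    nodes = np.empty((cfg.n_nodes, 2))
    nodes[0] = np.asarray(p1, dtype=float)
    steps = cfg.rod_length * np.stack([np.cos(alphas), np.sin(alphas)], axis=1)
    nodes[1:] = nodes[0] - np.cumsum(steps, axis=0)
    return nodes


def measure_wavelength(node_xy: np.ndarray, translation_dir: float,
                       cfg: BodyConfig | None = None) -> float:
    """Undulation wavelength / body length from a body snapshot.

    Takes the lateral offsets of the nodes perpendicular to the translation
    direction (about their mean) and estimates the spatial period as the
    distance *along the body* (arc length, node spacing = rod length) between
    alternate zero crossings of the lateral profile, with linear
    interpolation between nodes.  The arc-length abscissa makes the measure
    independent of how much the undulation compresses the body's projection
    onto the translation axis, so for a consistent travelling wave it equals
    the path length per cycle v*Tosc.  Raises if the body carries no wave.
    """
    cfg = cfg or BodyConfig()
    nodes = np.asarray(node_xy, dtype=float)
    u = np.array([np.cos(translation_dir), np.sin(translation_dir)])
    n = np.array([-u[1], u[0]])
    s = -cfg.rod_length * np.arange(len(nodes))  # arc position, head at 0
    lat = nodes @ n
    lat = lat - lat.mean()
    if np.max(np.abs(lat)) < 1e-9:
        raise ValueError("no undulation wave: fewer than 2 lateral zero crossings")
    crossings = []
    for i in range(len(lat) - 1):
        if lat[i] * lat[i + 1] < 0:
            frac = -lat[i] / (lat[i + 1] - lat[i])
            crossings.append(s[i] + frac * (s[i + 1] - s[i]))
    if len(crossings) < 2:
        raise ValueError("no undulation wave: fewer than 2 lateral zero crossings")
    crossings = np.asarray(crossings)
    if len(crossings) >= 3:
        wavelength = float(np.mean(np.abs(crossings[2:] - crossings[:-2])))
    else:
        wavelength = 2.0 * float(abs(crossings[1] - crossings[0]))
    return wavelength / cfg.length
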