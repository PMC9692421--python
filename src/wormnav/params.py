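"""Parameter containers for the worm model and strict YAML (de)serialisation.

The model is split into four parameter groups mirroring the circuit layout:

* :class:`CPGParams` -- the three-neuron central pattern generator (15 free
  parameters, normally obtained by evolution, see :mod:`wormnav.cpg`).
* :class:`HeadParams` -- head motoneurons (SMBD/V, SMDV) and head muscles
  (DM0/VM0) that turn the CPG rhythm into the Joint-1 angle and inject the
  two steering pathways.
* :class:`VNCParams` -- the single parameter set shared by all ten repeating
  ventral-nerve-cord units that propagate the bending wave to Joints 2-11.
* :class:`ASEParams` -- the adaptive conductance-based ASEL/ASER chemosensors.

:class:`BodyConfig` holds the kinematic constants of the 12-rod body and
:class:`ModelParams` bundles everything, including load/save round-trips to a
flat YAML file with strict schema validation (unknown keys are rejected).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

__all__ = [
    "CPGParams",
    "HeadParams",
    "VNCParams",
    "ASEParams",
    "BodyConfig",
    "SimSettings",
    "ModelParams",
    "default_params",
]

_DATA_DIR = Path(__file__).parent / "data"
DEFAULT_PARAM_FILE = _DATA_DIR / "default_params.yaml"


class ParameterError(ValueError):
    """Raised when a parameter file violates the schema or a range constraint."""


def _as_array(x: Any, n: int, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape != (n,):
        raise ParameterError(f"{name} must have shape ({n},), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name} contains non-finite values")
    return arr


@dataclass
class CPGParams:
    """Three coupled leaky-integrator neurons C1-C3.

    ``tau`` (s), ``w`` (3x3 connection weights, zero diagonal -- the six
    directed off-diagonal connections are the evolvable ones), ``e_rest`` and
    ``bias`` (mV).  Evolution ranges: tau in [0.05, 2], everything else in
    [-10, 10].
    """

    tau: np.ndarray
    w: np.ndarray
    e_rest: np.ndarray
    bias: np.ndarray

    def __post_init__(self) -> None:
        self.tau = _as_array(self.tau, 3, "cpg.tau")
        self.e_rest = _as_array(self.e_rest, 3, "cpg.e_rest")
        self.bias = _as_array(self.bias, 3, "cpg.bias")
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (3, 3):
            raise ParameterError(f"cpg.w must be 3x3, got {self.w.shape}")
        if not np.all(np.isfinite(self.w)):
            raise ParameterError("cpg.w contains non-finite values")
        if np.any(np.abs(np.diag(self.w)) > 1e-12):
            raise ParameterError("cpg.w must have a zero diagonal (no self-connections)")
        if np.any(self.tau < 0.05 - 1e-9) or np.any(self.tau > 2 + 1e-9):
            raise ParameterError("cpg.tau outside the evolution range [0.05, 2] s")
        for name, arr in (("w", self.w), ("e_rest", self.e_rest), ("bias", self.bias)):
            if np.any(np.abs(arr) > 10 + 1e-9):
                raise ParameterError(f"cpg.{name} outside the evolution range [-10, 10]")

    def to_dict(self) -> dict:
        return {
            "tau": self.tau.tolist(),
            "w": self.w.tolist(),
            "e_rest": self.e_rest.tolist(),
            "bias": self.bias.tolist(),
        }


@dataclass
class HeadParams:
    """Head circuit: SMBD/V and SMDV motoneurons, DM0/VM0 muscles, Joint 1.

    Sign conventions (enforced at load time): the CPG output neuron C3 excites
    SMBD and inhibits SMBV with the same magnitude ``w_smbd_c3`` (> 0, the
    SMBV weight is defined as its negative and is not stored); ASEL inhibits
    and ASER excites both SMB neurons (``w_smb_asel`` < 0, ``w_smb_aser`` > 0);
    the muscle output bias ``b0m`` < 0 parks both muscle outputs in the lower
    saturation region of the logistic, which implements the state-dependent
    gating that klinotaxis relies on.

    ``b_smdv`` is the threshold bias of the ASER->SMDV synaptic gate: the gate
    is the baseline-subtracted logistic sigma(v_aser + b_smdv) - sigma(b_smdv),
    so SMDV is exactly silent at rest and responds in a thresholded, saturating
    fashion to sustained ASER depolarisation (the klinokinesis logic function).
    """

    tau_smb: float
    e_smb_rest: float
    w_smbd_c3: float
    w_smb_asel: float
    w_smb_aser: float
    tau_a0: float
    w_m0_smb: float
    w_m0_smdv: float
    b0m: float
    omega0: float
    tau_smdv: float
    e_smdv_rest: float
    w_smdv_aser: float
    e_smdv_aser: float
    b_smdv: float

    def __post_init__(self) -> None:
        for name in ("tau_smb", "tau_a0", "tau_smdv"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"head.{name} must be > 0")
        if self.w_smbd_c3 <= 0:
            raise ParameterError("head.w_smbd_c3 must be > 0 (SMBV gets the negative)")
        if self.w_smb_asel >= 0:
            raise ParameterError("head.w_smb_asel must be < 0 (ASEL inhibits SMB)")
        if self.w_smb_aser <= 0:
            raise ParameterError("head.w_smb_aser must be > 0 (ASER excites SMB)")
        if self.w_m0_smb <= 0 or self.w_m0_smdv <= 0:
            raise ParameterError("head neuromuscular weights must be > 0")
        if self.b0m >= 0:
            raise ParameterError("head.b0m must be < 0 (lower-saturation gating)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class VNCParams:
    """One repeating VNC unit (DB/VB neuron pair + DM/VM muscle pair).

    All ten units share this parameter set.  ``w_shape``/``e_shape``/``p``
    index ``j = 0`` (proprioceptive feedback from the unit's own joint) and
    ``j = 1`` (drive from the anterior joint).
    """

    tau_b: float
    e_b_rest: float
    w_shape: np.ndarray
    e_shape: np.ndarray
    p: np.ndarray
    tau_am: float
    w_am_b: float
    b1m: float
    omega1: float

    def __post_init__(self) -> None:
        self.w_shape = _as_array(self.w_shape, 2, "vnc.w_shape")
        self.e_shape = _as_array(self.e_shape, 2, "vnc.e_shape")
        self.p = _as_array(self.p, 2, "vnc.p")
        if self.tau_b <= 0 or self.tau_am <= 0:
            raise ParameterError("vnc time constants must be > 0")

    def to_dict(self) -> dict:
        return {
            "tau_b": self.tau_b,
            "e_b_rest": self.e_b_rest,
            "w_shape": self.w_shape.tolist(),
            "e_shape": self.e_shape.tolist(),
            "p": self.p.tolist(),
            "tau_am": self.tau_am,
            "w_am_b": self.w_am_b,
            "b1m": self.b1m,
            "omega1": self.omega1,
        }


@dataclass
class ASEParams:
    """Adaptive conductance-based ASEL/ASER sensory neurons.

    ``a`` and ``b`` (1/mM) set the gradient sensitivity and the strength of
    the divisive adaptation by the windowed mean |dC| (window ``window_n``
    seconds, sampled every ``sample_dt`` seconds).  Both neurons share all
    constants; they differ only in the sign of dC they respond to.
    """

    tau_ase: float
    e_ase_rest: float
    e_ase_ext: float
    g_max: float
    tau_g: float
    a: float
    b: float
    window_n: float
    sample_dt: float

    def __post_init__(self) -> None:
        if self.g_max <= 0:
            raise ParameterError("ase.g_max must be > 0")
        if self.a <= 0 or self.b <= 0:
            raise ParameterError("ase.a and ase.b must be > 0")
        if self.window_n <= 0 or self.sample_dt <= 0:
            raise ParameterError("ase.window_n and ase.sample_dt must be > 0")
        if self.e_ase_ext <= self.e_ase_rest:
            raise ParameterError("ase.e_ase_ext must exceed e_ase_rest (depolarising)")
        for name in ("tau_ase", "tau_g"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"ase.{name} must be > 0")

    @property
    def window_samples(self) -> int:
        return max(1, int(round(self.window_n / self.sample_dt)))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class BodyConfig:
    """Kinematic constants of the 12-rod body (lengths in mm, speed in mm/s)."""

    rod_length: float = 0.1
    n_rods: int = 12
    speed: float = 0.25
    steer_tau: float = 1.0

    def __post_init__(self) -> None:
        if self.rod_length <= 0 or self.speed <= 0 or self.steer_tau <= 0:
            raise ParameterError("body.rod_length, speed and steer_tau must be > 0")
        if self.n_rods < 2:
            raise ParameterError("body.n_rods must be >= 2")

    @property
    def n_joints(self) -> int:
        return self.n_rods - 1

    @property
    def n_nodes(self) -> int:
        return self.n_rods + 1

    @property
    def length(self) -> float:
        return self.n_rods * self.rod_length

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimSettings:
    """Integration settings shared by every simulation."""

    dt: float = 0.01
    warmup: float = 10.0
    arrival_radius: float = 1.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ParameterError("sim.dt must be > 0")
        if self.warmup < 0:
            raise ParameterError("sim.warmup must be >= 0")
        if self.arrival_radius <= 0:
            raise ParameterError("sim.arrival_radius must be > 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "cpg": CPGParams,
    "head": HeadParams,
    "vnc": VNCParams,
    "ase": ASEParams,
    "body": BodyConfig,
    "sim": SimSettings,
}


@dataclass
class ModelParams:
    """The complete parameter set of the model."""

    cpg: CPGParams
    head: HeadParams
    vnc: VNCParams
    ase: ASEParams
    body: BodyConfig = field(default_factory=BodyConfig)
    sim: SimSettings = field(default_factory=SimSettings)

    def replace(self, **groups: Any) -> "ModelParams":
        """Return a copy with whole sections replaced (``head=...`` etc.)."""
        return dataclasses.replace(self, **groups)

    def copy(self) -> "ModelParams":
        return ModelParams.from_dict(self.to_dict())

    # -- serialisation ----------------------------------------------------

    def to_dict(self) -> dict:
        return {name: getattr(self, name).to_dict() for name in _SECTIONS}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        if not isinstance(data, dict):
            raise ParameterError("parameter document must be a mapping")
        unknown = set(data) - set(_SECTIONS)
        if unknown:
            raise ParameterError(f"unknown parameter sections: {sorted(unknown)}")
        kwargs = {}
        for name, klass in _SECTIONS.items():
            if name not in data:
                if name in ("body", "sim"):
                    kwargs[name] = klass()
                    continue
                raise ParameterError(f"missing parameter section '{name}'")
            section = data[name]
            if not isinstance(section, dict):
                raise ParameterError(f"section '{name}' must be a mapping")
            fields = {f.name for f in dataclasses.fields(klass)}
            bad = set(section) - fields
            if bad:
                raise ParameterError(f"unknown keys in section '{name}': {sorted(bad)}")
            missing = fields - set(section)
            if missing and name not in ("body", "sim"):
                raise ParameterError(f"missing keys in section '{name}': {sorted(missing)}")
            kwargs[name] = klass(**section)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParams":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)


def default_params() -> ModelParams:
    """Load the shipped default parameter file.

    The CPG block is a stable oscillator evolved with :func:`wormnav.cpg.evolve`;
    the head/VNC/sensor blocks were tuned with :mod:`wormnav.tuning` to satisfy
    the model's behavioural invariants (antiphase SMB voltages, ~Tosc/10 joint
    lag, straight zero-input travel, the gating phase-response structure).
    """
    return ModelParams.from_yaml(DEFAULT_PARAM_FILE)
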