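"""Generative (forward) model: bilinear neural dynamics plus hemodynamics.

Neural dynamics follow the bilinear state equation

    dx/dt = (A + sum_j u_j(t) B^j) x + C u(t)

with A the endogenous coupling (1/s), B^j the input-dependent modulation of
coupling, and C the direct driving-input gains. The observation model is the
balloon-Windkessel hemodynamic cascade (vasodilatory signal s, inflow f,
venous volume v, deoxyhemoglobin q) with the classic BOLD output equation;
output is percent signal change about a zero baseline, decimated to the
scanner TR with optional additive white Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .model_space import DCMModelSpec, INPUT_LABELS

__all__ = [
    "DCMParameters",
    "InputTimeline",
    "NeuralTrajectory",
    "HemodynamicParams",
    "BOLDSeries",
    "DivergenceError",
    "integrate_neural",
    "balloon_transform",
    "simulate_bold",
    "sample_and_noise",
    "parameters_from_masks",
]


class DivergenceError(RuntimeError):
    """Neural state left the finite range (unstable parameters)."""


@dataclass
class DCMParameters:
    """Numeric A/B/C coupling values for one subject and model structure.

    A is (n, n) in 1/s with strictly negative diagonal; B is (m, n, n) with
    one slice per input; C is (n, m). Entries outside the model's masks must
    be exactly zero.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if self.B.ndim != 3 or self.B.shape[1:] != (n, n):
            raise ValueError("B must be (m, n, n)")
        if self.C.shape != (n, self.B.shape[0]):
            raise ValueError("C must be (n, m)")
        if np.any(np.diag(self.A) >= 0):
            raise ValueError("diagonal of A must be strictly negative")

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]

    @property
    def m(self) -> int:
        return self.B.shape[0]

    def validate_masks(self, model: DCMModelSpec) -> None:
        """Check that entries outside the model's structural masks are zero."""
        if np.any(self.A[~model.a_mask] != 0):
            raise ValueError("A has nonzero entries outside a_mask")
        if np.any(self.B[~model.b_mask] != 0):
            raise ValueError("B has nonzero entries outside b_mask")
        if np.any(self.C[~model.c_mask] != 0):
            raise ValueError("C has nonzero entries outside c_mask")


@dataclass
class InputTimeline:
    """Experimental inputs u_j(t) on a uniform fine grid.

    ``u`` is (T, m) with values in [0, 1]; ``labels`` names the inputs
    (fixation, visual stimulation and the two switch types by default).
    Switch inputs are brief rectangular pulses at the (reaction-time
    corrected) switch times.
    """

    u: np.ndarray
    dt: float
    labels: tuple[str, ...] = INPUT_LABELS

    def __post_init__(self) -> None:
        self.u = np.atleast_2d(np.asarray(self.u, dtype=float))
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.u.shape[1] != len(self.labels):
            raise ValueError("u columns must match labels")

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.u.shape[0]) * self.dt

    @property
    def duration(self) -> float:
        return (self.u.shape[0] - 1) * self.dt

    @classmethod
    def from_events(
        cls,
        boxcars: dict[str, Sequence[tuple[float, float]]],
        pulses: dict[str, Sequence[float]],
        duration: float,
        dt: float = 0.05,
        pulse_width: float = 1.0,
        labels: tuple[str, ...] = INPUT_LABELS,
    ) -> "InputTimeline":
        """Build the timeline from (onset, duration) boxcars and pulse times."""
        T = int(round(duration / dt)) + 1
        u = np.zeros((T, len(labels)))
        for name, intervals in boxcars.items():
            j = labels.index(name)
            for onset, dur in intervals:
                a = int(round(onset / dt))
                b = int(round((onset + dur) / dt))
                u[max(a, 0): min(b, T), j] = 1.0
        for name, times in pulses.items():
            j = labels.index(name)
            w = max(1, int(round(pulse_width / dt)))
            for t0 in times:
                a = int(round(t0 / dt))
                u[max(a, 0): min(a + w, T), j] = 1.0
        return cls(u=u, dt=dt, labels=labels)


@dataclass
class NeuralTrajectory:
    """Per-region neural state over time (arbitrary activity units)."""

    x: np.ndarray
    dt: float

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.x.shape[0]) * self.dt


@dataclass
class HemodynamicParams:
    """Balloon-Windkessel constants (canonical DCM-for-fMRI defaults)."""

    kappa: float = 0.64   # vasodilatory signal decay, 1/s
    gamma: float = 0.32   # flow autoregulation, 1/s
    tau: float = 2.0      # venous transit time, s
    alpha: float = 0.32   # vessel stiffness exponent
    E0: float = 0.4       # resting oxygen extraction fraction
    V0: float = 0.04      # resting venous volume fraction
    k1: float = field(default=None)  # type: ignore[assignment]
    k2: float = 2.0
    k3: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.k1 is None:
            self.k1 = 7.0 * self.E0
        if self.k3 is None:
            self.k3 = 2.0 * self.E0 - 0.2
        for name in ("kappa", "gamma", "tau", "V0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.E0 < 1:
            raise ValueError("E0 must lie in (0, 1)")


@dataclass
class BOLDSeries:
    """Per-region BOLD sampled at the TR grid, percent signal change."""

    y: np.ndarray
    TR: float = 2.1
    region_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        if self.region_labels is None:
            self.region_labels = tuple(f"roi{i}" for i in range(self.y.shape[1]))

    @property
    def n_volumes(self) -> int:
        return self.y.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.TR

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.y, columns=list(self.region_labels))
        df.insert(0, "time_s", self.t)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def from_tsv(cls, path) -> "BOLDSeries":
        df = pd.read_csv(path, sep="\t")
        t = df.pop("time_s").to_numpy()
        TR = float(t[1] - t[0]) if len(t) > 1 else 2.1
        return cls(y=df.to_numpy(), TR=TR, region_labels=tuple(df.columns))


def _check_finite(x: np.ndarray, dt: float) -> None:
    bad = ~np.isfinite(x).all(axis=1)
    if bad.any():
        t_bad = int(np.argmax(bad)) * dt
        raise DivergenceError(
            f"neural state became non-finite at t = {t_bad:.3f} s "
            "(unstable parameters)"
        )


def integrate_neural(
    params: DCMParameters,
    inputs: InputTimeline,
    x0: np.ndarray | None = None,
) -> NeuralTrajectory:
    """Integrate the bilinear neural ODE with classical RK4 on the input grid."""
    n = params.n_regions
    if params.m != inputs.u.shape[1]:
        raise ValueError(
            f"parameter input count m={params.m} does not match "
            f"timeline with {inputs.u.shape[1]} inputs"
        )
    if x0 is None:
        x0 = np.zeros(n)
    x0 = np.asarray(x0, dtype=float)
    x = _kernels.integrate_neural_rk4(
        inputs.u, params.A, params.B, params.C, x0, inputs.dt
    )
    _check_finite(x, inputs.dt)
    return NeuralTrajectory(x=x, dt=inputs.dt)


def balloon_transform(
    traj: NeuralTrajectory, h: HemodynamicParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Hemodynamic states (s, f, v, q) and fine-grid BOLD for a trajectory.

    Returns ``(states, y_fine)`` where states is (T, n, 4) and y_fine is
    (T, n) percent signal change.
    """
    if h is None:
        h = HemodynamicParams()
    states, y = _kernels.integrate_balloon_rk4(
        np.ascontiguousarray(traj.x, dtype=float),
        h.kappa, h.gamma, h.tau, h.alpha, h.E0, h.V0, h.k1, h.k2, h.k3,
        traj.dt,
    )
    return states, y


def simulate_bold(
    params: DCMParameters,
    inputs: InputTimeline,
    h: HemodynamicParams | None = None,
    x0: np.ndarray | None = None,
) -> np.ndarray:
    """Fine-grid BOLD (percent signal change) from parameters and inputs."""
    traj = integrate_neural(params, inputs, x0=x0)
    _, y = balloon_transform(traj, h)
    return y


def sample_and_noise(
    y_fine: np.ndarray,
    dt: float,
    TR: float,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    region_labels: tuple[str, ...] | None = None,
) -> BOLDSeries:
    """Decimate a fine-grid signal to the TR grid and add white Gaussian noise."""
    step = TR / dt
    if abs(step - round(step)) > 1e-9:
        raise ValueError(f"TR={TR} is not an integer multiple of dt={dt}")
    step = int(round(step))
    y = np.atleast_2d(np.asarray(y_fine, dtype=float))[::step].copy()
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if noise_sd > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        y += rng.normal(0.0, noise_sd, size=y.shape)
    return BOLDSeries(y=y, TR=TR, region_labels=region_labels)


def parameters_from_masks(
    model: DCMModelSpec,
    a_values: dict[tuple[str, str], float] | None = None,
    b_values: dict[tuple[str, str, str], float] | None = None,
    c_values: dict[tuple[str, str], float] | None = None,
    self_coupling: float = -0.5,
) -> DCMParameters:
    """Build DCMParameters on a model's masks from sparse (source, target) maps.

    ``a_values`` maps (source, target) -> rate; ``b_values`` maps
    (input_label, source, target); ``c_values`` maps (input_label, region).
    Entries not listed default to zero; keys outside the masks raise.
    """
    regions = model.regions
    n, m = regions.n, len(INPUT_LABELS)
    A = np.diag(np.full(n, self_coupling))
    B = np.zeros((m, n, n))
    C = np.zeros((n, m))
    a_mask, b_mask, c_mask = model.a_mask, model.b_mask, model.c_mask
    for (src, tgt), val in (a_values or {}).items():
        i, j = regions.index(tgt), regions.index(src)
        if not a_mask[i, j]:
            raise ValueError(f"A connection {src}->{tgt} outside a_mask")
        A[i, j] = val
    for (label, src, tgt), val in (b_values or {}).items():
        k = INPUT_LABELS.index(label)
        i, j = regions.index(tgt), regions.index(src)
        if not b_mask[k, i, j]:
            raise ValueError(f"B[{label}] {src}->{tgt} outside b_mask")
        B[k, i, j] = val
    for (label, region), val in (c_values or {}).items():
        k = INPUT_LABELS.index(label)
        i = regions.index(region)
        if not c_mask[i, k]:
            raise ValueError(f"C[{label}] -> {region} outside c_mask")
        C[i, k] = val
    return DCMParameters(A=A, B=B, C=C)
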