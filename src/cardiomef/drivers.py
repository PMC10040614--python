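"""Synthetic driving signals and small ready-made configurations.

In the full organ model the wall solve supplies each cell with its stretch
history and the ionic model supplies calcium; the generators here stand in
for those signals so that the cell-level models are testable in isolation,
and the fixture registry provides complete fast-running heart configurations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "StretchProtocol",
    "CalciumTransientSpec",
    "make_stretch",
    "make_calcium",
    "make_fixture",
    "FIXTURE_NAMES",
]

_KINDS = ("hold", "step", "ramp", "sinusoid", "quick-release")


@dataclass(frozen=True)
class StretchProtocol:
    """Piecewise-analytic fiber stretch waveform lambda(t).

    kinds: hold (constant baseline), step (jump by ``amplitude`` at
    ``onset``), ramp (linear at ``rate`` from ``onset``), sinusoid
    (baseline + amplitude * sin(2 pi (t-onset)/period) after onset),
    quick-release (held at baseline+amplitude, released to baseline at onset).
    """

    kind: str = "hold"
    baseline: float = 1.0
    amplitude: float = 0.0
    onset: float = 0.0
    rate: float = 0.0        # 1/ms, for ramp
    period: float = 600.0    # ms, for sinusoid
    duration: float = 600.0  # ms

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown stretch protocol kind {self.kind!r}")
        if self.duration <= 0 or self.period <= 0:
            raise ValueError("duration and period must be > 0")

    def evaluate(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """lambda(t) and its exact analytic derivative."""
        t = np.asarray(t, dtype=float)
        lam = np.full_like(t, self.baseline)
        dlam = np.zeros_like(t)
        on = t >= self.onset
        if self.kind == "step":
            lam = np.where(on, self.baseline + self.amplitude, lam)
        elif self.kind == "quick-release":
            lam = np.where(on, self.baseline, self.baseline + self.amplitude)
        elif self.kind == "ramp":
            lam = np.where(on, self.baseline + self.rate * (t - self.onset), lam)
            dlam = np.where(on, self.rate, 0.0)
        elif self.kind == "sinusoid":
            w = 2.0 * math.pi / self.period
            ph = w * (t - self.onset)
            lam = np.where(on, self.baseline + self.amplitude * np.sin(ph), lam)
            dlam = np.where(on, self.amplitude * w * np.cos(ph), 0.0)
        return lam, dlam


def make_stretch(protocol: StretchProtocol, dt: float):
    """Sampled (t, lambda, lambda_dot) series over the protocol duration.

    The derivative is the protocol's analytic derivative (zero across jump
    discontinuities), never a finite difference. Raises if the waveform
    leaves the admissible band (0.7, 1.3).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, protocol.duration + 0.5 * dt, dt)
    lam, dlam = protocol.evaluate(t)
    if lam.min() <= 0.7 or lam.max() >= 1.3:
        raise ValueError("stretch protocol leaves the admissible band (0.7, 1.3)")
    return t, lam, dlam


@dataclass(frozen=True)
class CalciumTransientSpec:
    """Idealized intracellular calcium transient (mM), one peak per cycle:

        Cai(t) = diastolic + amplitude * (t/tau_p) * exp(1 - t/tau_p)

    (so the peak equals diastolic + amplitude at exactly t = tau_p). If
    ``decay_tau`` is given, a two-timescale rise/decay product is used
    instead, normalized to the same peak value and peak time.
    """

    diastolic: float = 1.0e-4
    amplitude: float = 7.5e-4
    time_to_peak: float = 40.0
    decay_tau: Optional[float] = None
    cycle_length: float = 600.0

    def __post_init__(self) -> None:
        if min(self.diastolic, self.amplitude, self.time_to_peak,
               self.cycle_length) <= 0:
            raise ValueError("all calcium-transient parameters must be > 0")
        if self.decay_tau is not None and self.decay_tau <= 0:
            raise ValueError("decay_tau must be > 0")

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        t = np.mod(np.asarray(t, dtype=float), self.cycle_length)
        tp = self.time_to_peak
        if self.decay_tau is None:
            shape = (t / tp) * np.exp(1.0 - t / tp)
        else:
            td = self.decay_tau
            # rise constant chosen so the product peaks at t = tau_p
            def peak_err(tr):
                return tr * math.log(1.0 + td / tr) - tp
            tr = brentq(peak_err, 1e-6, 100.0 * tp)
            f = (1.0 - np.exp(-t / tr)) * np.exp(-t / td)
            fpk = (1.0 - math.exp(-tp / tr)) * math.exp(-tp / td)
            shape = f / fpk
        return self.diastolic + self.amplitude * shape


def make_calcium(spec: CalciumTransientSpec, dt: float):
    """Sampled (t, Cai) series over one cycle."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0.0, spec.cycle_length + 0.5 * dt, dt)
    return t, spec.evaluate(t)


FIXTURE_NAMES = ("single-cell", "two-patch-toy", "mini-heart")


def make_fixture(name: str):
    """Complete, deterministic, fast-running configurations by name.

    - "single-cell": cell + stimulus + calcium-transient spec for cell tests.
    - "two-patch-toy": a 2-patch ventricle with 10% reference-area asymmetry
      for the equilibrium-solver oracle tests.
    - "mini-heart": a 4-patch-per-ventricle, 2-beat closed-loop configuration.
    """
    from . import config as cfg
    from .ionic import CellParams, StimulusSpec

    if name == "single-cell":
        return {
            "cell": CellParams.for_cell_type("epi"),
            "stimulus": StimulusSpec(onset=10.0),
            "cycle_length": 600.0,
            "calcium": CalciumTransientSpec(),
            "seed": 0,
        }
    if name == "two-patch-toy":
        return cfg.two_patch_toy()
    if name == "mini-heart":
        c = cfg.default_config()
        c = cfg.with_patch_counts(c, lv_free=3, septal=1, rv_free=4)
        c.protocol.n_beats = 2
        return c
    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
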