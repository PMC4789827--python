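"""Three-pool hyperpolarised magnetization dynamics.

Longitudinal magnetization of the pyruvate (P), lactate (L) and alanine (A)
pools obeys a linear exchange system with T1 losses and a rectangular bolus
input b(t) feeding pyruvate:

    dP/dt = -(k_pl + k_pa + 1/T1p) P + k_lp L + k_ap A + b(t)
    dL/dt =  k_pl P - (k_lp + 1/T1l) L
    dA/dt =  k_pa P - (k_ap + 1/T1a) A

Each RF excitation at flip angle alpha reads out a transverse component
proportional to M sin(alpha) and multiplies all longitudinal magnetizations by
cos(alpha).  Between events the system is piecewise linear time-invariant, so
propagation uses exact matrix exponentials of the augmented 4x4 system (the
fourth coordinate carries the constant bolus term); there is no step-size
error to control.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .rates import ExchangeParams, _rate_or_zero

__all__ = ["simulate_magnetization", "Propagator"]


def system_matrix(params: ExchangeParams) -> np.ndarray:
    """Exchange + relaxation generator of the three-pool system."""
    r1p = _rate_or_zero(params.t1_pyr)
    r1l = _rate_or_zero(params.t1_lac)
    r1a = _rate_or_zero(params.t1_ala)
    return np.array(
        [
            [-(params.k_pl + params.k_pa + r1p), params.k_lp, params.k_ap],
            [params.k_pl, -(params.k_lp + r1l), 0.0],
            [params.k_pa, 0.0, -(params.k_ap + r1a)],
        ]
    )


class Propagator:
    """Piecewise-exact propagator for one set of exchange parameters.

    Caches the augmented matrix exponential per (dt, bolus-on) pair, which
    makes repeated propagation over the uniform TR grid of a CSI acquisition
    cheap.
    """

    def __init__(self, params: ExchangeParams):
        self.params = params
        a = system_matrix(params)
        self._aug_on = np.zeros((4, 4))
        self._aug_on[:3, :3] = a
        self._aug_on[:3, 3] = [params.bolus_amplitude, 0.0, 0.0]
        self._aug_off = np.zeros((4, 4))
        self._aug_off[:3, :3] = a
        self._cache: dict[tuple[float, bool], np.ndarray] = {}

    def _step(self, m: np.ndarray, dt: float, bolus_on: bool) -> np.ndarray:
        if dt <= 0:
            return m
        key = (dt, bolus_on)
        e = self._cache.get(key)
        if e is None:
            e = expm((self._aug_on if bolus_on else self._aug_off) * dt)
            self._cache[key] = e
        return e[:3, :3] @ m + e[:3, 3]

    def advance(self, m: np.ndarray, t0: float, t1: float) -> np.ndarray:
        """Propagate magnetization from t0 to t1, splitting at bolus edges."""
        p = self.params
        edges = [t0]
        for edge in (p.bolus_start, p.bolus_start + p.bolus_duration):
            if t0 < edge < t1:
                edges.append(edge)
        edges.append(t1)
        for a, b in zip(edges, edges[1:]):
            mid = 0.5 * (a + b)
            on = (
                p.bolus_amplitude != 0.0
                and p.bolus_start <= mid < p.bolus_start + p.bolus_duration
            )
            m = self._step(m, b - a, on)
        return m


def simulate_magnetization(
    params: ExchangeParams,
    flip_schedule: Sequence[tuple[float, float]],
    t_grid: Sequence[float],
) -> np.ndarray:
    """Simulate three-pool longitudinal magnetization over time.

    Parameters
    ----------
    params
        Exchange/relaxation/bolus parameters; ``params.m0`` is the state at
        t = 0.
    flip_schedule
        RF events as (time s, flip angle degrees) pairs; each multiplies all
        longitudinal magnetizations by cos(flip).  Flip angles must lie in
        (0, 90].
    t_grid
        Strictly increasing sample times (s).  Samples taken at the exact
        time of an RF event report the magnetization *before* the event,
        i.e. the magnetization available to that excitation.

    Returns
    -------
    numpy.ndarray, shape (len(t_grid), 3)
        Longitudinal magnetization of (pyruvate, lactate, alanine) at each
        sample time.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    flips = sorted((float(t), float(a)) for t, a in flip_schedule)
    for _, angle in flips:
        if not 0.0 < angle <= 90.0:
            raise ValueError(f"flip angles must lie in (0, 90], got {angle}")

    prop = Propagator(params)
    m = np.asarray(params.m0, dtype=float).copy()
    t = min(0.0, t_grid[0])
    out = np.empty((t_grid.size, 3))
    events = iter(flips)
    next_flip = next(events, None)
    for i, ts in enumerate(t_grid):
        # apply all flips strictly before this sample time
        while next_flip is not None and next_flip[0] < ts:
            m = prop.advance(m, t, next_flip[0])
            t = next_flip[0]
            m = m * np.cos(np.deg2rad(next_flip[1]))
            next_flip = next(events, None)
        m = prop.advance(m, t, ts)
        t = ts
        out[i] = m
        # a flip exactly at the sample time acts after the sample
        while next_flip is not None and next_flip[0] == ts:
            m = m * np.cos(np.deg2rad(next_flip[1]))
            next_flip = next(events, None)
    return out
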