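"""Spatially homogeneous (well-mixed) reduction of the growth model.

With gradients removed the dynamics are Lotka-Volterra-like:

    dB1/dt = B1 (1 - (B1+B2)/k) [- B1 B2]
    dB2/dt = r B2 (1 - (B1+B2)/k) [- c B1 B2]

In the isogenic case both strains share one growth law, so the strain
ratio B1/B2 is a conserved quantity and the outcome is fixed entirely by
the initial ratio.  In the antagonistic case the boundary equilibria
(k, 0) and (0, k) and an interior equilibrium are classified by linear
stability, and the winner from the homogeneous 1:1 start is determined
by integration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.integrate import solve_ivp

from .pde import ModelParams

WIN_THRESHOLD = 1e-3  # loser density below this multiple of k counts as excluded
WIN_HORIZON = 1e3


@dataclass
class WellMixedState:
    B1: float
    B2: float
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.B1 < 0 or self.B2 < 0:
            raise ValueError("densities must be nonnegative")


@dataclass
class SteadyState:
    B1: float
    B2: float
    eigenvalues: tuple[complex, complex]

    @property
    def stable(self) -> bool:
        return all(ev.real < 0 for ev in self.eigenvalues)


@dataclass
class StabilityReport:
    """Steady states, their eigenvalues and the outcome classification."""

    params: ModelParams
    steady_states: list[SteadyState]
    classification: str  # strain1_wins | strain2_wins | coexistence | bistable
    endpoint: tuple[float, float]  # trajectory endpoint from the 1:1 start
    notes: str = ""

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "params": {"mode": self.params.mode, "r": self.params.r,
                       "d": self.params.d, "c": self.params.c, "k": self.params.k},
            "steady_states": [
                {"B1": s.B1, "B2": s.B2,
                 "eigenvalues": [[ev.real, ev.imag] for ev in s.eigenvalues],
                 "stable": s.stable}
                for s in self.steady_states
            ],
            "classification": self.classification,
            "endpoint_from_1_1": list(self.endpoint),
            "notes": self.notes,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def ode_rhs(state: WellMixedState, params: ModelParams) -> tuple[float, float]:
    """Time derivatives (dB1/dt, dB2/dt)."""
    return _rhs(state.B1, state.B2, params)


def _rhs(b1: float, b2: float, params: ModelParams) -> tuple[float, float]:
    g = 1.0 - (b1 + b2) / params.k
    d1 = b1 * g
    d2 = params.r * b2 * g
    if params.antagonistic:
        d1 -= b1 * b2
        d2 -= params.c * b1 * b2
    return d1, d2


def _jacobian(b1: float, b2: float, p: ModelParams) -> np.ndarray:
    a = 1.0 if p.antagonistic else 0.0
    j11 = 1.0 - (2.0 * b1 + b2) / p.k - a * b2
    j12 = -b1 / p.k - a * b1
    j21 = -p.r * b2 / p.k - a * p.c * b2
    j22 = p.r * (1.0 - (b1 + 2.0 * b2) / p.k) - a * p.c * b1
    return np.array([[j11, j12], [j21, j22]])


def ratio_drift(state: WellMixedState, params: ModelParams) -> float:
    """d/dt (B1/B2) by the quotient rule; zero identically when isogenic."""
    if state.B2 <= 0:
        raise ValueError("ratio drift undefined for B2 = 0")
    d1, d2 = _rhs(state.B1, state.B2, params)
    return (d1 * state.B2 - state.B1 * d2) / state.B2**2


def integrate_wellmixed(
    init: WellMixedState,
    params: ModelParams,
    horizon: float,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    t_eval: np.ndarray | None = None,
):
    """Adaptive integration of the well-mixed system.

    Returns ``(times, B1, B2)`` arrays; the terminal state respects
    nonnegativity and the capacity bound.
    """
    sol = solve_ivp(
        lambda _t, y: _rhs(y[0], y[1], params),
        (init.time, init.time + horizon),
        [init.B1, init.B2],
        method="RK45", rtol=rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    b1, b2 = np.clip(sol.y[0], 0.0, None), np.clip(sol.y[1], 0.0, None)
    return sol.t, b1, b2


def steady_states(params: ModelParams) -> list[SteadyState]:
    """Boundary and interior equilibria with Jacobian eigenvalues.

    Interior equilibrium (antagonistic, c > 0), from intersecting the two
    nontrivial nullclines 1-(B1+B2)/k = B2 and r(1-(B1+B2)/k) = c B1:
    B1* = r k / (k c + r + c), B2* = k c / (k c + r + c).
    """
    k = params.k
    pts = [(0.0, 0.0), (k, 0.0), (0.0, k)]
    if params.antagonistic and params.c > 0:
        denom = k * params.c + params.r + params.c
        pts.append((params.r * k / denom, k * params.c / denom))
    out = []
    for b1, b2 in pts:
        ev = np.linalg.eigvals(_jacobian(b1, b2, params))
        out.append(SteadyState(b1, b2, (complex(ev[0]), complex(ev[1]))))
    return out


def winner_analysis(params: ModelParams) -> StabilityReport:
    """Classify the well-mixed outcome from the homogeneous 1:1 start.

    Isogenic dynamics have a neutral line of equilibria (B1+B2 = k) and
    conserve the ratio, hence "coexistence".  Otherwise the trajectory
    from B1 = B2 = k/2 decides: exclusion of one strain names the winner;
    a stable interior equilibrium is coexistence; both boundary states
    stable with no exclusion along the 1:1 trajectory is bistable (the
    start sits on the separatrix).
    """
    states = steady_states(params)
    if not params.antagonistic:
        return StabilityReport(
            params, states, "coexistence", (params.k / 2, params.k / 2),
            notes="isogenic: neutral line of equilibria B1+B2=k; ratio conserved",
        )
    k = params.k
    _t, b1, b2 = integrate_wellmixed(WellMixedState(k / 2, k / 2), params, WIN_HORIZON)
    end = (float(b1[-1]), float(b2[-1]))
    interior = [s for s in states if s.B1 > 0 and s.B2 > 0]
    if interior and interior[0].stable:
        cls = "coexistence"
    elif end[1] < WIN_THRESHOLD * k <= end[0]:
        cls = "strain1_wins"
    elif end[0] < WIN_THRESHOLD * k <= end[1]:
        cls = "strain2_wins"
    elif all(s.stable for s in states if (s.B1, s.B2) in ((k, 0.0), (0.0, k))):
        cls = "bistable"
    else:
        cls = "coexistence"
    return StabilityReport(params, states, cls, end)
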