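"""Two-strain degenerate-diffusion growth model on the disk.

Scaled strain densities ``B1``, ``B2`` obey

    dB1/dt = div( Id (1 - (B1+B2)/k) grad B1 ) + B1 (1 - (B1+B2)/k) [- B1 B2]
    dB2/dt = div( Id d (1 - (B1+B2)/k) grad B2 ) + r B2 (1 - (B1+B2)/k) [- c B1 B2]

with no-flux outer boundary.  The bracketed bilinear loss terms are
present only in the antagonistic mode; ``r``, ``d`` and ``c`` are the
strain ratios of maximum growth rate, diffusion coefficient and
competition coefficient, ``k`` the nondimensional carrying capacity.  The
indicator ``Id`` (1 where B1+B2 <= k, else 0) keeps the effective
diffusion coefficient nonnegative; it is realised by clamping the
mobility at zero.  Mobility vanishing at capacity makes established
colonies abut rather than merge.

Discretisation: method of lines with mass-lumped P1 finite elements on
the same triangulation used for founder placement (element mobility =
arithmetic mean of the nodal mobilities, clamped at zero) and explicit
Heun time stepping under a diffusion CFL bound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Callable

import numpy as np
import pandas as pd

from .mesh import TriangularMesh

if TYPE_CHECKING:  # pragma: no cover
    from .founders import FounderConfiguration


class SolverError(RuntimeError):
    """Raised when time integration fails its validity checks."""


class DomainTooSmallError(SolverError):
    """The colony front reached the outer boundary; enlarge R."""


@dataclass(frozen=True)
class ModelParams:
    """Nondimensional model parameters.

    ``mode`` is ``"isogenic"`` (identical strains, competition for space
    only: r = d = k = 1 and no bilinear loss) or ``"antagonistic"``
    (bilinear losses -B1*B2 and -c*B1*B2 active).  ``c`` < 1 makes strain
    2 the intrinsically stronger competitor; the default c = 0.2 is a
    five-fold difference in competition strength.
    """

    mode: str = "isogenic"
    r: float = 1.0
    d: float = 1.0
    c: float = 0.2
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("isogenic", "antagonistic"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if min(self.r, self.d, self.k) <= 0 or self.c < 0:
            raise ValueError("require r, d, k > 0 and c >= 0")
        if self.mode == "isogenic" and not (self.r == self.d == self.k == 1.0):
            raise ValueError("isogenic mode fixes r = d = k = 1")

    @property
    def antagonistic(self) -> bool:
        return self.mode == "antagonistic"

    @classmethod
    def isogenic(cls) -> "ModelParams":
        return cls(mode="isogenic")

    @classmethod
    def antagonism(cls, r: float = 1.0, d: float = 1.0, c: float = 0.2, k: float = 1.0) -> "ModelParams":
        return cls(mode="antagonistic", r=r, d=d, c=c, k=k)

    def swapped(self) -> "ModelParams":
        """Parameters of the same model with the strain labels exchanged.

        Exchanging labels, rescaling time by r and densities by r/c maps
        the antagonistic system back to standard form with
        r' = 1/r, d' = 1/d, c' = 1/c, k' = k c / r.
        """
        if not self.antagonistic:
            return self
        if self.c == 0:
            raise ValueError("label swap undefined for c = 0 (one-sided antagonism)")
        return ModelParams(
            mode="antagonistic", r=1.0 / self.r, d=1.0 / self.d,
            c=1.0 / self.c, k=self.k * self.c / self.r,
        )


@dataclass(frozen=True)
class SolverSettings:
    """Time-integration controls.

    ``end_time`` is the nondimensional horizon (default 25, about 72 h in
    the motivating assay).  ``dt_safety`` scales the explicit diffusion
    CFL estimate; ``front_threshold`` is the total-density level defining
    the colony front for the domain-size assertion.
    """

    end_time: float = 25.0
    dt_safety: float = 0.45
    max_dt: float = 0.1
    front_threshold: float = 0.01
    check_front: bool = True
    negative_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.end_time <= 0 or self.dt_safety <= 0 or self.max_dt <= 0:
            raise ValueError("end_time, dt_safety and max_dt must be positive")


@dataclass
class FieldState:
    """Per-node density fields at a given time."""

    mesh: TriangularMesh
    B1: np.ndarray
    B2: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.B1 = np.asarray(self.B1, float)
        self.B2 = np.asarray(self.B2, float)
        if self.B1.shape != self.B2.shape or len(self.B1) != self.mesh.n_nodes:
            raise ValueError("field arrays must be per-node")

    def copy(self) -> "FieldState":
        return FieldState(self.mesh, self.B1.copy(), self.B2.copy(), self.time)

    def swap_labels(self) -> "FieldState":
        return FieldState(self.mesh, self.B2.copy(), self.B1.copy(), self.time)

    def front_radius(self, threshold: float, k: float = 1.0) -> float:
        """Radius of the outermost node with total density above threshold*k."""
        mask = self.B1 + self.B2 > threshold * k
        return float(self.mesh.node_radii[mask].max()) if mask.any() else 0.0

    # ------------------------------------------------------------------
    def to_table(self, path: str | Path) -> None:
        """Snapshot as a plain-text table (x, y, B1, B2)."""
        pd.DataFrame({
            "x": self.mesh.node_coords[:, 0], "y": self.mesh.node_coords[:, 1],
            "B1": self.B1, "B2": self.B2,
        }).to_csv(path, index=False)


def homogeneous_ic(mesh: TriangularMesh, level1: float, level2: float, k: float = 1.0) -> FieldState:
    """Piecewise spatially homogeneous start: given levels on the inoculum
    footprint, zero elsewhere (the high-founder-density limit)."""
    if level1 < 0 or level2 < 0:
        raise ValueError("levels must be nonnegative")
    if level1 + level2 > k:
        raise ValueError("levels exceed carrying capacity")
    B1 = np.zeros(mesh.n_nodes)
    B2 = np.zeros(mesh.n_nodes)
    B1[mesh.inoculum_node_ids] = level1
    B2[mesh.inoculum_node_ids] = level2
    return FieldState(mesh, B1, B2)


def initial_state_from_config(
    config: "FounderConfiguration", mesh: TriangularMesh, k: float = 1.0
) -> FieldState:
    """Each microcolony at carrying capacity on its node, zero elsewhere."""
    if config.N == 0:
        return FieldState(mesh, np.zeros(mesh.n_nodes), np.zeros(mesh.n_nodes))
    if config.node_ids is not None:
        ids = np.asarray(config.node_ids, int)
        if not np.allclose(mesh.node_coords[ids], config.positions):
            raise ValueError("configuration node_ids do not match mesh coordinates")
    else:
        # tolerate configurations carrying only coordinates
        from scipy.spatial import cKDTree

        dist, ids = cKDTree(mesh.node_coords).query(config.positions)
        if np.any(dist > 1e-9):
            raise ValueError("configuration positions are not mesh nodes")
    B1 = np.zeros(mesh.n_nodes)
    B2 = np.zeros(mesh.n_nodes)
    B1[ids[config.strains == 1]] = k
    B2[ids[config.strains == 2]] = k
    return FieldState(mesh, B1, B2)


def rhs(state: FieldState, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Semi-discrete time derivative of both fields (per node)."""
    B1, B2 = state.B1, state.B2
    if np.isnan(B1).any() or np.isnan(B2).any():
        raise SolverError("NaN density in input state")
    if B1.min() < 0 or B2.min() < 0:
        raise SolverError("negative density in input state")
    fem = state.mesh.fem
    tris = state.mesh.triangles
    return _rhs_arrays(B1, B2, tris, fem["stiff"], fem["lumped_mass"], params)


def _rhs_arrays(B1, B2, tris, stiff, lumped, params: ModelParams):
    growth = 1.0 - (B1 + B2) / params.k
    mob = np.clip(growth[tris].mean(axis=1), 0.0, None)  # element mobility, Id via clamp
    flux1 = np.einsum("e,eij,ej->ei", mob, stiff, B1[tris])
    flux2 = np.einsum("e,eij,ej->ei", params.d * mob, stiff, B2[tris])
    out1 = np.zeros_like(B1)
    out2 = np.zeros_like(B2)
    np.add.at(out1, tris.ravel(), -flux1.ravel())
    np.add.at(out2, tris.ravel(), -flux2.ravel())
    out1 /= lumped
    out2 /= lumped
    out1 += B1 * growth
    out2 += params.r * B2 * growth
    if params.antagonistic:
        inter = B1 * B2
        out1 -= inter
        out2 -= params.c * inter
    return out1, out2


def solve(
    state: FieldState,
    params: ModelParams | None = None,
    settings: SolverSettings | None = None,
    snapshot_times: tuple[float, ...] = (),
    callback: Callable[[FieldState], None] | None = None,
) -> FieldState:
    """Advance the state to ``settings.end_time`` (Heun / explicit RK2).

    The step size is fixed from a diffusion CFL estimate on the lumped P1
    operator.  Round-off negatives are clipped; negatives beyond
    ``negative_tol`` abort.  Unless disabled, the colony front (total
    density above ``front_threshold * k``) must stay clear of the outer
    boundary, otherwise :class:`DomainTooSmallError` is raised.
    """
    params = params or ModelParams.isogenic()
    settings = settings or SolverSettings()
    mesh = state.mesh
    fem = mesh.fem
    tris = mesh.triangles
    lumped, kdiag = fem["lumped_mass"], fem["kdiag"]

    dt = settings.dt_safety * float(np.min(lumped / kdiag)) / max(1.0, params.d)
    dt = min(dt, settings.max_dt)
    n_steps = int(np.ceil(settings.end_time / dt))
    dt = settings.end_time / n_steps

    snaps = sorted(set(snapshot_times))
    B1, B2 = state.B1.copy(), state.B2.copy()
    t0 = state.time
    front_limit = mesh.geometry.R - 2.0 * mesh.geometry.spacing

    def _post(step_b1, step_b2):
        lo = min(step_b1.min(), step_b2.min())
        if lo < -settings.negative_tol:
            raise SolverError(f"density undershoot {lo:.3e} beyond tolerance; reduce dt_safety")
        np.clip(step_b1, 0.0, None, out=step_b1)
        np.clip(step_b2, 0.0, None, out=step_b2)

    for step in range(n_steps):
        k11, k12 = _rhs_arrays(B1, B2, tris, fem["stiff"], lumped, params)
        P1 = B1 + dt * k11
        P2 = B2 + dt * k12
        _post(P1, P2)
        k21, k22 = _rhs_arrays(P1, P2, tris, fem["stiff"], lumped, params)
        B1 += 0.5 * dt * (k11 + k21)
        B2 += 0.5 * dt * (k12 + k22)
        _post(B1, B2)
        t = t0 + (step + 1) * dt
        if settings.check_front and step % 25 == 24:
            _check_front(mesh, B1, B2, settings, params, front_limit)
        while snaps and t >= snaps[0] - 1e-12:
            snaps.pop(0)
            if callback is not None:
                callback(FieldState(mesh, B1.copy(), B2.copy(), t))

    final = FieldState(mesh, B1, B2, t0 + settings.end_time)
    if settings.check_front:
        _check_front(mesh, B1, B2, settings, params, front_limit)
    total = B1 + B2
    if total.max() > params.k + 1e-6:
        raise SolverError("total density exceeded carrying capacity")  # pragma: no cover
    return final


def _check_front(mesh, B1, B2, settings, params, limit):
    mask = B1 + B2 > settings.front_threshold * params.k
    if mask.any() and mesh.node_radii[mask].max() >= limit:
        raise DomainTooSmallError(
            f"colony front reached r={mesh.node_radii[mask].max():.1f} "
            f">= {limit:.1f}; increase the domain radius R"
        )


def mass_totals(state: FieldState) -> tuple[float, float]:
    """Integrals of the two fields over the domain (lumped P1 quadrature)."""
    w = state.mesh.fem["lumped_mass"]
    return float(w @ state.B1), float(w @ state.B2)


def competitive_outcome(state: FieldState) -> float:
    """Relative final mass of strain 1: B1_mass / (B1_mass + B2_mass)."""
    m1, m2 = mass_totals(state)
    if m1 + m2 <= 0:
        raise ValueError("competitive outcome undefined for zero total mass")
    return m1 / (m1 + m2)


def overlap_fraction(state: FieldState) -> float:
    """Mass of pointwise min(B1, B2) relative to total mass (merging diagnostic)."""
    w = state.mesh.fem["lumped_mass"]
    tot = float(w @ (state.B1 + state.B2))
    if tot <= 0:
        return 0.0
    return float(w @ np.minimum(state.B1, state.B2)) / tot


def save_snapshot(state: FieldState, basepath: str | Path, params: ModelParams,
                  settings: SolverSettings, seed: int | None = None) -> None:
    """Write a snapshot table plus a JSON sidecar with run metadata."""
    base = Path(basepath)
    state.to_table(base.with_suffix(".csv"))
    meta = {
        "time": state.time,
        "params": vars(params) | {"mode": params.mode},
        "settings": {f: getattr(settings, f) for f in (
            "end_time", "dt_safety", "max_dt", "front_threshold", "check_front")},
        "geometry": vars(state.mesh.geometry),
        "seed": seed,
        "units": {"time_unit_hours": 2.9, "space_unit_mm": 0.15},
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def render_png(state: FieldState, path: str | Path, dpi: int = 150) -> None:
    """Render the two fields (strain 1 magenta, strain 2 green, overlap grey)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = state.mesh.node_coords.T
    b1 = np.clip(state.B1, 0, 1)
    b2 = np.clip(state.B2, 0, 1)
    colors = np.column_stack([b1, b2, b1])  # magenta + green mix
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.set_facecolor("black")
    ax.scatter(x, y, c=colors, s=2, linewidths=0)
    ax.set_aspect("equal")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)


def coarsened(settings: SolverSettings, **overrides) -> SolverSettings:
    """Convenience copy-with-overrides for solver settings."""
    return replace(settings, **overrides)
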