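"""Access-to-free-space (AFS) score of a founder configuration.

A reference circle is drawn around the initial microcolonies; every point
of the circle is assigned to its nearest microcolony, and AFS_1 is the
fraction of the circumference owned by strain-1 microcolonies.  The score
quantifies a strain's potential for radial expansion beyond the inoculum
and predicts its competitive outcome; AFS_2 = 1 - AFS_1.

Two reference-circle conventions are implemented:

* the *radial-expansion limit* (default): the circle radius is taken to
  infinity, so a direction belongs to the microcolony that is furthest
  advanced in that direction.  Ownership then coincides with the normal
  fan of the convex hull of the microcolony positions, and each hull
  vertex owns an arc equal to its exterior angle.  This is exact,
  parameter-free, and scale invariant.
* a finite circle (any :class:`ReferenceCircle`, e.g. the minimal
  enclosing circle inflated by a few percent): the partition is computed
  from candidate arc boundaries obtained by localising owner changes on a
  fine angular sample and solving the two-site equidistance equation in
  closed form.

The sampled estimator :func:`afs_brute` serves as an independent check of
both constructions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError, cKDTree

from .founders import FounderConfiguration

TWO_PI = 2.0 * np.pi


class AFSError(ValueError):
    """Raised for configurations on which the score is undefined."""


@dataclass(frozen=True)
class ReferenceCircle:
    """Circle used to measure access to free space."""

    center: tuple[float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise AFSError("radius must be positive")

    def point(self, theta: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center)
        return c + self.radius * np.column_stack([np.cos(theta), np.sin(theta)])


@dataclass
class ArcPartition:
    """Ownership of the reference circle by microcolony.

    ``arcs`` is an ordered list of ``(start, end, site_index, strain)``
    with angles in [0, 2*pi), wraparound handled by splitting; arcs are
    disjoint and cover the full circle.
    """

    arcs: list[tuple[float, float, int, int]]
    circle: ReferenceCircle | None = None

    def strain_lengths(self) -> dict[int, float]:
        tot = {1: 0.0, 2: 0.0}
        for a, b, _i, s in self.arcs:
            tot[s] += b - a
        return tot

    def afs1(self) -> float:
        tot = self.strain_lengths()
        return tot[1] / (tot[1] + tot[2])


# ----------------------------------------------------------------------
# minimal enclosing circle (Welzl, hull-prefiltered)

def enclosing_circle(config: FounderConfiguration, inflation: float = 1.05) -> ReferenceCircle:
    """Minimal enclosing circle of the positions, radius inflated so all
    sites are strictly interior.  Coincident sites yield a tiny circle."""
    if config.N < 1:
        raise AFSError("need at least one microcolony")
    pts = config.positions
    c, r = _mec(pts)
    if r < 1e-12:
        r = 1e-6  # all points coincident
    return ReferenceCircle((float(c[0]), float(c[1])), float(r * inflation))


def _mec(points: np.ndarray) -> tuple[np.ndarray, float]:
    pts = np.unique(points, axis=0)
    if len(pts) > 8:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) sets: Welzl handles them directly
    pts = pts[np.random.default_rng(0).permutation(len(pts))]

    def circle_two(a, b):
        c = (a + b) / 2.0
        return c, float(np.linalg.norm(a - c))

    def circle_three(a, b, c):
        d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
        if abs(d) < 1e-14:
            return None
        ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
        uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
        ctr = np.array([ux, uy])
        return ctr, float(np.linalg.norm(a - ctr))

    def inside(c, r, p):
        return np.linalg.norm(p - c) <= r * (1 + 1e-10) + 1e-12

    c, r = pts[0], 0.0
    for i in range(1, len(pts)):
        if inside(c, r, pts[i]):
            continue
        c, r = pts[i], 0.0
        for j in range(i):
            if inside(c, r, pts[j]):
                continue
            c, r = circle_two(pts[i], pts[j])
            for m in range(j):
                if inside(c, r, pts[m]):
                    continue
                res = circle_three(pts[i], pts[j], pts[m])
                if res is not None:
                    c, r = res
    return np.asarray(c, float), r


# ----------------------------------------------------------------------
# radial-expansion limit (normal fan of the convex hull)

def radial_arc_partition(config: FounderConfiguration) -> ArcPartition:
    """Arc partition in the large-circle limit.

    Direction angle theta belongs to the site maximising the projection
    onto (cos theta, sin theta); the owners are the convex hull vertices
    and each owns the angular interval between the outward normals of its
    two incident hull edges (its exterior-angle cone).
    """
    pts = config.positions
    n = config.N
    if n < 1:
        raise AFSError("empty configuration")
    if n == 1:
        return ArcPartition([(0.0, TWO_PI, 0, int(config.strains[0]))])
    verts = _hull_vertices(pts)
    if len(verts) == 1:  # all sites coincident: tie broken by lowest index
        i = int(verts[0])
        return ArcPartition([(0.0, TWO_PI, i, int(config.strains[i]))])
    if len(verts) == 2:
        i, j = (int(v) for v in verts)
        d = pts[j] - pts[i]
        # split at the two directions orthogonal to the segment
        a = np.arctan2(d[1], d[0])
        cuts = np.sort([(a + np.pi / 2) % TWO_PI, (a - np.pi / 2) % TWO_PI])
        mid = (cuts[0] + cuts[1]) / 2.0
        own_mid = i if pts[i] @ np.array([np.cos(mid), np.sin(mid)]) > pts[j] @ np.array([np.cos(mid), np.sin(mid)]) else j
        other = i + j - own_mid
        arcs = [
            (0.0, cuts[0], other, int(config.strains[other])),
            (cuts[0], cuts[1], own_mid, int(config.strains[own_mid])),
            (cuts[1], TWO_PI, other, int(config.strains[other])),
        ]
        return ArcPartition([a_ for a_ in arcs if a_[1] - a_[0] > 0])

    # outward normal angle of each ccw hull edge (verts[i] -> verts[i+1])
    P = pts[verts]
    edges = np.roll(P, -1, axis=0) - P
    normals = np.arctan2(-edges[:, 0], edges[:, 1]) % TWO_PI  # rotate edge by -90 deg
    arcs = []
    for idx in range(len(verts)):
        v = int(verts[idx])
        start = normals[idx - 1]  # normal of incoming edge
        end = normals[idx]        # normal of outgoing edge
        strain = int(config.strains[v])
        if end < start:
            end += TWO_PI
        if end - start <= 1e-15:
            continue
        if end <= TWO_PI:
            arcs.append((start, end, v, strain))
        else:  # wraparound
            arcs.append((start, TWO_PI, v, strain))
            arcs.append((0.0, end - TWO_PI, v, strain))
    arcs.sort(key=lambda a: a[0])
    return ArcPartition(arcs)


def _hull_vertices(pts: np.ndarray) -> np.ndarray:
    """CCW hull vertex indices, robust to collinear/coincident inputs."""
    uniq = np.unique(pts, axis=0)
    if len(uniq) == 1:
        d2 = ((pts - uniq[0]) ** 2).sum(axis=1)
        return np.array([int(np.argmin(d2))])
    try:
        return ConvexHull(pts).vertices
    except QhullError:
        # collinear: the two extremes along the principal direction
        d = pts - pts.mean(axis=0)
        u = d[np.argmax((d ** 2).sum(axis=1))]
        proj = d @ u
        return np.array([int(np.argmin(proj)), int(np.argmax(proj))])


# ----------------------------------------------------------------------
# finite reference circle

def arc_partition(config: FounderConfiguration, circle: ReferenceCircle,
                  n_localise: int | None = None) -> ArcPartition:
    """Exact nearest-site partition of a finite reference circle.

    Owner changes are localised on a fine angular sample and each
    boundary angle is then solved in closed form from the equidistance
    condition of the two neighbouring sites (the intersection of their
    perpendicular bisector with the circle).  Ties are deterministic
    (lower site index).
    """
    pts = config.positions
    n = config.N
    if n < 1:
        raise AFSError("empty configuration")
    cx, cy = circle.center
    rel = pts - np.array([cx, cy])
    if np.any(np.hypot(rel[:, 0], rel[:, 1]) >= circle.radius):
        raise AFSError("all sites must lie strictly inside the reference circle")
    if n == 1:
        return ArcPartition([(0.0, TWO_PI, 0, int(config.strains[0]))], circle)

    m = n_localise or min(max(1024, 16 * n), 16384)
    theta = np.arange(m) * (TWO_PI / m)
    owners = cKDTree(pts).query(circle.point(theta))[1]

    changes = np.flatnonzero(owners != np.roll(owners, -1))
    if len(changes) == 0:
        i = int(owners[0])
        return ArcPartition([(0.0, TWO_PI, i, int(config.strains[i]))], circle)

    cuts = []
    for idx in changes:
        i, j = int(owners[idx]), int(owners[(idx + 1) % m])
        lo, hi = theta[idx], theta[idx] + TWO_PI / m
        cuts.append((_crossing_angle(rel[i], rel[j], circle.radius, lo, hi), j))
    cuts.sort(key=lambda c: c[0])

    arcs = []
    for b in range(len(cuts)):
        start, owner = cuts[b - 1][0] if b else cuts[-1][0] - TWO_PI, cuts[b - 1][1]
        end = cuts[b][0]
        arcs.append((start % TWO_PI, end, int(owner), int(config.strains[owner])))
    # normalise wraparound: first arc may start past its end after the modulo
    fixed = []
    for start, end, i, s in arcs:
        if start > end:
            fixed.append((start, TWO_PI, i, s))
            fixed.append((0.0, end, i, s))
        else:
            fixed.append((start, end, i, s))
    fixed.sort(key=lambda a: a[0])
    return ArcPartition(fixed, circle)


def _crossing_angle(si: np.ndarray, sj: np.ndarray, R: float, lo: float, hi: float) -> float:
    """Angle in [lo, hi] where circle points are equidistant from sites i, j.

    With sites relative to the circle centre, |P(t)-si| = |P(t)-sj| reads
    a cos t + b sin t = c with a = R(si-sj)_x, b = R(si-sj)_y and
    c = (|si|^2-|sj|^2)/2.
    """
    a = R * (si[0] - sj[0])
    b = R * (si[1] - sj[1])
    c = ((si @ si) - (sj @ sj)) / 2.0
    amp = np.hypot(a, b)
    phi = np.arctan2(b, a)
    x = np.clip(c / amp, -1.0, 1.0)
    for cand in (phi + np.arccos(x), phi - np.arccos(x)):
        for kk in range(-1, 3):
            t = cand + kk * TWO_PI
            if lo - 1e-12 <= t <= hi + 1e-12:
                return float(np.clip(t, lo, hi))
    return (lo + hi) / 2.0  # numerically degenerate pair; midpoint is measure-zero


# ----------------------------------------------------------------------
# scores

def afs(config: FounderConfiguration, circle: ReferenceCircle | None = None) -> float:
    """AFS_1 of the configuration.

    With ``circle=None`` (default) the radial-expansion limit is used;
    otherwise the exact partition of the given finite circle.
    """
    if config.N < 1:
        raise AFSError("empty configuration")
    part = radial_arc_partition(config) if circle is None else arc_partition(config, circle)
    return part.afs1()


def afs_brute(config: FounderConfiguration, n_samples: int = 100_000,
              circle: ReferenceCircle | None = None) -> float:
    """Sampled AFS_1: fraction of equally spaced circle points whose
    nearest site is strain 1.  Independent oracle for :func:`afs`.

    With ``circle=None`` the nearest-site rule is evaluated in the
    radial limit (ownership by maximal directional projection).
    """
    if n_samples < 1:
        raise AFSError("n_samples must be >= 1")
    if config.N < 1:
        raise AFSError("empty configuration")
    theta = np.arange(n_samples) * (TWO_PI / n_samples)
    if circle is None:
        u = np.column_stack([np.cos(theta), np.sin(theta)])
        owners = np.argmax(u @ config.positions.T, axis=1)
    else:
        owners = cKDTree(config.positions).query(circle.point(theta))[1]
    return float(np.mean(config.strains[owners] == 1))
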