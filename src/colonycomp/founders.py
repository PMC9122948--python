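"""Random founder (microcolony) configurations and inoculum sampling.

A founder configuration is the model's synthetic inoculum: ``N`` mesh
nodes inside the inoculum footprint, each holding a single-strain
microcolony at carrying capacity.  By default an even ``N`` is split
exactly half/half between the two strains and both the node choice and
the label assignment are uniform at random.  The cell-picking sampler
emulates drawing a small inoculum volume from a large well-mixed culture:
the total picked count is Poisson with the intended mean and each picked
cell is strain 1 independently with the culture's strain-1 fraction
(the standard limit of hypergeometric sampling from a large culture).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import DomainGeometry, TriangularMesh


class FounderError(ValueError):
    """Raised for invalid founder-placement requests."""


@dataclass(frozen=True)
class InoculumSample:
    """Strain counts picked from a well-mixed culture."""

    n1: int
    n2: int
    intended_total: float
    culture_ratio: float

    def __post_init__(self) -> None:
        if self.n1 < 0 or self.n2 < 0:
            raise FounderError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.n1 + self.n2


@dataclass
class FounderConfiguration:
    """Positions and strain labels of the initial microcolonies.

    ``positions`` are node coordinates (one microcolony per node),
    ``strains`` are labels in {1, 2}, ``node_ids`` the mesh node indices
    (may be absent for configurations read from bare point tables).
    """

    positions: np.ndarray
    strains: np.ndarray
    seed: int | None = None
    node_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.strains = np.asarray(self.strains, dtype=int)
        if len(self.positions) != len(self.strains):
            raise FounderError("positions and strains must have equal length")
        if not np.isin(self.strains, (1, 2)).all():
            raise FounderError("strain labels must be 1 or 2")

    @property
    def N(self) -> int:
        return len(self.positions)

    def swap_labels(self) -> "FounderConfiguration":
        """Exchange the two strain labels."""
        return FounderConfiguration(
            self.positions.copy(), 3 - self.strains, seed=self.seed,
            node_ids=None if self.node_ids is None else self.node_ids.copy(),
        )

    # ------------------------------------------------------------------
    # serialisation
    def to_table(self, path: str | Path) -> None:
        """Write a plain-text table with columns x, y, strain."""
        df = pd.DataFrame(
            {"x": self.positions[:, 0], "y": self.positions[:, 1], "strain": self.strains}
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_table(cls, path: str | Path) -> "FounderConfiguration":
        df = pd.read_csv(path)
        return cls(df[["x", "y"]].to_numpy(float), df["strain"].to_numpy(int))

    def to_json(self, path: str | Path, geometry: DomainGeometry | None = None) -> None:
        payload = {
            "positions": self.positions.tolist(),
            "strains": self.strains.tolist(),
            "seed": self.seed,
            "node_ids": None if self.node_ids is None else self.node_ids.tolist(),
        }
        if geometry is not None:
            payload["geometry"] = {
                "R": geometry.R, "R0": geometry.R0,
                "target_element_area": geometry.target_element_area,
            }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "FounderConfiguration":
        payload = json.loads(Path(path).read_text())
        node_ids = payload.get("node_ids")
        return cls(
            np.array(payload["positions"], float),
            np.array(payload["strains"], int),
            seed=payload.get("seed"),
            node_ids=None if node_ids is None else np.array(node_ids, int),
        )


def place_founders(
    mesh: TriangularMesh,
    N: int,
    ratio_rule: str = "fixed_half",
    sample: InoculumSample | None = None,
    seed: int = 0,
) -> FounderConfiguration:
    """Place ``N`` microcolonies uniformly at random on inoculum nodes.

    Nodes are drawn without replacement (one microcolony per node).  Under
    ``fixed_half`` an even ``N`` is split exactly ``N/2`` per strain;
    under ``from_sample`` the counts come from an :class:`InoculumSample`.
    Label order is a uniform random permutation.  The same seed, mesh and
    rule reproduce the configuration bit for bit.
    """
    avail = mesh.inoculum_node_ids
    if N > len(avail):
        raise FounderError(f"N={N} exceeds {len(avail)} available inoculum nodes")
    if N < 1:
        raise FounderError("N must be >= 1")
    if ratio_rule == "fixed_half":
        if N % 2:
            raise FounderError("fixed_half requires an even N")
        labels = np.repeat([1, 2], N // 2)
    elif ratio_rule == "from_sample":
        if sample is None:
            raise FounderError("from_sample requires an InoculumSample")
        if sample.total != N:
            raise FounderError(f"sample total {sample.total} != N={N}")
        labels = np.repeat([1, 2], [sample.n1, sample.n2])
    else:
        raise FounderError(f"unknown ratio_rule {ratio_rule!r}")

    rng = np.random.default_rng(seed)
    chosen = rng.choice(avail, size=N, replace=False)
    labels = rng.permutation(labels)
    return FounderConfiguration(
        mesh.node_coords[chosen], labels, seed=seed, node_ids=chosen
    )


def sample_inoculum(
    culture_ratio: float, intended_total: float, seed: int = 0
) -> InoculumSample:
    """Pick an inoculum from a large 1:1-mixed culture.

    Total count ~ Poisson(``intended_total``); each picked cell is strain 1
    independently with probability ``culture_ratio``.  Expected counts are
    ``intended_total * culture_ratio`` and ``intended_total * (1 - culture_ratio)``.
    """
    if not 0.0 <= culture_ratio <= 1.0:
        raise FounderError("culture_ratio must lie in [0, 1]")
    if intended_total <= 0:
        raise FounderError("intended_total must be positive")
    rng = np.random.default_rng(seed)
    total = int(rng.poisson(intended_total))
    n1 = int(rng.binomial(total, culture_ratio)) if total else 0
    return InoculumSample(n1, total - n1, intended_total, culture_ratio)
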