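"""Synthetic landscape generation.

Emulates the statistical structure of empirical habitat-suitability maps
for a territorial forest raptor: a spatially autocorrelated suitability
field in [0, 1] whose binary habitat (suitability > 0.2) covers a small,
controllable fraction of the landscape. The autocorrelation range
(``aggregation_length``) is the fragmentation dial: long ranges give few
large aggregated patches ("low fragmentation"), short ranges give many
small scattered patches ("high fragmentation") at the same habitat amount.

Resistance to movement is a bounded negative-exponential transform of
suitability, mapping suitability 1 -> resistance 1 and suitability 0 ->
resistance 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import Raster, ResistanceSurface, SuitabilitySurface

__all__ = [
    "LandscapeConfig",
    "NodeSet",
    "generate_suitability",
    "suitability_to_resistance",
    "binarize_habitat",
    "place_nodes",
]


@dataclass(frozen=True)
class LandscapeConfig:
    """Parameters of one synthetic landscape.

    aggregation_length : float
        Autocorrelation range of the suitability field, meters. Controls
        fragmentation at fixed habitat amount.
    habitat_fraction_target : float
        Fraction of cells that binarize to habitat at ``suitability_threshold``.
    transform_shape : float
        Shape ``c`` of the suitability->resistance negative exponential.
    """

    n_rows: int = 200
    n_cols: int = 200
    cell_size: float = 500.0
    aggregation_length: float = 10_000.0
    habitat_fraction_target: float = 0.0175
    suitability_threshold: float = 0.2
    background_mean_suitability: float = 0.02
    transform_shape: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.habitat_fraction_target < 1):
            raise ValueError("habitat_fraction_target must be in (0, 1)")
        if not self.aggregation_length > 0:
            raise ValueError("aggregation_length must be positive")
        if not (0 < self.background_mean_suitability < self.suitability_threshold):
            raise ValueError("background_mean_suitability must be in (0, threshold)")
        if self.n_rows < 1 or self.n_cols < 1 or self.cell_size <= 0:
            raise ValueError("invalid grid geometry")


@dataclass
class NodeSet:
    """Potentially occupiable territory locations.

    Each node holds at most ``capacity`` (= 2) individuals: a monogamous
    territorial pair. ``occupied_at_init`` flags the nodes populated at
    generation 0.
    """

    node_id: np.ndarray
    x: np.ndarray
    y: np.ndarray
    capacity: int = 2
    occupied_at_init: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.node_id = np.asarray(self.node_id, dtype=int)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.occupied_at_init is None:
            self.occupied_at_init = np.ones(len(self.node_id), dtype=bool)
        self.occupied_at_init = np.asarray(self.occupied_at_init, dtype=bool)
        if len({len(self.node_id), len(self.x), len(self.y), len(self.occupied_at_init)}) != 1:
            raise ValueError("node field lengths differ")
        if len(np.unique(self.node_id)) != len(self.node_id):
            raise ValueError("node_ids must be unique")
        if self.capacity != 2:
            raise ValueError("node capacity is fixed at 2 (one territorial pair)")

    def __len__(self) -> int:
        return len(self.node_id)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "node_id": self.node_id,
                "x": self.x,
                "y": self.y,
                "capacity": self.capacity,
                "occupied_at_init": self.occupied_at_init.astype(int),
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "NodeSet":
        df = pd.read_csv(path)
        cap = int(df["capacity"].iloc[0]) if "capacity" in df else 2
        return cls(
            df["node_id"].to_numpy(),
            df["x"].to_numpy(),
            df["y"].to_numpy(),
            capacity=cap,
            occupied_at_init=df["occupied_at_init"].to_numpy().astype(bool),
        )


def generate_suitability(config: LandscapeConfig) -> SuitabilitySurface:
    """Synthesize a spatially autocorrelated suitability raster.

    Gaussian-kernel convolution of white noise (correlation length =
    ``aggregation_length``), rank-transformed so that exactly
    ``round(habitat_fraction_target * n_cells)`` cells exceed
    ``suitability_threshold``. Deterministic given ``config.seed``.

    The marginal distribution emulates an empirical habitat-probability
    map for a rare, highly selective species: below-threshold (background)
    cells follow a right-skewed power-law curve with mean
    ``background_mean_suitability``, so most of the landscape sits near
    zero suitability and the map's probability mass concentrates in and
    around habitat.
    """
    extent = min(config.n_rows, config.n_cols) * config.cell_size
    if extent < 4 * config.aggregation_length:
        raise ValueError(
            "grid too small for aggregation_length "
            f"({extent:.0f} m extent < 4 x {config.aggregation_length:.0f} m)"
        )
    rng = np.random.default_rng(config.seed)
    noise = rng.standard_normal((config.n_rows, config.n_cols))
    sigma_cells = config.aggregation_length / config.cell_size
    fld = gaussian_filter(noise, sigma=sigma_cells, mode="reflect")

    # Rank transform: continuous field -> uniform ranks -> piecewise map so
    # the top habitat_fraction_target of cells land strictly above threshold.
    n = fld.size
    n_hab = int(round(config.habitat_fraction_target * n))
    n_low = n - n_hab
    rank = np.empty(n, dtype=float)
    rank[np.argsort(fld.ravel(), kind="stable")] = np.arange(n)
    thr = config.suitability_threshold
    # power-law exponent giving the background segment its target mean:
    # E[thr * u^g] = thr / (g + 1)
    g = thr / config.background_mean_suitability - 1.0
    u_low = (rank + 0.5) / max(n_low, 1)
    u_high = (rank - n_low + 0.5) / max(n_hab, 1)
    s = np.where(rank < n_low, thr * u_low**g, thr + (1.0 - thr) * u_high)
    return SuitabilitySurface(s.reshape(fld.shape), config.cell_size)


def suitability_to_resistance(
    s: SuitabilitySurface,
    transform_shape: float = 2.0,
    r_min: float = 1.0,
    r_max: float = 10.0,
) -> ResistanceSurface:
    """Bounded negative-exponential transform of suitability to resistance.

    R = r_min + (r_max - r_min) * (exp(-c*S) - exp(-c)) / (1 - exp(-c)),
    a monotone-decreasing bijection of [0, 1] onto [r_min, r_max] with
    R(1) = r_min and R(0) = r_max for any shape c > 0.
    """
    c = float(transform_shape)
    if not c > 0:
        raise ValueError("transform_shape must be positive")
    if not r_min < r_max:
        raise ValueError("require r_min < r_max")
    scale = (np.exp(-c * s.values) - np.exp(-c)) / (1.0 - np.exp(-c))
    r = r_min + (r_max - r_min) * scale
    # guard against fp undershoot at the endpoints
    r = np.clip(r, r_min, r_max)
    return ResistanceSurface(r, s.cell_size, s.origin, r_min=r_min, r_max=r_max)


def binarize_habitat(s: SuitabilitySurface, threshold: float = 0.2) -> np.ndarray:
    """Binary habitat map: habitat iff suitability strictly exceeds threshold."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    return s.values > threshold


def place_nodes(
    s: SuitabilitySurface,
    n_nodes: int,
    occupancy: float = 0.8,
    min_spacing: float | None = None,
    seed: int = 0,
) -> NodeSet:
    """Place territory nodes by suitability-weighted spatially balanced sampling.

    Cells are drawn without replacement with probability proportional to
    suitability; candidates closer than ``min_spacing`` (default 2 cell
    sizes) to an already accepted node are rejected. ``round(occupancy *
    n_nodes)`` nodes are flagged occupied at initialization, chosen
    uniformly at random. Deterministic given ``seed``.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if not (0 < occupancy <= 1):
        raise ValueError("occupancy must be in (0, 1]")
    if min_spacing is None:
        min_spacing = 2.0 * s.cell_size
    rng = np.random.default_rng(seed)

    p = s.values.ravel().astype(float)
    nz = np.flatnonzero(p > 0)
    if len(nz) < n_nodes:
        raise RuntimeError("not enough cells with positive suitability")
    weights = p[nz] / p[nz].sum()
    n_draw = min(len(nz), max(50 * n_nodes, n_nodes + 100))
    candidates = rng.choice(nz, size=n_draw, replace=False, p=weights)

    rows, cols = np.divmod(candidates, s.n_cols)
    cx, cy = s.rowcol_to_xy(rows, cols)
    acc_x: list[float] = []
    acc_y: list[float] = []
    sp2 = float(min_spacing) ** 2
    for xi, yi in zip(cx, cy):
        if acc_x and sp2 > 0:
            ax = np.asarray(acc_x)
            ay = np.asarray(acc_y)
            if np.min((ax - xi) ** 2 + (ay - yi) ** 2) < sp2:
                continue
        acc_x.append(float(xi))
        acc_y.append(float(yi))
        if len(acc_x) == n_nodes:
            break
    if len(acc_x) < n_nodes:
        raise RuntimeError(
            f"could only place {len(acc_x)} of {n_nodes} nodes at min_spacing="
            f"{min_spacing:.0f} m after {n_draw} candidate draws; "
            "reduce min_spacing or n_nodes"
        )

    n_occ = int(round(occupancy * n_nodes))
    occupied = np.zeros(n_nodes, dtype=bool)
    occupied[rng.choice(n_nodes, size=n_occ, replace=False)] = True
    return NodeSet(np.arange(n_nodes), np.asarray(acc_x), np.asarray(acc_y), occupied_at_init=occupied)
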