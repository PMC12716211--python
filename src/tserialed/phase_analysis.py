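"""Quantitative phase analysis from clustered unit cells.

Each successfully indexed lattice contributes one Niggli-reduced cell; cells
are clustered by plain Euclidean distance over the six parameters (lengths
in Å, angles in degrees) with average-linkage hierarchical clustering cut at
a distance threshold.  Lattice counts per cluster are the relative volume
fractions; multiplying by phase densities and renormalizing gives weight
fractions.  One indexed lattice = one count, so aggregates contribute once
per resolved lattice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy

from .exceptions import InvalidArgumentError
from .geometry import UnitCell, is_niggli_reduced

__all__ = [
    "PhaseCluster",
    "PhaseReport",
    "cell_distance",
    "cluster_cells",
    "quantify",
    "indexing_rate",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (54.85 → 54.9), as printed percentages are."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


def cell_distance(c1: UnitCell, c2: UnitCell, check_reduced: bool = True) -> float:
    """Euclidean distance between six cell parameters of two reduced cells."""
    if check_reduced and not (is_niggli_reduced(c1) and is_niggli_reduced(c2)):
        raise InvalidArgumentError("cells must be Niggli-reduced before comparison")
    p1 = np.array(c1.parameters)
    p2 = np.array(c2.parameters)
    return float(np.linalg.norm(p1 - p2))


@dataclass
class PhaseCluster:
    cluster_id: int
    centroid_cell: UnitCell
    member_ids: list
    count: int
    density: float | None = None
    volume_fraction: float | None = None
    weight_fraction: float | None = None

    def to_dict(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "centroid_cell": list(self.centroid_cell.parameters),
            "member_ids": list(self.member_ids),
            "count": self.count,
            "density": self.density,
            "volume_fraction": self.volume_fraction,
            "volume_percent": None
            if self.volume_fraction is None
            else round_half_away(100.0 * self.volume_fraction),
            "weight_fraction": self.weight_fraction,
            "weight_percent": None
            if self.weight_fraction is None
            else round_half_away(100.0 * self.weight_fraction),
        }


@dataclass
class PhaseReport:
    """Phase composition of one experiment.

    ``n_indexed`` counts indexed lattices (clustered members plus outliers);
    aggregates contribute one per resolved lattice, so both denominators —
    collected datasets and indexed lattices — are reported to keep the
    percentages unambiguous.
    """

    clusters: list[PhaseCluster]
    outlier_ids: list = field(default_factory=list)
    n_collected: int | None = None

    @property
    def n_indexed(self) -> int:
        return sum(c.count for c in self.clusters) + len(self.outlier_ids)

    @property
    def indexing_rate_percent(self) -> float | None:
        if not self.n_collected:
            return None
        return indexing_rate(self.n_indexed, self.n_collected)

    def to_dict(self) -> dict:
        return {
            "clusters": [c.to_dict() for c in self.clusters],
            "outlier_ids": list(self.outlier_ids),
            "n_collected": self.n_collected,
            "n_indexed": self.n_indexed,
            "indexing_rate_percent": self.indexing_rate_percent,
        }


def cluster_cells(
    cells: list[UnitCell],
    ids: list | None = None,
    threshold: float = 1.5,
    linkage: str = "average",
    min_members: int = 2,
    check_reduced: bool = True,
) -> tuple[list[PhaseCluster], list]:
    """Hierarchical clustering of reduced cells; small clusters are outliers.

    The dendrogram (``linkage`` ∈ single/complete/average on Euclidean
    distance) is cut at ``threshold``; flat clusters with fewer than
    ``min_members`` members are declared outliers and excluded from the
    fraction denominators.  Order-invariant in the input cells.
    """
    if not cells:
        raise InvalidArgumentError("no cells to cluster")
    if linkage not in {"single", "complete", "average"}:
        raise InvalidArgumentError(f"unsupported linkage {linkage!r}")
    ids = list(range(len(cells))) if ids is None else list(ids)
    if check_reduced:
        for c in cells:
            if not is_niggli_reduced(c):
                raise InvalidArgumentError(f"cell {c.parameters} is not Niggli-reduced")
    params = np.array([c.parameters for c in cells])
    if len(cells) == 1:
        labels = np.array([1])
    else:
        link = hierarchy.linkage(params, method=linkage, metric="euclidean")
        labels = hierarchy.fcluster(link, t=threshold, criterion="distance")

    clusters: list[PhaseCluster] = []
    outliers: list = []
    # deterministic ordering: clusters sorted by descending size then centroid
    order = sorted(set(labels), key=lambda lab: (-np.sum(labels == lab), lab))
    next_id = 0
    for lab in order:
        members = np.flatnonzero(labels == lab)
        if len(members) < min_members:
            outliers.extend(ids[m] for m in members)
            continue
        centroid = UnitCell(*params[members].mean(axis=0))
        clusters.append(
            PhaseCluster(
                cluster_id=next_id,
                centroid_cell=centroid,
                member_ids=[ids[m] for m in members],
                count=len(members),
            )
        )
        next_id += 1
    return clusters, outliers


def quantify(
    clusters: list[PhaseCluster],
    densities: list[float] | dict[int, float] | None = None,
    outlier_ids: list | None = None,
    n_collected: int | None = None,
) -> PhaseReport:
    """Volume fractions from lattice counts; weight fractions via densities.

    v_k = count_k / Σ counts (outliers excluded from the denominator);
    w_k = v_k ρ_k / Σ_j v_j ρ_j when every cluster has a density, otherwise
    weight fractions are omitted with a warning.
    """
    if not clusters:
        return PhaseReport(clusters=[], outlier_ids=list(outlier_ids or []), n_collected=n_collected)
    for c in clusters:
        if c.count < 1:
            raise InvalidArgumentError("cluster counts must be >= 1")
    total = sum(c.count for c in clusters)
    rho: dict[int, float | None]
    if densities is None:
        rho = {c.cluster_id: None for c in clusters}
    elif isinstance(densities, dict):
        rho = {c.cluster_id: densities.get(c.cluster_id) for c in clusters}
    else:
        if len(densities) != len(clusters):
            raise InvalidArgumentError("need one density per cluster")
        rho = {c.cluster_id: d for c, d in zip(clusters, densities)}

    for c in clusters:
        c.volume_fraction = c.count / total
        c.density = rho[c.cluster_id]

    if all(r is not None for r in rho.values()):
        weights = {c.cluster_id: c.volume_fraction * rho[c.cluster_id] for c in clusters}
        wsum = sum(weights.values())
        for c in clusters:
            c.weight_fraction = weights[c.cluster_id] / wsum
    else:
        if densities is not None:
            warnings.warn("missing densities for some clusters; weight fractions omitted")
        for c in clusters:
            c.weight_fraction = None
    return PhaseReport(clusters=clusters, outlier_ids=list(outlier_ids or []), n_collected=n_collected)


def indexing_rate(n_indexed: int, n_collected: int) -> float:
    """Indexing success rate in percent, printed to one decimal.

    indexing_rate(495, 902) → 54.9.
    """
    if n_collected <= 0:
        raise InvalidArgumentError("n_collected must be positive")
    if not 0 <= n_indexed:
        raise InvalidArgumentError("n_indexed must be non-negative")
    return round_half_away(100.0 * n_indexed / n_collected)
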