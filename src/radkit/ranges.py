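"""Species ranges and pairwise geographic metrics.

Ranges are planar polygons in km.  A species range is the convex hull of
its occurrence points; narrow endemics known from one or two localities
get 0.5-km buffer disks instead, with the conventional analytic areas
pi*0.5^2 km^2 (one locality) and 2*pi*0.5^2 km^2 (two localities).

Pairwise metrics:

* overlap  O = area(Ri ∩ Rj) / min(area_i, area_j), in [0, 1]
* asymmetry A = max(area) / min(area), in [1, inf)
* habitat distance D comes from the niche ordination (Euclidean distance
  on retained axes) and is carried alongside O and A in the pair matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

__all__ = [
    "SpeciesRange",
    "build_range",
    "build_ranges",
    "range_overlap",
    "range_asymmetry",
    "pair_metrics",
    "overlap_density",
    "pair_summary",
    "PairMetricsMatrix",
]

BUFFER_KM = 0.5
#: analytic areas for 1- and 2-locality species (buffer radius 0.5 km)
ONE_POINT_AREA = math.pi * BUFFER_KM ** 2
TWO_POINT_AREA = 2.0 * math.pi * BUFFER_KM ** 2


@dataclass
class SpeciesRange:
    label: str
    geometry: BaseGeometry
    area: float  # km^2; analytic constant for 1-2 locality species

    def __post_init__(self):
        if self.area <= 0:
            raise ValueError(f"range of {self.label!r} has non-positive area")
        if not self.geometry.is_valid:
            repaired = self.geometry.buffer(0)
            if not repaired.is_valid:
                raise ValueError(f"invalid range geometry for {self.label!r}")
            self.geometry = repaired


def build_range(label: str, points: Sequence[Tuple[float, float]],
                buffer_km: float = BUFFER_KM) -> SpeciesRange:
    """Convex hull of >=3 non-collinear points; buffered disk(s) otherwise."""
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) == 0:
        raise ValueError(f"no occurrence points for {label!r}")
    if len(pts) == 1:
        geom = Point(pts[0]).buffer(buffer_km, quad_segs=64)
        return SpeciesRange(label, geom, math.pi * buffer_km ** 2)
    if len(pts) == 2:
        geom = unary_union([Point(p).buffer(buffer_km, quad_segs=64) for p in pts])
        # area is the stated two-disk constant even if the disks intersect;
        # the union geometry is still what enters overlap computations
        return SpeciesRange(label, geom, 2.0 * math.pi * buffer_km ** 2)
    hull = MultiPoint(pts).convex_hull
    if hull.area <= 0:  # collinear points: degenerate hull, buffer it
        geom = hull.buffer(buffer_km, quad_segs=64)
        return SpeciesRange(label, geom, geom.area)
    return SpeciesRange(label, hull, hull.area)


def build_ranges(occurrences: pd.DataFrame,
                 buffer_km: float = BUFFER_KM) -> Dict[str, SpeciesRange]:
    """Build one range per species from a (species, x_km, y_km) table."""
    required = {"species", "x_km", "y_km"}
    if not required.issubset(occurrences.columns):
        raise ValueError(f"occurrence table needs columns {sorted(required)}")
    out: Dict[str, SpeciesRange] = {}
    for label, grp in occurrences.groupby("species", sort=True):
        out[str(label)] = build_range(
            str(label), list(zip(grp["x_km"], grp["y_km"])), buffer_km
        )
    return out


def range_overlap(ri: SpeciesRange, rj: SpeciesRange) -> float:
    inter = ri.geometry.intersection(rj.geometry).area
    o = inter / min(ri.area, rj.area)
    return float(min(max(o, 0.0), 1.0))


def range_asymmetry(ri: SpeciesRange, rj: SpeciesRange) -> float:
    a, b = ri.area, rj.area
    return float(max(a, b) / min(a, b))


@dataclass
class PairMetricsMatrix:
    """Symmetric pairwise overlap O, asymmetry A, habitat distance D."""

    labels: List[str]
    O: pd.DataFrame
    A: pd.DataFrame
    D: pd.DataFrame | None = None

    def off_diagonal(self, which: str = "O") -> np.ndarray:
        M = getattr(self, which).values
        iu = np.triu_indices(len(self.labels), k=1)
        return M[iu]

    def to_tsv(self, path: str) -> None:
        rows = []
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                row = {
                    "species_1": self.labels[i],
                    "species_2": self.labels[j],
                    "overlap": self.O.iloc[i, j],
                    "asymmetry": self.A.iloc[i, j],
                }
                if self.D is not None:
                    row["habitat_distance"] = self.D.iloc[i, j]
                rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def pair_metrics(ranges: Dict[str, SpeciesRange],
                 habitat_distance: pd.DataFrame | None = None) -> PairMetricsMatrix:
    labels = sorted(ranges)
    n = len(labels)
    O = np.eye(n)
    A = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            O[i, j] = O[j, i] = range_overlap(ranges[labels[i]], ranges[labels[j]])
            A[i, j] = A[j, i] = range_asymmetry(ranges[labels[i]], ranges[labels[j]])
    D = None
    if habitat_distance is not None:
        D = habitat_distance.loc[labels, labels].copy()
    return PairMetricsMatrix(
        labels=labels,
        O=pd.DataFrame(O, index=labels, columns=labels),
        A=pd.DataFrame(A, index=labels, columns=labels),
        D=D,
    )


def _silverman_bw(x: np.ndarray) -> float:
    n = len(x)
    sd = np.std(x, ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return 0.01  # degenerate sample: near-delta kernel
    return 0.9 * spread * n ** (-0.2)


def overlap_density(values: Sequence[float],
                    bandwidth: float | None = None,
                    grid: np.ndarray | None = None
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of overlap values on [-0.05, 1.05].

    Overlaps live on [0, 1]; mass that a plain Gaussian kernel would leak
    past the boundaries is reflected back, so the curve integrates to 1.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values for a density estimate")
    bw = bandwidth if bandwidth is not None else _silverman_bw(x)
    if grid is None:
        grid = np.linspace(-0.05, 1.05, 441)

    def gauss(u: np.ndarray) -> np.ndarray:
        z = (grid[:, None] - u[None, :]) / bw
        return np.exp(-0.5 * z ** 2) / (bw * math.sqrt(2 * math.pi))

    dens = gauss(x) + gauss(-x) + gauss(2.0 - x)  # reflect at 0 and 1
    dens = dens.mean(axis=1)
    dens[(grid < 0) | (grid > 1)] = 0.0
    return grid, dens


def sister_pair_overlaps(tree, matrix: PairMetricsMatrix) -> List[float]:
    """Overlap values of cherries (sister-species pairs) in the tree."""
    lab_idx = {l: i for i, l in enumerate(matrix.labels)}
    out = []
    for node in tree.dendropy_tree.preorder_node_iter():
        ch = node.child_nodes()
        if len(ch) == 2 and all(c.is_leaf() for c in ch):
            i = lab_idx[ch[0].taxon.label]
            j = lab_idx[ch[1].taxon.label]
            out.append(float(matrix.O.iloc[i, j]))
    return out


def pair_summary(matrix: PairMetricsMatrix) -> Dict[str, float]:
    """Mean/SD of pairwise overlap and the count of overlapping pairs."""
    o = matrix.off_diagonal("O")
    return {
        "n_pairs": int(o.size),
        "mean_overlap": float(o.mean()),
        "sd_overlap": float(o.std(ddof=1)) if o.size > 1 else 0.0,
        "n_overlapping": int((o > 0).sum()),
    }
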