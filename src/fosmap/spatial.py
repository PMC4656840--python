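"""Spatial randomness and lateralization statistics for labeled cell maps.

A coronal section of the dorsal lateral geniculate nucleus (dLGN) is
represented as a region polygon, a lateral-edge polyline (the retinal-input
border), and a set of marker-flagged cell points.  The module tests whether
the activated (c-Fos positive) subset of the neuronal (NeuN positive)
population is spatially random:

* Voronoi-tessellation entropy of the activated point pattern, against a
  Monte Carlo null built from random NeuN subsamples of the same size;
* a stripe partition parallel to the lateral edge with an area-normalized
  G-test of count uniformity;
* a Monte Carlo test of whether the activated cells' median distance to the
  lateral edge is smaller than expected under random subsampling;
* Holm step-down adjustment for multiplicity across sections.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon

from ._geometry import (
    _subsample_entropies,
    clipped_voronoi_areas,
    polyline_distances,
    region_ring,
)

__all__ = [
    "SectionPattern",
    "VoronoiEntropyResult",
    "LateralizationResult",
    "StripePartition",
    "GTestResult",
    "lateral_distance",
    "voronoi_entropy",
    "mc_entropy_test",
    "stripe_rule",
    "stripe_partition",
    "gtest_uniform",
    "median_lateralization_test",
    "holm_adjust",
]


@dataclass
class SectionPattern:
    """Cell point pattern of one dLGN section.

    ``points`` is a DataFrame with columns ``x_um``, ``y_um`` and boolean
    marker columns ``neun``, ``cfos``, ``gad``.  Coordinates are Cartesian
    micrometres in the section plane, origin at the image top-left with y
    increasing downward (image convention).
    """

    section_id: str
    rat_id: str
    hemisphere: str
    region: Polygon
    lateral_edge: np.ndarray  # (m, 2) polyline on the region boundary
    points: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lateral_edge = np.atleast_2d(np.asarray(self.lateral_edge, float))
        required = {"x_um", "y_um", "neun", "cfos", "gad"}
        missing = required - set(self.points.columns)
        if missing:
            raise ValueError(f"points table missing columns {sorted(missing)}")
        region_ring(self.region)  # validates the polygon

    def coords(self, marker: str | None = None) -> np.ndarray:
        """(n, 2) coordinate array, optionally filtered by a marker column."""
        df = self.points
        if marker is not None:
            df = df[df[marker].astype(bool)]
        return df[["x_um", "y_um"]].to_numpy(dtype=float)

    @property
    def lateromedial_extent(self) -> float:
        """Maximum distance from the region to the lateral edge (µm)."""
        boundary = self.region.exterior.segmentize(2.0)
        verts = np.asarray(boundary.coords, dtype=float)
        return float(polyline_distances(verts, self.lateral_edge).max())


@dataclass
class VoronoiEntropyResult:
    H_obs: float
    n_cfos: int
    N_sim: int
    n_below: int
    p_value: float
    seed: int
    degenerate: bool = False

    @property
    def p_label(self) -> str:
        """Monte Carlo p with zero counts reported as a bound, not as 0."""
        if self.n_below == 0:
            return f"< {1.0 / self.N_sim:g}"
        return f"{self.p_value:g}"


@dataclass
class LateralizationResult:
    median_obs: float
    n_cfos: int
    N_sim: int
    n_below: int
    p_value: float
    seed: int

    @property
    def p_label(self) -> str:
        if self.n_below == 0:
            return f"< {1.0 / self.N_sim:g}"
        return f"{self.p_value:g}"


@dataclass
class StripePartition:
    k: int
    thickness: float
    areas: np.ndarray  # S_i, µm²
    observed: np.ndarray  # O_i
    expected: np.ndarray  # E_i = (S_i / ΣS) · n
    n_total: int


@dataclass
class GTestResult:
    G: float
    df: int
    p_value: float


def lateral_distance(points: np.ndarray, edge: np.ndarray) -> np.ndarray:
    """Distance (µm) from each point to the lateral-edge polyline."""
    edge = np.atleast_2d(np.asarray(edge, float))
    if edge.size == 0:
        raise ValueError("lateral edge polyline is empty")
    return polyline_distances(np.atleast_2d(np.asarray(points, float)), edge)


def voronoi_entropy(points: np.ndarray, region: Polygon) -> float:
    """Shannon entropy (nats) of the clipped Voronoi cell-area fractions.

    H = -Σ (A_i/ΣA) ln(A_i/ΣA) where A_i is the area of the Voronoi polygon
    of point i intersected with the region.  The clipped areas tile the
    region, so ΣA equals the region area; H is maximal (= ln n) when all
    cells have equal area, and decreases as the pattern clusters.
    """
    areas = clipped_voronoi_areas(points, region)
    return entropy_from_areas(areas)


def entropy_from_areas(areas: np.ndarray) -> float:
    areas = np.asarray(areas, dtype=float)
    total = areas.sum()
    if total <= 0:
        raise ValueError("total tessellation area is zero")
    p = areas[areas > 0] / total
    return float(-(p * np.log(p)).sum())


def _marker_subsets(section: SectionPattern) -> tuple[np.ndarray, np.ndarray]:
    neun = section.coords("neun")
    df = section.points
    cfos = df[df["neun"].astype(bool) & df["cfos"].astype(bool)]
    return neun, cfos[["x_um", "y_um"]].to_numpy(dtype=float)


def mc_entropy_test(
    section: SectionPattern,
    N_sim: int = 50_000,
    seed: int | np.random.Generator = 0,
    batch: int = 2048,
) -> VoronoiEntropyResult:
    """Monte Carlo test of spatial randomness of the activated pattern.

    Draws ``N_sim`` subsamples of size n_cfos without replacement from the
    NeuN point set, computes the Voronoi entropy of each, and reports
    p = #(H_sim < H_obs) / N_sim.  Small p means the activated pattern is
    more clustered (lower entropy) than a random draw from the neuronal
    population.  Ties count as not-below (conservative).
    """
    neun, cfos = _marker_subsets(section)
    n_neun, n_cfos = len(neun), len(cfos)
    if n_cfos < 3:
        raise ValueError("need at least 3 activated cells")
    if n_cfos > n_neun:
        raise ValueError("activated set larger than the NeuN set")
    rng = np.random.default_rng(seed)
    clipped_voronoi_areas(cfos, section.region)  # validates the observed set
    ring = region_ring(section.region)
    px = np.ascontiguousarray(neun[:, 0])
    py = np.ascontiguousarray(neun[:, 1])
    rx = np.ascontiguousarray(ring[:, 0])
    ry = np.ascontiguousarray(ring[:, 1])
    # observed entropy through the same kernel/summation path as the null
    h_obs = float(
        _subsample_entropies(
            np.ascontiguousarray(cfos[:, 0]),
            np.ascontiguousarray(cfos[:, 1]),
            rx,
            ry,
            np.arange(n_cfos, dtype=np.int64)[None, :],
        )[0]
    )
    n_below = 0
    done = 0
    while done < N_sim:
        nb = min(batch, N_sim - done)
        idx = np.empty((nb, n_cfos), dtype=np.int64)
        for i in range(nb):
            # sorted so the degenerate full-set subsample reproduces H_obs
            # bit-exactly (summation order)
            idx[i] = np.sort(rng.choice(n_neun, size=n_cfos, replace=False))
        h_sim = _subsample_entropies(px, py, rx, ry, idx)
        n_below += int((h_sim < h_obs).sum())
        done += nb
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    return VoronoiEntropyResult(
        H_obs=h_obs,
        n_cfos=n_cfos,
        N_sim=N_sim,
        n_below=n_below,
        p_value=n_below / N_sim,
        seed=int(seed_val),
        degenerate=(n_cfos == n_neun),
    )


def stripe_rule(sections: Iterable[SectionPattern]) -> tuple[int, float]:
    """Stripe count and thickness shared by all sections of one dLGN.

    The number of stripes is round(sqrt(N_max)) where N_max is the NeuN
    count of the densest section, and the thickness is the latero-medial
    extent of that section divided by the stripe count.  Expected per-stripe
    counts are then of order sqrt(N_max), which keeps the per-stripe count
    index away from very small values.
    """
    sections = list(sections)
    if not sections:
        raise ValueError("no sections supplied")
    counts = [int(s.points["neun"].astype(bool).sum()) for s in sections]
    best = int(np.argmax(counts))
    n_max = counts[best]
    if n_max < 1:
        raise ValueError("no NeuN cells in any section")
    k = max(2, round(math.sqrt(n_max)))
    thickness = sections[best].lateromedial_extent / k
    return k, thickness


def stripe_partition(
    section: SectionPattern,
    marker: str = "neun",
    thickness: float | None = None,
    k: int | None = None,
) -> StripePartition:
    """Partition the section into bands parallel to the lateral edge.

    Each point falls in stripe floor(d/thickness) where d is its distance to
    the lateral edge; the most medial stripe absorbs the remainder of the
    section.  Stripe areas come from intersecting the region with distance
    bands (buffers of the edge polyline), so they sum to the region area.
    """
    if thickness is None or k is None:
        k_auto, t_auto = stripe_rule([section])
        k = k if k is not None else k_auto
        thickness = thickness if thickness is not None else t_auto
    if thickness <= 0:
        raise ValueError("stripe thickness must be positive")
    if k < 2:
        raise ValueError("need at least two stripes")
    pts = section.coords(marker)
    d = (
        lateral_distance(pts, section.lateral_edge)
        if len(pts)
        else np.empty(0)
    )
    idx = np.minimum((d // thickness).astype(int), k - 1)
    observed = np.bincount(idx, minlength=k).astype(float)

    from shapely.geometry import LineString

    edge_line = LineString(section.lateral_edge)
    region_area = section.region.area
    cum = np.empty(k)
    for i in range(k - 1):
        band = edge_line.buffer((i + 1) * thickness, quad_segs=32)
        cum[i] = section.region.intersection(band).area
    cum[k - 1] = region_area
    areas = np.diff(np.concatenate(([0.0], cum)))
    n = int(observed.sum())
    expected = areas / areas.sum() * n
    return StripePartition(
        k=k,
        thickness=float(thickness),
        areas=areas,
        observed=observed,
        expected=expected,
        n_total=n,
    )


def gtest_uniform(partition: StripePartition) -> GTestResult:
    """Area-normalized G-test of uniform counts across stripes.

    G = 2 Σ O_i ln(O_i/E_i) with E_i = (S_i/ΣS)·n, referred to a χ²
    distribution with k-1 degrees of freedom; empty stripes contribute 0.
    """
    O = np.asarray(partition.observed, dtype=float)
    E = np.asarray(partition.expected, dtype=float)
    if partition.k < 2:
        raise ValueError("G-test needs at least two stripes")
    if partition.n_total <= 0:
        raise ValueError("G-test needs at least one observed count")
    if np.any((E == 0) & (O > 0)):
        raise ValueError("observed count in a stripe with zero expected count")
    mask = O > 0
    G = 2.0 * float((O[mask] * np.log(O[mask] / E[mask])).sum())
    df = partition.k - 1
    p = float(stats.chi2.sf(G, df))
    return GTestResult(G=G, df=df, p_value=p)


def median_lateralization_test(
    section: SectionPattern,
    N_sim: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> LateralizationResult:
    """Monte Carlo test that activated cells sit closer to the lateral edge.

    The observed statistic is the median lateral distance of activated
    (NeuN/c-Fos double positive) cells; the null distribution is the median
    over random NeuN subsamples of the same size.  p = #(median_sim <
    median_obs)/N_sim, small when the activated cells are laterally biased.
    """
    neun, cfos = _marker_subsets(section)
    n_neun, n_cfos = len(neun), len(cfos)
    if n_cfos < 1:
        raise ValueError("need at least one activated cell")
    if n_cfos > n_neun:
        raise ValueError("activated set larger than the NeuN set")
    rng = np.random.default_rng(seed)
    d_neun = lateral_distance(neun, section.lateral_edge)
    med_obs = float(np.median(lateral_distance(cfos, section.lateral_edge)))
    n_below = 0
    for _ in range(N_sim):
        sub = rng.choice(d_neun, size=n_cfos, replace=False)
        if np.median(sub) < med_obs:
            n_below += 1
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    return LateralizationResult(
        median_obs=med_obs,
        n_cfos=n_cfos,
        N_sim=N_sim,
        n_below=n_below,
        p_value=n_below / N_sim,
        seed=int(seed_val),
    )


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj
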