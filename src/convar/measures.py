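"""Richness and variability statistics of max-pooled filter responses.

For a response stack of ``k`` filter maps, the map is divided into ``n x n``
(near-)equally sized subregions and the per-filter maximum is recorded in each
subregion, giving a three-dimensional max-pooling map ``M`` (two positional
axes plus the filter axis).  Each subregion's ``k``-vector is then L1
normalized so it sums to one — a histogram of relative filter activation —
which makes everything downstream invariant to the overall response scale.

Three variances summarise a normalized map:

* ``p_a`` — the variance over *all* entries of *all* histograms.  Low values
  mean many diverse filters respond in every subregion (**richness**); high
  values mean responses are concentrated on few filters (sparseness), as in
  images with large homogeneous areas.
* ``p_g`` — the median over subregions of each histogram's internal variance.
* ``p_f`` — the median over filters of each filter's variance across
  subregions (**variability**); low when the same features repeat everywhere,
  i.e. it behaves as the inverse of self-similarity.

Each measure is evaluated for grid sizes ``n = 2, 4, ..., 30``, giving a
45-value descriptor per layer.  ``P_a(n)`` denotes ``p_a`` at grid ``n``.

The self-similarity comparator pools at the *ground level* (n = 1) and over 64
subregions (n = 8) and averages the histogram intersection between the ground
histogram and every subregion histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .backbone import ResponseStack
from .errors import ContractError, GridError

log = logging.getLogger(__name__)

#: Pooling grid sizes: 2..30 in steps of 2 → 15 grids, 45 features per layer.
GRID_SIZES: tuple[int, ...] = tuple(range(2, 31, 2))

MEASURES = ("pa", "pg", "pf")


def feature_names(grids: tuple[int, ...] = GRID_SIZES) -> list[str]:
    """Column names grouped by measure, then grid: pa_02..pa_30, pg_.., pf_.."""
    return [f"{m}_{n:02d}" for m in MEASURES for n in grids]


@dataclass
class MaxPoolMap:
    """``n x n x k`` array of per-subregion, per-filter maxima."""

    layer_id: int
    grid: int
    values: np.ndarray
    normalized: bool = False

    @property
    def n_filters(self) -> int:
        return self.values.shape[2]


def _bounds(size: int, n: int) -> np.ndarray:
    """Subregion boundaries at round(j * size / n); near-equal, no pixel dropped."""
    return np.floor(np.arange(n + 1) * size / n + 0.5).astype(np.intp)


def max_pool_map(resp: ResponseStack, n: int) -> MaxPoolMap:
    """Divide each filter map into ``n x n`` subregions and take the maxima."""
    k, h, w = resp.responses.shape
    if n < 1 or n > min(h, w):
        raise GridError(
            f"grid size {n} invalid for a {h} x {w} response map "
            f"(must be 1..{min(h, w)})"
        )
    rb, cb = _bounds(h, n), _bounds(w, n)
    pooled = np.maximum.reduceat(resp.responses, rb[:-1], axis=1)
    pooled = np.maximum.reduceat(pooled, cb[:-1], axis=2)
    return MaxPoolMap(resp.layer_id, n, np.moveaxis(pooled, 0, 2), normalized=False)


def normalize_histograms(m: MaxPoolMap) -> MaxPoolMap:
    """L1-normalize every subregion's k-vector to sum to one.

    Idempotent.  A subregion whose responses are all zero (possible after
    rectification of a perfectly uniform area) is filled with the uniform
    vector ``1/k``, which keeps the sum-to-one invariant and contributes zero
    within-histogram variance; the fill is logged.
    """
    if m.normalized:
        return m
    v = m.values
    if v.min() < 0:
        raise ContractError(
            "negative max-pooled responses: histograms require rectified input"
        )
    sums = v.sum(axis=2, keepdims=True)
    zero = sums[:, :, 0] == 0.0
    out = np.empty_like(v, dtype=np.float64)
    np.divide(v, np.where(sums == 0.0, 1.0, sums), out=out)
    if zero.any():
        log.debug(
            "uniform-filled %d all-zero subregions at grid %d", int(zero.sum()), m.grid
        )
        out[zero] = 1.0 / m.n_filters
    return MaxPoolMap(m.layer_id, m.grid, out, normalized=True)


def _require_normalized(m: MaxPoolMap) -> np.ndarray:
    if not m.normalized:
        raise ContractError("measure requires a normalized MaxPoolMap")
    return m.values


def p_a(m: MaxPoolMap, ddof: int = 0) -> float:
    """Total variance over all entries of all subregion histograms."""
    return float(np.var(_require_normalized(m), ddof=ddof))


def p_g(m: MaxPoolMap, ddof: int = 0) -> float:
    """Median over subregions of the within-histogram variance."""
    v = _require_normalized(m)
    return float(np.median(np.var(v, axis=2, ddof=ddof)))


def p_f(m: MaxPoolMap, ddof: int = 0) -> float:
    """Median over filters of each filter's variance across subregions."""
    v = _require_normalized(m)
    k = v.shape[2]
    return float(np.median(np.var(v.reshape(-1, k), axis=0, ddof=ddof)))


@dataclass
class VarianceFeatures:
    """The 45-value per-layer descriptor: 3 measures x 15 grid sizes."""

    layer_id: int
    grid_sizes: tuple[int, ...]
    pa: np.ndarray
    pg: np.ndarray
    pf: np.ndarray

    def _at(self, arr: np.ndarray, n: int) -> float:
        try:
            return float(arr[self.grid_sizes.index(n)])
        except ValueError:
            raise GridError(f"grid {n} not among computed sizes {self.grid_sizes}")

    def P_a(self, n: int) -> float:
        return self._at(self.pa, n)

    def P_g(self, n: int) -> float:
        return self._at(self.pg, n)

    def P_f(self, n: int) -> float:
        return self._at(self.pf, n)

    def as_array(self) -> np.ndarray:
        """Fixed column order: pa over all grids, then pg, then pf."""
        return np.concatenate([self.pa, self.pg, self.pf])

    def names(self) -> list[str]:
        return feature_names(self.grid_sizes)

    def to_dict(self) -> dict[str, float]:
        return dict(zip(self.names(), self.as_array()))


def feature_vector(
    resp: ResponseStack,
    grids: tuple[int, ...] = GRID_SIZES,
    ddof: int = 0,
) -> VarianceFeatures:
    """Compute ``P_a``, ``P_g`` and ``P_f`` on every grid size."""
    h, w = resp.geometry
    need = max(grids)
    if min(h, w) < need:
        raise GridError(
            f"response map {h} x {w} too small: grids up to {need} require at "
            f"least {need} pixels per axis"
        )
    pa, pg, pf = [], [], []
    for n in grids:
        m = normalize_histograms(max_pool_map(resp, n))
        pa.append(p_a(m, ddof))
        pg.append(p_g(m, ddof))
        pf.append(p_f(m, ddof))
    return VarianceFeatures(
        resp.layer_id, tuple(grids), np.array(pa), np.array(pg), np.array(pf)
    )


@dataclass
class SelfSimilarityScore:
    """Mean histogram intersection between ground level and 64 subregions."""

    layer_id: int
    value: float


def self_similarity(resp: ResponseStack, grid: int = 8) -> SelfSimilarityScore:
    """Similarity between the whole image and its ``grid x grid`` parts.

    The ground-level histogram (max pooling over the entire map, n = 1) is
    compared with each subregion histogram by histogram intersection
    ``sum_i min(g_i, h_i)`` and the intersections are averaged.  Both vectors
    are L1 normalized, so the score lies in [0, 1] and equals 1 exactly when
    every subregion histogram matches the ground level.
    """
    h, w = resp.geometry
    if min(h, w) < grid:
        raise GridError(
            f"response map {h} x {w} too small for the {grid} x {grid} "
            "self-similarity grid"
        )
    ground = normalize_histograms(max_pool_map(resp, 1)).values[0, 0]
    subs = normalize_histograms(max_pool_map(resp, grid)).values
    inter = np.minimum(ground[None, None, :], subs).sum(axis=2)
    return SelfSimilarityScore(resp.layer_id, float(inter.mean()))
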