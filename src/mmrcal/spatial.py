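"""Queen-contiguity spatial weights and Moran-family autocorrelation statistics.

Conventions (recorded in all outputs):

* weights are row-standardised for every statistic (binary form retained);
* pseudo p-values are one-sided toward the observed direction, with ties
  counted as extreme: p = (extreme + 1) / (permutations + 1);
* the permutation engine seeds a single generator and visits units in the
  weights object's canonical (sorted-id) order, so results are reproducible
  given (seed, n_permutations);
* islands (degree-0 units) have no spatial lag: they are dropped from the
  statistics, reported, and carry NaN local statistics.

Global Moran's I on row-standardised weights with mean-centred values z:

    I = (n / S0) * (z' W* z) / (z' z),    E[I] = -1 / (n - 1)

and the local decomposition I_i = (z_i / m2) * (W* z)_i with m2 = z'z / n,
whose average over units equals the global statistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse

from mmrcal.exceptions import ValidationError

__all__ = [
    "SpatialWeights",
    "MoranResult",
    "build_weights",
    "weights_from_geojson",
    "global_moran",
    "moran_permutation_p",
    "local_moran",
    "lisa_permutation",
    "bivariate_local_moran",
]

QUADRANTS = ("HH", "LL", "HL", "LH")


@dataclass
class SpatialWeights:
    """Queen-contiguity weights: binary and row-standardised forms.

    ``ids`` is the canonical sorted unit order; matrices are aligned to it.
    """

    ids: np.ndarray
    W: scipy.sparse.csr_matrix
    W_star: scipy.sparse.csr_matrix = field(init=False)
    degrees: np.ndarray = field(init=False)
    islands: list = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if n < 2:
            raise ValidationError("weights: need at least 2 units")
        if self.W.shape != (n, n):
            raise ValidationError("weights: matrix shape does not match id list")
        if (self.W != self.W.T).nnz != 0:
            raise ValidationError("weights: binary adjacency must be symmetric")
        if self.W.diagonal().any():
            raise ValidationError("weights: diagonal must be zero")
        self.degrees = np.asarray(self.W.sum(axis=1)).ravel()
        self.islands = [self.ids[i] for i in np.flatnonzero(self.degrees == 0)]
        inv = np.where(self.degrees > 0, 1.0 / np.maximum(self.degrees, 1.0), 0.0)
        self.W_star = (scipy.sparse.diags(inv) @ self.W).tocsr()

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def s0(self) -> float:
        """Sum of row-standardised weights (= number of non-island units)."""
        return float(self.W_star.sum())

    def align(self, values) -> np.ndarray:
        """Align a value vector to the canonical id order."""
        if isinstance(values, pd.Series):
            missing = [i for i in self.ids if i not in values.index]
            if missing:
                raise ValidationError(f"values: missing units {missing[:5]}...")
            return values.reindex(self.ids).to_numpy(dtype=float)
        arr = np.asarray(values, dtype=float)
        if arr.shape != (self.n,):
            raise ValidationError(
                f"values: expected length {self.n}, got {arr.shape}"
            )
        return arr


@dataclass(frozen=True)
class MoranResult:
    """Global Moran's I with optional permutation inference."""

    I: float
    expected_I: float
    n: int
    s0: float
    z: np.ndarray
    pseudo_p: float | None = None
    n_permutations: int | None = None
    seed: int | None = None
    islands: tuple = ()


def build_weights(
    edges: pd.DataFrame | list[tuple] | None = None,
    polygons: list | None = None,
    ids=None,
) -> SpatialWeights:
    """Build queen-contiguity weights from an edge list or shapely polygons.

    From polygons, units are neighbours iff their geometries share at least
    one boundary point (queen rule). From an edge list, the adjacency is
    symmetrised. ``ids`` may list units beyond those in the edge list so that
    islands are retained (and flagged) rather than silently dropped.
    """
    if (edges is None) == (polygons is None):
        raise ValidationError("weights: provide exactly one of edges or polygons")

    if polygons is not None:
        if ids is None or len(ids) != len(polygons):
            raise ValidationError("weights: polygon input needs one id per geometry")
        order = np.argsort(np.asarray(ids, dtype=object))
        sorted_ids = np.asarray(ids, dtype=object)[order]
        geoms = [polygons[k] for k in order]
        from shapely.strtree import STRtree

        tree = STRtree(geoms)
        left, right = tree.query(geoms, predicate="intersects")
        keep = left != right
        pairs = set()
        for i, j in zip(left[keep], right[keep]):
            pairs.add((min(i, j), max(i, j)))
        return _weights_from_index_pairs(sorted_ids, pairs)

    if isinstance(edges, pd.DataFrame):
        pair_list = list(zip(edges.iloc[:, 0].astype(str), edges.iloc[:, 1].astype(str)))
    else:
        pair_list = [(str(a), str(b)) for a, b in edges]
    edge_ids = {u for pair in pair_list for u in pair}
    if ids is None:
        id_arr = np.array(sorted(edge_ids), dtype=object)
    else:
        id_arr = np.array(sorted(str(i) for i in ids), dtype=object)
        unknown = edge_ids - set(id_arr)
        if unknown:
            raise ValidationError(f"edges: unknown unit ids {sorted(unknown)}")
    pos = {u: k for k, u in enumerate(id_arr)}
    pairs = set()
    for a, b in pair_list:
        if a == b:
            continue
        i, j = pos[a], pos[b]
        pairs.add((min(i, j), max(i, j)))
    return _weights_from_index_pairs(id_arr, pairs)


def _weights_from_index_pairs(ids: np.ndarray, pairs: set) -> SpatialWeights:
    n = len(ids)
    if pairs:
        rows = [i for i, j in pairs] + [j for i, j in pairs]
        cols = [j for i, j in pairs] + [i for i, j in pairs]
        w = scipy.sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
    else:
        w = scipy.sparse.csr_matrix((n, n))
    sw = SpatialWeights(ids=ids, W=w)
    if sw.islands:
        warnings.warn(
            f"weights: {len(sw.islands)} island unit(s) with no neighbours "
            f"excluded from spatial statistics: {sw.islands[:5]}",
            stacklevel=3,
        )
    return sw


def weights_from_geojson(path: str | Path, id_property: str = "district_id") -> SpatialWeights:
    """Queen weights from a GeoJSON FeatureCollection of polygons."""
    from shapely.geometry import shape

    doc = json.loads(Path(path).read_text())
    geoms, ids = [], []
    for feat in doc["features"]:
        geoms.append(shape(feat["geometry"]))
        ids.append(str(feat["properties"][id_property]))
    return build_weights(polygons=geoms, ids=ids)


def _effective(values: np.ndarray, w: SpatialWeights) -> tuple[np.ndarray, np.ndarray]:
    """(mask of non-island units, mean-centred z over that subset)."""
    if np.isnan(values).any():
        bad = [w.ids[i] for i in np.flatnonzero(np.isnan(values))]
        raise ValidationError(f"values: NaN for units {bad[:5]}")
    mask = w.degrees > 0
    if mask.sum() < 3:
        raise ValidationError("values: need at least 3 connected units")
    z = np.zeros_like(values)
    z[mask] = values[mask] - values[mask].mean()
    if np.allclose(z[mask], 0.0):
        raise ValidationError("values: constant field has no spatial autocorrelation")
    return mask, z


def global_moran(values, weights: SpatialWeights) -> MoranResult:
    """Global Moran's I on row-standardised weights (statistic only)."""
    x = weights.align(values)
    mask, z = _effective(x, weights)
    n_eff = int(mask.sum())
    lag = weights.W_star @ z
    num = float(z[mask] @ lag[mask])
    den = float(z[mask] @ z[mask])
    i_stat = (n_eff / weights.s0) * num / den
    return MoranResult(
        I=i_stat,
        expected_I=-1.0 / (n_eff - 1),
        n=n_eff,
        s0=weights.s0,
        z=z,
        islands=tuple(weights.islands),
    )


def moran_permutation_p(
    values, weights: SpatialWeights, n_permutations: int = 999, seed: int = 0
) -> MoranResult:
    """Permutation pseudo p-value for global Moran's I.

    Values are randomly reassigned to units ``n_permutations`` times; the
    pseudo p is one-sided toward the observed side of E[I], ties extreme.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations: must be >= 1")
    obs = global_moran(values, weights)
    x = weights.align(values)
    mask = weights.degrees > 0
    idx = np.flatnonzero(mask)
    z = obs.z
    den = float(z[idx] @ z[idx])
    rng = np.random.default_rng(seed)
    w_sub = weights.W_star[np.ix_(idx, idx)].tocsr()
    zsub = z[idx]
    count = 0
    upper = obs.I >= obs.expected_I
    scale = obs.n / weights.s0
    for _ in range(n_permutations):
        zp = rng.permutation(zsub)
        i_perm = scale * float(zp @ (w_sub @ zp)) / den
        if (upper and i_perm >= obs.I) or (not upper and i_perm <= obs.I):
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return MoranResult(
        I=obs.I,
        expected_I=obs.expected_I,
        n=obs.n,
        s0=obs.s0,
        z=obs.z,
        pseudo_p=p,
        n_permutations=n_permutations,
        seed=seed,
        islands=obs.islands,
    )


def _quadrant(z_i: float, lag_i: float) -> str:
    if z_i > 0:
        return "HH" if lag_i > 0 else "HL"
    return "LH" if lag_i > 0 else "LL"


def local_moran(values, weights: SpatialWeights) -> pd.DataFrame:
    """Local Moran I_i with cluster quadrants (statistics only).

    Returns a frame indexed by unit id with columns z, lag, local_i and
    quadrant (HH/LL/HL/LH from the signs of z_i and its spatial lag; ties on
    zero are assigned to the low side). Island units carry NaN.
    """
    x = weights.align(values)
    mask, z = _effective(x, weights)
    n_eff = int(mask.sum())
    m2 = float(z[mask] @ z[mask]) / n_eff
    lag = weights.W_star @ z
    local = np.where(mask, z / m2 * lag, np.nan)
    out = pd.DataFrame(
        {
            "z": np.where(mask, z, np.nan),
            "lag": np.where(mask, lag, np.nan),
            "local_i": local,
            "quadrant": [
                _quadrant(z[k], lag[k]) if mask[k] else None for k in range(weights.n)
            ],
        },
        index=pd.Index(weights.ids, name="district_id"),
    )
    return out


def _conditional_permutation(
    z_self: np.ndarray,
    z_pool_source: np.ndarray,
    weights: SpatialWeights,
    mask: np.ndarray,
    m2: float,
    observed: np.ndarray,
    n_permutations: int,
    seed: int,
) -> np.ndarray:
    """Conditional-permutation pseudo p per unit.

    For unit i, hold its own value fixed and resample the other units'
    (pool) values without replacement into its neighbour set; the permuted
    statistic is z_i/m2 times the mean of the sampled neighbour values.
    ``z_self`` supplies z_i (x in the bivariate case), ``z_pool_source`` the
    values permuted among the other units (y in the bivariate case).
    """
    rng = np.random.default_rng(seed)
    n = weights.n
    idx_eff = np.flatnonzero(mask)
    pos_in_eff = {j: k for k, j in enumerate(idx_eff)}
    n_eff = len(idx_eff)
    pvals = np.full(n, np.nan)
    indptr, indices = weights.W.indptr, weights.W.indices
    base = np.arange(n_eff - 1)
    perm_buf = np.tile(base, (n_permutations, 1))
    for i in idx_eff:
        nbrs = indices[indptr[i] : indptr[i + 1]]
        nbrs = nbrs[mask[nbrs]]
        k = len(nbrs)
        if k == 0:
            continue
        pool = np.delete(z_pool_source[idx_eff], pos_in_eff[i])
        rng.permuted(perm_buf, axis=1, out=perm_buf)
        lag_perm = pool[perm_buf[:, :k]].mean(axis=1)
        i_perm = z_self[i] / m2 * lag_perm
        if observed[i] >= 0:
            extreme = int((i_perm >= observed[i]).sum())
        else:
            extreme = int((i_perm <= observed[i]).sum())
        pvals[i] = (extreme + 1) / (n_permutations + 1)
    return pvals


def lisa_permutation(
    values,
    weights: SpatialWeights,
    n_permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    selection_correction: bool = True,
) -> pd.DataFrame:
    """Univariate LISA with conditional-permutation significance.

    Adds pseudo_p and significant to the local_moran frame. The attainable
    minimum pseudo p is 1/(n_permutations + 1).

    The pseudo p is one-sided toward the observed sign of I_i — a tail chosen
    after seeing the statistic, so under a no-autocorrelation null
    ``pseudo_p < alpha`` occurs with probability ~2*alpha. The default
    significance flag therefore applies the equal-tail selection correction
    (flag iff pseudo_p < alpha/2), giving the test size alpha;
    ``selection_correction=False`` restores the raw map convention
    (flag iff pseudo_p < alpha).
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations: must be >= 1")
    if not 0 < alpha < 1:
        raise ValidationError("alpha: must lie in (0, 1)")
    out = local_moran(values, weights)
    x = weights.align(values)
    mask, z = _effective(x, weights)
    n_eff = int(mask.sum())
    m2 = float(z[mask] @ z[mask]) / n_eff
    observed = np.where(mask, out["local_i"].to_numpy(), np.nan)
    pvals = _conditional_permutation(
        z, z, weights, mask, m2, observed, n_permutations, seed
    )
    out["pseudo_p"] = pvals
    threshold = alpha / 2 if selection_correction else alpha
    out["significant"] = (out["pseudo_p"] < threshold).fillna(False)
    return out


def bivariate_local_moran(
    x,
    y,
    weights: SpatialWeights,
    n_permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    selection_correction: bool = True,
) -> pd.DataFrame:
    """Bivariate LISA: association of x at i with y among i's neighbours.

    I_i^xy = (zx_i / m2x) * (W* zy)_i; quadrants from the signs of zx_i and
    the lag of zy; permutation holds x_i fixed and permutes y among the
    other units. With y = x this reduces to the univariate local Moran.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations: must be >= 1")
    xa = weights.align(x)
    ya = weights.align(y)
    mask, zx = _effective(xa, weights)
    _, zy = _effective(ya, weights)  # also validates y (finite, non-constant)
    n_eff = int(mask.sum())
    m2x = float(zx[mask] @ zx[mask]) / n_eff
    lag_y = weights.W_star @ zy
    local = np.where(mask, zx / m2x * lag_y, np.nan)
    out = pd.DataFrame(
        {
            "zx": np.where(mask, zx, np.nan),
            "lag_y": np.where(mask, lag_y, np.nan),
            "local_i": local,
            "quadrant": [
                _quadrant(zx[k], lag_y[k]) if mask[k] else None
                for k in range(weights.n)
            ],
        },
        index=pd.Index(weights.ids, name="district_id"),
    )
    pvals = _conditional_permutation(
        zx, zy, weights, mask, m2x, local, n_permutations, seed
    )
    out["pseudo_p"] = pvals
    threshold = alpha / 2 if selection_correction else alpha
    out["significant"] = (out["pseudo_p"] < threshold).fillna(False)
    return out
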