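"""CRF regularization of probability maps via graph cuts.

The segmentation energy couples per-voxel data terms with an anisotropic
Potts-with-distance-matrix pairwise term over the 6-connected grid:

    E(Y) = sum_i -log P(y_i | f_i)
         + theta_xy * sum_{(i,j) in E_XY} D[y_i, y_j]
         + theta_z  * sum_{(i,j) in E_Z}  D[y_i, y_j]

where E_XY are the 4 in-plane neighbor pairs, E_Z the 2 across-slice
pairs, and D is a symmetric label distance matrix with zero diagonal
(1 = allowed transition, INF = forbidden adjacency, e.g. a synaptic
junction touching a mitochondrion).  On anisotropic stacks the default
across-slice weight is ``theta_z = theta_xy / rho``.

For two labels a single max-flow/min-cut computation yields the exact
global minimizer (the pairwise terms are submodular); for three or more
labels the alpha-beta swap algorithm applies exact binary cuts to label
pairs until no swap lowers the energy.  Large volumes are processed in
overlapping tiles: each tile is extended by a margin, minimized, and
only the core voxels are written back.

Max-flow runs on ``scipy.sparse.csgraph.maximum_flow``, which needs
integer capacities; float capacities are converted with an adaptive
fixed-point scale, and INF surrogates saturate at 2**30.  Infeasibility
(a forced forbidden adjacency) is detected on the float energy of the
returned labeling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, maximum_flow

from .classifier import ProbabilityMap
from .errors import InfeasibleEnergyError
from .volumes import LabelVolume

POSTERIOR_FLOOR = 1e-12
_CAP_INF = 2**30  # saturation value for forbidden-adjacency capacities
_CAP_SAFE = 2**29  # max finite capacity after fixed-point scaling
_MAX_SCALE = 1e7


def default_distance_matrix(
    n_labels: int, forbidden_pairs: Sequence[tuple[int, int]] = ()
) -> np.ndarray:
    """Zero-diagonal matrix, 1 off-diagonal, INF on forbidden index pairs."""
    d = np.ones((n_labels, n_labels)) - np.eye(n_labels)
    for a, b in forbidden_pairs:
        d[a, b] = d[b, a] = np.inf
    return d


@dataclass(frozen=True)
class CRFConfig:
    """Regularization hyperparameters.

    ``theta_z=None`` resolves to ``theta_xy / rho`` at energy-build time.
    ``distance_matrix=None`` resolves to all-ones off-diagonal with the
    synapse/mitochondrion pair forbidden when those labels are present.
    """

    theta_xy: float = 1.0
    theta_z: float | None = None
    distance_matrix: np.ndarray | None = None
    tile_shape: tuple[int, int, int] = (256, 256, 64)
    margin: int = 10
    inf_value: float | None = None

    def __post_init__(self) -> None:
        if self.theta_xy < 0 or (self.theta_z is not None and self.theta_z < 0):
            raise ValueError("pairwise weights must be non-negative")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")
        if self.distance_matrix is not None:
            d = np.asarray(self.distance_matrix, dtype=np.float64)
            if d.ndim != 2 or d.shape[0] != d.shape[1]:
                raise ValueError("distance matrix must be square")
            if not np.array_equal(d, d.T):
                raise ValueError("distance matrix must be symmetric")
            if np.any(np.diag(d) != 0):
                raise ValueError("distance matrix must have a zero diagonal")
            object.__setattr__(self, "distance_matrix", d)


@dataclass(frozen=True)
class EnergyInstance:
    """A concrete energy: unary costs plus resolved pairwise parameters.

    The 6-neighborhood edge sets E_XY and E_Z are implicit in the grid:
    E_XY are the +X/+Y forward differences, E_Z the +Z ones.
    """

    unary: np.ndarray  # (X, Y, Z, L) = -log posterior
    label_ids: tuple[int, ...]
    theta_xy: float
    theta_z: float
    dist: np.ndarray  # (L, L), may contain np.inf
    inf_value: float
    label_table: Mapping[int, str] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.unary.shape[:3]

    @property
    def n_labels(self) -> int:
        return len(self.label_ids)

    @property
    def dist_surrogate(self) -> np.ndarray:
        """Distance matrix with INF replaced by the finite surrogate."""
        return np.where(np.isinf(self.dist), self.inf_value, self.dist)

    def sub(self, sl: tuple[slice, slice, slice]) -> "EnergyInstance":
        """Restriction to a subvolume; pairwise parameters are shared."""
        return replace(self, unary=self.unary[sl])


def build_energy(
    probmap: ProbabilityMap,
    config: CRFConfig,
    rho: float | None = None,
) -> EnergyInstance:
    """Assemble unary terms (-log posterior, floored) and resolve weights."""
    theta_z = config.theta_z
    if theta_z is None:
        if rho is None:
            raise ValueError("either config.theta_z or the stack anisotropy rho is required")
        theta_z = config.theta_xy / rho
    n_labels = len(probmap.label_ids)
    dist = config.distance_matrix
    if dist is None:
        forbidden = []
        ids = list(probmap.label_ids)
        if 2 in ids and 3 in ids:  # synapse and mitochondrion may not touch
            forbidden.append((ids.index(2), ids.index(3)))
        dist = default_distance_matrix(n_labels, forbidden)
    if dist.shape[0] != n_labels:
        raise ValueError(
            f"distance matrix is {dist.shape[0]}x{dist.shape[0]} but the "
            f"probability map has {n_labels} labels"
        )
    unary = -np.log(np.clip(probmap.probs, POSTERIOR_FLOOR, 1.0))
    inf_value = config.inf_value
    if inf_value is None:
        inf_value = 1e6 * (float(unary.max()) + config.theta_xy + theta_z)
    return EnergyInstance(
        unary=unary,
        label_ids=tuple(probmap.label_ids),
        theta_xy=config.theta_xy,
        theta_z=theta_z,
        dist=dist,
        inf_value=float(inf_value),
        label_table=dict(probmap.label_table),
    )


def _label_indices(energy: EnergyInstance, labels: np.ndarray) -> np.ndarray:
    lut = {lab: i for i, lab in enumerate(energy.label_ids)}
    idx = np.empty(labels.shape, dtype=np.intp)
    seen = np.unique(labels)
    unknown = [int(v) for v in seen if int(v) not in lut]
    if unknown:
        raise ValueError(f"labeling contains ids {unknown} not in the energy instance")
    for lab, i in lut.items():
        idx[labels == lab] = i
    return idx


def labeling_energy(labeling: LabelVolume | np.ndarray, energy: EnergyInstance) -> float:
    """Evaluate E(Y); INF pairwise entries contribute ``inf_value``."""
    labels = labeling.labels if isinstance(labeling, LabelVolume) else np.asarray(labeling)
    if labels.shape != energy.shape:
        raise ValueError(f"labeling shape {labels.shape} != energy shape {energy.shape}")
    idx = _label_indices(energy, labels)
    total = float(
        np.take_along_axis(energy.unary, idx[..., None], axis=-1).sum()
    )
    d = energy.dist_surrogate
    total += energy.theta_xy * float(d[idx[:-1], idx[1:]].sum())
    total += energy.theta_xy * float(d[idx[:, :-1], idx[:, 1:]].sum())
    total += energy.theta_z * float(d[idx[:, :, :-1], idx[:, :, 1:]].sum())
    return total


# ---------------------------------------------------------------------------
# Binary min-cut core
# ---------------------------------------------------------------------------

def _binary_graphcut(
    d_a: np.ndarray,
    d_b: np.ndarray,
    mask: np.ndarray,
    w_xy: float,
    w_z: float,
    inf_value: float,
) -> np.ndarray:
    """Exact minimizer of a masked binary grid energy.

    Voxels inside ``mask`` choose between cost ``d_a`` and ``d_b``;
    adjacent masked voxels with different choices pay ``w_xy``/``w_z``.
    Returns a boolean array, True where label b is chosen.
    """
    n = int(mask.sum())
    choose_b = np.zeros(mask.shape, dtype=bool)
    if n == 0:
        return choose_b
    idx = np.full(mask.shape, -1, dtype=np.int64)
    idx[mask] = np.arange(n)

    # Normalize terminal costs so one of the two is zero per voxel.
    base = np.minimum(d_a, d_b)
    cap_src = (d_b - base)[mask]  # cut when voxel ends on sink side (label b? no: see below)
    cap_snk = (d_a - base)[mask]
    # Convention: voxel on the source side keeps label a and pays its edge
    # to the sink (cap d_a - base); voxel on the sink side takes label b
    # and pays the edge from the source (cap d_b - base).

    pair_rows, pair_cols, pair_caps = [], [], []
    for axis, w in ((0, w_xy), (1, w_xy), (2, w_z)):
        if w <= 0:
            continue
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        both = mask[tuple(sl_lo)] & mask[tuple(sl_hi)]
        u = idx[tuple(sl_lo)][both]
        v = idx[tuple(sl_hi)][both]
        pair_rows.append(u)
        pair_cols.append(v)
        pair_caps.append(np.full(u.shape, w))

    s, t = n, n + 1
    voxels = np.arange(n)
    rows = [np.full(n, s), voxels]
    cols = [voxels, np.full(n, t)]
    caps = [cap_src, cap_snk]
    if pair_rows:
        pu = np.concatenate(pair_rows)
        pv = np.concatenate(pair_cols)
        pw = np.concatenate(pair_caps)
        rows += [pu, pv]
        cols += [pv, pu]
        caps += [pw, pw]
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    caps = np.concatenate(caps)

    # Fixed-point conversion: scale by the largest finite capacity, then
    # saturate forbidden-adjacency surrogates.
    fin_threshold = 1e-3 * inf_value
    finite = caps[caps < fin_threshold]
    max_finite = float(finite.max()) if finite.size else 1.0
    scale = float(np.clip(_CAP_SAFE / max(max_finite, 1e-30), 1.0, _MAX_SCALE))
    icaps = np.minimum(np.round(caps * scale), _CAP_INF).astype(np.int32)
    # Deterministic tie-break: an exactly indifferent voxel stays on the
    # source side (label a, the lower id), matching the argmax rule.
    icaps[:n] += (cap_src == cap_snk).astype(np.int32)

    keep = icaps > 0
    graph = csr_matrix(
        (icaps[keep], (rows[keep], cols[keep])), shape=(n + 2, n + 2)
    )
    result = maximum_flow(graph, s, t)
    residual = graph - result.flow
    residual.data = np.maximum(residual.data, 0)
    residual.eliminate_zeros()
    reach = breadth_first_order(residual, s, directed=True, return_predecessors=False)
    on_source = np.zeros(n + 2, dtype=bool)
    on_source[reach] = True
    choose_b[mask] = ~on_source[:n]
    return choose_b


def _check_submodular(dist: np.ndarray, a: int, b: int) -> None:
    if dist[a, a] + dist[b, b] > dist[a, b] + dist[b, a]:
        raise ValueError(
            f"pairwise term for labels ({a}, {b}) is not submodular: "
            f"D[a,a]+D[b,b] > D[a,b]+D[b,a]"
        )


def minimize_binary(energy: EnergyInstance) -> LabelVolume:
    """Global minimizer of a 2-label energy via a single max-flow."""
    if energy.n_labels != 2:
        raise ValueError(f"minimize_binary needs exactly 2 labels, got {energy.n_labels}")
    _check_submodular(energy.dist, 0, 1)
    d = energy.dist_surrogate
    mask = np.ones(energy.shape, dtype=bool)
    choose_b = _binary_graphcut(
        energy.unary[..., 0],
        energy.unary[..., 1],
        mask,
        energy.theta_xy * d[0, 1],
        energy.theta_z * d[0, 1],
        energy.inf_value,
    )
    ids = np.asarray(energy.label_ids)
    labels = ids[choose_b.astype(np.intp)]
    out = LabelVolume(labels=labels, label_table=_output_table(energy))
    _assert_feasible(out, energy)
    return out


def argmin_unary(energy: EnergyInstance) -> LabelVolume:
    """The no-regularization labeling (per-voxel minimal unary cost)."""
    ids = np.asarray(energy.label_ids)
    return LabelVolume(labels=ids[np.argmin(energy.unary, axis=-1)],
                       label_table=_output_table(energy))


def _output_table(energy: EnergyInstance) -> dict[int, str]:
    return {0: "unlabeled", **{int(i): energy.label_table.get(int(i), f"label_{int(i)}")
                               for i in energy.label_ids}}


def _assert_feasible(labeling: LabelVolume, energy: EnergyInstance) -> None:
    if labeling_energy(labeling, energy) >= energy.inf_value:
        raise InfeasibleEnergyError(
            "minimized energy still contains a forbidden label adjacency"
        )


def minimize_multilabel(
    energy: EnergyInstance,
    init: LabelVolume | None = None,
    max_sweeps: int = 20,
    return_trace: bool = False,
):
    """Alpha-beta swap: iterated exact binary cuts over label pairs.

    Starts from the argmax (minimal-unary) labeling, visits label pairs in
    ascending lexicographic order, and accepts a swap only if it strictly
    lowers the energy.  Terminates when a full sweep yields no decrease.
    """
    d = energy.dist_surrogate
    if init is not None:
        y = _label_indices(energy, np.asarray(init.labels))
    else:
        y = np.argmin(energy.unary, axis=-1)
    current = labeling_energy(np.asarray(energy.label_ids)[y], energy)
    trace = [current]
    n_lab = energy.n_labels
    for _ in range(max_sweeps):
        improved = False
        for ia in range(n_lab):
            for ib in range(ia + 1, n_lab):
                _check_submodular(energy.dist, ia, ib)
                part = (y == ia) | (y == ib)
                if not part.any():
                    continue
                d_a = energy.unary[..., ia].copy()
                d_b = energy.unary[..., ib].copy()
                # Neighbors outside the swap keep their labels and act as
                # extra unary context for the participating voxels.
                ctx_a = np.where(part, 0.0, d[ia][y])
                ctx_b = np.where(part, 0.0, d[ib][y])
                for axis, w in ((0, energy.theta_xy), (1, energy.theta_xy),
                                (2, energy.theta_z)):
                    if w <= 0:
                        continue
                    lo = [slice(None)] * 3
                    hi = [slice(None)] * 3
                    lo[axis] = slice(None, -1)
                    hi[axis] = slice(1, None)
                    d_a[tuple(hi)] += w * ctx_a[tuple(lo)]
                    d_a[tuple(lo)] += w * ctx_a[tuple(hi)]
                    d_b[tuple(hi)] += w * ctx_b[tuple(lo)]
                    d_b[tuple(lo)] += w * ctx_b[tuple(hi)]
                choose_b = _binary_graphcut(
                    d_a, d_b, part,
                    energy.theta_xy * d[ia, ib],
                    energy.theta_z * d[ia, ib],
                    energy.inf_value,
                )
                candidate = y.copy()
                candidate[part & ~choose_b] = ia
                candidate[part & choose_b] = ib
                cand_energy = labeling_energy(
                    np.asarray(energy.label_ids)[candidate], energy
                )
                if cand_energy < current - 1e-9:
                    y = candidate
                    current = cand_energy
                    trace.append(current)
                    improved = True
        if not improved:
            break
    out = LabelVolume(labels=np.asarray(energy.label_ids)[y],
                      label_table=_output_table(energy))
    _assert_feasible(out, energy)
    if return_trace:
        return out, trace
    return out


def minimize(energy: EnergyInstance) -> LabelVolume:
    """Exact cut for 2 labels, alpha-beta swap otherwise."""
    if energy.n_labels == 2:
        return minimize_binary(energy)
    return minimize_multilabel(energy)


# ---------------------------------------------------------------------------
# Overlapping-tile regularization
# ---------------------------------------------------------------------------

def _tile_slices(size: int, tile: int, margin: int):
    for start in range(0, size, tile):
        stop = min(start + tile, size)
        ext_lo = max(start - margin, 0)
        ext_hi = min(stop + margin, size)
        core = slice(start, stop)
        ext = slice(ext_lo, ext_hi)
        rel = slice(start - ext_lo, stop - ext_lo)
        yield core, ext, rel


def regularize_tiled(
    probmap: ProbabilityMap,
    config: CRFConfig,
    rho: float | None = None,
) -> LabelVolume:
    """Minimize the CRF energy in overlapping tiles.

    The volume is partitioned into disjoint tiles of ``config.tile_shape``;
    each tile is extended by ``config.margin`` voxels per direction
    (clipped at the borders), minimized with full context, and only the
    core voxels are written to the output.
    """
    energy = build_energy(probmap, config, rho)
    shape = energy.shape
    out = np.zeros(shape, dtype=np.int64)
    for cx, ex, rx in _tile_slices(shape[0], config.tile_shape[0], config.margin):
        for cy, ey, ry in _tile_slices(shape[1], config.tile_shape[1], config.margin):
            for cz, ez, rz in _tile_slices(shape[2], config.tile_shape[2], config.margin):
                sub = energy.sub((ex, ey, ez))
                res = minimize(sub)
                out[cx, cy, cz] = res.labels[rx, ry, rz]
    return LabelVolume(labels=out, label_table=_output_table(energy))
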