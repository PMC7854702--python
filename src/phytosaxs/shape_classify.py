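"""Classification of ab initio bead-model ensembles into representative
molecular shapes.

A single scattering profile does not determine a unique shape: independent
ab initio reconstructions of the same data scatter over a family of
morphologies.  The protocol implemented here sorts a large ensemble into a
small number of shape groups:

1. superimpose every model on its moment-of-inertia axes
   (:func:`align_principal_axes`);
2. express each model as DR number density on a shared grid of cubic
   voxels, 6 A on a side by default (:func:`voxelize`);
3. treat each density array as one point in voxel space and project the
   ensemble onto the plane of the first two principal components
   (:func:`embed_pca`);
4. partition the plane with K-means, k = 10 by default
   (:func:`cluster_kmeans`);
5. average the members of each group after re-superimposition on a
   reference member to obtain the group's representative shape
   (:func:`average_cluster`).

Group selection among the representatives (which morphology to believe) is
scientific judgement informed by external evidence; the code ranks groups
but never auto-selects.

Separately, :func:`optimize_dr_count` runs the survey loop that picks the
dummy-residue count minimising the mean chi-square of reconstructions over
repeated runs of a pluggable reconstruction engine.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .bead_models import BeadModel, chi_square, debye_intensity, read_bead_pdb
from .saxs_core import ScatteringProfile

logger = logging.getLogger(__name__)

__all__ = [
    "VoxelGrid",
    "Embedding",
    "ClusterAssignment",
    "AveragedShape",
    "align_principal_axes",
    "voxelize",
    "shared_extent",
    "embed_pca",
    "cluster_kmeans",
    "average_cluster",
    "classify_ensemble",
    "optimize_dr_count",
]

DEFAULT_VOXEL_SIZE = 6.0  # A, cubic
DEFAULT_K = 10


@dataclass
class VoxelGrid:
    """DR number density on a corner-anchored cubic grid.

    ``density[i, j, k]`` is count / voxel volume for the half-open voxel
    [origin + i*size, origin + (i+1)*size) along each axis.  Conservation:
    sum(density) * voxel volume equals the bead count.
    """

    origin: np.ndarray
    voxel_size: float
    density: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.density.shape

    @property
    def n_beads(self) -> float:
        return float(self.density.sum() * self.voxel_size ** 3)


@dataclass
class Embedding:
    coords: np.ndarray                    # M x 2
    explained_variance_ratio: np.ndarray  # full spectrum
    component_axes: np.ndarray            # 2 x n_voxels
    mean_vector: np.ndarray


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    k: int
    centroids: np.ndarray
    seed: int
    inertia: float

    @property
    def group_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


@dataclass
class AveragedShape:
    occupancy: np.ndarray
    threshold: float
    n_members: int
    reference_index: int
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    voxel_size: float = DEFAULT_VOXEL_SIZE

    @property
    def mask(self) -> np.ndarray:
        return self.occupancy >= self.threshold

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape


# ---------------------------------------------------------------------------
# alignment


def _inertia_axes(coords: np.ndarray) -> np.ndarray:
    """Eigenvectors of the unit-mass inertia tensor, columns ordered by
    ascending eigenvalue (long axis first onto x)."""
    c = coords - coords.mean(axis=0)
    r2 = (c ** 2).sum(axis=1).sum()
    inertia = r2 * np.eye(3) - c.T @ c
    evals, evecs = np.linalg.eigh(inertia)
    return evecs  # ascending eigenvalues


def _canonical_signs(coords: np.ndarray) -> np.ndarray:
    """Proper sign fix: third moment positive on the first two axes, the
    third sign forced by det = +1."""
    signs = np.ones(3)
    for ax in range(2):
        m3 = (coords[:, ax] ** 3).sum()
        if m3 < 0:
            signs[ax] = -1.0
    signs[2] = signs[0] * signs[1]  # keep handedness (product of flips = +1)
    return signs


def _binary_occupancy(coords: np.ndarray, origin: np.ndarray, size: float,
                      shape: tuple[int, int, int]) -> np.ndarray:
    idx = np.floor((coords - origin) / size).astype(int)
    idx = np.clip(idx, 0, np.array(shape) - 1)
    occ = np.zeros(shape, dtype=bool)
    occ[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return occ


def _overlap(a: np.ndarray, b_occ: np.ndarray, origin: np.ndarray, size: float) -> int:
    occ = _binary_occupancy(a, origin, size, b_occ.shape)
    return int(np.logical_and(occ, b_occ).sum())


_PROPER_FLIPS = [np.array(f) for f in
                 [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)]]


def align_principal_axes(
    model: BeadModel,
    reference: BeadModel | None = None,
    enantiomer: bool = False,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
) -> BeadModel:
    """Superimpose a bead model on its moment-of-inertia frame.

    The centroid is moved to the origin and the inertia eigenvectors are
    mapped to x, y, z in ascending-eigenvalue order with det = +1.  The
    remaining four-fold proper-flip degeneracy (and, with ``enantiomer``,
    the mirror image — reconstructions from orientationally averaged data
    cannot determine handedness) is resolved by maximising voxel overlap
    with ``reference``; without a reference, by the canonical third-moment
    sign rule.
    """
    if model.n_beads < 3:
        raise ValueError("need >= 3 beads for inertia alignment")
    c = model.coords - model.coords.mean(axis=0)
    evecs = _inertia_axes(model.coords)
    if np.linalg.det(evecs) < 0:
        evecs[:, 2] = -evecs[:, 2]
    rotated = c @ evecs  # principal frame
    s = np.linalg.svd(c, compute_uv=False)
    if s[0] > 0 and s[1] / s[0] < 1e-8:
        raise ValueError("collinear model: inertia frame undefined")

    if reference is None:
        signs = _canonical_signs(rotated)
        out = rotated * signs
    else:
        ref = reference.coords - reference.coords.mean(axis=0)
        lo = np.minimum(rotated.min(axis=0), ref.min(axis=0)) - voxel_size
        hi = np.maximum(rotated.max(axis=0), ref.max(axis=0)) + voxel_size
        shape = tuple(np.ceil((hi - lo) / voxel_size).astype(int))
        ref_occ = _binary_occupancy(ref, lo, voxel_size, shape)
        candidates = [rotated * f for f in _PROPER_FLIPS]
        if enantiomer:
            mirrored = rotated * np.array([1.0, 1.0, -1.0])
            candidates += [mirrored * f for f in _PROPER_FLIPS]
        scores = [_overlap(cand, ref_occ, lo, voxel_size) for cand in candidates]
        out = candidates[int(np.argmax(scores))]
    return BeadModel(coords=out, bead_radius=model.bead_radius, label=model.label)


# ---------------------------------------------------------------------------
# voxelisation


def shared_extent(models: list[BeadModel], voxel_size: float = DEFAULT_VOXEL_SIZE,
                  margin_voxels: int = 1) -> tuple[np.ndarray, tuple[int, int, int]]:
    """Common corner-anchored bounding box (origin, shape in voxels) covering
    every model plus a margin, so all density vectors live in one space."""
    lo = np.min([m.coords.min(axis=0) for m in models], axis=0)
    hi = np.max([m.coords.max(axis=0) for m in models], axis=0)
    origin = lo - margin_voxels * voxel_size
    shape = tuple(
        (np.ceil((hi - origin) / voxel_size).astype(int) + margin_voxels).tolist()
    )
    return origin, shape


def voxelize(
    model: BeadModel,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    extent: tuple[np.ndarray, tuple[int, int, int]] | None = None,
) -> VoxelGrid:
    """Bead number density on the (shared) voxel grid.

    Each bead is counted in exactly one half-open voxel [edge, edge+size);
    a bead on a shared face belongs to the higher-index voxel.  A bead
    outside the extent is an error — the extent must then be recomputed.
    """
    if extent is None:
        extent = shared_extent([model], voxel_size)
    origin, shape = extent
    idx = np.floor((model.coords - np.asarray(origin)) / voxel_size).astype(int)
    if np.any(idx < 0) or np.any(idx >= np.array(shape)):
        raise ValueError("bead outside voxel extent; recompute the shared extent")
    counts = np.zeros(shape, dtype=float)
    np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    return VoxelGrid(origin=np.asarray(origin, dtype=float),
                     voxel_size=float(voxel_size),
                     density=counts / voxel_size ** 3)


# ---------------------------------------------------------------------------
# PCA + K-means


def embed_pca(grids: list[VoxelGrid]) -> Embedding:
    """Project density vectors onto the plane of the two leading principal
    components (mean-centred covariance PCA).

    The ensemble size M is much smaller than the voxel count, so the
    decomposition goes through the M x M Gram matrix (an equivalent
    factorization of the covariance): all M-1 variance ratios come out, and
    only the two leading eigenvectors are mapped back to voxel space.
    Component signs are fixed deterministically: the largest-magnitude
    loading of each component is made positive.
    """
    if len(grids) < 3:
        raise ValueError("need >= 3 grids")
    shapes = {g.shape for g in grids}
    if len(shapes) != 1:
        raise ValueError("grids must share one extent")
    x = np.stack([g.density.ravel() for g in grids])
    # restrict to voxels touched by at least one model (the rest carry no
    # variance); loadings are scattered back to the full voxel space below
    active = np.where(x.any(axis=0))[0]
    xa = x[:, active]
    mean_a = xa.mean(axis=0)
    xc = xa - mean_a
    gram = xc @ xc.T
    total_var = float(np.trace(gram))
    if total_var <= 0 or np.allclose(total_var, 0.0):
        raise ValueError("zero total variance across the ensemble")
    evals, evecs = np.linalg.eigh(gram)          # ascending
    evals = np.maximum(evals[::-1], 0.0)         # descending
    evecs = evecs[:, ::-1]
    n_comp = min(len(grids) - 1, active.size)
    evr = evals[:n_comp] / evals.sum()
    coords = np.empty((len(grids), 2))
    comps_full = np.zeros((2, x.shape[1]))
    mean_vector = np.zeros(x.shape[1])
    mean_vector[active] = mean_a
    for i in range(2):
        s = np.sqrt(evals[i])
        axis = xc.T @ evecs[:, i] / s            # unit loading in voxel space
        j = int(np.argmax(np.abs(axis)))
        sign = 1.0 if axis[j] >= 0 else -1.0
        comps_full[i, active] = sign * axis
        coords[:, i] = sign * s * evecs[:, i]
    return Embedding(
        coords=coords,
        explained_variance_ratio=evr,
        component_axes=comps_full,
        mean_vector=mean_vector,
    )


def cluster_kmeans(embedding: Embedding, k: int = DEFAULT_K, seed: int = 0,
                   n_restarts: int = 50) -> ClusterAssignment:
    """K-means on the PC plane: Lloyd iteration with k-means++ seeding, best
    of ``n_restarts`` by inertia; deterministic for fixed seed."""
    m = embedding.coords.shape[0]
    if m < k:
        raise ValueError(f"cannot form {k} clusters from {m} points")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(embedding.coords)
    sizes = np.bincount(labels, minlength=k)
    if np.any(sizes == 0):
        logger.warning("empty clusters: %s", np.where(sizes == 0)[0].tolist())
    return ClusterAssignment(labels=labels, k=k, centroids=km.cluster_centers_,
                             seed=seed, inertia=float(km.inertia_))


def average_models(
    models: list[BeadModel],
    reference: BeadModel,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    threshold: float = 0.5,
    reference_index: int = 0,
) -> AveragedShape:
    """Mean binary voxel occupancy of ``models`` after re-superimposition
    (with enantiomer handling) on an already-aligned ``reference``."""
    aligned = [
        align_principal_axes(m, reference=reference, enantiomer=True,
                             voxel_size=voxel_size)
        for m in models
    ]
    origin, shape = shared_extent(aligned, voxel_size)
    occ_sum = np.zeros(shape, dtype=float)
    for m in aligned:
        occ_sum += _binary_occupancy(m.coords, origin, voxel_size, shape)
    occupancy = occ_sum / len(aligned)
    return AveragedShape(occupancy=occupancy, threshold=threshold,
                         n_members=len(models),
                         reference_index=int(reference_index),
                         origin=np.asarray(origin, dtype=float),
                         voxel_size=float(voxel_size))


def average_cluster(
    models: list[BeadModel],
    assignment: ClusterAssignment,
    cluster_id: int,
    embedding: Embedding | None = None,
    reference: int | None = None,
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    threshold: float = 0.5,
) -> AveragedShape:
    """Representative shape of one group: mean binary voxel occupancy of the
    members after re-superimposition (with enantiomer handling) on a
    reference member.

    The reference defaults to the member nearest the cluster centroid in PC
    space (requires ``embedding``), else the first member.
    """
    member_idx = np.where(assignment.labels == cluster_id)[0]
    if member_idx.size == 0:
        raise ValueError(f"cluster {cluster_id} is empty")
    if reference is None:
        if embedding is not None:
            d = np.linalg.norm(
                embedding.coords[member_idx] - assignment.centroids[cluster_id],
                axis=1,
            )
            reference = int(member_idx[np.argmin(d)])
        else:
            reference = int(member_idx[0])
    ref_model = align_principal_axes(models[reference], voxel_size=voxel_size)
    return average_models(
        [models[i] for i in member_idx], ref_model,
        voxel_size=voxel_size, threshold=threshold, reference_index=reference,
    )


def mask_jaccard(avg: AveragedShape, template: BeadModel,
                 reference: BeadModel) -> float:
    """Jaccard index between an averaged shape's thresholded mask and a
    template model's voxel mask, after aligning the template onto the same
    reference the average was built on."""
    aligned_t = align_principal_axes(template, reference=reference,
                                     enantiomer=True, voxel_size=avg.voxel_size)
    size = avg.voxel_size
    # common grid anchored on the averaged shape's lattice
    t_lo = aligned_t.coords.min(axis=0)
    shift = np.floor((t_lo - avg.origin) / size).astype(int)
    shift = np.minimum(shift, 0)
    origin = avg.origin + shift * size
    t_hi = aligned_t.coords.max(axis=0)
    hi = np.maximum(t_hi + size, avg.origin + np.array(avg.shape) * size)
    shape = tuple(np.ceil((hi - origin) / size).astype(int))
    mask_avg = np.zeros(shape, dtype=bool)
    off = (-shift).astype(int)
    a = avg.mask
    mask_avg[off[0]:off[0] + a.shape[0], off[1]:off[1] + a.shape[1],
             off[2]:off[2] + a.shape[2]] = a
    idx = np.floor((aligned_t.coords - origin) / size).astype(int)
    mask_t = np.zeros(shape, dtype=bool)
    mask_t[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    inter = np.logical_and(mask_avg, mask_t).sum()
    union = np.logical_or(mask_avg, mask_t).sum()
    return float(inter / union) if union else 0.0


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class ClassificationReport:
    embedding: Embedding
    assignment: ClusterAssignment
    averaged: dict[int, AveragedShape]
    group_sizes: list[int]


def classify_ensemble(
    models: list[BeadModel] | list[str | Path],
    voxel_size: float = DEFAULT_VOXEL_SIZE,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_restarts: int = 50,
    threshold: float = 0.5,
    out_dir: str | Path | None = None,
) -> ClassificationReport:
    """Run the full align -> voxelize -> PCA -> K-means -> average protocol.

    ``models`` may be BeadModel objects or paths to bead PDB files.  With
    ``out_dir`` set, writes the PC scatter + labels as CSV, group sizes and
    run parameters as JSON, and per-group occupancy maps in CCP4 format.
    """
    loaded = [m if isinstance(m, BeadModel) else read_bead_pdb(m) for m in models]
    aligned = [align_principal_axes(m, voxel_size=voxel_size) for m in loaded]
    extent = shared_extent(aligned, voxel_size)
    grids = [voxelize(m, voxel_size, extent) for m in aligned]
    embedding = embed_pca(grids)
    assignment = cluster_kmeans(embedding, k=k, seed=seed, n_restarts=n_restarts)
    averaged = {
        cid: average_cluster(loaded, assignment, cid, embedding=embedding,
                             voxel_size=voxel_size, threshold=threshold)
        for cid in range(k) if np.any(assignment.labels == cid)
    }
    sizes = assignment.group_sizes.tolist()
    report = ClassificationReport(embedding=embedding, assignment=assignment,
                                  averaged=averaged, group_sizes=sizes)
    if out_dir is not None:
        _write_report(report, Path(out_dir), voxel_size, k, seed)
    return report


def _write_report(report: ClassificationReport, out_dir: Path,
                  voxel_size: float, k: int, seed: int) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "pc1": report.embedding.coords[:, 0],
        "pc2": report.embedding.coords[:, 1],
        "label": report.assignment.labels,
    }).to_csv(out_dir / "pc_scatter.csv", index_label="model")
    with open(out_dir / "run_report.json", "w") as fh:
        json.dump({
            "k": k, "seed": seed, "voxel_size": voxel_size,
            "group_sizes": report.group_sizes,
            "explained_variance_ratio":
                report.embedding.explained_variance_ratio[:10].tolist(),
            "inertia": report.assignment.inertia,
        }, fh, indent=2)
    for cid, avg in report.averaged.items():
        write_occupancy_map(avg, out_dir / f"group_{cid:02d}.ccp4")


def write_occupancy_map(avg: AveragedShape, path: str | Path) -> None:
    """Write a group's occupancy as a CCP4 map (unit cell = grid extent)."""
    import gemmi

    grid = gemmi.FloatGrid(np.ascontiguousarray(avg.occupancy, dtype=np.float32))
    nx, ny, nz = avg.occupancy.shape
    grid.set_unit_cell(gemmi.UnitCell(
        nx * avg.voxel_size, ny * avg.voxel_size, nz * avg.voxel_size,
        90.0, 90.0, 90.0))
    ccp4 = gemmi.Ccp4Map()
    ccp4.grid = grid
    ccp4.update_ccp4_header()
    ccp4.write_ccp4_map(str(path))


# ---------------------------------------------------------------------------
# dummy-residue count survey


def optimize_dr_count(
    profile: ScatteringProfile,
    engine,
    dr_range: tuple[int, int] = (900, 1200),
    step: int = 25,
    n_repeats: int = 14,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Survey the dummy-residue count that minimises mean chi-square.

    ``engine(profile, dr_count, seed) -> BeadModel`` is the pluggable
    reconstruction backend.  For each count in ``range(dr_range[0],
    dr_range[1] + 1, step)`` the chi-square of the engine output's Debye
    profile against ``profile`` is averaged over ``n_repeats`` seeds; the
    count with the smallest mean wins, ties broken toward the smaller count.
    """
    counts = list(range(dr_range[0], dr_range[1] + 1, step))
    mean_chi2: dict[int, float] = {}
    for count in counts:
        vals = []
        for rep in range(n_repeats):
            run_seed = seed * 100003 + count * 17 + rep
            try:
                model = engine(profile, count, run_seed)
            except Exception as exc:  # annotate and re-raise
                raise RuntimeError(
                    f"reconstruction engine failed at dr_count={count}, "
                    f"seed={run_seed}"
                ) from exc
            mode = "exact" if model.n_beads <= 2000 else "histogram"
            sim = debye_intensity(model, profile.s, mode=mode)
            vals.append(chi_square(profile, sim).chi2)
        mean_chi2[count] = float(np.mean(vals))
    best = min(counts, key=lambda c: (mean_chi2[c], c))
    return best, mean_chi2
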