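"""Dummy-residue (bead) models: PDB I/O, geometry, forward Debye scattering,
chi-square goodness of fit, and parametric shape generation.

Ab initio SAXS reconstructions represent a protein as an assembly of
dummy residues (DRs), interpenetrating beads of radius 3.8 A carrying one
residue-equivalent of scattering mass each.  This module is the forward
side of that picture: given bead coordinates it computes the orientationally
averaged intensity by the Debye sum and compares it to experiment with the
reduced chi-square used to score reconstructions,

    chi^2 = 1/(N-1) * sum_j [(I_exp(S_j) - alpha I_model(S_j)) / sigma(S_j)]^2

where alpha is the optimal linear scale factor (closed form, no search).
The sinc kernel uses 2*pi*S, consistent with the S = 2 sin(theta)/lambda
convention of :mod:`.saxs_core`.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial.distance import pdist

from .saxs_core import ScatteringProfile

__all__ = [
    "BeadModel",
    "PairDistanceHistogram",
    "FitQuality",
    "read_bead_pdb",
    "write_bead_pdb",
    "radius_of_gyration",
    "pair_distance_histogram",
    "debye_intensity",
    "chi_square",
    "generate_shape",
]

DEFAULT_BEAD_RADIUS = 3.8  # A, one dummy residue


@dataclass
class BeadModel:
    """N beads in 3-D, each a point scatterer of unit weight."""

    coords: np.ndarray
    bead_radius: float = DEFAULT_BEAD_RADIUS
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or self.coords.shape[0] < 1:
            raise ValueError("coords must be an N x 3 array with N >= 1")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.bead_radius <= 0:
            raise ValueError("bead_radius must be positive")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]


@dataclass
class PairDistanceHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    n_beads: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts)
        expected = self.n_beads * (self.n_beads - 1) // 2
        if int(self.counts.sum()) != expected:
            raise ValueError("histogram does not conserve pair count")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class FitQuality:
    chi2: float
    alpha: float
    n_points: int


# ---------------------------------------------------------------------------
# PDB I/O (GASBOR-style CA/DUM records; any CA-only PDB accepted)


def read_bead_pdb(path) -> BeadModel:
    st = gemmi.read_pdb(str(path))
    coords = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.name == "CA":
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    if not coords:
        raise ValueError(f"{path}: no CA atoms found")
    return BeadModel(coords=np.array(coords), label=str(path))


def write_bead_pdb(model: BeadModel, path, chain_split: int | None = None) -> None:
    """Write beads as DUM/CA ATOM records; ``chain_split`` starts chain B at
    the given bead index (dimer subunits)."""
    st = gemmi.Structure()
    st.name = model.label or "beads"
    md = gemmi.Model("1")
    boundaries = [(0, model.n_beads, "A")]
    if chain_split is not None:
        boundaries = [(0, chain_split, "A"), (chain_split, model.n_beads, "B")]
    for start, stop, cname in boundaries:
        chain = gemmi.Chain(cname)
        for i in range(start, stop):
            res = gemmi.Residue()
            res.name = "DUM"
            res.seqid = gemmi.SeqId(i - start + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            x, y, z = model.coords[i]
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            res.add_atom(atom)
            chain.add_residue(res)
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# geometry


def radius_of_gyration(model: BeadModel) -> float:
    """Rg = sqrt(mean squared distance from the centroid), beads as points."""
    c = model.coords - model.coords.mean(axis=0)
    return float(np.sqrt((c ** 2).sum(axis=1).mean()))


def _iter_pair_distances(coords: np.ndarray, chunk: int = 1000):
    """Yield the N(N-1)/2 pair distances in bounded-memory chunks."""
    n = coords.shape[0]
    if n <= chunk:
        yield pdist(coords)
        return
    sq = (coords ** 2).sum(axis=1)
    for i0 in range(0, n, chunk):
        block = coords[i0:i0 + chunk]
        if block.shape[0] > 1:
            yield pdist(block)
        rest = coords[i0 + chunk:]
        if rest.shape[0]:
            d2 = (sq[i0:i0 + chunk, None] + sq[None, i0 + chunk:]
                  - 2.0 * block @ rest.T)
            yield np.sqrt(np.maximum(d2, 0.0)).ravel()


def pair_distance_histogram(model: BeadModel, bin_width: float = 0.5) -> PairDistanceHistogram:
    """Histogram of all N(N-1)/2 pair distances with half-open bins,
    accumulated in chunks so large models stay within memory."""
    if model.n_beads < 2:
        raise ValueError("need >= 2 beads")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    # upper bound on any pair distance: bounding-box diagonal
    span = model.coords.max(axis=0) - model.coords.min(axis=0)
    n_bins_max = int(np.floor(np.linalg.norm(span) / bin_width)) + 1
    counts = np.zeros(n_bins_max, dtype=np.int64)
    for d in _iter_pair_distances(model.coords):
        idx = np.minimum((d / bin_width).astype(np.intp), n_bins_max - 1)
        counts += np.bincount(idx, minlength=n_bins_max)
    last = int(np.nonzero(counts)[0][-1]) + 1
    counts = counts[:last]
    edges = np.arange(last + 1) * bin_width
    return PairDistanceHistogram(bin_edges=edges, counts=counts, n_beads=model.n_beads)


# ---------------------------------------------------------------------------
# Debye scattering


def _sphere_form_factor(s: np.ndarray, radius: float) -> np.ndarray:
    x = 2.0 * np.pi * np.asarray(s, dtype=float) * radius
    out = np.ones_like(x)
    nz = x != 0
    xs = x[nz]
    out[nz] = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs ** 3
    return out


def debye_intensity(
    model: BeadModel,
    s_grid: np.ndarray,
    mode: str = "histogram",
    bin_width: float = 0.5,
    form_factor: bool = False,
) -> ScatteringProfile:
    """Orientationally averaged intensity of the bead model by the Debye sum

        I(S) = sum_i sum_j sinc(2 pi S r_ij),   sinc(0) = 1,

    so I(0) = N^2 for point scatterers.  ``mode="exact"`` sums every pair;
    ``mode="histogram"`` bins the pair distances (default 0.5 A) and sums
    over bin midpoints, which agrees with the exact sum to better than 0.2%
    for S <= 0.02 1/A at the default bin width.  ``form_factor=True`` multiplies
    by the uniform-sphere form factor of ``bead_radius`` squared.
    """
    s = np.asarray(s_grid, dtype=float)
    if s.size == 0:
        raise ValueError("empty s grid")
    n = model.n_beads
    if mode == "exact":
        if n == 1:
            intensity = np.full(s.shape, 1.0)
        else:
            acc = np.zeros(s.shape)
            two_pi_s = 2.0 * np.pi * s
            for d in _iter_pair_distances(model.coords):
                # accumulate sum_j sinc(2 pi S d_j) in sub-chunks
                for j0 in range(0, d.size, 200_000):
                    x = np.outer(two_pi_s, d[j0:j0 + 200_000])
                    sinc = np.ones_like(x)
                    nzmask = x != 0
                    sinc[nzmask] = np.sin(x[nzmask]) / x[nzmask]
                    acc += sinc.sum(axis=1)
            intensity = n + 2.0 * acc
    elif mode == "histogram":
        if n == 1:
            intensity = np.full(s.shape, 1.0)
        else:
            hist = pair_distance_histogram(model, bin_width)
            mids = hist.midpoints
            keep = hist.counts > 0
            mids, counts = mids[keep], hist.counts[keep].astype(float)
            x = 2.0 * np.pi * np.outer(s, mids)
            sinc = np.ones_like(x)
            nzmask = x != 0
            sinc[nzmask] = np.sin(x[nzmask]) / x[nzmask]
            intensity = n + 2.0 * sinc @ counts
    else:
        raise ValueError("mode must be 'exact' or 'histogram'")
    if form_factor:
        intensity = intensity * _sphere_form_factor(s, model.bead_radius) ** 2
    sigma = np.maximum(np.sqrt(np.maximum(intensity, 0.0)), 1e-6)
    return ScatteringProfile(s=s, intensity=intensity, sigma=sigma,
                             label=f"debye:{model.label}")


def chi_square(i_exp: ScatteringProfile, i_model: ScatteringProfile) -> FitQuality:
    """Reduced chi-square with the optimal scale factor.

    alpha* = sum(I_e I_m / sigma^2) / sum(I_m^2 / sigma^2) minimises the
    weighted squared residual analytically; the model is interpolated onto
    the experimental s grid when the grids differ.
    """
    if len(i_exp) < 2:
        raise ValueError("need >= 2 points")
    if np.array_equal(i_exp.s, i_model.s):
        im = i_model.intensity
        ie, sig = i_exp.intensity, i_exp.sigma
        n = len(i_exp)
    else:
        mask = (i_exp.s >= i_model.s[0]) & (i_exp.s <= i_model.s[-1])
        n = int(mask.sum())
        if n < 2:
            raise ValueError("no overlapping s range")
        im = np.interp(i_exp.s[mask], i_model.s, i_model.intensity)
        ie, sig = i_exp.intensity[mask], i_exp.sigma[mask]
    w = 1.0 / sig ** 2
    denom = (w * im ** 2).sum()
    if denom == 0:
        raise ValueError("all-zero model intensity")
    alpha = float((w * ie * im).sum() / denom)
    chi2 = float((w * (ie - alpha * im) ** 2).sum() / (n - 1))
    return FitQuality(chi2=chi2, alpha=alpha, n_points=n)


# ---------------------------------------------------------------------------
# parametric shape generation


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _sample_cylinder(rng: np.random.Generator, n: int, length: float, radius: float) -> np.ndarray:
    """Rejection-sample n points uniformly inside a z-aligned cylinder
    centred at the origin."""
    pts = np.empty((0, 3))
    while pts.shape[0] < n:
        cand = rng.uniform(
            low=[-radius, -radius, -length / 2],
            high=[radius, radius, length / 2],
            size=(2 * n, 3),
        )
        keep = cand[:, 0] ** 2 + cand[:, 1] ** 2 <= radius ** 2
        pts = np.vstack([pts, cand[keep]])
    return pts[:n]


def _sample_ellipsoid(rng: np.random.Generator, n: int, semi: np.ndarray) -> np.ndarray:
    pts = np.empty((0, 3))
    while pts.shape[0] < n:
        cand = rng.uniform(low=-semi, high=semi, size=(2 * n, 3))
        keep = ((cand / semi) ** 2).sum(axis=1) <= 1.0
        pts = np.vstack([pts, cand[keep]])
    return pts[:n]


def generate_shape(
    kind: str,
    params: dict,
    n_beads: int,
    seed: int,
    bead_radius: float = DEFAULT_BEAD_RADIUS,
) -> BeadModel:
    """Generate a bead model of a parametric solid by rejection sampling.

    Kinds and parameters (lengths in A, angles in degrees):

    - ``straight_rod``: length, diameter — a cylinder along z.
    - ``bent_rod``: length, diameter, bend_angle — the half of the rod with
      z > 0 is rotated about x so the two arms subtend ``bend_angle``;
      180 deg reproduces the straight rod bead-for-bead at equal seed.
    - ``two_subunit_dimer``: subunit (a nested generate_shape spec) plus
      crossing_angle and optional offset — two copies related by a two-fold
      axis along z, each tilted by crossing_angle/2.
    - ``sphere``: radius.
    - ``ellipsoid``: semi_axes (3-list).

    Fixed seed gives bitwise-identical output.
    """
    rng = np.random.default_rng(seed)
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if kind == "straight_rod" or kind == "bent_rod":
        length = float(params["length"])
        diameter = float(params["diameter"])
        if length <= 0 or diameter <= 0:
            raise ValueError("infeasible rod parameters")
        coords = _sample_cylinder(rng, n_beads, length, diameter / 2.0)
        if kind == "bent_rod":
            bend = float(params.get("bend_angle", 180.0))
            if not (0.0 < bend <= 180.0):
                raise ValueError("bend_angle must be in (0, 180]")
            rot = _rotation_about_axis([1.0, 0.0, 0.0], np.deg2rad(180.0 - bend))
            top = coords[:, 2] > 0
            coords[top] = coords[top] @ rot.T
    elif kind == "sphere":
        r = float(params["radius"])
        if r <= 0:
            raise ValueError("infeasible sphere radius")
        coords = _sample_ellipsoid(rng, n_beads, np.array([r, r, r]))
    elif kind == "ellipsoid":
        semi = np.asarray(params["semi_axes"], dtype=float)
        if semi.shape != (3,) or np.any(semi <= 0):
            raise ValueError("infeasible ellipsoid semi-axes")
        coords = _sample_ellipsoid(rng, n_beads, semi)
    elif kind == "two_subunit_dimer":
        sub = params["subunit"]
        crossing = float(params.get("crossing_angle", 60.0))
        if not (0.0 < crossing < 180.0):
            raise ValueError("crossing_angle must be in (0, 180)")
        offset = float(params.get("offset", 0.0))
        half = n_beads // 2
        sub_model = generate_shape(
            sub["kind"], sub.get("params", {}), half,
            seed=int(rng.integers(0, 2 ** 31)), bead_radius=bead_radius,
        )
        tilt = _rotation_about_axis([0.0, 1.0, 0.0], np.deg2rad(crossing / 2.0))
        a = sub_model.coords @ tilt.T
        a[:, 0] += offset
        dyad = _rotation_about_axis([0.0, 0.0, 1.0], np.pi)
        b = a @ dyad.T
        coords = np.vstack([a, b])
    else:
        raise ValueError(f"unknown shape kind {kind!r}")
    return BeadModel(coords=coords, bead_radius=bead_radius,
                     label=f"{kind}(n={coords.shape[0]},seed={seed})")
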