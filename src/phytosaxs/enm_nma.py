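"""Elastic-network normal-mode analysis of Cα structures.

The protein is reduced to its Cα atoms, every pair closer than a cutoff
distance is connected by an identical Hookean spring (anisotropic network
model, unit masses), and the normal modes are the eigenvectors of the
resulting 3N x 3N Hessian.  A connected 3-D network has exactly six zero
modes (rigid translations and rotations); the low-frequency internal modes
that follow describe the collective motions available to the fold — for a
phytochrome photosensory module, the hinge-bending of the PHY domain
against the PAS-GAF core.

Per-pair Hessian super-element for beads i, j at unit distance vector r̂:

    H_ij = -k r̂ r̂ᵀ          (off-diagonal 3x3 block)
    H_ii = -Σ_{j≠i} H_ij     (diagonal blocks; block rows sum to zero)

Mean-square fluctuations follow from the pseudo-inverse over non-zero
modes, B_i ∝ Σ_m λ_m⁻¹ |v_m,i|², and are compared with crystallographic
B-factors to calibrate the cutoff (argmax of the Pearson correlation) and
the force constant (equalising ΣB_pred with ΣB_exp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

__all__ = [
    "CalphaStructure",
    "ENMModel",
    "ModeSet",
    "BFactorPrediction",
    "read_calpha_pdb",
    "build_enm",
    "compute_modes",
    "predict_bfactors",
    "calibrate_cutoff",
    "scale_force_constant",
    "mode_displacements",
    "write_mode_pdb",
]

DEFAULT_CUTOFF = 7.0          # A
DEFAULT_CUTOFF_GRID = np.arange(6.0, 15.0 + 1e-9, 0.5)
ZERO_MODE_TOL = 1e-10         # relative to the largest eigenvalue


@dataclass
class CalphaStructure:
    """Cα trace with optional experimental B-factors."""

    coords: np.ndarray
    b_exp: np.ndarray | None = None
    residue_ids: list | None = None
    chain_id: str = "A"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or self.coords.shape[0] < 2:
            raise ValueError("need an N x 3 coordinate array, N >= 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.b_exp is not None:
            self.b_exp = np.asarray(self.b_exp, dtype=float)
            if self.b_exp.shape != (self.coords.shape[0],):
                raise ValueError("b_exp length must equal residue count")
        if self.residue_ids is None:
            self.residue_ids = list(range(1, self.coords.shape[0] + 1))

    @property
    def n_residues(self) -> int:
        return self.coords.shape[0]


@dataclass
class ENMModel:
    cutoff: float
    k: float
    contacts: np.ndarray          # P x 2 (i < j)
    n_residues: int
    connected: bool


@dataclass
class ModeSet:
    eigenvalues: np.ndarray       # ascending, length 3N
    eigenvectors: np.ndarray      # 3N x 3N, columns are modes
    n_zero: int


@dataclass
class BFactorPrediction:
    b_pred: np.ndarray
    correlation: float
    scale: float


# ---------------------------------------------------------------------------


def read_calpha_pdb(path, chain: str = "A") -> CalphaStructure:
    """Read the Cα trace of one chain; first altloc kept, insertion codes
    preserved in the residue ids, residues in file order."""
    st = gemmi.read_pdb(str(path))
    st.remove_alternative_conformations()  # keeps the first altloc
    coords, bfac, ids = [], [], []
    found_chain = False
    for model in st:
        for ch in model:
            if ch.name != chain:
                continue
            found_chain = True
            for res in ch:
                for atom in res:
                    if atom.name == "CA":
                        coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                        bfac.append(atom.b_iso)
                        ids.append(str(res.seqid))
                        break
        break
    if not found_chain:
        raise ValueError(f"{path}: chain {chain!r} not found")
    if not coords:
        raise ValueError(f"{path}: chain {chain!r} has no CA atoms")
    return CalphaStructure(coords=np.array(coords), b_exp=np.array(bfac),
                           residue_ids=ids, chain_id=chain)


def build_enm(structure: CalphaStructure, cutoff: float = DEFAULT_CUTOFF,
              k: float = 1.0) -> tuple[ENMModel, np.ndarray]:
    """Anisotropic-network Hessian for all pairs within ``cutoff``
    (inclusive: distance == cutoff is a contact).

    Returns the network description and the symmetric 3N x 3N Hessian whose
    3x3 block rows sum to zero (translation invariance).  Missing segments
    are bridged only by whatever contacts remain; a disconnected contact
    graph is flagged, and a network with no contacts at all is an error.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = structure.n_residues
    dist = squareform(pdist(structure.coords))
    contact_mask = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    ii, jj = np.where(np.triu(contact_mask))
    if ii.size == 0:
        raise ValueError("disconnected network: no contacts at this cutoff")
    hessian = np.zeros((3 * n, 3 * n))
    diff = structure.coords[ii] - structure.coords[jj]
    d = dist[ii, jj]
    unit = diff / d[:, None]
    blocks = -k * unit[:, :, None] * unit[:, None, :]   # P x 3 x 3
    for (i, j), blk in zip(zip(ii, jj), blocks):
        hessian[3 * i:3 * i + 3, 3 * j:3 * j + 3] += blk
        hessian[3 * j:3 * j + 3, 3 * i:3 * i + 3] += blk
        hessian[3 * i:3 * i + 3, 3 * i:3 * i + 3] -= blk
        hessian[3 * j:3 * j + 3, 3 * j:3 * j + 3] -= blk
    connected = _is_connected(n, ii, jj)
    if not connected:
        logger.warning("contact graph is not a single component at cutoff %.2f", cutoff)
    model = ENMModel(cutoff=float(cutoff), k=float(k),
                     contacts=np.column_stack([ii, jj]),
                     n_residues=n, connected=connected)
    return model, hessian


def _is_connected(n: int, ii: np.ndarray, jj: np.ndarray) -> bool:
    # union-find over the contact graph
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in zip(ii, jj):
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[ri] = rj
    return len({find(i) for i in range(n)}) == 1


def compute_modes(hessian: np.ndarray) -> ModeSet:
    """Full symmetric eigen-decomposition; eigenvalues ascending, zero modes
    identified as eigenvalues below 1e-10 times the largest."""
    h = np.asarray(hessian, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ValueError("hessian must be square")
    if np.max(np.abs(h - h.T)) > 1e-8 * max(np.max(np.abs(h)), 1.0):
        raise ValueError("hessian not symmetric")
    evals, evecs = eigh((h + h.T) / 2.0)
    lam_max = float(evals[-1])
    tol = ZERO_MODE_TOL * max(lam_max, 1.0)
    n_zero = int((np.abs(evals) < tol).sum())
    return ModeSet(eigenvalues=evals, eigenvectors=evecs, n_zero=n_zero)


def predict_bfactors(modes: ModeSet, structure: CalphaStructure) -> np.ndarray:
    """Relative per-residue B-factors from the Hessian pseudo-inverse:

        B_i ∝ Σ_{m > n_zero} λ_m⁻¹ (v_m,3i² + v_m,3i+1² + v_m,3i+2²)
    """
    nz = modes.n_zero
    if nz >= modes.eigenvalues.size:
        raise ValueError("all modes are zero modes")
    lam = modes.eigenvalues[nz:]
    vec = modes.eigenvectors[:, nz:]
    msf = (vec ** 2 / lam[None, :]).sum(axis=1)          # 3N vector
    b = msf.reshape(structure.n_residues, 3).sum(axis=1)  # per residue
    return b


def scale_force_constant(b_pred_relative: np.ndarray, b_exp: np.ndarray) -> BFactorPrediction:
    """Scale relative B-factors so their sum equals the experimental sum
    (equivalently: calibrate the spring force constant).  Scaling leaves the
    Pearson correlation unchanged."""
    b_pred_relative = np.asarray(b_pred_relative, dtype=float)
    b_exp = np.asarray(b_exp, dtype=float)
    if b_pred_relative.shape != b_exp.shape:
        raise ValueError("length mismatch")
    total = b_pred_relative.sum()
    if total <= 0:
        raise ValueError("sum of predicted B-factors must be positive")
    scale = float(b_exp.sum() / total)
    b_scaled = scale * b_pred_relative
    if np.std(b_exp) == 0 or np.std(b_pred_relative) == 0:
        raise ValueError("correlation undefined for constant B-factors")
    r = float(pearsonr(b_scaled, b_exp)[0])
    return BFactorPrediction(b_pred=b_scaled, correlation=r, scale=scale)


def calibrate_cutoff(
    structure: CalphaStructure,
    cutoff_grid: np.ndarray = DEFAULT_CUTOFF_GRID,
) -> tuple[float, dict[float, float]]:
    """Pick the cutoff that maximises the Pearson correlation between
    predicted and experimental B-factors; ties toward the smaller cutoff,
    disconnected cutoffs skipped with a warning."""
    if structure.b_exp is None:
        raise ValueError("structure carries no experimental B-factors")
    if np.std(structure.b_exp) == 0:
        raise ValueError("correlation undefined for constant b_exp")
    curve: dict[float, float] = {}
    for cutoff in np.atleast_1d(cutoff_grid):
        try:
            model, hess = build_enm(structure, float(cutoff))
        except ValueError:
            logger.warning("cutoff %.2f: no contacts, skipped", cutoff)
            continue
        if not model.connected:
            logger.warning("cutoff %.2f: disconnected network, skipped", cutoff)
            continue
        modes = compute_modes(hess)
        b = predict_bfactors(modes, structure)
        curve[float(cutoff)] = float(pearsonr(b, structure.b_exp)[0])
    if not curve:
        raise ValueError("every cutoff in the grid gives a disconnected network")
    best = min(curve, key=lambda c: (-curve[c], c))
    return best, curve


def mode_displacements(
    modes: ModeSet,
    structure: CalphaStructure,
    mode_index: int = 1,
    magnification: float = 3.0,
) -> np.ndarray:
    """Per-residue displacement vectors of one internal mode.

    ``mode_index`` counts internal modes from 1 = the lowest-energy mode
    above the rigid-body spectrum; the vectors are scaled by
    ``magnification`` (default 3, the conventional factor for rendering).
    """
    if mode_index < 1:
        raise ValueError("mode_index addresses internal modes, starting at 1")
    col = modes.n_zero + mode_index - 1
    if col >= modes.eigenvalues.size:
        raise ValueError("mode index beyond the spectrum")
    vec = modes.eigenvectors[:, col]
    return magnification * vec.reshape(structure.n_residues, 3)


def write_mode_pdb(structure: CalphaStructure, displacements: np.ndarray, path,
                  single_model: bool = False) -> None:
    """Two-MODEL PDB (start pose / displaced pose) for arrow rendering;
    ``single_model=True`` writes just the start pose (with any ``b_exp`` in
    the B-factor column)."""
    st = gemmi.Structure()
    st.name = "enm-mode"
    poses = [structure.coords] if single_model else [
        structure.coords, structure.coords + displacements]
    for imod, coords in enumerate(poses, start=1):
        md = gemmi.Model(str(imod))
        chain = gemmi.Chain(structure.chain_id)
        for i, xyz in enumerate(coords):
            res = gemmi.Residue()
            res.name = "GLY"
            res.seqid = gemmi.SeqId(i + 1, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            if structure.b_exp is not None:
                atom.b_iso = float(structure.b_exp[i])
            res.add_atom(atom)
            chain.add_residue(res)
        md.add_chain(chain)
        st.add_model(md)
    st.write_pdb(str(path))
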