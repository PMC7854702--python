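"""Synthetic ground-truth generators for every stage of the pipeline.

The experimental inputs this pipeline was designed for (beamline scattering
curves of pea phytochrome A, absorption spectra, and the ab initio model
ensembles reconstructed from them) are not publicly deposited, so each
generator here emulates one class of input at desk scale with a known
ground truth: a monodisperse dilution series with planted virial and
interference coefficients, two-component photosteady-state mixtures with a
planted Pr/Pfr split, Gaussian-band absorption spectra, bead-model
ensembles falling into distinct shape families, and Cα traces whose
B-factors derive from a known elastic network.

Every generator is a pure function of (parameters, seed): fixed seed gives
bitwise-identical output.
"""

from __future__ import annotations

import numpy as np

from .bead_models import BeadModel, debye_intensity, generate_shape
from .enm_nma import CalphaStructure, build_enm, compute_modes, predict_bfactors
from .saxs_core import (
    DEFAULT_GUINIER_S2_MAX,
    DEFAULT_GUINIER_S2_MIN,
    AbsorptionSpectrum,
    ScatteringProfile,
)

__all__ = [
    "PAPER_CONCENTRATIONS",
    "make_dilution_series",
    "make_steady_mixture",
    "make_spectra",
    "make_model_ensemble",
    "make_enm_structure",
    "default_families",
]

# the dilution series used in the study this pipeline emulates (mg/mL)
PAPER_CONCENTRATIONS = (0.5, 1.5, 2.0, 3.0, 4.0)


# ---------------------------------------------------------------------------
# scattering fixtures


def make_dilution_series(
    shape: BeadModel,
    concentrations=PAPER_CONCENTRATIONS,
    mw: float = 250.0,
    a2: float = 0.0,
    b_if: float = 0.0,
    rg0: float | None = None,
    k_const: float = 1.0,
    noise_level: float = 0.0,
    s_max: float = 0.05,
    n_points: int = 400,
    window: tuple[float, float] = (DEFAULT_GUINIER_S2_MIN, DEFAULT_GUINIER_S2_MAX),
    seed: int = 0,
) -> list[ScatteringProfile]:
    """Monodisperse dilution series with planted interparticle coefficients.

    The base curve is the Debye profile of ``shape``.  For concentration C
    the zero-angle intensity follows K C / I(0, C) = 1/mw + 2 a2 C and the
    radius of gyration follows Rg(C)^2 = rg0^2 - b_if * C (``rg0`` defaults
    to the base curve's own Guinier-level Rg).  The interparticle effects
    are injected analytically: the base curve is rescaled and reweighted by
    a Gaussian factor relative to its own Guinier fit over ``window``, so a
    noise-free series inverts exactly at Guinier level.  Noise-free
    profiles carry a constant relative error (uniform ln-fit weights);
    with ``noise_level`` > 0, Gaussian noise with
    sigma = noise_level * sqrt(I) / sqrt(C) is added instead.
    """
    rng = np.random.default_rng(seed)
    s = np.linspace(1e-3, s_max, n_points)
    base = debye_intensity(shape, s, mode="histogram")
    # unweighted Guinier-level reference of the base curve over the window
    s2 = s ** 2
    win = (s2 >= window[0]) & (s2 <= window[1])
    if win.sum() < 3:
        raise ValueError("s grid too coarse for the Guinier window")
    slope_b, inter_b = np.polyfit(s2[win], np.log(base.intensity[win]), 1)
    i0_ref = float(np.exp(inter_b))
    rg2_ref = float(-3.0 * slope_b / (4.0 * np.pi ** 2))
    rg2_zero = rg0 ** 2 if rg0 is not None else rg2_ref
    out = []
    for c in concentrations:
        i0_target = k_const * c / (1.0 / mw + 2.0 * a2 * c)
        rg2_target = rg2_zero - b_if * c
        if rg2_target <= 0:
            raise ValueError("planted b_if drives Rg^2 negative")
        gauss = np.exp(-(4.0 * np.pi ** 2 / 3.0) * (rg2_target - rg2_ref) * s2)
        intensity = base.intensity * (i0_target / i0_ref) * gauss
        if noise_level > 0:
            sigma = np.maximum(
                noise_level * np.sqrt(np.maximum(intensity, 0.0)) / np.sqrt(c), 1e-12)
            intensity = intensity + rng.normal(0.0, sigma)
        else:
            sigma = np.maximum(1e-3 * intensity, 1e-12)
        out.append(ScatteringProfile(
            s=s, intensity=intensity, sigma=sigma, concentration=float(c),
            label=f"dilution-C{c:g}",
        ))
    return out


def make_steady_mixture(
    i_pr: ScatteringProfile,
    i_pfr: ScatteringProfile,
    w_prpr: float = 0.39,
    noise_level: float = 0.0,
    seed: int = 0,
) -> ScatteringProfile:
    """Photosteady-state profile w * I_Pr + (1 - w) * I_Pfr (+ noise)."""
    if not np.array_equal(i_pr.s, i_pfr.s):
        raise ValueError("component profiles must share one s grid")
    rng = np.random.default_rng(seed)
    intensity = w_prpr * i_pr.intensity + (1.0 - w_prpr) * i_pfr.intensity
    sigma = np.maximum(noise_level * np.sqrt(np.maximum(intensity, 0.0)), 1e-12)
    if noise_level > 0:
        intensity = intensity + rng.normal(0.0, sigma)
    else:
        sigma = np.sqrt(w_prpr ** 2 * i_pr.sigma ** 2
                        + (1 - w_prpr) ** 2 * i_pfr.sigma ** 2)
    return ScatteringProfile(s=i_pr.s, intensity=intensity, sigma=sigma,
                             label=f"steady(w_prpr={w_prpr:g})")


# ---------------------------------------------------------------------------
# absorption spectra


def _gauss_band(wl: np.ndarray, center: float, width: float, height: float) -> np.ndarray:
    return height * np.exp(-0.5 * ((wl - center) / width) ** 2)


def make_spectra(
    fraction_pfr: float = 0.61,
    pr_band: tuple[float, float, float] = (667.0, 25.0, 1.0),
    pfr_band: tuple[float, float, float] = (730.0, 35.0, 0.8),
    overlap: float = 0.25,
    noise: float = 0.0,
    seed: int = 0,
    wl_range: tuple[float, float] = (450.0, 850.0),
    n_points: int = 401,
) -> tuple[AbsorptionSpectrum, AbsorptionSpectrum, AbsorptionSpectrum]:
    """(Pr, Pfr, steady-state) absorption spectra from Gaussian bands.

    Band centers default to the classical red (Pr ~ 667 nm) and far-red
    (Pfr ~ 730 nm) absorbance of plant phytochromes — configuration
    defaults, not measured values.  ``overlap`` adds a fraction of the
    other form's band to each spectrum (the real spectra overlap heavily);
    the steady state is (1 - f) * Pr + f * Pfr plus optional noise.
    """
    if not (0.0 <= fraction_pfr <= 1.0):
        raise ValueError("fraction_pfr must be in [0, 1]")
    rng = np.random.default_rng(seed)
    wl = np.linspace(*wl_range, n_points)
    band_r = _gauss_band(wl, *pr_band)
    band_fr = _gauss_band(wl, *pfr_band)
    a_pr = band_r + overlap * band_fr * 0.3
    a_pfr = band_fr + overlap * band_r
    a_steady = (1.0 - fraction_pfr) * a_pr + fraction_pfr * a_pfr
    if noise > 0:
        a_steady = np.maximum(a_steady + rng.normal(0.0, noise, wl.shape), 0.0)
    return (
        AbsorptionSpectrum(wavelength=wl, absorbance=a_pr, label="Pr"),
        AbsorptionSpectrum(wavelength=wl, absorbance=a_pfr, label="Pfr"),
        AbsorptionSpectrum(wavelength=wl, absorbance=a_steady,
                           label=f"steady(f_pfr={fraction_pfr:g})"),
    )


# ---------------------------------------------------------------------------
# bead-model ensembles


def default_families(n_beads: int = 4000) -> list[dict]:
    """Three shape families echoing the morphologies seen in phytochrome
    reconstructions: an anti-parallel pair of rods ('twisted tubes'), a
    crossed dimer of bent rods ('cross / four-leaf'), and a wide-angle
    crossed dimer ('butterfly').

    2000 beads per subunit matches the dummy-residue scale of real
    reconstructions; the rod girth is trimmed to 35 A so the bead packing
    density (roughly one per residue volume) is realistic at that count.
    """
    rod = {"kind": "straight_rod", "params": {"length": 175.0, "diameter": 35.0}}
    bent = {"kind": "bent_rod",
            "params": {"length": 175.0, "diameter": 35.0, "bend_angle": 140.0}}
    return [
        {"kind": "two_subunit_dimer",
         "params": {"subunit": rod, "crossing_angle": 20.0, "offset": 30.0},
         "n_beads": n_beads, "name": "twisted_tubes"},
        {"kind": "two_subunit_dimer",
         "params": {"subunit": bent, "crossing_angle": 80.0, "offset": 25.0},
         "n_beads": n_beads, "name": "cross"},
        {"kind": "two_subunit_dimer",
         "params": {"subunit": rod, "crossing_angle": 120.0, "offset": 40.0},
         "n_beads": n_beads, "name": "butterfly"},
    ]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # uniform rotation via QR of a Gaussian matrix, det fixed to +1
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def make_model_ensemble(
    families: list[dict] | None = None,
    n_per_family: int | list[int] = 187,
    jitter_sigma: float = 2.0,
    outlier_fraction: float = 0.0,
    rigid_motion: bool = True,
    resample: bool = True,
    seed: int = 0,
) -> tuple[list[BeadModel], np.ndarray]:
    """Ensemble of noisy bead models in planted shape families.

    Each model is its family template with per-bead Gaussian jitter, a
    random rigid motion with a random handedness flip (``rigid_motion``),
    and ±5% bead-count resampling (``resample``); outliers are Gaussian
    blobs with label -1.  Returns (models, truth_labels).
    """
    if families is None:
        families = default_families()
    rng = np.random.default_rng(seed)
    if isinstance(n_per_family, int):
        n_per_family = [n_per_family] * len(families)
    templates = [
        generate_shape(f["kind"], f.get("params", {}), f["n_beads"],
                       seed=int(rng.integers(0, 2 ** 31)))
        for f in families
    ]
    models: list[BeadModel] = []
    labels: list[int] = []
    for fam_idx, (tpl, n_models) in enumerate(zip(templates, n_per_family)):
        for _ in range(n_models):
            n = tpl.n_beads
            if resample:
                n_keep = int(round(n * rng.uniform(0.95, 1.0)))
                pick = rng.choice(n, size=n_keep, replace=False)
                coords = tpl.coords[pick].copy()
            else:
                coords = tpl.coords.copy()
            if jitter_sigma > 0:
                coords = coords + rng.normal(0.0, jitter_sigma, coords.shape)
            if rigid_motion:
                if rng.random() < 0.5:
                    coords = coords * np.array([1.0, 1.0, -1.0])  # enantiomer
                coords = coords @ _random_rotation(rng).T + rng.normal(0.0, 20.0, 3)
            models.append(BeadModel(coords=coords,
                                    label=f"fam{fam_idx}"))
            labels.append(fam_idx)
    n_out = int(round(outlier_fraction * len(models) / max(1e-12, 1 - outlier_fraction)))
    for _ in range(n_out):
        # protein-sized isotropic blob (Rg ~ 52 A, comparable to the families)
        n = templates[0].n_beads
        coords = rng.normal(0.0, 30.0, (n, 3))
        models.append(BeadModel(coords=coords, label="outlier"))
        labels.append(-1)
    order = rng.permutation(len(models))
    return [models[i] for i in order], np.array(labels)[order]


# ---------------------------------------------------------------------------
# ENM fixtures


def _helix_trace(n: int) -> np.ndarray:
    """Ideal alpha-helix Cα trace: rise 1.5 A, 100 deg per residue, radius
    chosen so consecutive Cα atoms sit exactly 3.8 A apart."""
    rise, turn = 1.5, np.deg2rad(100.0)
    radius = np.sqrt(3.8 ** 2 - rise ** 2) / (2.0 * np.sin(turn / 2.0))
    t = np.arange(n) * turn
    return np.column_stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)])


def make_enm_structure(
    n_residues: int = 120,
    architecture: str = "two_domain",
    planted_cutoff: float = 9.0,
    noise: float = 0.0,
    seed: int = 0,
    b_mean: float = 30.0,
) -> CalphaStructure:
    """Cα structure whose B-factors come from a known elastic network.

    The trace (helix, hairpin of two strands, or two helical domains with a
    linker) has ~3.8 A virtual bonds.  ``b_exp`` is the network's own
    B-factor prediction at ``planted_cutoff``, scaled to mean ``b_mean``
    (A^2, a typical crystallographic magnitude), with multiplicative
    Gaussian noise of relative width ``noise``.
    """
    rng = np.random.default_rng(seed)
    if architecture == "helix":
        coords = _helix_trace(n_residues)
    elif architecture == "hairpin":
        half = n_residues // 2
        up = np.column_stack([np.zeros(half), np.zeros(half), 3.8 * np.arange(half)])
        rest = n_residues - half
        down = np.column_stack([
            np.full(rest, 4.8), np.zeros(rest),
            3.8 * (half - 1) - 3.8 * np.arange(rest),
        ])
        coords = np.vstack([up, down])
    elif architecture == "two_domain":
        # 6 A lateral offset keeps the inter-domain contacts within the
        # usual ENM cutoff range, so the calibration grid stays connected
        h1 = _helix_trace(n_residues // 2)
        h2 = _helix_trace(n_residues - n_residues // 2)
        h2 = h2 + np.array([6.0, 0.0, h1[-1, 2] + 3.8])
        coords = np.vstack([h1, h2])
    else:
        raise ValueError(f"unknown architecture {architecture!r}")
    structure = CalphaStructure(coords=coords)
    _, hess = build_enm(structure, cutoff=planted_cutoff)
    modes = compute_modes(hess)
    b = predict_bfactors(modes, structure)
    b = b * (b_mean / b.mean())
    if noise > 0:
        b = b * (1.0 + rng.normal(0.0, noise, b.shape))
        b = np.maximum(b, 1e-3)
    structure.b_exp = b
    return structure
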