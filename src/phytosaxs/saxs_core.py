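"""Solution SAXS primitives: profile I/O, Guinier analysis, dilution-series
extrapolation, spectral population estimation and photosteady-state
decomposition.

Scattering-vector convention
----------------------------
Throughout this package the scattering vector length is ``S = 2 sin(theta) /
lambda`` (units 1/Angstrom).  The Guinier approximation in this convention is

    I(S, C) = I(0, C) * exp(-(4 pi^2 / 3) * Rg(C)^2 * S^2)

and every Fourier kernel downstream (Debye sums in :mod:`.bead_models`) uses
``2 pi S`` where the classic ``q``-convention formulas use ``q``.  Readers of
``q = 4 pi sin(theta)/lambda`` data can pass ``q_convention="q"`` to
:func:`read_profile`, which halves the first column on input.

For a monodisperse dilute solution the zero-angle intensity and radius of
gyration depend linearly on concentration ``C``:

    K C / I(0, C)  = 1/M_W + 2 A2 * C
    Rg(C)^2        = Rg(0)^2 - B_if * C

with ``K`` an experimental constant, ``M_W`` the apparent molecular weight,
``A2`` the second virial coefficient and ``B_if`` the interference slope
(same sign as ``A2`` for consistent interparticle interactions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

logger = logging.getLogger(__name__)

__all__ = [
    "ScatteringProfile",
    "GuinierFit",
    "DilutionSeriesFit",
    "MixtureWeights",
    "AbsorptionSpectrum",
    "read_profile",
    "write_profile",
    "guinier_fit",
    "fit_dilution_series",
    "estimate_populations",
    "decompose_steady",
    "compute_pfr_spectrum",
]

# default sigma model for 2-column files: sigma = max(EPS, C_SQRT * sqrt(max(I, 0)))
_SIGMA_EPS = 1e-6
_SIGMA_C = 1.0

# default Guinier window in S^2 (1/A^2)
DEFAULT_GUINIER_S2_MIN = 4e-6
DEFAULT_GUINIER_S2_MAX = 20e-6


@dataclass
class ScatteringProfile:
    """A 1-D scattering profile I(S) with per-point 1-sigma errors.

    ``s`` is the scattering vector length 2 sin(theta)/lambda in 1/A,
    strictly increasing.  ``concentration`` (mg/mL) is optional and carried
    for dilution-series analysis.
    """

    s: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray
    concentration: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.s.ndim != 1 or self.s.size < 2:
            raise ValueError("profile needs >= 2 points")
        if not (self.intensity.shape == self.s.shape == self.sigma.shape):
            raise ValueError("s, intensity, sigma must have equal length")
        if np.any(self.s < 0):
            raise ValueError("negative scattering vector length")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")
        finite = np.isfinite(self.sigma)
        if np.any(self.sigma[finite] <= 0):
            raise ValueError("sigma must be positive where finite")

    def __len__(self) -> int:
        return self.s.size


@dataclass
class GuinierFit:
    """Result of a Guinier fit: I(0), Rg and their standard errors."""

    i0: float
    rg: float
    i0_err: float
    rg_err: float
    s2_range: tuple[float, float]
    n_points: int
    r_squared: float
    concentration: float | None = None


@dataclass
class DilutionSeriesFit:
    """Zero-concentration extrapolation of a Guinier dilution series."""

    mw_apparent: float
    a2: float
    rg0: float
    b_if: float
    k_const: float
    mw_err: float = float("nan")
    a2_err: float = float("nan")
    rg0_err: float = float("nan")
    b_if_err: float = float("nan")


@dataclass
class MixtureWeights:
    """Populations of the two homodimer species in the red-light
    photosteady state: w_prpr + w_pfrpfr = 1."""

    w_prpr: float
    w_pfrpfr: float
    method: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_prpr <= 1.0 and 0.0 <= self.w_pfrpfr <= 1.0):
            raise ValueError("weights must lie in [0, 1]")
        if abs(self.w_prpr + self.w_pfrpfr - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


@dataclass
class AbsorptionSpectrum:
    """UV-visible absorption spectrum A(lambda), wavelength in nm."""

    wavelength: np.ndarray
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelength.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance must have equal length")
        if np.any(np.diff(self.wavelength) <= 0):
            raise ValueError("wavelength must be strictly increasing")


# ---------------------------------------------------------------------------
# I/O


def read_profile(
    path: str | Path,
    concentration: float | None = None,
    q_convention: str = "s",
) -> ScatteringProfile:
    """Read an ATSAS-style whitespace-delimited .dat profile.

    Lines that do not parse as 2 or 3 numbers (headers, footers, comments)
    are skipped.  With two columns the errors are filled by the Poisson-like
    default ``sigma = max(1e-6, sqrt(max(I, 0)))`` and a warning is logged.
    ``q_convention="q"`` declares the first column to be
    ``q = 4 pi sin(theta)/lambda``; it is converted to S = q / (2 pi).
    """
    path = Path(path)
    if q_convention not in ("s", "q"):
        raise ValueError("q_convention must be 's' or 'q'")
    rows: list[tuple[float, float, float]] = []
    saw_two_col = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) not in (2, 3):
                continue
            try:
                nums = [float(p) for p in parts]
            except ValueError:
                continue
            if nums[0] < 0:
                raise ValueError(f"{path}:{lineno}: negative s value {nums[0]}")
            if len(nums) == 2:
                saw_two_col = True
                sig = max(_SIGMA_EPS, _SIGMA_C * np.sqrt(max(nums[1], 0.0)))
                nums.append(sig)
            rows.append(tuple(nums))
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 numeric data rows")
    if saw_two_col:
        logger.warning(
            "%s: no error column; using sigma = max(%.0e, %.0f*sqrt(I))",
            path, _SIGMA_EPS, _SIGMA_C,
        )
    arr = np.array(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    s = arr[:, 0]
    if q_convention == "q":
        s = s / (2.0 * np.pi)
    return ScatteringProfile(
        s=s, intensity=arr[:, 1], sigma=arr[:, 2],
        concentration=concentration, label=path.stem,
    )


def write_profile(profile: ScatteringProfile, path: str | Path,
                  comments: list[str] | None = None) -> None:
    """Write a 3-column .dat profile with '#' provenance comments."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# phytosaxs profile: {profile.label}\n")
        if profile.concentration is not None:
            fh.write(f"# concentration_mg_ml: {profile.concentration}\n")
        for c in comments or []:
            fh.write(f"# {c}\n")
        for s, i, sig in zip(profile.s, profile.intensity, profile.sigma):
            fh.write(f"{s:.8e} {i:.8e} {sig:.8e}\n")


# ---------------------------------------------------------------------------
# Guinier analysis


def guinier_fit(
    profile: ScatteringProfile,
    s2_min: float = DEFAULT_GUINIER_S2_MIN,
    s2_max: float = DEFAULT_GUINIER_S2_MAX,
) -> GuinierFit:
    """Error-weighted linear fit of ln I vs S^2 over [s2_min, s2_max].

    Returns I(0) = exp(intercept) and Rg = sqrt(-3 * slope / (4 pi^2)).
    Points are weighted by (I / sigma)^2, the delta-method weight for
    ln I.  A positive slope beyond two standard errors (negative Rg^2)
    raises: there is no Guinier region in the window.
    """
    s2 = profile.s ** 2
    mask = (s2 >= s2_min) & (s2 <= s2_max) & (profile.intensity > 0)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(
            f"Guinier window [{s2_min:g}, {s2_max:g}] contains {n} usable "
            "points; need >= 3"
        )
    x = s2[mask]
    y = np.log(profile.intensity[mask])
    w = (profile.intensity[mask] / profile.sigma[mask]) ** 2

    # weighted least squares y = a + b x via normal equations
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    sxy = (w * (x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm

    resid = y - (intercept + slope * x)
    dof = max(n - 2, 1)
    # scale the formal covariance by reduced chi^2 so errors reflect scatter
    chi2_red = (w * resid ** 2).sum() / dof
    slope_var = chi2_red / sxx
    intercept_var = chi2_red * (1.0 / sw + xm ** 2 / sxx)
    slope_err = float(np.sqrt(slope_var))

    if slope > 2.0 * slope_err and slope > 0:
        raise ValueError("no Guinier region: positive slope beyond 2 sigma")
    rg2 = -3.0 * slope / (4.0 * np.pi ** 2)
    rg = float(np.sqrt(max(rg2, 0.0)))
    i0 = float(np.exp(intercept))
    # propagate: rg = sqrt(-3 b /(4 pi^2)) -> drg/db = -3/(8 pi^2 rg)
    rg_err = float(3.0 / (8.0 * np.pi ** 2 * rg) * slope_err) if rg > 0 else float("nan")
    i0_err = float(i0 * np.sqrt(intercept_var))

    ss_tot = (w * (y - ym) ** 2).sum()
    r_squared = float(1.0 - (w * resid ** 2).sum() / ss_tot) if ss_tot > 0 else 1.0
    return GuinierFit(
        i0=i0, rg=rg, i0_err=i0_err, rg_err=rg_err,
        s2_range=(float(s2_min), float(s2_max)), n_points=n,
        r_squared=r_squared, concentration=profile.concentration,
    )


def fit_dilution_series(fits: list[GuinierFit], k_const: float = 1.0) -> DilutionSeriesFit:
    """Extrapolate a concentration series of Guinier fits to C = 0.

    Fits (unweighted) ``K C / I(0)`` vs ``C`` (intercept 1/M_W, slope
    2 A2) and ``Rg^2`` vs ``C`` (intercept Rg(0)^2, slope -B_if).
    """
    conc = np.array([f.concentration for f in fits], dtype=float)
    if np.any(np.isnan(conc)):
        raise ValueError("every fit needs a concentration")
    if np.unique(conc).size < 2:
        raise ValueError("need >= 2 distinct concentrations")
    i0 = np.array([f.i0 for f in fits], dtype=float)
    rg = np.array([f.rg for f in fits], dtype=float)

    y1 = k_const * conc / i0
    (slope1, inter1), cov1 = np.polyfit(conc, y1, 1, cov=True) if conc.size > 3 else (
        np.polyfit(conc, y1, 1), np.full((2, 2), np.nan))
    y2 = rg ** 2
    (slope2, inter2), cov2 = np.polyfit(conc, y2, 1, cov=True) if conc.size > 3 else (
        np.polyfit(conc, y2, 1), np.full((2, 2), np.nan))

    if inter1 <= 0:
        raise ValueError("extrapolation invalid: non-positive 1/M_W intercept")
    if inter2 < 0:
        raise ValueError("extrapolation invalid: negative Rg^2 intercept")
    mw = 1.0 / inter1
    a2 = slope1 / 2.0
    rg0 = float(np.sqrt(inter2))
    b_if = -slope2
    mw_err = float(mw ** 2 * np.sqrt(cov1[1, 1]))
    a2_err = float(0.5 * np.sqrt(cov1[0, 0]))
    rg0_err = float(np.sqrt(cov2[1, 1]) / (2 * rg0)) if rg0 > 0 else float("nan")
    b_if_err = float(np.sqrt(cov2[0, 0]))
    return DilutionSeriesFit(
        mw_apparent=float(mw), a2=float(a2), rg0=rg0, b_if=float(b_if),
        k_const=float(k_const), mw_err=mw_err, a2_err=a2_err,
        rg0_err=rg0_err, b_if_err=b_if_err,
    )


# ---------------------------------------------------------------------------
# spectra and photosteady-state decomposition


def _common_grid(*spectra: AbsorptionSpectrum) -> np.ndarray:
    lo = max(sp.wavelength[0] for sp in spectra)
    hi = min(sp.wavelength[-1] for sp in spectra)
    if hi <= lo:
        raise ValueError("spectra have no overlapping wavelength range")
    base = spectra[0].wavelength
    grid = base[(base >= lo) & (base <= hi)]
    if grid.size < 2:
        raise ValueError("overlap range too narrow")
    return grid


def estimate_populations(
    spec_steady: AbsorptionSpectrum,
    spec_pr: AbsorptionSpectrum,
    spec_pfr_ref: AbsorptionSpectrum,
    window: tuple[float, float] = (550.0, 800.0),
    cond_threshold: float = 1e8,
) -> MixtureWeights:
    """Estimate (w_prpr, w_pfrpfr) by non-negative least squares.

    The steady-state spectrum is unmixed against the Pr and Pfr reference
    spectra over ``window`` (nm); weights are renormalised to sum to 1.
    """
    grid = _common_grid(spec_steady, spec_pr, spec_pfr_ref)
    sel = (grid >= window[0]) & (grid <= window[1])
    if sel.sum() < 2:
        raise ValueError("empty unmixing window")
    grid = grid[sel]
    y = np.interp(grid, spec_steady.wavelength, spec_steady.absorbance)
    a = np.column_stack([
        np.interp(grid, spec_pr.wavelength, spec_pr.absorbance),
        np.interp(grid, spec_pfr_ref.wavelength, spec_pfr_ref.absorbance),
    ])
    if np.linalg.cond(a) > cond_threshold:
        raise ValueError("unmixing ill-posed: reference spectra nearly dependent")
    coef, rnorm = nnls(a, y)
    total = coef.sum()
    if total <= 0:
        raise ValueError("unmixing ill-posed: zero total weight")
    w = coef / total
    rms = rnorm / np.sqrt(len(y))
    return MixtureWeights(
        w_prpr=float(w[0]), w_pfrpfr=float(w[1]),
        method=(f"NNLS on {window[0]:g}-{window[1]:g} nm, "
                f"{len(y)} points, residual RMS {rms:.3e}"),
    )


def _overlap_interp(ref_s: np.ndarray, prof: ScatteringProfile) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = prof.s[0], prof.s[-1]
    mask = (ref_s >= lo) & (ref_s <= hi)
    if mask.sum() < 2:
        raise ValueError("profiles have no overlapping s range")
    grid = ref_s[mask]
    return mask, grid


def decompose_steady(
    i_steady: ScatteringProfile,
    i_pr: ScatteringProfile,
    weights: MixtureWeights,
) -> ScatteringProfile:
    """Recover the pure Pfr-Pfr profile from a photosteady-state mixture.

    The steady state under red light is modelled as a two-component sum
    I_steady = w_prpr * I_PrPr + w_pfrpfr * I_PfrPfr, so

        I_PfrPfr(S) = (I_steady(S) - w_prpr * I_Pr(S)) / w_pfrpfr

    with errors propagated as sqrt(sigma_steady^2 + w_prpr^2 * sigma_Pr^2)
    / w_pfrpfr.  Negative intensities are kept (not clipped) and counted in
    a logged diagnostic so linearity and error statistics are preserved.
    """
    if weights.w_pfrpfr == 0:
        raise ZeroDivisionError("w_pfrpfr = 0: nothing to decompose")
    mask, grid = _overlap_interp(i_steady.s, i_pr)
    i_st = i_steady.intensity[mask]
    sig_st = i_steady.sigma[mask]
    if np.array_equal(grid, i_pr.s):
        i_p, sig_p = i_pr.intensity, i_pr.sigma
    else:
        i_p = np.interp(grid, i_pr.s, i_pr.intensity)
        sig_p = np.interp(grid, i_pr.s, i_pr.sigma)
    out = (i_st - weights.w_prpr * i_p) / weights.w_pfrpfr
    sig = np.sqrt(sig_st ** 2 + weights.w_prpr ** 2 * sig_p ** 2) / weights.w_pfrpfr
    n_neg = int((out < 0).sum())
    if n_neg:
        logger.warning("decompose_steady: %d negative intensities retained", n_neg)
    return ScatteringProfile(
        s=grid, intensity=out, sigma=sig,
        concentration=i_steady.concentration,
        label=f"{i_steady.label}-decomposed-pfr",
    )


def compute_pfr_spectrum(
    spec_steady: AbsorptionSpectrum,
    spec_pr: AbsorptionSpectrum,
    weights: MixtureWeights,
) -> AbsorptionSpectrum:
    """Pure-Pfr absorption spectrum from the steady-state spectrum, same
    two-component inversion as :func:`decompose_steady`."""
    if weights.w_pfrpfr == 0:
        raise ZeroDivisionError("w_pfrpfr = 0: nothing to decompose")
    grid = _common_grid(spec_steady, spec_pr)
    a_st = np.interp(grid, spec_steady.wavelength, spec_steady.absorbance)
    a_pr = np.interp(grid, spec_pr.wavelength, spec_pr.absorbance)
    out = (a_st - weights.w_prpr * a_pr) / weights.w_pfrpfr
    return AbsorptionSpectrum(wavelength=grid, absorbance=out,
                              label=f"{spec_steady.label}-pfr")
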