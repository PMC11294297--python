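"""Recovery-coefficient partial-volume correction and local-energy-deposition dose.

The recovery coefficient (RC) of a VOI is the ratio measured/true of the
mean concentration for a uniformly filled object imaged at finite
resolution; correction therefore divides the measured concentration by the
RC.  Two modes are supported: the fixed guideline value 0.85, and a
shape-specific RC computed by blurring the VOI's own mask with the system
PSF (a Gaussian surrogate for a Monte-Carlo resolution model).

The absorbed dose follows the local-energy-deposition (LED) model: every
decay deposits a fixed mean electron energy (default 147.9 keV) at the
decay site, and the time-integrated activity concentration (decays/mL) is
converted to dose via the tissue density (default 1.05 g/mL):

    D[Gy] = TIAC[decays/mL] / rho[g/mL] * E[keV] * 1.602176634e-16 J/keV
            * 1e3 g/kg * photon_self_dose_factor

The optional ``photon_self_dose_factor`` (default 1, i.e. disabled)
accounts for self-absorbed photon irradiation on top of the electron LED.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, zoom

from .grids import VOI
from .phantom import FWHM_TO_SIGMA

__all__ = [
    "KEV_TO_JOULE",
    "SECONDS_PER_HOUR",
    "RecoveryCoefficient",
    "DosimetryConstants",
    "DoseEstimate",
    "fixed_rc",
    "compute_rc",
    "apply_rc",
    "absorbed_dose",
    "tiac_conc_to_decays_per_mL",
]

KEV_TO_JOULE = 1.602176634e-16
SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class RecoveryCoefficient:
    value: float
    mode: str  # "fixed" or "specific"
    provenance: tuple[str, float] | None = None  # (shape id, FWHM mm)

    def __post_init__(self) -> None:
        if not 0.0 < self.value <= 1.0:
            raise ValueError("RC must lie in (0, 1]")
        if self.mode not in ("fixed", "specific"):
            raise ValueError(f"unknown RC mode {self.mode!r}")


@dataclass(frozen=True)
class DosimetryConstants:
    """LED dose-model constants (defaults for 177Lu kidney self-dose)."""

    led_keV_per_decay: float = 147.9
    density_g_per_mL: float = 1.05
    photon_self_dose_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.led_keV_per_decay, self.density_g_per_mL, self.photon_self_dose_factor) <= 0:
            raise ValueError("dosimetry constants must be positive")


@dataclass(frozen=True)
class DoseEstimate:
    dose_Gy: float
    tiac_Bq_h_per_mL: float
    rc: RecoveryCoefficient
    strategy: str

    def __post_init__(self) -> None:
        if self.dose_Gy < 0:
            raise ValueError("dose must be >= 0")


def fixed_rc(value: float = 0.85) -> RecoveryCoefficient:
    """The guideline fixed recovery coefficient (default 0.85)."""
    return RecoveryCoefficient(value, "fixed")


def compute_rc(
    voi: VOI,
    psf_fwhm_mm: float,
    pad_sigmas: float = 5.0,
    target_spacing_mm: float = 2.3,
) -> RecoveryCoefficient:
    """Shape-specific RC of the VOI's object under an isotropic Gaussian PSF.

    The object's sharp surface is recovered from the (possibly fractional)
    coverage mask by cubic-spline upsampling to about ``target_spacing_mm``
    and re-thresholding at coverage 0.5 (the 0.5 level tracks the surface to
    sub-voxel accuracy for smooth shapes).  A unit concentration is painted
    on the recovered shape, convolved with the PSF, and averaged back over
    the shape: for a uniform object this is measured/true of an ideal
    resolution-limited measurement, and agrees with a dense-grid convolution
    oracle to well under 1% for organ-sized objects on the SPECT grid.

    The array is zero-padded by ~5 sigma before convolution so spill-out is
    never clipped at the grid edge.
    """
    w = voi.mask.sum()
    if w <= 0:
        raise ValueError("zero-volume VOI")
    if psf_fwhm_mm < 0:
        raise ValueError("FWHM must be >= 0")
    if psf_fwhm_mm == 0:
        return RecoveryCoefficient(1.0, "specific", (voi.label, 0.0))

    factors = tuple(
        max(1, int(np.ceil(sp / target_spacing_mm))) for sp in voi.geometry.spacing
    )
    if any(f > 1 for f in factors):
        fine = zoom(voi.mask, factors, order=3, grid_mode=True, mode="grid-constant")
        mask = (fine >= 0.5).astype(np.float64)
        if mask.sum() == 0:  # object below recovery resolution; keep coverage
            mask = np.clip(fine, 0.0, 1.0)
        spacing = tuple(sp / f for sp, f in zip(voi.geometry.spacing, factors))
    else:
        mask = voi.mask
        spacing = voi.geometry.spacing

    sigma_mm = psf_fwhm_mm * FWHM_TO_SIGMA
    pad = [int(np.ceil(pad_sigmas * sigma_mm / sp)) for sp in spacing]
    field = np.pad(mask, [(p, p) for p in pad])
    sigma_vox = [sigma_mm / sp for sp in spacing]
    blurred = gaussian_filter(field, sigma_vox, mode="constant", truncate=8.0)
    core = blurred[pad[0] : field.shape[0] - pad[0],
                   pad[1] : field.shape[1] - pad[1],
                   pad[2] : field.shape[2] - pad[2]]
    rc = float((core * mask).sum() / mask.sum())
    rc = min(rc, 1.0)
    return RecoveryCoefficient(rc, "specific", (voi.label, float(psf_fwhm_mm)))


def apply_rc(conc_measured: float, rc: RecoveryCoefficient) -> float:
    """Partial-volume-correct a measured concentration (divide by RC)."""
    if rc.value <= 0:
        raise ValueError("RC must be > 0")
    return conc_measured / rc.value


def tiac_conc_to_decays_per_mL(tiac_Bq_h_per_mL: float) -> float:
    """Unit chain Bq*h/mL -> decays/mL (x3600 s/h; 1 Bq = 1 decay/s)."""
    return tiac_Bq_h_per_mL * SECONDS_PER_HOUR


def absorbed_dose(tiac_decays_per_mL: float, constants: DosimetryConstants | None = None) -> float:
    """LED absorbed dose (Gy) from a time-integrated activity concentration.

    ``tiac_decays_per_mL`` is in decays/mL (use
    :func:`tiac_conc_to_decays_per_mL` from Bq*h/mL).  The chain is
    decays/mL -> /density -> decays/g -> x LED keV -> J/g -> x1e3 -> J/kg = Gy,
    optionally scaled by the photon self-dose factor.
    """
    if tiac_decays_per_mL < 0:
        raise ValueError("TIAC must be >= 0")
    k = constants or DosimetryConstants()
    return (
        tiac_decays_per_mL
        / k.density_g_per_mL
        * k.led_keV_per_decay
        * KEV_TO_JOULE
        * 1e3
        * k.photon_self_dose_factor
    )
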