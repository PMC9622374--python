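"""Corneal and pseudophakic eye models built from biometry and IOL geometry.

The cornea is modelled as two conic refracting surfaces (stromal index 1.376,
aqueous 1.336); the implanted IOL as a thick lens in aqueous, with vitreous
(1.338) behind it.  Keratometric power — the clinical convention that folds
the whole cornea into a single surface with a fictitious index of 1.3375 or
1.3315 — is provided alongside the physically based two-surface (Snell-law)
Gaussian power so that the two conventions can be compared: for normal
corneas the keratometric reading overestimates the optical power by roughly
half a diopter to a diopter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .optics import OpticalSystem, Surface, paraxial_power

__all__ = [
    "N_STROMA",
    "N_AQUEOUS",
    "N_VITREOUS",
    "CornealGeometry",
    "IOLPowerEntry",
    "IOLDesign",
    "keratometric_power",
    "corneal_gaussian_power",
    "corneal_system",
    "build_pseudophakic_system",
]

N_STROMA = 1.376
N_AQUEOUS = 1.336
N_VITREOUS = 1.338

_CORNEA_HALF_APERTURE = 6.0
_IOL_HALF_APERTURE = 3.25  # 6.5 mm optic


@dataclass(frozen=True)
class CornealGeometry:
    """Central corneal geometry: radii are apical (mm), eccentricities map to
    conic constants k = -e**2 (prolate for e > 0)."""

    r_anterior: float
    r_posterior: float
    cct: float
    e_anterior: float = 0.0
    e_posterior: float = 0.0
    n_stroma: float = N_STROMA
    n_aqueous: float = N_AQUEOUS

    def __post_init__(self):
        if not 5.0 < self.r_anterior < 12.0:
            raise ValueError(f"anterior corneal radius {self.r_anterior} mm out of range")
        if self.r_posterior <= 0:
            raise ValueError("posterior corneal radius must be positive")
        if not 0.3 < self.cct < 0.8:
            raise ValueError(f"central corneal thickness {self.cct} mm out of range")

    @property
    def k_anterior(self) -> float:
        return -self.e_anterior ** 2

    @property
    def k_posterior(self) -> float:
        return -self.e_posterior ** 2


@dataclass(frozen=True)
class IOLPowerEntry:
    """Physical IOL geometry for one labeled power: signed radii (front > 0 and
    back < 0 for a biconvex optic, inf planar), centre thickness and index."""

    labeled_power: float
    r_front: float
    r_back: float
    thickness: float
    n_iol: float

    def __post_init__(self):
        if not 0.2 < self.thickness < 1.5:
            raise ValueError(f"IOL centre thickness {self.thickness} mm out of range")
        if self.n_iol <= 1.0:
            raise ValueError("IOL refractive index must exceed 1")
        if self.r_front == 0 or self.r_back == 0:
            raise ValueError("IOL radii must be nonzero (inf for planar)")


@dataclass
class IOLDesign:
    """A labeled-power -> geometry table for one IOL model."""

    name: str
    entries: list
    power_step: float = 0.5

    def __post_init__(self):
        self.entries = sorted(self.entries, key=lambda e: e.labeled_power)
        powers = [e.labeled_power for e in self.entries]
        if len(powers) != len(set(powers)):
            raise ValueError("duplicate labeled powers in design table")
        if len(powers) >= 2:
            steps = [round(b - a, 9) for a, b in zip(powers, powers[1:])]
            if any(abs(s - steps[0]) > 1e-9 for s in steps):
                raise ValueError("labeled powers must be uniformly spaced")

    @property
    def powers(self) -> list:
        return [e.labeled_power for e in self.entries]

    def entry_for(self, power: float) -> IOLPowerEntry:
        for e in self.entries:
            if abs(e.labeled_power - power) < 1e-9:
                return e
        raise KeyError(f"power {power} D not in design table")


def keratometric_power(r_anterior: float, keratometric_index: float = 1.3375) -> float:
    """Single-surface clinical corneal power (n_k - 1)/r in diopters, r in mm."""
    if r_anterior <= 0:
        raise ValueError("anterior corneal radius must be positive")
    return 1000.0 * (keratometric_index - 1.0) / r_anterior


def corneal_gaussian_power(c: CornealGeometry) -> float:
    """Thick-lens (Gaussian) equivalent power of the two-surface cornea, diopters.

    P = P1 + P2 - (cct/n_stroma) P1 P2 with P1 = (n_s - 1)/r_a and
    P2 = (n_aq - n_s)/r_p.  Agrees with the matrix cascade of
    :func:`oformula.optics.paraxial_power` to numerical precision.
    """
    p1 = 1000.0 * (c.n_stroma - 1.0) / c.r_anterior
    p2 = 1000.0 * (c.n_aqueous - c.n_stroma) / c.r_posterior
    return p1 + p2 - (c.cct / 1000.0 / c.n_stroma) * p1 * p2


def corneal_system(c: CornealGeometry, image_z: float = 40.0) -> OpticalSystem:
    """The bare two-surface cornea (air -> stroma -> aqueous)."""
    return OpticalSystem(
        [
            Surface(0.0, c.r_anterior, 1.0, c.n_stroma, conic_k=c.k_anterior,
                    half_aperture=_CORNEA_HALF_APERTURE),
            Surface(c.cct, c.r_posterior, c.n_stroma, c.n_aqueous, conic_k=c.k_posterior,
                    half_aperture=_CORNEA_HALF_APERTURE),
        ],
        image_z=image_z,
    )


def build_pseudophakic_system(c: CornealGeometry, iol: IOLPowerEntry, iol_depth: float,
                              photoreceptor_z: float) -> OpticalSystem:
    """Four-surface pseudophakic eye on the optical axis.

    ``iol_depth`` is the posterior-cornea to anterior-IOL distance (mm); the
    image plane sits at ``photoreceptor_z`` — the segmented axial length, i.e.
    the external limiting membrane.  Media: air / stroma / aqueous / IOL /
    vitreous.
    """
    if iol_depth <= 0:
        raise ValueError("iol_depth must be positive")
    z_front = c.cct + iol_depth
    z_back = z_front + iol.thickness
    if photoreceptor_z <= z_back:
        raise ValueError("photoreceptor plane must lie behind the IOL")
    return OpticalSystem(
        [
            Surface(0.0, c.r_anterior, 1.0, c.n_stroma, conic_k=c.k_anterior,
                    half_aperture=_CORNEA_HALF_APERTURE),
            Surface(c.cct, c.r_posterior, c.n_stroma, c.n_aqueous, conic_k=c.k_posterior,
                    half_aperture=_CORNEA_HALF_APERTURE),
            Surface(z_front, iol.r_front, c.n_aqueous, iol.n_iol,
                    half_aperture=_IOL_HALF_APERTURE),
            Surface(z_back, iol.r_back, iol.n_iol, N_VITREOUS,
                    half_aperture=_IOL_HALF_APERTURE),
        ],
        image_z=photoreceptor_z,
    )
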