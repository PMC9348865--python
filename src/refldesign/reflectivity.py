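"""Specular reflectivity of slab models via the Abelès matrix formalism.

A sample is a stack of contiguous homogeneous layers (slabs) between a
semi-infinite incident medium (superphase) and a semi-infinite backing
medium (substrate).  Each layer carries a nuclear scattering length
density (SLD), an optional magnetic SLD offset for polarized channels, a
Gaussian interfacial roughness with the medium above it, and a solvent
volume fraction (hydration) mixed linearly into the SLD.

Unit conventions
----------------
* lengths and roughnesses in Å
* SLDs user-facing in 1e-6 Å⁻² and converted to Å⁻² once, inside the kernel
* Q in Å⁻¹, angles in degrees

Roughness uses Nevot–Croce Gaussian attenuation factors at each
interface.  Resolution smearing is a Gaussian in Q with constant dQ/Q
interpreted as FWHM, evaluated with fixed-order Gaussian quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np

SLD_UNIT = 1e-6  # user-facing SLDs are in units of 1e-6 Å⁻²
_FWHM_TO_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))


class ReflectivityError(ValueError):
    """Invalid sample or kernel input."""


@dataclass
class Layer:
    """One homogeneous slab.

    ``roughness`` is the Gaussian roughness of the interface between this
    layer and the medium **above** it (towards the superphase).
    ``hydration`` is the solvent volume fraction; the effective SLD is
    ``(1 - hydration) * sld + hydration * solvent_sld``.
    """

    thickness: float
    sld: float
    magnetic_sld: float = 0.0
    roughness: float = 0.0
    hydration: float = 0.0
    isld: float = 0.0  # imaginary (absorption) part; no bundled sample needs it
    name: str = ""

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ReflectivityError(f"layer {self.name!r}: thickness must be >= 0")
        if not 0.0 <= self.hydration <= 1.0:
            raise ReflectivityError(f"layer {self.name!r}: hydration must lie in [0, 1]")
        if self.roughness < 0:
            raise ReflectivityError(f"layer {self.name!r}: roughness must be >= 0")


@dataclass
class Sample:
    """A slab stack with experimental scale factor and background.

    ``substrate_roughness`` is the roughness of the substrate interface
    with the bottom layer (or with the superphase for a bare substrate).
    If ``substrate_tracks_solvent`` the backing medium *is* the bulk
    solvent, so :meth:`with_contrast` retargets both.
    """

    superphase_sld: float
    layers: list[Layer]
    substrate_sld: float
    solvent_sld: float = 0.0
    scale: float = 1.0
    background: float = 0.0
    substrate_roughness: float = 0.0
    substrate_tracks_solvent: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ReflectivityError("scale must be > 0")
        if self.background < 0:
            raise ReflectivityError("background must be >= 0")

    def with_contrast(self, solvent_sld: float) -> "Sample":
        """Return a copy measured against a different bulk solvent SLD."""
        sub = solvent_sld if self.substrate_tracks_solvent else self.substrate_sld
        return replace(self, solvent_sld=solvent_sld, substrate_sld=sub)


@dataclass
class Parameter:
    """A named model parameter with bounds and an importance weight.

    ``importance`` is the weight used when scaling the Fisher information
    to a common (dimensionless) scale; ``None`` means the default of
    equal importance per fractional change, i.e. a weight of ``|value|``.
    """

    name: str
    value: float
    bounds: tuple[float, float] = (-math.inf, math.inf)
    varying: bool = True
    importance: float | None = None

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if lo > hi:
            raise ReflectivityError(f"parameter {self.name!r}: bounds reversed")
        if self.varying and not (lo <= self.value <= hi):
            raise ReflectivityError(
                f"parameter {self.name!r}: value {self.value} outside bounds {self.bounds}"
            )


def momentum_transfer(wavelength, angle):
    """Q = 4π sin(θ) / λ with λ in Å and θ in degrees."""
    wavelength = np.asarray(wavelength, dtype=float)
    if np.any(wavelength <= 0):
        raise ReflectivityError("wavelength must be > 0")
    angle = np.asarray(angle, dtype=float)
    if np.any(angle < 0) or np.any(angle >= 90):
        raise ReflectivityError("angle must lie in [0, 90) degrees")
    out = 4.0 * np.pi * np.sin(np.radians(angle)) / wavelength
    return out if out.ndim else float(out)


def _sld_profile(sample: Sample, spin: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Complex SLDs (Å⁻²), thicknesses and interfacial roughnesses."""
    if spin not in ("unpolarized", "up", "down"):
        raise ReflectivityError(f"unknown spin channel {spin!r}")
    sign = {"unpolarized": 0.0, "up": 1.0, "down": -1.0}[spin]
    slds = [complex(sample.superphase_sld)]
    thick = [0.0]
    rough = []
    for lay in sample.layers:
        nuclear = lay.sld + sign * lay.magnetic_sld
        eff = (1.0 - lay.hydration) * nuclear + lay.hydration * sample.solvent_sld
        slds.append(complex(eff, lay.isld))
        thick.append(lay.thickness)
        rough.append(lay.roughness)
    slds.append(complex(sample.substrate_sld))
    thick.append(0.0)
    rough.append(sample.substrate_roughness)
    return (
        np.asarray(slds) * SLD_UNIT,
        np.asarray(thick, dtype=float),
        np.asarray(rough, dtype=float),
    )


def abeles(q, slds, thicknesses, roughnesses) -> np.ndarray:
    """Bare reflectance |r|² for a stack of media.

    Parameters are in internal units: ``slds`` complex in Å⁻² (one per
    medium, superphase first), ``thicknesses`` per medium (outer media
    ignored), ``roughnesses`` one per interface (Nevot–Croce).
    """
    q = np.asarray(q, dtype=float).reshape(-1)
    if q.size == 0:
        raise ReflectivityError("empty Q array")
    if np.any(q <= 0):
        raise ReflectivityError("Q values must be > 0")
    k0 = q[:, None] / 2.0
    # normal wavevector in each medium, referenced to the superphase
    kn = np.sqrt(k0**2 - 4.0 * np.pi * (slds[None, :] - slds[0]) + 0j)
    ka, kb = kn[:, :-1], kn[:, 1:]
    rj = (ka - kb) / (ka + kb) * np.exp(-2.0 * ka * kb * roughnesses[None, :] ** 2)

    beta = 1j * kn[:, 1:-1] * thicknesses[None, 1:-1]
    m00 = np.ones(q.shape, dtype=complex)
    m01 = rj[:, 0].copy()
    m10 = rj[:, 0].copy()
    m11 = np.ones(q.shape, dtype=complex)
    for i in range(1, rj.shape[1]):
        ep = np.exp(beta[:, i - 1])
        em = np.exp(-beta[:, i - 1])
        a00, a01 = ep, rj[:, i] * ep
        a10, a11 = rj[:, i] * em, em
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )
    r = m10 / m00
    return np.abs(r) ** 2


def abeles_batch(q, slds, thicknesses, roughnesses) -> np.ndarray:
    """Vectorized :func:`abeles` over a batch of stacks with shared geometry.

    ``slds`` (B, M) complex Å⁻², ``thicknesses`` (B, M), ``roughnesses``
    (B, M−1); returns reflectance of shape (B, len(q)).  Used to
    evaluate all finite-difference parameter perturbations of a model in
    one pass.
    """
    q = np.asarray(q, dtype=float).reshape(-1)
    if q.size == 0:
        raise ReflectivityError("empty Q array")
    if np.any(q <= 0):
        raise ReflectivityError("Q values must be > 0")
    slds = np.asarray(slds)
    k0 = q[None, :, None] / 2.0
    kn = np.sqrt(k0**2 - 4.0 * np.pi * (slds[:, None, :] - slds[:, None, :1]) + 0j)
    ka, kb = kn[:, :, :-1], kn[:, :, 1:]
    rj = (ka - kb) / (ka + kb) * np.exp(-2.0 * ka * kb * roughnesses[:, None, :] ** 2)

    beta = 1j * kn[:, :, 1:-1] * thicknesses[:, None, 1:-1]
    shape = rj.shape[:2]
    m00 = np.ones(shape, dtype=complex)
    m01 = rj[:, :, 0].copy()
    m10 = rj[:, :, 0].copy()
    m11 = np.ones(shape, dtype=complex)
    for i in range(1, rj.shape[2]):
        ep = np.exp(beta[:, :, i - 1])
        em = 1.0 / ep
        rje = rj[:, :, i]
        a00, a01 = ep, rje * ep
        a10, a11 = rje * em, em
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )
    r = m10 / m00
    return np.abs(r) ** 2


@lru_cache(maxsize=8)
def _smear_weights(n_points: int, width: float) -> tuple[np.ndarray, np.ndarray]:
    nodes, wts = np.polynomial.legendre.leggauss(n_points)
    t = nodes * width
    gw = wts * np.exp(-0.5 * t**2)
    gw /= gw.sum()
    return t, gw


def batch_total_reflectivity(
    samples: Sequence[Sample],
    q,
    dq_over_q: float = 0.02,
    spin: str = "unpolarized",
    n_points: int = 17,
    width: float = 3.5,
) -> np.ndarray:
    """Smeared, scaled reflectivity with background for a batch of samples.

    All samples must share the same layer count (e.g. finite-difference
    perturbations of one model).  Identical numerics to
    :func:`total_reflectivity`, evaluated in a single vectorized pass.
    """
    q = np.asarray(q, dtype=float).reshape(-1)
    profiles = [_sld_profile(s, spin) for s in samples]
    slds = np.stack([p[0] for p in profiles])
    thick = np.stack([p[1] for p in profiles])
    rough = np.stack([p[2] for p in profiles])
    scales = np.array([s.scale for s in samples])
    bgs = np.array([s.background for s in samples])
    if not 0.0 <= dq_over_q < 1.0:
        raise ReflectivityError("dq_over_q must lie in [0, 1)")
    if dq_over_q == 0.0:
        bare = abeles_batch(q, slds, thick, rough)
    else:
        t, gw = _smear_weights(n_points, width)
        sigma = dq_over_q / _FWHM_TO_SIGMA
        qs = q[:, None] * (1.0 + t[None, :] * sigma)
        r = abeles_batch(qs.ravel(), slds, thick, rough)
        bare = r.reshape(len(samples), len(q), n_points) @ gw
    return scales[:, None] * bare + bgs[:, None]


def bare_reflectivity(sample: Sample, q, spin: str = "unpolarized") -> np.ndarray:
    """Unsmeared reflectance of the stack, without scale or background."""
    slds, thick, rough = _sld_profile(sample, spin)
    return abeles(q, slds, thick, rough)


def reflectivity(sample: Sample, q, spin: str = "unpolarized") -> np.ndarray:
    """Unsmeared model reflectivity ``scale * |r|² + background``."""
    return sample.scale * bare_reflectivity(sample, q, spin) + sample.background


def smear(
    model_r: Callable[[np.ndarray], np.ndarray],
    q,
    dq_over_q: float,
    n_points: int = 17,
    width: float = 3.5,
) -> np.ndarray:
    """Constant-dQ/Q Gaussian resolution smearing of a model curve.

    ``dq_over_q`` is the FWHM of the Gaussian resolution kernel as a
    fraction of Q.  The convolution uses ``n_points`` Gauss–Legendre
    nodes over ±``width`` standard deviations with weights renormalized
    to unit sum, so a constant curve is conserved exactly and
    ``dq_over_q = 0`` returns the unsmeared curve.
    """
    if not 0.0 <= dq_over_q < 1.0:
        raise ReflectivityError("dq_over_q must lie in [0, 1)")
    q = np.asarray(q, dtype=float).reshape(-1)
    if dq_over_q == 0.0:
        return np.asarray(model_r(q))
    t, gw = _smear_weights(n_points, width)
    sigma = dq_over_q / _FWHM_TO_SIGMA
    qs = q[:, None] * (1.0 + t[None, :] * sigma)
    r = np.asarray(model_r(qs.ravel())).reshape(qs.shape)
    return r @ gw


def total_reflectivity(
    sample: Sample, q, dq_over_q: float = 0.02, spin: str = "unpolarized"
) -> np.ndarray:
    """Smeared, scaled reflectivity with additive background.

    The background is added after smearing:
    ``R_tot = scale * smear(|r|²) + background``.
    """
    bare = smear(lambda qq: bare_reflectivity(sample, qq, spin), q, dq_over_q)
    return sample.scale * bare + sample.background


def critical_edge(superphase_sld: float, substrate_sld: float) -> float:
    """Critical Q (Å⁻¹) of a bare interface; SLDs in 1e-6 Å⁻²."""
    delta = (substrate_sld - superphase_sld) * SLD_UNIT
    if delta <= 0:
        return 0.0
    return 4.0 * math.sqrt(math.pi * delta)
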