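"""Time-of-flight instrument model.

A white-beam reflectometer measures a whole Q range in one shot: at a
fixed angle θ each neutron wavelength λ maps to a single momentum
transfer Q = 4π sin θ / λ.  The instrument is characterised by its
incident flux versus wavelength at a reference angle; both collimation
apertures are opened linearly with angle to keep a constant footprint on
the sample, which scales the incident flux by (θ/θ_ref)².

A synthetic Maxwellian-like flux generator stands in for a measured
instrument table; measured two-column tables load unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .reflectivity import momentum_transfer

DEFAULT_BAND = (1.0, 14.0)  # Å, white-beam wavelength band
DEFAULT_THETA_REF = 0.3  # degrees; footprint (60 mm) absorbed into normalization
DEFAULT_TOTAL_RATE = 5e5  # neutrons/s over the band at theta_ref


class InstrumentError(ValueError):
    pass


@dataclass
class FluxProfile:
    """Incident neutrons per second per wavelength bin at ``theta_ref``."""

    wavelength_edges: np.ndarray
    flux: np.ndarray
    polarized: bool = False
    theta_ref: float = DEFAULT_THETA_REF

    def __post_init__(self) -> None:
        self.wavelength_edges = np.asarray(self.wavelength_edges, dtype=float)
        self.flux = np.asarray(self.flux, dtype=float)
        if len(self.flux) != len(self.wavelength_edges) - 1:
            raise InstrumentError("flux needs exactly one value per wavelength bin")
        if np.any(np.diff(self.wavelength_edges) <= 0):
            raise InstrumentError("wavelength edges must be strictly increasing")
        if np.any(self.flux < 0):
            raise InstrumentError("flux must be non-negative")

    @property
    def band(self) -> tuple[float, float]:
        return float(self.wavelength_edges[0]), float(self.wavelength_edges[-1])

    @property
    def centres(self) -> np.ndarray:
        return 0.5 * (self.wavelength_edges[:-1] + self.wavelength_edges[1:])

    def density(self) -> np.ndarray:
        """Flux per unit wavelength (neutrons s⁻¹ Å⁻¹) in each bin."""
        return self.flux / np.diff(self.wavelength_edges)

    def integrate(self, lo: float, hi: float) -> float:
        """Rate (neutrons/s) in the wavelength interval [lo, hi].

        The profile is treated as piecewise constant in density; the
        interval must lie within the profile support.
        """
        if lo > hi:
            lo, hi = hi, lo
        e = self.wavelength_edges
        if lo < e[0] - 1e-9 or hi > e[-1] + 1e-9:
            raise InstrumentError(
                f"wavelength interval [{lo:.3f}, {hi:.3f}] outside profile band {self.band}"
            )
        return float(np.diff(self.integrate_many(np.array([lo, hi])))[0])

    def integrate_many(self, points: np.ndarray) -> np.ndarray:
        """Cumulative rate from the band start to each wavelength in ``points``."""
        e = self.wavelength_edges
        cum = np.concatenate([[0.0], np.cumsum(self.flux)])
        return np.interp(np.clip(points, e[0], e[-1]), e, cum)


@dataclass
class MeasurementCondition:
    """One cell of an experiment design: angle, time, contrast, spin."""

    angle: float
    time: float
    n_points: int = 100
    contrast_sld: float | None = None
    spin: str = "unpolarized"

    def __post_init__(self) -> None:
        if self.time < 0:
            raise InstrumentError("counting time must be >= 0")
        if self.n_points < 1:
            raise InstrumentError("n_points must be >= 1")
        if not 0 < self.angle < 90:
            raise InstrumentError("angle must lie in (0, 90) degrees")


def angle_scaled_flux(profile: FluxProfile, angle: float) -> np.ndarray:
    """Per-bin flux at ``angle`` under constant-footprint aperture scaling.

    Both apertures scale linearly with angle, so the flux scales with
    (angle / theta_ref)².
    """
    if angle <= 0:
        raise InstrumentError("angle must be > 0")
    return profile.flux * (angle / profile.theta_ref) ** 2


def q_binning(
    condition: MeasurementCondition, wavelength_band: tuple[float, float]
) -> np.ndarray:
    """Log-spaced Q bin edges covering the wavelength band at the angle.

    Returns ``n_points + 1`` strictly increasing edges; each Q bin maps
    back to a unique wavelength sub-interval at the given angle.
    """
    lo, hi = wavelength_band
    if not 0 < lo < hi:
        raise InstrumentError("wavelength band must satisfy 0 < lo < hi")
    qmin = momentum_transfer(hi, condition.angle)
    qmax = momentum_transfer(lo, condition.angle)
    return np.geomspace(qmin, qmax, condition.n_points + 1)


def bin_incident_rate(
    profile: FluxProfile, condition: MeasurementCondition, q_edges: np.ndarray
) -> np.ndarray:
    """Incident rate (neutrons/s) arriving in each Q bin at the condition angle."""
    lam_edges = 4.0 * np.pi * np.sin(np.radians(condition.angle)) / q_edges
    lo, hi = profile.band
    if lam_edges[-1] < lo - 1e-9 or lam_edges[0] > hi + 1e-9:
        raise InstrumentError(
            "Q bin edges map outside the flux profile's wavelength band"
        )
    scale = (condition.angle / profile.theta_ref) ** 2
    cum = profile.integrate_many(lam_edges)  # descending in k
    return (cum[:-1] - cum[1:]) * scale


def synthesize_flux(
    band: tuple[float, float] = DEFAULT_BAND,
    total_rate: float = DEFAULT_TOTAL_RATE,
    polarized: bool = False,
    n_bins: int = 100,
    theta_ref: float = DEFAULT_THETA_REF,
) -> FluxProfile:
    """Generate a smooth, unimodal white-beam flux profile.

    The spectrum is Maxwellian-like in wavelength, φ(λ) ∝ λ⁻⁵
    exp(−(λ_T/λ)²) with λ_T = 4 Å (peak near 2.5 Å), normalized so the
    *unpolarized* spectrum integrates to ``total_rate`` over the band.
    ``polarized=True`` multiplies bins by a smooth polarizer
    transmission that suppresses low wavelengths, so the polarized
    profile is binwise ≤ its unpolarized counterpart.
    """
    lo, hi = band
    if not 0 < lo < hi:
        raise InstrumentError("band must satisfy 0 < lo < hi")
    if total_rate <= 0:
        raise InstrumentError("total_rate must be > 0")
    edges = np.linspace(lo, hi, n_bins + 1)
    centres = 0.5 * (edges[:-1] + edges[1:])
    lam_t = 4.0
    dens = centres**-5 * np.exp(-((lam_t / centres) ** 2))
    flux = dens * np.diff(edges)
    flux *= total_rate / flux.sum()
    if polarized:
        # smooth cut-on around 3.5 Å; floor transmission 5 %
        trans = 0.05 + 0.95 / (1.0 + np.exp(-(centres - 3.5) / 0.6))
        flux = flux * np.minimum(trans, 1.0)
    return FluxProfile(edges, flux, polarized=polarized, theta_ref=theta_ref)


def save_flux(profile: FluxProfile, path: str | Path) -> None:
    """Write a two-column ASCII flux table (bin centre Å, rate s⁻¹).

    Bin edges and metadata are kept in '#' comment lines so the table
    round-trips exactly while staying readable by generic tools.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# wavelength-bin centre (A)   rate (neutrons/s)\n")
        fh.write(f"# theta_ref = {profile.theta_ref!r}\n")
        fh.write(f"# polarized = {profile.polarized}\n")
        fh.write(
            "# edges = " + json.dumps([repr(float(e)) for e in profile.wavelength_edges]) + "\n"
        )
        for c, f in zip(profile.centres, profile.flux):
            fh.write(f"{float(c)!r} {float(f)!r}\n")


def load_flux(path: str | Path, theta_ref: float | None = None) -> FluxProfile:
    """Read a two-column ASCII flux table.

    Accepts both tables written by :func:`save_flux` (exact round-trip
    via the edge comment) and plain instrument tables, for which bin
    edges are reconstructed at the midpoints between centres.
    """
    path = Path(path)
    centres, flux = [], []
    edges = None
    polarized = False
    ref = theta_ref
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("edges ="):
                edges = np.array([float(x) for x in json.loads(body[7:].strip())])
            elif body.startswith("theta_ref =") and ref is None:
                ref = float(body.split("=", 1)[1])
            elif body.startswith("polarized ="):
                polarized = body.split("=", 1)[1].strip().lower() == "true"
            continue
        parts = line.split()
        if len(parts) < 2:
            raise InstrumentError(f"{path}:{lineno}: expected two columns, got {line!r}")
        centres.append(float(parts[0]))
        flux.append(float(parts[1]))
    if not centres:
        raise InstrumentError(f"{path}: no data rows")
    centres_arr = np.asarray(centres)
    if edges is None:
        inner = 0.5 * (centres_arr[:-1] + centres_arr[1:])
        first = centres_arr[0] - (inner[0] - centres_arr[0])
        last = centres_arr[-1] + (centres_arr[-1] - inner[-1])
        edges = np.concatenate([[first], inner, [last]])
    return FluxProfile(
        edges,
        np.asarray(flux),
        polarized=polarized,
        theta_ref=DEFAULT_THETA_REF if ref is None else ref,
    )
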