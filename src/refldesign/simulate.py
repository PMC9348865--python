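"""Counting-statistics experiment simulation.

Expected neutron counts per Q bin are the product of the model
reflectivity, the (angle- and time-scaled) incident counts in the bin's
wavelength sub-interval, and the counting time.  Observed counts are
Poisson realizations; reflectivity datasets are counts normalized by
incident counts, with √N uncertainties.  Data are synthesized without
background subtraction — the constant background lives in the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .instrument import FluxProfile, MeasurementCondition, bin_incident_rate, q_binning
from .reflectivity import Sample, total_reflectivity

DEFAULT_DQ_OVER_Q = 0.02  # constant FWHM dQ/Q resolution


class DatasetParseError(ValueError):
    pass


@dataclass
class CountsModel:
    """Expected (noise-free) counts per Q bin for one measurement condition."""

    q: np.ndarray  # bin centres, Å⁻¹
    dq: np.ndarray  # FWHM resolution widths, Å⁻¹
    expected_counts: np.ndarray
    incident_counts: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.q)
        if not (len(self.dq) == len(self.expected_counts) == len(self.incident_counts) == n):
            raise ValueError("CountsModel arrays must share one length")
        if np.any(self.expected_counts < 0):
            raise ValueError("expected counts must be >= 0")


@dataclass
class ReflectivityDataset:
    """A (Q, R, dR, dQ) curve plus provenance metadata."""

    q: np.ndarray
    r: np.ndarray
    dr: np.ndarray
    dq: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)


def expected_counts(
    sample: Sample,
    condition: MeasurementCondition,
    flux_profile: FluxProfile,
    dq_over_q: float = DEFAULT_DQ_OVER_Q,
) -> CountsModel:
    """Expected counts λ_k = R_tot(Q_k) · incident_k(angle) · time.

    ``condition.contrast_sld`` (if set) re-targets the sample's bulk
    solvent before the reflectivity is evaluated; ``condition.spin``
    selects the polarized channel.
    """
    if condition.contrast_sld is not None:
        sample = sample.with_contrast(condition.contrast_sld)
    edges = q_binning(condition, flux_profile.band)
    centres = np.sqrt(edges[:-1] * edges[1:])  # geometric mean of log-spaced edges
    incident = bin_incident_rate(flux_profile, condition, edges) * condition.time
    r_tot = total_reflectivity(sample, centres, dq_over_q, condition.spin)
    return CountsModel(
        q=centres,
        dq=dq_over_q * centres,
        expected_counts=r_tot * incident,
        incident_counts=incident,
    )


def realize(
    counts_model: CountsModel, seed: int | np.random.Generator, metadata: dict | None = None
) -> ReflectivityDataset:
    """Poisson-realize a counts model into a reflectivity dataset.

    ``r = n/incident`` and ``dr = √n/incident``; zero-count bins are
    kept, with dr set by a single-count floor so log-scale fitting stays
    possible.  The seed is mandatory: identical (seed, λ) give identical
    datasets.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam = counts_model.expected_counts
    n = rng.poisson(lam).astype(float)
    n[lam == 0.0] = 0.0
    incident = counts_model.incident_counts
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(incident > 0, n / incident, 0.0)
        dr = np.where(incident > 0, np.sqrt(np.maximum(n, 1.0)) / incident, 0.0)
    md = dict(metadata or {})
    return ReflectivityDataset(
        q=counts_model.q.copy(), r=r, dr=dr, dq=counts_model.dq.copy(), metadata=md
    )


def simulate_dataset(
    sample: Sample,
    condition: MeasurementCondition,
    flux_profile: FluxProfile,
    seed: int | np.random.Generator,
    dq_over_q: float = DEFAULT_DQ_OVER_Q,
) -> ReflectivityDataset:
    """Convenience: expected counts then one Poisson realization."""
    cm = expected_counts(sample, condition, flux_profile, dq_over_q)
    md = {
        "angle": condition.angle,
        "time": condition.time,
        "contrast_sld": condition.contrast_sld,
        "spin": condition.spin,
    }
    if isinstance(seed, (int, np.integer)):
        md["seed"] = int(seed)
    return realize(cm, seed, metadata=md)


def write_dataset(dataset: ReflectivityDataset, path: str | Path) -> None:
    """Write a 3/4-column ASCII file (Q, R, dR[, dQ]) with '#' metadata header."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in dataset.metadata.items():
            fh.write(f"# {key} = {val}\n")
        cols = "Q (1/A)  R  dR" + ("  dQ (FWHM, 1/A)" if dataset.dq is not None else "")
        fh.write(f"# {cols}\n")
        for i in range(len(dataset.q)):
            row = [dataset.q[i], dataset.r[i], dataset.dr[i]]
            if dataset.dq is not None:
                row.append(dataset.dq[i])
            fh.write(" ".join(f"{v:.12e}" for v in row) + "\n")


def read_dataset(path: str | Path) -> ReflectivityDataset:
    """Read a 3/4-column ASCII reflectivity file.

    Three columns → dQ treated as absent.  Malformed lines raise
    :class:`DatasetParseError` naming the line number.
    """
    path = Path(path)
    metadata: dict = {}
    rows: list[list[float]] = []
    ncols = None
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                metadata[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) not in (3, 4):
            raise DatasetParseError(f"{path}:{lineno}: expected 3 or 4 columns, got {len(parts)}")
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise DatasetParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
        if ncols is None:
            ncols = len(vals)
        elif len(vals) != ncols:
            raise DatasetParseError(f"{path}:{lineno}: inconsistent column count")
        rows.append(vals)
    if not rows:
        raise DatasetParseError(f"{path}: no data rows")
    arr = np.asarray(rows)
    dq = arr[:, 3] if ncols == 4 else None
    return ReflectivityDataset(q=arr[:, 0], r=arr[:, 1], dr=arr[:, 2], dq=dq, metadata=metadata)
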