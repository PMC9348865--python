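"""Fisher information for Poisson-counted reflectivity experiments.

For independent Poisson-distributed Q bins with expected counts λ_k(θ),
the Fisher information matrix over model parameters θ is

    G_ij = Σ_k (1/λ_k) (∂λ_k/∂θ_i) (∂λ_k/∂θ_j),

summed over every bin of every measurement condition (angles, contrasts,
spin states, kinetic snapshots — the FI is additive over independent
measurements).  Its units are nats per (parameter unit)², so parameters
of different units are brought onto a common scale by a congruence with
an importance-weight diagonal, D G D with D = diag(w_i); the default
w_i = |θ_i| makes the scaled matrix dimensionless (equal importance per
fractional change).  The design objective is the smallest eigenvalue of
the scaled matrix — maximizing it is a maximin (E-optimal) criterion
that improves the worst-determined combination of parameters — and the
Cramér–Rao bound maps the matrix back to parameter uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .instrument import FluxProfile, MeasurementCondition
from .reflectivity import Parameter
from .samples import ParametricModel
from .simulate import DEFAULT_DQ_OVER_Q, expected_counts

REL_STEP = 1e-3  # relative central-difference step
ABS_STEP_FLOOR = 1e-8
IMPORTANCE_FLOOR = 1e-8  # |value| fallback for parameters at exactly zero


class FisherError(ValueError):
    pass


@dataclass
class FisherResult:
    """Importance-scaled FI with its eigen-decomposition."""

    parameters: list[Parameter]
    raw_matrix: np.ndarray  # nats per parameter-unit²
    matrix: np.ndarray  # importance-scaled, dimensionless with default weights
    eigenvalues: np.ndarray  # ascending
    importance: np.ndarray

    @property
    def min_eigenvalue(self) -> float:
        return float(self.eigenvalues[0])


def _default_importance(parameters: Sequence[Parameter]) -> np.ndarray:
    out = []
    for p in parameters:
        if p.importance is not None:
            if p.importance <= 0:
                raise FisherError(f"parameter {p.name!r}: importance must be > 0")
            out.append(p.importance)
        else:
            out.append(max(abs(p.value), IMPORTANCE_FLOOR))
    return np.asarray(out)


def expected_counts_vector(
    model: ParametricModel,
    conditions: Sequence[MeasurementCondition],
    flux: FluxProfile,
    dq_over_q: float = DEFAULT_DQ_OVER_Q,
) -> np.ndarray:
    """Concatenated λ_k over every bin of every condition, at current parameters."""
    parts = [
        expected_counts(model.build(), c, flux, dq_over_q).expected_counts for c in conditions
    ]
    return np.concatenate(parts)


def _lambda_and_gradients(
    model: ParametricModel,
    conditions: Sequence[MeasurementCondition],
    flux: FluxProfile,
    parameters: Sequence[Parameter],
    dq_over_q: float,
) -> tuple[np.ndarray, np.ndarray]:
    """λ_k and ∂λ_k/∂θ_i by central differences, evaluated batch-wise.

    Builds one perturbed Sample per stencil point (base, ±h for every
    parameter) and evaluates them together with the vectorized Abelès
    kernel, condition by condition.  Numerically identical to repeated
    :func:`expected_counts` calls.
    """
    from .reflectivity import batch_total_reflectivity
    from .instrument import bin_incident_rate, q_binning

    steps = []
    builds = [model.build()]
    for p in parameters:
        v0 = p.value
        h = max(REL_STEP * abs(v0), ABS_STEP_FLOOR)
        steps.append(h)
        try:
            p.value = v0 + h
            builds.append(model.build())
            p.value = v0 - h
            builds.append(model.build())
        finally:
            p.value = v0

    lam_parts = []
    for cond in conditions:
        samples = (
            [s.with_contrast(cond.contrast_sld) for s in builds]
            if cond.contrast_sld is not None
            else builds
        )
        edges = q_binning(cond, flux.band)
        centres = np.sqrt(edges[:-1] * edges[1:])
        incident = bin_incident_rate(flux, cond, edges) * cond.time
        r_tot = batch_total_reflectivity(samples, centres, dq_over_q, cond.spin)
        lam_parts.append(r_tot * incident[None, :])
    lam_all = np.concatenate(lam_parts, axis=1)

    lam = lam_all[0]
    grads = np.empty((len(parameters), lam_all.shape[1]))
    for i, (p, h) in enumerate(zip(parameters, steps)):
        grads[i] = (lam_all[1 + 2 * i] - lam_all[2 + 2 * i]) / (2.0 * h)
        if not np.all(np.isfinite(grads[i])):
            raise FisherError(f"non-finite gradient for parameter {p.name!r}")
    return lam, grads


def importance_scale(raw_matrix: np.ndarray, parameters: Sequence[Parameter]) -> np.ndarray:
    """Congruence D·G·D with D = diag(importance weights).

    Positive semidefiniteness is preserved; all-unit weights return the
    raw matrix unchanged.
    """
    w = _default_importance(parameters)
    return raw_matrix * np.outer(w, w)


def fisher_matrix(
    model: ParametricModel,
    conditions: Sequence[MeasurementCondition],
    flux: FluxProfile,
    dq_over_q: float = DEFAULT_DQ_OVER_Q,
) -> FisherResult:
    """Poisson FI over all varying parameters of the model.

    Bins with λ_k = 0 contribute zero information (the Poisson FI
    limit), not NaN.  The matrix is symmetrized against round-off and
    eigen-decomposed with a symmetric solver.
    """
    params = model.varying_parameters()
    if not params:
        raise FisherError("model has no varying parameters")
    lam, grads = _lambda_and_gradients(model, conditions, flux, params, dq_over_q)
    if np.any(lam < 0):
        raise FisherError("negative expected counts")
    mask = lam > 0
    inv_lam = np.zeros_like(lam)
    inv_lam[mask] = 1.0 / lam[mask]
    raw = (grads * inv_lam) @ grads.T
    raw = 0.5 * (raw + raw.T)
    scaled = importance_scale(raw, params)
    eigenvalues = np.linalg.eigvalsh(scaled)
    return FisherResult(
        parameters=list(params),
        raw_matrix=raw,
        matrix=scaled,
        eigenvalues=eigenvalues,
        importance=_default_importance(params),
    )


def min_eigenvalue(result: FisherResult) -> float:
    """The design objective; pass its negative to a minimizer."""
    return result.min_eigenvalue


@dataclass
class CRBUncertainties:
    """Cramér–Rao lower bounds derived from a Fisher matrix."""

    sigma: np.ndarray  # per-parameter, native units
    sigma_scaled: np.ndarray  # per-parameter, fractional (importance) units
    worst_combination: float  # 1/sqrt(min eigenvalue of the scaled matrix)


def crb_uncertainties(result: FisherResult) -> CRBUncertainties:
    """Lower-bound standard deviations from the FI.

    Per-parameter bounds are √ of the diagonal of the inverse matrix
    (native units from the raw matrix, fractional units from the scaled
    one); a singular matrix yields unbounded (inf) per-parameter bounds
    while the worst-combination bound, min_eigenvalue^{-1/2}, is still
    returned.
    """
    n = len(result.parameters)
    try:
        inv_raw = np.linalg.inv(result.raw_matrix)
        inv_scaled = np.linalg.inv(result.matrix)
        sigma = np.sqrt(np.abs(np.diag(inv_raw)))
        sigma_scaled = np.sqrt(np.abs(np.diag(inv_scaled)))
    except np.linalg.LinAlgError:
        sigma = np.full(n, np.inf)
        sigma_scaled = np.full(n, np.inf)
    min_eig = result.min_eigenvalue
    worst = float(1.0 / np.sqrt(min_eig)) if min_eig > 0 else np.inf
    return CRBUncertainties(sigma=sigma, sigma_scaled=sigma_scaled, worst_combination=worst)


def kinetic_fisher(
    snapshots: Sequence[ParametricModel],
    per_step_condition: MeasurementCondition,
    flux: FluxProfile,
    parameter: str,
    dq_over_q: float = DEFAULT_DQ_OVER_Q,
) -> float:
    """Scalar FI of one tracked parameter summed over a kinetic series.

    Each snapshot (e.g. one APM value of a degrading monolayer) is an
    independent measurement under ``per_step_condition``; the total FI
    over the whole series quantifies the maximum information obtainable
    about the tracked parameter from the full experiment.
    """
    if not snapshots:
        raise FisherError("empty snapshot sequence")
    total = 0.0
    for snap in snapshots:
        p = snap.param(parameter)
        lam, grads = _lambda_and_gradients(snap, [per_step_condition], flux, [p], dq_over_q)
        mask = lam > 0
        total += float(np.sum(grads[0][mask] ** 2 / lam[mask]))
    return total
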