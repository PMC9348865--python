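"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's own code paths: the Parratt
recursion checks the Abelès kernel, dense quadrature checks the fixed
17-point smearing, and the observed-information average checks the
analytic Poisson Fisher matrix.
"""

from __future__ import annotations

import numpy as np


def parratt_reflectivity(q, slds, thicknesses, roughnesses):
    """Parratt recursive reflectance for a stack of media.

    ``slds`` complex Å⁻² (superphase first), ``thicknesses`` one per
    medium (outer two ignored), ``roughnesses`` one per interface with
    Nevot–Croce attenuation.
    """
    q = np.asarray(q, dtype=float).reshape(-1)
    slds = np.asarray(slds)
    k = np.sqrt((q[:, None] / 2.0) ** 2 - 4.0 * np.pi * (slds[None, :] - slds[0]) + 0j)
    r = np.zeros(len(q), dtype=complex)
    n_interfaces = len(slds) - 1
    for i in range(n_interfaces - 1, -1, -1):
        f = (k[:, i] - k[:, i + 1]) / (k[:, i] + k[:, i + 1])
        f = f * np.exp(-2.0 * k[:, i] * k[:, i + 1] * roughnesses[i] ** 2)
        if i == n_interfaces - 1:
            r = f
        else:
            phase = np.exp(2j * k[:, i + 1] * thicknesses[i + 1])
            r = (f + r * phase) / (1.0 + f * r * phase)
    return np.abs(r) ** 2


def dense_gaussian_smear(model_r, q, dq_over_q, n_points=501, width=3.5):
    """Brute-force constant-dQ/Q Gaussian smearing on a dense trapezoid grid."""
    q = np.asarray(q, dtype=float).reshape(-1)
    sigma = dq_over_q / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = np.linspace(-width, width, n_points)
    kernel = np.exp(-0.5 * t**2)
    out = np.empty_like(q)
    for i, qi in enumerate(q):
        qs = qi * (1.0 + t * sigma)
        out[i] = np.trapezoid(kernel * model_r(qs), t) / np.trapezoid(kernel, t)
    return out


def observed_information_mc(lam, grads, hess, n_datasets, rng):
    """Monte-Carlo average of the observed information of a Poisson model.

    For counts n ~ Poisson(λ(θ)), the observed information is
    −∂²ij log L = Σ_k [ n_k (∂iλ ∂jλ / λ² − ∂²ijλ / λ) + ∂²ijλ ].
    Averaged over datasets this estimates the Fisher matrix.  ``grads``
    has shape (P, K), ``hess`` shape (P, P, K).
    """
    n_params, n_bins = grads.shape
    counts = rng.poisson(lam, size=(n_datasets, n_bins))
    nbar = counts.mean(axis=0)
    info = np.empty((n_params, n_params))
    for i in range(n_params):
        for j in range(n_params):
            coeff = grads[i] * grads[j] / lam**2 - hess[i, j] / lam
            info[i, j] = np.sum(nbar * coeff + hess[i, j])
    return info
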