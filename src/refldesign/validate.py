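"""Likelihood-based validation of designs and Fisher predictions.

Provides a Gaussian log-likelihood of a reflectivity dataset under a
model, the log likelihood-ratio between a moment and a null model as a
function of counting time (detectability of a small induced magnetic
moment), and a brute-force two-parameter grid posterior used as ground
truth against the Cramér–Rao bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .design import time_budget_split
from .instrument import FluxProfile, MeasurementCondition
from .reflectivity import Sample, total_reflectivity
from .samples import ParametricModel
from .simulate import DEFAULT_DQ_OVER_Q, ReflectivityDataset, expected_counts, realize

POLARIZED_ANGLES = (0.5, 1.0, 2.0)  # degrees, standard polarized setup
POLARIZED_TIME_FRACTIONS = (1.0, 2.0, 4.0)  # 30 : 60 : 120 min


class ValidationError(ValueError):
    pass


def log_likelihood(
    dataset: ReflectivityDataset,
    sample: Sample,
    dq_over_q: float = DEFAULT_DQ_OVER_Q,
    spin: str = "unpolarized",
) -> float:
    """Gaussian log-likelihood −½ Σ [(R_i − R_model(Q_i)) / δR_i]².

    The additive normalization constant is omitted — it cancels in every
    likelihood ratio used here.  Maximal (zero) when the model
    reproduces the data exactly.
    """
    if np.any(dataset.dr <= 0):
        raise ValidationError("all dR must be > 0 for the Gaussian likelihood")
    r_model = total_reflectivity(sample, dataset.q, dq_over_q, spin)
    return float(-0.5 * np.sum(((dataset.r - r_model) / dataset.dr) ** 2))


@dataclass
class LikelihoodScanResult:
    times: np.ndarray  # seconds per measured spin state
    log_ratio: np.ndarray  # mean over replicates
    log_ratio_sd: np.ndarray
    seed: int


def likelihood_ratio_vs_time(
    sample_with_moment: ParametricModel | Sample,
    sample_null: ParametricModel | Sample,
    times: Sequence[float],
    flux: FluxProfile,
    n_reps: int = 50,
    seed: int = 0,
    angles: Sequence[float] = POLARIZED_ANGLES,
    angle_fractions: Sequence[float] = POLARIZED_TIME_FRACTIONS,
    n_points: int = 100,
    dq_over_q: float = DEFAULT_DQ_OVER_Q,
) -> LikelihoodScanResult:
    """Mean log L(moment) − log L(null) versus counting time.

    For each total time (per measured spin state), data for both
    non-spin-flip channels at each angle are simulated from the *moment*
    model and scored under both models; the correct model should grow
    more likely with time.  Zero-count bins (dr = 0 impossible by the
    single-count floor) are retained.
    """
    def as_sample(m):
        return m.build() if isinstance(m, ParametricModel) else m

    s_moment, s_null = as_sample(sample_with_moment), as_sample(sample_null)
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    means, sds = [], []
    for t in times:
        per_angle = time_budget_split(angle_fractions, t)
        conds = [
            MeasurementCondition(angle=a, time=ta, n_points=n_points, spin=spin)
            for a, ta in zip(angles, per_angle)
            for spin in ("up", "down")
        ]
        # expected counts and model curves are condition-, not replicate-, dependent
        cms = [expected_counts(s_moment, c, flux, dq_over_q) for c in conds]
        r_m = [
            total_reflectivity(s_moment, cm.q, dq_over_q, c.spin) for c, cm in zip(conds, cms)
        ]
        r_0 = [total_reflectivity(s_null, cm.q, dq_over_q, c.spin) for c, cm in zip(conds, cms)]
        ratios = np.empty(n_reps)
        for rep in range(n_reps):
            acc = 0.0
            for cm, rm, r0 in zip(cms, r_m, r_0):
                ds = realize(cm, rng)
                good = ds.dr > 0
                acc += -0.5 * np.sum(((ds.r[good] - rm[good]) / ds.dr[good]) ** 2)
                acc -= -0.5 * np.sum(((ds.r[good] - r0[good]) / ds.dr[good]) ** 2)
            ratios[rep] = acc
        means.append(ratios.mean())
        sds.append(ratios.std(ddof=1) if n_reps > 1 else 0.0)
    return LikelihoodScanResult(
        times=times, log_ratio=np.asarray(means), log_ratio_sd=np.asarray(sds), seed=seed
    )


@dataclass
class GridPosterior:
    grids: tuple[np.ndarray, np.ndarray]
    posterior: np.ndarray  # normalized to sum 1
    sigma: tuple[float, float]  # marginal standard deviations
    mean: tuple[float, float]


def grid_posterior(
    datasets: Sequence[ReflectivityDataset] | ReflectivityDataset,
    model: ParametricModel,
    parameter_names: Sequence[str],
    grids: Sequence[np.ndarray],
    dq_over_q: float = DEFAULT_DQ_OVER_Q,
) -> GridPosterior:
    """Brute-force posterior over two parameters with flat priors on the grid.

    The posterior is ∝ exp(log-likelihood) summed over the supplied
    datasets (each dataset's contrast/spin read from its metadata).
    A warning is emitted when more than 1% of the posterior mass sits on
    the grid boundary.
    """
    if len(parameter_names) != 2 or len(grids) != 2:
        raise ValidationError("grid_posterior needs exactly two free parameters")
    if isinstance(datasets, ReflectivityDataset):
        datasets = [datasets]
    p1, p2 = (model.param(name) for name in parameter_names)
    g1, g2 = (np.asarray(g, dtype=float) for g in grids)
    v1_0, v2_0 = p1.value, p2.value
    ll = np.empty((len(g1), len(g2)))
    try:
        for i, a in enumerate(g1):
            p1.value = float(a)
            for j, b in enumerate(g2):
                p2.value = float(b)
                acc = 0.0
                for ds in datasets:
                    contrast = ds.metadata.get("contrast_sld")
                    contrast = None if contrast in (None, "None") else float(contrast)
                    spin = ds.metadata.get("spin", "unpolarized")
                    acc += log_likelihood(ds, model.build(contrast), dq_over_q, spin)
                ll[i, j] = acc
    finally:
        p1.value, p2.value = v1_0, v2_0
    post = np.exp(ll - ll.max())
    post /= post.sum()
    boundary = post[0, :].sum() + post[-1, :].sum() + post[:, 0].sum() + post[:, -1].sum()
    boundary -= post[0, 0] + post[0, -1] + post[-1, 0] + post[-1, -1]
    if boundary > 0.01:
        warnings.warn(
            f"{boundary:.1%} of posterior mass on the grid boundary; widen the grid",
            stacklevel=2,
        )
    m1 = post.sum(axis=1)
    m2 = post.sum(axis=0)
    mean1 = float(np.sum(m1 * g1))
    mean2 = float(np.sum(m2 * g2))
    sd1 = float(np.sqrt(np.sum(m1 * (g1 - mean1) ** 2)))
    sd2 = float(np.sqrt(np.sum(m2 * (g2 - mean2) ** 2)))
    return GridPosterior(grids=(g1, g2), posterior=post, sigma=(sd1, sd2), mean=(mean1, mean2))
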