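"""Constrained search over experimental conditions.

The objective is the minimum eigenvalue of the importance-scaled Fisher
information computed from noise-free expected counts (the exact
large-time-budget limit, so landscapes are deterministic).  1D/2D grid
scans visualize the optimization space; differential evolution (DE)
performs the joint search over contrast SLDs (or angles, or underlayer
properties) together with the split of a fixed total counting-time
budget, the split living on the probability simplex via renormalized
non-negative weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import differential_evolution

from .fisher import fisher_matrix, kinetic_fisher
from .instrument import FluxProfile, MeasurementCondition
from .samples import CONTRAST_BOUNDS, ContrastBilayer, ParametricModel, Underlayer, with_underlayer

ANGLE_BOUNDS = (0.2, 4.0)  # degrees, realistic white-beam reflectometer limits
DEFAULT_ANGLES = (0.7, 2.3)
DEFAULT_ANGLE_FRACTIONS = (0.2, 0.8)  # 15 min : 60 min
DE_DEFAULTS = dict(strategy="best1bin", popsize=15, tol=0.01, maxiter=200, polish=True)
MERGE_TOLERANCE = 0.05  # 1e-6 Å⁻²: near-identical contrasts are reported merged


class DesignError(ValueError):
    pass


@dataclass
class DesignSpace:
    """Bounds and structure of a design search."""

    angle_bounds: tuple[float, float] = ANGLE_BOUNDS
    contrast_bounds: tuple[float, float] = CONTRAST_BOUNDS
    underlayer_sld_bounds: tuple[float, float] = Underlayer.SLD_BOUNDS
    underlayer_thickness_bounds: tuple[float, float] = Underlayer.THICKNESS_BOUNDS
    n_contrasts: int = 2
    n_angles: int = 2
    n_underlayers: int = 0
    time_budget: float = 4500.0  # seconds
    angles: tuple[float, ...] = DEFAULT_ANGLES
    angle_fractions: tuple[float, ...] = DEFAULT_ANGLE_FRACTIONS
    contrasts: tuple[float, ...] = (6.36, -0.56)
    contrast_fractions: tuple[float, ...] | None = None
    n_points: int = 100
    shared_angles_across_contrasts: bool = True
    optimize_what: str = "contrasts"  # contrasts | angles | underlayers


@dataclass
class DesignResult:
    """Optimal conditions and the recomputed objective."""

    contrasts: list[float]
    time_fractions: list[float]
    angles: list[float]
    angle_fractions: list[float]
    underlayers: list[Underlayer]
    objective: float  # minimum eigenvalue at the returned conditions
    trace: list[float]  # per-generation best objective
    seed: int | None = None

    def merged_contrasts(self, tol: float = MERGE_TOLERANCE) -> list[tuple[float, float]]:
        """(contrast, summed time fraction) with near-identical SLDs combined."""
        pairs = sorted(zip(self.contrasts, self.time_fractions))
        merged: list[list[float]] = []
        for c, f in pairs:
            if merged and abs(c - merged[-1][0]) <= tol:
                tot = merged[-1][1] + f
                if tot > 0:
                    merged[-1][0] = (merged[-1][0] * merged[-1][1] + c * f) / tot
                merged[-1][1] = tot
            else:
                merged.append([c, f])
        return [(c, f) for c, f in merged]


def time_budget_split(fractions: Sequence[float], total_time: float) -> np.ndarray:
    """Per-condition times from non-negative weights on the simplex.

    Weights are renormalized to sum to one, so the returned times sum to
    ``total_time`` to machine precision.
    """
    f = np.asarray(fractions, dtype=float)
    if np.any(f < 0):
        raise DesignError("time fractions must be >= 0")
    s = f.sum()
    if s == 0:
        raise DesignError("at least one time fraction must be positive")
    return f / s * total_time


def build_conditions(
    contrasts: Sequence[float],
    contrast_fractions: Sequence[float],
    angles: Sequence[float],
    angle_fractions: Sequence[float],
    total_time: float,
    n_points: int = 100,
    spins: Sequence[str] = ("unpolarized",),
) -> list[MeasurementCondition]:
    """Expand a (contrast × angle × spin) design into measurement conditions.

    All contrasts share the same angles and the same proportion of time
    between angles; each contrast's share of the budget is further split
    across its angles (and equally across spin states).
    """
    c_times = time_budget_split(contrast_fractions, total_time)
    a_frac = np.asarray(time_budget_split(angle_fractions, 1.0))
    out = []
    for c, tc in zip(contrasts, c_times):
        for a, fa in zip(angles, a_frac):
            for spin in spins:
                out.append(
                    MeasurementCondition(
                        angle=a,
                        time=tc * fa / len(spins),
                        n_points=n_points,
                        contrast_sld=c,
                        spin=spin,
                    )
                )
    return out


def design_objective(
    model: ParametricModel,
    flux: FluxProfile,
    contrasts: Sequence[float],
    contrast_fractions: Sequence[float],
    space: DesignSpace,
) -> float:
    """Minimum eigenvalue of the scaled FI for one candidate design."""
    conditions = build_conditions(
        contrasts,
        contrast_fractions,
        space.angles,
        space.angle_fractions,
        space.time_budget,
        space.n_points,
    )
    return fisher_matrix(model, conditions, flux).min_eigenvalue


def scan_1d(evaluate: Callable[[float], float], grid: Sequence[float]) -> np.ndarray:
    """Deterministic 1D landscape of the objective over a grid."""
    return np.asarray([evaluate(g) for g in grid], dtype=float)


def scan_2d(
    evaluate: Callable[[float, float], float],
    grid_x: Sequence[float],
    grid_y: Sequence[float],
) -> np.ndarray:
    """2D landscape; entry [i, j] is the objective at (grid_x[i], grid_y[j])."""
    return np.asarray([[evaluate(x, y) for y in grid_y] for x in grid_x], dtype=float)


def contrast_scan(
    model: ParametricModel,
    flux: FluxProfile,
    grid: Sequence[float],
    space: DesignSpace,
    fixed_contrasts: Sequence[float] = (),
    fractions: Sequence[float] | None = None,
) -> np.ndarray:
    """Landscape of the objective versus one scanned contrast SLD.

    ``fixed_contrasts`` are already-committed measurements (e.g. D2O and
    H2O when scanning a third contrast); ``fractions`` gives the time
    split over (fixed..., scanned), default equal.
    """
    n = len(fixed_contrasts) + 1
    frac = np.full(n, 1.0 / n) if fractions is None else np.asarray(fractions, dtype=float)

    def evaluate(c: float) -> float:
        return design_objective(model, flux, list(fixed_contrasts) + [c], frac, space)

    return scan_1d(evaluate, grid)


def underlayer_scan(
    bilayer: ContrastBilayer,
    flux: FluxProfile,
    sld_grid: Sequence[float],
    thickness_grid: Sequence[float],
    space: DesignSpace,
) -> np.ndarray:
    """2D landscape over a single underlayer's SLD and thickness."""
    frac = space.contrast_fractions or [1.0 / len(space.contrasts)] * len(space.contrasts)

    def evaluate(sld: float, thickness: float) -> float:
        model = with_underlayer(bilayer, [Underlayer(sld=sld, thickness=thickness)])
        return design_objective(model, flux, space.contrasts, frac, space)

    return scan_2d(evaluate, sld_grid, thickness_grid)


def _run_de(func, bounds, seed, de_settings):
    settings = dict(DE_DEFAULTS)
    settings.update(de_settings or {})
    trace: list[float] = []

    def callback(xk, convergence=0.0):  # noqa: ARG001 - scipy callback signature
        trace.append(-func(xk))

    result = differential_evolution(
        func,
        bounds=bounds,
        seed=seed,
        callback=callback,
        strategy=settings["strategy"],
        popsize=settings["popsize"],
        tol=settings["tol"],
        maxiter=settings["maxiter"],
        polish=settings["polish"],
    )
    return result, trace


def optimize(
    space: DesignSpace,
    model: ParametricModel,
    flux: FluxProfile,
    seed: int = 0,
    de_settings: dict | None = None,
) -> DesignResult:
    """Joint DE search over the design space (negative-min-eigenvalue objective).

    Depending on ``space.optimize_what`` the variables are

    * ``"contrasts"``: n_contrasts solvent SLDs plus their simplex time
      split, at fixed angles/angle split;
    * ``"angles"``: n_angles measurement angles plus their time split,
      at fixed contrasts (by default D2O + H2O);
    * ``"underlayers"``: n_underlayers (SLD, thickness) pairs at fixed
      contrasts and equal contrast times (underlayer parameters are
      nuisance quantities and never enter the FI itself).

    Non-finite objectives during the search are penalized, not fatal.
    """
    mode = space.optimize_what
    budget_frac = space.contrast_fractions

    if mode == "contrasts":
        n = space.n_contrasts
        bounds = [space.contrast_bounds] * n + [(0.01, 1.0)] * n

        def func(x):
            contrasts, weights = x[:n], x[n:]
            try:
                val = design_objective(model, flux, contrasts, weights, space)
            except Exception:
                return np.inf
            return -val if np.isfinite(val) else np.inf

        result, trace = _run_de(func, bounds, seed, de_settings)
        contrasts = list(result.x[:n])
        fractions = list(time_budget_split(result.x[n:], 1.0))
        objective = design_objective(model, flux, contrasts, fractions, space)
        return DesignResult(
            contrasts=contrasts,
            time_fractions=fractions,
            angles=list(space.angles),
            angle_fractions=list(time_budget_split(space.angle_fractions, 1.0)),
            underlayers=[],
            objective=objective,
            trace=trace,
            seed=seed,
        )

    if mode == "angles":
        n = space.n_angles
        contrasts = list(space.contrasts)
        cfrac = budget_frac or [1.0 / len(contrasts)] * len(contrasts)
        bounds = [space.angle_bounds] * n + [(0.01, 1.0)] * n

        def func(x):
            angles, weights = x[:n], x[n:]
            sp = _replace_angles(space, angles, weights)
            try:
                val = design_objective(model, flux, contrasts, cfrac, sp)
            except Exception:
                return np.inf
            return -val if np.isfinite(val) else np.inf

        result, trace = _run_de(func, bounds, seed, de_settings)
        angles = list(result.x[:n])
        afrac = list(time_budget_split(result.x[n:], 1.0))
        objective = design_objective(
            model, flux, contrasts, cfrac, _replace_angles(space, angles, afrac)
        )
        return DesignResult(
            contrasts=contrasts,
            time_fractions=list(cfrac),
            angles=angles,
            angle_fractions=afrac,
            underlayers=[],
            objective=objective,
            trace=trace,
            seed=seed,
        )

    if mode == "underlayers":
        if not isinstance(model, ContrastBilayer):
            raise DesignError("underlayer optimization needs a ContrastBilayer model")
        n = space.n_underlayers
        if n < 1:
            raise DesignError("n_underlayers must be >= 1 for underlayer optimization")
        contrasts = list(space.contrasts)
        cfrac = budget_frac or [1.0 / len(contrasts)] * len(contrasts)
        bounds = [space.underlayer_sld_bounds, space.underlayer_thickness_bounds] * n

        def to_underlayers(x):
            return [Underlayer(sld=x[2 * i], thickness=x[2 * i + 1]) for i in range(n)]

        def func(x):
            try:
                m = with_underlayer(model, to_underlayers(x))
                val = design_objective(m, flux, contrasts, cfrac, space)
            except Exception:
                return np.inf
            return -val if np.isfinite(val) else np.inf

        result, trace = _run_de(func, bounds, seed, de_settings)
        uls = to_underlayers(result.x)
        objective = design_objective(with_underlayer(model, uls), flux, contrasts, cfrac, space)
        return DesignResult(
            contrasts=contrasts,
            time_fractions=list(cfrac),
            angles=list(space.angles),
            angle_fractions=list(time_budget_split(space.angle_fractions, 1.0)),
            underlayers=uls,
            objective=objective,
            trace=trace,
            seed=seed,
        )

    raise DesignError(f"unknown optimize_what {mode!r}")


def _replace_angles(space: DesignSpace, angles, fractions) -> DesignSpace:
    from dataclasses import replace

    return replace(space, angles=tuple(angles), angle_fractions=tuple(fractions))


def kinetic_contrast_scan(
    snapshots: Sequence[ParametricModel],
    flux: FluxProfile,
    grid: Sequence[float],
    angle: float,
    total_time: float,
    parameter: str = "apm",
    n_points: int = 100,
) -> np.ndarray:
    """FI in the tracked kinetic parameter versus solvent contrast SLD.

    Each snapshot gets an equal share of the total budget; the scan is
    deterministic (noise-free expected counts).
    """
    per_step = total_time / len(snapshots)

    def evaluate(contrast: float) -> float:
        cond = MeasurementCondition(
            angle=angle, time=per_step, n_points=n_points, contrast_sld=contrast
        )
        return kinetic_fisher(snapshots, cond, flux, parameter)

    return scan_1d(evaluate, grid)
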