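"""Inverse identification of constitutive parameters from tensile curves.

The anisotropic sheath fit minimises the weighted sum of squared PK2-stress
residuals over both test directions,

    e2 = sum_i [ w1 (S_theta^E - S_theta^M)_i^2 + w2 (S_z^E - S_z^M)_i^2 ],

over (C10, k1, k2, kappa) within physical bounds, using generalized
simulated annealing (best of several seeded restarts) followed by a
bounded local least-squares polish.  Model stresses S^M come from the
uniaxial-stress response (zero transverse PK2) evaluated at the data
abscissae.

Two deterministic companions mirror the isotropic re-analyses: a
single-parameter neo-Hookean fit to the pointwise-averaged curve pair, and
a bounded least-squares refit of reduced-polynomial coefficients to a raw
engineering curve over a restricted strain range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.optimize import dual_annealing, least_squares

from .kinematics import FiberArchitecture
from .models import HolzapfelParams, MaterialModel, ReducedPolynomialParams
from .tension import (
    Direction,
    StrainMeasure,
    StressMeasure,
    StressStrainCurve,
    TensileDataset,
    reanalyze_raw_curve,
    uniaxial_response_grid,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "objective_e2",
    "fit_holzapfel_anisotropic",
    "fit_isotropic_ons",
    "fit_reduced_polynomial",
    "r_squared",
]

# Identification bounds: wide enough for ocular connective tissue, tight
# enough to keep the anneal efficient.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "C10": (1e-4, 10.0),     # MPa
    "k1": (1e-4, 1000.0),    # MPa
    "k2": (1e-4, 500.0),     # dimensionless
    "kappa": (0.0, 1.0 / 3.0),
}


@dataclass
class FitConfig:
    """Settings for the annealing fit; defaults match the standard run."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    w1: float = 1.0
    w2: float = 1.0
    n_restarts: int = 5
    seed: int = 0
    polish: bool = True
    max_iterations: int = 150
    alpha1_deg: float = 0.0
    alpha2_deg: float = 90.0

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name} are not well-ordered: ({lo}, {hi})")
        if self.w1 < 0.0 or self.w2 < 0.0 or (self.w1 == 0.0 and self.w2 == 0.0):
            raise ValueError("weights must be non-negative and not both zero")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be at least 1")


@dataclass
class FitResult:
    """Outcome of one identification run."""

    params: MaterialModel
    objective_e2: float
    r_squared: dict[str, float]
    n_evals: int
    seed: int | None
    converged: bool
    bounds: dict[str, tuple[float, float]] | None = None
    n_iterations: int = 0
    details: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.objective_e2 < 0.0:
            raise ValueError("objective must be non-negative")


def r_squared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must be equal-length, size >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R^2 undefined for a constant observed vector")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _require_fit_space(dataset: TensileDataset) -> TensileDataset:
    """Return the dataset in Green-Lagrange / PK2 space, converting raw data."""
    if (
        dataset.strain_measure is StrainMeasure.GREEN_LAGRANGE
        and dataset.stress_measure is StressMeasure.PK2
    ):
        return dataset
    if (
        dataset.strain_measure is StrainMeasure.ENGINEERING
        and dataset.stress_measure is StressMeasure.ENGINEERING
    ):
        return TensileDataset(
            circumferential=reanalyze_raw_curve(dataset.circumferential),
            longitudinal=reanalyze_raw_curve(dataset.longitudinal),
            metadata=dict(dataset.metadata),
        )
    raise ValueError(
        "dataset must be engineering/engineering or green_lagrange/pk2, got "
        f"{dataset.strain_measure.value}/{dataset.stress_measure.value}"
    )


def _stretch_from_green_lagrange(e: np.ndarray) -> np.ndarray:
    return np.sqrt(2.0 * e + 1.0)


def _predicted_pk2(model: MaterialModel, dataset: TensileDataset) -> tuple[np.ndarray, np.ndarray]:
    lam_c = _stretch_from_green_lagrange(dataset.circumferential.strain)
    lam_l = _stretch_from_green_lagrange(dataset.longitudinal.strain)
    s_c, _ = uniaxial_response_grid(model, lam_c, axis="theta")
    s_l, _ = uniaxial_response_grid(model, lam_l, axis="z")
    return s_c, s_l


def objective_e2(
    model: MaterialModel, dataset: TensileDataset, config: FitConfig | None = None
) -> float:
    """Weighted SSE of PK2 stresses over both directions, in MPa^2."""
    config = config or FitConfig()
    dataset = _require_fit_space(dataset)
    s_c, s_l = _predicted_pk2(model, dataset)
    r_c = dataset.circumferential.stress - s_c
    r_l = dataset.longitudinal.stress - s_l
    return float(config.w1 * np.sum(r_c**2) + config.w2 * np.sum(r_l**2))


def _goh_from_vector(x: np.ndarray, config: FitConfig) -> HolzapfelParams:
    c10, k1, k2, kappa = (float(v) for v in x)
    kappa = min(max(kappa, 0.0), 1.0 / 3.0)
    arch = FiberArchitecture(config.alpha1_deg, config.alpha2_deg, kappa)
    return HolzapfelParams(C10=c10, k1=k1, k2=k2, arch=arch, name="fit")


def fit_holzapfel_anisotropic(dataset: TensileDataset, config: FitConfig | None = None) -> FitResult:
    """Identify (C10, k1, k2, kappa) of the shared-moduli GOH model.

    Best of ``config.n_restarts`` generalized-simulated-annealing runs,
    each started from a seeded draw within bounds (log-uniform for the
    scale parameters k1 and k2) and followed, when ``config.polish``, by a
    bounded trust-region least-squares polish of the stress residuals.
    Restart ties within 1e-14 in e2 break toward the smaller k1
    (parsimony).  Fixed ``config.seed`` makes the result reproducible.
    """
    config = config or FitConfig()
    data = _require_fit_space(dataset)
    names = ("C10", "k1", "k2", "kappa")
    bounds = [tuple(config.bounds[n]) for n in names]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    obs_c = data.circumferential.stress
    obs_l = data.longitudinal.stress
    sw1, sw2 = np.sqrt(config.w1), np.sqrt(config.w2)
    n_evals = 0

    def residuals(x: np.ndarray) -> np.ndarray:
        nonlocal n_evals
        n_evals += 1
        model = _goh_from_vector(x, config)
        s_c, s_l = _predicted_pk2(model, data)
        return np.concatenate([sw1 * (obs_c - s_c), sw2 * (obs_l - s_l)])

    def scalar_objective(x: np.ndarray) -> float:
        r = residuals(x)
        with np.errstate(over="ignore"):
            val = float(r @ r)
        # Infeasible corners (clipped fiber exponent) yield astronomically
        # large residuals; cap so the anneal's acceptance arithmetic stays
        # finite while the region remains hopeless.
        if not np.isfinite(val) or val > 1e100:
            return 1e100
        return val

    ss = np.random.SeedSequence(config.seed)
    restart_seeds = [int(s) % (2**31 - 1) for s in ss.generate_state(config.n_restarts)]

    best_x: np.ndarray | None = None
    best_e2 = np.inf
    restart_log = []
    for rs in restart_seeds:
        rng = np.random.default_rng(rs)
        x0 = np.array(
            [
                rng.uniform(lo[0], hi[0]),                            # C10
                np.exp(rng.uniform(np.log(lo[1]), np.log(hi[1]))),    # k1
                np.exp(rng.uniform(np.log(lo[2]), np.log(hi[2]))),    # k2
                rng.uniform(lo[3], hi[3]),                            # kappa
            ]
        )
        sa = dual_annealing(
            scalar_objective,
            bounds=bounds,
            x0=x0,
            seed=rs,
            maxiter=config.max_iterations,
            no_local_search=True,
        )
        x_best, e2 = sa.x, float(sa.fun)
        if config.polish:
            ls = least_squares(
                residuals, x_best, bounds=(lo, hi), method="trf",
                xtol=1e-15, ftol=1e-15, gtol=1e-15,
                x_scale=np.maximum(np.abs(x_best), 1e-3),
            )
            if float(2 * ls.cost) <= e2:
                x_best, e2 = ls.x, float(2 * ls.cost)
        restart_log.append({"seed": rs, "e2": e2, "x": [float(v) for v in x_best]})
        better = e2 < best_e2 - 1e-14
        tied = abs(e2 - best_e2) <= 1e-14 and best_x is not None and x_best[1] < best_x[1]
        if best_x is None or better or tied:
            best_x, best_e2 = x_best, e2

    if best_x is None or not np.isfinite(best_e2):
        raise RuntimeError("all annealing restarts failed to produce a finite objective")

    model = _goh_from_vector(best_x, config)
    s_c, s_l = _predicted_pk2(model, data)
    r2 = {
        "circumferential": r_squared(obs_c, s_c),
        "longitudinal": r_squared(obs_l, s_l),
        "pooled": r_squared(np.concatenate([obs_c, obs_l]), np.concatenate([s_c, s_l])),
    }
    return FitResult(
        params=model,
        objective_e2=best_e2,
        r_squared=r2,
        n_evals=n_evals,
        seed=config.seed,
        converged=bool(np.isfinite(best_e2)),
        bounds={n: b for n, b in zip(names, bounds)},
        n_iterations=config.max_iterations,
        details={"restarts": restart_log},
    )


def average_curves(dataset: TensileDataset) -> StressStrainCurve:
    """Pointwise average of the two directions on a common strain grid.

    The longitudinal curve is linearly interpolated onto the part of the
    circumferential grid covered by both; the averaged curve inherits the
    dataset's measures.
    """
    c, l = dataset.circumferential, dataset.longitudinal
    lo = max(c.strain[0], l.strain[0])
    hi = min(c.strain[-1], l.strain[-1])
    if hi <= lo:
        raise ValueError("curves have non-overlapping strain ranges")
    mask = (c.strain >= lo) & (c.strain <= hi)
    grid = c.strain[mask]
    stress = 0.5 * (c.stress[mask] + np.interp(grid, l.strain, l.stress))
    return StressStrainCurve(
        direction=Direction.AVERAGED,
        strain_measure=c.strain_measure,
        stress_measure=c.stress_measure,
        strain=grid,
        stress=stress,
    )


def fit_isotropic_ons(dataset: TensileDataset, config: FitConfig | None = None) -> FitResult:
    """Neo-Hookean C10 from the averaged circumferential/longitudinal curve.

    The anisotropic term is dropped, leaving a one-parameter model whose
    uniaxial PK2 response is exactly linear in C10; the bounded
    least-squares solution is the projection onto the unit response,
    clipped to the C10 bounds.
    """
    config = config or FitConfig()
    data = _require_fit_space(dataset)
    avg = average_curves(data)
    lam = _stretch_from_green_lagrange(avg.strain)
    unit = ReducedPolynomialParams(C=(1.0,), name="unit neo-Hookean")
    s_unit, _ = uniaxial_response_grid(unit, lam, axis="theta")
    denom = float(s_unit @ s_unit)
    if denom == 0.0:
        raise ValueError("averaged curve has no nonzero strain points")
    c10 = float(s_unit @ avg.stress) / denom
    lo, hi = config.bounds["C10"]
    c10 = min(max(c10, lo), hi)
    model = ReducedPolynomialParams(C=(c10,), name="isotropic ONS")
    pred = c10 * s_unit
    e2 = float(np.sum((avg.stress - pred) ** 2))
    return FitResult(
        params=model,
        objective_e2=e2,
        r_squared={"averaged": r_squared(avg.stress, pred)},
        n_evals=1,
        seed=config.seed,
        converged=True,
        bounds={"C10": (lo, hi)},
        details={"n_points": int(lam.size)},
    )


def fit_reduced_polynomial(
    curve: StressStrainCurve,
    order: int = 2,
    strain_range: tuple[float, float] = (0.0, 0.5),
    x0: tuple[float, ...] | None = None,
) -> FitResult:
    """Bounded least-squares refit of reduced-polynomial coefficients.

    The curve is taken to (or kept in) raw engineering measures, restricted
    to ``strain_range`` in engineering strain, and the coefficients
    (C10[, C20]) are fit against the model's uniaxial engineering-stress
    prediction from a fixed initial guess.  R^2 is reported on the fitted
    ordinate.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if (
        curve.strain_measure is StrainMeasure.GREEN_LAGRANGE
        and curve.stress_measure is StressMeasure.PK2
    ):
        lam_all = _stretch_from_green_lagrange(curve.strain)
        eps_all = lam_all - 1.0
        sig_all = curve.stress * lam_all
    elif (
        curve.strain_measure is StrainMeasure.ENGINEERING
        and curve.stress_measure is StressMeasure.ENGINEERING
    ):
        eps_all = curve.strain
        sig_all = curve.stress
    else:
        raise ValueError("curve must be engineering/engineering or green_lagrange/pk2")

    mask = (eps_all >= strain_range[0]) & (eps_all <= strain_range[1])
    eps, sig = eps_all[mask], sig_all[mask]
    if eps.size <= order:
        raise ValueError(
            f"need more than {order} points in strain range {strain_range}, have {eps.size}"
        )
    lam = 1.0 + eps

    def predict(c: np.ndarray) -> np.ndarray:
        model = ReducedPolynomialParams(C=tuple(np.maximum(c, 1e-12)))
        s_pk2, _ = uniaxial_response_grid(model, lam, axis="theta")
        return s_pk2 * lam  # engineering stress

    x_init = np.asarray(x0 if x0 is not None else (0.1, 1.0)[:order], dtype=float)
    lower = np.full(order, 1e-8)
    upper = np.array([10.0, 500.0])[:order]
    ls = least_squares(
        lambda c: predict(c) - sig, x_init, bounds=(lower, upper),
        method="trf", xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    coeffs = tuple(float(v) for v in ls.x)
    model = ReducedPolynomialParams(C=coeffs, name="refit")
    pred = predict(ls.x)
    return FitResult(
        params=model,
        objective_e2=float(2 * ls.cost),
        r_squared={"curve": r_squared(sig, pred)},
        n_evals=int(ls.nfev),
        seed=None,
        converged=bool(ls.success),
        bounds={"C": (tuple(float(v) for v in lower), tuple(float(v) for v in upper))},
        details={"strain_range": strain_range, "order": order},
    )
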