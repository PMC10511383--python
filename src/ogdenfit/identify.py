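"""Inverse identification of the Ogden parameters m = (mu, alpha).

The forward model G(m) produces the three simulated mode curves on the
experimental abscissa grids; the optimal parameter set minimizes the
normalized squared error

    chi^2 = sum_i (y_exp_i - y_sim_i)^2 / sum_i (y_exp_i)^2

over the concatenated residual vector (compression/tension plus the two
torsion sweeps; all modes contribute 60 points each, so shear is implicitly
weighed 2:1).  The normalization guards against vanishing gradients at
small residuals.  Minimization uses the trust-region-reflective
least-squares algorithm with bound constraints and forward finite
differences; Nelder-Mead (xatol 1e-3, fatol 1e-4) is kept as a fallback.
Forward evaluations are cached by rounded parameter key, and the
independent modes of one evaluation may be computed concurrently with
order-independent results.

The Poisson's ratio is fixed per fit (0.45 or 0.49 in the study design);
with the first/third-cycle curves this yields four parameter sets per
specimen.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.stats import qmc

from .constitutive import (
    OgdenParameters,
    apparent_torsion_stress,
    homogeneous_uniaxial,
)
from .fe import SpecimenGeometry, simulate_axial_test
from .preprocess import ProcessedCurve

__all__ = [
    "FitProblem",
    "FitResult",
    "chi_squared",
    "rmse",
    "forward_residuals",
    "fit_specimen",
    "multi_start",
    "fit_region_average",
    "DEFAULT_BOUNDS",
]

#: (mu, alpha) box constraints; fitted alpha values for brain tissue are
#: strongly negative, but the upper alpha bound is configurable
DEFAULT_BOUNDS = ((1.0, 5000.0), (-60.0, -0.1))

#: relative forward-difference step of the optimizer
DIFF_STEP = 1e-3

#: parameter scaling to balance the Jacobian (mu in hPa, alpha raw)
X_SCALE = (100.0, 10.0)

_CACHE_DIGITS = 12


def chi_squared(y_exp: np.ndarray, y_sim: np.ndarray) -> float:
    """Normalized squared error sum((y_exp - y_sim)^2) / sum(y_exp^2).

    Invariant under a common rescaling of both vectors.
    """
    y_exp = np.asarray(y_exp, float)
    y_sim = np.asarray(y_sim, float)
    if y_exp.shape != y_sim.shape:
        raise ValueError("vector lengths differ")
    denom = float(np.sum(y_exp**2))
    if denom == 0.0:
        raise ZeroDivisionError("all-zero experimental vector: chi^2 undefined")
    return float(np.sum((y_exp - y_sim) ** 2) / denom)


def rmse(y_exp: np.ndarray, y_sim: np.ndarray) -> float:
    """Root mean square error over the concatenated residual vector (Pa)."""
    y_exp = np.asarray(y_exp, float)
    y_sim = np.asarray(y_sim, float)
    if y_exp.shape != y_sim.shape:
        raise ValueError("vector lengths differ")
    return float(np.sqrt(np.mean((y_exp - y_sim) ** 2)))


@dataclass
class FitProblem:
    """One specimen's identification problem.

    ``curves`` maps mode name to its processed experimental curve;
    ``forward`` selects the axial forward model: ``"fe"`` (glued or slipping
    finite-element simulation) or ``"homogeneous"`` (closed-form slipping
    solution).  Torsion uses the radial-integration reduction in both cases
    (the torsion response is insensitive to the end conditions).
    """

    curves: dict[str, ProcessedCurve]
    geom: SpecimenGeometry
    nu: float = 0.45
    bounds: tuple = DEFAULT_BOUNDS
    m0: tuple[float, float] | None = None
    forward: str = "homogeneous"
    bc_kind: str = "glued"
    fe_refinement: int = 1
    normalization: str = "global"  # "global" | "per_mode"
    n_workers: int = 1

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("at least one mode curve is required")
        unknown = set(self.curves) - {"compression_tension", "shear_015", "shear_030"}
        if unknown:
            raise ValueError(f"unknown modes {sorted(unknown)}")
        if self.forward not in ("fe", "homogeneous"):
            raise ValueError(f"unknown forward model {self.forward!r}")
        if self.normalization not in ("global", "per_mode"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        (lo_m, hi_m), (lo_a, hi_a) = self.bounds
        if not (np.isfinite([lo_m, hi_m, lo_a, hi_a]).all() and lo_m < hi_m and lo_a < hi_a):
            raise ValueError("bounds must be finite, ordered intervals")
        if self.m0 is None:
            self.m0 = self._default_initial_guess()
        m, a = self.m0
        if not (lo_m <= m <= hi_m and lo_a <= a <= hi_a):
            raise ValueError(f"initial guess {self.m0} outside bounds {self.bounds}")
        self._cache: dict[tuple, dict[str, np.ndarray]] = {}
        self.n_forward_evals = 0

    def _default_initial_guess(self) -> tuple[float, float]:
        """mu0 from the small-strain secant slope of the softest shear sweep."""
        (lo_m, hi_m), (lo_a, hi_a) = self.bounds
        mu0 = 0.5 * (lo_m + hi_m)
        for mode in ("shear_015", "shear_030"):
            c = self.curves.get(mode)
            if c is None:
                continue
            mask = c.abscissa > 1e-9
            if mask.sum() >= 2:
                k = min(mask.sum(), max(2, mask.sum() // 4))
                idx = np.argsort(c.abscissa[mask])[:k]
                g = c.abscissa[mask][idx]
                t = c.ordinate[mask][idx]
                slope = float(np.sum(g * t) / np.sum(g * g))
                if np.isfinite(slope) and slope > 0:
                    mu0 = slope
                break
        alpha0 = -15.0 if lo_a < -15.0 < hi_a else 0.5 * (lo_a + hi_a)
        return (float(np.clip(mu0, lo_m, hi_m)), alpha0)

    # -- forward evaluation --------------------------------------------------

    def _key(self, m) -> tuple:
        def sig(x):
            if x == 0.0:
                return 0.0
            from math import floor, log10

            d = _CACHE_DIGITS - 1 - floor(log10(abs(x)))
            return round(x, d)

        return (sig(m[0]), sig(m[1]))

    def _simulate_mode(self, mode: str, p: OgdenParameters) -> np.ndarray:
        grid = self.curves[mode].abscissa
        if mode == "compression_tension":
            if self.forward == "fe":
                curve = simulate_axial_test(
                    self.geom, p, self.bc_kind, grid, refinement=self.fe_refinement
                )
                # simulate_axial_test returns sorted abscissae
                return np.interp(grid, curve.abscissa, curve.ordinate)
            return np.array([homogeneous_uniaxial(lam, p) for lam in grid])
        return apparent_torsion_stress(grid, p)

    def simulate(self, m) -> dict[str, np.ndarray]:
        """All requested mode curves at m, cached by rounded parameter key."""
        key = self._key(m)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        p = OgdenParameters(mu=float(m[0]), alpha=float(m[1]), nu=self.nu)
        modes = sorted(self.curves)
        if self.n_workers > 1 and len(modes) > 1:
            with ThreadPoolExecutor(max_workers=self.n_workers) as ex:
                futs = {mode: ex.submit(self._simulate_mode, mode, p) for mode in modes}
                out = {mode: futs[mode].result() for mode in modes}
        else:
            out = {mode: self._simulate_mode(mode, p) for mode in modes}
        self._cache[key] = out
        self.n_forward_evals += 1
        return out

    def stacked_exp(self) -> np.ndarray:
        return np.concatenate([self.curves[m].ordinate for m in sorted(self.curves)])

    def stacked_sim(self, m) -> np.ndarray:
        sim = self.simulate(m)
        return np.concatenate([sim[mode] for mode in sorted(self.curves)])


@dataclass
class FitResult:
    """Identified parameter set with its goodness-of-fit measures."""

    mu: float
    alpha: float
    nu: float
    chi2: float
    rmse: float
    n_forward_evals: int
    converged: bool
    message: str = ""
    multi_start_spread: dict | None = None

    def parameters(self) -> OgdenParameters:
        return OgdenParameters(mu=self.mu, alpha=self.alpha, nu=self.nu)


def forward_residuals(m, problem: FitProblem) -> np.ndarray:
    """Normalized residual vector y_exp - y_sim at parameters m.

    With global normalization the vector is divided by sqrt(sum y_exp^2) so
    that chi^2 equals its squared norm; per-mode normalization applies the
    same per mode block.  A failed forward evaluation returns a large
    penalty residual instead of raising, keeping the optimizer inside the
    feasible region.
    """
    try:
        sim = problem.simulate(m)
    except Exception:  # noqa: BLE001 - optimizer robustness barrier
        y = problem.stacked_exp()
        return np.full(y.size, 1e3)
    blocks = []
    for mode in sorted(problem.curves):
        y_exp = problem.curves[mode].ordinate
        res = y_exp - sim[mode]
        if problem.normalization == "per_mode":
            res = res / np.sqrt(np.sum(y_exp**2))
        blocks.append(res)
    r = np.concatenate(blocks)
    if problem.normalization == "global":
        r = r / np.sqrt(np.sum(problem.stacked_exp() ** 2))
    return r


def fit_specimen(problem: FitProblem, optimizer: str = "trf") -> FitResult:
    """Bound-constrained least squares for one specimen.

    ``optimizer`` is ``"trf"`` (trust-region reflective with forward finite
    differences, the default) or ``"nelder-mead"`` (gradient-free fallback
    minimizing chi^2 directly with xatol 1e-3, fatol 1e-4).
    """
    lo = [problem.bounds[0][0], problem.bounds[1][0]]
    hi = [problem.bounds[0][1], problem.bounds[1][1]]
    x0 = np.asarray(problem.m0, float)

    if optimizer == "trf":
        sol = least_squares(
            forward_residuals,
            x0,
            args=(problem,),
            bounds=(lo, hi),
            method="trf",
            diff_step=DIFF_STEP,
            x_scale=np.asarray(X_SCALE),
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
        )
        x, converged, message = sol.x, bool(sol.success), sol.message
    elif optimizer == "nelder-mead":
        def cost(m):
            m = np.clip(m, lo, hi)
            return chi_squared(problem.stacked_exp(), problem.stacked_sim(m))

        sol = minimize(
            cost,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-4, "maxiter": 400},
        )
        x, converged, message = np.clip(sol.x, lo, hi), bool(sol.success), sol.message
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")

    y_exp = problem.stacked_exp()
    y_sim = problem.stacked_sim(x)
    return FitResult(
        mu=float(x[0]),
        alpha=float(x[1]),
        nu=problem.nu,
        chi2=chi_squared(y_exp, y_sim),
        rmse=rmse(y_exp, y_sim),
        n_forward_evals=problem.n_forward_evals,
        converged=converged,
        message=str(message),
    )


def multi_start(
    problem: FitProblem, n_starts: int, seed: int, optimizer: str = "trf"
) -> tuple[list[FitResult], dict]:
    """Latin-hypercube multi-start over the bounds; reports the optima spread.

    The spread is the maximum relative pairwise distance of the converged
    optima per parameter - a small spread replicates the absence of multiple
    local minima.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if n_starts == 1:
        res = fit_specimen(problem, optimizer=optimizer)
        return [res], {"mu": 0.0, "alpha": 0.0}
    sampler = qmc.LatinHypercube(d=2, seed=seed)
    unit = sampler.random(n_starts)
    lo = np.array([problem.bounds[0][0], problem.bounds[1][0]])
    hi = np.array([problem.bounds[0][1], problem.bounds[1][1]])
    starts = qmc.scale(unit, lo, hi)
    results = []
    for s in starts:
        prob = replace_problem_start(problem, tuple(s))
        results.append(fit_specimen(prob, optimizer=optimizer))
    conv = [r for r in results if r.converged] or results
    mus = np.array([r.mu for r in conv])
    als = np.array([r.alpha for r in conv])
    spread = {
        "mu": float((mus.max() - mus.min()) / max(abs(mus.mean()), 1e-30)),
        "alpha": float((als.max() - als.min()) / max(abs(als.mean()), 1e-30)),
    }
    for r in results:
        r.multi_start_spread = spread
    return results, spread


def replace_problem_start(problem: FitProblem, m0: tuple) -> FitProblem:
    """Copy of the problem with a new initial guess but shared forward cache."""
    new = FitProblem(
        curves=problem.curves,
        geom=problem.geom,
        nu=problem.nu,
        bounds=problem.bounds,
        m0=m0,
        forward=problem.forward,
        bc_kind=problem.bc_kind,
        fe_refinement=problem.fe_refinement,
        normalization=problem.normalization,
        n_workers=problem.n_workers,
    )
    new._cache = problem._cache
    return new


def fit_region_average(
    curves_by_specimen: dict[str, dict[str, ProcessedCurve]],
    geometries: dict[str, SpecimenGeometry],
    **problem_kw,
) -> FitResult:
    """Fit the point-wise mean of the specimens' curves with mean geometry.

    Averaging the experimental data before fitting represents the region's
    mean response, which differs from averaging individually fitted
    parameters.  All specimens must share mode grids of equal length; the
    mean abscissa grid is used.
    """
    if not curves_by_specimen:
        raise ValueError("empty region")
    modes = set.intersection(*(set(c) for c in curves_by_specimen.values()))
    if not modes:
        raise ValueError("no common loading mode across specimens")
    avg_curves = {}
    for mode in sorted(modes):
        cs = [curves_by_specimen[s][mode] for s in sorted(curves_by_specimen)]
        n = {c.abscissa.size for c in cs}
        if len(n) != 1:
            raise ValueError(f"inconsistent grid sizes for mode {mode}")
        absc = np.mean([c.abscissa for c in cs], axis=0)
        ordi = np.mean([c.ordinate for c in cs], axis=0)
        avg_curves[mode] = ProcessedCurve(
            mode=mode, abscissa=absc, ordinate=ordi, cycle_used=cs[0].cycle_used
        )
    geoms = [geometries[s] for s in sorted(curves_by_specimen)]
    mean_geom = SpecimenGeometry(
        radius=float(np.mean([g.radius for g in geoms])),
        height=float(np.mean([g.height for g in geoms])),
    )
    problem = FitProblem(curves=avg_curves, geom=mean_geom, **problem_kw)
    return fit_specimen(problem)
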