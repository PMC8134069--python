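"""Two-population gating-spring model of antennal receiver stiffness.

The antennal sound receiver behaves as a Hookean spring in series/parallel
with force-gated transducer channels.  Channel gating feeds back on receiver
mechanics: around the displacements where channels flicker between open and
closed, the apparent slope stiffness drops (a "gating compliance").  With two
transducer populations -- sensitive channels with a large single-channel
gating force z_s and insensitive channels with a small z_i -- the slope
stiffness as a function of receiver displacement X is

    K(X) = K_inf - sum_j N_j * z_j**2 / (k_B*T) * p_j(X) * (1 - p_j(X))

where p_j is the two-state Boltzmann open probability

    p_j(X) = 1 / (1 + exp(-z_j * (X - X0_j) / (k_B*T)))

N_j is the number of channels of population j, X0_j the displacement of
half-maximal open probability, and K_inf the asymptotic stiffness far from
the gating regime.  Integrating K gives the quasi-static force-displacement
relation used by the simulator and the force-step front-end.

Fitting recovers {N_j, z_j, X0_j, K_inf} per receiver by bounded nonlinear
least squares with Latin-hypercube multi-start.  Derived quantities follow
the conventions documented in ``derived_parameters``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import interpolate, optimize, stats
from scipy.special import expit
from scipy.stats import qmc

from .constants import K_B, DEFAULT_T

__all__ = [
    "TransducerPopulation",
    "GatingSpringParams",
    "StiffnessCurve",
    "DerivedGatingParams",
    "GatingFitConfig",
    "open_probability",
    "model_stiffness",
    "model_force",
    "slope_stiffness_from_force_steps",
    "fit_gating_spring",
    "derived_parameters",
    "flatten_fit",
    "compare_conditions",
]

SENSITIVE = "sensitive"
INSENSITIVE = "insensitive"


@dataclass
class TransducerPopulation:
    """One channel population: count N, gating force z (N), set point X0 (m)."""

    label: str
    N: float
    z: float
    X0: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in (SENSITIVE, INSENSITIVE):
            raise ValueError(f"unknown population label {self.label!r}")
        if not (self.N >= 0):
            raise ValueError("invalid channel count: N must be >= 0")
        if not (self.z > 0):
            raise ValueError("invalid gating force: z must be > 0")


@dataclass
class GatingSpringParams:
    """Full parameterization of the (one- or two-population) stiffness model."""

    populations: list[TransducerPopulation]
    K_inf: float
    K_steady: float | None = None
    T: float = DEFAULT_T

    def __post_init__(self) -> None:
        if not 1 <= len(self.populations) <= 2:
            raise ValueError("model supports 1 or 2 transducer populations")
        if not (self.K_inf > 0):
            raise ValueError("invalid asymptotic stiffness")
        if not (self.T > 0):
            raise ValueError("invalid temperature")
        if self.K_steady is not None and not (0 <= self.K_steady <= self.K_inf):
            raise ValueError("inconsistent stiffnesses: require 0 <= K_steady <= K_inf")
        if len(self.populations) == 2:
            # label-ordering convention: sensitive population has the larger z
            zs = {p.label: p.z for p in self.populations}
            if set(zs) == {SENSITIVE, INSENSITIVE} and zs[SENSITIVE] < zs[INSENSITIVE]:
                raise ValueError("sensitive population must have z >= insensitive z")


@dataclass
class StiffnessCurve:
    """Paired (displacement, slope stiffness[, stderr]) observations, SI units."""

    X: np.ndarray
    K: np.ndarray
    K_err: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        if self.X.shape != self.K.shape or self.X.ndim != 1:
            raise ValueError("X and K must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.K)):
            raise ValueError("non-finite values in stiffness curve")
        if np.any(np.diff(self.X) <= 0):
            raise ValueError("X must be strictly increasing")
        if np.any(self.K <= 0):
            raise ValueError("all stiffness values must be positive")
        if self.K_err is not None:
            self.K_err = np.asarray(self.K_err, dtype=float)
            if self.K_err.shape != self.K.shape or np.any(self.K_err < 0):
                raise ValueError("K_err must match K and be non-negative")

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class DerivedGatingParams:
    """Derived mechanics: gating-spring stiffness, stiffness relief, nonlinearity."""

    K_GS: float
    dK_s: float
    dK_i: float
    dK_total: float
    NL_s: float
    NL_i: float
    NL_total: float


@dataclass
class GatingFitConfig:
    """Multi-start bounded least-squares settings for the stiffness fit."""

    n_restarts: int = 20
    seed: int = 0
    N_bounds: tuple[float, float] = (0.0, 1e7)
    z_bounds_fN: tuple[float, float] = (0.1, 1000.0)
    K_inf_factor: float = 10.0  # upper bound = factor * max(K)
    symmetric_dips: bool = False  # tie X0_s == X0_i
    k_steady: str | float = "fit"  # "fit" (model-minimum convention) or a measured value
    xtol: float = 1e-12
    ftol: float = 1e-12


def _check_displacement(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("invalid displacement")
    return X


def open_probability(X, pop: TransducerPopulation, T: float = DEFAULT_T):
    """Two-state Boltzmann open probability p(X) of one population.

    p(X) = 1 / (1 + exp(-z (X - X0) / (k_B T))); p(X0) = 0.5 and p is
    strictly increasing in X with slope set by z.
    """
    X = _check_displacement(X)
    if not T > 0:
        raise ValueError("invalid temperature")
    p = expit(pop.z * (X - pop.X0) / (K_B * T))
    return p if p.ndim else float(p)


def model_stiffness(X, params: GatingSpringParams):
    """Slope stiffness K(X) of the gating-spring model (N/m)."""
    X = _check_displacement(X)
    K = np.full_like(X, params.K_inf, dtype=float)
    for pop in params.populations:
        p = open_probability(X, pop, params.T)
        K -= pop.N * pop.z**2 / (K_B * params.T) * p * (1.0 - p)
    if np.any(K <= 0):
        raise ValueError("non-physical parameters: model stiffness <= 0")
    return K if K.ndim else float(K)


def model_force(X, params: GatingSpringParams):
    """Quasi-static force F(X) (N), the antiderivative of ``model_stiffness``.

    F(X) = K_inf*X - sum_j N_j z_j p_j(X) + C with C chosen so F(0) = 0.
    Strictly increasing whenever K(X) > 0 everywhere.
    """
    X = _check_displacement(X)
    F = params.K_inf * X
    for pop in params.populations:
        F -= pop.N * pop.z * (open_probability(X, pop, params.T)
                              - open_probability(0.0, pop, params.T))
    return F if F.ndim else float(F)


def slope_stiffness_from_force_steps(steps, lam: float | None = None) -> StiffnessCurve:
    """Differentiate (force, peak displacement) pairs into a slope-stiffness curve.

    Sorts by displacement, fits a cubic smoothing spline to F(X) (smoothing
    parameter ``lam``; default chosen by generalized cross-validation) and
    evaluates its analytic derivative at the interior displacements.
    """
    steps = [(float(f), float(x)) for f, x in steps]
    if len(steps) < 5:
        raise ValueError("insufficient force steps: need at least 5")
    order = np.argsort([x for _, x in steps])
    F = np.array([steps[i][0] for i in order])
    X = np.array([steps[i][1] for i in order])
    if np.any(np.diff(X) <= 0):
        raise ValueError("non-monotone force-displacement data: duplicate displacements")
    if np.any(np.diff(F) <= 0):
        raise ValueError("non-monotone force-displacement data")
    # normalize to O(1): GCV is numerically ill-posed at SI magnitudes
    Xs, Fs = np.abs(X).max(), np.abs(F).max()
    spl = interpolate.make_smoothing_spline(X / Xs, F / Fs, lam=lam)
    Xi = X[1:-1]
    K = spl.derivative()(Xi / Xs) * (Fs / Xs)
    if np.any(K <= 0):
        raise ValueError("non-physical parameters: derived stiffness <= 0")
    return StiffnessCurve(X=Xi, K=K)


def _unpack(theta: np.ndarray, n_populations: int, symmetric: bool,
            T: float) -> GatingSpringParams:
    """Optimizer vector -> parameters; N and z are carried in log10 space."""
    K_inf = theta[0]
    pops = []
    for j in range(n_populations):
        logN, logz, X0 = theta[1 + 3 * j: 4 + 3 * j]
        if symmetric and j > 0:
            X0 = theta[3]
        pops.append(TransducerPopulation(label=SENSITIVE, N=10.0**logN,
                                         z=10.0**logz, X0=X0))
    # assign labels by descending z (convention: sensitive = larger z)
    pops.sort(key=lambda p: -p.z)
    labels = [SENSITIVE, INSENSITIVE]
    pops = [replace(p, label=labels[j]) for j, p in enumerate(pops)]
    if n_populations == 1:
        pops[0] = replace(pops[0], label=SENSITIVE)
    return GatingSpringParams(populations=pops, K_inf=K_inf, T=T)


def _model_K_unchecked(X: np.ndarray, params: GatingSpringParams) -> np.ndarray:
    # like model_stiffness but without the positivity guard (optimizer may roam)
    K = np.full_like(X, params.K_inf, dtype=float)
    for pop in params.populations:
        p = open_probability(X, pop, params.T)
        K -= pop.N * pop.z**2 / (K_B * params.T) * p * (1.0 - p)
    return K


def fit_gating_spring(curve: StiffnessCurve, n_populations: int = 2,
                      T: float = DEFAULT_T,
                      config: GatingFitConfig | None = None):
    """Fit the gating-spring stiffness model to a measured stiffness curve.

    Weighted (1/K_err**2 when errors are given) bounded least squares with
    ``config.n_restarts`` Latin-hypercube initializations plus one
    data-driven start.  Populations in the result are ordered sensitive
    (larger z) first.  Returns ``(GatingSpringParams, diagnostics dict)``.
    """
    config = config or GatingFitConfig()
    if n_populations not in (1, 2):
        raise ValueError("n_populations must be 1 or 2")
    n_min = 8 if n_populations == 1 else 12
    if len(curve) < n_min:
        raise ValueError(
            f"insufficient data: need >= {n_min} points for {n_populations} population(s)")

    X, K = curve.X, curve.K
    w = np.ones_like(K)
    if curve.K_err is not None and np.all(curve.K_err > 0):
        w = 1.0 / curve.K_err

    K_max = float(K.max())
    z_lo, z_hi = (b * 1e-15 for b in config.z_bounds_fN)
    logN_lo = 0.0  # N < 1 is indistinguishable from absent; bounded away from log(0)
    logN_hi = np.log10(max(config.N_bounds[1], 10.0))
    lo = [K_max * 0.1] + [logN_lo, np.log10(z_lo), X.min()] * n_populations
    hi = [K_max * config.K_inf_factor] + [logN_hi, np.log10(z_hi), X.max()] * n_populations
    lo, hi = np.array(lo), np.array(hi)

    ln10 = np.log(10.0)

    def residuals(theta):
        params = _unpack(theta, n_populations, config.symmetric_dips, T)
        return w * (_model_K_unchecked(X, params) - K)

    def jacobian(theta):
        # analytic dK/dtheta; theta = [K_inf, (logN, logz, X0) x pops]
        J = np.zeros((len(X), len(theta)))
        J[:, 0] = w
        for j in range(n_populations):
            b = 1 + 3 * j
            N, z = 10.0 ** theta[b], 10.0 ** theta[b + 1]
            X0 = theta[3] if (config.symmetric_dips and j > 0) else theta[b + 2]
            u = z * (X - X0) / (K_B * T)
            p = expit(u)
            q = p * (1.0 - p)
            c = N * z**2 / (K_B * T)
            J[:, b] = -w * ln10 * c * q
            J[:, b + 1] = -w * ln10 * c * q * (2.0 + (1.0 - 2.0 * p) * u)
            dX0 = w * c * q * (1.0 - 2.0 * p) * z / (K_B * T)
            if config.symmetric_dips and j > 0:
                J[:, 3] += dX0
            else:
                J[:, b + 2] = dX0
        return J

    # data-driven start: K_inf from the curve maximum, dip depth/width heuristics
    dip = K_max - K.min()
    X_dip = X[np.argmin(K)]
    width = max((X.max() - X.min()) / 8, 1e-9)
    z_guess = np.clip(K_B * T / width, z_lo * 2, z_hi / 2)
    starts = []
    if n_populations == 1:
        N_guess = max(dip, 0.01 * K_max) * 4 * K_B * T / z_guess**2
        starts.append(np.array([K_max, np.log10(N_guess), np.log10(z_guess), X_dip]))
    else:
        for frac, zf in ((0.7, 1.0), (0.5, 0.5), (0.9, 2.0)):
            N1 = max(dip * frac, 0.01 * K_max) * 4 * K_B * T / (z_guess * zf) ** 2
            N2 = max(dip * (1 - frac), 0.005 * K_max) * 4 * K_B * T / (z_guess * zf / 5) ** 2
            starts.append(np.array(
                [K_max, np.log10(N1), np.log10(z_guess * zf), X_dip,
                 np.log10(N2), np.log10(z_guess * zf / 5), X_dip]))

    # Latin-hypercube restarts: log-uniform in N and z, uniform X0 in range
    sampler = qmc.LatinHypercube(d=len(lo), seed=config.seed)
    unit = sampler.random(config.n_restarts)
    for u in unit:
        theta = lo + u * (hi - lo)
        theta[0] = K_max * (0.8 + 0.7 * u[0])
        starts.append(theta)

    x_scale = np.array([K_max] + [1.0, 0.5, (X.max() - X.min()) / 4] * n_populations)
    best = None
    n_used = 0
    for theta0 in starts:
        theta0 = np.clip(theta0, lo + 1e-12, hi - 1e-12)
        try:
            res = optimize.least_squares(
                residuals, theta0, jac=jacobian, bounds=(lo, hi), method="trf",
                xtol=config.xtol, ftol=config.ftol, gtol=1e-15,
                max_nfev=400, x_scale=x_scale)
        except Exception:
            continue
        n_used += 1
        if not res.success:
            continue
        params = _unpack(res.x, n_populations, config.symmetric_dips, T)
        dK = sum(p.N * p.z**2 / (4 * K_B * T) for p in params.populations)
        cand = (res.cost, dK, params, res)
        if best is None or cand[0] < best[0] * (1 - 1e-10) or (
                abs(cand[0] - best[0]) <= best[0] * 1e-10 and dK < best[1]):
            best = cand

    if best is None:
        raise RuntimeError("fit failed: no optimizer start converged")

    cost, dK_total, params, res = best
    collapsed = n_populations == 2 and any(
        p.N <= 10.0 ** (logN_lo + 1e-6) for p in params.populations)
    if collapsed:
        warnings.warn("population collapsed: one channel count at the zero bound")

    k_steady = config.k_steady
    if isinstance(k_steady, str) and k_steady.startswith("fixed:"):
        k_steady = float(k_steady.split(":", 1)[1])
    if k_steady == "fit":
        # convention: steady-state stiffness taken as the model minimum over the
        # measured displacement range (the receiver's most compliant state)
        grid = np.linspace(X.min(), X.max(), 2001)
        k_steady = float(_model_K_unchecked(grid, params).min())
    params = replace(params, K_steady=float(np.clip(k_steady, 0.0, params.K_inf)))

    diagnostics = {
        "residual_norm": float(np.sqrt(2 * cost)),
        "converged": True,
        "n_restarts_used": n_used,
        "population_collapsed": bool(collapsed),
        "parameters": flatten_fit(params),
    }
    return params, diagnostics


def derived_parameters(params: GatingSpringParams) -> DerivedGatingParams:
    """Stiffness relief, gating-spring stiffness and nonlinearity extents.

    Conventions (stated, not asserted to be universal): per-population
    stiffness relief dK_j = N_j z_j^2 / (4 k_B T), the stiffness drop each
    population would produce at its own half-open point; K_GS = K_inf -
    K_steady (gating springs in parallel with the steady-state element);
    NL_j = dK_j / K_inf.
    """
    if params.K_steady is None:
        raise ValueError("K_steady required (fitted or independently measured)")
    if params.K_steady > params.K_inf:
        raise ValueError("inconsistent stiffnesses: K_steady > K_inf")
    dK = {SENSITIVE: 0.0, INSENSITIVE: 0.0}
    for pop in params.populations:
        dK[pop.label] += pop.N * pop.z**2 / (4 * K_B * params.T)
    dK_total = dK[SENSITIVE] + dK[INSENSITIVE]
    if dK_total >= params.K_inf:
        raise ValueError("non-physical parameters: total stiffness relief >= K_inf")
    return DerivedGatingParams(
        K_GS=params.K_inf - params.K_steady,
        dK_s=dK[SENSITIVE], dK_i=dK[INSENSITIVE], dK_total=dK_total,
        NL_s=dK[SENSITIVE] / params.K_inf,
        NL_i=dK[INSENSITIVE] / params.K_inf,
        NL_total=dK_total / params.K_inf,
    )


_PARAM_KEYS = ["N_s", "z_s", "X0_s", "N_i", "z_i", "X0_i", "K_inf", "K_steady",
               "K_GS", "dK_s", "dK_i", "dK_total", "NL_s", "NL_i", "NL_total"]


def flatten_fit(params: GatingSpringParams,
                derived: DerivedGatingParams | None = None) -> dict:
    """Flatten a fit into the per-animal parameter dict used for comparisons."""
    out = {"K_inf": params.K_inf, "K_steady": params.K_steady}
    for pop in params.populations:
        s = "s" if pop.label == SENSITIVE else "i"
        out[f"N_{s}"] = pop.N
        out[f"z_{s}"] = pop.z
        out[f"X0_{s}"] = pop.X0
    if derived is None and params.K_steady is not None:
        try:
            derived = derived_parameters(params)
        except ValueError:  # non-physical best fit: derived quantities undefined
            pass
    if derived is not None:
        out.update(K_GS=derived.K_GS, dK_s=derived.dK_s, dK_i=derived.dK_i,
                   dK_total=derived.dK_total, NL_s=derived.NL_s,
                   NL_i=derived.NL_i, NL_total=derived.NL_total)
    else:
        out.update({k: float("nan") for k in
                    ("K_GS", "dK_s", "dK_i", "dK_total", "NL_s", "NL_i", "NL_total")})
    return out


def compare_conditions(fits_a: list[dict], fits_b: list[dict],
                       test: str = "student"):
    """Per-parameter condition-b/condition-a mean ratios with two-sample t-tests.

    ``fits_a``/``fits_b`` are lists of flattened per-animal parameter dicts
    (see ``flatten_fit``).  Returns a pandas DataFrame indexed by parameter
    with columns mean_a, mean_b, ratio, p_value.
    """
    import pandas as pd

    if len(fits_a) < 2 or len(fits_b) < 2:
        raise ValueError("insufficient animals: need >= 2 fits per condition")
    keys_a = set().union(*(f.keys() for f in fits_a))
    keys_b = set().union(*(f.keys() for f in fits_b))
    if keys_a != keys_b:
        raise ValueError("mismatched parameter sets between conditions")
    rows = {}
    for key in [k for k in _PARAM_KEYS if k in keys_a] + sorted(keys_a - set(_PARAM_KEYS)):
        a = np.array([f[key] for f in fits_a], dtype=float)
        b = np.array([f[key] for f in fits_b], dtype=float)
        if len(a) == len(b) and np.array_equal(a, b):
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)  # degenerate variance
                p = float(stats.ttest_ind(b, a, equal_var=(test == "student")).pvalue)
            if math.isnan(p):  # zero variance in both groups
                p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        rows[key] = {
            "mean_a": a.mean(), "mean_b": b.mean(),
            "ratio": b.mean() / a.mean() if a.mean() != 0 else np.nan,
            "p_value": p,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
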