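"""Ground-truth-known synthetic data for every analysis stage.

Each generator draws from the forward model its analysis counterpart fits,
with independent Gaussian measurement noise, so the whole pipeline is
testable by parameter recovery without any external recordings.  All
randomness derives from a single integer seed fanned out to per-generator
child streams by fixed offsets, so adding a generator never perturbs the
draws of another.

Default parameter sets mirror the experimental conditions the analyses
address: a two-population receiver with ~100 sensitive / ~1000 insensitive
channels (gating forces 50 / 10 fN) on a 1 mN/m receiver; a logistic FRAP
recovery with tau = 2.29 hr, F_start = 0.212, F_end = 1.435, t_half =
15.67 hr; a ~200 Hz receiver resonance with Q ~ 2; and qPCR tables with
3 technical x 5 biological replicates at 0.15-cycle technical scatter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, optimize, signal

from .constants import K_B, DEFAULT_T
from .frap import FrapSeries, LogisticFit, logistic_model
from .fluctuation import FluctuationTrace
from .gating_spring import (GatingSpringParams, StiffnessCurve,
                            TransducerPopulation, model_force, model_stiffness)
from .qpcr import REFERENCE_GENE

__all__ = [
    "child_rng",
    "default_gating_params",
    "default_frap_fit",
    "gen_stiffness_curve",
    "gen_force_steps",
    "gen_frap_series",
    "gen_fluctuation_trace",
    "gen_ct_table",
]

# fixed per-generator seed offsets (spawning convention)
_OFFSETS = {
    "stiffness": 101,
    "force_steps": 211,
    "frap": 307,
    "fluctuation": 401,
    "qpcr": 503,
}


def child_rng(seed: int, generator: str) -> np.random.Generator:
    """Deterministic child stream for one generator from the global seed."""
    return np.random.default_rng([_OFFSETS[generator], int(seed)])


def default_gating_params(T: float = DEFAULT_T) -> GatingSpringParams:
    """Reference two-population receiver: the standard recovery test-bed."""
    return GatingSpringParams(
        populations=[
            TransducerPopulation("sensitive", N=100.0, z=50e-15, X0=0.0),
            TransducerPopulation("insensitive", N=1000.0, z=10e-15, X0=0.0),
        ],
        K_inf=1e-3, K_steady=8e-4, T=T)


def default_frap_fit() -> LogisticFit:
    """Reference logistic recovery parameter set."""
    return LogisticFit(F_start=0.212, F_end=1.435, t_half=15.67, tau=2.29)


def gen_stiffness_curve(params: GatingSpringParams, x_grid,
                        noise_sd_frac: float = 0.02,
                        seed: int = 0) -> StiffnessCurve:
    """Noisy slope-stiffness curve: K_i = K(X_i) * (1 + eps_i).

    Multiplicative Gaussian noise with fractional SD ``noise_sd_frac``;
    K_err is set to the known noise scale.  Draws that would push K <= 0 are
    redrawn (truncation; practically never triggered at realistic noise).
    """
    x_grid = np.asarray(x_grid, dtype=float)
    K_true = model_stiffness(x_grid, params)
    rng = child_rng(seed, "stiffness")
    K = K_true * (1.0 + noise_sd_frac * rng.standard_normal(len(x_grid)))
    for _ in range(100):
        bad = K <= 0
        if not bad.any():
            break
        K[bad] = K_true[bad] * (1.0 + noise_sd_frac * rng.standard_normal(bad.sum()))
    err = noise_sd_frac * K_true if noise_sd_frac > 0 else None
    return StiffnessCurve(X=x_grid, K=K, K_err=err)


def gen_force_steps(params: GatingSpringParams, forces,
                    noise_sd: float = 0.0, seed: int = 0) -> list[tuple[float, float]]:
    """(force, peak displacement) pairs by inverting the force-displacement curve.

    X is found by bracketed root-finding on model_force (monotone, so the
    root is unique); optional Gaussian displacement noise of SD ``noise_sd`` m.
    """
    rng = child_rng(seed, "force_steps")
    steps = []
    for F in np.asarray(forces, dtype=float):
        if F == 0.0:
            x = 0.0
        else:
            s = np.sign(F)
            hi = max(4 * abs(F) / params.K_inf, 1e-7)
            while model_force(s * hi, params) * s < abs(F):
                hi *= 2
            x = optimize.brentq(lambda X: model_force(X, params) - F,
                                -hi, hi, xtol=1e-18, rtol=1e-15)
        if noise_sd > 0:
            x += noise_sd * rng.standard_normal()
        steps.append((float(F), float(x)))
    return steps


def gen_frap_series(fit: LogisticFit, timepoints, noise_sd: float = 0.05,
                    n_animals: int = 1, seed: int = 0) -> list[FrapSeries]:
    """Cross-sectional FRAP observations: one value per animal per timepoint."""
    t = np.asarray(timepoints, dtype=float)
    rng = child_rng(seed, "frap")
    series = []
    for a in range(n_animals):
        F = logistic_model(t, fit) + noise_sd * rng.standard_normal(len(t))
        series.append(FrapSeries(t=t, F=np.clip(F, 0.0, None),
                                 animal_id=f"animal{a:02d}"))
    return series


def gen_fluctuation_trace(f0: float = 200.0, Q: float = 2.0,
                          T_eff: float = DEFAULT_T, K: float = 1e-3,
                          fs: float = 4000.0, duration_s: float = 60.0,
                          T_bath: float = DEFAULT_T,
                          noise_floor: float = 0.0,
                          seed: int = 0) -> FluctuationTrace:
    """Simulated free-fluctuation trace of a thermally driven oscillator.

    Samples m*x'' + gamma*x' + K*x = sqrt(2*gamma*k_B*T_eff)*xi(t) with
    m = K/(2*pi*f0)^2 and gamma = sqrt(m*K)/Q, using the exact-in-
    distribution discretization of the linear SDE: the one-step transition
    matrix is expm(M*dt) and the per-step noise covariance follows from the
    stationary covariance diag(kB*T_eff/K, kB*T_eff/m), so the sampled
    process has the exact stationary variance k_B*T_eff/K at any step size.
    A burn-in of 20 ring-down times removes the zero start transient.
    ``noise_floor`` adds white measurement noise (m^2/Hz) on top.
    """
    if fs < 5 * f0:
        # exact discretization has no stability bound; this guards only
        # against the spectral peak crowding the Nyquist frequency
        raise ValueError("increase fs: need fs >= 5*f0")
    if duration_s * f0 < 10 * Q:
        raise ValueError("duration too short: need many correlation times")
    m = K / (2 * np.pi * f0) ** 2
    gamma = np.sqrt(m * K) / Q
    dt = 1.0 / fs

    M = np.array([[0.0, 1.0], [-K / m, -gamma / m]])
    A = linalg.expm(M * dt)
    P_inf = np.diag([K_B * T_eff / K, K_B * T_eff / m])  # equipartition
    Q_d = P_inf - A @ P_inf @ A.T
    Q_d = (Q_d + Q_d.T) / 2

    # diagonalize: the conjugate eigenmode pair gives a complex AR(1) that
    # scipy.signal.lfilter iterates in C
    lam, V = np.linalg.eig(A)
    burn = int(np.ceil(20 * Q / f0 * fs))
    n = int(round(duration_s * fs)) + burn
    rng = child_rng(seed, "fluctuation")
    w = rng.standard_normal((n, 2)) @ np.linalg.cholesky(Q_d).T
    if np.iscomplexobj(lam) and abs(lam[0].imag) > 0:
        eta = (np.linalg.inv(V) @ w.T)[0]  # mode 2 is the conjugate of mode 1
        y = signal.lfilter([1.0], [1.0, -lam[0]], eta)
        x = 2.0 * np.real(V[0, 0] * y)
    else:  # overdamped: two real AR(1) modes
        eta = np.linalg.inv(V) @ w.T
        y0 = signal.lfilter([1.0], [1.0, -lam[0].real], eta[0].real)
        y1 = signal.lfilter([1.0], [1.0, -lam[1].real], eta[1].real)
        x = V[0, 0].real * y0 + V[0, 1].real * y1
    x = x[burn:]
    if noise_floor > 0:
        x = x + np.sqrt(noise_floor * fs / 2) * rng.standard_normal(len(x))
    return FluctuationTrace(x=x, fs=fs, T_bath=T_bath, K_receiver=K)


def gen_ct_table(fold_changes: dict, base_ct: dict | None = None,
                 reference_gene: str = REFERENCE_GENE, ct_sd: float = 0.15,
                 n_technical: int = 3, n_biological: int = 5,
                 seed: int = 0) -> pd.DataFrame:
    """Long-format Ct table with known relative quantities.

    ``fold_changes`` maps gene -> rq of treated vs control; treated target
    Cts are shifted by -log2(rq), the reference gene is unshifted, and every
    replicate gets Normal(0, ct_sd) noise.  Biological replicates are
    distinct samples; technical replicates repeat within a sample.
    """
    rng = child_rng(seed, "qpcr")
    base_ct = base_ct or {}
    rows = []
    genes = list(fold_changes) + [reference_gene]
    for condition in ("control", "treated"):
        for b in range(n_biological):
            sample = f"s{b:02d}"  # shared across conditions: supports paired designs
            for gene in genes:
                ct0 = base_ct.get(gene, 18.0 if gene == reference_gene else 24.0)
                if condition == "treated" and gene != reference_gene:
                    ct0 = ct0 - np.log2(fold_changes[gene])
                for r in range(n_technical):
                    rows.append({
                        "sample_id": sample, "condition": condition, "gene": gene,
                        "replicate_id": f"tech{r}", "replicate_kind": "technical",
                        "ct": ct0 + (ct_sd * rng.standard_normal() if ct_sd > 0 else 0.0),
                    })
    return pd.DataFrame(rows)
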