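"""Free-fluctuation analysis: tuning, frequency selectivity and energy gain.

The unstimulated antennal receiver fluctuates under thermal forcing plus any
active energy injection by the transduction machinery.  Its displacement
power spectral density is modelled as a driven damped harmonic oscillator on
an additive noise floor,

    S(f) = A / [(f0^2 - f^2)^2 + (f0*f/Q)^2] + B

with natural frequency f0 (Hz), quality factor Q, amplitude A (m^2 Hz^3) and
floor B (m^2/Hz).  The spectral peak sits at the best frequency
f0*sqrt(1 - 1/(2 Q^2)) (underdamped case).  By equipartition, the
band-integrated mean-square displacement times the receiver stiffness defines
an effective temperature T_eff = K <x^2> / k_B; the excess of T_eff over the
bath temperature measures active amplification ("energy gain").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal, stats

from .constants import K_B, DEFAULT_T

__all__ = [
    "FluctuationTrace",
    "OscillatorFit",
    "PsdConfig",
    "compute_psd",
    "oscillator_psd",
    "fit_oscillator",
    "energy_gain",
    "compare_exposures",
]


@dataclass
class FluctuationTrace:
    """Displacement samples (m) at sampling rate fs with bath/receiver context."""

    x: np.ndarray
    fs: float
    T_bath: float = DEFAULT_T
    K_receiver: float = 1e-3  # N/m; steady-state receiver stiffness by default
    animal_id: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1 or not np.all(np.isfinite(self.x)):
            raise ValueError("displacement trace must be finite and 1-D")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if len(self.x) < 2 * self.fs:
            raise ValueError("trace too short: need >= 2 s of data")

    @property
    def duration(self) -> float:
        return len(self.x) / self.fs


@dataclass
class OscillatorFit:
    f0: float
    Q: float
    A: float
    B: float
    residual_norm: float = 0.0
    overdamped: bool = False
    peak_at_band_edge: bool = False

    @property
    def best_frequency(self) -> float:
        """Spectral-peak frequency; below f0 for any finite Q."""
        if self.Q <= 1 / np.sqrt(2):
            return np.nan  # overdamped: no spectral peak
        return self.f0 * np.sqrt(1 - 1 / (2 * self.Q**2))


@dataclass
class PsdConfig:
    segment_s: float | None = None  # Welch segment length, seconds (default: 1 s)
    detrend: str = "constant"


def compute_psd(trace: FluctuationTrace, config: PsdConfig | None = None):
    """One-sided Welch PSD (Hann window, 50% overlap) of a displacement trace.

    Returns (frequencies Hz, psd m^2/Hz); the integral of the PSD over the
    full band equals the (windowed) signal variance (Parseval).
    """
    config = config or PsdConfig()
    seg = config.segment_s if config.segment_s is not None else 1.0
    nperseg = int(round(seg * trace.fs))
    if len(trace.x) < 2 * nperseg:
        raise ValueError("trace too short: need at least 2 Welch segments")
    f, pxx = signal.welch(trace.x, fs=trace.fs, window="hann", nperseg=nperseg,
                          noverlap=nperseg // 2, detrend=config.detrend)
    return f, pxx


def oscillator_psd(f, f0: float, Q: float, A: float, B: float = 0.0):
    """Driven damped harmonic oscillator displacement PSD plus noise floor."""
    f = np.asarray(f, dtype=float)
    return A / ((f0**2 - f**2) ** 2 + (f0 * f / Q) ** 2) + B


def fit_oscillator(freqs, psd, band: tuple[float, float],
                   config=None) -> OscillatorFit:
    """Fit the oscillator PSD model within ``band`` in log-power space.

    Log-space least squares keeps the peak from dominating the residuals.
    Multi-start over Q; the fitted Q is the reported frequency selectivity.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    f_lo, f_hi = band
    sel = (freqs >= f_lo) & (freqs <= f_hi) & (psd > 0)
    f, p = freqs[sel], psd[sel]
    if len(f) < 20:
        raise ValueError("insufficient frequency bins in band: need >= 20")

    peak_edge = np.argmax(p) in (0, len(p) - 1)
    logp = np.log(p)

    f0_guess = f[np.argmax(p)]
    b_guess = max(np.median(p[p <= np.percentile(p, 25)]), p.min() * 0.5)

    def residuals(theta):
        lf0, lQ, lA, lB = theta
        model = oscillator_psd(f, np.exp(lf0), np.exp(lQ), np.exp(lA), np.exp(lB))
        return np.log(model) - logp

    best = None
    for q_guess in (0.8, 2.0, 5.0, 15.0):
        a_guess = (p.max() - b_guess) * f0_guess**4 / q_guess**2
        theta0 = np.log([f0_guess, q_guess, max(a_guess, 1e-300), b_guess])
        try:
            res = optimize.least_squares(residuals, theta0, method="lm",
                                         xtol=1e-13, ftol=1e-13)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not best.success:
        raise RuntimeError("fit failed: oscillator PSD fit did not converge")

    f0, Q, A, B = np.exp(best.x)
    return OscillatorFit(f0=float(f0), Q=float(Q), A=float(A), B=float(B),
                         residual_norm=float(np.sqrt(2 * best.cost)),
                         overdamped=bool(Q <= 1 / np.sqrt(2)),
                         peak_at_band_edge=bool(peak_edge))


def _band_ms_displacement(freqs, psd, fit: OscillatorFit,
                          band: tuple[float, float],
                          correct_band: bool = True) -> float:
    """Noise-floor-subtracted <x^2> from the PSD, extrapolated to full band.

    The measured PSD minus the fitted floor is integrated over the analysis
    band; the fitted oscillator shape then scales the result by the ratio of
    its full-band to in-band integral, compensating tails the band clips.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    x2_band = np.trapezoid(np.clip(psd[sel] - fit.B, 0, None), freqs[sel])
    if x2_band <= 0:
        raise ValueError("power below noise floor in analysis band")
    if not correct_band:
        return float(x2_band)
    grid_full = np.linspace(0, max(20 * fit.f0, band[1] * 2), 200001)
    model_full = np.trapezoid(oscillator_psd(grid_full, fit.f0, fit.Q, fit.A), grid_full)
    grid_band = np.linspace(band[0], band[1], 20001)
    model_band = np.trapezoid(oscillator_psd(grid_band, fit.f0, fit.Q, fit.A), grid_band)
    if model_band <= 0:
        raise ValueError("power below noise floor in analysis band")
    return float(x2_band * model_full / model_band)


def energy_gain(trace: FluctuationTrace, band: tuple[float, float],
                config: PsdConfig | None = None,
                fit: OscillatorFit | None = None) -> dict:
    """Effective temperature and energy gain of the receiver fluctuations.

    T_eff = K_receiver * <x^2> / k_B with <x^2> from the noise-floor-
    subtracted, band-corrected PSD integral; gain = T_eff / T_bath - 1
    (dimensionless) and energy_excess_J = k_B * (T_eff - T_bath).  A passive
    receiver in thermal equilibrium has gain 0.
    """
    if not trace.K_receiver > 0:
        raise ValueError("receiver stiffness must be positive")
    if not trace.T_bath > 0:
        raise ValueError("invalid temperature")
    freqs, psd = compute_psd(trace, config)
    if fit is None:
        fit = fit_oscillator(freqs, psd, band)
    x2 = _band_ms_displacement(freqs, psd, fit, band)
    T_eff = trace.K_receiver * x2 / K_B
    return {
        "T_eff": float(T_eff),
        "gain": float(T_eff / trace.T_bath - 1.0),
        "energy_excess_J": float(K_B * (T_eff - trace.T_bath)),
        "ms_displacement": float(x2),
        "fit": fit,
    }


def compare_exposures(fits_control: list[dict], fits_exposed: list[dict],
                      test: str = "student"):
    """Cohort comparison of per-animal metric dicts (best_frequency, Q, gain, ...).

    Two-sided two-sample t-test per metric; returns a DataFrame with means,
    mean difference, ratio and p-value.
    """
    import pandas as pd

    if len(fits_control) < 3 or len(fits_exposed) < 3:
        raise ValueError("insufficient animals: need >= 3 per cohort")
    keys_c = set().union(*(f.keys() for f in fits_control))
    keys_e = set().union(*(f.keys() for f in fits_exposed))
    if keys_c != keys_e:
        raise ValueError("mismatched metric sets between cohorts")
    rows = {}
    for key in sorted(keys_c):
        c = np.array([f[key] for f in fits_control], dtype=float)
        e = np.array([f[key] for f in fits_exposed], dtype=float)
        if len(c) == len(e) and np.array_equal(c, e):
            p = 1.0
        else:
            p = float(stats.ttest_ind(e, c, equal_var=(test == "student")).pvalue)
        rows[key] = {"mean_control": c.mean(), "mean_exposed": e.mean(),
                     "difference": e.mean() - c.mean(),
                     "ratio": e.mean() / c.mean() if c.mean() != 0 else np.nan,
                     "p_value": p}
    return pd.DataFrame.from_dict(rows, orient="index")
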