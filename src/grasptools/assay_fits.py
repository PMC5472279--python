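"""Binding-assay computations: HTRF ratio algebra, 4PL competition
fitting, Boltzmann thermal-shift fitting, and one-site ITC analysis.

The models are the field-standard ones:

* HTRF signal change  dF = 100 * (R_sample - R_NSB) / R_NSB, with R the
  acceptor/donor (A665/A615) emission ratio and NSB the non-specific
  binding control; competition curves are expressed as dF/dF0 where dF0
  is the uncompeted maximum.
* Four-parameter logistic in log10 molar concentration with variable
  Hill slope: y = bottom + (top - bottom) / (1 + 10^((logIC50 - x) h)).
  A fit is flagged significant only when R^2 > 0.99.
* Boltzmann melt sigmoid f = f_min + (f_max - f_min)/(1 + exp((Tm-T)/a)),
  fitted after truncating at the fluorescence maximum (post-peak dye
  dissociation is not part of the unfolding model).
* Wiseman one-site isotherm for integrated injection heats, followed by
  dG = -R T ln K_A and T dS = dH - dG (R = 8.314 J/mol/K).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .synthetic import boltzmann_sigmoid, four_pl, wiseman_one_site

__all__ = [
    "R_GAS",
    "DoseResponseFit",
    "MeltFit",
    "ItcFit",
    "delta_f",
    "normalize_competition",
    "fit_4pl",
    "fit_boltzmann",
    "fit_itc_one_site",
    "derive_thermo",
]

R_GAS = 8.314  # J / (mol K)


@dataclass
class DoseResponseFit:
    top: float
    bottom: float
    log_ic50: float
    hill: float
    r_squared: float
    significant: bool

    @property
    def ic50_molar(self) -> float:
        return 10.0**self.log_ic50


@dataclass
class MeltFit:
    f_min: float
    f_max: float
    tm_c: float
    slope_a: float
    r_squared: float
    delta_tm_c: float = float("nan")


@dataclass
class ItcFit:
    n_sites: float
    K_A: float               # 1/M
    delta_H: float           # kJ/mol
    T_kelvin: float
    delta_G: float           # kJ/mol
    T_delta_S: float         # kJ/mol
    r_squared: float
    low_confidence: bool = False

    @property
    def K_d(self) -> float:
        return 1.0 / self.K_A


# ---------------------------------------------------------------------------
# HTRF algebra
# ---------------------------------------------------------------------------

def delta_f(r_sample: float, r_nsb: float) -> float:
    """Background-corrected HTRF signal change in percent."""
    if r_nsb <= 0:
        raise ValueError(f"R_NSB must be positive, got {r_nsb}")
    return 100.0 * (r_sample - r_nsb) / r_nsb


def normalize_competition(dF, dF0: float) -> np.ndarray:
    """Express competition signals relative to the uncompeted maximum."""
    if dF0 <= 0:
        raise ValueError("dF0 must be positive")
    return np.asarray(dF, dtype=float) / dF0


# ---------------------------------------------------------------------------
# shared least-squares helpers
# ---------------------------------------------------------------------------

def _r_squared(y, y_fit) -> float:
    y = np.asarray(y, dtype=float)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - float(np.sum((y - y_fit) ** 2)) / ss_tot


def _multistart_fit(func, x, y, starts, bounds=(-np.inf, np.inf), maxfev=20000):
    best = None
    best_ss = np.inf
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", OptimizeWarning)
                popt, _ = curve_fit(func, x, y, p0=p0, bounds=bounds, maxfev=maxfev)
        except (RuntimeError, ValueError):
            continue
        ss = float(np.sum((func(x, *popt) - y) ** 2))
        if ss < best_ss:
            best_ss, best = ss, popt
    if best is None:
        raise RuntimeError(f"fit did not converge from any start (best residual {best_ss})")
    return best


# ---------------------------------------------------------------------------
# 4PL competition fitting
# ---------------------------------------------------------------------------

def fit_4pl(x_log_molar, y, multistart: int = 8, seed: int = 0) -> DoseResponseFit:
    """Variable-slope four-parameter logistic fit in log10 concentration.

    Starting values come from the data (y extremes for the plateaus, the
    half-maximum crossing for logIC50, Hill slope +/-1), with seeded
    random perturbations providing additional starts to escape local
    minima.
    """
    x = np.asarray(x_log_molar, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.unique(x).size < 5:
        raise ValueError("need at least 5 distinct doses")

    if np.ptp(y) == 0:
        # flat data: logistic degenerate, report the constant with r^2 = 0
        return DoseResponseFit(
            top=float(y[0]), bottom=float(y[0]), log_ic50=float(np.median(x)),
            hill=1.0, r_squared=0.0, significant=False,
        )

    top0, bot0 = float(y.max()), float(y.min())
    half = (top0 + bot0) / 2.0
    mid0 = float(x[np.argmin(np.abs(y - half))])
    rng = np.random.default_rng(seed)
    starts = [(top0, bot0, mid0, 1.0), (top0, bot0, mid0, -1.0)]
    for _ in range(max(0, multistart - len(starts))):
        starts.append(
            (
                top0 * rng.uniform(0.8, 1.2),
                bot0 + rng.normal(0, 0.1 * np.ptp(y)),
                mid0 + rng.normal(0, 1.0),
                rng.choice([-1.0, 1.0]) * rng.uniform(0.3, 3.0),
            )
        )

    popt = _multistart_fit(lambda xx, t, b, m, h: four_pl(xx, t, b, m, h), x, y, starts)
    r2 = _r_squared(y, four_pl(x, *popt))
    return DoseResponseFit(
        top=float(popt[0]), bottom=float(popt[1]), log_ic50=float(popt[2]),
        hill=float(popt[3]), r_squared=r2, significant=bool(r2 > 0.99),
    )


# ---------------------------------------------------------------------------
# Boltzmann thermal shift
# ---------------------------------------------------------------------------

def fit_boltzmann(t_c, f, reference_tm_c: float | None = None) -> MeltFit:
    """Fit the Boltzmann melt sigmoid and extract Tm.

    The curve is truncated at the global fluorescence maximum before
    fitting.  ``reference_tm_c`` (e.g. a DMSO control Tm) fills the
    ``delta_tm_c`` field.  Monotone-decreasing input (no unfolding
    transition) raises.
    """
    t = np.asarray(t_c, dtype=float)
    f = np.asarray(f, dtype=float)
    if t.size < 8:
        raise ValueError("need at least 8 temperature points")
    peak = int(np.argmax(f))
    if peak == 0 or np.all(np.diff(f) <= 0):
        raise ValueError("fluorescence never rises: no melting transition to fit")
    t_fit, f_fit = t[: peak + 1], f[: peak + 1]

    fmin0, fmax0 = float(f_fit.min()), float(f_fit.max())
    half = (fmin0 + fmax0) / 2.0
    tm0 = float(t_fit[np.argmin(np.abs(f_fit - half))])
    starts = [(fmin0, fmax0, tm0, a0) for a0 in (0.5, 2.0, 5.0)]
    popt = _multistart_fit(
        lambda tt, lo, hi, tm, a: boltzmann_sigmoid(tt, lo, hi, tm, a),
        t_fit, f_fit, starts,
        bounds=([-np.inf, -np.inf, t.min() - 5.0, 1e-6], [np.inf, np.inf, t.max() + 5.0, np.inf]),
    )
    r2 = _r_squared(f_fit, boltzmann_sigmoid(t_fit, *popt))
    tm = float(popt[2])
    return MeltFit(
        f_min=float(popt[0]), f_max=float(popt[1]), tm_c=tm, slope_a=float(popt[3]),
        r_squared=r2,
        delta_tm_c=tm - reference_tm_c if reference_tm_c is not None else float("nan"),
    )


# ---------------------------------------------------------------------------
# ITC one-site fitting and thermodynamics
# ---------------------------------------------------------------------------

def derive_thermo(K_A: float, delta_H_kj: float, T_kelvin: float) -> tuple[float, float]:
    """Gibbs energy and entropic term from K_A and dH.

    dG = -R T ln K_A (returned in kJ/mol); T dS = dH - dG.
    """
    if K_A <= 0 or T_kelvin <= 0:
        raise ValueError("K_A and T must be positive")
    delta_G = -R_GAS * T_kelvin * np.log(K_A) / 1000.0
    return float(delta_G), float(delta_H_kj - delta_G)


def fit_itc_one_site(
    molar_ratio,
    ndh,
    cell_conc: float,
    T_kelvin: float = 298.15,
    multistart: int = 8,
    seed: int = 0,
    drop_first: bool = True,
    control_ndh=None,
) -> ItcFit:
    """One-site nonlinear least-squares fit of integrated injection heats.

    ``ndh`` are heats per mole of injectant (same units as the fitted
    dH, kJ/mol here) against the syringe/cell molar ratio.  The first
    injection is discarded by default (air-bubble purge); an optional
    dilution-control series is subtracted elementwise.  Fits with
    c = n K_A [cell] < 1 are flagged low-confidence.
    """
    x = np.asarray(molar_ratio, dtype=float)
    y = np.asarray(ndh, dtype=float)
    if control_ndh is not None:
        y = y - np.asarray(control_ndh, dtype=float)
    if drop_first:
        x, y = x[1:], y[1:]
    if x.size < 10:
        raise ValueError("need at least 10 usable injections")
    if cell_conc <= 0:
        raise ValueError("cell concentration must be positive")
    if np.allclose(y, 0.0):
        raise ValueError("all heats are zero: nothing to fit")

    dh0 = float(y[np.argmax(np.abs(y))])
    rng = np.random.default_rng(seed)
    starts = [(1.0, 1e6, dh0), (1.0, 1e4, dh0), (0.5, 1e5, dh0)]
    for _ in range(max(0, multistart - len(starts))):
        starts.append(
            (rng.uniform(0.3, 3.0), 10 ** rng.uniform(3, 8), dh0 * rng.uniform(0.5, 2.0))
        )
    popt = _multistart_fit(
        lambda xx, n, ka, dh: wiseman_one_site(xx, n, ka, dh, cell_conc),
        x, y, starts,
        bounds=([1e-3, 1e-3, -np.inf], [100.0, 1e15, np.inf]),
    )
    n, ka, dh = (float(v) for v in popt)
    dg, tds = derive_thermo(ka, dh, T_kelvin)
    return ItcFit(
        n_sites=n, K_A=ka, delta_H=dh, T_kelvin=T_kelvin,
        delta_G=dg, T_delta_S=tds,
        r_squared=_r_squared(y, wiseman_one_site(x, n, ka, dh, cell_conc)),
        low_confidence=bool(n * ka * cell_conc < 1.0),
    )
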