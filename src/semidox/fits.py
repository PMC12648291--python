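"""Biophysical curve models and least-squares fitting.

Four phenomenological models cover the characterisation experiments of an
iron–sulfur peptide:

* **Two-state van't Hoff melt** — the CD signal of a thermal denaturation is
  a population-weighted mix of sloping native and denatured baselines,

  ``y(T) = [(aN + bN*T) + (aD + bD*T) * E] / (1 + E)``,
  ``E = exp[-dH/R * (1/T - 1/Tm)]``,

  with R = 1.9872e-3 kcal/(K*mol), dH the van't Hoff enthalpy and Tm the
  midpoint temperature.

* **Hill melt** — after linear-baseline normalisation, the unfolded fraction
  is fitted to ``theta(T) = T**h / (T**h + Tm**h)``; Tm is the
  half-transition temperature in both melt models so they are comparable.

* **Nernst titration** — the fraction reduced as a function of electrode
  potential E (mV) for an n = 1 couple,
  ``f(E) = 1 / (1 + exp[(E - Em)/(RT/nF)])`` with RT/nF ~ 25.7 mV at 298 K.
  A pure-exponential variant (no "1 +" in the denominator) is evaluable
  behind ``form="as_printed"`` for auditability; only the logistic form maps
  potentials to fractions in [0, 1] with f(Em) = 0.5 and is used for
  fitting.

* **First-order decay** — oxygen-driven cluster loss monitored by the
  Fe-S absorption band, ``A(t) = A0 * exp(-k t)``, half-life ln 2 / k.

All fits use scipy trust-region least squares with fixed, documented
initialisations (no random restarts), so results are deterministic.
Composite EPR spectra are decomposed onto monomer/dimer basis line shapes by
nonnegative least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import constants
from scipy.optimize import least_squares, nnls
from scipy.special import expit

__all__ = [
    "R_GAS_KCAL",
    "FitError",
    "FitReport",
    "MeltModelParams",
    "HillParams",
    "NernstParams",
    "DecayParams",
    "Spectrum",
    "DecompResult",
    "vant_hoff_signal",
    "fit_melt",
    "hill_fraction",
    "hill_tm",
    "nernst_scale_mv",
    "nernst_fraction",
    "fit_nernst",
    "fit_decay",
    "decompose_spectrum",
    "read_curve",
    "write_curve",
]

#: Universal gas constant in kcal K^-1 mol^-1 (fixed for the melt model).
R_GAS_KCAL = 1.9872e-3


class FitError(RuntimeError):
    """A fit failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best_params: dict | None = None):
        super().__init__(message)
        self.best_params = best_params or {}


@dataclass
class FitReport:
    """Diagnostics shared by all fit operations."""

    residuals: np.ndarray
    cost: float
    stderr: dict[str, float]
    success: bool

    @property
    def residual_norm(self) -> float:
        return float(np.linalg.norm(self.residuals))


def _stderr_from_jacobian(jac: np.ndarray, residuals: np.ndarray, names: list[str]) -> dict[str, float]:
    """Asymptotic standard errors from the Jacobian at the solution."""
    m, p = jac.shape
    dof = max(m - p, 1)
    s2 = float(residuals @ residuals) / dof
    try:
        cov = s2 * np.linalg.inv(jac.T @ jac)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return dict(zip(names, se.tolist()))


def _as_xy(curve) -> tuple[np.ndarray, np.ndarray]:
    """Accept (x, y) arrays or an (n, 2) array; return float arrays sorted by x."""
    if isinstance(curve, tuple) and len(curve) == 2:
        x, y = (np.asarray(c, dtype=float) for c in curve)
    else:
        arr = np.asarray(curve, dtype=float)
        x, y = arr[:, 0], arr[:, 1]
    order = np.argsort(x, kind="stable")
    return x[order], y[order]


# ---------------------------------------------------------------------------
# Two-state van't Hoff melt


@dataclass
class MeltModelParams:
    """Parameters of the two-state melt with sloping baselines.

    ``aN``/``bN`` and ``aD``/``bD`` are the native and denatured baseline
    intercepts (signal units) and slopes (signal/K); ``dH_vant`` is the
    van't Hoff enthalpy in kcal/mol and ``Tm`` the midpoint in Kelvin.
    """

    aN: float
    bN: float
    aD: float
    bD: float
    dH_vant: float
    Tm: float
    R_const: float = field(default=R_GAS_KCAL)

    def __post_init__(self) -> None:
        if self.Tm <= 0:
            raise ValueError("Tm must be positive (Kelvin)")
        if self.R_const != R_GAS_KCAL:
            raise ValueError("R_const is fixed to 1.9872e-3 kcal/K/mol")


def vant_hoff_signal(T, p: MeltModelParams):
    """Evaluate the two-state melt signal at temperature(s) T (K).

    Uses the logistic (overflow-safe) form: with
    ``u = -dH/R * (1/T - 1/Tm)``, the denatured population is
    ``s = expit(u)`` and ``y = (aN + bN*T)*(1-s) + (aD + bD*T)*s``.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (Kelvin)")
    u = -p.dH_vant / p.R_const * (1.0 / T - 1.0 / p.Tm)
    s = expit(u)
    y = (p.aN + p.bN * T) * (1.0 - s) + (p.aD + p.bD * T) * s
    return y if y.ndim else float(y)


def _melt_init(T: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Documented default initialisation: baselines from the first/last three
    points, Tm at the steepest-slope temperature, dH = 50 kcal/mol."""
    bN, aN = np.polyfit(T[:3], y[:3], 1)
    bD, aD = np.polyfit(T[-3:], y[-3:], 1)
    slopes = np.gradient(y, T)
    tm0 = float(T[np.argmax(np.abs(slopes))])
    tm0 = min(max(tm0, T[0] + 1e-6), T[-1] - 1e-6)
    return np.array([aN, bN, aD, bD, 50.0, tm0])


def fit_melt(curve, init: MeltModelParams | None = None) -> tuple[MeltModelParams, FitReport]:
    """Least-squares fit of the two-state van't Hoff melt model.

    Requires at least 8 points spanning the transition.  Raises
    :class:`FitError` (carrying the best iterate) if the optimiser fails or
    the fitted transition is not actually traversed by the data — e.g. for
    monotone featureless input.
    """
    T, y = _as_xy(curve)
    if T.size < 8:
        raise ValueError("melt fit requires at least 8 points")
    if init is not None:
        x0 = np.array([init.aN, init.bN, init.aD, init.bD, init.dH_vant, init.Tm])
    else:
        x0 = _melt_init(T, y)

    def resid(x):
        p = MeltModelParams(*x[:4], dH_vant=x[4], Tm=max(x[5], 1e-6))
        return vant_hoff_signal(T, p) - y

    res = least_squares(resid, x0, method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10)
    names = ["aN", "bN", "aD", "bD", "dH_vant", "Tm"]
    best = dict(zip(names, res.x.tolist()))
    # a real melt has a resolvable step between the baselines at Tm,
    # located inside the measured temperature range
    tm = max(best["Tm"], 1e-6)
    amplitude = abs(
        (best["aD"] + best["bD"] * tm) - (best["aN"] + best["bN"] * tm)
    )
    span = max(float(y.max() - y.min()), 1e-12)
    if not res.success or amplitude < 0.05 * span or not (T[0] <= best["Tm"] <= T[-1]):
        raise FitError("melt fit did not converge to a transition within the data range", best)
    params = MeltModelParams(
        aN=best["aN"], bN=best["bN"], aD=best["aD"], bD=best["bD"],
        dH_vant=best["dH_vant"], Tm=best["Tm"],
    )
    report = FitReport(
        residuals=res.fun,
        cost=float(res.cost),
        stderr=_stderr_from_jacobian(res.jac, res.fun, names),
        success=True,
    )
    return params, report


# ---------------------------------------------------------------------------
# Hill-form melt


@dataclass
class HillParams:
    Tm: float
    h: float


def hill_fraction(T, Tm: float, h: float):
    """Unfolded fraction under the Hill form, theta = T^h / (T^h + Tm^h).

    Evaluated in log space for numerical stability at large h;
    theta(Tm) = 0.5 exactly.
    """
    T = np.asarray(T, dtype=float)
    theta = expit(h * (np.log(T) - math.log(Tm)))
    return theta if theta.ndim else float(theta)


def hill_tm(curve) -> tuple[HillParams, FitReport]:
    """Melting temperature via the Hill equation.

    The raw signal is normalised to an unfolded fraction using linear
    baselines through the first and last three points, then
    ``theta(T) = T^h/(T^h + Tm^h)`` is fitted; Tm is the half-transition
    temperature.
    """
    T, y = _as_xy(curve)
    if T.size < 6:
        raise ValueError("Hill fit requires at least 6 points")
    bN, aN = np.polyfit(T[:3], y[:3], 1)
    bD, aD = np.polyfit(T[-3:], y[-3:], 1)
    denom = (aD + bD * T) - (aN + bN * T)
    if np.any(np.abs(denom) < 1e-12):
        raise FitError("baselines coincide; cannot normalise to a fraction")
    theta = (y - (aN + bN * T)) / denom

    crossing = np.argmin(np.abs(theta - 0.5))
    tm0 = float(np.clip(T[crossing], T[0] + 1e-6, T[-1] - 1e-6))

    def resid(x):
        return hill_fraction(T, x[0], x[1]) - theta

    res = least_squares(resid, np.array([tm0, 40.0]), method="trf",
                        bounds=([T[0] * 0.5, 1e-3], [T[-1] * 2.0, 1e4]),
                        xtol=1e-10, ftol=1e-10, gtol=1e-10)
    if not res.success:
        raise FitError("Hill fit did not converge", {"Tm": res.x[0], "h": res.x[1]})
    params = HillParams(Tm=float(res.x[0]), h=float(res.x[1]))
    report = FitReport(
        residuals=res.fun,
        cost=float(res.cost),
        stderr=_stderr_from_jacobian(res.jac, res.fun, ["Tm", "h"]),
        success=True,
    )
    return params, report


# ---------------------------------------------------------------------------
# Nernst titration


@dataclass
class NernstParams:
    """Midpoint potential Em (mV vs reference) for an n-electron couple.

    ``form="logistic"`` is the standard Nernst sigmoid; ``form="as_printed"``
    is the pure-exponential variant without the "1 +" term (not a fraction
    outside the reduced plateau; retained for auditability only).
    """

    Em: float
    n: int = 1
    T: float = 298.0
    form: str = "logistic"

    def __post_init__(self) -> None:
        if self.n != 1:
            raise ValueError("a single-electron couple (n = 1) is assumed")
        if self.T <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        if self.form not in {"logistic", "as_printed"}:
            raise ValueError(f"unknown Nernst form {self.form!r}")


def nernst_scale_mv(T: float = 298.0, n: int = 1) -> float:
    """The thermal voltage RT/nF in millivolts (~25.7 mV at 298 K, n = 1)."""
    return 1000.0 * constants.R * T / (n * constants.physical_constants["Faraday constant"][0])


def nernst_fraction(E, p: NernstParams):
    """Fraction reduced at electrode potential(s) E (mV).

    Logistic form: ``1 / (1 + exp[(E - Em)/(RT/nF)])`` — strictly decreasing
    in E, 0.5 at Em, symmetric about the midpoint.
    """
    E = np.asarray(E, dtype=float)
    scale = nernst_scale_mv(p.T, p.n)
    z = (E - p.Em) / scale
    if p.form == "as_printed":
        f = np.exp(-z)
    else:
        f = expit(-z)
    return f if f.ndim else float(f)


@dataclass
class NernstFit:
    Em: float
    a_ox: float
    a_red: float


def fit_nernst(curve, T: float = 298.0) -> tuple[NernstFit, FitReport]:
    """Midpoint potential from an absorbance-vs-potential titration.

    The absorbance is modelled as ``A(E) = a_ox + (a_red - a_ox) * f(E)``
    with f the logistic Nernst fraction (n = 1), so the plateaus are fitted
    rather than imposed.  Requires at least 6 points and a bracketed
    transition (both plateaus represented in the data).  Works identically
    for reduction- and oxidation-direction sweeps.
    """
    E, A = _as_xy(curve)
    if E.size < 6:
        raise ValueError("Nernst fit requires at least 6 points")
    a_hi0 = float(np.mean(A[np.argsort(E)[-3:]]))  # oxidised plateau (high E)
    a_lo0 = float(np.mean(A[np.argsort(E)[:3]]))  # reduced plateau (low E)
    if abs(a_hi0 - a_lo0) < 1e-12:
        raise FitError("flat titration: no transition to fit")
    frac0 = (A - a_hi0) / (a_lo0 - a_hi0)
    if frac0.max() < 0.75 or frac0.min() > 0.25:
        raise FitError("transition not bracketed by the potential range")
    Em0 = float(E[np.argmin(np.abs(frac0 - 0.5))])

    def resid(x):
        em, a_ox, a_red = x
        f = nernst_fraction(E, NernstParams(Em=em, T=T))
        return a_ox + (a_red - a_ox) * f - A

    res = least_squares(resid, np.array([Em0, a_hi0, a_lo0]), method="trf",
                        xtol=1e-10, ftol=1e-10, gtol=1e-10)
    best = dict(zip(["Em", "a_ox", "a_red"], res.x.tolist()))
    if not res.success:
        raise FitError("Nernst fit did not converge", best)
    # both plateaus must be approached within the measured potential window
    f_ends = nernst_fraction(np.array([E[0], E[-1]]), NernstParams(Em=best["Em"], T=T))
    if not (f_ends[0] >= 0.9 and f_ends[1] <= 0.1):
        raise FitError("transition not bracketed by the potential range", best)
    fit = NernstFit(Em=float(res.x[0]), a_ox=float(res.x[1]), a_red=float(res.x[2]))
    report = FitReport(
        residuals=res.fun,
        cost=float(res.cost),
        stderr=_stderr_from_jacobian(res.jac, res.fun, ["Em", "a_ox", "a_red"]),
        success=True,
    )
    return fit, report


# ---------------------------------------------------------------------------
# First-order decay


@dataclass
class DecayParams:
    """First-order decay: A(t) = A0 * exp(-k t); half_life = ln 2 / k (min)."""

    A0: float
    k: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("decay rate k must be positive")

    @property
    def half_life(self) -> float:
        return math.log(2.0) / self.k


def fit_decay(curve) -> tuple[DecayParams, FitReport]:
    """Fit a single-exponential decay to a time/absorbance trace.

    Initialised from the log-linear regression of ln A on t, then refined by
    nonlinear least squares on the raw absorbances.  Requires >= 5 points
    with t >= 0 and positive absorbances; a non-decaying trace (fitted slope
    >= 0) raises :class:`FitError`.
    """
    t, A = _as_xy(curve)
    if t.size < 5:
        raise ValueError("decay fit requires at least 5 points")
    if np.any(t < 0):
        raise ValueError("time points must be nonnegative")
    if np.any(A <= 0):
        raise ValueError("absorbances must be positive for a decay fit")
    slope, intercept = np.polyfit(t, np.log(A), 1)
    if slope >= 0:
        raise FitError("trace is non-decaying (log-linear slope >= 0)",
                       {"A0": float(np.exp(intercept)), "k": float(-slope)})
    x0 = np.array([np.exp(intercept), -slope])

    def resid(x):
        return x[0] * np.exp(-x[1] * t) - A

    res = least_squares(resid, x0, method="trf",
                        bounds=([0.0, 1e-12], [np.inf, np.inf]),
                        xtol=1e-10, ftol=1e-10, gtol=1e-10)
    if not res.success or res.x[1] <= 1e-10:
        raise FitError("decay fit did not converge to a positive rate",
                       {"A0": float(res.x[0]), "k": float(res.x[1])})
    params = DecayParams(A0=float(res.x[0]), k=float(res.x[1]))
    report = FitReport(
        residuals=res.fun,
        cost=float(res.cost),
        stderr=_stderr_from_jacobian(res.jac, res.fun, ["A0", "k"]),
        success=True,
    )
    return params, report


# ---------------------------------------------------------------------------
# Spectral decomposition


@dataclass
class Spectrum:
    """A field-swept spectrum: magnetic field grid (mT) and intensities."""

    field: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.field = np.asarray(self.field, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field.shape != self.intensity.shape or self.field.ndim != 1:
            raise ValueError("field and intensity must be equal-length 1-D arrays")
        if self.field.size and np.any(np.diff(self.field) <= 0):
            raise ValueError("field grid must be strictly increasing")


@dataclass
class DecompResult:
    w_mono: float
    w_dimer: float
    monomer_dimer_ratio: float
    residual_norm: float


def decompose_spectrum(
    composite: Spectrum,
    basis_mono: Spectrum,
    basis_dimer: Spectrum,
    scale_mono: float = 1.0,
    scale_dimer: float = 1.0,
) -> DecompResult:
    """Nonnegative two-basis decomposition of a composite spectrum.

    Solves ``min ||composite - w_m * B_m - w_d * B_d||^2`` with w >= 0 via
    NNLS.  The monomer:dimer ratio is ``(w_m * scale_mono) / (w_d *
    scale_dimer)``; with the default unit scales it is a signal-weight
    ratio.  All three spectra must share the field grid, and the bases must
    not be collinear.
    """
    for name, spec in (("basis_mono", basis_mono), ("basis_dimer", basis_dimer)):
        if not np.array_equal(spec.field, composite.field):
            raise ValueError(f"{name} field grid differs from the composite's")
    B = np.column_stack([basis_mono.intensity, basis_dimer.intensity])
    norms = np.linalg.norm(B, axis=0)
    if np.any(norms == 0):
        raise ValueError("a basis spectrum is identically zero")
    cosine = abs(float(B[:, 0] @ B[:, 1]) / (norms[0] * norms[1]))
    if cosine > 1.0 - 1e-10:
        raise ValueError("basis spectra are collinear; decomposition is ill-posed")
    w, rnorm = nnls(B, composite.intensity)
    w_m, w_d = float(w[0]), float(w[1])
    ratio = math.inf if w_d * scale_dimer == 0 else (w_m * scale_mono) / (w_d * scale_dimer)
    return DecompResult(
        w_mono=w_m, w_dimer=w_d, monomer_dimer_ratio=ratio, residual_norm=float(rnorm)
    )


# ---------------------------------------------------------------------------
# Curve file I/O


def read_curve(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    """Read a two-column delimited curve file with a one-line header.

    Returns (x, y, (x_name, y_name)).  Tab, comma and whitespace delimiters
    are all accepted.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if df.shape[1] != 2:
        raise ValueError(f"curve file {path} must have exactly two columns")
    x = df.iloc[:, 0].to_numpy(dtype=float)
    y = df.iloc[:, 1].to_numpy(dtype=float)
    return x, y, (str(df.columns[0]), str(df.columns[1]))


def write_curve(x, y, path: str | Path, names: tuple[str, str] = ("x", "y")) -> None:
    pd.DataFrame({names[0]: np.asarray(x), names[1]: np.asarray(y)}).to_csv(
        path, sep="\t", index=False
    )
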