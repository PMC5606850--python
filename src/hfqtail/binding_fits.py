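"""Binding, competition and kinetic curve analysis.

Implements the mathematics of the fluorescence-anisotropy and
stopped-flow experiments: the single-site isotherm
y = Ka·x / (1 + Ka·x), the Hill isotherm y = xⁿ/(Kdⁿ + xⁿ), the
four-parameter IC50 competition curve, single/double exponential
progress curves, ordinary least-squares with adjusted R², and the
derived quantities K_rel = Kd(product)/Kd(substrate),
ΔΔG° = −RT·ln(Kd_mut/Kd_wt), and the three-state anisotropy
deconvolution into molar fractions of released duplex, ternary
complex and binary complex.

Nonlinear fits use trust-region least squares with a coarse-grid
multi-start fallback; confidence intervals come from the
Jacobian-based covariance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import statsmodels.api as sm
from scipy.optimize import curve_fit

__all__ = [
    "TitrationDataset",
    "AnisotropyPhases",
    "ProgressCurve",
    "FitResult",
    "FitError",
    "fit_single_site",
    "fit_hill",
    "fit_ic50",
    "fit_exponential",
    "compute_krel",
    "compute_ddg",
    "relative_rate",
    "molar_fractions",
    "linear_fit",
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
]

GAS_CONSTANT_KCAL = 1.987e-3   # kcal/(mol*K)
DEFAULT_TEMPERATURE = 303.15   # K; binding assays at 30 °C


class FitError(RuntimeError):
    """A curve fit could not be performed or did not converge."""


@dataclass
class TitrationDataset:
    """Concentration series with a normalized binding signal.

    ``unit`` and ``basis`` record the concentration scale (e.g. "µM"
    on a monomer basis for peptide binding, "nM" on a hexamer basis
    for RNA binding); fits report parameters on that same scale.
    """

    x: np.ndarray
    y: np.ndarray
    y_sd: np.ndarray | None = None
    unit: str = "µM"
    basis: str = "monomer"
    replicates: int = 1

    def __post_init__(self) -> None:
        order = np.argsort(np.asarray(self.x, dtype=float))
        self.x = np.asarray(self.x, dtype=float)[order]
        self.y = np.asarray(self.y, dtype=float)[order]
        if self.y_sd is not None:
            self.y_sd = np.asarray(self.y_sd, dtype=float)[order]
        if np.any(self.x < 0):
            raise ValueError("concentrations must be non-negative")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("signal contains non-finite values")
        if len(self.x) != len(self.y):
            raise ValueError("x and y lengths differ")


@dataclass
class AnisotropyPhases:
    """Endpoint and reference anisotropies of the release experiment.

    r_AP    anisotropy at the end of the annealing-and-release phase
    r_Mdr   free duplex (fully released product)
    r_Mhdr  ternary complex (equilibrium maximum)
    r_Mhd   binary complex (equilibrium maximum, reporting only)
    r_hd    binary complex at the annealing-phase endpoint (used in
            the deconvolution)
    K_rel   Kd(product)/Kd(substrate), fixing χ_hd = K_rel·χ_hdr
    """

    r_AP: float
    r_Mdr: float
    r_Mhdr: float
    r_Mhd: float
    r_hd: float
    K_rel: float

    def __post_init__(self) -> None:
        for name in ("r_AP", "r_Mdr", "r_Mhdr", "r_Mhd", "r_hd"):
            v = getattr(self, name)
            if not (0 < v < 0.4):
                raise ValueError(f"{name} = {v} outside the physical (0, 0.4)")
        if self.K_rel < 0:
            raise ValueError("K_rel must be non-negative")


@dataclass
class ProgressCurve:
    """Stopped-flow style time course."""

    t: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(self.t < 0) or np.any(np.diff(self.t) <= 0):
            raise ValueError("time must be non-negative and increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("signal contains non-finite values")


@dataclass
class FitResult:
    """Fitted parameters with Jacobian-based standard errors."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    rss: float
    n: int
    unit: str = ""
    basis: str = ""

    def __getitem__(self, key: str) -> float:
        return self.params[key]


def _run_fit(
    model_name: str,
    func,
    x: np.ndarray,
    y: np.ndarray,
    p0: list[float],
    bounds,
    param_names: list[str],
    starts: list[list[float]] | None = None,
    unit: str = "",
    basis: str = "",
) -> FitResult:
    attempts = [p0] + (starts or [])
    last_err: Exception | None = None
    best = None
    for start in attempts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, pcov = curve_fit(
                    func, x, y, p0=start, bounds=bounds,
                    method="trf", maxfev=20000, xtol=1e-12, ftol=1e-12,
                )
            rss = float(np.sum((func(x, *popt) - y) ** 2))
            if best is None or rss < best[2]:
                best = (popt, pcov, rss)
        except Exception as err:  # noqa: BLE001 - collected as diagnostics
            last_err = err
    if best is None:
        raise FitError(f"{model_name} fit failed: {last_err}")
    popt, pcov, rss = best
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    params = dict(zip(param_names, map(float, popt)))
    stderr = dict(zip(param_names, map(float, se)))
    ci95 = {
        k: (params[k] - 1.96 * stderr[k], params[k] + 1.96 * stderr[k])
        for k in param_names
    }
    return FitResult(
        model=model_name, params=params, stderr=stderr, ci95=ci95,
        rss=rss, n=len(x), unit=unit, basis=basis,
    )


def _require_curvature(y: np.ndarray, model: str) -> None:
    scale = max(abs(float(np.max(y))), 1e-12)
    if np.ptp(y) < 1e-3 * scale:
        raise FitError(f"{model}: signal shows no curvature (y is constant)")


def fit_single_site(data: TitrationDataset) -> FitResult:
    """Single-site isotherm y = Ka·x/(1 + Ka·x); reports Ka and Kd = 1/Ka."""
    if len(data.x) < 5:
        raise FitError("single-site fit needs at least 5 points")
    _require_curvature(data.y, "single-site")

    def model(x, ka):
        return ka * x / (1.0 + ka * x)

    xpos = data.x[data.x > 0]
    p0 = [1.0 / float(np.median(xpos))]
    starts = [[1.0 / v] for v in np.geomspace(xpos.min(), xpos.max(), 5)]
    res = _run_fit(
        "single_site", model, data.x, data.y, p0, (1e-12, np.inf),
        ["Ka"], starts, unit=data.unit, basis=data.basis,
    )
    ka, ka_se = res.params["Ka"], res.stderr["Ka"]
    res.params["Kd"] = 1.0 / ka
    res.stderr["Kd"] = ka_se / ka**2  # delta method
    res.ci95["Kd"] = (
        res.params["Kd"] - 1.96 * res.stderr["Kd"],
        res.params["Kd"] + 1.96 * res.stderr["Kd"],
    )
    return res


def fit_hill(data: TitrationDataset, fix_n: float | None = None) -> FitResult:
    """Hill isotherm y = xⁿ/(Kdⁿ + xⁿ); n free unless *fix_n* given."""
    if len(data.x) < 5:
        raise FitError("Hill fit needs at least 5 points")
    _require_curvature(data.y, "hill")
    xpos = data.x[data.x > 0]
    half = float(data.x[np.argmin(np.abs(data.y - 0.5 * np.max(data.y)))])
    half = half if half > 0 else float(np.median(xpos))

    if fix_n is not None:
        def model(x, kd):
            with np.errstate(divide="ignore", invalid="ignore"):
                out = np.where(
                    x > 0, x**fix_n / (kd**fix_n + x**fix_n), 0.0
                )
            return out
        res = _run_fit(
            "hill", model, data.x, data.y, [half], (1e-12, np.inf),
            ["Kd"], [[v] for v in np.geomspace(xpos.min(), xpos.max(), 5)],
            unit=data.unit, basis=data.basis,
        )
        res.params["n"] = float(fix_n)
        res.stderr["n"] = 0.0
        res.ci95["n"] = (float(fix_n), float(fix_n))
        return res

    def model(x, kd, n):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(x > 0, x**n / (kd**n + x**n), 0.0)

    starts = [[v, n] for v in np.geomspace(xpos.min(), xpos.max(), 3)
              for n in (0.7, 1.0, 2.0)]
    return _run_fit(
        "hill", model, data.x, data.y, [half, 1.0],
        ([1e-12, 0.05], [np.inf, 20.0]), ["Kd", "n"], starts,
        unit=data.unit, basis=data.basis,
    )


def fit_ic50(data: TitrationDataset) -> FitResult:
    """Competition curve y = minY + (maxY − minY)/(1 + (x/IC50)ⁿ)."""
    if len(data.x) < 5:
        raise FitError("IC50 fit needs at least 5 points")
    _require_curvature(data.y, "ic50")
    lo = data.y[: max(2, len(data.y) // 4)].mean()
    hi = data.y[-max(2, len(data.y) // 4):].mean()
    if hi > lo:
        raise FitError(
            "signal increases with competitor; a competition curve must "
            "decrease toward minY"
        )

    def model(x, ic50, n, min_y, max_y):
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(x > 0, 1.0 / (1.0 + (x / ic50) ** n), 1.0)
        return min_y + (max_y - min_y) * frac

    xpos = data.x[data.x > 0]
    ymin, ymax = float(np.min(data.y)), float(np.max(data.y))
    p0 = [float(np.median(xpos)), 1.0, ymin, ymax]
    starts = [[v, n, ymin, ymax]
              for v in np.geomspace(xpos.min(), xpos.max(), 3)
              for n in (0.7, 1.5)]
    return _run_fit(
        "ic50", model, data.x, data.y, p0,
        ([1e-12, 0.05, -np.inf, -np.inf], [np.inf, 20.0, np.inf, np.inf]),
        ["IC50", "n", "minY", "maxY"], starts,
        unit=data.unit, basis=data.basis,
    )


def fit_exponential(curve: ProgressCurve, order: str = "single") -> FitResult:
    """Exponential progress-curve fit.

    single: y = A·(1 − exp(−k·t)) + c
    double: y = A1·(1 − exp(−k1·t)) + A2·(1 − exp(−k2·t)) + c,
    reporting the larger-amplitude rate as ``k_obs``.
    """
    if len(curve.t) < 10:
        raise FitError("exponential fit needs at least 10 points")
    _require_curvature(curve.y, "exponential")
    t, y = curve.t, curve.y
    amp0 = float(np.ptp(y))
    c0 = float(y[0])
    t_half = t[len(t) // 3] if t[len(t) // 3] > 0 else t[-1] / 3
    k0 = math.log(2) / max(t_half, 1e-9)

    if order == "single":
        def model(tt, a, k, c):
            return a * (1.0 - np.exp(-k * tt)) + c
        res = _run_fit(
            "exp_single", model, t, y, [amp0, k0, c0],
            ([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
            ["A", "k", "c"],
            [[amp0, k0 * f, c0] for f in (0.1, 0.5, 2.0, 10.0)],
        )
        res.params["k_obs"] = res.params["k"]
        res.stderr["k_obs"] = res.stderr["k"]
        res.ci95["k_obs"] = res.ci95["k"]
        return res
    if order == "double":
        def model(tt, a1, k1, a2, k2, c):
            return (a1 * (1.0 - np.exp(-k1 * tt))
                    + a2 * (1.0 - np.exp(-k2 * tt)) + c)
        res = _run_fit(
            "exp_double", model, t, y,
            [0.7 * amp0, 2 * k0, 0.3 * amp0, 0.2 * k0, c0],
            ([-np.inf, 1e-9, -np.inf, 1e-9, -np.inf],
             [np.inf, np.inf, np.inf, np.inf, np.inf]),
            ["A1", "k1", "A2", "k2", "c"],
            [[0.5 * amp0, k0 * f, 0.5 * amp0, k0 / f, c0] for f in (2, 5, 20)],
        )
        dominant = "k1" if abs(res.params["A1"]) >= abs(res.params["A2"]) else "k2"
        res.params["k_obs"] = res.params[dominant]
        res.stderr["k_obs"] = res.stderr[dominant]
        res.ci95["k_obs"] = res.ci95[dominant]
        return res
    raise ValueError("order must be 'single' or 'double'")


def compute_krel(
    kd_product: float,
    kd_substrate: float,
    unit_product: str | None = None,
    unit_substrate: str | None = None,
) -> float:
    """K_rel = Kd(product)/Kd(substrate), rounded half-up to 1 decimal.

    Large K_rel means the annealed duplex is bound much more weakly
    than the single-stranded substrate, i.e. efficient product release.
    """
    if kd_product <= 0 or kd_substrate <= 0:
        raise ValueError("dissociation constants must be positive")
    if (
        unit_product is not None
        and unit_substrate is not None
        and unit_product != unit_substrate
    ):
        raise ValueError(
            f"unit mismatch: {unit_product!r} vs {unit_substrate!r}"
        )
    ratio = Decimal(str(kd_product)) / Decimal(str(kd_substrate))
    return float(ratio.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def compute_ddg(
    kd_mut: float,
    kd_wt: float,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """ΔΔG° = −RT·ln(Kd_mut/Kd_wt) in kcal/mol (negative = weaker mutant)."""
    if kd_mut <= 0 or kd_wt <= 0:
        raise ValueError("dissociation constants must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return -GAS_CONSTANT_KCAL * temperature * math.log(kd_mut / kd_wt)


def relative_rate(k_obs_variant: float, k_obs_reference: float) -> float:
    """k_rel = k_obs(variant)/k_obs(reference); < 1 means slower variant."""
    if k_obs_variant <= 0 or k_obs_reference <= 0:
        raise ValueError("rates must be positive")
    return k_obs_variant / k_obs_reference


def molar_fractions(
    phases: AnisotropyPhases,
) -> tuple[float, float, float]:
    """(χ_dr, χ_hdr, χ_hd) from the endpoint anisotropy.

    Solves r_AP = χ_dr·r_Mdr + χ_hdr·r_Mhdr + χ_hd·r_hd together with
    mass conservation (χ's sum to 1) and the affinity-ratio constraint
    χ_hd = K_rel·χ_hdr, which gives

        χ_hdr = (r_AP − r_Mdr)
                / (r_Mhdr + K_rel·r_hd − (1 + K_rel)·r_Mdr).

    A fraction outside [0, 1] raises a warning, not an error: small
    excursions reflect anisotropy measurement noise.
    """
    k = phases.K_rel
    denom = phases.r_Mhdr + k * phases.r_hd - (1.0 + k) * phases.r_Mdr
    if abs(denom) < 1e-9:
        raise ZeroDivisionError(
            "degenerate anisotropy system: denominator ~ 0"
        )
    chi_hdr = (phases.r_AP - phases.r_Mdr) / denom
    chi_hd = k * chi_hdr
    chi_dr = 1.0 - chi_hdr - chi_hd
    for name, v in (("chi_dr", chi_dr), ("chi_hdr", chi_hdr), ("chi_hd", chi_hd)):
        if not (0.0 <= v <= 1.0):
            warnings.warn(
                f"{name} = {v:.4f} outside [0, 1]; check input anisotropies",
                stacklevel=2,
            )
    return chi_dr, chi_hdr, chi_hd


def linear_fit(x, y) -> dict[str, float]:
    """OLS of y on x: slope, intercept, adjusted R², slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r_squared": float(model.rsquared),
        "adjusted_r_squared": float(model.rsquared_adj),
        "p_value_slope": float(model.pvalues[1]),
        "n": int(len(x)),
    }
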