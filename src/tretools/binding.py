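"""One-site ligand-binding models for fluorescence polarization assays.

Two classical pharmacology fits are implemented as Model/Results pairs:

*Saturation ("one site -- total binding")*::

    signal(L) = Bmax * L / (Kd + L) + ns * L + background

a specific hyperbola plus linear nonspecific binding, fitted to a titration
of the labelled ligand.

*Competition ("one site -- fit Ki")*::

    signal(I) = bottom + (top - bottom) / (1 + 10**(log10 I - log10 IC50))
    IC50 = Ki * (1 + [hot] / Kd_hot)

a four-parameter logistic in log10 concentration with unit slope, with the
midpoint tied to the competitor's inhibition constant Ki through the
Cheng-Prusoff correction for the labelled ("hot") ligand present at a known
concentration and affinity.

Both fits run in log10 space for the affinity parameter, which enforces
positivity; 95% confidence intervals are asymptotic (t-based on the
least-squares covariance).  Replicates are pooled into one residual vector
by default rather than averaged first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DilutionSeries",
    "make_dilution_series",
    "saturation_model",
    "competition_model",
    "SaturationBindingModel",
    "SaturationResults",
    "CompetitionBindingModel",
    "CompetitionResults",
    "fit_saturation",
    "fit_competition",
    "normalize_mp",
    "FitError",
    "NoDisplacementError",
]


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge."""


class NoDisplacementError(ValueError):
    """Competition data show no concentration-dependent transition."""


@dataclass(frozen=True)
class DilutionSeries:
    """A serial dilution: start_conc / factor**i for i = 0..n_points-1 (molar)."""

    start_conc: float
    factor: float
    n_points: int

    def __post_init__(self) -> None:
        if self.start_conc <= 0:
            raise ValueError("start_conc must be positive")
        if self.factor <= 1:
            raise ValueError("dilution factor must exceed 1")
        if self.n_points < 2:
            raise ValueError("need at least 2 dilution points")

    @property
    def concentrations(self) -> np.ndarray:
        return self.start_conc / self.factor ** np.arange(self.n_points)

    @property
    def min_conc(self) -> float:
        return float(self.start_conc / self.factor ** (self.n_points - 1))


def make_dilution_series(
    start_conc: float, factor: float, n_points: int
) -> DilutionSeries:
    """The assay's titration design, e.g. (2.7e-4 M, 3-fold, 18 points)."""
    return DilutionSeries(start_conc, factor, n_points)


def saturation_model(conc, kd, bmax, ns_slope=0.0, background=0.0):
    """Total-binding signal at ligand concentration ``conc`` (molar)."""
    conc = np.asarray(conc, dtype=float)
    return bmax * conc / (kd + conc) + ns_slope * conc + background


def competition_model(log10_conc, ki, top, bottom, hot_conc, hot_kd):
    """Normalized polarization at competitor concentration 10**log10_conc."""
    ic50 = ki * (1.0 + hot_conc / hot_kd)
    x = np.asarray(log10_conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + 10.0 ** (x - np.log10(ic50)))


def _as_arrays(observations) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(observations, pd.DataFrame):
        conc = observations["conc"].to_numpy(dtype=float)
        signal = observations["signal"].to_numpy(dtype=float)
        if "replicate" in observations.columns:
            rep = observations["replicate"].to_numpy()
        else:
            rep = np.zeros(len(conc), dtype=int)
        return conc, signal, rep
    conc, signal = observations
    conc = np.asarray(conc, dtype=float)
    signal = np.asarray(signal, dtype=float)
    return conc, signal, np.zeros(conc.size, dtype=int)


def _ci95(estimates: np.ndarray, cov: np.ndarray, dof: int) -> np.ndarray:
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    tcrit = stats.t.ppf(0.975, max(dof, 1))
    return np.column_stack([estimates - tcrit * se, estimates + tcrit * se])


@dataclass
class SaturationResults:
    """Fitted one-site total-binding parameters with asymptotic 95% CIs."""

    kd: float
    bmax: float
    ns_slope: float
    background: float
    ci95: Mapping[str, tuple[float, float]]
    rss: float
    nobs: int
    fittedvalues: np.ndarray
    resid: np.ndarray

    def summary(self) -> str:
        lines = ["One site - total binding", "=" * 48]
        for name in ("kd", "bmax", "ns_slope", "background"):
            lo, hi = self.ci95[name]
            lines.append(
                f"  {name:<10s} {getattr(self, name):>12.4g}"
                f"   95% CI [{lo:.4g}, {hi:.4g}]"
            )
        lines.append(f"  n = {self.nobs}, RSS = {self.rss:.4g}")
        return "\n".join(lines)


class SaturationBindingModel:
    """Saturation (total) binding fit of a labelled-ligand titration.

    ``data`` is a DataFrame with columns ``conc`` (molar), ``signal`` and
    optionally ``replicate``, or a ``(conc, signal)`` pair of arrays.
    Replicates are pooled into one residual vector.
    """

    def __init__(self, data, average_replicates: bool = False):
        conc, signal, rep = _as_arrays(data)
        if average_replicates:
            df = pd.DataFrame({"conc": conc, "signal": signal})
            g = df.groupby("conc", as_index=False)["signal"].mean()
            conc, signal = g["conc"].to_numpy(), g["signal"].to_numpy()
            rep = np.zeros(conc.size, dtype=int)
        if np.any(conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.unique(conc).size < 5:
            raise ValueError("need at least 5 distinct concentrations")
        order = np.argsort(conc)
        self.conc = conc[order]
        self.signal = signal[order]
        self.replicate = rep[order]

    def fit(self) -> SaturationResults:
        conc, signal = self.conc, self.signal
        bg0 = float(signal.min())
        bmax0 = max(float(signal.max() - bg0), 1e-12)
        half = bg0 + bmax0 / 2.0
        kd0 = float(conc[np.argmin(np.abs(signal - half))])
        kd0 = max(kd0, conc[conc > 0].min())

        def f(c, log10_kd, bmax, ns, bg):
            return saturation_model(c, 10.0 ** log10_kd, bmax, ns, bg)

        p0 = [np.log10(kd0), bmax0, 0.0, bg0]
        try:
            popt, pcov = optimize.curve_fit(f, conc, signal, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            resid = signal - f(conc, *p0)
            raise FitError(
                f"saturation fit did not converge (residual SS at start "
                f"{float(resid @ resid):.4g}): {exc}"
            ) from exc
        fitted = f(conc, *popt)
        resid = signal - fitted
        dof = conc.size - 4
        ci = _ci95(popt, pcov, dof)
        kd = 10.0 ** popt[0]
        ci95 = {
            "kd": (10.0 ** ci[0, 0], 10.0 ** ci[0, 1]),
            "bmax": tuple(ci[1]),
            "ns_slope": tuple(ci[2]),
            "background": tuple(ci[3]),
        }
        return SaturationResults(
            kd=float(kd), bmax=float(popt[1]), ns_slope=float(popt[2]),
            background=float(popt[3]), ci95=ci95,
            rss=float(resid @ resid), nobs=conc.size,
            fittedvalues=fitted, resid=resid,
        )


@dataclass
class CompetitionResults:
    """Fitted one-site competition parameters; IC50 is tied to Ki."""

    ki: float
    ic50: float
    top: float
    bottom: float
    hot_conc: float
    hot_kd: float
    ci95: Mapping[str, tuple[float, float]]
    rss: float
    nobs: int
    fittedvalues: np.ndarray
    resid: np.ndarray

    def summary(self) -> str:
        lines = ["One site - fit Ki (Cheng-Prusoff)", "=" * 48]
        for name in ("ki", "ic50", "top", "bottom"):
            lo, hi = self.ci95[name]
            lines.append(
                f"  {name:<8s} {getattr(self, name):>12.4g}"
                f"   95% CI [{lo:.4g}, {hi:.4g}]"
            )
        lines.append(
            f"  hot ligand: {self.hot_conc:.3g} M at Kd {self.hot_kd:.3g} M"
        )
        lines.append(f"  n = {self.nobs}, RSS = {self.rss:.4g}")
        return "\n".join(lines)


class CompetitionBindingModel:
    """Competitive displacement fit with known hot-ligand concentration and Kd."""

    def __init__(self, data, hot_conc: float, hot_kd: float,
                 average_replicates: bool = False):
        if hot_conc <= 0 or hot_kd <= 0:
            raise ValueError("hot_conc and hot_kd must be positive")
        conc, signal, rep = _as_arrays(data)
        if np.any(conc <= 0):
            raise ValueError("competitor concentrations must be positive")
        if average_replicates:
            df = pd.DataFrame({"conc": conc, "signal": signal})
            g = df.groupby("conc", as_index=False)["signal"].mean()
            conc, signal = g["conc"].to_numpy(), g["signal"].to_numpy()
            rep = np.zeros(conc.size, dtype=int)
        if np.unique(conc).size < 5:
            raise ValueError("need at least 5 distinct concentrations")
        order = np.argsort(conc)
        self.conc = conc[order]
        self.signal = signal[order]
        self.replicate = rep[order]
        self.hot_conc = float(hot_conc)
        self.hot_kd = float(hot_kd)

    def _check_displacement(self) -> None:
        df = pd.DataFrame({"conc": self.conc, "signal": self.signal})
        g = df.groupby("conc")["signal"]
        means = g.mean().to_numpy()
        sizes = g.size().to_numpy()
        rng = float(means.max() - means.min())
        if (sizes > 1).any():
            noise = float(g.std(ddof=1).dropna().mean())
        elif means.size > 2:
            noise = float(np.std(np.diff(means)) / np.sqrt(2.0))
        else:
            noise = 0.0
        scale = max(1.0, float(np.abs(self.signal).max()))
        if rng <= max(3.0 * noise, 1e-9 * scale):
            raise NoDisplacementError(
                "no displacement detected: signal range "
                f"{rng:.3g} is within noise ({noise:.3g})"
            )

    def fit(self) -> CompetitionResults:
        self._check_displacement()
        x = np.log10(self.conc)
        signal = self.signal
        df = pd.DataFrame({"x": x, "y": signal}).groupby("x")["y"].mean()
        top0 = float(df.iloc[0])
        bottom0 = float(df.iloc[-1])
        mid = (top0 + bottom0) / 2.0
        x_mid = float(df.index[np.argmin(np.abs(df.to_numpy() - mid))])
        cp = 1.0 + self.hot_conc / self.hot_kd
        ki0 = 10.0 ** x_mid / cp

        def f(xx, log10_ki, top, bottom):
            return competition_model(
                xx, 10.0 ** log10_ki, top, bottom, self.hot_conc, self.hot_kd
            )

        p0 = [np.log10(ki0), top0, bottom0]
        try:
            popt, pcov = optimize.curve_fit(f, x, signal, p0=p0, maxfev=20000)
        except RuntimeError as exc:
            resid = signal - f(x, *p0)
            raise FitError(
                f"competition fit did not converge (residual SS at start "
                f"{float(resid @ resid):.4g}): {exc}"
            ) from exc
        fitted = f(x, *popt)
        resid = signal - fitted
        dof = x.size - 3
        ci = _ci95(popt, pcov, dof)
        ki = 10.0 ** popt[0]
        ci95 = {
            "ki": (10.0 ** ci[0, 0], 10.0 ** ci[0, 1]),
            "ic50": (10.0 ** ci[0, 0] * cp, 10.0 ** ci[0, 1] * cp),
            "top": tuple(ci[1]),
            "bottom": tuple(ci[2]),
        }
        return CompetitionResults(
            ki=float(ki), ic50=float(ki * cp), top=float(popt[1]),
            bottom=float(popt[2]), hot_conc=self.hot_conc, hot_kd=self.hot_kd,
            ci95=ci95, rss=float(resid @ resid), nobs=x.size,
            fittedvalues=fitted, resid=resid,
        )


def fit_saturation(observations, **kw) -> SaturationResults:
    return SaturationBindingModel(observations, **kw).fit()


def fit_competition(observations, hot_conc: float, hot_kd: float, **kw) -> CompetitionResults:
    return CompetitionBindingModel(observations, hot_conc, hot_kd, **kw).fit()


def normalize_mp(observations: pd.DataFrame) -> pd.DataFrame:
    """Rescale each replicate series to 0-100 by its observed min and max.

    Requires columns ``conc``, ``signal``, ``replicate``; a constant series
    (no dynamic range) is an error.
    """
    out = observations.copy()

    def _scale(s: pd.Series) -> pd.Series:
        lo, hi = float(s.min()), float(s.max())
        if hi == lo:
            raise ValueError("cannot normalize a constant signal series")
        return (s - lo) / (hi - lo) * 100.0

    out["signal"] = out.groupby("replicate")["signal"].transform(_scale)
    return out
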