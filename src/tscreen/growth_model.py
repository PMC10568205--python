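"""Growth-rate extraction and Arrhenius-type growth-temperature modelling.

Maximal specific growth rates are the steepest log-linear slope of OD(t)
over a sliding window restricted to clean exponential stretches. The
growth-temperature relationship of a TS mutant is described by the
empirical two-term Arrhenius difference

    mu(T) = exp(a_act - E_act / (R*T)) - exp(a_inact - E_inact / (R*T))

with T in kelvin and R the gas constant: the activating term captures the
thermal acceleration of metabolism, the steeper inactivating term
(E_inact > E_act) the collapse of the TS protein, producing a growth
optimum followed by a high-temperature crash. Predicted rates are clipped
at zero. Two summary parameters characterize a mutant as a growth switch:
the switching temperature (above the optimum, where mu has fallen to half
its maximum) and the responsiveness (the maximal rate of growth-rate loss
per kelvin).

``GrowthTemperatureModel`` follows the model/results idiom: build it from
(temperature, rate) data, call :meth:`~GrowthTemperatureModel.fit`, and
read estimates and diagnostics off the returned :class:`ArrheniusFit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.cluster import KMeans

__all__ = [
    "GrowthCurve",
    "GrowthTemperatureModel",
    "ArrheniusFit",
    "max_growth_rate",
    "fit_arrhenius",
    "switch_metrics",
    "classify_response",
    "arrhenius_mu",
    "R_GAS",
]

R_GAS = 8.314462618  # J mol^-1 K^-1
_C0 = 273.15


@dataclass
class GrowthCurve:
    """One plate-reader OD(600 nm) time series."""

    time_h: np.ndarray
    od: np.ndarray
    temperature: float  # degC
    strain_id: str = ""
    replicate: str = ""

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.od <= 0):
            raise ValueError("OD must be positive (floor at the instrument blank)")


def max_growth_rate(
    curve: GrowthCurve, window: int = 9, min_window_r2: float = 0.98
) -> float:
    """Maximal specific growth rate (h^-1) from a sliding log-linear fit.

    The slope of ln(OD) vs time is fitted in every window of ``window``
    points (about 90 min at 10-min sampling); only windows with a
    log-linear R^2 of at least ``min_window_r2`` count as exponential
    phase. The maximum qualifying slope is returned; a negative maximum
    (or no qualifying window) is no growth, 0 h^-1.
    """
    t, y = curve.time_h, np.log(curve.od)
    n = t.size
    if n < window:
        raise ValueError(f"need at least {window} points, have {n}")
    # rolling least squares via sliding windows (vectorized)
    tw = np.lib.stride_tricks.sliding_window_view(t, window)
    yw = np.lib.stride_tricks.sliding_window_view(y, window)
    tm = tw.mean(axis=1, keepdims=True)
    ym = yw.mean(axis=1, keepdims=True)
    sxx = ((tw - tm) ** 2).sum(axis=1)
    syy = ((yw - ym) ** 2).sum(axis=1)
    sxy = ((tw - tm) * (yw - ym)).sum(axis=1)
    slope = sxy / sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = sxy**2 / (sxx * syy)
    ok = np.isfinite(r2) & (r2 >= min_window_r2)
    if not ok.any():
        return 0.0
    best = float(slope[ok].max())
    return max(best, 0.0)


def arrhenius_mu(T_celsius, a_act, E_act, a_inact, E_inact, clip: bool = True):
    """mu(T) of the two-term model; ``clip`` floors predictions at 0."""
    TK = np.asarray(T_celsius, dtype=float) + _C0
    mu = np.exp(a_act - E_act / (R_GAS * TK)) - np.exp(a_inact - E_inact / (R_GAS * TK))
    return np.maximum(mu, 0.0) if clip else mu


@dataclass
class ArrheniusFit:
    """Fitted growth-temperature relationship with switch diagnostics."""

    params: dict[str, float]
    r2: float
    rss: float
    converged: bool
    temperatures: np.ndarray
    rates: np.ndarray
    T_opt: float | None = None
    T_switch: float | None = None
    responsiveness: float | None = None

    def predict(self, T_celsius, clip: bool = True):
        p = self.params
        return arrhenius_mu(
            T_celsius, p["a_act"], p["E_act"], p["a_inact"], p["E_inact"], clip=clip
        )

    def summary(self) -> str:
        lines = [
            "Arrhenius-type growth-temperature fit",
            "=" * 46,
            f"{'n temperatures':<24}{len(self.temperatures):>10d}",
            f"{'R^2 (mu scale)':<24}{self.r2:>10.4f}",
            f"{'RSS':<24}{self.rss:>10.4g}",
            f"{'converged':<24}{str(self.converged):>10}",
            "-" * 46,
        ]
        for k in ("a_act", "E_act", "a_inact", "E_inact"):
            unit = "J/mol" if k.startswith("E") else "-"
            lines.append(f"{k:<12}{self.params[k]:>18.6g}  [{unit}]")
        lines.append("-" * 46)
        fmt = lambda v, u: "undefined" if v is None else f"{v:.3f} {u}"
        lines.append(f"{'T_opt':<16}{fmt(self.T_opt, 'degC')}")
        lines.append(f"{'T_switch':<16}{fmt(self.T_switch, 'degC')}")
        lines.append(f"{'responsiveness':<16}{fmt(self.responsiveness, 'h^-1 K^-1')}")
        return "\n".join(lines)


class GrowthTemperatureModel:
    """Arrhenius-type model of specific growth rate vs temperature.

    Parameters
    ----------
    temperatures : array-like, degC
    rates : array-like, h^-1, nonnegative

    ``fit()`` runs multi-start nonlinear least squares (grid over
    activation-energy scales and inactivation/activation ratios, the
    E_inact > E_act constraint built into the parameterization) and
    returns an :class:`ArrheniusFit`.
    """

    def __init__(self, temperatures: Sequence[float], rates: Sequence[float]):
        self.temperatures = np.asarray(temperatures, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if self.temperatures.size != self.rates.size:
            raise ValueError("temperatures and rates differ in length")
        if self.temperatures.size < 5:
            raise ValueError("need rates at >= 5 temperatures")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, temp_col: str = "temperature", rate_col: str = "rate"
    ) -> "GrowthTemperatureModel":
        return cls(df[temp_col].to_numpy(), df[rate_col].to_numpy())

    # Internally the two exponentials are centered on a reference
    # temperature (37 degC) so all four parameters are O(1)-O(100):
    #   mu(T) = exp(lnA - (E1/R)(1/T - 1/Tref)) - exp(lnI - (E2/R)(1/T - 1/Tref))
    # with E in kJ/mol and E2 = E1 + dE > E1 enforced by the
    # parameterization q = (lnA, log10 E1, lnI, log10 dE).
    _TREF = 310.15  # K

    @classmethod
    def _unpack(cls, q):
        lnA, lE1, lnI, ldE = q
        E1 = 10.0**lE1 * 1e3  # J/mol
        E2 = E1 + 10.0**ldE * 1e3
        a1 = lnA + E1 / (R_GAS * cls._TREF)
        a2 = lnI + E2 / (R_GAS * cls._TREF)
        return a1, E1, a2, E2

    def _residuals(self, q):
        a1, E1, a2, E2 = self._unpack(q)
        TK = self.temperatures + _C0
        arg1 = np.minimum(a1 - E1 / (R_GAS * TK), 50.0)
        arg2 = np.minimum(a2 - E2 / (R_GAS * TK), 50.0)
        # the observable is clipped at zero (no negative growth), so the
        # model prediction is clipped before comparison
        return np.maximum(np.exp(arg1) - np.exp(arg2), 0.0) - self.rates

    _BOUNDS = ([-30.0, 0.3, -60.0, 0.3], [30.0, 3.2, 30.0, 3.5])

    def _starts(self):
        T, mu = self.temperatures, self.rates
        if mu.max() == 0:
            return []
        i_opt = int(np.argmax(mu))
        TK = T + _C0
        mu_opt = max(mu.max(), 1e-6)

        # activation term from Arrhenius regression on the ascending side,
        # where the inactivating term is negligible
        asc = (np.arange(T.size) <= i_opt) & (mu > 0)
        E1_guesses = [40e3, 70e3]
        if asc.sum() >= 3:
            x = 1.0 / TK[asc] - 1.0 / self._TREF
            y = np.log(mu[asc])
            slope = np.polyfit(x, y, 1)[0]  # = -E1/R
            E1_hat = float(np.clip(-slope * R_GAS, 5e3, 1.2e6))
            E1_guesses = [E1_hat, max(E1_hat, 40e3)]
        starts = []
        for E1 in dict.fromkeys(E1_guesses):
            lnA = np.log(mu_opt) + (E1 / R_GAS) * (1 / TK[i_opt] - 1 / self._TREF)
            for ratio in (3.0, 6.0, 10.0):
                dE = (ratio - 1.0) * E1
                for dT in (1.5, 4.0):
                    Tc = TK[i_opt] + dT
                    lnI = lnA + (dE / R_GAS) * (1 / Tc - 1 / self._TREF)
                    starts.append(
                        [lnA, np.log10(E1 / 1e3), lnI, np.log10(dE / 1e3)]
                    )
        lo, hi = self._BOUNDS
        return [np.clip(s, np.array(lo) + 1e-9, np.array(hi) - 1e-9) for s in starts]

    def fit(self) -> ArrheniusFit:
        best = None
        for q0 in self._starts():
            try:
                sol = optimize.least_squares(
                    self._residuals, q0, method="trf", bounds=self._BOUNDS,
                    xtol=1e-10, ftol=1e-10, max_nfev=150,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is not None:
            # polish the winning start to machine accuracy
            try:
                polished = optimize.least_squares(
                    self._residuals, best.x, method="trf", bounds=self._BOUNDS,
                    xtol=2.3e-16, ftol=2.3e-16, gtol=1e-15, max_nfev=3000,
                )
                if polished.cost <= best.cost:
                    best = polished
            except Exception:
                pass
        if best is None:
            return ArrheniusFit(
                params={k: np.nan for k in ("a_act", "E_act", "a_inact", "E_inact")},
                r2=np.nan, rss=np.nan, converged=False,
                temperatures=self.temperatures, rates=self.rates,
            )
        a1, E1, a2, E2 = self._unpack(best.x)
        pred = arrhenius_mu(self.temperatures, a1, E1, a2, E2)
        rss = float(np.sum((pred - self.rates) ** 2))
        tss = float(np.sum((self.rates - self.rates.mean()) ** 2))
        if tss > 0:
            r2 = 1.0 - rss / tss
        else:
            # degenerate flat data: judge against signal power instead
            r2 = 1.0 - rss / float(np.sum(self.rates**2))
        fit = ArrheniusFit(
            params={"a_act": a1, "E_act": E1, "a_inact": a2, "E_inact": E2},
            r2=r2, rss=rss, converged=bool(best.success),
            temperatures=self.temperatures, rates=self.rates,
        )
        fit.T_opt, fit.T_switch, fit.responsiveness = switch_metrics(fit)
        return fit


def fit_arrhenius(temperatures, rates) -> ArrheniusFit:
    """Functional wrapper around :class:`GrowthTemperatureModel`."""
    if np.all(np.asarray(rates, dtype=float) == 0):
        return ArrheniusFit(
            params={k: np.nan for k in ("a_act", "E_act", "a_inact", "E_inact")},
            r2=np.nan, rss=0.0, converged=False,
            temperatures=np.asarray(temperatures, float),
            rates=np.asarray(rates, float),
        )
    return GrowthTemperatureModel(temperatures, rates).fit()


def _mu_derivative(fit: ArrheniusFit, T_celsius):
    p = fit.params
    TK = np.asarray(T_celsius, dtype=float) + _C0
    act = np.exp(p["a_act"] - p["E_act"] / (R_GAS * TK))
    inact = np.exp(p["a_inact"] - p["E_inact"] / (R_GAS * TK))
    return (act * p["E_act"] - inact * p["E_inact"]) / (R_GAS * TK**2)


def switch_metrics(
    fit: ArrheniusFit,
    T_range: tuple[float, float] = (25.0, 48.0),
    tol_K: float = 0.01,
) -> tuple[float | None, float | None, float | None]:
    """(T_opt, T_switch, responsiveness) of a fitted curve, or Nones.

    T_switch is found by bisection (to ``tol_K``) for mu = mu_max/2 above
    the optimum; responsiveness is the maximum of -d mu/dT over the
    descending flank, from the analytic derivative. Metrics are undefined
    (None) when mu has no interior maximum on ``T_range``.
    """
    if not np.isfinite(list(fit.params.values())).all():
        return None, None, None
    grid = np.linspace(*T_range, 2301)
    mu = fit.predict(grid, clip=False)
    i = int(np.argmax(mu))
    if i == 0 or i == grid.size - 1 or mu[i] <= 0:
        return None, None, None
    # refine the optimum
    res = optimize.minimize_scalar(
        lambda T: -fit.predict(T, clip=False),
        bounds=(grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]),
        method="bounded",
    )
    T_opt = float(res.x)
    mu_max = float(fit.predict(T_opt, clip=False))

    # bracket mu = mu_max/2 above the optimum (extend past T_range if needed)
    hi = T_opt + 1.0
    while fit.predict(hi, clip=False) > mu_max / 2 and hi < T_opt + 100:
        hi += 1.0
    if fit.predict(hi, clip=False) > mu_max / 2:
        return T_opt, None, None
    lo = T_opt
    while hi - lo > tol_K:
        mid = (lo + hi) / 2
        if fit.predict(mid, clip=False) > mu_max / 2:
            lo = mid
        else:
            hi = mid
    T_switch = (lo + hi) / 2

    # steepest descent between the optimum and the zero crossing
    hi0 = T_opt + 1.0
    while fit.predict(hi0, clip=False) > 0 and hi0 < T_opt + 100:
        hi0 += 1.0
    dgrid = np.linspace(T_opt, hi0, 2001)
    neg_slope = -_mu_derivative(fit, dgrid)
    j = int(np.argmax(neg_slope))
    res2 = optimize.minimize_scalar(
        lambda T: _mu_derivative(fit, T),
        bounds=(dgrid[max(j - 1, 0)], dgrid[min(j + 1, dgrid.size - 1)]),
        method="bounded",
    )
    responsiveness = float(-res2.fun)
    return T_opt, float(T_switch), responsiveness


def classify_response(
    profiles: pd.DataFrame,
    seed: int = 1,
    ref_temp: float = 30.0,
    fallback_threshold: float = 0.25,
) -> pd.Series:
    """Label strains switch-like vs gradual from their mu(T) profiles.

    ``profiles``: strains x temperatures (columns in degC). Each profile is
    normalized to the strain's rate at the reference temperature, then
    k-means with k=2 splits the panel; the cluster with the larger mean
    steepness (max normalized rate loss per kelvin) is labelled
    switch-like. If the two clusters cannot be distinguished (degenerate
    panel), labels fall back to thresholding the per-strain steepness at
    ``fallback_threshold`` K^-1.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 strains")
    temps = np.asarray(profiles.columns, dtype=float)
    ref_col = profiles.columns[int(np.argmin(np.abs(temps - ref_temp)))]
    ref = profiles[ref_col].replace(0, np.nan)
    norm = profiles.div(ref, axis=0).fillna(0.0)
    steep = pd.Series(
        -np.min(np.diff(norm.to_numpy(), axis=1) / np.diff(temps), axis=1),
        index=profiles.index,
    )
    km = KMeans(n_clusters=2, n_init=20, random_state=seed)
    labels = km.fit_predict(norm.to_numpy())
    m0 = steep[labels == 0].mean()
    m1 = steep[labels == 1].mean()
    if np.isclose(m0, m1) or len(set(labels)) < 2:
        return pd.Series(
            np.where(steep > fallback_threshold, "switch-like", "gradual"),
            index=profiles.index,
        )
    switch_cluster = 0 if m0 > m1 else 1
    return pd.Series(
        np.where(labels == switch_cluster, "switch-like", "gradual"),
        index=profiles.index,
    )
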