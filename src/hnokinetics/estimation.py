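"""Rate-constant recovery from kinetic traces.

The analysis is paired: the uninhibited probe-oxidation rate
v0 and the inhibited rates vi are measured on traces from the same donor
lot, their ratio is formed per scavenger concentration, and the unknown
second-order constant is the through-origin slope of (v0/vi - 1) against
[nucleophile]/[O2], multiplied by the known HNO + O2 rate constant.

Two initial-rate readouts are provided.  ``method="ols"`` is the plain
least-squares absorbance slope on a window — exactly what the competition
ratio needs, because first-order donor decay rescales control and
inhibited traces identically and cancels in v0/vi.  ``method="exponential"``
fits first-order product growth A(t) = A0 + dA*(1 - e^-kt) and reports the
tangent at t = 0; this is the right readout when the quantity of interest
is an absolute rate (donor calibration), since over a 600 s window the
donor has decayed by ~38% and a straight-line slope underestimates the
true initial rate by ~20%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .params import DEFAULT_OPTICS, DEFAULT_RATES, OpticsModel
from .simulate import CompetitionSeries, KineticTrace

#: Molar absorptivity of Angeli's salt at 248 nm, M^-1 cm^-1.
EPSILON_AS_248 = 8.3e3


def as_concentration_from_absorbance(a248: float, path_length: float = 1.0) -> float:
    """Angeli's salt concentration (M) from its 248 nm absorbance."""
    if a248 < 0:
        raise ValueError("absorbance must be >= 0")
    if path_length <= 0:
        raise ValueError("path_length must be > 0")
    return a248 / (EPSILON_AS_248 * path_length)


def _window_slice(trace: KineticTrace, window) -> np.ndarray:
    lo, hi = window
    mask = (trace.times >= lo) & (trace.times <= hi)
    if mask.sum() < 5:
        raise ValueError(
            f"initial-rate window {window} contains {int(mask.sum())} samples; "
            "need at least 5"
        )
    return mask


def initial_rate(
    trace: KineticTrace,
    optics: OpticsModel = DEFAULT_OPTICS,
    window: tuple[float, float] = (0.0, 600.0),
    method: str = "ols",
) -> float:
    """Fluorescein production rate (M/s) from an absorbance trace.

    The fitted absorbance rate is divided by epsilon_FlOH * path length.
    A nonpositive result (noise-dominated trace) is returned as-is with a
    warning.  See the module docstring for the two fitting methods.
    """
    mask = _window_slice(trace, window)
    t = trace.times[mask]
    a = trace.absorbance[mask]
    scale = optics.epsilon_floh * optics.path_length
    if scale <= 0:
        raise ValueError("optics must have epsilon_floh * path_length > 0")

    if method == "ols":
        slope = np.polyfit(t, a, 1)[0]
    elif method == "exponential":
        slope = _exponential_initial_slope(t, a)
    else:
        raise ValueError(f"unknown initial-rate method {method!r}")

    rate = slope / scale
    if rate <= 0:
        warnings.warn(
            f"nonpositive initial rate ({rate:.3e} M/s) fitted on window {window}",
            RuntimeWarning,
            stacklevel=2,
        )
    return rate


def _exponential_initial_slope(t: np.ndarray, a: np.ndarray) -> float:
    """Tangent at t[0] of a first-order growth fit to the absorbance."""
    span = float(a[-1] - a[0])
    if abs(span) < 1e-12:
        return 0.0

    def model(tt, a0, amp, k):
        return a0 + amp * (1.0 - np.exp(-k * (tt - t[0])))

    t_span = t[-1] - t[0]
    p0 = (float(a[0]), 1.5 * span, 1.0 / t_span)
    try:
        popt, _ = optimize.curve_fit(
            model, t, a, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-8 / t_span], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError:
        # fall back to the straight-line slope if the growth fit diverges
        return float(np.polyfit(t, a, 1)[0])
    return float(popt[1] * popt[2])


def estimate_kas(control_rate: float, as0: float) -> float:
    """First-order donor constant (s^-1) from the uninhibited initial rate.

    In the steady-state model v0 = k_as*[AS]0, so k_as = v0/[AS]0.
    """
    if as0 <= 0:
        raise ValueError("as0 must be > 0")
    return control_rate / as0


def hno_flux(k_as: float, as0: float) -> float:
    """Initial HNO release flux k_as*[AS]0 (M/s)."""
    if k_as < 0 or as0 < 0:
        raise ValueError("inputs must be >= 0")
    return k_as * as0


def _linear_rate_and_se(
    trace: KineticTrace, optics: OpticsModel, window
) -> tuple[float, float]:
    """OLS absorbance slope converted to M/s, with its standard error."""
    mask = _window_slice(trace, window)
    t = trace.times[mask]
    a = trace.absorbance[mask]
    n = t.size
    tbar = t.mean()
    sxx = float(np.sum((t - tbar) ** 2))
    slope = float(np.sum((t - tbar) * (a - a.mean()))) / sxx
    resid = a - a.mean() - slope * (t - tbar)
    s2 = float(resid @ resid) / (n - 2)
    se = np.sqrt(s2 / sxx)
    scale = optics.epsilon_floh * optics.path_length
    return slope / scale, se / scale


def inhibition_points(
    series: CompetitionSeries,
    optics: OpticsModel = DEFAULT_OPTICS,
    window: tuple[float, float] | None = None,
    rate_method: str = "ols",
) -> pd.DataFrame:
    """Per-trace competition coordinates for the slope plot.

    Returns a DataFrame with columns ``ratio`` ([nuc]/[O2]), ``inhibition``
    (v0/vi - 1), ``conc``, ``replicate``, ``vi`` and ``vi_se``, plus the
    (constant) ``v0`` and ``v0_se`` columns carrying the control rate and
    its standard error — the control is shared by every point, so its
    uncertainty is a *common* error that the slope fit must propagate
    separately from per-point scatter.  Traces whose fitted vi is
    nonpositive are excluded with a warning.
    """
    if window is None:
        window = (0.0, series.conditions.duration)
    if rate_method == "ols":
        v0, v0_se = _linear_rate_and_se(series.control, optics, window)
    else:
        v0 = initial_rate(series.control, optics, window, rate_method)
        v0_se = 0.0
    if v0 <= 0:
        raise ValueError("control rate v0 must be > 0")
    o2 = series.conditions.o2
    rows = []
    for trace in series.inhibited:
        if rate_method == "ols":
            vi, vi_se = _linear_rate_and_se(trace, optics, window)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                vi = initial_rate(trace, optics, window, rate_method)
            vi_se = 0.0
        if vi <= 0:
            warnings.warn(
                f"excluding noise-dominated trace (vi={vi:.3e} M/s) at "
                f"[nuc]={trace.metadata.nucleophile_conc:.3e} M",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        rows.append(
            {
                "ratio": trace.metadata.nucleophile_conc / o2,
                "inhibition": v0 / vi - 1.0,
                "conc": trace.metadata.nucleophile_conc,
                "replicate": trace.metadata.replicate,
                "vi": vi,
                "vi_se": vi_se,
                "v0": v0,
                "v0_se": v0_se,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CompetitionResults:
    """Fitted competition slope and the derived rate constant.

    ``k_hat = slope * k_o2`` exactly; the slope standard error propagates
    linearly to ``k_se``.  ``intercept`` reports the free-intercept
    diagnostic refit (the default estimator forces it to zero, as the
    competition law has no intercept).
    """

    k_hat: float
    k_se: float
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    n_points: int
    df_resid: int
    k_o2: float
    through_origin: bool
    per_replicate: dict[int, float]
    points: pd.DataFrame = field(repr=False)

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """Two-sided (1-alpha) t-interval for k_hat."""
        half = stats.t.ppf(1.0 - alpha / 2.0, self.df_resid) * self.k_se
        return (self.k_hat - half, self.k_hat + half)

    def summary(self) -> str:
        lo, hi = self.conf_int()
        lines = [
            "Competition-kinetics fit ((v0/vi)-1 vs [nucleophile]/[O2])",
            "-" * 58,
            f"points                 {self.n_points}",
            f"fit                    {'through origin' if self.through_origin else 'free intercept'}",
            f"slope                  {self.slope:.6g} +/- {self.slope_se:.3g}",
            f"intercept (diagnostic) {self.intercept:.6g} +/- {self.intercept_se:.3g}",
            f"k_O2 (reference)       {self.k_o2:.6g} M^-1 s^-1",
            f"k_nucleophile          {self.k_hat:.6g} +/- {self.k_se:.3g} M^-1 s^-1",
            f"95% CI                 [{lo:.6g}, {hi:.6g}]",
        ]
        if self.per_replicate:
            reps = ", ".join(
                f"{r}: {k:.4g}" for r, k in sorted(self.per_replicate.items())
            )
            lines.append(f"per-replicate k        {reps}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Slope plot: points and the fitted competition line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.points["ratio"], self.points["inhibition"], label="traces")
        x = np.linspace(0.0, float(self.points["ratio"].max()) * 1.05, 50)
        b0 = 0.0 if self.through_origin else self.intercept
        ax.plot(x, b0 + self.slope * x, "k-", label=f"slope = {self.slope:.3g}")
        ax.set_xlabel("[nucleophile] / [O$_2$]")
        ax.set_ylabel("$v_0/v_i - 1$")
        ax.legend()
        return ax


class CompetitionModel:
    """Model for the competition slope plot of one scavenger.

    Built either from precomputed inhibition points or directly from a
    :class:`CompetitionSeries` via :meth:`from_series`; :meth:`fit`
    returns a :class:`CompetitionResults`.
    """

    def __init__(self, points: pd.DataFrame, k_o2: float = DEFAULT_RATES.k_o2):
        if k_o2 <= 0:
            raise ValueError("k_o2 must be > 0")
        required = {"ratio", "inhibition"}
        if not required <= set(points.columns):
            raise ValueError(f"points must have columns {sorted(required)}")
        if len(points) < 2 or points["ratio"].nunique() < 2:
            raise ValueError(
                "need >= 2 points spanning >= 2 distinct concentration ratios"
            )
        self.points = points.reset_index(drop=True)
        self.k_o2 = k_o2

    @classmethod
    def from_series(
        cls,
        series: CompetitionSeries,
        optics: OpticsModel = DEFAULT_OPTICS,
        window: tuple[float, float] | None = None,
        k_o2: float | None = None,
        rate_method: str = "ols",
    ) -> "CompetitionModel":
        pts = inhibition_points(series, optics, window, rate_method)
        return cls(pts, k_o2=series.rates_true.k_o2 if k_o2 is None else k_o2)

    def _common_v0_variance(self, x: np.ndarray, y: np.ndarray) -> float:
        """Slope variance contribution of the shared control-rate error.

        A relative error delta on v0 shifts every inhibition point by
        (1+y_j)*delta coherently, moving the through-origin slope by
        delta * sum(x_j (1+y_j)) / sum(x_j^2).  Residual scatter cannot
        see this common mode, so it is added in quadrature.
        """
        if "v0" not in self.points.columns or "v0_se" not in self.points.columns:
            return 0.0
        v0 = float(self.points["v0"].iloc[0])
        v0_se = float(self.points["v0_se"].iloc[0])
        if v0 <= 0 or v0_se <= 0:
            return 0.0
        rel = v0_se / v0
        sens = float(x @ (1.0 + y)) / float(x @ x)
        return (rel * sens) ** 2

    def fit(self, through_origin: bool = True) -> CompetitionResults:
        x = self.points["ratio"].to_numpy(dtype=float)
        y = self.points["inhibition"].to_numpy(dtype=float)
        n = x.size

        # free-intercept fit, always computed as a diagnostic
        free = stats.linregress(x, y)

        if through_origin:
            sxx = float(x @ x)
            slope = float(x @ y) / sxx
            df = n - 1
            resid = y - slope * x
            s2 = float(resid @ resid) / df if df > 0 else np.nan
            slope_se = np.sqrt(s2 / sxx + self._common_v0_variance(x, y))
            if abs(free.intercept) > 2.0 * free.intercept_stderr:
                warnings.warn(
                    f"free-intercept diagnostic fit gives intercept "
                    f"{free.intercept:.3g} +/- {free.intercept_stderr:.3g} "
                    "(beyond 2 SE of zero); the through-origin competition "
                    "law may be inadequate for these traces",
                    RuntimeWarning,
                    stacklevel=2,
                )
        else:
            slope, slope_se = free.slope, free.stderr
            df = n - 2

        per_rep = {}
        if "replicate" in self.points.columns:
            for rep, grp in self.points.groupby("replicate"):
                gx = grp["ratio"].to_numpy(dtype=float)
                gy = grp["inhibition"].to_numpy(dtype=float)
                if gx.size >= 2 and np.unique(gx).size >= 2:
                    per_rep[int(rep)] = float(gx @ gy) / float(gx @ gx) * self.k_o2

        return CompetitionResults(
            k_hat=slope * self.k_o2,
            k_se=slope_se * self.k_o2,
            slope=slope,
            slope_se=slope_se,
            intercept=float(free.intercept),
            intercept_se=float(free.intercept_stderr),
            n_points=n,
            df_resid=df,
            k_o2=self.k_o2,
            through_origin=through_origin,
            per_replicate=per_rep,
            points=self.points,
        )


def competition_fit(
    points: pd.DataFrame,
    k_o2: float = DEFAULT_RATES.k_o2,
    through_origin: bool = True,
) -> CompetitionResults:
    """Functional shorthand for ``CompetitionModel(points, k_o2).fit()``."""
    return CompetitionModel(points, k_o2).fit(through_origin=through_origin)


def recover_rate_constant(
    series: CompetitionSeries,
    optics: OpticsModel = DEFAULT_OPTICS,
    window: tuple[float, float] | None = None,
    k_o2: float | None = None,
    through_origin: bool = True,
) -> CompetitionResults:
    """Series-to-estimate convenience: inhibition points + slope fit."""
    model = CompetitionModel.from_series(series, optics, window, k_o2)
    return model.fit(through_origin=through_origin)
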