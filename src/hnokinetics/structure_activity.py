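"""Structure–activity analysis: activation barrier vs log rate constant.

A linear free-energy-style relationship links the computed barrier of the
carbanion + HNO addition to the measured second-order rate constant: the
barrier is regressed on log10(k) by ordinary least squares, and the fitted
line can be inverted to predict a rate constant from a barrier alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .compounds import CompoundRecord


@dataclass
class BarrierFitResults:
    """OLS fit of barrier (kJ/mol) on log_base(k).

    ``slope`` has units kJ/mol per decade of k (for base 10) and is
    expected to be negative: higher barrier, slower reaction.
    """

    slope: float
    intercept: float
    r_squared: float
    n: int
    log_base: float
    residuals: dict[int, float]
    excluded: list[int] = field(default_factory=list)

    def predict_barrier(self, k: float) -> float:
        """Barrier (kJ/mol) predicted for a rate constant k (M^-1 s^-1)."""
        return self.intercept + self.slope * math.log(k, self.log_base)

    def predict_rate(self, barrier: float) -> float:
        """Rate constant (M^-1 s^-1) predicted by inverting the fit line."""
        # real barrier sensitivities are O(10) kJ/mol per decade; anything
        # below this is numerically zero and cannot be inverted
        if abs(self.slope) < 1e-9:
            raise ZeroDivisionError("cannot invert a (numerically) zero-slope fit")
        return self.log_base ** ((barrier - self.intercept) / self.slope)

    def summary(self) -> str:
        lines = [
            f"Barrier vs log{self.log_base:g}(k) ordinary least squares",
            "-" * 52,
            f"n compounds   {self.n}",
            f"slope         {self.slope:.4f} kJ/mol per log unit",
            f"intercept     {self.intercept:.4f} kJ/mol",
            f"R^2           {self.r_squared:.4f}",
        ]
        if self.excluded:
            lines.append(f"excluded (incomplete records): {self.excluded}")
        return "\n".join(lines)

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        # residuals alone cannot reconstruct the points; recompute y on the line
        ids = sorted(self.residuals)
        resid = np.array([self.residuals[i] for i in ids])
        # Plot residuals per compound as a diagnostic.
        ax.axhline(0.0, color="k", lw=0.8)
        ax.bar([str(i) for i in ids], resid)
        ax.set_xlabel("compound")
        ax.set_ylabel("barrier residual (kJ/mol)")
        return ax


class BarrierRegression:
    """Model relating computed barriers to measured rate constants.

    Records missing either quantity are excluded (and reported on the
    results); at least three complete records are required.  The default
    regresses barrier on log10(k); ``direction="logk_on_barrier"`` fits
    the inverse regression and re-expresses it on the same axes.
    """

    def __init__(
        self,
        records: list[CompoundRecord],
        log_base: float = 10.0,
        direction: str = "barrier_on_logk",
    ):
        if log_base <= 1.0:
            raise ValueError("log_base must be > 1")
        if direction not in ("barrier_on_logk", "logk_on_barrier"):
            raise ValueError(f"unknown direction {direction!r}")
        self.records = list(records)
        self.log_base = log_base
        self.direction = direction
        self.complete = [r for r in self.records if r.complete]
        self.excluded = [r.compound_id for r in self.records if not r.complete]
        if len(self.complete) < 3:
            raise ValueError(
                f"need >= 3 records with both k and barrier, got {len(self.complete)}"
            )

    @classmethod
    def from_records(cls, records, **kwargs) -> "BarrierRegression":
        return cls(records, **kwargs)

    def fit(self) -> BarrierFitResults:
        ids = [r.compound_id for r in self.complete]
        logk = np.array(
            [math.log(r.k_measured, self.log_base) for r in self.complete]
        )
        barrier = np.array([r.barrier for r in self.complete])

        if self.direction == "barrier_on_logk":
            x, y = logk, barrier
        else:
            x, y = barrier, logk

        coeffs, ss_resid = _ols_line(x, y)
        slope, intercept = coeffs
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_resid / ss_tot if ss_tot > 0 else 1.0

        if self.direction == "logk_on_barrier":
            # re-express logk = a + b*barrier as barrier = -a/b + (1/b)*logk
            slope, intercept = 1.0 / slope, -intercept / slope

        fitted = intercept + slope * logk
        residuals = {i: float(b - f) for i, b, f in zip(ids, barrier, fitted)}
        return BarrierFitResults(
            slope=float(slope),
            intercept=float(intercept),
            r_squared=float(r2),
            n=len(ids),
            log_base=self.log_base,
            residuals=residuals,
            excluded=self.excluded,
        )


def _ols_line(x: np.ndarray, y: np.ndarray):
    """Least-squares line via the normal equations; returns ((b, a), SS_resid)."""
    design = np.column_stack([x, np.ones_like(x)])
    coeffs, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coeffs
    return (float(coeffs[0]), float(coeffs[1])), float(resid @ resid)


def fit_barrier_loglinear(
    records: list[CompoundRecord], log_base: float = 10.0
) -> BarrierFitResults:
    """OLS of barrier on log(k) over the complete records (>= 3 required)."""
    return BarrierRegression(records, log_base=log_base).fit()


def predict_rate_from_barrier(fit: BarrierFitResults, barrier: float) -> float:
    """Invert a barrier fit to a rate constant (M^-1 s^-1)."""
    return fit.predict_rate(barrier)


def barrier_rank_correlation(records: list[CompoundRecord]) -> float:
    """Kendall's tau between barrier and k over the complete records."""
    from scipy.stats import kendalltau

    complete = [r for r in records if r.complete]
    if len(complete) < 3:
        raise ValueError("need >= 3 complete records")
    tau, _ = kendalltau(
        [r.barrier for r in complete], [r.k_measured for r in complete]
    )
    return float(tau)
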