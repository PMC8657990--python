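"""Reaction network of the donor / O2 / probe / C-nucleophile competition.

The chemistry
-------------
Angeli's salt (AS) decomposes with first-order rate constant ``k_as`` and
releases azanone (HNO).  HNO is consumed by three channels:

* oxidation by dissolved O2 to peroxynitrite (ONOO-), rate ``k_o2 [O2][HNO]``;
* addition to a C-nucleophile scavenger, rate ``k_nucleophile [nuc][HNO]``;
* self-dimerization, 2 HNO -> N2O + H2O, event rate ``k_dim [HNO]^2``
  (two HNO consumed per event).

Peroxynitrite is trapped stoichiometrically by the boronate probe (FlBA),
yielding fluorescein (FlOH) and nitrite — the optical readout at 490 nm.

Because the loss channels are fast relative to donor decomposition, both
intermediates sit at a quasi-steady state (QSS) and the closed forms hold:

    [HNO]_ss  = k_as [AS] / (k_nucleophile [nuc] + k_o2 [O2])
    v0        = k_as [AS]                       (no scavenger)
    v_i       = v0 * k_o2 [O2] / (k_nucleophile [nuc] + k_o2 [O2])
    v0/v_i -1 = (k_nucleophile / k_o2) * [nuc] / [O2]

The last identity is the competition law used to determine unknown
scavenger rate constants from the inhibition of probe oxidation.

This module provides the full (non-QSS) ODE model, a stiff-capable
integrator wrapper, the closed-form steady-state quantities, and a flux
partition that quantifies how much HNO each channel actually consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ExperimentConditions, RateConstantSet

#: State-vector ordering used throughout the package.
SPECIES = (
    "AS",
    "HNO",
    "ONOO",
    "FlBA",
    "FlOH",
    "nucleophile",
    "adduct",
    "N2O",
    "NO2",
    "O2",
)

_IDX = {name: i for i, name in enumerate(SPECIES)}


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the offending conditions."""


def _rhs(t, y, r: RateConstantSet, o2_clamped: bool, o2_fixed: float):
    """Unvalidated right-hand side used inside the integrator."""
    as_, hno, onoo, flba, _floh, nuc, _add, _n2o, _no2, o2 = y
    o2_eff = o2_fixed if o2_clamped else o2

    v_release = r.hno_yield * r.k_as * as_
    v_o2 = r.k_o2 * o2_eff * hno
    v_nuc = r.k_nucleophile * nuc * hno
    v_dim_event = r.k_dim * hno * hno
    v_probe = r.k_probe * flba * onoo
    v_onoo_decay = r.k_onoo_decay * onoo

    d = np.empty(10)
    d[_IDX["AS"]] = -r.k_as * as_
    d[_IDX["HNO"]] = v_release - v_o2 - v_nuc - 2.0 * v_dim_event
    d[_IDX["ONOO"]] = v_o2 - v_probe - v_onoo_decay
    d[_IDX["FlBA"]] = -v_probe
    d[_IDX["FlOH"]] = v_probe
    d[_IDX["nucleophile"]] = -v_nuc
    d[_IDX["adduct"]] = v_nuc
    d[_IDX["N2O"]] = v_dim_event
    d[_IDX["NO2"]] = v_probe
    d[_IDX["O2"]] = 0.0 if o2_clamped else -v_o2
    return d


def rhs_full_model(
    state, rates: RateConstantSet, conditions: ExperimentConditions
) -> np.ndarray:
    """Time derivatives (M/s) of all species for a given state.

    ``state`` maps species names to concentrations (M) or is an array in
    :data:`SPECIES` order; omitted species default to zero and O2 defaults
    to the conditions' value.  Negative concentrations are rejected.
    """
    if isinstance(state, dict):
        unknown = set(state) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species: {sorted(unknown)}")
        y = np.zeros(10)
        y[_IDX["O2"]] = conditions.o2
        for name, value in state.items():
            y[_IDX[name]] = value
    else:
        y = np.asarray(state, dtype=float)
        if y.shape != (10,):
            raise ValueError(f"state must have {len(SPECIES)} entries, got {y.shape}")
    if np.any(y < 0):
        bad = [SPECIES[i] for i in np.flatnonzero(y < 0)]
        raise ValueError(f"negative concentration in state for {bad}")
    return _rhs(0.0, y, rates, conditions.o2_clamped, conditions.o2)


@dataclass
class Trajectory:
    """Concentration time-courses from one integration of the full model.

    ``data`` has shape (len(times), len(SPECIES)) in :data:`SPECIES`
    order, all molar.
    """

    times: np.ndarray
    data: np.ndarray
    rates: RateConstantSet
    conditions: ExperimentConditions

    def species(self, name: str) -> np.ndarray:
        return self.data[:, _IDX[name]]

    def __getitem__(self, name: str) -> np.ndarray:
        return self.species(name)

    def floh_rate(self) -> np.ndarray:
        """Instantaneous fluorescein formation rate k_probe*[FlBA][ONOO] (M/s)."""
        return self.rates.k_probe * self.species("FlBA") * self.species("ONOO")

    def nitrogen_residual(self) -> np.ndarray:
        """HNO-lineage nitrogen balance error (M) at each time point.

        Every donor molecule decomposed should be accounted for as free
        HNO, ONOO-, probe-derived nitrite, scavenger adduct, or N2O (two
        HNO per N2O).  With a sub-unit donor yield the released fraction
        is compared instead.
        """
        released = self.rates.hno_yield * (self.conditions.as0 - self.species("AS"))
        pooled = (
            self.species("HNO")
            + self.species("ONOO")
            + self.species("NO2")
            + self.species("adduct")
            + 2.0 * self.species("N2O")
        )
        return released - pooled

    def probe_residual(self) -> np.ndarray:
        """Fluorophore balance error [FlBA]+[FlOH]-FlBA0 (M) per time point."""
        return self.species("FlBA") + self.species("FlOH") - self.conditions.probe0

    def to_frame(self, tidy: bool = True) -> pd.DataFrame:
        """Tidy (time_s, species, concentration_M) or wide DataFrame."""
        wide = pd.DataFrame(self.data, columns=list(SPECIES))
        wide.insert(0, "time_s", self.times)
        if not tidy:
            return wide
        return wide.melt(
            id_vars="time_s", var_name="species", value_name="concentration_M"
        )

    def to_csv(self, path) -> None:
        self.to_frame(tidy=True).to_csv(path, index=False)


def initial_state(conditions: ExperimentConditions) -> np.ndarray:
    y0 = np.zeros(10)
    y0[_IDX["AS"]] = conditions.as0
    y0[_IDX["FlBA"]] = conditions.probe0
    y0[_IDX["nucleophile"]] = conditions.nucleophile0
    y0[_IDX["O2"]] = conditions.o2
    return y0


def integrate_full_model(
    rates: RateConstantSet,
    conditions: ExperimentConditions,
    time_grid=None,
    *,
    method: str = "LSODA",
    rtol: float = 1e-8,
    atol: float = 1e-14,
) -> Trajectory:
    """Integrate the full reaction network on a strictly increasing grid.

    The system is stiff — rate constants span ~10 orders of magnitude —
    so the default solver is LSODA with rtol 1e-8 and atol 1e-14 M (the
    HNO steady state is a few nM and must be resolved).  The returned
    trajectory starts at ``time_grid[0]`` which must be 0.
    """
    if time_grid is None:
        time_grid = np.linspace(0.0, conditions.duration, 601)
    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be 1-D and strictly increasing")
    if t[0] != 0.0:
        raise ValueError("time_grid must start at 0")

    sol = solve_ivp(
        _rhs,
        (t[0], t[-1]),
        initial_state(conditions),
        method=method,
        t_eval=t,
        rtol=rtol,
        atol=atol,
        args=(rates, conditions.o2_clamped, conditions.o2),
    )
    if not sol.success:
        raise IntegrationError(
            f"ODE integration failed: {sol.message}; "
            f"rates={rates.to_dict()}, conditions={conditions.to_dict()}"
        )
    data = sol.y.T.copy()
    floor = -10.0 * max(atol, 1e-16)
    if data.min() < floor * 1e4 and data.min() < -1e-9:
        raise IntegrationError(
            f"integration produced a substantially negative concentration "
            f"({data.min():.3e} M); conditions={conditions.to_dict()}"
        )
    np.clip(data, 0.0, None, out=data)
    return Trajectory(times=t, data=data, rates=rates, conditions=conditions)


# ---------------------------------------------------------------------------
# Closed-form quasi-steady-state quantities
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteadyStateSolution:
    """QSS intermediate levels and probe-oxidation rates (all molar / M/s)."""

    hno_ss: float
    onoo_ss: float
    v0: float
    vi: float

    def inhibition(self) -> float:
        """The competition statistic v0/vi - 1."""
        if self.vi == 0:
            raise ZeroDivisionError("vi is zero; inhibition statistic undefined")
        return self.v0 / self.vi - 1.0


def _loss_rate(rates: RateConstantSet, conditions: ExperimentConditions) -> float:
    return (
        rates.k_nucleophile * conditions.nucleophile0 + rates.k_o2 * conditions.o2
    )


def hno_steady_state(
    rates: RateConstantSet, conditions: ExperimentConditions
) -> float:
    """Quasi-steady-state HNO concentration (M) at the initial donor load.

    [HNO]_ss = yield * k_as * [AS]0 / (k_nucleophile [nuc] + k_o2 [O2]).
    """
    loss = _loss_rate(rates, conditions)
    if loss <= 0:
        raise ValueError(
            "HNO steady state undefined: no loss channel "
            "(k_nucleophile*[nuc] + k_o2*[O2] must be > 0)"
        )
    return rates.hno_yield * rates.k_as * conditions.as0 / loss


def fluorescein_rates(
    rates: RateConstantSet, conditions: ExperimentConditions
) -> SteadyStateSolution:
    """Closed-form probe-oxidation rates with and without the scavenger.

    v0 = yield*k_as*[AS]0 is the uninhibited fluorescein formation rate;
    vi partitions it by the O2 channel's share of HNO consumption.  The
    ONOO- steady state requires a nonzero probe concentration.
    """
    loss = _loss_rate(rates, conditions)
    if loss <= 0:
        raise ValueError("loss rate must be > 0 (see hno_steady_state)")
    hno_ss = rates.hno_yield * rates.k_as * conditions.as0 / loss
    v0 = rates.hno_yield * rates.k_as * conditions.as0
    vi = v0 * rates.k_o2 * conditions.o2 / loss
    if conditions.probe0 <= 0:
        raise ValueError(
            "onoo_ss undefined with probe0 = 0 (v0 and vi are still "
            "k_as*[AS]0 and its O2-channel share; supply probe0 > 0)"
        )
    onoo_ss = rates.k_o2 * conditions.o2 * hno_ss / (rates.k_probe * conditions.probe0)
    return SteadyStateSolution(hno_ss=hno_ss, onoo_ss=onoo_ss, v0=v0, vi=vi)


def qssa_rate(
    rates: RateConstantSet,
    conditions: ExperimentConditions,
    as_conc,
    nucleophile_conc=None,
) -> np.ndarray:
    """Closed-form fluorescein formation rate at instantaneous reagent levels.

    Evaluates vi with [AS] (and optionally [nuc]) taken at their current
    values instead of the initial ones; used to test the quasi-steady-state
    approximation against the full model along a trajectory.
    """
    nuc = conditions.nucleophile0 if nucleophile_conc is None else nucleophile_conc
    loss = rates.k_nucleophile * np.asarray(nuc) + rates.k_o2 * conditions.o2
    return (
        rates.hno_yield
        * rates.k_as
        * np.asarray(as_conc)
        * rates.k_o2
        * conditions.o2
        / loss
    )


def inhibition_prediction(
    rates: RateConstantSet, nucleophile_conc: float, o2_conc: float
) -> float:
    """Competition law: v0/vi - 1 = (k_nucleophile/k_o2) * [nuc]/[O2]."""
    if o2_conc <= 0:
        raise ValueError("o2_conc must be > 0")
    if rates.k_o2 <= 0:
        raise ValueError("k_o2 must be > 0")
    return (rates.k_nucleophile / rates.k_o2) * (nucleophile_conc / o2_conc)


def flux_partition(
    trajectory: Trajectory,
    rates: RateConstantSet | None = None,
    conditions: ExperimentConditions | None = None,
) -> dict:
    """Fraction of HNO consumed by each loss channel over the trajectory.

    Channel fluxes are counted in HNO molecules: the dimerization channel
    consumes two HNO per event, so its flux is 2*k_dim*[HNO]^2.  Returns
    ``{"o2": f, "nucleophile": f, "dimerization": f}`` with the fractions
    summing to 1.
    """
    r = trajectory.rates if rates is None else rates
    c = trajectory.conditions if conditions is None else conditions
    t = trajectory.times
    hno = trajectory.species("HNO")
    o2 = np.full_like(hno, c.o2) if c.o2_clamped else trajectory.species("O2")

    o2_flux = np.trapezoid(r.k_o2 * o2 * hno, t)
    nuc_flux = np.trapezoid(
        r.k_nucleophile * trajectory.species("nucleophile") * hno, t
    )
    dim_flux = np.trapezoid(2.0 * r.k_dim * hno * hno, t)
    total = o2_flux + nuc_flux + dim_flux
    if total <= 0:
        raise ValueError("no HNO was consumed along this trajectory")
    return {
        "o2": o2_flux / total,
        "nucleophile": nuc_flux / total,
        "dimerization": dim_flux / total,
    }
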