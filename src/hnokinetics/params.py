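"""Parameter containers for the HNO competition-kinetics network.

All concentrations are molar (M) and all times are seconds internally;
second-order rate constants are M^-1 s^-1.  The constructors below accept SI
values; :meth:`ExperimentConditions.from_micromolar` is provided because the
bench work this package models is planned in micromolar.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field


def _require_nonnegative(obj, *names: str) -> None:
    for name in names:
        value = getattr(obj, name)
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value!r}")


def _require_positive(obj, *names: str) -> None:
    for name in names:
        value = getattr(obj, name)
        if value <= 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class RateConstantSet:
    """Rate constants of the donor / probe / scavenger reaction network.

    Parameters
    ----------
    k_as : float
        First-order decomposition rate of the HNO donor (Angeli's salt),
        s^-1.  Default 8.0e-4 s^-1 (pH 7.4).
    k_o2 : float
        Second-order HNO + O2 -> ONOO- rate constant, M^-1 s^-1.  This is
        the reference channel of the competition scheme; default 1.8e4.
    k_probe : float
        Second-order ONOO- + boronate probe (FlBA) rate constant,
        M^-1 s^-1; default 1e6.
    k_dim : float
        Second-order HNO self-dimerization rate constant (2 HNO -> N2O +
        H2O), M^-1 s^-1; default 8e6.  The rate law is written per
        dimerization event, so HNO is consumed at 2*k_dim*[HNO]^2.
    k_nucleophile : float
        Second-order HNO + C-nucleophile rate constant, M^-1 s^-1.  Zero
        when no scavenger is present (control runs).
    k_onoo_decay : float
        Optional first-order loss of ONOO- outside the probe channel,
        s^-1.  Off (0.0) by default; provided only for sensitivity
        analysis — the closed-form inhibition law assumes it is absent.
    hno_yield : float
        Moles of HNO released per mole of donor decomposed, in (0, 1].
        Unit yield is the standard assumption for Angeli's salt.
    """

    k_as: float = 8.0e-4
    k_o2: float = 1.8e4
    k_probe: float = 1.0e6
    k_dim: float = 8.0e6
    k_nucleophile: float = 0.0
    k_onoo_decay: float = 0.0
    hno_yield: float = 1.0

    def __post_init__(self) -> None:
        _require_nonnegative(
            self, "k_as", "k_o2", "k_probe", "k_dim", "k_nucleophile", "k_onoo_decay"
        )
        if not (0.0 < self.hno_yield <= 1.0):
            raise ValueError(f"hno_yield must be in (0, 1], got {self.hno_yield!r}")

    def with_nucleophile(self, k_nucleophile: float) -> "RateConstantSet":
        """Return a copy with a different scavenger rate constant."""
        return dataclasses.replace(self, k_nucleophile=k_nucleophile)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ExperimentConditions:
    """Initial concentrations and run geometry of one kinetic experiment.

    Defaults mirror the reference assay: 20 uM Angeli's salt, 25 uM FlBA
    probe, 225 uM dissolved O2, 600 s observation window, 1 cm cuvette,
    pH 7.4 (metadata only).  ``o2_clamped`` keeps [O2] constant during
    integration, consistent with treating it as a known excess reagent;
    maximum possible O2 consumption at the default donor load is < 9%.
    """

    as0: float = 20e-6
    probe0: float = 25e-6
    o2: float = 225e-6
    nucleophile0: float = 0.0
    o2_clamped: bool = True
    duration: float = 600.0
    path_length: float = 1.0
    ph_label: str = "7.4"
    temperature_label: str = "ambient"

    def __post_init__(self) -> None:
        _require_nonnegative(self, "as0", "probe0", "o2", "nucleophile0")
        _require_positive(self, "duration", "path_length")

    @classmethod
    def from_micromolar(
        cls,
        as0: float = 20.0,
        probe0: float = 25.0,
        o2: float = 225.0,
        nucleophile0: float = 0.0,
        **kwargs,
    ) -> "ExperimentConditions":
        """Build conditions from concentrations given in micromolar."""
        return cls(
            as0=as0 * 1e-6,
            probe0=probe0 * 1e-6,
            o2=o2 * 1e-6,
            nucleophile0=nucleophile0 * 1e-6,
            **kwargs,
        )

    def with_nucleophile(self, nucleophile0: float) -> "ExperimentConditions":
        """Return a copy with a different scavenger concentration (M)."""
        return dataclasses.replace(self, nucleophile0=nucleophile0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class OpticsModel:
    """Beer–Lambert transform from species concentrations to absorbance.

    The readout wavelength is 490 nm, where the fluorescein product
    absorbs; the boronate probe itself absorbs at 378 nm, so its residual
    490 nm absorptivity defaults to zero.  The fluorescein molar
    absorptivity is not part of the kinetic contract — every estimator in
    this package uses rate *ratios*, so ``epsilon_floh`` only sets the
    scale of synthetic traces.
    """

    epsilon_floh: float = 7.5e4
    epsilon_probe: float = 0.0
    path_length: float = 1.0
    noise_sd: float = 2.0e-3
    baseline: float = 0.0

    def __post_init__(self) -> None:
        _require_nonnegative(self, "epsilon_floh", "epsilon_probe", "noise_sd")
        _require_positive(self, "path_length")

    def absorbance(self, floh, probe):
        """Deterministic 490 nm absorbance for given concentrations (M)."""
        return self.baseline + self.path_length * (
            self.epsilon_floh * floh + self.epsilon_probe * probe
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def noiseless(self) -> "OpticsModel":
        return dataclasses.replace(self, noise_sd=0.0)


DEFAULT_RATES = RateConstantSet()
DEFAULT_CONDITIONS = ExperimentConditions()
DEFAULT_OPTICS = OpticsModel()
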