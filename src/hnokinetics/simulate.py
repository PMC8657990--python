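"""Synthetic spectrophotometer traces and competition series.

Emulates the reference assay: the donor decomposes in an aerated, probed
solution while the 490 nm absorbance of the fluorescein product is sampled
on a regular grid; additive Gaussian instrument noise is drawn from a
seeded generator so every trace is exactly reproducible.

Seed scheme: a master seed is expanded with ``numpy.random.SeedSequence``
and the successive 31-bit words of its stream become the per-trace seeds,
assigned in a fixed order (control first, then concentration-major,
replicate-minor).  Regenerating a series from the same master seed is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .network import Trajectory, integrate_full_model
from .params import (
    DEFAULT_CONDITIONS,
    DEFAULT_OPTICS,
    DEFAULT_RATES,
    ExperimentConditions,
    OpticsModel,
    RateConstantSet,
)


@dataclass(frozen=True)
class TraceMetadata:
    """Provenance of one synthetic trace."""

    nucleophile: str | None = None
    nucleophile_conc: float = 0.0
    replicate: int = 0
    seed: int | None = None
    is_control: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class KineticTrace:
    """One time / 490 nm absorbance series with replicate metadata."""

    times: np.ndarray
    absorbance: np.ndarray
    metadata: TraceMetadata = field(default_factory=TraceMetadata)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.shape != self.absorbance.shape:
            raise ValueError("times and absorbance must have matching shapes")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "absorbance_490": self.absorbance}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata: TraceMetadata | None = None) -> "KineticTrace":
        frame = pd.read_csv(path)
        return cls(
            times=frame["time_s"].to_numpy(),
            absorbance=frame["absorbance_490"].to_numpy(),
            metadata=metadata or TraceMetadata(),
        )


def trace_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic 31-bit per-trace seeds from a master seed."""
    words = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)
    return [int(w & 0x7FFFFFFF) for w in words]


def simulate_trace(
    rates: RateConstantSet,
    conditions: ExperimentConditions,
    optics: OpticsModel = DEFAULT_OPTICS,
    sampling: float = 5.0,
    seed: int | None = None,
    *,
    trajectory: Trajectory | None = None,
    metadata: TraceMetadata | None = None,
) -> KineticTrace:
    """Simulate one 490 nm absorbance trace.

    The concentration time-courses come from the full ODE model (or a
    pre-computed ``trajectory`` for the same rates/conditions, so that
    replicates differing only in noise can share one integration);
    absorbance is the Beer–Lambert transform of [FlOH] and residual
    [FlBA] plus N(0, noise_sd) instrument noise.
    """
    if sampling <= 0:
        raise ValueError("sampling interval must be > 0")
    if trajectory is None:
        n = int(np.floor(conditions.duration / sampling)) + 1
        grid = np.arange(n) * sampling
        trajectory = integrate_full_model(rates, conditions, grid)
    signal = optics.absorbance(trajectory.species("FlOH"), trajectory.species("FlBA"))
    if optics.noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, optics.noise_sd, size=signal.shape)
    meta = metadata or TraceMetadata(
        nucleophile_conc=conditions.nucleophile0,
        seed=seed,
        is_control=conditions.nucleophile0 == 0.0,
    )
    return KineticTrace(times=trajectory.times.copy(), absorbance=signal, metadata=meta)


@dataclass
class CompetitionSeries:
    """A control trace plus inhibited traces — the unit of estimation."""

    control: KineticTrace
    inhibited: list[KineticTrace]
    conditions: ExperimentConditions
    rates_true: RateConstantSet
    nucleophile: str = "nucleophile"
    master_seed: int | None = None

    def __post_init__(self) -> None:
        if self.control.metadata.nucleophile_conc != 0.0:
            raise ValueError("control trace must have zero nucleophile")
        concs = {t.metadata.nucleophile_conc for t in self.inhibited}
        if len(concs) < 2:
            raise ValueError(
                "competition series needs >= 2 distinct nucleophile concentrations"
            )
        names = {t.metadata.nucleophile for t in self.inhibited}
        if len(names) > 1:
            raise ValueError("one nucleophile identity per series")

    @property
    def concentrations(self) -> list[float]:
        return sorted({t.metadata.nucleophile_conc for t in self.inhibited})

    def __len__(self) -> int:
        return 1 + len(self.inhibited)

    def save(self, directory) -> Path:
        """Write traces as CSV plus a JSON manifest; returns manifest path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.control.to_csv(directory / "control.csv")
        entries = []
        for i, trace in enumerate(self.inhibited):
            name = f"inhibited_{i:03d}.csv"
            trace.to_csv(directory / name)
            entries.append({"file": name, **trace.metadata.to_dict()})
        manifest = {
            "schema_version": 1,
            "nucleophile": self.nucleophile,
            "master_seed": self.master_seed,
            "conditions": self.conditions.to_dict(),
            "rates_true": self.rates_true.to_dict(),
            "control": {"file": "control.csv", **self.control.metadata.to_dict()},
            "inhibited": entries,
        }
        path = directory / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return path

    @classmethod
    def load(cls, directory) -> "CompetitionSeries":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        conditions = ExperimentConditions(**manifest["conditions"])
        rates = RateConstantSet(**manifest["rates_true"])

        def _trace(entry):
            meta = {k: v for k, v in entry.items() if k != "file"}
            return KineticTrace.from_csv(
                directory / entry["file"], TraceMetadata(**meta)
            )

        return cls(
            control=_trace(manifest["control"]),
            inhibited=[_trace(e) for e in manifest["inhibited"]],
            conditions=conditions,
            rates_true=rates,
            nucleophile=manifest["nucleophile"],
            master_seed=manifest["master_seed"],
        )


def default_concentration_grid(
    k_true: float,
    o2: float = DEFAULT_CONDITIONS.o2,
    k_o2: float = DEFAULT_RATES.k_o2,
    inhibition_targets=(0.3, 0.75, 1.5, 3.0),
) -> list[float]:
    """Scavenger concentrations (M) placing v0/vi - 1 at the given targets.

    Solving the competition law for [nuc] gives [nuc] = y * [O2] * k_o2 /
    k_true; the default targets span the 0.3–3 inhibition range where the
    slope plot is well conditioned.
    """
    if k_true <= 0:
        raise ValueError("k_true must be > 0")
    return [y * o2 * k_o2 / k_true for y in inhibition_targets]


def generate_series(
    k_true: float,
    nucleophile_concs,
    replicates: int = 3,
    conditions: ExperimentConditions = DEFAULT_CONDITIONS,
    optics: OpticsModel = DEFAULT_OPTICS,
    seed: int = 0,
    *,
    nucleophile: str = "nucleophile",
    sampling: float = 5.0,
    rates: RateConstantSet = DEFAULT_RATES,
    trajectory_cache: dict | None = None,
) -> CompetitionSeries:
    """Simulate a full competition series for one scavenger.

    One control trace plus ``replicates`` traces at each concentration.
    ``trajectory_cache`` (concentration -> Trajectory) lets callers reuse
    the deterministic integrations when only the noise differs between
    series; entries are added as needed and must correspond to the same
    rates and conditions.
    """
    concs = list(nucleophile_concs)
    if not concs:
        raise ValueError("need at least one nucleophile concentration")
    if len(set(concs)) != len(concs) or any(c <= 0 for c in concs):
        raise ValueError("nucleophile concentrations must be distinct and > 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    rates_true = rates.with_nucleophile(k_true)
    n_traces = 1 + len(concs) * replicates
    seeds = trace_seeds(seed, n_traces)
    cache = {} if trajectory_cache is None else trajectory_cache

    def _trajectory(conc: float) -> Trajectory:
        if conc not in cache:
            cond = conditions.with_nucleophile(conc)
            n = int(np.floor(cond.duration / sampling)) + 1
            cache[conc] = integrate_full_model(
                rates_true, cond, np.arange(n) * sampling
            )
        return cache[conc]

    control = simulate_trace(
        rates_true,
        conditions.with_nucleophile(0.0),
        optics,
        sampling,
        seeds[0],
        trajectory=_trajectory(0.0),
        metadata=TraceMetadata(
            nucleophile=nucleophile, nucleophile_conc=0.0, replicate=0,
            seed=seeds[0], is_control=True,
        ),
    )
    inhibited = []
    k = 1
    for conc in concs:
        traj = _trajectory(conc)
        for rep in range(1, replicates + 1):
            inhibited.append(
                simulate_trace(
                    rates_true,
                    conditions.with_nucleophile(conc),
                    optics,
                    sampling,
                    seeds[k],
                    trajectory=traj,
                    metadata=TraceMetadata(
                        nucleophile=nucleophile, nucleophile_conc=conc,
                        replicate=rep, seed=seeds[k], is_control=False,
                    ),
                )
            )
            k += 1
    return CompetitionSeries(
        control=control,
        inhibited=inhibited,
        conditions=conditions,
        rates_true=rates_true,
        nucleophile=nucleophile,
        master_seed=seed,
    )
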