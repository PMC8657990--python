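"""Reference set of cyclic C-nucleophiles.

Thirteen 1,3-dicarbonyl ring systems with experimentally determined HNO
rate constants (M^-1 s^-1, pH 7.4 competition kinetics against O2) and
computed activation barriers (kJ/mol) for the addition of the carbanion to
the N=O bond.  Three rate constants (compounds 3, 10, 11) and one barrier
(compound 6) were reported only in tabular/graphical form not carried by
this package and are stored as ``None`` rather than guessed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class CompoundRecord:
    """One C-nucleophile: identity, measured k and computed barrier."""

    compound_id: int
    name: str
    k_measured: float | None = None  # M^-1 s^-1
    barrier: float | None = None  # kJ/mol

    def __post_init__(self) -> None:
        if self.k_measured is not None and self.k_measured <= 0:
            raise ValueError("k_measured must be > 0 when present")
        if self.barrier is not None and self.barrier <= 0:
            raise ValueError("barrier must be > 0 when present")

    @property
    def complete(self) -> bool:
        return self.k_measured is not None and self.barrier is not None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_REFERENCE = (
    CompoundRecord(1, "1,3-cyclopentanedione", 2.8e2, 72.53),
    CompoundRecord(2, "2-methyl-1,3-cyclopentanedione", 3.2e3, 57.92),
    CompoundRecord(3, "2-acetyl-1,3-cyclopentanedione", None, 90.93),
    CompoundRecord(4, "1,3-cyclohexanedione", 2.2e3, 59.28),
    CompoundRecord(5, "2-methyl-1,3-cyclohexanedione", 1.1e4, 50.03),
    CompoundRecord(6, "dimedone", 2.5e3, None),
    CompoundRecord(7, "1,3-cycloheptanedione", 6.8e3, 57.52),
    CompoundRecord(8, "2,4-piperidinedione", 2.0e4, 45.65),
    CompoundRecord(9, "1-(4-methoxybenzyl)-2,4-piperidinedione", 1.4e4, 41.34),
    CompoundRecord(10, "1,3-dimethylbarbituric acid", None, 50.93),
    CompoundRecord(11, "barbituric acid", None, 64.65),
    CompoundRecord(12, "2-thiobarbituric acid", 8.2e2, 76.28),
    CompoundRecord(13, "Meldrum's acid", 8.7e2, 70.15),
)


def load_reference_compounds() -> list[CompoundRecord]:
    """The packaged reference compound set, ordered by compound id."""
    return list(_REFERENCE)


def get_compound(compound_id: int) -> CompoundRecord:
    for record in _REFERENCE:
        if record.compound_id == compound_id:
            return record
    raise KeyError(f"no compound with id {compound_id}")


def compounds_frame(records=None) -> pd.DataFrame:
    records = load_reference_compounds() if records is None else records
    return pd.DataFrame([r.to_dict() for r in records]).rename(
        columns={"k_measured": "k_M_per_s", "barrier": "barrier_kJ_mol"}
    )


def write_compounds_csv(path, records=None) -> None:
    compounds_frame(records).to_csv(path, index=False)


def read_compounds_csv(path) -> list[CompoundRecord]:
    """Read a compound table (id, name, k_M_per_s, barrier_kJ_mol)."""
    frame = pd.read_csv(path)
    records = []
    for row in frame.itertuples(index=False):
        k = getattr(row, "k_M_per_s", None)
        b = getattr(row, "barrier_kJ_mol", None)
        records.append(
            CompoundRecord(
                compound_id=int(row.compound_id),
                name=str(row.name),
                k_measured=None if pd.isna(k) else float(k),
                barrier=None if pd.isna(b) else float(b),
            )
        )
    return records
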