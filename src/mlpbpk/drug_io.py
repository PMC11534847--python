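"""Drug-specific input records: the 40-drug benchmark table and synthetic drugs.

A drug record carries the compound-specific inputs of the simulator: LogP,
ionization constants, fraction unbound in plasma (fup), blood:plasma ratio
(BP), Caco-2 apparent permeability (Papp, used as the universal membrane
permeability), and either intrinsic hepatic clearance (CLint, "in vitro" mode)
or total plasma clearance (CLt, "ml" mode with model-predicted inputs).

The packaged CSV fixture transcribes the published 40-compound benchmark
table, with observed and predicted variants of fup, Papp and clearance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "DrugRecord",
    "DrugTableError",
    "load_drug_table",
    "load_benchmark_table",
    "default_drug_table_path",
    "generate_synthetic_drugs",
]

REQUIRED_COLUMNS = [
    "name", "logp", "pka1", "pka1_kind", "pka2", "pka2_kind",
    "fup_ob", "fup_pr", "bp", "caco2_ob", "caco2_pr",
    "clint_ob", "clt_ob", "clt_pr",
]

MODES = ("ml", "invitro")


class DrugTableError(ValueError):
    pass


@dataclass
class DrugRecord:
    """Compound-specific simulator inputs in declared units.

    fup is a fraction in (0, 1]; papp_caco2 in 1e-6 cm/s; clint in
    mL/min/kg; clt in L/h/kg; bp dimensionless.  ``pka_entries`` holds up to
    two (value, kind) pairs with kind 'a' (acid) or 'b' (base); a compound
    with no ionizable group has an empty list and ``neutral`` True.
    """

    name: str
    logp: float
    pka_entries: list[tuple[float, str]]
    fup: float
    papp_caco2: float
    bp: float | None = None
    clint: float | None = None
    clt: float | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def neutral(self) -> bool:
        return len(self.pka_entries) == 0

    def validate(self) -> None:
        if not (0.0 < self.fup <= 1.0):
            raise DrugTableError(f"{self.name}: fup {self.fup} outside (0, 1]")
        if not self.papp_caco2 > 0:
            raise DrugTableError(f"{self.name}: papp_caco2 {self.papp_caco2} not positive")
        if self.bp is not None and not self.bp > 0:
            raise DrugTableError(f"{self.name}: bp {self.bp} not positive")
        if self.clint is not None and self.clint < 0:
            raise DrugTableError(f"{self.name}: clint {self.clint} negative")
        if self.clt is not None and not self.clt > 0:
            raise DrugTableError(f"{self.name}: clt {self.clt} not positive")
        if len(self.pka_entries) > 2:
            raise DrugTableError(f"{self.name}: more than 2 pKa entries")
        for value, kind in self.pka_entries:
            if kind not in ("a", "b"):
                raise DrugTableError(f"{self.name}: pKa kind {kind!r} not 'a'/'b'")
            if not math.isfinite(value):
                raise DrugTableError(f"{self.name}: non-finite pKa")


def default_drug_table_path() -> str:
    ref = resources.files("mlpbpk.data").joinpath("drug_table.csv")
    with resources.as_file(ref) as path:
        return str(path)


def _parse_pka(row: pd.Series, name: str) -> list[tuple[float, str]]:
    entries: list[tuple[float, str]] = []
    for vcol, kcol in (("pka1", "pka1_kind"), ("pka2", "pka2_kind")):
        v, k = row[vcol], row[kcol]
        if pd.isna(v) and (pd.isna(k) or k == ""):
            continue
        if pd.isna(v) or pd.isna(k):
            raise DrugTableError(f"{name}: pKa value/kind pair incomplete ({vcol})")
        entries.append((float(v), str(k).strip()))
    return entries


def load_drug_table(path: str, mode: str) -> list[DrugRecord]:
    """Read a drug CSV and build records for the requested input mode.

    ``mode='ml'`` populates fup/Papp/CLt from the predicted columns;
    ``mode='invitro'`` populates fup/Papp/CLint from the observed columns.
    BP is always taken from the (observed) ``bp`` column when present.
    """
    if mode not in MODES:
        raise DrugTableError(f"mode must be one of {MODES}, got {mode!r}")
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DrugTableError(f"drug table missing required columns: {missing}")
    records: list[DrugRecord] = []
    for _, row in df.iterrows():
        name = str(row["name"])
        pka = _parse_pka(row, name)
        bp = None if pd.isna(row["bp"]) else float(row["bp"])
        if mode == "ml":
            rec = DrugRecord(
                name=name,
                logp=float(row["logp"]),
                pka_entries=pka,
                fup=float(row["fup_pr"]),
                papp_caco2=float(row["caco2_pr"]),
                bp=bp,
                clt=float(row["clt_pr"]),
                provenance={"fup": "predicted", "papp_caco2": "predicted",
                            "clt": "predicted", "bp": "observed"},
            )
        else:
            clint = None if pd.isna(row["clint_ob"]) else float(row["clint_ob"])
            rec = DrugRecord(
                name=name,
                logp=float(row["logp"]),
                pka_entries=pka,
                fup=float(row["fup_ob"]),
                papp_caco2=float(row["caco2_ob"]),
                bp=bp,
                clint=clint,
                provenance={"fup": "observed", "papp_caco2": "observed",
                            "clint": "observed", "bp": "observed"},
            )
        rec.validate()
        records.append(rec)
    return records


def load_benchmark_table(path: str | None = None) -> pd.DataFrame:
    """Raw benchmark table as a DataFrame (all observed + predicted columns)."""
    df = pd.read_csv(path or default_drug_table_path())
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DrugTableError(f"drug table missing required columns: {missing}")
    return df


def generate_synthetic_drugs(n: int, seed: int) -> list[DrugRecord]:
    """Seeded synthetic drug records spanning the benchmarked property space.

    Properties are drawn uniformly over LogP [-1, 8.5], fup [0.002, 1],
    Papp [1, 110] 1e-6 cm/s, CLt [0.01, 1.6] L/h/kg and CLint [0.3, 300]
    mL/min/kg (log-uniform), cycling through acid / base / neutral /
    ampholyte ionization kinds so every kind appears for n >= 8.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    kinds = ["acid", "base", "neutral", "ampholyte"]
    records = []
    for i in range(n):
        kind = kinds[i % len(kinds)]
        if kind == "acid":
            pka = [(float(rng.uniform(3.0, 11.0)), "a")]
        elif kind == "base":
            pka = [(float(rng.uniform(3.0, 11.0)), "b")]
        elif kind == "ampholyte":
            pka = [(float(rng.uniform(3.0, 11.0)), "a"),
                   (float(rng.uniform(3.0, 11.0)), "b")]
        else:
            pka = []
        rec = DrugRecord(
            name=f"SYN{i:04d}",
            logp=float(rng.uniform(-1.0, 8.5)),
            pka_entries=pka,
            fup=float(rng.uniform(0.002, 1.0)),
            papp_caco2=float(rng.uniform(1.0, 110.0)),
            bp=None,
            clint=float(10 ** rng.uniform(math.log10(0.3), math.log10(300.0))),
            clt=float(rng.uniform(0.01, 1.6)),
            provenance={"all": "synthetic"},
        )
        rec.validate()
        records.append(rec)
    return records
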