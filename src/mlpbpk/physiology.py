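"""Human whole-body physiology: tissue volumes, flows, surface areas, composition.

The model divides the body into 14 tissues (lung, liver, kidney, heart, brain,
muscle, adipose, skin, bone, gut, spleen, pancreas, thymus and a lumped
rest-of-body) plus arterial, venous and portal blood vessels.  Each tissue is
split into vascular plasma, vascular blood cells, interstitial and
intracellular sub-compartments; vessels carry only plasma and blood cells.

Internal units are fixed: volume L, time h, flow L/h, surface area cm2,
amount mg, concentration mg/L.  All conversions happen at I/O boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import Any

__all__ = [
    "TissuePhysiology",
    "BodyPhysiology",
    "PhysiologyError",
    "load_physiology",
    "load_default_physiology",
    "validate_physiology",
    "dump_physiology",
]

FLOW_TOLERANCE = 0.01  # relative tolerance on cardiac-output conservation


class PhysiologyError(ValueError):
    """Raised when a physiology file is malformed or violates an invariant."""


@dataclass
class TissuePhysiology:
    """Volumes, flows, exchange surfaces and composition of one tissue.

    Composition fields (``f_*``, ``conc_acidic_phospholipid``,
    ``albumin_ratio``) parameterize tissue-to-plasma partitioning; volume
    fractions (``frac_*``) define the four sub-compartment volumes.
    """

    name: str
    volume_total: float          # L
    frac_vascular_plasma: float  # volume fractions, dimensionless
    frac_blood_cells: float
    frac_interstitial: float
    frac_intracellular: float
    blood_flow: float            # effluent blood flow, L/h
    sa_vascular: float           # cm2, plasma <-> interstitial interface
    sa_cellular: float           # cm2, interstitial <-> intracellular interface
    f_neutral_lipid: float
    f_neutral_phospholipid: float
    f_extracellular_water: float
    f_intracellular_water: float
    conc_acidic_phospholipid: float  # mg/g
    albumin_ratio: float             # tissue:plasma albumin ratio
    ph_intracellular: float

    def plasma_flow(self, hematocrit: float) -> float:
        return self.blood_flow * (1.0 - hematocrit)

    def blood_cell_flow(self, hematocrit: float) -> float:
        return self.blood_flow * hematocrit

    def subvolume(self, compartment: str) -> float:
        frac = {
            "vascular_plasma": self.frac_vascular_plasma,
            "vascular_blood_cells": self.frac_blood_cells,
            "interstitial": self.frac_interstitial,
            "intracellular": self.frac_intracellular,
        }[compartment]
        return self.volume_total * frac


@dataclass
class BodyPhysiology:
    """Whole-body parameterization: 14 tissues plus vessels and scalars."""

    tissues: dict[str, TissuePhysiology]
    hematocrit: float
    body_weight: float        # kg
    cardiac_output: float     # L blood/h
    gfr: float                # L/h
    plasma_ph: float
    blood_cell_ph: float
    vessel_volumes: dict[str, float]       # total blood L per vessel
    portal_tissues: list[str]
    sa_blood_cells_per_l: float            # cm2 per L blood
    blood_cells: dict[str, float]          # composition of blood cells
    plasma: dict[str, float]               # neutral lipid/phospholipid of plasma
    extra: dict[str, Any] = field(default_factory=dict)

    @property
    def venous_returning(self) -> list[str]:
        """Tissues whose effluent drains directly to venous blood."""
        return [
            n for n in self.tissues
            if n != "lung" and n not in self.portal_tissues
        ]

    def hepatic_artery_flow(self) -> float:
        portal = sum(self.tissues[n].blood_flow for n in self.portal_tissues)
        return self.tissues["liver"].blood_flow - portal

    def vessel_plasma_volume(self, vessel: str) -> float:
        return self.vessel_volumes[vessel] * (1.0 - self.hematocrit)

    def vessel_blood_cell_volume(self, vessel: str) -> float:
        return self.vessel_volumes[vessel] * self.hematocrit


def _tissue_from_dict(d: dict[str, Any]) -> TissuePhysiology:
    try:
        return TissuePhysiology(**d)
    except TypeError as exc:
        raise PhysiologyError(f"malformed tissue entry {d.get('name', '?')}: {exc}") from exc


def _body_from_dict(d: dict[str, Any]) -> BodyPhysiology:
    required = [
        "tissues", "hematocrit", "body_weight", "cardiac_output", "gfr",
        "plasma_ph", "blood_cell_ph", "vessel_volumes", "portal_tissues",
        "sa_blood_cells_per_l", "blood_cells", "plasma",
    ]
    missing = [k for k in required if k not in d]
    if missing:
        raise PhysiologyError(f"physiology file missing fields: {missing}")
    tissues = {t["name"]: _tissue_from_dict(t) for t in d["tissues"]}
    extra = {k: v for k, v in d.items() if k not in required}
    return BodyPhysiology(
        tissues=tissues,
        hematocrit=d["hematocrit"],
        body_weight=d["body_weight"],
        cardiac_output=d["cardiac_output"],
        gfr=d["gfr"],
        plasma_ph=d["plasma_ph"],
        blood_cell_ph=d["blood_cell_ph"],
        vessel_volumes=dict(d["vessel_volumes"]),
        portal_tissues=list(d["portal_tissues"]),
        sa_blood_cells_per_l=d["sa_blood_cells_per_l"],
        blood_cells=dict(d["blood_cells"]),
        plasma=dict(d["plasma"]),
        extra=extra,
    )


def validate_physiology(body: BodyPhysiology) -> list[str]:
    """Diagnostic report: list of violated invariants (empty iff all pass)."""
    report: list[str] = []
    if not (0.0 < body.hematocrit < 1.0):
        report.append(f"hematocrit {body.hematocrit} outside (0, 1)")
    for scalar in ("body_weight", "cardiac_output", "gfr"):
        if getattr(body, scalar) <= 0:
            report.append(f"{scalar} must be positive")
    for name, t in body.tissues.items():
        fracs = (t.frac_vascular_plasma, t.frac_blood_cells,
                 t.frac_interstitial, t.frac_intracellular)
        if any(f < 0 for f in fracs):
            report.append(f"{name}: negative volume fraction {fracs}")
        if sum(fracs) > 1.0 + 1e-9:
            report.append(f"{name}: volume fractions sum to {sum(fracs):.6f} > 1")
        if t.blood_flow <= 0:
            report.append(f"{name}: blood_flow {t.blood_flow} not positive")
        if t.sa_vascular <= 0 or t.sa_cellular <= 0:
            report.append(
                f"{name}: surface areas must be positive "
                f"(sa_vascular={t.sa_vascular}, sa_cellular={t.sa_cellular})"
            )
        if t.volume_total <= 0:
            report.append(f"{name}: volume_total {t.volume_total} not positive")
    for vessel, v in body.vessel_volumes.items():
        if v <= 0:
            report.append(f"vessel {vessel}: volume {v} not positive")
    missing = [n for n in body.portal_tissues if n not in body.tissues]
    if missing:
        report.append(f"portal tissues not in roster: {missing}")
    for required in ("lung", "liver", "kidney", "muscle", "skin", "adipose"):
        if required not in body.tissues:
            report.append(f"required tissue '{required}' missing")
    if "lung" in body.tissues and "liver" in body.tissues and not missing:
        venous_flow = sum(body.tissues[n].blood_flow for n in body.venous_returning)
        dev = abs(venous_flow - body.cardiac_output) / body.cardiac_output
        if dev > FLOW_TOLERANCE:
            report.append(
                f"venous-return flow {venous_flow:.3f} L/h deviates from cardiac "
                f"output {body.cardiac_output:.3f} L/h by {100 * dev:.2f}%"
            )
        if body.hepatic_artery_flow() <= 0:
            report.append(
                "liver blood flow does not exceed summed portal-tissue flows "
                f"(hepatic artery flow {body.hepatic_artery_flow():.3f} L/h)"
            )
        if abs(body.tissues["lung"].blood_flow - body.cardiac_output) \
                > FLOW_TOLERANCE * body.cardiac_output:
            report.append("lung blood flow must equal cardiac output")
    return report


def load_physiology(path: str) -> BodyPhysiology:
    """Load and validate a physiology JSON file."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise PhysiologyError(f"cannot parse physiology JSON {path}: {exc}") from exc
    body = _body_from_dict(data)
    violations = validate_physiology(body)
    if violations:
        raise PhysiologyError(
            "physiology invariant violations:\n  " + "\n  ".join(violations)
        )
    return body


def load_default_physiology() -> BodyPhysiology:
    """Packaged reference adult-human physiology (14 tissues, 70 kg)."""
    ref = resources.files("mlpbpk.data").joinpath("human_default.json")
    with resources.as_file(ref) as path:
        return load_physiology(str(path))


def dump_physiology(body: BodyPhysiology, path: str) -> None:
    """Write a BodyPhysiology back to JSON (round-trips bit-for-bit)."""
    data: dict[str, Any] = {
        "body_weight": body.body_weight,
        "hematocrit": body.hematocrit,
        "cardiac_output": body.cardiac_output,
        "gfr": body.gfr,
        "plasma_ph": body.plasma_ph,
        "blood_cell_ph": body.blood_cell_ph,
        "vessel_volumes": body.vessel_volumes,
        "portal_tissues": body.portal_tissues,
        "sa_blood_cells_per_l": body.sa_blood_cells_per_l,
        "blood_cells": body.blood_cells,
        "plasma": body.plasma,
        **body.extra,
        "tissues": [asdict(t) for t in body.tissues.values()],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2)
        fh.write("\n")
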