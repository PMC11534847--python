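"""Tissue partitioning: ionization, blood-cell partition and Rodgers-Rowland Kpu.

The tissue-to-unbound-plasma partition coefficient (Kpu) is computed with the
Rodgers-Rowland mechanistic equations from tissue composition (neutral lipid,
neutral phospholipid, intra/extracellular water, acidic phospholipid, tissue
albumin) and the drug's LogP, pKa and fup:

* moderate-to-strong bases (any basic pKa >= 7) partition into acidic
  phospholipids; the association constant Ka_AP is back-calculated from the
  measured blood-cell partition (kbc / fup) using blood-cell composition;
* acids, neutrals and weak bases instead carry an albumin-binding term scaled
  by the tissue:plasma albumin ratio.

LogP (not LogD) enters the neutral-lipid term, and neutral phospholipid
affinity is the conventional 0.3*P + 0.7 mix.  The Kpu terms are assigned to
the interstitial (extracellular water + albumin binding) and intracellular
(cell water, acidic phospholipid, lipids) sub-compartments so that the
volume-weighted whole-tissue Kp is preserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .drug_io import DrugRecord
from .physiology import BodyPhysiology, TissuePhysiology

__all__ = [
    "PartitionSet",
    "ionized_ratio",
    "kbc_from_bp",
    "kpu_rodgers_rowland",
    "bp_predicted",
    "build_partition_set",
    "KBC_FLOOR",
]

logger = logging.getLogger(__name__)

# Floor on the blood-cell:plasma partition: a measured BP at or below 1 - hct
# yields kbc <= 0, which would put an infinite sink in the plasma<->blood-cell
# flux term.  The floor keeps that flux finite; it is configurable per call.
KBC_FLOOR = 0.01

STRONG_BASE_PKA = 7.0


def _ionization_factors(pka_entries, ph: float) -> tuple[float, float, float]:
    """(X_total, X_base, X_acid) at the given pH.

    X_base = 10^(pKa - pH) per basic group, X_acid = 10^(pH - pKa) per acidic
    group (Henderson-Hasselbalch).  Independent groups combine
    multiplicatively in the neutral fraction, so the total ionized:neutral
    ratio is X_total = prod(1 + X_i) - 1.
    """
    x_base = 0.0
    x_acid = 0.0
    prod = 1.0
    for value, kind in pka_entries:
        if kind == "b":
            x = 10.0 ** (value - ph)
            x_base += x
        else:
            x = 10.0 ** (ph - value)
            x_acid += x
        prod *= 1.0 + x
    return prod - 1.0, x_base, x_acid


def ionized_ratio(drug: DrugRecord, ph: float) -> tuple[float, float]:
    """Neutral fraction and total ionized:neutral ratio X at the given pH."""
    if not (0.0 <= ph <= 14.0):
        raise ValueError(f"pH {ph} outside [0, 14]")
    x_total, _, _ = _ionization_factors(drug.pka_entries, ph)
    return 1.0 / (1.0 + x_total), x_total


def kbc_from_bp(bp: float, fup: float, hematocrit: float,
                floor: float = KBC_FLOOR) -> float:
    """Blood-cell:plasma partition from the blood:plasma ratio.

    BP = (1 - hct) + hct * kbc, hence kbc = (BP - (1 - hct)) / hct, floored
    at ``floor`` to keep the plasma<->blood-cell exchange flux finite.
    """
    if bp <= 0:
        raise ValueError(f"bp must be positive, got {bp}")
    if not (0.0 < hematocrit < 1.0):
        raise ValueError(f"hematocrit {hematocrit} outside (0, 1)")
    kbc = (bp - (1.0 - hematocrit)) / hematocrit
    return max(kbc, floor)


def _is_strong_base(drug: DrugRecord) -> bool:
    return any(kind == "b" and value >= STRONG_BASE_PKA
               for value, kind in drug.pka_entries)


def _lipid_term(p: float, f_nl: float, f_np: float) -> float:
    return p * f_nl + (0.3 * p + 0.7) * f_np


def _ka_ap_from_blood_cells(drug: DrugRecord, body: BodyPhysiology,
                            kbc: float) -> float:
    """Acidic-phospholipid association constant from the blood-cell partition."""
    p = 10.0 ** drug.logp
    bc = body.blood_cells
    _, xp, _ = _ionization_factors(drug.pka_entries, body.plasma_ph)
    _, xbc, _ = _ionization_factors(drug.pka_entries, body.blood_cell_ph)
    kpu_bc = kbc / drug.fup
    residual = (
        kpu_bc
        - (1.0 + xbc) / (1.0 + xp) * bc["f_intracellular_water"]
        - _lipid_term(p, bc["f_neutral_lipid"], bc["f_neutral_phospholipid"])
        / (1.0 + xp)
    )
    ka_ap = residual * (1.0 + xp) / (bc["conc_acidic_phospholipid"] * xbc)
    if ka_ap < 0.0:
        logger.warning(
            "%s: negative acidic-phospholipid association constant (%.3g) "
            "back-calculated from blood cells; clamped to 0", drug.name, ka_ap)
        ka_ap = 0.0
    return ka_ap


def _plasma_protein_binding(drug: DrugRecord, body: BodyPhysiology) -> float:
    """Albumin-binding estimate 1/fup - 1 - plasma lipid partition, clamped.

    For very lipophilic compounds the plasma lipid partition alone can exceed
    1/fup - 1, driving the estimate (and then Kpu) negative; the clamp treats
    such drugs as having no protein-mediated tissue binding.
    """
    p = 10.0 ** drug.logp
    plasma_lipids = _lipid_term(
        p, body.plasma["f_neutral_lipid"], body.plasma["f_neutral_phospholipid"])
    protein_binding = 1.0 / drug.fup - 1.0 - plasma_lipids
    if protein_binding < 0.0:
        logger.warning(
            "%s: plasma lipid partition exceeds 1/fup - 1; albumin binding "
            "term clamped to 0", drug.name)
        protein_binding = 0.0
    return protein_binding


def _kpu_terms(drug: DrugRecord, tissue: TissuePhysiology,
               body: BodyPhysiology, ka_ap: float | None,
               protein_binding: float | None = None) -> tuple[float, float]:
    """(interstitial share, intracellular share) of Kpu for one tissue."""
    p = 10.0 ** drug.logp
    lipids = _lipid_term(p, tissue.f_neutral_lipid, tissue.f_neutral_phospholipid)
    if _is_strong_base(drug):
        if ka_ap is None:
            raise ValueError(f"{drug.name}: strong base requires Ka_AP")
        _, xp, _ = _ionization_factors(drug.pka_entries, body.plasma_ph)
        _, xiw, _ = _ionization_factors(drug.pka_entries, tissue.ph_intracellular)
        ist = tissue.f_extracellular_water
        icl = (
            (1.0 + xiw) / (1.0 + xp) * tissue.f_intracellular_water
            + ka_ap * tissue.conc_acidic_phospholipid * xiw / (1.0 + xp)
            + lipids / (1.0 + xp)
        )
    else:
        xp, _, _ = _ionization_factors(drug.pka_entries, body.plasma_ph)
        xiw, _, _ = _ionization_factors(drug.pka_entries, tissue.ph_intracellular)
        if protein_binding is None:
            protein_binding = _plasma_protein_binding(drug, body)
        ist = tissue.f_extracellular_water + tissue.albumin_ratio * protein_binding
        icl = (
            (1.0 + xiw) / (1.0 + xp) * tissue.f_intracellular_water
            + lipids / (1.0 + xp)
        )
    return ist, icl


def kpu_rodgers_rowland(drug: DrugRecord, tissue: TissuePhysiology,
                        body: BodyPhysiology, kbc: float | None = None) -> float:
    """Tissue-to-unbound-plasma partition coefficient for one tissue."""
    if kbc is None:
        bp = drug.bp if drug.bp is not None else bp_predicted(drug, body)
        kbc = kbc_from_bp(bp, drug.fup, body.hematocrit)
    ka_ap = _ka_ap_from_blood_cells(drug, body, kbc) if _is_strong_base(drug) else None
    ist, icl = _kpu_terms(drug, tissue, body, ka_ap)
    return ist + icl


def bp_predicted(drug: DrugRecord, body: BodyPhysiology) -> float:
    """Blood:plasma ratio predicted from blood-cell composition.

    BP = (1 - hct) + hct * fup * Kpu_bc, with the blood-cell Kpu from cell
    water and lipids.  The acidic-phospholipid term is omitted (its
    association constant is only identifiable from a measured BP), so
    predictions for strong bases are conservative.
    """
    p = 10.0 ** drug.logp
    bc = body.blood_cells
    xp, _, _ = _ionization_factors(drug.pka_entries, body.plasma_ph)
    xbc, _, _ = _ionization_factors(drug.pka_entries, body.blood_cell_ph)
    kpu_bc = (
        (1.0 + xbc) / (1.0 + xp) * bc["f_intracellular_water"]
        + _lipid_term(p, bc["f_neutral_lipid"], bc["f_neutral_phospholipid"])
        / (1.0 + xp)
    )
    hct = body.hematocrit
    return (1.0 - hct) + hct * drug.fup * kpu_bc


@dataclass
class PartitionSet:
    """Equilibrium partition coefficients of one drug across all tissues.

    ``kpu``/``kp`` are extravascular tissue:unbound-plasma and tissue:plasma
    coefficients; ``interstitial_ratio``/``intracellular_ratio`` are the
    sub-compartment:plasma concentration ratios used by the flux terms; and
    ``kp_total`` is the volume-fraction-weighted whole-tissue:plasma ratio
    (including the vascular sub-compartments), which the simulator recovers
    at distribution equilibrium.
    """

    drug_name: str
    bp: float
    kbc: float
    kpu: dict[str, float]
    kp: dict[str, float]
    interstitial_ratio: dict[str, float]
    intracellular_ratio: dict[str, float]
    kp_total: dict[str, float]

    def consistency_residual(self, body: BodyPhysiology) -> float:
        """Max |volume-weighted sub-compartment sum - kp_total| over tissues."""
        worst = 0.0
        for name, t in body.tissues.items():
            s = (t.frac_vascular_plasma * 1.0
                 + t.frac_blood_cells * self.kbc
                 + t.frac_interstitial * self.interstitial_ratio[name]
                 + t.frac_intracellular * self.intracellular_ratio[name])
            worst = max(worst, abs(s - self.kp_total[name]))
        return worst


def build_partition_set(drug: DrugRecord, body: BodyPhysiology,
                        kbc_floor: float = KBC_FLOOR) -> PartitionSet:
    """Assemble per-tissue partition coefficients and sub-compartment ratios.

    A measured BP (from the drug record) takes precedence; otherwise BP is
    predicted from blood-cell composition.  kbc always derives from the BP
    actually used.
    """
    bp = drug.bp if drug.bp is not None else bp_predicted(drug, body)
    kbc = kbc_from_bp(bp, drug.fup, body.hematocrit, floor=kbc_floor)
    if _is_strong_base(drug):
        ka_ap, protein_binding = _ka_ap_from_blood_cells(drug, body, kbc), None
    else:
        ka_ap, protein_binding = None, _plasma_protein_binding(drug, body)

    kpu: dict[str, float] = {}
    kp: dict[str, float] = {}
    r_ist: dict[str, float] = {}
    r_icl: dict[str, float] = {}
    kp_total: dict[str, float] = {}
    for name, tissue in body.tissues.items():
        ist, icl = _kpu_terms(drug, tissue, body, ka_ap, protein_binding)
        k = ist + icl
        if not k > 0:
            raise ValueError(f"{drug.name}/{name}: non-positive Kpu {k:.3g}")
        kpu[name] = k
        kp[name] = k * drug.fup
        # Sub-compartment equilibrium ratios: the Kpu shares are per L of
        # whole tissue; dividing by the sub-compartment volume fraction
        # converts them to concentration ratios vs plasma.
        r_ist[name] = drug.fup * ist / tissue.frac_interstitial
        r_icl[name] = drug.fup * icl / tissue.frac_intracellular
        kp_total[name] = (tissue.frac_vascular_plasma
                          + tissue.frac_blood_cells * kbc
                          + drug.fup * k)
    return PartitionSet(
        drug_name=drug.name, bp=bp, kbc=kbc, kpu=kpu, kp=kp,
        interstitial_ratio=r_ist, intracellular_ratio=r_icl,
        kp_total=kp_total,
    )
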