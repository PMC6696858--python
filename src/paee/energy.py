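"""Energy-component bookkeeping shared by every expenditure source.

TEE decomposes as BMR + DIT + PAEE, with diet-induced thermogenesis (DIT)
approximated as a fixed fraction of TEE (0.1 by default).  Physical
activity level is PAL = TEE / BMR.  The same summary is used whether TEE
comes from doubly labeled water, the metabolic chamber, or a wearable
device, so the identities

    PAEE = (1 - dit_fraction) * TEE - BMR
    PAEE = BMR * ((1 - dit_fraction) * PAL - 1)

hold by construction for every instance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import DIT_FRACTION


@dataclass
class EnergySummary:
    """Daily energy-expenditure components for one source (kcal/day)."""

    source: str
    tee_kcal_day: float
    bmr_kcal_day: float
    dit_kcal_day: float
    paee_kcal_day: float
    pal: float
    paee_per_wt_kcal_kg_day: float | None = None
    flags: list[str] = field(default_factory=list)


def energy_summary(
    source: str,
    tee: float,
    bmr: float,
    weight_kg: float | None = None,
    dit_fraction: float = DIT_FRACTION,
    dit_included_in_tee: bool = False,
) -> EnergySummary:
    """Build an :class:`EnergySummary` from TEE and BMR.

    When ``dit_included_in_tee`` the source's TEE already folds DIT into
    its baseline, so PAEE = TEE - BMR and the DIT component is reported
    as zero (the CaloriScan-style reduction rule).
    """
    if tee <= 0 or bmr <= 0:
        raise ValueError("TEE and BMR must be positive")
    dit = 0.0 if dit_included_in_tee else dit_fraction * tee
    paee = tee - bmr - dit
    flags = []
    if paee < -0.5 * bmr:
        flags.append("implausible-paee")
    return EnergySummary(
        source=source,
        tee_kcal_day=tee,
        bmr_kcal_day=bmr,
        dit_kcal_day=dit,
        paee_kcal_day=paee,
        pal=tee / bmr,
        paee_per_wt_kcal_kg_day=None if weight_kg is None else paee / weight_kg,
        flags=flags,
    )
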