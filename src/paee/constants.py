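"""Physical and physiological constants used across the pipeline.

All constants that enter a published equation are collected in frozen
dataclasses so they can be overridden in one place (e.g. for sensitivity
analyses) while the defaults remain the literature values.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class DLWConstants:
    """Constants of the doubly-labeled-water CO2-production equation.

    The CO2 production rate is computed as

        rCO2 (mol/day) = rco2_coef * TBW * (frac_o * ko - frac_d * kd)

    where TBW is total body water in mol and kd, ko are the first-order
    elimination rates of deuterium and oxygen-18 (per day).  The
    fractionation factors assume isotope fractionation applies only to
    breath water.  Dilution spaces are converted to TBW by dividing the
    deuterium space by ``tbw_div_d`` and the oxygen-18 space by
    ``tbw_div_o`` and averaging.

    Total energy expenditure follows a food-quotient Weir form

        TEE (kcal/day) = weir_co2_coef * rCO2_L + weir_fq_coef * rCO2_L / FQ

    with rCO2 in litres/day.
    """

    frac_o: float = 1.007
    frac_d: float = 1.041
    rco2_coef: float = 0.4554
    tbw_div_d: float = 1.041
    tbw_div_o: float = 1.007
    weir_co2_coef: float = 1.1
    weir_fq_coef: float = 3.9
    #: litres per mol of CO2 at STP; 22.26 L/mol is also used in the
    #: DLW literature, hence configurable.
    molar_volume_L: float = 22.414
    #: acceptable dilution-space-ratio window (QC flag outside it)
    ratio_qc_lo: float = 1.015
    ratio_qc_hi: float = 1.060


@dataclass(frozen=True)
class WeirConstants:
    """Classic Weir coefficients (kcal per litre of gas), no protein term.

    EE (kcal) = o2_coef * VO2_L + co2_coef * VCO2_L
    """

    o2_coef: float = 3.941
    co2_coef: float = 1.106


# Natural-abundance isotope ratios of the VSMOW water standard.
VSMOW_RATIO_2H = 155.76e-6   # 2H/1H
VSMOW_RATIO_18O = 2005.20e-6  # 18O/16O

# Atomic masses (g/mol) for dose bookkeeping.
MASS_1H = 1.00794
MASS_2H = 2.01410
MASS_16O = 15.9949
MASS_18O = 17.9992
MASS_H2O = 2 * MASS_1H + MASS_16O  # light water

#: fraction of total energy expenditure attributed to diet-induced
#: thermogenesis when deriving activity energy expenditure
DIT_FRACTION = 0.1

#: resting oxygen uptake defining 1 MET, mL O2 per kg per minute
MET_VO2_ML_KG_MIN = 3.5
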