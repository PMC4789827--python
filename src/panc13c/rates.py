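"""Mapping enzyme activities and pool sizes to label-exchange rate constants.

The hyperpolarised 13C label moves between the injected pyruvate pool and the
endogenous lactate and alanine pools by enzyme-catalysed isotope exchange at
chemical steady state.  Below the Michaelis constants the unidirectional
exchange flux through each enzyme scales with both the enzyme activity and the
substrate pool (mass action):

    J_lac = kappa * LDH * [lactate]       J_ala = kappa * ALT * [alanine]

which gives apparent first-order rate constants

    k_lp = kappa * LDH            k_pl = k_lp * [lactate] / P
    k_ap = kappa * ALT            k_pa = k_ap * [alanine] / P

where P is the tissue pyruvate pool reached after injection.  Forward and
reverse fluxes balance exactly (k_pl * P = k_lp * L), so the mapping describes
pure exchange with no net chemical conversion.  The proportionality kappa
(s^-1 per mU/mg protein) is not measurable from the reported data and is a
calibration constant; only orderings and limits of the resulting ratios are
quantitative claims of this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .stages import DiseaseStageProfile


@dataclass(frozen=True)
class CalibrationConstants:
    """Free constants of the activity-to-rate mapping.

    Attributes
    ----------
    rate_per_activity
        kappa, apparent first-order exchange constant per unit enzyme
        activity, s^-1 per (mU/mg protein).
    pyruvate_pool
        Tissue pyruvate pool reached after injection, μmol/g wet tissue.
    t1
        Longitudinal relaxation time assumed for all three carbonyl
        carbons, s.
    bolus_start, bolus_duration, bolus_amplitude
        Rectangular pyruvate delivery function (s, s, arbitrary
        magnetization units per second).
    """

    rate_per_activity: float = 5e-5
    pyruvate_pool: float = 5.0
    t1: float = 30.0
    bolus_start: float = 0.0
    bolus_duration: float = 10.0
    bolus_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_per_activity <= 0 or self.pyruvate_pool <= 0:
            raise ValueError("calibration constants must be > 0")


#: Default calibration for in-vivo imaging simulations: apparent k_pl in the
#: 0.003-0.09 s^-1 range across stages, the regime reported for hyperpolarised
#: pyruvate experiments in vivo.
IN_VIVO_CALIBRATION = CalibrationConstants(rate_per_activity=5e-5)

#: Default calibration for the cell-free homogenate assay, where the buffer is
#: optimised for exchange: tissue-referenced pools approach isotopic
#: equilibrium over tens of seconds while the 5-point initial window of the
#: diluted homogenate stays close to linear.
ASSAY_CALIBRATION = CalibrationConstants(rate_per_activity=5e-4)


@dataclass(frozen=True)
class ExchangeParams:
    """Three-pool exchange model parameters for one tissue type.

    Rates are apparent first-order constants (s^-1): ``k_pl``/``k_pa`` move
    label from pyruvate into lactate/alanine, ``k_lp``/``k_ap`` return it.
    ``m0`` is the longitudinal magnetization (pyruvate, lactate, alanine) at
    t = 0, for experiments that start from a prepared state instead of a
    bolus.
    """

    k_pl: float = 0.0
    k_pa: float = 0.0
    k_lp: float = 0.0
    k_ap: float = 0.0
    t1_pyr: float = 30.0
    t1_lac: float = 30.0
    t1_ala: float = 30.0
    bolus_start: float = 0.0
    bolus_duration: float = 10.0
    bolus_amplitude: float = 0.0
    m0: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("k_pl", "k_pa", "k_lp", "k_ap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("t1_pyr", "t1_lac", "t1_ala"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0 (use math.inf for no decay)")
        if not self.bolus_duration > 0:
            raise ValueError("bolus_duration must be > 0")


def activities_to_rates(
    profile: DiseaseStageProfile,
    calib: CalibrationConstants = IN_VIVO_CALIBRATION,
) -> ExchangeParams:
    """Convert a stage profile into three-pool exchange rate constants.

    The forward constants grow linearly with the corresponding enzyme
    activity and with the product pool (mass-action exchange flux); reverse
    constants follow from flux balance, ``k_lp = k_pl * P / L``.

    Raises
    ------
    ValueError
        If either activity is negative.
    """
    if profile.ldh_activity < 0 or profile.alt_activity < 0:
        raise ValueError("enzyme activities must be >= 0")
    kappa = calib.rate_per_activity
    pyr = calib.pyruvate_pool
    k_lp = kappa * profile.ldh_activity
    k_ap = kappa * profile.alt_activity
    k_pl = k_lp * profile.lactate_conc / pyr
    k_pa = k_ap * profile.alanine_conc / pyr
    return ExchangeParams(
        k_pl=k_pl,
        k_pa=k_pa,
        k_lp=k_lp,
        k_ap=k_ap,
        t1_pyr=calib.t1,
        t1_lac=calib.t1,
        t1_ala=calib.t1,
        bolus_start=calib.bolus_start,
        bolus_duration=calib.bolus_duration,
        bolus_amplitude=calib.bolus_amplitude,
    )


def _rate_or_zero(t1: float) -> float:
    """Relaxation rate 1/T1, with T1 = inf meaning no decay."""
    return 0.0 if math.isinf(t1) else 1.0 / t1
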