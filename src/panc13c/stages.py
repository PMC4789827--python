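"""Disease-stage metabolic profiles of the mouse pancreas.

Each stage of pancreatic disease progression — from healthy pancreas through
caerulein-induced pancreatitis and murine pancreatic intraepithelial neoplasia
(mPanIN, carried by Kras-mutant KC mice imaged at 2, 4 and 9 months) to frank
tumour — is summarised by four tissue-extract measurements: the alanine and
lactate pool concentrations (μmol per g wet tissue) and the activities of
lactate dehydrogenase (LDH) and alanine aminotransferase (ALT) (mU per mg
protein).  These four numbers govern how injected [1-13C]pyruvate partitions
its hyperpolarised label between the alanine and lactate pools, and are the
inputs to every simulation in this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum


class Stage(str, Enum):
    """Stages of disease progression in the KC / KPC mouse models."""

    CONTROL = "control"
    PANCREATITIS = "pancreatitis"
    KC_2MO = "kc_2mo"
    KC_4MO = "kc_4mo"
    KC_9MO = "kc_9mo"
    TUMOUR_SARCOMATOID = "tumour_sarcomatoid"
    TUMOUR_PDA = "tumour_pda"


@dataclass(frozen=True)
class DiseaseStageProfile:
    """Mean tissue-extract metabolite pools and enzyme activities for one stage.

    Attributes
    ----------
    stage
        Disease stage this profile describes.
    alanine_conc, lactate_conc
        Endogenous pool concentrations, μmol per g wet tissue.
    ldh_activity, alt_activity
        Lactate dehydrogenase and alanine aminotransferase activities,
        mU per mg protein.
    """

    stage: Stage
    alanine_conc: float
    lactate_conc: float
    ldh_activity: float
    alt_activity: float

    def __post_init__(self) -> None:
        for name in ("alanine_conc", "lactate_conc", "ldh_activity", "alt_activity"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        if not isinstance(self.stage, Stage):
            object.__setattr__(self, "stage", Stage(self.stage))


# Mean tissue-extract values per stage (alanine, lactate in μmol/g wet tissue;
# LDH, ALT in mU/mg protein), measured by 1H NMR (TSP-referenced) and
# spectrophotometric assay respectively.
_PROFILES: dict[Stage, tuple[float, float, float, float]] = {
    Stage.CONTROL: (1.82, 1.55, 204.35, 6.10),
    Stage.PANCREATITIS: (1.19, 1.36, 300.78, 9.09),
    Stage.KC_4MO: (0.98, 1.80, 616.44, 5.09),
    Stage.KC_9MO: (1.08, 4.24, 763.46, 3.94),
    Stage.TUMOUR_SARCOMATOID: (4.58, 17.80, 1008.9, 0.28),
    Stage.TUMOUR_PDA: (1.70, 8.14, 1142.44, 0.17),
}

# Synthetic profile for 2-month-old KC pancreas: no extract measurements exist
# for this age, whose tissue is predominantly normal with low-grade mPanIN, so
# it is represented by the midpoint of the control and 4-month profiles.
_PROFILES[Stage.KC_2MO] = tuple(
    (a + b) / 2.0 for a, b in zip(_PROFILES[Stage.CONTROL], _PROFILES[Stage.KC_4MO])
)  # type: ignore[assignment]


def stage_profile(stage: Stage | str) -> DiseaseStageProfile:
    """Return the canonical metabolic profile for a disease stage.

    Parameters
    ----------
    stage
        One of the :class:`Stage` members (or its string value).

    Returns
    -------
    DiseaseStageProfile
        Mean alanine/lactate pool sizes and LDH/ALT activities for the stage.
        The 2-month KC profile is synthetic (interpolated between control and
        4 months, where no extract measurements exist).
    """
    try:
        stage = Stage(stage)
    except ValueError:
        valid = ", ".join(s.value for s in Stage)
        raise ValueError(f"unknown stage {stage!r}; valid stages: {valid}") from None
    ala, lac, ldh, alt = _PROFILES[stage]
    return DiseaseStageProfile(
        stage=stage,
        alanine_conc=ala,
        lactate_conc=lac,
        ldh_activity=ldh,
        alt_activity=alt,
    )
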