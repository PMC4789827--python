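"""Cell-free homogenate isotope-exchange computation.

Freeze-clamped pancreas is homogenised into a buffer mimicking intracellular
conditions, unlabelled alanine and lactate are added at concentrations
matching the tissue, and [3-13C]pyruvate is added.  1H NMR then follows the
13C label entering the alanine and lactate methyl resonances.  The analysis
chain is: simulate (or load) the labelling time courses; fit a straight line
to the initial five points of the labelled alanine and lactate curves;
correct the fitted rates for the dilution of the tissue in the NMR tube
(slope in mM/s = μmol/mL/s, times sample volume in mL, over wet weight in
g); and integrate the same exchange law forward for 20 s with the tissue
pool sizes to predict the label partition a hyperpolarised in-vivo
measurement would see.

Kinetic law: bidirectional isotope exchange at chemical steady state with
flux proportional to enzyme activity times substrate pool.  With labelled
fractions f = [X*]/[X] of each pool,

    d[lac*]/dt = J_L (f_pyr - f_lac),   J_L = kappa * LDH * [lac]

and likewise for alanine with J_A = kappa * ALT * [ala].  Totals of each
pool and the total labelled species are conserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.stats import linregress

from .rates import ASSAY_CALIBRATION, CalibrationConstants, ExchangeParams, activities_to_rates
from .stages import DiseaseStageProfile, Stage, stage_profile

__all__ = [
    "HomogenateAssay",
    "LabelTimeCourse",
    "InitialRateFit",
    "InVivoPrediction",
    "assay_for_stage",
    "simulate_label_exchange",
    "fit_initial_rate",
    "dilution_correct",
    "predict_in_vivo",
    "quantify_extract",
]

#: Added unlabelled metabolite concentrations (alanine mM, lactate mM) per
#: stage, chosen to match the respective tissue concentrations.
ADDED_CONCENTRATIONS: dict[Stage, tuple[float, float]] = {
    Stage.CONTROL: (2.0, 2.0),
    Stage.PANCREATITIS: (1.0, 1.0),
    Stage.KC_4MO: (1.0, 2.0),
    Stage.KC_9MO: (1.0, 4.0),
    Stage.TUMOUR_PDA: (2.0, 9.0),
}


@dataclass(frozen=True)
class HomogenateAssay:
    """One cell-free exchange assay: tissue profile plus tube composition."""

    profile: DiseaseStageProfile
    added_alanine: float  # mM
    added_lactate: float  # mM
    added_labelled_pyruvate: float = 5.0  # mM
    wet_weight: float = 0.2  # g
    sample_volume: float = 0.6  # mL
    temperature: float = 37.0  # degrees C

    def __post_init__(self) -> None:
        if min(self.added_alanine, self.added_lactate, self.added_labelled_pyruvate) < 0:
            raise ValueError("added concentrations must be >= 0")
        if self.wet_weight <= 0 or self.sample_volume <= 0:
            raise ValueError("wet_weight and sample_volume must be > 0")

    @property
    def dilution(self) -> float:
        """Tissue dilution factor in the tube, (g wet tissue) / (mL sample)."""
        return self.wet_weight / self.sample_volume


def assay_for_stage(stage: Stage | str, **overrides) -> HomogenateAssay:
    """Standard assay for a stage: tissue profile plus its added pools."""
    stage = Stage(stage)
    if stage not in ADDED_CONCENTRATIONS:
        raise ValueError(
            f"no homogenate assay defined for stage {stage.value!r}; "
            f"available: {[s.value for s in ADDED_CONCENTRATIONS]}"
        )
    ala, lac = ADDED_CONCENTRATIONS[stage]
    return HomogenateAssay(
        profile=stage_profile(stage),
        added_alanine=ala,
        added_lactate=lac,
        **overrides,
    )


@dataclass(frozen=True)
class LabelTimeCourse:
    """Concentrations of labelled and unlabelled species over time (mM)."""

    times: np.ndarray  # s
    labelled: dict[str, np.ndarray]  # keys: pyruvate, alanine, lactate
    unlabelled: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def total(self, metabolite: str) -> np.ndarray:
        return self.labelled[metabolite] + self.unlabelled[metabolite]


@dataclass(frozen=True)
class InitialRateFit:
    """Ordinary least-squares line through the first five labelling points."""

    slope: float  # mM/s
    intercept: float  # mM
    r_squared: float
    n_points: int
    metabolite: str


@dataclass(frozen=True)
class InVivoPrediction:
    """Predicted 20-s label partition in tissue (μmol/g) and its ratio."""

    labelled_alanine_20s: float
    labelled_lactate_20s: float
    ala_lac_label_ratio: float
    horizon: float
    mode: str
    ratio_defined: bool


def exchange_rates_for_assay(
    assay: HomogenateAssay,
    calib: CalibrationConstants = ASSAY_CALIBRATION,
) -> ExchangeParams:
    """Exchange rate constants for the assay's tissue, at tissue strength."""
    return activities_to_rates(assay.profile, calib)


def simulate_label_exchange(
    assay: HomogenateAssay,
    rates: ExchangeParams,
    times: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> LabelTimeCourse:
    """Simulate 13C label incorporation into alanine and lactate.

    ``rates.k_lp`` and ``rates.k_ap`` are the tissue-strength pool exchange
    constants (s^-1); in the tube they are scaled down by the tissue
    dilution factor (wet weight / sample volume).  All added pyruvate starts
    labelled; alanine and lactate start unlabelled.  Optional Gaussian
    measurement noise is added to the labelled concentrations (totals are
    preserved and concentrations clipped to physical range).
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or times[0] < 0:
        raise ValueError("times must be a non-empty, non-negative 1-D grid")
    if times.size > 1 and np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    p_tot = assay.added_labelled_pyruvate
    a_tot = assay.added_alanine
    l_tot = assay.added_lactate
    g_l = rates.k_lp * assay.dilution  # fraction-exchange rate, s^-1
    g_a = rates.k_ap * assay.dilution

    # labelled concentrations x = [pyr*, lac*, ala*]; fluxes J = g * pool
    if p_tot > 0:
        gen = np.array(
            [
                [-(g_l * l_tot + g_a * a_tot) / p_tot, g_l, g_a],
                [g_l * l_tot / p_tot, -g_l, 0.0],
                [g_a * a_tot / p_tot, 0.0, -g_a],
            ]
        )
    else:
        gen = np.zeros((3, 3))
    x0 = np.array([p_tot, 0.0, 0.0])
    labelled = np.empty((times.size, 3))
    cache: dict[float, np.ndarray] = {}
    x = x0
    prev_t = 0.0
    for i, t in enumerate(times):
        dt = t - prev_t
        if dt > 0:
            e = cache.get(dt)
            if e is None:
                e = expm(gen * dt)
                cache[dt] = e
            x = e @ x
        labelled[i] = x
        prev_t = t

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = labelled + noise_sd * rng.standard_normal(labelled.shape)
        totals = np.array([p_tot, l_tot, a_tot])
        labelled = np.clip(noisy, 0.0, totals[None, :])

    lab = {
        "pyruvate": labelled[:, 0],
        "lactate": labelled[:, 1],
        "alanine": labelled[:, 2],
    }
    unlab = {
        "pyruvate": p_tot - lab["pyruvate"],
        "lactate": l_tot - lab["lactate"],
        "alanine": a_tot - lab["alanine"],
    }
    return LabelTimeCourse(times=times, labelled=lab, unlabelled=unlab)


def fit_initial_rate(tc: LabelTimeCourse, metabolite: str) -> InitialRateFit:
    """Fit a straight line to the initial five labelled-concentration points."""
    if metabolite not in tc.labelled:
        raise ValueError(f"unknown metabolite {metabolite!r}")
    if tc.times.size < 5:
        raise ValueError("need at least 5 time points for the initial-rate fit")
    t = tc.times[:5]
    y = tc.labelled[metabolite][:5]
    if np.ptp(y) == 0:
        return InitialRateFit(0.0, float(y[0]), 1.0, 5, metabolite)
    res = linregress(t, y)
    return InitialRateFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=5,
        metabolite=metabolite,
    )


def dilution_correct(
    fit: InitialRateFit | float, wet_weight: float, sample_volume: float
) -> float:
    """Convert a tube-frame rate (mM/s) to a tissue-frame rate (μmol/s/g).

    mM/s equals μmol/mL/s, so the whole-tube rate is slope * sample volume
    (mL) and the per-gram rate divides by the wet weight (g).
    """
    if wet_weight <= 0 or sample_volume <= 0:
        raise ValueError("wet_weight and sample_volume must be > 0")
    slope = fit.slope if isinstance(fit, InitialRateFit) else float(fit)
    return slope * sample_volume / wet_weight


def predict_in_vivo(
    rate_ala: float,
    rate_lac: float,
    pools: DiseaseStageProfile,
    horizon: float = 20.0,
    mode: str = "integrated",
) -> InVivoPrediction:
    """Extrapolate dilution-corrected exchange rates to the in-vivo label
    partition ``horizon`` seconds after a pyruvate injection.

    ``integrated`` (default) integrates the same exchange law with the
    tissue pool sizes, assuming the injected pyruvate pool stays essentially
    fully labelled over the horizon:

        ala*(t) = A (1 - exp(-rate_ala t / A)),  A the tissue alanine pool,

    and likewise for lactate.  ``linear`` uses rate * horizon without
    back-exchange.  In the short-horizon limit both modes give
    ala*/lac* -> rate_ala / rate_lac.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if rate_ala < 0 or rate_lac < 0:
        raise ValueError("rates must be >= 0")
    if mode not in ("integrated", "linear"):
        raise ValueError("mode must be 'integrated' or 'linear'")

    if mode == "linear":
        ala = rate_ala * horizon
        lac = rate_lac * horizon
    else:
        a_pool = pools.alanine_conc
        l_pool = pools.lactate_conc
        ala = a_pool * -np.expm1(-rate_ala * horizon / a_pool) if a_pool > 0 else 0.0
        lac = l_pool * -np.expm1(-rate_lac * horizon / l_pool) if l_pool > 0 else 0.0

    defined = lac > 0 or ala > 0
    ratio = ala / lac if lac > 0 else (float("inf") if ala > 0 else float("nan"))
    return InVivoPrediction(
        labelled_alanine_20s=float(ala),
        labelled_lactate_20s=float(lac),
        ala_lac_label_ratio=float(ratio),
        horizon=horizon,
        mode=mode,
        ratio_defined=bool(defined),
    )


def quantify_extract(
    peak_integrals: Mapping[str, float],
    tsp_area: float,
    tissue_mass: float,
    extract_volume: float,
    tsp_conc: float = 5.0,
    protons_per_resonance: Mapping[str, int] | None = None,
) -> dict[str, float]:
    """TSP-referenced quantification of extract metabolites, μmol/g tissue.

    Resonance areas are normalised to the TSP reference (9 equivalent
    protons, ``tsp_conc`` mM); the methyl resonances of lactate and alanine
    carry 3 protons each:

        conc = (area / tsp_area) * (9 / protons) * tsp_conc
               * extract_volume / tissue_mass
    """
    if tsp_area <= 0:
        raise ValueError("TSP area must be > 0")
    if tissue_mass <= 0 or extract_volume <= 0:
        raise ValueError("tissue_mass and extract_volume must be > 0")
    protons = {"alanine": 3, "lactate": 3}
    if protons_per_resonance:
        protons.update(protons_per_resonance)
    out: dict[str, float] = {}
    for name, area in peak_integrals.items():
        if name not in protons:
            raise ValueError(f"proton count not supplied for resonance {name!r}")
        out[name] = (
            (area / tsp_area)
            * (9.0 / protons[name])
            * tsp_conc
            * extract_volume
            / tissue_mass
        )
    return out
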