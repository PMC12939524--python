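"""Synthetic vignette cohorts for suspected periprosthetic joint infection (PJI).

The study design this package benchmarks rests on a fixed-composition cohort
of clinical vignettes: each vignette carries an 11-marker synovial-fluid (SF)
biomarker panel with realistic missingness, a culture result, a binary
adjudicated clinical diagnosis (the reference standard) and a ternary
2018-ICM class.  This module generates such cohorts, simulates two-stage
physician survey responses against them, and carries the three published
false-negative edge cases as in-code fixtures.

Composition is deterministic: the number of infected cases is
``round(n * prevalence)`` (half away from zero), not a Bernoulli draw, so
that tallies derived from printed prevalences reproduce exactly for every
seed.  Random streams are split per purpose (labels, biomarkers,
missingness) so that, e.g., adding raters never perturbs the cohort.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._util import check_fraction, round_half_away

__all__ = [
    "MARKERS",
    "BiomarkerPanel",
    "Vignette",
    "CohortSpec",
    "RaterProfile",
    "RaterCall",
    "IcmRuleTable",
    "MinorCriterion",
    "DEFAULT_AVAILABILITY",
    "DEFAULT_CLASS_DISTRIBUTIONS",
    "DEFAULT_ICM_RULES",
    "generate_cohort",
    "simulate_raters",
    "fixture_fn_cases",
    "icm2018_classify",
    "default_rater_profiles",
    "vignettes_to_csv",
    "vignettes_from_csv",
    "rater_calls_to_csv",
    "rater_calls_from_csv",
]

#: Canonical order of the 11 synovial-fluid biomarkers consumed by the score:
#: alpha-defensin (signal/cutoff ratio), SF white cells (cells/uL), SF
#: polymorphonuclear fraction (%), SF red cells (cells/uL), C-reactive
#: protein, absorbance at 280 nm, and five microbial antigen signals
#: (Candida, Enterococcus, two Staphylococcus targets, Cutibacterium acnes).
MARKERS = (
    "ad",
    "sf_wbc",
    "sf_pmn_pct",
    "sf_rbc",
    "crp",
    "a280",
    "cp",
    "ef",
    "spa",
    "spb",
    "pac",
)

_ANTIGENS = ("cp", "ef", "spa", "spb", "pac")


@dataclass
class BiomarkerPanel:
    """One case's synovial-fluid biomarker panel; ``None`` marks a missing assay.

    ``crp`` is the CRP value available to the score (synovial-fluid CRP slot);
    ``serum_crp`` is an optional serum measurement that imputation may
    substitute for a missing SF-CRP.  ``crp_unit`` is an explicit tag so a
    panel never carries an ambiguous concentration.
    """

    ad: Optional[float] = None
    sf_wbc: Optional[float] = None
    sf_pmn_pct: Optional[float] = None
    sf_rbc: Optional[float] = None
    crp: Optional[float] = None
    a280: Optional[float] = None
    cp: Optional[float] = None
    ef: Optional[float] = None
    spa: Optional[float] = None
    spb: Optional[float] = None
    pac: Optional[float] = None
    crp_unit: str = "mg/L"
    serum_crp: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sf_pmn_pct is not None and not (0.0 <= self.sf_pmn_pct <= 100.0):
            raise ValueError(
                f"sf_pmn_pct must lie in [0, 100], got {self.sf_pmn_pct!r}"
            )
        for name in MARKERS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v!r}")

    def value(self, marker: str) -> Optional[float]:
        if marker not in MARKERS:
            raise KeyError(f"unknown biomarker {marker!r}")
        return getattr(self, marker)

    def available(self, marker: str) -> bool:
        return self.value(marker) is not None

    @property
    def complete(self) -> bool:
        return all(self.available(m) for m in MARKERS)


@dataclass
class Vignette:
    """A suspected-PJI case: panel, joint, culture, labels.

    ``clinical_dx`` is the binary adjudicated reference diagnosis (never
    undecided); ``icm_class`` is the ternary 2018-ICM classification.
    """

    id: str
    joint: str
    panel: BiomarkerPanel
    sf_culture: str = "not_done"
    clinical_dx: str = "aseptic"
    icm_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.joint not in ("hip", "knee"):
            raise ValueError(f"joint must be 'hip' or 'knee', got {self.joint!r}")
        if self.sf_culture not in ("positive", "negative", "not_done"):
            raise ValueError(f"invalid sf_culture {self.sf_culture!r}")
        if self.clinical_dx not in ("PJI", "aseptic"):
            raise ValueError(
                f"clinical_dx must be binary 'PJI'/'aseptic', got {self.clinical_dx!r}"
            )
        if self.icm_class is not None and self.icm_class not in (
            "infected",
            "inconclusive",
            "aseptic",
        ):
            raise ValueError(f"invalid icm_class {self.icm_class!r}")


#: Per-biomarker availability fractions of the 274-vignette study panel.
#: The five antigen assays and A280 were never measured in the vignettes.
DEFAULT_AVAILABILITY: Mapping[str, float] = {
    "ad": 0.996,
    "sf_wbc": 0.978,
    "sf_pmn_pct": 0.967,
    "sf_rbc": 0.635,
    "crp": 0.869,
    "a280": 0.0,
    "cp": 0.0,
    "ef": 0.0,
    "spa": 0.0,
    "spb": 0.0,
    "pac": 0.0,
}

# Class-conditional marker distributions.  "lognormal" takes a median and a
# log-scale sigma; "beta" is scaled to [0, scale].  Antigen entries may add a
# Bernoulli spike (probability, multiplicative factor) representing a
# detectable pathogen signal in infected joints.  Borderline cases are
# clinically aseptic joints whose inflammation markers sit in the
# intermediate 2018-ICM band (moderately raised SF-WBC and CRP, but low
# alpha-defensin and sub-threshold PMN%).
DEFAULT_CLASS_DISTRIBUTIONS: Mapping[str, Mapping[str, Mapping[str, float]]] = {
    "septic": {
        "ad": {"dist": "lognormal", "median": 3.0, "sigma": 0.6},
        "sf_wbc": {"dist": "lognormal", "median": 30000.0, "sigma": 0.8},
        "sf_pmn_pct": {"dist": "beta", "a": 9.0, "b": 2.0, "scale": 100.0},
        "sf_rbc": {"dist": "lognormal", "median": 15000.0, "sigma": 1.2},
        "crp": {"dist": "lognormal", "median": 80.0, "sigma": 0.8},
        "a280": {"dist": "lognormal", "median": 0.9, "sigma": 0.3},
        "cp": {"dist": "lognormal", "median": 0.48, "sigma": 0.3, "spike_prob": 0.03, "spike_factor": 20.0},
        "ef": {"dist": "lognormal", "median": 0.5, "sigma": 0.3, "spike_prob": 0.05, "spike_factor": 20.0},
        "spa": {"dist": "lognormal", "median": 0.73, "sigma": 0.3, "spike_prob": 0.20, "spike_factor": 20.0},
        "spb": {"dist": "lognormal", "median": 0.46, "sigma": 0.3, "spike_prob": 0.20, "spike_factor": 20.0},
        "pac": {"dist": "lognormal", "median": 0.1, "sigma": 0.3, "spike_prob": 0.05, "spike_factor": 20.0},
    },
    "aseptic": {
        "ad": {"dist": "lognormal", "median": 0.2, "sigma": 0.5},
        "sf_wbc": {"dist": "lognormal", "median": 500.0, "sigma": 0.8},
        "sf_pmn_pct": {"dist": "beta", "a": 4.0, "b": 6.0, "scale": 100.0},
        "sf_rbc": {"dist": "lognormal", "median": 15000.0, "sigma": 1.2},
        "crp": {"dist": "lognormal", "median": 2.0, "sigma": 0.7},
        "a280": {"dist": "lognormal", "median": 0.643, "sigma": 0.3},
        "cp": {"dist": "lognormal", "median": 0.48, "sigma": 0.3},
        "ef": {"dist": "lognormal", "median": 0.5, "sigma": 0.3},
        "spa": {"dist": "lognormal", "median": 0.73, "sigma": 0.3},
        "spb": {"dist": "lognormal", "median": 0.46, "sigma": 0.3},
        "pac": {"dist": "lognormal", "median": 0.1, "sigma": 0.3},
    },
    "borderline": {
        "ad": {"dist": "lognormal", "median": 0.4, "sigma": 0.4},
        "sf_wbc": {"dist": "lognormal", "median": 6000.0, "sigma": 0.35},
        "sf_pmn_pct": {"dist": "beta", "a": 12.0, "b": 8.0, "scale": 100.0},
        "sf_rbc": {"dist": "lognormal", "median": 15000.0, "sigma": 1.2},
        "crp": {"dist": "lognormal", "median": 20.0, "sigma": 0.5},
        "a280": {"dist": "lognormal", "median": 0.7, "sigma": 0.3},
        "cp": {"dist": "lognormal", "median": 0.48, "sigma": 0.3},
        "ef": {"dist": "lognormal", "median": 0.5, "sigma": 0.3},
        "spa": {"dist": "lognormal", "median": 0.73, "sigma": 0.3},
        "spb": {"dist": "lognormal", "median": 0.46, "sigma": 0.3},
        "pac": {"dist": "lognormal", "median": 0.1, "sigma": 0.3},
    },
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic vignette cohort.

    ``inconclusive_fraction`` is the fraction of all cases generated as
    clinically aseptic "borderline" joints calibrated to the intermediate
    2018-ICM band (these are always culture-negative, matching the study's
    inconclusive subset).  ``culture_sensitivity`` is the probability an
    infected joint yields a positive SF culture.
    """

    n_cases: int
    prevalence: float = 0.153
    availability_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AVAILABILITY)
    )
    class_distributions: Mapping[str, Mapping[str, Mapping[str, float]]] = field(
        default_factory=lambda: DEFAULT_CLASS_DISTRIBUTIONS
    )
    inconclusive_fraction: float = 0.109
    culture_sensitivity: float = 0.70
    culture_not_done_rate: float = 0.03
    hip_fraction: float = 0.45
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError(f"n_cases must be >= 1, got {self.n_cases!r}")
        check_fraction(self.prevalence, "prevalence")
        check_fraction(self.inconclusive_fraction, "inconclusive_fraction")
        check_fraction(self.culture_sensitivity, "culture_sensitivity")
        check_fraction(self.culture_not_done_rate, "culture_not_done_rate")
        check_fraction(self.hip_fraction, "hip_fraction")
        for marker in MARKERS:
            if marker not in self.availability_rates:
                raise ValueError(f"availability_rates missing biomarker {marker!r}")
            check_fraction(
                self.availability_rates[marker], f"availability_rates[{marker!r}]"
            )


@dataclass
class RaterProfile:
    """Behavioural targets of one simulated survey physician.

    ``stage1_indecision_rate`` applies to vignettes outside the ICM
    inconclusive band; ``inconclusive_indecision_rate`` overrides it on the
    inconclusive subset, where physician indecision is known to concentrate.
    ``target_ppa``/``target_npa`` are the Stage-II agreement targets against
    the clinical reference.
    """

    rater_id: str
    group: str
    stage1_indecision_rate: float
    target_ppa: float
    target_npa: float
    inconclusive_indecision_rate: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in ("academic_surgeon", "community_surgeon", "id_physician"):
            raise ValueError(f"invalid rater group {self.group!r}")
        check_fraction(self.stage1_indecision_rate, "stage1_indecision_rate")
        check_fraction(self.target_ppa, "target_ppa")
        check_fraction(self.target_npa, "target_npa")
        if self.inconclusive_indecision_rate is None:
            self.inconclusive_indecision_rate = self.stage1_indecision_rate
        check_fraction(self.inconclusive_indecision_rate, "inconclusive_indecision_rate")


@dataclass(frozen=True)
class RaterCall:
    """One physician's two-stage diagnosis of one vignette.

    Stage II is always a definitive binary call; when Stage I is decided the
    two stages agree by construction.
    """

    rater_id: str
    group: str
    vignette_id: str
    stage1: str
    stage2: str

    def __post_init__(self) -> None:
        if self.stage1 not in ("PJI", "aseptic", "undecided"):
            raise ValueError(f"invalid stage1 call {self.stage1!r}")
        if self.stage2 not in ("PJI", "aseptic"):
            raise ValueError(f"invalid stage2 call {self.stage2!r}")
        if self.stage1 != "undecided" and self.stage1 != self.stage2:
            raise ValueError("stage2 must equal stage1 when stage1 is decided")


def _draw_marker(rng: np.random.Generator, params: Mapping[str, float], n: int) -> np.ndarray:
    dist = params["dist"]
    if dist == "lognormal":
        x = rng.lognormal(mean=np.log(params["median"]), sigma=params["sigma"], size=n)
        prob = params.get("spike_prob", 0.0)
        if prob > 0:
            spike = rng.random(n) < prob
            x = np.where(spike, x * params["spike_factor"], x)
        return x
    if dist == "beta":
        return rng.beta(params["a"], params["b"], size=n) * params["scale"]
    raise ValueError(f"unknown distribution {dist!r}")


def generate_cohort(spec: CohortSpec) -> list[Vignette]:
    """Generate a synthetic vignette cohort with deterministic composition.

    Exactly ``round(n_cases * prevalence)`` vignettes are infected (clinical
    reference ``PJI``); among the aseptic remainder, ``round(n_cases *
    inconclusive_fraction)`` are borderline cases.  Each biomarker is flagged
    missing independently with probability ``1 - availability``.  Identical
    spec (including seed) yields an identical cohort.
    """
    ss = np.random.SeedSequence(spec.rng_seed)
    rng_labels, rng_bio, rng_miss, rng_misc = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n = spec.n_cases
    n_pji = round_half_away(n * spec.prevalence)
    n_border = min(round_half_away(n * spec.inconclusive_fraction), n - n_pji)

    groups = np.array(
        ["septic"] * n_pji
        + ["borderline"] * n_border
        + ["aseptic"] * (n - n_pji - n_border)
    )
    rng_labels.shuffle(groups)

    # draw every marker for every case from each class distribution, then
    # select per-case by group; keeps the stream layout independent of the
    # label shuffle.
    values: dict[str, np.ndarray] = {}
    for marker in MARKERS:
        per_class = {
            g: _draw_marker(rng_bio, spec.class_distributions[g][marker], n)
            for g in ("septic", "borderline", "aseptic")
        }
        col = np.empty(n)
        for g, draws in per_class.items():
            mask = groups == g
            col[mask] = draws[mask]
        if marker == "sf_pmn_pct":
            col = np.clip(col, 0.0, 100.0)
        values[marker] = col

    missing = {
        marker: rng_miss.random(n) >= spec.availability_rates[marker]
        for marker in MARKERS
    }

    joints = np.where(rng_misc.random(n) < spec.hip_fraction, "hip", "knee")
    culture_u = rng_misc.random(n)
    not_done_u = rng_misc.random(n)

    width = max(4, len(str(n)))
    vignettes: list[Vignette] = []
    for i in range(n):
        panel_kwargs = {
            marker: (None if missing[marker][i] else float(values[marker][i]))
            for marker in MARKERS
        }
        panel = BiomarkerPanel(**panel_kwargs)
        g = groups[i]
        if g == "septic":
            culture = "positive" if culture_u[i] < spec.culture_sensitivity else "negative"
        elif g == "borderline":
            culture = "negative"  # study's inconclusive subset was all culture-negative
        else:
            culture = "not_done" if not_done_u[i] < spec.culture_not_done_rate else "negative"
        v = Vignette(
            id=f"V{i + 1:0{width}d}",
            joint=str(joints[i]),
            panel=panel,
            sf_culture=culture,
            clinical_dx="PJI" if g == "septic" else "aseptic",
        )
        v.icm_class = icm2018_classify(v, DEFAULT_ICM_RULES)
        vignettes.append(v)
    return vignettes


# ---------------------------------------------------------------------------
# 2018 ICM classification


@dataclass(frozen=True)
class MinorCriterion:
    marker: str
    threshold: float
    points: int


@dataclass(frozen=True)
class IcmRuleTable:
    """Configurable rule table for the 2018-ICM style ternary classification.

    A positive SF culture is treated as a major criterion when
    ``culture_major`` is set; otherwise classification rests on the weighted
    minor criteria summed over available markers and mapped through the two
    band cut points (score >= ``infected_min`` -> infected; score >=
    ``inconclusive_min`` -> inconclusive; below -> aseptic).
    """

    minor_criteria: tuple[MinorCriterion, ...]
    culture_major: bool = True
    infected_min: int = 6
    inconclusive_min: int = 2


DEFAULT_ICM_RULES = IcmRuleTable(
    minor_criteria=(
        MinorCriterion("sf_wbc", 3000.0, 3),
        MinorCriterion("ad", 1.0, 3),
        MinorCriterion("sf_pmn_pct", 80.0, 2),
        MinorCriterion("crp", 10.0, 2),
    )
)


def icm2018_classify(v: Vignette, rules: IcmRuleTable) -> str:
    """Classify a vignette as infected / inconclusive / aseptic.

    Markers missing from the panel contribute no minor points.
    """
    if rules is None:
        raise ValueError("an IcmRuleTable is required")
    if rules.culture_major and v.sf_culture == "positive":
        return "infected"
    score = 0
    for crit in rules.minor_criteria:
        value = v.panel.value(crit.marker)
        if value is not None and value >= crit.threshold:
            score += crit.points
    if score >= rules.infected_min:
        return "infected"
    if score >= rules.inconclusive_min:
        return "inconclusive"
    return "aseptic"


# ---------------------------------------------------------------------------
# Simulated physician survey


def simulate_raters(
    vignettes: Sequence[Vignette],
    profiles: Sequence[RaterProfile],
    seed: int,
) -> list[RaterCall]:
    """Simulate two-stage survey responses for each rater x vignette.

    Stage-II calls realize each rater's PPA/NPA targets by exact error
    counts (``round(n * (1 - target))`` discordant calls at randomized
    positions), so realized agreement equals the target up to count
    rounding for every seed.  Stage-I undecided calls are likewise assigned
    by exact counts, with the inconclusive-subset rate applied on ICM
    inconclusive vignettes; decided Stage-I calls always equal Stage II.
    """
    if not profiles:
        raise ValueError("at least one RaterProfile is required")
    for v in vignettes:
        if v.clinical_dx not in ("PJI", "aseptic"):
            raise ValueError(f"vignette {v.id} lacks a binary clinical_dx")

    pos_idx = np.array([i for i, v in enumerate(vignettes) if v.clinical_dx == "PJI"])
    neg_idx = np.array([i for i, v in enumerate(vignettes) if v.clinical_dx == "aseptic"])
    inc_idx = np.array(
        [i for i, v in enumerate(vignettes) if v.icm_class == "inconclusive"]
    )
    other_idx = np.array(
        [i for i, v in enumerate(vignettes) if v.icm_class != "inconclusive"]
    )

    ss = np.random.SeedSequence(seed)
    calls: list[RaterCall] = []
    for profile, child in zip(profiles, ss.spawn(len(profiles))):
        rng = np.random.default_rng(child)
        stage2 = np.array([v.clinical_dx for v in vignettes], dtype=object)
        n_fn = round_half_away(len(pos_idx) * (1.0 - profile.target_ppa))
        n_fp = round_half_away(len(neg_idx) * (1.0 - profile.target_npa))
        if n_fn and len(pos_idx):
            stage2[rng.choice(pos_idx, size=n_fn, replace=False)] = "aseptic"
        if n_fp and len(neg_idx):
            stage2[rng.choice(neg_idx, size=n_fp, replace=False)] = "PJI"

        undecided = np.zeros(len(vignettes), dtype=bool)
        n_und_inc = round_half_away(len(inc_idx) * profile.inconclusive_indecision_rate)
        n_und_other = round_half_away(len(other_idx) * profile.stage1_indecision_rate)
        if n_und_inc and len(inc_idx):
            undecided[rng.choice(inc_idx, size=n_und_inc, replace=False)] = True
        if n_und_other and len(other_idx):
            undecided[rng.choice(other_idx, size=n_und_other, replace=False)] = True

        for i, v in enumerate(vignettes):
            calls.append(
                RaterCall(
                    rater_id=profile.rater_id,
                    group=profile.group,
                    vignette_id=v.id,
                    stage1="undecided" if undecided[i] else str(stage2[i]),
                    stage2=str(stage2[i]),
                )
            )
    return calls


# Published per-rater Stage-I indecision rates (overall) and Stage-II
# PPA/NPA, with group-level indecision rates on the ICM-inconclusive subset.
_RATER_TABLE = {
    # rater: (group, overall_indecision, ppa, npa)
    "AS1": ("academic_surgeon", 0.153, 1.000, 0.970),
    "AS2": ("academic_surgeon", 0.051, 1.000, 0.948),
    "AS3": ("academic_surgeon", 0.058, 0.952, 0.978),
    "AS4": ("academic_surgeon", 0.369, 0.976, 0.836),
    "CS1": ("community_surgeon", 0.208, 1.000, 0.832),
    "CS2": ("community_surgeon", 0.219, 1.000, 0.918),
    "CS3": ("community_surgeon", 0.332, 0.952, 0.935),
    "CS4": ("community_surgeon", 0.383, 1.000, 0.858),
    "ID1": ("id_physician", 0.186, 0.976, 0.858),
    "ID2": ("id_physician", 0.434, 0.976, 0.879),
    "ID3": ("id_physician", 0.102, 0.976, 0.858),
    "ID4": ("id_physician", 0.255, 1.000, 0.862),
}

_GROUP_INCONCLUSIVE_INDECISION = {
    "academic_surgeon": 0.383,
    "community_surgeon": 0.483,
    "id_physician": 0.475,
}


def default_rater_profiles(inconclusive_fraction: float = 0.109) -> list[RaterProfile]:
    """Twelve physician profiles matching the published survey behaviour.

    The stored per-rater indecision rates are overall rates; the
    non-inconclusive rate is back-solved so that, combined with the group
    rate on the inconclusive subset (fraction ``inconclusive_fraction`` of
    cases), the realized overall indecision reproduces the published value.
    """
    profiles = []
    f = inconclusive_fraction
    for rater_id, (group, overall, ppa, npa) in _RATER_TABLE.items():
        r_inc = _GROUP_INCONCLUSIVE_INDECISION[group]
        r_other = (overall - f * r_inc) / (1.0 - f)
        profiles.append(
            RaterProfile(
                rater_id=rater_id,
                group=group,
                stage1_indecision_rate=min(max(r_other, 0.0), 1.0),
                target_ppa=ppa,
                target_npa=npa,
                inconclusive_indecision_rate=r_inc,
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# Published false-negative fixtures


def fixture_fn_cases() -> list[Vignette]:
    """The three published false-negative cases of the score vs the reference.

    FN-001/002 are culture-positive infections missed on biomarkers alone
    (extremely low SF-WBC; CRP-dominated presentation); FN-003 is
    culture-negative with a very high SF-RBC suggesting blood contamination
    of the aspirate.  All three carry the clinical reference diagnosis PJI.
    CRP values are carried verbatim with the package's declared unit tag.
    """
    return [
        Vignette(
            id="FN-001",
            joint="hip",
            panel=BiomarkerPanel(crp=15.0, sf_wbc=40.0, sf_rbc=None, sf_pmn_pct=72.0, ad=1.599),
            sf_culture="positive",
            clinical_dx="PJI",
        ),
        Vignette(
            id="FN-002",
            joint="knee",
            panel=BiomarkerPanel(crp=200.4, sf_wbc=200.0, sf_rbc=None, sf_pmn_pct=42.0, ad=0.34),
            sf_culture="positive",
            clinical_dx="PJI",
        ),
        Vignette(
            id="FN-003",
            joint="hip",
            panel=BiomarkerPanel(crp=1.0, sf_wbc=5354.0, sf_rbc=786000.0, sf_pmn_pct=93.0, ad=0.156),
            sf_culture="negative",
            clinical_dx="PJI",
        ),
    ]


# ---------------------------------------------------------------------------
# CSV interchange

_VIGNETTE_COLUMNS = [
    "id",
    "joint",
    "ad",
    "sf_wbc",
    "sf_pmn_pct",
    "sf_rbc",
    "crp",
    "crp_unit",
    "a280",
    "cp",
    "ef",
    "spa",
    "spb",
    "pac",
    "sf_culture",
    "clinical_dx",
    "icm_class",
]


def _fmt(x: Optional[float]) -> str:
    if x is None:
        return ""
    return repr(float(x))


def vignettes_to_csv(vignettes: Iterable[Vignette], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_VIGNETTE_COLUMNS)
        for v in vignettes:
            w.writerow(
                [v.id, v.joint]
                + [_fmt(v.panel.value(m)) for m in MARKERS[:5]]
                + [v.panel.crp_unit]
                + [_fmt(v.panel.value(m)) for m in MARKERS[5:]]
                + [v.sf_culture, v.clinical_dx, v.icm_class or ""]
            )


def vignettes_from_csv(path) -> list[Vignette]:
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(_VIGNETTE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"vignette CSV missing columns: {sorted(missing)}")
        for row in reader:
            panel = BiomarkerPanel(
                crp_unit=row["crp_unit"],
                **{m: (float(row[m]) if row[m] != "" else None) for m in MARKERS},
            )
            out.append(
                Vignette(
                    id=row["id"],
                    joint=row["joint"],
                    panel=panel,
                    sf_culture=row["sf_culture"],
                    clinical_dx=row["clinical_dx"],
                    icm_class=row["icm_class"] or None,
                )
            )
    return out


def rater_calls_to_csv(calls: Iterable[RaterCall], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rater_id", "group", "vignette_id", "stage1", "stage2"])
        for c in calls:
            w.writerow([c.rater_id, c.group, c.vignette_id, c.stage1, c.stage2])


def rater_calls_from_csv(path) -> list[RaterCall]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return [
            RaterCall(
                rater_id=row["rater_id"],
                group=row["group"],
                vignette_id=row["vignette_id"],
                stage1=row["stage1"],
                stage2=row["stage2"],
            )
            for row in reader
        ]
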