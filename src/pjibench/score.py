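"""Surrogate two-stage probability score for suspected PJI.

A desk-scale re-creation of the architecture of a deployed synovial-fluid
probability score: constant-value imputation of incomplete 11-marker panels,
a feature-scaling step (log10(x+1) on counts and concentrations, identity on
percentages and signal ratios, then standardization), an unsupervised
Gaussian-mixture stage, and a logistic stage mapping mixture
responsibilities plus scaled features to a 0-100 probability of infection.
Scores feed a 20/80 triage rule (low / equivocal / high) and a forced binary
call at a cutoff of 20.

The surrogate makes no claim to the deployed model's weights; its contract
is architectural fidelity (two-stage, culture-free, 0-100 output) and strong
discrimination on its own synthetic training distribution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import multivariate_normal
from sklearn.linear_model import LogisticRegression
from sklearn.mixture import GaussianMixture

from .cohort import MARKERS, BiomarkerPanel, Vignette

__all__ = [
    "DEFAULT_IMPUTED_VALUES",
    "DEFAULT_TRANSFORMS",
    "ImputationTable",
    "ScoreModel",
    "TriageClass",
    "impute_panel",
    "fit_surrogate",
    "score_panel",
    "score_vignettes",
    "triage",
    "forced_call",
]

#: Published constant imputation values (raw scale, one per biomarker),
#: representing the central tendency of the score's training cohort.
DEFAULT_IMPUTED_VALUES: Mapping[str, float] = {
    "ad": 0.196,
    "sf_wbc": 843.0,
    "sf_pmn_pct": 48.0,
    "sf_rbc": 18895.0,
    "crp": 1.7,
    "a280": 0.643,
    "cp": 0.48,
    "ef": 0.5,
    "spa": 0.73,
    "spb": 0.46,
    "pac": 0.1,
}

#: Per-marker scaling transform: log10(x+1) on counts/concentrations,
#: identity on percentages and signal(-to-cutoff) ratios.
DEFAULT_TRANSFORMS: Mapping[str, str] = {
    "ad": "identity",
    "sf_wbc": "log10p",
    "sf_pmn_pct": "identity",
    "sf_rbc": "log10p",
    "crp": "log10p",
    "a280": "identity",
    "cp": "identity",
    "ef": "identity",
    "spa": "identity",
    "spb": "identity",
    "pac": "identity",
}

TriageClass = str  # one of "low", "equivocal", "high"

#: Triage bands on the 0-100 score: low = [0, 20), equivocal = [20, 80),
#: high = [80, 100]; the forced binary call is PJI iff score >= 20.
TRIAGE_LOW_MAX = 20.0
TRIAGE_HIGH_MIN = 80.0
FORCED_CALL_CUTOFF = 20.0


@dataclass(frozen=True)
class ImputationTable:
    """Constant imputation values per biomarker, with optional serum-CRP
    substitution for a missing synovial-fluid CRP."""

    values: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_IMPUTED_VALUES)
    )
    crp_substitution: bool = True

    def __post_init__(self) -> None:
        for marker, v in self.values.items():
            if marker not in MARKERS:
                raise ValueError(f"unknown biomarker {marker!r} in imputation table")
            if v < 0:
                raise ValueError(f"imputed value for {marker!r} must be non-negative")


def impute_panel(panel: BiomarkerPanel, table: ImputationTable | None = None) -> BiomarkerPanel:
    """Return a complete panel: present values untouched, missing values
    replaced by the table constants.

    If serum-CRP substitution is enabled and the panel carries a serum CRP,
    it stands in for a missing SF-CRP instead of the table constant.  A
    biomarker absent from both panel and table is an error naming it.
    """
    if table is None:
        table = ImputationTable()
    updates: dict[str, float] = {}
    for marker in MARKERS:
        if panel.available(marker):
            continue
        if marker == "crp" and table.crp_substitution and panel.serum_crp is not None:
            updates["crp"] = panel.serum_crp
            continue
        if marker not in table.values:
            raise ValueError(
                f"biomarker {marker!r} missing from panel and imputation table"
            )
        updates[marker] = table.values[marker]
    return replace(panel, **updates) if updates else panel


@dataclass
class ScoreModel:
    """Fitted surrogate: scaling, mixture and logistic parameters.

    Scores are computed from stored parameters only (no fitted sklearn
    objects are retained), so a model round-trips exactly through its JSON
    form.
    """

    transforms: Mapping[str, str]
    scale_mean: np.ndarray
    scale_std: np.ndarray
    mixture_weights: np.ndarray
    mixture_means: np.ndarray  # (k, p)
    mixture_covariances: np.ndarray  # (k, p, p)
    logistic_coef: np.ndarray
    logistic_intercept: float
    imputation: ImputationTable = field(default_factory=ImputationTable)
    version: str = "pjibench-surrogate-1"

    @property
    def k_components(self) -> int:
        return len(self.mixture_weights)

    # -- feature pipeline ---------------------------------------------------

    def _raw_features(self, panel: BiomarkerPanel) -> np.ndarray:
        if not panel.complete:
            missing = [m for m in MARKERS if not panel.available(m)]
            raise ValueError(f"panel incomplete (impute first); missing {missing}")
        out = np.empty(len(MARKERS))
        for j, marker in enumerate(MARKERS):
            x = panel.value(marker)
            if self.transforms[marker] == "log10p":
                x = np.log10(x + 1.0)
            out[j] = x
        return out

    def _scaled(self, raw: np.ndarray) -> np.ndarray:
        return (raw - self.scale_mean) / self.scale_std

    def _responsibilities(self, z: np.ndarray) -> np.ndarray:
        logp = np.array(
            [
                np.log(self.mixture_weights[c])
                + multivariate_normal.logpdf(
                    z, mean=self.mixture_means[c], cov=self.mixture_covariances[c],
                    allow_singular=True,
                )
                for c in range(self.k_components)
            ]
        )
        logp -= logp.max()
        p = np.exp(logp)
        return p / p.sum()

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        doc = {
            "version": self.version,
            "transforms": dict(self.transforms),
            "scale_mean": self.scale_mean.tolist(),
            "scale_std": self.scale_std.tolist(),
            "mixture_weights": self.mixture_weights.tolist(),
            "mixture_means": self.mixture_means.tolist(),
            "mixture_covariances": self.mixture_covariances.tolist(),
            "logistic_coef": self.logistic_coef.tolist(),
            "logistic_intercept": self.logistic_intercept,
            "imputation": {
                "values": dict(self.imputation.values),
                "crp_substitution": self.imputation.crp_substitution,
            },
            "thresholds": {
                "triage_low_max": TRIAGE_LOW_MAX,
                "triage_high_min": TRIAGE_HIGH_MIN,
                "forced_call_cutoff": FORCED_CALL_CUTOFF,
            },
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScoreModel":
        doc = json.loads(text)
        return cls(
            transforms=doc["transforms"],
            scale_mean=np.asarray(doc["scale_mean"]),
            scale_std=np.asarray(doc["scale_std"]),
            mixture_weights=np.asarray(doc["mixture_weights"]),
            mixture_means=np.asarray(doc["mixture_means"]),
            mixture_covariances=np.asarray(doc["mixture_covariances"]),
            logistic_coef=np.asarray(doc["logistic_coef"]),
            logistic_intercept=float(doc["logistic_intercept"]),
            imputation=ImputationTable(
                values=doc["imputation"]["values"],
                crp_substitution=doc["imputation"]["crp_substitution"],
            ),
            version=doc["version"],
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ScoreModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _feature_matrix(
    panels: Sequence[BiomarkerPanel], transforms: Mapping[str, str]
) -> np.ndarray:
    X = np.empty((len(panels), len(MARKERS)))
    for i, panel in enumerate(panels):
        for j, marker in enumerate(MARKERS):
            x = panel.value(marker)
            if x is None:
                raise ValueError(f"panel {i} incomplete: {marker} missing")
            X[i, j] = np.log10(x + 1.0) if transforms[marker] == "log10p" else x
    return X


def fit_surrogate(
    training: Sequence[Vignette],
    k_components: int = 2,
    seed: int = 0,
    imputation: ImputationTable | None = None,
    transforms: Mapping[str, str] | None = None,
) -> ScoreModel:
    """Fit the two-stage surrogate on a training cohort.

    Stage 1 fits a full-covariance Gaussian mixture on scaled, imputed
    panels ignoring labels; stage 2 fits a logistic regression from the
    mixture responsibilities and scaled features to the clinical labels.
    Deterministic under a fixed seed.
    """
    if imputation is None:
        imputation = ImputationTable()
    if transforms is None:
        transforms = dict(DEFAULT_TRANSFORMS)
    labels = np.array([1 if v.clinical_dx == "PJI" else 0 for v in training])
    if len(set(labels.tolist())) < 2:
        raise ValueError("training cohort must contain both classes")
    panels = [impute_panel(v.panel, imputation) for v in training]
    X = _feature_matrix(panels, transforms)
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    Z = (X - mean) / std

    gmm = GaussianMixture(
        n_components=k_components,
        covariance_type="full",
        random_state=seed,
        n_init=3,
        reg_covar=1e-6,
    ).fit(Z)
    resp = gmm.predict_proba(Z)

    design = np.hstack([resp, Z])
    clf = LogisticRegression(max_iter=2000, random_state=seed).fit(design, labels)

    return ScoreModel(
        transforms=transforms,
        scale_mean=mean,
        scale_std=std,
        mixture_weights=gmm.weights_.copy(),
        mixture_means=gmm.means_.copy(),
        mixture_covariances=gmm.covariances_.copy(),
        logistic_coef=clf.coef_[0].copy(),
        logistic_intercept=float(clf.intercept_[0]),
        imputation=imputation,
    )


def score_panel(model: ScoreModel, panel: BiomarkerPanel) -> float:
    """Probability score in [0, 100] for a complete (post-imputation) panel."""
    z = model._scaled(model._raw_features(panel))
    resp = model._responsibilities(z)
    eta = float(np.dot(model.logistic_coef, np.concatenate([resp, z]))) + model.logistic_intercept
    return float(100.0 * expit(eta))


def score_vignettes(
    model: ScoreModel, vignettes: Sequence[Vignette]
) -> np.ndarray:
    """Impute (with the model's table) and score a sequence of vignettes."""
    return np.array(
        [score_panel(model, impute_panel(v.panel, model.imputation)) for v in vignettes]
    )


def _check_score(score: float) -> float:
    if not (0.0 <= score <= 100.0):
        raise ValueError(f"score must lie in [0, 100], got {score!r}")
    return float(score)


def triage(score: float) -> TriageClass:
    """Map a 0-100 score to low / equivocal / high.

    Bands: low = [0, 20), equivocal = [20, 80), high = [80, 100].
    """
    s = _check_score(score)
    if s < TRIAGE_LOW_MAX:
        return "low"
    if s < TRIAGE_HIGH_MIN:
        return "equivocal"
    return "high"


def forced_call(score: float, cutoff: float = FORCED_CALL_CUTOFF) -> str:
    """Forced binary call: PJI iff score >= cutoff (default 20)."""
    s = _check_score(score)
    return "PJI" if s >= cutoff else "aseptic"
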