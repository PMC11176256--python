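"""Combined variant-effect-predictor (VEP) damage score.

Raw scores from heterogeneous predictors live on incompatible scales
(probabilities, log-likelihood ratios, meta-learner outputs).  They are
made comparable by percentile normalization against a gene-specific
background: the set of missense variants of the same gene observed in a
population reference.  The normalized value of one predictor is the
fraction of background variants predicted *less damaging* than the
variant of interest (ties counted half), and the combined score is the
unweighted mean over available predictors — by construction in [0, 1],
with ~0.5 for a typical population variant and →1 for a variant more
damaging than essentially all standing variation in the gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PredictorCatalog",
    "DamageScore",
    "normalize_one",
    "combined_damage_score",
    "classify_damaging",
    "DEFAULT_THRESHOLD",
]

#: Inclusive classification threshold for "predicted damaging".
DEFAULT_THRESHOLD = 0.7


@dataclass(frozen=True)
class PredictorCatalog:
    """Predictor names with their raw-scale orientations.

    ``orientation[name]`` is True when a *larger* raw score means *more*
    damaging.  ESM-1v and DeepSequence emit log-likelihood-style scores
    where more negative is more damaging, so they carry False.
    """

    orientation: Mapping[str, bool]

    def __post_init__(self) -> None:
        if not self.orientation:
            raise ValueError("predictor catalog is empty")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.orientation)

    @classmethod
    def default(cls) -> "PredictorCatalog":
        """The seven-predictor panel shipped with the package."""
        text = resources.files("lupuskit.data").joinpath("predictors.yaml").read_text()
        return cls.from_yaml_text(text)

    @classmethod
    def from_yaml_text(cls, text: str) -> "PredictorCatalog":
        raw = yaml.safe_load(text)
        return cls(orientation={str(k): bool(v) for k, v in raw["orientation"].items()})

    @classmethod
    def from_yaml(cls, path) -> "PredictorCatalog":
        with open(path) as fh:
            return cls.from_yaml_text(fh.read())


@dataclass(frozen=True)
class DamageScore:
    per_predictor: Mapping[str, float]
    combined: float
    n_used: int


def normalize_one(
    raw: float, background: Sequence[float], higher_is_damaging: bool = True
) -> float:
    """Percentile-normalize one raw score against its gene background.

    Returns (#{strictly less damaging} + ½·#{tied}) / N after orienting
    both score and background so that larger = more damaging.  Mid-rank
    tie handling means a background member scores exactly 0.5 against its
    own (otherwise distinct) distribution on average.
    """
    bg = np.asarray(background, dtype=float)
    if bg.size == 0:
        raise ValueError("background score list is empty")
    if not np.isfinite(raw):
        raise ValueError("raw score must be finite")
    if not np.all(np.isfinite(bg)):
        raise ValueError("background contains non-finite scores")
    if not higher_is_damaging:
        raw, bg = -raw, -bg
    less = np.count_nonzero(bg < raw)
    tied = np.count_nonzero(bg == raw)
    return (less + 0.5 * tied) / bg.size


def combined_damage_score(
    raw_scores: Mapping[str, float],
    backgrounds: Mapping[str, Sequence[float]],
    catalog: PredictorCatalog | None = None,
) -> DamageScore:
    """Mean percentile over the predictors with both a score and a background.

    Predictors missing either the variant's raw score or a background are
    skipped (and excluded from ``n_used``); zero usable predictors is an
    error rather than a NaN.
    """
    catalog = catalog or PredictorCatalog.default()
    per: dict[str, float] = {}
    for name in catalog.names:
        if name not in raw_scores or raw_scores[name] is None:
            continue
        if name not in backgrounds or len(backgrounds[name]) == 0:
            continue
        per[name] = normalize_one(
            float(raw_scores[name]), backgrounds[name], catalog.orientation[name]
        )
    if not per:
        raise ValueError("no predictor has both a raw score and a background")
    return DamageScore(
        per_predictor=per,
        combined=float(np.mean(list(per.values()))),
        n_used=len(per),
    )


def classify_damaging(score: float, threshold: float = DEFAULT_THRESHOLD) -> bool:
    """True iff ``score >= threshold`` (inclusive)."""
    if not 0 <= score <= 1:
        raise ValueError("combined damage score must lie in [0, 1]")
    return score >= threshold
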