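"""The Index for Postural Abnormalities (IPA).

IPA is the weighted sum of the six posture features,

    IPA = 0.132 F1 + 0.126 F2 + 0.165 F3 + 0.113 F4 + 0.067 F5 + 0.400 F7,

with weights taken from the published feature importances of the
decision-tree model the feature set was selected with.  The printed
weights sum to 1.003 and are used exactly as printed -- no renormalization,
since the published group-mean IPA values only reproduce under the printed
constants.

Two published cut-offs classify a score: 12.96 separates parkinsonian from
healthy-control posture, 20.14 separates clinically rated postural
abnormality (MDS-UPDRS-III item 3.13 >= 2) from its absence.  A score
equal to a cut-off classifies positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureVector

#: Cut-off separating PD-like from healthy-control-like posture.
PD_CUTOFF = 12.96
#: Cut-off separating postural-abnormality-like from unremarkable PD posture.
PA_CUTOFF = 20.14

DEFAULT_CUTOFFS = (PD_CUTOFF, PA_CUTOFF)


@dataclass(frozen=True)
class IPAWeights:
    """Feature weights of the index, in canonical order (F1..F5, F7)."""

    w1: float = 0.132
    w2: float = 0.126
    w3: float = 0.165
    w4: float = 0.113
    w5: float = 0.067
    w7: float = 0.400

    def __post_init__(self):
        if any(w < 0 for w in self.as_array()):
            raise ValueError("IPA weights must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3, self.w4, self.w5, self.w7])


DEFAULT_WEIGHTS = IPAWeights()


@dataclass(frozen=True)
class IPAResult:
    """An IPA score with its classifications against the two cut-offs."""

    ipa: float
    pd_like: bool
    pa_like: bool
    cutoffs: tuple[float, float] = DEFAULT_CUTOFFS


def compute_ipa(features, weights: IPAWeights = DEFAULT_WEIGHTS) -> float:
    """Weighted-sum index of a feature vector.

    ``features`` is a :class:`~posturekit.features.FeatureVector` or a
    sequence of the six values in canonical order (F1, F2, F3, F4, F5, F7).
    Linear and deterministic; by linearity the mean IPA of a cohort equals
    the index applied to the per-feature means.
    """
    if isinstance(features, FeatureVector):
        values = features.values()
    else:
        values = np.asarray(features, dtype=float)
        if values.shape != (6,):
            raise ValueError(f"expected 6 feature values, got shape {values.shape}")
    return float(values @ weights.as_array())


def classify(ipa: float, cutoffs: tuple[float, float] = DEFAULT_CUTOFFS) -> IPAResult:
    """Classify a score against the two cut-offs (boundary counts positive)."""
    pd_cut, pa_cut = cutoffs
    if pd_cut <= 0 or pa_cut <= 0:
        raise ValueError("cut-offs must be positive")
    return IPAResult(
        ipa=float(ipa),
        pd_like=ipa >= pd_cut,
        pa_like=ipa >= pa_cut,
        cutoffs=(pd_cut, pa_cut),
    )
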