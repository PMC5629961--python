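"""Whole-image benign/malignant decision.

The four-class gland maps already separate benign (C0, C1) from malignant
(C2, C3) tissue, so the image-level class is the argmax of the spatially
averaged class-pair probabilities:

    P(benign)    = mean_x [I_C0(x) + I_C1(x)]
    P(malignant) = mean_x [I_C2(x) + I_C3(x)]

The winning average is reported as the decision confidence for the image.
Exact ties resolve to benign (deterministic, logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .networks import ClassProbabilityMaps

logger = logging.getLogger(__name__)

__all__ = ["TissueDecision", "classify_tissue", "BENIGN", "MALIGNANT"]

BENIGN = 0
MALIGNANT = 1


@dataclass
class TissueDecision:
    """Image-level class with the averaged class-pair probabilities."""

    c_star: int  # 0 benign, 1 malignant
    p_benign: float
    p_malignant: float

    @property
    def label(self) -> str:
        return "benign" if self.c_star == BENIGN else "malignant"

    @property
    def confidence(self) -> float:
        """Averaged probability of the winning class over the image."""
        return self.p_benign if self.c_star == BENIGN else self.p_malignant

    def to_dict(self) -> dict:
        return {
            "class": self.label,
            "confidence": self.confidence,
            "p_benign": self.p_benign,
            "p_malignant": self.p_malignant,
        }


def classify_tissue(maps: ClassProbabilityMaps) -> TissueDecision:
    """Decide benign vs. malignant from the four class probability maps."""
    p_benign = float((maps.maps[0] + maps.maps[1]).mean())
    p_malignant = float((maps.maps[2] + maps.maps[3]).mean())
    if p_benign == p_malignant:
        logger.info("exact tie between benign and malignant; resolving to benign")
    c_star = BENIGN if p_benign >= p_malignant else MALIGNANT
    return TissueDecision(c_star=c_star, p_benign=p_benign, p_malignant=p_malignant)
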