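"""Reference worked example shipped with the package.

Fifteen candidate drivers of self-medication with antimicrobial drugs
among health-science students, together with sum-to-zero logit-scale
utilities estimated in a published best-worst scaling survey of 300
respondents (15 choice sets of 7 options).  The first 14 utilities are the
survey's printed estimates; the last item was its baseline, whose utility
under effects coding is minus the sum of the others (-0.500).

These values serve as ground truth for the simulator's study-scale
fixture and as the inputs of the deterministic worked examples in the
documentation and tests.
"""

from __future__ import annotations

import numpy as np

from .design import ItemSet

__all__ = [
    "SELF_MEDICATION_FACTORS",
    "SELF_MEDICATION_UTILITIES",
    "reference_item_set",
    "reference_utilities",
]

# label, printed utility estimate (baseline row last, reconstructed)
_REFERENCE = [
    ("Consider minor illness", -0.083),
    ("Dissatisfaction with hospital workers' attitudes", -0.392),
    ("Easy access to antimicrobial drugs over the counter/pharmacies", 0.171),
    ("Frustration with hospital protocols (long waiting times/queues to seek medical care)", -0.358),
    ("Good knowledge of antimicrobial drugs", 0.695),
    ("Idea of self-care", 0.107),
    ("Long-distance travel to health facilities", -0.362),
    ("Poor control of antimicrobial drug dispensation", -0.269),
    ("Poor quality of the provided care", -0.374),
    ("Previous experience with the same illness", 0.488),
    ("Previous knowledge of health condition", 0.620),
    ("Previous use of antimicrobial drugs", 0.218),
    ("Recommendation from a friend/relative", 0.036),
    ("Relatively lower cost of purchasing antimicrobials than that of seeking care from a medical doctor", 0.003),
]
_BASELINE_LABEL = "Use of leftover antimicrobial drugs"

SELF_MEDICATION_FACTORS: tuple[str, ...] = tuple(
    [label for label, _ in _REFERENCE] + [_BASELINE_LABEL])

SELF_MEDICATION_UTILITIES: np.ndarray = np.array(
    [u for _, u in _REFERENCE] + [-sum(u for _, u in _REFERENCE)])


def reference_item_set() -> ItemSet:
    """The 15 self-medication factors as an :class:`~bws.design.ItemSet`."""
    return ItemSet(SELF_MEDICATION_FACTORS)


def reference_utilities() -> np.ndarray:
    """Copy of the reference sum-to-zero utilities (length 15)."""
    return SELF_MEDICATION_UTILITIES.copy()
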