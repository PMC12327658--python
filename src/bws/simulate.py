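"""Synthetic best-worst response data.

The generator mirrors the layout the analysis assumes: every respondent
answers every choice set of a shared design, picking a best and a worst
item.  Two choice rules are available:

``maxdiff_pair`` (default)
    The ordered (best, worst) pair is drawn in one categorical draw from
    the k(k-1)-category maximum-difference distribution — the same model
    family the estimator fits, so parameter recovery is clean.
``sequential_best_worst``
    Best is drawn from the best-choice logit, then worst from the
    worst-choice logit over the remaining k-1 items.  Useful as a
    robustness probe, since the cognitive process behind real responses
    is not observed.  The two rules coincide when all utilities are equal.

Randomness comes from ``numpy.random.default_rng`` (PCG64).  The draw
order is fixed — respondents in the outer loop, blocks in the inner, one
uniform variate per categorical draw via inverse-CDF — so a seed pins the
dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ChoiceDataset, ChoiceRecord
from .design import BWSDesign
from .datasets import reference_item_set, reference_utilities
from .model import best_prob, maxdiff_pair_prob, worst_prob

__all__ = ["SimulationConfig", "simulate_responses", "make_study_fixture"]

_RULES = ("maxdiff_pair", "sequential_best_worst")


@dataclass(frozen=True)
class SimulationConfig:
    """Study layout and generating process for one synthetic dataset.

    Defaults emulate the reference study: one shared design answered in
    full by 300 respondents.
    """

    design: BWSDesign
    true_utilities: np.ndarray
    n_respondents: int = 300
    seed: int = 0
    choice_rule: str = "maxdiff_pair"
    metadata: dict = field(default_factory=lambda: {"rng": "numpy PCG64"})

    def __post_init__(self):
        g = np.asarray(self.true_utilities, dtype=float)
        if g.shape != (self.design.v,):
            raise ValueError(
                f"true_utilities must have length v={self.design.v}")
        if not np.all(np.isfinite(g)):
            raise ValueError("true_utilities must be finite")
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if self.choice_rule not in _RULES:
            raise ValueError(f"choice_rule must be one of {_RULES}")
        object.__setattr__(self, "true_utilities", g)


def _inverse_cdf_draw(cdf: np.ndarray, u: float) -> int:
    return int(np.searchsorted(cdf, u, side="right"))


def simulate_responses(config: SimulationConfig) -> ChoiceDataset:
    """Draw one record per (respondent, block) under the chosen rule."""
    design = config.design
    g = config.true_utilities
    rng = np.random.default_rng(config.seed)
    labels = design.item_set.items

    # per-block lookup tables, computed once
    if config.choice_rule == "maxdiff_pair":
        pair_tables = []
        for blk in design.blocks:
            probs = maxdiff_pair_prob(g, blk)
            pairs = list(probs)
            cdf = np.cumsum([probs[p] for p in pairs])
            pair_tables.append((pairs, cdf))
    else:
        best_cdfs = [np.cumsum(best_prob(g, blk)) for blk in design.blocks]

    width = len(str(config.n_respondents))
    records = []
    for resp in range(config.n_respondents):
        rid = f"R{resp + 1:0{width}d}"
        for j, blk in enumerate(design.blocks):
            if config.choice_rule == "maxdiff_pair":
                pairs, cdf = pair_tables[j]
                a, b = pairs[_inverse_cdf_draw(cdf, rng.random())]
            else:
                a = blk[_inverse_cdf_draw(best_cdfs[j], rng.random())]
                rest = [i for i in blk if i != a]
                wcdf = np.cumsum(worst_prob(g, rest))
                b = rest[_inverse_cdf_draw(wcdf, rng.random())]
            records.append(ChoiceRecord(rid, j + 1, labels[a], labels[b]))
    return ChoiceDataset(design, records)


def make_study_fixture(seed: int = 0,
                       n_respondents: int = 300
                       ) -> tuple[BWSDesign, ChoiceDataset, np.ndarray]:
    """Deterministic study-scale replica: the 15 reference factors in the
    cyclic (15, 15, 7, 7, 3) design, answered in full by ``n_respondents``
    simulated respondents whose choices follow the reference utilities.

    Returns ``(design, dataset, true_utilities)``.
    """
    from .design import make_bibd_design

    items = reference_item_set()
    design = make_bibd_design(items, n_sets=items.v, set_size=7)
    utilities = reference_utilities()
    dataset = simulate_responses(SimulationConfig(
        design=design, true_utilities=utilities,
        n_respondents=n_respondents, seed=seed))
    return design, dataset, utilities
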