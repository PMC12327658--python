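"""Reported quantities derived from a fitted best-worst model.

* marginal probabilities (MP): the logit share of each item over the full
  item list — the model-implied probability the item is picked as most
  influential when all items compete at once;
* pairwise utility-difference contrasts (DUE) with delta-method SEs;
* the greatest utility difference (GUD, max minus min utility);
* per-item significance flags (95% CI excluding zero);
* model-free best-minus-worst counting scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .data import ChoiceDataset, expand_pairs
from .design import check_balance
from .model import MaxDiffResults, Z_975

__all__ = [
    "complete_utilities",
    "marginal_probabilities",
    "pairwise_contrasts",
    "ContrastTable",
    "greatest_utility_difference",
    "significance_flags",
    "counting_scores",
]


def complete_utilities(partial) -> np.ndarray:
    """Append the omitted baseline utility under sum-to-zero coding.

    With effects coding the baseline's utility is minus the sum of the
    v-1 reported estimates, so a table that prints only the non-baseline
    rows can be completed exactly.
    """
    partial = np.asarray(partial, dtype=float)
    return np.append(partial, -partial.sum())


def marginal_probabilities(utilities) -> np.ndarray:
    """Logit share exp(g_i) / sum_j exp(g_j) over all items.

    Invariant to adding a constant to every utility; sums to 1.
    """
    g = np.asarray(utilities, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("utilities must be finite")
    return np.exp(g - special.logsumexp(g))


@dataclass(frozen=True)
class ContrastTable:
    """All pairwise utility differences with SEs, p-values and 95% CIs.

    ``frame`` is long-format over ordered pairs (item_a != item_b); the
    table is antisymmetric: due(i, j) = -due(j, i).  The diagonal is
    handled by :meth:`lookup` (due 0, se 0, p 1).
    """

    labels: tuple[str, ...]
    due: np.ndarray        # v x v antisymmetric matrix
    se: np.ndarray         # v x v symmetric, zero diagonal
    frame: pd.DataFrame

    def lookup(self, item_a: str, item_b: str) -> dict:
        i = self.labels.index(item_a)
        j = self.labels.index(item_b)
        if i == j:
            return {"due": 0.0, "se": 0.0, "p": 1.0, "ci_low": 0.0, "ci_high": 0.0}
        d, s = float(self.due[i, j]), float(self.se[i, j])
        return {
            "due": d,
            "se": s,
            "p": float(2 * stats.norm.sf(abs(d) / s)),
            "ci_low": d - Z_975 * s,
            "ci_high": d + Z_975 * s,
        }


def pairwise_contrasts(fit: MaxDiffResults) -> ContrastTable:
    """Every ordered utility difference g_i - g_j with delta-method SE
    sqrt(var_i + var_j - 2 cov_ij), Wald p and 95% CI."""
    g = fit.utilities
    cov = fit.cov_utilities
    v = len(g)
    due = g[:, None] - g[None, :]
    var = np.diag(cov)[:, None] + np.diag(cov)[None, :] - 2.0 * cov
    off = ~np.eye(v, dtype=bool)
    if np.any(var[off] <= 0):
        i, j = np.argwhere((var <= 0) & off)[0]
        raise np.linalg.LinAlgError(
            "singular covariance: the contrast "
            f"{fit.model.labels[i]!r} - {fit.model.labels[j]!r} has "
            "non-positive variance")
    se = np.sqrt(np.where(off, var, 0.0))
    labels = tuple(fit.model.labels)
    rows = []
    for i in range(v):
        for j in range(v):
            if i == j:
                continue
            z = due[i, j] / se[i, j]
            rows.append({
                "item_a": labels[i], "item_b": labels[j],
                "due": due[i, j], "se": se[i, j],
                "p": 2 * stats.norm.sf(abs(z)),
                "ci_low": due[i, j] - Z_975 * se[i, j],
                "ci_high": due[i, j] + Z_975 * se[i, j],
            })
    return ContrastTable(labels, due, se, pd.DataFrame(rows))


def greatest_utility_difference(utilities) -> float:
    """Max minus min utility across all items, the baseline included."""
    g = np.asarray(utilities, dtype=float)
    if g.size < 2:
        raise ValueError("need at least two utilities")
    return float(g.max() - g.min())


def significance_flags(fit: MaxDiffResults, alpha: float = 0.05) -> np.ndarray:
    """True where the Wald CI excludes zero (strict inequalities: an
    interval touching zero is not significant)."""
    ci = fit.conf_int(alpha)
    return (ci[:, 0] > 0) | (ci[:, 1] < 0)


def counting_scores(dataset: ChoiceDataset) -> pd.DataFrame:
    """Best/worst choice frequencies per item.

    ``bw_score = best_count - worst_count``; the standardised score
    divides by (replication x respondents), the number of times each
    respondent could have chosen the item, and so lies in [-1, 1].
    """
    items = dataset.design.item_set
    best = np.zeros(items.v, dtype=int)
    worst = np.zeros(items.v, dtype=int)
    exp = expand_pairs(dataset)
    for a, b in exp.chosen:
        best[a] += 1
        worst[b] += 1
    rep = np.asarray(check_balance(dataset.design).replication)
    denom = rep * max(dataset.n_respondents, 1)
    bw = best - worst
    return pd.DataFrame({
        "best_count": best,
        "worst_count": worst,
        "bw_score": bw,
        "std_score": np.where(denom > 0, bw / np.where(denom > 0, denom, 1), 0.0),
    }, index=pd.Index(items.items, name="item"))
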