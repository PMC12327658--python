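"""The maximum-difference (best-worst) choice model and its MLE.

Random-utility setup: each item ``i`` carries a latent utility ``gamma_i``
on the logit scale.  In a choice set ``T``:

* best choice:   ``Q_T(i)  = exp(gamma_i) / sum_{r in T} exp(gamma_r)``
* worst choice:  ``R_T(i)  = exp(-gamma_i) / sum_{r in T} exp(-gamma_r)``
* best-worst pair (the model fitted here): for an ordered pair ``(a, b)``
  with ``a != b``,

  ``QR_T(a, b) = exp(gamma_a - gamma_b) / sum_{(u,w) in T, u != w}
  exp(gamma_u - gamma_w)``

The worst scale is the negative of the best scale, which makes the
two-item reversal identity ``Q_{a,b}(a) = R_{a,b}(b)`` exact.  Utilities
are identified only up to an additive constant; the estimator uses
effects (sum-to-zero) coding, so the reported utility of the omitted
baseline item equals minus the sum of the others.

The log-likelihood is a sum of pair-multinomial terms and is concave in
``gamma``, so a Newton-type optimiser started at zero converges reliably.
Standard errors come from the inverse observed information of the v-1
free parameters, mapped back to all v items through the sum-to-zero
contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .data import ChoiceDataset, expand_pairs

__all__ = [
    "best_prob",
    "worst_prob",
    "maxdiff_pair_prob",
    "log_likelihood",
    "MaxDiffModel",
    "MaxDiffResults",
    "SeparationError",
    "fit_maxdiff",
    "Z_975",
]

Z_975 = float(stats.norm.ppf(0.975))  # 1.959964...


class SeparationError(ValueError):
    """An item is always (or never) chosen whenever shown, so its MLE
    utility diverges; carries the offending item labels."""

    def __init__(self, items: list[str], reason: str):
        self.items = items
        super().__init__(f"separation: item(s) {items} {reason}")


def _check_block(block) -> np.ndarray:
    block = np.asarray(block, dtype=int)
    if block.size < 2:
        raise ValueError("a choice set needs at least 2 items")
    if len(set(block.tolist())) != block.size:
        raise ValueError("choice set repeats an item")
    return block


def best_prob(utilities, block) -> np.ndarray:
    """P(item chosen as best) for each item of ``block``, in block order."""
    g = np.asarray(utilities, dtype=float)[_check_block(block)]
    return np.exp(g - special.logsumexp(g))


def worst_prob(utilities, block) -> np.ndarray:
    """P(item chosen as worst) for each item of ``block``; the worst scale
    is the negated best scale."""
    g = -np.asarray(utilities, dtype=float)[_check_block(block)]
    return np.exp(g - special.logsumexp(g))


def maxdiff_pair_prob(utilities, block) -> dict[tuple[int, int], float]:
    """Joint best-worst probabilities over the k(k-1) ordered pairs.

    Returns a dict mapping each ordered item-index pair ``(a, b)``,
    ``a != b``, to its probability; the values sum to 1.
    """
    block = _check_block(block)
    if block.size < 3:
        raise ValueError("the best-worst pair model needs sets of 3+ items")
    g = np.asarray(utilities, dtype=float)
    pairs = [(int(a), int(b)) for a in block for b in block if a != b]
    eta = np.array([g[a] - g[b] for a, b in pairs])
    p = np.exp(eta - special.logsumexp(eta))
    return dict(zip(pairs, p))


def log_likelihood(dataset: ChoiceDataset, utilities) -> float:
    """Sum over records of the log pair-probability of the chosen pair."""
    g = np.asarray(utilities, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("utilities must be finite")
    ll = 0.0
    exp = expand_pairs(dataset)
    for rec in range(exp.n_records):
        blk = dataset.design.blocks[exp.block_of[rec]]
        probs = maxdiff_pair_prob(g, blk)
        ll += float(np.log(probs[exp.chosen[rec]]))
    return ll


# ---------------------------------------------------------------------------
# Estimation


class MaxDiffModel:
    """Maximum-difference model for a best-worst :class:`ChoiceDataset`.

    Follows the Model/Results convention: construct from data, call
    :meth:`fit`, read estimates off the returned :class:`MaxDiffResults`.

    Internally records are aggregated to per-block pair counts, so the
    cost of one likelihood evaluation depends on the design size
    (b blocks x k(k-1) pairs), not on the number of respondents.
    """

    def __init__(self, dataset: ChoiceDataset):
        self.dataset = dataset
        design = dataset.design
        self.v = design.v
        self.labels = list(design.item_set.items)

        # pair space and signed incidence per block: row (a,b) -> e_a - e_b
        self._pairs: list[list[tuple[int, int]]] = []
        self._X: list[np.ndarray] = []
        for blk in design.blocks:
            pairs = [(a, b) for a in blk for b in blk if a != b]
            X = np.zeros((len(pairs), self.v))
            for r, (a, b) in enumerate(pairs):
                X[r, a] = 1.0
                X[r, b] = -1.0
            self._pairs.append(pairs)
            self._X.append(X)

        # observed counts per (block, pair)
        exp = expand_pairs(dataset)
        self._counts = [np.zeros(len(p)) for p in self._pairs]
        for rec in range(exp.n_records):
            j = exp.block_of[rec]
            self._counts[j][self._pairs[j].index(exp.chosen[rec])] += 1
        self._n_per_block = np.array([c.sum() for c in self._counts])

        # sum-to-zero contrast: gamma = C @ theta, theta free of length v-1
        self._C = np.vstack([np.eye(self.v - 1), -np.ones(self.v - 1)])

        self._check_separation()

    @classmethod
    def from_csv(cls, responses_path, design) -> "MaxDiffModel":
        from .data import read_choices
        return cls(read_choices(responses_path, design))

    def _check_separation(self) -> None:
        best = np.zeros(self.v)
        worst = np.zeros(self.v)
        shown = np.zeros(self.v)
        for j, counts in enumerate(self._counts):
            n_j = counts.sum()
            for r, (a, b) in enumerate(self._pairs[j]):
                best[a] += counts[r]
                worst[b] += counts[r]
            for i in self.dataset.design.blocks[j]:
                shown[i] += n_j
        never = [self.labels[i] for i in range(self.v)
                 if shown[i] == 0 or (best[i] == 0 and worst[i] == 0)]
        if never:
            raise SeparationError(
                never, "never chosen as best or worst (utility not estimable)")
        always = [self.labels[i] for i in range(self.v)
                  if best[i] == shown[i] or worst[i] == shown[i]]
        if always:
            raise SeparationError(
                always, "chosen as best (or worst) in every set shown")

    # -- likelihood machinery on the free parameters theta ------------------

    def _gamma(self, theta: np.ndarray) -> np.ndarray:
        return self._C @ theta

    def loglike(self, theta: np.ndarray) -> float:
        g = self._gamma(theta)
        ll = 0.0
        for X, counts, n_j in zip(self._X, self._counts, self._n_per_block):
            if n_j == 0:
                continue
            eta = X @ g
            ll += counts @ eta - n_j * special.logsumexp(eta)
        return float(ll)

    def score(self, theta: np.ndarray) -> np.ndarray:
        g = self._gamma(theta)
        grad = np.zeros(self.v)
        for X, counts, n_j in zip(self._X, self._counts, self._n_per_block):
            if n_j == 0:
                continue
            eta = X @ g
            w = np.exp(eta - special.logsumexp(eta))
            grad += X.T @ counts - n_j * (X.T @ w)
        return self._C.T @ grad

    def hessian(self, theta: np.ndarray) -> np.ndarray:
        """Hessian of the log-likelihood (negative definite)."""
        g = self._gamma(theta)
        H = np.zeros((self.v, self.v))
        for X, n_j in zip(self._X, self._n_per_block):
            if n_j == 0:
                continue
            eta = X @ g
            w = np.exp(eta - special.logsumexp(eta))
            mean = X.T @ w
            H -= n_j * (X.T @ (w[:, None] * X) - np.outer(mean, mean))
        return self._C.T @ H @ self._C

    @property
    def llnull(self) -> float:
        """Log-likelihood at equal utilities (uniform pair probabilities)."""
        return float(sum(-n_j * np.log(len(p))
                         for n_j, p in zip(self._n_per_block, self._pairs)))

    def fit(self, tolerance: float = 1e-8, max_iter: int = 200) -> "MaxDiffResults":
        """Maximise the likelihood; converged when the score's infinity
        norm drops below ``tolerance``.  Starts at zero utilities (the
        likelihood is concave, so the start is not delicate)."""
        theta0 = np.zeros(self.v - 1)
        res = optimize.minimize(
            lambda t: -self.loglike(t),
            theta0,
            jac=lambda t: -self.score(t),
            hess=lambda t: -self.hessian(t),
            method="trust-exact",
            options={"gtol": tolerance / 10, "maxiter": max_iter},
        )
        theta = res.x
        converged = bool(np.linalg.norm(self.score(theta), np.inf) <= tolerance)

        info = -self.hessian(theta)             # observed information, (v-1)^2
        cov_theta = np.linalg.inv(info)
        cov_full = self._C @ cov_theta @ self._C.T
        cov_full = 0.5 * (cov_full + cov_full.T)
        return MaxDiffResults(self, theta, cov_theta, cov_full, converged)


@dataclass
class MaxDiffResults:
    """Fitted maximum-difference model.

    ``utilities`` holds all v sum-to-zero utilities (baseline included);
    ``cov_utilities`` is the corresponding v x v covariance (rank v-1).
    """

    model: MaxDiffModel
    params: np.ndarray                 # the v-1 free parameters
    cov_params: np.ndarray             # (v-1) x (v-1)
    cov_utilities: np.ndarray          # v x v, via the sum-to-zero contrast
    converged: bool

    def __post_init__(self):
        self.utilities = self.model._gamma(self.params)
        self.bse = np.sqrt(np.diag(self.cov_utilities))
        self.llf = self.model.loglike(self.params)
        self.llnull = self.model.llnull
        self.df_model = self.model.v - 1
        self.n_tasks = int(self.model._n_per_block.sum())

    # -- fit statistics ------------------------------------------------------

    @property
    def lr_chisq(self) -> float:
        return 2.0 * (self.llf - self.llnull)

    @property
    def lr_pvalue(self) -> float:
        return float(stats.chi2.sf(self.lr_chisq, self.df_model))

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.df_model

    @property
    def aicc(self) -> float:
        k = self.df_model
        n = self.n_tasks
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.df_model * np.log(self.n_tasks)

    # -- inference per item --------------------------------------------------

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """(v, 2) Wald confidence bounds for every item's utility."""
        z = float(stats.norm.ppf(1 - alpha / 2))
        return np.column_stack([self.utilities - z * self.bse,
                                self.utilities + z * self.bse])

    def zvalues(self) -> np.ndarray:
        return self.utilities / self.bse

    def pvalues(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.zvalues()))

    # -- post-estimation (delegates) ------------------------------------------

    def marginal_probabilities(self) -> pd.Series:
        from .postestimation import marginal_probabilities
        return pd.Series(marginal_probabilities(self.utilities),
                         index=self.model.labels, name="mp")

    def contrasts(self):
        from .postestimation import pairwise_contrasts
        return pairwise_contrasts(self)

    def greatest_utility_difference(self) -> float:
        from .postestimation import greatest_utility_difference
        return greatest_utility_difference(self.utilities)

    def significance_flags(self) -> np.ndarray:
        from .postestimation import significance_flags
        return significance_flags(self)

    # -- presentation ----------------------------------------------------------

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        return pd.DataFrame({
            "estimate": self.utilities,
            "se": self.bse,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": self.pvalues(),
            "significant": self.significance_flags(),
            "mp": self.marginal_probabilities().to_numpy(),
        }, index=pd.Index(self.model.labels, name="item"))

    def summary(self) -> str:
        df = self.summary_frame()
        lines = ["Maximum difference model results",
                 "=" * 32,
                 df.to_string(float_format=lambda x: f"{x: .4f}"),
                 "-" * 32,
                 f"N tasks            {self.n_tasks}",
                 f"Log-likelihood     {self.llf:.2f}",
                 f"L-R chi-square     {self.lr_chisq:.2f}  (df={self.df_model}, "
                 f"p={self.lr_pvalue:.3g})",
                 f"AIC                {self.aic:.2f}",
                 f"AICc               {self.aicc:.2f}",
                 f"BIC                {self.bic:.2f}",
                 f"Converged          {self.converged}"]
        return "\n".join(lines)


def fit_maxdiff(dataset: ChoiceDataset, tolerance: float = 1e-8,
                max_iter: int = 200) -> MaxDiffResults:
    """One-call convenience wrapper: ``MaxDiffModel(dataset).fit()``."""
    return MaxDiffModel(dataset).fit(tolerance=tolerance, max_iter=max_iter)
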