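"""Two-state Markov (Mk) ancestral-state reconstruction.

The character evolves on the tree as a continuous-time Markov chain with
forward rate ``q01`` (state 0 -> 1, per Myr) and backward rate ``q10``.
Likelihoods use Felsenstein pruning with the closed-form 2x2 transition
probabilities.  Bayesian machinery on top:

* :func:`asr_marginal_posteriors` — slice-sampling MCMC over the two rates
  (exponential prior), averaging analytic per-node marginal state
  probabilities over the retained draws;
* :func:`node_bayes_factor` — per-node significance test comparing the two
  models in which the node's state is fixed ("fossilised") to 0 or to 1,
  with each log marginal likelihood estimated by stepping-stone sampling and
  BF = 2 (ln mL_best - ln mL_other); BF > 5 (strictly) counts as significant.

Polymorphic and missing tips enter as flat partials (1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .pollen import CharacterMatrix
from .samplers import AdaptiveWidths, slice_update
from .trees import Phylogeny

__all__ = [
    "MkModel",
    "MkMcmcSettings",
    "ASRResult",
    "NodeReconstruction",
    "mk_loglik",
    "mk_marginal_posteriors_fixed",
    "asr_marginal_posteriors",
    "node_bayes_factor",
    "parsimony_change_count",
    "default_rate_prior_mean",
    "asr_table",
    "annotated_newick",
]

BF_SIGNIFICANCE_THRESHOLD = 5.0  # strict: BF must exceed this


@dataclass(frozen=True)
class MkModel:
    """Two-state CTMC: rates per Myr and the root state prior."""

    q01: float
    q10: float
    root_prior: str = "uniform"  # uniform | stationary

    def __post_init__(self):
        if self.q01 < 0 or self.q10 < 0 or not np.isfinite([self.q01, self.q10]).all():
            raise InputError(f"rates must be finite and >= 0: {self.q01}, {self.q10}")
        if self.root_prior not in ("uniform", "stationary"):
            raise InputError(f"unknown root prior {self.root_prior!r}")
        if self.root_prior == "stationary" and self.q01 + self.q10 == 0:
            raise InputError("stationary prior undefined when q01 + q10 = 0")

    def root_probs(self) -> np.ndarray:
        if self.root_prior == "uniform":
            return np.array([0.5, 0.5])
        s = self.q01 + self.q10
        return np.array([self.q10 / s, self.q01 / s])


def transition_matrix(q01: float, q10: float, t: float) -> np.ndarray:
    """Closed-form P(t) = exp(Qt) for the 2-state chain."""
    s = q01 + q10
    if s == 0.0 or t == 0.0:
        return np.eye(2)
    pi1 = q01 / s
    pi0 = q10 / s
    e = np.exp(-s * t)
    return np.array(
        [
            [pi0 + pi1 * e, pi1 * (1.0 - e)],
            [pi0 * (1.0 - e), pi1 + pi0 * e],
        ]
    )


def _tip_partials(tree: Phylogeny, chars: CharacterMatrix) -> np.ndarray:
    codes = chars.state_codes(tree.tip_labels)
    partials = np.zeros((tree.n_tips, 2))
    partials[codes == 0, 0] = 1.0
    partials[codes == 1, 1] = 1.0
    partials[codes == 2] = 1.0
    return partials


def _down_pass(
    tree: Phylogeny,
    tips: np.ndarray,
    model: MkModel,
    node_constraints: dict[int, int] | None = None,
):
    """Pruning pass; returns per-node partials, per-edge P matrices, log scale.

    ``node_constraints`` maps internal node index -> fixed state; the node's
    partial is masked to that state after its children are combined.
    """
    n = tree.n_nodes
    partials = np.zeros((n, 2))
    partials[: tree.n_tips] = tips
    P = np.zeros((n, 2, 2))  # P for the edge above each node
    for i in range(n):
        P[i] = transition_matrix(model.q01, model.q10, float(tree.blen[i]))
    log_scale = 0.0
    for node in tree.postorder:
        l, r = tree.left[node], tree.right[node]
        part = (P[l] @ partials[l]) * (P[r] @ partials[r])
        if node_constraints and int(node) in node_constraints:
            mask = np.zeros(2)
            mask[node_constraints[int(node)]] = 1.0
            part = part * mask
        m = part.max()
        if m > 0 and (m < 1e-280 or m > 1e280):
            part = part / m
            log_scale += np.log(m)
        partials[node] = part
    return partials, P, log_scale


def mk_loglik(
    tree: Phylogeny,
    chars: CharacterMatrix,
    model: MkModel,
    node_constraints: dict[int, int] | None = None,
) -> float:
    """Log-likelihood of the tip data; ``-inf`` when the data are impossible."""
    tips = _tip_partials(tree, chars)
    partials, _, log_scale = _down_pass(tree, tips, model, node_constraints)
    lik = float(model.root_probs() @ partials[tree.root])
    if lik <= 0.0:
        return -np.inf
    return np.log(lik) + log_scale


def mk_marginal_posteriors_fixed(
    tree: Phylogeny, chars: CharacterMatrix, model: MkModel
) -> np.ndarray:
    """Analytic marginal ancestral-state posteriors at fixed rates.

    Down/up two-pass algorithm; returns an ``(n_nodes, 2)`` array whose rows
    sum to 1 for internal nodes (tip rows give the conditional tip state
    posterior, informative for ambiguous tips).
    """
    tips = _tip_partials(tree, chars)
    down, P, _ = _down_pass(tree, tips, model)
    n = tree.n_nodes
    up = np.zeros((n, 2))
    up[tree.root] = model.root_probs()
    for node in tree.postorder[::-1]:
        for child, sib in (
            (tree.left[node], tree.right[node]),
            (tree.right[node], tree.left[node]),
        ):
            sib_msg = P[sib] @ down[sib]
            # prob of everything outside child's subtree, per child state
            up[child] = (up[node] * sib_msg) @ P[child]
    marg = up * down
    total = marg.sum(axis=1, keepdims=True)
    if np.any(total <= 0):
        raise InputError("impossible data: zero marginal likelihood at a node")
    return marg / total


def parsimony_change_count(tree: Phylogeny, chars: CharacterMatrix) -> int:
    """Fitch parsimony change count (ambiguous/missing tips = {0, 1})."""
    codes = chars.state_codes(tree.tip_labels)
    sets = np.zeros((tree.n_nodes, 2), dtype=bool)
    sets[: tree.n_tips][codes == 0, 0] = True
    sets[: tree.n_tips][codes == 1, 1] = True
    sets[: tree.n_tips][codes == 2] = True
    changes = 0
    for node in tree.postorder:
        l, r = tree.left[node], tree.right[node]
        inter = sets[l] & sets[r]
        if inter.any():
            sets[node] = inter
        else:
            sets[node] = sets[l] | sets[r]
            changes += 1
    return changes


def default_rate_prior_mean(
    tree: Phylogeny, chars: CharacterMatrix, floor: float = 0.01
) -> float:
    """Exponential-prior mean: parsimony changes per unit of total tree length."""
    total = tree.total_branch_length
    if total <= 0:
        return floor
    return max(parsimony_change_count(tree, chars) / total, floor)


@dataclass(frozen=True)
class MkMcmcSettings:
    """Settings for the rate MCMC and the stepping-stone estimator."""

    n_iter: int = 10_000
    burn_in_frac: float = 0.2
    seed: int = 0
    rate_prior_mean: float | None = None  # None -> parsimony-informed default
    root_prior: str = "uniform"
    fixed_rates: tuple[float, float] | None = None  # skip rate sampling
    marginal_thin: int = 1
    ss_rungs: int = 10
    ss_iter_per_rung: int = 500
    ss_beta_shape: float = 0.3  # beta_k = (k/K) ** (1/shape)


@dataclass(frozen=True)
class NodeReconstruction:
    node: int
    posterior: tuple[float, float]
    bayes_factor: float = np.nan
    preferred_state: int | None = None
    significant: bool | None = None


@dataclass(frozen=True)
class ASRResult:
    node_posteriors: np.ndarray  # (n_nodes, 2), rows sum to 1
    rate_samples: np.ndarray  # retained (q01, q10) draws, or empty if fixed
    acceptance_note: str
    settings: MkMcmcSettings
    tree: Phylogeny = field(repr=False)


def _rate_log_posterior(tree, chars, root_prior, prior_rate):
    """Log posterior in x = (log q01, log q10), exponential prior on rates."""

    def logpost(x):
        q01, q10 = np.exp(x)
        ll = mk_loglik(tree, chars, MkModel(q01, q10, root_prior))
        if not np.isfinite(ll):
            return -np.inf
        # exponential prior density + Jacobian of the log transform
        return ll - prior_rate * (q01 + q10) + x[0] + x[1]

    return logpost


def asr_marginal_posteriors(
    tree: Phylogeny, chars: CharacterMatrix, settings: MkMcmcSettings
) -> ASRResult:
    """Bayesian marginal ancestral-state posteriors.

    Slice-samples ``(log q01, log q10)`` under independent exponential rate
    priors, and for each retained draw (optionally thinned) computes the
    analytic node marginals, returning their posterior mean.  With
    ``settings.fixed_rates`` the MCMC is skipped and the analytic marginals
    at those rates are returned directly.
    """
    if settings.fixed_rates is not None:
        q01, q10 = settings.fixed_rates
        model = MkModel(q01, q10, settings.root_prior)
        marg = mk_marginal_posteriors_fixed(tree, chars, model)
        return ASRResult(marg, np.empty((0, 2)), "fixed rates", settings, tree)

    counts = chars.counts()
    if (counts["0"] == 0) or (counts["1"] == 0):
        note = "fewer than 2 distinct observed states: rates informed by prior only"
    else:
        note = ""
    prior_mean = settings.rate_prior_mean or default_rate_prior_mean(tree, chars)
    prior_rate = 1.0 / prior_mean
    logpost = _rate_log_posterior(tree, chars, settings.root_prior, prior_rate)

    rng = np.random.default_rng(settings.seed)
    x = np.log([prior_mean, prior_mean])
    lp = logpost(x)
    n_burn = int(settings.n_iter * settings.burn_in_frac)
    widths = AdaptiveWidths(np.full(2, 1.0))
    samples = []
    marg_sum = np.zeros((tree.n_nodes, 2))
    n_marg = 0
    for it in range(settings.n_iter):
        x, lp, _, moves = slice_update(x, logpost, lp, widths.widths, rng)
        if it < n_burn:
            widths.observe(moves)
            continue
        q01, q10 = np.exp(x)
        samples.append((q01, q10))
        if (it - n_burn) % settings.marginal_thin == 0:
            marg_sum += mk_marginal_posteriors_fixed(
                tree, chars, MkModel(q01, q10, settings.root_prior)
            )
            n_marg += 1
    marg = marg_sum / n_marg
    return ASRResult(marg, np.asarray(samples), note, settings, tree)


def _stepping_stone_lnml(
    tree, chars, settings: MkMcmcSettings, node_constraints, seed
) -> float:
    """Stepping-stone estimate of ln marginal likelihood over the rate prior.

    Power-posterior ladder beta_k = (k/K)^(1/shape), the Beta(shape, 1)
    quantile spacing, which concentrates rungs near the prior where the
    integrand varies fastest.  The beta = 0 rung samples the prior directly.
    """
    prior_mean = settings.rate_prior_mean or default_rate_prior_mean(tree, chars)
    prior_rate = 1.0 / prior_mean
    root_prior = settings.root_prior

    def loglik(x):
        q01, q10 = np.exp(x)
        return mk_loglik(
            tree, chars, MkModel(q01, q10, root_prior), node_constraints
        )

    K = settings.ss_rungs
    betas = (np.arange(K + 1) / K) ** (1.0 / settings.ss_beta_shape)
    rng = np.random.default_rng(seed)
    n = settings.ss_iter_per_rung
    ln_ml = 0.0
    x = np.log([prior_mean, prior_mean])
    for k in range(K):
        beta = betas[k]
        delta = betas[k + 1] - beta
        lls = np.empty(n)
        if beta == 0.0:
            # iid draws from the exponential prior
            draws = rng.exponential(prior_mean, size=(n, 2))
            for i in range(n):
                lls[i] = loglik(np.log(draws[i]))
            x = np.log(np.maximum(draws[-1], 1e-12))
        else:

            def logpost(z, _b=beta):
                ll = loglik(z)
                if not np.isfinite(ll):
                    return -np.inf
                q01, q10 = np.exp(z)
                return _b * ll - prior_rate * (q01 + q10) + z[0] + z[1]

            lp = logpost(x)
            if not np.isfinite(lp):
                x = np.log([prior_mean, prior_mean])
                lp = logpost(x)
            widths = AdaptiveWidths(np.full(2, 1.0))
            n_burn = max(n // 4, 10)
            for it in range(n_burn + n):
                x, lp, _, moves = slice_update(x, logpost, lp, widths.widths, rng)
                if it < n_burn:
                    widths.observe(moves)
                else:
                    lls[it - n_burn] = loglik(x)
        finite = lls[np.isfinite(lls)]
        if len(finite) == 0:
            return -np.inf
        m = finite.max()
        # mean over all draws; -inf log-likelihoods contribute zero weight
        ln_ml += delta * m + np.log(
            np.sum(np.exp(delta * (finite - m))) / len(lls)
        )
    return ln_ml


@dataclass(frozen=True)
class BayesFactorResult:
    node: int
    bayes_factor: float
    preferred_state: int
    lnml: tuple[float, float]
    significant: bool
    infinite: bool


def node_bayes_factor(
    tree: Phylogeny,
    chars: CharacterMatrix,
    node: int,
    settings: MkMcmcSettings,
) -> BayesFactorResult:
    """Bayes-factor test of the ancestral state at one internal node.

    Runs two constrained analyses with the node's state fossilised to 0 and
    to 1, estimates each ln marginal likelihood by stepping-stone sampling
    and reports BF = 2 (ln mL_best - ln mL_other), significant iff BF > 5
    (strict inequality).  A fixation with zero likelihood yields an infinite
    BF, flagged.
    """
    if tree.is_tip(node):
        raise InputError(f"node {node} is a tip; Bayes factors test internal nodes")
    lnml = []
    for state in (0, 1):
        lnml.append(
            _stepping_stone_lnml(
                tree, chars, settings, {int(node): state}, settings.seed + state
            )
        )
    lnml = tuple(lnml)
    preferred = int(np.argmax(lnml))
    if np.isinf(lnml[1 - preferred]):
        bf = np.inf
        infinite = True
    else:
        bf = 2.0 * (lnml[preferred] - lnml[1 - preferred])
        infinite = False
    return BayesFactorResult(
        node=int(node),
        bayes_factor=float(bf),
        preferred_state=preferred,
        lnml=lnml,
        significant=bool(bf > BF_SIGNIFICANCE_THRESHOLD),
        infinite=infinite,
    )


def asr_table(result: ASRResult, bf_results=None):
    """Per-internal-node table: node id, P(0), P(1) and, if given, BF columns."""
    import pandas as pd

    tree = result.tree
    rows = []
    bf_by_node = {b.node: b for b in (bf_results or [])}
    for node in tree.postorder:
        node = int(node)
        row = {
            "node": node,
            "P0": result.node_posteriors[node, 0],
            "P1": result.node_posteriors[node, 1],
        }
        if node in bf_by_node:
            b = bf_by_node[node]
            row.update(
                BF=b.bayes_factor,
                preferred_state=b.preferred_state,
                significant=b.significant,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def annotated_newick(tree: Phylogeny, result: ASRResult) -> str:
    """Newick with per-internal-node [&P0=..,P1=..] comments."""

    def rec(node: int) -> str:
        if tree.is_tip(node):
            core = tree.tip_labels[node]
        else:
            core = f"({rec(int(tree.left[node]))},{rec(int(tree.right[node]))})"
            p0, p1 = result.node_posteriors[node]
            core += f"[&P0={p0:.4f},P1={p1:.4f}]"
        if node == tree.root:
            return core
        return f"{core}:{tree.blen[node]:.10g}"

    return rec(tree.root) + ";"
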