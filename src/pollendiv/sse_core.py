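"""State-dependent speciation–extinction (SSE) likelihood engine.

Joint likelihood of a time-calibrated tree and binary tip states where
speciation rate ``lambda``, extinction rate ``mu`` and the transition matrix
``Q`` depend on a combined state space of 2 observed states (accessible
``A`` = 0, restricted ``R`` = 1) times 1, 2 or 4 hidden states.  Per-lineage
probabilities ``D`` (observed clade density) and ``E`` (no sampled
descendants) are propagated root-ward by the standard coupled ODEs with
incomplete sampling entering through per-state tip sampling fractions
``rho``.

Combined-state ordering is observed-fastest: index ``h * 2 + s`` for
observed state ``s`` in hidden class ``h``, i.e. ``[A0, R0, A1, R1, ...]``.

Two integrators back :func:`sse_loglik`: the default compiled fixed-substep
RK4 kernel (``method="fast"``), and a scipy adaptive Dormand–Prince path
(``method="reference"``, rtol 1e-10) retained as the numerical cross-check.

Dual transitions (simultaneous observed + hidden change) have rate zero;
only observed<->observed rates within a hidden class and a single
hidden<->hidden rate between classes are populated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from . import _kernels
from .errors import InputError, IntegrationError, LikelihoodError
from .pollen import CharacterMatrix
from .trees import Phylogeny

__all__ = [
    "SSEStateSpace",
    "SSEParameters",
    "SamplingFractions",
    "LikelihoodState",
    "build_transition_matrix",
    "initialize_tips",
    "integrate_branch",
    "sse_loglik",
    "bd_loglik",
    "DEFAULT_H_FACTOR",
]

#: RK4 substep = DEFAULT_H_FACTOR / (fastest total per-state rate).
DEFAULT_H_FACTOR = 0.02

OBSERVED_STATES = ("A", "R")


@dataclass(frozen=True)
class SSEStateSpace:
    """Observed x hidden product space; ordering ``[A0, R0, A1, R1, ...]``."""

    n_hidden: int = 1

    def __post_init__(self):
        if self.n_hidden not in (1, 2, 4):
            raise InputError(f"n_hidden must be 1, 2 or 4, got {self.n_hidden}")

    @property
    def n_combined(self) -> int:
        return 2 * self.n_hidden

    @property
    def combined_labels(self) -> tuple[str, ...]:
        return tuple(
            f"{OBSERVED_STATES[s]}{h}"
            for h in range(self.n_hidden)
            for s in range(2)
        )

    def observed_index(self) -> np.ndarray:
        """Observed-state component (0/1) of each combined state."""
        return np.tile(np.array([0, 1]), self.n_hidden)


def build_transition_matrix(
    q01: float, q10: float, q_hidden: float, n_hidden: int = 1
) -> np.ndarray:
    """Transition-rate matrix over combined states.

    Observed transitions (rates ``q01``, ``q10``) act within each hidden
    class; hidden transitions act between every pair of hidden classes at the
    single rate ``q_hidden``; dual transitions are zero.  The diagonal makes
    rows sum to zero.
    """
    if min(q01, q10, q_hidden if n_hidden > 1 else 0.0) < 0:
        raise InputError("transition rates must be >= 0")
    k = 2 * n_hidden
    Q = np.zeros((k, k))
    for h in range(n_hidden):
        Q[2 * h + 0, 2 * h + 1] = q01
        Q[2 * h + 1, 2 * h + 0] = q10
        for h2 in range(n_hidden):
            if h2 != h:
                Q[2 * h + 0, 2 * h2 + 0] = q_hidden
                Q[2 * h + 1, 2 * h2 + 1] = q_hidden
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


@dataclass(frozen=True)
class SSEParameters:
    """Per-combined-state rates; ``Q`` rows sum to zero, dual transitions 0."""

    lam: np.ndarray
    mu: np.ndarray
    Q: np.ndarray

    def __post_init__(self):
        lam = np.asarray(self.lam, dtype=float)
        mu = np.asarray(self.mu, dtype=float)
        Q = np.asarray(self.Q, dtype=float)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "Q", Q)
        k = len(lam)
        if k % 2 or len(mu) != k or Q.shape != (k, k):
            raise InputError("inconsistent parameter dimensions")
        if not (np.isfinite(lam).all() and np.isfinite(mu).all() and np.isfinite(Q).all()):
            raise InputError("rates must be finite")
        if (lam < 0).any() or (mu < 0).any():
            raise InputError("lambda and mu must be >= 0")
        off = Q - np.diag(np.diag(Q))
        if (off < 0).any():
            raise InputError("off-diagonal Q entries must be >= 0")
        if np.abs(Q.sum(axis=1)).max() > 1e-10:
            raise InputError("Q rows must sum to 0")
        n_hidden = k // 2
        for h in range(n_hidden):
            for h2 in range(n_hidden):
                if h != h2:
                    if off[2 * h, 2 * h2 + 1] != 0 or off[2 * h + 1, 2 * h2] != 0:
                        raise InputError("dual transitions must have rate 0")

    @property
    def n_combined(self) -> int:
        return len(self.lam)

    @property
    def n_hidden(self) -> int:
        return self.n_combined // 2

    @classmethod
    def bisse(cls, lam0, lam1, mu0, mu1, q01, q10) -> "SSEParameters":
        """Plain 2-state (no hidden) parameterisation."""
        return cls(
            lam=np.array([lam0, lam1]),
            mu=np.array([mu0, mu1]),
            Q=build_transition_matrix(q01, q10, 0.0, 1),
        )

    def max_total_rate(self) -> float:
        out = self.lam + self.mu - np.diag(self.Q)
        return float(out.max())

    def to_yaml(self, path=None) -> str:
        import yaml

        text = yaml.safe_dump(
            {
                "lam": self.lam.tolist(),
                "mu": self.mu.tolist(),
                "Q": self.Q.tolist(),
            },
            sort_keys=False,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, text_or_path) -> "SSEParameters":
        import os

        import yaml

        if isinstance(text_or_path, (str, os.PathLike)) and os.path.exists(
            text_or_path
        ):
            with open(text_or_path) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(text_or_path)
        return cls(
            lam=np.asarray(data["lam"], dtype=float),
            mu=np.asarray(data["mu"], dtype=float),
            Q=np.asarray(data["Q"], dtype=float),
        )


@dataclass(frozen=True)
class SamplingFractions:
    """Per-observed-state sampling probabilities in (0, 1].

    ``f`` (the assumed accessible-state share among unsampled species) is
    recorded when the fractions were derived from it; it does not enter the
    likelihood directly.
    """

    rho: np.ndarray  # shape (2,): per observed state
    f: float | None = None

    def __post_init__(self):
        rho = np.atleast_1d(np.asarray(self.rho, dtype=float))
        if rho.size == 1:
            rho = np.repeat(rho, 2)
        object.__setattr__(self, "rho", rho)
        if rho.shape != (2,):
            raise InputError("rho must be scalar or length-2 (per observed state)")
        if (rho <= 0).any() or (rho > 1).any():
            raise InputError(f"rho must lie in (0, 1], got {rho}")

    @classmethod
    def complete(cls) -> "SamplingFractions":
        return cls(rho=np.array([1.0, 1.0]))

    @classmethod
    def global_fraction(cls, rho: float) -> "SamplingFractions":
        return cls(rho=np.array([rho, rho]))

    def expand(self, n_hidden: int) -> np.ndarray:
        return np.tile(self.rho, n_hidden)


@dataclass
class LikelihoodState:
    """D/E pair for one lineage plus its accumulated log rescale factor."""

    D: np.ndarray
    E: np.ndarray
    log_scale: float = 0.0


def initialize_tips(
    chars: CharacterMatrix,
    space: SSEStateSpace,
    sampling: SamplingFractions,
    tip_labels,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-tip initial D and E.

    An observed state puts ``D = rho_s`` on every combined state whose
    observed part matches (hidden part unknown), 0 elsewhere; ambiguous or
    missing tips put ``D = rho`` everywhere; ``E = 1 - rho`` everywhere.
    """
    codes = chars.state_codes(tip_labels)
    k = space.n_combined
    rho_k = sampling.expand(space.n_hidden)
    obs = space.observed_index()
    n = len(codes)
    D = np.zeros((n, k))
    E = np.tile(1.0 - rho_k, (n, 1))
    for i, c in enumerate(codes):
        if c == 2:
            D[i] = rho_k
        else:
            D[i, obs == c] = rho_k[obs == c]
    return D, E


def _ode_rhs(t, y, lam, mu, Qd):
    k = len(lam)
    D, E = y[:k], y[k:]
    tot = lam + mu
    dD = Qd @ D - tot * D + 2.0 * lam * E * D
    dE = mu + Qd @ E - tot * E + lam * E * E
    return np.concatenate([dD, dE])


def integrate_branch(
    state: LikelihoodState,
    params: SSEParameters,
    t: float,
    method: str = "fast",
    h_factor: float = DEFAULT_H_FACTOR,
) -> LikelihoodState:
    """Propagate a lineage's (D, E) root-ward over a branch of duration t."""
    if t < 0:
        raise InputError(f"branch duration must be >= 0, got {t}")
    D = np.array(state.D, dtype=float)
    E = np.array(state.E, dtype=float)
    if t == 0:
        return LikelihoodState(D, E, state.log_scale)
    if method == "fast":
        h_max = _h_max(params, h_factor)
        ls = _kernels.integrate_edge(D, E, params.lam, params.mu, params.Q, t, h_max)
        return LikelihoodState(D, E, state.log_scale + ls)
    if method != "reference":
        raise InputError(f"unknown method {method!r}")
    sol = solve_ivp(
        _ode_rhs,
        (0.0, t),
        np.concatenate([D, E]),
        args=(params.lam, params.mu, params.Q),
        method="RK45",
        rtol=1e-10,
        atol=1e-12,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"branch integration failed: {sol.message}")
    k = params.n_combined
    y = sol.y[:, -1]
    return LikelihoodState(y[:k], np.clip(y[k:], 0.0, 1.0), state.log_scale)


def _h_max(params: SSEParameters, h_factor: float) -> float:
    return _h_from_rate(params.max_total_rate(), h_factor)


def _h_from_rate(rate: float, h_factor: float) -> float:
    """RK4 substep bound: accuracy-driven (h*rate = h_factor) for rates up
    to 1/Myr, then held at ``h_factor`` Myr — still far inside the RK4
    stability region, and precision in such implausible-rate regions is
    irrelevant to inference on Myr-scale trees."""
    if rate <= 0:
        return 1e12
    return h_factor / min(rate, 1.0)


def sse_loglik(
    tree: Phylogeny,
    chars: CharacterMatrix,
    params: SSEParameters,
    sampling: SamplingFractions,
    condition_on_survival: bool = True,
    root_weighting: str = "observed_weighted",
    method: str = "fast",
    h_factor: float = DEFAULT_H_FACTOR,
) -> float:
    """SSE log-likelihood of the tree plus tip states.

    Post-order pruning: at each internal node
    ``D_parent,i = lambda_i D_left,i D_right,i``; at the root the per-state
    terms are combined with equal weights or weights proportional to the
    root D (``root_weighting='observed_weighted'``, the default), and with
    ``condition_on_survival`` each root term is divided by
    ``lambda_i (1 - E_i)^2``.
    """
    if root_weighting not in ("equal", "observed_weighted"):
        raise InputError(f"unknown root weighting {root_weighting!r}")
    space = SSEStateSpace(params.n_hidden)
    tipD, tipE = initialize_tips(chars, space, sampling, tree.tip_labels)
    root_mode = 1 if root_weighting == "observed_weighted" else 0
    if method == "fast":
        ll = _kernels.tree_loglik(
            tree.postorder,
            tree.left,
            tree.right,
            tree.blen,
            tipD,
            tipE,
            params.lam,
            params.mu,
            params.Q,
            _h_max(params, h_factor),
            condition_on_survival,
            root_mode,
        )
    elif method == "reference":
        ll = _loglik_reference(
            tree, tipD, tipE, params, condition_on_survival, root_mode
        )
    else:
        raise InputError(f"unknown method {method!r}")
    if np.isnan(ll):
        raise LikelihoodError(
            "non-finite SSE likelihood (conditioning degeneracy)", params=params
        )
    return float(ll)


def _loglik_reference(tree, tipD, tipE, params, condition, root_mode):
    k = params.n_combined
    n = tree.n_nodes
    D = np.zeros((n, k))
    E = np.zeros((n, k))
    D[: tree.n_tips] = tipD
    E[: tree.n_tips] = tipE
    acc = 0.0
    for node in tree.postorder:
        for child in (tree.left[node], tree.right[node]):
            st = integrate_branch(
                LikelihoodState(D[child], E[child]),
                params,
                float(tree.blen[child]),
                method="reference",
            )
            D[child], E[child] = st.D, st.E
            acc += st.log_scale
        l, r = tree.left[node], tree.right[node]
        D[node] = params.lam * D[l] * D[r]
        E[node] = 0.5 * (E[l] + E[r])
        m = D[node].max()
        if m <= 0:
            return -np.inf
        D[node] /= m
        acc += np.log(m)
    root = tree.root
    w = D[root] / D[root].sum() if root_mode == 1 else np.full(k, 1.0 / k)
    terms = w * D[root]
    if condition:
        denom = params.lam * (1.0 - E[root]) ** 2
        out = np.zeros(k)
        for j in range(k):
            if terms[j] > 0:
                if denom[j] <= 0:
                    return np.nan
                out[j] = terms[j] / denom[j]
        terms = out
    total = terms.sum()
    if total <= 0:
        return -np.inf
    return float(np.log(total) + acc)


def make_loglik_fn(
    tree: Phylogeny,
    chars: CharacterMatrix,
    sampling: SamplingFractions,
    n_hidden: int = 1,
    condition_on_survival: bool = True,
    root_weighting: str = "observed_weighted",
    h_factor: float = DEFAULT_H_FACTOR,
):
    """Cached fast path for optimisers and samplers.

    Precomputes the tip conditioning once and returns
    ``fn(lam, mu, Q) -> lnL`` taking raw per-combined-state arrays with no
    validation; NaN (conditioning degeneracy) is mapped to ``-inf``.
    Numerically identical to :func:`sse_loglik` at the same ``h_factor``.
    """
    space = SSEStateSpace(n_hidden)
    tipD, tipE = initialize_tips(chars, space, sampling, tree.tip_labels)
    root_mode = 1 if root_weighting == "observed_weighted" else 0
    post, left, right, blen = tree.postorder, tree.left, tree.right, tree.blen

    def fn(lam, mu, Q):
        rate = float((lam + mu - np.diag(Q)).max())
        h_max = _h_from_rate(rate, h_factor)
        ll = _kernels.tree_loglik(
            post, left, right, blen, tipD, tipE,
            np.ascontiguousarray(lam, dtype=float),
            np.ascontiguousarray(mu, dtype=float),
            np.ascontiguousarray(Q, dtype=float),
            h_max, condition_on_survival, root_mode,
        )
        return -np.inf if np.isnan(ll) else float(ll)

    return fn


# ----------------------------------------------------------------------
# constant-rate birth–death (no character): closed forms
# ----------------------------------------------------------------------
def bd_loglik(
    tree: Phylogeny,
    lam: float,
    mu: float,
    rho: float = 1.0,
    condition_on_survival: bool = True,
) -> float:
    """Constant-rate birth–death log-likelihood with sampling fraction rho.

    Uses the closed-form E(t) and per-branch D ratio of the constant-rate
    process, assembled exactly as the SSE pruning does (tips start at
    ``D = rho``, every internal node including the root contributes a factor
    ``lambda``, conditioning divides by ``lambda (1 - E(T))^2``); it is the
    1-state specialisation of :func:`sse_loglik`, computed without any ODE
    solver, and serves as an independent factorisation oracle.
    """
    if lam < 0 or mu < 0 or not 0 < rho <= 1:
        raise InputError("need lam, mu >= 0 and rho in (0, 1]")
    r = lam - mu
    if abs(r) < 1e-12:
        r = 1e-12  # critical process: nudge off the removable singularity

    def g(t):
        return rho * lam + (lam * (1.0 - rho) - mu) * np.exp(-r * t)

    ages = tree.node_ages()
    gv = g(ages)
    if (gv <= 0.0).any():
        # E(t) would leave [0, 1): the closed form is outside its valid
        # regime (heavy subcritical extinction with sparse sampling)
        return -np.inf
    ll = 0.0
    for i in range(tree.n_nodes):
        if i == tree.root:
            continue
        t0 = ages[i]
        t1 = ages[tree.parent[i]]
        # D(t1)/D(t0) along the branch
        ll += -r * (t1 - t0) + 2.0 * (np.log(g(t0)) - np.log(g(t1)))
    n_tips = tree.n_tips
    ll += n_tips * np.log(rho)
    if lam > 0:
        ll += (n_tips - 1) * np.log(lam)
    elif n_tips > 1:
        return -np.inf
    if condition_on_survival:
        T = ages[tree.root]
        E_T = 1.0 - rho * r / g(T)
        if E_T >= 1.0:
            return -np.inf
        ll -= np.log(lam) + 2.0 * np.log1p(-E_T)
    return float(ll)
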