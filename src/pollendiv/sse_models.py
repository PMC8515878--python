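"""The six-model SSE ladder: specification, ML fitting and AIC comparison.

Every model shares one three-rate transition structure — two rates between
the observed states (``q01``: A->R, ``q10``: R->A) and one rate between
hidden classes (``q_hidden``) — and differs only in how speciation and
extinction rates are tied across the combined observed x hidden space:

=======  ========  ==========================================  ==
model    n_hidden  diversification-rate structure               k
=======  ========  ==========================================  ==
Mase     2         lambda, mu vary by observed state (2 + 2)    7
Mas      2         lambda by observed state, single mu (2 + 1)  6
Mahse    2         lambda, mu free over all combinations        11
M0       2         single lambda, single mu (null)              5
M0h2     2         lambda, mu vary by hidden class only         7
M0h4     4         lambda, mu vary by hidden class only         11
=======  ========  ==========================================  ==

Mase/Mas/M0 carry a formally 2-class hidden channel with rates tied across
classes; such a tied space is exactly lumpable onto the plain 2-state model
(the likelihood is independent of ``q_hidden``), and the fitter evaluates
them on the collapsed space.

Fitting is multi-start Nelder–Mead on log-scale parameters: short runs from
five starting points (the first built from the character-independent
birth–death MLE and a parsimony-informed transition rate, the rest jittered
by lognormal noise), then a full polish from the best start.  Models are
compared by AIC = 2k - 2 lnL; a trait-dependent model is flagged as
supported when its AIC undercuts the best null model's by at least 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import FitFailureError, InputError
from .mk import parsimony_change_count
from .pollen import CharacterMatrix
from .sse_core import (
    SamplingFractions,
    SSEParameters,
    bd_loglik,
    build_transition_matrix,
    make_loglik_fn,
    sse_loglik,
)
from .trees import Phylogeny

__all__ = [
    "MODEL_NAMES",
    "NULL_MODELS",
    "SSEModelSpec",
    "FitResult",
    "build_model_spec",
    "fit_ml",
    "compare_aic",
    "bd_mle",
]

MODEL_NAMES = ("Mase", "Mas", "Mahse", "M0", "M0h2", "M0h4")
NULL_MODELS = ("M0", "M0h2", "M0h4")
AIC_SUPPORT_MARGIN = 2.0


@dataclass(frozen=True)
class SSEModelSpec:
    """Constraint mapping from free parameters to the full SSE rate set.

    ``lambda_map``/``mu_map`` give, per combined state (ordering
    ``[A0, R0, A1, R1, ...]``), the index of the free parameter providing
    that rate; the last three free parameters are always
    ``(q01, q10, q_hidden)``.
    """

    name: str
    n_hidden: int
    lambda_map: tuple[int, ...]
    mu_map: tuple[int, ...]
    free_parameters: tuple[str, ...]

    @property
    def n_free(self) -> int:
        return len(self.free_parameters)

    @property
    def collapsible(self) -> bool:
        """True when rates are tied across hidden classes (exact lumping)."""
        lm = np.array(self.lambda_map).reshape(self.n_hidden, 2)
        mm = np.array(self.mu_map).reshape(self.n_hidden, 2)
        return bool((lm == lm[0]).all() and (mm == mm[0]).all())

    def to_parameters(self, theta, collapse: bool = False) -> SSEParameters:
        """Expand a free-parameter vector; ``collapse`` drops the inert
        hidden channel of a collapsible model."""
        theta = np.asarray(theta, dtype=float)
        if len(theta) != self.n_free:
            raise InputError(
                f"{self.name} expects {self.n_free} parameters, got {len(theta)}"
            )
        q01, q10, qh = theta[-3:]
        if collapse:
            if not self.collapsible:
                raise InputError(f"{self.name} is not collapsible")
            lam = theta[np.array(self.lambda_map[:2])]
            mu = theta[np.array(self.mu_map[:2])]
            return SSEParameters(lam, mu, build_transition_matrix(q01, q10, 0.0, 1))
        lam = theta[np.array(self.lambda_map)]
        mu = theta[np.array(self.mu_map)]
        Q = build_transition_matrix(q01, q10, qh, self.n_hidden)
        return SSEParameters(lam, mu, Q)


def build_model_spec(name: str) -> SSEModelSpec:
    """Construct one of the six named model specifications."""
    q_names = ("q01", "q10", "q_hidden")
    if name == "Mase":
        return SSEModelSpec(
            name, 2, (0, 1, 0, 1), (2, 3, 2, 3),
            ("lam_A", "lam_R", "mu_A", "mu_R") + q_names,
        )
    if name == "Mas":
        return SSEModelSpec(
            name, 2, (0, 1, 0, 1), (2, 2, 2, 2), ("lam_A", "lam_R", "mu") + q_names
        )
    if name == "Mahse":
        return SSEModelSpec(
            name, 2, (0, 1, 2, 3), (4, 5, 6, 7),
            ("lam_A0", "lam_R0", "lam_A1", "lam_R1",
             "mu_A0", "mu_R0", "mu_A1", "mu_R1") + q_names,
        )
    if name == "M0":
        return SSEModelSpec(name, 2, (0, 0, 0, 0), (1, 1, 1, 1), ("lam", "mu") + q_names)
    if name == "M0h2":
        return SSEModelSpec(
            name, 2, (0, 0, 1, 1), (2, 2, 3, 3),
            ("lam_h0", "lam_h1", "mu_h0", "mu_h1") + q_names,
        )
    if name == "M0h4":
        return SSEModelSpec(
            name, 4,
            (0, 0, 1, 1, 2, 2, 3, 3), (4, 4, 5, 5, 6, 6, 7, 7),
            ("lam_h0", "lam_h1", "lam_h2", "lam_h3",
             "mu_h0", "mu_h1", "mu_h2", "mu_h3") + q_names,
        )
    raise InputError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")


def bd_mle(tree: Phylogeny, rho: float = 1.0) -> tuple[float, float]:
    """Character-independent constant-rate birth–death MLE (lambda, mu)."""

    def nll(x):
        lam, mu = np.exp(x)
        ll = bd_loglik(tree, lam, mu, rho)
        return -ll if np.isfinite(ll) else 1e10

    # Yule-like initial guess
    lam0 = max((tree.n_tips - 1) / max(tree.total_branch_length, 1e-9) / rho, 1e-4)
    best = None
    for mu_frac in (0.05, 0.5):
        res = minimize(
            nll,
            np.log([lam0, max(mu_frac * lam0, 1e-6)]),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    lam, mu = np.exp(best.x)
    return float(lam), float(mu)


@dataclass(frozen=True)
class FitResult:
    spec: SSEModelSpec
    mle: dict[str, float]
    lnL: float
    AIC: float
    per_start_lnL: tuple[float, ...]
    n_starts_converged: int
    data_key: int = 0

    @property
    def k(self) -> int:
        return self.spec.n_free

    @property
    def parameters(self) -> SSEParameters:
        return self.spec.to_parameters([self.mle[p] for p in self.spec.free_parameters])

    def net_diversification(self) -> dict[str, float]:
        """d_s = lambda_s - mu_s per observed state, hidden classes weighted
        equally."""
        params = self.parameters
        d = params.lam - params.mu
        obs = np.tile(np.array([0, 1]), params.n_hidden)
        return {
            "d_A": float(d[obs == 0].mean()),
            "d_R": float(d[obs == 1].mean()),
        }


def _data_key(tree: Phylogeny, chars: CharacterMatrix) -> int:
    return hash(
        (tree.tip_labels, tuple(np.round(tree.blen, 12)),
         chars.partition, tuple(sorted(chars.states.items())))
    )


def _initial_theta(tree, chars, spec, sampling) -> np.ndarray:
    lam_hat, mu_hat = bd_mle(tree, float(sampling.rho.mean()))
    q_hat = max(
        parsimony_change_count(tree, chars) / max(tree.total_branch_length, 1e-9),
        1e-4,
    )
    theta = np.empty(spec.n_free)
    n_lam = len(set(spec.lambda_map))
    n_mu = len(set(spec.mu_map))
    theta[:n_lam] = lam_hat
    theta[n_lam : n_lam + n_mu] = max(mu_hat, 1e-4)
    theta[-3:] = q_hat
    return theta


def fit_ml(
    tree: Phylogeny,
    chars: CharacterMatrix,
    spec: SSEModelSpec,
    sampling: SamplingFractions,
    n_starts: int = 5,
    seed: int = 0,
    condition_on_survival: bool = True,
    root_weighting: str = "observed_weighted",
    explore_maxiter: int = 200,
    polish_maxiter: int = 5000,
    h_factor: float = 0.05,
    extra_starts=(),
) -> FitResult:
    """Multi-start simplex maximum likelihood for one model.

    Optimisation is over log parameters (positivity by construction).  Each
    start gets a short Nelder–Mead exploration; the best start is then
    polished to convergence (simplex tolerance 1e-8 or ``polish_maxiter``
    iterations).  ``extra_starts`` (free-parameter vectors, e.g. a nested
    model's MLE embedded in this model's parameterisation) are explored in
    addition to the ``n_starts`` default points.
    """
    collapse = spec.collapsible
    n_hidden_eff = 1 if collapse else spec.n_hidden
    lam_map = np.array(spec.lambda_map[:2] if collapse else spec.lambda_map)
    mu_map = np.array(spec.mu_map[:2] if collapse else spec.mu_map)
    raw_loglik = make_loglik_fn(
        tree, chars, sampling,
        n_hidden=n_hidden_eff,
        condition_on_survival=condition_on_survival,
        root_weighting=root_weighting,
        h_factor=h_factor,
    )

    def nll(x):
        theta = np.exp(x)
        # rates beyond ~20 events/lineage/Myr are biologically absurd for
        # Myr-scale trees and make the ODE grid explode; treat as infeasible
        if not np.isfinite(theta).all() or theta.max() > 20.0:
            return 1e10
        q01, q10, qh = theta[-3:]
        Q = build_transition_matrix(q01, q10, 0.0 if collapse else qh, n_hidden_eff)
        ll = raw_loglik(theta[lam_map], theta[mu_map], Q)
        return -ll if np.isfinite(ll) else 1e10

    rng = np.random.default_rng(seed)
    base = _initial_theta(tree, chars, spec, sampling)
    starts = [base]
    for _ in range(n_starts - 1):
        starts.append(base * rng.lognormal(0.0, 0.5, size=spec.n_free))
    for theta in extra_starts:
        theta = np.asarray(theta, dtype=float)
        if len(theta) != spec.n_free or (theta <= 0).any():
            raise InputError("extra_starts must be positive free-parameter vectors")
        starts.append(theta)

    explored = []
    for x0 in starts:
        res = minimize(
            nll, np.log(x0), method="Nelder-Mead",
            options={"maxiter": explore_maxiter, "xatol": 1e-6, "fatol": 1e-8},
        )
        explored.append(res)
    per_start = tuple(-r.fun if r.fun < 1e9 else -np.inf for r in explored)
    finite = [r for r in explored if r.fun < 1e9]
    if not finite:
        raise FitFailureError(
            f"{spec.name}: all {n_starts} starts produced non-finite likelihoods"
        )
    best = min(finite, key=lambda r: r.fun)
    polished = minimize(
        nll, best.x, method="Nelder-Mead",
        options={"maxiter": polish_maxiter, "xatol": 1e-8, "fatol": 1e-10},
    )
    if polished.fun >= 1e9:  # pragma: no cover - polish cannot regress the start
        polished = best
    theta = np.exp(polished.x)
    lnL = -polished.fun
    return FitResult(
        spec=spec,
        mle=dict(zip(spec.free_parameters, theta)),
        lnL=float(lnL),
        AIC=float(2 * spec.n_free - 2 * lnL),
        per_start_lnL=per_start,
        n_starts_converged=len(finite),
        data_key=_data_key(tree, chars),
    )


def compare_aic(fits: list[FitResult]) -> pd.DataFrame:
    """Rank fits by AIC (ties broken by fewer parameters).

    ``supported_over_null`` flags models whose AIC undercuts the best null
    model (M0/M0h2/M0h4 among the fits) by at least 2.
    """
    if len(fits) < 2:
        raise InputError("need at least two fits to compare")
    keys = {f.data_key for f in fits}
    if len(keys) != 1:
        raise InputError("fits were made on different data")
    rows = []
    null_aics = [f.AIC for f in fits if f.spec.name in NULL_MODELS]
    best_null = min(null_aics) if null_aics else np.nan
    for f in fits:
        d = f.net_diversification()
        rows.append(
            {
                "model": f.spec.name,
                "k": f.k,
                "lnL": f.lnL,
                "AIC": f.AIC,
                "d_A": d["d_A"],
                "d_R": d["d_R"],
                "supported_over_null": bool(
                    null_aics and f.AIC <= best_null - AIC_SUPPORT_MARGIN
                ),
                **{p: v for p, v in f.mle.items()},
            }
        )
    df = pd.DataFrame(rows).sort_values(["AIC", "k"], kind="stable")
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    return df.reset_index(drop=True)
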