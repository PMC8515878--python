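"""Bayesian MCMC over BiSSE parameters and net-diversification contrasts.

Two model variants, both on the plain 2-observed-state space:

* ``five_param_equal_mu`` — state-dependent speciation, one shared
  extinction rate, unequal transition rates: (lam0, lam1, mu, q01, q10);
* ``full_bisse`` — additionally state-dependent extinction:
  (lam0, lam1, mu0, mu1, q01, q10).

Each parameter carries an independent exponential prior; by default every
prior mean is twice the character-independent net-diversification MLE, the
convention of the standard BiSSE MCMC tooling.  Sampling is coordinate-wise
slice sampling on the natural scale (positivity enforced by the prior
support), with bracket widths tuned during burn-in and then frozen.

The quantity of interest is the posterior of the per-state net
diversification d_s = lambda_s - mu_s, summarised as PP(d_1 > d_0): the
fraction of retained samples in which the state-1 (restricted) rate exceeds
the state-0 (accessible) rate, together with the full difference and ratio
sample sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, LikelihoodError
from .pollen import CharacterMatrix
from .samplers import AdaptiveWidths, slice_update
from .sse_core import SamplingFractions, make_loglik_fn
from .sse_models import bd_mle
from .trees import Phylogeny

__all__ = [
    "PriorSpec",
    "PosteriorTrace",
    "DiversificationSummary",
    "default_priors",
    "run_mcmc",
    "summarize_diversification",
]

MODEL_PARAMS = {
    "five_param_equal_mu": ("lam0", "lam1", "mu", "q01", "q10"),
    "full_bisse": ("lam0", "lam1", "mu0", "mu1", "q01", "q10"),
}


@dataclass(frozen=True)
class PriorSpec:
    """Independent exponential priors; ``rates`` are 1/mean per parameter."""

    rates: np.ndarray

    def __post_init__(self):
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        if (rates <= 0).any() or not np.isfinite(rates).all():
            raise InputError("prior rates must be positive and finite")

    def logpdf(self, x: np.ndarray) -> float:
        if (x < 0).any():
            return -np.inf
        return float(np.sum(np.log(self.rates) - self.rates * x))

    @property
    def means(self) -> np.ndarray:
        return 1.0 / self.rates


def default_priors(
    tree: Phylogeny, model: str, sampling: SamplingFractions
) -> PriorSpec:
    """Exponential prior with mean 2 r-hat on every parameter, r-hat the
    character-independent net-diversification MLE (floored at a small
    positive value for near-Yule trees)."""
    lam_hat, mu_hat = bd_mle(tree, float(sampling.rho.mean()))
    r_hat = max(lam_hat - mu_hat, 1e-3)
    n = len(MODEL_PARAMS[model])
    return PriorSpec(np.full(n, 1.0 / (2.0 * r_hat)))


@dataclass(frozen=True)
class PosteriorTrace:
    """Full MCMC trace with the burn-in boundary marked."""

    model: str
    param_names: tuple[str, ...]
    samples: np.ndarray  # (n_iter, n_params), includes burn-in
    loglik: np.ndarray
    logpost: np.ndarray
    n_iter: int
    burn_in_frac: float
    seed: int
    mean_evals_per_iter: float = np.nan

    @property
    def n_burn(self) -> int:
        return int(self.n_iter * self.burn_in_frac)

    @property
    def retained(self) -> np.ndarray:
        return self.samples[self.n_burn :]

    def to_frame(self, retained_only: bool = True) -> pd.DataFrame:
        s = self.retained if retained_only else self.samples
        df = pd.DataFrame(s, columns=list(self.param_names))
        off = self.n_burn if retained_only else 0
        df["loglik"] = self.loglik[off:]
        df["logpost"] = self.logpost[off:]
        return df

    def net_diversification_samples(self) -> tuple[np.ndarray, np.ndarray]:
        """(d0, d1) per retained sample."""
        s = self.retained
        names = self.param_names
        lam0 = s[:, names.index("lam0")]
        lam1 = s[:, names.index("lam1")]
        if "mu" in names:
            mu0 = mu1 = s[:, names.index("mu")]
        else:
            mu0 = s[:, names.index("mu0")]
            mu1 = s[:, names.index("mu1")]
        return lam0 - mu0, lam1 - mu1


def run_mcmc(
    tree: Phylogeny,
    chars: CharacterMatrix,
    model: str = "five_param_equal_mu",
    sampling: SamplingFractions | None = None,
    priors: PriorSpec | None = None,
    n_iter: int = 10_000,
    burn_in_frac: float = 0.2,
    seed: int = 0,
    condition_on_survival: bool = True,
    root_weighting: str = "observed_weighted",
    prior_only: bool = False,
    h_factor: float = 0.1,
) -> PosteriorTrace:
    """Slice-sampling MCMC over the BiSSE posterior; deterministic per seed.

    ``prior_only=True`` replaces the likelihood by a constant, so the chain
    targets the prior — the standard sampler-correctness check.
    """
    if model not in MODEL_PARAMS:
        raise InputError(f"unknown model {model!r}; expected {set(MODEL_PARAMS)}")
    if sampling is None:
        sampling = SamplingFractions.complete()
    if priors is None:
        priors = default_priors(tree, model, sampling)
    names = MODEL_PARAMS[model]
    if len(priors.rates) != len(names):
        raise InputError("prior dimension does not match model")

    raw_loglik = make_loglik_fn(
        tree, chars, sampling,
        n_hidden=1,
        condition_on_survival=condition_on_survival,
        root_weighting=root_weighting,
        h_factor=h_factor,
    )

    def loglik(x):
        if prior_only:
            return 0.0
        if model == "five_param_equal_mu":
            lam = np.array([x[0], x[1]])
            mu = np.array([x[2], x[2]])
            q01, q10 = x[3], x[4]
        else:
            lam = np.array([x[0], x[1]])
            mu = np.array([x[2], x[3]])
            q01, q10 = x[4], x[5]
        Q = np.array([[-q01, q01], [q10, -q10]])
        return raw_loglik(lam, mu, Q)

    cache = {"ll": np.nan}

    def logpost(x):
        lp = priors.logpdf(x)
        if not np.isfinite(lp):
            cache["ll"] = -np.inf
            return -np.inf
        ll = loglik(x)
        cache["ll"] = ll
        return lp + ll

    rng = np.random.default_rng(seed)
    # initial point: character-independent MLE-ish; redraw from prior if the
    # likelihood is non-finite there
    lam_hat, mu_hat = bd_mle(tree, float(sampling.rho.mean()))
    q0 = max(0.1 * max(lam_hat - mu_hat, 1e-3), 1e-4)
    if model == "five_param_equal_mu":
        x = np.array([lam_hat, lam_hat, max(mu_hat, 1e-4), q0, q0])
    else:
        x = np.array([lam_hat, lam_hat, max(mu_hat, 1e-4), max(mu_hat, 1e-4), q0, q0])
    lp = logpost(x)
    tries = 0
    while not np.isfinite(lp):
        if tries >= 20:
            raise LikelihoodError(
                "could not find a finite-likelihood starting point in 20 draws"
            )
        x = rng.exponential(priors.means)
        lp = logpost(x)
        tries += 1

    n_params = len(names)
    samples = np.empty((n_iter, n_params))
    lls = np.empty(n_iter)
    lps = np.empty(n_iter)
    n_burn = int(n_iter * burn_in_frac)
    widths = AdaptiveWidths(np.maximum(0.3 * priors.means, 1e-3))
    total_evals = 0
    for it in range(n_iter):
        x, lp, n_evals, moves = slice_update(x, logpost, lp, widths.widths, rng)
        total_evals += n_evals
        if it < n_burn:
            widths.observe(moves)
        samples[it] = x
        lls[it] = cache["ll"]
        lps[it] = lp
    return PosteriorTrace(
        model=model,
        param_names=names,
        samples=samples,
        loglik=lls,
        logpost=lps,
        n_iter=n_iter,
        burn_in_frac=burn_in_frac,
        seed=seed,
        mean_evals_per_iter=total_evals / n_iter,
    )


@dataclass(frozen=True)
class DiversificationSummary:
    """Posterior contrast of per-state net diversification (state 1 vs 0)."""

    pp_greater: float  # P(d1 > d0), strict inequality
    diff_samples: np.ndarray  # d1 - d0
    ratio_samples: np.ndarray  # d1 / d0
    median_d0: float
    median_d1: float

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format quantity/value table (violin-plot ready)."""
        return pd.DataFrame(
            {
                "quantity": ["difference"] * len(self.diff_samples)
                + ["ratio"] * len(self.ratio_samples),
                "value": np.concatenate([self.diff_samples, self.ratio_samples]),
            }
        )

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        return tuple(np.quantile(self.diff_samples, [a, 1.0 - a]))


def summarize_diversification(trace: PosteriorTrace) -> DiversificationSummary:
    """PP(d1 > d0) plus difference/ratio sample sets from retained draws."""
    if len(trace.retained) == 0:
        raise InputError("trace has no retained samples")
    d0, d1 = trace.net_diversification_samples()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d0 != 0, d1 / d0, np.inf)
    return DiversificationSummary(
        pp_greater=float(np.mean(d1 > d0)),
        diff_samples=d1 - d0,
        ratio_samples=ratio,
        median_d0=float(np.median(d0)),
        median_d1=float(np.median(d1)),
    )
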