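"""Coordinate-wise slice sampling (Neal 2003), shared by the MCMC modules.

Slice sampling needs no step-size tuning to remain valid; the interval widths
only affect efficiency, so they are adapted during burn-in from the observed
move sizes and then frozen.
"""

from __future__ import annotations

import numpy as np

__all__ = ["slice_update", "AdaptiveWidths"]

_MAX_STEPOUT = 50
_MAX_SHRINK = 200


def slice_update(x, logpost, logp, widths, rng):
    """One full sweep of coordinate-wise slice updates.

    Parameters
    ----------
    x : ndarray
        Current point (modified copy returned).
    logpost : callable
        Log target density.
    logp : float
        ``logpost(x)`` (avoid recomputation).
    widths : ndarray
        Per-coordinate initial bracket widths.
    rng : numpy Generator

    Returns
    -------
    x_new, logp_new, n_evals, move_sizes
    """
    x = np.array(x, dtype=float)
    n_evals = 0
    moves = np.zeros(len(x))
    for i in range(len(x)):
        y = logp + np.log(rng.random())
        w = widths[i]
        L = x[i] - w * rng.random()
        R = L + w
        # stepping out
        j = 0
        xi = x.copy()
        while j < _MAX_STEPOUT:
            xi[i] = L
            if logpost(xi) < y:
                break
            L -= w
            j += 1
        n_evals += j + 1
        j = 0
        while j < _MAX_STEPOUT:
            xi[i] = R
            if logpost(xi) < y:
                break
            R += w
            j += 1
        n_evals += j + 1
        # shrinkage
        x0 = x[i]
        for _ in range(_MAX_SHRINK):
            prop = L + (R - L) * rng.random()
            xi[i] = prop
            lp = logpost(xi)
            n_evals += 1
            if lp >= y:
                moves[i] = abs(prop - x0)
                x[i] = prop
                logp = lp
                break
            if prop < x0:
                L = prop
            else:
                R = prop
        else:  # pragma: no cover - numerically degenerate target
            xi[i] = x0
    return x, logp, n_evals, moves


class AdaptiveWidths:
    """Running width adaptation: widths -> 2 x mean accepted move size."""

    def __init__(self, widths):
        self.widths = np.array(widths, dtype=float)
        self._acc = np.zeros_like(self.widths)
        self._n = 0

    def observe(self, moves):
        self._acc += moves
        self._n += 1
        if self._n >= 50:
            mean = self._acc / self._n
            ok = mean > 0
            self.widths[ok] = 2.0 * mean[ok]
            self._acc[:] = 0.0
            self._n = 0
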