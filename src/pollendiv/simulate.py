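"""Forward simulation: state-dependent birth–death trees, Mk tip traits,
incomplete-sampling pruning, and the synthetic pollen-table generator.

The tree simulator is a Gillespie process started from a crown pair of
lineages sharing a root state.  Events per lineage in state ``s``:
speciation at ``lambda_s``, extinction at ``mu_s``, state flips at
``q_s->s'``.  Extinct lineages are pruned from the returned tree, which is
ultrametric by construction; replicates whose surviving tip count falls
below a floor are rejected and resimulated (survivorship handled by
acceptance-rejection so the stopping rule stays exact).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InfeasibleSamplingError, InputError, SimulationAbortError
from .pollen import CatalogEntry, PollenCatalog, PollenSample
from .sse_core import SamplingFractions, SSEParameters
from .trees import Phylogeny

__all__ = [
    "SimConfig",
    "SimReplicate",
    "simulate_bisse_tree",
    "simulate_mk_traits",
    "prune_to_tips",
    "apply_incomplete_sampling",
    "state_specific_rho",
    "generate_synthetic_pollen_dataset",
    "default_catalog_template",
    "samples_to_frame",
]


@dataclass(frozen=True)
class SimConfig:
    """Conditions of one simulation scenario.

    ``stop`` is ``("n_tips", n)`` (run until n extant lineages, the present
    being placed just before the next event would occur) or ``("time", T)``.
    """

    params: SSEParameters
    stop: tuple[str, float]
    seed: int = 0
    min_surviving_tips: int = 3
    root_state: int | None = None  # None -> draw from stationary Q frequencies
    max_attempts: int = 1000

    def __post_init__(self):
        kind, value = self.stop
        if kind not in ("n_tips", "time") or value <= 0:
            raise InputError(f"bad stop rule {self.stop!r}")
        if self.params.n_hidden != 1 and self.root_state is None:
            pass  # stationary draw covers hidden states too


@dataclass(frozen=True)
class SimReplicate:
    tree: Phylogeny
    tip_states: dict[str, int]  # observed state per tip label
    true_params: SSEParameters
    seed: int
    n_attempts: int = 1


def _stationary_frequencies(Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


class _Lineage:
    __slots__ = ("parent", "state", "birth", "death", "children")

    def __init__(self, parent, state, birth):
        self.parent = parent
        self.state = state
        self.birth = birth
        self.death = None
        self.children = []


def _attempt(params: SSEParameters, stop, root_state, rng):
    kind, value = stop
    k = params.n_combined
    lam, mu, Q = params.lam, params.mu, params.Q
    off = Q - np.diag(np.diag(Q))
    out_rate = off.sum(axis=1)
    total_state_rate = lam + mu + out_rate

    root = _Lineage(None, root_state, 0.0)
    a = _Lineage(root, root_state, 0.0)
    b = _Lineage(root, root_state, 0.0)
    root.children = [a, b]
    root.death = 0.0
    extant = [a, b]
    t = 0.0
    while True:
        rates = np.array([total_state_rate[ln.state] for ln in extant])
        total = rates.sum()
        if total <= 0:
            if kind == "time":
                t = value
                break
            return None, t  # frozen process can never reach the tip target
        dt = rng.exponential(1.0 / total)
        if kind == "time" and t + dt > value:
            t = value
            break
        if kind == "n_tips" and len(extant) >= int(value):
            # present sits just before the next event would fire
            t = t + dt
            break
        t += dt
        i = rng.choice(len(extant), p=rates / total)
        ln = extant[i]
        s = ln.state
        u = rng.random() * total_state_rate[s]
        if u < lam[s]:
            c1 = _Lineage(ln, s, t)
            c2 = _Lineage(ln, s, t)
            ln.children = [c1, c2]
            ln.death = t
            extant[i] = c1
            extant.append(c2)
        elif u < lam[s] + mu[s]:
            ln.death = t
            extant.pop(i)
            if not extant:
                return None, t
        else:
            u -= lam[s] + mu[s]
            for s2 in range(k):
                if s2 == s:
                    continue
                if u < off[s, s2]:
                    ln.state = s2
                    break
                u -= off[s, s2]
    return (root, extant, t), t


def _reduce(node, present, survivors):
    """Collapse the simulated lineage tree onto surviving tips."""
    if not node.children:
        if id(node) in survivors:
            return ("tip", node, present - node.birth)
        return None
    subs = [_reduce(c, present, survivors) for c in node.children]
    subs = [s for s in subs if s is not None]
    if not subs:
        return None
    if len(subs) == 1:
        kind, payload, blen = subs[0]
        return (kind, payload, blen + (node.death - node.birth))
    return ("node", subs, node.death - node.birth)


def _build_phylogeny(reduced, obs_index):
    tips = []

    def collect(entry):
        kind, payload, _ = entry
        if kind == "tip":
            tips.append(payload)
        else:
            for sub in payload:
                collect(sub)

    collect(reduced)
    n_tips = len(tips)
    labels = [f"t{i + 1}" for i in range(n_tips)]
    tip_ids = {id(ln): i for i, ln in enumerate(tips)}
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    blen = np.zeros(n_nodes)
    postorder = []
    counter = [n_tips]

    def build(entry):
        kind, payload, length = entry
        if kind == "tip":
            i = tip_ids[id(payload)]
        else:
            l = build(payload[0])
            r = build(payload[1])
            i = counter[0]
            counter[0] += 1
            left[i], right[i] = l, r
            parent[l] = parent[r] = i
            postorder.append(i)
        blen[i] = length
        return i

    root = build(reduced)
    blen[root] = 0.0
    tree = Phylogeny(
        tip_labels=tuple(labels),
        parent=parent,
        left=left,
        right=right,
        blen=blen,
        postorder=np.array(postorder, dtype=np.int64),
    )
    states = {labels[tip_ids[id(ln)]]: int(obs_index[ln.state]) for ln in tips}
    return tree, states


def simulate_bisse_tree(config: SimConfig) -> SimReplicate:
    """Simulate one replicate; rejects and resimulates until the pruned tree
    keeps at least ``min_surviving_tips`` extant tips (and, under an
    ``n_tips`` stopping rule, exactly reaches the target)."""
    rng = np.random.default_rng(config.seed)
    params = config.params
    obs_index = np.tile(np.array([0, 1]), params.n_hidden)
    pi = _stationary_frequencies(params.Q)
    kind, value = config.stop
    for attempt in range(1, config.max_attempts + 1):
        root_state = (
            config.root_state
            if config.root_state is not None
            else int(rng.choice(params.n_combined, p=pi))
        )
        result, _ = _attempt(params, config.stop, root_state, rng)
        if result is None:
            continue
        root, extant, present = result
        if kind == "n_tips" and len(extant) < int(value):
            continue
        if len(extant) < config.min_surviving_tips:
            continue
        survivors = {id(ln) for ln in extant}
        reduced = _reduce(root, present, survivors)
        if reduced is None or reduced[0] == "tip":
            continue
        tree, states = _build_phylogeny(reduced, obs_index)
        if tree.n_tips < config.min_surviving_tips:
            continue
        return SimReplicate(tree, states, params, config.seed, attempt)
    raise SimulationAbortError(
        f"no surviving replicate in {config.max_attempts} attempts; "
        "survival probability too low under these parameters"
    )


def simulate_mk_traits(
    tree: Phylogeny,
    q01: float,
    q10: float,
    root_state: int | None = None,
    seed: int = 0,
) -> dict[str, int]:
    """Forward-simulate a binary character along a fixed tree.

    ``root_state=None`` draws the root from the stationary distribution
    (q01/(q01+q10) mass on state 1).
    """
    if q01 < 0 or q10 < 0:
        raise InputError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    rates = (q01, q10)
    if root_state is None:
        s = q01 + q10
        p1 = q01 / s if s > 0 else 0.5
        root_state = int(rng.random() < p1)
    states = np.empty(tree.n_nodes, dtype=np.int64)
    states[tree.root] = root_state
    for node in tree.postorder[::-1]:
        for child in (tree.left[node], tree.right[node]):
            s = states[node]
            remaining = float(tree.blen[child])
            while True:
                rate = rates[s]
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if wait >= remaining:
                    break
                remaining -= wait
                s = 1 - s
            states[child] = s
    return {tree.tip_labels[i]: int(states[i]) for i in range(tree.n_tips)}


def prune_to_tips(tree: Phylogeny, keep_labels) -> Phylogeny:
    """Subtree induced by ``keep_labels`` (unifurcations collapsed)."""
    keep = set(keep_labels)
    unknown = keep - set(tree.tip_labels)
    if unknown:
        raise InputError(f"labels not in tree: {sorted(unknown)}")
    if len(keep) < 2:
        raise InputError("need at least two tips to keep")

    def rec(node):
        if tree.is_tip(node):
            if tree.tip_labels[node] in keep:
                return (tree.tip_labels[node], float(tree.blen[node]))
            return None
        subs = [rec(int(c)) for c in (tree.left[node], tree.right[node])]
        subs = [s for s in subs if s is not None]
        if not subs:
            return None
        if len(subs) == 1:
            payload, blen = subs[0]
            return (payload, blen + float(tree.blen[node]))
        return (subs, float(tree.blen[node]))

    reduced = rec(tree.root)
    labels = sorted(keep)
    tip_idx = {lab: i for i, lab in enumerate(labels)}
    n_tips = len(labels)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    blen = np.zeros(n_nodes)
    postorder = []
    counter = [n_tips]

    def build(entry):
        payload, length = entry
        if isinstance(payload, str):
            i = tip_idx[payload]
        else:
            l = build(payload[0])
            r = build(payload[1])
            i = counter[0]
            counter[0] += 1
            left[i], right[i] = l, r
            parent[l] = parent[r] = i
            postorder.append(i)
        blen[i] = length
        return i

    root = build(reduced)
    blen[root] = 0.0
    return Phylogeny(
        tip_labels=tuple(labels),
        parent=parent,
        left=left,
        right=right,
        blen=blen,
        postorder=np.array(postorder, dtype=np.int64),
    )


def state_specific_rho(
    n0_kept: int, n1_kept: int, total_richness: int, f: float
) -> SamplingFractions:
    """Per-state sampling fractions given an assumed unsampled composition.

    Of the ``total_richness - kept`` unsampled species, a fraction ``f`` is
    assumed to carry the accessible state (0):
    ``rho_0 = n0 / (n0 + f N_u)``, ``rho_1 = n1 / (n1 + (1 - f) N_u)``.
    """
    if not 0.0 <= f <= 1.0:
        raise InputError(f"f must lie in [0, 1], got {f}")
    n_unsampled = total_richness - (n0_kept + n1_kept)
    if n_unsampled < 0:
        raise InfeasibleSamplingError(
            f"kept {n0_kept + n1_kept} tips exceed total richness {total_richness}"
        )
    rho0 = n0_kept / (n0_kept + f * n_unsampled)
    rho1 = n1_kept / (n1_kept + (1.0 - f) * n_unsampled)
    if rho0 <= 0 or rho1 <= 0:
        raise InfeasibleSamplingError("a state has no sampled species")
    return SamplingFractions(rho=np.array([rho0, rho1]), f=f)


def apply_incomplete_sampling(
    rep: SimReplicate,
    total_richness: int,
    f: float,
    n_keep: int,
    seed: int = 0,
) -> tuple[SimReplicate, SamplingFractions]:
    """Prune a replicate down to ``n_keep`` tips with unsampled composition f.

    The tips removed are chosen so that a fraction ``f`` of the
    ``total_richness - n_keep`` unsampled species carries state 0
    (accessible); the returned per-state sampling fractions follow the
    :func:`state_specific_rho` formula with the realised kept counts.
    """
    if rep.tree.n_tips < n_keep:
        raise InfeasibleSamplingError(
            f"replicate has {rep.tree.n_tips} tips < n_keep={n_keep}"
        )
    rng = np.random.default_rng(seed)
    labels0 = [l for l, s in rep.tip_states.items() if s == 0]
    labels1 = [l for l, s in rep.tip_states.items() if s == 1]
    n_prune = rep.tree.n_tips - n_keep
    n0_prune = int(round(f * n_prune))
    n1_prune = n_prune - n0_prune
    if n0_prune > len(labels0) or n1_prune > len(labels1):
        raise InfeasibleSamplingError(
            "requested unsampled composition infeasible: "
            f"need to drop {n0_prune} state-0 and {n1_prune} state-1 tips "
            f"but replicate has {len(labels0)}/{len(labels1)}"
        )
    drop = set(rng.choice(labels0, size=n0_prune, replace=False)) | set(
        rng.choice(labels1, size=n1_prune, replace=False)
    )
    keep = [l for l in rep.tree.tip_labels if l not in drop]
    pruned = prune_to_tips(rep.tree, keep)
    states = {l: rep.tip_states[l] for l in keep}
    n0 = sum(1 for s in states.values() if s == 0)
    n1 = len(states) - n0
    fractions = state_specific_rho(n0, n1, total_richness, f)
    return (
        SimReplicate(pruned, states, rep.true_params, rep.seed, rep.n_attempts),
        fractions,
    )


# ----------------------------------------------------------------------
# synthetic pollen tables
# ----------------------------------------------------------------------
def default_catalog_template() -> PollenCatalog:
    """Small catalog spanning accessible and restricted host families."""
    entries = {
        "Ast-Centaurea": CatalogEntry("Asteraceae", "accessible", "Centaurea"),
        "Ast-Helianthus": CatalogEntry("Asteraceae", "accessible", "Helianthus"),
        "Mal-Malva": CatalogEntry("Malvaceae", "accessible", "Malva"),
        "Cuc-Cucurbita": CatalogEntry("Cucurbitaceae", "accessible", "Cucurbita"),
        "Fab-Trifolium": CatalogEntry("Fabaceae", "restricted", "Trifolium"),
        "Fab-Vicia": CatalogEntry("Fabaceae", "restricted", "Vicia"),
        "Lam-Salvia": CatalogEntry("Lamiaceae", "restricted", "Salvia"),
        "Bor-Echium": CatalogEntry("Boraginaceae", "restricted", "Echium"),
    }
    return PollenCatalog(entries)


def generate_synthetic_pollen_dataset(
    true_states: dict[str, str],
    n_samples_range: tuple[int, int] = (1, 22),
    contamination_max: float = 0.049,
    seed: int = 0,
    catalog: PollenCatalog | None = None,
) -> tuple[list[PollenSample], PollenCatalog]:
    """Generate pollen tables whose coding provably recovers ``true_states``.

    Per species: a uniform number of sample replicates in
    ``n_samples_range``; per sample, the reward-category split matches the
    true state (pure for A/R; for AR both categories get at least 0.25
    before contamination), within-category proportions are Dirichlet over
    one or two pollen types, and with probability 0.7 one opposite-category
    contaminant type is added at a share capped strictly below the 5%
    per-sample exclusion rule, so filtering removes it by construction.
    """
    if not 0 <= contamination_max < 0.05:
        raise InputError(
            "contamination_max must stay below the 0.05 minor-type filter "
            "for guaranteed recovery"
        )
    if catalog is None:
        catalog = default_catalog_template()
    acc_types = [t for t, e in catalog.items() if e.accessibility == "accessible"]
    res_types = [t for t, e in catalog.items() if e.accessibility == "restricted"]
    if len(acc_types) < 2 or len(res_types) < 2:
        raise InputError("catalog template needs >= 2 accessible and 2 restricted types")
    rng = np.random.default_rng(seed)
    lo, hi = n_samples_range
    samples: list[PollenSample] = []

    def category_mix(pool, share):
        n_types = 1 if share < 0.12 or rng.random() < 0.3 else 2
        chosen = rng.choice(pool, size=n_types, replace=False)
        if n_types == 1:
            return {str(chosen[0]): share}
        w = rng.dirichlet([6.0, 6.0])
        return {str(t): share * wi for t, wi in zip(chosen, w)}

    for species, state in true_states.items():
        if state not in ("A", "R", "AR"):
            raise InputError(f"true state for {species!r} must be A, R or AR")
        n_samples = int(rng.integers(lo, hi + 1))
        for j in range(n_samples):
            comp: dict[str, float] = {}
            if state == "AR":
                s_acc = 0.25 + 0.5 * rng.beta(5.0, 5.0)
                comp.update(category_mix(acc_types, s_acc))
                comp.update(category_mix(res_types, 1.0 - s_acc))
            else:
                pool = acc_types if state == "A" else res_types
                comp.update(category_mix(pool, 1.0))
            if contamination_max > 0 and rng.random() < 0.7:
                other = res_types if state == "A" else acc_types
                cont = str(rng.choice(other))
                while cont in comp:
                    cont = str(rng.choice(other))
                c = rng.uniform(0.005, contamination_max)
                comp = {t: v * (1.0 - c) for t, v in comp.items()}
                comp[cont] = c
            samples.append(
                PollenSample(
                    species=species,
                    sample_id=f"{species}_s{j + 1}",
                    load_weight=float(rng.integers(1, 6)),
                    composition={t: 100.0 * v for t, v in comp.items()},
                )
            )
    return samples, catalog


def samples_to_frame(samples: list[PollenSample]):
    """Long-format DataFrame (CSV-ready; deterministic row order)."""
    import pandas as pd

    rows = []
    for s in samples:
        for t in sorted(s.composition):
            rows.append(
                {
                    "species": s.species,
                    "sample_id": s.sample_id,
                    "load_weight": s.load_weight,
                    "pollen_type": t,
                    "percent": s.composition[t],
                }
            )
    return pd.DataFrame(rows)
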