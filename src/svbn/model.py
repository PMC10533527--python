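"""Discrete Bayesian networks: BIC scoring, exact structure search, fitting.

The structure score is the decomposable BIC in natural-log units,

    score(G) = sum_v [ LL_hat(v | pa(v)) - 0.5 * ln(N) * k_v ],

where ``LL_hat`` is the maximized multinomial log-likelihood of each child
given its parent configurations and ``k_v = (|states(v)| - 1) * prod
|states(pa)|`` counts free parameters.  Larger is better.  The globally
optimal DAG under a parent-count cap is found by dynamic programming over
variable subsets (best parent set per (node, candidate set), then best sink
per subset, then order reconstruction) — exact, not heuristic, so the result
provably attains the maximum score over all DAGs respecting the cap.

Parameters are Dirichlet posterior means: ``(count + alpha) / (total +
alpha * |states|)`` with a uniform prior weight ``alpha`` (pseudocount);
``alpha = 0`` gives the pure MLE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import DiscreteCohort

__all__ = [
    "DAGStructure",
    "FamilyScore",
    "BayesianNetwork",
    "ModelError",
    "family_score_bic",
    "network_score",
    "exact_structure_search",
    "fit_parameters",
    "learn_network",
    "save_network",
    "load_network",
]

MAX_EXACT_NODES = 20

# scores within this of each other are treated as tied by the search
# (Markov-equivalent DAGs have mathematically equal BIC but their
# log-likelihoods are accumulated in different orders)
SCORE_TIE_TOL = 1e-9


class ModelError(Exception):
    """Invalid structure, score request, or fit configuration."""


@dataclass(frozen=True)
class DAGStructure:
    """Node list with state sets plus a parent map; acyclicity is enforced."""

    nodes: tuple[str, ...]
    state_sets: Mapping[str, tuple[str, ...]]
    parents: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        declared = set(self.nodes)
        for child, pars in self.parents.items():
            if child not in declared:
                raise ModelError(f"parent map references undeclared node {child!r}")
            for p in pars:
                if p not in declared:
                    raise ModelError(f"undeclared parent {p!r} of {child!r}")
            if child in pars:
                raise ModelError(f"node {child!r} is its own parent")
        self.topological_order()  # raises on cycles

    def parent_tuple(self, node: str) -> tuple[str, ...]:
        return tuple(sorted(self.parents.get(node, ())))

    def edges(self) -> list[tuple[str, str]]:
        return sorted(
            (p, c) for c in self.nodes for p in self.parents.get(c, ())
        )

    def n_edges(self) -> int:
        return sum(len(self.parents.get(c, ())) for c in self.nodes)

    def topological_order(self) -> list[str]:
        indeg = {v: len(self.parents.get(v, ())) for v in self.nodes}
        children: dict[str, list[str]] = {v: [] for v in self.nodes}
        for c in self.nodes:
            for p in self.parents.get(c, ()):
                children[p].append(c)
        ready = sorted(v for v, d in indeg.items() if d == 0)
        order: list[str] = []
        while ready:
            v = ready.pop(0)
            order.append(v)
            newly = []
            for c in children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    newly.append(c)
            ready = sorted(ready + newly)
        if len(order) != len(self.nodes):
            raise ModelError("structure contains a cycle")
        return order


@dataclass(frozen=True)
class FamilyScore:
    """BIC decomposition element for one (child, parent-set) family."""

    child: str
    parents: tuple[str, ...]
    loglik: float
    n_params: int
    n_obs: int
    bic: float


@dataclass
class BayesianNetwork:
    """Fitted network: structure + one CPT per node.

    ``cpts[v]`` has shape ``(prod parent-state-counts, |states(v)|)``; rows
    enumerate parent configurations lexicographically with parents sorted by
    name (first parent most significant).  Every row sums to 1.
    """

    structure: DAGStructure
    cpts: dict[str, np.ndarray]
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        for v in self.structure.nodes:
            cpt = self.cpts[v]
            n_rows = 1
            for p in self.structure.parent_tuple(v):
                n_rows *= len(self.structure.state_sets[p])
            if cpt.shape != (n_rows, len(self.structure.state_sets[v])):
                raise ModelError(
                    f"CPT for {v!r} has shape {cpt.shape}, expected "
                    f"({n_rows}, {len(self.structure.state_sets[v])})"
                )
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-12):
                raise ModelError(f"CPT rows for {v!r} do not sum to 1")
            if (cpt < 0).any() or (cpt > 1).any():
                raise ModelError(f"CPT entries for {v!r} outside [0, 1]")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.structure.nodes

    def states(self, node: str) -> tuple[str, ...]:
        return self.structure.state_sets[node]

    def parent_config_index(self, node: str, assignment: Mapping[str, str]) -> int:
        """Row index of the CPT for the given parent states."""
        idx = 0
        for p in self.structure.parent_tuple(node):
            states = self.structure.state_sets[p]
            idx = idx * len(states) + states.index(assignment[p])
        return idx


def _encode(cohort: DiscreteCohort, names: Sequence[str]) -> tuple[np.ndarray, list[int]]:
    codes = cohort.codes(names)
    cards = [len(cohort.state_sets[n]) for n in names]
    return codes, cards


def _family_loglik(
    child_codes: np.ndarray,
    parent_codes: np.ndarray | None,
    child_card: int,
    parent_cards: Sequence[int],
) -> float:
    """Maximized multinomial log-likelihood with the 0*ln(0) = 0 convention."""
    if parent_codes is None or parent_codes.shape[1] == 0:
        counts = np.bincount(child_codes, minlength=child_card).astype(float)
        n = counts.sum()
        nz = counts > 0
        return float(np.sum(counts[nz] * (np.log(counts[nz]) - np.log(n))))
    config = np.zeros(len(child_codes), dtype=np.int64)
    for j, card in enumerate(parent_cards):
        config = config * card + parent_codes[:, j]
    n_config = int(np.prod(parent_cards))
    flat = config * child_card + child_codes
    counts = np.bincount(flat, minlength=n_config * child_card).astype(float)
    counts = counts.reshape(n_config, child_card)
    row_tot = counts.sum(axis=1, keepdims=True)
    nz = counts > 0
    terms = np.zeros_like(counts)
    # 0 * ln(0) == 0 convention: only positive counts contribute
    terms[nz] = counts[nz] * (
        np.log(counts[nz]) - np.log(np.broadcast_to(row_tot, counts.shape)[nz])
    )
    return float(terms.sum())


def family_score_bic(
    child: str, parents: Sequence[str], cohort: DiscreteCohort
) -> FamilyScore:
    """BIC score of one family: ``loglik - 0.5 * ln(N) * n_params``."""
    parents = tuple(sorted(parents))
    if child in parents:
        raise ModelError(f"child {child!r} appears among its parents")
    for name in (child, *parents):
        if name not in cohort.state_sets:
            raise ModelError(f"variable {name!r} not in cohort")
    n = cohort.n_subjects
    if n == 0:
        raise ModelError("empty cohort")
    child_card = len(cohort.state_sets[child])
    parent_cards = [len(cohort.state_sets[p]) for p in parents]
    codes, _ = _encode(cohort, [child, *parents])
    loglik = _family_loglik(
        codes[:, 0], codes[:, 1:] if parents else None, child_card, parent_cards
    )
    n_params = (child_card - 1) * int(np.prod(parent_cards)) if parents else child_card - 1
    bic = loglik - 0.5 * np.log(n) * n_params
    return FamilyScore(
        child=child,
        parents=parents,
        loglik=loglik,
        n_params=n_params,
        n_obs=n,
        bic=float(bic),
    )


def network_score(structure: DAGStructure, cohort: DiscreteCohort) -> float:
    """Decomposable network BIC: sum of family scores (raises on cycles)."""
    structure.topological_order()
    return float(
        sum(
            family_score_bic(v, structure.parent_tuple(v), cohort).bic
            for v in structure.nodes
        )
    )


def _all_family_scores(
    cohort: DiscreteCohort, names: Sequence[str], max_parents: int
) -> list[dict[int, float]]:
    """scores[i][parent_mask] = BIC of family (names[i] | parents in mask).

    Masks are bitmasks over ``names``; only masks with popcount <= max_parents
    and not containing bit i are present.
    """
    n = len(names)
    codes, cards = _encode(cohort, names)
    n_obs = len(codes)
    log_n = np.log(n_obs)
    scores: list[dict[int, float]] = [dict() for _ in range(n)]
    others = lambda i: [j for j in range(n) if j != i]  # noqa: E731
    for i in range(n):
        child_card = cards[i]
        child_codes = codes[:, i]
        for k in range(0, max_parents + 1):
            for combo in combinations(others(i), k):
                mask = 0
                for j in combo:
                    mask |= 1 << j
                parent_cards = [cards[j] for j in combo]
                ll = _family_loglik(
                    child_codes,
                    codes[:, list(combo)] if combo else None,
                    child_card,
                    parent_cards,
                )
                n_params = (child_card - 1) * int(np.prod(parent_cards)) if combo else child_card - 1
                scores[i][mask] = ll - 0.5 * log_n * n_params
    return scores


def exact_structure_search(
    cohort: DiscreteCohort,
    max_parents: int = 3,
    *,
    node_order: Sequence[str] | None = None,
) -> DAGStructure:
    """Globally optimal DAG under the BIC, by subset dynamic programming.

    Ties (within ``SCORE_TIE_TOL``) are broken toward fewer parents per
    family, then lexicographically smaller parent sets, then the
    lexicographically smaller sink during order reconstruction; the result is
    deterministic and independent of row order.
    """
    names = sorted(cohort.state_sets) if node_order is None else list(node_order)
    n = len(names)
    if n > MAX_EXACT_NODES:
        raise ModelError(
            f"{n} nodes exceeds the exact-search guard ({MAX_EXACT_NODES}); "
            "select a variable subset"
        )
    if max_parents < 0:
        raise ModelError("max_parents must be nonnegative")
    if cohort.n_subjects == 0:
        raise ModelError("empty cohort")
    max_parents = min(max_parents, n - 1) if n > 1 else 0

    if n == 1:
        return DAGStructure(
            nodes=tuple(names),
            state_sets=dict(cohort.state_sets),
            parents={names[0]: ()},
        )

    fam = _all_family_scores(cohort, names, max_parents)

    # Stage 1: best parent set per (node, candidate set).  bps[i][S] = best
    # score of a parent set for node i drawn from candidate set S (bitmask,
    # bit i never in S); bps_set[i][S] = that parent set's mask.
    full = (1 << n) - 1
    bps: list[np.ndarray] = []
    bps_set: list[np.ndarray] = []
    for i in range(n):
        best = np.full(1 << n, -np.inf)
        best_set = np.zeros(1 << n, dtype=np.int64)
        cand_all = full & ~(1 << i)
        # iterate candidate sets in increasing popcount so subsets are done
        subsets_by_size: list[list[int]] = [[] for _ in range(n)]
        s = cand_all
        # enumerate all subsets of cand_all
        sub = 0
        while True:
            subsets_by_size[bin(sub).count("1")].append(sub)
            if sub == cand_all:
                break
            sub = (sub - cand_all) & cand_all
        for size in range(n):
            for S in subsets_by_size[size]:
                cur_score = fam[i].get(S, -np.inf) if bin(S).count("1") <= max_parents else -np.inf
                cur_set = S
                # best over proper subsets: remove one element at a time
                T = S
                while T:
                    low = T & (-T)
                    sub_mask = S & ~low
                    sc = best[sub_mask]
                    st = best_set[sub_mask]
                    if sc > cur_score + SCORE_TIE_TOL:
                        cur_score, cur_set = sc, st
                    elif sc > cur_score - SCORE_TIE_TOL:
                        # tie: prefer fewer parents, then lexicographically
                        # smaller mask (lower-indexed names first)
                        pc_new, pc_cur = bin(st).count("1"), bin(cur_set).count("1")
                        if pc_new < pc_cur or (pc_new == pc_cur and st < cur_set):
                            cur_score, cur_set = sc, st
                    T &= T - 1
                best[S] = cur_score
                best_set[S] = cur_set
        bps.append(best)
        bps_set.append(best_set)

    # Stage 2: best network over each subset; sink = last node in the order.
    net_score = np.full(1 << n, -np.inf)
    net_sink = np.full(1 << n, -1, dtype=np.int64)
    net_score[0] = 0.0
    for S in range(1, 1 << n):
        best_sc, best_i = -np.inf, -1
        T = S
        while T:
            low = T & (-T)
            i = low.bit_length() - 1
            rest = S & ~low
            sc = net_score[rest] + bps[i][rest]
            if sc > best_sc + SCORE_TIE_TOL or (
                sc > best_sc - SCORE_TIE_TOL and best_i != -1 and i < best_i
            ):
                best_sc, best_i = sc, i
            elif best_i == -1:
                best_sc, best_i = sc, i
            T &= T - 1
        net_score[S] = best_sc
        net_sink[S] = best_i

    # Reconstruct: peel sinks off the full set.
    parents: dict[str, tuple[str, ...]] = {}
    S = full
    while S:
        i = int(net_sink[S])
        rest = S & ~(1 << i)
        pset = int(bps_set[i][rest])
        parents[names[i]] = tuple(
            sorted(names[j] for j in range(n) if pset & (1 << j))
        )
        S = rest

    return DAGStructure(
        nodes=tuple(names),
        state_sets=dict(cohort.state_sets),
        parents=parents,
    )


def fit_parameters(
    structure: DAGStructure,
    cohort: DiscreteCohort,
    pseudocount: float = 1.0,
) -> BayesianNetwork:
    """Dirichlet posterior-mean CPTs: (count + a) / (total + a * |states|).

    ``pseudocount = 0`` gives the pure MLE and raises if any parent
    configuration is unobserved (the row would be undefined).
    """
    if pseudocount < 0:
        raise ModelError("pseudocount must be nonnegative")
    if set(structure.nodes) != set(cohort.state_sets):
        raise ModelError("structure nodes do not match cohort columns")
    cpts: dict[str, np.ndarray] = {}
    for v in structure.nodes:
        pars = structure.parent_tuple(v)
        child_card = len(structure.state_sets[v])
        parent_cards = [len(structure.state_sets[p]) for p in pars]
        n_config = int(np.prod(parent_cards)) if pars else 1
        codes, _ = _encode(cohort, [v, *pars])
        config = np.zeros(cohort.n_subjects, dtype=np.int64)
        for j, card in enumerate(parent_cards):
            config = config * card + codes[:, 1 + j]
        flat = config * child_card + codes[:, 0]
        counts = np.bincount(flat, minlength=n_config * child_card).astype(float)
        counts = counts.reshape(n_config, child_card)
        totals = counts.sum(axis=1, keepdims=True)
        if pseudocount == 0:
            if (totals == 0).any():
                raise ModelError(
                    f"unseen parent configuration for {v!r} with pseudocount 0"
                )
            cpt = counts / totals
        else:
            cpt = (counts + pseudocount) / (totals + pseudocount * child_card)
        cpts[v] = cpt
    return BayesianNetwork(structure=structure, cpts=cpts, pseudocount=pseudocount)


@dataclass(frozen=True)
class LearnerConfig:
    """Learning configuration shared by search-and-fit call sites."""

    max_parents: int = 3
    pseudocount: float = 1.0


def learn_network(
    cohort: DiscreteCohort, config: LearnerConfig | None = None
) -> BayesianNetwork:
    """Exact structure search followed by parameter fitting."""
    config = config or LearnerConfig()
    structure = exact_structure_search(cohort, max_parents=config.max_parents)
    return fit_parameters(structure, cohort, pseudocount=config.pseudocount)


def network_to_dict(net: BayesianNetwork) -> dict:
    return {
        "nodes": [
            {
                "name": v,
                "states": list(net.structure.state_sets[v]),
                "parents": list(net.structure.parent_tuple(v)),
                "cpt": [[float(x) for x in row] for row in net.cpts[v]],
            }
            for v in net.structure.nodes
        ],
        "pseudocount": net.pseudocount,
    }


def network_from_dict(d: Mapping) -> BayesianNetwork:
    nodes = tuple(nd["name"] for nd in d["nodes"])
    state_sets = {nd["name"]: tuple(nd["states"]) for nd in d["nodes"]}
    parents = {nd["name"]: tuple(nd["parents"]) for nd in d["nodes"]}
    structure = DAGStructure(nodes=nodes, state_sets=state_sets, parents=parents)
    cpts = {nd["name"]: np.array(nd["cpt"], dtype=float) for nd in d["nodes"]}
    return BayesianNetwork(
        structure=structure, cpts=cpts, pseudocount=float(d.get("pseudocount", 0.0))
    )


def save_network(net: BayesianNetwork, path: str | Path) -> None:
    """JSON serialization; CPT rows in the documented lexicographic order."""
    Path(path).write_text(json.dumps(network_to_dict(net), indent=2) + "\n")


def load_network(path: str | Path) -> BayesianNetwork:
    return network_from_dict(json.loads(Path(path).read_text()))
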