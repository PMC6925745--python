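"""Score-based structure learning: greedy hill-climbing over
add/delete/reverse edge moves maximizing the BIC score.

BIC(G) = log-likelihood(data | G, MLE) - (log n / 2) * free parameters,
which decomposes over node families, so each move is scored locally and
family scores are cached. The search is deterministic given the seed:
candidate moves are enumerated in sorted order and the best strictly
improving move is applied; random restarts perturb the starting graph.
"""

from __future__ import annotations

import numpy as np

from ..survey import SurveyTable
from .dag import Dag
from .fit import _family_counts, encode_table


class _FamilyScorer:
    """Cached decomposable BIC family scores on an encoded data matrix."""

    def __init__(self, data: np.ndarray, cards: np.ndarray):
        self.data = data
        self.cards = cards
        self.n = data.shape[0]
        self.log_n = np.log(max(self.n, 1))
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def family_score(self, child: int, parents: tuple[int, ...]) -> float:
        key = (child, tuple(sorted(parents)))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        counts = _family_counts(self.data, self.cards, child, key[1])
        totals = counts.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            ll = counts * (np.log(counts) - np.log(totals))
        loglik = float(np.nansum(ll))
        k = int(self.cards[child])
        n_conf = int(np.prod([self.cards[p] for p in key[1]], dtype=np.int64))
        penalty = 0.5 * self.log_n * n_conf * (k - 1)
        score = loglik - penalty
        self._cache[key] = score
        return score


def bic_score(table: SurveyTable, dag: Dag) -> float:
    """BIC of a DAG on a survey table (MLE plug-in log-likelihood)."""
    data, cards, nodes = encode_table(table, dag.nodes)
    pos = {node: j for j, node in enumerate(nodes)}
    scorer = _FamilyScorer(data, cards)
    return sum(
        scorer.family_score(pos[v], tuple(pos[p] for p in dag.parents(v)))
        for v in dag.nodes
    )


def _hill_climb(
    dag: Dag,
    scorer: _FamilyScorer,
    pos: dict,
    max_parents: int,
    forbidden: set[tuple],
    required: set[tuple],
    tol: float = 1e-9,
) -> Dag:
    nodes = dag.nodes

    def fam(v, parents):
        return scorer.family_score(pos[v], tuple(pos[p] for p in parents))

    while True:
        best_delta, best_move = tol, None
        for u in nodes:
            for v in nodes:
                if u == v:
                    continue
                if dag.has_edge(u, v):
                    base_v = fam(v, dag.parents(v))
                    others = [p for p in dag.parents(v) if p != u]
                    if (u, v) not in required:
                        delta = fam(v, others) - base_v
                        if delta > best_delta:
                            best_delta, best_move = delta, ("del", u, v)
                    # reverse u->v to v->u
                    if (
                        (u, v) not in required
                        and (v, u) not in forbidden
                        and len(dag.parents(u)) < max_parents
                    ):
                        dag.remove_edge(u, v)
                        ok = not dag.would_cycle(v, u)
                        dag.add_edge(u, v)
                        if ok:
                            delta = (
                                fam(v, others)
                                - base_v
                                + fam(u, dag.parents(u) + [v])
                                - fam(u, dag.parents(u))
                            )
                            if delta > best_delta:
                                best_delta, best_move = delta, ("rev", u, v)
                elif (
                    (u, v) not in forbidden
                    and len(dag.parents(v)) < max_parents
                    and not dag.would_cycle(u, v)
                ):
                    delta = fam(v, dag.parents(v) + [u]) - fam(v, dag.parents(v))
                    if delta > best_delta:
                        best_delta, best_move = delta, ("add", u, v)
        if best_move is None:
            return dag
        op, u, v = best_move
        if op == "add":
            dag.add_edge(u, v)
        elif op == "del":
            dag.remove_edge(u, v)
        else:
            dag.remove_edge(u, v)
            dag.add_edge(v, u)


def learn_structure(
    table: SurveyTable,
    score: str = "bic",
    max_parents: int = 3,
    seed: int = 0,
    restarts: int = 1,
    nodes: list[str] | None = None,
    whitelist: list[tuple] | None = None,
    blacklist: list[tuple] | None = None,
) -> Dag:
    """Learn a DAG by BIC hill-climbing with random restarts.

    ``whitelist`` edges are forced into every candidate graph and never
    removed; ``blacklist`` edges are never added. The best-scoring graph
    over all restarts is returned; deterministic given ``seed``.
    """
    if score != "bic":
        raise ValueError(f"unsupported score {score!r}")
    if max_parents < 0:
        raise ValueError("max_parents must be >= 0")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if table.n < 1:
        raise ValueError("cannot learn structure from an empty table")
    data, cards, node_list = encode_table(table, nodes)
    pos = {node: j for j, node in enumerate(node_list)}
    scorer = _FamilyScorer(data, cards)
    required = set(tuple(e) for e in (whitelist or []))
    forbidden = set(tuple(e) for e in (blacklist or []))
    if required & forbidden:
        raise ValueError("edge both white- and blacklisted")

    def total(dag: Dag) -> float:
        return sum(
            scorer.family_score(pos[v], tuple(pos[p] for p in dag.parents(v)))
            for v in dag.nodes
        )

    best_dag, best_score = None, -np.inf
    for r in range(restarts):
        start = Dag(node_list, sorted(required))
        if r > 0:
            rng = np.random.default_rng([int(seed), r])
            order = list(rng.permutation(len(node_list)))
            for _ in range(len(node_list)):
                i, j = rng.integers(0, len(node_list), size=2)
                if order.index(i) >= order.index(j) or i == j:
                    continue
                u, v = node_list[i], node_list[j]
                if (
                    not start.has_edge(u, v)
                    and (u, v) not in forbidden
                    and len(start.parents(v)) < max_parents
                    and not start.would_cycle(u, v)
                ):
                    start.add_edge(u, v)
        result = _hill_climb(start, scorer, pos, max_parents, forbidden, required)
        s = total(result)
        if s > best_score:
            best_dag, best_score = result, s
    return best_dag
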