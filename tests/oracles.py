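"""Independent brute-force oracles used to check the package's
implementations. These deliberately avoid the library's factor/variable-
elimination code path: joints are enumerated assignment by assignment,
and AUC comes from the rank-statistic identity."""

from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import rankdata

from accidentbn.bn.model import DiscreteBN, index_to_code
from accidentbn.codebook import Codebook, VariableDef


def all_assignments(bn: DiscreteBN):
    """Every full assignment {node: stored code} of a small network."""
    nodes = bn.dag.nodes
    cards = [bn.cardinality(v) for v in nodes]
    for combo in itertools.product(*(range(c) for c in cards)):
        yield {
            v: index_to_code(bn.codebook[v], i) for v, i in zip(nodes, combo)
        }


def enumerate_joint(bn: DiscreteBN, assignment: dict) -> float:
    """Joint probability of one full assignment, by direct CPT lookup."""
    prob = 1.0
    for node in bn.dag.nodes:
        cpt = bn.cpts[node]
        var = bn.codebook[node]
        idx = []
        for s in cpt.scope:
            svar = bn.codebook[s]
            code = assignment[s]
            idx.append(svar.n_categories if code == 0 else code - 1)
        prob *= float(cpt.table[tuple(idx)])
    return prob


def brute_posterior(bn: DiscreteBN, target: str, evidence: dict) -> np.ndarray:
    """Posterior over the target's axis by renormalized full enumeration."""
    card = bn.cardinality(target)
    out = np.zeros(card)
    for assignment in all_assignments(bn):
        if any(assignment[v] != c for v, c in evidence.items()):
            continue
        tvar = bn.codebook[target]
        code = assignment[target]
        idx = tvar.n_categories if code == 0 else code - 1
        out[idx] += enumerate_joint(bn, assignment)
    total = out.sum()
    if total == 0:
        raise ZeroDivisionError("impossible evidence")
    return out / total


def mann_whitney_auc(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic with half-credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    ranks = rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def toy_codebook(cards: list[int], prefix: str = "X") -> Codebook:
    """A synthetic codebook of plain categorical variables."""
    variables = [
        VariableDef(
            id=f"{prefix}{i + 1}",
            label=f"synthetic variable {i + 1}",
            group="demographics",
            categories=tuple(f"c{j + 1}" for j in range(card)),
        )
        for i, card in enumerate(cards)
    ]
    return Codebook(variables, name="toy")


def random_bn(rng: np.random.Generator, n_nodes: int, max_card: int = 4):
    """A random small network with random DAG and Dirichlet CPTs."""
    from accidentbn.bn.dag import Dag
    from accidentbn.bn.model import Cpt, DiscreteBN

    cards = rng.integers(2, max_card + 1, size=n_nodes).tolist()
    codebook = toy_codebook(cards)
    ids = codebook.ids
    dag = Dag(ids)
    for j in range(n_nodes):
        for i in range(j):
            if rng.random() < 0.4:
                dag.add_edge(ids[i], ids[j])
    cpts = {}
    for j, node in enumerate(ids):
        parents = tuple(dag.parents(node))
        shape = tuple(cards[ids.index(p)] for p in parents) + (cards[j],)
        table = rng.dirichlet(np.ones(cards[j]), size=shape[:-1] or (1,))
        table = table.reshape(shape)
        cpts[node] = Cpt(node, parents, table)
    return DiscreteBN(codebook, dag, cpts)
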