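"""CPT estimation from survey data.

Counts are multinomial per parent configuration; the estimator is
maximum likelihood with an optional Laplace pseudo-count:

    P(child=c | parents=pi) = (N(c, pi) + a) / (N(pi) + a*K_child)

With ``pseudo_count=0`` an unseen parent configuration falls back to a
uniform row. DK/NA is an ordinary extra category for variables that
declare it, so no rows are discarded during counting.
"""

from __future__ import annotations

import numpy as np

from ..survey import SurveyTable
from .dag import Dag
from .model import Cpt, DiscreteBN


def encode_table(table: SurveyTable, nodes: list[str] | None = None):
    """Encode survey columns as a 0-based integer matrix.

    Returns ``(data, cards, node_list)`` where ``data`` is an
    (n, len(nodes)) int matrix of axis indices and ``cards`` the
    per-variable cardinalities (DK/NA counted where declared).
    """
    nodes = list(nodes) if nodes is not None else table.codebook.ids
    n = table.n
    data = np.empty((n, len(nodes)), dtype=np.int64)
    cards = np.empty(len(nodes), dtype=np.int64)
    for j, node in enumerate(nodes):
        var = table.codebook[node]
        col = table.column(node)
        # vectorised code->index: 1..K -> 0..K-1, DK/NA sentinel -> K
        enc = col - 1
        if var.dkna:
            enc = np.where(col == 0, var.n_categories, enc)
        elif (col == 0).any():
            raise ValueError(f"{node}: DK/NA present but not declared")
        data[:, j] = enc
        cards[j] = table.codebook.cardinality(node)
    return data, cards, nodes


def _family_counts(
    data: np.ndarray, cards: np.ndarray, child: int, parents: tuple[int, ...]
) -> np.ndarray:
    """Joint counts N(parents..., child) with parent axes first."""
    shape = tuple(int(cards[p]) for p in parents) + (int(cards[child]),)
    idx = data[:, child].copy()
    stride = int(cards[child])
    for p in reversed(parents):
        idx += data[:, p] * stride
        stride *= int(cards[p])
    counts = np.bincount(idx, minlength=int(np.prod(shape)))
    return counts.reshape(shape).astype(np.float64)


def fit_cpts(
    dag: Dag, table: SurveyTable, pseudo_count: float = 1.0
) -> DiscreteBN:
    """Estimate one CPT per DAG node from a survey table."""
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be non-negative")
    if table.n == 0 and pseudo_count == 0:
        raise ValueError("cannot fit with an empty table and no smoothing")
    data, cards, nodes = encode_table(table, dag.nodes)
    pos = {node: j for j, node in enumerate(nodes)}
    cpts = {}
    for node in dag.nodes:
        parents = tuple(dag.parents(node))
        counts = _family_counts(
            data, cards, pos[node], tuple(pos[p] for p in parents)
        )
        k = counts.shape[-1]
        totals = counts.sum(axis=-1, keepdims=True)
        if pseudo_count > 0:
            probs = (counts + pseudo_count) / (totals + pseudo_count * k)
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                probs = counts / totals
            probs = np.where(totals > 0, probs, 1.0 / k)
        cpts[node] = Cpt(node, parents, probs)
    return DiscreteBN(table.codebook, dag, cpts)
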