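"""Exact inference by variable elimination.

Factors are (scope, ndarray) pairs; evidence is applied by slicing the
factor arrays, hidden variables are summed out in min-degree order over
the moralized factor graph (ties broken by variable id), and the
surviving factor over the query variable is renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..codebook import Codebook, CodebookError
from .model import (
    DiscreteBN,
    ImpossibleEvidenceError,
    Posterior,
    category_names,
    code_to_index,
    validate_evidence,
)


@dataclass
class _Factor:
    scope: tuple[str, ...]
    values: np.ndarray

    def restrict(self, var: str, index: int) -> "_Factor":
        axis = self.scope.index(var)
        new_scope = self.scope[:axis] + self.scope[axis + 1 :]
        return _Factor(new_scope, np.take(self.values, index, axis=axis))

    def sum_out(self, var: str) -> "_Factor":
        axis = self.scope.index(var)
        new_scope = self.scope[:axis] + self.scope[axis + 1 :]
        return _Factor(new_scope, self.values.sum(axis=axis))


def _product(factors: list[_Factor]) -> _Factor:
    """Multiply factors over the union of their scopes via broadcasting."""
    union: list[str] = []
    for f in factors:
        for v in f.scope:
            if v not in union:
                union.append(v)
    union_t = tuple(union)
    out = None
    for f in factors:
        perm = sorted(range(len(f.scope)), key=lambda i: union.index(f.scope[i]))
        arr = np.transpose(f.values, perm)
        shape = [1] * len(union)
        for i in perm:
            shape[union.index(f.scope[i])] = f.values.shape[i]
        arr = arr.reshape(shape)
        out = arr if out is None else out * arr
    if out is None:
        return _Factor((), np.float64(1.0))
    return _Factor(union_t, out)


def _min_degree_order(scopes: list[tuple[str, ...]], hidden: set[str]) -> list[str]:
    """Min-degree elimination order; deterministic (ties by variable id)."""
    neighbors: dict[str, set[str]] = {}
    for scope in scopes:
        for v in scope:
            neighbors.setdefault(v, set()).update(set(scope) - {v})
    remaining = set(hidden)
    order = []
    while remaining:
        pick = min(
            remaining,
            key=lambda v: (len(neighbors.get(v, set()) & set(neighbors)), v),
        )
        order.append(pick)
        nbrs = neighbors.pop(pick, set())
        for u in nbrs:
            if u in neighbors:
                neighbors[u] |= nbrs - {u}
                neighbors[u].discard(pick)
        remaining.remove(pick)
    return order


def _eliminate(factors: list[_Factor], hidden: set[str]) -> list[_Factor]:
    order = _min_degree_order([f.scope for f in factors], hidden)
    for var in order:
        involved = [f for f in factors if var in f.scope]
        if not involved:
            continue
        factors = [f for f in factors if var not in f.scope]
        factors.append(_product(involved).sum_out(var))
    return factors


def posterior(bn: DiscreteBN, target: str, evidence: dict | None = None) -> Posterior:
    """Exact conditional distribution of ``target`` given ``evidence``.

    Raises :class:`ImpossibleEvidenceError` when the evidence
    configuration has probability zero under the network.
    """
    evidence = validate_evidence(bn.codebook, evidence or {})
    if target not in bn.codebook:
        raise CodebookError(f"unknown variable {target!r}")
    if target not in bn.dag.nodes:
        raise CodebookError(f"{target} is not a node of the network")
    if target in evidence:
        raise CodebookError(f"target {target} cannot also be evidence")

    ev_idx = {
        v: code_to_index(bn.codebook[v], c)
        for v, c in evidence.items()
        if v in bn.dag.nodes
    }
    factors = []
    for node in bn.dag.nodes:
        cpt = bn.cpts[node]
        f = _Factor(tuple(cpt.scope), cpt.table)
        for v, idx in ev_idx.items():
            if v in f.scope:
                f = f.restrict(v, idx)
        factors.append(f)

    hidden = {v for f in factors for v in f.scope} - {target}
    factors = _eliminate(factors, hidden)
    result = _product(factors)
    if result.scope == ():
        raise CodebookError(f"{target} does not appear in any factor")
    values = np.asarray(result.values, dtype=np.float64).reshape(-1)
    z = values.sum()
    if z <= 0.0:
        raise ImpossibleEvidenceError(
            f"evidence {evidence} has probability zero"
        )
    var = bn.codebook[target]
    return Posterior(
        target=target,
        distribution=values / z,
        evidence=dict(evidence),
        categories=category_names(var),
        dkna=var.dkna,
    )


def joint_probability(bn: DiscreteBN, full_assignment: dict) -> float:
    """Probability of one full assignment: the product over nodes of
    their CPT entries."""
    assignment = validate_evidence(bn.codebook, full_assignment)
    missing = [n for n in bn.dag.nodes if n not in assignment]
    if missing:
        raise CodebookError(
            f"assignment must cover all nodes (missing {missing}); "
            "use posterior() for partial queries"
        )
    idx = {
        v: code_to_index(bn.codebook[v], c) for v, c in assignment.items()
    }
    prob = 1.0
    for node in bn.dag.nodes:
        cpt = bn.cpts[node]
        coords = tuple(idx[v] for v in cpt.scope)
        prob *= float(cpt.table[coords])
    return prob
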