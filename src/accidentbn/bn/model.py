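"""Conditional probability tables and the discrete BN container.

Internally every variable is axis-indexed 0..card-1: substantive code c
maps to index c-1 and the DK/NA sentinel (code 0), where declared, maps
to the last index K. Public APIs speak stored codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..codebook import DKNA_CODE, Codebook, CodebookError
from .dag import Dag

_SUM_TOL = 1e-9


class ImpossibleEvidenceError(ValueError):
    """Evidence configuration has probability zero under the network."""


def code_to_index(var, code: int) -> int:
    """Stored category code -> 0-based CPT axis index."""
    if code == DKNA_CODE:
        if not var.dkna:
            raise CodebookError(f"{var.id}: DK/NA not declared")
        return var.n_categories
    if not 1 <= code <= var.n_categories:
        raise CodebookError(f"{var.id}: invalid code {code}")
    return code - 1


def index_to_code(var, index: int) -> int:
    """0-based CPT axis index -> stored category code."""
    if index == var.n_categories and var.dkna:
        return DKNA_CODE
    return index + 1


def category_names(var) -> list[str]:
    """Axis-ordered category labels, DK/NA last when declared."""
    return list(var.categories) + (["DK/NA"] if var.dkna else [])


def validate_evidence(codebook: Codebook, evidence: dict) -> dict:
    """Validate an evidence assignment {variable id: stored code}."""
    out = {}
    for var_id, code in evidence.items():
        var = codebook[var_id]
        if not var.is_valid_code(int(code)):
            raise CodebookError(f"{var_id}: invalid evidence code {code}")
        if var_id in out:
            raise CodebookError(f"{var_id}: repeated in evidence")
        out[var_id] = int(code)
    return out


@dataclass
class Cpt:
    """P(child | parents) as an ndarray of shape (*parent_cards, child_card).

    Every slice along the last axis is a probability vector over the
    child's categories for one parent configuration.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.float64)
        if self.table.ndim != len(self.parents) + 1:
            raise ValueError(
                f"{self.child}: table rank {self.table.ndim} does not match "
                f"{len(self.parents)} parents"
            )
        sums = self.table.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=_SUM_TOL, rtol=0):
            raise ValueError(f"{self.child}: CPT rows must sum to 1")
        if (self.table < 0).any():
            raise ValueError(f"{self.child}: negative probability")

    @property
    def scope(self) -> tuple[str, ...]:
        return self.parents + (self.child,)

    @property
    def child_card(self) -> int:
        return self.table.shape[-1]


@dataclass
class DiscreteBN:
    """Directed acyclic graph plus one CPT per node.

    The product of the CPTs defines the joint probability function over
    all variables; conditioning on evidence and marginalising yields
    accident probabilities under any working-conditions scenario.
    """

    codebook: Codebook
    dag: Dag
    cpts: dict[str, Cpt] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node in self.dag.nodes:
            if node not in self.cpts:
                raise ValueError(f"missing CPT for {node}")
            cpt = self.cpts[node]
            if tuple(sorted(cpt.parents)) != tuple(sorted(self.dag.parents(node))):
                raise ValueError(f"{node}: CPT parents differ from DAG parents")
            expect = tuple(
                self.codebook.cardinality(p) for p in cpt.parents
            ) + (self.codebook.cardinality(node),)
            if cpt.table.shape != expect:
                raise ValueError(
                    f"{node}: CPT shape {cpt.table.shape} != {expect}"
                )

    @property
    def nodes(self) -> list[str]:
        return self.dag.nodes

    def cardinality(self, var_id: str) -> int:
        return self.codebook.cardinality(var_id)

    def direct_neighbors(self, var_id: str) -> set[str]:
        """Parents and children of a node — its directly linked variables."""
        return self.dag.neighbors(var_id)


@dataclass
class Posterior:
    """Exact posterior of one variable given evidence.

    ``distribution`` is axis-ordered over the target's categories
    (DK/NA last when declared) and sums to one.
    """

    target: str
    distribution: np.ndarray
    evidence: dict
    categories: list[str]
    dkna: bool = False

    def __getitem__(self, code: int) -> float:
        """Probability of the target taking a stored category code."""
        n_subst = len(self.categories) - (1 if self.dkna else 0)
        if code == DKNA_CODE:
            if not self.dkna:
                raise CodebookError(f"{self.target}: DK/NA not declared")
            return float(self.distribution[-1])
        if not 1 <= code <= n_subst:
            raise CodebookError(f"invalid code {code} for {self.target}")
        return float(self.distribution[code - 1])

    def prob_of(self, label: str) -> float:
        try:
            return float(self.distribution[self.categories.index(label)])
        except ValueError:
            raise CodebookError(
                f"unknown category {label!r} of {self.target}"
            ) from None
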