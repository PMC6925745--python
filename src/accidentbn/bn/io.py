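"""Serialization of fitted networks as structured text.

Nodes, edges and CPT rows (in lexicographic parent-configuration order)
are written to YAML with probabilities at 12 significant digits, so a
write/read/write cycle is byte-stable. Edge lists are exported as
two-column delimited text for external graph rendering.
"""

from __future__ import annotations

import itertools

import yaml

from ..codebook import Codebook
from .dag import Dag
from .model import Cpt, DiscreteBN


def save_bn(bn: DiscreteBN, path) -> None:
    doc: dict = {"nodes": bn.dag.nodes, "edges": [list(e) for e in sorted(bn.dag.edges)]}
    cpts = {}
    for node in bn.dag.nodes:
        cpt = bn.cpts[node]
        rows = []
        parent_cards = cpt.table.shape[:-1]
        for conf in itertools.product(*(range(c) for c in parent_cards)):
            probs = [float(f"{p:.12g}") for p in cpt.table[conf]]
            rows.append({"config": list(conf), "probs": probs})
        cpts[node] = {"parents": list(cpt.parents), "rows": rows}
    doc["cpts"] = cpts
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_bn(path, codebook: Codebook) -> DiscreteBN:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    dag = Dag(doc["nodes"], [tuple(e) for e in doc.get("edges", [])])
    cpts = {}
    for node, entry in doc["cpts"].items():
        parents = tuple(entry["parents"])
        parent_cards = tuple(codebook.cardinality(p) for p in parents)
        child_card = codebook.cardinality(node)
        import numpy as np

        table = np.empty(parent_cards + (child_card,))
        for row in entry["rows"]:
            table[tuple(row["config"])] = np.asarray(row["probs"], dtype=float)
        cpts[node] = Cpt(node, parents, table)
    return DiscreteBN(codebook, dag, cpts)


def write_edge_list(dag: Dag, path, sep: str = "\t") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"parent{sep}child\n")
        for u, v in sorted(dag.edges):
            fh.write(f"{u}{sep}{v}\n")
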