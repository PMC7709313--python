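"""Disease DAGs from MeSH tree codes and Wang-style semantic similarity.

A MeSH tree code such as ``C04.588.180`` places a disease in the Medical
Subject Headings hierarchy; every dot-prefix truncation (``C04.588``,
``C04``) is an ancestor.  A disease is represented by the DAG of all its
codes and their prefixes.  Each node contributes to the disease's semantic
value with a factor that decays by ``delta`` per level away from the disease
itself, and two diseases are similar in proportion to the contributions of
the nodes their DAGs share.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .core_data import EntityRegistry, canonicalize
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

_CODE = re.compile(r"^[A-Za-z]\d+(\.\d+)*$")


class MeshCodeTable:
    """Mapping of disease name -> list of MeSH tree-code strings."""

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        self.entries: dict[str, list[str]] = {}
        for name, codes in entries.items():
            codes = [c.strip().upper() for c in codes if c.strip()]
            for code in codes:
                if not _CODE.match(code):
                    raise ValueError(f"invalid MeSH tree code {code!r} for {name!r}")
            self.entries[canonicalize(name)] = codes

    def codes_for(self, disease: str) -> list[str]:
        return self.entries.get(canonicalize(disease), [])

    def __contains__(self, disease: str) -> bool:
        return bool(self.codes_for(disease))

    @classmethod
    def read_tsv(cls, path: str | Path) -> "MeshCodeTable":
        """Read ``disease<TAB>code1; code2; ...`` lines."""
        entries: dict[str, list[str]] = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'disease<TAB>codes'")
            entries.setdefault(parts[0], []).extend(
                c for c in parts[1].replace(",", ";").split(";") if c.strip()
            )
        return cls(entries)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, codes in self.entries.items():
                fh.write(f"{name}\t{'; '.join(codes)}\n")


def _prefixes(code: str) -> list[str]:
    parts = code.split(".")
    return [".".join(parts[: k + 1]) for k in range(len(parts))]


@dataclass
class DiseaseDAG:
    """A disease plus all tree-code ancestors, as a code-string DAG.

    Node identity is the tree-code string, so two diseases share a node
    exactly when they share a code prefix.  ``self_nodes`` are the disease's
    own code positions (contribution 1 each); every other node's contribution
    is ``delta`` times the best contribution among its children inside the
    DAG.
    """

    disease: str
    nodes: frozenset[str]
    self_nodes: frozenset[str]
    delta: float = 0.5
    _contrib: dict[str, float] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must be in (0, 1)")
        if not self.self_nodes or not self.self_nodes <= self.nodes:
            raise ValueError("DAG must contain the disease's own node(s)")

    def children_of(self, node: str) -> list[str]:
        """One-level extensions of ``node`` present in this DAG."""
        depth = node.count(".") + 1
        prefix = node + "."
        return [n for n in self.nodes if n.startswith(prefix) and n.count(".") == depth]


def build_dag(disease: str, codes: MeshCodeTable, delta: float = 0.5) -> DiseaseDAG:
    """Build the disease DAG from all dot-prefix truncations of its codes."""
    code_list = codes.codes_for(disease)
    if not code_list:
        raise ValueError(f"no MeSH tree codes for disease {disease!r}")
    nodes: set[str] = set()
    for code in code_list:
        nodes.update(_prefixes(code))
    return DiseaseDAG(
        disease=canonicalize(disease),
        nodes=frozenset(nodes),
        self_nodes=frozenset(code_list),
        delta=delta,
    )


def contribution(dag: DiseaseDAG, node: str) -> float:
    """Semantic contribution of ``node`` to the disease (0 if absent, 1 at the
    disease itself, otherwise delta times the best child contribution)."""
    if node not in dag.nodes:
        return 0.0
    if node in dag._contrib:
        return dag._contrib[node]
    if node in dag.self_nodes:
        value = 1.0
    else:
        children = dag.children_of(node)
        # non-self nodes are ancestors of some own code, so children is non-empty
        value = dag.delta * max(contribution(dag, c) for c in children)
    dag._contrib[node] = value
    return value


def semantic_value(dag: DiseaseDAG) -> float:
    """Total semantic value D(d): the sum of contributions over the DAG."""
    return sum(contribution(dag, node) for node in dag.nodes)


def semantic_similarity(dag_i: DiseaseDAG, dag_j: DiseaseDAG) -> float:
    """Shared-node contribution ratio between two disease DAGs, in [0, 1]."""
    if dag_i.delta != dag_j.delta:
        raise ValueError("DAGs must be built with the same delta")
    shared = dag_i.nodes & dag_j.nodes
    if not shared:
        return 0.0
    num = sum(contribution(dag_i, t) + contribution(dag_j, t) for t in shared)
    return num / (semantic_value(dag_i) + semantic_value(dag_j))


def semantic_similarity_matrix(
    registry: EntityRegistry,
    codes: MeshCodeTable,
    delta: float = 0.5,
    on_missing: str = "error",
) -> SimilarityMatrix:
    """Pairwise semantic similarity over a disease registry.

    Diseases lacking tree codes raise by default; with ``on_missing="zero"``
    their off-diagonal similarities are 0 (diagonal stays 1) and a warning is
    logged.
    """
    if on_missing not in ("error", "zero"):
        raise ValueError("on_missing must be 'error' or 'zero'")
    dags: dict[str, DiseaseDAG | None] = {}
    missing = []
    for name in registry.names:
        if name in codes:
            dags[name] = build_dag(name, codes, delta=delta)
        elif on_missing == "error":
            raise ValueError(f"no MeSH tree codes for disease {name!r}")
        else:
            dags[name] = None
            missing.append(name)
    if missing:
        logger.warning(
            "semantic_similarity_matrix: %d diseases without codes get zero "
            "off-diagonal similarity", len(missing)
        )
    n = len(registry)
    values = np.eye(n)
    names = registry.names
    for i in range(n):
        di = dags[names[i]]
        if di is None:
            continue
        for j in range(i + 1, n):
            dj = dags[names[j]]
            if dj is None:
                continue
            values[i, j] = values[j, i] = semantic_similarity(di, dj)
    return SimilarityMatrix(labels=list(names), values=values)
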