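"""Readers and writers for association lists, disease ontologies and matrices.

The central object is the Boolean association matrix ``LD`` (lncRNAs in rows,
diseases in columns) together with stable id registries. Identifiers are
case-preserved but matched case-insensitively after whitespace trimming,
because lncRNA symbols in public association lists vary in capitalisation.

All user-facing text formats are plain delimited text (default tab). Lines
starting with ``#`` are comments. MAT-v5 containers can be read (never
written) so that deposited datasets distributed in that form are usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd


def _key(identifier: str) -> str:
    """Canonical matching key for an identifier."""
    return identifier.strip().casefold()


def _build_index(ids: Sequence[str], what: str) -> dict[str, int]:
    index: dict[str, int] = {}
    for pos, name in enumerate(ids):
        k = _key(name)
        if k in index:
            raise ValueError(f"duplicate {what} identifier: {name!r}")
        index[k] = pos
    return index


@dataclass
class AssociationMatrix:
    """Boolean lncRNA x disease association matrix with id registries.

    ``values[i, j] == 1`` iff lncRNA ``lncrna_ids[i]`` is known to associate
    with disease ``disease_ids[j]``.
    """

    values: np.ndarray
    lncrna_ids: list[str]
    disease_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("association matrix must be 2-D")
        if not np.isin(self.values, (0.0, 1.0)).all():
            bad = np.unique(self.values[~np.isin(self.values, (0.0, 1.0))])
            raise ValueError(f"association matrix must be Boolean; found values {bad[:5]}")
        nl, nd = self.values.shape
        if len(self.lncrna_ids) != nl or len(self.disease_ids) != nd:
            raise ValueError("id list lengths do not match matrix dimensions")
        self._l_index = _build_index(self.lncrna_ids, "lncRNA")
        self._d_index = _build_index(self.disease_ids, "disease")

    @property
    def nl(self) -> int:
        return self.values.shape[0]

    @property
    def nd(self) -> int:
        return self.values.shape[1]

    @property
    def n_associations(self) -> int:
        return int(self.values.sum())

    def lncrna_index(self, lncrna_id: str) -> int:
        try:
            return self._l_index[_key(lncrna_id)]
        except KeyError:
            raise KeyError(f"unknown lncRNA id: {lncrna_id!r}") from None

    def disease_index(self, disease_id: str) -> int:
        try:
            return self._d_index[_key(disease_id)]
        except KeyError:
            raise KeyError(f"unknown disease id: {disease_id!r}") from None

    def with_values(self, values: np.ndarray) -> "AssociationMatrix":
        """New matrix sharing the id registries (used by cross-validation)."""
        return AssociationMatrix(values, list(self.lncrna_ids), list(self.disease_ids))


@dataclass
class DiseaseOntology:
    """Disease ontology fragment as a parent -> child edge set.

    Per-disease DAGs (a node plus its ancestor closure) are carved out of
    this graph when computing semantic similarity. Diseases absent from the
    ontology are permitted; similarity construction falls back to the
    interaction-profile kernel for them.
    """

    edges: set = field(default_factory=set)
    node_ids: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.edges = {(str(p), str(c)) for p, c in self.edges}
        self.node_ids = set(map(str, self.node_ids)) | {n for e in self.edges for n in e}
        for parent, child in self.edges:
            if _key(parent) == _key(child):
                raise ValueError(f"self-edge in ontology: {parent!r}")
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(self.node_ids)
        self._graph.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle_node = nx.find_cycle(self._graph)[0][0]
            raise ValueError(f"ontology contains a cycle through node {cycle_node!r}")
        self._canon = {}
        for node in self.node_ids:
            k = _key(node)
            if k in self._canon and self._canon[k] != node:
                raise ValueError(f"ontology ids differ only by case/whitespace: {node!r}")
            self._canon[k] = node

    def __len__(self) -> int:
        return len(self.node_ids)

    def resolve(self, disease_id: str) -> str | None:
        """Canonical node id for ``disease_id``, or None if absent."""
        return self._canon.get(_key(disease_id))

    def graph(self) -> nx.DiGraph:
        return self._graph

    def ancestor_closure(self, disease_id: str) -> set:
        """All ancestors of a disease, including the disease itself."""
        node = self.resolve(disease_id)
        if node is None:
            raise KeyError(f"disease {disease_id!r} not in ontology")
        return nx.ancestors(self._graph, node) | {node}

    def parents_within(self, node: str, closure: set) -> set:
        return set(self._graph.predecessors(node)) & closure

    def children_within(self, node: str, closure: set) -> set:
        return set(self._graph.successors(node)) & closure


def _data_lines(path: str | Path, delimiter: str) -> list[tuple[int, list[str]]]:
    lines = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            lines.append((lineno, line.split(delimiter)))
    return lines


_HEADER_WORDS = {
    "lncrna", "lncrna_id", "lnc", "lncrnas", "rna",
    "disease", "disease_id", "diseases", "parent", "child",
}


def _looks_like_header(rows: list[list[str]]) -> bool:
    """Heuristic header detection: a first line whose fields never reoccur.

    To avoid discarding a genuine association in files where every pair is
    unique, the non-reoccurrence test only fires when the remaining lines
    show id reuse, or when the fields match common header vocabulary.
    """
    if len(rows) < 2:
        return False
    first = rows[0]
    if _key(first[0]) in _HEADER_WORDS or _key(first[1]) in _HEADER_WORDS:
        return True
    col0 = [_key(r[0]) for r in rows[1:]]
    col1 = [_key(r[1]) for r in rows[1:]]
    if _key(first[0]) in col0 or _key(first[1]) in col1:
        return False
    ids_reused = len(set(col0)) < len(col0) or len(set(col1)) < len(col1)
    return ids_reused


def read_associations(path: str | Path, delimiter: str = "\t") -> AssociationMatrix:
    """Read a two-column (lncRNA id, disease id) association list.

    Duplicate pairs collapse to a single link; ids are ordered by first
    appearance. An optional header line is detected heuristically (a first
    line whose fields never reoccur in their columns).
    """
    rows = _data_lines(path, delimiter)
    for lineno, fields in rows:
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(f"{path}: malformed association line {lineno}: need 2 fields")
    pairs = [fields[:2] for _, fields in rows]
    if pairs and _looks_like_header(pairs):
        pairs = pairs[1:]
    if not pairs:
        raise ValueError(f"{path}: no associations")

    lncrna_ids: list[str] = []
    disease_ids: list[str] = []
    l_seen: dict[str, int] = {}
    d_seen: dict[str, int] = {}
    links: set[tuple[int, int]] = set()
    for lname, dname in pairs:
        lk, dk = _key(lname), _key(dname)
        if lk not in l_seen:
            l_seen[lk] = len(lncrna_ids)
            lncrna_ids.append(lname.strip())
        if dk not in d_seen:
            d_seen[dk] = len(disease_ids)
            disease_ids.append(dname.strip())
        links.add((l_seen[lk], d_seen[dk]))

    values = np.zeros((len(lncrna_ids), len(disease_ids)))
    for i, j in links:
        values[i, j] = 1.0
    return AssociationMatrix(values, lncrna_ids, disease_ids)


def write_associations(ld: AssociationMatrix, path: str | Path, delimiter: str = "\t") -> None:
    """Write the association matrix back out as a two-column pair list."""
    with open(path, "w") as fh:
        for i, j in np.argwhere(ld.values == 1.0):
            fh.write(f"{ld.lncrna_ids[i]}{delimiter}{ld.disease_ids[j]}\n")


def read_disease_dag(path: str | Path, delimiter: str = "\t") -> DiseaseOntology:
    """Read a (parent, child) edge list into a DiseaseOntology.

    An empty file yields an empty ontology, in which case every disease
    similarity downstream falls back to the interaction-profile kernel.
    """
    rows = _data_lines(path, delimiter)
    edges = set()
    for lineno, fields in rows:
        if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
            raise ValueError(f"{path}: malformed ontology line {lineno}: need 2 fields")
        parent, child = fields[0].strip(), fields[1].strip()
        if _key(parent) == _key(child):
            raise ValueError(f"{path}: self-edge at line {lineno}: {parent!r}")
        edges.add((parent, child))
    return DiseaseOntology(edges=edges)


def load_mat_dataset(
    path: str | Path,
    var_map: Mapping[str, str] | None = None,
):
    """Load an association matrix (plus optional similarity blocks) from MAT-v5.

    The variables inside deposited containers are not standardised, so
    discovery is heuristic: the association candidate is a 2-D Boolean array
    (preferring a non-square one), and any square numeric arrays whose side
    matches one of its dimensions are offered as precomputed lncRNA/disease
    similarity matrices. ``var_map`` overrides discovery with explicit
    variable names for keys ``"ld"``, ``"ll"`` and ``"dd"``.

    Returns ``(associations, extras)`` where ``extras`` maps ``"ll"``/``"dd"``
    to SimilarityMatrix objects when square companions are present.
    """
    from scipy.io import loadmat

    from .similarity import SimilarityMatrix

    contents = {
        name: np.asarray(arr)
        for name, arr in loadmat(path).items()
        if not name.startswith("__") and np.asarray(arr).ndim == 2
    }
    if not contents:
        raise ValueError(f"{path}: no 2-D array found in MAT container")

    def _is_binary(a: np.ndarray) -> bool:
        return np.issubdtype(a.dtype, np.number) and bool(np.isin(a, (0, 1)).all())

    if var_map and "ld" in var_map:
        name = var_map["ld"]
        if name not in contents:
            raise ValueError(f"{path}: variable {name!r} not found")
        ld_arr = contents[name]
        if not _is_binary(ld_arr):
            bad = np.unique(ld_arr[~np.isin(ld_arr, (0, 1))])
            raise ValueError(f"{path}: association candidate {name!r} is not Boolean; found {bad[:5]}")
    else:
        binary = {n: a for n, a in contents.items() if _is_binary(a)}
        if not binary:
            name, arr = max(contents.items(), key=lambda kv: kv[1].size)
            bad = np.unique(arr[~np.isin(arr, (0, 1))])
            raise ValueError(f"{path}: no Boolean association array; best candidate {name!r} has values {bad[:5]}")
        nonsquare = {n: a for n, a in binary.items() if a.shape[0] != a.shape[1]}
        pool = nonsquare or binary
        name = max(pool, key=lambda n: pool[n].size)
        ld_arr = pool[name]

    nl, nd = ld_arr.shape
    ld = AssociationMatrix(
        ld_arr.astype(float),
        [f"l{i + 1}" for i in range(nl)],
        [f"d{j + 1}" for j in range(nd)],
    )

    extras: dict[str, SimilarityMatrix] = {}
    for kind_key, side, ids, kind in (
        ("ll", nl, ld.lncrna_ids, "lncrna_final"),
        ("dd", nd, ld.disease_ids, "disease_final"),
    ):
        candidate = None
        if var_map and kind_key in var_map:
            candidate = contents.get(var_map[kind_key])
            if candidate is None:
                raise ValueError(f"{path}: variable {var_map[kind_key]!r} not found")
        else:
            for cand_name, arr in contents.items():
                if arr.shape == (side, side) and arr is not ld_arr:
                    candidate = arr
                    break
        if candidate is not None and candidate.shape == (side, side):
            extras[kind_key] = SimilarityMatrix(candidate.astype(float), list(ids), kind)
    return ld, extras


def write_matrix(values: np.ndarray, row_ids: Sequence[str], col_ids: Sequence[str], path: str | Path) -> None:
    """Dense TSV with row/column id headers, lossless to >= 15 significant digits."""
    frame = pd.DataFrame(np.asarray(values), index=list(row_ids), columns=list(col_ids))
    frame.to_csv(path, sep="\t", float_format="%.17g")


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    frame = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return frame.to_numpy(dtype=float), [str(i) for i in frame.index], [str(c) for c in frame.columns]


def write_score_matrix(scores, path: str | Path) -> None:
    """Serialize a ScoreMatrix (row ids = lncRNAs for nl x nd stages)."""
    if scores.stage == "disease_projection":
        write_matrix(scores.values, scores.disease_ids, scores.lncrna_ids, path)
    else:
        write_matrix(scores.values, scores.lncrna_ids, scores.disease_ids, path)


def write_rankings(
    scores,
    disease_id: str,
    k: int,
    path: str | Path,
    ld: AssociationMatrix | None = None,
) -> None:
    """Write the top-k candidate lncRNAs for one disease.

    Output columns mirror published candidate tables: disease, lncRNA,
    rank (1-based), score. Known associates are excluded when ``ld`` is
    given. Ties are broken lexicographically by lncRNA id.
    """
    try:
        j = [_key(d) for d in scores.disease_ids].index(_key(disease_id))
    except ValueError:
        raise KeyError(f"unknown disease id: {disease_id!r}") from None
    column = scores.values[:, j] if scores.stage != "disease_projection" else scores.values[j, :]
    candidates = list(range(len(scores.lncrna_ids)))
    if ld is not None:
        jj = ld.disease_index(disease_id)
        candidates = [i for i in candidates if ld.values[i, jj] == 0.0]
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidate lncRNAs")
    order = sorted(candidates, key=lambda i: (-column[i], _key(scores.lncrna_ids[i])))
    with open(path, "w") as fh:
        fh.write("disease\tlncrna\trank\tscore\n")
        for rank, i in enumerate(order[:k], start=1):
            fh.write(f"{disease_id}\t{scores.lncrna_ids[i]}\t{rank}\t{column[i]:.17g}\n")
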