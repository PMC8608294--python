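"""Similarity layers over diseases and lncRNAs, and their integration.

Four layers are built from the known-association matrix ``LD`` and a disease
ontology:

* disease semantic similarity ``DD`` — shared-ancestor similarity over each
  disease's DAG, with ancestor contributions decaying by ``decay`` per
  generation;
* lncRNA functional similarity ``LL`` — best-match average of semantic
  similarities between the two lncRNAs' associated disease sets;
* Gaussian interaction profile (GIP) kernels ``DD_g`` / ``LL_g`` —
  ``exp(-gamma * ||profile_i - profile_j||^2)`` on columns / rows of ``LD``,
  with the bandwidth normalised by the mean squared profile norm;
* integrated similarities ``DD_f`` / ``LL_f`` — the semantic (functional)
  value where it is nonzero, the GIP value otherwise.

The integrated matrices are the diagonal blocks of the heterogeneous
adjacency matrix used by the KATZ stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_data import AssociationMatrix, DiseaseOntology, _key

KINDS = {
    "disease_semantic",
    "lncrna_functional",
    "disease_gip",
    "lncrna_gip",
    "disease_final",
    "lncrna_final",
}

_SYM_TOL = 1e-12


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity matrix with entries in [0, 1]."""

    values: np.ndarray
    entity_ids: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"unknown similarity kind: {self.kind!r}")
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square and match its id list")
        if np.abs(self.values - self.values.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("similarity matrix is not symmetric")
        if self.values.size and (self.values.min() < -_SYM_TOL or self.values.max() > 1 + _SYM_TOL):
            raise ValueError("similarity entries must lie in [0, 1]")
        if self.kind in ("disease_gip", "lncrna_gip", "disease_final", "lncrna_final"):
            if n and not np.allclose(np.diag(self.values), 1.0, atol=_SYM_TOL):
                raise ValueError(f"{self.kind} similarity requires a unit diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class SemanticContribution:
    """Semantic contributions of a disease's ancestors to that disease.

    ``contributions[t]`` is the contribution of ancestor ``t`` to the
    semantics of ``disease_id``: 1 for the disease itself, and for a strict
    ancestor the maximum over its children (within the ancestor closure) of
    ``decay`` times the child's contribution.
    """

    disease_id: str
    contributions: dict
    decay: float

    def __post_init__(self) -> None:
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must lie in (0, 1)")
        own = self.contributions.get(self.disease_id)
        if own != 1.0:
            raise ValueError("a disease must contribute 1 to itself")
        for node, value in self.contributions.items():
            if node != self.disease_id and not 0.0 < value <= self.decay:
                raise ValueError(f"strict-ancestor contribution out of range for {node!r}")

    @property
    def total(self) -> float:
        return float(sum(self.contributions.values()))


def semantic_contributions(dag: DiseaseOntology, disease_id: str, decay: float = 0.5) -> SemanticContribution:
    """Ancestor contributions for one disease by reverse-topological traversal.

    Raises KeyError when the disease is absent from the ontology; the caller
    decides whether to fall back to the GIP kernel.
    """
    node = dag.resolve(disease_id)
    if node is None:
        raise KeyError(f"disease {disease_id!r} not in ontology")
    closure = dag.ancestor_closure(node)
    # The owner is the unique sink of the closure subgraph, so children come
    # before parents in any reverse topological order.
    import networkx as nx

    sub = dag.graph().subgraph(closure)
    contributions: dict[str, float] = {}
    for current in reversed(list(nx.topological_sort(sub))):
        if current == node:
            contributions[current] = 1.0
        else:
            children = dag.children_within(current, closure)
            contributions[current] = decay * max(contributions[c] for c in children)
    return SemanticContribution(node, contributions, decay)


def disease_semantic_similarity(
    dag: DiseaseOntology,
    disease_ids: Sequence[str],
    decay: float = 0.5,
) -> SimilarityMatrix:
    """Pairwise shared-ancestor semantic similarity for an ordered disease list.

    For diseases i and j with ancestor closures T_i, T_j and contribution
    functions D_i, D_j, the similarity is
    ``sum_{t in T_i ∩ T_j} (D_i(t) + D_j(t)) / (sum D_i + sum D_j)``.
    Diseases absent from the ontology receive an all-zero row and column
    (diagonal included) so that integration falls back to the GIP kernel
    everywhere for them.
    """
    if not 0.0 < decay < 1.0:
        raise ValueError("decay must lie in (0, 1)")
    n = len(disease_ids)
    contribs: list[SemanticContribution | None] = []
    for d in disease_ids:
        if dag.resolve(d) is None:
            contribs.append(None)
        else:
            contribs.append(semantic_contributions(dag, d, decay))
    values = np.zeros((n, n))
    for i in range(n):
        ci = contribs[i]
        if ci is None:
            continue
        values[i, i] = 1.0
        for j in range(i + 1, n):
            cj = contribs[j]
            if cj is None:
                continue
            shared = ci.contributions.keys() & cj.contributions.keys()
            if not shared:
                continue
            numer = sum(ci.contributions[t] + cj.contributions[t] for t in shared)
            values[i, j] = values[j, i] = numer / (ci.total + cj.total)
    return SimilarityMatrix(values, list(disease_ids), "disease_semantic")


def _aligned_values(sim: SimilarityMatrix, ids: Sequence[str]) -> np.ndarray:
    """Similarity values reordered to the given id order (case-insensitive)."""
    if len(ids) == len(sim.entity_ids) and all(
        _key(a) == _key(b) for a, b in zip(ids, sim.entity_ids)
    ):
        return sim.values
    pos = {_key(e): i for i, e in enumerate(sim.entity_ids)}
    try:
        perm = [pos[_key(d)] for d in ids]
    except KeyError as exc:
        raise ValueError(f"similarity matrix does not cover entity {exc.args[0]!r}") from None
    return sim.values[np.ix_(perm, perm)]


def lncrna_functional_similarity(ld: AssociationMatrix, dd: SimilarityMatrix) -> SimilarityMatrix:
    """Best-match-average functional similarity between lncRNAs.

    With D(l_i) the diseases linked to l_i (size k) and D(l_j) (size k'),
    each disease of one set is matched to its most similar disease in the
    other set under ``dd``, and the matched similarities are averaged over
    k + k'. An lncRNA with no associations gets 0 off-diagonal (avoiding
    0/0); diagonals are forced to 1.
    """
    dd_values = _aligned_values(dd, ld.disease_ids)
    profiles = ld.values.astype(bool)
    nl, nd = profiles.shape
    # best_match[t, j] = max similarity between disease t and l_j's disease set
    best_match = np.zeros((nd, nl))
    for j in range(nl):
        cols = np.flatnonzero(profiles[j])
        if cols.size:
            best_match[:, j] = dd_values[:, cols].max(axis=1)
    counts = profiles.sum(axis=1).astype(float)
    cross = profiles.astype(float) @ best_match  # cross[i, j] = sum over D(l_i) of best matches in D(l_j)
    denom = counts[:, None] + counts[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(denom > 0, (cross + cross.T) / np.where(denom > 0, denom, 1.0), 0.0)
    values = np.clip((values + values.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(values, list(ld.lncrna_ids), "lncrna_functional")


def gip_similarity(ld: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """Gaussian interaction profile kernel on rows (lncrna) or columns (disease).

    The bandwidth is the reciprocal of the mean squared profile norm, so a
    matrix whose profiles all have unit squared norm gets bandwidth 1.
    """
    if axis not in ("disease", "lncrna"):
        raise ValueError("axis must be 'disease' or 'lncrna'")
    if not ld.values.any():
        raise ValueError("GIP bandwidth undefined: association matrix has no known links")
    profiles = ld.values if axis == "lncrna" else ld.values.T
    sq_norms = (profiles**2).sum(axis=1)
    gamma = 1.0 / sq_norms.mean()
    sq_dist = sq_norms[:, None] + sq_norms[None, :] - 2.0 * (profiles @ profiles.T)
    np.clip(sq_dist, 0.0, None, out=sq_dist)
    values = np.exp(-gamma * sq_dist)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    ids = ld.lncrna_ids if axis == "lncrna" else ld.disease_ids
    return SimilarityMatrix(values, list(ids), f"{axis}_gip")


_FINAL_KIND = {
    ("disease_semantic", "disease_gip"): "disease_final",
    ("lncrna_functional", "lncrna_gip"): "lncrna_final",
}


def integrate_similarity(base: SimilarityMatrix, gip: SimilarityMatrix) -> SimilarityMatrix:
    """Elementwise fallback integration: base where nonzero, GIP otherwise.

    The zero test is exact — semantic/functional zeros are structural
    (no shared ancestry, no associated diseases), not numerical noise.
    """
    kind = _FINAL_KIND.get((base.kind, gip.kind))
    if kind is None:
        raise ValueError(f"cannot integrate kinds {base.kind!r} and {gip.kind!r}")
    if base.n != gip.n or any(_key(a) != _key(b) for a, b in zip(base.entity_ids, gip.entity_ids)):
        raise ValueError("integration requires identical entity sets in identical order")
    values = np.where(base.values != 0.0, base.values, gip.values)
    return SimilarityMatrix(values, list(base.entity_ids), kind)


def integrated_similarities(
    ld: AssociationMatrix,
    dag: DiseaseOntology,
    decay: float = 0.5,
    dd_semantic: SimilarityMatrix | None = None,
) -> tuple[SimilarityMatrix, SimilarityMatrix, SimilarityMatrix]:
    """Build the full (LL_f, DD_f) pair from associations and an ontology.

    ``dd_semantic`` may be supplied to reuse the (association-independent)
    semantic layer across cross-validation folds; it is also returned so
    callers can cache it.

    Returns ``(ll_final, dd_final, dd_semantic)``.
    """
    if dd_semantic is None:
        dd_semantic = disease_semantic_similarity(dag, ld.disease_ids, decay)
    dd_final = integrate_similarity(dd_semantic, gip_similarity(ld, "disease"))
    ll_functional = lncrna_functional_similarity(ld, dd_semantic)
    ll_final = integrate_similarity(ll_functional, gip_similarity(ld, "lncrna"))
    return ll_final, dd_final, dd_semantic
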