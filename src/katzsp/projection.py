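"""Similarity-space projection refinement and the end-to-end pipeline.

The primary KATZ scores LD_p are refined by projecting each similarity
matrix onto them:

* lncRNA space:  score(i, j) = LL_f(i, :) . LD_p(:, j) / ||LD_p(:, j)||
* disease space: score(j, i) = DD_f(j, :) . LD_p(i, :)^T / ||LD_p(i, :)||

and the two projections are averaged into the final score matrix. A zero
normalising vector (a disease or lncRNA whose primary scores are all zero)
yields zeros for the affected entries rather than NaN.

``run_pipeline`` wires the stages into the four study variants:

* ``KATZSP`` (default) — KATZ scores, then projection refinement;
* ``KATZ``   — primary KATZ scores only;
* ``SP``     — projection applied directly to the Boolean associations;
* ``SPKATZ`` — SP scores substituted for the association block of the
  adjacency matrix, then one KATZ pass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .io_data import AssociationMatrix, DiseaseOntology
from .katz_core import (
    DEFAULT_K,
    HeterogeneousAdjacency,
    ScoreMatrix,
    build_adjacency,
    extract_primary,
    katz_scores,
    select_beta,
)
from .similarity import SimilarityMatrix, integrated_similarities

VARIANTS = ("SP", "KATZ", "SPKATZ", "KATZSP")

DEFAULT_DECAY = 0.5


@dataclass
class PipelineConfig:
    """Tunable knobs of a pipeline run.

    K: scale on the spectral bound, beta = K / lambda_max(A); decay: per-
    generation attenuation of ancestor contributions in semantic similarity;
    refold_similarities: whether cross-validation recomputes association-
    dependent similarities inside each fold (honest) or reuses full-data
    ones (optimistic, exploratory).
    """

    K: float = DEFAULT_K
    decay: float = DEFAULT_DECAY
    variant: str = "KATZSP"
    refold_similarities: bool = True

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not 0.0 < self.K < 1.0:
            raise ValueError("K must lie in (0, 1)")
        if not 0.0 < self.decay < 1.0:
            raise ValueError("decay must lie in (0, 1)")


def _normalize_columns(numerators: np.ndarray, norms: np.ndarray) -> np.ndarray:
    safe = np.where(norms > 0.0, norms, 1.0)
    return np.where(norms > 0.0, numerators / safe, 0.0)


def project_lncrna_space(ll_final: SimilarityMatrix, primary: ScoreMatrix) -> ScoreMatrix:
    """Project lncRNA similarities onto the columns of the primary scores."""
    if ll_final.n != len(primary.lncrna_ids):
        raise ValueError("lncRNA similarity does not match the score matrix")
    numer = ll_final.values @ primary.values
    norms = np.linalg.norm(primary.values, axis=0)[None, :]
    return ScoreMatrix(
        _normalize_columns(numer, norms), list(primary.lncrna_ids), list(primary.disease_ids), "lncrna_projection"
    )


def project_disease_space(dd_final: SimilarityMatrix, primary: ScoreMatrix) -> ScoreMatrix:
    """Project disease similarities onto the rows of the primary scores.

    Returned in the disease-space (nd x nl) orientation; its transpose is
    aligned with the primary matrix.
    """
    if dd_final.n != len(primary.disease_ids):
        raise ValueError("disease similarity does not match the score matrix")
    numer = primary.values @ dd_final.values  # (i, j) entry: LD_p(i, :) . DD_f(j, :)
    norms = np.linalg.norm(primary.values, axis=1)[:, None]
    values = _normalize_columns(numer, norms).T
    return ScoreMatrix(values, list(primary.lncrna_ids), list(primary.disease_ids), "disease_projection")


def fuse_projections(pl: ScoreMatrix, pd: ScoreMatrix) -> ScoreMatrix:
    """Average the lncRNA-space and (transposed) disease-space projections."""
    if pl.stage != "lncrna_projection" or pd.stage != "disease_projection":
        raise ValueError("fuse expects one lncRNA-space and one disease-space projection")
    if pl.values.shape != pd.values.T.shape:
        raise ValueError("projection shapes are incompatible")
    values = (pl.values + pd.values.T) / 2.0
    return ScoreMatrix(values, list(pl.lncrna_ids), list(pl.disease_ids), "final")


def _project_and_fuse(
    ll_final: SimilarityMatrix, dd_final: SimilarityMatrix, primary: ScoreMatrix
) -> ScoreMatrix:
    return fuse_projections(
        project_lncrna_space(ll_final, primary),
        project_disease_space(dd_final, primary),
    )


def _katz_block(
    ll_final: SimilarityMatrix,
    dd_final: SimilarityMatrix,
    off_diagonal: np.ndarray,
    ld: AssociationMatrix,
    K: float,
) -> ScoreMatrix:
    adjacency = HeterogeneousAdjacency(
        np.block([[ll_final.values, off_diagonal], [off_diagonal.T, dd_final.values]]),
        ld.nl,
        ld.nd,
    )
    params = select_beta(adjacency, K)
    return extract_primary(katz_scores(adjacency, params), ld.nl, ld.nd, ld.lncrna_ids, ld.disease_ids)


def run_pipeline(
    ld: AssociationMatrix,
    dag: DiseaseOntology,
    config: PipelineConfig | None = None,
    similarities: tuple[SimilarityMatrix, SimilarityMatrix] | None = None,
) -> ScoreMatrix:
    """Run one configured variant end to end and return its score matrix.

    ``similarities`` may carry precomputed ``(ll_final, dd_final)`` blocks
    (used by cross-validation to control similarity refolding); otherwise
    all layers are built from ``ld`` and ``dag``.
    """
    config = config or PipelineConfig()
    if not ld.values.any():
        raise ValueError("association matrix has no known links")
    if similarities is None:
        ll_final, dd_final, _ = integrated_similarities(ld, dag, config.decay)
    else:
        ll_final, dd_final = similarities

    raw = ScoreMatrix(ld.values.astype(float), list(ld.lncrna_ids), list(ld.disease_ids), "primary")
    if config.variant == "SP":
        return _project_and_fuse(ll_final, dd_final, raw)
    if config.variant == "SPKATZ":
        sp_scores = _project_and_fuse(ll_final, dd_final, raw)
        scored = _katz_block(ll_final, dd_final, sp_scores.values, ld, config.K)
        return replace(scored, stage="final")

    adjacency = build_adjacency(ll_final, dd_final, ld)
    params = select_beta(adjacency, config.K)
    primary = extract_primary(katz_scores(adjacency, params), ld.nl, ld.nd, ld.lncrna_ids, ld.disease_ids)
    if config.variant == "KATZ":
        return primary
    return _project_and_fuse(ll_final, dd_final, primary)
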