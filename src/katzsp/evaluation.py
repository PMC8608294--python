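"""Leave-one-out cross-validation, ROC/AUC, parameter sweeps and rankings.

Evaluation conventions
----------------------
The candidate (negative) pool for a held-out positive is the set of pairs
that are unknown in the *full* dataset — never-known pairs — so masking an
association for a fold does not promote it into the negative pool of other
folds. Within each fold the held-out positive is ranked against that pool;
the global AUC pools the per-fold normalised ranks, weighted by each fold's
candidate count (equivalent to a candidate-count-weighted average of
per-fold rank-AUCs). The per-fold rank list is part of the result so that
alternative poolings can be recomputed.

Similarity refolding: the interaction-profile and functional similarities
depend on the association matrix, so honest cross-validation recomputes
them inside every fold (``refold_similarities=True``, the default). Semantic
similarity is association-independent and cached across folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_data import AssociationMatrix, DiseaseOntology, _key
from .katz_core import ScoreMatrix
from .projection import PipelineConfig, run_pipeline
from .similarity import disease_semantic_similarity, integrated_similarities

_AUC_TOL = 1e-9


@dataclass
class FoldRecord:
    """Rank of one held-out positive within its fold's candidate pool.

    ``rank`` is 1-based with midranks for ties; ``candidate_count`` counts
    the positive plus its negatives. ``column_rank`` is the same rank
    restricted to the positive's own disease column (used for top-k
    recovery summaries).
    """

    lncrna_id: str
    disease_id: str
    rank: float
    candidate_count: int
    column_rank: float
    column_candidate_count: int

    @property
    def normalized_rank_auc(self) -> float:
        """Fraction of the fold's negatives ranked below the positive."""
        n_neg = self.candidate_count - 1
        return (self.candidate_count - self.rank) / n_neg


@dataclass
class EvalResult:
    """ROC points, pooled AUC and per-fold positive ranks with provenance."""

    auc: float
    roc_points: np.ndarray
    per_fold_ranks: list = field(default_factory=list)
    variant: str | None = None
    K: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.roc_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("roc_points must be an (n, 2) array of (FPR, TPR)")
        if not (np.allclose(pts[0], (0.0, 0.0)) and np.allclose(pts[-1], (1.0, 1.0))):
            raise ValueError("ROC must start at (0,0) and end at (1,1)")
        if (np.diff(pts[:, 0]) < -_AUC_TOL).any() or (np.diff(pts[:, 1]) < -_AUC_TOL).any():
            raise ValueError("ROC coordinates must be non-decreasing")
        area = float(np.trapezoid(pts[:, 1], pts[:, 0]))
        if abs(area - self.auc) > _AUC_TOL:
            raise ValueError("AUC does not equal the trapezoidal area of the ROC points")
        self.roc_points = pts

    def fold_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "lncrna": r.lncrna_id,
                    "disease": r.disease_id,
                    "rank": r.rank,
                    "candidates": r.candidate_count,
                    "column_rank": r.column_rank,
                    "column_candidates": r.column_candidate_count,
                }
                for r in self.per_fold_ranks
            ]
        )


def _midrank_stats(positive: float, negatives: np.ndarray) -> tuple[float, float]:
    """(1-based midrank among positive+negatives, fraction of negatives below)."""
    above = int((negatives > positive).sum())
    ties = int((negatives == positive).sum())
    rank = 1.0 + above + 0.5 * ties
    below_fraction = ((negatives < positive).sum() + 0.5 * ties) / negatives.size
    return rank, float(below_fraction)


def roc_auc(positive_scores, negative_scores, **provenance) -> EvalResult:
    """ROC curve and AUC from pooled positive and negative scores.

    A threshold sweep over the union of observed scores produces the curve;
    the trapezoidal area gives ties half credit, matching the rank-based
    (Mann-Whitney) estimate.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for t in thresholds:
        tpr.append((pos >= t).mean())
        fpr.append((neg >= t).mean())
    points = np.column_stack([fpr, tpr])
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return EvalResult(auc=auc, roc_points=points, **provenance)


def _roc_from_folds(exceedance: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """ROC of per-fold positives against their own negative pools.

    ``exceedance[f]`` is the fraction of fold f's negatives scoring at or
    above the positive (ties half-weighted); it is the FPR at which that
    positive becomes a true positive. Folds are weighted by candidate count.
    """
    order = np.argsort(exceedance)
    x = exceedance[order]
    w = weights[order].astype(float)
    w /= w.sum()
    points = [(0.0, 0.0)]
    tpr = 0.0
    for xv in np.unique(x):
        gained = w[x == xv].sum()
        points.append((float(xv), tpr))
        tpr += gained
        points.append((float(xv), tpr))
    points.append((1.0, 1.0))
    return np.asarray(points)


def _pooled_result(records, exceedance, weights, config: PipelineConfig, seed=None) -> EvalResult:
    exceedance = np.asarray(exceedance, dtype=float)
    weights = np.asarray(weights, dtype=float)
    roc = _roc_from_folds(exceedance, weights)
    auc = float(np.sum((1.0 - exceedance) * weights) / weights.sum())
    return EvalResult(
        auc=auc,
        roc_points=roc,
        per_fold_ranks=records,
        variant=config.variant,
        K=config.K,
        seed=seed,
    )


def loocv(
    ld: AssociationMatrix,
    dag: DiseaseOntology,
    config: PipelineConfig | None = None,
) -> EvalResult:
    """Leave-one-out cross-validation over all known associations.

    Each known pair is masked in turn, association-dependent similarities
    are recomputed from the masked matrix (when refolding is on), the
    configured variant is run, and the held-out pair's score is ranked
    against the scores of all never-known pairs.
    """
    config = config or PipelineConfig()
    positives = np.argwhere(ld.values == 1.0)
    if len(positives) < 2:
        raise ValueError("LOOCV requires at least two known associations")
    never_known = ld.values == 0.0
    dd_semantic = disease_semantic_similarity(dag, ld.disease_ids, config.decay)
    if not config.refold_similarities:
        ll_full, dd_full, _ = integrated_similarities(ld, dag, config.decay, dd_semantic)

    records: list[FoldRecord] = []
    exceedance: list[float] = []
    weights: list[int] = []
    for i, j in positives:
        masked_values = ld.values.copy()
        masked_values[i, j] = 0.0
        masked = ld.with_values(masked_values)
        if config.refold_similarities:
            ll_f, dd_f, _ = integrated_similarities(masked, dag, config.decay, dd_semantic)
        else:
            ll_f, dd_f = ll_full, dd_full
        scores = run_pipeline(masked, dag, config, similarities=(ll_f, dd_f)).values
        positive_score = scores[i, j]
        negatives = scores[never_known]
        rank, below = _midrank_stats(positive_score, negatives)
        column_negatives = scores[never_known[:, j], j]
        column_rank, _ = _midrank_stats(positive_score, column_negatives)
        records.append(
            FoldRecord(
                ld.lncrna_ids[i],
                ld.disease_ids[j],
                rank,
                negatives.size + 1,
                column_rank,
                column_negatives.size + 1,
            )
        )
        exceedance.append(1.0 - below)
        weights.append(negatives.size)
    return _pooled_result(records, exceedance, weights, config)


def novel_entity_cv(
    ld: AssociationMatrix,
    dag: DiseaseOntology,
    config: PipelineConfig | None = None,
    mode: str = "new_lncrna",
) -> EvalResult:
    """Cold-start cross-validation for new lncRNAs or isolated diseases.

    Each entity with at least one known association has its entire row
    (``new_lncrna``) or column (``isolated_disease``) removed; the pipeline
    is rerun and each removed association is ranked against the entity's
    never-known pairs.
    """
    if mode not in ("new_lncrna", "isolated_disease"):
        raise ValueError("mode must be 'new_lncrna' or 'isolated_disease'")
    config = config or PipelineConfig()
    if not ld.values.any():
        raise ValueError("association matrix has no known links")
    dd_semantic = disease_semantic_similarity(dag, ld.disease_ids, config.decay)
    if not config.refold_similarities:
        ll_full, dd_full, _ = integrated_similarities(ld, dag, config.decay, dd_semantic)

    by_row = mode == "new_lncrna"
    n_entities = ld.nl if by_row else ld.nd
    records: list[FoldRecord] = []
    exceedance: list[float] = []
    weights: list[int] = []
    for e in range(n_entities):
        full_vector = ld.values[e, :] if by_row else ld.values[:, e]
        if not full_vector.any():
            continue
        masked_values = ld.values.copy()
        if by_row:
            masked_values[e, :] = 0.0
        else:
            masked_values[:, e] = 0.0
        if not masked_values.any():
            continue  # no training signal left for this fold
        masked = ld.with_values(masked_values)
        if config.refold_similarities:
            ll_f, dd_f, _ = integrated_similarities(masked, dag, config.decay, dd_semantic)
        else:
            ll_f, dd_f = ll_full, dd_full
        scores = run_pipeline(masked, dag, config, similarities=(ll_f, dd_f)).values
        vector_scores = scores[e, :] if by_row else scores[:, e]
        negatives = vector_scores[full_vector == 0.0]
        if negatives.size == 0:
            continue
        for p in np.flatnonzero(full_vector == 1.0):
            rank, below = _midrank_stats(vector_scores[p], negatives)
            lnc = ld.lncrna_ids[e] if by_row else ld.lncrna_ids[p]
            dis = ld.disease_ids[p] if by_row else ld.disease_ids[e]
            records.append(FoldRecord(lnc, dis, rank, negatives.size + 1, rank, negatives.size + 1))
            exceedance.append(1.0 - below)
            weights.append(negatives.size)
    if not records:
        raise ValueError("no evaluable folds: every removal empties the training matrix")
    return _pooled_result(records, exceedance, weights, config)


def sweep_K(
    ld: AssociationMatrix,
    dag: DiseaseOntology,
    config: PipelineConfig | None = None,
    grid=None,
) -> tuple[pd.DataFrame, float]:
    """LOOCV AUC over a grid of K values; returns the table and the argmax K.

    The default grid runs from 0.1 to 0.9 in steps of 0.1.
    """
    from dataclasses import replace

    config = config or PipelineConfig()
    if grid is None:
        grid = np.round(np.arange(0.1, 1.0, 0.1), 10)
    grid = [float(k) for k in grid]
    if any(not 0.0 < k < 1.0 for k in grid):
        raise ValueError("grid values must lie in (0, 1)")
    rows = []
    for k in grid:
        result = loocv(ld, dag, replace(config, K=k))
        rows.append({"K": k, "auc": result.auc})
    table = pd.DataFrame(rows)
    best_K = float(table.loc[table["auc"].idxmax(), "K"])
    return table, best_K


def rank_candidates(
    final: ScoreMatrix,
    ld: AssociationMatrix,
    disease_id: str,
    k: int,
) -> pd.DataFrame:
    """Top-k candidate lncRNAs for a disease, excluding known associates.

    Candidates are sorted by descending score, ties broken lexicographically
    by lncRNA id; ranks are 1-based. If fewer than k candidates exist, all
    are returned without padding.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    j = ld.disease_index(disease_id)
    if final.stage == "disease_projection":
        column = final.values[j, :]
    else:
        column = final.values[:, j]
    candidates = [i for i in range(ld.nl) if ld.values[i, j] == 0.0]
    order = sorted(candidates, key=lambda i: (-column[i], _key(ld.lncrna_ids[i])))
    rows = [
        {"disease": ld.disease_ids[j], "lncrna": ld.lncrna_ids[i], "rank": r, "score": float(column[i])}
        for r, i in enumerate(order[:k], start=1)
    ]
    return pd.DataFrame(rows, columns=["disease", "lncrna", "rank", "score"])
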