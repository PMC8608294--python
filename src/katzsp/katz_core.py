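"""KATZ walk-counting on the heterogeneous lncRNA-disease network.

The integrated similarities and the association matrix are assembled into a
single symmetric adjacency matrix

    A = [[LL_f, LD], [LD^T, DD_f]]

and node-pair scores count all walks between nodes, a walk of length w
weighted by beta^w. For beta below the spectral bound the infinite sum has
the closed form (I - beta A)^{-1} - I; the lncRNA-by-disease block of that
matrix is the primary prediction score matrix LD_p.

The attenuation factor is parameterised as beta = K / lambda_max(A) with
K in (0, 1), so a single dimensionless knob controls how fast longer walks
are discounted regardless of the network's scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg

from .io_data import AssociationMatrix, _key
from .similarity import SimilarityMatrix

DEFAULT_K = 0.1

STAGES = {"primary", "lncrna_projection", "disease_projection", "final"}


@dataclass
class HeterogeneousAdjacency:
    """(nl+nd) x (nl+nd) adjacency of the joined lncRNA/disease network."""

    values: np.ndarray
    nl: int
    nd: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.nl + self.nd
        if self.values.shape != (n, n):
            raise ValueError(f"adjacency must be {n}x{n}")
        if not np.isfinite(self.values).all():
            raise ValueError("adjacency contains non-finite entries")


@dataclass
class KatzParams:
    """Attenuation parameters: beta = K / lambda_max(A), strictly convergent."""

    K: float
    beta: float
    lambda_max: float

    def __post_init__(self) -> None:
        if not 0.0 < self.K < 1.0:
            raise ValueError("K must lie in (0, 1)")
        if not self.beta * self.lambda_max < 1.0:
            raise ValueError("beta must be strictly below 1/lambda_max(A)")


@dataclass
class ScoreMatrix:
    """Real-valued prediction scores over (lncRNA, disease) pairs.

    Shaped nl x nd for every stage except ``disease_projection``, whose
    natural orientation is nd x nl (its transpose aligns with the others).
    """

    values: np.ndarray
    lncrna_ids: list[str]
    disease_ids: list[str]
    stage: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.stage not in STAGES:
            raise ValueError(f"unknown score stage: {self.stage!r}")
        shape = (len(self.lncrna_ids), len(self.disease_ids))
        if self.stage == "disease_projection":
            shape = shape[::-1]
        if self.values.shape != shape:
            raise ValueError(f"score matrix shape {self.values.shape} does not match ids {shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("score matrix contains non-finite entries")


def build_adjacency(
    ll_final: SimilarityMatrix,
    dd_final: SimilarityMatrix,
    ld: AssociationMatrix,
) -> HeterogeneousAdjacency:
    """Assemble A = [[LL_f, LD], [LD^T, DD_f]]; id orders must agree."""
    if ll_final.n != ld.nl or dd_final.n != ld.nd:
        raise ValueError("similarity block dimensions do not match the association matrix")
    if any(_key(a) != _key(b) for a, b in zip(ll_final.entity_ids, ld.lncrna_ids)):
        raise ValueError("lncRNA similarity ids do not match association rows")
    if any(_key(a) != _key(b) for a, b in zip(dd_final.entity_ids, ld.disease_ids)):
        raise ValueError("disease similarity ids do not match association columns")
    values = np.block([[ll_final.values, ld.values], [ld.values.T, dd_final.values]])
    return HeterogeneousAdjacency(values, ld.nl, ld.nd)


def select_beta(a: HeterogeneousAdjacency, K: float = DEFAULT_K) -> KatzParams:
    """Choose beta = K / lambda_max(A) for a scale factor K in (0, 1).

    lambda_max is computed on the symmetrised matrix (A + A^T)/2 to suppress
    roundoff asymmetry. For the nonnegative symmetric adjacency built here
    the Perron eigenvalue dominates in magnitude, so the eigenvalue bound and
    the spectral-norm bound on beta coincide; this is asserted.
    """
    if not 0.0 < K < 1.0:
        raise ValueError("K must lie in (0, 1)")
    sym = (a.values + a.values.T) / 2.0
    eigenvalues = scipy.linalg.eigvalsh(sym)
    lam_max = float(eigenvalues[-1])
    if lam_max <= 0.0:
        raise ValueError("adjacency has no positive eigenvalue; cannot choose beta")
    spectral_norm = float(np.abs(eigenvalues).max())
    if abs(spectral_norm - lam_max) > 1e-8 * max(1.0, spectral_norm):
        raise ValueError("largest eigenvalue does not dominate the spectrum in magnitude")
    return KatzParams(K=K, beta=K / lam_max, lambda_max=lam_max)


def katz_scores(a: HeterogeneousAdjacency, params: KatzParams) -> np.ndarray:
    """Closed-form KATZ score matrix S = (I - beta A)^{-1} - I.

    Computed by solving (I - beta A) X = beta A, which equals the closed
    form in exact arithmetic while using a single factorization and avoiding
    the subtraction of I after an explicit inverse.
    """
    n = a.values.shape[0]
    ba = params.beta * a.values
    system = np.eye(n) - ba
    try:
        scores = scipy.linalg.solve(system, ba, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("I - beta*A is numerically singular; choose a smaller K") from exc
    return scores


def extract_primary(
    s_katz: np.ndarray,
    nl: int,
    nd: int,
    lncrna_ids: Sequence[str] | None = None,
    disease_ids: Sequence[str] | None = None,
) -> ScoreMatrix:
    """Slice the lncRNA-by-disease block of the KATZ matrix (rows 0..nl-1,
    columns nl..nl+nd-1) as the primary score matrix LD_p."""
    s_katz = np.asarray(s_katz, dtype=float)
    if s_katz.shape != (nl + nd, nl + nd):
        raise ValueError(f"KATZ matrix must be {(nl + nd)}x{(nl + nd)}")
    if lncrna_ids is None:
        lncrna_ids = [f"l{i + 1}" for i in range(nl)]
    if disease_ids is None:
        disease_ids = [f"d{j + 1}" for j in range(nd)]
    return ScoreMatrix(s_katz[:nl, nl:], list(lncrna_ids), list(disease_ids), "primary")
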