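"""Phylogenetic fuzzy weighting and principal coordinates of phylogenetic
structure (PCPS).

Each species' incidence is redistributed over all species in proportion
to phylogenetic similarity (1 - d/d_max, row-standardized), giving the
phylogeny-weighted composition matrix P. A principal coordinates
analysis of dissimilarities among the rows of P yields the PCPS axes;
the first axis captures the dominant gradient in phylogenetic
composition. Species scores are P-weighted averages of site scores and
clade centroids are unweighted means of their member species scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from phylostruct.community import CommunityMatrix
from phylostruct.trees import DistanceMatrix, normalize_name

logger = logging.getLogger(__name__)

SQRT_BRAYCURTIS = "sqrt_braycurtis"
EUCLIDEAN = "euclidean"
_EIG_TOL = 1e-10


@dataclass
class FuzzyWeights:
    """Row-stochastic species × species phylogenetic weights Q."""

    labels: list[str]
    Q: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Q, index=self.labels, columns=self.labels)


@dataclass
class PCPSResult:
    P: pd.DataFrame
    eigenvalues: np.ndarray
    percentages: np.ndarray
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    clade_centroids: pd.DataFrame
    clade_map: dict


def fuzzy_weights(dm: DistanceMatrix) -> FuzzyWeights:
    """Phylogenetic fuzzy weights from a cophenetic distance matrix.

    s_jk = 1 - d_jk / d_max, then each row is standardized to sum to 1.
    """
    if len(dm.labels) < 2:
        raise ValueError("fuzzy weighting requires at least 2 species")
    d_max = dm.values.max()
    if d_max == 0:
        raise ValueError("all pairwise distances are zero (d_max = 0)")
    s = 1.0 - dm.values / d_max
    Q = s / s.sum(axis=1, keepdims=True)
    return FuzzyWeights(labels=list(dm.labels), Q=Q)


def matrix_p(cm: CommunityMatrix, fw: FuzzyWeights) -> pd.DataFrame:
    """Phylogeny-weighted species composition: P = row-normalized W · Q."""
    cm_keys = [normalize_name(s) for s in cm.species_names]
    fw_keys = [normalize_name(l) for l in fw.labels]
    if set(cm_keys) != set(fw_keys):
        diff = sorted(set(cm_keys) ^ set(fw_keys))
        raise ValueError(f"species mismatch between community and weights: {diff}")
    order = [fw_keys.index(k) for k in cm_keys]
    Q = fw.Q[np.ix_(order, order)]
    W = cm.incidence.to_numpy(dtype=float)
    Wn = W / W.sum(axis=1, keepdims=True)
    P = Wn @ Q
    return pd.DataFrame(P, index=cm.site_ids, columns=cm.species_names)


def _dissimilarity(P: np.ndarray, distance: str) -> np.ndarray:
    if distance == SQRT_BRAYCURTIS:
        return np.sqrt(squareform(pdist(P, metric="braycurtis")))
    if distance == EUCLIDEAN:
        return squareform(pdist(P, metric="euclidean"))
    raise ValueError(f"unknown distance {distance!r}")


def pcoa(
    P: pd.DataFrame, distance: str = SQRT_BRAYCURTIS
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Principal coordinates of the rows of P.

    Gower double-centering of -D²/2 followed by an eigendecomposition;
    axes with non-positive eigenvalues are discarded, scores are
    eigenvectors scaled by sqrt(eigenvalue), and each axis is flipped so
    the lexicographically smallest site id has a non-negative score.

    Returns (eigenvalues, percentages, site_scores).
    """
    if len(P) < 3:
        raise ValueError("PCoA requires at least 3 sites")
    D = _dissimilarity(P.to_numpy(dtype=float), distance)
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > _EIG_TOL * max(abs(eigval[0]), 1.0)
    if not keep.any():
        raise ValueError("degenerate ordination: no positive eigenvalues")
    eigval = eigval[keep]
    scores = eigvec[:, keep] * np.sqrt(eigval)
    percentages = 100.0 * eigval / eigval.sum()

    # canonical axis orientation, reproducible across site orderings
    lex = np.argsort(np.asarray(P.index.astype(str)))
    for a in range(scores.shape[1]):
        col = scores[:, a]
        for i in lex:
            if abs(col[i]) > 1e-12:
                if col[i] < 0:
                    scores[:, a] = -col
                break
    site_scores = pd.DataFrame(
        scores,
        index=P.index,
        columns=[f"pcps_{a + 1}" for a in range(scores.shape[1])],
    )
    return eigval, percentages, site_scores


def species_and_clade_scores(
    P: pd.DataFrame,
    site_scores: pd.DataFrame,
    clade_map: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Species scores (P-weighted site-score averages) and clade centroids."""
    Pm = P.to_numpy(dtype=float)
    Z = site_scores.to_numpy(dtype=float)
    mass = Pm.sum(axis=0)
    keep = mass > 0
    if not keep.all():
        excluded = [s for s, k in zip(P.columns, keep) if not k]
        logger.info("species with zero column mass excluded: %s", excluded)
    S = (Pm[:, keep].T @ Z) / mass[keep][:, None]
    species_scores = pd.DataFrame(
        S, index=[s for s, k in zip(P.columns, keep) if k],
        columns=site_scores.columns,
    )
    if clade_map is None:
        clade_map = {}
    clades = pd.Series(
        [clade_map.get(sp, clade_map.get(normalize_name(sp), "other"))
         for sp in species_scores.index],
        index=species_scores.index,
        name="clade",
    )
    clade_centroids = species_scores.groupby(clades).mean()
    clade_centroids.index.name = "clade"
    return species_scores, clade_centroids


def pcps_analysis(
    dm: DistanceMatrix,
    cm: CommunityMatrix,
    clade_map: dict | None = None,
    distance: str = SQRT_BRAYCURTIS,
) -> PCPSResult:
    """Full PCPS: fuzzy weights → matrix P → PCoA → species/clade scores."""
    fw = fuzzy_weights(dm)
    # the weights may cover a supertree; restrict to community species
    if set(normalize_name(s) for s in fw.labels) != set(
        normalize_name(s) for s in cm.species_names
    ):
        keys = {normalize_name(s) for s in cm.species_names}
        idx = [i for i, l in enumerate(fw.labels) if normalize_name(l) in keys]
        sub = dm.values[np.ix_(idx, idx)]
        fw = fuzzy_weights(
            DistanceMatrix(labels=[fw.labels[i] for i in idx], values=sub)
        )
    P = matrix_p(cm, fw)
    eigval, pct, site_scores = pcoa(P, distance=distance)
    species_scores, clade_centroids = species_and_clade_scores(
        P, site_scores, clade_map
    )
    return PCPSResult(
        P=P,
        eigenvalues=eigval,
        percentages=pct,
        site_scores=site_scores,
        species_scores=species_scores,
        clade_centroids=clade_centroids,
        clade_map=dict(clade_map or {}),
    )
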