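"""Cross-model comparison of signature rate profiles ("topotypes").

Rate profiles learned under different tissues' features are transferred to
one shared feature matrix, compared by cosine similarity over a held-out
evaluation chromosome, clustered with the Leiden algorithm on a symmetrized
kNN graph, and embedded in 2-D with UMAP.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd

from .binning import FeatureMatrix
from .model import ModelState, topography_distribution

logger = logging.getLogger(__name__)

DEFAULT_RESOLUTION = 0.2
DEFAULT_KNN = 10
DEFAULT_MIN_DIST = 0.1


@dataclass
class TopotypeResult:
    profiles: np.ndarray       # (n_signatures, N_bins) transferred profiles
    signature_ids: list[str]
    similarity: np.ndarray     # (n, n) cosine similarity, unit diagonal
    labels: np.ndarray         # Leiden community per signature
    embedding: np.ndarray | None  # (n, 2) UMAP coordinates


def transfer_profiles(models: Sequence[ModelState], shared_X: FeatureMatrix,
                      shared_t: np.ndarray
                      ) -> tuple[np.ndarray, list[str]]:
    """Evaluate every model's processes on a shared feature matrix.

    Each signature's topography (macro and spectra effects) is evaluated on
    the shared features and availability, and its genomic marginal returned;
    transferring a model onto its own training features reproduces its
    genomic marginals exactly.  Missing features raise with their names.
    """
    rows, ids = [], []
    for mi, model in enumerate(models):
        needed = (set(model.macro_features) | set(model.meso_features)
                  | set(model.strand_features))
        missing = sorted(needed - set(shared_X.feature_names))
        if missing:
            raise KeyError(
                f"shared feature matrix lacks features {missing} "
                f"required by model {mi}")
        for proc in model.processes:
            table = topography_distribution(proc, shared_X, shared_t)
            rows.append(table.sum(axis=1))
            ids.append(f"m{mi}:{proc.label or len(ids)}")
    return np.stack(rows), ids


def cosine_similarity_matrix(profiles: np.ndarray,
                             eval_mask: np.ndarray | None = None
                             ) -> np.ndarray:
    P = profiles if eval_mask is None else profiles[:, eval_mask]
    norms = np.linalg.norm(P, axis=1, keepdims=True)
    U = P / np.clip(norms, 1e-300, None)
    sim = U @ U.T
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, -1.0, 1.0)


def topotype_cluster(profiles: np.ndarray, eval_mask: np.ndarray | None = None,
                     knn: int = DEFAULT_KNN,
                     resolution: float = DEFAULT_RESOLUTION,
                     seed: int = 0, embed: bool = True,
                     min_dist: float = DEFAULT_MIN_DIST) -> TopotypeResult:
    """Leiden communities + UMAP embedding of rate profiles.

    The similarity graph is a symmetrized kNN graph weighted by cosine
    similarity, restricted to ``eval_mask`` bins (the held-out chromosome).
    """
    n = profiles.shape[0]
    if n <= knn:
        logger.warning("only %d profiles; reducing knn from %d to %d",
                       n, knn, max(1, n - 1))
        knn = max(1, n - 1)
    sim = cosine_similarity_matrix(profiles, eval_mask)
    edges, weights = set(), {}
    for i in range(n):
        order = np.argsort(-sim[i])
        neighbors = [j for j in order if j != i][:knn]
        for j in neighbors:
            e = (min(i, j), max(i, j))
            edges.add(e)
            weights[e] = max(weights.get(e, 0.0), float(sim[i, j]))
    edge_list = sorted(edges)
    g = ig.Graph(n=n, edges=edge_list)
    g.es["weight"] = [max(weights[e], 1e-12) for e in edge_list]
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights="weight", resolution_parameter=resolution, seed=seed)
    labels = np.array(part.membership)

    embedding = None
    if embed:
        import umap

        P = profiles if eval_mask is None else profiles[:, eval_mask]
        n_neighbors = min(knn, n - 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(n_neighbors=n_neighbors, min_dist=min_dist,
                                metric="cosine", random_state=seed,
                                negative_sample_rate=3)
            embedding = reducer.fit_transform(P)
    return TopotypeResult(profiles, [str(i) for i in range(n)], sim, labels,
                          embedding)


def topotype_attribution(labels: np.ndarray,
                         exposures_per_model: Sequence[np.ndarray],
                         burdens_per_model: Sequence[np.ndarray]
                         ) -> tuple[pd.DataFrame, list[np.ndarray]]:
    """Aggregate mutations over topotypes at signature and sample level.

    ``labels`` orders signatures as transfer_profiles emitted them (model by
    model).  Returns a signature-level table (cohort, signature, topotype,
    mutations) and, per cohort, sample-level topotype exposure vectors on
    the simplex.
    """
    n_topotypes = int(labels.max()) + 1
    sig_rows = []
    sample_level = []
    offset = 0
    for ci, (pi, burdens) in enumerate(zip(exposures_per_model,
                                           burdens_per_model)):
        K = pi.shape[1]
        lab = labels[offset:offset + K]
        offset += K
        muts_per_sig = (pi * np.asarray(burdens)[:, None]).sum(axis=0)
        for k in range(K):
            sig_rows.append({"cohort": ci, "signature": k,
                             "topotype": int(lab[k]),
                             "mutations": float(muts_per_sig[k])})
        topo_pi = np.zeros((pi.shape[0], n_topotypes))
        for k in range(K):
            topo_pi[:, lab[k]] += pi[:, k]
        sample_level.append(topo_pi)
    return pd.DataFrame(sig_rows), sample_level
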