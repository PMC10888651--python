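"""Signature similarity (Pearson + Ward clustering) and pathway enrichment.

The clustering step asks whether datasets respond to treatment in coherent
groups: each dataset is represented by a feature vector (by default its
signature logFC restricted to the consensus-selected genes, zero-filled where
absent), pairwise Pearson correlations are computed, and agglomerative Ward
clustering on the standardized vectors partitions the datasets. Enrichment of
consensus genes in pathway gene sets uses the hypergeometric upper tail with
Benjamini-Hochberg correction at q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import hypergeom

from .diffexpr import benjamini_hochberg
from .errors import ValidationError
from .formats_io import DenseMatrixFile, GeneSetCollection

ENRICHMENT_COLUMNS = [
    "set_id", "overlap", "set_size", "query_size", "universe_size",
    "p_value", "q_value", "significant",
]


@dataclass
class ClusterResult:
    labels: pd.Series  # dataset -> cluster id (1-based)
    linkage: np.ndarray  # scipy linkage matrix
    n_clusters: int


def _as_frame(vectors) -> pd.DataFrame:
    if isinstance(vectors, pd.DataFrame):
        return vectors
    return pd.DataFrame(vectors)


def signature_correlation(vectors) -> pd.DataFrame:
    """Pearson correlation matrix between dataset vectors on a shared gene set.

    ``vectors`` is a genes x datasets frame (or mapping of dataset -> vector).
    A constant vector has no defined correlation and raises an error naming the
    dataset.
    """
    frame = _as_frame(vectors)
    if frame.shape[1] < 2:
        raise ValidationError("signature_correlation needs at least 2 datasets")
    if frame.shape[0] == 0:
        raise ValidationError("shared gene set is empty")
    stds = frame.std(ddof=0)
    constant = list(stds.index[stds == 0])
    if constant:
        raise ValidationError(f"constant vector(s), correlation undefined: {constant}")
    corr = frame.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def ward_cluster(vectors, n_clusters: int | None = None) -> ClusterResult:
    """Ward agglomerative clustering of standardized dataset vectors.

    Vectors are z-scored per dataset so Euclidean distance tracks correlation.
    With ``n_clusters`` omitted, the tree is cut at the largest gap between
    consecutive merge heights.
    """
    frame = _as_frame(vectors)
    if frame.shape[1] < 2:
        raise ValidationError("ward_cluster needs at least 2 datasets")
    x = frame.to_numpy(dtype=float).T  # datasets x genes
    sd = x.std(axis=1, ddof=0)
    mu = x.mean(axis=1)
    standardized = np.where(sd[:, None] > 0, (x - mu[:, None]) / np.where(sd[:, None] > 0, sd[:, None], 1.0), 0.0)
    z = linkage(standardized, method="ward")
    if n_clusters is None:
        heights = z[:, 2]
        if len(heights) < 2:
            n_clusters = 2
            labels = fcluster(z, t=2, criterion="maxclust")
        else:
            gaps = np.diff(heights)
            i = int(np.argmax(gaps))
            threshold = (heights[i] + heights[i + 1]) / 2.0
            labels = fcluster(z, t=threshold, criterion="distance")
            n_clusters = int(labels.max())
    else:
        labels = fcluster(z, t=n_clusters, criterion="maxclust")
    return ClusterResult(
        labels=pd.Series(labels, index=frame.columns, name="cluster"),
        linkage=z,
        n_clusters=int(n_clusters),
    )


def hypergeom_pvalue(overlap: int, set_size: int, query_size: int, universe_size: int) -> float:
    """Upper-tail P[X >= overlap], X ~ Hypergeometric(universe, set, query)."""
    return float(hypergeom.sf(overlap - 1, universe_size, set_size, query_size))


def hypergeom_enrich(
    query: Sequence[str],
    sets: GeneSetCollection,
    universe: Sequence[str],
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Gene sets and the query are intersected with the universe first; BH
    correction runs across all tested sets and significance is called at
    q < ``q_cutoff``.
    """
    universe_set = set(universe)
    query_set = set(query) & universe_set
    if not query_set:
        raise ValidationError("enrichment query is empty (after universe intersection)")
    rows = []
    for s in sets:
        members = set(s.genes) & universe_set
        overlap = len(members & query_set)
        p = hypergeom_pvalue(overlap, len(members), len(query_set), len(universe_set))
        rows.append(
            {
                "set_id": s.set_id,
                "overlap": overlap,
                "set_size": len(members),
                "query_size": len(query_set),
                "universe_size": len(universe_set),
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValidationError("no gene sets to test")
    table["q_value"] = benjamini_hochberg(table["p_value"].to_numpy())
    table["significant"] = table["q_value"] < q_cutoff
    return table.sort_values(["p_value", "set_id"], kind="stable").reset_index(drop=True)


def compound_pathway_matrix(records: Mapping[str, pd.DataFrame]) -> DenseMatrixFile:
    """Pathways x compounds matrix of overlap gene counts for significant pairs.

    Rows are the union of pathways significant for at least one compound;
    entries are the overlap counts where q < cutoff, NA otherwise.
    """
    pathways: list[str] = []
    for table in records.values():
        for sid in table.loc[table["significant"], "set_id"]:
            if sid not in pathways:
                pathways.append(str(sid))
    compounds = list(records.keys())
    values = np.full((len(pathways), len(compounds)), np.nan)
    for j, (pert, table) in enumerate(records.items()):
        sig = table[table["significant"]].set_index("set_id")["overlap"]
        for i, pathway in enumerate(pathways):
            if pathway in sig.index:
                values[i, j] = float(sig.loc[pathway])
    return DenseMatrixFile(pathways, compounds, values)


def feature_vectors(
    deg_tables: Mapping[str, pd.DataFrame], genes: Sequence[str]
) -> pd.DataFrame:
    """Dataset feature vectors: logFC on a shared gene list, zero-filled.

    ``deg_tables`` maps dataset id to its DEG table; ``genes`` is typically the
    union of consensus-selected genes across datasets.
    """
    genes = list(dict.fromkeys(genes))
    if not genes:
        raise ValidationError("feature_vectors: empty gene list")
    data = {}
    for name, table in deg_tables.items():
        lfc = table.set_index("gene_id")["logFC"]
        data[name] = [float(lfc.get(g, 0.0)) for g in genes]
    return pd.DataFrame(data, index=genes)
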