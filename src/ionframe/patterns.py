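"""Six-pattern classification of metastasis-specific proteins.

Each protein's four tumor-group means (non-metastatic NM, primary-site P,
kidney-metastasis K, lung-metastasis L) are standardized to z-scores and
classified by an explicit, deterministic rule cascade with a margin
``delta`` (default 0.5): a group (or group set) "dominates" when its
z-score clears the competing groups by at least ``delta``.  Hierarchical
clustering (average linkage, 1 - Pearson distance) is kept for ordering
and visualization; the label cascade, not the dendrogram, is the
classification of record.  Proteins labelled NON_METASTATIC are excluded
from the final metastasis-specific list.
"""

from __future__ import annotations

import warnings
from enum import Enum

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .types import ProteinMatrix

DEFAULT_MARGIN = 0.5


class Pattern(str, Enum):
    METASTATIC = "METASTATIC"
    NON_METASTATIC = "NON_METASTATIC"
    PRIMARY_SITE = "PRIMARY_SITE"
    KIDNEY_LUNG = "KIDNEY_LUNG"
    KIDNEY = "KIDNEY"
    LUNG = "LUNG"


#: Fallback label of each tumor group (argmax tie-break order NM, P, K, L).
_FALLBACK = (Pattern.NON_METASTATIC, Pattern.PRIMARY_SITE, Pattern.KIDNEY, Pattern.LUNG)


def standardize_profiles(
    matrix: ProteinMatrix, tumor_groups: list[str], proteins: list[str] | None = None
) -> pd.DataFrame:
    """Protein x tumor-group z-score table of group means.

    Group means are standardized per protein across the four tumor groups
    (sample sd, ddof = 1); a constant profile gets all-zero z-scores with a
    warning.
    """
    if len(tumor_groups) != 4:
        raise ValueError("pattern classification expects exactly four tumor groups")
    means = pd.DataFrame(
        {g: matrix.group_columns(g).mean(axis=1) for g in tumor_groups}
    )
    if proteins is not None:
        means = means.loc[list(proteins)]
    if means.empty:
        raise ValueError("no proteins to standardize")
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant profiles standardized to all-zero z-scores",
            stacklevel=2,
        )
    z = means.sub(mu, axis=0).div(sd.mask(constant, 1.0), axis=0)
    z.loc[constant, :] = 0.0
    return z


def assign_pattern(z: np.ndarray, margin: float = DEFAULT_MARGIN) -> Pattern:
    """Classify one standardized 4-vector ordered (NM, P, K, L).

    Decision cascade (first matching rule wins):

    1. NM clears the metastatic groups by ``margin``  -> NON_METASTATIC
    2. every metastatic group clears NM by ``margin`` -> METASTATIC
    3. P clears all others by ``margin``              -> PRIMARY_SITE
    4. K and L both clear NM and P by ``margin``      -> KIDNEY_LUNG
    5. K clears all others by ``margin``              -> KIDNEY
    6. L clears all others by ``margin``              -> LUNG

    Fallback: the label of the argmax group, ties broken NM -> P -> K -> L.
    The cascade is invariant to adding a constant to all four z-scores.
    """
    z = np.asarray(z, dtype=float)
    if z.shape != (4,):
        raise ValueError("pattern assignment expects a 4-vector (NM, P, K, L)")
    nm, p, k, l = z
    if nm - max(p, k, l) >= margin:
        return Pattern.NON_METASTATIC
    if min(p, k, l) - nm >= margin:
        return Pattern.METASTATIC
    if p - max(nm, k, l) >= margin:
        return Pattern.PRIMARY_SITE
    if min(k, l) - nm >= margin and min(k, l) - p >= margin:
        return Pattern.KIDNEY_LUNG
    if k - max(nm, p, l) >= margin:
        return Pattern.KIDNEY
    if l - max(nm, p, k) >= margin:
        return Pattern.LUNG
    return _FALLBACK[int(np.argmax(z))]


def assign_patterns(z_table: pd.DataFrame, margin: float = DEFAULT_MARGIN) -> pd.DataFrame:
    """Label every protein; ``excluded`` flags the NON_METASTATIC pattern."""
    labels = [assign_pattern(row, margin=margin).value for row in z_table.to_numpy()]
    out = z_table.copy()
    out["pattern"] = labels
    out["excluded"] = out["pattern"] == Pattern.NON_METASTATIC.value
    return out


def exclude_non_metastatic(assignments: pd.DataFrame) -> pd.DataFrame:
    """Drop NON_METASTATIC proteins; |output| = |input| - |pattern NM|."""
    return assignments[~assignments["excluded"]].copy()


def cluster_profiles(
    z_table: pd.DataFrame, n_clusters: int = 6
) -> tuple[np.ndarray, list[str], pd.Series]:
    """Average-linkage clustering on 1 - Pearson distance over z profiles.

    Returns ``(linkage matrix, leaf order (protein ids), flat cluster ids)``.
    A single profile yields a single leaf and cluster.
    """
    ids = list(z_table.index)
    if len(ids) < 2:
        return np.empty((0, 4)), ids, pd.Series(1, index=z_table.index)
    x = z_table.to_numpy(dtype=float)
    # guard constant rows: correlation undefined, treat as zero vectors
    d = pdist(x, metric="correlation")
    d = np.nan_to_num(d, nan=1.0)
    link = hierarchy.linkage(d, method="average")
    order = [ids[i] for i in hierarchy.leaves_list(link)]
    flat = hierarchy.fcluster(link, t=min(n_clusters, len(ids)), criterion="maxclust")
    return link, order, pd.Series(flat, index=z_table.index, name="cluster")


def dendrogram_newick(link: np.ndarray, ids: list[str]) -> str:
    """Serialize a scipy linkage matrix as a Newick string (branch lengths =
    merge-height differences)."""
    if len(ids) == 1:
        return f"{ids[0]};"
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{ids[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
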