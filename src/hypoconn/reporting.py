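"""Atlas-overlap labeling and hierarchical network clustering."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform


@dataclass
class AtlasVolume:
    """Integer-labeled region volume (0 = background) with a name table."""

    labels: np.ndarray
    names: dict                      # int label -> region name

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.names)
        if missing:
            raise ValueError(f"atlas labels without names: {sorted(missing)}")


def atlas_overlap(active_map: np.ndarray, atlas: AtlasVolume,
                  min_fraction: float = 0.05) -> pd.DataFrame:
    """Fraction of each atlas region's voxels inside the active map.

    A region is flagged ``reported`` when at least ``min_fraction`` of its
    voxels fall inside the component (default: 5%).  Sorted by fraction,
    descending.
    """
    active = np.asarray(active_map, dtype=bool)
    if active.shape != atlas.labels.shape:
        raise ValueError("active map and atlas have mismatched geometry")
    rows = []
    for label, name in sorted(atlas.names.items()):
        region = atlas.labels == label
        n_region = int(region.sum())
        if n_region == 0:
            continue
        n_overlap = int((region & active).sum())
        frac = n_overlap / n_region
        rows.append({"label": label, "region": name, "region_voxels": n_region,
                     "overlap_voxels": n_overlap, "fraction": frac,
                     "reported": frac >= min_fraction})
    df = pd.DataFrame(rows, columns=["label", "region", "region_voxels",
                                     "overlap_voxels", "fraction", "reported"])
    return df.sort_values("fraction", ascending=False, kind="stable",
                          ignore_index=True)


@dataclass
class NetMat:
    """Full correlation matrix of component time courses plus linkage tree."""

    correlation: np.ndarray          # (K, K)
    linkage_tree: np.ndarray         # scipy linkage matrix
    leaf_order: np.ndarray
    excluded: list = field(default_factory=list)
    distance: str = "1 - r, average linkage"


def netmat_cluster(timecourses: np.ndarray) -> NetMat:
    """Pearson netmat with average-linkage clustering on distance 1 - r.

    ``timecourses``: (T, K).  Constant time courses are excluded with a
    warning (their correlations are undefined).
    """
    tc = np.asarray(timecourses, dtype=float)
    T, K = tc.shape
    if K < 2:
        raise ValueError("need at least 2 components")
    if T <= K:
        raise ValueError("need more timepoints than components")
    sd = tc.std(axis=0)
    excluded = list(np.flatnonzero(sd == 0))
    if excluded:
        warnings.warn(f"excluding constant time courses: {excluded}")
    keep = np.flatnonzero(sd > 0)
    r = np.corrcoef(tc[:, keep].T)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    dist = squareform(np.maximum(1.0 - r, 0.0), checks=False)
    tree = linkage(dist, method="average")
    from scipy.cluster.hierarchy import leaves_list
    order = keep[leaves_list(tree)]
    full = np.full((K, K), np.nan)
    full[np.ix_(keep, keep)] = r
    return NetMat(correlation=full, linkage_tree=tree, leaf_order=order,
                  excluded=excluded)


def cut_clusters(net: NetMat, n_clusters: int) -> np.ndarray:
    """Flat cluster labels for the retained components."""
    from scipy.cluster.hierarchy import fcluster
    return fcluster(net.linkage_tree, t=n_clusters, criterion="maxclust")
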