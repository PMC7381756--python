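"""Observed per-site alpha metrics: Faith's PD, MPD, MNTD, richness."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from phylostruct.community import CommunityMatrix
from phylostruct.trees import DistanceMatrix, PhyloTree, TreeError, normalize_name


def pd_faith(tree: PhyloTree, present, include_root: bool = True) -> float:
    """Total branch length of the minimal subtree spanning *present* tips.

    With ``include_root`` the path from the tips' most recent common
    ancestor up to the root is included, so the whole tip set yields the
    total tree length. A single species without the root path has PD 0.
    """
    present = list(present)
    keys = {normalize_name(s) for s in present}
    if not keys:
        raise TreeError("empty species set")
    dtree = tree.dendropy_tree
    tip_keys = {normalize_name(l) for l in tree.tip_labels}
    unknown = sorted(s for s in present if normalize_name(s) not in tip_keys)
    if unknown:
        raise TreeError(f"species not on the tree: {unknown}")

    total = 0.0
    mrca_depth = 0.0
    # postorder flag: does this subtree contain a present tip?
    has_present: dict[int, bool] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            flag = normalize_name(node.taxon.label) in keys
        else:
            flag = any(has_present[id(c)] for c in node.child_nodes())
        has_present[id(node)] = flag
        if flag and node is not dtree.seed_node:
            total += node.edge.length or 0.0
    if not include_root:
        # a single tip spans no edges once the root path is removed
        if len(keys) == 1:
            return 0.0
        # depth of the MRCA: walk from the root down the unique present lineage
        node = dtree.seed_node
        while True:
            present_children = [
                c for c in node.child_nodes() if has_present[id(c)]
            ]
            if len(present_children) != 1:
                break
            mrca_depth += present_children[0].edge.length or 0.0
            node = present_children[0]
        return total - mrca_depth
    return total


def mpd(dm: DistanceMatrix, present) -> float:
    """Mean pairwise distance over all unordered distinct pairs.

    Returns NaN for fewer than two species (missing value, not an error,
    so pipelines can propagate it).
    """
    present = list(present)
    if len(present) < 2:
        return math.nan
    sub = dm.submatrix(present)
    n = sub.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(sub[iu].mean())


def mntd(dm: DistanceMatrix, present) -> float:
    """Mean distance from each species to its nearest co-occurring relative."""
    present = list(present)
    if len(present) < 2:
        return math.nan
    sub = dm.submatrix(present).copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def site_metrics(
    tree: PhyloTree,
    dm: DistanceMatrix,
    cm: CommunityMatrix,
    include_root: bool = True,
) -> pd.DataFrame:
    """Per-site SR, PD, MPD_obs and MNTD_obs as a frame indexed by site."""
    rows = []
    for site in cm.site_ids:
        present = cm.present_at(site)
        rows.append(
            {
                "site_id": site,
                "SR": len(present),
                "PD": pd_faith(tree, present, include_root=include_root),
                "MPD_obs": mpd(dm, present),
                "MNTD_obs": mntd(dm, present),
            }
        )
    return pd.DataFrame(rows).set_index("site_id")
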