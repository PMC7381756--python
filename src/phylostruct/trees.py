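"""Rooted phylogenies: Newick I/O, megatree pruning/grafting, patristic distances.

The tree representation wraps :mod:`dendropy` behind a small validated
facade so the rest of the package only deals with tip labels and a
symmetric cophenetic (patristic) distance matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class NewickParseError(ValueError):
    """Malformed Newick input (syntax, duplicate tips, negative lengths)."""


class TreeError(ValueError):
    """Invalid tree operation (unknown taxa, too few tips, ...)."""


def normalize_name(name: str) -> str:
    """Canonical matching key for a taxon name.

    Spaces become underscores and the comparison is case-insensitive.
    """
    return "_".join(str(name).strip().split()).lower()


def canonical_label(name: str) -> str:
    """Display form of a taxon name: whitespace collapsed to underscores."""
    return "_".join(str(name).strip().split())


@dataclass
class DistanceMatrix:
    """Symmetric matrix of tip-to-tip path lengths (patristic distances)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal is not zero")
        if np.any(self.values < 0):
            raise ValueError("distance matrix has negative entries")
        self._index = {normalize_name(l): i for i, l in enumerate(self.labels)}

    def indexer(self, labels) -> np.ndarray:
        """Positions of *labels* (normalized match) in this matrix."""
        try:
            return np.array([self._index[normalize_name(l)] for l in labels])
        except KeyError as exc:
            raise KeyError(f"label not in distance matrix: {exc.args[0]}") from None

    def submatrix(self, labels) -> np.ndarray:
        idx = self.indexer(labels)
        return self.values[np.ix_(idx, idx)]

    def get(self, a: str, b: str) -> float:
        i, j = self.indexer([a, b])
        return float(self.values[i, j])


class PhyloTree:
    """A rooted tree with branch lengths and unique tip labels."""

    def __init__(self, dtree: dendropy.Tree):
        self._tree = dtree
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        return parse_newick(text)

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        leaves = [lf for lf in self._tree.leaf_node_iter()]
        labels = []
        for lf in leaves:
            if lf.taxon is None or lf.taxon.label is None:
                raise NewickParseError("tree has an unlabeled tip")
            labels.append(canonical_label(lf.taxon.label))
        seen: set[str] = set()
        for lab in labels:
            key = normalize_name(lab)
            if key in seen:
                raise NewickParseError(f"duplicate tip label: {lab!r}")
            seen.add(key)
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                head = edge.head_node
                name = head.taxon.label if head.taxon else "<internal>"
                raise NewickParseError(
                    f"negative branch length {edge.length} on edge above {name!r}"
                )
        self._labels = labels

    # -- basic queries ------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return list(self._labels)

    @property
    def n_tips(self) -> int:
        return len(self._labels)

    def total_branch_length(self) -> float:
        return float(
            sum(
                e.length or 0.0
                for e in self._tree.preorder_edge_iter()
                if e.head_node is not self._tree.seed_node
            )
        )

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip() + "\n"

    # internal accessor used by sibling modules
    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_tips={self.n_tips})"


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`."""
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except NewickParseError:
        raise
    except Exception as exc:
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    dtree.is_rooted = True  # treated as rooted at the outermost node
    return PhyloTree(dtree)


def _leaf_by_key(dtree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {
        normalize_name(lf.taxon.label): lf
        for lf in dtree.leaf_node_iter()
    }


def _path_length_to_ancestor(node: dendropy.Node, anc: dendropy.Node) -> float:
    total = 0.0
    cur = node
    while cur is not anc:
        total += cur.edge.length or 0.0
        cur = cur.parent_node
        if cur is None:
            raise TreeError("node is not a descendant of the given ancestor")
    return total


def prune_to_taxa(
    tree: PhyloTree,
    taxa,
    graft_missing: bool = False,
) -> tuple[PhyloTree, pd.DataFrame]:
    """Restrict *tree* to *taxa*, optionally grafting absent congeners.

    Names are matched case-insensitively after collapsing whitespace to
    underscores. A requested name absent from the tree is, when
    ``graft_missing`` is set, attached as a polytomy child of the most
    recent common ancestor of its congeners (same genus token) with a
    pendant length equal to the mean path length from that ancestor to
    the congener tips; with a single congener the attachment point is
    that tip's parent. Names with no congener are dropped.

    Returns the pruned tree and a report frame with columns
    ``name`` and ``status`` (``kept`` / ``grafted`` / ``dropped``).
    """
    taxa = list(taxa)
    if not taxa:
        raise TreeError("no taxa requested")

    work = tree.dendropy_tree.clone(depth=1)
    by_key = _leaf_by_key(work)

    records: list[tuple[str, str]] = []
    keep_labels: list[str] = []
    missing: list[str] = []
    requested_keys: set[str] = set()
    for name in taxa:
        key = normalize_name(name)
        if key in requested_keys:
            continue
        requested_keys.add(key)
        if key in by_key:
            keep_labels.append(by_key[key].taxon.label)
            records.append((canonical_label(name), "kept"))
        else:
            missing.append(canonical_label(name))

    if graft_missing and missing:
        genus_index: dict[str, list[dendropy.Node]] = {}
        for key, leaf in by_key.items():
            genus_index.setdefault(key.split("_")[0], []).append(leaf)
        for name in missing:
            genus = normalize_name(name).split("_")[0]
            congeners = genus_index.get(genus, [])
            if not congeners:
                records.append((name, "dropped"))
                continue
            if len(congeners) == 1:
                attach = congeners[0].parent_node
                pendant = congeners[0].edge.length or 0.0
            else:
                attach = work.mrca(taxa=[lf.taxon for lf in congeners])
                pendant = float(
                    np.mean(
                        [_path_length_to_ancestor(lf, attach) for lf in congeners]
                    )
                )
            new_taxon = work.taxon_namespace.new_taxon(label=name)
            attach.new_child(taxon=new_taxon, edge_length=pendant)
            keep_labels.append(name)
            records.append((name, "grafted"))
            logger.info("grafted %r at mean congener depth %.6g", name, pendant)
    else:
        records.extend((name, "dropped") for name in missing)

    if not keep_labels:
        raise TreeError("no resolvable taxa")

    for name, status in records:
        if status == "dropped":
            logger.warning("taxon %r not resolvable on the tree; dropped", name)

    work.retain_taxa_with_labels(keep_labels)
    work.purge_taxon_namespace()
    report = pd.DataFrame(records, columns=["name", "status"])
    return PhyloTree(work), report


def cophenetic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Pairwise tip-to-tip path lengths (sum of branch lengths)."""
    if tree.n_tips < 2:
        raise TreeError("cophenetic matrix requires at least 2 tips")
    dtree = tree.dendropy_tree
    pdm = dtree.phylogenetic_distance_matrix()
    leaves = list(dtree.leaf_node_iter())
    labels = [canonical_label(lf.taxon.label) for lf in leaves]
    n = len(leaves)
    values = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(leaves[i].taxon, leaves[j].taxon)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)
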