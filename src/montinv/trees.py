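"""Rooted, branch-length-bearing phylogenies with genus/family tip annotations.

A thin wrapper around :mod:`dendropy` trees.  Tip labels are species
binomials; the genus defaults to the first token of the binomial and the
family comes from a genus-to-family map (required by the grafting step,
which attaches unsampled species at genus or family basal nodes).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np

__all__ = ["Phylogeny", "read_newick", "write_newick"]


class Phylogeny:
    """A rooted tree with branch lengths and per-tip genus/family annotations.

    Branch lengths are in arbitrary time-like units (Myr for dated trees);
    all must be non-negative and tip labels unique.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        genus_to_family: Mapping[str, str] | None = None,
    ):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None or edge.length < 0:
                raise ValueError("all branch lengths must be present and >= 0")
        self._genus_to_family = dict(genus_to_family or {})
        self._dist_cache: tuple[list[str], np.ndarray] | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @staticmethod
    def genus_of(tip_label: str) -> str:
        return tip_label.split()[0].split("_")[0]

    def family_of(self, tip_label: str) -> str:
        g = self.genus_of(tip_label)
        try:
            return self._genus_to_family[g]
        except KeyError:
            raise KeyError(f"no family annotation for genus {g!r}") from None

    @property
    def genus_to_family(self) -> dict[str, str]:
        return dict(self._genus_to_family)

    def annotate_families(self, genus_to_family: Mapping[str, str]) -> None:
        self._genus_to_family.update(genus_to_family)

    # -- geometry ----------------------------------------------------------
    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path lengths."""
        out = {}
        for leaf in self.tree.leaf_node_iter():
            out[leaf.taxon.label] = leaf.distance_from_root()
        return out

    @property
    def height(self) -> float:
        return max(self.tip_depths().values())

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        d = list(self.tip_depths().values())
        return (max(d) - min(d)) <= tol

    def distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """All pairwise patristic (path-length) distances among tips.

        O(n^2) via node depths: ``d(a, b) = depth(a) + depth(b) -
        2 * depth(mrca(a, b))``, accumulated per internal node over pairs of
        tips in distinct child subtrees.  Cached (invalidated on graft).
        """
        if self._dist_cache is not None:
            return self._dist_cache
        labels: list[str] = []
        index: dict[int, int] = {}
        depths: list[float] = []
        # assign tip indices in leaf-iteration order
        for leaf in self.tree.leaf_node_iter():
            index[id(leaf)] = len(labels)
            labels.append(leaf.taxon.label)
            depths.append(leaf.distance_from_root())
        dep = np.asarray(depths)
        n = len(labels)
        D = np.zeros((n, n))
        tipsets: dict[int, np.ndarray] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                tipsets[id(node)] = np.array([index[id(node)]], dtype=np.intp)
                continue
            child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
            dn = node.distance_from_root()
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    ia, ib = child_sets[a], child_sets[b]
                    block = dep[ia][:, None] + dep[ib][None, :] - 2.0 * dn
                    D[np.ix_(ia, ib)] = block
                    D[np.ix_(ib, ia)] = block.T
            tipsets[id(node)] = np.concatenate(child_sets)
        self._dist_cache = (labels, D)
        return self._dist_cache

    def invalidate_cache(self) -> None:
        self._dist_cache = None

    def tip_index(self) -> dict[str, int]:
        """Tip label -> distance-matrix row, accepting space- and
        underscore-separated binomials interchangeably."""
        labels, _ = self.distance_matrix()
        index: dict[str, int] = {}
        for i, l in enumerate(labels):
            index[l] = i
            index[l.replace("_", " ")] = i
        return index

    def clone(self) -> "Phylogeny":
        return Phylogeny(
            self.tree.clone(depth=1), genus_to_family=self._genus_to_family
        )

    def as_newick(self) -> str:
        s = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".12g",
        )
        return s.strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips, height {self.height:.4g}>"


def read_newick(
    path_or_string: str | Path,
    genus_to_family: Mapping[str, str] | None = None,
    missing_lengths: str = "error",
) -> Phylogeny:
    """Parse a Newick tree into a :class:`Phylogeny`.

    ``missing_lengths`` is ``"error"`` (reject edges without lengths) or
    ``"unit"`` (assign length 1 to unlabelled edges).  The string form is
    accepted directly when it contains a semicolon.
    """
    if missing_lengths not in {"error", "unit"}:
        raise ValueError("missing_lengths must be 'error' or 'unit'")
    text: str
    s = str(path_or_string)
    if isinstance(path_or_string, Path) or ("(" not in s and ";" not in s):
        text = Path(path_or_string).read_text(encoding="utf-8")
    else:
        text = s
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as err:
        raise ValueError(f"malformed Newick: {err}") from None
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            if edge.length is None:
                edge.length = 0.0
            continue
        if edge.length is None:
            if missing_lengths == "unit":
                edge.length = 1.0
            else:
                raise ValueError("tree has edges without branch lengths")
    return Phylogeny(tree, genus_to_family=genus_to_family)


def write_newick(phylo: Phylogeny, path: str | Path) -> None:
    """Write a tree as Newick; round-trips preserve topology and branch
    lengths to 1e-9."""
    Path(path).write_text(phylo.as_newick() + "\n", encoding="utf-8")
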