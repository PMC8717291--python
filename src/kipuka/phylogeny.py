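"""Rooted phylogenies with branch lengths, Newick I/O, and community-tree construction.

The :class:`Phylogeny` container is array-backed and canonicalised to preorder
(every parent index precedes its children) with depth-first-contiguous tip
numbering, which lets patristic distance matrices and subtree statistics be
computed with vectorised block operations.  Newick reading and writing is
delegated to :mod:`dendropy`.

Community phylogenies are built from a dated megaphylogeny by (a) resolving a
regional species checklist against the megaphylogeny tips — keeping exact
matches, substituting an unclaimed congener for missing species, dropping the
rest — and (b) pruning the megaphylogeny to the resolved tip set while
preserving all pairwise patristic distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import dendropy
import numpy as np

from ._errors import ParseError, ValidationError

__all__ = [
    "Phylogeny",
    "NameResolution",
    "read_newick",
    "write_newick",
    "resolve_names",
    "prune_to_taxa",
]


class Phylogeny:
    """A rooted tree with nonnegative branch lengths and unique tip labels.

    Parameters
    ----------
    parent
        Integer array, one entry per node; ``parent[i] == -1`` exactly for the
        root.  Any topological order is accepted; the constructor re-indexes
        nodes into preorder.
    blen
        Branch length above each node (root entry ignored, stored as 0).
    labels
        Sequence of tip labels aligned with ``parent``; ``None`` for internal
        nodes.
    """

    def __init__(
        self,
        parent: Sequence[int],
        blen: Sequence[float],
        labels: Sequence[str | None],
    ) -> None:
        parent = np.asarray(parent, dtype=np.int64)
        blen = np.asarray(blen, dtype=np.float64)
        n = parent.shape[0]
        if blen.shape[0] != n or len(labels) != n:
            raise ValidationError("parent, blen and labels must have equal length")
        roots = np.flatnonzero(parent == -1)
        if roots.size != 1:
            raise ValidationError(f"tree must have exactly one root, found {roots.size}")
        if np.any(blen[np.arange(n) != roots[0]] < 0):
            raise ValidationError("negative branch length")

        # children lists in original indexing
        kids: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            p = parent[i]
            if p >= 0:
                kids[p].append(i)

        # iterative preorder DFS; children visited in original index order
        order = np.empty(n, dtype=np.int64)
        stack = [int(roots[0])]
        pos = 0
        while stack:
            v = stack.pop()
            order[pos] = v
            pos += 1
            stack.extend(reversed(kids[v]))
        if pos != n:
            raise ValidationError("tree contains nodes unreachable from the root")
        new_id = np.empty(n, dtype=np.int64)
        new_id[order] = np.arange(n)

        self.n_nodes: int = n
        self.parent = np.where(parent[order] >= 0, new_id[parent[order]], -1)
        self.blen = blen[order].copy()
        self.blen[0] = 0.0
        self.children: list[list[int]] = [[new_id[c] for c in kids[v]] for v in order]
        self.is_tip = np.array([len(c) == 0 for c in self.children])

        tip_nodes = np.flatnonzero(self.is_tip)  # ascending == DFS order
        self.tip_nodes = tip_nodes
        self.tip_labels: list[str] = []
        for v in tip_nodes:
            lab = labels[order[v]]
            if lab is None:
                raise ValidationError(f"tip node {v} has no label")
            self.tip_labels.append(str(lab))
        if len(set(self.tip_labels)) != len(self.tip_labels):
            dups = sorted({x for x in self.tip_labels if self.tip_labels.count(x) > 1})
            raise ValidationError(f"duplicate tip labels: {dups}")
        self.tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}

        # contiguous tip range [tip_lo, tip_hi) spanned by each node's subtree
        tip_pos = np.full(n, -1, dtype=np.int64)
        tip_pos[tip_nodes] = np.arange(tip_nodes.size)
        self.tip_lo = np.empty(n, dtype=np.int64)
        self.tip_hi = np.empty(n, dtype=np.int64)
        for v in range(n - 1, -1, -1):
            if self.is_tip[v]:
                self.tip_lo[v] = tip_pos[v]
                self.tip_hi[v] = tip_pos[v] + 1
            else:
                c = self.children[v]
                self.tip_lo[v] = min(self.tip_lo[u] for u in c)
                self.tip_hi[v] = max(self.tip_hi[u] for u in c)

        self._depths: np.ndarray | None = None

    # ------------------------------------------------------------------ basics
    @property
    def n_tips(self) -> int:
        return self.tip_nodes.size

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        if self._depths is None:
            d = np.empty(self.n_nodes)
            d[0] = 0.0
            for v in range(1, self.n_nodes):
                d[v] = d[self.parent[v]] + self.blen[v]
            self._depths = d
        return self._depths

    def tip_depths(self) -> np.ndarray:
        return self.depths()[self.tip_nodes]

    @property
    def height(self) -> float:
        return float(self.tip_depths().max())

    def is_ultrametric(self, tol: float = 1e-6) -> bool:
        td = self.tip_depths()
        return bool(td.max() - td.min() <= tol * max(td.max(), 1.0))

    def total_branch_length(self) -> float:
        return float(self.blen[1:].sum())

    # --------------------------------------------------------------- distances
    def mrca_depth_matrix(self) -> np.ndarray:
        """Depth of the most recent common ancestor, per tip pair."""
        nt = self.n_tips
        d = self.depths()
        m = np.zeros((nt, nt))
        for v in range(self.n_nodes):
            c = self.children[v]
            if len(c) < 2:
                continue
            dv = d[v]
            for a in range(len(c)):
                lo_a, hi_a = self.tip_lo[c[a]], self.tip_hi[c[a]]
                for b in range(a + 1, len(c)):
                    lo_b, hi_b = self.tip_lo[c[b]], self.tip_hi[c[b]]
                    m[lo_a:hi_a, lo_b:hi_b] = dv
                    m[lo_b:hi_b, lo_a:hi_a] = dv
        td = self.tip_depths()
        np.fill_diagonal(m, td)
        return m

    def patristic_matrix(self) -> np.ndarray:
        """Pairwise sum of branch lengths along tip-to-tip paths.

        Rows/columns follow ``tip_labels`` order.
        """
        td = self.tip_depths()
        return td[:, None] + td[None, :] - 2.0 * self.mrca_depth_matrix()

    # ----------------------------------------------------------------- pruning
    def prune(self, tips: Iterable[str]) -> "Phylogeny":
        """Restrict the tree to ``tips``, preserving patristic distances.

        Degree-two internal nodes created by the pruning are suppressed with
        their branch lengths summed, so pairwise distances among the retained
        tips are unchanged.
        """
        tips = list(tips)
        unknown = sorted(set(tips) - set(self.tip_labels))
        if unknown:
            raise ValidationError(f"tips not in tree: {unknown}")
        if len(set(tips)) < 2:
            raise ValidationError("pruning requires at least two distinct tips")
        keep_tip = set(tips)

        keep = np.zeros(self.n_nodes, dtype=bool)
        for v in self.tip_nodes:
            if self.tip_labels[self.tip_index_of_node(v)] in keep_tip:
                keep[v] = True
        for v in range(self.n_nodes - 1, 0, -1):
            if keep[v]:
                keep[self.parent[v]] = True

        kept_children = np.zeros(self.n_nodes, dtype=np.int64)
        for v in range(1, self.n_nodes):
            if keep[v]:
                kept_children[self.parent[v]] += 1
        real = keep & (self.is_tip | (kept_children >= 2))
        # topmost real node becomes the new root
        anc = np.full(self.n_nodes, -1, dtype=np.int64)  # nearest real proper ancestor
        acc = np.zeros(self.n_nodes)
        for v in range(1, self.n_nodes):
            if not keep[v]:
                continue
            p = self.parent[v]
            if real[p]:
                anc[v], acc[v] = p, self.blen[v]
            else:
                anc[v], acc[v] = anc[p], acc[p] + self.blen[v]

        real_nodes = np.flatnonzero(real)
        new_id = {int(v): i for i, v in enumerate(real_nodes)}
        parent_new = [new_id[int(anc[v])] if anc[v] >= 0 else -1 for v in real_nodes]
        blen_new = [acc[v] for v in real_nodes]
        labels_new: list[str | None] = [
            self.tip_labels[self.tip_index_of_node(int(v))] if self.is_tip[v] else None
            for v in real_nodes
        ]
        return Phylogeny(parent_new, blen_new, labels_new)

    def tip_index_of_node(self, node: int) -> int:
        """Position in tip ordering of a tip node index."""
        lo = self.tip_lo[node]
        if not self.is_tip[node]:
            raise ValidationError(f"node {node} is not a tip")
        return int(lo)

    # -------------------------------------------------------------- shape stats
    def colless_index(self, normalized: bool = True) -> float:
        """Sum over internal nodes of child-subtree size imbalance.

        For multifurcating nodes the imbalance is summed over child pairs.
        Normalisation divides by ``(n-1)(n-2)/2``.
        """
        sizes = self.tip_hi - self.tip_lo
        total = 0.0
        for v in range(self.n_nodes):
            c = self.children[v]
            for a in range(len(c)):
                for b in range(a + 1, len(c)):
                    total += abs(int(sizes[c[a]]) - int(sizes[c[b]]))
        if not normalized:
            return total
        n = self.n_tips
        denom = (n - 1) * (n - 2) / 2.0
        return total / denom if denom > 0 else 0.0

    def gamma_statistic(self) -> float:
        """Pybus–Harvey statistic on internal-node times (ultrametric trees).

        Positive values indicate nodes concentrated toward the tips, negative
        toward the root.
        """
        n = self.n_tips
        if n < 3:
            return 0.0
        d = self.depths()
        node_times = np.sort(d[~self.is_tip])  # includes root at 0
        T_height = self.height
        # g[k] = interval during which k lineages exist, k = 2..n
        times = np.concatenate([node_times, [T_height]])
        g = np.diff(times)  # length n-1, g[k-2] is interval with k lineages
        k = np.arange(2, n + 1)
        kg = k * g
        T = kg.sum()
        cum = np.cumsum(kg)[:-1]  # i = 2..n-1
        stat = cum.mean() - T / 2.0
        return float(stat / (T * math.sqrt(1.0 / (12.0 * (n - 2)))))

    def faith_pd(self, tips: Sequence[str]) -> float:
        """Total branch length of the minimal subtree spanning ``tips`` and the root."""
        idx = np.array([self.tip_index[t] for t in tips])
        ind = np.zeros(self.n_tips)
        ind[idx] = 1.0
        csum = np.concatenate([[0.0], np.cumsum(ind)])
        counts = csum[self.tip_hi] - csum[self.tip_lo]
        return float(self.blen[(counts > 0)].sum())

    # ----------------------------------------------------------------- newick
    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = []
        blen = []
        labels: list[str | None] = []
        for nd in nodes:
            parent.append(index[id(nd.parent_node)] if nd.parent_node else -1)
            el = nd.edge.length
            blen.append(0.0 if el is None else float(el))
            if nd.is_leaf():
                lab = nd.taxon.label if nd.taxon is not None else None
                labels.append(None if lab is None else lab.replace(" ", "_"))
            else:
                labels.append(None)
        return cls(parent, blen, labels)

    def to_dendropy(self) -> dendropy.Tree:
        tns = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=tns)
        nodes = [dendropy.Node() for _ in range(self.n_nodes)]
        tree.seed_node = nodes[0]
        for v in range(1, self.n_nodes):
            nodes[self.parent[v]].add_child(nodes[v])
            nodes[v].edge.length = float(self.blen[v])
        for v in self.tip_nodes:
            tax = tns.new_taxon(self.tip_labels[self.tip_index_of_node(int(v))])
            nodes[v].taxon = tax
        return tree

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            if "Duplicate taxon labels" in str(exc):
                raise ValidationError(f"duplicate tip labels: {exc}") from exc
            raise ParseError(f"malformed Newick: {exc}") from exc
        return cls.from_dendropy(tree)

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()


def read_newick(path) -> Phylogeny:
    """Read a Newick file, validating uniqueness of tips and branch-length signs."""
    with open(path) as fh:
        text = fh.read()
    return Phylogeny.from_newick(text)


def write_newick(tree: Phylogeny, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


# --------------------------------------------------------------------------
# Checklist resolution against a megaphylogeny
# --------------------------------------------------------------------------

def default_genus_extractor(name: str) -> str:
    """Genus = token before the first underscore or space."""
    return name.replace(" ", "_").split("_")[0]


@dataclass
class NameResolution:
    """Outcome of resolving a species checklist against megaphylogeny tips.

    ``kept`` are exact tip matches; ``replaced`` maps a checklist species to
    the congeneric stand-in tip chosen for it; ``dropped`` species had no
    genus match or no unclaimed congener left.  A megaphylogeny tip serves as
    a replacement at most once.
    """

    kept: list[str] = field(default_factory=list)
    replaced: dict[str, str] = field(default_factory=dict)
    dropped: list[str] = field(default_factory=list)

    @property
    def final_tips(self) -> list[str]:
        return sorted(set(self.kept) | set(self.replaced.values()))

    def to_frame(self):
        import pandas as pd

        rows = [(s, "kept", s) for s in self.kept]
        rows += [(s, "replaced", r) for s, r in self.replaced.items()]
        rows += [(s, "dropped", "") for s in self.dropped]
        return pd.DataFrame(rows, columns=["species", "status", "replacement"]).sort_values(
            "species", ignore_index=True
        )


def resolve_names(
    species_list: Sequence[str],
    megaphylogeny_tips: Iterable[str],
    genus_extractor: Callable[[str], str] = default_genus_extractor,
) -> NameResolution:
    """Classify each checklist species as kept, replaced by a congener, or dropped.

    Species are processed in sorted order (deterministic first-come claims);
    the replacement for a missing species is the alphabetically first congener
    present in the megaphylogeny and not already claimed by another checklist
    species, either as an exact match or as a previous replacement.
    """
    species = sorted(set(str(s).replace(" ", "_") for s in species_list))
    if not species:
        raise ValidationError("empty species list")
    mega = set(str(t).replace(" ", "_") for t in megaphylogeny_tips)
    by_genus: dict[str, list[str]] = {}
    for t in mega:
        by_genus.setdefault(genus_extractor(t), []).append(t)
    for g in by_genus:
        by_genus[g].sort()

    res = NameResolution()
    claimed: set[str] = set()
    # pass 1: exact matches claim their own tip
    misses = []
    for s in species:
        if s in mega:
            res.kept.append(s)
            claimed.add(s)
        else:
            misses.append(s)
    # pass 2: congeneric replacement
    for s in misses:
        genus = genus_extractor(s)
        candidates = [t for t in by_genus.get(genus, []) if t not in claimed]
        if candidates:
            res.replaced[s] = candidates[0]
            claimed.add(candidates[0])
        else:
            res.dropped.append(s)
    return res


def prune_to_taxa(tree: Phylogeny, tips: Iterable[str]) -> Phylogeny:
    """Prune ``tree`` down to ``tips`` (patristic distances preserved)."""
    return tree.prune(tips)


# --------------------------------------------------------------------------
# Brownian-motion pruning pass (phylogenetic GLS in linear time)
# --------------------------------------------------------------------------

def bm_pruning(tree: Phylogeny, x: np.ndarray):
    """One post-order contrasts pass under a Brownian covariance.

    For tip values ``x`` (ordered as ``tree.tip_labels``) and the Brownian
    covariance ``C`` (shared root-to-MRCA path lengths, unit rate), returns

    ``(root_value, root_var, ss_contrasts, logdet)`` where

    - ``root_value`` is the GLS/phylogenetic mean ``(1'C⁻¹x)/(1'C⁻¹1)``,
    - ``root_var`` equals ``1/(1'C⁻¹1)``,
    - ``ss_contrasts`` equals ``(x − root_value·1)' C⁻¹ (x − root_value·1)``,
    - ``logdet`` equals ``log|C|``.

    Multifurcations are folded pairwise, which leaves the four returned
    quantities exact.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.shape[0] != tree.n_tips:
        raise ValidationError("trait vector length must equal tip count")
    val = np.empty(tree.n_nodes)
    var = np.empty(tree.n_nodes)
    ss = 0.0
    logdet = 0.0
    for v in range(tree.n_nodes - 1, -1, -1):
        if tree.is_tip[v]:
            val[v] = x[tree.tip_lo[v]]
            var[v] = tree.blen[v]
        else:
            c = tree.children[v]
            v1, d1 = val[c[0]], var[c[0]]
            for u in c[1:]:
                v2, d2 = val[u], var[u]
                s = d1 + d2
                if s <= 0:
                    raise ValidationError("zero-length cherry makes covariance singular")
                ss += (v1 - v2) ** 2 / s
                logdet += math.log(s)
                v1 = (d2 * v1 + d1 * v2) / s
                d1 = d1 * d2 / s
            val[v] = v1
            var[v] = tree.blen[v] + d1
    logdet += math.log(var[0])
    return float(val[0]), float(var[0]), float(ss), float(logdet)
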