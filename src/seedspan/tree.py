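"""Phylogeny construction, dating and covariance extraction.

Trees are dendropy ``Tree`` objects throughout. A taxonomy tree is built
from the order/family/genus columns of the species table (polytomies
where no finer resolution exists), dated by even interpolation between
nodes with known ages, and converted into the tip covariance matrix used
by signal statistics and PGLS: V[i,j] = shared root-to-MRCA path length,
V[i,i] = root-to-tip path length.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from seedspan.errors import PhylogenyError, SchemaError

logger = logging.getLogger(__name__)

_MIN_TERMINAL = 1e-6  # Myr; perturbation for zero-length terminal branches


def canonical_label(label: str) -> str:
    """Newick writers swap spaces for underscores; compare labels modulo that."""
    return str(label).replace("_", " ")


@dataclass
class PhyloCovariance:
    """Tip covariance matrix with its species order and any applied lambda."""

    taxa: list[str]
    matrix: np.ndarray
    lam: Optional[float] = None

    def reorder(self, taxa: Sequence[str]) -> "PhyloCovariance":
        lookup = {canonical_label(t): i for i, t in enumerate(self.taxa)}
        try:
            idx = [lookup[canonical_label(t)] for t in taxa]
        except KeyError as exc:
            raise PhylogenyError(f"species not among covariance taxa: {exc}") from exc
        return PhyloCovariance(list(taxa), self.matrix[np.ix_(idx, idx)], self.lam)


def build_taxonomy_tree(records) -> dendropy.Tree:
    """Rooted tree from order/family/genus/species nesting, unit branch lengths.

    Internal nodes are labelled with the taxon name ('Fabales', 'Fabaceae',
    'Trifolium'); congeners become sisters under the genus node. Resolution
    below genus is a polytomy. Branch lengths are 1 pending dating.
    """
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.is_rooted = True
    root = tree.seed_node
    root.label = "root"

    order_nodes: dict[str, dendropy.Node] = {}
    family_nodes: dict[tuple[str, str], dendropy.Node] = {}
    genus_nodes: dict[tuple[str, str, str], dendropy.Node] = {}
    for rec in records:
        if not rec.order or not rec.family or not rec.species_id:
            raise SchemaError(f"record {rec!r} lacks order/family/species")
        genus = rec.species_id.split()[0]
        onode = order_nodes.get(rec.order)
        if onode is None:
            onode = root.new_child(edge_length=1.0)
            onode.label = rec.order
            order_nodes[rec.order] = onode
        fkey = (rec.order, rec.family)
        fnode = family_nodes.get(fkey)
        if fnode is None:
            fnode = onode.new_child(edge_length=1.0)
            fnode.label = rec.family
            family_nodes[fkey] = fnode
        gkey = (rec.order, rec.family, genus)
        gnode = genus_nodes.get(gkey)
        if gnode is None:
            gnode = fnode.new_child(edge_length=1.0)
            gnode.label = genus
            genus_nodes[gkey] = gnode
        tip = gnode.new_child(edge_length=1.0)
        tip.taxon = ns.new_taxon(label=rec.species_id)
    logger.info(
        "taxonomy tree: %d tips, %d orders, %d families (genus grouping is an assumption)",
        len(tree.leaf_nodes()), len(order_nodes), len(family_nodes),
    )
    return tree


def load_node_ages(path: str | Path) -> dict[str, float]:
    """Read a taxon -> age (Myr) table from CSV (columns taxon, age_myr)."""
    df = pd.read_csv(path)
    missing = {"taxon", "age_myr"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    ages = {str(t).strip(): float(a) for t, a in zip(df["taxon"], df["age_myr"])}
    if any(a < 0 for a in ages.values()):
        raise SchemaError(f"{path}: negative age")
    return ages


def bladj_adjust(tree: dendropy.Tree, ages: Mapping[str, float]) -> dendropy.Tree:
    """Date the tree by even age interpolation between nodes of known age.

    Nodes whose label appears in ``ages`` take that age; tips get age 0;
    each remaining node is spaced evenly in age along the path between its
    nearest dated ancestor and nearest dated descendant (minimum number of
    intervening nodes; ties resolved toward the older candidate so ages
    never invert). Branch length becomes parent age minus child age, so
    the result is ultrametric with depth equal to the root age.
    """
    tree = tree.clone(depth=1)
    root = tree.seed_node
    if root.label not in ages:
        raise PhylogenyError("root has no age in the node-age table")

    fixed: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            fixed[node] = 0.0
        elif node.label is not None and node.label in ages:
            fixed[node] = float(ages[node.label])

    # verify dated nesting before interpolation
    for node, age in fixed.items():
        p = node.parent_node
        while p is not None:
            if p in fixed and fixed[p] < age - 1e-12:
                raise PhylogenyError(
                    f"age inversion: {node.label or node.taxon} ({age}) older than "
                    f"ancestor {p.label} ({fixed[p]})"
                )
            p = p.parent_node

    def nearest_fixed_below(node: dendropy.Node) -> tuple[float, int]:
        """(age, n intervening undated nodes) of the chosen dated descendant."""
        best: Optional[tuple[int, float]] = None
        stack = [(child, 0) for child in node.child_nodes()]
        while stack:
            n, depth = stack.pop()
            if n in fixed:
                cand = (depth, fixed[n])
                if best is None or depth < best[0] or (depth == best[0] and cand[1] > best[1]):
                    best = cand
            else:
                stack.extend((c, depth + 1) for c in n.child_nodes())
        if best is None:  # cannot happen: every tip is fixed
            raise PhylogenyError("no dated descendant found")
        return best[1], best[0]

    for node in tree.preorder_node_iter():
        if node in fixed:
            continue
        parent = node.parent_node
        if parent not in fixed:
            raise PhylogenyError("preorder invariant violated (undated parent)")
        d_age, k = nearest_fixed_below(node)
        age = fixed[parent] - (fixed[parent] - d_age) / (k + 2)
        # guard against inversion with deeper dated descendants
        deepest = max(
            (fixed[n] for n in node.preorder_iter() if n in fixed and n is not node),
            default=0.0,
        )
        fixed[node] = max(age, deepest)

    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            length = fixed[node.parent_node] - fixed[node]
            if length < -1e-9:
                raise PhylogenyError(
                    f"negative branch to {node.label or node.taxon} after dating"
                )
            node.edge.length = max(length, 0.0)
        node.age = fixed[node]
    return tree


def phylo_covariance(tree: dendropy.Tree) -> PhyloCovariance:
    """Tip covariance matrix: shared root-to-MRCA path lengths.

    Zero-length terminal branches are perturbed by 1e-6 Myr (warned) so
    the matrix stays invertible for same-aged congeners.
    """
    leaves = tree.leaf_nodes()
    taxa = [lf.taxon.label for lf in leaves]
    index = {lf: i for i, lf in enumerate(leaves)}
    n = len(leaves)

    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        length = node.edge.length if node.edge.length is not None else 0.0
        if length < 0:
            raise PhylogenyError(f"negative branch length at {node.label or node.taxon}")
        if node.is_leaf() and length == 0.0:
            warnings.warn(
                f"zero-length terminal branch at {node.taxon.label}; "
                f"perturbing by {_MIN_TERMINAL} Myr to keep V invertible",
                stacklevel=2,
            )
            length = _MIN_TERMINAL
        depth[node] = depth[node.parent_node] + length

    V = np.zeros((n, n))
    for lf in leaves:
        V[index[lf], index[lf]] = depth[lf]
    # postorder: tips below each child subtree share the node's depth
    below: dict[dendropy.Node, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [index[node]]
            continue
        groups = [below[c] for c in node.child_nodes()]
        d = depth[node]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    V[a, groups[gj]] = d
                    V[np.asarray(groups[gj]), a] = d
        below[node] = [i for g in groups for i in g]
    return PhyloCovariance(taxa=taxa, matrix=V)


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Multiply off-diagonal covariances by lambda in [0, 1]."""
    if not (0.0 <= lam <= 1.0):
        raise PhylogenyError(f"lambda must be in [0, 1], got {lam}")
    V = cov.matrix.copy()
    d = np.diag(V).copy()
    V *= lam
    np.fill_diagonal(V, d)
    return PhyloCovariance(taxa=list(cov.taxa), matrix=V, lam=lam)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Parse a rooted Newick tree with branch lengths and internal labels."""
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhylogenyError(f"failed to parse Newick file {path}: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write Newick with branch lengths to 6 decimals; round-trip safe."""
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )


def prune_to_species(tree: dendropy.Tree, species: Sequence[str]) -> dendropy.Tree:
    """Subtree restricted to the given tip labels; errors on unmatched names."""
    tips = {lf.taxon.label for lf in tree.leaf_nodes()}
    missing = [s for s in species if s not in tips]
    if missing:
        raise PhylogenyError(f"species not in tree: {missing}")
    tree = tree.clone(depth=1)
    keep = [t for t in tree.taxon_namespace if t.label in set(species)]
    tree.retain_taxa(keep)
    return tree
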