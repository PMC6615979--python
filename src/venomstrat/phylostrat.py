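"""Gene-age assignment (phylostratigraphy) over orthogroups on a rooted species tree.

The central question answered here is: *when did each gene of a focal species
arise?*  The substrate is an orthogroup table (sets of genes across species
that descend from a single ancestral gene) and a rooted species tree with one
designated focal leaf.  Every internal vertex on the path from the root to the
focal leaf defines a *lineage node* (phylostratum): node 1 is the deepest
split, indices increase toward the focal leaf.  An orthogroup is dated to the
deepest node whose sister clade contributes at least one member species —
equivalently, to the most recent common ancestor of the focal species and all
member species.  Because orthogroups are assumed to arise once (but may be
lost repeatedly), this is a Dollo-style lower bound on gene age: taxon
sampling can only make an origin look *younger* than it is, never older.

Orthogroups whose members are all focal genes are ``FOCAL_EXCLUSIVE`` — a
stratum of their own, distinct from ``UNASSIGNED`` genes, which were never
clustered into any orthogroup.  Orthogroups without a focal member are
``NOT_APPLICABLE`` and excluded from all focal summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy

logger = logging.getLogger(__name__)

#: Stratum sentinel: orthogroup whose members are all genes of the focal species.
FOCAL_EXCLUSIVE = "focal_exclusive"
#: Stratum sentinel: focal gene that belongs to no orthogroup at all.
UNASSIGNED = "unassigned"
#: Stratum sentinel: orthogroup with no focal member (ignored in focal summaries).
NOT_APPLICABLE = "not_applicable"

#: A stratum is either a lineage-node index (int >= 1) or one of the sentinels.
Stratum = Union[int, str]


class SpeciesTree:
    """A rooted species tree with an optional designated focal leaf.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the invariants
    this package relies on: unique leaf labels and a bifurcating root (a
    trifurcating root is the conventional serialization of an *unrooted*
    tree and is rejected).  Polytomies below the root are accepted.
    """

    def __init__(self, tree: dendropy.Tree, focal: Optional[str] = None):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf labels in tree: {sorted(dupes)}")
        n_root_children = len(tree.seed_node.child_nodes())
        if n_root_children != 2:
            raise ValueError(
                f"tree root has {n_root_children} children; a rooted tree with a "
                "bifurcating root is required — root the tree on a branch first"
            )
        self._leaves = tuple(labels)
        if focal is not None and focal not in self._leaves:
            raise ValueError(f"focal species {focal!r} is not a leaf of the tree")
        self.focal = focal

    @classmethod
    def from_newick(cls, newick: str, focal: Optional[str] = None) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as err:
            raise ValueError(f"duplicate leaf labels in tree: {err}") from None
        tree.is_rooted = True
        return cls(tree, focal=focal)

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaves(self) -> tuple:
        return self._leaves

    def with_focal(self, focal: str) -> "SpeciesTree":
        return SpeciesTree(self._tree, focal=focal)

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", unquoted_underscores=True).strip()

    # -- internal helpers -------------------------------------------------

    def _focal_leaf_node(self):
        if self.focal is None:
            raise ValueError("no focal species designated on this tree")
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon.label == self.focal:
                return leaf
        raise ValueError(f"focal species {self.focal!r} not found")  # pragma: no cover

    def mrca_stratum_oracle(self, species: Iterable[str]) -> Optional[int]:
        """Index of the focal-path vertex that is the MRCA of focal + *species*.

        Brute-force helper used by tests as an independent check of
        :func:`assign_origin`; ``None`` if the MRCA is the focal leaf itself.
        """
        labels = set(species) | {self.focal}
        mrca = self._tree.mrca(taxon_labels=sorted(labels))
        node = self._focal_leaf_node()
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        path.reverse()  # root ... focal leaf
        # translate vertex position to lineage-node index (skipping unifurcations)
        idx = 0
        for vertex, child in zip(path[:-1], path[1:]):
            if len(vertex.child_nodes()) > 1:
                idx += 1
            if vertex is mrca:
                return idx
        return None


@dataclass(frozen=True)
class LineageNode:
    """One split on the root-to-focal path; index 1 is the deepest split."""

    index: int
    sister_clade: frozenset
    label: str


@dataclass(frozen=True)
class StratumAssignment:
    """The stratum assigned to one unit (an orthogroup id or a gene id)."""

    unit_id: str
    stratum: Stratum


def focal_lineage(tree: SpeciesTree) -> list:
    """Enumerate the lineage nodes (strata) of the focal species.

    Walks the path from the root to the focal leaf and emits one
    :class:`LineageNode` per internal vertex, deepest first.  The sister
    clade of a node is every leaf under that vertex that is *not* under the
    next vertex on the path.  Unifurcating vertices (empty sister) are
    skipped; polytomous vertices contribute a single node.
    """
    leaf = tree._focal_leaf_node()
    path = []
    node = leaf
    while node is not None:
        path.append(node)
        node = node.parent_node
    path.reverse()  # root first

    nodes = []
    index = 1
    for vertex, child in zip(path[:-1], path[1:]):
        under_vertex = {lf.taxon.label for lf in vertex.leaf_iter()}
        under_child = {lf.taxon.label for lf in child.leaf_iter()}
        sister = under_vertex - under_child
        if not sister:
            continue
        nodes.append(LineageNode(index=index, sister_clade=frozenset(sister), label=f"Node {index}"))
        index += 1
    # sanity: sister clades partition the non-focal leaves
    union = set().union(*(n.sister_clade for n in nodes)) if nodes else set()
    assert union | {tree.focal} == set(tree.leaves)
    return nodes


def species_stratum_map(lineage: Sequence[LineageNode]) -> dict:
    """Map each non-focal species to the index of the node whose sister holds it."""
    out = {}
    for node in lineage:
        for sp in node.sister_clade:
            out[sp] = node.index
    return out


def assign_origin(
    og_members: Mapping[str, Sequence[str]],
    tree: SpeciesTree,
    lineage: Optional[Sequence[LineageNode]] = None,
) -> Stratum:
    """Date one orthogroup: the deepest lineage node with a sister-clade member.

    Parameters
    ----------
    og_members
        Mapping species -> member gene ids.  Species with an empty member
        list are treated as absent.
    tree
        Species tree with a designated focal leaf.
    lineage
        Precomputed :func:`focal_lineage` output (recomputed if omitted).

    Returns
    -------
    The lineage-node index (int), ``FOCAL_EXCLUSIVE`` if every member is a
    focal gene, or ``NOT_APPLICABLE`` if the focal species has no member.
    """
    members = {sp for sp, genes in og_members.items() if genes}
    if not members:
        raise ValueError("orthogroup has no members")
    unknown = members - set(tree.leaves)
    if unknown:
        raise ValueError(f"member species not in tree: {sorted(unknown)}")
    if tree.focal not in members:
        return NOT_APPLICABLE
    if lineage is None:
        lineage = focal_lineage(tree)
    for node in lineage:  # deepest first => first hit is the origin
        if node.sister_clade & members:
            return node.index
    return FOCAL_EXCLUSIVE


def assign_gene_strata(genes, table, tree: SpeciesTree) -> list:
    """Assign a stratum to each focal gene via its orthogroup.

    *genes* may be :class:`~venomstrat.formats_io.GeneModel` objects or bare
    gene-id strings.  A gene found in no orthogroup is ``UNASSIGNED``.
    """
    lineage = focal_lineage(tree)
    og_of_gene = table.gene_to_orthogroup()
    og_stratum: dict = {}
    out = []
    for gene in genes:
        gene_id = getattr(gene, "gene_id", gene)
        og = og_of_gene.get(gene_id)
        if og is None:
            out.append(StratumAssignment(gene_id, UNASSIGNED))
            continue
        if og not in og_stratum:
            og_stratum[og] = assign_origin(table.entries[og], tree, lineage)
        out.append(StratumAssignment(gene_id, og_stratum[og]))
    return out


def count_per_stratum(
    table,
    tree: SpeciesTree,
    restrict_to: Optional[set] = None,
) -> dict:
    """Count focal-containing orthogroups per stratum.

    Returns a dict keyed by every lineage-node index plus ``FOCAL_EXCLUSIVE``
    (zero counts included).  Orthogroups without a focal member are excluded;
    *restrict_to* limits the count to a subset of orthogroup ids (e.g. the
    toxin-bearing or predominant-toxin orthogroups).
    """
    lineage = focal_lineage(tree)
    counts: dict = {node.index: 0 for node in lineage}
    counts[FOCAL_EXCLUSIVE] = 0
    for og_id, members in table.entries.items():
        if restrict_to is not None and og_id not in restrict_to:
            continue
        stratum = assign_origin(members, tree, lineage)
        if stratum == NOT_APPLICABLE:
            continue
        counts[stratum] += 1
    return counts
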