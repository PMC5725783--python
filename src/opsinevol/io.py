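"""Readers, writers and labeling conventions for codon alignments and trees.

Coordinate conventions used throughout the package:

* codon columns are 0-based internally and 1-based in every report;
* trees are stored unrooted; for traversal they are deterministically
  (re)rooted at the node adjacent to the alphabetically smallest leaf,
  children everywhere sorted by smallest descendant leaf label, so
  branch ids do not depend on the leaf order of the input Newick;
* a branch id identifies the edge above a non-root node of that
  canonical rooting; ids are assigned in post-order.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .codons import FULL_SET, SENSE_CODONS, codon_cell

log = logging.getLogger(__name__)

_IUPAC_SYMBOLS = "ACGTRYSWKMBDHVN"
_iupac_codon_table: dict | None = None


def iupac_codon_for(cell: frozenset) -> str:
    """Shortest/lexicographically-first IUPAC codon whose sense-codon
    expansion equals ``cell``; missing cells render as ``---``.
    Falls back to ``NNN`` for sets with no exact IUPAC encoding."""
    global _iupac_codon_table
    if cell == FULL_SET:
        return "---"
    if len(cell) == 1:
        return SENSE_CODONS[next(iter(cell))]
    if _iupac_codon_table is None:
        table = {}
        for t in itertools.product(_IUPAC_SYMBOLS, repeat=3):
            codon = "".join(t)
            try:
                states = codon_cell(codon)
            except ValueError:
                continue
            table.setdefault(states, codon)
        _iupac_codon_table = table
    return _iupac_codon_table.get(cell, "NNN")


@dataclass
class CodonAlignment:
    """Taxa x codon-site matrix over the 61 sense codons.

    Each cell is a non-empty frozenset of sense-codon indices; a
    singleton is an observed codon, a larger set an ambiguity, the full
    61-state set a gap/missing cell.
    """

    taxa: list
    cells: list  # list (per taxon) of list (per column) of frozenset
    nt_length: int

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return len(self.cells[0]) if self.cells else 0

    def subset(self, taxa) -> "CodonAlignment":
        idx = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in taxa if t not in idx]
        if missing:
            raise KeyError(f"taxa not in alignment: {missing}")
        return CodonAlignment(
            taxa=list(taxa),
            cells=[list(self.cells[idx[t]]) for t in taxa],
            nt_length=self.nt_length,
        )

    def drop_missing_columns(self) -> "CodonAlignment":
        """Strict 'cleandata' mode: drop every column with any missing cell."""
        keep = [
            j
            for j in range(self.n_sites)
            if all(self.cells[i][j] != FULL_SET for i in range(self.n_taxa))
        ]
        return CodonAlignment(
            taxa=list(self.taxa),
            cells=[[row[j] for j in keep] for row in self.cells],
            nt_length=3 * len(keep),
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for t, row in zip(self.taxa, self.cells):
                fh.write(f">{t}\n")
                fh.write("".join(iupac_codon_for(c) for c in row) + "\n")


def read_alignment(path, frame_check: bool = True, cleandata: bool = False) -> CodonAlignment:
    """Read an in-frame codon FASTA alignment.

    Unambiguous in-frame stop codons are rejected (taxon and 1-based
    codon column reported) unless they form the terminal column, which
    is trimmed with a log message.  With ``frame_check=False`` stops
    become missing cells instead of errors.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    taxa = [r.id for r in records]
    if len(set(taxa)) != len(taxa):
        dupes = sorted({t for t in taxa if taxa.count(t) > 1})
        raise ValueError(f"duplicate taxon labels: {dupes}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: sequence lengths {sorted(lengths)}")
    (nt_length,) = lengths
    if nt_length % 3 != 0:
        raise ValueError(f"alignment length {nt_length} not divisible by 3")
    n_cols = nt_length // 3

    cells = []
    trim_last = False
    for rec in records:
        s = str(rec.seq).upper()
        row = []
        for j in range(n_cols):
            codon = s[3 * j : 3 * j + 3]
            try:
                row.append(codon_cell(codon))
            except ValueError:
                if j == n_cols - 1:
                    trim_last = True
                    row.append(FULL_SET)
                elif frame_check:
                    raise ValueError(
                        f"internal stop codon {codon} in taxon {rec.id!r} "
                        f"at codon column {j + 1}"
                    ) from None
                else:
                    row.append(FULL_SET)
        cells.append(row)
    if trim_last:
        log.info("terminal stop codon(s) trimmed from alignment %s", path)
        cells = [row[:-1] for row in cells]
        n_cols -= 1

    keep = [
        j for j in range(n_cols) if any(cells[i][j] != FULL_SET for i in range(len(taxa)))
    ]
    if len(keep) != n_cols:
        log.info("dropped %d all-missing codon columns", n_cols - len(keep))
        cells = [[row[j] for j in keep] for row in cells]
    aln = CodonAlignment(taxa=taxa, cells=cells, nt_length=nt_length)
    if cleandata:
        aln = aln.drop_missing_columns()
    return aln


class LabeledTree:
    """Unrooted tree with branch lengths and stable branch ids.

    Internally held in the canonical rooted form described in the
    module docstring.  ``branch_lengths[b]`` is the length of branch
    ``b``; ``branch_leafset(b)`` gives the leaves on the side of the
    branch away from the canonical root.
    """

    def __init__(self, adjacency: dict, lengths: dict):
        # adjacency: node -> set of neighbors; lengths: frozenset({u,v}) -> float
        self._build(adjacency, lengths)

    # -- construction -------------------------------------------------
    def _build(self, adj, lengths):
        leaves = sorted(n for n, nb in adj.items() if len(nb) == 1 and isinstance(n, str))
        if not leaves:
            raise ValueError("tree has no labeled leaves")
        self.taxa = list(leaves)
        first = leaves[0]
        root = next(iter(adj[first])) if len(adj) > 2 else first

        # min descendant leaf label per node, for canonical child order
        parent = {root: None}
        children = {}
        order = []
        stack = [root]
        while stack:
            u = stack.pop()
            order.append(u)
            kids = [v for v in adj[u] if v != parent[u]]
            children[u] = kids
            for v in kids:
                parent[v] = u
                stack.append(v)
        min_leaf = {}
        for u in reversed(order):
            if not children[u]:
                min_leaf[u] = u
            else:
                min_leaf[u] = min(min_leaf[v] for v in children[u])
        for u in children:
            children[u].sort(key=lambda v: min_leaf[v])

        # canonical post-order
        post = []

        def _post(u):
            for v in children[u]:
                _post(v)
            post.append(u)

        _post(root)

        index = {u: i for i, u in enumerate(post)}
        n = len(post)
        self.n_nodes = n
        self.root = index[root]
        self.postorder = np.arange(n)  # nodes already stored in post-order
        self.parent = np.full(n, -1, dtype=np.intp)
        self.children = [[] for _ in range(n)]
        self.leaf_label = [None] * n
        self.node_branch = np.full(n, -1, dtype=np.intp)
        b = 0
        branch_len = []
        branch_node = []
        for u in post:
            iu = index[u]
            if parent[u] is not None:
                self.parent[iu] = index[parent[u]]
                self.node_branch[iu] = b
                branch_len.append(lengths[frozenset((u, parent[u]))])
                branch_node.append(iu)
                b += 1
            if isinstance(u, str):  # taxon handle; may have children if
                self.leaf_label[iu] = u  # the canonical root is a leaf
        for u in post:
            iu = index[u]
            for v in children[u]:
                self.children[iu].append(index[v])
        self.n_branches = b
        self.branch_lengths = np.asarray(branch_len, dtype=float)
        self.branch_node = np.asarray(branch_node, dtype=np.intp)

        leafsets = [None] * n
        for iu in range(n):
            if self.leaf_label[iu] is not None:
                leafsets[iu] = frozenset([self.leaf_label[iu]])
        for iu in self.postorder:
            if self.children[iu]:
                leafsets[iu] = frozenset().union(*(leafsets[v] for v in self.children[iu]))
        self._leafsets = leafsets

    # -- queries ------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return len(self.taxa)

    def branch_ids(self):
        return list(range(self.n_branches))

    def branch_leafset(self, branch_id: int) -> frozenset:
        return self._leafsets[self.branch_node[branch_id]]

    def with_branch_lengths(self, vec) -> "LabeledTree":
        import copy

        t = copy.copy(self)
        t.branch_lengths = np.asarray(vec, dtype=float).copy()
        return t

    def leaf_branch(self, taxon: str) -> int:
        for iu in range(self.n_nodes):
            if self.leaf_label[iu] == taxon:
                return int(self.node_branch[iu])
        raise KeyError(taxon)

    # -- serialization ------------------------------------------------
    def _newick_node(self, iu, fmt) -> str:
        if not self.children[iu]:
            s = self.leaf_label[iu]
        else:
            s = "(" + ",".join(self._newick_node(v, fmt) for v in self.children[iu]) + ")"
        b = self.node_branch[iu]
        if b >= 0:
            s += f":{fmt % self.branch_lengths[b]}"
        return s

    def to_newick(self, precision: int = 10) -> str:
        return self._newick_node(self.root, f"%.{precision}g") + ";"

    def write(self, path, precision: int = 10) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(precision) + "\n")

    def __repr__(self):
        return f"LabeledTree({self.n_leaves} leaves, {self.n_branches} branches)"


def _adjacency_from_dendropy(dtree):
    """Flatten a dendropy tree into an unrooted adjacency with merged
    degree-2 root; internal nodes become opaque integer handles."""
    counter = itertools.count()
    handle = {}

    def h(nd):
        if nd not in handle:
            handle[nd] = nd.taxon.label if nd.taxon is not None else next(counter)
        return handle[nd]

    adj: dict = {}
    lengths: dict = {}

    def add_edge(u, v, ln):
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
        lengths[frozenset((u, v))] = ln

    seed = dtree.seed_node
    for nd in dtree.preorder_node_iter():
        if nd is seed:
            continue
        ln = nd.edge.length
        if ln is None:
            raise ValueError("missing branch length")
        add_edge(h(nd.parent_node), h(nd), float(ln))

    sh = h(seed)
    if len(adj.get(sh, ())) == 2:  # collapse a rooted (degree-2) basal node
        a, b = sorted(adj[sh], key=str)
        ln = lengths.pop(frozenset((sh, a))) + lengths.pop(frozenset((sh, b)))
        adj[a].discard(sh)
        adj[b].discard(sh)
        del adj[sh]
        add_edge(a, b, ln)
    return adj, lengths


def _prune_leaf(adj, lengths, leaf):
    (nb,) = adj[leaf]
    lengths.pop(frozenset((leaf, nb)))
    adj[nb].discard(leaf)
    del adj[leaf]
    if len(adj[nb]) == 2 and not isinstance(nb, str):
        a, b = list(adj[nb])
        ln = lengths.pop(frozenset((nb, a))) + lengths.pop(frozenset((nb, b)))
        adj[a].discard(nb)
        adj[b].discard(nb)
        del adj[nb]
        adj[a].add(b)
        adj[b].add(a)
        lengths[frozenset((a, b))] = ln


def read_tree(
    path_or_string,
    taxa=None,
    extra_leaf: str = "error",
    default_length: float | None = None,
) -> LabeledTree:
    """Read a Newick tree into the canonical unrooted representation.

    ``taxa`` (optional) restricts the leaf set: extra leaves are pruned
    (``extra_leaf='prune'``, with a log message) or rejected.  Missing
    branch lengths are rejected unless ``default_length`` is given.
    """
    s = str(path_or_string)
    if "(" in s and ";" in s:
        src = {"data": s, "schema": "newick"}
    else:
        src = {"path": s, "schema": "newick"}
    dtree = dendropy.Tree.get(**src, suppress_internal_node_taxa=True)
    if default_length is not None:
        for nd in dtree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length is None:
                nd.edge.length = default_length
    adj, lengths = _adjacency_from_dendropy(dtree)
    if taxa is not None:
        taxa = set(taxa)
        extras = sorted(n for n in adj if isinstance(n, str) and n not in taxa)
        if extras:
            if extra_leaf == "prune":
                log.info("pruning leaves absent from alignment: %s", extras)
                for leaf in extras:
                    _prune_leaf(adj, lengths, leaf)
            else:
                raise ValueError(f"tree leaves not in alignment: {extras}")
        missing = taxa - {n for n in adj if isinstance(n, str)}
        if missing:
            raise ValueError(f"alignment taxa not in tree: {sorted(missing)}")
    if any(ln < 0 for ln in lengths.values()):
        raise ValueError("negative branch length")
    return LabeledTree(adj, lengths)


@dataclass
class ActivityTable:
    """Species -> (activity, clade) with activity in {D, N}."""

    rows: dict  # species -> (activity, clade)

    ACTIVITIES = {"D", "N"}

    def activity(self, species: str) -> str:
        return self.rows[species][0]

    def clade(self, species: str) -> str:
        return self.rows[species][1]

    @classmethod
    def from_records(cls, records) -> "ActivityTable":
        rows = {}
        for rec in records:
            species, activity, *rest = rec
            activity = {"DIURNAL": "D", "NOCTURNAL": "N"}.get(activity.upper(), activity.upper())
            if activity not in cls.ACTIVITIES:
                raise ValueError(f"activity for {species!r} must be D or N, got {activity!r}")
            clade = rest[0].lower() if rest and rest[0] else "colubrid"
            rows[species] = (activity, clade)
        return cls(rows)


def read_activity_table(path) -> ActivityTable:
    records = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            records.append(line.split("\t"))
    return ActivityTable.from_records(records)


@dataclass
class BranchPartition:
    """Assignment of every branch to one omega class.

    ``classes[0]`` is the background class that mixed internal branches
    fall back to.  ``foreground`` (branch ids) marks branch-site
    foreground lineages.
    """

    classes: list
    assignment: dict  # branch_id -> class index
    foreground: frozenset = field(default_factory=frozenset)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def branches_of_class(self, name: str):
        k = self.classes.index(name)
        return sorted(b for b, c in self.assignment.items() if c == k)

    def class_sizes(self) -> dict:
        sizes = {c: 0 for c in self.classes}
        for c in self.assignment.values():
            sizes[self.classes[c]] += 1
        return sizes

    def with_foreground(self, branch_ids) -> "BranchPartition":
        fg = frozenset(branch_ids)
        unknown = fg - set(self.assignment)
        if unknown:
            raise ValueError(f"foreground branches not in partition: {sorted(unknown)}")
        return BranchPartition(self.classes, dict(self.assignment), fg)


SCHEMES = ("1w", "2w", "3w", "4w", "4w-activity", "free")

_NONSNAKE = {"nonsnake", "non-snake", "outgroup"}
_HENO = {"henophidian"}


def _leaf_class(scheme: str, activity: str, clade: str) -> str:
    if scheme == "1w":
        return "all"
    if clade in _NONSNAKE:
        return "nonsnake"
    if scheme == "2w":
        return "snake"
    if clade in _HENO:
        return "henophidian"
    if scheme == "3w":
        return "colubrid"
    if scheme == "4w":
        if clade not in ("colubrinae", "dipsadinae"):
            raise ValueError(f"4w scheme needs colubrinae/dipsadinae clade, got {clade!r}")
        return clade
    if scheme == "4w-activity":
        return "diurnal" if activity == "D" else "nocturnal"
    raise ValueError(f"unknown scheme {scheme!r}")


_SCHEME_CLASSES = {
    "1w": ["all"],
    "2w": ["nonsnake", "snake"],
    "3w": ["nonsnake", "henophidian", "colubrid"],
    "4w": ["nonsnake", "henophidian", "colubrinae", "dipsadinae"],
    "4w-activity": ["nonsnake", "henophidian", "diurnal", "nocturnal"],
}


def label_branches(
    tree: LabeledTree,
    table: ActivityTable,
    scheme: str,
    internal: str = "clade",
) -> BranchPartition:
    """Assign every branch of ``tree`` to an omega class under ``scheme``.

    Leaf branches take their species' class.  With ``internal='clade'``
    (default) an internal branch takes a class iff all its descendant
    leaves share it, otherwise the background class; ``internal='leaf-only'``
    sends every internal branch to background.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {SCHEMES}, got {scheme!r}")
    missing = [t for t in tree.taxa if t not in table.rows]
    if missing and scheme != "free":
        raise ValueError(f"species missing from activity table: {missing}")

    if scheme == "free":
        classes = [f"branch_{b}" for b in tree.branch_ids()]
        return BranchPartition(classes, {b: b for b in tree.branch_ids()})

    classes = list(_SCHEME_CLASSES[scheme])
    leaf_cls = {
        t: _leaf_class(scheme, table.activity(t), table.clade(t)) for t in tree.taxa
    }
    # orient every branch away from a background reference leaf, so
    # "the clade below a branch" matches the conventional rooting at
    # the outgroup/background lineage
    background = [t for t in tree.taxa if leaf_cls[t] == classes[0]]
    ref = min(background) if background else tree.taxa[0]
    all_taxa = frozenset(tree.taxa)
    assignment = {}
    for b in tree.branch_ids():
        leaves = tree.branch_leafset(b)
        if len(leaves) > 1 and ref in leaves and leaves != all_taxa:
            leaves = all_taxa - leaves
        seen = {leaf_cls[t] for t in leaves}
        if len(seen) == 1 and (internal == "clade" or len(leaves) == 1):
            assignment[b] = classes.index(next(iter(seen)))
        else:
            assignment[b] = 0
    return BranchPartition(classes, assignment)


def foreground_from_class(partition: BranchPartition, name: str) -> BranchPartition:
    """Mark all branches of one class as branch-site foreground."""
    return partition.with_foreground(partition.branches_of_class(name))
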