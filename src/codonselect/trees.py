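"""Rooted phylogenies with codeml-style ``#1`` foreground branch tags.

Newick reading/writing is delegated to dendropy; the ``#1`` tag dialect used
by codeml to mark foreground branches is layered on top (``#`` is not a
reserved Newick character, so tags survive parsing as part of the label and
are split off here).

Every non-root node defines a branch named after that node: tips are named
by their taxon label, internal branches by their node label (``A``, ``B``,
``C`` for the study topology) or an automatic ``nodeN`` id.  Branch names
are the keys used by per-branch omega maps, estimates tables and foreground
sets throughout the package.
"""

from __future__ import annotations

import io
import itertools
import re

import dendropy

__all__ = [
    "Node",
    "Phylogeny",
    "make_study_tree",
    "HIGHLAND",
    "SUBHIGHLAND",
    "LOWLAND",
    "DEFAULT_BRANCH_LENGTHS",
]

HIGHLAND = ("G_dobula", "P_kaznakovi")
SUBHIGHLAND = ("S_gongshanensis", "S_prenanti")
LOWLAND = ("C_idella", "D_rerio")

#: Default branch lengths (expected substitutions per codon) for the
#: six-taxon study topology.  The paper's tree is dated in MYA, not
#: substitutions; these values are the package's simulation conditions,
#: chosen so per-branch rate parameters are well resolved at supergene scale
#: (see docs/methods.md).
DEFAULT_BRANCH_LENGTHS: dict[str, float] = {
    "G_dobula": 0.35,
    "P_kaznakovi": 0.35,
    "S_gongshanensis": 0.35,
    "S_prenanti": 0.35,
    "A": 0.35,
    "B": 0.35,
    "C": 0.40,
    "C_idella": 0.50,
    "D_rerio": 0.70,
}

_TAG_RE = re.compile(r"\s*#\s*(\d+)\s*$")


class Node:
    """One node of a rooted phylogeny; the edge above it is 'its' branch."""

    __slots__ = ("name", "length", "children", "foreground", "parent")

    def __init__(self, name=None, length=None, children=None, foreground=False):
        self.name = name
        self.length = length
        self.children: list[Node] = list(children or [])
        self.foreground = bool(foreground)
        self.parent: Node | None = None
        for c in self.children:
            c.parent = self

    @property
    def is_tip(self) -> bool:
        return not self.children

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Node {self.name!r} t={self.length} fg={self.foreground}>"


class Phylogeny:
    """Rooted tree with named branches and an optional foreground set."""

    def __init__(self, root: Node):
        self.root = root
        self._autoname()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        """Parse Newick, honouring codeml ``#1`` branch tags."""
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

        def convert(dnode) -> Node:
            label = dnode.taxon.label if dnode.taxon else dnode.label
            fg = False
            if label is not None:
                m = _TAG_RE.search(label)
                if m:
                    fg = int(m.group(1)) >= 1
                    label = label[: m.start()] or None
            node = Node(name=label, length=dnode.edge.length, foreground=fg)
            for child in dnode.child_nodes():
                c = convert(child)
                c.parent = node
                node.children.append(c)
            return node

        return cls(convert(dtree.seed_node))

    @classmethod
    def read(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def _autoname(self):
        seen = set()
        counter = itertools.count(1)
        for nd in self.root.postorder():
            if nd.name is None and nd is not self.root:
                nd.name = f"node{next(counter)}"
                while nd.name in seen:
                    nd.name = f"node{next(counter)}"
            if nd.name is not None:
                if nd.name in seen:
                    raise ValueError(f"duplicate node/branch name {nd.name!r}")
                seen.add(nd.name)

    # -- queries ------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return [nd.name for nd in self.root.postorder() if nd.is_tip]

    def branches(self) -> dict[str, Node]:
        """Branch name -> child node of that branch (root excluded)."""
        return {nd.name: nd for nd in self.root.postorder() if nd is not self.root}

    @property
    def foreground(self) -> set[str]:
        return {n for n, nd in self.branches().items() if nd.foreground}

    def node(self, name: str) -> Node:
        for nd in self.root.postorder():
            if nd.name == name:
                return nd
        raise KeyError(name)

    # -- edits --------------------------------------------------------

    def set_foreground(self, branch_names) -> "Phylogeny":
        branch_names = set(branch_names)
        known = set(self.branches())
        unknown = branch_names - known
        if unknown:
            raise KeyError(f"unknown foreground branch(es): {sorted(unknown)}")
        for name, nd in self.branches().items():
            nd.foreground = name in branch_names
        return self

    def set_lengths(self, lengths: dict[str, float]) -> "Phylogeny":
        br = self.branches()
        unknown = set(lengths) - set(br)
        if unknown:
            raise KeyError(f"unknown branch(es): {sorted(unknown)}")
        for name, t in lengths.items():
            if t < 0:
                raise ValueError(f"branch length must be >= 0 (branch {name}: {t})")
            br[name].length = float(t)
        return self

    def copy(self) -> "Phylogeny":
        return Phylogeny.from_newick(self.to_newick())

    def unroot(self) -> "Phylogeny":
        """Collapse a degree-2 root by merging its two child branches.

        Under a reversible model the two branches incident to a bifurcating
        root are only jointly identifiable; fits operate on the unrooted
        (multifurcating-root) form.  Trees whose root already has three or
        more children are returned unchanged.
        """
        tree = self.copy()
        root = tree.root
        if len(root.children) != 2:
            return tree
        left, right = root.children
        # graft the shallower side onto the deeper one's child list
        keep, fold = (left, right) if not left.is_tip else (right, left)
        if keep.is_tip:
            raise ValueError("cannot unroot a two-taxon tree")
        fold.length = (fold.length or 0.0) + (keep.length or 0.0)
        fold.foreground = fold.foreground or keep.foreground
        new_root = Node(name=keep.name, children=list(keep.children) + [fold])
        return Phylogeny(new_root)

    def prune_to(self, taxa) -> "Phylogeny":
        """Restrict to a taxon subset, fusing resulting unary branches.

        Fused branch lengths add; a fused branch is foreground if either
        component was.  The retained branch keeps the name of its lower
        (tipward) component, so pruning the six-taxon study tree to the four
        branch-site taxa leaves the highland stem named ``A``.
        """
        taxa = set(taxa)
        missing = taxa - set(self.taxa)
        if missing:
            raise KeyError(f"taxa not in tree: {sorted(missing)}")

        def rebuild(nd: Node) -> Node | None:
            if nd.is_tip:
                if nd.name not in taxa:
                    return None
                return Node(nd.name, nd.length, foreground=nd.foreground)
            kids = [k for k in (rebuild(c) for c in nd.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                (k,) = kids
                if nd is not self.root:
                    k.length = (k.length or 0.0) + (nd.length or 0.0)
                    k.foreground = k.foreground or nd.foreground
                return k
            out = Node(nd.name, nd.length, children=kids, foreground=nd.foreground)
            return out

        new_root = rebuild(self.root)
        if new_root is None or new_root.is_tip:
            raise ValueError("pruning removed the whole tree")
        new_root.length = None
        new_root.foreground = False
        return Phylogeny(new_root)

    # -- output -------------------------------------------------------

    def to_newick(self, tags: bool = True, internal_labels: bool = True) -> str:
        def fmt(nd: Node) -> str:
            if nd.is_tip:
                s = nd.name
            else:
                inner = ",".join(fmt(c) for c in nd.children)
                label = nd.name if (internal_labels and nd is not self.root) else ""
                s = f"({inner}){label or ''}"
            if tags and nd.foreground:
                s += "#1"
            if nd.length is not None:
                s += f":{nd.length:g}"
            return s

        return fmt(self.root) + ";"

    def write(self, path, **kw):
        with open(path, "w") as fh:
            fh.write(self.to_newick(**kw) + "\n")

    def __repr__(self):  # pragma: no cover
        return f"<Phylogeny {self.to_newick()}>"


def make_study_tree(branch_lengths=None, foreground=()) -> Phylogeny:
    """Six-taxon study topology with labelled ancestral nodes.

    ``(((G_dobula, P_kaznakovi)A, (S_gongshanensis, S_prenanti)B)C,
    C_idella, D_rerio)`` — the highland pair under node A, the subhighland
    pair under node B, the Schizothoracine ancestor at node C, with the two
    lowland cyprinids attached at the (multifurcating, unrooted-style) root.

    Parameters
    ----------
    branch_lengths : mapping branch -> substitutions per codon; defaults to
        :data:`DEFAULT_BRANCH_LENGTHS`.  All lengths must be positive.
    foreground : iterable of branch names to tag ``#1`` (e.g. the highland
        clade ``{"G_dobula", "P_kaznakovi", "A"}``).
    """
    lengths = dict(DEFAULT_BRANCH_LENGTHS)
    if branch_lengths:
        lengths.update(branch_lengths)
    if any(t <= 0 for t in lengths.values()):
        raise ValueError("make_study_tree requires strictly positive branch lengths")
    newick = (
        "(((G_dobula,P_kaznakovi)A,(S_gongshanensis,S_prenanti)B)C,"
        "C_idella,D_rerio);"
    )
    tree = Phylogeny.from_newick(newick)
    tree.set_lengths({k: lengths[k] for k in tree.branches()})
    tree.set_foreground(foreground)
    return tree
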