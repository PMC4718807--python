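"""Alignment and tree I/O plus alignment-level bookkeeping.

Amino-acid alignments are held in :class:`AminoAcidAlignment` (labels plus a
character matrix over the 20 residues, gap ``-`` and unknown ``X``); trees are
held in :class:`Phylogeny`, a lightweight rooted/unrooted structure with branch
lengths in expected substitutions per site. Newick text is parsed and written
through dendropy; FASTA through Biopython.

Sites are stored 0-based internally; every human-facing report uses 1-based
site numbers.
"""

from __future__ import annotations

import io
import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical one-letter residue order (the PAML/WAG convention).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
UNKNOWN = "X"
ALPHABET = set(AMINO_ACIDS) | {GAP, UNKNOWN}
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class AlignmentError(ValueError):
    """Malformed alignment: ragged rows, bad symbols, duplicate labels."""


class TreeError(ValueError):
    """Malformed or unusable tree."""


class ReconciliationError(ValueError):
    """Alignment rows and tree leaves do not match one-to-one."""


@dataclass(frozen=True)
class AminoAcidAlignment:
    """Labeled, equal-length amino-acid sequences with gaps.

    ``states`` is an (n_taxa, n_sites) array of single characters drawn from
    the 20 residues plus ``-`` (gap) and ``X`` (unknown).
    """

    labels: tuple[str, ...]
    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype="U1")
        if states.ndim != 2:
            raise AlignmentError("states must be a 2-D character matrix")
        object.__setattr__(self, "states", states)
        if len(self.labels) != states.shape[0]:
            raise AlignmentError(
                f"{len(self.labels)} labels for {states.shape[0]} rows"
            )
        if len(set(self.labels)) != len(self.labels):
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise AlignmentError(f"duplicate sequence labels: {dupes}")
        if any(not l for l in self.labels):
            raise AlignmentError("empty sequence label")
        bad = set(states.ravel()) - ALPHABET
        if bad:
            # name the first offending record and column for the error message
            for i, row in enumerate(states):
                for j, c in enumerate(row):
                    if c not in ALPHABET:
                        raise AlignmentError(
                            f"illegal symbol {c!r} in record {self.labels[i]!r}"
                            f" at site {j + 1} (1-based)"
                        )
        object.__setattr__(self, "labels", tuple(self.labels))

    @classmethod
    def from_sequences(
        cls, labels: Sequence[str], sequences: Sequence[str]
    ) -> "AminoAcidAlignment":
        seqs = [s.upper() for s in sequences]
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
        n_sites = lengths.pop() if lengths else 0
        states = np.array([list(s) for s in seqs], dtype="U1").reshape(
            len(seqs), n_sites
        )
        return cls(tuple(labels), states)

    @property
    def n_taxa(self) -> int:
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    def sequence(self, label: str) -> str:
        return "".join(self.states[self.labels.index(label)])

    def row(self, label: str) -> np.ndarray:
        return self.states[self.labels.index(label)]

    def take_sites(self, sites: Sequence[int]) -> "AminoAcidAlignment":
        return AminoAcidAlignment(self.labels, self.states[:, list(sites)])


@dataclass(frozen=True)
class SiteMask:
    """Ordered original-column indices retained after site filtering (0-based)."""

    kept_sites: tuple[int, ...]
    n_sites_origin: int

    def __post_init__(self) -> None:
        ks = tuple(int(i) for i in self.kept_sites)
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("kept_sites must be strictly increasing")
        if ks and (ks[0] < 0 or ks[-1] >= self.n_sites_origin):
            raise ValueError("kept_sites out of range")
        object.__setattr__(self, "kept_sites", ks)

    def __len__(self) -> int:
        return len(self.kept_sites)

    def one_based(self) -> tuple[int, ...]:
        """Original site numbers as reported to humans."""
        return tuple(i + 1 for i in self.kept_sites)

    def compose(self, inner: "SiteMask") -> "SiteMask":
        """Mask-of-a-mask: map ``inner`` (defined on my output) to my origin."""
        if inner.n_sites_origin != len(self.kept_sites):
            raise ValueError("inner mask does not match this mask's output size")
        return SiteMask(
            tuple(self.kept_sites[i] for i in inner.kept_sites),
            self.n_sites_origin,
        )


class TreeNode:
    """Node of a :class:`Phylogeny`; leaves carry ``label``, all nodes an ``id``."""

    __slots__ = ("id", "label", "length", "support", "parent", "children")

    def __init__(
        self,
        id: str,
        label: str | None = None,
        length: float = 0.0,
        support: float | None = None,
    ) -> None:
        self.id = id
        self.label = label
        self.length = float(length)
        self.support = support
        self.parent: "TreeNode | None" = None
        self.children: list["TreeNode"] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = f"leaf {self.label!r}" if self.is_leaf else f"internal ({self.id})"
        return f"<TreeNode {kind} t={self.length:g}>"


class Phylogeny:
    """Rooted or unrooted tree with branch lengths in substitutions/site."""

    def __init__(self, root: TreeNode, rooted: bool | None = None) -> None:
        self.root = root
        self.root.length = 0.0
        self.rooted = (
            rooted if rooted is not None else len(root.children) == 2
        )
        self._validate()

    def _validate(self) -> None:
        labels = [n.label for n in self.leaves()]
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")
        for node in self.preorder():
            if not np.isfinite(node.length) or node.length < 0:
                raise TreeError(
                    f"branch length of node {node.id} is {node.length!r}"
                )

    # -- traversals ------------------------------------------------------
    def preorder(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterable[TreeNode]:
        return reversed(list(self.preorder()))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def node(self, node_id: str) -> TreeNode:
        for n in self.preorder():
            if n.id == node_id:
                return n
        raise TreeError(f"no node with id {node_id!r}")

    def mrca(self, labels: Iterable[str]) -> TreeNode:
        """Most recent common ancestor of a set of leaf labels (rooted trees)."""
        want = set(labels)
        below: dict[TreeNode, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.label}
            else:
                below[node] = set().union(*(below[c] for c in node.children))
        missing = want - below[self.root]
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")
        best = self.root
        changed = True
        while changed:
            changed = False
            for c in best.children:
                if want <= below[c]:
                    best = c
                    changed = True
                    break
        return best

    def copy(self) -> "Phylogeny":
        mapping: dict[TreeNode, TreeNode] = {}
        for node in self.preorder():
            clone = TreeNode(node.id, node.label, node.length, node.support)
            mapping[node] = clone
            if node.parent is not None:
                mapping[node.parent].add_child(clone)
        return Phylogeny(mapping[self.root], rooted=self.rooted)

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.preorder() if n.parent is not None)

    def reroot_on_edge(self, child_id: str, fraction: float = 0.5) -> "Phylogeny":
        """Return a copy rerooted on the edge above node ``child_id``.

        The edge is split at ``fraction`` of its length (measured from the
        child). For a reversible model the likelihood is invariant to this.
        """
        tree = self.copy()
        child = tree.node(child_id)
        if child.parent is None:
            raise TreeError("cannot reroot on the root's (nonexistent) edge")
        # path from the child's parent up to the old root; these edges reverse
        path: list[TreeNode] = []
        node: TreeNode | None = child.parent
        while node is not None:
            path.append(node)
            node = node.parent
        up_lengths = [n.length for n in path[:-1]]
        path[0].children.remove(child)
        for lower, upper in zip(path, path[1:]):
            upper.children.remove(lower)
        for i, (lower, upper) in enumerate(zip(path, path[1:])):
            lower.add_child(upper)
            upper.length = up_lengths[i]
        t = child.length
        new_root = TreeNode("reroot")
        new_root.add_child(child)
        child.length = t * fraction
        new_root.add_child(path[0])
        path[0].length = t * (1.0 - fraction)
        # collapse degree-2 nodes left by reversal (the old root, typically)
        _suppress_unifurcations(new_root)
        return Phylogeny(new_root, rooted=True)


def _suppress_unifurcations(root: TreeNode) -> None:
    stack = [root]
    while stack:
        node = stack.pop()
        for child in list(node.children):
            while len(child.children) == 1:
                grand = child.children[0]
                grand.length += child.length
                grand.parent = node
                node.children[node.children.index(child)] = grand
                child = grand
            stack.append(child)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta_alignment(source) -> AminoAcidAlignment:
    """Read a sequential FASTA alignment from a path or text stream."""
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return read_fasta_alignment(fh)
    records = list(SeqIO.parse(source, "fasta"))
    if not records:
        raise AlignmentError("no FASTA records found")
    labels = [r.id for r in records]
    return AminoAcidAlignment.from_sequences(labels, [str(r.seq) for r in records])


def write_fasta_alignment(aln: AminoAcidAlignment, sink) -> None:
    """Write sequential FASTA, 60-column wrapped. Refuses empty alignments."""
    if aln.n_taxa == 0:
        raise AlignmentError("refusing to write an alignment with zero records")
    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8") as fh:
            write_fasta_alignment(aln, fh)
            return
    records = [
        SeqRecord(Seq("".join(row)), id=label, description="")
        for label, row in zip(aln.labels, aln.states)
    ]
    SeqIO.write(records, sink, "fasta")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(source) -> Phylogeny:
    """Parse one Newick statement; internal labels become support values."""
    if isinstance(source, str) and "(" not in source:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    if ";" not in text:
        raise TreeError(
            f"truncated Newick (no terminating ';') near offset {len(text)}"
        )
    if text.count("(") != text.count(")"):
        raise TreeError(
            "unbalanced parentheses: "
            f"{text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeError(f"Newick parse error: {exc}") from exc

    counter = itertools.count()

    def convert(dnode) -> TreeNode:
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
            node = TreeNode(f"leaf_{label}", label=label)
        else:
            support = None
            if dnode.label is not None:
                try:
                    support = float(dnode.label)
                except ValueError:
                    support = None
            node = TreeNode(f"node{next(counter)}", support=support)
        if dnode.edge.length is None:
            if dnode.parent_node is not None:
                logger.warning("missing branch length treated as 0")
            node.length = 0.0
        else:
            node.length = float(dnode.edge.length)
        for dchild in dnode.child_nodes():
            node.add_child(convert(dchild))
        return node

    root = convert(dtree.seed_node)
    return Phylogeny(root)


def write_newick(tree: Phylogeny, sink=None) -> str:
    """Serialize to Newick; support values become internal labels."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            label = node.label or node.id
            body = _quote_label(label)
        else:
            inner = ",".join(fmt(c) for c in node.children)
            sup = "" if node.support is None else _format_float(node.support)
            body = f"({inner}){sup}"
        if node.parent is None:
            return body
        return f"{body}:{_format_float(node.length)}"

    text = fmt(tree.root) + ";"
    if sink is not None:
        if isinstance(sink, str):
            with open(sink, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        else:
            sink.write(text + "\n")
    return text


def _quote_label(label: str) -> str:
    if any(c in label for c in "():;,[] \t'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _format_float(x: float) -> str:
    return format(float(x), ".10g")


# ---------------------------------------------------------------------------
# Alignment bookkeeping
# ---------------------------------------------------------------------------

def strip_gapped_sites(
    aln: AminoAcidAlignment, scope: Sequence[str] | None = None
) -> tuple[AminoAcidAlignment, SiteMask]:
    """Drop every column with a gap in any scoped taxon.

    ``scope`` defaults to all taxa. Returns the reduced alignment and a
    :class:`SiteMask` mapping retained columns back to original indices.
    """
    if scope is None:
        rows = aln.states
    else:
        missing = [t for t in scope if t not in aln.labels]
        if missing:
            raise AlignmentError(f"scope taxa not in alignment: {missing}")
        rows = aln.states[[aln.labels.index(t) for t in scope]]
    keep = ~np.any(rows == GAP, axis=0)
    if not keep.any():
        raise AlignmentError("all columns contain gaps in the scoped taxa")
    kept = tuple(int(i) for i in np.flatnonzero(keep))
    return aln.take_sites(kept), SiteMask(kept, aln.n_sites)


def reconcile(aln: AminoAcidAlignment, tree: Phylogeny) -> dict[str, int]:
    """Bijection tree-leaf-label -> alignment-row index by exact match."""
    leaf_set = set(tree.leaf_labels())
    row_set = set(aln.labels)
    only_tree = sorted(leaf_set - row_set)
    only_aln = sorted(row_set - leaf_set)
    if only_tree or only_aln:
        raise ReconciliationError(
            f"unmatched tree leaves: {only_tree}; unmatched alignment rows: {only_aln}"
        )
    return {label: aln.labels.index(label) for label in tree.leaf_labels()}
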