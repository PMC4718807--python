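"""Empirical-Bayes marginal ancestral reconstruction and its downstream
summaries: maximum-likelihood and "Alt-All" ancestral sequences, posterior-
probability statistics, replacement sets between ancestors, conservation
filtering, and Dollo-parsimony gene-age placement.

Marginal reconstruction fixes the model parameters at their ML values and
computes, per internal node and site, the posterior distribution over the 20
residues: within each rate category the posterior of state x is proportional
to the product of the conditional likelihood of the data below the node and
the "outside" partial propagated from the root (which carries the stationary
prior); categories are then mixed with each site's posterior category
probability. A site is called ambiguously reconstructed when its second-best
state has posterior probability strictly greater than the threshold (0.20 by
default); the Alt-All sequence carries that second-best state at exactly
those sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .likelihood import prune
from .models import SubstitutionModel, N_STATES
from .phyloio import (
    AMINO_ACIDS,
    AminoAcidAlignment,
    GAP,
    Phylogeny,
    SiteMask,
    TreeError,
    TreeNode,
    UNKNOWN,
)

AMBIGUITY_THRESHOLD = 0.20

#: residue order used for deterministic tie-breaking (alphabetical one-letter)
_ALPHA_ORDER = np.argsort(list(AMINO_ACIDS), kind="stable")


class ReconstructionError(ValueError):
    pass


@dataclass
class AncestralReconstruction:
    """Per-site posterior state distributions at one internal node."""

    node_id: str
    posteriors: np.ndarray  # (n_sites, 20) in ARNDCQEGHILKMFPSTWYV order
    ml_state: np.ndarray  # (n_sites,) one-letter codes
    pp_ml: np.ndarray
    alt_state: np.ndarray
    pp_alt: np.ndarray
    likely_gap: np.ndarray  # majority of the node's descendants are gapped
    threshold: float = AMBIGUITY_THRESHOLD

    @property
    def n_sites(self) -> int:
        return self.posteriors.shape[0]

    @property
    def ambiguous(self) -> np.ndarray:
        return self.pp_alt > self.threshold

    @property
    def n_ambiguous(self) -> int:
        return int(np.count_nonzero(self.ambiguous))


def _best_two(posteriors: np.ndarray) -> tuple[np.ndarray, ...]:
    """Top and second state per site with alphabetical tie-breaking."""
    # reorder columns alphabetically so argmax resolves ties alphabetically
    alpha_posteriors = posteriors[:, _ALPHA_ORDER]
    aas = np.array(list(AMINO_ACIDS))[_ALPHA_ORDER]
    order = np.argsort(-alpha_posteriors, axis=1, kind="stable")
    ml_idx, alt_idx = order[:, 0], order[:, 1]
    rows = np.arange(posteriors.shape[0])
    return (
        aas[ml_idx],
        alpha_posteriors[rows, ml_idx],
        aas[alt_idx],
        alpha_posteriors[rows, alt_idx],
    )


def marginal_posteriors(
    aln: AminoAcidAlignment,
    tree: Phylogeny,
    model: SubstitutionModel,
    node_id: str,
    threshold: float = AMBIGUITY_THRESHOLD,
) -> AncestralReconstruction:
    """Empirical-Bayes marginal posteriors at an internal node of a rooted tree.

    Model parameters (branch lengths, gamma shape, frequencies) are taken as
    given, i.e. they should already be at their ML values.
    """
    if not tree.rooted:
        raise TreeError(
            "marginal reconstruction needs a rooted tree (reroot first or "
            "pass a rooted topology)"
        )
    target = tree.node(node_id)
    if target.is_leaf:
        raise ReconstructionError("ancestral states are defined at internal nodes")
    result, tables = prune(aln, tree, model, keep_tables=True)
    index, K = tables.pattern_index, len(tables.down)
    n_pat = tables.lnL_cat.shape[1]

    # path root -> target
    path: list[TreeNode] = []
    node = target
    while node is not None:
        path.append(node)
        node = node.parent
    path.reverse()

    # per-pattern posterior weight of each category
    from scipy.special import logsumexp

    logw = tables.lnL_cat - np.log(K)
    cat_post = np.exp(logw - logsumexp(logw, axis=0, keepdims=True))  # (K, n_pat)

    mixed = np.zeros((n_pat, N_STATES))
    for k in range(K):
        down, P = tables.down[k], tables.transition[k]
        up = np.tile(model.pi, (n_pat, 1))
        for parent, child in zip(path, path[1:]):
            msg = up.copy()
            for sib in parent.children:
                if sib is not child:
                    msg *= down[sib.id] @ P[sib.id].T
            up = msg @ P[child.id]
            up /= up.max(axis=1, keepdims=True)  # rescale; normalized later
        post = up * down[target.id]
        post /= post.sum(axis=1, keepdims=True)
        mixed += cat_post[k][:, None] * post

    posteriors = mixed[index]
    ml_state, pp_ml, alt_state, pp_alt = _best_two(posteriors)

    # flag sites where most of the target's descendant leaves carry a gap
    leaf_rows = [
        aln.labels.index(leaf.label)
        for leaf in [n for n in _subtree_leaves(target)]
    ]
    gap_frac = np.mean(aln.states[leaf_rows] == GAP, axis=0)
    likely_gap = gap_frac > 0.5

    return AncestralReconstruction(
        node_id=node_id,
        posteriors=posteriors,
        ml_state=ml_state,
        pp_ml=pp_ml,
        alt_state=alt_state,
        pp_alt=pp_alt,
        likely_gap=likely_gap,
        threshold=threshold,
    )


def _subtree_leaves(node: TreeNode) -> list[TreeNode]:
    out, stack = [], [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            out.append(n)
        stack.extend(n.children)
    return out


def ml_sequence(rec: AncestralReconstruction, mask_gaps: bool = False) -> str:
    """Per-site maximum-posterior sequence (ties resolved alphabetically)."""
    seq = rec.ml_state.copy()
    if mask_gaps:
        seq = np.where(rec.likely_gap, GAP, seq)
    return "".join(seq)


def altall_sequence(
    rec: AncestralReconstruction,
    threshold: float | None = None,
    mask_gaps: bool = False,
) -> str:
    """ML sequence with the second-best state at every ambiguous site.

    A site is ambiguous when its second-highest posterior exceeds
    ``threshold`` (strictly). Even if more than two states pass the
    threshold, the sequence still carries exactly the second-best state.
    """
    if threshold is None:
        threshold = rec.threshold
    if not (0.0 < threshold < 1.0):
        raise ReconstructionError(
            f"ambiguity threshold must lie in (0, 1), got {threshold}"
        )
    seq = np.where(rec.pp_alt > threshold, rec.alt_state, rec.ml_state)
    if mask_gaps:
        seq = np.where(rec.likely_gap, GAP, seq)
    return "".join(seq)


@dataclass(frozen=True)
class ReconstructionSummary:
    mean_pp: float
    n_ambiguous: int
    expected_errors: float
    n_sites_included: int


def summarize(
    rec: AncestralReconstruction, mask: SiteMask | None = None
) -> ReconstructionSummary:
    """Posterior-probability summary over the masked-in sites.

    ``mask`` selects the columns that enter the averages (e.g. the indel-free
    sites); ``None`` includes every site.
    """
    if mask is None:
        sites = np.arange(rec.n_sites)
    else:
        if mask.n_sites_origin != rec.n_sites:
            raise ReconstructionError(
                f"mask is over {mask.n_sites_origin} sites but the "
                f"reconstruction has {rec.n_sites}"
            )
        if len(mask) == 0:
            raise ReconstructionError("empty site mask")
        sites = np.asarray(mask.kept_sites)
    pp = rec.pp_ml[sites]
    return ReconstructionSummary(
        mean_pp=float(pp.mean()),
        n_ambiguous=int(np.count_nonzero(rec.ambiguous[sites])),
        expected_errors=float(np.sum(1.0 - pp)),
        n_sites_included=len(sites),
    )


@dataclass(frozen=True)
class ReplacementSet:
    """Residue->residue differences between two aligned sequences.

    ``sites`` are 0-based alignment columns; ``skipped_sites`` are columns
    where either sequence carries a gap or X (not counted as replacements).
    """

    replacements: tuple[tuple[int, str, str], ...]
    skipped_sites: tuple[int, ...]

    @property
    def count(self) -> int:
        return len(self.replacements)

    def sites_one_based(self) -> tuple[int, ...]:
        return tuple(s + 1 for s, _, _ in self.replacements)


def compare_ancestors(seq_a: str, seq_b: str) -> ReplacementSet:
    """List the amino-acid replacements between two aligned sequences."""
    if len(seq_a) != len(seq_b):
        raise ReconstructionError(
            f"sequences have different lengths ({len(seq_a)} vs {len(seq_b)})"
        )
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    repl, skipped = [], []
    missing = {GAP, UNKNOWN}
    for i, (x, y) in enumerate(zip(seq_a, seq_b)):
        if x in missing or y in missing:
            skipped.append(i)
        elif x != y:
            repl.append((i, x, y))
    return ReplacementSet(tuple(repl), tuple(skipped))


def conserved_replacements(
    repl: ReplacementSet,
    descendants: AminoAcidAlignment,
    region_mask: set[int] | None = None,
    min_conservation: float = 0.9,
) -> ReplacementSet:
    """Filter replacements to those in a region of interest whose derived
    state is conserved among descendant sequences.

    ``region_mask`` holds 0-based columns (``None`` keeps all); a replacement
    is retained when its derived state occurs in at least ``min_conservation``
    of the non-gap descendant residues at that column.
    """
    out_of_range = [
        s + 1
        for s in {r[0] for r in repl.replacements} | set(region_mask or ())
        if s >= descendants.n_sites
    ]
    if out_of_range:
        raise ReconstructionError(
            f"sites {sorted(out_of_range)} outside descendant alignment "
            f"({descendants.n_sites} columns)"
        )
    kept = []
    for site, old, new in repl.replacements:
        if region_mask is not None and site not in region_mask:
            continue
        column = descendants.states[:, site]
        residues = column[(column != GAP) & (column != UNKNOWN)]
        if len(residues) == 0:
            continue
        if np.mean(residues == new) >= min_conservation:
            kept.append((site, old, new))
    return ReplacementSet(tuple(kept), repl.skipped_sites)


@dataclass(frozen=True)
class GeneAge:
    """Dollo-parsimony placement of a gene family's origin."""

    origin_node_id: str
    origin_is_root: bool
    origin_clade: tuple[str, ...]  # leaves subtended by the origin branch
    losses: tuple[tuple[str, ...], ...]  # maximal absent clades, as leaf sets


def dollo_gene_age(presence: dict[str, bool], species_tree: Phylogeny) -> GeneAge:
    """Single-gain/any-loss placement of a gene's origin on a species tree.

    The origin is the branch subtending the most recent common ancestor of
    all species where the gene is present; implied losses are the maximal
    clades inside that subtree in which the gene is absent everywhere.
    Species absent from ``presence`` are treated as lacking the gene.
    """
    leaves = set(species_tree.leaf_labels())
    unknown = sorted(set(presence) - leaves)
    if unknown:
        raise TreeError(f"species not in tree: {unknown}")
    present = sorted(s for s, p in presence.items() if p)
    if not present:
        raise ReconstructionError("gene present in no species; no origin to infer")
    mrca = species_tree.mrca(present)
    present_set = set(present)
    losses: list[tuple[str, ...]] = []

    def visit(node: TreeNode) -> None:
        labels = tuple(sorted(l.label for l in _subtree_leaves(node)))
        if not any(l in present_set for l in labels):
            losses.append(labels)
            return
        for child in node.children:
            visit(child)

    for child in mrca.children:
        visit(child)
    return GeneAge(
        origin_node_id=mrca.id,
        origin_is_root=mrca.parent is None,
        origin_clade=tuple(sorted(l.label for l in _subtree_leaves(mrca))),
        losses=tuple(losses),
    )
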