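import itertools

import numpy as np
import pytest
from hypothesis import settings

import gkasr as g
from gkasr.phyloio import AA_INDEX

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wag():
    return g.wag_model()


@pytest.fixture(scope="session")
def wag_gamma():
    return g.wag_model(alpha=0.5, n_categories=4)


@pytest.fixture
def quartet_tree():
    return g.read_newick("((A:0.1,B:0.2):0.15,(C:0.3,D:0.1):0.05);")


@pytest.fixture
def six_taxon_tree():
    return g.read_newick(
        "(((A:0.12,B:0.27):0.1,(C:0.2,D:0.33):0.08):0.15,(E:0.4,F:0.18):0.22);"
    )


def random_model(rng, n_categories=1, alpha=None):
    """Random reversible model: random symmetric exchangeabilities and
    Dirichlet frequencies."""
    S = rng.uniform(0.2, 3.0, size=(20, 20))
    S = 0.5 * (S + S.T)
    np.fill_diagonal(S, 0.0)
    pi = rng.dirichlet(np.ones(20) * 4)
    return g.build_model(S, pi=pi, alpha=alpha, n_categories=n_categories)


def brute_force_lnL(aln, tree, model):
    """Likelihood by full enumeration over internal-node state assignments."""
    cats = model.rate_categories
    nodes = list(tree.preorder())
    internal = [n for n in nodes if not n.is_leaf]
    total = 0.0
    for s in range(aln.n_sites):
        L = 0.0
        for k in range(cats.k):
            P = {
                n.id: model.transition_matrix(n.length, cats.rates[k])
                for n in nodes
                if n.parent is not None
            }
            for assign in itertools.product(range(20), repeat=len(internal)):
                st = {n.id: a for n, a in zip(internal, assign)}
                for leaf in tree.leaves():
                    st[leaf.id] = AA_INDEX[aln.sequence(leaf.label)[s]]
                p = model.pi[st[tree.root.id]]
                for n in nodes:
                    if n.parent is not None:
                        p *= P[n.id][st[n.parent.id], st[n.id]]
                L += cats.weights[k] * p
        total += np.log(L)
    return total


def brute_force_posterior(aln, tree, model, node_id, site):
    """Marginal posterior at one node and site by enumerating all internal
    assignments and summing the joint probability per target state."""
    cats = model.rate_categories
    nodes = list(tree.preorder())
    internal = [n for n in nodes if not n.is_leaf]
    target_pos = [n.id for n in internal].index(node_id)
    joint = np.zeros(20)
    for k in range(cats.k):
        P = {
            n.id: model.transition_matrix(n.length, cats.rates[k])
            for n in nodes
            if n.parent is not None
        }
        for assign in itertools.product(range(20), repeat=len(internal)):
            st = {n.id: a for n, a in zip(internal, assign)}
            for leaf in tree.leaves():
                st[leaf.id] = AA_INDEX[aln.sequence(leaf.label)[site]]
            p = model.pi[st[tree.root.id]]
            for n in nodes:
                if n.parent is not None:
                    p *= P[n.id][st[n.parent.id], st[n.id]]
            joint[assign[target_pos]] += cats.weights[k] * p
    return joint / joint.sum()
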