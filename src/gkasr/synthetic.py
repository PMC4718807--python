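"""Synthetic data with known ground truth for every stage of the pipeline.

Covers sequence evolution along a tree (so true ancestral states are known),
Michaelis–Menten initial-rate data, one-site saturation-binding anisotropy
data, and spindle-angle samples from oriented (concentrated) or unoriented
(uniform) distributions. Every generator is a pure function of its
parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import SubstitutionModel
from .phyloio import AMINO_ACIDS, AminoAcidAlignment, Phylogeny, TreeError


@dataclass(frozen=True)
class NoiseSpec:
    """Additive gaussian noise in response units."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class SimulatedEvolution:
    """An alignment evolved along a known tree, with full internal truth."""

    alignment: AminoAcidAlignment  # leaves only
    ancestral_states: dict[str, str]  # internal node id -> true sequence
    site_rate_category: np.ndarray  # (n_sites,) true category index
    tree: Phylogeny
    model: SubstitutionModel
    seed: int


def simulate_alignment(
    tree: Phylogeny, model: SubstitutionModel, n_sites: int, seed: int
) -> SimulatedEvolution:
    """Evolve ``n_sites`` residues down a rooted tree under the model.

    Per site a rate category is drawn uniformly, the root state from the
    stationary distribution, and each branch transition from the row of
    P(t·r) for the site's rate r.
    """
    if not tree.rooted:
        raise TreeError("simulation needs a rooted tree")
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    cats = model.rate_categories
    site_cat = rng.integers(0, cats.k, size=n_sites)
    states: dict[str, np.ndarray] = {}
    aas = np.array(list(AMINO_ACIDS))
    root_states = rng.choice(20, size=n_sites, p=model.pi)
    states[tree.root.id] = root_states
    for node in tree.preorder():
        if node.parent is None:
            continue
        parent_states = states[node.parent.id]
        child_states = np.empty(n_sites, dtype=int)
        for k in range(cats.k):
            sel = site_cat == k
            if not sel.any():
                continue
            P = model.transition_matrix(node.length, cats.rates[k])
            # vectorized multinomial draw via inverse CDF per parent state
            cdf = np.cumsum(P, axis=1)
            u = rng.random(np.count_nonzero(sel))
            rows = cdf[parent_states[sel]]
            child_states[sel] = (rows < u[:, None]).sum(axis=1)
        states[node.id] = child_states
    leaves = tree.leaves()
    aln = AminoAcidAlignment.from_sequences(
        [l.label for l in leaves],
        ["".join(aas[states[l.id]]) for l in leaves],
    )
    ancestral = {
        n.id: "".join(aas[states[n.id]])
        for n in tree.preorder()
        if not n.is_leaf
    }
    return SimulatedEvolution(aln, ancestral, site_cat, tree, model, seed)


#: log-spaced substrate grid emulating a GMP titration, 0.5 µM to 1 mM
DEFAULT_SUBSTRATE_GRID_UM = tuple(np.geomspace(0.5, 1000.0, 12).round(4))


def simulate_kinetics(
    kcat: float,
    km: float,
    e0: float,
    substrate_grid=None,
    noise: NoiseSpec = NoiseSpec(),
) -> pd.DataFrame:
    """Michaelis–Menten initial rates v(S) = kcat·E0·S/(KM+S) + noise.

    Units are the caller's; the default grid is in µM (0.5 µM – 1 mM).
    Returns a DataFrame with columns ``substrate`` and ``rate``.
    """
    if kcat <= 0 or km <= 0 or e0 <= 0:
        raise ValueError("kcat, KM and E0 must all be positive")
    S = np.asarray(
        substrate_grid if substrate_grid is not None else DEFAULT_SUBSTRATE_GRID_UM,
        dtype=float,
    )
    if np.any(S < 0):
        raise ValueError("negative substrate concentration")
    v = kcat * e0 * S / (km + S)
    if noise.sd > 0:
        v = v + np.random.default_rng(noise.seed).normal(0.0, noise.sd, len(S))
    return pd.DataFrame({"substrate": S, "rate": v})


def simulate_binding(
    kd: float,
    r_free: float,
    r_bound: float,
    titrant_grid=None,
    noise: NoiseSpec = NoiseSpec(),
) -> pd.DataFrame:
    """One-site saturation binding r(L) = r_free + (r_bound−r_free)·L/(Kd+L)."""
    if kd <= 0:
        raise ValueError("Kd must be positive")
    if r_bound == r_free:
        raise ValueError("r_bound must differ from r_free")
    L = np.asarray(
        titrant_grid
        if titrant_grid is not None
        else np.concatenate([[0.0], np.geomspace(kd / 50, kd * 50, 11)]),
        dtype=float,
    )
    if np.any(L < 0):
        raise ValueError("negative titrant concentration")
    r = r_free + (r_bound - r_free) * L / (kd + L)
    if noise.sd > 0:
        r = r + np.random.default_rng(noise.seed).normal(0.0, noise.sd, len(L))
    return pd.DataFrame({"titrant": L, "anisotropy": r})


def simulate_angles(
    mode: str,
    n: int = 20,
    kappa: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Spindle-angle samples in degrees on [0, 90].

    ``unoriented`` draws uniformly; ``oriented`` draws a von Mises deviate on
    the doubled-angle circle (concentration ``kappa`` around 0) and folds it
    back to the axial 0–90° range, modeling concentration around perfect
    alignment. The default n of 20 mirrors a typical per-condition cell count.
    """
    if n < 1:
        raise ValueError("need at least one angle")
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    if mode == "unoriented":
        return rng.uniform(0.0, 90.0, size=n)
    if mode == "oriented":
        phi = rng.vonmises(0.0, kappa if kappa > 0 else 1e-12, size=n)
        return np.abs(phi) / 2.0 * (180.0 / np.pi)
    raise ValueError(f"unknown mode {mode!r}; use 'oriented' or 'unoriented'")
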