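# Methods

`gkasr` reimplements, as a tested library, the computational chain used to
study how the guanylate-kinase enzyme family gave rise to the GK protein-
interaction domain (GK_PID) that orients mitotic spindles: phylogenetic
likelihood on a fixed topology, empirical-Bayes marginal ancestral sequence
reconstruction with robustness ("Alt-All") sequences, parsimony dating of
gene-family origins, and the statistics of the downstream biochemical and
cell-biological assays.

## Substitution model

Sequence evolution is modeled as a reversible continuous-time Markov chain
on the 20 amino acids. The rate matrix is Q = S·diag(π) with the diagonal
set so rows sum to zero, where S is a symmetric exchangeability matrix and π
the stationary frequencies; Q is rescaled so the expected rate
−Σᵢ πᵢQᵢᵢ = 1, making branch lengths expected substitutions per site. The
WAG exchangeabilities ship with the package in the standard lower-triangle
text layout; any same-layout matrix (LG, JTT, …) can be loaded for model
comparison by AIC. Frequencies are either the matrix's own ("model") or
counted from the alignment ("empirical", the default, matching the `+F`
convention); empirical frequencies are floored at 1e−6 and renormalized so Q
stays irreducible — a zero-frequency state would break the symmetric
eigendecomposition used for P(t) = exp(Qt) and detailed balance with it.

Among-site rate variation uses the discrete-gamma approximation: K
equal-probability categories of Gamma(α, α), each represented by its
conditional mean computed in closed form from regularized incomplete gamma
functions, so the mean rate is exactly 1 for every (α, K). The default K = 4
is the convention of the standard ML phylogenetics tools; category means
(not medians) keep the normalization exact. No invariant-sites class is
offered. Transition matrices are computed through the symmetrized
eigendecomposition diag(√π)·Q·diag(1/√π), which is numerically stable and
guarantees real eigenvalues; entries are clipped to [0, 1] against roundoff
at the 1e−15 level and rows renormalized.

## Likelihood and optimization

The alignment likelihood is computed by Felsenstein's pruning algorithm over
the fixed, user-supplied topology, with per-node rescaling of conditional
likelihoods (log-scale accumulators) so alignments of hundreds of taxa do
not underflow. Identical site patterns are collapsed first. Gap (`-`) and
unknown (`X`) characters are treated as missing data — all-ones leaf
vectors — though they remain distinct symbols in storage. Per-site
log-likelihoods and posterior rate-category weights are retained for
ancestral inference. For reversible models the likelihood is invariant to
root placement; this is exercised by rerooting tests rather than assumed.

Branch lengths are estimated by cyclic coordinate-wise bounded scalar
minimization (Brent) on [1e−8, 20] substitutions/site, sweeping all branches
until the total log-likelihood improves by less than 1e−6 (cap 100 sweeps,
warning on hitting it). The gamma shape is optimized on a log scale over
[0.02, 100] to tolerance 1e−4. The two are interleaved once in the full
pipeline since they interact only weakly. Tree topology search is
deliberately out of scope: reconstruction, not tree inference, is the
load-bearing computation, and fixed-topology results are reproducible.

One caveat the recovery analyses respect: the two edges meeting at the root
of a rooted binary tree are not separately identifiable under a reversible
model — only their sum is. Recovery statistics therefore score the merged
root-spanning edge alongside the other branches.

Branch support uses the approximate likelihood-ratio test: the statistic is
2·(lnL of the current resolution − lnL of the better of its two
nearest-neighbor-interchange alternatives), floored at zero, re-optimizing
only the five branches incident to the rearranged quartet (the standard
speed/fidelity compromise). Confidence is the cumulative probability of the
½χ²₀ + ½χ²₁ mixture at the statistic, so a branch with no signal gets 0.5
and strong branches approach 1. AIC comparison of candidate model fits is
2k − 2·lnL with ties broken toward fewer parameters.

## Ancestral reconstruction

Marginal (not joint) reconstruction, in the empirical-Bayes style: model
parameters are fixed at their ML estimates, and per node and site the
posterior over the 20 states is computed from the product of the conditional
likelihood of the data below the node and the outside partial propagated
root-to-node (which carries the stationary prior). Within-category
posteriors are mixed using each site's posterior category weight — not the
single best category — matching the empirical-Bayes treatment of rate
uncertainty; a best-category variant exists only as a cross-check.

Per site the reconstruction records the ML state, its posterior pp_ml, the
second-best state and its pp_alt, with exact ties broken alphabetically by
one-letter code for determinism. A site is *ambiguously reconstructed* when
pp_alt > 0.20, strictly. The Alt-All sequence substitutes the second-best
state at exactly those sites, so its Hamming distance from the ML sequence
always equals the ambiguous-site count — an invariant the tests enforce on
every reconstruction. If more than two states clear the threshold the
Alt-All still carries exactly the second-best.

Summary statistics (mean pp_ml, ambiguous-site count, expected errors
Σ(1 − pp_ml)) are computed over an explicit site mask, by default the
columns free of gaps in the alignment, since posterior averages over
indel-containing columns would mix alignment uncertainty into reconstruction
confidence. Ancestral gaps themselves are not modeled (gaps are missing
data); instead, sites where the majority of the target node's descendant
leaves are gapped are flagged `likely_gap` in reports rather than assigned a
residue.

Replacement sets between two ancestral sequences list residue→residue
differences; columns where either sequence has a gap or X are reported
separately, not counted — an "amino acid replacement" means both states are
residues. The conservation filter keeps replacements whose derived state
appears in at least `min_conservation` (default 0.9) of the non-gap
descendant residues at that column, inside an optional region mask (e.g.
ligand-interface or hinge positions). The default is a parameter, not a
claim: conservation cutoffs are sensitivity-dependent and should be swept.

Gene-family ages are placed by Dollo parsimony — one gain, any number of
losses: the origin is the branch subtending the MRCA of all species carrying
the gene, and the implied losses are the maximal absent clades inside that
subtree. Species missing from the presence table are treated as absent.

## Synthetic data

The simulator draws, per site, a rate category uniformly and a root state
from π, then propagates state down each branch by sampling rows of P(t·r);
all internal-node states and the per-site category are kept, so recovery
accuracy and posterior calibration can be scored exactly. All generators are
pure functions of (parameters, seed).

Assay generators mirror the study's designs: Michaelis–Menten initial rates
on a 12-point log-spaced substrate grid from 0.5 µM to 1 mM (the GMP range
of the coupled enzyme assay) with enzyme at 50–200 nM scale; one-site
saturation binding r(L) = r_free + (r_bound − r_free)·L/(Kd + L); and
spindle angles either uniform on [0°, 90°] (unoriented) or von Mises on the
doubled-angle circle folded back to [0°, 90°] (oriented, concentration κ) —
the doubling because the observable is axial, an angle between undirected
lines. Default angle sample size is 20, a typical per-condition cell count.
Noise is additive gaussian with user-set SD in response units; the study
reports no noise model, so nothing fancier is defensible. The simulations
make no attempt to emulate alignment error, compositional heterogeneity
across lineages, site-specific selection or ligand depletion, so green tests
certify the estimators under the stated model, not robustness to model
violation.

## Assay fitting and angle statistics

Both curve fits are plain nonlinear least squares (Levenberg–Marquardt) with
asymptotic standard errors from the Jacobian. Kinetics initialization:
Vmax₀ = max observed rate, KM₀ = substrate level closest to half of it;
kcat = Vmax/E₀. Binding uses the hyperbolic (trace-probe) form — the labeled
peptide is held far below Kd in the assay this models — with the
ligand-depletion quadratic available as a sensitivity option. "No detectable
binding" is operationalized as the 95% confidence interval of the fitted
amplitude containing zero, turning the study's qualitative "does not bind"
calls into a reproducible rule.

The spindle-angle operator returns the acute angle between two undirected
2-D segments, θ = arccos(|u·v|/(‖u‖‖v‖)) ∈ [0°, 90°], invariant to endpoint
order and rigid motion; degenerate segments are errors, not zeros. Radial
histograms use nine 10° bins, half-open except the last ([80°, 90°]
closed).

## Problem sizes and numerical checks

The test and acceptance runs use sizes chosen to make the statistical claims
sharp on a desk machine: enumeration oracles on 3–4 taxa × ≤3 sites × K ≤ 2
(exact, tolerance 1e−10); parameter recovery on a 6-taxon tree at 5,000
sites (branch-length CV for the shortest branches is then under ~10%);
calibration and Alt-All checks at 400–5,000 sites; 100 noisy replicates for
the kinetics error distribution and 500 for binding bias. Determinism is
pinned by seeding every stochastic step and by bit-stable table output
(fixed column order, 1-based site numbering).

## Known limitations

- No topology search, no NNI/SPR beyond the aLRT's local rearrangements.
- No invariant-sites category; no codon or nucleotide models.
- Ancestral indels are flagged, not reconstructed; a gap-aware model (e.g.
  Dollo on indel characters) would be needed to place them.
- The aLRT here is the plain (non-SH) variant with a parametric mixture
  calibration; bootstrap-style corrections are out of scope.
- Binding fits assume equilibrium and a single site; cooperative or
  depletion regimes need the quadratic option or a different model.
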