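# gkasr

Ancestral sequence reconstruction and assay statistics for the gk/GK_PID
protein family — the guanylate-kinase enzymes and the guanylate-kinase-
derived protein-interaction domains (GK_PIDs) of Dlg-family scaffolds that
orient the mitotic spindle by binding the Pins linker peptide.

The package is for molecular evolutionists and protein biochemists who want
to rerun or probe this kind of analysis end to end: infer ancestral proteins
at internal nodes of a fixed phylogeny, quantify how confident each
reconstructed residue is, build the conservative "Alt-All" alternative
ancestor, date gene-family origins from presence/absence, and fit the
biochemical readouts (enzyme kinetics, binding, spindle angles) used to
assay resurrected proteins — all with a synthetic-data module that knows the
ground truth, so every estimator can be scored exactly.

## What it computes

**Likelihood.** For an amino-acid alignment on a fixed tree, the pruning
algorithm evaluates L = Πₛ Σₖ (1/K) Σₓ πₓ CLₖ(x) under a reversible model
Q = S·diag(π) (WAG bundled; any PAML-layout matrix loads) normalized to one
expected substitution per site, with discrete-gamma rate variation (K
equal-probability categories of Gamma(α, α) at their conditional means).
Branch lengths and α are optimized by bounded scalar search; models are
compared by AIC; branches get aLRT support, 2·(lnL − lnL_best-NNI)
calibrated against ½χ²₀ + ½χ²₁.

**Ancestors.** Empirical-Bayes marginal posteriors per node and site,
P(x | data) ∝ πₓ·CL_below(x)·CL_above(x) mixed over rate categories by their
per-site posterior weights. A site is ambiguous when its second-best state
has PP > 0.20; the Alt-All sequence carries the second-best state at exactly
those sites. Summaries (mean PP, ambiguous count, expected errors) are taken
over indel-free columns. Replacement sets between ancestors, a descendant-
conservation filter, and Dollo-parsimony gene ages round out the analysis.

**Assays.** Michaelis–Menten (v = V_max·S/(K_M+S), k_cat = V_max/E₀) and
one-site binding (r = r_free + (r_bound−r_free)·L/(K_d+L)) by nonlinear
least squares with asymptotic errors and a principled "no detectable
binding" call; acute spindle angles between undirected axes and their
radial histograms.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate 300 sites along a known quartet tree under WAG+Γ(α=0.5), then run
the full reconstruction pipeline on the result:

```python
import gkasr as g

tree = g.read_newick("((A:0.2,B:0.3):0.1,(C:0.25,D:0.15):0.1);")
model = g.wag_model(alpha=0.5, n_categories=4)
sim = g.simulate_alignment(tree, model, 300, seed=7)
g.write_fasta_alignment(sim.alignment, "example.fasta")
g.write_newick(tree, "example.nwk")
```

```sh
$ gkasr asr --alignment example.fasta --tree example.nwk --out out --alpha optimize
lnL = -2052.5620
alpha = 0.5372
node0: mean PP 0.8527, 49 ambiguous sites, 44.18 expected errors over 300 indel-free sites
node1: mean PP 0.8825, 31 ambiguous sites, 35.24 expected errors over 300 indel-free sites
node2: mean PP 0.9007, 31 ambiguous sites, 29.80 expected errors over 300 indel-free sites
```

The optimizer recovers the simulating shape (α̂ = 0.54 vs true 0.5). Each
internal node gets a mean posterior probability over its reconstructed
residues, a count of ambiguously reconstructed sites (second-best PP >
0.20), and the expected number of wrong residues in the ML sequence,
Σ(1 − PP). `out/` contains the ML and Alt-All sequences as FASTA, a
per-site 20-column posterior table per node (TSV, 1-based sites), and a
summary table. Because the data are simulated, the claim can be checked
against truth:

```sh
$ gkasr recovery-study --tree "((A:0.2,B:0.3):0.1,(C:0.25,D:0.15):0.1);" --sites 300 --seed 7
recovery accuracy = 0.8500
mean PP = 0.8518
ambiguous sites = 52
ML vs Alt-All differences = 52
```

85% of true root states are recovered, the mean PP (0.85) tracks the
realized accuracy (the reconstruction is well calibrated), and the Alt-All
sequence differs from the ML sequence at exactly the ambiguous sites — an
invariant, not a coincidence.

Other subcommands: `simulate`, `fit-kinetics`, `fit-binding`, `angles`,
`gene-age` (`gkasr --help`). Everything is equally usable as a library.

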