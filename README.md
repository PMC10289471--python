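# spacephylo

Continuous-space speciation simulation and the diagnostics that reveal how
geography distorts phylogenetic inference.

Phylogenetic models built on the multispecies coalescent (MSC) treat every
species-tree branch as a panmictic population: gene lineages coalesce at
rate 1/(2Ne), discordant gene-tree topologies appear in fixed ratios, and
node heights estimate divergence times as π₁₂ = 2μ(T_D + 2Ne). Real
populations live on landscapes. When dispersal is short relative to the
range, ancestry stays spatially autocorrelated across speciation events and
every one of those MSC predictions bends: mirror discordant topologies
become unequal (an asymmetry due to ancestral structure rather than
hybridization, "Slatkin's skew"), gene-tree branch lengths inflate and their
variance explodes, and the unfolded site frequency spectrum (SFS) shifts
toward intermediate-frequency alleles.

`spacephylo` is a tool for phylogeneticists and phylogeographers who want to
see, quantify, or control for those effects. It provides:

- **`spatial_sim`** — a forward-time, individual-based simulator of diploid
  populations on a continuous 2-D range. Local density is measured with a
  truncated Gaussian kernel (maximum 1/(2πσ_I²), cut off at 3σ_I); focal
  parents produce Poisson(2/(1 + D_i/D\*)) offspring with mates drawn within
  3σ_M by Gaussian weight; offspring disperse by uniform(−3σ_D, 3σ_D) steps
  with reflecting boundaries. Speciation is scheduled as *vicariance*
  (a barrier fragments the range) or *peripatry* (expansion into new
  territory, then cut-off). Every generation's parent pairs are recorded in
  a pedigree archive.
- **`genealogy`** — exact per-locus gene trees extracted from the pedigree
  by backward Mendelian coin flips (unlinked loci), panmictic-coalescent
  recapitation of uncoalesced roots, infinite-sites mutation overlay, and
  pseudo-gene construction (SNPs concatenated in blocks).
- **`msc_theory`** — closed-form MSC topology probabilities for 3- and
  4-taxon combs, a Monte-Carlo MSC oracle, Wright's neighborhood size
  4πρσ², the expected coalescent times 2Ne and 4Ne/[k(k−1)], and a
  deme-Markov caricature of the scattering/collecting-phase transition
  (matrix powers and uniform-mixing times).
- **`treestats`** — topology censuses, exact binomial skew tests, weighted
  Robinson–Foulds tree space with non-metric MDS, geographic monophyly,
  topology-vs-distance regression, and binary-trait simulation for
  morphological-delimitation thought experiments.
- **`sfs`** — the unfolded SFS, its neutral θ/i expectation, an
  intermediate-frequency skew score, and the ABBA-BABA D statistic with a
  locus-bootstrap significance test.

## Worked example

How long does spatial memory of ancestry last? Take three demes on a line
with 1–2% of lineages moving to a neighboring deme per generation, the
worked transition matrix built by
`MarkovDemeModel.three_deme_example()`:

```bash
$ spacephylo theory markov -t 5
deme0	deme1	deme2
0.951951	0.047089	0.000961
0.047089	0.905823	0.047089
0.000961	0.047089	0.951951
# time_to_mixing(eps=0.01)	390
```

After five generations a lineage sampled in the left deme still has a 95%
chance its ancestor sat in the same deme (rounded: 0.952, with 0.047 to the
neighbor and 0.001 across the range; the central deme retains 0.906). The
chain does not become uniform (all entries ≈ 1/3 within one percentage
point) until ~390 generations — only then does the coalescent behave like
Kingman's. At t = 45 the package computes central retention 0.5026 (a coin
flip) versus peripheral retention 0.6937, showing that central samples
scatter sooner than peripheral ones.

The MSC baseline those spatial effects distort:

```bash
$ spacephylo theory three-taxon -t 1.0
topology	probability
((AB)C)	0.754747
((AC)B)	0.122626
((BC)A)	0.122626
```

At one coalescent unit the two discordant topologies are exactly equal —
any significant inequality in data is ancestral structure or gene flow,
not incomplete lineage sorting. The simulator reproduces this in its
near-panmictic limit: the unclustered 3-taxon study condition
(`experiments.msc_equivalence(seed=3)`) measured a concordant fraction of
0.785 over 600 loci against an expectation of 0.806 at its realised
t = 1.23 (inside the 99% binomial band, half-width 0.042), with mirror
discordant classes at 0.488 (exact binomial p = 0.86). Under the clustered
vicariance condition the same census is strongly skewed toward the
topology pairing the geographically adjacent species (mean skew ≈ 0.59–0.61,
p < 0.01 in 9–10 of 10 seeds), while peripatric budding shows no skew but a
concordant excess of ~0.09 above the MSC expectation.

A full pipeline run (simulate → sample → gene trees → mutations →
diagnostics → exports for SNaQ/BEAST2/BPP) is driven by a TOML config:

```bash
spacephylo pipeline --config sim.toml --out run1/ --seed 7
```

and writes a `manifest.json` whose recorded seed reproduces the simulator
archive byte for byte.

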