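# Methods

## The spatial model

`spatial_sim` implements a forward-time, individual-based model of diploid
hermaphrodites on a continuous rectangular range with non-overlapping
generations. Three Gaussian length scales control the biology:

| parameter | meaning | clustered preset | unclustered preset |
|---|---|---|---|
| σ_I | interaction (competition) kernel scale | 0.75 | 0.5 |
| σ_M | mate-search kernel scale | 0.25 | 1.0 |
| σ_D | dispersal scale (uniform ±3σ_D per axis) | 0.25 | 1.0 |

All kernels are truncated at 3σ. The local density experienced by
individual *i* is D_i = Σ_j exp(−d_ij²/2σ_I²)/(2πσ_I²) over same-species
neighbors within 3σ_I, so a uniform field of density ρ gives
D_i ≈ ρ(1 − e^{−9/2}). Each generation, every individual acts once as a
focal parent producing Poisson(f/(1 + D_i/D\*)) offspring with fecundity
f = 2 — a Beverton–Holt-style regulation whose per-capita replacement is 1
exactly when D_i = D\*, making the equilibrium density an emergent property
close to the target D\* (realised densities run ~10–30% above nominal
because edge individuals experience truncated kernels). Offspring start at
the focal parent, disperse by independent uniform(−3σ_D, 3σ_D) steps per
axis, and reflect off range and barrier edges.

**Mating.** A mate is drawn for *each offspring* independently from
same-species candidates within 3σ_M, weighted by exp(−d²/2σ_M²), selfing
excluded; an individual with no candidate in range produces nothing. The
per-offspring redraw is deliberate: with one shared mate per brood the
offspring-number variance is ~3 (Poisson focal side plus a compound-Poisson
mate side), which depresses the panmictic-limit Ne to ~0.8N. Redrawing
restores Wright–Fisher-like variance so that Ne ≈ census size — the
calibration the genealogy pipeline is tested against.

**Density.** The preset kernel scales do not fix a density, and the model
has a hard viability constraint: with the clustered preset's mate radius of
0.75, a population near density 1 cannot find mates, enters an Allee
spiral, and goes extinct. Study conditions therefore run at target density
5 (≈9 candidates in the mate radius), or 3 where a shallower coalescent
timescale is needed; paired clustered/unclustered comparisons always share
a density.

**Speciation.** Species ranges are axis-aligned rectangles. A vicariance
event splits a rectangle with an axis-aligned line and relabels individuals
by side; thereafter all interaction, mating and dispersal are confined to
each side (enforced jointly by same-species-only kernels and per-species
reflection). A peripatry event opens an edge-adjacent rectangle (the union
must again be a rectangle), lets the species expand into it, and seals the
former boundary `expansion_lag` generations later, relabelling the
colonists. Built-in builders produce the 3-, 4- and 6-taxon comb trees
((..(AB)C)..) by serial fragmentation (vicariance) or serial outward
budding (peripatry); the 6-taxon default places splits 45,000 … 15,000 and
5,000 generations before present, with a uniform 10,000-generation spacing
except the most recent split, and a `scale` argument shrinks the whole
schedule for desk-scale work. The default peripatric lag is 10% of the
interval to the next event; note the lag is structurally capped by the
previous seal (the parent species must exist when its expansion starts).

## Gene trees from the pedigree

Every generation's parent pairs, positions and labels are archived. A
sampled diploid contributes two lineages (homologs 0/1); tracing one
generation back, homolog 0 moves to parent 1 and homolog 1 to parent 2,
then lands on one of the parent's two homologs with probability 1/2,
independently per locus. Two lineages coalesce when they occupy the same
(individual, homolog) slot. For unlinked loci this realises the exact
marginal genealogy distribution conditional on the pedigree while storing
nothing per locus during the forward pass; memory scales with the pedigree,
not the number of loci. Per-locus streams are `SeedSequence([seed, locus])`
with a per-(locus, generation, lineage-slot) coin table, so single-locus
and batched extraction are bit-identical.

Lineages alive at the founding generation remain as multiple roots and are
completed by `recapitate`: a panmictic Kingman coalescent with waiting
times Exp(k(k−1)/2 · 1/(2Ne)) and uniform pair choice, starting at the
founding generation. The default ancestral Ne is the founding census. Rare
simultaneous multi-mergers inside the pedigree (probability ~1/N² per pair)
leave polytomies; recapitated portions are strictly binary.

`overlay_mutations` drops Poisson(μ·L·branch length) infinite-sites
mutations per branch; carriers are the tips below. Variants export as a
carriers TSV and a minimal phased VCF, alignments as A (ancestral) /
T (derived) FASTA or NEXUS. `make_pseudogenes` orders SNPs by (locus,
site) and cuts blocks of 500 × 10 by default.

## Closed-form expectations

`msc_theory` works in coalescent units of 2Ne generations. The three-taxon
comb gives P(concordant) = 1 − (2/3)e^{−t}; the four-taxon distribution
over all 15 rooted topologies is computed by exact enumeration of
coalescent histories (merger counts per interval from the Kingman death
process — e^{−t}, 1.5(e^{−t} − e^{−3t}), … — and uniform pair choices),
validated against an independent vectorised Monte-Carlo oracle at nine
(t₁, t₂) grid points to within 3 standard errors at 10⁶ draws. The A↔B
mirror classes are equal by construction, which is the null every skew
test rests on.

`expected_tmrca` exposes both conventions compressed in the usual phrase
"2Ne for k=2 and 4Ne/[i(i−1)]": the mean *interval* while k lineages
remain, 4Ne/(k(k−1)), and the mean *total* depth 4Ne(1 − 1/k); they agree
at k = 2.

`time_to_mixing` returns the smallest t with max|P^t − 1/n| ≤ ε (default
ε = 0.01). This is the standard mixing-time definition; it evaluates the
chain state after t steps, so even an already-uniform transition matrix has
mixing time 1, not 0. For the worked 3-deme chain (retentions 0.99, 0.98,
0.99; eigenvalues 1, 0.99, 0.97) it gives 390 generations.

## Diagnostics

- **Census and skew.** One representative genome per species (seeded
  random choice among sampled tips, fresh per tree), canonical rooted
  labels, exact two-sided binomial test of mirror-class equality (valid at
  small counts, unlike chi-square). The package deliberately reports skew
  as nA/(nA+nB) plus the binomial p; no literature-standard scalar exists.
- **Weighted Robinson–Foulds.** Σ over the union of rooted clades
  (pendant edges included) of |l₁ − l₂|, a clade absent from one tree
  contributing its full length; an L1 metric on clade-length vectors.
- **Tree space.** Kruskal stress-1 non-metric MDS on the weighted RF
  matrix, 8 seeded random starts by default (the stress landscape is
  multi-modal), coordinates centred on the pooled centroid.
  `centroid_displacement` is the distance from a group's centroid to the
  pooled centroid. Two equal-size groups sit at *equal* displacements by
  construction, so contrasts embed a third, panmictic Kingman baseline
  tree set (matched Ne, same tip labels) alongside the two arms.
- **SFS.** Unfolded (allele 0 ancestral by construction);
  `intermediate_skew` is the observed minus neutral (1/i-implied) share of
  segregating sites in the middle third of frequency classes — the cutoff
  is exposed as a parameter since no standard exists.
- **D statistic.** ABBA−BABA over sites where the outgroup is ancestral;
  significance by bootstrap over loci (the locus is the exchangeable
  block; sites within a locus share one genealogy).
- **Binary traits.** The symmetric two-state (Mk) Markov model with flip
  probability (1 − e^{−2rt})/2 per branch: an equal-rate Q matrix on {0,1}.
  (The corresponding delimitation literature sometimes says
  "Brownian motion" while describing exactly this Q matrix; a continuous
  model cannot produce binary states, so Mk is what is implemented.)

## Study conditions (`experiments.py`)

All headline numbers are computed at desk scale — tens of thousands of
individual-generations rather than the millions a full-scale study would
use — with realised census sizes converting generations to coalescent
units. Replicate seeds are `seed·1000 + i`.

- **MSC equivalence:** unclustered preset, 12×5 range, density 5, splits
  700/100 generations back (realised t ≈ 1.2 coalescent units of the AB
  ancestor), 600 loci, one genome per species. Checks the concordant
  fraction against 1 − (2/3)e^{−t} (99% binomial band) and mirror-class
  equality.
- **Slatkin's skew, vicariance:** clustered preset, 12×5, density 3,
  splits 25/10 generations back, 1200-generation pedigree, 800 loci, five
  sampled individuals per species. The regime matters: the skew exists
  only while the coalescent timescale sits inside the spatial-memory
  window (strip width/per-generation dispersal sd)² ≈ 85 generations —
  with deeper splits or a deeper coalescent the memory erases and the MSC
  ratios return, which is itself the theory's central claim.
- **Slatkin's skew, peripatry:** clustered preset, density 5 (colonisation
  waves stall at lower density), seals 65/25 generations back, lag 15,
  400 loci. Scored as per-seed *absence* of significant skew plus a pooled
  one-sided test of concordant excess over the MSC expectation, the excess
  being driven by lineages funnelling through the serial founder
  bottlenecks.
- **Coalescent calibration:** a 6.3×6.3 unclustered population (realised
  N ≈ 240) run 1800 generations; mean pairwise TMRCA over 200 loci × 8
  haplotypes against 2N̄; recapitation depth means over 2000 replicates
  against closed forms; and a two-species split (T_D = 150) whose
  cross-species divergence is compared with π₁₂ = 2μ(T_D + 2N̄_anc) over
  300 loci with μ = 2×10⁻⁵, L = 1000.
- **SFS neutrality:** an explicitly panmictic configuration (10×10,
  density 2, σ_D = σ_M = 2.5, σ_I = 1.5 — range crossed in a few
  generations, smooth regulation), 2200 loci thinned to one random SNP
  each. Thinning is essential: sites within a locus share a genealogy, and
  a chi-square over all sites is overdispersed enough to reject even
  perfectly neutral input. The unclustered *preset* is intentionally not
  used here — its Wright neighborhood size (4πρσ² ≈ 230 < 1000) leaves
  mild structure, visible as a small singleton deficit.
- **Structure contrast:** paired clustered/unclustered runs (16×5, density
  3, 1500 generations) sampled with the two-edges-plus-center design
  (3 individuals per location). Location-clustered sampling is what turns
  spatial clans into intermediate-frequency variants; scattered sampling
  dissolves the same structure into singletons. Per pair: the
  intermediate-skew difference and the tree-space displacement contrast
  (40 trees per arm plus 40 Kingman baseline trees, NMDS with 4 starts).

## What the generator does and does not emulate

The simulator produces genuine continuous-space pedigrees with isolation
by distance, central-versus-peripheral density gradients, founder effects,
and barrier-driven divergence. It does not include within-locus
recombination (loci are exactly unlinked; there are no linked tree
sequences and no "c-gene" boundaries to discover), selection, overlapping
generations, habitat heterogeneity, or range movement, and recapitation is
panmictic rather than spatial — deep history beyond the recorded pedigree
therefore carries no spatial signal, which *dilutes* (never inflates) the
spatial effects measured here. Passing tests show the diagnostics behave
as the theory predicts under these idealised conditions; real data add
rate variation, inference error, and sampling designs outside the
package's control.

## Numerical and design notes

- Determinism: one seeded PCG64 generator drives the forward pass;
  per-locus tracing and recapitation use `SeedSequence([seed, locus])` and
  `[seed, locus, 1]`. Identical (config, schedule, seed) give
  byte-identical archives; archives round-trip through gzipped TSV with
  `%.9g` coordinates (exact for float32).
- Reflection uses the triangle-wave fold, correct for arbitrarily large
  displacements.
- Topology labels: nested parentheses, children sorted lexicographically,
  names joined without commas when all are single characters (commas
  otherwise). The parser treats comma-free labels as single-character
  taxa.
- NMDS stress is Kruskal stress-1; "exactly embeddable" inputs reach
  stress < 10⁻³ with the default 8 starts.
- Degenerate inputs raise informative errors: empty founding regions,
  barriers that empty one side, insufficient SNPs for pseudo-genes
  (reporting the shortfall), non-stochastic matrices, periodic chains
  (mixing-time cap), monomorphic sites (excluded with a warning count).

## Known limitations

- The tree-space displacement contrast is the noisiest diagnostic
  (NMDS stress ≈ 0.3 on these distance matrices); it prefers the clustered
  arm in ~9/10 paired seeds but individual seed sets can dip to 7/10.
- Peripatric colonisation can stall at low density (a real Allee
  phenomenon, reported as an event error rather than silently absorbed).
- Realised densities exceed D\* near edges; all calibrations therefore use
  realised, not nominal, census sizes.
- The 4-taxon enumeration covers the comb species tree only; other shapes
  go through the Monte-Carlo simulator.
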