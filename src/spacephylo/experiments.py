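"""Canned study conditions for the package's headline diagnostics.

Each function runs a complete pipeline (simulate -> sample -> gene trees ->
diagnostics) at desk scale and returns plain dictionaries of numbers, so
the same code backs the test suite, the acceptance script and the worked
examples in the documentation.

Shared conditions: individuals live at target density 3-5 per unit area
(the clustered preset's mate-search radius of 0.75 needs several
candidates within range to avoid an Allee collapse, so density 1 is
inviable; paired clustered/unclustered comparisons always share one
density); species ranges are strips of a 12 x 5 (three-taxon) or
comparable rectangle. Interval lengths are chosen so that the "deep
interval" case sits above one coalescent unit and the "short interval"
skew cases sit inside the spatial-memory window. Realised (not nominal)
census sizes convert generations to coalescent units, because edge
effects inflate the equilibrium density by ~10-30%.
"""

from __future__ import annotations

import numpy as np

from . import genealogy as G
from . import msc_theory as M
from . import sfs as S
from . import treestats as T
from .spatial_sim import (
    SimulationConfig,
    comb_peripatry_schedule,
    comb_vicariance_schedule,
    run_simulation,
    sample_individuals,
)

__all__ = [
    "DENSITY",
    "markov_worked_example",
    "msc_equivalence",
    "slatkin_skew_replicate",
    "skew_by_mode",
    "coalescent_calibration",
    "sfs_neutral_fit",
    "structure_contrast",
    "weighted_rf_example",
]

DENSITY = 5.0


def _mean_census(archive, species: str) -> float:
    c = archive.census(species).astype(float)
    alive = c > 0
    if not alive.any():
        raise ValueError(f"species {species!r} never alive")
    return float(c[alive].mean())


def _full_trees(archive, samples, n_loci, seed, haplotypes="both"):
    trees = G.extract_gene_trees(archive, samples, n_loci, seed, haplotypes)
    out = []
    for t in trees:
        rng = np.random.default_rng(np.random.SeedSequence([seed, t.locus, 1]))
        out.append(G.recapitate(t, archive.founding_count, rng))
    return out


def _one_per_species(archive, rng):
    import pandas as pd

    tables = [
        sample_individuals(archive, sp, "random", 1, rng)
        for sp in sorted(archive.species_at_final())
    ]
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# deme-Markov worked example
# ---------------------------------------------------------------------------


def markov_worked_example() -> dict:
    """The 3-deme chain: P^5 entries, t=45 retentions, mixing time."""
    model = M.MarkovDemeModel.three_deme_example()
    p5 = M.markov_power(model, 5)
    p45 = M.markov_power(model, 45)
    return {
        "p5_corner_retention": float(p5[0, 0]),
        "p5_center_retention": float(p5[1, 1]),
        "p5_nearest_neighbor": float(p5[0, 1]),
        "p5_corner_to_corner": float(p5[0, 2]),
        "t45_center_retention": float(p45[1, 1]),
        "t45_peripheral_retention": float(p45[0, 0]),
        "mixing_time_generations": int(M.time_to_mixing(model, 0.01)),
    }


# ---------------------------------------------------------------------------
# MSC equivalence in the unclustered (near-panmictic) limit
# ---------------------------------------------------------------------------


def msc_equivalence(seed: int, n_loci: int = 600) -> dict:
    """Three-taxon vicariance, deep interval, unclustered preset.

    With the internal interval above one coalescent unit the gene-tree
    census should match 1 - (2/3)exp(-t) and the mirror discordant classes
    should be statistically equal.
    """
    burn, interval, post = 800, 600, 100
    cfg = SimulationConfig(
        range_width=12.0,
        range_height=5.0,
        n_generations=burn + interval + post,
        seed=seed,
        preset="unclustered",
        target_density=DENSITY,
    )
    schedule = comb_vicariance_schedule(cfg, [interval + post, post])
    archive = run_simulation(cfg, schedule)
    rng = np.random.default_rng(seed + 1)
    samples = _one_per_species(archive, rng)
    trees = _full_trees(archive, samples, n_loci, seed + 2, haplotypes=0)
    census = T.census_topologies(trees, ("A", "B", "C"))
    ne_ab = _mean_census(archive, "AB")
    t_hat = interval / (2.0 * ne_ab)
    expected = M.three_taxon_topology_probs(t_hat)["((AB)C)"]
    obs = census.proportion("((AB)C)")
    half = 2.576 * np.sqrt(expected * (1.0 - expected) / n_loci)
    mirror = T.slatkin_skew_test(census, "((BC)A)", "((AC)B)")
    return {
        "n_loci": n_loci,
        "t_coalescent_units": t_hat,
        "concordant_observed": obs,
        "concordant_expected": expected,
        "ci99_halfwidth": float(half),
        "within_ci99": bool(abs(obs - expected) <= half),
        "mirror_skew": mirror.skew,
        "mirror_pvalue": mirror.pvalue,
    }


# ---------------------------------------------------------------------------
# Slatkin's skew by mode of speciation
# ---------------------------------------------------------------------------


#: Study conditions for the speciation-mode contrast. The vicariant skew
#: needs the coalescent timescale (~2N) to sit inside the spatial-memory
#: window ((strip width / per-generation dispersal sd)^2 ~ 85 generations
#: here), which at desk scale means density 3 and very shallow splits; the
#: peripatric colonisation wave instead needs density 5 to advance
#: reliably through the clustered preset's short mate radius, with
#: correspondingly longer intervals.
SKEW_CONDITIONS = {
    "vicariance": dict(
        density=3.0, burn=1200, interval=15, post=10, n_loci=800, lag=None
    ),
    "peripatry": dict(
        density=5.0, burn=700, interval=40, post=25, n_loci=400, lag=15
    ),
}


def slatkin_skew_replicate(seed: int, mode: str) -> dict:
    """One clustered 3-taxon replicate with short intervals.

    Strip ranges A|B|C along x; under vicariance the skew should favour
    ((BC)A) (B and C are geographically adjacent) over its mirror
    ((AC)B). Under peripatry (serial budding from the C strip) the two
    classes should stay balanced while the concordant fraction exceeds the
    MSC expectation because colonists funnel through founder bottlenecks.
    Five individuals per species are sampled; each locus census uses a
    random representative genome per species.
    """
    try:
        cond = SKEW_CONDITIONS[mode]
    except KeyError:
        raise ValueError("mode must be 'vicariance' or 'peripatry'") from None
    burn, interval, post = cond["burn"], cond["interval"], cond["post"]
    cfg = SimulationConfig(
        range_width=12.0,
        range_height=5.0,
        n_generations=burn + interval + post,
        seed=seed,
        preset="clustered",
        target_density=cond["density"],
    )
    if mode == "vicariance":
        schedule = comb_vicariance_schedule(cfg, [interval + post, post])
    else:
        schedule = comb_peripatry_schedule(
            cfg, [interval + post, post], expansion_lag=cond["lag"]
        )
    archive = run_simulation(cfg, schedule)
    rng = np.random.default_rng(seed + 1)
    import pandas as pd

    samples = pd.concat(
        [
            sample_individuals(archive, sp, "random", 5, rng)
            for sp in sorted(archive.species_at_final())
        ],
        ignore_index=True,
    )
    trees = _full_trees(
        archive, samples, cond["n_loci"], seed + 2, haplotypes=0
    )
    census = T.census_topologies(
        trees, ("A", "B", "C"), rng=np.random.default_rng(seed + 9)
    )
    skew = T.slatkin_skew_test(census, "((BC)A)", "((AC)B)")
    ne_ab = _mean_census(archive, "AB")
    t_hat = interval / (2.0 * ne_ab)
    expected = M.three_taxon_topology_probs(t_hat)["((AB)C)"]
    return {
        "mode": mode,
        "skew": skew.skew,
        "skew_pvalue": float(skew.pvalue),
        "n_adjacent": skew.n_a,
        "n_mirror": skew.n_b,
        "n_loci": census.total,
        "n_concordant": census.counts.get("((AB)C)", 0),
        "concordant_observed": census.proportion("((AB)C)"),
        "concordant_expected": expected,
        "t_coalescent_units": t_hat,
    }


def skew_by_mode(seed: int, n_replicates: int = 10) -> dict:
    """Replicated skew contrast between vicariance and peripatry.

    Vicariance is scored by the per-seed count of significant
    geographically-adjacent skews (exact binomial, alpha = 0.01);
    peripatry by the per-seed count of *non*-significant skews plus a
    single pooled one-sided test of concordant excess over the MSC
    expectation across replicates.
    """
    vic, peri = [], []
    for i in range(n_replicates):
        s = seed * 1000 + i
        vic.append(slatkin_skew_replicate(s, "vicariance"))
        peri.append(slatkin_skew_replicate(s, "peripatry"))
    vic_sig = sum(
        r["skew_pvalue"] < 0.01 and r["skew"] > 0.5 for r in vic
    )
    peri_nonsig = sum(r["skew_pvalue"] >= 0.01 for r in peri)
    # pooled normal-approximation one-sided excess test
    excess = sum(
        r["n_concordant"] - r["n_loci"] * r["concordant_expected"]
        for r in peri
    )
    var = sum(
        r["n_loci"]
        * r["concordant_expected"]
        * (1.0 - r["concordant_expected"])
        for r in peri
    )
    from scipy import stats

    z = excess / np.sqrt(var)
    peri_excess_p = float(stats.norm.sf(z))
    return {
        "n_replicates": n_replicates,
        "vicariance_significant_adjacent_skew": vic_sig,
        "vicariance_mean_skew": float(np.mean([r["skew"] for r in vic])),
        "peripatry_nonsignificant_skew": peri_nonsig,
        "peripatry_concordant_excess_z": float(z),
        "peripatry_concordant_excess_pvalue": peri_excess_p,
        "peripatry_mean_concordant_minus_msc": float(
            np.mean(
                [
                    r["concordant_observed"] - r["concordant_expected"]
                    for r in peri
                ]
            )
        ),
        "replicates": {"vicariance": vic, "peripatry": peri},
    }


# ---------------------------------------------------------------------------
# coalescent calibration
# ---------------------------------------------------------------------------


def coalescent_calibration(seed: int) -> dict:
    """Panmictic-limit checks of the whole genealogy pipeline.

    (a) mean pairwise TMRCA ~= 2N in a single unclustered population;
    (b) recapitation adds ~2*Ne depth for two roots (and first mergers of
    three roots average 2*Ne/3); (c) cross-species divergence matches
    pi12 = 2*mu*(T_D + 2*Ne).
    """
    # (a) single population
    cfg = SimulationConfig(
        range_width=6.3,
        range_height=6.3,
        n_generations=1800,
        seed=seed,
        preset="unclustered",
        target_density=DENSITY,
    )
    archive = run_simulation(cfg)
    n_bar = float(archive.census()[300:].mean())
    rng = np.random.default_rng(seed + 1)
    samples = sample_individuals(
        archive, archive.species_at_final()[0], "random", 4, rng
    )
    trees = _full_trees(archive, samples, 200, seed + 2)
    tmrcas = []
    for t in trees:
        labs = t.tip_labels
        for i in range(len(labs)):
            for j in range(i + 1, len(labs)):
                tmrcas.append(t.tmrca(labs[i], labs[j]))
    tmrca_ratio = float(np.mean(tmrcas) / (2.0 * n_bar))

    # (b) recapitation closed-form check
    rrng = np.random.default_rng(seed + 3)
    ne = 1000.0
    stub2 = G.GeneTree(
        parent=np.array([-1, -1]),
        time=np.zeros(2),
        tip_labels=["a", "b"],
    )
    depths = [
        G.recapitate(stub2, ne, rrng).depth for _ in range(2000)
    ]
    recap_mean_2 = float(np.mean(depths))
    stub3 = G.GeneTree(
        parent=np.array([-1, -1, -1]),
        time=np.zeros(3),
        tip_labels=["a", "b", "c"],
    )
    firsts = []
    for _ in range(2000):
        rt = G.recapitate(stub3, ne, rrng)
        internal = rt.time[rt.time > 0]
        firsts.append(internal.min())
    recap_first_merge_3 = float(np.mean(firsts))

    # (c) two-species divergence
    t_d = 150
    cfg2 = SimulationConfig(
        range_width=8.0,
        range_height=4.0,
        n_generations=700 + t_d,
        seed=seed + 4,
        preset="unclustered",
        target_density=DENSITY,
    )
    schedule = comb_vicariance_schedule(cfg2, [t_d])
    arc2 = run_simulation(cfg2, schedule)
    anc = arc2.census("AB")[200:].astype(float)
    ne_anc = float(anc[anc > 0].mean())  # ancestor alive only pre-split
    rng2 = np.random.default_rng(seed + 5)
    import pandas as pd

    samp2 = pd.concat(
        [
            sample_individuals(arc2, sp, "random", 2, rng2)
            for sp in ("A", "B")
        ],
        ignore_index=True,
    )
    trees2 = _full_trees(arc2, samp2, 300, seed + 6)
    mu, length = 2e-5, 1000
    mrng = np.random.default_rng(seed + 7)
    tables = [G.overlay_mutations(t, mu, length, mrng) for t in trees2]
    variants = G.VariantTable.concat(tables)
    haps_a = [h for h in variants.haplotypes if h.startswith("A_")]
    haps_b = [h for h in variants.haplotypes if h.startswith("B_")]
    pi_obs = G.pairwise_divergence(
        variants, haps_a, haps_b, total_length=length * len(trees2)
    )
    pi_exp = G.expected_divergence(
        G.DivergenceParams(T_D=t_d, Ne=ne_anc, mu=mu)
    )
    return {
        "mean_census": n_bar,
        "tmrca_ratio_to_2N": tmrca_ratio,
        "recap_mean_depth_2_roots": recap_mean_2,
        "recap_expected_2_roots": 2.0 * ne,
        "recap_first_merge_3_roots": recap_first_merge_3,
        "recap_expected_first_merge_3": 2.0 * ne / 3.0,
        "pi12_observed": pi_obs,
        "pi12_expected": pi_exp,
        "pi12_ratio": pi_obs / pi_exp,
    }


# ---------------------------------------------------------------------------
# SFS diagnostics
# ---------------------------------------------------------------------------


def _thin_one_site_per_locus(tables, rng) -> G.VariantTable:
    """Keep one uniformly chosen site per locus.

    Sites within a locus share one genealogy, so a goodness-of-fit test
    over all sites is overdispersed; thinning to a single random site per
    unlinked locus restores the independence a chi-square test assumes.
    """
    kept = []
    for t in tables:
        if t.n_sites:
            i = int(rng.integers(t.n_sites))
            kept.append(
                G.VariantTable(
                    haplotypes=t.haplotypes,
                    locus=t.locus[i : i + 1],
                    site=t.site[i : i + 1],
                    carriers=t.carriers[i : i + 1],
                )
            )
    return G.VariantTable.concat(kept)


def sfs_neutral_fit(seed: int, n_loci: int = 2200) -> dict:
    """Panmictic-limit SFS against theta/i (chi-square goodness of fit).

    Uses an explicitly panmictic configuration (dispersal spanning the
    range within a few generations and a wide, smooth interaction kernel)
    rather than the unclustered preset, and one random SNP per unlinked
    locus so that sites are independent.
    """
    cfg = SimulationConfig(
        range_width=10.0,
        range_height=10.0,
        n_generations=1800,
        seed=seed,
        sigma_D=2.5,
        sigma_M=2.5,
        sigma_I=1.5,
        target_density=2.0,
    )
    archive = run_simulation(cfg)
    rng = np.random.default_rng(seed + 1)
    samples = sample_individuals(
        archive, archive.species_at_final()[0], "random", 8, rng
    )
    trees = _full_trees(archive, samples, n_loci, seed + 2)
    mu, length = 2.5e-6, 1000
    mrng = np.random.default_rng(seed + 3)
    variants = _thin_one_site_per_locus(
        [G.overlay_mutations(t, mu, length, mrng) for t in trees],
        np.random.default_rng(seed + 5),
    )
    spectrum = S.compute_sfs(variants)
    k = spectrum.counts.size
    w = 1.0 / np.arange(1, k + 1)
    expected = spectrum.n_segregating * w / w.sum()
    from scipy import stats

    chi2, p = stats.chisquare(spectrum.counts, expected)
    return {
        "n_segregating": spectrum.n_segregating,
        "n_haplotypes": spectrum.n,
        "chi2": float(chi2),
        "pvalue": float(p),
        "sfs": [int(c) for c in spectrum.counts],
    }


# ---------------------------------------------------------------------------
# clustered vs unclustered paired contrast (SFS skew and tree space)
# ---------------------------------------------------------------------------


def _relabel(tree: G.GeneTree, mapping: dict[str, str]) -> G.GeneTree:
    return G.GeneTree(
        parent=tree.parent.copy(),
        time=tree.time.copy(),
        tip_labels=[mapping[l] for l in tree.tip_labels],
        locus=tree.locus,
        origin_time=tree.origin_time,
    )


def structure_contrast(
    seed: int,
    n_pairs: int = 10,
    n_loci: int = 200,
    n_trees_embedded: int = 40,
) -> dict:
    """Paired-seed clustered vs unclustered single-population runs.

    Per pair: the intermediate-frequency SFS skew of each arm, and the
    tree-space displacement of each arm's gene trees from the pooled
    centroid of a joint NMDS embedding that also contains a matched
    panmictic Kingman baseline (without the baseline, two equal-size
    groups sit at exactly equal distances from their pooled centroid and
    the contrast would be meaningless). The range (16 x 5 at density 3)
    keeps the clustered arm's range-crossing diffusion time well above
    2N, so its genealogies carry strong spatial structure, while the
    unclustered arm mixes within a tenth of that. Sampling follows the
    two-edges-plus-center field design: spatial clans then segregate at
    intermediate frequencies instead of dissolving into singletons.
    """
    pairs = []
    for i in range(n_pairs):
        s = seed * 1000 + i
        arm = {}
        trees_by_arm = {}
        ne_unclustered = None
        for preset in ("clustered", "unclustered"):
            cfg = SimulationConfig(
                range_width=16.0,
                range_height=5.0,
                n_generations=1500,
                seed=s,
                preset=preset,
                target_density=3.0,
            )
            archive = run_simulation(cfg)
            rng = np.random.default_rng(s + 1)
            samples = sample_individuals(
                archive,
                archive.species_at_final()[0],
                "three_location",
                3,
                rng,
            )
            trees = _full_trees(archive, samples, n_loci, s + 2)
            mu, length = 4e-6, 500
            mrng = np.random.default_rng(s + 3)
            variants = G.VariantTable.concat(
                [G.overlay_mutations(t, mu, length, mrng) for t in trees]
            )
            spectrum = S.compute_sfs(variants)
            arm[preset] = S.intermediate_skew(spectrum)
            # tips arrive as (individual, homolog) pairs in sample order
            mapping = {
                lab: f"s{i // 2}_{i % 2}"
                for i, lab in enumerate(trees[0].tip_labels)
            }
            trees_by_arm[preset] = [
                _relabel(t, mapping) for t in trees[:n_trees_embedded]
            ]
            if preset == "unclustered":
                ne_unclustered = float(archive.census()[300:].mean())
        krng = np.random.default_rng(s + 4)
        labels16 = trees_by_arm["unclustered"][0].tip_labels
        baseline = [
            M.simulate_kingman_tree(
                len(labels16), ne_unclustered, krng, tip_labels=labels16
            )
            for _ in range(n_trees_embedded)
        ]
        pool = (
            trees_by_arm["clustered"]
            + trees_by_arm["unclustered"]
            + baseline
        )
        groups = (
            ["clustered"] * n_trees_embedded
            + ["unclustered"] * n_trees_embedded
            + ["panmictic"] * n_trees_embedded
        )
        D = T.rf_distance_matrix(pool)
        emb = T.nmds_embed(
            D, seed=s, labels=groups, n_init=4, max_iter=300, eps=1e-6
        )
        pairs.append(
            {
                "skew_clustered": arm["clustered"],
                "skew_unclustered": arm["unclustered"],
                "displacement_clustered": T.centroid_displacement(
                    emb, "clustered"
                ),
                "displacement_unclustered": T.centroid_displacement(
                    emb, "unclustered"
                ),
                "stress": emb.stress,
            }
        )
    return {
        "n_pairs": n_pairs,
        "skew_clustered_gt_unclustered": sum(
            p["skew_clustered"] > p["skew_unclustered"] for p in pairs
        ),
        "displacement_clustered_gt_unclustered": sum(
            p["displacement_clustered"] > p["displacement_unclustered"]
            for p in pairs
        ),
        "mean_skew_clustered": float(
            np.mean([p["skew_clustered"] for p in pairs])
        ),
        "mean_skew_unclustered": float(
            np.mean([p["skew_unclustered"] for p in pairs])
        ),
        "pairs": pairs,
    }


def weighted_rf_example() -> float:
    """The hand-enumerable weighted RF distance between two 3-tip trees."""
    t1 = G.GeneTree.from_newick("((A:1,B:1):1,C:2);")
    t2 = G.GeneTree.from_newick("((A:1,C:1):1,B:2);")
    return T.weighted_rf(t1, t2)
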