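"""Per-locus gene trees from recorded pedigrees.

A sampled diploid contributes two lineages (homolog 0 and 1). Tracing one
generation back, the lineage at homolog 0 moves to ``parent1`` and the
lineage at homolog 1 to ``parent2``, then lands on one of that parent's two
homologs with equal probability, independently per locus. Two lineages
coalesce when they occupy the same (individual, homolog) slot. Because loci
are unlinked, repeating the coin flips with an independent stream per locus
realises the exact marginal genealogy distribution of each locus given the
pedigree, without storing anything per locus during the forward pass.

Lineages that survive to the founding generation remain as multiple roots;
:func:`recapitate` completes them under a panmictic Kingman coalescent.
:func:`overlay_mutations` drops infinite-sites mutations on the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spatial_sim import PedigreeArchive

__all__ = [
    "GeneTree",
    "VariantTable",
    "DivergenceParams",
    "extract_gene_tree",
    "extract_gene_trees",
    "recapitate",
    "overlay_mutations",
    "expected_divergence",
    "make_pseudogenes",
    "pairwise_divergence",
]


@dataclass
class GeneTree:
    """Rooted, time-calibrated genealogy of sampled allele copies.

    Nodes ``0..n_tips-1`` are tips at time 0; internal nodes follow in
    creation order. ``parent[i] == -1`` marks a root; a freshly extracted
    tree may have several roots (uncoalesced lineages at the founding
    generation) until :func:`recapitate` joins them. Times are generations
    before present.
    """

    parent: np.ndarray
    time: np.ndarray
    tip_labels: list[str]
    tip_meta: pd.DataFrame | None = None
    locus: int = 0
    origin_time: float = 0.0
    _children: list[list[int]] | None = field(default=None, repr=False)
    _tipsets: list[frozenset] | None = field(default=None, repr=False)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def roots(self) -> np.ndarray:
        return np.flatnonzero(self.parent < 0)

    @property
    def root(self) -> int:
        r = self.roots
        if r.size != 1:
            raise ValueError(f"tree has {r.size} roots; recapitate first")
        return int(r[0])

    @property
    def depth(self) -> float:
        """Time of the (single) root."""
        return float(self.time[self.root])

    def children(self) -> list[list[int]]:
        if self._children is None:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    def tipsets(self) -> list[frozenset]:
        """Set of tip labels below each node."""
        if self._tipsets is None:
            sets: list[frozenset | None] = [None] * self.n_nodes
            ch = self.children()
            for i in range(self.n_nodes):  # children precede parents
                if not ch[i]:
                    sets[i] = frozenset([self.tip_labels[i]])
                else:
                    acc: set = set()
                    for c in ch[i]:
                        acc |= sets[c]
                    sets[i] = frozenset(acc)
            self._tipsets = sets  # type: ignore[assignment]
        return self._tipsets  # type: ignore[return-value]

    def _invalidate(self):
        self._children = None
        self._tipsets = None

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        return float(self.time[p] - self.time[node]) if p >= 0 else 0.0

    def total_length(self) -> float:
        p = self.parent
        internal = p >= 0
        return float(np.sum(self.time[p[internal]] - self.time[internal]))

    def clades(self) -> dict[frozenset, float]:
        """Map tip-set below each non-root edge -> branch length above it."""
        sets = self.tipsets()
        out: dict[frozenset, float] = {}
        for i in range(self.n_nodes):
            if self.parent[i] >= 0:
                out[sets[i]] = out.get(sets[i], 0.0) + self.branch_length(i)
        return out

    def mrca(self, labels) -> int:
        want = frozenset(labels)
        sets = self.tipsets()
        best, best_size = None, None
        for i, s in enumerate(sets):
            if want <= s and (best is None or len(s) < best_size):
                best, best_size = i, len(s)
        if best is None:
            raise ValueError(f"labels {sorted(want)} not all present")
        return best

    def tmrca(self, label_a: str, label_b: str) -> float:
        return float(self.time[self.mrca([label_a, label_b])])

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        ch = self.children()
        tips = [i for i in range(self.n_nodes) if not ch[i]]
        return bool(np.all(np.abs(self.time[tips]) <= tol))

    def is_binary(self) -> bool:
        return all(len(c) == 2 for c in self.children() if c)

    # -- topology -----------------------------------------------------------

    def induced_topology(self, representatives: dict[str, str]) -> str:
        """Canonical label of the rooted topology induced on one tip per taxon.

        ``representatives`` maps taxon name -> tip label. Labels are nested
        parentheses with children sorted lexicographically, e.g.
        ``(((AB)C)D)`` (taxa joined without commas when all names are single
        characters).
        """
        tip_to_taxon = {}
        for taxon, tip in representatives.items():
            if tip not in self.tip_labels:
                raise ValueError(f"tip {tip!r} not in tree")
            tip_to_taxon[tip] = taxon
        sep = "" if all(len(t) == 1 for t in representatives) else ","
        ch = self.children()

        def reduce(node: int):
            if not ch[node]:
                return tip_to_taxon.get(self.tip_labels[node])
            parts = [r for c in ch[node] if (r := reduce(c)) is not None]
            if not parts:
                return None
            if len(parts) == 1:
                return parts[0]
            return "(" + sep.join(sorted(parts)) + ")"

        out = []
        for r in self.roots:
            lab = reduce(int(r))
            if lab is not None:
                out.append(lab)
        if len(out) != 1:
            raise ValueError("taxa do not form a connected rooted topology")
        return out[0]

    # -- serialisation ------------------------------------------------------

    def to_newick(self, precision: int = 6) -> str:
        ch = self.children()

        def fmt(node: int) -> str:
            if not ch[node]:
                body = self.tip_labels[node]
            else:
                body = "(" + ",".join(fmt(c) for c in ch[node]) + ")"
            p = self.parent[node]
            if p < 0:
                return body
            return f"{body}:{self.time[p] - self.time[node]:.{precision}f}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(
        cls, newick: str, locus: int = 0, tip_meta: pd.DataFrame | None = None
    ) -> "GeneTree":
        """Parse a rooted, time-calibrated (ultrametric) Newick string."""
        import dendropy

        dt = dendropy.Tree.get(
            data=newick, schema="newick", rooting="force-rooted"
        )
        nodes = list(dt.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        # tips first, preserving postorder among themselves
        tips = [nd for nd in nodes if nd.is_leaf()]
        internal = [nd for nd in nodes if not nd.is_leaf()]
        ordered = tips + internal
        index = {id(nd): i for i, nd in enumerate(ordered)}
        heights = {}
        for nd in nodes:  # postorder: children first
            if nd.is_leaf():
                heights[id(nd)] = 0.0
            else:
                hs = [
                    heights[id(c)] + (c.edge.length or 0.0)
                    for c in nd.child_nodes()
                ]
                if max(hs) - min(hs) > 1e-6 * max(max(hs), 1.0):
                    warnings.warn(
                        "tree is not ultrametric; node times set to height"
                    )
                heights[id(nd)] = max(hs)
        parent = np.full(len(ordered), -1, dtype=np.int64)
        time = np.zeros(len(ordered))
        labels = []
        for nd in ordered:
            i = index[id(nd)]
            time[i] = heights[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            if nd.is_leaf():
                labels.append(nd.taxon.label.replace(" ", "_"))
        return cls(
            parent=parent,
            time=time,
            tip_labels=labels,
            tip_meta=tip_meta,
            locus=locus,
        )


# ---------------------------------------------------------------------------
# extraction from the pedigree
# ---------------------------------------------------------------------------


def _tip_table(archive: PedigreeArchive, samples: pd.DataFrame, haplotypes):
    """Expand a sample table into (individual, homolog) tips with labels."""
    rows = []
    for rec in samples.itertuples(index=False):
        homs = (0, 1) if haplotypes == "both" else tuple(np.atleast_1d(haplotypes))
        for h in homs:
            rows.append(
                {
                    "label": f"{rec.species}_{int(rec.id)}_{h}",
                    "individual": int(rec.id),
                    "homolog": int(h),
                    "species": rec.species,
                    "x": float(rec.x),
                    "y": float(rec.y),
                }
            )
    return pd.DataFrame(rows)


def extract_gene_trees(
    archive: PedigreeArchive,
    samples: pd.DataFrame,
    loci,
    seed: int,
    haplotypes="both",
) -> list[GeneTree]:
    """Trace per-locus genealogies of sampled haplotypes through the pedigree.

    ``loci`` is an integer count or an explicit list of locus indices; each
    locus uses the stream ``SeedSequence([seed, locus])`` so single-locus
    and batched extraction are bit-identical. Returns one (possibly
    multi-root) :class:`GeneTree` per locus.
    """
    if isinstance(loci, (int, np.integer)):
        loci = list(range(int(loci)))
    else:
        loci = [int(l) for l in loci]
    tips = _tip_table(archive, samples, haplotypes)
    m = len(tips)
    if m == 0:
        raise ValueError("no sampled haplotypes")
    T = archive.n_generations
    n_loci = len(loci)
    coins = np.empty((n_loci, T, m), dtype=np.uint8)
    for li, locus in enumerate(loci):
        lrng = np.random.default_rng(np.random.SeedSequence([seed, locus]))
        coins[li] = lrng.integers(0, 2, size=(T, m), dtype=np.uint8)

    # per-locus node tables (tips pre-filled)
    parents = [np.full(m, -1, dtype=np.int64) for _ in loci]
    times = [[0.0] * m for _ in loci]

    # active lineage arrays
    al = np.repeat(np.arange(n_loci), m)
    aslot = np.tile(np.arange(m), n_loci)
    anode = aslot.copy()
    aind = np.tile(tips["individual"].to_numpy(np.int64), n_loci)
    ahom = np.tile(tips["homolog"].to_numpy(np.int64), n_loci)

    max_rows = max(g.x.size for g in archive.generations)
    stride = 2 * (max_rows + 1)

    extra_parents: list[list[int]] = [[] for _ in loci]  # child -> new parent
    for g in range(T, 0, -1):
        if al.size == 0:
            break
        rec = archive.state(g)
        par = np.where(ahom == 0, rec.parent1[aind], rec.parent2[aind])
        par = par.astype(np.int64)
        nh = coins[al, g - 1, aslot].astype(np.int64)
        key = al * stride + par * 2 + nh
        order = np.lexsort((aslot, key))
        ks = key[order]
        starts = np.concatenate(
            [[0], np.flatnonzero(np.diff(ks)) + 1, [ks.size]]
        )
        keep = order[starts[:-1]]
        sizes = np.diff(starts)
        new_node = anode[keep].copy()
        t_coal = float(T - (g - 1))
        for gi in np.flatnonzero(sizes >= 2):
            members = order[starts[gi] : starts[gi + 1]]
            li = int(al[members[0]])
            nid = len(times[li])
            times[li].append(t_coal)
            for mem in members:
                node = int(anode[mem])
                if node < m:
                    parents[li][node] = nid
                else:
                    extra_parents[li][node - m] = nid
            extra_parents[li].append(-1)
            new_node[gi] = nid  # keep[gi] == members[0] (min slot in group)
        al, aslot, anode = al[keep], aslot[keep], new_node
        aind, ahom = par[keep], nh[keep]
        # drop fully coalesced loci
        counts = np.bincount(al, minlength=n_loci)
        if np.any(counts[al] == 1):
            live = counts[al] > 1
            al, aslot, anode = al[live], aslot[live], anode[live]
            aind, ahom = aind[live], ahom[live]

    trees = []
    for li, locus in enumerate(loci):
        parent = np.concatenate(
            [parents[li], np.asarray(extra_parents[li], dtype=np.int64)]
        )
        trees.append(
            GeneTree(
                parent=parent,
                time=np.asarray(times[li]),
                tip_labels=list(tips["label"]),
                tip_meta=tips,
                locus=locus,
                origin_time=float(T),
            )
        )
    return trees


def extract_gene_tree(
    archive: PedigreeArchive,
    samples: pd.DataFrame,
    locus: int,
    seed: int,
    haplotypes="both",
) -> GeneTree:
    """Single-locus convenience wrapper around :func:`extract_gene_trees`."""
    return extract_gene_trees(archive, samples, [locus], seed, haplotypes)[0]


def recapitate(
    tree: GeneTree, ne_anc: float, rng: np.random.Generator
) -> GeneTree:
    """Join remaining roots under a panmictic Kingman coalescent.

    Starting at the founding generation, the waiting time to the next
    merger of k lineages is exponential with rate ``k(k-1)/2 * 1/(2*Ne)``
    per generation and merging pairs are uniform. Single-root trees are
    returned unchanged (as a copy).
    """
    if ne_anc <= 0:
        raise ValueError("ne_anc must be positive")
    roots = list(tree.roots)
    parent = tree.parent.copy()
    time = list(tree.time)
    t = float(max(tree.origin_time, max(tree.time, default=0.0)))
    while len(roots) > 1:
        k = len(roots)
        rate = k * (k - 1) / 2.0 / (2.0 * ne_anc)
        t += rng.exponential(1.0 / rate)
        i, j = rng.choice(k, size=2, replace=False)
        a, b = roots[i], roots[j]
        nid = len(time)
        time.append(t)
        parent = np.append(parent, -1)
        parent[a] = nid
        parent[b] = nid
        roots = [r for r in roots if r not in (a, b)] + [nid]
    return GeneTree(
        parent=parent,
        time=np.asarray(time),
        tip_labels=list(tree.tip_labels),
        tip_meta=tree.tip_meta,
        locus=tree.locus,
        origin_time=tree.origin_time,
    )


# ---------------------------------------------------------------------------
# mutations and variant tables
# ---------------------------------------------------------------------------


@dataclass
class VariantTable:
    """Biallelic infinite-sites variants: one row per site.

    Ancestral state is 0 by construction; ``carriers[i]`` is the frozenset
    of haplotype labels carrying the derived allele at site ``i``.
    """

    haplotypes: list[str]
    locus: np.ndarray
    site: np.ndarray
    carriers: list[frozenset]
    locus_length: int | None = None

    @property
    def n_sites(self) -> int:
        return len(self.carriers)

    @classmethod
    def concat(cls, tables: list["VariantTable"]) -> "VariantTable":
        if not tables:
            raise ValueError("nothing to concatenate")
        haps = tables[0].haplotypes
        for t in tables[1:]:
            if t.haplotypes != haps:
                raise ValueError("haplotype rosters differ between tables")
        return cls(
            haplotypes=list(haps),
            locus=np.concatenate([t.locus for t in tables]),
            site=np.concatenate([t.site for t in tables]),
            carriers=[c for t in tables for c in t.carriers],
            locus_length=tables[0].locus_length,
        )

    def derived_counts(self, subset=None) -> np.ndarray:
        """Derived-allele count per site among ``subset`` haplotypes."""
        pool = set(self.haplotypes if subset is None else subset)
        return np.array([len(c & pool) for c in self.carriers], dtype=np.int64)

    def matrix(self, haplotypes=None) -> np.ndarray:
        """0/1 matrix of shape (n_sites, n_haplotypes)."""
        haps = list(self.haplotypes if haplotypes is None else haplotypes)
        out = np.zeros((self.n_sites, len(haps)), dtype=np.uint8)
        col = {h: i for i, h in enumerate(haps)}
        for r, carr in enumerate(self.carriers):
            for h in carr:
                if h in col:
                    out[r, col[h]] = 1
        return out

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": self.locus,
                "site": self.site,
                "ancestral": 0,
                "derived": 1,
                "carriers": [",".join(sorted(c)) for c in self.carriers],
            }
        )


def overlay_mutations(
    tree: GeneTree,
    mu: float,
    locus_length: int,
    rng: np.random.Generator,
) -> VariantTable:
    """Drop infinite-sites mutations on a fully coalesced tree.

    Each branch receives Poisson(mu * locus_length * branch_length)
    mutations; each mutation gets a fresh site whose carriers are the tips
    below the branch.
    """
    if tree.roots.size != 1:
        raise ValueError("tree has multiple roots; recapitate first")
    sets = tree.tipsets()
    lengths = np.array(
        [tree.branch_length(i) for i in range(tree.n_nodes)]
    )
    counts = rng.poisson(mu * locus_length * lengths)
    carriers: list[frozenset] = []
    for node in range(tree.n_nodes):
        for _ in range(int(counts[node])):
            carriers.append(sets[node])
    n = len(carriers)
    return VariantTable(
        haplotypes=list(tree.tip_labels),
        locus=np.full(n, tree.locus, dtype=np.int64),
        site=np.arange(n, dtype=np.int64),
        carriers=carriers,
        locus_length=locus_length,
    )


@dataclass(frozen=True)
class DivergenceParams:
    """Pairwise-divergence model parameters (panmictic expectation)."""

    T_D: float
    Ne: float
    mu: float

    def __post_init__(self):
        if self.T_D < 0 or self.Ne <= 0 or self.mu <= 0:
            raise ValueError("T_D must be >= 0; Ne and mu positive")

    @property
    def theta(self) -> float:
        """Population-scaled mutation rate 4*Ne*mu."""
        return 4.0 * self.Ne * self.mu


def expected_divergence(params: DivergenceParams) -> float:
    """Expected per-site divergence between two species: 2*mu*(T_D + 2*Ne).

    Two lineages cannot coalesce before the divergence time T_D and then
    wait on average 2*Ne further generations in the (panmictic) ancestor.
    """
    return 2.0 * params.mu * (params.T_D + 2.0 * params.Ne)


def pairwise_divergence(
    variants: VariantTable, haps_a, haps_b, total_length: float
) -> float:
    """Mean per-site divergence between two haplotype sets."""
    haps_a, haps_b = list(haps_a), list(haps_b)
    mat = variants.matrix(haps_a + haps_b)
    a = mat[:, : len(haps_a)].astype(np.int32)
    b = mat[:, len(haps_a) :].astype(np.int32)
    diffs = 0
    for i in range(a.shape[1]):
        diffs += np.sum(a[:, i : i + 1] != b)
    return float(diffs) / (len(haps_a) * len(haps_b)) / total_length


def make_pseudogenes(
    variants, block_size: int = 500, n_blocks: int = 10
) -> list[dict[str, str]]:
    """Concatenate SNPs into pseudo-gene alignments.

    Sites are ordered by (locus, site) and cut into ``n_blocks`` alignments
    of ``block_size`` columns each, coded A (ancestral) / T (derived).
    Returns a list of dicts mapping haplotype label -> sequence.
    """
    if isinstance(variants, list):
        variants = VariantTable.concat(variants)
    need = block_size * n_blocks
    if variants.n_sites < need:
        raise ValueError(
            f"need {need} SNPs for {n_blocks} blocks of {block_size}, "
            f"have {variants.n_sites} (short by {need - variants.n_sites})"
        )
    order = np.lexsort((variants.site, variants.locus))
    mat = variants.matrix()[order]
    alleles = np.array(["A", "T"])
    out = []
    for b in range(n_blocks):
        block = mat[b * block_size : (b + 1) * block_size]
        aln = {
            hap: "".join(alleles[block[:, j]])
            for j, hap in enumerate(variants.haplotypes)
        }
        out.append(aln)
    return out
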