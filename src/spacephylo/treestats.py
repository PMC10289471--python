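"""Gene-tree summaries: topology censuses, skew tests, tree-space, traits.

The census machinery reduces each gene tree to one representative tip per
taxon ("one genome per species") and classifies the induced rooted
topology. "Slatkin's skew" is the departure from equal frequencies of
mirror discordant topology classes that the neutral MSC predicts to be
equiprobable; spatially structured ancestors bias the class pairing
geographically close taxa upward. Tree-space diagnostics use weighted
Robinson-Foulds distances (branch-length differences summed over the
union of clades, pendant edges included) embedded by non-metric MDS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genealogy import GeneTree

__all__ = [
    "TopologyCensus",
    "TreeSpaceEmbedding",
    "TraitMatrix",
    "SkewResult",
    "classify_topology",
    "census_topologies",
    "slatkin_skew_test",
    "weighted_rf",
    "nmds_embed",
    "centroid_displacement",
    "topology_distance_regression",
    "geographic_monophyly",
    "simulate_binary_traits",
    "count_supporting_traits",
    "parse_topology_label",
]


def _canonical_label(struct, sep: str) -> str:
    if isinstance(struct, str):
        return struct
    return "(" + sep.join(sorted(_canonical_label(s, sep) for s in struct)) + ")"


def parse_topology_label(label: str):
    """Parse a topology label like ``(((AB)C)D)`` into nested tuples.

    Labels without commas use single-character taxon names (the package's
    compact dialect); comma-separated labels may use longer names.
    """
    pos = 0
    single_char = "," not in label

    def parse():
        nonlocal pos
        if label[pos] == "(":
            pos += 1
            parts = []
            while label[pos] != ")":
                if label[pos] == ",":
                    pos += 1
                    continue
                parts.append(parse())
            pos += 1
            return tuple(parts)
        if single_char:
            pos += 1
            return label[pos - 1]
        start = pos
        while pos < len(label) and label[pos] not in "(),":
            pos += 1
        return label[start:pos]

    out = parse()
    if pos != len(label):
        raise ValueError(f"trailing characters in label {label!r}")
    return out


def canonicalize_label(label: str) -> str:
    """Rewrite a topology label with children in canonical (sorted) order."""
    struct = parse_topology_label(label)

    def taxa(s):
        return [s] if isinstance(s, str) else [t for c in s for t in taxa(c)]

    sep = "" if all(len(t) == 1 for t in taxa(struct)) else ","
    return _canonical_label(struct, sep)


def _representatives(
    tree: GeneTree, taxa, rng: np.random.Generator | None
) -> dict[str, str]:
    if tree.tip_meta is None:
        raise ValueError("tree has no tip metadata; cannot map taxa to tips")
    reps = {}
    for taxon in taxa:
        tips = [
            lab
            for lab, sp in zip(
                tree.tip_meta["label"], tree.tip_meta["species"]
            )
            if sp == taxon
        ]
        if not tips:
            raise ValueError(f"taxon {taxon!r} has no tips in tree")
        if len(tips) == 1:
            reps[taxon] = tips[0]
        else:
            if rng is None:
                raise ValueError(
                    "multiple tips per taxon: pass rng to pick representatives"
                )
            reps[taxon] = tips[rng.integers(len(tips))]
    return reps


def classify_topology(
    tree: GeneTree, taxa, rng: np.random.Generator | None = None
) -> str:
    """Canonical rooted-topology label induced on one tip per taxon."""
    return tree.induced_topology(_representatives(tree, taxa, rng))


@dataclass
class TopologyCensus:
    """Counts of rooted topology classes over a set of gene trees."""

    taxa: tuple
    counts: dict[str, int]
    total: int
    outgroup: str | None = None
    outgroup_ingroup: int = 0

    def __post_init__(self):
        if sum(self.counts.values()) != self.total:
            raise ValueError("class counts do not sum to total")

    def proportion(self, label: str) -> float:
        return self.counts.get(canonicalize_label(label), 0) / self.total

    def as_dataframe(self) -> pd.DataFrame:
        rows = sorted(
            self.counts.items(), key=lambda kv: (-kv[1], kv[0])
        )
        return pd.DataFrame(
            {
                "topology": [k for k, _ in rows],
                "count": [v for _, v in rows],
                "proportion": [v / self.total for _, v in rows],
            }
        )


def _outgroup_is_sister(label: str, outgroup: str) -> bool:
    struct = parse_topology_label(label)
    return isinstance(struct, tuple) and any(
        isinstance(c, str) and c == outgroup for c in struct
    )


def census_topologies(
    trees: list[GeneTree],
    taxa,
    outgroup: str | None = None,
    rng: np.random.Generator | None = None,
) -> TopologyCensus:
    """Count induced rooted topologies across gene trees.

    If ``outgroup`` is given, also counts trees in which the designated
    outgroup is *not* sister to all remaining taxa (discordance that drags
    the outgroup inside the ingroup).
    """
    if not trees:
        raise ValueError("empty tree set")
    taxa = tuple(taxa)
    counts: dict[str, int] = {}
    og_in = 0
    for tree in trees:
        label = classify_topology(tree, taxa, rng)
        counts[label] = counts.get(label, 0) + 1
        if outgroup is not None and not _outgroup_is_sister(label, outgroup):
            og_in += 1
    return TopologyCensus(
        taxa=taxa,
        counts=counts,
        total=len(trees),
        outgroup=outgroup,
        outgroup_ingroup=og_in,
    )


@dataclass(frozen=True)
class SkewResult:
    skew: float
    pvalue: float
    n_a: int
    n_b: int


def slatkin_skew_test(
    census: TopologyCensus, topology_a: str, topology_b: str
) -> SkewResult:
    """Exact binomial test of equality for two mirror discordant classes.

    Under the MSC the two classes are equiprobable; ``skew`` is
    ``nA / (nA + nB)`` and the p-value is two-sided with p0 = 1/2.
    """
    na = census.counts.get(canonicalize_label(topology_a), 0)
    nb = census.counts.get(canonicalize_label(topology_b), 0)
    if na + nb == 0:
        raise ValueError("neither topology class observed")
    res = stats.binomtest(na, na + nb, 0.5, alternative="two-sided")
    return SkewResult(
        skew=na / (na + nb), pvalue=res.pvalue, n_a=na, n_b=nb
    )


# -- tree space --------------------------------------------------------------


def weighted_rf(tree1: GeneTree, tree2: GeneTree) -> float:
    """Weighted Robinson-Foulds distance between two rooted trees.

    Sum over the union of clades (tip sets below non-root edges, pendant
    edges included) of |l1 - l2|, where a clade absent from one tree
    contributes its full length.
    """
    if set(tree1.tip_labels) != set(tree2.tip_labels):
        raise ValueError("trees have different tip sets")
    c1, c2 = tree1.clades(), tree2.clades()
    total = 0.0
    for clade in c1.keys() | c2.keys():
        total += abs(c1.get(clade, 0.0) - c2.get(clade, 0.0))
    return total


def rf_distance_matrix(trees: list[GeneTree]) -> np.ndarray:
    """Pairwise weighted RF distances (symmetric, zero diagonal)."""
    n = len(trees)
    clades = [t.clades() for t in trees]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = clades[i], clades[j]
            d = 0.0
            for clade in ci.keys() | cj.keys():
                d += abs(ci.get(clade, 0.0) - cj.get(clade, 0.0))
            D[i, j] = D[j, i] = d
    return D


@dataclass
class TreeSpaceEmbedding:
    """2-D NMDS coordinates, centred on the pooled centroid."""

    coords: np.ndarray
    stress: float
    labels: list[str]

    def group_coords(self, group: str) -> np.ndarray:
        mask = np.array([l == group for l in self.labels])
        if not mask.any():
            raise ValueError(f"no points labelled {group!r}")
        return self.coords[mask]


def nmds_embed(
    distance_matrix: np.ndarray,
    seed: int,
    labels: list[str] | None = None,
    n_init: int = 8,
    max_iter: int = 600,
    eps: float = 1e-9,
) -> TreeSpaceEmbedding:
    """Non-metric (Kruskal stress-1) 2-D embedding of a distance matrix.

    Runs ``n_init`` seeded random starts and keeps the lowest-stress
    solution; stress landscapes of tree distances are multi-modal, so a
    single start is unreliable. Coordinates are centred on the pooled
    centroid.
    """
    from sklearn.manifold import MDS

    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    mds = MDS(
        n_components=2,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_init,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=True,
        n_jobs=1,
    )
    coords = mds.fit_transform(D)
    coords = coords - coords.mean(axis=0, keepdims=True)
    if labels is None:
        labels = [""] * D.shape[0]
    return TreeSpaceEmbedding(
        coords=coords, stress=float(mds.stress_), labels=list(labels)
    )


def centroid_displacement(embedding: TreeSpaceEmbedding, group: str) -> float:
    """Distance between a group's centroid and the pooled centroid (origin)."""
    pts = embedding.group_coords(group)
    pooled = embedding.coords.mean(axis=0)
    return float(np.linalg.norm(pts.mean(axis=0) - pooled))


# -- geographic diagnostics --------------------------------------------------


def topology_distance_regression(
    census: TopologyCensus,
    coordinates: pd.DataFrame,
    outgroup: str,
) -> tuple[float, float]:
    """Regress outgroup-as-ingroup proportions on geographic distance.

    For each candidate sister taxon X, the proportion of gene trees in
    which the outgroup attaches as sister to X alone is regressed on the
    distance between the outgroup's and X's range centroids
    (``coordinates``: columns species, x, y). A significantly negative
    slope indicates geographically driven topology frequencies. Returns
    (slope, two-sided p of the slope t-test).
    """
    coords = coordinates.set_index("species")
    sisters = [t for t in census.taxa if t != outgroup]
    if len(sisters) < 3:
        raise ValueError("need >= 3 candidate sister classes")

    def d_sister(label: str) -> str | None:
        """Taxon to which the outgroup is sister, if a single taxon."""
        struct = parse_topology_label(label)

        def find(node):
            if isinstance(node, str):
                return None
            kids = list(node)
            if outgroup in kids:
                others = [k for k in kids if k != outgroup]
                if len(others) == 1 and isinstance(others[0], str):
                    return others[0]
                return False  # outgroup sister to a clade
            for k in kids:
                r = find(k)
                if r is not None:
                    return r
            return None

        r = find(struct)
        return r if isinstance(r, str) else None

    props, dists = [], []
    ox, oy = coords.loc[outgroup, "x"], coords.loc[outgroup, "y"]
    for x_taxon in sisters:
        n = sum(
            c
            for lab, c in census.counts.items()
            if d_sister(lab) == x_taxon
            and not _outgroup_is_sister(lab, outgroup)
        )
        props.append(n / census.total)
        dists.append(
            float(
                np.hypot(
                    coords.loc[x_taxon, "x"] - ox,
                    coords.loc[x_taxon, "y"] - oy,
                )
            )
        )
    if np.allclose(props, props[0]):
        return 0.0, 1.0
    res = stats.linregress(dists, props)
    return float(res.slope), float(res.pvalue)


def geographic_monophyly(
    trees: list[GeneTree], location_groups: dict[str, list[str]]
) -> dict[str, float]:
    """Fraction of trees in which each location group is monophyletic.

    Singleton groups are trivially monophyletic and trigger a warning.
    """
    out = {}
    for name, tips in location_groups.items():
        if len(tips) == 1:
            warnings.warn(
                f"group {name!r} is a singleton (trivially monophyletic)"
            )
        want = frozenset(tips)
        hits = 0
        for tree in trees:
            allt = frozenset(tree.tip_labels)
            if not want <= allt:
                raise ValueError(f"group {name!r} has tips absent from tree")
            if want == allt or len(want) == 1 or want in tree.clades():
                hits += 1
        out[name] = hits / len(trees)
    return out


# -- binary traits -----------------------------------------------------------


@dataclass
class TraitMatrix:
    """Binary tip-by-trait matrix from a symmetric 2-state Markov model."""

    matrix: np.ndarray
    tips: list[str]
    rate: float

    def states(self, tip: str) -> np.ndarray:
        return self.matrix[self.tips.index(tip)]


def simulate_binary_traits(
    tree: GeneTree,
    n_traits: int,
    rate: float,
    rng: np.random.Generator,
) -> TraitMatrix:
    """Evolve independent binary traits on an ultrametric tree.

    Symmetric 2-state continuous-time Markov chain (equal 0<->1 rates);
    the root state is a fair coin and the flip probability over a branch
    of length t is (1 - exp(-2*rate*t)) / 2.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    ch = tree.children()
    root = tree.root
    states = np.zeros((tree.n_nodes, n_traits), dtype=np.uint8)
    states[root] = rng.integers(0, 2, size=n_traits)
    order = [root]
    stack = [root]
    while stack:
        node = stack.pop()
        for c in ch[node]:
            order.append(c)
            stack.append(c)
    for node in order:
        if node == root:
            continue
        t = tree.branch_length(node)
        p_flip = 0.5 * (1.0 - np.exp(-2.0 * rate * t))
        flips = rng.random(n_traits) < p_flip
        states[node] = np.where(flips, 1 - states[tree.parent[node]],
                                states[tree.parent[node]])
    tips = [i for i in range(tree.n_nodes) if not ch[i]]
    return TraitMatrix(
        matrix=states[tips],
        tips=[tree.tip_labels[i] for i in tips],
        rate=rate,
    )


def count_supporting_traits(traits: TraitMatrix, clade_tips) -> int:
    """Number of traits that are strict synapomorphies of a tip set.

    A trait supports the clade when all clade tips share one state and no
    tip outside the clade carries that state.
    """
    clade = list(clade_tips)
    if not clade:
        raise ValueError("empty clade")
    inside = np.array([t in set(clade) for t in traits.tips])
    if inside.all():
        return 0  # no outside tips: nothing to contrast against
    m = traits.matrix
    count = 0
    for j in range(m.shape[1]):
        col = m[:, j]
        s = col[inside]
        if (s == s[0]).all() and not (col[~inside] == s[0]).any():
            count += 1
    return count
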