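"""Neutral multispecies-coalescent expectations and deme-Markov analytics.

Times are in coalescent units of 2*Ne generations unless a function says
otherwise. Species trees are the asymmetric combs used throughout the
package: ``((AB)C)`` with internal interval ``t`` and ``(((AB)C)D)`` with
intervals ``t2`` (duration of the AB ancestor) and ``t1`` (duration of the
ABC ancestor).

The deme-transition Markov model is a discrete caricature of the
scattering/collecting-phase picture: a lineage's location mixes toward the
uniform distribution at a rate set by dispersal, and only once mixed does
the coalescent behave like Kingman's.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .genealogy import GeneTree

__all__ = [
    "TopologyDistribution",
    "MarkovDemeModel",
    "three_taxon_topology_probs",
    "four_taxon_topology_probs",
    "mc_three_taxon_concordance",
    "mc_four_taxon_topologies",
    "simulate_kingman_tree",
    "markov_power",
    "time_to_mixing",
    "neighborhood_size",
    "is_panmixia_like",
    "expected_tmrca",
]


@dataclass
class TopologyDistribution:
    """Probabilities over rooted topology labels."""

    probs: dict[str, float]
    t1: float | None = None
    t2: float | None = None

    def __post_init__(self):
        total = sum(self.probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")

    def __getitem__(self, label: str) -> float:
        return self.probs.get(label, 0.0)

    def most_probable(self) -> str:
        return max(self.probs, key=self.probs.get)


def three_taxon_topology_probs(t: float) -> TopologyDistribution:
    """Rooted topology probabilities for species tree ((AB)C).

    With probability ``1 - e^-t`` the A and B lineages coalesce within the
    internal interval and the tree is concordant; otherwise all three
    topologies of the remaining lineages are equally likely:
    P(concordant) = 1 - (2/3)e^-t, each discordant = (1/3)e^-t.
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    e = math.exp(-t)
    return TopologyDistribution(
        probs={
            "((AB)C)": 1.0 - 2.0 * e / 3.0,
            "((AC)B)": e / 3.0,
            "((BC)A)": e / 3.0,
        },
        t2=t,
    )


# -- four-taxon enumeration --------------------------------------------------

_TAXA4 = ("A", "B", "C", "D")


def _label_from_clades(clades: frozenset) -> str:
    """Canonical label of a rooted 4-taxon topology from its internal clades."""
    cl = sorted(clades, key=len)
    pair, other = cl[0], cl[1]
    if set(pair) <= set(other):  # nested clades: caterpillar shape
        inner = "(" + "".join(sorted(pair)) + ")"
        mid = next(iter(set(other) - set(pair)))
        outer = next(iter(set(_TAXA4) - set(other)))
        return "((" + inner + mid + ")" + outer + ")"
    p1 = "(" + "".join(sorted(pair)) + ")"
    p2 = "(" + "".join(sorted(other)) + ")"
    a, b = sorted([p1, p2])
    return "(" + a + b + ")"


def _merge_outcomes(lineages: tuple, n_mergers: int):
    """All ordered merger sequences with probabilities and created clades."""
    if n_mergers == 0:
        yield lineages, (), 1.0
        return
    k = len(lineages)
    pairs = list(itertools.combinations(range(k), 2))
    for i, j in pairs:
        merged = frozenset(lineages[i]) | frozenset(lineages[j])
        rest = tuple(
            l for idx, l in enumerate(lineages) if idx not in (i, j)
        ) + (merged,)
        for lin2, clades2, p2 in _merge_outcomes(rest, n_mergers - 1):
            yield lin2, (merged,) + clades2, p2 / len(pairs)


def _n_merger_probs(k: int, t: float) -> list[float]:
    """P(exactly j coalescences among k lineages within time t), Kingman."""
    if k == 1:
        return [1.0]
    if k == 2:
        e = math.exp(-t)
        return [e, 1.0 - e]
    if k == 3:
        e1, e3 = math.exp(-t), math.exp(-3.0 * t)
        p0 = e3
        p1 = 1.5 * (e1 - e3)
        return [p0, p1, 1.0 - p0 - p1]
    raise NotImplementedError("only up to 3 lineages per interval needed")


def four_taxon_topology_probs(t1: float, t2: float) -> TopologyDistribution:
    """Probabilities of all 15 rooted topologies for species tree (((AB)C)D).

    ``t2`` is the AB-ancestor interval, ``t1`` the ABC-ancestor interval
    (both in coalescent units of their populations). Computed by exact
    enumeration of coalescent histories: merger counts per interval follow
    the Kingman death process, merging pairs are uniform, and the root
    population absorbs everything that remains.
    """
    if t1 < 0 or t2 < 0:
        raise ValueError("intervals must be non-negative")
    out: dict[str, float] = {}
    base = (frozenset("A"), frozenset("B"))
    for j_ab, p_ab in enumerate(_n_merger_probs(2, t2)):
        if p_ab == 0.0:
            continue
        for lin_ab, clades_ab, q_ab in _merge_outcomes(base, j_ab):
            lin_abc = lin_ab + (frozenset("C"),)
            for j1, p1 in enumerate(_n_merger_probs(len(lin_abc), t1)):
                if p1 == 0.0:
                    continue
                for lin2, clades2, q2 in _merge_outcomes(lin_abc, j1):
                    lin_root = lin2 + (frozenset("D"),)
                    for lin3, clades3, q3 in _merge_outcomes(
                        lin_root, len(lin_root) - 1
                    ):
                        clades = frozenset(
                            "".join(sorted(c))
                            for c in clades_ab + clades2 + clades3
                            if len(c) < 4
                        )
                        label = _label_from_clades(clades)
                        out[label] = out.get(label, 0.0) + (
                            p_ab * q_ab * p1 * q2 * q3
                        )
    return TopologyDistribution(probs=out, t1=t1, t2=t2)


# -- Monte-Carlo oracles -----------------------------------------------------


def mc_three_taxon_concordance(
    t: float, n_draws: int, rng: np.random.Generator
) -> float:
    """Monte-Carlo concordant fraction for species tree ((AB)C)."""
    merged = rng.random(n_draws) < 1.0 - math.exp(-t)
    # if not merged, the first root-phase pair is uniform over 3 choices
    pick_ab = rng.integers(0, 3, size=n_draws) == 0
    return float(np.mean(merged | pick_ab))


_POPCOUNT = np.array([bin(i).count("1") for i in range(16)], dtype=np.uint8)


def mc_four_taxon_topologies(
    t1: float, t2: float, n_draws: int, rng: np.random.Generator
) -> dict[str, float]:
    """Vectorised Monte-Carlo draw of rooted 4-taxon gene-tree topologies.

    Independent of :func:`four_taxon_topology_probs`: simulates exponential
    waiting times through the two intervals and the root population and
    reads the topology off the realised merger sequence.
    """
    n = n_draws
    masks = np.zeros((n, 4), dtype=np.uint8)
    masks[:, 0], masks[:, 1] = 1, 2  # A, B
    k = np.full(n, 2, dtype=np.int8)
    clades = np.zeros((n, 2), dtype=np.uint8)
    ncl = np.zeros(n, dtype=np.int8)

    pair_table = {
        kk: np.array(list(itertools.combinations(range(kk), 2)))
        for kk in (2, 3, 4)
    }

    def run_phase(duration: float):
        t_acc = np.zeros(n)
        while True:
            can = k >= 2
            if duration != np.inf:
                can &= t_acc < duration
            if not can.any():
                break
            idx = np.flatnonzero(can)
            kk = k[idx].astype(np.int64)
            rate = kk * (kk - 1) / 2.0
            t_new = t_acc[idx] + rng.exponential(1.0, idx.size) / rate
            if duration != np.inf:
                ok = t_new <= duration
                t_acc[idx] = np.where(ok, t_new, duration)
                idx, kk = idx[ok], kk[ok]
            else:
                t_acc[idx] = t_new
            if idx.size == 0:
                continue
            u = rng.integers(0, (kk * (kk - 1)) // 2)
            for kv in (2, 3, 4):
                sel = kk == kv
                if not sel.any():
                    continue
                rows = idx[sel]
                pr = pair_table[kv][u[sel]]
                i_sl, j_sl = pr[:, 0], pr[:, 1]
                merged = masks[rows, i_sl] | masks[rows, j_sl]
                rec = _POPCOUNT[merged] < 4
                rr = rows[rec]
                clades[rr, ncl[rr]] = merged[rec]
                ncl[rr] += 1
                masks[rows, i_sl] = merged
                last = kv - 1
                move = j_sl != last
                masks[rows[move], j_sl[move]] = masks[rows[move], last]
                masks[rows, last] = 0
                k[rows] -= 1

    run_phase(t2)
    # add C
    masks[np.arange(n), k] = 4
    k += 1
    run_phase(t1)
    masks[np.arange(n), k] = 8
    k += 1
    run_phase(np.inf)

    lo = np.minimum(clades[:, 0], clades[:, 1])
    hi = np.maximum(clades[:, 0], clades[:, 1])
    codes = lo.astype(np.int32) * 16 + hi
    label_of = {}
    mask_to_taxa = {
        m: frozenset(
            t for bit, t in zip((1, 2, 4, 8), _TAXA4) if m & bit
        )
        for m in range(1, 16)
    }
    uniq, counts = np.unique(codes, return_counts=True)
    out: dict[str, float] = {}
    for code, cnt in zip(uniq, counts):
        c1, c2 = mask_to_taxa[code // 16], mask_to_taxa[code % 16]
        label = _label_from_clades(
            frozenset(("".join(sorted(c1)), "".join(sorted(c2))))
        )
        out[label] = out.get(label, 0.0) + cnt / n
    return out


def simulate_kingman_tree(
    n_tips: int,
    ne: float,
    rng: np.random.Generator,
    tip_labels: list[str] | None = None,
) -> GeneTree:
    """Sample a panmictic Kingman genealogy (times in generations)."""
    if n_tips < 2 or ne <= 0:
        raise ValueError("need >= 2 tips and positive Ne")
    labels = tip_labels or [f"t{i}" for i in range(n_tips)]
    parent = np.full(2 * n_tips - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n_tips - 1)
    roots = list(range(n_tips))
    t = 0.0
    nid = n_tips
    while len(roots) > 1:
        k = len(roots)
        t += rng.exponential(2.0 * ne / (k * (k - 1) / 2.0))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = roots[i], roots[j]
        parent[a] = parent[b] = nid
        time[nid] = t
        roots = [r for r in roots if r not in (a, b)] + [nid]
        nid += 1
    return GeneTree(parent=parent, time=time, tip_labels=list(labels))


# -- deme-Markov analytics ---------------------------------------------------


@dataclass
class MarkovDemeModel:
    """Row-stochastic per-generation deme-transition matrix."""

    P: np.ndarray
    labels: tuple = field(default=())

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        if self.P.ndim != 2 or self.P.shape[0] != self.P.shape[1]:
            raise ValueError("transition matrix must be square")
        if np.any(self.P < 0) or np.any(self.P > 1):
            raise ValueError("entries must lie in [0, 1]")
        if np.max(np.abs(self.P.sum(axis=1) - 1.0)) > 1e-12:
            raise ValueError("rows must sum to 1 within 1e-12")
        if not self.labels:
            self.labels = tuple(f"deme{i}" for i in range(self.P.shape[0]))

    @property
    def n_demes(self) -> int:
        return self.P.shape[0]

    @classmethod
    def linear_chain(cls, retention: list[float]) -> "MarkovDemeModel":
        """Demes on a line; each generation's leak splits between neighbours."""
        n = len(retention)
        P = np.zeros((n, n))
        for i, r in enumerate(retention):
            P[i, i] = r
            nbrs = [j for j in (i - 1, i + 1) if 0 <= j < n]
            for j in nbrs:
                P[i, j] = (1.0 - r) / len(nbrs)
        return cls(P=P)

    @classmethod
    def three_deme_example(cls) -> "MarkovDemeModel":
        """The worked 3-deme chain with retention (0.99, 0.98, 0.99)."""
        return cls.linear_chain([0.99, 0.98, 0.99])


def markov_power(model: MarkovDemeModel, t: int) -> np.ndarray:
    """P^t by repeated squaring; the identity at t = 0."""
    if t < 0 or int(t) != t:
        raise ValueError("t must be a non-negative integer")
    return np.linalg.matrix_power(model.P, int(t))


def time_to_mixing(
    model: MarkovDemeModel, epsilon: float = 0.01, cap: int = 1_000_000
) -> int:
    """Smallest t with max_ij |P^t_ij - 1/n| <= epsilon.

    This is the generation at which a lineage's ancestral deme is uniform
    to within ``epsilon`` regardless of the sampled deme — the onset of the
    collecting phase in the deme caricature.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n = model.n_demes
    target = 1.0 / n
    M = np.eye(n)
    for t in range(cap + 1):
        if np.max(np.abs(M - target)) <= epsilon:
            return t
        M = M @ model.P
    raise RuntimeError(
        f"chain not mixed to epsilon={epsilon} within {cap} steps "
        "(irreducible and aperiodic?)"
    )


# -- classic spatial summaries ----------------------------------------------


def neighborhood_size(rho: float, sigma: float) -> float:
    """Wright's neighbourhood size 4*pi*rho*sigma^2."""
    if rho <= 0 or sigma <= 0:
        raise ValueError("rho and sigma must be positive")
    return 4.0 * math.pi * rho * sigma**2


def is_panmixia_like(ns: float) -> bool:
    """Whether a neighbourhood size is large enough (> 1000) to pass for
    panmixia in practice."""
    return ns > 1000.0


def expected_tmrca(k: int, ne: float, kind: str = "interval") -> float:
    """Expected coalescent times for k lineages in a panmictic population.

    ``kind="interval"``: mean time while exactly k lineages remain,
    4*Ne/(k(k-1)). ``kind="total"``: mean time to the single common
    ancestor, 4*Ne*(1 - 1/k). Both give 2*Ne at k = 2.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if ne <= 0:
        raise ValueError("Ne must be positive")
    if kind == "interval":
        return 4.0 * ne / (k * (k - 1))
    if kind == "total":
        return 4.0 * ne * (1.0 - 1.0 / k)
    raise ValueError("kind must be 'interval' or 'total'")
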