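"""Forward-time, individual-based simulation on a continuous 2-D range.

Diploid hermaphrodites live on a rectangular habitat. Local density is
measured with a truncated Gaussian interaction kernel of scale ``sigma_I``
(maximum ``1/(2*pi*sigma_I**2)`` at distance 0, zero beyond ``3*sigma_I``).
Each generation every individual acts once as a focal parent: its offspring
number is Poisson with mean ``fecundity_rate / (1 + D_i / D*)`` (a
Beverton-Holt style regulation whose equilibrium local density is ~= ``D*``),
each offspring receives a mate drawn from same-species neighbours within
``3*sigma_M`` with Gaussian weight, starts at the focal parent's position and
disperses by independent uniform(-3*sigma_D, 3*sigma_D) displacements per
axis, reflected at habitat and barrier edges. The parental generation then
dies (non-overlapping generations).

Speciation is scheduled: *vicariance* drops an axis-aligned barrier that
splits a species' rectangular range in two; *peripatry* opens an adjacent
rectangle, lets the species expand into it, and seals the former boundary
``expansion_lag`` generations later, isolating the colonists as a new
species.

Every generation's parent pairs, positions and species labels are recorded
in a :class:`PedigreeArchive`, the substrate from which per-locus gene
trees are later extracted (see :mod:`spacephylo.genealogy`).
"""

from __future__ import annotations

import dataclasses
import gzip
import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "Rect",
    "SimulationConfig",
    "SpeciationEvent",
    "Schedule",
    "PopulationState",
    "PedigreeArchive",
    "ExtinctionError",
    "init_population",
    "interaction_density",
    "step_generation",
    "apply_speciation_event",
    "run_simulation",
    "sample_individuals",
    "comb_vicariance_schedule",
    "comb_peripatry_schedule",
    "six_taxon_comb_times",
    "PRESETS",
]

TAXON_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"

#: Preset kernel scales. "Clustered" combines short dispersal and mate
#: search (0.25) with a wide interaction kernel, producing clumped ancestry;
#: "unclustered" is the near-panmictic opposite. The interaction scales are
#: fixed so that the unclustered neighbourhood (radius 3*sigma_I) holds
#: enough individuals at D*=1 for stable regulation while the clustered
#: kernel spans several dispersal scales.
PRESETS = {
    "clustered": {"sigma_D": 0.25, "sigma_M": 0.25, "sigma_I": 0.75},
    "unclustered": {"sigma_D": 1.0, "sigma_M": 1.0, "sigma_I": 0.5},
}


class ExtinctionError(RuntimeError):
    """Raised when a population produces zero offspring."""


class EventError(ValueError):
    """Raised for inconsistent speciation events."""


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle ``[x0, x1] x [y0, y1]``."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self):
        if not (self.x1 > self.x0 and self.y1 > self.y0):
            raise ValueError(f"degenerate rectangle {self}")

    @property
    def width(self) -> float:
        return self.x1 - self.x0

    @property
    def height(self) -> float:
        return self.y1 - self.y0

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return (0.5 * (self.x0 + self.x1), 0.5 * (self.y0 + self.y1))

    def contains(self, x, y) -> np.ndarray:
        return (
            (x >= self.x0) & (x <= self.x1) & (y >= self.y0) & (y <= self.y1)
        )

    def split(self, axis: str, position: float) -> tuple["Rect", "Rect"]:
        """Split along an axis-aligned line; returns (low, high)."""
        if axis == "x":
            if not (self.x0 < position < self.x1):
                raise EventError(f"split at x={position} outside {self}")
            return (
                Rect(self.x0, self.y0, position, self.y1),
                Rect(position, self.y0, self.x1, self.y1),
            )
        if axis == "y":
            if not (self.y0 < position < self.y1):
                raise EventError(f"split at y={position} outside {self}")
            return (
                Rect(self.x0, self.y0, self.x1, position),
                Rect(self.x0, position, self.x1, self.y1),
            )
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")

    def union(self, other: "Rect") -> "Rect":
        """Union with an edge-adjacent rectangle; must again be a rectangle."""
        if self.y0 == other.y0 and self.y1 == other.y1 and (
            self.x1 == other.x0 or self.x0 == other.x1
        ):
            return Rect(
                min(self.x0, other.x0), self.y0, max(self.x1, other.x1), self.y1
            )
        if self.x0 == other.x0 and self.x1 == other.x1 and (
            self.y1 == other.y0 or self.y0 == other.y1
        ):
            return Rect(
                self.x0, min(self.y0, other.y0), self.x1, max(self.y1, other.y1)
            )
        raise EventError(
            f"{other} is not edge-adjacent to {self}; union is not a rectangle"
        )

    def sample_uniform(self, n: int, rng: np.random.Generator):
        x = rng.uniform(self.x0, self.x1, size=n)
        y = rng.uniform(self.y0, self.y1, size=n)
        return x, y

    def reflect(self, x: np.ndarray, y: np.ndarray):
        """Fold coordinates back into the rectangle (reflecting boundary)."""
        return _fold(x, self.x0, self.x1), _fold(y, self.y0, self.y1)


def _fold(v: np.ndarray, lo: float, hi: float) -> np.ndarray:
    w = hi - lo
    u = np.mod(v - lo, 2.0 * w)
    u = np.where(u > w, 2.0 * w - u, u)
    return lo + u


@dataclass
class SimulationConfig:
    """Parameters of the spatial model.

    All length scales share the coordinate units of the habitat. ``preset``
    fills the kernel scales from :data:`PRESETS` ("clustered" /
    "unclustered"); explicit values for ``sigma_I`` etc. are then ignored.
    """

    range_width: float
    range_height: float
    n_generations: int
    seed: int
    sigma_I: float = 0.5
    sigma_D: float = 1.0
    sigma_M: float | None = None
    target_density: float = 1.0
    fecundity_rate: float = 2.0
    boundary: str = "reflecting"
    preset: str | None = None

    def __post_init__(self):
        if self.preset not in (None, "none"):
            try:
                values = PRESETS[self.preset]
            except KeyError:
                raise ValueError(
                    f"unknown preset {self.preset!r}; expected one of "
                    f"{sorted(PRESETS)}"
                ) from None
            self.sigma_I = values["sigma_I"]
            self.sigma_D = values["sigma_D"]
            self.sigma_M = values["sigma_M"]
        if self.sigma_M is None:
            self.sigma_M = self.sigma_I
        for name in ("sigma_I", "sigma_D", "sigma_M"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.target_density <= 0 or self.fecundity_rate <= 0:
            raise ValueError("target_density and fecundity_rate must be > 0")
        if self.boundary != "reflecting":
            raise ValueError("only the reflecting boundary is implemented")
        if min(self.range_width, self.range_height) <= 6 * self.sigma_I:
            raise ValueError(
                "range dimensions must exceed 6*sigma_I "
                f"({6 * self.sigma_I:g}); got "
                f"{self.range_width:g} x {self.range_height:g}"
            )

    @property
    def full_range(self) -> Rect:
        return Rect(0.0, 0.0, self.range_width, self.range_height)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SpeciationEvent:
    """A scheduled divergence of one species into two.

    ``time`` is the forward generation at which the event starts. For
    vicariance the barrier (``axis``/``position``) becomes active at
    ``time``. For peripatry ``new_region`` opens at ``time`` and the barrier
    at the shared edge seals ``expansion_lag`` generations later;
    ``child_labels`` is ``(low-side, high-side)`` with respect to the
    barrier coordinate in both modes.
    """

    time: int
    mode: str  # "vicariance" | "peripatry"
    parent: str
    child_labels: tuple[str, str]
    axis: str
    position: float
    new_region: Rect | None = None
    expansion_lag: int | None = None

    def __post_init__(self):
        if self.mode not in ("vicariance", "peripatry"):
            raise EventError(f"unknown speciation mode {self.mode!r}")
        if self.mode == "peripatry":
            if self.new_region is None or self.expansion_lag is None:
                raise EventError(
                    "peripatry requires new_region and expansion_lag"
                )
            if self.expansion_lag < 1:
                raise EventError("expansion_lag must be >= 1 generation")

    @property
    def seal_time(self) -> int:
        """Generation at which the two child species become separate."""
        if self.mode == "vicariance":
            return self.time
        return self.time + self.expansion_lag


@dataclass
class Schedule:
    """Ordered speciation events plus the founding region of the root."""

    events: list[SpeciationEvent] = field(default_factory=list)
    founding_region: Rect | None = None
    root_label: str | None = None

    def __post_init__(self):
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise EventError("event times must be strictly increasing")

    @property
    def n_terminal_species(self) -> int:
        return len(self.events) + 1


@dataclass
class PopulationState:
    """All living individuals at one generation.

    Individual ids are the row indices of the arrays; ``parent1``/``parent2``
    index rows of the *previous* generation (-1 for founders).
    """

    generation: int
    x: np.ndarray
    y: np.ndarray
    species: np.ndarray  # int16 codes into species_labels
    parent1: np.ndarray
    parent2: np.ndarray
    species_labels: list[str]
    regions: dict[str, Rect]

    @property
    def n(self) -> int:
        return self.x.size

    def label_of(self, code: int) -> str:
        return self.species_labels[code]

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for code, cnt in zip(*np.unique(self.species, return_counts=True)):
            out[self.species_labels[code]] = int(cnt)
        return out

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n),
                "x": self.x,
                "y": self.y,
                "species": [self.species_labels[c] for c in self.species],
                "parent1": self.parent1,
                "parent2": self.parent2,
            }
        )


@dataclass
class _GenRecord:
    x: np.ndarray
    y: np.ndarray
    species: np.ndarray
    parent1: np.ndarray
    parent2: np.ndarray


@dataclass
class PedigreeArchive:
    """Per-generation parent tables, positions and species labels."""

    config: SimulationConfig
    schedule: Schedule
    species_labels: list[str]
    species_parent: dict[str, str]
    generations: list[_GenRecord]
    final_regions: dict[str, Rect]
    status: str = "completed"
    founding_count: int = 0

    @property
    def n_generations(self) -> int:
        """Index of the final recorded generation (tips live here)."""
        return len(self.generations) - 1

    def state(self, generation: int) -> _GenRecord:
        return self.generations[generation]

    def final(self) -> _GenRecord:
        return self.generations[-1]

    def census(self, species: str | None = None) -> np.ndarray:
        """Per-generation count of one species (or of everyone)."""
        if species is None:
            return np.array([g.x.size for g in self.generations])
        code = self.species_labels.index(species)
        return np.array(
            [int(np.sum(g.species == code)) for g in self.generations]
        )

    def species_at_final(self) -> list[str]:
        codes = np.unique(self.final().species)
        return [self.species_labels[c] for c in codes]

    def checksum(self) -> str:
        h = hashlib.sha256()
        for g in self.generations:
            for arr in (g.x, g.y, g.species, g.parent1, g.parent2):
                h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    # -- persistence (gzipped TSV + JSON metadata) --------------------------

    def save(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        meta = {
            "format_version": 1,
            "config": self.config.to_dict(),
            "species_labels": self.species_labels,
            "species_parent": self.species_parent,
            "status": self.status,
            "founding_count": self.founding_count,
            "final_regions": {
                k: dataclasses.astuple(v) for k, v in self.final_regions.items()
            },
            "schedule": _schedule_to_dict(self.schedule),
        }
        with open(os.path.join(directory, "metadata.json"), "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)
        with gzip.open(
            os.path.join(directory, "pedigree.tsv.gz"), "wt"
        ) as fh:
            fh.write("generation\tid\tx\ty\tspecies\tparent1\tparent2\n")
            for gen, rec in enumerate(self.generations):
                for i in range(rec.x.size):
                    # %.9g round-trips float32 exactly through text
                    fh.write(
                        f"{gen}\t{i}\t{rec.x[i]:.9g}\t{rec.y[i]:.9g}\t"
                        f"{rec.species[i]}\t{rec.parent1[i]}\t{rec.parent2[i]}\n"
                    )

    @classmethod
    def load(cls, directory) -> "PedigreeArchive":
        import os

        with open(os.path.join(directory, "metadata.json")) as fh:
            meta = json.load(fh)
        config = SimulationConfig(**meta["config"])
        df = pd.read_csv(
            os.path.join(directory, "pedigree.tsv.gz"), sep="\t"
        )
        generations = []
        for gen, sub in df.groupby("generation", sort=True):
            sub = sub.sort_values("id")
            generations.append(
                _GenRecord(
                    x=sub["x"].to_numpy(np.float32),
                    y=sub["y"].to_numpy(np.float32),
                    species=sub["species"].to_numpy(np.int16),
                    parent1=sub["parent1"].to_numpy(np.int32),
                    parent2=sub["parent2"].to_numpy(np.int32),
                )
            )
        return cls(
            config=config,
            schedule=_schedule_from_dict(meta["schedule"]),
            species_labels=list(meta["species_labels"]),
            species_parent=dict(meta["species_parent"]),
            generations=generations,
            final_regions={
                k: Rect(*v) for k, v in meta["final_regions"].items()
            },
            status=meta["status"],
            founding_count=int(meta["founding_count"]),
        )


def _schedule_to_dict(schedule: Schedule) -> dict:
    return {
        "events": [
            {
                "time": e.time,
                "mode": e.mode,
                "parent": e.parent,
                "child_labels": list(e.child_labels),
                "axis": e.axis,
                "position": e.position,
                "new_region": (
                    dataclasses.astuple(e.new_region) if e.new_region else None
                ),
                "expansion_lag": e.expansion_lag,
            }
            for e in schedule.events
        ],
        "founding_region": (
            dataclasses.astuple(schedule.founding_region)
            if schedule.founding_region
            else None
        ),
        "root_label": schedule.root_label,
    }


def _schedule_from_dict(d: dict) -> Schedule:
    return Schedule(
        events=[
            SpeciationEvent(
                time=e["time"],
                mode=e["mode"],
                parent=e["parent"],
                child_labels=tuple(e["child_labels"]),
                axis=e["axis"],
                position=e["position"],
                new_region=Rect(*e["new_region"]) if e["new_region"] else None,
                expansion_lag=e["expansion_lag"],
            )
            for e in d["events"]
        ],
        founding_region=(
            Rect(*d["founding_region"]) if d["founding_region"] else None
        ),
        root_label=d["root_label"],
    )


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def init_population(
    config: SimulationConfig,
    founding_region: Rect | None = None,
    species_label: str = "A",
    rng: np.random.Generator | None = None,
) -> PopulationState:
    """Found a population of ``round(D* * area)`` uniform individuals."""
    region = founding_region or config.full_range
    if region.area <= 0:
        raise ValueError("founding region is empty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n0 = int(round(config.target_density * region.area))
    if n0 < 1:
        raise ValueError("founding region too small for target density")
    x, y = region.sample_uniform(n0, rng)
    return PopulationState(
        generation=0,
        x=x,
        y=y,
        species=np.zeros(n0, dtype=np.int16),
        parent1=np.full(n0, -1, dtype=np.int32),
        parent2=np.full(n0, -1, dtype=np.int32),
        species_labels=[species_label],
        regions={species_label: region},
    )


def _kernel_density(
    pts: np.ndarray, sigma_I: float, tree: cKDTree | None = None
) -> np.ndarray:
    """Summed truncated-Gaussian kernel over same-species neighbours."""
    n = pts.shape[0]
    dens = np.zeros(n)
    if n < 2:
        return dens
    if tree is None:
        tree = cKDTree(pts)
    pairs = tree.query_pairs(3.0 * sigma_I, output_type="ndarray")
    if pairs.size:
        d2 = np.sum((pts[pairs[:, 0]] - pts[pairs[:, 1]]) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * sigma_I**2)) / (2.0 * math.pi * sigma_I**2)
        np.add.at(dens, pairs[:, 0], w)
        np.add.at(dens, pairs[:, 1], w)
    return dens


def interaction_density(
    state: PopulationState, config: SimulationConfig, focal_id: int
) -> float:
    """Kernel-weighted local density experienced by one individual.

    Only same-species neighbours within ``3*sigma_I`` contribute; species
    separated by a barrier never interact (they carry different labels).
    """
    if focal_id < 0 or focal_id >= state.n:
        raise IndexError(f"no individual with id {focal_id}")
    code = state.species[focal_id]
    mask = state.species == code
    idx = np.flatnonzero(mask)
    pts = np.column_stack((state.x[idx], state.y[idx]))
    dx = pts[:, 0] - state.x[focal_id]
    dy = pts[:, 1] - state.y[focal_id]
    d2 = dx * dx + dy * dy
    keep = (d2 <= (3.0 * config.sigma_I) ** 2) & (idx != focal_id)
    s2 = config.sigma_I**2
    return float(
        np.sum(np.exp(-d2[keep] / (2.0 * s2)) / (2.0 * math.pi * s2))
    )


def step_generation(
    state: PopulationState,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PopulationState:
    """Advance one non-overlapping generation.

    Mates are redrawn independently for each offspring of a focal parent
    (multiple paternity). This keeps the offspring-number variance close to
    Wright-Fisher, so the panmictic limit of the model has Ne ~= census
    size; a single shared mate per brood would depress Ne by ~20%.
    """
    if state.n == 0:
        raise ValueError("cannot step an empty population")
    new_x, new_y, new_sp, new_p1, new_p2 = [], [], [], [], []
    sigma_I, sigma_M, sigma_D = config.sigma_I, config.sigma_M, config.sigma_D
    for code in np.unique(state.species):
        idx = np.flatnonzero(state.species == code)
        region = state.regions[state.species_labels[code]]
        pts = np.column_stack((state.x[idx], state.y[idx]))
        n = idx.size
        tree = cKDTree(pts)
        dens = _kernel_density(pts, sigma_I, tree)
        lam = config.fecundity_rate / (1.0 + dens / config.target_density)

        # mate adjacency (CSR over candidates within 3*sigma_M, self excluded)
        pairs = tree.query_pairs(3.0 * sigma_M, output_type="ndarray")
        src = np.concatenate([pairs[:, 0], pairs[:, 1]])
        dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
        order = np.argsort(src, kind="stable")
        src, dst = src[order], dst[order]
        counts = np.bincount(src, minlength=n)
        offsets = np.concatenate([[0], np.cumsum(counts)])
        d2 = np.sum((pts[src] - pts[dst]) ** 2, axis=1)
        w = np.exp(-d2 / (2.0 * sigma_M**2))
        cumw = np.cumsum(w)

        n_off = rng.poisson(lam)
        n_off[counts == 0] = 0  # no candidate mate in range: no offspring
        total = int(n_off.sum())
        if total == 0:
            continue
        focal = np.repeat(np.arange(n), n_off)
        # one categorical draw per offspring via global searchsorted
        lo = offsets[focal]
        base = np.where(lo > 0, cumw[lo - 1], 0.0)
        seg_tot = np.where(counts[focal] > 0, cumw[offsets[focal + 1] - 1] - base, 0.0)
        u = rng.random(total)
        pos = np.searchsorted(cumw, base + u * seg_tot, side="left")
        pos = np.clip(pos, lo, offsets[focal + 1] - 1)
        mates = dst[pos]
        disp = rng.uniform(-3.0 * sigma_D, 3.0 * sigma_D, size=(total, 2))
        ox, oy = region.reflect(
            pts[focal, 0] + disp[:, 0], pts[focal, 1] + disp[:, 1]
        )
        new_x.append(ox)
        new_y.append(oy)
        new_sp.append(np.full(total, code, dtype=np.int16))
        new_p1.append(idx[focal].astype(np.int32))
        new_p2.append(idx[mates].astype(np.int32))
    if not new_x:
        raise ExtinctionError(
            f"population extinct at generation {state.generation + 1}"
        )
    return PopulationState(
        generation=state.generation + 1,
        x=np.concatenate(new_x),
        y=np.concatenate(new_y),
        species=np.concatenate(new_sp),
        parent1=np.concatenate(new_p1),
        parent2=np.concatenate(new_p2),
        species_labels=list(state.species_labels),
        regions=dict(state.regions),
    )


def apply_speciation_event(
    state: PopulationState, event: SpeciationEvent
) -> PopulationState:
    """Apply the phase of ``event`` due at ``state.generation``.

    Vicariance relabels by side of the barrier immediately. Peripatry has
    two phases: range expansion at ``event.time`` and sealing (relabelling
    of the colonists) at ``event.time + expansion_lag``.
    """
    if event.parent not in state.species_labels:
        raise EventError(f"unknown parent species {event.parent!r}")
    if event.mode == "peripatry" and state.generation == event.time:
        return _expand_range(state, event)
    if state.generation != event.seal_time:
        raise EventError(
            f"event phase not due at generation {state.generation}"
        )
    return _seal_barrier(state, event)


def _expand_range(
    state: PopulationState, event: SpeciationEvent
) -> PopulationState:
    regions = dict(state.regions)
    regions[event.parent] = regions[event.parent].union(event.new_region)
    return dataclasses.replace(state, regions=regions)


def _seal_barrier(
    state: PopulationState, event: SpeciationEvent
) -> PopulationState:
    code = state.species_labels.index(event.parent)
    region = state.regions[event.parent]
    low_rect, high_rect = region.split(event.axis, event.position)
    coord = state.x if event.axis == "x" else state.y
    members = state.species == code
    low_side = members & (coord < event.position)
    high_side = members & ~low_side
    if not low_side.any() or not high_side.any():
        raise EventError(
            f"barrier {event.axis}={event.position} leaves one side of "
            f"{event.parent!r} empty at generation {state.generation}"
        )
    labels = list(state.species_labels)
    low_code, high_code = len(labels), len(labels) + 1
    labels.extend(event.child_labels)
    species = state.species.copy()
    species[low_side] = low_code
    species[high_side] = high_code
    regions = dict(state.regions)
    del regions[event.parent]
    regions[event.child_labels[0]] = low_rect
    regions[event.child_labels[1]] = high_rect
    return dataclasses.replace(
        state, species=species, species_labels=labels, regions=regions
    )


def run_simulation(
    config: SimulationConfig, schedule: Schedule | None = None
) -> PedigreeArchive:
    """Run the forward simulation, recording the full pedigree.

    The archive ends with ``len(schedule.events) + 1`` terminal species
    unless the population goes extinct first (partial archive with
    ``status == "extinct"``).
    """
    schedule = schedule or Schedule()
    for e in schedule.events:
        if e.seal_time > config.n_generations:
            raise EventError(
                f"event sealing at {e.seal_time} exceeds n_generations"
            )
    rng = np.random.default_rng(config.seed)
    root = schedule.root_label or TAXON_ALPHABET[: schedule.n_terminal_species]
    state = init_population(
        config, schedule.founding_region, species_label=root, rng=rng
    )
    # (generation, event) phases in forward order
    phases: list[tuple[int, SpeciationEvent]] = []
    for e in schedule.events:
        if e.mode == "peripatry":
            phases.append((e.time, e))
        phases.append((e.seal_time, e))
    phases.sort(key=lambda p: p[0])
    species_parent: dict[str, str] = {}

    def record(st: PopulationState) -> _GenRecord:
        return _GenRecord(
            x=st.x.astype(np.float32),
            y=st.y.astype(np.float32),
            species=st.species.astype(np.int16),
            parent1=st.parent1,
            parent2=st.parent2,
        )

    for _, e in phases:
        species_parent[e.child_labels[0]] = e.parent
        species_parent[e.child_labels[1]] = e.parent

    founding = state.n
    generations = [record(state)]
    status = "completed"
    pi = 0
    for gen in range(1, config.n_generations + 1):
        while pi < len(phases) and phases[pi][0] == state.generation:
            state = apply_speciation_event(state, phases[pi][1])
            generations[-1] = record(state)  # labels changed in place
            pi += 1
        try:
            state = step_generation(state, config, rng)
        except ExtinctionError:
            status = "extinct"
            break
        generations.append(record(state))
    else:
        while pi < len(phases) and phases[pi][0] == state.generation:
            state = apply_speciation_event(state, phases[pi][1])
            generations[-1] = record(state)
            pi += 1
    return PedigreeArchive(
        config=config,
        schedule=schedule,
        species_labels=list(state.species_labels),
        species_parent=species_parent,
        generations=generations,
        final_regions=dict(state.regions),
        status=status,
        founding_count=founding,
    )


# ---------------------------------------------------------------------------
# schedule builders
# ---------------------------------------------------------------------------


def six_taxon_comb_times(scale: float = 1.0) -> list[float]:
    """Backward divergence times for the 6-taxon comb.

    Uniform 10,000-generation spacing except the most recent A/B split at
    5,000 generations before present; ``scale`` shrinks the whole schedule
    for desk-scale runs.
    """
    return [scale * t for t in (45000.0, 35000.0, 25000.0, 15000.0, 5000.0)]


def comb_vicariance_schedule(
    config: SimulationConfig,
    divergence_times: list[float],
    axis: str = "x",
) -> Schedule:
    """Serial range fragmentation producing the comb tree ((..(AB)C)..).

    ``divergence_times`` are generations before present, strictly
    decreasing; the deepest event splits off the last taxon on the
    high-coordinate side. Ranges are divided into equal-width strips.
    """
    times = list(divergence_times)
    if any(t2 >= t1 for t1, t2 in zip(times, times[1:])):
        raise EventError("divergence times must be strictly decreasing")
    n = len(times) + 1
    taxa = TAXON_ALPHABET[:n]
    extent = config.range_width if axis == "x" else config.range_height
    events = []
    for i, tau in enumerate(times):
        forward = int(round(config.n_generations - tau))
        if forward <= 0:
            raise EventError("divergence time exceeds run length")
        k = n - 1 - i  # index of the taxon split off (high side)
        events.append(
            SpeciationEvent(
                time=forward,
                mode="vicariance",
                parent=taxa[: k + 1],
                child_labels=(taxa[:k], taxa[k]),
                axis=axis,
                position=extent * k / n,
            )
        )
    return Schedule(events=events, root_label=taxa)


def comb_peripatry_schedule(
    config: SimulationConfig,
    divergence_times: list[float],
    expansion_lag: int | None = None,
    axis: str = "x",
) -> Schedule:
    """Serial peripatric budding producing the same comb tree.

    The ancestor starts confined to the high-coordinate strip; each event
    expands the range one strip toward low coordinates and, ``expansion_lag``
    generations later, seals the former boundary, isolating the colonists.
    ``divergence_times`` (backwards) refer to the *seal* generations. The
    default lag is 10% of the interval to the next event.
    """
    times = list(divergence_times)
    if any(t2 >= t1 for t1, t2 in zip(times, times[1:])):
        raise EventError("divergence times must be strictly decreasing")
    n = len(times) + 1
    taxa = TAXON_ALPHABET[:n]
    extent = config.range_width if axis == "x" else config.range_height
    other = (
        (0.0, config.range_height)
        if axis == "x"
        else (0.0, config.range_width)
    )
    strip = extent / n

    def cell(i: int) -> Rect:
        lo, hi = i * strip, (i + 1) * strip
        if axis == "x":
            return Rect(lo, other[0], hi, other[1])
        return Rect(other[0], lo, other[1], hi)

    events = []
    for i, tau in enumerate(times):
        seal = int(round(config.n_generations - tau))
        if expansion_lag is None:
            nxt = times[i + 1] if i + 1 < len(times) else 0.0
            lag = max(1, int(round(0.1 * (tau - nxt))))
        else:
            lag = int(expansion_lag)
        start = seal - lag
        if start <= 0:
            raise EventError("expansion would begin before generation 0")
        k = n - 1 - i  # source currently occupies cells [k..], colonises k-1
        events.append(
            SpeciationEvent(
                time=start,
                mode="peripatry",
                parent=taxa[: k + 1],
                child_labels=(taxa[:k], taxa[k]),
                axis=axis,
                position=extent * k / n,
                new_region=cell(k - 1),
                expansion_lag=lag,
            )
        )
    return Schedule(
        events=events, founding_region=cell(n - 1), root_label=taxa
    )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def sample_individuals(
    archive: PedigreeArchive,
    species: str,
    scheme: str,
    n: int,
    rng: np.random.Generator,
    edge: str = "left",
) -> pd.DataFrame:
    """Sample ``n`` living individuals of one species at the final generation.

    Schemes: ``random`` (uniform, without replacement), ``center`` (nearest
    to the species-range centroid), ``edge`` (nearest to one side),
    ``three_location`` (``n`` each from two opposite edges and the center,
    3n total, mirroring a two-edges-plus-center field design).
    """
    rec = archive.final()
    if species not in archive.species_labels:
        raise ValueError(f"unknown species {species!r}")
    code = archive.species_labels.index(species)
    idx = np.flatnonzero(rec.species == code)
    if idx.size == 0:
        raise ValueError(f"species {species!r} not alive at final generation")
    region = archive.final_regions[species]
    x, y = rec.x[idx].astype(float), rec.y[idx].astype(float)

    def table(rows: np.ndarray, group: str) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": idx[rows],
                "species": species,
                "x": x[rows],
                "y": y[rows],
                "location": group,
            }
        )

    def nearest(d: np.ndarray, k: int, exclude=()) -> np.ndarray:
        order = np.argsort(d, kind="stable")
        order = order[~np.isin(order, exclude)]
        if order.size < k:
            raise ValueError(
                f"requested {k} individuals, only {order.size} available"
            )
        return order[:k]

    edge_coord = {
        "left": lambda: x - region.x0,
        "right": lambda: region.x1 - x,
        "bottom": lambda: y - region.y0,
        "top": lambda: region.y1 - y,
    }
    if scheme == "random":
        if n > idx.size:
            raise ValueError(
                f"requested {n} individuals, only {idx.size} alive"
            )
        rows = rng.choice(idx.size, size=n, replace=False)
        return table(rows, "random")
    if scheme == "center":
        cx, cy = region.center
        d = np.hypot(x - cx, y - cy)
        return table(nearest(d, n), "center")
    if scheme == "edge":
        if edge not in edge_coord:
            raise ValueError(f"edge must be one of {sorted(edge_coord)}")
        return table(nearest(edge_coord[edge](), n), edge)
    if scheme == "three_location":
        left = nearest(edge_coord["left"](), n)
        right = nearest(edge_coord["right"](), n, exclude=left)
        cx, cy = region.center
        d = np.hypot(x - cx, y - cy)
        center = nearest(d, n, exclude=np.concatenate([left, right]))
        return pd.concat(
            [table(left, "edge1"), table(right, "edge2"),
             table(center, "center")],
            ignore_index=True,
        )
    raise ValueError(f"unknown sampling scheme {scheme!r}")
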