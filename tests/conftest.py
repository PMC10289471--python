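import numpy as np
import pandas as pd
import pytest

from spacephylo.spatial_sim import (
    PedigreeArchive,
    Rect,
    Schedule,
    SimulationConfig,
    _GenRecord,
    run_simulation,
)


def make_state(coords, species=None, config=None):
    """Build a PopulationState from a list of (x, y) coordinates."""
    from spacephylo.spatial_sim import PopulationState

    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if species is None:
        species = np.zeros(n, dtype=np.int16)
    cfg = config or SimulationConfig(
        range_width=20, range_height=20, n_generations=10, seed=0
    )
    return PopulationState(
        generation=0,
        x=coords[:, 0],
        y=coords[:, 1],
        species=np.asarray(species, dtype=np.int16),
        parent1=np.full(n, -1, dtype=np.int32),
        parent2=np.full(n, -1, dtype=np.int32),
        species_labels=["A"],
        regions={"A": cfg.full_range},
    )


def hand_archive(generations, n_generations=None):
    """Build a PedigreeArchive from explicit per-generation rows.

    ``generations`` is a list of lists of (x, y, species, p1, p2).
    """
    recs = []
    for rows in generations:
        rows = list(rows)
        recs.append(
            _GenRecord(
                x=np.array([r[0] for r in rows], dtype=np.float32),
                y=np.array([r[1] for r in rows], dtype=np.float32),
                species=np.array([r[2] for r in rows], dtype=np.int16),
                parent1=np.array([r[3] for r in rows], dtype=np.int32),
                parent2=np.array([r[4] for r in rows], dtype=np.int32),
            )
        )
    cfg = SimulationConfig(
        range_width=10, range_height=10, n_generations=len(recs) - 1, seed=0
    )
    return PedigreeArchive(
        config=cfg,
        schedule=Schedule(),
        species_labels=["A"],
        species_parent={},
        generations=recs,
        final_regions={"A": Rect(0, 0, 10, 10)},
        founding_count=len(generations[0]),
    )


def sample_rows(archive, ids):
    rec = archive.final()
    return pd.DataFrame(
        {
            "id": ids,
            "species": [archive.species_labels[rec.species[i]] for i in ids],
            "x": rec.x[ids].astype(float),
            "y": rec.y[ids].astype(float),
        }
    )


@pytest.fixture(scope="session")
def unclustered_archive():
    """A modest single-species unclustered run shared across tests."""
    cfg = SimulationConfig(
        range_width=12,
        range_height=5,
        n_generations=300,
        seed=42,
        preset="unclustered",
        target_density=5,
    )
    return run_simulation(cfg)


@pytest.fixture(scope="session")
def three_taxon_archive():
    """A small 3-taxon vicariance run (unclustered)."""
    from spacephylo.spatial_sim import comb_vicariance_schedule

    cfg = SimulationConfig(
        range_width=12,
        range_height=5,
        n_generations=300,
        seed=7,
        preset="unclustered",
        target_density=5,
    )
    schedule = comb_vicariance_schedule(cfg, [120, 60])
    return run_simulation(cfg, schedule)
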