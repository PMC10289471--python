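"""Spatial simulator: kernels, regulation, speciation events, sampling."""

import math

import numpy as np
import pandas as pd
import pytest

from spacephylo.spatial_sim import (
    ExtinctionError,
    Rect,
    Schedule,
    SimulationConfig,
    SpeciationEvent,
    apply_speciation_event,
    comb_peripatry_schedule,
    comb_vicariance_schedule,
    init_population,
    interaction_density,
    run_simulation,
    sample_individuals,
    six_taxon_comb_times,
    step_generation,
)

from conftest import make_state


def cfg(**kw):
    base = dict(
        range_width=10, range_height=10, n_generations=10, seed=1,
        sigma_I=1.0, sigma_D=1.0,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestInitPopulation:
    def test_founder_count_is_density_times_area(self):
        state = init_population(cfg(target_density=1.0))
        assert state.n == 100
        assert state.generation == 0
        assert len(set(state.species)) == 1

    def test_peripatric_founding_region_confines_founders(self):
        c = cfg(range_width=20, target_density=1.0)
        state = init_population(c, founding_region=Rect(0, 0, 10, 10))
        assert state.n == 100
        assert np.all(state.x < 10)

    def test_same_seed_reproduces_founder_coordinates(self):
        a = init_population(cfg())
        b = init_population(cfg())
        np.testing.assert_array_equal(a.x, b.x)
        np.testing.assert_array_equal(a.y, b.y)

    def test_invalid_scales_rejected(self):
        with pytest.raises(ValueError):
            cfg(sigma_D=-1)
        with pytest.raises(ValueError, match="6\\*sigma_I"):
            cfg(sigma_I=2.0)  # range dims must exceed 6 sigma_I


class TestInteractionDensity:
    def test_isolated_individual_sees_zero(self):
        state = make_state([(5, 5)])
        assert interaction_density(state, cfg(), 0) == 0.0

    def test_coincident_neighbor_gives_kernel_maximum(self):
        state = make_state([(5, 5), (5, 5)])
        d = interaction_density(state, cfg(sigma_I=1.0), 0)
        assert d == pytest.approx(1.0 / (2 * math.pi), rel=1e-12)

    def test_neighbor_beyond_3_sigma_truncated(self):
        state = make_state([(5, 5), (5 + 3.01, 5)])
        assert interaction_density(state, cfg(sigma_I=1.0), 0) == 0.0

    def test_other_species_do_not_contribute(self):
        state = make_state([(5, 5), (5.1, 5)], species=[0, 1])
        state.species_labels = ["A", "B"]
        state.regions = {"A": Rect(0, 0, 10, 10), "B": Rect(0, 0, 10, 10)}
        assert interaction_density(state, cfg(), 0) == 0.0

    def test_uniform_field_matches_truncated_kernel_mass(self):
        # oracle: D of a central individual in a uniform field of density
        # rho is rho * (1 - exp(-9/2)) (mass of the truncated kernel)
        rho = 40.0
        rng = np.random.default_rng(0)
        c = cfg(range_width=14, range_height=14, sigma_I=1.0)
        vals = []
        for _ in range(40):
            n = rng.poisson(rho * 14 * 14)
            pts = np.column_stack(
                [rng.uniform(0, 14, n), rng.uniform(0, 14, n)]
            )
            pts = np.vstack([[7.0, 7.0], pts])
            state = make_state(pts, config=c)
            vals.append(interaction_density(state, c, 0))
        expected = rho * (1 - math.exp(-4.5))
        assert np.mean(vals) == pytest.approx(expected, rel=0.02)


class TestStepGeneration:
    def test_lone_individual_goes_extinct_without_mate(self):
        state = make_state([(5, 5)])
        with pytest.raises(ExtinctionError):
            step_generation(state, cfg(), np.random.default_rng(0))

    def test_displacements_bounded_by_3_sigma_d(self):
        # central cluster far from edges: no reflection can occur
        c = cfg(range_width=30, range_height=30, sigma_D=0.5, sigma_M=3.0)
        pts = [(15 + dx, 15 + dy) for dx in range(-2, 3) for dy in range(-2, 3)]
        state = make_state(pts, config=c)
        state.regions = {"A": c.full_range}
        new = step_generation(state, c, np.random.default_rng(1))
        for i in range(new.n):
            p = new.parent1[i]
            assert abs(new.x[i] - state.x[p]) <= 3 * c.sigma_D + 1e-12
            assert abs(new.y[i] - state.y[p]) <= 3 * c.sigma_D + 1e-12

    def test_no_selfing(self, unclustered_archive):
        for rec in unclustered_archive.generations[1:]:
            assert np.all(rec.parent1 != rec.parent2)

    def test_parents_exist_and_share_species(self, unclustered_archive):
        gens = unclustered_archive.generations
        for g in range(1, len(gens)):
            prev, rec = gens[g - 1], gens[g]
            assert np.all(rec.parent1 >= 0) and np.all(rec.parent1 < prev.x.size)
            assert np.all(rec.parent2 >= 0) and np.all(rec.parent2 < prev.x.size)
            np.testing.assert_array_equal(
                prev.species[rec.parent1], rec.species
            )
            np.testing.assert_array_equal(
                prev.species[rec.parent2], rec.species
            )

    def test_census_settles_near_target_density(self):
        # emergent equilibrium ~= D* * area under the fecundity regulation
        means = []
        for seed in (1, 2, 3):
            c = SimulationConfig(
                range_width=20, range_height=20, n_generations=400,
                seed=seed, preset="unclustered", target_density=1.0,
            )
            arc = run_simulation(c)
            means.append(arc.census()[100:].mean())
        assert abs(np.mean(means) - 400) / 400 < 0.25

    def test_unclustered_mating_is_near_random_within_radius(self):
        # among available candidates, mate choice should look like the
        # Gaussian-weighted uniform expectation, not strong localisation:
        # P(mate within 3*sigma_I) ~ integral of w(d) * 2 pi d over [0,1.5]
        # normalised on [0, 3]
        c = SimulationConfig(
            range_width=20, range_height=20, n_generations=30, seed=5,
            preset="unclustered", target_density=5.0,
        )
        arc = run_simulation(c)
        frac = []
        for g in range(10, 31):
            rec, prev = arc.state(g), arc.state(g - 1)
            d = np.hypot(
                prev.x[rec.parent1] - prev.x[rec.parent2],
                prev.y[rec.parent1] - prev.y[rec.parent2],
            )
            frac.append(np.mean(d <= 3 * c.sigma_I))
        s2 = c.sigma_M**2
        r_in, r_out = 3 * c.sigma_I, 3 * c.sigma_M
        expected = (1 - math.exp(-(r_in**2) / (2 * s2))) / (
            1 - math.exp(-(r_out**2) / (2 * s2))
        )
        assert np.mean(frac) == pytest.approx(expected, abs=0.05)


class TestSpeciationEvents:
    def test_vicariance_conserves_individuals(self, three_taxon_archive):
        arc = three_taxon_archive
        assert sorted(arc.species_at_final()) == ["A", "B", "C"]
        # at the first split generation the two children partition the parent
        split1 = 300 - 120
        total = arc.census("AB")[split1] + arc.census("C")[split1]
        assert total == arc.census()[split1]
        assert arc.census("AB")[split1] > 0 and arc.census("C")[split1] > 0

    def test_no_mating_across_barrier_after_vicariance(
        self, three_taxon_archive
    ):
        arc = three_taxon_archive
        code = {l: i for i, l in enumerate(arc.species_labels)}
        for g in range(300 - 120 + 1, 301):
            prev, rec = arc.state(g - 1), arc.state(g)
            # both parents of every child belong to the same species
            np.testing.assert_array_equal(
                prev.species[rec.parent1], prev.species[rec.parent2]
            )
        # species ranges stay on their side of the barriers
        final = arc.final()
        assert final.x[final.species == code["C"]].min() >= 8.0 - 1e-6
        assert final.x[final.species == code["A"]].max() <= 4.0 + 1e-6
        b = final.x[final.species == code["B"]]
        assert b.min() >= 4.0 - 1e-6 and b.max() <= 8.0 + 1e-6

    def test_peripatry_shares_range_before_seal(self):
        c = SimulationConfig(
            range_width=12, range_height=5, n_generations=120, seed=3,
            preset="unclustered", target_density=5,
        )
        sch = comb_peripatry_schedule(c, [40, 20], expansion_lag=10)
        arc = run_simulation(c, sch)
        # between expansion and seal one label occupies both strips
        e1 = sch.events[0]
        rec = arc.state(e1.time + 5)
        code = arc.species_labels.index("ABC")
        xs = rec.x[rec.species == code]
        assert xs.min() < e1.position < xs.max()
        assert sorted(arc.species_at_final()) == ["A", "B", "C"]

    def test_event_errors(self):
        state = make_state([(2, 2), (3, 3)])
        ev = SpeciationEvent(
            time=0, mode="vicariance", parent="A",
            child_labels=("A1", "A2"), axis="x", position=8.0,
        )
        with pytest.raises(Exception, match="empty"):
            apply_speciation_event(state, ev)
        with pytest.raises(Exception, match="increasing"):
            Schedule(events=[
                SpeciationEvent(5, "vicariance", "A", ("B", "C"), "x", 1.0),
                SpeciationEvent(5, "vicariance", "B", ("D", "E"), "x", 0.5),
            ])


class TestRunSimulation:
    def test_empty_schedule_keeps_single_species(self, unclustered_archive):
        assert unclustered_archive.species_at_final() == ["A"]
        assert unclustered_archive.status == "completed"

    def test_two_events_give_three_terminal_species(
        self, three_taxon_archive
    ):
        assert len(three_taxon_archive.species_at_final()) == 3

    def test_six_taxon_builder_times(self):
        assert six_taxon_comb_times() == [45000, 35000, 25000, 15000, 5000]
        assert six_taxon_comb_times(scale=0.01) == [450, 350, 250, 150, 50]
        c = SimulationConfig(
            range_width=24, range_height=5, n_generations=500, seed=1,
            preset="unclustered",
        )
        sch = comb_vicariance_schedule(c, six_taxon_comb_times(scale=0.01))
        assert sch.n_terminal_species == 6
        assert sch.root_label == "ABCDEF"
        # deepest event splits off the last taxon, high side
        assert sch.events[0].child_labels == ("ABCDE", "F")

    def test_identical_config_gives_byte_identical_archive(self):
        c = SimulationConfig(
            range_width=10, range_height=5, n_generations=60, seed=9,
            preset="clustered", target_density=5,
        )
        sch = comb_vicariance_schedule(c, [30, 15])
        assert run_simulation(c, sch).checksum() == run_simulation(
            c, sch
        ).checksum()


class TestSampling:
    def test_three_location_returns_three_clusters(self, unclustered_archive):
        rng = np.random.default_rng(0)
        s = sample_individuals(unclustered_archive, "A", "three_location", 5, rng)
        assert len(s) == 15
        assert sorted(s["location"].unique()) == ["center", "edge1", "edge2"]
        assert s["id"].is_unique
        left = s[s.location == "edge1"].x.max()
        right = s[s.location == "edge2"].x.min()
        assert left < right

    def test_random_with_full_population_returns_everyone(
        self, unclustered_archive
    ):
        n = int(unclustered_archive.census()[-1])
        rng = np.random.default_rng(0)
        s = sample_individuals(unclustered_archive, "A", "random", n, rng)
        assert len(s) == n
        with pytest.raises(ValueError, match="only"):
            sample_individuals(unclustered_archive, "A", "random", n + 1, rng)

    def test_center_sampling_is_closer_than_random(self, unclustered_archive):
        rng = np.random.default_rng(1)
        center = sample_individuals(unclustered_archive, "A", "center", 10, rng)
        rand = sample_individuals(unclustered_archive, "A", "random", 10, rng)
        cx, cy = unclustered_archive.final_regions["A"].center
        d = lambda t: np.hypot(t.x - cx, t.y - cy).mean()
        assert d(center) <= d(rand)

    def test_archive_save_load_roundtrip(self, unclustered_archive, tmp_path):
        from spacephylo.spatial_sim import PedigreeArchive

        unclustered_archive.save(tmp_path / "arc")
        loaded = PedigreeArchive.load(tmp_path / "arc")
        assert loaded.checksum() == unclustered_archive.checksum()
        assert loaded.species_labels == unclustered_archive.species_labels
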