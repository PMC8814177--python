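"""Perception, binding, the reaction automaton and the tick scheduler."""

import dataclasses

import numpy as np
import pytest

from cytoabm import engine, fixtures, observables
from cytoabm.engine import (BindingModel, ConfigurationError,
                            SimulationConfig, World, perception_radius)
from cytoabm.model_io import PathwayModel, ReactionSpec, SpeciesSpec
from cytoabm.physics import EnvironmentParams, radius_from_mass


def micro_model(side=300.0, n_s=1, n_e=1, kcat=100.0, reversible=False,
                substrates=(("S", 1),), products=(("P", 1),),
                extra_species=()):
    env = EnvironmentParams(side=side)
    from cytoabm.model_io import count_to_concentration as c2c

    species = [
        SpeciesSpec(id="E", role="enzyme", molecular_weight=54000.0,
                    initial_concentration=c2c(n_e, env.volume)),
        SpeciesSpec(id="S", molecular_weight=220.0,
                    initial_concentration=c2c(n_s, env.volume)),
        SpeciesSpec(id="P", molecular_weight=220.0, initial_concentration=0.0),
    ]
    species += list(extra_species)
    model = PathwayModel(
        species=tuple(species),
        reactions=(ReactionSpec(id="R", enzyme_species="E",
                                substrates=substrates, products=products,
                                reversible=reversible, kcat=kcat),),
        environment=env)
    model.validate()
    return model


def micro_config(model, distance=None, seed=0, duration=0.01, law="uniform",
                 **kw):
    env = model.environment
    if distance is None:
        distance = 2 * env.side  # covers the whole box diagonal
    return SimulationConfig(
        binding=BindingModel(distance=distance, law=law), duration=duration,
        seed=seed, record_every=1, env=env, **kw)


class TestPerceptionRadius:
    def test_sum_of_enzyme_radius_and_distance(self):
        assert perception_radius(25.0, 300.0) == 325.0
        assert perception_radius(25.0, 0.0) == 25.0

    def test_larger_enzyme_larger_sphere(self):
        assert perception_radius(30.0, 10.0) > perception_radius(25.0, 10.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            perception_radius(25.0, -1.0)


class TestBindingModel:
    def test_certain_at_contact_zero_beyond_cutoff(self):
        for law in ("cubic", "sextic", "uniform"):
            b = BindingModel(distance=300.0, law=law)
            assert b.probability(0.0) == 1.0
            assert b.probability(5.0) == 1.0
            assert b.probability(300.1) == 0.0

    def test_nonincreasing(self):
        b = BindingModel(distance=300.0, law="cubic")
        s = np.linspace(0.1, 300.0, 200)
        p = np.array([b.probability(x) for x in s])
        assert np.all(np.diff(p) <= 1e-15)

    def test_cubic_decay(self):
        b = BindingModel(distance=300.0)
        assert b.probability(10.0) == pytest.approx((5 / 10) ** 3)
        assert b.probability(50.0) == pytest.approx((5 / 50) ** 3)

    def test_bad_configuration_rejected(self):
        with pytest.raises(ConfigurationError):
            BindingModel(distance=-1.0)
        with pytest.raises(ConfigurationError):
            BindingModel(distance=10.0, law="quartic")
        with pytest.raises(ConfigurationError):
            BindingModel(distance=10.0, mode="greedy")


class TestPerceive:
    def test_matches_brute_force_filter(self):
        model = micro_model(side=500.0, n_s=40)
        config = micro_config(model, distance=120.0)
        world = World(model, config)
        (enz,) = [int(a) for a in world.index.live_ids()
                  if world.agent_kind[a] == engine.KIND_ENZYME]
        ids, surface = world.perceive(enz)
        # brute force: every free S metabolite within surface distance d
        expect = {}
        for aid in world.index.live_ids():
            aid = int(aid)
            if world.agent_kind[aid] != engine.KIND_METABOLITE:
                continue
            if world.species_list[world.agent_species[aid]].id != "S":
                continue
            dist = float(np.linalg.norm(world.index.pos[aid]
                                        - world.index.pos[enz]))
            s = dist - world.index.radius[enz] - world.index.radius[aid]
            if s <= 120.0:
                expect[aid] = s
        assert dict(zip(ids.tolist(), surface.tolist())) == pytest.approx(
            expect)

    def test_no_cognate_in_range_is_empty(self):
        model = micro_model(side=1000.0, n_s=1)
        config = micro_config(model, distance=0.0)
        world = World(model, config)
        (enz,) = [int(a) for a in world.index.live_ids()
                  if world.agent_kind[a] == engine.KIND_ENZYME]
        ids, _ = world.perceive(enz)
        assert len(ids) == 0

    def test_boundary_is_closed_ball(self):
        model = micro_model(side=500.0, n_s=1)
        config = micro_config(model, distance=100.0)
        world = World(model, config)
        enz, met = None, None
        for aid in world.index.live_ids():
            aid = int(aid)
            if world.agent_kind[aid] == engine.KIND_ENZYME:
                enz = aid
            elif world.species_list[world.agent_species[aid]].id == "S":
                met = aid
        # put the metabolite at surface distance exactly d
        gap = world.index.radius[enz] + world.index.radius[met] + 100.0
        world.index.move(met, world.index.pos[enz] + np.array([gap, 0, 0]))
        ids, surface = world.perceive(enz)
        assert ids.tolist() == [met]
        assert surface[0] == pytest.approx(100.0)


class TestSelectAndBind:
    def test_single_candidate_at_contact_always_bound(self):
        for seed in range(20):
            model = micro_model(side=200.0, n_s=1)
            world = World(model, micro_config(model, distance=5.0, seed=seed,
                                              law="cubic"))
            enz, met = None, None
            for aid in world.index.live_ids():
                aid = int(aid)
                if world.agent_kind[aid] == engine.KIND_ENZYME:
                    enz = aid
                elif world.species_list[world.agent_species[aid]].id == "S":
                    met = aid
            gap = world.index.radius[enz] + world.index.radius[met] + 4.0
            world.index.move(met, world.index.pos[enz]
                             + np.array([gap, 0, 0.0]))
            ids, surface = world.perceive(enz)
            assert world.select_and_bind(enz, ids, surface) == met

    def test_empty_candidates_bind_nothing(self):
        model = micro_model()
        world = World(model, micro_config(model))
        (enz,) = [int(a) for a in world.index.live_ids()
                  if world.agent_kind[a] == engine.KIND_ENZYME]
        assert world.select_and_bind(
            enz, np.empty(0, dtype=np.intp), np.empty(0)) is None
        assert not world.automata

    def test_equidistant_candidates_picked_uniformly(self):
        # two cognates at the same surface distance: each should be bound
        # first about half of the time (binomial 3 sigma band)
        n_trials, first_a = 4000, 0
        model = micro_model(side=400.0, n_s=2)
        config = micro_config(model, distance=400.0)
        base = World(model, config)
        for seed in range(n_trials):
            world = World(model, config, rng=np.random.default_rng(seed))
            enz = None
            mets = []
            for aid in world.index.live_ids():
                aid = int(aid)
                if world.agent_kind[aid] == engine.KIND_ENZYME:
                    enz = aid
                elif world.species_list[world.agent_species[aid]].id == "S":
                    mets.append(aid)
            gap = world.index.radius[enz] + world.index.radius[mets[0]] + 50.0
            world.index.move(mets[0], world.index.pos[enz]
                             + np.array([gap, 0, 0.0]))
            world.index.move(mets[1], world.index.pos[enz]
                             + np.array([-gap, 0, 0.0]))
            ids, surface = world.perceive(enz)
            bound = world.select_and_bind(enz, ids, surface)
            if bound == min(mets):
                first_a += 1
        p = first_a / n_trials
        assert abs(p - 0.5) < 3 * 0.5 / np.sqrt(n_trials)

    def test_specificity_mode_requires_km(self):
        model = micro_model()
        config = SimulationConfig(
            binding=BindingModel(distance=100.0, law="uniform",
                                 mode="specificity"),
            duration=0.01, seed=0, env=model.environment)
        with pytest.raises(ConfigurationError, match="Km"):
            World(model, config)


class TestFormOrExtendComplex:
    def _bound_world(self, kcat, n_s=1):
        model = micro_model(side=300.0, n_s=n_s, kcat=kcat)
        world = World(model, micro_config(model, seed=3))
        enz, met = None, None
        for aid in world.index.live_ids():
            aid = int(aid)
            if world.agent_kind[aid] == engine.KIND_ENZYME:
                enz = aid
            elif (world.species_list[world.agent_species[aid]].id == "S"
                  and met is None):
                met = aid
        world.form_or_extend_complex(enz, met)
        return world, enz

    @pytest.mark.parametrize("kcat, expected_wait", [
        (100.0, 100),    # (1/100 s) / 1e-4 s
        (1.0, 10000),
        (1e6, 1),        # faster than a tick floors at one
    ])
    def test_wait_ticks_from_kcat(self, kcat, expected_wait):
        world, enz = self._bound_world(kcat)
        assert world.automata[enz].saturated
        assert world.automata[enz].wait_ticks == expected_wait

    def test_single_substrate_complex_immediately_saturated(self):
        world, enz = self._bound_world(100.0)
        st = world.automata[enz]
        assert st.saturated and st.direction == "forward"
        assert world.agent_kind[enz] == engine.KIND_COMPLEX

    def test_complex_radius_volume_additive(self):
        world, enz = self._bound_world(100.0)
        r_e = radius_from_mass(54000.0)
        r_m = radius_from_mass(220.0)
        assert world.index.radius[enz] == pytest.approx(
            (r_e**3 + r_m**3) ** (1 / 3))

    def test_first_bound_metabolite_fixes_direction(self):
        # reversible A <-> B, world initially holds only B: binding B must
        # start the reverse direction
        model, config = fixtures.toy_reversible_pair(n_a=0, n_each=10)
        world = World(model, config)
        world.tick()
        assert world.automata
        assert all(st.direction == "reverse"
                   for st in world.automata.values())


class TestReleaseProducts:
    def test_aldolase_like_split_creates_both_products(self):
        # E + S -> DHAP-like + GAP-like: one release must create one of
        # each and consume the single substrate
        model = micro_model(
            side=300.0, n_s=1, kcat=1e6,
            products=(("P", 1), ("Q", 1)),
            extra_species=(SpeciesSpec(id="Q", molecular_weight=220.0,
                                       initial_concentration=0.0),))
        world = World(model, micro_config(model, seed=1))
        for _ in range(10):
            world.tick()
            if world.completed[("R", "forward")]:
                break
        assert world.completed[("R", "forward")] == 1
        assert world.count_free("S") == 0
        assert world.count_free("P") == 1
        assert world.count_free("Q") == 1
        assert world.count_free("E") == 1
        assert world.check_conservation()

    def test_release_ledger_over_many_events(self):
        model = micro_model(side=1000.0, n_s=200, kcat=1e6)
        world = World(model, micro_config(model, seed=2, duration=0.05))
        for _ in range(500):
            world.tick()
        n = world.completed[("R", "forward")]
        assert n > 50
        assert world.count_free("P") == n
        assert world.count_free("S") + n + sum(
            st.bound.total() for st in world.automata.values()) == 200
        assert world.check_conservation()


class TestStepScheduler:
    def test_metabolites_alone_are_inert(self):
        model = micro_model(n_e=0, n_s=30)
        world = World(model, micro_config(model))
        before = world.free_counts.copy()
        for _ in range(50):
            world.tick()
        assert np.array_equal(world.free_counts, before)

    def test_two_agent_schedule_hand_traced(self):
        """Single enzyme + single substrate with a box-covering perception
        sphere: the substrate is bound in the first tick's binding phase and
        the product appears exactly wait_ticks later."""
        model = micro_model(side=300.0, n_s=1, kcat=100.0)  # wait = 100
        world = World(model, micro_config(model, seed=5))
        world.tick()
        assert world.automata and world.count_free("S") == 0  # bound at t=1
        for t in range(2, 100):
            world.tick()
            assert world.completed[("R", "forward")] == 0
        world.tick()   # tick 100: countdown reaches zero, product released
        assert world.completed[("R", "forward")] == 1
        assert world.count_free("P") == 1

    def test_fixed_seed_reproduces_trajectory(self):
        model, config = fixtures.toy_single_reaction(n_substrate=50)
        config = dataclasses.replace(config, duration=0.01)
        s1, w1 = engine.run(model, config)
        s2, w2 = engine.run(model, config)
        assert np.array_equal(s1.times, s2.times)
        for sp in s1.species():
            assert np.array_equal(s1.get(sp), s2.get(sp))
        assert np.array_equal(w1.index.pos[w1.index.live_ids()],
                              w2.index.pos[w2.index.live_ids()])

    def test_duration_zero_records_only_initial_snapshot(self):
        model, config = fixtures.toy_single_reaction(n_substrate=10)
        config = dataclasses.replace(config, duration=0.0)
        series, _ = engine.run(model, config)
        assert len(series.times) == 1 and series.times[0] == 0.0

    def test_irreversible_reaction_never_runs_backwards(self):
        model, config = fixtures.toy_reversible_pair(reversible=False,
                                                     n_a=0, n_each=40)
        config = dataclasses.replace(config, duration=0.05)
        series, world = engine.run(model, config)
        assert world.completed[("RAB", "reverse")] == 0
        assert world.count_free("A") == 0          # no A ever produced
        assert not world.automata                  # B is never even bound

    def test_reversible_pair_relaxes_toward_balance(self):
        model, config = fixtures.toy_reversible_pair(n_a=120, n_each=0)
        config = dataclasses.replace(config, duration=0.5)
        series, world = engine.run(model, config)
        a, b = world.count_free("A"), world.count_free("B")
        assert b > 0
        assert 0.25 < a / (a + b) < 0.75   # fluctuates around 1:1

    def test_unbinding_timeout_dissociates_stuck_complexes(self):
        # two-substrate reaction with the co-substrate absent: the partial
        # complex must give its metabolite back after the timeout
        model = micro_model(
            side=300.0, n_s=5,
            substrates=(("S", 1), ("C", 1)),
            extra_species=(SpeciesSpec(id="C", molecular_weight=300.0,
                                       initial_concentration=0.0),))
        world = World(model, micro_config(model, seed=1,
                                          unbinding_timeout=5))
        world.tick()
        assert world.automata      # S bound, waiting for C forever
        dissociated = False
        for _ in range(12):
            world.tick()
            if not world.automata:
                dissociated = True   # metabolite handed back (may re-bind)
        assert dissociated
        assert world.count_free("S") + sum(
            st.bound.total() for st in world.automata.values()) == 5
        assert world.check_conservation()

    def test_conservation_on_random_pathways(self):
        for seed in range(10):
            model = fixtures.random_pathway(n_species=5, n_reactions=3,
                                            seed=seed)
            config = SimulationConfig(
                binding=BindingModel(distance=500.0, law="cubic"),
                duration=0.005, seed=seed, record_every=10,
                env=model.environment)
            series, world = engine.run(model, config)
            assert world.check_conservation(raise_on_error=True)


class TestCheckpointing:
    def test_snapshot_resume_reproduces_trajectory(self):
        model, config = fixtures.toy_single_reaction(n_substrate=60)
        config = dataclasses.replace(config, duration=0.02)
        # straight-through run
        s_full, w_full = engine.run(model, config)
        # run half, snapshot, resume
        w = World(model, config)
        for _ in range(100):
            w.tick()
        snap = w.to_snapshot()
        import json

        snap = json.loads(json.dumps(snap))   # through-JSON fidelity
        w2 = World.from_snapshot(model, config, snap)
        for _ in range(100):
            w.tick()
            w2.tick()
        assert np.array_equal(w.index.pos[w.index.live_ids()],
                              w2.index.pos[w2.index.live_ids()])
        assert w.completed == w2.completed
        assert np.array_equal(w.free_counts, w2.free_counts)
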