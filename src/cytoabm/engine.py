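"""The agent layer: perception-sphere binding, reaction automata, tick loop.

Each molecule is a reactive agent of the classic 6-tuple form
⟨E, Per, Ac, see, action, do⟩: it observes the environment within its
perception sphere (*see*), selects an action (*action*) and applies it
(*do*).  Metabolites only move; enzymes and complexes also act: an enzyme
projects a perception sphere of radius (own radius + perception distance d)
and probabilistically binds cognate metabolites that enter it, building up a
complex one substrate at a time.  A saturated complex waits 1/kcat seconds
(in ticks) and then releases the reaction products, restoring the free
enzyme.  One master RNG drives every stochastic choice, so a run is a pure
function of (model, config, seed).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np

from . import observables as obs
from .constants import CONTACT_CERTAIN_DISTANCE
from .model_io import PathwayModel, ReactionSpec, concentration_to_count
from .physics import (EnvironmentParams, diffusion_coefficient,
                      radius_from_mass, random_unit_vector, step_length)
from .space import Box, SpatialIndex, place_sphere, propose_move, try_commit_move

KIND_METABOLITE = 0
KIND_ENZYME = 1
KIND_COMPLEX = 2

_KIND_NAMES = {KIND_METABOLITE: "metabolite", KIND_ENZYME: "enzyme",
               KIND_COMPLEX: "complex"}


class ConfigurationError(ValueError):
    pass


# --------------------------------------------------------------------------
# Binding model
# --------------------------------------------------------------------------

def _law_cubic(s: float) -> float:
    return min(1.0, (CONTACT_CERTAIN_DISTANCE / s) ** 3)


def _law_sextic(s: float) -> float:
    return min(1.0, (CONTACT_CERTAIN_DISTANCE / s) ** 6)


def _law_uniform(s: float) -> float:
    return 1.0


BINDING_LAWS = {"cubic": _law_cubic, "sextic": _law_sextic,
                "uniform": _law_uniform}


@dataclass(frozen=True)
class BindingModel:
    """Perception distance and distance→probability law (one per simulation).

    ``distance`` is the perception distance d in Å beyond the enzyme surface;
    the perception radius of an enzyme is its own radius + d.  The law maps
    the surface-to-surface distance s to a binding probability per tick:
    certain for s ≤ 5 Å, non-increasing in s, zero beyond d.  The default
    ``cubic`` law decays as 1/s³, mirroring the resonant long-range potential
    U(r) ~ r⁻³ that the long-distance regime abstracts; ``sextic`` (1/s⁶,
    van der Waals-like) and ``uniform`` ship for comparison.

    ``mode`` is "random" (candidates tried in uniformly random order) or
    "specificity" (candidates ranked by kcat/Km before the same trials).
    """

    distance: float
    law: str = "cubic"
    mode: str = "random"

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ConfigurationError("perception distance must be >= 0")
        if isinstance(self.law, str) and self.law not in BINDING_LAWS:
            raise ConfigurationError(
                f"unknown binding law {self.law!r}; "
                f"choose from {sorted(BINDING_LAWS)}")
        if self.mode not in ("random", "specificity"):
            raise ConfigurationError(f"unknown binding mode {self.mode!r}")

    def probability(self, s: float) -> float:
        """Binding probability for a candidate at surface distance ``s`` Å."""
        if s > self.distance:
            return 0.0
        if s <= CONTACT_CERTAIN_DISTANCE:
            return 1.0
        law = BINDING_LAWS[self.law] if isinstance(self.law, str) else self.law
        return law(s)


def perception_radius(enzyme_radius: float, distance: float) -> float:
    """Perception-sphere radius: enzyme radius + perception distance (Å)."""
    if distance < 0:
        raise ValueError("perception distance must be >= 0")
    return enzyme_radius + distance


# --------------------------------------------------------------------------
# Configuration and automaton state
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationConfig:
    binding: BindingModel
    duration: float = 1.0          # s
    seed: int = 0
    record_every: int = 100        # ticks
    env: EnvironmentParams = field(default_factory=EnvironmentParams)
    step_policy: str = "fold"      # "fold" | "reject"
    move_retries: int = 5
    gaussian_steps: bool = False
    msd_3d: bool = False
    #: partial complexes dissociate after this many ticks without saturating;
    #: None (default) disables unbinding entirely.
    unbinding_timeout: int | None = None
    validate_every: int = 0        # ticks between debug invariant checks

    def __post_init__(self) -> None:
        if self.record_every < 1:
            raise ConfigurationError("record_every must be >= 1")
        if self.duration < 0:
            raise ConfigurationError("duration must be >= 0")
        if self.step_policy not in ("fold", "reject"):
            raise ConfigurationError(f"unknown step policy {self.step_policy!r}")
        n = self.duration / self.env.tick
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"duration {self.duration} s is not a whole number of "
                f"{self.env.tick} s ticks")

    @property
    def n_ticks(self) -> int:
        return int(round(self.duration / self.env.tick))


@dataclass
class ComplexAutomatonState:
    """Per-complex reaction automaton: which substrates are bound, the fixed
    direction, and the release countdown once saturated."""

    reaction: str
    direction: str                     # "forward" | "reverse"
    bound: Counter = field(default_factory=Counter)   # species idx -> n
    saturated: bool = False
    wait_ticks: int = 0
    release_pending: bool = False
    ticks_partial: int = 0


@dataclass(frozen=True)
class AgentState:
    """Read-only snapshot of one agent (introspection / export)."""

    id: int
    species: str
    kind: str
    position: np.ndarray
    radius: float
    automaton: ComplexAutomatonState | None = None

    @property
    def wait_ticks(self) -> int:
        return self.automaton.wait_ticks if self.automaton else 0


# --------------------------------------------------------------------------
# World
# --------------------------------------------------------------------------

class World:
    """Mutable simulation state: spatial index + agent attributes + ledger."""

    def __init__(self, model: PathwayModel, config: SimulationConfig,
                 rng: np.random.Generator | None = None):
        model.validate(strict=True)
        self.model = model
        self.config = config
        env = config.env
        self.env = env
        self.box = Box(env.side)
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.tick_index = 0

        self.species_list = list(model.species)
        self.sp_index = {s.id: i for i, s in enumerate(self.species_list)}
        n_sp = len(self.species_list)
        self.sp_radius = np.array(
            [radius_from_mass(s.molecular_weight) for s in self.species_list])
        self._step_by_radius: dict[float, float] = {}

        # reaction tables
        self.reactions = {r.id: r for r in model.reactions}
        self.required: dict[tuple[str, str], Counter] = {}
        self.net_stoich: dict[tuple[str, str], dict[int, int]] = {}
        self.enzyme_options: dict[int, dict[int, list[tuple[str, str]]]] = {}
        for r in model.reactions:
            e = self.sp_index[r.enzyme_species]
            options = self.enzyme_options.setdefault(e, {})
            dirs = ("forward", "reverse") if r.reversible else ("forward",)
            for direction in dirs:
                subs = r.side(direction, "substrates")
                prods = r.side(direction, "products")
                key = (r.id, direction)
                self.required[key] = Counter(
                    {self.sp_index[sp]: 0 for sp, _ in subs})
                for sp, n in subs:
                    self.required[key][self.sp_index[sp]] += n
                net: dict[int, int] = {}
                for sp, n in subs:
                    net[self.sp_index[sp]] = net.get(self.sp_index[sp], 0) - n
                for sp, n in prods:
                    net[self.sp_index[sp]] = net.get(self.sp_index[sp], 0) + n
                self.net_stoich[key] = net
                for sp, _ in subs:
                    options.setdefault(self.sp_index[sp], []).append(
                        (r.id, direction))
        if config.binding.mode == "specificity":
            missing = [
                (r.id, sp) for r in model.reactions
                for direction in (("forward", "reverse") if r.reversible
                                  else ("forward",))
                for sp, _ in r.side(direction, "substrates")
                if sp not in r.km
            ]
            if missing:
                raise ConfigurationError(
                    f"specificity binding mode needs Km values; missing for "
                    f"{missing[:5]}{'...' if len(missing) > 5 else ''}")

        # spatial index + per-agent attributes
        self.index = SpatialIndex(self.box)
        cap = len(self.index.alive)
        self.agent_species = np.full(cap, -1, dtype=np.int32)
        self.agent_kind = np.full(cap, -1, dtype=np.int8)
        self.automata: dict[int, ComplexAutomatonState] = {}
        self.saturated: set[int] = set()
        self.free_mets: list[set[int]] = [set() for _ in range(n_sp)]
        self.free_counts = np.zeros(n_sp, dtype=np.int64)
        self.completed: Counter = Counter()   # (reaction id, direction) -> n

        volume = env.volume
        self.initial_counts = np.zeros(n_sp, dtype=np.int64)
        for i, s in enumerate(self.species_list):
            count = concentration_to_count(s.initial_concentration, volume)
            self.initial_counts[i] = count
            kind = KIND_ENZYME if s.role == "enzyme" else KIND_METABOLITE
            for _ in range(count):
                aid = place_sphere(self.index, self.sp_radius[i], self.box,
                                   self.rng)
                self._sync_capacity()
                self.agent_species[aid] = i
                self.agent_kind[aid] = kind
                if kind == KIND_METABOLITE:
                    self.free_mets[i].add(aid)
                self.free_counts[i] += 1

    # -- small helpers -----------------------------------------------------

    def _sync_capacity(self) -> None:
        cap = len(self.index.alive)
        if cap > len(self.agent_species):
            for name, fill in (("agent_species", -1), ("agent_kind", -1)):
                arr = getattr(self, name)
                grown = np.full(cap, fill, dtype=arr.dtype)
                grown[: len(arr)] = arr
                setattr(self, name, grown)

    def _step_for_radius(self, radius: float) -> float:
        L = self._step_by_radius.get(radius)
        if L is None:
            D = diffusion_coefficient(radius, self.env)
            L = step_length(D, self.env.tick, msd_3d=self.config.msd_3d)
            self._step_by_radius[radius] = L
        return L

    def agent(self, aid: int) -> AgentState:
        if not self.index.alive[aid]:
            raise KeyError(f"agent {aid} is not alive")
        return AgentState(
            id=aid, species=self.species_list[self.agent_species[aid]].id,
            kind=_KIND_NAMES[int(self.agent_kind[aid])],
            position=self.index.pos[aid].copy(),
            radius=float(self.index.radius[aid]),
            automaton=self.automata.get(aid))

    def count_free(self, species_id: str) -> int:
        return int(self.free_counts[self.sp_index[species_id]])

    def complex_compositions(self) -> Counter:
        """Complex counts keyed "ENZ[SUB,SUB,...]" (bound multiset, sorted)."""
        out: Counter = Counter()
        for aid, st in self.automata.items():
            enz = self.species_list[self.agent_species[aid]].id
            parts = []
            for sp_idx in sorted(st.bound, key=lambda i: self.species_list[i].id):
                parts.extend([self.species_list[sp_idx].id] * st.bound[sp_idx])
            out[f"{enz}[{','.join(parts)}]"] += 1
        return out

    # -- perception and binding -------------------------------------------

    def _needed_species(self, aid: int) -> list[int]:
        if self.agent_kind[aid] == KIND_ENZYME:
            return sorted(self.enzyme_options[self.agent_species[aid]])
        st = self.automata[aid]
        req = self.required[(st.reaction, st.direction)]
        return sorted(sp for sp in req if st.bound[sp] < req[sp])

    def perceive(self, aid: int) -> tuple[np.ndarray, np.ndarray]:
        """Free cognate metabolites within the perception sphere.

        Returns (agent ids, surface-to-surface distances); only metabolites
        of species still required by the agent's open reactions/automaton,
        and not already inside a complex, are candidates (closed ball ≤ d).
        """
        d = self.config.binding.distance
        pos = self.index.pos[aid]
        r_self = self.index.radius[aid]
        ids_out: list[np.ndarray] = []
        s_out: list[np.ndarray] = []
        for sp in self._needed_species(aid):
            pool = self.free_mets[sp]
            if not pool:
                continue
            ids = np.fromiter(sorted(pool), dtype=np.intp, count=len(pool))
            disp = self.index.pos[ids] - pos
            if self.box.boundary == "periodic":
                disp -= self.box.side * np.round(disp / self.box.side)
            dist = np.sqrt(np.einsum("ij,ij->i", disp, disp))
            surface = dist - r_self - self.sp_radius[sp]
            keep = surface <= d
            if np.any(keep):
                ids_out.append(ids[keep])
                s_out.append(surface[keep])
        if not ids_out:
            return (np.empty(0, dtype=np.intp), np.empty(0))
        return np.concatenate(ids_out), np.concatenate(s_out)

    def _specificity_key(self, aid: int, met_species: int) -> float:
        if self.agent_kind[aid] == KIND_COMPLEX:
            st = self.automata[aid]
            r = self.reactions[st.reaction]
            sp_id = self.species_list[met_species].id
            return r.kcat_for(st.direction) / r.km[sp_id]
        best = 0.0
        for rid, direction in self.enzyme_options[
                self.agent_species[aid]][met_species]:
            r = self.reactions[rid]
            sp_id = self.species_list[met_species].id
            best = max(best, r.kcat_for(direction) / r.km[sp_id])
        return best

    def select_and_bind(self, aid: int, candidates: np.ndarray,
                        surface: np.ndarray) -> int | None:
        """Try candidates (random order, or kcat/Km priority in specificity
        mode); the first probabilistic success is bound.  Returns the bound
        metabolite id or None."""
        n = len(candidates)
        if n == 0:
            return None
        binding = self.config.binding
        order = self.rng.permutation(n)
        if binding.mode == "specificity":
            keys = np.array([
                self._specificity_key(aid, int(self.agent_species[m]))
                for m in candidates])
            order = order[np.argsort(-keys[order], kind="stable")]
        draws = self.rng.random(n)
        for k, i in enumerate(order):
            if draws[k] < binding.probability(float(surface[i])):
                met = int(candidates[i])
                self.form_or_extend_complex(aid, met)
                return met
        return None

    def form_or_extend_complex(self, aid: int, met: int) -> None:
        """Bind metabolite ``met`` to a free enzyme or partial complex."""
        sp = int(self.agent_species[met])
        if self.agent_kind[aid] == KIND_ENZYME:
            options = self.enzyme_options[self.agent_species[aid]].get(sp)
            if not options:
                raise RuntimeError(
                    f"metabolite {self.species_list[sp].id} is not a substrate "
                    "of any open reaction (perceive contract violated)")
            pick = options[self.rng.integers(len(options))] \
                if len(options) > 1 else options[0]
            st = ComplexAutomatonState(reaction=pick[0], direction=pick[1])
            self.automata[aid] = st
            self.agent_kind[aid] = KIND_COMPLEX
            self.free_counts[self.agent_species[aid]] -= 1
        else:
            st = self.automata[aid]
            req = self.required[(st.reaction, st.direction)]
            if st.bound[sp] >= req.get(sp, 0):
                raise RuntimeError(
                    f"metabolite {self.species_list[sp].id} not required by "
                    f"complex automaton (perceive contract violated)")
        st.bound[sp] += 1
        # consume the metabolite agent
        self.index.remove(met)
        self.free_mets[sp].discard(met)
        self.free_counts[sp] -= 1
        # complex radius from volume additivity over enzyme + bound metabolites
        enz_sp = int(self.agent_species[aid])
        r3 = self.sp_radius[enz_sp] ** 3 + sum(
            self.sp_radius[i] ** 3 * n for i, n in st.bound.items())
        new_radius = r3 ** (1.0 / 3.0)
        self._resize_agent(aid, new_radius)
        req = self.required[(st.reaction, st.direction)]
        if st.bound == req:
            st.saturated = True
            kcat = self.reactions[st.reaction].kcat_for(st.direction)
            st.wait_ticks = max(
                1, int(round((1.0 / kcat) / self.env.tick)))
            self.saturated.add(aid)

    def _resize_agent(self, aid: int, new_radius: float) -> None:
        """Grow/shrink an agent in place, nudging it to a free spot if the
        new radius overlaps a neighbour."""
        self.index.set_radius(aid, new_radius)
        if self.index.overlap_free(self.index.pos[aid], new_radius,
                                   exclude=aid):
            return
        pos = self.index.pos[aid].copy()
        for attempt in range(10):
            offset = (0.5 + 0.5 * attempt) * random_unit_vector(self.rng)
            cand = propose_move(pos, offset / np.linalg.norm(offset),
                                float(np.linalg.norm(offset)), self.box)
            if self.index.overlap_free(cand, new_radius, exclude=aid):
                self.index.move(aid, cand)
                return
        # rare: stay slightly overlapped; movement resolves it next tick

    # -- dissociation and release -----------------------------------------

    def _dissociate(self, aid: int) -> None:
        """Return a partial complex's metabolites to the free pool."""
        st = self.automata.pop(aid)
        enz_sp = int(self.agent_species[aid])
        self.agent_kind[aid] = KIND_ENZYME
        self.index.set_radius(aid, self.sp_radius[enz_sp])
        self.free_counts[enz_sp] += 1
        for sp, n in st.bound.items():
            for _ in range(n):
                self._spawn_near(aid, sp)

    def _spawn_near(self, aid: int, sp: int, tries: int = 30) -> int | None:
        """Place one molecule of species ``sp`` adjacent to agent ``aid``'s
        surface (expanding shell, bounded retries)."""
        r_center = self.index.radius[aid]
        r_new = self.sp_radius[sp]
        base = r_center + r_new + 0.1
        pos = self.index.pos[aid]
        for attempt in range(tries):
            gap = base * (1.0 + 0.2 * (attempt // 6))
            direction = random_unit_vector(self.rng)
            cand = propose_move(pos, direction, gap, self.box)
            if self.index.overlap_free(cand, r_new):
                new_id = self.index.add(cand, r_new)
                self._sync_capacity()
                self.agent_species[new_id] = sp
                self.agent_kind[new_id] = KIND_METABOLITE
                self.free_mets[sp].add(new_id)
                self.free_counts[sp] += 1
                return new_id
        return None

    def release_products(self, aid: int) -> bool:
        """Release the products of a saturated complex whose wait has elapsed.

        Products are placed collision-free adjacent to the enzyme surface;
        if space cannot be found the whole release is deferred one tick.
        Returns True on success."""
        st = self.automata[aid]
        r = self.reactions[st.reaction]
        products = r.side(st.direction, "products")
        enz_sp = int(self.agent_species[aid])
        old_radius = float(self.index.radius[aid])
        self.index.set_radius(aid, self.sp_radius[enz_sp])
        placed: list[tuple[int, int]] = []
        ok = True
        for sp_id, n in products:
            sp = self.sp_index[sp_id]
            for _ in range(n):
                new_id = self._spawn_near(aid, sp)
                if new_id is None:
                    ok = False
                    break
                placed.append((new_id, sp))
            if not ok:
                break
        if not ok:
            for new_id, sp in placed:
                self.index.remove(new_id)
                self.free_mets[sp].discard(new_id)
                self.free_counts[sp] -= 1
            self.index.set_radius(aid, old_radius)
            st.release_pending = True
            return False
        self.automata.pop(aid)
        self.saturated.discard(aid)
        self.agent_kind[aid] = KIND_ENZYME
        self.free_counts[enz_sp] += 1
        self.completed[(st.reaction, st.direction)] += 1
        return True

    # -- tick --------------------------------------------------------------

    def tick(self) -> None:
        """One tick: move all agents, let enzymes/complexes perceive and
        bind, then advance saturated-complex timers and release products."""
        rng = self.rng
        cfg = self.config
        live = self.index.live_ids()

        # phase 1: movement, fresh random order (no agent is created or
        # destroyed during this phase, so the order array stays valid)
        order = live[rng.permutation(len(live))]
        if cfg.gaussian_steps:
            raw = rng.standard_normal((len(order), 3))
        else:
            from .physics import random_unit_vectors

            dirs = random_unit_vectors(len(order), rng)
        for k, aid in enumerate(order):
            radius = float(self.index.radius[aid])
            if cfg.gaussian_steps:
                vec = raw[k] * self._step_for_radius(radius)
                length = float(np.linalg.norm(vec))
                direction = vec / length if length > 0 else vec
            else:
                length = self._step_for_radius(radius)
                direction = dirs[k]
            try_commit_move(self.index, int(aid), direction, length, self.box,
                            rng, retries=cfg.move_retries,
                            policy=cfg.step_policy)

        # phase 2: perception and binding, fresh random order
        live = self.index.live_ids()
        actors = live[(self.agent_kind[live] == KIND_ENZYME)
                      | (self.agent_kind[live] == KIND_COMPLEX)]
        order = actors[rng.permutation(len(actors))]
        for aid in order:
            aid = int(aid)
            if not self.index.alive[aid]:
                continue
            st = self.automata.get(aid)
            if st is not None and st.saturated:
                continue
            candidates, surface = self.perceive(aid)
            bound = self.select_and_bind(aid, candidates, surface)
            if bound is None and st is not None:
                st.ticks_partial += 1
                if (cfg.unbinding_timeout is not None
                        and st.ticks_partial >= cfg.unbinding_timeout):
                    self._dissociate(aid)

        # phase 3: countdown and product release
        for aid in sorted(self.saturated):
            st = self.automata.get(aid)
            if st is None or not st.saturated:
                continue
            if st.release_pending:
                self.release_products(aid)
                continue
            st.wait_ticks -= 1
            if st.wait_ticks <= 0:
                self.release_products(aid)

        self.tick_index += 1
        if cfg.validate_every and self.tick_index % cfg.validate_every == 0:
            self.check_conservation(raise_on_error=True)

    # -- checkpointing -----------------------------------------------------

    def to_snapshot(self) -> dict:
        """JSON-serialisable snapshot of the full dynamic state."""
        idx = self.index
        return {
            "tick_index": int(self.tick_index),
            "rng_state": self.rng.bit_generator.state,
            "pos": idx.pos.tolist(),
            "radius": idx.radius.tolist(),
            "alive": idx.alive.astype(int).tolist(),
            "free_slots": [int(i) for i in idx._free],
            "max_radius": float(idx.max_radius),
            "agent_species": self.agent_species.tolist(),
            "agent_kind": self.agent_kind.tolist(),
            "automata": {
                str(aid): {
                    "reaction": st.reaction, "direction": st.direction,
                    "bound": {str(k): int(v) for k, v in st.bound.items()},
                    "saturated": st.saturated,
                    "wait_ticks": int(st.wait_ticks),
                    "release_pending": st.release_pending,
                    "ticks_partial": int(st.ticks_partial),
                }
                for aid, st in self.automata.items()},
            "completed": [[rid, direction, int(n)]
                          for (rid, direction), n in self.completed.items()],
            "initial_counts": self.initial_counts.tolist(),
        }

    @classmethod
    def from_snapshot(cls, model: PathwayModel, config: SimulationConfig,
                      snap: dict) -> "World":
        """Rebuild a world mid-run; continuing it reproduces the original
        trajectory exactly (the RNG state is part of the snapshot)."""
        world = cls(model, config)   # static tables; placement is overwritten
        idx = world.index
        cap = len(snap["alive"])
        while len(idx.alive) < cap:
            idx._grow()
        idx.pos[:cap] = np.array(snap["pos"])
        idx.radius[:cap] = np.array(snap["radius"])
        idx.alive[:] = False
        idx.alive[:cap] = np.array(snap["alive"], dtype=bool)
        idx._free = [int(i) for i in snap["free_slots"]]
        idx.max_radius = float(snap["max_radius"])
        idx._cells = {}
        idx._cell_of = {}
        idx._live_cache = None
        for aid in np.flatnonzero(idx.alive):
            key = idx._cell_key(idx.pos[aid])
            idx._cells.setdefault(key, set()).add(int(aid))
            idx._cell_of[int(aid)] = key
        world._sync_capacity()
        world.agent_species[:cap] = np.array(snap["agent_species"],
                                             dtype=np.int32)
        world.agent_kind[:cap] = np.array(snap["agent_kind"], dtype=np.int8)
        world.automata = {
            int(aid): ComplexAutomatonState(
                reaction=st["reaction"], direction=st["direction"],
                bound=Counter({int(k): v for k, v in st["bound"].items()}),
                saturated=st["saturated"], wait_ticks=st["wait_ticks"],
                release_pending=st["release_pending"],
                ticks_partial=st["ticks_partial"])
            for aid, st in snap["automata"].items()}
        world.saturated = {aid for aid, st in world.automata.items()
                          if st.saturated}
        world.completed = Counter({(rid, direction): n
                                   for rid, direction, n in snap["completed"]})
        world.initial_counts = np.array(snap["initial_counts"], dtype=np.int64)
        world.free_mets = [set() for _ in world.species_list]
        world.free_counts = np.zeros(len(world.species_list), dtype=np.int64)
        for aid in np.flatnonzero(idx.alive):
            sp = int(world.agent_species[aid])
            kind = int(world.agent_kind[aid])
            if kind == KIND_METABOLITE:
                world.free_mets[sp].add(int(aid))
            if kind != KIND_COMPLEX:
                world.free_counts[sp] += 1
        world.tick_index = int(snap["tick_index"])
        world.rng = np.random.default_rng()
        world.rng.bit_generator.state = snap["rng_state"]
        return world

    # -- invariants --------------------------------------------------------

    def bound_counts(self) -> np.ndarray:
        """Per-species molecule counts currently inside complexes."""
        out = np.zeros(len(self.species_list), dtype=np.int64)
        for aid, st in self.automata.items():
            out[self.agent_species[aid]] += 1  # the enzyme itself
            for sp, n in st.bound.items():
                out[sp] += n
        return out

    def check_conservation(self, raise_on_error: bool = False) -> bool:
        """Exact integer ledger: free + bound − initial = Σ completed × net
        stoichiometry, for every species."""
        balance = self.free_counts + self.bound_counts() - self.initial_counts
        expected = np.zeros_like(balance)
        for (rid, direction), n in self.completed.items():
            for sp, net in self.net_stoich[(rid, direction)].items():
                expected[sp] += n * net
        ok = bool(np.array_equal(balance, expected))
        if not ok and raise_on_error:
            bad = np.flatnonzero(balance != expected)
            names = [self.species_list[i].id for i in bad]
            raise AssertionError(
                f"conservation ledger violated for species {names}: "
                f"balance {balance[bad]} expected {expected[bad]}")
        return ok


# --------------------------------------------------------------------------
# Driver
# --------------------------------------------------------------------------

def step(world: World) -> World:
    """Advance the world by one tick (in place; returned for chaining)."""
    world.tick()
    return world


def run(model: PathwayModel, config: SimulationConfig,
        world: World | None = None,
        checkpoint_every: int | None = None,
        checkpoint_callback=None) -> tuple["obs.ConcentrationSeries", World]:
    """Run a full simulation and record the concentration series.

    A snapshot is recorded at tick 0 and then every ``config.record_every``
    ticks.  With ``checkpoint_every`` set, ``checkpoint_callback(world)`` is
    invoked at that tick interval (used by the CLI for resumable runs).
    """
    if world is None:
        world = World(model, config)
    builder = obs.SeriesBuilder(world)
    builder.record(world)   # state at the start of this (possibly resumed) leg
    for _ in range(world.tick_index, config.n_ticks):
        world.tick()
        if world.tick_index % config.record_every == 0:
            builder.record(world)
        if (checkpoint_every and checkpoint_callback
                and world.tick_index % checkpoint_every == 0):
            checkpoint_callback(world)
    series = builder.finalize(metadata={
        "seed": config.seed,
        "distance": config.binding.distance,
        "law": str(config.binding.law),
        "mode": config.binding.mode,
        "duration": config.duration,
        "record_every": config.record_every,
        "provenance": model.provenance,
        "config_hash": config_hash(config),
    })
    return series, world


def config_hash(config: SimulationConfig) -> str:
    import hashlib

    return hashlib.sha256(repr(config).encode()).hexdigest()[:12]
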