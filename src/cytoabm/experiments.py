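"""Reusable study protocols built on the simulator.

These functions encode the package's headline computations at desk scale:
the three-regime force comparison on the glycolysis network (perception
distances 5, 10 and 300 Å), the well-mixed turnover oracle (product rate vs
the Michaelis–Menten Vmax limit kcat) and the free-diffusion mean-squared-
displacement check.  They are shared by the test suite, the acceptance
script and the CLI so that every consumer measures the same thing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import engine, fixtures, observables, physics

#: hexokinase/glucokinase-glucose complex keys in the glycolysis fixture
HEXOKINASE_GLUCOSE_KEYS = ("HXK1[GLC]", "HXK2[GLC]", "GLK1[GLC]")


@dataclass
class RegimeResult:
    """Per-regime summary over seeds of the glycolysis comparison."""

    distance: float
    glucose_consumed: list[float] = field(default_factory=list)   # mmol/l
    atp_initial: list[float] = field(default_factory=list)
    atp_final: list[float] = field(default_factory=list)
    pyruvate_gain: list[float] = field(default_factory=list)
    hxk_glc_presence: list[float] = field(default_factory=list)
    # fraction of recorded ticks in the 2nd half with >= 1 HXK/GLK-GLC complex

    @property
    def mean_glucose_consumed(self) -> float:
        return float(np.mean(self.glucose_consumed))

    @property
    def mean_atp_drop_fraction(self) -> float:
        init = np.array(self.atp_initial)
        fin = np.array(self.atp_final)
        return float(np.mean((init - fin) / np.where(init > 0, init, 1.0)))

    @property
    def mean_hxk_glc_presence(self) -> float:
        return float(np.mean(self.hxk_glc_presence))


def _hxk_glc_presence(series: observables.ConcentrationSeries) -> float:
    """Fraction of recorded ticks in the second half of the run with at
    least one hexokinase/glucokinase-glucose complex present."""
    n = len(series.times)
    half = n // 2
    total = np.zeros(n, dtype=np.int64)
    for key in HEXOKINASE_GLUCOSE_KEYS:
        if key in series.complex_counts:
            total += series.complex_counts[key]
    tail = total[half:]
    return float(np.mean(tail >= 1)) if len(tail) else 0.0


def run_regime(distance: float, scale: float, duration: float, seed: int,
               record_every: int = 20) -> observables.ConcentrationSeries:
    """One glycolysis run at the given perception distance."""
    model = fixtures.glycolysis_model(scale=scale)
    config = fixtures.glycolysis_config(
        distance=distance, seed=seed, duration=duration,
        record_every=record_every)
    series, _ = engine.run(model, config)
    return series


def regime_comparison(scale: float = 0.2, duration: float = 0.2,
                      seeds: tuple[int, ...] = (0, 1, 2, 3, 4),
                      distances: tuple[float, ...] = (5.0, 10.0, 300.0),
                      ) -> dict[float, RegimeResult]:
    """The force-regime study: identical networks and seeds, only the
    perception distance differs.  Larger perception distances model longer-
    range attractive interactions; the expectation is a monotone increase of
    glucose consumption with distance and a short-range (5 Å) stall in which
    free ATP stays nearly flat while hexokinase-glucose complexes persist."""
    results = {d: RegimeResult(distance=d) for d in distances}
    for d in distances:
        for seed in seeds:
            series = run_regime(d, scale, duration, seed)
            res = results[d]
            glc = series.get("GLC")
            atp = series.get("ATP")
            res.glucose_consumed.append(float(glc[0] - glc[-1]))
            res.atp_initial.append(float(atp[0]))
            res.atp_final.append(float(atp[-1]))
            pyr = series.get("PYR")
            res.pyruvate_gain.append(float(pyr[-1] - pyr[0]))
            res.hxk_glc_presence.append(_hxk_glc_presence(series))
    return results


def turnover_rate(kcat: float = 100.0, n_substrate: int = 500,
                  duration: float = 1.0, seed: int = 0) -> float:
    """Measured product rate (1/s) of the single-enzyme toy with saturating
    substrate and non-limiting binding; approaches kcat (the Vmax limit)."""
    model, config = fixtures.toy_single_reaction(
        n_substrate=n_substrate, kcat=kcat, seed=seed)
    import dataclasses

    config = dataclasses.replace(config, duration=duration)
    series, world = engine.run(model, config)
    products = world.completed[("R1", "forward")]
    return products / duration


def msd_relative_error(n_replicas: int = 1000, n_ticks: int = 1000,
                       radius: float = 20.0, seed: int = 0) -> float:
    """Relative error of the empirical MSD of free fixed-modulus random
    walks against the Brownian law <x²> = 2 D t after ``n_ticks`` ticks."""
    env = physics.EnvironmentParams()
    D = physics.diffusion_coefficient(radius, env)
    L = physics.step_length(D, env.tick)
    rng = np.random.default_rng(seed)
    pos = physics.free_diffusion_positions(n_replicas, n_ticks, L, rng)
    msd = float(np.mean(np.einsum("ij,ij->i", pos, pos)))
    expected = n_ticks * L * L  # = 2 D (n Δt) in Å²
    return abs(msd - expected) / expected
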