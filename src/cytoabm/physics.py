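"""Continuous physics: sphere radii, Stokes-Einstein diffusion, step lengths.

Every molecule is a sphere whose radius follows from its molecular weight M
and the average partial specific volume v̄ of a protein in solution:

    r = (3 v̄ M / (4 π N_A))^(1/3)

Its diffusion coefficient is the Stokes-Einstein value D = k_B T / (6 π η r),
and the displacement per simulation tick Δt is the fixed root-mean-square
modulus of a Brownian walker, L = sqrt(2 D Δt), applied along an isotropic
random direction.  Working units are ångströms for space and seconds for time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import AVOGADRO, BOLTZMANN, DEFAULT_VBAR


@dataclass(frozen=True)
class EnvironmentParams:
    """Thermodynamic and discretisation parameters of the simulated cytoplasm.

    Defaults: water-like cytosol at room temperature (T = 298.15 K,
    η = 0.0011 Pa·s), a tick of 1e-4 s, and a cube of side 1000 Å
    (one attolitre).
    """

    temperature: float = 298.15  # K
    viscosity: float = 0.0011    # Pa s
    tick: float = 1e-4           # s
    side: float = 1000.0         # Å

    def __post_init__(self) -> None:
        for name in ("temperature", "viscosity", "tick", "side"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def volume(self) -> float:
        """Box volume in litres: (side × 1e-10 m)³ × 1e3 l/m³."""
        return (self.side * 1e-10) ** 3 * 1e3


def radius_from_mass(molecular_weight: float,
                     v_bar: float = DEFAULT_VBAR) -> float:
    """Sphere radius in Å for a molecule of ``molecular_weight`` g/mol.

    ``v_bar`` is the partial specific volume in cm³/g (0.73 for an average
    protein; applied to metabolites as well, since every molecule is modelled
    as a sphere derived from its weight).
    """
    if not molecular_weight > 0:
        raise ValueError(f"molecular weight must be > 0, got {molecular_weight}")
    if not v_bar > 0:
        raise ValueError(f"v_bar must be > 0, got {v_bar}")
    vol_m3 = v_bar * molecular_weight / AVOGADRO * 1e-6  # cm³ -> m³
    r_m = (3.0 * vol_m3 / (4.0 * math.pi)) ** (1.0 / 3.0)
    return r_m * 1e10


def diffusion_coefficient(radius: float,
                          env: EnvironmentParams | None = None) -> float:
    """Stokes-Einstein diffusion coefficient (m²/s) for a sphere of
    ``radius`` Å in environment ``env`` (paper-default T and η if omitted)."""
    if not radius > 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    if env is None:
        env = EnvironmentParams()
    r_m = radius * 1e-10
    return BOLTZMANN * env.temperature / (6.0 * math.pi * env.viscosity * r_m)


def step_length(diffusion: float, tick: float, msd_3d: bool = False) -> float:
    """Per-tick displacement modulus in Å.

    The default is the one-dimensional mean-squared-displacement form
    L = sqrt(2 D Δt), used as a fixed 3-D step modulus; ``msd_3d`` switches
    to the sqrt(6 D Δt) form for sensitivity studies.
    """
    if diffusion < 0:
        raise ValueError(f"diffusion coefficient must be >= 0, got {diffusion}")
    if not tick > 0:
        raise ValueError(f"tick must be > 0, got {tick}")
    factor = 6.0 if msd_3d else 2.0
    return math.sqrt(factor * diffusion * tick) * 1e10


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Isotropic unit vector: cos θ uniform on [-1, 1], φ uniform on [0, 2π)."""
    u, v = rng.random(2)
    cos_t = 2.0 * u - 1.0
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    phi = 2.0 * math.pi * v
    return np.array([sin_t * math.cos(phi), sin_t * math.sin(phi), cos_t])


def random_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised form of :func:`random_unit_vector`: (n, 3) array."""
    u = rng.random((n, 2))
    cos_t = 2.0 * u[:, 0] - 1.0
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    phi = 2.0 * np.pi * u[:, 1]
    return np.column_stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def free_diffusion_positions(n_replicas: int, n_ticks: int, step: float,
                             rng: np.random.Generator) -> np.ndarray:
    """Endpoints (n_replicas, 3) of free random walks of ``n_ticks`` fixed-
    modulus steps in unbounded space.

    Each walker starts at the origin and takes steps of modulus ``step`` Å
    along fresh isotropic directions; used to check the Brownian law
    <x²> = 2 D t empirically.
    """
    pos = np.zeros((n_replicas, 3))
    for _ in range(n_ticks):
        pos += step * random_unit_vectors(n_replicas, rng)
    return pos
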