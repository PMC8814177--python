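"""Concentration time series and derived quantities.

A simulation records, at fixed tick intervals, the FREE-molecule count of
every species (converted to mmol/l at the box volume) plus the count of every
complex composition (keyed ``"ENZ[SUB,...]"``).  Molecules inside complexes
are deliberately not counted in their species' concentration; complexes are
reported separately — this reproduces the short-range stall signature, where
hexokinase–glucose complexes persist while free ATP stays flat.

Derived quantities: depletion times, the dominant oscillation frequency of a
species (periodogram of the linearly detrended series, zero bin excluded,
with a peak-over-median significance check) and pairwise synchrony (Pearson
correlation of detrended series at zero lag).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from .model_io import count_to_concentration


@dataclass
class ConcentrationSeries:
    """Recorded trajectories: times (s), mmol/l per species, counts per
    complex composition, plus run metadata (seed, config hash, ...)."""

    times: np.ndarray
    concentrations: dict[str, np.ndarray]
    complex_counts: dict[str, np.ndarray]
    volume: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    def species(self) -> list[str]:
        return list(self.concentrations)

    def get(self, species: str) -> np.ndarray:
        return self.concentrations[species]

    def counts(self, species: str) -> np.ndarray:
        """Free-molecule counts (inverse of the concentration conversion)."""
        factor = 1e-3 * 6.02214076e23 * self.volume
        return np.rint(self.concentrations[species] * factor).astype(np.int64)

    def window(self, t0: float, t1: float) -> np.ndarray:
        return (self.times >= t0) & (self.times <= t1)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: time, kind (species|complex), name, value."""
        rows = []
        for name, vals in self.concentrations.items():
            rows.append(pd.DataFrame({
                "time": self.times, "kind": "species", "name": name,
                "value": vals}))
        for name, vals in self.complex_counts.items():
            rows.append(pd.DataFrame({
                "time": self.times, "kind": "complex", "name": name,
                "value": vals.astype(float)}))
        if not rows:
            return pd.DataFrame(columns=["time", "kind", "name", "value"])
        return pd.concat(rows, ignore_index=True)


class SeriesBuilder:
    """Accumulates per-tick snapshots into a :class:`ConcentrationSeries`.

    Complex compositions may appear mid-run; earlier rows are back-filled
    with zeros at finalisation."""

    def __init__(self, world) -> None:
        self.species_names = [s.id for s in world.species_list]
        self.volume = world.env.volume
        self.tick = world.env.tick
        self.times: list[float] = []
        self.rows: list[np.ndarray] = []
        self.complex_rows: list[dict[str, int]] = []

    def record(self, world) -> None:
        self.times.append(world.tick_index * self.tick)
        self.rows.append(world.free_counts.copy())
        self.complex_rows.append(dict(world.complex_compositions()))

    def finalize(self, metadata: dict | None = None) -> ConcentrationSeries:
        counts = np.array(self.rows, dtype=np.int64).reshape(
            len(self.rows), len(self.species_names))
        conc = {
            name: np.array([count_to_concentration(int(n), self.volume)
                            for n in counts[:, i]])
            for i, name in enumerate(self.species_names)}
        keys = sorted({k for row in self.complex_rows for k in row})
        complexes = {
            k: np.array([row.get(k, 0) for row in self.complex_rows],
                        dtype=np.int64)
            for k in keys}
        return ConcentrationSeries(
            times=np.array(self.times), concentrations=conc,
            complex_counts=complexes, volume=self.volume,
            metadata=dict(metadata or {}))


def record_snapshot(world, t: float | None = None) -> dict:
    """One-off snapshot row (free concentrations + complex counts)."""
    volume = world.env.volume
    return {
        "time": world.tick_index * world.env.tick if t is None else t,
        "concentrations": {
            s.id: count_to_concentration(int(n), volume)
            for s, n in zip(world.species_list, world.free_counts)},
        "complexes": dict(world.complex_compositions()),
    }


# --------------------------------------------------------------------------
# Derived quantities
# --------------------------------------------------------------------------

def depletion_time(series: ConcentrationSeries, species: str) -> float | None:
    """First recorded time at which the species' free count is zero and stays
    zero to the end of the run; None if it is never depleted."""
    c = series.get(species)
    zero = c == 0
    if not zero[-1]:
        return None
    nonzero = np.flatnonzero(~zero)
    first = nonzero[-1] + 1 if len(nonzero) else 0
    return float(series.times[first])


def _windowed(series: ConcentrationSeries, species: str,
              window: tuple[float, float] | None) -> tuple[np.ndarray, np.ndarray]:
    mask = (series.window(*window) if window is not None
            else np.ones(len(series.times), dtype=bool))
    return series.times[mask], series.get(species)[mask]


def dominant_frequency(series: ConcentrationSeries, species: str,
                       window: tuple[float, float] | None = None,
                       min_peak_factor: float = 4.0) -> float | None:
    """Frequency (Hz) of the periodogram maximum of the linearly detrended
    series, zero bin excluded; None if the peak is not significant (peak
    power ≤ ``min_peak_factor`` × median periodogram power)."""
    t, x = _windowed(series, species, window)
    if len(t) < 32:
        raise ValueError(f"need at least 32 samples, got {len(t)}")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("dominant_frequency requires uniform sampling")
    raw = x.astype(float)
    x = signal.detrend(raw, type="linear")
    # a constant or purely linear series leaves only rounding residue
    if np.std(x) <= 1e-10 * max(1.0, float(np.max(np.abs(raw)))):
        return None
    freqs, power = signal.periodogram(x, fs=1.0 / dt[0], window="boxcar",
                                      detrend=False)
    freqs, power = freqs[1:], power[1:]   # exclude the zero bin
    if not np.any(power > 0):
        return None
    peak = int(np.argmax(power))
    med = float(np.median(power))
    if med > 0 and power[peak] <= min_peak_factor * med:
        return None
    if med == 0 and power[peak] == 0:
        return None
    return float(freqs[peak])


def synchrony(series: ConcentrationSeries, species_a: str, species_b: str,
              window: tuple[float, float] | None = None) -> float | None:
    """Pearson correlation at zero lag of the two linearly detrended series;
    None when either input has zero variance."""
    _, xa = _windowed(series, species_a, window)
    _, xb = _windowed(series, species_b, window)
    ra, rb = xa.astype(float), xb.astype(float)
    xa = signal.detrend(ra, type="linear")
    xb = signal.detrend(rb, type="linear")
    for resid, raw in ((xa, ra), (xb, rb)):
        if np.std(resid) <= 1e-10 * max(1.0, float(np.max(np.abs(raw)))):
            return None
    r, _ = stats.pearsonr(xa, xb)
    return float(r)


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

def write_series(series: ConcentrationSeries, path: str | Path,
                 fmt: str | None = None) -> None:
    """Write a series to CSV (long format, metadata in a header comment) or
    to an HDF5 container (``.h5``/``.hdf5``)."""
    path = Path(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in (".h5", ".hdf5") else "csv"
    if fmt == "csv":
        header = "# cytoabm-series v1 " + json.dumps(
            {"volume": series.volume, "metadata": series.metadata},
            sort_keys=True)
        body = series.to_frame().to_csv(index=False, float_format="%.17g")
        path.write_text(header + "\n" + body)
    elif fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["format"] = "cytoabm-series"
            f.attrs["version"] = 1
            f.attrs["volume"] = series.volume
            f.attrs["metadata"] = json.dumps(series.metadata, sort_keys=True)
            f.create_dataset("times", data=series.times)
            g = f.create_group("concentrations")
            for k, v in series.concentrations.items():
                g.create_dataset(k, data=v)
            g = f.create_group("complexes")
            for k, v in series.complex_counts.items():
                g.create_dataset(k, data=v)
    else:
        raise ValueError(f"unknown series format {fmt!r}")


def read_series(path: str | Path) -> ConcentrationSeries:
    """Read a series written by :func:`write_series` (CSV or HDF5)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != "cytoabm-series":
                raise ValueError(f"{path}: not a cytoabm series container")
            return ConcentrationSeries(
                times=f["times"][()],
                concentrations={k: f["concentrations"][k][()]
                                for k in f["concentrations"]},
                complex_counts={k: f["complexes"][k][()].astype(np.int64)
                                for k in f["complexes"]},
                volume=float(f.attrs["volume"]),
                metadata=json.loads(f.attrs["metadata"]))
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# cytoabm-series v1 "):
            raise ValueError(f"{path}: missing cytoabm series header")
        head = json.loads(first[len("# cytoabm-series v1 "):])
        frame = pd.read_csv(fh)
    times = np.array(sorted(frame["time"].unique()))
    conc = {}
    complexes = {}
    for name, sub in frame.groupby("name", sort=True):
        sub = sub.sort_values("time")
        if (sub["kind"] == "species").all():
            conc[str(name)] = sub["value"].to_numpy()
        else:
            complexes[str(name)] = np.rint(
                sub["value"].to_numpy()).astype(np.int64)
    return ConcentrationSeries(
        times=times, concentrations=conc, complex_counts=complexes,
        volume=float(head["volume"]), metadata=head["metadata"])
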