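"""Synthetic auditory-nerve frontend.

Octopus cells in the posteroventral cochlear nucleus receive convergent input
from hundreds of auditory-nerve fibers (ANFs) whose characteristic frequencies
(CFs) span several octaves.  Because the basilar-membrane traveling wave
reaches low-CF (apical) places later than high-CF (basal) places, a broadband
click evokes first spikes whose latencies differ systematically across the
fiber array — the *traveling-wave delay*.

This module generates click-evoked spike rasters that carry exactly that delay
structure, without simulating the cochlea itself: each fiber gets a CF on a
log-spaced tonotopic axis and a CF-dependent latency from a parametric delay
map, and click responses are single jittered spikes per fiber per click.  A
CSV import/export path exists so rasters produced by a full peripheral model
can be substituted.

All times are SI seconds, frequencies Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DELAY_MODELS",
    "FiberPopulation",
    "ClickStimulus",
    "SpikeRaster",
    "traveling_wave_delay",
    "build_population",
    "generate_raster",
    "write_raster",
    "read_raster",
    "write_population",
    "read_population",
]

#: Supported traveling-wave delay maps.
#:
#: ``"log-linear"``  — delay falls linearly in log(CF); combined with
#:   log-spaced CFs this yields delays uniformly spread over the span.
#: ``"reciprocal-cf"`` — delay proportional to (1/cf − 1/cf_max); convex in
#:   CF, closer to physiological group-delay curves.
DELAY_MODELS = ("log-linear", "reciprocal-cf")


def _normalize_model(name: str) -> str:
    key = str(name).strip().lower().replace("_", "-")
    if key == "reciprocal-cf" or key == "reciprocal":
        return "reciprocal-cf"
    if key == "log-linear":
        return "log-linear"
    raise ValueError(
        f"unknown delay model {name!r}; expected one of {DELAY_MODELS}"
    )


def traveling_wave_delay(
    cf,
    delay_model: str = "log-linear",
    *,
    cf_min: float = 6000.0,
    cf_max: float = 20000.0,
    delay_span: float = 0.5e-3,
):
    """Cochlear traveling-wave delay (s) at characteristic frequency ``cf``.

    Both maps are continuous, strictly decreasing in CF, equal to
    ``delay_span`` at ``cf_min`` and 0 at ``cf_max``:

    * log-linear:      ``delay_span * log(cf_max/cf) / log(cf_max/cf_min)``
    * reciprocal-cf:   ``k * (1/cf − 1/cf_max)`` with
      ``k = delay_span / (1/cf_min − 1/cf_max)``

    Accepts a scalar or array ``cf``; returns the same shape.
    """
    model = _normalize_model(delay_model)
    if not (0.0 < cf_min < cf_max):
        raise ValueError(f"need 0 < cf_min < cf_max, got {cf_min}, {cf_max}")
    if delay_span <= 0.0:
        raise ValueError(f"delay_span must be positive, got {delay_span}")
    cf_arr = np.asarray(cf, dtype=float)
    if np.any(cf_arr < cf_min) or np.any(cf_arr > cf_max):
        raise ValueError(
            f"cf outside [{cf_min}, {cf_max}]: {cf_arr[(cf_arr < cf_min) | (cf_arr > cf_max)]}"
        )
    if model == "log-linear":
        out = delay_span * np.log(cf_max / cf_arr) / np.log(cf_max / cf_min)
    else:
        k = delay_span / (1.0 / cf_min - 1.0 / cf_max)
        out = k * (1.0 / cf_arr - 1.0 / cf_max)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FiberPopulation:
    """The tonotopic axis: per-fiber CF (Hz) and traveling-wave delay (s).

    CFs are strictly increasing; delays are non-negative and non-increasing
    with CF (lower CF ⇒ later basilar-membrane arrival).
    """

    cf: np.ndarray
    t_tw: np.ndarray

    def __post_init__(self):
        cf = np.asarray(self.cf, dtype=float)
        t_tw = np.asarray(self.t_tw, dtype=float)
        object.__setattr__(self, "cf", cf)
        object.__setattr__(self, "t_tw", t_tw)
        if cf.ndim != 1 or t_tw.shape != cf.shape:
            raise ValueError("cf and t_tw must be 1-D arrays of equal length")
        if cf.size < 2:
            raise ValueError("need at least 2 fibers")
        if np.any(np.diff(cf) <= 0):
            raise ValueError("cf must be strictly increasing")
        if np.any(t_tw < 0):
            raise ValueError("traveling-wave delays must be non-negative")
        if np.any(np.diff(t_tw) > 0):
            raise ValueError("t_tw must be non-increasing with cf")

    @property
    def n_fibers(self) -> int:
        return self.cf.size

    @property
    def delay_span(self) -> float:
        """max(t_tw) − min(t_tw), the across-population delay asynchrony."""
        return float(self.t_tw.max() - self.t_tw.min())


def build_population(
    n_fibers: int = 400,
    cf_min: float = 6000.0,
    cf_max: float = 20000.0,
    delay_model: str = "log-linear",
    delay_span: float = 0.5e-3,
) -> FiberPopulation:
    """Build ``n_fibers`` log-spaced fibers between ``cf_min`` and ``cf_max``.

    The defaults are the 400-fiber, 6–20 kHz array whose delay asynchrony is
    0.5 ms — the transmission time of PSPs along an octopus-cell dendrite.
    """
    if n_fibers < 2:
        raise ValueError(f"n_fibers must be >= 2, got {n_fibers}")
    if not (0.0 < cf_min < cf_max):
        raise ValueError(f"need 0 < cf_min < cf_max, got {cf_min}, {cf_max}")
    cf = np.geomspace(cf_min, cf_max, n_fibers)
    # geomspace endpoints carry float error; pin them so the delay endpoints
    # (delay_span at cf_min, 0 at cf_max) are exact.
    cf[0], cf[-1] = cf_min, cf_max
    t_tw = traveling_wave_delay(
        cf, delay_model, cf_min=cf_min, cf_max=cf_max, delay_span=delay_span
    )
    return FiberPopulation(cf=cf, t_tw=np.asarray(t_tw))


@dataclass(frozen=True)
class ClickStimulus:
    """A train of broadband clicks presented once per learning epoch.

    Each epoch is ``epoch_duration`` long (default 50 ms) and holds
    ``n_clicks`` clicks (default 4) separated by ``click_period`` (10 ms).
    Per click, each fiber fires at most one spike, with probability
    ``p_spike_per_click``, at ``t_click + t_tw(fiber)`` plus Gaussian timing
    jitter of SD ``jitter_sd``.  An independent homogeneous Poisson process at
    ``spont_rate`` adds spontaneous spikes.
    """

    epoch_duration: float = 0.05
    click_period: float = 0.01
    n_clicks: int = 4
    first_click_time: float = 2e-3
    p_spike_per_click: float = 0.9
    jitter_sd: float = 50e-6
    spont_rate: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.p_spike_per_click <= 1.0):
            raise ValueError("p_spike_per_click must be in [0, 1]")
        if self.jitter_sd < 0 or self.spont_rate < 0:
            raise ValueError("jitter_sd and spont_rate must be non-negative")
        if self.n_clicks < 1 or self.click_period <= 0 or self.epoch_duration <= 0:
            raise ValueError("need n_clicks >= 1 and positive periods/durations")
        if self.first_click_time < 0:
            raise ValueError("first_click_time must be non-negative")
        last = self.first_click_time + (self.n_clicks - 1) * self.click_period
        if last >= self.epoch_duration:
            raise ValueError(
                f"last click at {last} s falls outside epoch of {self.epoch_duration} s"
            )

    @property
    def click_times(self) -> np.ndarray:
        return self.first_click_time + self.click_period * np.arange(self.n_clicks)


@dataclass(frozen=True)
class SpikeRaster:
    """Time-stamped (fiber, time) spike events for one epoch.

    Events are sorted ascending by time (ties broken by fiber index), all
    times lie in [0, duration) and all fiber indices in [0, n_fibers).
    """

    fiber_index: np.ndarray
    time: np.ndarray
    duration: float
    n_fibers: int

    def __post_init__(self):
        fi = np.asarray(self.fiber_index, dtype=np.int64)
        t = np.asarray(self.time, dtype=float)
        object.__setattr__(self, "fiber_index", fi)
        object.__setattr__(self, "time", t)
        if fi.ndim != 1 or t.shape != fi.shape:
            raise ValueError("fiber_index and time must be 1-D arrays of equal length")
        if fi.size:
            if fi.min() < 0 or fi.max() >= self.n_fibers:
                raise ValueError(
                    f"fiber indices must lie in [0, {self.n_fibers}); "
                    f"got range [{fi.min()}, {fi.max()}]"
                )
            if t.min() < 0 or t.max() >= self.duration:
                raise ValueError(
                    f"spike times must lie in [0, {self.duration}); "
                    f"got range [{t.min()}, {t.max()}]"
                )
            if np.any(np.diff(t) < 0):
                raise ValueError("events must be sorted ascending by time")

    @property
    def n_events(self) -> int:
        return self.time.size

    def events_by_fiber(self) -> list[np.ndarray]:
        """Spike times of each fiber, as a list of sorted arrays."""
        order = np.argsort(self.fiber_index, kind="stable")
        counts = np.bincount(self.fiber_index, minlength=self.n_fibers)
        return np.split(self.time[order], np.cumsum(counts)[:-1])


def _sorted_raster(fibers: np.ndarray, times: np.ndarray, duration: float,
                   n_fibers: int) -> SpikeRaster:
    order = np.lexsort((fibers, times))
    return SpikeRaster(
        fiber_index=fibers[order], time=times[order],
        duration=duration, n_fibers=n_fibers,
    )


def generate_raster(
    population: FiberPopulation,
    stimulus: ClickStimulus,
    seed: int,
) -> SpikeRaster:
    """Generate one epoch of click-evoked + spontaneous ANF spikes.

    Deterministic given (population, stimulus, seed).  Jittered click spikes
    that would land outside [0, duration) are redrawn, so spike *counts* never
    depend on the clipping.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an explicit integer")
    rng = np.random.default_rng(int(seed))
    n = population.n_fibers
    dur = stimulus.epoch_duration
    max_latency = float(population.t_tw.max())
    last_click = float(stimulus.click_times[-1])
    if last_click + max_latency >= dur:
        raise ValueError(
            "click responses extend past the epoch: last click at "
            f"{last_click} s + max latency {max_latency} s >= {dur} s"
        )

    fibers_parts = []
    times_parts = []
    for t_click in stimulus.click_times:
        fires = rng.random(n) < stimulus.p_spike_per_click
        base = t_click + population.t_tw
        if stimulus.jitter_sd > 0:
            t = base + rng.normal(0.0, stimulus.jitter_sd, n)
            bad = (t < 0.0) | (t >= dur)
            while np.any(bad):  # redraw, never drop
                t[bad] = base[bad] + rng.normal(0.0, stimulus.jitter_sd, int(bad.sum()))
                bad = (t < 0.0) | (t >= dur)
        else:
            t = base.copy()
        fibers_parts.append(np.nonzero(fires)[0])
        times_parts.append(t[fires])

    if stimulus.spont_rate > 0:
        counts = rng.poisson(stimulus.spont_rate * dur, n)
        fibers_parts.append(np.repeat(np.arange(n), counts))
        times_parts.append(rng.random(int(counts.sum())) * dur)

    fibers = np.concatenate(fibers_parts) if fibers_parts else np.empty(0, np.int64)
    times = np.concatenate(times_parts) if times_parts else np.empty(0, float)
    return _sorted_raster(fibers.astype(np.int64), times, dur, n)


# ---------------------------------------------------------------------------
# CSV plumbing


def write_raster(raster: SpikeRaster, path) -> None:
    """Write a raster as CSV with header ``fiber_id,time_s``.

    17 significant digits are written so the round-trip reproduces the
    float64 times exactly.
    """
    df = pd.DataFrame({"fiber_id": raster.fiber_index, "time_s": raster.time})
    df.to_csv(path, index=False, float_format="%.17g")


def read_raster(path, duration: float | None = None,
                n_fibers: int | None = None) -> SpikeRaster:
    """Read a ``fiber_id,time_s`` CSV back into a :class:`SpikeRaster`.

    ``duration`` and ``n_fibers`` may be given explicitly (e.g. from a config);
    otherwise they are inferred from the events.  Malformed rows are rejected
    with the offending row number (1-based, header = row 1).
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise ValueError(f"cannot parse raster CSV {path}: {exc}") from exc
    if list(df.columns) != ["fiber_id", "time_s"]:
        raise ValueError(
            f"raster CSV {path} must have header 'fiber_id,time_s', got {list(df.columns)}"
        )
    fibers = df["fiber_id"].to_numpy()
    times = df["time_s"].to_numpy(dtype=float)
    if fibers.size and not np.allclose(fibers, np.round(fibers)):
        row = int(np.nonzero(fibers != np.round(fibers))[0][0]) + 2
        raise ValueError(f"{path} row {row}: fiber_id is not an integer")
    fibers = fibers.astype(np.int64) if fibers.size else np.empty(0, np.int64)
    if fibers.size and fibers.min() < 0:
        row = int(np.nonzero(fibers < 0)[0][0]) + 2
        raise ValueError(f"{path} row {row}: fiber_id {fibers[row - 2]} is negative")
    if times.size and np.any(np.diff(times) < 0):
        row = int(np.nonzero(np.diff(times) < 0)[0][0]) + 3
        raise ValueError(f"{path} row {row}: times not sorted ascending")
    if times.size and times.min() < 0:
        row = int(np.nonzero(times < 0)[0][0]) + 2
        raise ValueError(f"{path} row {row}: negative spike time")
    if n_fibers is None:
        n_fibers = int(fibers.max()) + 1 if fibers.size else 0
    if duration is None:
        duration = float(np.nextafter(times.max(), np.inf)) if times.size else 0.0
    if fibers.size and fibers.max() >= n_fibers:
        row = int(np.nonzero(fibers >= n_fibers)[0][0]) + 2
        raise ValueError(
            f"{path} row {row}: fiber_id {fibers[row - 2]} >= n_fibers {n_fibers}"
        )
    return SpikeRaster(fiber_index=fibers, time=times,
                       duration=float(duration), n_fibers=int(n_fibers))


def write_population(population: FiberPopulation, path) -> None:
    """Write the tonotopic axis as CSV ``fiber_id,cf_hz,t_tw_s``."""
    pd.DataFrame({
        "fiber_id": np.arange(population.n_fibers),
        "cf_hz": population.cf,
        "t_tw_s": population.t_tw,
    }).to_csv(path, index=False, float_format="%.17g")


def read_population(path) -> FiberPopulation:
    df = pd.read_csv(path)
    expected = ["fiber_id", "cf_hz", "t_tw_s"]
    if list(df.columns) != expected:
        raise ValueError(f"population CSV {path} must have header {','.join(expected)}")
    df = df.sort_values("fiber_id")
    return FiberPopulation(cf=df["cf_hz"].to_numpy(float),
                           t_tw=df["t_tw_s"].to_numpy(float))
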