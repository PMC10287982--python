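"""Ground-truth event timelines and rendered multi-channel fluorescence traces.

The raw observable in the single-molecule assay is a set of per-waveguide
intensity time series: a Cy3B channel reporting ribosome conformation
(high = free 30S initiation complex or split subunits, low = non-rotated 70S,
medium = rotated 70S), a Cy5.5 channel reporting class-I RF occupancy and a
Cy5 channel reporting RF3 occupancy.  This module generates such data from
the termination schemes: :func:`simulate_timelines` draws exact continuous
-time Markov event sequences (the ground truth), and :func:`render_trace`
turns a timeline into frame-binned intensities with optional Gaussian noise
and exponential photobleaching.

The generative model for the termination phase follows the first-bound /
rebound schemes: an RF3-independent activation clock (``k_iIA``), RF3
sampling arrivals at ``k_3on * [RF3]`` with occupancies drawn from the
``k_3off`` mixture, spontaneous rotation at ``k_iAR_minus`` on the activated
RF3-free ribosome (with class-I RF release coincident with rotation), and a
productive branch on the activated RF3-bound ribosome: rotation at ``k_3BR``,
class-I RF release at ``k_iRD_plus`` (or the RF3-measured ``k_1RD_plus``),
then RF3 release at ``k_31D``.  With GDP there is no productive branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .params import RF3Kinetics, SchemeRates

__all__ = [
    "RF3Visit",
    "EventTimeline",
    "Trace",
    "STATE_LEVELS",
    "simulate_timelines",
    "render_trace",
]

# State -> intensity map (arbitrary units).  The published traces give only
# ordinal levels (high/medium/low); the spacing here is a rendering choice.
STATE_LEVELS = {
    "cy3b": {
        "PIC": 1.0,          # 30S preinitiation complex (or split subunits)
        "split": 1.0,
        "nonrotated": 0.15,  # quenched 70S, non-rotated
        "rotated": 0.5,
        "interim": 0.33,     # partial rotation seen with GDPCP
    },
    "bound": 1.0,            # Cy5 / Cy5.5 factor bound
    "unbound": 0.05,
    "bleached": 0.05,
}


@dataclass(frozen=True)
class RF3Visit:
    """One RF3 occupancy interval, tagged sampling or productive."""

    t_bind: float
    t_dissoc: Optional[float]   # None if the movie ended while bound
    tag: str                    # "sampling" | "productive"

    def __post_init__(self) -> None:
        if self.tag not in ("sampling", "productive"):
            raise ValueError(f"bad visit tag {self.tag!r}")
        if self.t_dissoc is not None and self.t_dissoc < self.t_bind:
            raise ValueError("visit ends before it starts")


@dataclass
class EventTimeline:
    """Ground-truth event sequence for one ribosome, times in s from movie start.

    Events that did not occur before ``movie_length`` are None; the invariant
    checker ignores them.  ``elongation_rotations`` holds (enter, exit) times
    of the rotated state during each elongation cycle.
    """

    trace_id: str
    rf3_conc: float                     # uM
    nucleotide: str
    temperature: float                  # deg C
    mode: str                           # first_bound | rebound
    movie_length: float                 # s
    subunit_join: Optional[float] = None
    elongation_rotations: list[tuple[float, float]] = field(default_factory=list)
    rf_i_bind: Optional[float] = None
    rf3_visits: list[RF3Visit] = field(default_factory=list)
    rotation: Optional[float] = None
    rf_i_dissoc: Optional[float] = None
    subunit_split: Optional[float] = None

    def ordered_times(self) -> list[float]:
        """All recorded event times in occurrence order (for the ordering invariant)."""
        times: list[float] = []
        if self.subunit_join is not None:
            times.append(self.subunit_join)
        for a, b in self.elongation_rotations:
            times.extend((a, b))
        if self.rf_i_bind is not None:
            times.append(self.rf_i_bind)
        if self.rotation is not None:
            times.append(self.rotation)
        if self.rf_i_dissoc is not None:
            times.append(self.rf_i_dissoc)
        if self.subunit_split is not None:
            times.append(self.subunit_split)
        return times

    def validate(self) -> None:
        times = self.ordered_times()
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError(f"{self.trace_id}: events out of order")
        for v in self.rf3_visits:
            if self.nucleotide == "GDP" and v.tag == "productive":
                raise ValueError(f"{self.trace_id}: productive visit with GDP")

    @property
    def productive_visits(self) -> list[RF3Visit]:
        return [v for v in self.rf3_visits if v.tag == "productive"]


@dataclass
class Trace:
    """Frame-binned multi-channel intensities for one waveguide."""

    frame_times: np.ndarray       # s, uniform at 1/frame_rate
    cy3b: np.ndarray
    cy5: np.ndarray
    cy5_5: np.ndarray
    frame_rate: float             # Hz
    movie_length: float           # s
    noise_sd: float
    bleach_times: dict[str, Optional[float]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.frame_times)
        if not (len(self.cy3b) == len(self.cy5) == len(self.cy5_5) == n):
            raise ValueError("channel arrays must all have the frame count length")

    @property
    def n_frames(self) -> int:
        return len(self.frame_times)


def _exp(rng: np.random.Generator, rate: float) -> float:
    """Exponential waiting time; infinite for rate 0."""
    if rate <= 0:
        return math.inf
    return rng.exponential(1.0 / rate)


def _simulate_one(rates: SchemeRates, rf3k: RF3Kinetics, rf3_conc: float,
                  n_codons: int, mode: str, movie_length: float,
                  rf_conc: float, k_join: float, k_elong: float,
                  k_split_post: float, trace_id: str,
                  rng: np.random.Generator) -> EventTimeline:
    tl = EventTimeline(trace_id=trace_id, rf3_conc=rf3_conc,
                       nucleotide=rf3k.nucleotide, temperature=rates.temperature,
                       mode=mode, movie_length=movie_length)
    off_rates = np.array([r for r, _ in rf3k.k_3off])
    off_amps = np.array([a for _, a in rf3k.k_3off])
    k_rot_bound = rf3k.k_3BR if rf3k.k_3BR is not None else rates.k_iAR_plus
    k_rd = rf3k.k_1RD_plus if rf3k.k_1RD_plus is not None else rates.k_iRD_plus
    k_31d = rf3k.k_31D if rf3k.k_31D is not None else math.inf

    t = _exp(rng, k_join)
    if t >= movie_length:
        return tl
    tl.subunit_join = t

    for _ in range(n_codons):
        enter = t + _exp(rng, k_elong)
        leave = enter + _exp(rng, k_elong)
        if enter >= movie_length:
            return tl
        tl.elongation_rotations.append((enter, min(leave, movie_length)))
        if leave >= movie_length:
            return tl
        t = leave

    t_bind = t + _exp(rng, rates.k_ion * rf_conc)
    if t_bind >= movie_length:
        return tl
    tl.rf_i_bind = t_bind

    # termination-phase CTMC
    t = t_bind
    activated = mode == "rebound"
    t_act = t + _exp(rng, rates.k_iIA) if not activated else t
    lam3 = rf3k.k_3on * rf3_conc
    rotation: Optional[float] = None
    productive_pending = False

    while t < movie_length and rotation is None:
        # RF3-free ribosome: race next RF3 arrival / activation / spontaneous rotation
        t_rf3 = t + _exp(rng, lam3)
        t_rot = t + _exp(rng, rates.k_iAR_minus) if activated else math.inf
        if not activated and t_act < min(t_rf3, t_rot):
            t = t_act
            activated = True
            continue
        if t_rot <= t_rf3:
            rotation = t_rot
            break
        # RF3 binds; draw a sampling component, race dissociation vs
        # activation vs productive rotation
        tb = t_rf3
        if tb >= movie_length:
            t = tb
            break
        comp = rng.choice(len(off_rates), p=off_amps)
        t_off = tb + _exp(rng, off_rates[comp])
        tc = tb
        while True:
            t_rotb = tc + _exp(rng, k_rot_bound) \
                if (activated and rf3k.supports_rotation) else math.inf
            if not activated and t_act < min(t_off, t_rotb):
                tc = t_act
                activated = True
                continue
            if t_rotb < t_off:
                rotation = t_rotb
                productive_pending = True
                break
            break
        if productive_pending:
            if rotation >= movie_length:
                tl.rf3_visits.append(RF3Visit(tb, None, "sampling"))
                rotation = None
                t = movie_length
            break
        # sampling visit
        if t_off >= movie_length:
            tl.rf3_visits.append(RF3Visit(tb, None, "sampling"))
            t = movie_length
            break
        tl.rf3_visits.append(RF3Visit(tb, t_off, "sampling"))
        t = t_off

    if rotation is None or rotation >= movie_length:
        return tl
    tl.rotation = rotation

    if productive_pending:
        t_rfd = rotation + _exp(rng, k_rd)
        if t_rfd >= movie_length:
            tl.rf3_visits.append(RF3Visit(tb, None, "productive"))
            return tl
        tl.rf_i_dissoc = t_rfd
        t_3d = t_rfd + _exp(rng, k_31d)
        tl.rf3_visits.append(
            RF3Visit(tb, t_3d if t_3d < movie_length else None, "productive"))
        t_free = t_3d
    else:
        # spontaneous rotation: class-I RF release coincides with rotation
        tl.rf_i_dissoc = rotation
        t_free = rotation

    if t_free < movie_length:
        t_split = t_free + _exp(rng, k_split_post)
        if t_split < movie_length:
            tl.subunit_split = t_split
    tl.validate()
    return tl


def simulate_timelines(rates: SchemeRates, rf3k: RF3Kinetics, rf3_conc: float,
                       n_codons_before_stop: int, n_traces: int, seed: int,
                       mode: str = "first_bound", movie_length: float = 360.0,
                       rf_conc: float = 0.02, k_join: float = 0.2,
                       k_elong: float = 1.0,
                       k_split_post: float = 0.5) -> list[EventTimeline]:
    """Draw ``n_traces`` ground-truth timelines from the termination scheme.

    Parameters
    ----------
    rf3_conc
        RF3 concentration in uM (0 switches the RF3 branch off entirely).
    n_codons_before_stop
        Number of elongation cycles rendered before the stop codon.
    rf_conc
        Free class-I RF concentration in uM (default 20 nM as delivered in
        the assay); arrival rate is ``k_ion * rf_conc``.
    k_join, k_elong, k_split_post
        Plumbing rates (s^-1) for subunit joining, each half elongation
        cycle, and post-termination subunit splitting.

    Identical inputs and seed give identical output.
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    if rf3_conc < 0:
        raise ValueError("rf3_conc must be >= 0")
    if mode not in ("first_bound", "rebound"):
        raise ValueError(f"bad mode {mode!r}")
    rng = np.random.default_rng(seed)
    return [
        _simulate_one(rates, rf3k, rf3_conc, n_codons_before_stop, mode,
                      movie_length, rf_conc, k_join, k_elong, k_split_post,
                      f"trace{i:05d}", rng)
        for i in range(n_traces)
    ]


def _level_track(changes: list[tuple[float, float]], frame_ends: np.ndarray,
                 baseline: float) -> np.ndarray:
    """Piecewise-constant levels sampled per frame.

    ``changes`` are (time, new_level) pairs; a frame covering [k/f, (k+1)/f)
    shows the level in force just before its right edge, so an event's effect
    appears in the frame containing it and two events inside one frame are
    seen as simultaneous (only the final one is visible).
    """
    if not changes:
        return np.full(len(frame_ends), baseline)
    ts = np.array([c[0] for c in changes])
    levels = np.array([baseline] + [c[1] for c in changes])
    idx = np.searchsorted(ts, frame_ends, side="left")
    return levels[idx]


def render_trace(timeline: EventTimeline, frame_rate: float = 10.0,
                 noise_sd: float = 0.0,
                 bleach_rates: Optional[dict[str, float]] = None,
                 seed: int = 0) -> Trace:
    """Render a timeline as frame-binned three-channel intensities.

    Ideal levels follow :data:`STATE_LEVELS`; i.i.d. Gaussian noise of
    ``noise_sd`` is added per frame, and each channel may photobleach at an
    exponential rate (s^-1) given in ``bleach_rates`` (default: none), after
    which it shows baseline + noise only.
    """
    if not frame_rate > 0:
        raise ValueError("frame_rate must be > 0")
    rng = np.random.default_rng(seed)
    n = int(math.floor(timeline.movie_length * frame_rate))
    frame_ends = (np.arange(n) + 1) / frame_rate
    L = STATE_LEVELS

    # Cy3B: ribosome conformation
    c3: list[tuple[float, float]] = []
    if timeline.subunit_join is not None:
        c3.append((timeline.subunit_join, L["cy3b"]["nonrotated"]))
    for a, b in timeline.elongation_rotations:
        c3.append((a, L["cy3b"]["rotated"]))
        c3.append((b, L["cy3b"]["nonrotated"]))
    if timeline.rotation is not None:
        if (timeline.nucleotide == "GDPCP" and timeline.rf_i_dissoc is not None
                and timeline.rf_i_dissoc > timeline.rotation):
            # partial rotation until class-I RF departure completes it
            c3.append((timeline.rotation, L["cy3b"]["interim"]))
            c3.append((timeline.rf_i_dissoc, L["cy3b"]["rotated"]))
        else:
            c3.append((timeline.rotation, L["cy3b"]["rotated"]))
    if timeline.subunit_split is not None:
        c3.append((timeline.subunit_split, L["cy3b"]["split"]))
    cy3b = _level_track(sorted(c3), frame_ends, L["cy3b"]["PIC"])

    # Cy5.5: class-I RF occupancy
    c55: list[tuple[float, float]] = []
    if timeline.rf_i_bind is not None:
        c55.append((timeline.rf_i_bind, L["bound"]))
        if timeline.rf_i_dissoc is not None:
            c55.append((timeline.rf_i_dissoc, L["unbound"]))
    cy5_5 = _level_track(c55, frame_ends, L["unbound"])

    # Cy5: RF3 occupancy
    c5: list[tuple[float, float]] = []
    for v in timeline.rf3_visits:
        c5.append((v.t_bind, L["bound"]))
        if v.t_dissoc is not None:
            c5.append((v.t_dissoc, L["unbound"]))
    cy5 = _level_track(sorted(c5), frame_ends, L["unbound"])

    bleach_rates = bleach_rates or {}
    bleach_times: dict[str, Optional[float]] = {}
    for name, arr in (("cy3b", cy3b), ("cy5", cy5), ("cy5_5", cy5_5)):
        rate = bleach_rates.get(name, 0.0)
        tb = _exp(rng, rate)
        if tb < timeline.movie_length:
            bleach_times[name] = tb
            arr[frame_ends > tb] = L["bleached"]
        else:
            bleach_times[name] = None

    if noise_sd > 0:
        cy3b = cy3b + rng.normal(0.0, noise_sd, n)
        cy5 = cy5 + rng.normal(0.0, noise_sd, n)
        cy5_5 = cy5_5 + rng.normal(0.0, noise_sd, n)

    return Trace(
        frame_times=np.arange(n) / frame_rate,
        cy3b=np.asarray(cy3b, dtype=float),
        cy5=np.asarray(cy5, dtype=float),
        cy5_5=np.asarray(cy5_5, dtype=float),
        frame_rate=frame_rate, movie_length=timeline.movie_length,
        noise_sd=noise_sd, bleach_times=bleach_times,
        metadata={
            "trace_id": timeline.trace_id,
            "rf3_conc_uM": timeline.rf3_conc,
            "nucleotide": timeline.nucleotide,
            "temperature_C": timeline.temperature,
            "mode": timeline.mode,
        },
    )
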