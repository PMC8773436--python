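"""Ground-truthed synthetic flash traces, 2-D flash scenes, and spectra.

The generator emulates the night-time recordings this pipeline analyzes:
dark, noisy frames in which flying fireflies leave trails of oblong,
motion-blurred flashes tens of pixels apart and perching ones produce tight
clusters of round flashes, with species-specific single- or triple-pulse
timing.

**Timing model.**  Flash intervals and durations are drawn from truncated
normal distributions whose truncation bounds are the species' Min–Max
ranges.  The parent location is *moment-matched* (solved numerically) so
the mean of the truncated distribution equals the species' published mean —
using the published mean directly as the parent location would bias the
emitted mean wherever the Min–Max window is asymmetric about it.  The scale
is the published SD; on narrow windows the realized SD is necessarily
smaller (no truncated normal on a width-w interval has SD above w/sqrt(12)).

**Pulse model.**  Each pulse is a raised cosine whose width at 10% of peak
height equals the drawn FD (the measurement definition used downstream), so
zero-noise traces close the loop exactly.  Triple-pulse species render
three sub-pulses per event separated by ``intra_triple_gap`` (a free
parameter, default 0.08 s — small against the between-event FI and below
the grouping threshold); the event-level ground-truth FD is then
``2 * gap + sub_pulse_width``.

All randomness flows from a single seed through ``numpy`` SeedSequence
spawning, so every individual's stream is independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .pulse_timing import IntensityTrace, estimate_baseline
from .species_match import FLYING_MALE_TABLE, PERCHING_TABLE
from .video_io import FrameSequence, InputError

__all__ = [
    "SpeciesProfile",
    "IndividualSpec",
    "SceneSpec",
    "TraceTruth",
    "SceneTruth",
    "flying_profile",
    "perching_profile",
    "default_profiles",
    "matched_truncnorm",
    "simulate_trace",
    "simulate_scene",
    "simulate_case_study",
    "simulate_spectrum",
]

# width of a raised cosine at 10% of its height, as a fraction of its support
_TEN_PCT_WIDTH_FRACTION = float(np.arccos(2 * 0.10 - 1) / np.pi)  # ~0.7952


class ConfigurationError(ValueError):
    """Simulator settings that cannot produce an analyzable signal."""


@dataclass
class SpeciesProfile:
    """Flash-timing parameters of one species/behavior (seconds).

    FI and FD are truncated normals: mean/sd are the *target* statistics of
    the emitted draws, lo/hi the truncation bounds (the Min–Max range).
    """

    name: str
    pulse_form: str  # "single" | "triple"
    fi_mean: float
    fi_sd: float
    fi_lo: float
    fi_hi: float
    fd_mean: float
    fd_sd: float
    fd_lo: float
    fd_hi: float
    intra_triple_gap: float = 0.08
    sub_pulse_width: float = 0.06  # 10%-height width of one triple sub-pulse
    relative_brightness: float = 1.0

    def __post_init__(self) -> None:
        if not (self.fi_lo <= self.fi_mean <= self.fi_hi):
            raise InputError(f"{self.name}: FI mean outside its Min-Max range")
        if min(self.fi_lo, self.fd_lo, self.fi_sd, self.fd_sd) <= 0:
            raise InputError(f"{self.name}: FI/FD parameters must be positive")


def _profile_from_row(name: str, row: dict, **overrides) -> SpeciesProfile:
    return SpeciesProfile(
        name=name,
        pulse_form=row["pulse_form"],
        fi_mean=row["fi"]["mean"], fi_sd=row["fi"]["sd"],
        fi_lo=row["fi"]["lo"], fi_hi=row["fi"]["hi"],
        fd_mean=row["fd"]["mean"], fd_sd=row["fd"]["sd"],
        fd_lo=row["fd"]["lo"], fd_hi=row["fd"]["hi"],
        **overrides,
    )


def flying_profile(species: str) -> SpeciesProfile:
    """Packaged flying-male profile ('A. cerata', 'L. kagiana', 'L. curtithorax')."""
    if species not in FLYING_MALE_TABLE:
        raise InputError(f"unknown species {species!r}; have {list(FLYING_MALE_TABLE)}")
    return _profile_from_row(species, FLYING_MALE_TABLE[species])


def perching_profile(which: str = "A. cerata male") -> SpeciesProfile:
    """Packaged perching A. cerata profile ('A. cerata male' or '... female')."""
    if which not in PERCHING_TABLE:
        raise InputError(f"unknown profile {which!r}; have {list(PERCHING_TABLE)}")
    return _profile_from_row(which, PERCHING_TABLE[which], relative_brightness=0.8)


def default_profiles() -> dict[str, SpeciesProfile]:
    return {name: flying_profile(name) for name in FLYING_MALE_TABLE}


def matched_truncnorm(
    mean: float, sd: float, lo: float, hi: float
) -> stats.rv_continuous:
    """Truncated normal on [lo, hi] whose *truncated* mean equals ``mean``.

    The parent scale stays at ``sd``; the parent location is solved with
    brentq so that truncation does not shift the emitted mean.  Requires
    lo < mean < hi.
    """
    if not (lo < mean < hi):
        raise InputError(f"target mean {mean} must lie inside ({lo}, {hi})")

    def emitted_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd)

    span = 10 * sd + (hi - lo)
    mu = optimize.brentq(lambda m: emitted_mean(m) - mean, lo - span, hi + span,
                         xtol=1e-12)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm(a, b, loc=mu, scale=sd)


@dataclass
class TraceTruth:
    """Ground truth for one simulated trace."""

    event_times: np.ndarray  # first-peak time of each flash event (s)
    fi: np.ndarray  # drawn intervals (s), len = n_events - 1
    fd: np.ndarray  # ground-truth event-level 10%-width (s)
    pulse_form: str
    species: str


def _raised_cosine(t: np.ndarray, t_peak: float, width_10pct: float) -> np.ndarray:
    """Temporal pulse envelope, peak 1, 10%-height width = width_10pct."""
    support = width_10pct / _TEN_PCT_WIDTH_FRACTION
    x = (t - t_peak) / support
    env = np.where(np.abs(x) <= 0.5, 0.5 * (1.0 + np.cos(2 * np.pi * x)), 0.0)
    return env


def _check_resolution(width_10pct_lo: float, sample_rate: float) -> None:
    # a pulse spanning T seconds covers ~T*rate + 1 sample instants
    support = width_10pct_lo / _TEN_PCT_WIDTH_FRACTION
    if support * sample_rate + 1 < 3:
        raise ConfigurationError(
            f"sample rate {sample_rate} Hz leaves fewer than 3 samples on the "
            f"narrowest pulse ({width_10pct_lo} s at 10% height)"
        )


def _draw_schedule(
    profile: SpeciesProfile, duration: float, rng: np.random.Generator,
    t_start: float = 1.0, max_events: int | None = None,
) -> TraceTruth:
    """Event times from successive truncated-normal FI draws, with FDs."""
    fi_dist = matched_truncnorm(profile.fi_mean, profile.fi_sd,
                                profile.fi_lo, profile.fi_hi)
    times = [t_start]
    while max_events is None or len(times) < max_events:
        nxt = times[-1] + float(fi_dist.rvs(random_state=rng))
        if nxt > duration - profile.fd_hi:
            break
        times.append(nxt)
    times = np.asarray(times)
    if profile.pulse_form == "triple":
        fd = np.full(len(times),
                     2 * profile.intra_triple_gap + profile.sub_pulse_width)
    else:
        fd_dist = matched_truncnorm(profile.fd_mean, profile.fd_sd,
                                    profile.fd_lo, profile.fd_hi)
        fd = np.asarray(fd_dist.rvs(size=len(times), random_state=rng), dtype=float)
    return TraceTruth(event_times=times, fi=np.diff(times), fd=fd,
                      pulse_form=profile.pulse_form, species=profile.name)


def simulate_trace(
    profile: SpeciesProfile,
    duration: float,
    sample_rate: float = 30.0,
    seed: int | np.random.Generator = 0,
    amplitude: float = 100.0,
    noise_sd: float = 1.0,
    baseline: float = 10.0,
) -> tuple[IntensityTrace, TraceTruth]:
    """Simulate one individual's ROI intensity trace.

    Events follow a truncated-normal renewal process; each event is one
    raised-cosine pulse (or three sub-pulses for triple-form species) on a
    flat baseline with additive Gaussian noise.  Deterministic for a fixed
    seed.  Returns the trace and its ground truth.
    """
    if duration <= 2 * profile.fi_hi:
        raise ConfigurationError(
            f"duration {duration}s too short: need > 2*fi_hi = {2 * profile.fi_hi}s"
        )
    if profile.pulse_form == "triple":
        _check_resolution(profile.sub_pulse_width, sample_rate)
    else:
        _check_resolution(profile.fd_lo, sample_rate)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    truth = _draw_schedule(profile, duration, rng)
    t = np.arange(0.0, duration, 1.0 / sample_rate)
    v = np.full_like(t, baseline)
    amp = amplitude * profile.relative_brightness
    for k, t0 in enumerate(truth.event_times):
        if profile.pulse_form == "triple":
            for j in range(3):
                v += amp * _raised_cosine(
                    t, t0 + j * profile.intra_triple_gap, profile.sub_pulse_width
                )
        else:
            v += amp * _raised_cosine(t, t0, truth.fd[k])
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=len(t))
    trace = IntensityTrace(t=t, v=v)
    trace.baseline = estimate_baseline(v)
    return trace, truth


# ---------------------------------------------------------------------------
# 2-D scenes


@dataclass
class IndividualSpec:
    """One firefly in a scene."""

    profile: SpeciesProfile
    behavior: str  # "flying" | "perching"
    t_start: float = 0.0
    t_end: float | None = None  # None = scene duration
    step_mean: float = 59.2  # flying: mean consecutive flash displacement (px)
    step_sd: float = 27.4
    step_lo: float = 5.0
    step_hi: float = 150.0
    perch_jitter_sd: float = 6.3  # per-axis; gives ~11 px mean pair distance
    spot_radius: float = 4.0  # px, spatial footprint radius
    n_flashes: int | None = None  # cap on events within the active window
    home: tuple[float, float, float, float] | None = None  # (x0, y0, x1, y1)


@dataclass
class SceneSpec:
    """Ground-truth recipe of a synthetic flash scene."""

    duration: float = 30.0
    fps: float = 30.0
    width: int = 320
    height: int = 240
    individuals: Sequence[IndividualSpec] = field(default_factory=list)
    background_level: float = 10.0
    noise_sd: float = 3.0
    amplitude: float = 220.0
    seed: int = 0
    edge_margin: int = 40


@dataclass
class IndividualTruth:
    species: str
    behavior: str
    flash_times: np.ndarray  # event (first-)peak times
    flash_centers: np.ndarray  # (n, 2) x/y at event peak
    fi: np.ndarray
    fd: np.ndarray

    @property
    def consecutive_distances(self) -> np.ndarray:
        return np.hypot(*np.diff(self.flash_centers, axis=0).T)


@dataclass
class SceneTruth:
    individuals: list[IndividualTruth]

    @property
    def n_flashes(self) -> int:
        return sum(len(ind.flash_times) for ind in self.individuals)


def _assign_homes(
    individuals: Sequence[IndividualSpec], scene: "SceneSpec",
    rng: np.random.Generator,
) -> list[tuple[float, float, float, float]]:
    """A home region per individual: its own cell of a shuffled grid.

    Patrolling males keep to a local stretch of habitat, so each simulated
    individual is confined to one cell of a near-square partition of the
    frame (inside the edge margin); explicit ``home`` boxes are honored.
    """
    n = len(individuals)
    if n == 0:
        return []
    nc = int(np.ceil(np.sqrt(n)))
    nr = int(np.ceil(n / nc))
    m = scene.edge_margin
    xs = np.linspace(m, scene.width - m, nc + 1)
    ys = np.linspace(m, scene.height - m, nr + 1)
    cells = [(xs[i], ys[j], xs[i + 1], ys[j + 1])
             for j in range(nr) for i in range(nc)]
    order = rng.permutation(len(cells))[:n]
    return [
        ind.home if ind.home is not None else cells[order[k]]
        for k, ind in enumerate(individuals)
    ]


def _flying_path(
    n: int, spec: IndividualSpec, home: tuple[float, float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Flash-to-flash waypoints with truncated-normal step lengths.

    The heading turns smoothly between flashes; a step that would leave the
    home region re-draws its direction (length preserved — it is the
    ground-truth statistic), falling back to the farthest-corner direction
    on pathologically long steps.
    """
    lo = np.array(home[:2], dtype=float)
    hi = np.array(home[2:], dtype=float)
    step_dist = matched_truncnorm(spec.step_mean, spec.step_sd,
                                  spec.step_lo, spec.step_hi)
    pos = rng.uniform(lo, hi)
    theta = rng.uniform(0, 2 * np.pi)
    pts = [pos.copy()]
    for _ in range(n - 1):
        L = float(step_dist.rvs(random_state=rng))
        theta = theta + rng.normal(0.0, 0.6)
        nxt = pts[-1] + L * np.array([np.cos(theta), np.sin(theta)])
        tries = 0
        while (np.any(nxt < lo) or np.any(nxt > hi)) and tries < 100:
            theta = rng.uniform(0, 2 * np.pi)
            nxt = pts[-1] + L * np.array([np.cos(theta), np.sin(theta)])
            tries += 1
        if np.any(nxt < lo) or np.any(nxt > hi):
            corners = np.array([[lo[0], lo[1]], [lo[0], hi[1]],
                                [hi[0], lo[1]], [hi[0], hi[1]]])
            far = corners[np.argmax(np.hypot(*(corners - pts[-1]).T))]
            d = far - pts[-1]
            nxt = pts[-1] + d / np.hypot(*d) * min(L, float(np.hypot(*d)))
            theta = float(np.arctan2(d[1], d[0]))
        pts.append(nxt)
    return np.asarray(pts)


def _spatial_kernel(radius: float) -> tuple[np.ndarray, int]:
    r = int(np.ceil(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    d = np.hypot(xx, yy)
    k = np.where(d <= radius, 0.5 * (1 + np.cos(np.pi * d / radius)), 0.0)
    return k, r


def _stamp(frame: np.ndarray, x: float, y: float, kernel: np.ndarray,
           r: int, intensity: float) -> None:
    h, w = frame.shape
    cx, cy = int(round(x)), int(round(y))
    x0, x1 = max(cx - r, 0), min(cx + r + 1, w)
    y0, y1 = max(cy - r, 0), min(cy + r + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    kx0, ky0 = x0 - (cx - r), y0 - (cy - r)
    frame[y0:y1, x0:x1] += intensity * kernel[ky0 : ky0 + (y1 - y0),
                                              kx0 : kx0 + (x1 - x0)]


def simulate_scene(spec: SceneSpec) -> tuple[FrameSequence, SceneTruth]:
    """Render a synthetic flash scene with exact ground truth.

    Flying individuals move along smooth random paths; during a flash the
    position advances toward the next waypoint, and sub-frame substepping
    integrates the footprint along the path, producing the oblong motion-
    blurred shape.  Perching individuals jitter about a fixed point with
    round footprints.  Identical specs (including seed) render bit-identical
    frames.
    """
    ss = np.random.SeedSequence(spec.seed)
    noise_seed, layout_seed = ss.spawn(2)
    noise_rng = np.random.default_rng(noise_seed)
    homes = _assign_homes(spec.individuals, spec,
                          np.random.default_rng(layout_seed))
    ind_seeds = ss.spawn(max(len(spec.individuals), 1))

    frame_delay = 1.0 / spec.fps
    n_frames = int(round(spec.duration * spec.fps))
    truths: list[IndividualTruth] = []
    # (t_peak, fd, path of (x,y) during the pulse, profile, sub-offsets)
    stamps: list[tuple] = []

    for ind, home, iseed in zip(spec.individuals, homes, ind_seeds):
        rng = np.random.default_rng(iseed)
        t_end = ind.t_end if ind.t_end is not None else spec.duration
        window = t_end - ind.t_start
        if window <= 2 * ind.profile.fi_hi:
            raise ConfigurationError(
                f"{ind.profile.name}: active window {window}s too short"
            )
        sched = _draw_schedule(ind.profile, window, rng, max_events=ind.n_flashes)
        times = sched.event_times + ind.t_start
        n = len(times)
        if ind.behavior == "flying":
            centers = _flying_path(n, ind, home, rng)
        elif ind.behavior == "perching":
            pad = 3 * ind.perch_jitter_sd
            anchor = rng.uniform(
                [min(home[0] + pad, home[2]), min(home[1] + pad, home[3])],
                [max(home[2] - pad, home[0]), max(home[3] - pad, home[1])],
            )
            centers = anchor + rng.normal(0.0, ind.perch_jitter_sd, size=(n, 2))
            centers = np.clip(centers, 0, [spec.width - 1, spec.height - 1])
        else:
            raise InputError(f"unknown behavior {ind.behavior!r}")
        truths.append(
            IndividualTruth(
                species=ind.profile.name, behavior=ind.behavior,
                flash_times=times, flash_centers=centers,
                fi=sched.fi, fd=sched.fd,
            )
        )
        for k in range(n):
            if ind.behavior == "flying" and k + 1 < n:
                vel = (centers[k + 1] - centers[k]) / (times[k + 1] - times[k])
            else:
                vel = np.zeros(2)
            stamps.append((times[k], sched.fd[k], centers[k], vel, ind))

    # render frame by frame (uint8 output, float accumulation per frame)
    frames = np.empty((n_frames, spec.height, spec.width), dtype=np.uint8)
    kernels = {}
    amp = spec.amplitude
    substeps = 3
    for i in range(n_frames):
        t = i * frame_delay
        frame = np.full((spec.height, spec.width), spec.background_level, dtype=np.float64)
        if spec.noise_sd > 0:
            frame += noise_rng.normal(0.0, spec.noise_sd, size=frame.shape)
        for t_peak, fd, center, vel, ind in stamps:
            prof = ind.profile
            if prof.pulse_form == "triple":
                sub = [(j * prof.intra_triple_gap, prof.sub_pulse_width)
                       for j in range(3)]
            else:
                sub = [(0.0, fd)]
            for off, width in sub:
                support = width / _TEN_PCT_WIDTH_FRACTION
                tp = t_peak + off
                if abs(t - tp) > support / 2 + frame_delay:
                    continue
                key = (ind.spot_radius,)
                if key not in kernels:
                    kernels[key] = _spatial_kernel(ind.spot_radius)
                kernel, r = kernels[key]
                a = amp * prof.relative_brightness
                for s in range(substeps):
                    ts = t + (s - (substeps - 1) / 2) * frame_delay / substeps
                    env = _raised_cosine(np.array([ts]), tp, width)[0]
                    if env <= 0:
                        continue
                    p = center + vel * (ts - t_peak)
                    _stamp(frame, p[0], p[1], kernel, r, a * env / substeps)
        frames[i] = np.clip(np.round(frame), 0, 255).astype(np.uint8)

    seq = FrameSequence(frames=frames, frame_delay=frame_delay)
    return seq, SceneTruth(individuals=truths)


# ---------------------------------------------------------------------------
# case-study population and spectra


@dataclass
class CaseIndividual:
    """One regenerated flying individual of the case-study population."""

    individual_id: str
    group: str  # "G1" (A. cerata-like) | "G2" (L. kagiana-like) | "G3" (irregular)
    fi_points: np.ndarray


def simulate_case_study(
    composition: tuple[int, int, int] = (56, 10, 12),
    seed: int | np.random.SeedSequence = 0,
    points_range: tuple[int, int] = (7, 21),
    g3_span: tuple[float, float] = (0.13, 2.03),
) -> list[CaseIndividual]:
    """Regenerate a case-study flying population's FI point sets.

    ``composition`` gives the sizes of the three groups: G1 draws each
    individual's 7–21 FI points from the A. cerata flying profile (all
    inside its Min–Max range), G2 likewise from L. kagiana, and G3 — the
    irregular, unidentifiable group — uniformly over ``g3_span`` (the span
    of FI points observed in that group).  Returns labeled point sets.
    """
    g1, g2, g3 = composition
    if min(g1, g2, g3) < 0:
        raise InputError("group counts must be >= 0")
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    rng = np.random.default_rng(ss)
    profiles = {
        "G1": flying_profile("A. cerata"),
        "G2": flying_profile("L. kagiana"),
    }
    dists = {
        g: matched_truncnorm(p.fi_mean, p.fi_sd, p.fi_lo, p.fi_hi)
        for g, p in profiles.items()
    }
    out: list[CaseIndividual] = []
    lo_n, hi_n = points_range
    for group, count in zip(("G1", "G2", "G3"), (g1, g2, g3)):
        for i in range(count):
            k = int(rng.integers(lo_n, hi_n + 1))
            if group in dists:
                pts = np.asarray(dists[group].rvs(size=k, random_state=rng))
            else:
                pts = rng.uniform(g3_span[0], g3_span[1], size=k)
            out.append(CaseIndividual(f"{group}-{i:03d}", group, pts))
    return out


def simulate_spectrum(
    lambda_max: float,
    fwhm: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    wavelength_range: tuple[float, float] = (400.0, 700.0),
    amplitude: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic Gaussian emission spectrum on a 1 nm grid.

    sigma = fwhm / (2*sqrt(2*ln 2)); additive Gaussian noise when
    ``noise_sd`` > 0.
    """
    if not (wavelength_range[0] <= lambda_max <= wavelength_range[1]):
        raise InputError(f"lambda_max {lambda_max} outside {wavelength_range}")
    wl = np.arange(wavelength_range[0], wavelength_range[1] + 1.0, 1.0)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    inten = amplitude * np.exp(-0.5 * ((wl - lambda_max) / sigma) ** 2)
    if noise_sd > 0:
        inten = inten + np.random.default_rng(seed).normal(0, noise_sd, size=wl.shape)
    return wl, inten
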