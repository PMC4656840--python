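"""Synthetic data generators emulating the study's data-generating processes.

Every analyzer input can be simulated with known ground truth:

* dLGN section point patterns — a crescent region (outer disc minus a
  medially offset disc, lateral edge = the outer arc) with homogeneous
  Poisson NeuN and GAD point processes at the reported densities
  (1704 and 278 cells/mm²) and a c-Fos positive subset of the NeuN set
  drawn either uniformly or with an exponential lateral bias;
* paired control / 4-AP retinal ganglion cell spike trains: ON/OFF gain
  during light pulses in control, a 6.2-fold spontaneous-rate increase with
  a periodic-bursting subpopulation (frequency ~ N(3.52, 0.86) Hz truncated
  to the 5 Hz spectral range) and collapsed stimulus gains under 4-AP;
* confocal fluorescence fields with planted GAD-cell blobs of known effect
  size (in units of the background ROI-mean SD) and an exclusion mask over
  planted c-Fos blobs;
* VEP sweeps built from damped-sinusoid ON/OFF templates plus white noise;
* Poisson count records from the treatment-by-area mixed model.

All generators are deterministic given a seed and record their ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from ._geometry import polyline_distances
from .scoring import FluorescenceField
from .spatial import SectionPattern
from .spiketrain import SpikeTrain, StimulusProtocol
from .vep import VepSweep

__all__ = [
    "SectionParams",
    "SpikeGenParams",
    "CellTrains",
    "crescent_region",
    "make_section",
    "make_spike_trains",
    "make_field",
    "make_vep_sweeps",
    "make_count_records",
]


# ---------------------------------------------------------------------------
# Section point patterns
# ---------------------------------------------------------------------------


@dataclass
class SectionParams:
    """Geometry and intensities of one synthetic dLGN section.

    The region is the set difference of an outer disc and a medially offset
    disc; the lateral edge is the surviving outer arc.  Densities are in
    cells/mm² on µm coordinates.  ``lateral_bias_scale`` is the length scale
    (µm) of the exponential decay of activation probability with distance
    from the lateral edge; 0 draws the activated subset uniformly.
    """

    outer_radius: float = 900.0
    inner_radius: float = 1100.0
    inner_offset: float = 1500.0
    y_scale: float = 1.2  # vertical stretch turning the arcs into ellipses
    edge_fraction: float = 0.6  # central fraction of the outer arc used as edge
    neun_density: float = 1704.0
    gad_density: float = 278.0
    cfos_density: float = 228.0
    n_cfos: int | None = None
    lateral_bias_scale: float = 0.0
    section_id: str = "S1"
    rat_id: str = "R1"
    hemisphere: str = "contra"


def crescent_region(
    params: SectionParams, n_arc: int = 256
) -> tuple[Polygon, np.ndarray]:
    """Crescent polygon and its lateral-edge polyline (outer-arc vertices)."""
    R, r, off = params.outer_radius, params.inner_radius, params.inner_offset
    if off >= R + r:
        raise ValueError("discs do not overlap; no crescent")
    if off + R <= r:
        raise ValueError("outer disc swallowed by the inner disc")
    # intersection angle of the two circles, seen from the outer center
    cos_t = (R * R + off * off - r * r) / (2.0 * R * off)
    t = math.acos(min(1.0, max(-1.0, cos_t)))
    # outer arc (lateral edge): angles sweeping away from the inner disc
    ang_out = np.linspace(t, 2.0 * math.pi - t, n_arc)
    outer = np.column_stack([R * np.cos(ang_out), R * np.sin(ang_out)])
    # inner arc (medial border), seen from the inner center
    sin_phi = R * math.sin(t) / r
    phi = math.asin(min(1.0, max(-1.0, sin_phi)))
    ang_in = np.linspace(-(math.pi - phi), math.pi - phi, n_arc)
    inner = np.column_stack(
        [off - r * np.cos(ang_in), -r * np.sin(ang_in)]
    )
    ring = np.vstack([outer, inner[1:-1][::-1]])
    ring[:, 1] *= params.y_scale
    # lateral edge: central fraction of the outer arc (retinal fibers enter
    # the dLGN across its lateral border, not the whole perimeter)
    frac = min(max(params.edge_fraction, 0.05), 1.0)
    span = ang_out[-1] - ang_out[0]
    mid = 0.5 * (ang_out[0] + ang_out[-1])
    keep = np.abs(ang_out - mid) <= 0.5 * frac * span
    edge = outer[keep].copy()
    edge[:, 1] *= params.y_scale
    region = Polygon(ring)
    if not region.is_valid:
        region = region.buffer(0)
    return region, edge


def _uniform_in_region(
    region: Polygon, n: int, rng: np.random.Generator
) -> np.ndarray:
    minx, miny, maxx, maxy = region.bounds
    pts = np.empty((n, 2))
    got = 0
    import shapely

    while got < n:
        k = max(64, int((n - got) * 2.5))
        cand = np.column_stack(
            [rng.uniform(minx, maxx, k), rng.uniform(miny, maxy, k)]
        )
        inside = shapely.contains_xy(region, cand[:, 0], cand[:, 1])
        take = cand[inside][: n - got]
        pts[got : got + len(take)] = take
        got += len(take)
    return pts


def make_section(
    params: SectionParams | None = None,
    seed: int | np.random.Generator = 0,
) -> SectionPattern:
    """Simulate one section: NeuN/GAD Poisson points plus a c-Fos subset.

    NeuN and GAD points are independent homogeneous Poisson processes in the
    region.  The activated subset is drawn from the NeuN points without
    replacement with weight exp(-d_lateral/scale) (uniform when scale = 0).
    """
    params = params or SectionParams()
    rng = np.random.default_rng(seed)
    region, edge = crescent_region(params)
    area_mm2 = region.area / 1e6
    if area_mm2 <= 0:
        raise ValueError("region area is zero")
    n_neun = rng.poisson(params.neun_density * area_mm2)
    n_gad = rng.poisson(params.gad_density * area_mm2)
    if params.n_cfos is not None:
        n_cfos = int(params.n_cfos)
    else:
        n_cfos = int(round(params.cfos_density * area_mm2))
    n_neun = max(n_neun, n_cfos, 1)
    neun = _uniform_in_region(region, n_neun, rng)
    gad = _uniform_in_region(region, n_gad, rng) if n_gad else np.empty((0, 2))
    d_lat = polyline_distances(neun, edge)
    if params.lateral_bias_scale > 0:
        logw = -d_lat / params.lateral_bias_scale
    else:
        logw = np.zeros(n_neun)
    # weighted sampling without replacement via Gumbel keys
    keys = logw + rng.gumbel(size=n_neun)
    chosen = np.argsort(-keys)[:n_cfos]
    cfos_flag = np.zeros(n_neun, dtype=bool)
    cfos_flag[chosen] = True
    df = pd.DataFrame(
        {
            "x_um": np.concatenate([neun[:, 0], gad[:, 0]]),
            "y_um": np.concatenate([neun[:, 1], gad[:, 1]]),
            "neun": np.concatenate([np.ones(n_neun, bool), np.zeros(len(gad), bool)]),
            "cfos": np.concatenate([cfos_flag, np.zeros(len(gad), bool)]),
            "gad": np.concatenate([np.zeros(n_neun, bool), np.ones(len(gad), bool)]),
        }
    )
    truth = {
        "n_neun": int(n_neun),
        "n_gad": int(len(gad)),
        "n_cfos": int(n_cfos),
        "area_mm2": float(area_mm2),
        "lateral_bias_scale": float(params.lateral_bias_scale),
        "lateromedial_extent": float(
            polyline_distances(
                np.asarray(region.exterior.coords), edge
            ).max()
        ),
    }
    return SectionPattern(
        section_id=params.section_id,
        rat_id=params.rat_id,
        hemisphere=params.hemisphere,
        region=region,
        lateral_edge=edge,
        points=df,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------


@dataclass
class SpikeGenParams:
    """Population parameters for paired control / 4-AP spike trains."""

    n_cells: int = 20
    n_rats: int = 8
    on_fraction: float = 9 / 20  # 9 ON and 11 OFF cells of 20 recorded
    base_rate: float = 1.5  # Hz, control spontaneous rate
    fold_4ap: float = 6.2  # spontaneous-rate multiplier under 4-AP
    periodic_fraction: float = 12 / 20  # cells turning periodic under 4-AP
    period_freq_mean: float = 3.52  # Hz
    period_freq_sd: float = 0.86
    freq_bounds: tuple[float, float] = (0.5, 5.0)
    burst_sizes: tuple[int, ...] = (1, 2, 4, 5)
    intra_burst_isi: float = 0.03  # s; bursts span ~100 ms, dilating ACG peaks
    period_jitter_cv: float = 0.05
    stimulus_gain: float = 6.0  # rate multiplier in the preferred window
    gain_collapse_4ap: float = 0.05  # residual fraction of (gain-1) under 4-AP
    spont_duration: float = 120.0  # s of spontaneous recording


@dataclass
class CellTrains:
    """All four recordings of one cell with its generator ground truth."""

    cell_id: str
    rat_id: str
    is_on: bool
    control_stim: SpikeTrain
    ap4_stim: SpikeTrain
    control_spont: SpikeTrain
    ap4_spont: SpikeTrain
    ground_truth: dict = field(default_factory=dict)


def _poisson_train(
    rate: float, duration: float, rng: np.random.Generator
) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, n))


def _gain_profile_train(
    base: float,
    gain: float,
    window: tuple[float, float],
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Piecewise-constant-rate Poisson sweep with a gain inside ``window``."""
    w0, w1 = window
    parts = []
    for lo, hi, r in (
        (0.0, w0, base),
        (w0, w1, base * gain),
        (w1, duration, base),
    ):
        if hi > lo and r > 0:
            parts.append(_poisson_train(r, hi - lo, rng) + lo)
    t = np.sort(np.concatenate(parts)) if parts else np.empty(0)
    return _strictify(t)


def _strictify(t: np.ndarray, eps: float = 1e-9) -> np.ndarray:
    """Nudge coincident spike times so sweeps stay strictly increasing."""
    if t.size < 2:
        return t
    for i in range(1, t.size):
        if t[i] <= t[i - 1]:
            t[i] = t[i - 1] + eps
    return t


def _burst_train(
    freq: float,
    burst_size: int,
    intra_isi: float,
    jitter_cv: float,
    duration: float,
    rng: np.random.Generator,
) -> np.ndarray:
    period = 1.0 / freq
    times = []
    t = rng.uniform(0.0, period)
    while t < duration:
        for k in range(burst_size):
            s = t + k * intra_isi
            if s < duration:
                times.append(s)
        step = period * (1.0 + jitter_cv * rng.standard_normal())
        t += max(step, 0.1 * period)
    return _strictify(np.asarray(times))


def _truncnorm(
    mean: float, sd: float, bounds: tuple[float, float], rng: np.random.Generator
) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if bounds[0] < v <= bounds[1]:
            return float(v)
    return float(np.clip(mean, bounds[0] + 1e-6, bounds[1]))


def make_spike_trains(
    params: SpikeGenParams | None = None,
    protocol: StimulusProtocol | None = None,
    seed: int | np.random.Generator = 0,
) -> list[CellTrains]:
    """Simulate the paired control/4-AP recordings of a cell population.

    Control: spontaneous homogeneous Poisson at ``base_rate`` and stimulated
    sweeps with the ON/OFF gain in the class-appropriate window.  4-AP:
    spontaneous rate multiplied by ``fold_4ap`` with a ``periodic_fraction``
    of cells replaced by jittered periodic burst trains, and stimulus gains
    collapsed toward 1.
    """
    params = params or SpikeGenParams()
    protocol = protocol or StimulusProtocol(pulse_onset=5.0)
    rng = np.random.default_rng(seed)
    sweep_dur = protocol.sweep_duration
    on0 = protocol.pulse_onset
    on1 = on0 + protocol.pulse_duration
    off1 = on1 + protocol.pulse_duration
    n_on = int(round(params.on_fraction * params.n_cells))
    n_periodic = int(round(params.periodic_fraction * params.n_cells))
    is_on = np.zeros(params.n_cells, dtype=bool)
    is_on[:n_on] = True
    rng.shuffle(is_on)
    periodic = np.zeros(params.n_cells, dtype=bool)
    periodic[:n_periodic] = True
    rng.shuffle(periodic)
    gain4 = 1.0 + (params.stimulus_gain - 1.0) * params.gain_collapse_4ap
    cells = []
    for c in range(params.n_cells):
        cell_id = f"C{c + 1:02d}"
        rat_id = f"R{c % params.n_rats + 1}"
        window = (on0, on1) if is_on[c] else (on1, off1)
        ctrl_sweeps = [
            _gain_profile_train(
                params.base_rate, params.stimulus_gain, window, sweep_dur, rng
            )
            for _ in range(protocol.n_sweeps)
        ]
        rate4 = params.base_rate * params.fold_4ap
        freq = None
        burst = 0
        if periodic[c]:
            freq = _truncnorm(
                params.period_freq_mean,
                params.period_freq_sd,
                params.freq_bounds,
                rng,
            )
            burst = int(rng.choice(params.burst_sizes))
            spont4 = _burst_train(
                freq,
                burst,
                params.intra_burst_isi,
                params.period_jitter_cv,
                params.spont_duration,
                rng,
            )
            ap4_sweeps = [
                _burst_train(
                    freq,
                    burst,
                    params.intra_burst_isi,
                    params.period_jitter_cv,
                    sweep_dur,
                    rng,
                )
                for _ in range(protocol.n_sweeps)
            ]
        else:
            spont4 = _poisson_train(rate4, params.spont_duration, rng)
            ap4_sweeps = [
                _gain_profile_train(rate4, gain4, window, sweep_dur, rng)
                for _ in range(protocol.n_sweeps)
            ]
        cells.append(
            CellTrains(
                cell_id=cell_id,
                rat_id=rat_id,
                is_on=bool(is_on[c]),
                control_stim=SpikeTrain(cell_id, rat_id, "control", ctrl_sweeps, sweep_dur),
                ap4_stim=SpikeTrain(cell_id, rat_id, "4AP", ap4_sweeps, sweep_dur),
                control_spont=SpikeTrain(
                    cell_id,
                    rat_id,
                    "control",
                    [_poisson_train(params.base_rate, params.spont_duration, rng)],
                    params.spont_duration,
                ),
                ap4_spont=SpikeTrain(
                    cell_id, rat_id, "4AP", [spont4], params.spont_duration
                ),
                ground_truth={
                    "is_on": bool(is_on[c]),
                    "periodic": bool(periodic[c]),
                    "frequency": freq,
                    "burst_size": burst,
                    "base_rate": params.base_rate,
                    "rate_4ap": rate4,
                },
            )
        )
    return cells


# ---------------------------------------------------------------------------
# Fluorescence fields
# ---------------------------------------------------------------------------


def make_field(
    shape: tuple[int, int] = (512, 512),
    background_mean: float = 100.0,
    noise_sd: float = 10.0,
    n_gad: int = 10,
    gad_effects: float | Sequence[float] = 0.0,
    n_cfos_blobs: int = 3,
    roi_radius: int = 20,
    blob_sigma: float = 8.0,
    seed: int | np.random.Generator = 0,
    field_location: tuple[str, str] = ("central", "central"),
    field_id: str = "field",
) -> FluorescenceField:
    """Simulate a confocal c-Fos channel field with planted GAD cells.

    The background is i.i.d. Gaussian noise (clipped at zero) around
    ``background_mean``.  Each GAD cell adds a Gaussian-profile blob scaled
    so its ROI-disc mean is elevated by exactly ``effect`` times the
    theoretical background ROI-mean SD (noise_sd/sqrt(m), m = disc pixels);
    planted non-GAD c-Fos blobs are bright and covered by the exclusion
    mask.  Ground truth records the per-cell effects.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    img = background_mean + noise_sd * rng.standard_normal((h, w))
    effects = np.broadcast_to(
        np.atleast_1d(np.asarray(gad_effects, float)), (n_gad,)
    ).copy() if n_gad else np.empty(0)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = np.mgrid[-roi_radius : roi_radius + 1, -roi_radius : roi_radius + 1]
    disc = dy * dy + dx * dx <= roi_radius * roi_radius
    m = int(disc.sum())
    sigma_roi = noise_sd / math.sqrt(m)

    margin = 2 * roi_radius + 2
    mask = np.zeros((h, w), dtype=bool)
    # bright non-GAD c-Fos blobs, covered by the exclusion mask
    for _ in range(n_cfos_blobs):
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        rr2 = (yy - r) ** 2 + (xx - c) ** 2
        img += 8.0 * noise_sd * np.exp(-rr2 / (2.0 * blob_sigma**2))
        mask |= rr2 <= (1.5 * roi_radius) ** 2

    centers = []
    attempts = 0
    while len(centers) < n_gad:
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not place GAD centers away from the mask")
        r = int(rng.integers(margin, h - margin))
        c = int(rng.integers(margin, w - margin))
        if mask[max(0, r - margin) : r + margin, max(0, c - margin) : c + margin].any():
            continue
        if any((r - r0) ** 2 + (c - c0) ** 2 < (2 * roi_radius) ** 2 for r0, c0 in centers):
            continue
        centers.append((r, c))
    for (r, c), eff in zip(centers, effects):
        if eff == 0.0:
            continue
        rr2 = (yy - r) ** 2 + (xx - c) ** 2
        profile = np.exp(-rr2 / (2.0 * blob_sigma**2))
        # scale so the ROI-disc mean rises by exactly eff * sigma_roi
        local = profile[r + dy[disc], c + dx[disc]].sum()
        img += (eff * sigma_roi * m / local) * profile
        if eff >= 2.0:
            # clearly elevated cells are "putative c-Fos positive" and must
            # be avoided when resampling the background
            mask |= rr2 <= (1.5 * roi_radius) ** 2
    img = np.clip(img, 0.0, None)
    return FluorescenceField(
        image=img,
        gad_centers=np.asarray(centers, dtype=float).reshape(-1, 2),
        exclusion_mask=mask,
        field_location=field_location,
        field_id=field_id,
        ground_truth={
            "effects": effects,
            "sigma_roi": sigma_roi,
            "background_mean": background_mean,
            "noise_sd": noise_sd,
        },
    )


# ---------------------------------------------------------------------------
# VEP sweeps
# ---------------------------------------------------------------------------


def _damped_template(
    t: np.ndarray, amplitude: float, latency: float
) -> np.ndarray:
    """Damped sinusoid whose first crest has height ``amplitude`` at ``latency``."""
    if amplitude == 0.0:
        return np.zeros_like(t)
    f = 1.0 / (4.0 * latency)
    tau = 2.0 * latency
    # analytic crest of sin(2πft)·exp(-t/τ)
    w = 2.0 * math.pi * f
    t_star = math.atan(w * tau) / w
    shift = latency - t_star
    tt = t - shift
    g = np.where(tt > 0, np.sin(w * tt) * np.exp(-tt / tau), 0.0)
    peak = math.sin(w * t_star) * math.exp(-t_star / tau)
    return amplitude / peak * g


def make_vep_sweeps(
    on_amplitude: float = 150e-6,
    off_amplitude: float = 80e-6,
    on_latency: float = 0.040,
    off_latency: float = 0.070,
    noise_sd: float = 10e-6,
    n_sweeps: int = 30,
    sampling_rate: float = 20_000.0,
    stim_onset: float = 0.1,
    stim_duration: float = 0.3,
    duration: float = 0.7,
    condition: str = "control",
    seed: int | np.random.Generator = 0,
) -> tuple[list[VepSweep], dict]:
    """Simulate VEP sweeps: ON/OFF damped-sinusoid responses plus noise.

    The ON component peaks ``on_latency`` after stimulus onset (the P wave,
    40 ms by default) and the OFF component ``off_latency`` after stimulus
    end.  Returns the sweeps and the noise-free template ground truth.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    template = _damped_template(t - stim_onset, on_amplitude, on_latency)
    template += _damped_template(
        t - stim_onset - stim_duration, off_amplitude, off_latency
    )
    # noise band-limited like the acquisition chain (1 kHz low-pass)
    from scipy.signal import butter, filtfilt

    b, a = butter(4, 1000.0, fs=sampling_rate)

    def _noise() -> np.ndarray:
        return filtfilt(b, a, noise_sd * rng.standard_normal(n))

    sweeps = [
        VepSweep(
            voltage=template + _noise(),
            sampling_rate=sampling_rate,
            stim_onset=stim_onset,
            stim_duration=stim_duration,
            sweep_index=i,
            condition=condition,
        )
        for i in range(n_sweeps)
    ]
    truth = {
        "template": template,
        "on_amplitude": on_amplitude,
        "off_amplitude": off_amplitude,
        "on_latency": on_latency,
        "off_latency": off_latency,
    }
    return sweeps, truth


# ---------------------------------------------------------------------------
# Count records
# ---------------------------------------------------------------------------


def make_count_records(
    alpha: Sequence[float] = (3.0, 0.5, 0.8, -0.3),
    sigma_rat: float = 0.2,
    n_rats: int = 8,
    slices_per_rat: int = 9,
    areas: Sequence[float] | None = None,
    region: str = "dLGN",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate section counts from the treatment-by-area Poisson model.

    Treatment is assigned per rat (half the rats each); counts are Poisson
    with ln λ = (α0 + α1·I_t) + (α2 + α3·I_t)·area + b_rat and b_rat ~
    N(0, σ²).  Areas (mm²) default to Uniform(0.4, 0.9) per slice.
    """
    if sigma_rat < 0:
        raise ValueError("sigma_rat must be non-negative")
    a0, a1, a2, a3 = (float(v) for v in alpha)
    rng = np.random.default_rng(seed)
    rows = []
    b = rng.normal(0.0, sigma_rat, size=n_rats)
    for r in range(n_rats):
        it = 1 if r >= n_rats // 2 else 0
        for s in range(slices_per_rat):
            if areas is None:
                area = float(rng.uniform(0.4, 0.9))
            else:
                area = float(areas[s % len(areas)])
            if area <= 0:
                raise ValueError("areas must be positive")
            lam = math.exp(a0 + a1 * it + (a2 + a3 * it) * area + b[r])
            rows.append(
                {
                    "rat_id": f"R{r + 1}",
                    "region": region,
                    "hemisphere": "contra",
                    "treatment": it,
                    "area_mm2": area,
                    "count": int(rng.poisson(lam)),
                }
            )
    return pd.DataFrame(rows)
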