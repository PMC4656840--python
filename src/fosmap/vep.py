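"""Visual evoked potential (VEP) quantification and permutation tests.

Cortical responses to 300 ms light flashes are quantified per sweep in two
windows: 0-150 ms from stimulus onset (ON response) and 300-450 ms from
onset, i.e. the 150 ms after stimulus end (OFF response).  For each window
the metrics are the height of the first positive peak (relative to a 50 ms
pre-onset baseline; the recording chain is DC-decoupled so only
baseline-relative heights are meaningful) and the integral of the RMS
(window RMS x window duration, in V·s, computed on the raw trace).

Condition comparisons use two-sample permutation tests on a t-type
statistic, making no distributional assumption.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "VepSweep",
    "VepMetrics",
    "PermutationResult",
    "vep_metrics",
    "permutation_test",
    "sweep_matrix",
]

ON_WINDOW = (0.0, 0.150)  # s from stimulus onset
OFF_WINDOW = (0.300, 0.450)
BASELINE = 0.050


@dataclass
class VepSweep:
    voltage: np.ndarray  # V
    sampling_rate: float = 20_000.0
    stim_onset: float = 0.1
    stim_duration: float = 0.3
    sweep_index: int = 0
    condition: str = "control"

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float).ravel()
        if self.sampling_rate <= 0:
            raise ValueError("sampling rate must be positive")
        needed = self.stim_onset + OFF_WINDOW[1]
        if self.voltage.size / self.sampling_rate < needed:
            raise ValueError("trace too short for the ON/OFF analysis windows")


@dataclass
class VepMetrics:
    on_peak: float  # V, baseline-relative height of the first positive peak
    off_peak: float
    on_rms_integral: float  # V·s
    off_rms_integral: float
    on_peak_found: bool
    off_peak_found: bool


@dataclass
class PermutationResult:
    t_obs: float
    n_perm: int
    p_value: float
    seed: int
    exact: bool = False


def _window_slice(sweep: VepSweep, window: tuple[float, float]) -> np.ndarray:
    fs = sweep.sampling_rate
    i0 = int(round((sweep.stim_onset + window[0]) * fs))
    i1 = int(round((sweep.stim_onset + window[1]) * fs))
    return sweep.voltage[i0:i1]


def _first_positive_peak(segment: np.ndarray, baseline: float) -> tuple[float, bool]:
    """First positive local maximum with non-negligible prominence.

    A prominence floor of a quarter of the window's peak-to-peak excursion
    keeps single-sample noise crests from masquerading as the P wave while
    remaining scale-free.
    """
    v = segment - baseline
    span = float(v.max() - v.min())
    if span <= 0:
        return 0.0, False
    idx, _ = find_peaks(v, prominence=0.25 * span)
    for i in idx:
        if v[i] > 0:
            return float(v[i]), True
    return 0.0, False


def vep_metrics(sweep: VepSweep) -> VepMetrics:
    """Peak heights and RMS integrals of the ON and OFF responses.

    The peak is the first positive local maximum of the baseline-subtracted
    trace within the window (0 with a flag when none exists, e.g. on a
    constant trace); the RMS integral is sqrt(mean(v^2)) x 0.15 s over the
    raw window.
    """
    fs = sweep.sampling_rate
    b1 = int(round(sweep.stim_onset * fs))
    b0 = max(0, b1 - int(round(BASELINE * fs)))
    baseline = float(sweep.voltage[b0:b1].mean()) if b1 > b0 else 0.0
    on = _window_slice(sweep, ON_WINDOW)
    off = _window_slice(sweep, OFF_WINDOW)
    on_peak, on_found = _first_positive_peak(on, baseline)
    off_peak, off_found = _first_positive_peak(off, baseline)
    dur_on = ON_WINDOW[1] - ON_WINDOW[0]
    dur_off = OFF_WINDOW[1] - OFF_WINDOW[0]
    return VepMetrics(
        on_peak=on_peak,
        off_peak=off_peak,
        on_rms_integral=float(np.sqrt(np.mean(on**2)) * dur_on),
        off_rms_integral=float(np.sqrt(np.mean(off**2)) * dur_off),
        on_peak_found=on_found,
        off_peak_found=off_found,
    )


def _t_statistic(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance")
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb)))


def permutation_test(
    group_a,
    group_b,
    n_perm: int = 10_000,
    seed: int | np.random.Generator = 0,
    exact: bool = False,
) -> PermutationResult:
    """Two-sided permutation test on the two-sample t statistic.

    Labels are permuted ``n_perm`` times and p = (1 + #{|t*| >= |t_obs|}) /
    (1 + n_perm) (add-one so p is never exactly 0).  With ``exact=True`` all
    label assignments are enumerated instead and p is the plain proportion,
    which includes the identity assignment and is therefore >= 1/n_total.
    """
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least two values")
    pooled = np.concatenate([a, b])
    t_obs = _t_statistic(a, b)
    na = a.size
    n = pooled.size
    tol = 1e-12
    if exact:
        count = 0
        total = 0
        for idx in combinations(range(n), na):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx)] = True
            t = _t_statistic(pooled[mask], pooled[~mask])
            if abs(t) >= abs(t_obs) - tol:
                count += 1
            total += 1
        return PermutationResult(
            t_obs=t_obs, n_perm=total, p_value=count / total, seed=-1, exact=True
        )
    rng = np.random.default_rng(seed)
    # canonical form (sorted pool, smaller group permuted first) makes the
    # p-value exactly invariant to swapping the two groups
    canon = np.sort(pooled)
    k = min(na, n - na)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        t = _t_statistic(canon[perm[:k]], canon[perm[k:]])
        if abs(t) >= abs(t_obs) - tol:
            count += 1
    seed_val = seed if isinstance(seed, (int, np.integer)) else -1
    return PermutationResult(
        t_obs=t_obs,
        n_perm=n_perm,
        p_value=(1 + count) / (1 + n_perm),
        seed=int(seed_val),
    )


def sweep_matrix(sweeps) -> np.ndarray:
    """Stack equal-length sweeps into a trials x time matrix (heat-map view)."""
    sweeps = list(sweeps)
    if not sweeps:
        return np.empty((0, 0))
    traces = [np.asarray(s.voltage if hasattr(s, "voltage") else s, float) for s in sweeps]
    lengths = {t.size for t in traces}
    if len(lengths) > 1:
        raise ValueError("sweeps have unequal lengths")
    return np.vstack(traces)
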