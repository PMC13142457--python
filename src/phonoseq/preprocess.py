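"""Session preprocessing: z-scoring, PSTH smoothing, window extraction.

Conventions: all times are seconds relative to an alignment event; windows
are half-open ``[start, end)``; bin 0 starts at the event.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .exceptions import EmptySelectionError, EpochError
from .session import EVENT_NAMES, SessionData


@dataclass(frozen=True)
class EpochWindow:
    """A half-open time window relative to a trial alignment event."""

    align_event: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.align_event not in EVENT_NAMES:
            raise EpochError(f"unknown alignment event {self.align_event!r}")
        if self.end_s <= self.start_s:
            raise EpochError("window end must exceed start")

    @property
    def width_s(self) -> float:
        return self.end_s - self.start_s


#: windows used by the figure-level scenarios (preparatory widths differ
#: by analysis; each operation takes the window explicitly)
PREP_08 = EpochWindow("go_cue", -0.8, 0.0)
PREP_07 = EpochWindow("go_cue", -0.7, 0.0)
PREP_06 = EpochWindow("go_cue", -0.6, 0.0)
PREP_05 = EpochWindow("go_cue", -0.5, 0.0)


def zscore_session(session: SessionData, block_subtract: bool = True) -> SessionData:
    """Z-score each feature over all bins of the session.

    With ``block_subtract`` the per-block mean of each feature is removed
    first (slow-drift correction), then features are standardized to zero
    mean and unit variance over the whole session.  Zero-variance features
    pass through as all-zeros.
    """
    x = session.features.copy()
    if block_subtract:
        for b in np.unique(session.block_ids):
            sel = session.block_ids == b
            x[sel] -= x[sel].mean(axis=(0, 1), keepdims=True)
    mu = x.mean(axis=(0, 1), keepdims=True)
    sd = x.std(axis=(0, 1), keepdims=True)
    safe = np.where(sd > 0, sd, 1.0)
    z = (x - mu) / safe
    z[..., sd[0, 0] == 0] = 0.0
    out = replace(session, features=z)
    out.meta = dict(session.meta, zscored=True, block_subtract=block_subtract)
    return out


# ---------------------------------------------------------------------------
# window extraction
# ---------------------------------------------------------------------------

@dataclass
class WindowExtraction:
    """Result of pulling event-aligned windows out of a session."""

    matrix: np.ndarray          # average: (n, F); sliding: (n, T, F)
    times: np.ndarray | None    # sliding-window start offsets (s), or None
    kept: np.ndarray            # trial indices into the parent session
    n_dropped: int


def _bin_range(event_s: float, start_s: float, end_s: float, bin_s: float,
               n_bins: int) -> tuple[int, int] | None:
    """Indices of bins whose start time lies in [event+start, event+end)."""
    lo = int(np.ceil((event_s + start_s) / bin_s - 1e-9))
    hi = int(np.ceil((event_s + end_s) / bin_s - 1e-9))
    if lo < 0 or hi > n_bins or hi <= lo:
        return None
    return lo, hi


def extract_windows(
    session: SessionData,
    window: EpochWindow,
    mode: str = "average",
    width_ms: float | None = None,
    step_ms: float | None = None,
    trials=None,
) -> WindowExtraction:
    """Average or sliding-window features aligned to a trial event.

    ``average`` returns the mean over bins in ``[start, end)`` per trial.
    ``sliding`` emits windows of ``width_ms`` starting at ``start``,
    ``start+step``, ... while the window still fits inside ``[start, end]``.
    Trials for which the window is not fully recorded (or whose alignment
    event is missing) are dropped and counted.
    """
    idx = np.arange(session.n_trials) if trials is None \
        else np.asarray(trials, dtype=int)
    ev = session.events[window.align_event][idx]
    n_bins = session.n_bins
    bin_s = session.bin_s

    if mode == "average":
        rows, kept = [], []
        for j, (i, e) in enumerate(zip(idx, ev)):
            if not np.isfinite(e):
                continue
            rng = _bin_range(e, window.start_s, window.end_s, bin_s, n_bins)
            if rng is None:
                continue
            rows.append(session.features[i, rng[0]:rng[1]].mean(axis=0))
            kept.append(i)
        if not rows:
            raise EmptySelectionError("no trial covers the requested window")
        return WindowExtraction(
            matrix=np.array(rows), times=None, kept=np.array(kept),
            n_dropped=len(idx) - len(kept),
        )

    if mode != "sliding":
        raise ValueError(f"unknown mode {mode!r}")
    if width_ms is None or step_ms is None:
        raise ValueError("sliding mode needs width_ms and step_ms")
    width_s, step_s = width_ms / 1000.0, step_ms / 1000.0
    n_windows = int(np.floor(
        (window.width_s - width_s) / step_s + 1e-9
    )) + 1
    if n_windows < 1:
        raise EpochError("window narrower than the sliding width")
    starts = window.start_s + step_s * np.arange(n_windows)

    stacks, kept = [], []
    for i, e in zip(idx, ev):
        if not np.isfinite(e):
            continue
        per_t = []
        for s in starts:
            rng = _bin_range(e, s, s + width_s, bin_s, n_bins)
            if rng is None:
                per_t = None
                break
            per_t.append(session.features[i, rng[0]:rng[1]].mean(axis=0))
        if per_t is None:
            continue
        stacks.append(np.array(per_t))
        kept.append(i)
    if not stacks:
        raise EmptySelectionError("no trial covers the requested windows")
    return WindowExtraction(
        matrix=np.array(stacks), times=starts, kept=np.array(kept),
        n_dropped=len(idx) - len(kept),
    )


# ---------------------------------------------------------------------------
# PSTHs
# ---------------------------------------------------------------------------

def gaussian_smooth(traces: np.ndarray, sigma_bins: float, axis: int = -2
                    ) -> np.ndarray:
    """Gaussian smoothing along the time axis.

    The kernel is truncated at ±4σ and renormalized; edge bins use
    renormalized partial kernels (division by the smoothed all-ones trace)
    rather than padding, so a constant trace is exactly unchanged.
    """
    if sigma_bins <= 0:
        return traces
    half = int(np.ceil(4 * sigma_bins))
    t = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (t / sigma_bins) ** 2)
    k /= k.sum()

    traces = np.moveaxis(np.asarray(traces, float), axis, -1)
    shape = traces.shape
    flat = traces.reshape(-1, shape[-1])
    sm = np.apply_along_axis(lambda v: np.convolve(v, k, mode="same"), 1, flat)
    norm = np.convolve(np.ones(shape[-1]), k, mode="same")
    sm = sm / norm
    return np.moveaxis(sm.reshape(shape), -1, axis)


@dataclass
class PSTH:
    times: np.ndarray           # bin start offsets relative to the event (s)
    mean: np.ndarray            # (T, F)
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_trials: int


def smooth_psth(
    session: SessionData,
    trials,
    window: EpochWindow,
    sigma_ms: float = 60.0,
    n_boot: int = 10000,
    seed: int = 0,
    level: float = 0.95,
) -> PSTH:
    """Trial-averaged Gaussian-smoothed trace with a percentile bootstrap CI.

    ``trials`` selects the condition group (indices into the session); a CI
    over the mean requires at least two trials.
    """
    idx = np.asarray(trials, dtype=int)
    if idx.size == 0:
        raise EmptySelectionError("empty trial group")
    ext = extract_windows(
        session, window, mode="sliding",
        width_ms=session.bin_s * 1000.0, step_ms=session.bin_s * 1000.0,
        trials=idx,
    )
    if ext.matrix.shape[0] < 2:
        raise EmptySelectionError("need >= 2 trials for a bootstrap CI")
    sigma_bins = sigma_ms / (session.bin_s * 1000.0)
    smoothed = gaussian_smooth(ext.matrix, sigma_bins, axis=1)  # (n, T, F)
    mean = smoothed.mean(axis=0)
    rng = np.random.default_rng(seed)
    n = smoothed.shape[0]
    draws = rng.integers(0, n, size=(n_boot, n))
    boot = smoothed[draws].mean(axis=1)  # (n_boot, T, F)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(boot, [alpha, 1 - alpha], axis=0)
    return PSTH(times=ext.times, mean=mean, ci_low=lo, ci_high=hi, n_trials=n)
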