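"""Pupil trace preprocessing.

Cleaning proceeds in a fixed order: (i) linear interpolation across blinks
with a 150 ms margin on each side, (ii) zero-phase third-order Butterworth
band-pass (0.01-6 Hz), (iii) estimation of the stereotypical pupil responses
to blinks and saccades by FIR deconvolution and their removal by multiple
linear regression, (iv) conversion to percent signal change around the block
mean.  Blink/saccade *detection* is out of scope: event lists are inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "PupilTrace",
    "ArtifactIRFSet",
    "interpolate_blinks",
    "bandpass",
    "remove_artifact_responses",
    "to_percent_signal",
    "PupilPreprocessor",
]


@dataclass
class PupilTrace:
    """Uniformly sampled pupil diameter series for one block.

    samples are in arbitrary units before percent conversion, percent
    modulation after; blink/saccade events are (start_s, end_s) pairs.
    """

    samples: np.ndarray
    sample_rate: float
    block_id: int = 0
    blink_events: list = field(default_factory=list)
    saccade_events: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate

    @classmethod
    def from_csv(cls, trace_path, events_path=None, block_id=0):
        """Build a trace from a two-column (time_s, diameter) CSV; the
        optional events CSV needs columns kind ('blink'/'saccade'),
        start_s, end_s.  Sampling must be uniform."""
        import pandas as pd

        df = pd.read_csv(trace_path)
        t = df.iloc[:, 0].to_numpy(float)
        dt = np.diff(t)
        if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("trace CSV must be uniformly sampled")
        blinks, saccades = [], []
        if events_path is not None:
            ev = pd.read_csv(events_path)
            for row in ev.itertuples():
                target = blinks if row.kind == "blink" else saccades
                target.append((float(row.start_s), float(row.end_s)))
        return cls(samples=df.iloc[:, 1].to_numpy(float),
                   sample_rate=1.0 / dt[0], block_id=block_id,
                   blink_events=blinks, saccade_events=saccades)


@dataclass
class ArtifactIRFSet:
    """Deconvolved mean post-event responses (blink and saccade)."""

    blink_irf: np.ndarray | None
    saccade_irf: np.ndarray | None
    estimation_window_s: float

    def __post_init__(self):
        if self.estimation_window_s <= 0:
            raise ValueError("estimation window must be positive")


def _merge_events(events, margin, duration):
    """Expand events by the margin, clamp to the trace, merge overlaps."""
    expanded = sorted((max(0.0, s - margin), min(duration, e + margin))
                      for s, e in events)
    merged = []
    for s, e in expanded:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interpolate_blinks(trace: PupilTrace, margin_s: float = 0.15) -> PupilTrace:
    """Linearly interpolate across blinks, from ``margin_s`` before each
    blink until ``margin_s`` after it.

    Samples inside the expanded window are replaced by the straight line
    between the boundary samples; blinks touching a trace edge are clamped
    flat to the nearest valid sample.
    """
    x = trace.samples.copy()
    n = x.size
    fs = trace.sample_rate
    for s, e in _merge_events(trace.blink_events, margin_s, trace.duration):
        i0 = int(np.floor(s * fs))
        i1 = int(np.ceil(e * fs))
        lo = i0 - 1
        hi = min(i1 + 1, n - 1)
        if lo < 0 and hi >= n - 1:
            warnings.warn("blink spans the entire trace; leaving unchanged")
            continue
        if lo < 0:
            warnings.warn("blink touches trace start; extrapolating flat")
            x[: hi] = x[hi]
            continue
        if i1 >= n - 1:
            warnings.warn("blink touches trace end; extrapolating flat")
            x[lo + 1:] = x[lo]
            continue
        idx = np.arange(lo + 1, hi)
        x[idx] = np.interp(idx, [lo, hi], [x[lo], x[hi]])
    return replace(trace, samples=x)


def bandpass(trace: PupilTrace, low: float = 0.01, high: float = 6.0,
             order: int = 3, zero_phase: bool = True) -> PupilTrace:
    """Butterworth band-pass; zero-phase (forward-backward) by default so the
    filter adds no lag to response timing."""
    fs = trace.sample_rate
    if fs <= 2 * high:
        raise ValueError(f"sample rate {fs} too low for high cutoff {high}")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    # require ~3 time constants of the slowest corner, else edge transients
    # dominate the whole trace
    min_len = int(np.ceil(3.0 / (2.0 * np.pi * low) * fs)) if low > 0 else 0
    min_len = max(min_len, 3 * 3 * (2 * order + 1))
    if trace.samples.size <= min_len:
        raise ValueError(
            f"trace too short ({trace.samples.size / fs:.1f} s) for stable "
            f"band-pass filtering at low cutoff {low} Hz")
    if zero_phase:
        y = signal.sosfiltfilt(sos, trace.samples)
    else:
        y = signal.sosfilt(sos, trace.samples)
    return replace(trace, samples=y)


def _fir_design(n, fs, event_lists, window_s):
    """Stacked FIR (deconvolution) design: one column per post-event lag per
    event type, 1 where an event started lag samples earlier."""
    L = int(round(window_s * fs))
    cols = []
    for events in event_lists:
        X = np.zeros((n, L))
        for s, _ in events:
            i0 = int(round(s * fs))
            for lag in range(L):
                if 0 <= i0 + lag < n:
                    X[i0 + lag, lag] = 1.0
        cols.append(X)
    return np.hstack(cols), L


def remove_artifact_responses(trace: PupilTrace, window_s: float = 6.0,
                              min_events: int = 5):
    """Estimate and remove pupil responses to blinks and saccades.

    The mean response over ``window_s`` after each event is estimated for
    both event types jointly by least-squares FIR deconvolution; regressors
    formed by convolving the event sticks with the estimated responses are
    then regressed out of the trace.  Event types with fewer than
    ``min_events`` occurrences are skipped with a warning.

    Returns (residual trace, ArtifactIRFSet).
    """
    n = trace.samples.size
    fs = trace.sample_rate
    kinds = []
    if len(trace.blink_events) >= min_events:
        kinds.append(("blink", trace.blink_events))
    elif trace.blink_events:
        warnings.warn("fewer than %d blinks; skipping blink response removal"
                      % min_events)
    if len(trace.saccade_events) >= min_events:
        kinds.append(("saccade", trace.saccade_events))
    elif trace.saccade_events:
        warnings.warn("fewer than %d saccades; skipping saccade response removal"
                      % min_events)
    irfs = {"blink": None, "saccade": None}
    if not kinds:
        return replace(trace, samples=trace.samples.copy()), ArtifactIRFSet(
            None, None, window_s)

    X, L = _fir_design(n, fs, [ev for _, ev in kinds], window_s)
    beta, *_ = np.linalg.lstsq(X, trace.samples - trace.samples.mean(), rcond=None)
    for i, (name, _) in enumerate(kinds):
        irfs[name] = beta[i * L:(i + 1) * L]

    # second stage: convolve sticks with estimated responses, regress out
    regs = [np.ones(n)]
    for name, events in kinds:
        stick = np.zeros(n)
        for s, _ in events:
            i = int(round(s * fs))
            if 0 <= i < n:
                stick[i] += 1.0
        regs.append(np.convolve(stick, irfs[name])[:n])
    R = np.column_stack(regs)
    coef, *_ = np.linalg.lstsq(R, trace.samples, rcond=None)
    resid = trace.samples - R[:, 1:] @ coef[1:]
    return replace(trace, samples=resid), ArtifactIRFSet(
        irfs["blink"], irfs["saccade"], window_s)


def to_percent_signal(trace: PupilTrace, block_mean: float | None = None) -> PupilTrace:
    """Convert to percent modulation around the block mean:
    x -> 100*(x - m)/m.

    ``block_mean`` should be the mean of the interpolated, pre-band-pass
    trace (a band-passed trace has ~zero mean, which would make the ratio
    meaningless); it defaults to the mean of the given samples.
    """
    m = float(np.mean(trace.samples)) if block_mean is None else float(block_mean)
    if m <= 0:
        raise ValueError("block mean must be positive for percent conversion")
    return replace(trace, samples=100.0 * (trace.samples - m) / m)


class PupilPreprocessor(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer chaining the four cleaning steps in order:
    interpolate -> band-pass -> artifact-response removal -> percent signal.

    The block mean for the percent conversion is taken after interpolation
    and before band-passing.  ``transform`` accepts and returns PupilTrace
    objects (a single trace or a list)."""

    def __init__(self, margin_s=0.15, low=0.01, high=6.0, order=3,
                 zero_phase=True, artifact_window_s=6.0, remove_artifacts=True):
        self.margin_s = margin_s
        self.low = low
        self.high = high
        self.order = order
        self.zero_phase = zero_phase
        self.artifact_window_s = artifact_window_s
        self.remove_artifacts = remove_artifacts

    def fit(self, X, y=None):
        return self

    def transform_one(self, trace: PupilTrace) -> PupilTrace:
        t = interpolate_blinks(trace, self.margin_s)
        block_mean = float(np.mean(t.samples))
        t = bandpass(t, self.low, self.high, self.order, self.zero_phase)
        if self.remove_artifacts:
            t, self.artifact_irfs_ = remove_artifact_responses(
                t, self.artifact_window_s)
        # band-passed trace is a modulation around the (removed) mean; express
        # it as percent of the pre-band-pass block mean
        out = replace(t, samples=100.0 * t.samples / block_mean)
        if np.any(~np.isfinite(out.samples)):
            raise ValueError("preprocessing produced non-finite samples")
        return out

    def transform(self, X):
        if isinstance(X, PupilTrace):
            return self.transform_one(X)
        return [self.transform_one(t) for t in X]
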