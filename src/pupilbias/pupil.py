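"""Task-evoked pupil response (TPR) quantification and the pupil GLM.

The TPR of a trial is the mean percent pupil modulation in the window
-1 s to +1.5 s around the behavioral choice, minus the mean baseline value in
the 0.5 s before the cue.  Because the peripheral pupil apparatus low-pass
filters its neural input, longer decisions mechanically produce larger TPRs;
RT-driven variance is therefore removed by linear regression before trials
are binned by TPR.

The pupil GLM decomposes trial-evoked dilation into three neural input
components — a transient at cue, a transient 0.24 s before the button press
(the lead time of phasic locus-coeruleus firing over the overt response), and
a sustained boxcar spanning the decision interval — each convolved with a
canonical pupil impulse response function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "TPRRecord",
    "IRFParams",
    "PupilGLMResult",
    "compute_tpr",
    "residualize",
    "bin_trials",
    "pupil_irf",
    "build_design",
    "fit_pupil_glm",
    "PupilGLM",
]


@dataclass
class IRFParams:
    """Canonical pupil impulse response h(t) = (t/t_max)^w exp(-w(t/t_max-1)),
    an Erlang-like kernel normalized to peak 1 at t = t_max.

    Defaults (w=10.1, t_max=0.93 s) follow the canonical pupil IRF
    literature; both are exposed in config.
    """

    w: float = 10.1
    t_max: float = 0.93

    def __post_init__(self):
        if self.w <= 0 or self.t_max <= 0:
            raise ValueError("IRF parameters must be positive")


@dataclass
class TPRRecord:
    """Per-trial TPR quantities (percent modulation units)."""

    trial_id: int
    baseline: float
    amplitude_raw: float
    amplitude: float = np.nan  # RT-residualized
    bin_label: str | int | None = None
    complete: bool = True


@dataclass
class PupilGLMResult:
    beta_cue: float
    beta_choice: float
    beta_sustained: float
    r_squared: float
    predicted: np.ndarray


def pupil_irf(t, params: IRFParams = IRFParams()):
    """Canonical pupil impulse response; 0 for t < 0, peak 1 at t_max."""
    t = np.asarray(t, float)
    out = np.zeros_like(t)
    pos = t > 0
    r = t[pos] / params.t_max
    out[pos] = r**params.w * np.exp(-params.w * (r - 1.0))
    return out


def compute_tpr(trace, trial_table, response_window=(-1.0, 1.5),
                baseline_window=0.5) -> list[TPRRecord]:
    """Per-trial baseline and TPR amplitude from a preprocessed trace.

    ``trace`` is a PupilTrace in percent modulation; ``trial_table`` needs
    columns cue_time, choice_time (NaN for non-responses), trial_id.  Trials
    without a response are excluded; trials whose windows extend past the
    trace are flagged ``complete=False``.
    """
    fs = trace.sample_rate
    x = trace.samples
    n = x.size
    records = []
    for row in trial_table.itertuples():
        if not np.isfinite(row.choice_time):
            continue
        b0 = int(round((row.cue_time - baseline_window) * fs))
        b1 = int(round(row.cue_time * fs))
        r0 = int(round((row.choice_time + response_window[0]) * fs))
        r1 = int(round((row.choice_time + response_window[1]) * fs))
        complete = b0 >= 0 and r1 <= n and b1 > b0 and r1 > r0
        if not complete:
            records.append(TPRRecord(row.trial_id, np.nan, np.nan, complete=False))
            continue
        baseline = float(np.mean(x[b0:b1]))
        amp = float(np.mean(x[max(r0, 0):r1])) - baseline
        records.append(TPRRecord(row.trial_id, baseline, amp))
    return records


def residualize(values, covariate):
    """Remove a covariate by OLS, preserving the mean level.

    The covariate is centered, so the returned series equals the OLS
    residuals plus the mean of ``values``; its correlation with the covariate
    is zero by construction.  Used for removing RT from TPR and for removing
    RT or stimulus from fMRI responses.
    """
    y = np.asarray(values, float)
    x = np.asarray(covariate, float)
    xc = x - x.mean()
    denom = float(xc @ xc)
    if denom == 0:
        return y.copy()
    slope = float(xc @ (y - y.mean())) / denom
    return y - slope * xc


def bin_trials(amplitudes, scheme="three_40_20_40"):
    """Assign TPR-bin labels.

    ``three_40_20_40``: lowest 40% -> 'low', middle 20% -> 'mid', highest
    40% -> 'high' (the low/high bins are the analysis bins).
    ``quantile_k`` (k in {2..5}): k equally populated bins labeled 0..k-1.
    Ties are broken by stable order of trial index.
    """
    amp = np.asarray(amplitudes, float)
    n = amp.size
    order = np.argsort(amp, kind="stable")
    labels = np.empty(n, object)
    if scheme == "three_40_20_40":
        n_low = int(round(0.4 * n))
        n_high = int(round(0.4 * n))
        labels[order[:n_low]] = "low"
        labels[order[n_low:n - n_high]] = "mid"
        labels[order[n - n_high:]] = "high"
    elif scheme.startswith("quantile_"):
        k = int(scheme.split("_")[1])
        if not 2 <= k <= 5:
            raise ValueError("quantile schemes support 2-5 bins")
        for i, chunk in enumerate(np.array_split(order, k)):
            labels[chunk] = i
    else:
        raise ValueError(f"unknown binning scheme {scheme!r}")
    return labels


def build_design(trial_table, sample_rate, irf: IRFParams = IRFParams(),
                 epoch=(-1.0, 5.0), baseline_window=0.5, choice_offset=0.24):
    """Concatenated-epoch design for the pupil GLM.

    Epochs run from 1 s before cue to 5 s after cue.  Within each epoch three
    regressors are built and convolved with the IRF: a unit stick at cue, a
    unit stick at choice minus ``choice_offset`` (clamped to cue if earlier,
    with a warning), and a boxcar from cue to choice whose height is one over
    its sample count — so every pre-convolution column sums to 1 per trial
    and the three regressors share the same norm.

    Returns (design matrix [n_samples x 3], epoch slices per trial).
    """
    fs = sample_rate
    ep_len = int(round((epoch[1] - epoch[0]) * fs))
    kern = pupil_irf(np.arange(0, 6.0, 1.0 / fs), irf)
    rows = []
    slices = []
    pos = 0
    for row in trial_table.itertuples():
        if not np.isfinite(row.choice_time):
            continue
        sticks = np.zeros((ep_len, 3))
        i_cue = int(round(-epoch[0] * fs))
        rt = row.choice_time - row.cue_time
        i_choice = i_cue + int(round((rt - choice_offset) * fs))
        if i_choice < i_cue:
            warnings.warn("choice transient before cue; clamping to cue")
            i_choice = i_cue
        i_resp = i_cue + int(round(rt * fs))
        sticks[i_cue, 0] = 1.0
        if i_choice < ep_len:
            sticks[min(i_choice, ep_len - 1), 1] = 1.0
        n_box = max(i_resp - i_cue, 1)
        sticks[i_cue:min(i_resp, ep_len), 2] = 1.0 / n_box
        conv = np.column_stack(
            [np.convolve(sticks[:, j], kern)[:ep_len] for j in range(3)])
        rows.append(conv)
        slices.append(slice(pos, pos + ep_len))
        pos += ep_len
    if not rows:
        raise ValueError("no responded trials to build a design from")
    return np.vstack(rows), slices


def build_design_session(trial_table, sample_rate, n_samples,
                         irf: IRFParams = IRFParams(), choice_offset=0.24):
    """Design matrix over a whole continuous session (no epoching).

    Same three components as :func:`build_design` but convolved over the full
    session grid — the exact forward model of the synthetic trace generator,
    so noiseless traces are identified exactly.  Returns [n_samples x 3].
    """
    fs = sample_rate
    sticks = np.zeros((n_samples, 3))
    for row in trial_table.itertuples():
        if not np.isfinite(row.choice_time):
            continue
        i_cue = int(round(row.cue_time * fs))
        i_choice = max(int(round((row.choice_time - choice_offset) * fs)), i_cue)
        i_resp = int(round(row.choice_time * fs))
        sticks[i_cue, 0] += 1.0
        sticks[min(i_choice, n_samples - 1), 1] += 1.0
        n_box = max(i_resp - i_cue, 1)
        sticks[i_cue:min(i_resp, n_samples), 2] += 1.0 / n_box
    kern = pupil_irf(np.arange(0, 6.0, 1.0 / fs), irf)
    return np.column_stack(
        [np.convolve(sticks[:, j], kern)[:n_samples] for j in range(3)])


def concatenate_epochs(trace, trial_table, epoch=(-1.0, 5.0), baseline_window=0.5):
    """Cut baseline-corrected single-trial epochs and concatenate them,
    mirroring the design construction (responded trials only)."""
    fs = trace.sample_rate
    x = trace.samples
    ep_len = int(round((epoch[1] - epoch[0]) * fs))
    segs = []
    for row in trial_table.itertuples():
        if not np.isfinite(row.choice_time):
            continue
        i0 = int(round((row.cue_time + epoch[0]) * fs))
        seg = np.zeros(ep_len)
        avail = x[max(i0, 0):i0 + ep_len]
        seg[:avail.size] = avail
        b0 = int(round((row.cue_time - baseline_window) * fs))
        b1 = int(round(row.cue_time * fs))
        seg = seg - np.mean(x[max(b0, 0):b1])
        segs.append(seg)
    return np.concatenate(segs)


class PupilGLM(BaseEstimator, RegressorMixin):
    """OLS of the concatenated pupil time series on the three IRF-convolved
    input components (cue transient, choice transient, sustained boxcar).

    Fitted attributes: ``coef_`` (beta_cue, beta_choice, beta_sustained),
    ``r_squared_``, ``result_`` (PupilGLMResult)."""

    def __init__(self, irf: IRFParams = IRFParams(), epoch=(-1.0, 5.0),
                 baseline_window=0.5, choice_offset=0.24):
        self.irf = irf
        self.epoch = epoch
        self.baseline_window = baseline_window
        self.choice_offset = choice_offset

    def fit(self, X, y):
        """X: design matrix from :func:`build_design`; y: concatenated trace."""
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ beta
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.coef_ = beta
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        self.result_ = PupilGLMResult(*beta, self.r_squared_, pred)
        return self

    def fit_trace(self, trace, trial_table, bin_labels=None):
        """Fit from a trace + trial table; if ``bin_labels`` is given, fit
        separately per bin and return a dict label -> PupilGLMResult."""
        if bin_labels is None:
            X, _ = build_design(trial_table, trace.sample_rate, self.irf,
                                self.epoch, self.baseline_window, self.choice_offset)
            y = concatenate_epochs(trace, trial_table, self.epoch,
                                   self.baseline_window)
            return self.fit(X, y).result_
        out = {}
        responded = trial_table[np.isfinite(trial_table["choice_time"])]
        for lbl in np.unique(np.asarray(bin_labels)):
            sub = responded[np.asarray(bin_labels) == lbl]
            X, _ = build_design(sub, trace.sample_rate, self.irf, self.epoch,
                                self.baseline_window, self.choice_offset)
            y = concatenate_epochs(trace, sub, self.epoch, self.baseline_window)
            out[lbl] = PupilGLM(self.irf, self.epoch, self.baseline_window,
                                self.choice_offset).fit(X, y).result_
        return out

    def predict(self, X):
        return np.asarray(X, float) @ self.coef_


def fit_pupil_glm(trace, trial_table, irf: IRFParams = IRFParams(),
                  bin_labels=None, **kw) -> PupilGLMResult:
    """Functional wrapper over :class:`PupilGLM`."""
    return PupilGLM(irf=irf, **kw).fit_trace(trace, trial_table, bin_labels)
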