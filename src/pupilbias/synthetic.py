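"""Ground-truth generators for every input the pipeline consumes.

Each generator draws from a :class:`GroundTruth` whose defaults mirror the
study conditions the pipeline is meant for: blocks of 40 yes/no detection
trials with 50% signal prevalence, inter-trial intervals uniform on 4-12 s,
a 2 s pre-cue baseline, a 3.5 s response deadline; pupil traces built from
cue/choice transients and a sustained decision-interval boxcar convolved
with a canonical impulse response; choices and RTs from a stimulus-coded
diffusion whose drift criterion covaries with the trial's latent arousal
state (this latent state also scales the sustained pupil input, creating the
TPR-bias coupling downstream analyses must detect); weak orientation- and
choice-specific multivoxel patterns; and brainstem ROI responses coupled to
TPR.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddm import DDMParams, simulate
from .preproc import PupilTrace
from .pupil import IRFParams, pupil_irf

__all__ = [
    "GroundTruth",
    "generate_trial_table",
    "generate_pupil_trace",
    "session_trace",
    "generate_patterns",
    "generate_roi_responses",
    "WeibullObserver",
    "QuestStaircase",
    "StaircaseResult",
    "simulate_staircase",
]

BLOCK_SIZE = 40
DEADLINE_S = 3.5
BASELINE_S = 2.0
ITI_RANGE_S = (4.0, 12.0)

_DEFAULT_ROIS = ("LC", "VTA", "SN", "BF-sept", "BF-subl", "SC", "IC")


def _default_ddm_params():
    # shared a, z, v, t0, sv; only the drift criterion differs with the
    # latent arousal state: a conservative bias under low arousal that is
    # nearly neutralized under high arousal
    return {
        "low": DDMParams(a=1.4, z=0.5, v=0.7, dc=-0.30, t0=0.4, sv=0.2),
        "high": DDMParams(a=1.4, z=0.5, v=0.7, dc=-0.05, t0=0.4, sv=0.2),
    }


@dataclass
class GroundTruth:
    """Known parameters from which every synthetic input is generated."""

    ddm_params_per_bin: dict = field(default_factory=_default_ddm_params)
    pupil_betas: tuple = (1.0, 1.0, 2.0)  # cue, choice, sustained (% units)
    irf_params: IRFParams = field(default_factory=IRFParams)
    noise_sd: float = 1.0  # white trace noise, percent units
    blink_rate: float = 6.0  # events per minute
    n_trials: int = 400
    signal_fraction: float = 0.5
    # pattern amplitudes calibrated so the predictive indices land in the
    # empirically observed range (orientation ~0.63, choice ~0.55-0.6)
    voxel_effect_sizes: dict = field(
        default_factory=lambda: {"orientation": 0.07, "choice": 0.03, "noise": 1.0})
    roi_tpr_couplings: dict = field(
        default_factory=lambda: {"LC": 0.30, "VTA": 0.25, "SN": 0.25,
                                 "BF-sept": 0.20, "BF-subl": 0.20,
                                 "SC": 0.15, "IC": 0.15})
    seed: int = 0
    sample_rate: float = 50.0  # Hz; traces support up to 1000 Hz
    mean_level: float = 1000.0  # raw pupil units (a.u.)
    sustained_gain: tuple = (0.5, 1.5)  # sustained-beta scale (low, high)
    blink_response_amp: float = 1.0  # post-blink dilation, percent units

    def __post_init__(self):
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")


def generate_trial_table(gt: GroundTruth) -> pd.DataFrame:
    """Trial table with timing, stimulus, latent arousal state, choice, RT.

    Trials come in blocks of 40 with exactly ``signal_fraction`` signal
    trials per block; the latent arousal state ('low'/'high') is balanced
    within block and sets the trial's drift criterion and sustained pupil
    gain.  Choices/RTs are produced by the diffusion simulator; RTs beyond
    the 3.5 s deadline are recorded as non-responses.
    """
    n = gt.n_trials
    if n % BLOCK_SIZE:
        pad = BLOCK_SIZE - n % BLOCK_SIZE
        warnings.warn(f"n_trials={n} is not a multiple of {BLOCK_SIZE}; "
                      f"padding the final block with {pad} trials")
        n += pad
    n_blocks = n // BLOCK_SIZE
    rng = np.random.default_rng(gt.seed)

    rows = []
    t = BASELINE_S  # first cue after the initial baseline
    for b in range(n_blocks):
        n_sig = int(round(gt.signal_fraction * BLOCK_SIZE))
        stim = np.zeros(BLOCK_SIZE, int)
        stim[rng.permutation(BLOCK_SIZE)[:n_sig]] = 1
        cond = np.array(["low"] * (BLOCK_SIZE // 2) + ["high"] * (BLOCK_SIZE // 2))
        rng.shuffle(cond)
        orientation = "CW" if b % 2 == 0 else "CCW"
        for i in range(BLOCK_SIZE):
            rows.append({"block": b, "stimulus": stim[i], "tpr_condition": cond[i],
                         "orientation": orientation, "cue_time": np.nan})
    table = pd.DataFrame(rows)
    table.insert(0, "trial_id", np.arange(n))

    # choices/RTs per latent condition from the diffusion simulator
    rt = np.full(n, np.nan)
    choice = np.full(n, -1)
    for cond, params in gt.ddm_params_per_bin.items():
        m = (table["tpr_condition"] == cond).to_numpy()
        s = 2 * table.loc[m, "stimulus"].to_numpy() - 1
        seed = int(rng.integers(0, 2**31 - 1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rt[m], choice[m] = simulate(params, s, dt=1e-4, seed=seed)
    responded = np.isfinite(rt) & (rt <= DEADLINE_S) & (choice >= 0)
    table["rt"] = np.where(responded, rt, np.nan)
    table["choice"] = np.where(responded, choice, -1).astype(int)
    table["responded"] = responded

    # timing: cue after 2 s baseline; next trial after response (or
    # deadline) plus an ITI uniform on [4, 12] s
    cue_times = np.empty(n)
    block_start = np.empty(n)
    for i in range(n):
        if i > 0 and table.loc[i, "block"] != table.loc[i - 1, "block"]:
            t = np.ceil(t)  # align block starts to whole seconds
        cue_times[i] = t
        block_start[i] = np.nan
        dur = table.loc[i, "rt"] if responded[i] else DEADLINE_S
        t = t + dur + rng.uniform(*ITI_RANGE_S) + BASELINE_S
    table["cue_time"] = cue_times
    table["choice_time"] = table["cue_time"] + table["rt"]
    return table


def _block_bounds(table, sample_rate):
    """Per-block (start, end) in seconds, aligned to the sample grid."""
    bounds = []
    for b, sub in table.groupby("block"):
        start = sub["cue_time"].iloc[0] - BASELINE_S
        end_time = sub["cue_time"].iloc[-1] + DEADLINE_S + 10.0
        start = np.floor(start * sample_rate) / sample_rate
        bounds.append((b, max(start, 0.0), end_time))
    # a block ends where the next begins
    out = []
    for i, (b, s, e) in enumerate(bounds):
        e = bounds[i + 1][1] if i + 1 < len(bounds) else e
        out.append((b, s, e))
    return out


def generate_pupil_trace(trial_table: pd.DataFrame, gt: GroundTruth):
    """Per-block raw pupil traces generated from the pupil GLM forward model.

    trace = mean_level * (1 + modulation/100), where the modulation is the
    sum of cue/choice transients and the sustained boxcar (height 1/n
    samples, scaled by the latent arousal state) convolved with the canonical
    IRF, plus white noise and an AR(1) (rho=0.99) low-frequency drift, plus
    blink artifacts: sharp 100-300 ms dropouts followed by a small recovery
    dilation, with event times logged.

    Returns a list of PupilTrace (one per block, contiguous in session time).
    """
    if (trial_table["cue_time"].diff().dropna() <= 0).any():
        raise ValueError("overlapping or unordered trials")
    fs = gt.sample_rate
    rng = np.random.default_rng(gt.seed + 1)
    total = float(trial_table["cue_time"].iloc[-1]) + DEADLINE_S + 10.0
    n = int(np.ceil(total * fs))
    sticks = np.zeros((n, 3))
    gain = {"low": gt.sustained_gain[0], "high": gt.sustained_gain[1]}
    for row in trial_table.itertuples():
        i_cue = int(round(row.cue_time * fs))
        sticks[i_cue, 0] += 1.0
        if np.isfinite(row.choice_time):
            i_ch = int(round((row.choice_time - 0.24) * fs))
            sticks[max(i_ch, i_cue), 1] += 1.0
            i_resp = int(round(row.choice_time * fs))
        else:
            i_resp = i_cue + int(round(DEADLINE_S * fs))
        n_box = max(i_resp - i_cue, 1)
        sticks[i_cue:i_resp, 2] += gain[row.tpr_condition] / n_box
    kern = pupil_irf(np.arange(0, 6.0, 1.0 / fs), gt.irf_params)
    mod = np.zeros(n)
    for j, beta in enumerate(gt.pupil_betas):
        mod += beta * np.convolve(sticks[:, j], kern)[:n]

    # noise: white + slow AR(1) drift
    mod += rng.normal(0.0, gt.noise_sd, n)
    drift = np.empty(n)
    drift[0] = 0.0
    innov = rng.normal(0.0, gt.noise_sd / 5.0, n)
    for i in range(1, n):
        drift[i] = 0.99 * drift[i - 1] + innov[i]
    mod += drift

    # blinks: Poisson event times, 100-300 ms dropouts + recovery response
    n_blinks = rng.poisson(gt.blink_rate * total / 60.0)
    blink_times = np.sort(rng.uniform(1.0, total - 2.0, n_blinks))
    blink_events = []
    resp_kern = gt.blink_response_amp * pupil_irf(
        np.arange(0, 4.0, 1.0 / fs), IRFParams(w=2.0, t_max=1.0))
    for t0 in blink_times:
        dur = rng.uniform(0.1, 0.3)
        i0, i1 = int(round(t0 * fs)), int(round((t0 + dur) * fs))
        mod[i0:i1] = -60.0  # hard dropout, percent units
        i_end = min(i1 + resp_kern.size, n)
        mod[i1:i_end] += resp_kern[: i_end - i1]
        blink_events.append((t0, t0 + dur))
    # saccade events logged but given no artifact by default
    n_sacc = rng.poisson(8.0 * total / 60.0)
    sacc_times = np.sort(rng.uniform(1.0, total - 1.0, n_sacc))
    saccade_events = [(t0, t0 + 0.05) for t0 in sacc_times]

    raw = gt.mean_level * (1.0 + mod / 100.0)
    traces = []
    for b, start, end in _block_bounds(trial_table, fs):
        i0, i1 = int(round(start * fs)), min(int(round(end * fs)), n)
        traces.append(PupilTrace(
            samples=raw[i0:i1], sample_rate=fs, block_id=int(b),
            blink_events=[(s - start, e - start) for s, e in blink_events
                          if i0 / fs <= s < i1 / fs],
            saccade_events=[(s - start, e - start) for s, e in saccade_events
                            if i0 / fs <= s < i1 / fs],
        ))
    return traces


def save_traces(traces, path):
    """Write block traces as an NPZ array bundle plus a JSON sidecar holding
    sample rate, block ids and event lists."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez(path.with_suffix(".npz"),
             **{f"block_{t.block_id}": t.samples for t in traces})
    sidecar = {
        "sample_rate": traces[0].sample_rate,
        "blocks": [
            {"block_id": t.block_id,
             "blink_events": [list(map(float, e)) for e in t.blink_events],
             "saccade_events": [list(map(float, e)) for e in t.saccade_events]}
            for t in traces
        ],
    }
    with open(path.with_suffix(".json"), "w") as f:
        json.dump(sidecar, f)


def load_traces(path):
    """Read traces written by :func:`save_traces`."""
    import json
    from pathlib import Path

    path = Path(path)
    arrays = np.load(path.with_suffix(".npz"))
    with open(path.with_suffix(".json")) as f:
        sidecar = json.load(f)
    out = []
    for block in sidecar["blocks"]:
        b = block["block_id"]
        out.append(PupilTrace(
            samples=arrays[f"block_{b}"], sample_rate=sidecar["sample_rate"],
            block_id=b,
            blink_events=[tuple(e) for e in block["blink_events"]],
            saccade_events=[tuple(e) for e in block["saccade_events"]]))
    return out


def session_trace(traces):
    """Concatenate contiguous per-block traces back into one session trace
    on the global timeline (block 0 starts at its session offset)."""
    fs = traces[0].sample_rate
    samples = np.concatenate([t.samples for t in traces])
    return PupilTrace(samples=samples, sample_rate=fs, block_id=-1)


def generate_patterns(trial_table: pd.DataFrame, gt: GroundTruth,
                      n_voxels=100) -> "PatternSet":
    """Trial-by-voxel responses with weak orientation- and choice-specific
    components.

    Voxels split into two mirrored hemispheres (homotopic partner = the
    mirror voxel).  Response = baseline + orientation pattern (sign set by
    the CW/CCW block, present only on signal trials) + an antisymmetric
    choice/motor pattern (sign set by the choice) + i.i.d. Gaussian noise.
    Non-responded trials are dropped.
    """
    from .patterns import PatternSet

    if n_voxels % 2:
        raise ValueError("n_voxels must be even (two hemispheres)")
    rng = np.random.default_rng(gt.seed + 2)
    sub = trial_table[trial_table["responded"]].reset_index(drop=True)
    n_tr = len(sub)
    half = n_voxels // 2
    partner = np.concatenate([np.arange(half, n_voxels), np.arange(half)])
    hemisphere = np.array(["L"] * half + ["R"] * half)
    coords_half = rng.uniform([5, -40, -20], [45, 40, 40], size=(half, 3))
    coords = np.vstack([coords_half * [-1, 1, 1], coords_half])

    w_orient = rng.normal(0, 1, n_voxels)
    w_choice_half = rng.normal(0, 1, half)
    w_choice = np.concatenate([w_choice_half, -w_choice_half])  # lateralized
    baseline = rng.normal(0, 0.5, n_voxels)

    eff = gt.voxel_effect_sizes
    orient_sign = np.where(sub["orientation"].to_numpy() == "CCW", 1.0, -1.0)
    sig = sub["stimulus"].to_numpy().astype(float)
    ch_sign = np.where(sub["choice"].to_numpy() == 1, 1.0, -1.0)
    X = (baseline[None, :]
         + eff["orientation"] * (orient_sign * sig)[:, None] * w_orient[None, :]
         + eff["choice"] * ch_sign[:, None] * w_choice[None, :]
         + rng.normal(0, eff["noise"], (n_tr, n_voxels)))
    return PatternSet(
        responses=X,
        stimulus=sub["stimulus"].to_numpy(),
        choice=sub["choice"].to_numpy(),
        block_orientation=sub["orientation"].to_numpy(),
        hemisphere=hemisphere,
        homotopic_partner=partner,
        coords=coords,
    )


def generate_roi_responses(trial_table: pd.DataFrame, tpr, gt: GroundTruth,
                           shared_load=0.5, noise_sd=1.0,
                           nuisance_load=0.3) -> "ROIResponseSet":
    """Per-ROI trial responses: a shared latent factor common to all ROIs,
    an ROI-specific component coupled to (z-scored) TPR with the ground-truth
    coupling, leakage of a fourth-ventricle nuisance series (itself
    uncorrelated with TPR), and i.i.d. noise."""
    from .patterns import ROIResponseSet

    rng = np.random.default_rng(gt.seed + 3)
    tpr = np.asarray(tpr, float)
    n_tr = tpr.size
    tpr_z = (tpr - tpr.mean()) / tpr.std() if tpr.std() > 0 else tpr * 0
    names = list(gt.roi_tpr_couplings)
    shared = rng.normal(0, 1, n_tr)
    nuisance = rng.normal(0, 1, n_tr)
    X = np.column_stack([
        shared_load * shared + gt.roi_tpr_couplings[r] * tpr_z
        + nuisance_load * nuisance + rng.normal(0, noise_sd, n_tr)
        for r in names
    ])
    return ROIResponseSet(responses=X, roi_names=names, nuisance=nuisance,
                          tpr=tpr)


# ---------------------------------------------------------------------------
# adaptive staircase (Quest) with a simulated observer
# ---------------------------------------------------------------------------


@dataclass
class WeibullObserver:
    """Two-interval forced-choice observer with a Weibull psychometric
    function: P(correct | c) = dg + (1-d)[1 - (1-g) exp(-(c/alpha)^beta)],
    guess rate g=0.5 for 2IFC."""

    alpha: float  # threshold contrast
    beta: float = 3.5  # slope
    gamma: float = 0.5
    lapse: float = 0.01

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")

    def p_correct(self, contrast):
        c = np.asarray(contrast, float)
        core = 1.0 - (1.0 - self.gamma) * np.exp(-((c / self.alpha) ** self.beta))
        return self.lapse * self.gamma + (1.0 - self.lapse) * core

    def __call__(self, contrast):
        return self.p_correct(contrast)


@dataclass
class StaircaseResult:
    threshold_contrast: float  # contrast at the target accuracy
    threshold_estimate: float  # estimated Weibull threshold alpha
    contrasts: np.ndarray
    responses: np.ndarray


class QuestStaircase:
    """Bayesian adaptive staircase (Quest).

    Maintains a posterior over the log10 threshold of an assumed Weibull
    psychometric function; each trial is placed at the posterior-mean
    threshold shifted to the target-accuracy point of the assumed function,
    and the final recommendation is the contrast at which the assumed
    function predicts ``p_target`` correct.
    """

    def __init__(self, guess_contrast, prior_sd=0.5, p_target=0.75,
                 beta=3.5, gamma=0.5, lapse=0.01, grid_half_width=2.5,
                 grid_step=0.005):
        self.t_grid = np.arange(-grid_half_width, grid_half_width + grid_step,
                                grid_step) + np.log10(guess_contrast)
        self.log_post = -0.5 * ((self.t_grid - np.log10(guess_contrast))
                                / prior_sd) ** 2
        self.beta = beta
        self.gamma = gamma
        self.lapse = lapse
        self.p_target = p_target
        # offset from threshold to the target-accuracy point
        core = (p_target - lapse * gamma) / (1.0 - lapse)
        if not gamma < core < 1.0:
            raise ValueError("p_target unreachable for this psychometric")
        u = np.log10(-np.log((1.0 - core) / (1.0 - gamma)))
        self.epsilon = u / beta

    def _psi(self, x, T):
        core = 1.0 - (1.0 - self.gamma) * np.exp(-(10.0 ** (self.beta * (x - T))))
        return self.lapse * self.gamma + (1.0 - self.lapse) * core

    @property
    def threshold_mean(self):
        p = np.exp(self.log_post - self.log_post.max())
        p /= p.sum()
        return float(p @ self.t_grid)

    def next_contrast(self):
        return 10.0 ** (self.threshold_mean + self.epsilon)

    def update(self, contrast, correct):
        p = self._psi(np.log10(contrast), self.t_grid)
        self.log_post += np.log(np.clip(p if correct else 1.0 - p, 1e-12, None))


def simulate_staircase(observer, n_trials=200, seed=0, guess_contrast=None,
                       p_target=0.75, **quest_kw) -> StaircaseResult:
    """Run the Quest staircase against a simulated observer.

    ``observer`` is a WeibullObserver or any monotone callable mapping
    contrast to P(correct); a non-monotone psychometric is rejected.
    """
    probe = np.logspace(-4, 1, 200)
    pv = np.asarray([float(observer(c)) for c in probe])
    if np.any(np.diff(pv) < -1e-9):
        raise ValueError("observer psychometric function must be monotone")
    if guess_contrast is None:
        guess_contrast = (observer.alpha * 2.0
                          if isinstance(observer, WeibullObserver)
                          else float(probe[np.searchsorted(pv, 0.75)]))
    rng = np.random.default_rng(seed)
    q = QuestStaircase(guess_contrast, p_target=p_target, **quest_kw)
    contrasts = np.empty(n_trials)
    responses = np.empty(n_trials, bool)
    for i in range(n_trials):
        c = q.next_contrast()
        correct = rng.random() < float(observer(c))
        q.update(c, correct)
        contrasts[i] = c
        responses[i] = correct
    return StaircaseResult(
        threshold_contrast=q.next_contrast(),
        threshold_estimate=10.0 ** q.threshold_mean,
        contrasts=contrasts,
        responses=responses,
    )
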