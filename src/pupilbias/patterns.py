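"""fMRI response quantification and multivoxel pattern statistics.

Operates on trial-by-voxel pattern matrices (percent-signal-change scalars)
and trial-by-ROI scalar responses.  Includes scalar response extraction,
orientation/choice template-correlation scores with leave-one-trial-out
cross-validation, per-voxel choice logistic regression with hemispheric
lateralization, searchlight classification, ROC predictive indices with
condition balancing, combined (weighted) ROI signals, TPR-brainstem
correlation and partial correlation, and probability-threshold ROI masking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.svm import SVC

from .pupil import residualize

__all__ = [
    "PatternSet",
    "ROIResponseSet",
    "ChoiceLogisticFit",
    "trial_scalar_response",
    "voxel_tstat",
    "select_voxels",
    "template_response",
    "choice_logistic",
    "lateralize",
    "searchlight_choice",
    "roc_predictive_index",
    "combine_signals",
    "tpr_brainstem_correlation",
    "bin_linear_fit",
    "probability_mask",
    "roi_timeseries",
]


@dataclass
class PatternSet:
    """Trial-by-voxel responses with voxel metadata and per-trial labels.

    ``homotopic_partner`` maps each voxel to its mirror voxel in the other
    hemisphere (an involution); ``hemisphere`` is 'L'/'R' per voxel.
    """

    responses: np.ndarray  # trials x voxels
    stimulus: np.ndarray  # 1 signal+noise / 0 noise
    choice: np.ndarray  # 1 yes / 0 no
    block_orientation: np.ndarray  # 'CW'/'CCW' per trial
    hemisphere: np.ndarray | None = None
    homotopic_partner: np.ndarray | None = None
    coords: np.ndarray | None = None  # voxels x 3, mm

    def __post_init__(self):
        self.responses = np.asarray(self.responses, float)
        if self.homotopic_partner is not None:
            p = np.asarray(self.homotopic_partner)
            if not np.array_equal(p[p], np.arange(p.size)):
                raise ValueError("homotopic partner mapping must be an involution")


@dataclass
class ROIResponseSet:
    """Trial-by-ROI scalar responses with a nuisance (fourth ventricle)
    series and per-trial TPR."""

    responses: np.ndarray  # trials x ROIs
    roi_names: list
    nuisance: np.ndarray | None = None  # fourth-ventricle series per trial
    tpr: np.ndarray | None = None

    def __post_init__(self):
        self.responses = np.asarray(self.responses, float)
        if self.responses.shape[1] != len(self.roi_names):
            raise ValueError("roi_names length must match response columns")


@dataclass
class ChoiceLogisticFit:
    beta0: np.ndarray
    beta1: np.ndarray
    separation_flagged: np.ndarray = field(default=None)


def trial_scalar_response(epoch, times, response_window=(2.0, 12.0),
                          baseline_window=(-2.0, 2.0)):
    """Scalar task-evoked response: mean over 2-12 s from cue minus the mean
    over the -2 to 2 s baseline.  ``epoch`` may be 1-D (one trial) or
    trials x samples; ``times`` is seconds from cue per sample."""
    epoch = np.atleast_2d(np.asarray(epoch, float))
    times = np.asarray(times, float)
    resp = (times >= response_window[0]) & (times <= response_window[1])
    base = (times >= baseline_window[0]) & (times <= baseline_window[1])
    if not resp.any() or not base.any():
        raise ValueError("epoch does not cover the required windows")
    out = epoch[:, resp].mean(axis=1) - epoch[:, base].mean(axis=1)
    return out[0] if out.size == 1 else out


def voxel_tstat(responses, cond_a, cond_b):
    """Per-voxel Welch two-sample t contrasting two trial conditions:
    t = (mean_a - mean_b) / sqrt(sem_a^2 + sem_b^2)."""
    X = np.asarray(responses, float)
    a = X[np.asarray(cond_a, bool)]
    b = X[np.asarray(cond_b, bool)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 trials per condition")
    sem_a = a.std(axis=0, ddof=1) / np.sqrt(len(a))
    sem_b = b.std(axis=0, ddof=1) / np.sqrt(len(b))
    denom = np.sqrt(sem_a**2 + sem_b**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.where(denom > 0, t, 0.0)


def select_voxels(t_values, n_each=50):
    """The ``n_each`` most positive plus ``n_each`` most negative t-values
    (ties broken by voxel index); returns sorted voxel indices."""
    t = np.asarray(t_values, float)
    order = np.argsort(t, kind="stable")
    sel = np.concatenate([order[:n_each], order[-n_each:]])
    return np.sort(np.unique(sel))


def _pearson_rows(X, v):
    Xc = X - X.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(vc)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc @ vc) / denom
    return np.where(denom > 0, r, 0.0)


def template_response(patterns: PatternSet, mode="orientation", n_each=50,
                      selection=None):
    """Leave-one-trial-out template-correlation scores.

    For each held-out trial, a template is built from all *other* trials as
    the difference of condition-mean patterns — CCW minus CW for orientation
    mode (computed on signal trials), yes minus no for choice mode — over the
    voxels with the strongest condition preference (50 most positive + 50
    most negative t-values, reselected within each fold unless ``selection``
    gives independent indices).  The held-out pattern is Pearson-correlated
    with the template; in orientation mode the template is inverted on CW
    blocks so positive scores always mean 'stimulus-consistent'.

    Returns one correlation score per trial.
    """
    X = patterns.responses
    n = X.shape[0]
    scores = np.empty(n)
    if mode == "orientation":
        cond = np.asarray([o == "CCW" for o in patterns.block_orientation])
        train_mask_all = np.asarray(patterns.stimulus) == 1
    elif mode == "choice":
        cond = np.asarray(patterns.choice) == 1
        train_mask_all = np.ones(n, bool)
    else:
        raise ValueError("mode must be 'orientation' or 'choice'")

    for i in range(n):
        train = train_mask_all.copy()
        train[i] = False
        if len(np.unique(cond[train])) < 2:
            raise ValueError("a training fold contains a single condition")
        if selection is None:
            t = voxel_tstat(X[train], cond[train], ~cond[train])
            sel = select_voxels(t, min(n_each, X.shape[1] // 2))
        else:
            sel = np.asarray(selection)
        tmpl = X[train & cond][:, sel].mean(axis=0) - \
            X[train & ~cond][:, sel].mean(axis=0)
        if mode == "orientation" and patterns.block_orientation[i] == "CW":
            tmpl = -tmpl
        scores[i] = _pearson_rows(X[i:i + 1, sel], tmpl)[0]
    return scores


def choice_logistic(responses, choices, stimulus=None, maxiter=50):
    """Per-voxel ML logistic regression of choice on response amplitude:
    P(yes) = logistic(b0 + b1*A).

    With ``stimulus`` given, the fit is run separately on signal+noise and
    noise trials and the coefficient maps are averaged, isolating choice from
    stimulus.  Perfect separation is flagged (capped-iteration fit) rather
    than returned as a silently huge coefficient.
    """
    X = np.atleast_2d(np.asarray(responses, float))
    if X.shape[0] == np.asarray(choices).size and X.ndim == 2:
        pass
    y = np.asarray(choices, int)
    groups = [np.ones(y.size, bool)] if stimulus is None else [
        np.asarray(stimulus) == 1, np.asarray(stimulus) != 1]
    n_vox = X.shape[1]
    b0 = np.zeros((len(groups), n_vox))
    b1 = np.zeros((len(groups), n_vox))
    flagged = np.zeros(n_vox, bool)
    for g, mask in enumerate(groups):
        yy = y[mask]
        for j in range(n_vox):
            design = sm.add_constant(X[mask, j])
            with np.errstate(all="ignore"):
                try:
                    res = sm.Logit(yy, design).fit(disp=0, maxiter=maxiter)
                    b0[g, j], b1[g, j] = res.params
                    if not res.mle_retvals.get("converged", True):
                        flagged[j] = True
                except Exception:
                    flagged[j] = True
    return ChoiceLogisticFit(b0.mean(axis=0), b1.mean(axis=0), flagged)


def lateralize(patterns: PatternSet, yes_hand="right"):
    """Hemispheric lateralization of each voxel's response.

    For subjects whose 'yes' report uses the right hand the voxel map is
    first flipped with its homotopic counterpart, so lateralization is always
    expressed with respect to the hand used for 'yes'; each voxel's value is
    then its response minus that of its homotopic partner.  Applying the
    hemisphere flip twice is the identity.
    """
    if patterns.homotopic_partner is None:
        raise ValueError("patterns lack a homotopic partner mapping")
    X = patterns.responses
    partner = np.asarray(patterns.homotopic_partner)
    if yes_hand == "right":
        X = X[:, partner]
    elif yes_hand != "left":
        raise ValueError("yes_hand must be 'left' or 'right'")
    return X - X[:, partner]


def _sphere_members(coords, center, radius):
    d = np.linalg.norm(coords - coords[center], axis=1)
    return np.flatnonzero(d < radius)


def searchlight_choice(patterns: PatternSet, radius_mm=10.0, cost=1.0,
                       min_voxels=3, centers=None):
    """Leave-one-trial-out linear max-margin choice classification in a
    moving sphere; the mean cross-validated accuracy is assigned to the
    center voxel.  Computed separately per stimulus condition and averaged;
    spheres with fewer than ``min_voxels`` members are NaN-masked.
    """
    if patterns.coords is None:
        raise ValueError("patterns lack voxel coordinates")
    X = patterns.responses
    y = np.asarray(patterns.choice, int)
    stim = np.asarray(patterns.stimulus)
    coords = np.asarray(patterns.coords, float)
    centers = range(coords.shape[0]) if centers is None else centers
    out = np.full(coords.shape[0], np.nan)
    for c in centers:
        members = _sphere_members(coords, c, radius_mm)
        if members.size < min_voxels:
            continue
        accs = []
        for sval in (1, 0):
            m = stim == sval
            ym = y[m]
            if len(np.unique(ym)) < 2:
                continue
            Xm = X[m][:, members]
            correct = 0
            for i in range(len(ym)):
                train = np.ones(len(ym), bool)
                train[i] = False
                if len(np.unique(ym[train])) < 2:
                    continue
                clf = SVC(kernel="linear", C=cost)
                clf.fit(Xm[train], ym[train])
                correct += int(clf.predict(Xm[i:i + 1])[0] == ym[i])
            accs.append(correct / len(ym))
        if accs:
            out[c] = float(np.mean(accs))
    return out


def roc_predictive_index(scores, labels, balance_by=None):
    """Area under the ROC curve for predicting a binary trial variable from
    single-trial scores; 0.5 is chance.

    With ``balance_by`` given (e.g. choice when predicting the stimulus), the
    index is computed within each level of the balancing variable and
    averaged, removing the influence of the other variable.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    levels = [np.ones(labels.size, bool)] if balance_by is None else [
        np.asarray(balance_by) == lv for lv in np.unique(np.asarray(balance_by))]
    aucs = []
    for mask in levels:
        ll = labels[mask]
        if len(np.unique(ll)) < 2:
            continue
        pos = scores[mask][ll == np.max(ll)]
        neg = scores[mask][ll == np.min(ll)]
        # Mann-Whitney form of the AUC (ties count 1/2)
        ranks = stats.rankdata(np.concatenate([pos, neg]))
        auc = (ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2) \
            / (len(pos) * len(neg))
        aucs.append(auc)
    if not aucs:
        raise ValueError("no level of balance_by contains both classes")
    return float(np.mean(aucs))


def combine_signals(roi_responses, target, mode="linear"):
    """Weighted combination of single-trial ROI responses that best predicts
    ``target`` (multiple linear regression against TPR for the brainstem
    signal; multiple logistic regression of choice for the cortical
    variants).  Returns (weights, z-scored combined signal)."""
    X = np.atleast_2d(np.asarray(roi_responses, float))
    t = np.asarray(target, float)
    if mode == "linear":
        D = sm.add_constant(X)
        w = np.linalg.lstsq(D, t, rcond=None)[0][1:]
    elif mode == "logistic":
        D = sm.add_constant(X)
        w = sm.Logit(t.astype(int), D).fit(disp=0).params[1:]
    else:
        raise ValueError("mode must be 'linear' or 'logistic'")
    combined = X @ w
    sd = combined.std()
    combined = (combined - combined.mean()) / sd if sd > 0 else combined * 0.0
    return w, combined


def tpr_brainstem_correlation(roi_set: ROIResponseSet, stimulus):
    """Correlation and partial correlation between TPR and per-ROI trial
    responses.

    Fourth-ventricle nuisance fluctuations are first removed from every ROI
    response; effects of signal presence are removed from both TPR and the
    ROI responses; ``r`` is then the Pearson correlation per ROI.  The
    partial coefficient additionally removes all *other* ROI responses from
    both the ROI and TPR, isolating each ROI's unique TPR coupling.

    Returns a DataFrame indexed by ROI with columns r, partial_r.
    """
    if roi_set.tpr is None:
        raise ValueError("ROIResponseSet lacks TPR values")
    X = roi_set.responses.copy()
    stim = np.asarray(stimulus, float)
    if roi_set.nuisance is not None:
        for j in range(X.shape[1]):
            X[:, j] = residualize(X[:, j], roi_set.nuisance)
    tpr = residualize(roi_set.tpr, stim)
    for j in range(X.shape[1]):
        X[:, j] = residualize(X[:, j], stim)
    n_roi = X.shape[1]
    r = np.array([np.corrcoef(tpr, X[:, j])[0, 1] for j in range(n_roi)])
    partial = np.empty(n_roi)
    for j in range(n_roi):
        others = np.delete(X, j, axis=1)
        D = np.column_stack([np.ones(X.shape[0]), others])
        res_roi = X[:, j] - D @ np.linalg.lstsq(D, X[:, j], rcond=None)[0]
        res_tpr = tpr - D @ np.linalg.lstsq(D, tpr, rcond=None)[0]
        partial[j] = np.corrcoef(res_roi, res_tpr)[0, 1]
    return pd.DataFrame({"r": r, "partial_r": partial}, index=roi_set.roi_names)


def bin_linear_fit(ctx_residual, tpr, n_bins=5):
    """Linear fit of binned stimulus-residualized choice-specific responses
    on bin-mean TPR: Ctx = b0 + b1*TPR over ``n_bins`` TPR bins.

    Returns (b0, b1)."""
    from .pupil import bin_trials

    ctx = np.asarray(ctx_residual, float)
    tpr = np.asarray(tpr, float)
    labels = bin_trials(tpr, f"quantile_{n_bins}")
    xs = np.array([tpr[labels == k].mean() for k in range(n_bins)])
    ys = np.array([ctx[labels == k].mean() for k in range(n_bins)])
    b1, b0 = np.polyfit(xs, ys, 1)
    return float(b0), float(b1)


def probability_mask(probabilities, n_voxels=12):
    """Probability-threshold ROI rule: keep exactly the ``n_voxels`` voxels
    with the largest probability of containing the structure (ties broken by
    voxel index).  Returns (indices, normalized weights)."""
    p = np.asarray(probabilities, float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    if p.size < n_voxels:
        raise ValueError("fewer voxels than requested mask size")
    order = np.argsort(-p, kind="stable")
    idx = np.sort(order[:n_voxels])
    w = p[idx]
    total = w.sum()
    return idx, (w / total if total > 0 else np.full(n_voxels, 1.0 / n_voxels))


def roi_timeseries(voxel_responses, probabilities, n_voxels=12):
    """Probability-weighted average ROI response over the masked voxels."""
    idx, w = probability_mask(probabilities, n_voxels)
    return np.asarray(voxel_responses, float)[:, idx] @ w
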