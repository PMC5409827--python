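"""Signal-detection analyses of yes/no choice behavior conditioned on TPR.

d' = z(H) - z(F) measures sensitivity; criterion = -(z(H) + z(F))/2 measures
bias (negative = liberal, positive = conservative).  Because the fraction of
'yes' choices confounds bias with stimulus base rate, per-bin fractions are
computed on stimulus-balanced subsamples (repeated random subsampling to the
smallest TPR x stimulus cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SDTResult",
    "PolyRegressionSpec",
    "sdt_metrics",
    "sdt_from_trials",
    "balanced_fraction_yes",
    "nonpreferred_fraction",
    "abs_criterion",
    "sequential_poly_regression",
    "sliding_window_criterion",
    "paired_permutation_test",
]


@dataclass
class SDTResult:
    hit_rate: float
    fa_rate: float
    dprime: float
    criterion: float
    n_signal: int
    n_noise: int


@dataclass
class PolyRegressionSpec:
    """Sequential (hierarchical) polynomial regression of a per-bin metric on
    bin-mean TPR with orthogonalized bases of order 0-2."""

    betas: np.ndarray
    selected_order: int
    f_stats: list = field(default_factory=list)
    p_values: list = field(default_factory=list)
    subject_coefs: np.ndarray | None = None


def _rate(k, n):
    """Proportion with log-linear edge correction applied only when the raw
    rate is degenerate (0 or 1)."""
    if n <= 0:
        raise ValueError("empty cell")
    if k == 0 or k == n:
        return (k + 0.5) / (n + 1.0)
    return k / n


def sdt_metrics(hits, misses, fas, crs) -> SDTResult:
    """d' and criterion from the four response counts.

    Edge-corrected rates (add 0.5/1 when a rate would be 0 or 1);
    d' = z(H) - z(F); criterion = -(z(H) + z(F))/2.
    """
    for name, k in (("hits", hits), ("misses", misses), ("fas", fas), ("crs", crs)):
        if k < 0:
            raise ValueError(f"negative count in cell {name}")
    n_sig = hits + misses
    n_noise = fas + crs
    if n_sig == 0:
        raise ValueError("empty cell: no signal trials (hits+misses)")
    if n_noise == 0:
        raise ValueError("empty cell: no noise trials (fas+crs)")
    H = _rate(hits, n_sig)
    F = _rate(fas, n_noise)
    zH = stats.norm.ppf(H)
    zF = stats.norm.ppf(F)
    return SDTResult(H, F, zH - zF, -0.5 * (zH + zF), n_sig, n_noise)


def sdt_from_trials(stimulus, choice) -> SDTResult:
    """SDT metrics from per-trial stimulus (1 signal / 0 or -1 noise) and
    choice (1 yes / 0 no) vectors."""
    s = np.asarray(stimulus) > 0
    y = np.asarray(choice) == 1
    return sdt_metrics(int(np.sum(s & y)), int(np.sum(s & ~y)),
                       int(np.sum(~s & y)), int(np.sum(~s & ~y)))


def _balanced_fractions(stimulus, choice, bins, labels, count_fn,
                        n_resamples, seed):
    """Core balancing loop: per resample, draw the minimum cell count from
    every TPR x stimulus cell (without replacement) and apply ``count_fn``
    to the subsample of each bin."""
    s = np.asarray(stimulus) > 0
    y = np.asarray(choice) == 1
    bins = np.asarray(bins)
    cells = {}
    for lbl in labels:
        for sig in (True, False):
            idx = np.flatnonzero((bins == lbl) & (s == sig))
            if idx.size == 0:
                raise ValueError(f"empty cell: bin {lbl!r}, signal={sig}")
            cells[(lbl, sig)] = idx
    m = min(v.size for v in cells.values())
    rng = np.random.default_rng(seed)
    acc = {lbl: 0.0 for lbl in labels}
    for _ in range(n_resamples):
        for lbl in labels:
            take = np.concatenate([
                rng.choice(cells[(lbl, True)], m, replace=False),
                rng.choice(cells[(lbl, False)], m, replace=False),
            ])
            acc[lbl] += count_fn(y[take])
    return {lbl: acc[lbl] / n_resamples for lbl in labels}


def balanced_fraction_yes(stimulus, choice, bin_labels, n_resamples=1000, seed=0):
    """Fraction of 'yes' choices per TPR bin on stimulus-balanced subsamples,
    averaged over ``n_resamples`` random subsamples."""
    labels = list(np.unique(np.asarray(bin_labels)))
    return _balanced_fractions(stimulus, choice, bin_labels, labels,
                               lambda yy: float(np.mean(yy)), n_resamples, seed)


def nonpreferred_fraction(stimulus, choice, bin_labels, n_resamples=1000, seed=0):
    """Per-bin stimulus-balanced fraction of non-preferred choices.

    The preferred choice is the subject's overall majority choice across all
    trials irrespective of bin; an exact 50/50 tie prefers 'yes' (logged as
    the tie-break convention).  Returns (fractions per bin, preferred)."""
    y = np.asarray(choice) == 1
    preferred_yes = bool(np.mean(y) >= 0.5)  # tie -> 'yes'
    labels = list(np.unique(np.asarray(bin_labels)))

    def frac_nonpref(yy):
        return float(np.mean(~yy)) if preferred_yes else float(np.mean(yy))

    fracs = _balanced_fractions(stimulus, choice, bin_labels, labels,
                                frac_nonpref, n_resamples, seed)
    return fracs, ("yes" if preferred_yes else "no")


def abs_criterion(stimulus, choice, bin_labels):
    """|criterion| per bin — a relabeling-invariant bias magnitude."""
    bins = np.asarray(bin_labels)
    return {lbl: abs(sdt_from_trials(np.asarray(stimulus)[bins == lbl],
                                     np.asarray(choice)[bins == lbl]).criterion)
            for lbl in np.unique(bins)}


def _orthogonal_polys(x, order=2):
    """Gram-Schmidt-orthogonalized polynomial basis of x, columns 0..order."""
    x = np.asarray(x, float)
    X = np.column_stack([x**k for k in range(order + 1)])
    Q = np.zeros_like(X)
    for j in range(X.shape[1]):
        v = X[:, j].copy()
        for i in range(j):
            v -= (Q[:, i] @ X[:, j]) / (Q[:, i] @ Q[:, i]) * Q[:, i]
        Q[:, j] = v
    return Q


def sequential_poly_regression(metric, bin_values=None, alpha=0.05) -> PolyRegressionSpec:
    """Serial hierarchical polynomial regression of a per-bin metric.

    ``metric`` is a subjects x bins array.  The metric is modeled as
    y ~ b0 + b1*TPR + b2*TPR^2 on orthogonalized bases of the bin values
    (bin-mean TPR by default, bin index via ``bin_values=None`` -> 0..k-1),
    with subject intercepts (repeated-measures form).  Order k is accepted
    over k-1 by a nested-model F-test at level ``alpha``; testing stops at
    the first non-significant step.  If order >= 1 is selected, per-subject
    polynomial coefficients are returned for group-level testing.
    """
    Y = np.atleast_2d(np.asarray(metric, float))
    n_sub, n_bins = Y.shape
    if n_bins < 3:
        raise ValueError("need at least 3 bins")
    if n_sub < 2:
        raise ValueError("need at least 2 subjects")
    x = np.arange(n_bins, dtype=float) if bin_values is None \
        else np.asarray(bin_values, float)
    Q = _orthogonal_polys(x, 2)
    y = Y.ravel()
    subj = np.repeat(np.arange(n_sub), n_bins)
    S = np.eye(n_sub)[subj]  # subject intercepts

    def rss(order):
        X = np.hstack([S] + [np.tile(Q[:, k], n_sub)[:, None]
                             for k in range(1, order + 1)])
        b, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ b) ** 2)), X.shape[1]

    f_stats, p_values = [], []
    selected = 0
    prev_rss, prev_k = rss(0)
    for order in (1, 2):
        cur_rss, cur_k = rss(order)
        df2 = y.size - cur_k
        F = ((prev_rss - cur_rss) / (cur_k - prev_k)) / (cur_rss / df2)
        p = float(stats.f.sf(F, cur_k - prev_k, df2))
        f_stats.append(float(F))
        p_values.append(p)
        if p < alpha:
            selected = order
        prev_rss, prev_k = cur_rss, cur_k

    # group fit on bin means, plus per-subject coefficients at the
    # selected order (or linear if order 0) for group testing
    order_fit = max(selected, 1)
    Xg = Q[:, : order_fit + 1]
    betas, *_ = np.linalg.lstsq(Xg, Y.mean(axis=0), rcond=None)
    subject_coefs = np.array([np.linalg.lstsq(Xg, Y[i], rcond=None)[0]
                              for i in range(n_sub)])
    return PolyRegressionSpec(betas, selected, f_stats, p_values, subject_coefs)


def sliding_window_criterion(trace, trial_table, stimulus, choice,
                             window=0.25, step=0.025, n_bins=5,
                             t_start=-4.0, t_end=3.0, baseline_window=0.5):
    """Time course of the correlation between windowed pupil size and SDT
    criterion, aligned to the button press.

    For each window position, the baseline-corrected mean pupil value per
    trial is computed, trials are sorted into ``n_bins`` equal bins on it,
    criterion is estimated per bin, and the Pearson correlation between
    bin-mean pupil value and bin criterion is recorded.  Default span covers
    1 s before the (median-RT) cue to 3 s after the response.

    Returns (window start times relative to button press, correlations).
    """
    fs = trace.sample_rate
    x = trace.samples
    n = x.size
    rows = [r for r in trial_table.itertuples() if np.isfinite(r.choice_time)]
    stim = np.asarray(stimulus)
    ch = np.asarray(choice)
    baselines = []
    for r in rows:
        b0 = int(round((r.cue_time - baseline_window) * fs))
        b1 = int(round(r.cue_time * fs))
        baselines.append(np.mean(x[max(b0, 0):b1]))
    baselines = np.asarray(baselines)
    n_windows = int(np.floor((t_end - t_start - window) / step)) + 1
    starts = t_start + step * np.arange(n_windows)
    corrs = np.full(n_windows, np.nan)
    from .pupil import bin_trials  # local import to avoid cycle

    for i, w0 in enumerate(starts):
        vals = np.full(len(rows), np.nan)
        for j, r in enumerate(rows):
            i0 = int(round((r.choice_time + w0) * fs))
            i1 = int(round((r.choice_time + w0 + window) * fs))
            if 0 <= i0 and i1 <= n and i1 > i0:
                vals[j] = np.mean(x[i0:i1]) - baselines[j]
        ok = np.isfinite(vals)
        if ok.sum() < 4 * n_bins:
            continue
        labels = bin_trials(vals[ok], f"quantile_{n_bins}")
        means, crits = [], []
        for lbl in range(n_bins):
            m = labels == lbl
            try:
                res = sdt_from_trials(stim[ok][m], ch[ok][m])
            except ValueError:
                continue
            means.append(np.mean(vals[ok][m]))
            crits.append(res.criterion)
        if len(means) >= 3:
            corrs[i] = np.corrcoef(means, crits)[0, 1]
    return starts, corrs


def paired_permutation_test(a, b, n_perm=10000, seed=0, alternative="two-sided"):
    """Sign-flip permutation test on paired observations.

    The observed statistic is the mean paired difference; labels within each
    pair are randomly permuted (sign flips) and the p-value is the fraction
    of permutations whose statistic is at least as extreme.  For n pairs with
    2^n <= n_perm all sign patterns are enumerated exactly.
    """
    d = np.asarray(a, float) - np.asarray(b, float)
    n = d.size
    obs = float(np.mean(d))
    if 2**n <= n_perm:
        signs = np.array(np.meshgrid(*[[1.0, -1.0]] * n)).T.reshape(-1, n)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([1.0, -1.0], size=(n_perm, n))
    null = signs @ d / n
    if alternative == "two-sided":
        p = np.mean(np.abs(null) >= abs(obs) - 1e-12)
    elif alternative == "greater":
        p = np.mean(null >= obs - 1e-12)
    elif alternative == "less":
        p = np.mean(null <= obs + 1e-12)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(p)
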