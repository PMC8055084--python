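"""Time-resolved and spatial decoding of display-wise stimulus variables.

A ridge regression (on principal components of the sensor array, refit
inside every cross-validation fold) predicts each display's stimulus value
from the multichannel response at a fixed lag after display onset;
performance is the mean over held-out trials of the Pearson correlation
between predicted and true display sequences.  Cluster-based permutation
tests control multiple comparisons over lags or sensors; peak latency is
the t-weighted centroid of the largest supra-threshold cluster within
100-500 ms.  Cross-validated confound regression (CVCR) removes
confound-explained variance using coefficients estimated on training
folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from .synth import Recording

DECODE_SRATE = 120.0


# ------------------------------------------------------------ preparation

def downsample(recording: Recording, target: float = DECODE_SRATE) -> Recording:
    """Polyphase resampling of the epoch data to the decoding rate."""
    if abs(recording.srate - target) < 1e-9:
        return recording
    frac = Fraction(target / recording.srate).limit_denominator(1000)
    data = sp_signal.resample_poly(recording.data, frac.numerator,
                                   frac.denominator, axis=-1)
    return Recording(data=data, srate=target, tmin=recording.tmin,
                     ch_names=recording.ch_names, ch_kinds=recording.ch_kinds,
                     coords=recording.coords, trials=recording.trials,
                     displays=recording.displays)


def _display_values(recording: Recording, variable) -> np.ndarray:
    if isinstance(variable, str):
        if variable == "p":
            return recording.displays["p_actual"].to_numpy(dtype=float)
        if variable == "u":
            p = recording.displays["p_actual"].to_numpy(dtype=float)
            return p * (1 - p)
        return recording.displays[variable].to_numpy(dtype=float)
    return np.asarray(variable, dtype=float)


def _gather_features(rec: Recording, lags_idx: np.ndarray, values: np.ndarray,
                     confound_names=None):
    """Per-trial display onsets -> (trial_ids, onset samples, y, confounds)."""
    n_samp = rec.data.shape[2]
    max_lag = int(lags_idx.max())
    disp = rec.displays
    onset_idx = np.round((disp["onset_s"].to_numpy() - rec.tmin) * rec.srate).astype(int)
    ok = (onset_idx >= 0) & (onset_idx + max_lag < n_samp)
    trial_ids = disp["epoch"].to_numpy()[ok]
    y = values[ok]
    conf = None
    if confound_names is not None:
        conf = disp.loc[ok, list(confound_names)].to_numpy(dtype=float)
    return trial_ids, onset_idx[ok], y, conf


def _pearson(a, b):
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a ** 2).sum() * (b ** 2).sum())
    return float(a @ b / denom) if denom > 0 else np.nan


def _drop_bad_columns(C_train):
    """Indices of confound columns to keep: non-constant and full rank."""
    keep = [j for j in range(C_train.shape[1]) if C_train[:, j].std() > 1e-12]
    pruned = []
    for j in keep:
        cand = pruned + [j]
        X = np.column_stack([np.ones(len(C_train))] + [C_train[:, c] for c in cand])
        if np.linalg.matrix_rank(X) == X.shape[1]:
            pruned.append(j)
    return pruned


def cvcr_regress_out(features: np.ndarray, confounds: np.ndarray, folds):
    """Cross-validated confound regression on a displays x channels array.

    ``folds`` is a list of (train_idx, test_idx) over the display axis.
    Coefficients are estimated on each fold's training displays only and
    applied to that fold's test displays; the output rows are the
    residuals each display receives as a member of a test set.  Constant
    or collinear confound columns are dropped with a warning.
    """
    features = np.asarray(features, dtype=float)
    confounds = np.asarray(confounds, dtype=float)
    out = np.empty_like(features)
    warned = False
    for train, test in folds:
        keep = _drop_bad_columns(confounds[train])
        if len(keep) < confounds.shape[1] and not warned:
            warnings.warn("dropping constant/collinear confound columns",
                          RuntimeWarning)
            warned = True
        if keep:
            Xtr = np.column_stack([np.ones(len(train)), confounds[train][:, keep]])
            Xte = np.column_stack([np.ones(len(test)), confounds[test][:, keep]])
        else:
            Xtr = np.ones((len(train), 1))
            Xte = np.ones((len(test), 1))
        beta, *_ = np.linalg.lstsq(Xtr, features[train], rcond=None)
        out[test] = features[test] - Xte @ beta
    return out


# ------------------------------------------------------ time-resolved decode

@dataclass
class DecodingCourse:
    lags_ms: np.ndarray
    r: np.ndarray
    n_pca: int
    ridge: float
    n_trials: int
    n_excluded_folds: int = 0


def _decode_features(X, y, trial_ids, n_pca, ridge, confounds=None):
    """Leave-one-trial-out decoding of y from X (displays x channels)."""
    trials = np.unique(trial_ids)
    if len(trials) < 3:
        raise ValueError("need at least 3 trials for leave-one-out decoding")
    if confounds is not None:
        folds = [(np.where(trial_ids != t)[0], np.where(trial_ids == t)[0])
                 for t in trials]
        X = cvcr_regress_out(X, confounds, folds)
    rs, excluded = [], 0
    for t in trials:
        te = trial_ids == t
        tr = ~te
        ytr = y[tr]
        if ytr.std() == 0 or y[te].std() == 0:
            excluded += 1
            continue
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr = (X[tr] - mu) / sd
        Xte = (X[te] - mu) / sd
        # PCA fit on training displays only
        cov = Xtr.T @ Xtr / len(Xtr)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:min(n_pca, X.shape[1])]
        V = evecs[:, order]
        Ztr, Zte = Xtr @ V, Xte @ V
        ys = (ytr - ytr.mean()) / ytr.std()
        A = Ztr.T @ Ztr + ridge * np.eye(Ztr.shape[1])
        w = np.linalg.solve(A, Ztr.T @ ys)
        rs.append(_pearson(Zte @ w, y[te]))
    return float(np.nanmean(rs)), excluded


def timeresolved_decode(recording: Recording, variable="u", lags_ms=None,
                        n_pca: int = 30, ridge: float = 1.0,
                        confounds=None, autocorr_warn: float = 0.2) -> DecodingCourse:
    """Per-lag leave-one-trial-out decoding course.

    ``variable`` is ``"p"``, ``"u"``, a column of ``recording.displays``
    or an explicit per-display array.  ``confounds`` may list confound
    column names for CVCR.  The decoded sequence should be aperiodic: a
    lag-1 autocorrelation above ``autocorr_warn`` triggers a warning.
    """
    rec = downsample(recording)
    if lags_ms is None:
        lags_ms = np.arange(0.0, 901.0, 1000.0 / rec.srate)
    lags_ms = np.asarray(lags_ms, dtype=float)
    lags_idx = np.round(lags_ms / 1000.0 * rec.srate).astype(int)
    values = _display_values(rec, variable)
    conf_names = list(confounds) if confounds is not None else None
    trial_ids, onsets, y, conf = _gather_features(rec, lags_idx, values, conf_names)

    rho1 = _lag1_autocorr(y, trial_ids)
    if abs(rho1) > autocorr_warn:
        warnings.warn(f"decoded sequence has lag-1 autocorrelation {rho1:.2f}; "
                      "time-resolved decoding assumes an aperiodic variable",
                      RuntimeWarning)
    r = np.empty(len(lags_idx))
    excluded = 0
    for li, lag in enumerate(lags_idx):
        X = rec.data[trial_ids, :, onsets + lag]
        r[li], exc = _decode_features(X, y, trial_ids, n_pca, ridge, conf)
        excluded += exc
    return DecodingCourse(lags_ms=lags_ms, r=r, n_pca=n_pca, ridge=ridge,
                          n_trials=len(np.unique(trial_ids)),
                          n_excluded_folds=excluded)


def _lag1_autocorr(y, trial_ids):
    pairs_a, pairs_b = [], []
    for t in np.unique(trial_ids):
        v = y[trial_ids == t]
        pairs_a.append(v[:-1])
        pairs_b.append(v[1:])
    a, b = np.concatenate(pairs_a), np.concatenate(pairs_b)
    return _pearson(a, b)


def decode_shuffle_null(recording: Recording, variable="u", n_perm: int = 20,
                        rng_seed: int = 0, **kw) -> np.ndarray:
    """Null decoding courses from per-trial shuffles of the display sequence.

    This is the permutation scheme of the cluster test: the stimulus
    sequence of each trial is shuffled and the full decoding rerun.
    Returns an (n_perm, n_lags) array for one subject.
    """
    rng = np.random.default_rng(rng_seed)
    rec = downsample(recording)
    values = _display_values(rec, variable)
    epochs = rec.displays["epoch"].to_numpy()
    out = []
    for _ in range(n_perm):
        shuffled = values.copy()
        for t in np.unique(epochs):
            m = epochs == t
            shuffled[m] = rng.permutation(shuffled[m])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out.append(timeresolved_decode(rec, shuffled, **kw).r)
    return np.array(out)


# ------------------------------------------------- cluster-based inference

def _contiguous_clusters(mask):
    runs, start = [], None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append(np.arange(start, i))
            start = None
    if start is not None:
        runs.append(np.arange(start, len(mask)))
    return runs


def _t_right(r_subjects):
    r = np.asarray(r_subjects, dtype=float)
    n = r.shape[0]
    t = stats.ttest_1samp(r, 0.0, axis=0).statistic
    p = stats.t.sf(t, df=n - 1)
    return t, p


def cluster_permutation_time(r_subjects, lags_ms, n_perm: int = 500,
                             rng_seed: int = 0, alpha: float = 0.05,
                             null_r=None) -> dict:
    """Cluster-based permutation test of a subjects x lags decoding matrix.

    Adjacent lags with right-sided one-sample t-test p < ``alpha`` form
    clusters; the statistic is the summed t.  The null maximum-cluster
    distribution comes from ``null_r`` (n_perm x subjects x lags decoding
    courses obtained by per-trial stimulus shuffling) when provided;
    otherwise a subject sign-flip surrogate is used and flagged in the
    returned ``method``.
    """
    r = np.asarray(r_subjects, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2:
        raise ValueError("need a subjects x lags matrix with >= 2 subjects")
    lags_ms = np.asarray(lags_ms, dtype=float)
    t_obs, p_obs = _t_right(r)
    clusters = _contiguous_clusters(p_obs < alpha)

    def max_stat(matrix):
        t, p = _t_right(matrix)
        runs = _contiguous_clusters(p < alpha)
        return max((t[run].sum() for run in runs), default=0.0)

    rng = np.random.default_rng(rng_seed)
    if null_r is not None:
        null_r = np.asarray(null_r, dtype=float)
        null_max = np.array([max_stat(null_r[i]) for i in range(null_r.shape[0])])
        method = "stimulus-shuffle"
    else:
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=r.shape[0])[:, None]
            null_max[i] = max_stat(r * signs)
        method = "signflip-surrogate"
    out = []
    for run in clusters:
        stat = float(t_obs[run].sum())
        p_cl = float((1 + np.sum(null_max >= stat)) / (1 + len(null_max)))
        out.append({"lags_idx": run, "start_ms": float(lags_ms[run[0]]),
                    "end_ms": float(lags_ms[run[-1]]), "sum_t": stat, "p": p_cl})
    return {"t": t_obs, "p_uncorrected": p_obs, "clusters": out,
            "lags_ms": lags_ms, "method": method}


def estimate_peak_latency(lags_ms, t_vals, clusters, window=(100.0, 500.0)):
    """t-weighted centroid of the largest-sum cluster within the window.

    Returns None when no supra-threshold cluster intersects the window.
    """
    lags_ms = np.asarray(lags_ms, dtype=float)
    best, best_sum = None, -np.inf
    for cl in clusters:
        run = cl["lags_idx"] if isinstance(cl, dict) else np.asarray(cl)
        inside = run[(lags_ms[run] >= window[0]) & (lags_ms[run] <= window[1])]
        if len(inside) == 0:
            continue
        s = float(np.sum(t_vals[inside]))
        if s > best_sum:
            best, best_sum = inside, s
    if best is None:
        return None
    w = t_vals[best]
    return float(np.sum(w * lags_ms[best]) / np.sum(w))


def bootstrap_latency_difference(latencies_p, latencies_u, n_boot: int = 1000,
                                 rng_seed: int = 0):
    """Mean latency difference (u - p) with a percentile bootstrap 95% CI.

    Subjects are resampled with replacement as pairs.
    """
    lp = np.asarray(latencies_p, dtype=float)
    lu = np.asarray(latencies_u, dtype=float)
    if lp.shape != lu.shape or lp.size < 3:
        raise ValueError("need >= 3 paired per-subject latencies")
    diff = lu - lp
    rng = np.random.default_rng(rng_seed)
    idx = rng.integers(0, lp.size, size=(n_boot, lp.size))
    boots = diff[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(diff.mean()), (float(lo), float(hi))


# ------------------------------------------------------------ spatial decode

def sensor_adjacency(loc_coords, threshold: float = 0.04) -> np.ndarray:
    """Boolean adjacency of sensor locations separated by gaps < threshold."""
    loc = np.asarray(loc_coords, dtype=float)
    d = np.linalg.norm(loc[:, None, :] - loc[None, :, :], axis=-1)
    adj = (d < threshold) & (d > 0)
    return adj


def spatial_decode(recording: Recording, variable="u", window_ms=(250.0, 400.0),
                   var_threshold: float = 0.99, max_components=None,
                   ridge: float = 1.0, sensors: str = "all") -> pd.DataFrame:
    """Leave-one-out decoding per sensor location within a lag window.

    Per location the features are the lags in ``window_ms`` times the
    location's channels (``sensors``: 'all' -> mag + both gradiometers;
    'mag' or 'grad' restrict the channel kinds).  PCA keeps the smallest
    component count reaching ``var_threshold`` of variance (capped by
    ``max_components``).  Returns a DataFrame with one row per location.
    """
    rec = downsample(recording)
    lag_lo = int(np.round(window_ms[0] / 1000 * rec.srate))
    lag_hi = int(np.round(window_ms[1] / 1000 * rec.srate))
    lags_idx = np.arange(lag_lo, lag_hi + 1)
    values = _display_values(rec, variable)
    trial_ids, onsets, y, _ = _gather_features(rec, lags_idx, values)

    kinds = np.array(rec.ch_kinds)
    n_loc = rec.n_channels // 3
    loc_of_chan = np.repeat(np.arange(n_loc), 3)
    rows = []
    for loc in range(n_loc):
        chans = np.where(loc_of_chan == loc)[0]
        if sensors == "mag":
            chans = chans[kinds[chans] == "mag"]
        elif sensors == "grad":
            chans = chans[kinds[chans] != "mag"]
        # displays x (lags * channels)
        feats = []
        for l in lags_idx:
            feats.append(rec.data[trial_ids][:, chans, :]
                         [np.arange(len(trial_ids)), :, onsets + l])
        X = np.concatenate(feats, axis=1)
        n_comp = _components_for_variance(X, var_threshold, max_components)
        r, _ = _decode_features(X, y, trial_ids, n_comp, ridge)
        rows.append({"location": loc, "r": r, "n_components": n_comp,
                     "x": rec.coords[chans[0], 0], "y": rec.coords[chans[0], 1],
                     "z": rec.coords[chans[0], 2]})
    return pd.DataFrame(rows)


def _components_for_variance(X, threshold, max_components=None):
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    sd[sd == 0] = 1.0
    Xc = Xc / sd
    evals = np.linalg.eigvalsh(Xc.T @ Xc / len(Xc))[::-1]
    frac = np.cumsum(evals) / evals.sum()
    n = int(np.searchsorted(frac, threshold) + 1)
    if max_components is not None:
        n = min(n, max_components)
    return min(n, X.shape[1])


def cluster_permutation_space(r_subjects, adjacency, n_perm: int = 500,
                              rng_seed: int = 0, alpha: float = 0.05) -> dict:
    """Cluster-based permutation test over sensor locations.

    Clusters are connected components (on the adjacency graph) of
    locations with right-sided one-sample t-test p < alpha; the null uses
    subject sign-flips.  With an all-false adjacency every supra-threshold
    location is its own cluster.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    r = np.asarray(r_subjects, dtype=float)
    adjacency = np.asarray(adjacency, dtype=bool)
    t_obs, p_obs = _t_right(r)

    def clusters_of(p, t):
        mask = p < alpha
        idx = np.where(mask)[0]
        if len(idx) == 0:
            return []
        sub = adjacency[np.ix_(idx, idx)]
        n_comp, labels = connected_components(csr_matrix(sub), directed=False)
        return [idx[labels == c] for c in range(n_comp)]

    obs_clusters = clusters_of(p_obs, t_obs)
    rng = np.random.default_rng(rng_seed)
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=r.shape[0])[:, None]
        t, p = _t_right(r * signs)
        null_max[i] = max((t[c].sum() for c in clusters_of(p, t)), default=0.0)
    out = []
    for c in obs_clusters:
        stat = float(t_obs[c].sum())
        out.append({"locations": c, "sum_t": stat,
                    "p": float((1 + np.sum(null_max >= stat)) / (1 + n_perm))})
    return {"t": t_obs, "clusters": out}
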