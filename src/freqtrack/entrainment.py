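"""Phase coherence between stimulus sequences and sensor time series.

The coherence at frequency f across trials is

    kappa(f) = |mean_trials cross-spectrum(stim, resp)|
               / sqrt(mean power(stim) * mean power(resp)),

which lies in [0, 1] by Cauchy-Schwarz and is invariant to channel gain
and to any fixed stimulus-response delay.  Single trials are demeaned,
Hann-windowed, and zero-padded (default 10000 samples at 300 Hz, i.e.
0.03 Hz resolution).  The permutation null shuffles the response samples
within each trial; p-values use the +1 correction and are FDR-adjusted
(Benjamini-Hochberg).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sp_signal
from statsmodels.stats.multitest import multipletests

from .stimuli import TrialSpec, p_step_function

DEFAULT_PAD = 10000
DEFAULT_SRATE = 300.0


def stimulus_timeseries(trial: TrialSpec, variable: str = "p",
                        srate: float = DEFAULT_SRATE, n_samples=None) -> np.ndarray:
    """Display-value step function sampled at ``srate`` (see stimuli module)."""
    return p_step_function(trial, variable=variable, srate=srate, n_samples=n_samples)


def _spectra(x, pad_to):
    """Demean + Hann window per trial, zero-pad, rfft.  x: (..., time)."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if pad_to < n:
        raise ValueError("pad_to must be >= the trial length")
    w = sp_signal.windows.hann(n, sym=False)
    xw = (x - x.mean(axis=-1, keepdims=True)) * w
    return np.fft.rfft(xw, n=pad_to, axis=-1)


def phase_coherence(stim, resp, pad_to: int = DEFAULT_PAD,
                    srate: float = DEFAULT_SRATE):
    """Trial-averaged phase coherence spectrum.

    ``stim``: (n_trials, n_samples); ``resp``: (n_trials, n_samples) or
    (n_trials, n_channels, n_samples).  Returns (freqs, kappa) where kappa
    has shape (n_freqs,) or (n_channels, n_freqs).
    """
    stim = np.asarray(stim, dtype=float)
    resp = np.asarray(resp, dtype=float)
    if stim.shape[0] != resp.shape[0]:
        raise ValueError("stim and resp must have equal trial counts")
    if stim.shape[0] == 1:
        warnings.warn("single trial: kappa is identically 1 at frequencies "
                      "with nonzero power", RuntimeWarning)
    S = _spectra(stim, pad_to)  # (T, F)
    R = _spectra(resp, pad_to)  # (T, F) or (T, C, F)
    per_channel = R.ndim == 3
    if per_channel:
        S = S[:, None, :]
    cross = np.mean(np.conj(S) * R, axis=0)
    pss = np.mean(np.abs(S) ** 2, axis=0)
    prr = np.mean(np.abs(R) ** 2, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = np.abs(cross) / np.sqrt(pss * prr)
    kappa = np.nan_to_num(kappa, nan=0.0)
    freqs = np.fft.rfftfreq(pad_to, 1.0 / srate)
    return freqs, np.minimum(kappa, 1.0)


def kappa_at(freqs, kappa, f0: float):
    """kappa at the frequency bin nearest to f0 (last axis indexes frequency)."""
    return np.take(kappa, int(np.argmin(np.abs(freqs - f0))), axis=-1)


def coherence_permutation_test(stim, resp, n_perm: int = 500, rng_seed: int = 0,
                               pad_to: int = DEFAULT_PAD,
                               srate: float = DEFAULT_SRATE,
                               fmax: float = 7.0, fdr_axis: str = "freq"):
    """Within-trial time-shuffle permutation null for the coherence spectrum.

    Returns a dict with observed kappa, frequency grid (restricted to
    (0, fmax]), per-bin p-values (+1 corrected) and BH-FDR q-values,
    computed across frequency bins (``fdr_axis='freq'``) or across
    channels (``fdr_axis='channel'``).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(rng_seed)
    stim = np.asarray(stim, dtype=float)
    resp = np.asarray(resp, dtype=float)
    freqs, obs = phase_coherence(stim, resp, pad_to=pad_to, srate=srate)
    sel = (freqs > 0) & (freqs <= fmax)
    obs_sel = obs[..., sel]
    exceed = np.zeros_like(obs_sel)
    n_samp = resp.shape[-1]
    for _ in range(n_perm):
        perm = np.stack([rng.permutation(n_samp) for _ in range(resp.shape[0])])
        shuffled = np.take_along_axis(
            resp, perm[:, None, :] if resp.ndim == 3 else perm, axis=-1)
        _, null = phase_coherence(stim, shuffled, pad_to=pad_to, srate=srate)
        exceed += null[..., sel] >= obs_sel
    p = (1.0 + exceed) / (1.0 + n_perm)
    if fdr_axis == "freq":
        q = np.apply_along_axis(lambda v: multipletests(v, method="fdr_bh")[1], -1, p)
    elif fdr_axis == "channel":
        if p.ndim != 2:
            raise ValueError("channel-wise FDR needs channels x freq p-values")
        q = np.apply_along_axis(lambda v: multipletests(v, method="fdr_bh")[1], 0, p)
    else:
        raise ValueError("fdr_axis must be 'freq' or 'channel'")
    return {"freqs": freqs[sel], "kappa": obs_sel, "p": p, "q": q,
            "n_perm": n_perm}
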