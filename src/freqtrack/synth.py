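"""Synthetic behavior and sensor-array recordings with known ground truth.

Behavior: reported proportions are generated from the BLO model applied to
the last display of each trial, plus a log-linear response-time model whose
slopes follow the empirically expected directions (RT increases with the
uncertainty proxy p(1-p), decreases with numerosity and with p).

Recordings: each display evokes a gamma-shaped response kernel per encoded
variable (p and p(1-p); optionally the display confounds), scaled by the
session-standardized value of the variable and projected through a smooth
spatial weight map over a hemispherical sensor layout (1 "magnetometer" +
2 "gradiometers" per location).  Channel traces are the linear
superposition of all display responses plus white and 1/f noise.  The
layout is a synthetic stand-in (Fibonacci hemisphere), not the geometry of
any real acquisition system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .distortion import BLOParams, blo_sample
from .stimuli import Session

DEFAULT_BLO = dict(delta_minus=-1.8, delta_plus=1.8, a=0.42, b=1.91,
                   eta=0.9, lambda0=0.0, alpha=20.0, sigma_lambda=0.3)

#: log-RT model: intercept, slope on p(1-p), slope on ln N, slope on p.
DEFAULT_RT_COEFS = (0.0, 1.0, -0.08, -0.15)


@dataclass
class SubjectProfile:
    """Ground-truth generative parameters of one simulated subject."""

    blo_params: BLOParams = field(default_factory=lambda: BLOParams(**DEFAULT_BLO))
    rt_coefs: tuple = DEFAULT_RT_COEFS
    rt_sigma: float = 0.15
    rng_seed: int = 0


def simulate_behavior(session: Session, profile: SubjectProfile) -> pd.DataFrame:
    """One reported proportion and RT per trial (response to the last display)."""
    rng = np.random.default_rng(profile.rng_seed)
    rows = []
    c0, cu, cN, cp = profile.rt_coefs
    for ti, trial in enumerate(session.trials):
        d = trial.displays[-1]
        p, N = d.p_actual, d.N
        u = p * (1.0 - p)
        pi = float(blo_sample(p, N, profile.blo_params, rng))
        log_rt = (c0 + cu * u + cN * np.log(N) + cp * p
                  + profile.rt_sigma * rng.standard_normal())
        rows.append({"trial": ti, "cycle": trial.cycle,
                     "numerosity": trial.numerosity, "is_catch": trial.is_catch,
                     "p": p, "N": N, "u": u, "pi": pi, "rt": float(np.exp(log_rt))})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- forward model

def gamma_kernel(peak_s: float, srate: float, shape: float = 5.0,
                 support_s: float = 0.9) -> np.ndarray:
    """Causal unit-energy gamma bump t**shape * exp(-t/theta), peak at shape*theta."""
    theta = peak_s / shape
    t = np.arange(0.0, support_s, 1.0 / srate)
    k = t ** shape * np.exp(-t / theta)
    return k / np.sqrt(np.sum(k ** 2))


def fibonacci_hemisphere(n: int, radius: float = 0.1) -> np.ndarray:
    """Quasi-uniform points on the upper hemisphere (head radius in meters)."""
    i = np.arange(n)
    golden = (1 + 5 ** 0.5) / 2
    z = (i + 0.5) / n  # upper hemisphere only
    r = np.sqrt(1 - z ** 2)
    phi = 2 * np.pi * i / golden
    return radius * np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _smooth_map(coords: np.ndarray, rng, length: float = 0.03,
                center=None, spread: float = 0.08) -> np.ndarray:
    """Smooth random spatial weight map with an optional focal envelope."""
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    K = np.exp(-0.5 * (d / length) ** 2)
    w = K @ rng.standard_normal(len(coords))
    w = w / (np.std(w) + 1e-12)
    if center is not None:
        env = np.exp(-0.5 * np.sum((coords - center) ** 2, axis=1) / spread ** 2)
        w = w * env
    return w


@dataclass
class ForwardModel:
    """Linear superposition forward model for display-evoked responses."""

    n_locations: int = 102
    srate: float = 1000.0
    latency_p: float = 0.327
    latency_u: float = 0.419
    latency_conf: float = 0.15
    amp_p: float = 2.0
    amp_u: float = 2.0
    amp_conf: float = 0.0
    noise_sd: float = 0.5
    pink_sd: float = 0.2
    kernel_shape: float = 5.0
    seed: int = 0
    coords: np.ndarray = None
    ch_names: list = None
    ch_kinds: list = None
    w_p: np.ndarray = None
    w_u: np.ndarray = None
    w_conf: np.ndarray = None

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        loc = fibonacci_hemisphere(self.n_locations)
        self.coords = np.repeat(loc, 3, axis=0)
        self.ch_kinds = ["mag", "grad1", "grad2"] * self.n_locations
        self.ch_names = [f"LOC{i:03d}_{k}" for i in range(self.n_locations)
                         for k in ("mag", "grad1", "grad2")]
        # parietal-occipital focus: posterior (negative y), superior cap
        center = np.array([0.0, -0.07, 0.07])
        if self.w_p is None:
            self.w_p = np.repeat(_smooth_map(loc, rng, center=center), 3)
        if self.w_u is None:
            self.w_u = np.repeat(_smooth_map(loc, rng, center=center), 3)
        if self.w_conf is None:
            self.w_conf = np.repeat(_smooth_map(loc, rng, center=None), 3)

    @property
    def n_channels(self) -> int:
        return 3 * self.n_locations

    def kernels(self):
        return {"p": self.amp_p * gamma_kernel(self.latency_p, self.srate, self.kernel_shape),
                "u": self.amp_u * gamma_kernel(self.latency_u, self.srate, self.kernel_shape),
                "conf": self.amp_conf * gamma_kernel(self.latency_conf, self.srate,
                                                     self.kernel_shape)}


@dataclass
class Recording:
    """Epoched trials x channels x samples array with layout metadata."""

    data: np.ndarray
    srate: float
    tmin: float
    ch_names: list
    ch_kinds: list
    coords: np.ndarray
    trials: pd.DataFrame  # one row per epoch: session trial idx, cycle, numerosity
    displays: pd.DataFrame  # one row per display of the recorded trials

    @property
    def n_trials(self):
        return self.data.shape[0]

    @property
    def n_channels(self):
        return self.data.shape[1]

    @property
    def times(self):
        return self.tmin + np.arange(self.data.shape[2]) / self.srate

    def magnetometer_index(self):
        return np.array([i for i, k in enumerate(self.ch_kinds) if k == "mag"])

    def save(self, path):
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f["srate"] = self.srate
            f["tmin"] = self.tmin
            f.create_dataset("ch_names", data=np.array(self.ch_names, dtype="S"))
            f.create_dataset("ch_kinds", data=np.array(self.ch_kinds, dtype="S"))
            f.create_dataset("coords", data=self.coords)
            for name, df in (("trials", self.trials), ("displays", self.displays)):
                grp = f.create_group(name)
                grp.attrs["columns"] = json.dumps(list(df.columns))
                for col in df.columns:
                    vals = df[col].to_numpy()
                    if vals.dtype == object or vals.dtype.kind in "US":
                        grp.create_dataset(col, data=vals.astype("S"))
                    else:
                        grp.create_dataset(col, data=vals)

    @classmethod
    def load(cls, path) -> "Recording":
        with h5py.File(path, "r") as f:
            def read_df(name):
                grp = f[name]
                cols = json.loads(grp.attrs["columns"])
                out = {}
                for col in cols:
                    v = grp[col][()]
                    if v.dtype.kind == "S":
                        v = v.astype(str)
                    out[col] = v
                return pd.DataFrame(out)

            return cls(
                data=f["data"][()], srate=float(f["srate"][()]),
                tmin=float(f["tmin"][()]),
                ch_names=[s.decode() for s in f["ch_names"][()]],
                ch_kinds=[s.decode() for s in f["ch_kinds"][()]],
                coords=f["coords"][()],
                trials=read_df("trials"), displays=read_df("displays"),
            )


def _pink_noise(rng, n_ch, n_samp):
    spec = (rng.standard_normal((n_ch, n_samp // 2 + 1))
            + 1j * rng.standard_normal((n_ch, n_samp // 2 + 1)))
    f = np.arange(n_samp // 2 + 1, dtype=float)
    f[0] = 1.0
    x = np.fft.irfft(spec / np.sqrt(f), n=n_samp, axis=1)
    return x / (x.std(axis=1, keepdims=True) + 1e-12)


def simulate_recording(session: Session, forward: ForwardModel,
                       encode_confounds: bool = False, rng=None,
                       tmin: float = -0.6, tmax: float = 7.0,
                       conditions=None, formal_only: bool = True) -> Recording:
    """Simulate sensor traces for (a subset of) the session's trials.

    Each channel trace is the superposition over displays of the p- and
    u-kernels scaled by the session-standardized display value, plus
    optional confound-driven components and white + 1/f noise.
    ``conditions`` may restrict to e.g. ``[("P", "large")]``.
    """
    if rng is None:
        rng = np.random.default_rng(forward.seed + 1)
    srate = forward.srate
    n_samp = int(round((tmax - tmin) * srate))
    kernels = forward.kernels()

    idx = [i for i, t in enumerate(session.trials)
           if (not formal_only or not t.is_catch)
           and (conditions is None or (t.cycle, t.numerosity) in conditions)]
    sdf = session.displays_frame()
    sdf = sdf[sdf["trial"].isin(idx)].reset_index(drop=True)

    # session-level standardization of encoded variables
    p_all = sdf["p_actual"].to_numpy()
    u_all = p_all * (1 - p_all)
    zp = (sdf["p_actual"] - p_all.mean()) / p_all.std()
    zu = (u_all - u_all.mean()) / u_all.std()
    sdf = sdf.assign(u=u_all, zp=zp, zu=zu.to_numpy() if hasattr(zu, "to_numpy") else zu)

    conf_cols = [c for c in ("N", "Nt", "No", "vCIE_a", "vCIE_b") ]
    conf_z = {}
    for c in conf_cols:
        v = sdf[c].to_numpy(dtype=float)
        if v.std() > 0:
            conf_z[c] = (v - v.mean()) / v.std()

    data = np.zeros((len(idx), forward.n_channels, n_samp))
    trial_rows = []
    for ei, ti in enumerate(idx):
        trial = session.trials[ti]
        sub = sdf[sdf["trial"] == ti]
        imp = {"p": np.zeros(n_samp), "u": np.zeros(n_samp), "conf": np.zeros(n_samp)}
        for r, (_, row) in enumerate(sub.iterrows()):
            s0 = int(round((row["onset_s"] - tmin) * srate))
            if not (0 <= s0 < n_samp):
                continue
            imp["p"][s0] += row["zp"]
            imp["u"][s0] += row["zu"]
            if encode_confounds:
                disp_i = sub.index[r]
                imp["conf"][s0] += np.mean([conf_z[c][disp_i] for c in conf_z])
        for var, w in (("p", forward.w_p), ("u", forward.w_u), ("conf", forward.w_conf)):
            if var == "conf" and not encode_confounds:
                continue
            comp = signal.fftconvolve(imp[var], kernels[var])[:n_samp]
            data[ei] += np.outer(w, comp)
        if forward.noise_sd > 0:
            data[ei] += forward.noise_sd * rng.standard_normal((forward.n_channels, n_samp))
        if forward.pink_sd > 0:
            data[ei] += forward.pink_sd * _pink_noise(rng, forward.n_channels, n_samp)
        trial_rows.append({"session_trial": ti, "cycle": trial.cycle,
                           "numerosity": trial.numerosity,
                           "n_displays": trial.n_displays})

    trials_df = pd.DataFrame(trial_rows)
    remap = {ti: ei for ei, ti in enumerate(idx)}
    sdf = sdf.assign(epoch=sdf["trial"].map(remap))
    return Recording(data=data, srate=srate, tmin=tmin,
                     ch_names=list(forward.ch_names), ch_kinds=list(forward.ch_kinds),
                     coords=forward.coords.copy(), trials=trials_df, displays=sdf)
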