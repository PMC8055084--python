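"""Stimulus-session generation for the relative-frequency tracking design.

A session presents rapid sequences of two-color dot displays (150 ms per
display).  Two trial types dissociate the relative frequency ``p`` of the
target color from its representational uncertainty ``p(1-p)``:

* **P-cycle** trials: ``p`` alternates between draws from ``U(0.1, 0.5)``
  and ``U(0.5, 0.9)``, so the ``p`` sequence is periodic at 3.33 Hz while
  ``p(1-p)`` is aperiodic.
* **U-cycle** trials: ``p`` alternates between ``(0.1,0.3) U (0.7,0.9)``
  and ``(0.3,0.7)``, so ``p(1-p)`` alternates around 0.21 at 3.33 Hz while
  ``p`` itself is aperiodic.

Numerosity ``N`` (total dot count) varies independently of ``p`` as a
linear transform of a Beta(0.1, 10) variable, to [10, 90] (N-small) or
[100, 900] (N-large).  Dot counts are rounded to integers, and the actual
(post-rounding) relative frequency is what downstream analyses use.

Each display also carries an 8-vector of potential confound variables
(numerosity, per-color counts, mean luminance, CIELAB color variances,
Michelson contrast) computed from an abstract element-mixture model of the
display rather than from rendered pixels.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

DISPLAY_DURATION = 0.15
"""Duration of one dot display in seconds."""

ALTERNATION_FREQ = 1.0 / (2 * DISPLAY_DURATION)
"""Frequency (Hz) of the low/high alternation: one cycle per two displays."""

CONFOUND_NAMES = ("N", "Nt", "No", "AvgLumi", "vCIE_L", "vCIE_a", "vCIE_b", "Mcontrast")

#: CIELAB coordinates (L*, a*, b*) of the display elements.
DEFAULT_PALETTE = {
    "orange": (43.0, 19.06, 52.33),
    "blue": (43.0, -15.49, -23.72),
    "gray": (43.0, 0.0, 0.0),
    "background": (56.5, 0.0, 0.0),
}

NUMEROSITY_RANGES = {"small": (10, 90), "large": (100, 900)}

#: Area of one dot expressed in filler-element units (a dot displaces the
#: luminance of this many gray filler elements).
DOT_AREA = 4.0


@dataclass(frozen=True)
class DisplaySpec:
    """One 150-ms dot display."""

    p_nominal: float
    p_actual: float
    N: int
    n_target: int
    n_other: int
    confounds: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_target + self.n_other != self.N:
            raise ValueError("n_target + n_other must equal N")
        if not (0.0 < self.p_actual < 1.0):
            raise ValueError("p_actual must lie strictly inside (0, 1)")

    @property
    def uncertainty(self) -> float:
        """The representational-uncertainty proxy p(1-p) of the display."""
        return self.p_actual * (1.0 - self.p_actual)


@dataclass
class TrialSpec:
    """An ordered sequence of displays with condition labels."""

    cycle: str  # "P" or "U"
    numerosity: str  # "small" or "large"
    is_catch: bool
    displays: list
    duration_s: float
    start_phase: int = 0  # 0 = low-first, 1 = high-first
    display_duration: float = DISPLAY_DURATION

    @property
    def n_displays(self) -> int:
        return len(self.displays)

    def onsets(self) -> np.ndarray:
        """Onset time of each display relative to trial onset (s)."""
        return np.arange(self.n_displays) * self.display_duration

    def values(self, variable: str) -> np.ndarray:
        """Display-wise ``p`` or ``u`` = p(1-p) (actual, post-rounding)."""
        p = np.array([d.p_actual for d in self.displays])
        if variable == "p":
            return p
        if variable == "u":
            return p * (1.0 - p)
        raise ValueError(f"unknown variable {variable!r}")


@dataclass
class Session:
    """A full 2 (cycle) x 2 (numerosity) session for one subject."""

    subject_id: str
    trials: list
    rng_seed: int

    def formal_trials(self):
        return [t for t in self.trials if not t.is_catch]

    def displays_frame(self) -> pd.DataFrame:
        """One row per display with trial/condition labels and confounds."""
        rows = []
        for ti, trial in enumerate(self.trials):
            for di, d in enumerate(trial.displays):
                row = {
                    "trial": ti,
                    "display": di,
                    "onset_s": di * trial.display_duration,
                    "cycle": trial.cycle,
                    "numerosity": trial.numerosity,
                    "is_catch": trial.is_catch,
                    "p_nominal": d.p_nominal,
                    "p_actual": d.p_actual,
                    "N": d.N,
                    "n_target": d.n_target,
                }
                row.update(d.confounds)
                rows.append(row)
        return pd.DataFrame(rows)

    def save(self, out_dir):
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "subject_id": self.subject_id,
            "rng_seed": self.rng_seed,
            "trials": [
                {
                    "cycle": t.cycle,
                    "numerosity": t.numerosity,
                    "is_catch": t.is_catch,
                    "duration_s": t.duration_s,
                    "start_phase": t.start_phase,
                    "n_displays": t.n_displays,
                }
                for t in self.trials
            ],
        }
        (out_dir / "session.json").write_text(json.dumps(meta, indent=1))
        self.displays_frame().to_csv(out_dir / "displays.csv", index=False)

    @classmethod
    def load(cls, in_dir) -> "Session":
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "session.json").read_text())
        df = pd.read_csv(in_dir / "displays.csv")
        trials = []
        for ti, tmeta in enumerate(meta["trials"]):
            sub = df[df["trial"] == ti]
            displays = [
                DisplaySpec(
                    p_nominal=r.p_nominal,
                    p_actual=r.p_actual,
                    N=int(r.N),
                    n_target=int(r.n_target),
                    n_other=int(r.N - r.n_target),
                    confounds={k: getattr(r, k) for k in CONFOUND_NAMES},
                )
                for r in sub.itertuples()
            ]
            trials.append(
                TrialSpec(
                    cycle=tmeta["cycle"],
                    numerosity=tmeta["numerosity"],
                    is_catch=tmeta["is_catch"],
                    displays=displays,
                    duration_s=tmeta["duration_s"],
                    start_phase=tmeta["start_phase"],
                )
            )
        return cls(subject_id=meta["subject_id"], trials=trials, rng_seed=meta["rng_seed"])


def sample_p_sequence(cycle: str, n_displays: int, rng, start_phase=None) -> np.ndarray:
    """Draw a display-wise ``p`` sequence for one trial.

    In P-cycle trials odd/even displays come from U(0.1, 0.5) and
    U(0.5, 0.9); in U-cycle trials they come from (0.1,0.3) U (0.7,0.9)
    (each sub-interval with probability 1/2) and (0.3, 0.7).  Which phase
    starts the trial is randomized unless ``start_phase`` is given.
    """
    if n_displays < 1:
        raise ValueError("n_displays must be >= 1")
    if cycle not in ("P", "U"):
        raise ValueError(f"cycle must be 'P' or 'U', got {cycle!r}")
    if start_phase is None:
        start_phase = int(rng.integers(2))
    p = np.empty(n_displays)
    for i in range(n_displays):
        low_phase = (i + start_phase) % 2 == 0
        if cycle == "P":
            p[i] = rng.uniform(0.1, 0.5) if low_phase else rng.uniform(0.5, 0.9)
        else:
            if low_phase:  # low p(1-p): p far from 0.5
                p[i] = rng.uniform(0.1, 0.3) if rng.integers(2) == 0 else rng.uniform(0.7, 0.9)
            else:
                p[i] = rng.uniform(0.3, 0.7)
    return p


def sample_numerosity(numerosity: str, rng) -> int:
    """Total dot count: linear transform of Beta(0.1, 10) into the range."""
    lo, hi = NUMEROSITY_RANGES[numerosity]
    x = rng.beta(0.1, 10.0)
    return int(np.clip(round(lo + (hi - lo) * x), lo, hi))


def compute_confounds(n_target: int, n_other: int, n_max: int,
                      palette=DEFAULT_PALETTE, dot_area: float = DOT_AREA) -> dict:
    """Confound 8-vector of a display from the abstract element mixture.

    The display is modeled as colored dots plus gray luminance-filler
    elements; the filler count is ``dot_area * (n_max - N)`` so the total
    luminous area is constant across displays (equal at the session's
    maximum numerosity ``n_max``).  ``vCIE_L`` is the population variance
    of L* over canvas cells (dark elements vs background); ``vCIE_a`` and
    ``vCIE_b`` are variances over the dot + filler element mixture.
    """
    for key in ("orange", "blue", "gray", "background"):
        if key not in palette:
            raise ValueError(f"palette missing color {key!r}")
    N = n_target + n_other
    p = n_target / N
    n_fill = dot_area * (n_max - N)
    canvas = 2.0 * dot_area * n_max  # total canvas cells
    dark_area = dot_area * N + n_fill  # == dot_area * n_max, constant
    L_dark, L_bg = palette["gray"][0], palette["background"][0]
    avg_lumi = (L_dark * dark_area + L_bg * (canvas - dark_area)) / canvas

    # L*: dark elements (one per dot, one per filler) against background cells
    n_dark_elem = N + n_fill
    n_bg = canvas - dark_area
    q = n_dark_elem / (n_dark_elem + n_bg)
    v_L = q * (1 - q) * (L_dark - L_bg) ** 2

    # a*, b*: over the dot + filler element mixture
    counts = np.array([n_target, n_other, n_fill], dtype=float)
    w = counts / counts.sum()
    v_ab = []
    for dim in (1, 2):
        vals = np.array([palette["orange"][dim], palette["blue"][dim], palette["gray"][dim]])
        mean = w @ vals
        v_ab.append(w @ (vals - mean) ** 2)

    m_contrast = (L_dark - L_bg) / (L_dark + L_bg)
    return {
        "N": float(N),
        "Nt": float(n_target),
        "No": float(n_other),
        "AvgLumi": avg_lumi,
        "vCIE_L": v_L,
        "vCIE_a": v_ab[0],
        "vCIE_b": v_ab[1],
        "Mcontrast": m_contrast,
    }


def make_display(p_nominal: float, N: int, n_max: int = 900,
                 palette=DEFAULT_PALETTE) -> DisplaySpec:
    """Round dot counts to integers and build the display record.

    If rounding drives the target count to 0 or N (possible only for small
    N with p near 0.1 or 0.9), one count is moved inward so the actual
    relative frequency stays strictly inside (0, 1) — its log-odds must be
    finite downstream.
    """
    if not (0.0 < p_nominal < 1.0):
        raise ValueError("p_nominal must lie in (0, 1)")
    if N < 2:
        raise ValueError("N must be >= 2 for a two-color display")
    n_target = int(round(p_nominal * N))
    n_target = min(max(n_target, 1), N - 1)
    n_other = N - n_target
    return DisplaySpec(
        p_nominal=p_nominal,
        p_actual=n_target / N,
        N=N,
        n_target=n_target,
        n_other=n_other,
        confounds=compute_confounds(n_target, n_other, n_max, palette),
    )


def _truncexp_mean_frac(x: float) -> float:
    """g(x) = 1/x - 1/(e^x - 1): mean position (0..1) of Exp truncated to a
    unit interval, as a function of x = rate * width.  g(0) = 1/2."""
    if abs(x) < 1e-6:
        return 0.5 - x / 12.0
    return 1.0 / x - 1.0 / math.expm1(x)


@lru_cache(maxsize=8)
def _truncexp_rate(mean: float, lo: float, hi: float) -> float:
    """Rate of an exponential whose truncation to [lo, hi] has the mean.

    The truncated mean decreases continuously in the rate; means above the
    interval midpoint require a negative rate (increasing density).
    """
    if not (lo < mean < hi):
        raise ValueError("target mean must lie strictly inside (lo, hi)")
    d = hi - lo
    target = (mean - lo) / d
    x = optimize.brentq(lambda x: _truncexp_mean_frac(x) - target, -200.0, 200.0)
    return x / d


def sample_catch_duration(rng, mean: float = 3.0, lo: float = 1.0, hi: float = 6.0,
                          size=None):
    """Catch-trial duration: exponential truncated to [lo, hi] s, mean 3 s.

    The rate is calibrated once by root finding and cached; sampling is by
    inverse CDF.
    """
    rate = _truncexp_rate(mean, lo, hi)
    u = rng.uniform(size=size)
    tail = -np.expm1(-rate * (hi - lo))
    return lo + np.log1p(-u * tail) / -rate


def _make_trial(cycle, numerosity, is_catch, rng, n_max) -> TrialSpec:
    if is_catch:
        duration = float(sample_catch_duration(rng))
        n_disp = int(math.ceil(duration / DISPLAY_DURATION))
    else:
        n_disp = int(rng.choice([40, 41]))
        duration = n_disp * DISPLAY_DURATION
    start_phase = int(rng.integers(2))
    p = sample_p_sequence(cycle, n_disp, rng, start_phase=start_phase)
    displays = [
        make_display(p[i], sample_numerosity(numerosity, rng), n_max=n_max)
        for i in range(n_disp)
    ]
    return TrialSpec(cycle=cycle, numerosity=numerosity, is_catch=is_catch,
                     displays=displays, duration_s=duration, start_phase=start_phase)


DEFAULT_SESSION_CONFIG = {
    "formal_per_condition": 50,
    "catch_per_condition": 10,
    "n_blocks": 10,
}

CONDITIONS = [(c, n) for c in ("P", "U") for n in ("small", "large")]


def generate_session(subject_id: str, config=None, rng_seed: int = 0) -> Session:
    """Generate a full interleaved session, deterministic given the seed.

    Defaults follow the 2x2 design: 50 formal + 10 catch trials per
    condition, interleaved over 10 blocks of 24 trials with balanced
    condition labels per block.
    """
    cfg = dict(DEFAULT_SESSION_CONFIG)
    if config:
        cfg.update(config)
    n_formal, n_catch, n_blocks = (cfg["formal_per_condition"],
                                   cfg["catch_per_condition"], cfg["n_blocks"])
    if n_formal < 1 or n_catch < 0 or n_blocks < 1:
        raise ValueError("counts must be positive (catch may be zero)")
    if n_formal % n_blocks or n_catch % n_blocks:
        raise ValueError(
            f"formal ({n_formal}) and catch ({n_catch}) trials per condition "
            f"must tile {n_blocks} blocks evenly; adjust n_blocks")
    rng = np.random.default_rng(rng_seed)
    n_max = max(hi for _, hi in NUMEROSITY_RANGES.values())
    fpb, cpb = n_formal // n_blocks, n_catch // n_blocks
    trials = []
    for _ in range(n_blocks):
        block = []
        for cyc, num in CONDITIONS:
            block += [(cyc, num, False)] * fpb + [(cyc, num, True)] * cpb
        order = rng.permutation(len(block))
        for idx in order:
            cyc, num, catch = block[idx]
            trials.append(_make_trial(cyc, num, catch, rng, n_max))
    return Session(subject_id=subject_id, trials=trials, rng_seed=rng_seed)


def p_step_function(trial: TrialSpec, variable: str = "p", srate: float = 300.0,
                    n_samples=None) -> np.ndarray:
    """Step-function time series holding each display's value for 150 ms."""
    vals = trial.values(variable)
    per = int(round(trial.display_duration * srate))
    ts = np.repeat(vals, per)
    if n_samples is not None:
        if len(ts) >= n_samples:
            ts = ts[:n_samples]
        else:
            ts = np.pad(ts, (0, n_samples - len(ts)), mode="edge")
    return ts
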