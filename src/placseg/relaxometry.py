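"""Voxel-wise T2* estimation from multi-echo gradient-echo magnitude data.

The signal model is the mono-exponential decay ``S(TE) = S0 exp(-TE/T2*)``.
The default estimator is weighted log-linear least squares on
``ln S = ln S0 - TE/T2*`` with weights proportional to S^2 (the first-order
variance of ln S under additive noise), which is closed-form and
deterministic.  An optional Levenberg-Marquardt refinement of the
exponential model is available for noisy data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

#: Upper bound on credible T2* (ms); slower decays are flagged invalid so
#: unstable estimates cannot pollute the clustering feature space.
T2STAR_CAP_MS = 300.0


@dataclass(frozen=True)
class EchoTrain:
    """Multi-echo magnitude signals: (..., n_echoes) plus echo times in ms."""

    signals: np.ndarray
    echo_times: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.signals, float)
        te = np.asarray(self.echo_times, float)
        object.__setattr__(self, "signals", s)
        object.__setattr__(self, "echo_times", te)
        if te.ndim != 1 or te.size < 3:
            raise ValueError("need at least 3 echo times")
        if te[0] <= 0 or np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be positive, strictly increasing")
        if s.shape[-1] != te.size:
            raise ValueError("signal echo dimension does not match echo times")


@dataclass
class T2StarMap:
    """Fitted T2* (ms) and S0 with a per-voxel validity flag."""

    t2star: np.ndarray
    s0: np.ndarray
    fit_valid: np.ndarray
    cap_ms: float = T2STAR_CAP_MS


def fit_t2star(train: EchoTrain, mask: np.ndarray | None = None,
               *, cap_ms: float = T2STAR_CAP_MS,
               nonlinear_refine: bool = False) -> T2StarMap:
    """Fit the mono-exponential decay in every masked voxel.

    Voxels with fewer than 3 positive echoes, a non-positive estimated decay
    rate, or T2* above ``cap_ms`` are flagged invalid rather than raising.
    With ``nonlinear_refine`` the log-linear solution seeds a per-voxel
    nonlinear least-squares fit of the exponential model.
    """
    signals = train.signals
    te = train.echo_times
    spatial = signals.shape[:-1]
    if mask is None:
        mask = np.ones(spatial, bool)
    mask = np.asarray(mask, bool)
    if mask.shape != spatial:
        raise ValueError("mask shape does not match signal volume")
    if not mask.any():
        raise ValueError("mask is empty")

    S = signals[mask]  # (n, e)
    pos = S > 0
    enough = pos.sum(axis=1) >= 3

    w = np.where(pos, S, 0.0) ** 2
    logS = np.where(pos, np.log(np.where(pos, S, 1.0)), 0.0)
    sw = w.sum(axis=1)
    sw = np.where(sw > 0, sw, 1.0)
    mt = (w * te).sum(axis=1) / sw
    my = (w * logS).sum(axis=1) / sw
    stt = (w * (te - mt[:, None]) ** 2).sum(axis=1)
    sty = (w * (te - mt[:, None]) * (logS - my[:, None])).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sty / stt  # = -1/T2*
    rate = -slope
    intercept = my - slope * mt

    valid = enough & np.isfinite(rate) & (rate > 0)
    with np.errstate(divide="ignore", over="ignore"):
        t2 = np.where(valid, 1.0 / np.where(rate > 0, rate, 1.0), np.nan)
        s0 = np.exp(intercept)
    valid &= np.isfinite(t2) & (t2 <= cap_ms)
    t2 = np.where(valid, t2, np.nan)
    s0 = np.where(valid, s0, np.nan)

    if nonlinear_refine:
        t2, s0 = _refine(S, te, t2, s0, valid)

    t2star = np.full(spatial, np.nan)
    s0_map = np.full(spatial, np.nan)
    fit_valid = np.zeros(spatial, bool)
    t2star[mask] = t2
    s0_map[mask] = s0
    fit_valid[mask] = valid
    return T2StarMap(t2star=t2star, s0=s0_map, fit_valid=fit_valid,
                     cap_ms=cap_ms)


def _model(te, s0, t2):
    return s0 * np.exp(-te / t2)


def _refine(S, te, t2, s0, valid):
    t2 = t2.copy()
    s0 = s0.copy()
    for i in np.flatnonzero(valid):
        try:
            popt, _ = curve_fit(_model, te, S[i], p0=(s0[i], t2[i]),
                                maxfev=200)
        except RuntimeError:
            continue
        if 0 < popt[1] <= T2STAR_CAP_MS:
            s0[i], t2[i] = popt
    return t2, s0
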