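"""Self-cleavage kinetics from co-transcriptional time courses.

During transcription under a constant transcription rate, the fraction of
full-length (uncleaved) transcript f = L/(L+S) decays with the observed
cleavage rate constant k_obs independently of the transcription rate.  The
model fitted here is the one-phase exponential decay

    f(t) = (y0 - plateau) * exp(-k * t) + plateau

with y0 the initial fraction, plateau the asymptote and k = k_obs in min^-1.
Replicate fits are averaged arithmetically; summaries are reported both at
full precision and rounded to two significant figures, matching how observed
rate constants are conventionally tabulated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TimeSeries",
    "DecayFit",
    "ReplicateSummary",
    "fraction_series",
    "fit_decay",
    "summarize_replicates",
    "round_sig",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TimeSeries:
    """A fraction-uncleaved time course: strictly increasing t (minutes), f in [0,1]."""

    t: tuple[float, ...]
    f: tuple[float, ...]
    construct: str = ""
    replicate: str = ""

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        f = np.asarray(self.f, dtype=float)
        if t.shape != f.shape or t.ndim != 1:
            raise ValueError("t and f must be equal-length 1-D vectors")
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("time points must be nonnegative and strictly increasing")
        if np.any(f < 0) or np.any(f > 1):
            raise ValueError("fractions must lie in [0, 1]")


def fraction_series(
    L,
    S,
    t,
    construct: str = "",
    replicate: str = "",
) -> TimeSeries:
    """Fraction full-length f_i = L_i / (L_i + S_i) from band intensities."""
    L = np.asarray(L, dtype=float)
    S = np.asarray(S, dtype=float)
    t = np.asarray(t, dtype=float)
    if not (L.shape == S.shape == t.shape):
        raise ValueError("L, S and t must have equal lengths")
    if np.any(L < 0) or np.any(S < 0):
        raise ValueError("intensities must be nonnegative")
    total = L + S
    zero = np.nonzero(total == 0)[0]
    if zero.size:
        raise ValueError(
            f"L + S is zero at time point index {zero[0]} (t={t[zero[0]]})"
        )
    return TimeSeries(
        t=tuple(t), f=tuple(L / total), construct=construct, replicate=replicate
    )


@dataclass(frozen=True)
class DecayFit:
    k_obs: float
    y0: float
    plateau: float
    r2: float
    se_k: float
    converged: bool
    n_points: int
    message: str = ""


def _model(t, y0, plateau, k):
    return (y0 - plateau) * np.exp(-k * t) + plateau


def _init_guess(t: np.ndarray, f: np.ndarray) -> tuple[float, float, float]:
    """Log-linear initialization of (y0, plateau, k) from (f - min f)."""
    fmin = float(f.min())
    shifted = f - fmin
    mask = shifted > 1e-9
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(t[mask], np.log(shifted[mask]), 1)
        k0 = max(-slope, 1e-6)
    else:
        k0 = 1e-3
    return float(f[0]), fmin, k0


def fit_decay(
    series: TimeSeries,
    fix_plateau: float | None = None,
    fix_y0: float | None = None,
) -> DecayFit:
    """Nonlinear least-squares fit of the one-phase exponential decay.

    Parameters may be constrained (``fix_plateau=0.0`` reproduces the
    two-parameter decay-to-zero model).  Requires >= 4 points.  Degenerate
    (constant) series and solver failures return ``converged=False`` with a
    diagnostic message rather than a silent fallback.
    """
    t = np.asarray(series.t, dtype=float)
    f = np.asarray(series.f, dtype=float)
    n = t.size
    if n < 4:
        raise ValueError("at least 4 time points are required for fitting")
    if np.allclose(f, f[0]):
        return DecayFit(
            k_obs=0.0, y0=float(f[0]), plateau=float(f[0]), r2=float("nan"),
            se_k=float("nan"), converged=False, n_points=n,
            message="degenerate: constant series, no decay to fit",
        )

    y0_g, c_g, k_g = _init_guess(t, f)

    free: list[str] = []
    p0: list[float] = []
    lo: list[float] = []
    hi: list[float] = []
    if fix_y0 is None:
        free.append("y0"); p0.append(min(max(y0_g, 0.0), 1.0)); lo.append(0.0); hi.append(1.0)
    if fix_plateau is None:
        free.append("plateau"); p0.append(min(max(c_g, 0.0), 1.0)); lo.append(0.0); hi.append(1.0)
    free.append("k"); p0.append(k_g); lo.append(1e-12); hi.append(np.inf)

    def fun(tt, *params):
        d = dict(zip(free, params))
        y0 = fix_y0 if fix_y0 is not None else d["y0"]
        c = fix_plateau if fix_plateau is not None else d["plateau"]
        return _model(tt, y0, c, d["k"])

    try:
        popt, pcov = curve_fit(
            fun, t, f, p0=p0, bounds=(lo, hi), maxfev=20000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except (RuntimeError, ValueError) as e:
        return DecayFit(
            k_obs=float("nan"), y0=float("nan"), plateau=float("nan"),
            r2=float("nan"), se_k=float("nan"), converged=False, n_points=n,
            message=f"solver failure: {e}",
        )
    d = dict(zip(free, popt))
    y0 = fix_y0 if fix_y0 is not None else d["y0"]
    plateau = fix_plateau if fix_plateau is not None else d["plateau"]
    k = d["k"]
    resid = f - fun(t, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((f - f.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    k_idx = free.index("k")
    with np.errstate(invalid="ignore"):
        se_k = float(np.sqrt(pcov[k_idx, k_idx])) if np.isfinite(
            pcov[k_idx, k_idx]
        ) else float("nan")
    converged = bool(np.isfinite(k) and k > 0)
    msg = "" if converged else "k at or below zero"
    if plateau > y0 + 1e-9:
        converged = False
        msg = "fitted plateau exceeds initial fraction (rising series?)"
    return DecayFit(
        k_obs=float(k), y0=float(y0), plateau=float(plateau), r2=r2,
        se_k=se_k, converged=converged, n_points=n, message=msg,
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class ReplicateSummary:
    mean_k: float
    sd_k: float | None
    n: int
    mean_k_2sig: float
    sd_k_2sig: float | None


def summarize_replicates(fits: list[DecayFit]) -> ReplicateSummary:
    """Mean and sample SD of k_obs over converged replicate fits.

    Reported both at full precision and rounded to two significant figures.
    Raises if no fit converged.
    """
    ks = [f.k_obs for f in fits if f.converged]
    if not ks:
        raise ValueError("no converged replicate fits to summarize")
    mean_k = float(np.mean(ks))
    sd_k = float(np.std(ks, ddof=1)) if len(ks) > 1 else None
    return ReplicateSummary(
        mean_k=mean_k,
        sd_k=sd_k,
        n=len(ks),
        mean_k_2sig=round_sig(mean_k),
        sd_k_2sig=round_sig(sd_k) if sd_k is not None else None,
    )
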