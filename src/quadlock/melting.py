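"""Two-state melting-curve analysis for CD (or UV) thermal denaturation.

The folded and unfolded states are each assigned a linear signal baseline
fitted over the low- and high-temperature ends of the curve.  The fraction
folded is

    theta(T) = (s_U(T) - s(T)) / (s_U(T) - s_F(T))

and the melting temperature Tm is the temperature at which theta crosses
0.5, found by linear interpolation between the bracketing samples.  Heating
and cooling branches are fitted independently and combined as mean and mean
deviation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Union

import numpy as np

__all__ = [
    "MeltingCurve",
    "MeltingFit",
    "fit_two_state",
    "tm_consensus",
    "delta_tm",
]


@dataclass
class MeltingCurve:
    """One branch of a melting experiment: temperature vs signal."""

    temperature: np.ndarray
    signal: np.ndarray
    branch: str = "heating"  # heating | cooling

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.shape != self.signal.shape:
            raise ValueError("temperature and signal lengths differ")
        if len(self.temperature) < 10:
            raise ValueError("need at least 10 samples per branch")
        d = np.diff(self.temperature)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError(
                "temperatures must be strictly monotone within a branch"
            )
        if self.branch not in ("heating", "cooling"):
            raise ValueError(f"unknown branch: {self.branch}")

    def ascending(self) -> tuple[np.ndarray, np.ndarray]:
        if self.temperature[0] <= self.temperature[-1]:
            return self.temperature, self.signal
        return self.temperature[::-1], self.signal[::-1]


@dataclass
class MeltingFit:
    folded_baseline: tuple[float, float]    # intercept, slope per deg C
    unfolded_baseline: tuple[float, float]
    theta: np.ndarray                       # fraction folded, clamped [0,1]
    temperature: np.ndarray
    tm: float
    tm_uncertainty: float
    branch: str = "heating"
    reliable: bool = True
    notes: list = field(default_factory=list)


def fit_two_state(
    curve: MeltingCurve, baseline_fraction: float = 0.15
) -> MeltingFit:
    """Fit baselines and extract Tm as the theta = 0.5 crossing.

    ``baseline_fraction`` is the proportion of the temperature span, at
    each end, used to fit the folded (low-T) and unfolded (high-T) linear
    baselines.  Raises ``ValueError`` when theta never crosses 0.5 ("no
    transition in range"); when it crosses more than once the crossing
    nearest the steepest point of the curve is taken, with a warning.
    """
    if not (0.0 < baseline_fraction <= 0.4):
        raise ValueError("baseline_fraction must be in (0, 0.4]")
    T, s = curve.ascending()
    span = T[-1] - T[0]
    lo = T <= T[0] + baseline_fraction * span
    hi = T >= T[-1] - baseline_fraction * span
    if lo.sum() < 2 or hi.sum() < 2:
        raise ValueError("too few points in a baseline window")
    f_slope, f_int = np.polyfit(T[lo], s[lo], 1)
    u_slope, u_int = np.polyfit(T[hi], s[hi], 1)
    s_f = f_int + f_slope * T
    s_u = u_int + u_slope * T

    amp = float(np.mean(np.abs(s_f - s_u)))
    noise = max(
        float(np.std(s[lo] - s_f[lo], ddof=1)),
        float(np.std(s[hi] - s_u[hi], ddof=1)),
    )
    if amp < 1e-12 or amp <= noise:
        raise ValueError("no transition in range: baselines coincide")

    # The end windows only initialize the baselines.  For broad two-state
    # transitions the pure-state tails extend past any end window (the
    # curve may never be fully folded within the measured range), which
    # biases window-only baselines and shifts the crossing by up to
    # ~0.5 deg C.  The baselines are therefore refined jointly with the
    # transition by least squares on the full two-state model
    # s(T) = theta*(f0+f1*T) + (1-theta)*(u0+u1*T); Tm stays defined as
    # the theta = 0.5 crossing, which for the fitted theta is the fitted
    # midpoint itself.
    refined = _refine_two_state(
        T, s, (f_int, f_slope), (u_int, u_slope)
    )
    tm_model = None
    if refined is not None:
        f_int, f_slope, u_int, u_slope, tm_model = refined
        s_f = f_int + f_slope * T
        s_u = u_int + u_slope * T

    denom = s_u - s_f
    theta_raw = (s_u - s) / denom
    notes: list = []
    reliable = True
    if amp < 4.0 * noise:
        reliable = False
        notes.append("low amplitude-to-noise ratio; fit unreliable")
        warnings.warn(notes[-1])

    diff = theta_raw - 0.5
    crossings = [
        i for i in range(len(T) - 1)
        if diff[i] == 0.0 or (diff[i] * diff[i + 1] < 0)
    ]
    if diff[-1] == 0.0:
        crossings.append(len(T) - 1)
    if not crossings:
        raise ValueError("no transition in range: theta never crosses 0.5")
    if len({_interp_tm(T, diff, i) for i in crossings}) > 1:
        slope = np.gradient(theta_raw, T)
        steep_t = T[int(np.argmax(np.abs(slope)))]
        crossings.sort(key=lambda i: abs(_interp_tm(T, diff, i) - steep_t))
        if len(crossings) > 1:
            notes.append(
                "theta crosses 0.5 more than once; "
                "took the crossing nearest the steepest slope"
            )
            warnings.warn(notes[-1])
    i = crossings[0]
    tm = _interp_tm(T, diff, i)
    if tm_model is not None and T[0] <= tm_model <= T[-1]:
        # the smooth fitted theta crosses 0.5 exactly at the fitted
        # midpoint; prefer it over the noise-limited sample interpolation
        tm = tm_model
    local_step = T[min(i + 1, len(T) - 1)] - T[i] if i + 1 < len(T) \
        else T[i] - T[i - 1]
    return MeltingFit(
        folded_baseline=(float(f_int), float(f_slope)),
        unfolded_baseline=(float(u_int), float(u_slope)),
        theta=np.clip(theta_raw, 0.0, 1.0),
        temperature=T,
        tm=float(tm),
        tm_uncertainty=float(abs(local_step) / 2.0),
        branch=curve.branch,
        reliable=reliable,
        notes=notes,
    )


#: gas constant, kcal / (mol K)
_R = 1.987204259e-3


def _refine_two_state(T, s, folded, unfolded):
    """Joint least-squares fit of (Tm, dH, both baselines).

    Returns (f_int, f_slope, u_int, u_slope, tm) or None when the
    optimization fails to improve on the initial window estimate.
    """
    from scipy.optimize import least_squares

    s_f = folded[0] + folded[1] * T
    s_u = unfolded[0] + unfolded[1] * T
    th0 = (s_u - s) / (s_u - s_f)
    d = th0 - 0.5
    idx = [i for i in range(len(T) - 1) if d[i] * d[i + 1] < 0]
    tm0 = _interp_tm(T, d, idx[0]) if idx else float(0.5 * (T[0] + T[-1]))

    def residual(p):
        tm, dh, fi, fs, ui, us = p
        tk = T + 273.15
        th = 1.0 / (
            1.0 + np.exp((dh / _R) * (1.0 / tk - 1.0 / (tm + 273.15)))
        )
        return th * (fi + fs * T) + (1.0 - th) * (ui + us * T) - s

    p0 = [tm0, -40.0, folded[0], folded[1], unfolded[0], unfolded[1]]
    try:
        fit = least_squares(
            residual,
            p0,
            bounds=(
                [T[0] - 30.0, -500.0, -np.inf, -np.inf, -np.inf, -np.inf],
                [T[-1] + 30.0, -0.5, np.inf, np.inf, np.inf, np.inf],
            ),
        )
    except Exception:
        return None
    if not fit.success or not np.all(np.isfinite(fit.x)):
        return None
    tm, _, fi, fs, ui, us = fit.x
    return float(fi), float(fs), float(ui), float(us), float(tm)


def _interp_tm(T, diff, i) -> float:
    if diff[i] == 0.0 or i + 1 >= len(T):
        return float(T[i])
    return float(T[i] + (T[i + 1] - T[i]) * (-diff[i])
                 / (diff[i + 1] - diff[i]))


def tm_consensus(
    heating: Union[MeltingFit, float], cooling: Union[MeltingFit, float]
) -> tuple[float, float]:
    """Mean and mean deviation of the heating- and cooling-branch Tm."""
    th = heating.tm if isinstance(heating, MeltingFit) else float(heating)
    tc = cooling.tm if isinstance(cooling, MeltingFit) else float(cooling)
    return (th + tc) / 2.0, abs(th - tc) / 2.0


def delta_tm(tm_variant: float, tm_reference: float) -> float:
    """Signed stability change of a sequence variant, variant - reference."""
    if not (np.isfinite(tm_variant) and np.isfinite(tm_reference)):
        raise ValueError("Tm values must be finite")
    return float(tm_variant) - float(tm_reference)
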