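"""In silico rheology: Green–Kubo viscosity and corrected diffusion.

Shear viscosity comes from the time integral of the pressure-tensor
autocorrelation functions, eta_ij = V/(kB T) * int C_ij(t) dt, evaluated
per tensor element as a numeric trapezoid over [0, t_num] plus the
analytic tail of a biexponential fitted on [t_num, t_fit_end].
Translational diffusion comes from the linear regime of the
center-of-mass MSD, finite-size corrected by the cubic-lattice
Yeh–Hummer term kB*T*xi/(6 pi eta L) and optionally rescaled by the
ratio of simulated to experimental solvent viscosity.

Units: pressure in bar, volume nm^3, time ps, viscosity mPa*s, diffusion
cm^2/s.  With those, eta[mPa*s] = 1e-26 * V * integral / (kB*T).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import (EstimationError, FitError, NonphysicalFitError,
                     WrappedInputError, ArgumentError)

__all__ = [
    "PressureTensorSeries", "ViscosityEstimate", "DiffusionEstimate",
    "green_kubo_viscosity", "msd_curve", "fit_diffusion",
    "KB", "XI_CUBIC", "ETA_EXPT_MPAS", "GK_UNIT_FACTOR",
]

log = logging.getLogger(__name__)

KB = 1.380649e-23            # J/K (SI exact)
XI_CUBIC = 2.837297          # cubic-lattice self-term
ETA_EXPT_MPAS = 0.694        # water at 310 K, 0.1 M salt
GK_UNIT_FACTOR = 1e-26       # bar^2*ps*nm^3 / (J/K * K) -> mPa*s
NM2_PER_PS_TO_CM2_PER_S = 1.0 / 100.0

ELEMENT_NAMES = ("Pxy", "Pxz", "Pyz", "dxxyy", "dxxzz", "dyyzz")


@dataclass
class PressureTensorSeries:
    """Six off-diagonal/difference pressure elements sampled at fixed dt.

    Columns: P_xy, P_xz, P_yz, (P_xx-P_yy)/2, (P_xx-P_zz)/2,
    (P_yy-P_zz)/2, all in bar.
    """

    dt: float
    elements: np.ndarray  # (n_steps, 6)
    V: float              # nm^3
    T: float              # K

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=float)
        if self.elements.ndim != 2 or self.elements.shape[1] != 6:
            raise ArgumentError("elements must have shape (n_steps, 6)")
        if not np.all(np.isfinite(self.elements)):
            raise ArgumentError("pressure series must be finite")
        if self.dt <= 0:
            raise ArgumentError("dt must be positive")

    @classmethod
    def from_csv(cls, path, V: float, T: float) -> "PressureTensorSeries":
        import pandas as pd

        df = pd.read_csv(path)
        cols = ["time_ps", *ELEMENT_NAMES]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ArgumentError(f"pressure CSV missing columns {missing}")
        t = df["time_ps"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        return cls(dt=dt, elements=df[list(ELEMENT_NAMES)].to_numpy(), V=V, T=T)

    def to_csv(self, path) -> None:
        import pandas as pd

        t = np.arange(len(self.elements)) * self.dt
        df = pd.DataFrame({"time_ps": t})
        for k, name in enumerate(ELEMENT_NAMES):
            df[name] = self.elements[:, k]
        df.to_csv(path, index=False)


@dataclass
class ViscosityEstimate:
    eta: float                       # mPa*s, mean over accepted elements
    eta_sd: float
    per_element: dict[str, float]
    fit_params: dict[str, tuple[float, float, float, float]]  # a0, tau0, a1, tau1
    t_num: float
    t_fit_end: float
    dropped: list[str] = field(default_factory=list)


def _acf_fft(x: np.ndarray, n_lags: int) -> np.ndarray:
    """Multiple-time-origin autocorrelation <x(t) x(0)> via FFT (biased 1/N)."""
    n = len(x)
    m = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, m)
    acov = np.fft.irfft(fx * np.conj(fx), m)[:n_lags]
    return acov / n


def _biexp(t, a0, tau0, a1, tau1):
    return a0 * np.exp(-t / tau0) + a1 * np.exp(-t / tau1)


def green_kubo_viscosity(series: PressureTensorSeries, t_num: float = 1.0,
                         t_fit_end: float = 4.0,
                         residual_threshold: float = 0.5,
                         ) -> ViscosityEstimate:
    """Green–Kubo shear viscosity from a pressure-tensor series.

    Per element: ACF over all time origins; trapezoidal integral on
    [0, t_num]; biexponential least-squares fit on [t_num, t_fit_end];
    analytic tail ``sum_k a_k tau_k exp(-t_num/tau_k)`` added.  The six
    element estimates are combined as unweighted mean +/- SD; elements
    with non-convergent fits are dropped with a log message.
    """
    dt = series.dt
    n_steps = len(series.elements)
    if n_steps * dt < 10 * t_fit_end:
        raise ArgumentError("series shorter than 10x the fit window")
    if dt > t_num / 10 + 1e-12:
        raise ArgumentError("dt must be <= t_num/10 to resolve the numeric window")

    from scipy.optimize import curve_fit

    n_num = int(round(t_num / dt))
    n_fit_end = int(round(t_fit_end / dt))
    lags = np.arange(n_fit_end + 1) * dt

    if np.allclose(series.elements, 0.0):
        zero = {name: 0.0 for name in ELEMENT_NAMES}
        return ViscosityEstimate(eta=0.0, eta_sd=0.0, per_element=zero,
                                 fit_params={}, t_num=t_num, t_fit_end=t_fit_end)

    unit = GK_UNIT_FACTOR * series.V / (KB * series.T)
    per_element: dict[str, float] = {}
    fit_params: dict[str, tuple] = {}
    dropped: list[str] = []
    for k, name in enumerate(ELEMENT_NAMES):
        acf = _acf_fft(series.elements[:, k], n_fit_end + 1)
        numeric = np.trapezoid(acf[:n_num + 1], dx=dt)
        t_tail = lags[n_num:]
        y_tail = acf[n_num:]
        # initialize from a log-linear single-exponential fit, split 70/30;
        # tau is bounded by 5x the fit window since a 1-4 ps tail cannot
        # constrain slower components (an unbounded slow mode just fits the
        # correlated noise floor and inflates the analytic tail)
        tau_max = 5.0 * t_fit_end
        pos = y_tail > 0
        if pos.sum() >= 2:
            slope, icpt = np.polyfit(t_tail[pos], np.log(y_tail[pos]), 1)
            tau_init = min(max(-1.0 / slope, dt), tau_max) if slope < 0 else 1.0
            amp = np.exp(icpt)
        else:
            tau_init, amp = 1.0, abs(acf[0])
        p0 = [0.7 * amp, tau_init, 0.3 * amp, min(2.0 * tau_init, tau_max)]
        try:
            popt, _ = curve_fit(_biexp, t_tail, y_tail, p0=p0, maxfev=20000,
                                bounds=([-np.inf, dt, -np.inf, dt],
                                        [np.inf, tau_max, np.inf, tau_max]))
            resid = np.linalg.norm(_biexp(t_tail, *popt) - y_tail)
            scale = np.linalg.norm(y_tail) + 1e-30
            if resid / scale > residual_threshold:
                raise FitError(f"relative residual {resid / scale:.2f} too large")
        except (RuntimeError, FitError) as exc:
            log.warning("element %s dropped: %s", name, exc)
            dropped.append(name)
            continue
        a0, tau0, a1, tau1 = popt
        tail = a0 * tau0 * np.exp(-t_num / tau0) + a1 * tau1 * np.exp(-t_num / tau1)
        per_element[name] = unit * (numeric + tail)
        fit_params[name] = (float(a0), float(tau0), float(a1), float(tau1))

    if not per_element:
        raise EstimationError("all pressure-tensor elements were rejected")
    vals = np.array(list(per_element.values()))
    return ViscosityEstimate(eta=float(vals.mean()), eta_sd=float(vals.std(ddof=0)),
                             per_element=per_element, fit_params=fit_params,
                             t_num=t_num, t_fit_end=t_fit_end, dropped=dropped)


# ---------------------------------------------------------------------------
# MSD and diffusion
# ---------------------------------------------------------------------------

def msd_curve(paths: np.ndarray, dt: float, box_edge: float | None = None,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Mean-squared displacement over all time origins and particles.

    ``paths`` has shape (n_frames, n_particles, 3) (a single particle may
    be passed as (n_frames, 3)) and must be *unwrapped*; if ``box_edge``
    is given, any single-frame jump exceeding L/2 raises
    :class:`WrappedInputError`.  Lags run to half the series length.
    Implemented with the standard FFT decomposition of the origin
    average.
    """
    paths = np.asarray(paths, dtype=float)
    if paths.ndim == 2:
        paths = paths[:, None, :]
    n_frames = paths.shape[0]
    if n_frames < 2:
        raise ArgumentError("MSD needs >= 2 frames")
    if box_edge is not None:
        jumps = np.abs(np.diff(paths, axis=0)).max() if n_frames > 1 else 0.0
        if jumps >= box_edge / 2:
            raise WrappedInputError(
                "input looks wrapped (jump >= L/2); unwrap first")
    n_lags = max(2, n_frames // 2)
    msd = np.zeros(n_lags)
    for p in range(paths.shape[1]):
        msd += _msd_fft(paths[:, p, :])[:n_lags]
    msd /= paths.shape[1]
    return np.arange(n_lags) * dt, msd


def _msd_fft(r: np.ndarray) -> np.ndarray:
    """Origin-averaged MSD of one 3-D path via the FFT identity."""
    n = len(r)
    d2 = np.square(r).sum(axis=1)
    # S2: autocorrelation of the coordinates
    m = 1 << (2 * n - 1).bit_length()
    s2 = np.zeros(n)
    for k in range(3):
        f = np.fft.rfft(r[:, k], m)
        s2 += np.fft.irfft(f * np.conj(f), m)[:n]
    counts = n - np.arange(n)
    s2 /= counts
    # S1 recursion
    sq = 2.0 * d2.sum()
    s1 = np.empty(n)
    for lag in range(n):
        if lag > 0:
            sq -= d2[lag - 1] + d2[n - lag]
        s1[lag] = sq / (n - lag)
    return s1 - 2.0 * s2


@dataclass
class DiffusionEstimate:
    c: float              # nm^2 intercept
    D_pbc: float          # cm^2/s, uncorrected
    D_t: float            # cm^2/s, Yeh–Hummer corrected
    D_pred: float         # cm^2/s, viscosity-rescaled
    fit_window: tuple[float, float]
    L: float
    eta_sim: float
    eta_expt: float
    xi: float = XI_CUBIC


def fit_diffusion(lags: np.ndarray, msd: np.ndarray,
                  fit_window: tuple[float, float], L: float, T: float,
                  eta_sim: float, eta_expt: float = ETA_EXPT_MPAS,
                  ) -> DiffusionEstimate:
    """Linear MSD fit plus finite-size correction and viscosity rescaling.

    MSD = c + 6 D_pbc tau on the window (lags in ps, MSD in nm^2);
    D_t = D_pbc + kB*T*xi / (6 pi eta_sim L); D_pred = D_t *
    eta_sim/eta_expt.  Diffusion coefficients are returned in cm^2/s.
    """
    lags = np.asarray(lags, dtype=float)
    msd = np.asarray(msd, dtype=float)
    if eta_sim <= 0 or eta_expt <= 0:
        raise ArgumentError("viscosities must be positive")
    lo, hi = fit_window
    mask = (lags >= lo) & (lags <= hi)
    if mask.sum() < 2:
        raise ArgumentError("fit window selects fewer than 2 lags")
    slope, intercept = np.polyfit(lags[mask], msd[mask], 1)
    if slope < 0:
        raise NonphysicalFitError(f"negative MSD slope {slope:.3e}")
    d_pbc = slope / 6.0 * NM2_PER_PS_TO_CM2_PER_S
    # kB[J/K]*T / (6 pi eta[mPa*s -> Pa*s] L[nm -> m]) = m^2/s -> cm^2/s
    corr = KB * T * XI_CUBIC / (6.0 * np.pi * (eta_sim * 1e-3) * (L * 1e-9)) * 1e4
    d_t = d_pbc + corr
    return DiffusionEstimate(c=float(intercept), D_pbc=float(d_pbc),
                             D_t=float(d_t),
                             D_pred=float(d_t * eta_sim / eta_expt),
                             fit_window=(float(lo), float(hi)), L=L,
                             eta_sim=eta_sim, eta_expt=eta_expt)
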