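"""Interactivity profiles and statistical motif (sticker) calling.

The motif caller mirrors a three-step scheme: (1) per-residue contact
counts are normalized to a max of one; (2) the profile's second
numerical derivative is obtained with quadratic Savitzky–Golay filters
at window sizes 5, 7 and 9; (3) positions whose second derivative lies
more than one standard deviation below its mean become candidate motif
centers, each expanded to a window-sized interval, and sequence
stretches covered by intervals from at least two window sizes are
reported as motifs (full certainty when all three agree).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .contacts import ContactFrameSet, valency_series
from .core import SystemTopology
from .errors import ArgumentError, EmptyProfileError, WindowError

__all__ = [
    "InteractivityProfile", "SmoothedProfile", "MotifCall",
    "interactivity_profile", "sg_smooth", "pick_minima", "consensus_motifs",
    "call_motifs", "SG_WINDOWS",
]

SG_WINDOWS = (5, 7, 9)


@dataclass
class InteractivityProfile:
    """Per-residue contact counts normalized so the maximum equals one."""

    counts: np.ndarray
    normalized: np.ndarray
    context: str                       # 'inter' or 'intra'
    valency_filter: int | None = None


def interactivity_profile(contact_sets: Sequence[ContactFrameSet],
                          topology: SystemTopology, context: str = "inter",
                          valency_filter: int | None = None,
                          ) -> InteractivityProfile:
    """Aggregate contact counts per sequence position over chains and frames.

    With ``valency_filter`` set, a residue of chain c contributes in a
    frame only if chain c has exactly that valency there.
    """
    if context not in ("inter", "intra"):
        raise ArgumentError("context must be 'inter' or 'intra'")
    if not contact_sets:
        raise ArgumentError("no contact frames")
    n_res = topology.n_residues(0)
    counts = np.zeros(n_res, dtype=float)
    vals = None
    if valency_filter is not None:
        vals = valency_series(contact_sets, topology.n_chains)
    for f, cs in enumerate(contact_sets):
        recs = cs.inter() if context == "inter" else cs.intra()
        for ca, ra, cb, rb in recs:
            if vals is None or vals[f, ca] == valency_filter:
                counts[ra - 1] += 1
            if vals is None or vals[f, cb] == valency_filter:
                counts[rb - 1] += 1
    peak = counts.max()
    if peak <= 0:
        raise EmptyProfileError("profile is all zero; nothing to normalize")
    return InteractivityProfile(counts=counts, normalized=counts / peak,
                                context=context, valency_filter=valency_filter)


@dataclass
class SmoothedProfile:
    """Savitzky–Golay output; positions where the window does not fit are NaN."""

    values: np.ndarray
    window: int
    derivative: int
    coefficients: np.ndarray

    def valid_slice(self) -> slice:
        half = (self.window - 1) // 2
        return slice(half, len(self.values) - half)


def sg_smooth(profile: np.ndarray, w: int, derivative: int = 0,
              ) -> SmoothedProfile:
    """Quadratic Savitzky–Golay smoothing or second derivative.

    Convolution coefficients come from the local least-squares quadratic
    fit (scipy's ``savgol_coeffs``); the ``(w-1)/2`` positions at either
    end, where the window does not fit, carry NaN rather than a padded
    value.
    """
    from scipy.signal import savgol_coeffs

    if w not in SG_WINDOWS:
        raise ArgumentError(f"window must be one of {SG_WINDOWS}")
    if derivative not in (0, 2):
        raise ArgumentError("derivative must be 0 or 2")
    profile = np.asarray(profile, dtype=float)
    if profile.ndim != 1 or len(profile) < w:
        raise WindowError(f"profile shorter than window {w}")
    coeffs = savgol_coeffs(w, polyorder=2, deriv=derivative, delta=1.0)
    half = (w - 1) // 2
    valid = np.convolve(profile, coeffs[::-1], mode="valid")
    values = np.full(len(profile), np.nan)
    values[half:len(profile) - half] = valid
    return SmoothedProfile(values=values, window=w, derivative=derivative,
                           coefficients=coeffs)


def pick_minima(second_derivative: SmoothedProfile,
                ) -> tuple[list[int], float]:
    """Candidate motif centers from deep second-derivative minima.

    Candidates are 1-based positions whose value is strictly below
    ``mean - 1*SD`` of the valid second-derivative values.  A
    Shapiro–Wilk normality p-value for those values is returned alongside
    (non-normality is reported, not fatal).
    """
    from scipy.stats import shapiro

    if second_derivative.derivative != 2:
        raise ArgumentError("pick_minima expects a second-derivative profile")
    vals = second_derivative.values
    finite = np.isfinite(vals)
    if finite.sum() < 5:
        raise ArgumentError("need >= 5 valid second-derivative positions")
    v = vals[finite]
    sd = v.std(ddof=0)
    if sd == 0.0:
        return [], float("nan")
    shapiro_p = float(shapiro(v).pvalue) if len(set(v.tolist())) > 1 else float("nan")
    threshold = v.mean() - sd
    candidates = [int(i) + 1 for i in np.nonzero(finite)[0]
                  if vals[i] < threshold]
    return candidates, shapiro_p


@dataclass
class MotifCall:
    """A called motif: 1-based inclusive interval with its support level."""

    start: int
    end: int
    support: int     # max number of window sizes covering the stretch (2 or 3)

    @property
    def certainty(self) -> str:
        return "full" if self.support == 3 else "reduced"


def consensus_motifs(candidates_by_window: Mapping[int, Sequence[int]],
                     n_res: int) -> list[MotifCall]:
    """Merge per-window candidate centers into consensus motif calls.

    Each center c at window w marks the interval ``[c-(w-1)/2,
    c+(w-1)/2]`` (clipped to the sequence).  Positions covered by
    intervals from >= 2 window sizes form motif stretches (maximal runs);
    a stretch has full certainty when some position in it is covered by
    all three windows.
    """
    missing = set(SG_WINDOWS) - set(candidates_by_window)
    if missing:
        raise ArgumentError(f"candidate sets missing for windows {sorted(missing)}")
    support = np.zeros(n_res + 1, dtype=int)  # 1-based
    for w in SG_WINDOWS:
        covered = np.zeros(n_res + 1, dtype=bool)
        half = (w - 1) // 2
        for c in candidates_by_window[w]:
            lo = max(1, c - half)
            hi = min(n_res, c + half)
            covered[lo:hi + 1] = True
        support += covered
    calls: list[MotifCall] = []
    pos = 1
    while pos <= n_res:
        if support[pos] >= 2:
            start = pos
            while pos <= n_res and support[pos] >= 2:
                pos += 1
            end = pos - 1
            calls.append(MotifCall(start=start, end=end,
                                   support=int(support[start:end + 1].max())))
        else:
            pos += 1
    return calls


def call_motifs(profile: InteractivityProfile, n_res: int | None = None,
                ) -> tuple[list[MotifCall], dict]:
    """End-to-end motif calling from a normalized interactivity profile."""
    values = profile.normalized
    n = len(values) if n_res is None else n_res
    candidates: dict[int, list[int]] = {}
    diagnostics: dict = {}
    for w in SG_WINDOWS:
        d2 = sg_smooth(values, w, derivative=2)
        cands, shapiro_p = pick_minima(d2)
        candidates[w] = cands
        diagnostics[w] = {"candidates": cands, "shapiro_p": shapiro_p}
    return consensus_motifs(candidates, n), diagnostics
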