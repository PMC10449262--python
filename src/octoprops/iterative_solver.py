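"""Joint depth-resolved estimation of mu(z) and R(z) by constrained
stationary iteration.

The depth-resolved attenuation baseline is exact only when the
backscattering fraction R is constant; when R varies with depth the
baseline is biased by every change of R *below* the evaluation depth.  The
solver removes this bias by alternating two half-steps:

1. given a piecewise-constant R_k, refine mu:  by default the intensity is
   divided by R_k first (``I/R`` is proportional to the pure irradiance
   derivative, so the baseline formula applied to it is exact when R_k is
   exact); the literal bracketed correction factor built from the
   distributional derivative of R_k is available as ``mode="correction"``;
2. given mu_{k+1}, re-segment the backscattering profile by *fuzzy
   processing* (runs of low |dR/dz| are replaced by their mean, so only
   large, structural changes of R survive) and re-anchor each segment's R:
   the segments are the locally homogeneous portions of the model, so each
   segment's attenuation is taken from its own exponential decay (a
   log-linear fit of I within the segment) and the local inversion of the
   intensity model then yields the segment's backscattering value.  This
   anchoring is what breaks the scale degeneracy of the coupled system:
   re-initialising R pointwise from mu_{k+1} alone reproduces the previous
   R exactly (the coupled equations are both derived from the same
   intensity model, hence underdetermined), whereas the within-segment
   decay is independent information that pulls the pair toward the true
   profile and makes it an attracting fixed point.

Constraints guard the loop (the underlying fixed-point iteration has no
global convergence guarantee): R must stay in (0,1) and within a band
around the sample-average backscattering, mu_k may not leave a fixed ratio
band around the baseline, the loop count is capped, and the loop stops once
the largest relative change of mu falls below a tolerance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import AScanProfile, BScan
from .estimators import (
    NEAR_SURFACE_EXCLUDE,
    _cumulative_from_surface,
    init_R,
    integral_to_infinity,
    mean_R,
    vermeer_mu,
)

__all__ = [
    "IterationConfig",
    "IterationState",
    "fuzzy_process_R",
    "update_mu",
    "solve",
    "solve_bscan",
]


@dataclass(frozen=True)
class IterationConfig:
    """Constraint scaling factors and loop controls.

    A, B : lower/upper factor on the sample-average backscattering R~
        bounding every segment mean of R_k (defaults 0.1 and 10)
    C, D : lower/upper bound on mu_k / mu0 (defaults 0.2 and 5)
    E : maximum number of loops (default 10)
    deriv_factor : threshold multiplier on the mean |dR/dz| used by the
        fuzzy processing (default 4.5, the midpoint of the four-to-five
        range that preserves edges while suppressing noise)
    rel_tol : relative-change stopping tolerance on mu at the depth of
        largest absolute change (default 0.01)
    mode : mu update rule, "ratio" (default) or "correction"
    """

    A: float = 0.1
    B: float = 10.0
    C: float = 0.2
    D: float = 5.0
    E: int = 10
    deriv_factor: float = 4.5
    rel_tol: float = 0.01
    mode: str = "ratio"

    def __post_init__(self) -> None:
        if not (self.A < 1 < self.B):
            raise ValueError("constraint factors require A < 1 < B")
        if not (self.C < 1 < self.D):
            raise ValueError("constraint factors require C < 1 < D")
        if self.E < 1:
            raise ValueError("E must be >= 1")
        if not self.deriv_factor > 0:
            raise ValueError("deriv_factor must be > 0")
        if not self.rel_tol > 0:
            raise ValueError("rel_tol must be > 0")
        if self.mode not in {"ratio", "correction"}:
            raise ValueError(f"unknown update mode {self.mode!r}")


@dataclass
class IterationState:
    """Trajectory of one solve: loop counter, current profiles, the segment
    breakpoints of the fuzzy processing, why the loop ended, and the
    per-loop largest relative change of mu."""

    k: int
    mu_k: np.ndarray
    R_k: np.ndarray
    segments: list[tuple[int, int]]
    stop_reason: str
    history: list[float] = field(default_factory=list)
    mu0: np.ndarray | None = None
    R_tilde: float | None = None


# ---------------------------------------------------------------------------
# fuzzy processing of R
# ---------------------------------------------------------------------------


def fuzzy_process_R(
    R: np.ndarray, dz: float, deriv_factor: float = 4.5
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Piecewise-constant regularisation of a backscattering profile.

    The backward-difference derivative is thresholded at ``deriv_factor``
    times its mean absolute value; contiguous low-derivative runs become
    segments replaced by their mean, while above-threshold (breakpoint)
    pixels join the adjacent *deeper* segment — the attenuation bias at a
    depth depends only on R variation below it, so boundary pixels must not
    contaminate the shallower segment.  A backward (one-sided) difference
    is used because it flags exactly the sample where a step occurs: the
    segmentation of a piecewise-constant profile then reproduces itself,
    keeping the breakpoints stationary from loop to loop (a centred
    difference smears each step over two pixels and shifts the regenerated
    breakpoint by one pixel per pass).

    Returns the piecewise-constant profile and the half-open index ranges
    of the segments (after breakpoint absorption).
    """
    R = np.asarray(R, dtype=float)
    n = R.size
    if n < 3:
        raise ValueError("fuzzy processing needs >= 3 samples")
    if np.any(~np.isfinite(R)):
        raise ValueError("R must be finite on its support")
    # the derivative is taken on ln R where possible: structural changes of
    # a backscattering profile are multiplicative, so a relative-change
    # threshold treats every decade of R alike (profiles of layered tissue
    # span several), while matching the linear criterion on a profile that
    # stays within one decade
    trace = np.log(R) if np.all(R > 0) else R
    d = np.diff(trace, prepend=trace[0]) / dz
    thr = deriv_factor * float(np.mean(np.abs(d)))
    low = np.abs(d) <= thr
    if not np.any(low):
        low = np.ones(n, dtype=bool)  # pathological: treat all as one run

    # label contiguous low runs
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1

    means = [float(np.mean(R[a:b])) for a, b in runs]
    # absorb breakpoint zones into the deeper adjacent segment; the zone
    # after the last run joins the last run
    segments: list[tuple[int, int]] = []
    out = np.empty(n)
    prev_end = 0
    for idx, (a, b) in enumerate(runs):
        start = prev_end if idx > 0 else 0
        # pixels in [start, a) belong to this (deeper) segment
        seg_start = start
        seg_end = b
        out[seg_start:seg_end] = means[idx]
        segments.append((seg_start, seg_end))
        prev_end = b
    if prev_end < n:  # trailing breakpoint zone
        a, b = segments[-1]
        segments[-1] = (a, n)
        out[prev_end:] = means[-1]
    return out, segments


# ---------------------------------------------------------------------------
# mu update
# ---------------------------------------------------------------------------


def update_mu(
    aline: AScanProfile,
    R_k: np.ndarray,
    mu0: np.ndarray,
    config: IterationConfig = IterationConfig(),
    mu_k: np.ndarray | None = None,
) -> np.ndarray:
    """One mu half-step given a piecewise-constant R_k.

    ``mode="ratio"``: apply the depth-resolved baseline to ``I/R_k`` (the
    deepest segment's R also scales the analytic tail).  ``mode=
    "correction"``: multiply the baseline of ``I`` by the explicit bracket
    ``1 + sum_b dR_b exp(-2 tau(z_b)) / (R_k(z) exp(-2 tau(z)))`` over
    downstream breakpoints ``b`` of the piecewise-constant R_k, with
    ``tau`` accumulated from ``mu_k``.  Both rules clamp the result to
    ``[C mu0, D mu0]``.
    """
    v = np.clip(aline.values, 0.0, None)
    R_k = np.asarray(R_k, dtype=float)
    support = v > 0
    if np.any(support & ~(R_k > 0)):
        raise ValueError("R_k must be > 0 on the signal support")

    if config.mode == "ratio":
        ratio = np.zeros_like(v)
        np.divide(v, R_k, out=ratio, where=support)
        r_last = float(R_k[support][-1]) if np.any(support) else 1.0
        s = integral_to_infinity(aline, ratio, tail_scale=1.0 / r_last)
        mu_new = np.zeros_like(v)
        good = s > 0
        np.divide(ratio, 2.0 * s, out=mu_new, where=good)
    else:
        if mu_k is None:
            mu_k = mu0
        base = vermeer_mu(aline)
        z = aline.grid.depths
        tau = _cumulative_from_surface(z, mu_k)
        att = np.exp(-2.0 * tau)
        # distributional derivative of the piecewise-constant R_k
        steps = np.nonzero(np.diff(R_k) != 0)[0]  # step between i and i+1
        bracket = np.ones_like(v)
        if steps.size:
            dR = R_k[steps + 1] - R_k[steps]
            att_b = att[steps + 1]
            # cumulative downstream sum: for each z_i, sum over steps at b >= i
            contrib = np.zeros_like(v)
            np.add.at(contrib, steps + 1, dR * att_b)
            downstream = np.cumsum(contrib[::-1])[::-1]
            with np.errstate(divide="ignore", invalid="ignore"):
                bracket = 1.0 + np.where(
                    support, downstream / (R_k * att), 0.0
                )
        mu_new = base * bracket
    lo = config.C * mu0
    hi = config.D * mu0
    return np.clip(mu_new, lo, hi)


# ---------------------------------------------------------------------------
# full solve
# ---------------------------------------------------------------------------


def _segment_mu_fit(
    z: np.ndarray, v: np.ndarray, a: int, b: int, fallback: float
) -> float:
    """Attenuation of one homogeneous segment from its own log-linear decay
    (trimming the absorbed breakpoint pixels at the segment ends); falls
    back to the supplied mean when the fit is impossible or non-decaying."""
    margin = 2 if (b - a) >= 12 else 0
    sl = slice(a + margin, b - margin)
    vv = v[sl]
    zz = z[sl]
    mask = vv > 0
    if mask.sum() >= 5:
        slope, _ = np.polyfit(zz[mask], np.log(vv[mask]), 1)
        mu_s = -slope / 2.0
        if mu_s > 0:
            return float(mu_s)
    return float(fallback)


def _anchored_R(
    aline: AScanProfile,
    segments: list[tuple[int, int]],
    mu_ref: np.ndarray,
    beta_L0: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment-anchored backscattering refresh.

    Builds a piecewise-constant attenuation profile from per-segment decay
    fits (``mu_ref`` supplies the fallback segment means), inverts the
    intensity model with it, and averages the result per segment.  Exact
    whenever the segmentation resolves the true layers; where layers stay
    merged, the unresolved backscattering steps inside a segment are
    absorbed into its fitted slope (the known hard regime for tissue with
    weakly contrasted layers).  Returns the piecewise-constant R, the
    anchored mu profile, and the raw (un-averaged) inversion — whose steps
    stay pinned to the data's interfaces, making it the stable
    segmentation source for the next loop.
    """
    z = aline.grid.depths
    v = np.clip(aline.values, 0.0, None)
    mu_anchor = np.zeros_like(v)
    for a, b in segments:
        fallback = float(np.mean(mu_ref[a:b]))
        mu_anchor[a:b] = _segment_mu_fit(z, v, a, b, fallback)
    R_raw = init_R(aline, mu_anchor, beta_L0)
    span = slice(segments[0][0], segments[-1][1])
    sub = R_raw[span]
    finite = np.isfinite(sub)
    if np.any(finite) and not np.all(finite):
        idx = np.arange(sub.size)
        R_raw[span] = np.interp(idx, idx[finite], sub[finite])
    R_out = np.full_like(v, np.nan)
    for a, b in segments:
        R_out[a:b] = np.nanmean(R_raw[a:b])
    return R_out, mu_anchor, R_raw


def _refine_segments(
    R_raw: np.ndarray,
    segments: list[tuple[int, int]],
    dz: float,
    deriv_factor: float,
    min_len: int = 5,
) -> list[tuple[int, int]]:
    """Hierarchical re-segmentation: run the fuzzy processing inside every
    current segment with the threshold computed from that segment's own
    mean |dR/dz|.

    A single global threshold cannot serve a profile whose backscattering
    spans decades — the noisiest bright region sets a scale that hides
    every step elsewhere.  Re-thresholding per segment adapts the scale to
    the local range of R each loop.  Sub-segments shorter than ``min_len``
    are merged into their deeper neighbour so breakpoint-zone pixels cannot
    spawn spurious slivers.
    """
    out: list[tuple[int, int]] = []
    for a, b in segments:
        sub = R_raw[a:b]
        if b - a < 2 * min_len or not np.all(np.isfinite(sub)):
            out.append((a, b))
            continue
        _, subsegs = fuzzy_process_R(sub, dz, deriv_factor)
        merged: list[tuple[int, int]] = []
        pending_start: int | None = None
        for sa, sb in subsegs:
            start = pending_start if pending_start is not None else sa
            if sb - start < min_len:
                pending_start = start  # too short: extend into the deeper one
                continue
            merged.append((start, sb))
            pending_start = None
        if pending_start is not None:
            if merged:
                la, _ = merged[-1]
                merged[-1] = (la, subsegs[-1][1])
            else:
                merged.append((subsegs[0][0], subsegs[-1][1]))
        out.extend((a + sa, a + sb) for sa, sb in merged)
    return out


def _fuzzy_full(
    R_raw: np.ndarray, support0: int, dz: float, deriv_factor: float
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Fuzzy-process R on the support (excluding the first pixels below the
    surface) and rebuild a full-length profile, extending the first segment
    up to the surface."""
    start = support0 + NEAR_SURFACE_EXCLUDE
    sub = R_raw[start:]
    finite = np.isfinite(sub)
    if not np.any(finite):
        raise ValueError("R undefined over the whole analysis range")
    if not np.all(finite):
        # interior zero-intensity bins (data gaps) leave R undefined there;
        # fill from the nearest defined sample
        idx = np.arange(sub.size)
        sub = np.interp(idx, idx[finite], sub[finite])
    pc, segs = fuzzy_process_R(sub, dz, deriv_factor)
    full = np.full_like(R_raw, np.nan)
    full[start:] = pc
    full[support0:start] = pc[0]
    segments = [(a + start, b + start) for a, b in segs]
    if segments:
        segments[0] = (support0, segments[0][1])
    return full, segments


def solve(
    aline: AScanProfile,
    beta_L0: float,
    config: IterationConfig = IterationConfig(),
    bottom_z: float | None = None,
) -> IterationState:
    """Run the constrained stationary iteration on one (preprocessed,
    tail-extrapolated) A-line.

    Initialises mu0 from the depth-resolved baseline and R0 from the
    fuzzily processed local inversion, then alternates the mu and R
    half-steps until the loop cap is reached, the ratio clamp saturates,
    or the change of mu becomes negligible.  The R constraints (within
    (0,1) and within the scaled band around the sample average) are
    enforced by projection at every refresh, so every emitted state is
    feasible.  If ``bottom_z`` is given (the depth where signal ends and
    extrapolation starts), mu below it is set to zero in the returned
    state.
    """
    v = np.clip(aline.values, 0.0, None)
    pos = np.nonzero(v > 0)[0]
    if pos.size < NEAR_SURFACE_EXCLUDE + 3:
        raise ValueError("too little signal to solve")
    s0 = int(pos[0])

    mu0 = vermeer_mu(aline)
    R_tilde = mean_R(aline, beta_L0)
    R_raw = init_R(aline, mu0, beta_L0)
    R_k, segments = _fuzzy_full(R_raw, s0, aline.grid.dz, config.deriv_factor)
    if len(segments) > 1:
        # the pointwise inversion of the baseline is constant by
        # construction; its derivative spikes still mark the interfaces, so
        # anchor each detected portion to its own decay immediately
        R_k, _, R_raw = _anchored_R(aline, segments, mu0, beta_L0)

    mu_k = mu0.copy()
    state = IterationState(
        k=0,
        mu_k=mu_k,
        R_k=R_k,
        segments=segments,
        stop_reason="max_iterations",
        history=[],
        mu0=mu0,
        R_tilde=R_tilde,
    )

    # the constraints bound the solution space; the initial profile is
    # projected into the feasible band (violations during the loop roll the
    # state back instead)
    lo_R = np.nextafter(config.A * R_tilde, np.inf)
    hi_R = np.nextafter(min(config.B * R_tilde, 1.0), -np.inf)
    state.R_k = np.clip(state.R_k, lo_R, hi_R)
    R_k = state.R_k

    for k in range(1, config.E + 1):
        mu_next = update_mu(aline, state.R_k, mu0, config, mu_k=state.mu_k)

        sup = slice(s0, None)
        delta = np.abs(mu_next[sup] - state.mu_k[sup])
        i0 = int(np.argmax(delta))
        denom = state.mu_k[sup][i0]
        rel = float(delta[i0] / denom) if denom > 0 else float("inf")
        state.history.append(rel)

        # overcompensation guard: stop if the update is pinned to the
        # ratio band everywhere on the support
        lo = config.C * mu0[sup]
        hi = config.D * mu0[sup]
        at_bound = (mu_next[sup] <= lo * (1 + 1e-12)) | (
            mu_next[sup] >= hi * (1 - 1e-12)
        )
        if np.all(at_bound[mu0[sup] > 0]):
            state.stop_reason = "mu ratio clamp saturated"
            return state

        # hierarchically refine the current segmentation on the
        # data-anchored raw inversion (its steps stay pinned to the
        # interfaces; re-segmenting the fed-back staircase would creep one
        # pixel per loop), with per-segment thresholds recomputed every loop
        segs_next = _refine_segments(
            R_raw, state.segments, aline.grid.dz, config.deriv_factor
        )
        if len(segs_next) > 1:
            # re-anchor each homogeneous portion to its own decay; with a
            # single segment the system degenerates to the baseline and R
            # stays at the fuzzy mean
            R_next, _, R_raw = _anchored_R(aline, segs_next, mu_next, beta_L0)
        else:
            R_next = state.R_k
        # project into the feasible band (R in (0,1) and within the scaled
        # band around the sample average), mirroring the mu ratio clamp
        R_next = np.clip(R_next, lo_R, hi_R)

        state.k = k
        state.mu_k = mu_next
        state.R_k = R_next
        state.segments = segs_next

        if rel <= config.rel_tol:
            state.stop_reason = "converged"
            break

    if bottom_z is not None:
        below = aline.grid.depths > bottom_z
        state.mu_k = state.mu_k.copy()
        state.mu_k[below] = 0.0
    return state


def solve_bscan(
    bscan: BScan,
    beta_L0: float,
    config: IterationConfig = IterationConfig(),
    bottom_z: float | None = None,
) -> tuple[np.ndarray, np.ndarray, list[IterationState]]:
    """Columnwise solve producing mu and R maps aligned with the input.

    Per-column failures are recorded in the state (``stop_reason`` starts
    with ``"error"``) and the column falls back to the baseline mu0 / raw
    R0 where computable, zeros otherwise.
    """
    mu_map = np.zeros_like(bscan.values)
    R_map = np.full_like(bscan.values, np.nan)
    states: list[IterationState] = []
    for j in range(bscan.n_alines):
        col = bscan.column(j)
        try:
            st = solve(col, beta_L0, config, bottom_z=bottom_z)
        except Exception as exc:  # degraded column: record and fall back
            try:
                mu0 = vermeer_mu(col)
                R0 = init_R(col, mu0, beta_L0)
            except Exception:
                mu0 = np.zeros(bscan.grid.n)
                R0 = np.full(bscan.grid.n, np.nan)
            st = IterationState(
                k=0,
                mu_k=mu0,
                R_k=R0,
                segments=[],
                stop_reason=f"error: {exc}",
                mu0=mu0,
            )
        states.append(st)
        mu_map[:, j] = st.mu_k
        R_map[:, j] = st.R_k
    return mu_map, R_map, states
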