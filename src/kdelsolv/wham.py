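"""Weighted histogram analysis of umbrella-sampling windows.

Biased samples from harmonically restrained windows are combined into an
unbiased potential of mean force (PMF) by self-consistent iteration of the
window free-energy constants:

    p_j ∝ n_j / Σ_i N_i exp(β f_i) exp(−β w_i(x_j)),
    exp(−β f_i) = Σ_j exp(−β w_i(x_j)) p_j,

with n_j the pooled histogram count in bin j, N_i the sample count and
w_i the harmonic bias of window i. The PMF is −k_BT ln p_j, anchored so
its global minimum is zero. Downstream reductions extract the unbinding
free energy (plateau height above the bound minimum) and forward/reverse
barrier heights between two states along the coordinate — the analyses
behind peptide-unbinding profiles and the His12→water→Asp9 proton-transfer
profiles.

Profiles are always reported in kcal/mol; force constants declared in
kJ/mol are converted on input (and the conversion logged).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .toy_models import Window, WindowSampleSet
from .units import KCAL_PER_KJ, beta as _beta

__all__ = [
    "PMFProfile",
    "BarrierReport",
    "ConvergenceError",
    "wham_solve",
    "pmf_from_repeats",
    "unbinding_free_energy",
    "barrier_heights",
    "write_pmf_tsv",
    "read_pmf_tsv",
]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """WHAM iteration failed to reach tolerance; carries the last residual."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"WHAM did not converge within {max_iter} iterations "
            f"(last max Δf = {residual:.3e} kcal/mol)"
        )
        self.residual = residual
        self.max_iter = max_iter


@dataclass(frozen=True)
class PMFProfile:
    """Binned free-energy profile, global minimum anchored at zero.

    Interior bins with no samples are masked (NaN); ``error`` is per-bin
    (kcal/mol) when repeat information is available, else None.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray
    temperature: float
    cv_unit: str = "nm"
    error: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.bin_centers, dtype=float)
        if len(c) > 1 and not np.all(np.diff(c) > 0):
            raise ValueError("bin centers must be strictly increasing")
        f = np.asarray(self.free_energy, dtype=float)
        if np.nanmin(f) > 1e-9:
            raise ValueError("PMF must be anchored with global minimum 0")
        if self.error is not None and np.any(np.asarray(self.error) < 0):
            raise ValueError("errors must be non-negative")

    @property
    def min_position(self) -> float:
        return float(self.bin_centers[np.nanargmin(self.free_energy)])


def _window_k_kcal(ws: WindowSampleSet) -> np.ndarray:
    k = np.array([w.force_constant for w in ws.windows], dtype=float)
    if ws.k_unit.lower().startswith("kj"):
        logger.info(
            "converting %d window force constants from kJ/mol to kcal/mol",
            len(k),
        )
        k = k * KCAL_PER_KJ
    elif not ws.k_unit.lower().startswith("kcal"):
        raise ValueError(f"unrecognised force-constant unit {ws.k_unit!r}")
    return k


def wham_solve(
    window_set: WindowSampleSet,
    n_bins: int = 100,
    tolerance: float = 1e-7,
    max_iter: int = 100000,
    bin_range: tuple[float, float] | None = None,
) -> PMFProfile:
    """Solve WHAM over the windows and return the anchored PMF.

    Bins default to 100 over the pooled sample range; samples outside an
    explicit ``bin_range`` are trimmed with a logged count. Convergence is
    max change of any window constant < ``tolerance`` (kcal/mol). The
    result is deterministic for fixed input and invariant to window order.

    Raises
    ------
    ConvergenceError
        If tolerance is not reached within ``max_iter`` iterations.
    """
    windows = window_set.windows
    if len(windows) < 1:
        raise ValueError("at least one window is required")
    kT = 1.0 / _beta(window_set.temperature)
    k_kcal = _window_k_kcal(window_set)
    centers = np.array([w.center for w in windows], dtype=float)

    pooled = np.concatenate([np.asarray(w.samples, dtype=float) for w in windows])
    if bin_range is None:
        lo, hi = pooled.min(), pooled.max()
        hi = hi + 1e-12 * max(1.0, abs(hi))  # include the max sample
    else:
        lo, hi = map(float, bin_range)
        if hi <= lo:
            raise ValueError("bin_range must be an increasing interval")
    edges = np.linspace(lo, hi, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])

    n_j = np.zeros(n_bins)
    N_i = np.empty(len(windows))
    trimmed = 0
    for i, w in enumerate(windows):
        s = np.asarray(w.samples, dtype=float)
        inside = (s >= lo) & (s <= hi)
        trimmed += int((~inside).sum())
        s = s[inside]
        N_i[i] = len(s)
        h, _ = np.histogram(s, bins=edges)
        n_j += h
    if trimmed:
        logger.info("trimmed %d samples outside the binned range", trimmed)
    if n_j.sum() == 0:
        raise ValueError("no samples fall inside the binned range")

    # Boltzmann factor of the bias averaged over each bin (5-point
    # Gauss-Legendre); a center-point evaluation biases narrow-bin PMFs
    gl_x, gl_w = np.polynomial.legendre.leggauss(5)
    half = 0.5 * (edges[1] - edges[0])
    pts = mids[None, :, None] + half * gl_x[None, None, :]
    bias = 0.5 * k_kcal[:, None, None] * (pts - centers[:, None, None]) ** 2
    c_ij = np.einsum("ijq,q->ij", np.exp(-bias / kT), gl_w) / 2.0

    f = np.zeros(len(windows))  # window free-energy constants, kcal/mol
    occupied = n_j > 0
    for _ in range(max_iter):
        denom = (N_i[:, None] * np.exp(f[:, None] / kT) * c_ij).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(occupied, n_j / denom, 0.0)
        z = c_ij @ p
        f_new = -kT * np.log(z)
        f_new -= f_new[0]
        residual = float(np.abs(f_new - f).max())
        f = f_new
        if residual < tolerance:
            break
    else:
        raise ConvergenceError(residual, max_iter)

    # interior empty bins: masked with a warning
    occ_idx = np.flatnonzero(occupied)
    first, last = occ_idx[0], occ_idx[-1]
    interior_empty = np.flatnonzero(~occupied[first : last + 1]) + first
    if interior_empty.size:
        warnings.warn(
            f"{interior_empty.size} empty bin(s) in the profile interior "
            "were masked; consider fewer bins or more sampling",
            stacklevel=2,
        )
    with np.errstate(divide="ignore"):
        F = np.where(occupied, -kT * np.log(np.where(occupied, p, 1.0)), np.nan)
    F = F[first : last + 1]
    F -= np.nanmin(F)
    return PMFProfile(
        bin_centers=mids[first : last + 1],
        free_energy=F,
        temperature=window_set.temperature,
        cv_unit=window_set.cv_unit,
    )


def pmf_from_repeats(
    repeats: Sequence[WindowSampleSet],
    n_bins: int = 100,
    bin_range: tuple[float, float] | None = None,
    **kwargs,
) -> PMFProfile:
    """Mean PMF over independently sampled repeats, with per-bin SD error.

    Each repeat is solved separately on a common binning; repeat profiles
    are aligned by their mean over jointly finite bins before averaging
    (the anchor bin of any single repeat is itself noisy). The returned
    profile is re-anchored at zero; ``error`` is the per-bin standard
    deviation across repeats, matching the repeat-based error convention.
    """
    if len(repeats) < 2:
        raise ValueError("at least two repeats are required for an error estimate")
    if bin_range is None:
        pooled = np.concatenate(
            [w.samples for rs in repeats for w in rs.windows]
        )
        bin_range = (float(pooled.min()), float(pooled.max()) * (1 + 1e-12))
    profiles = [
        wham_solve(rs, n_bins=n_bins, bin_range=bin_range, **kwargs)
        for rs in repeats
    ]
    # common grid: all profiles share bin_range/n_bins, but trimming of
    # empty edge bins may differ — re-embed on the full grid
    edges = np.linspace(bin_range[0], bin_range[1], n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    stack = np.full((len(profiles), n_bins), np.nan)
    for r, prof in enumerate(profiles):
        idx = np.searchsorted(mids, prof.bin_centers)
        stack[r, idx] = prof.free_energy
    finite = np.all(np.isfinite(stack), axis=0)
    if not finite.any():
        raise ValueError("repeats share no jointly sampled bins")
    stack -= np.nanmean(stack[:, finite], axis=1, keepdims=True)
    mean = np.nanmean(stack, axis=0)
    sd = np.nanstd(stack, axis=0, ddof=1)
    keep = np.isfinite(mean)
    mean = mean[keep] - np.nanmin(mean[keep])
    return PMFProfile(
        bin_centers=mids[keep],
        free_energy=mean,
        temperature=repeats[0].temperature,
        cv_unit=repeats[0].cv_unit,
        error=sd[keep],
    )


def unbinding_free_energy(
    pmf: PMFProfile, plateau_range: tuple[float, float]
) -> float:
    """Unbinding free energy: mean PMF over the dissociated plateau.

    The PMF is anchored at the bound-state minimum (zero), so the mean
    free energy over ``plateau_range`` is the work to release the ligand.
    The plateau must contain at least three bins and not the global
    minimum.
    """
    lo, hi = plateau_range
    mask = (pmf.bin_centers >= lo) & (pmf.bin_centers <= hi)
    if mask.sum() < 3:
        raise ValueError("plateau must cover at least 3 bins inside the profile")
    if lo <= pmf.min_position <= hi:
        raise ValueError(
            "plateau overlaps the global-minimum (bound-state) bin"
        )
    return float(np.nanmean(pmf.free_energy[mask]))


@dataclass(frozen=True)
class BarrierReport:
    """Forward/reverse barrier heights between two states on a PMF."""

    forward_barrier: float
    reverse_barrier: float
    state_A_range: tuple[float, float]
    state_B_range: tuple[float, float]
    ts_position: float

    def __post_init__(self) -> None:
        if self.forward_barrier < 0 or self.reverse_barrier < 0:
            raise ValueError("barriers must be non-negative")


def barrier_heights(
    pmf: PMFProfile,
    state_A_range: tuple[float, float],
    state_B_range: tuple[float, float],
) -> BarrierReport:
    """Barriers between two disjoint state ranges along the profile.

    forward = F(TS) − min F over state A; reverse = F(TS) − min F over
    state B, where the transition state is the maximum of the PMF strictly
    between the two ranges (ties broken toward the bin nearest the
    midpoint of the gap).
    """
    a_lo, a_hi = sorted(state_A_range)
    b_lo, b_hi = sorted(state_B_range)
    if not (a_hi < b_lo or b_hi < a_lo):
        raise ValueError("state ranges must be disjoint")
    x, F = pmf.bin_centers, pmf.free_energy
    if a_lo < x[0] or b_hi > x[-1] + 1e-12 or b_lo < x[0] or a_hi > x[-1] + 1e-12:
        raise ValueError("state ranges must lie inside the profile")
    mask_a = (x >= a_lo) & (x <= a_hi)
    mask_b = (x >= b_lo) & (x <= b_hi)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("state range contains no bins")
    gap_lo, gap_hi = (a_hi, b_lo) if a_hi < b_lo else (b_hi, a_lo)
    mask_ts = (x > gap_lo) & (x < gap_hi)
    if not mask_ts.any():
        raise ValueError("no interior bins between the state ranges")
    F_ts = np.nanmax(F[mask_ts])
    min_a = np.nanmin(F[mask_a])
    min_b = np.nanmin(F[mask_b])
    if F_ts <= max(min_a, min_b):
        raise ValueError("no interior maximum between the states")
    ts_idx = np.flatnonzero(mask_ts & (F == F_ts))
    mid = 0.5 * (gap_lo + gap_hi)
    ts_pos = float(x[ts_idx[np.argmin(np.abs(x[ts_idx] - mid))]])
    return BarrierReport(
        forward_barrier=float(F_ts - min_a),
        reverse_barrier=float(F_ts - min_b),
        state_A_range=(a_lo, a_hi),
        state_B_range=(b_lo, b_hi),
        ts_position=ts_pos,
    )


def write_pmf_tsv(pmf: PMFProfile, path) -> None:
    df = pd.DataFrame({"bin": pmf.bin_centers, "F": pmf.free_energy})
    df["err"] = pmf.error if pmf.error is not None else np.nan
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_pmf_tsv(path, temperature: float = 298.15, cv_unit: str = "nm") -> PMFProfile:
    df = pd.read_csv(path, sep="\t")
    err = df["err"].to_numpy(dtype=float) if "err" in df else None
    if err is not None and np.all(np.isnan(err)):
        err = None
    F = df["F"].to_numpy(dtype=float)
    return PMFProfile(
        bin_centers=df["bin"].to_numpy(dtype=float),
        free_energy=F - np.nanmin(F),
        temperature=temperature,
        cv_unit=cv_unit,
        error=err,
    )
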