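"""PMF reconstruction by WHAM with blocking errors and hysteresis reports.

The weighted histogram analysis method combines the biased histograms
n_i(b) of all umbrella windows into one unbiased probability profile by
iterating the self-consistent equations

    p(b)  =  sum_i n_i(b)  /  sum_i N_i exp((f_i - U_i(b)) / kT)
    f_i   =  -kT ln sum_b p(b) exp(-U_i(b) / kT)

to convergence of the per-window free-energy constants f_i, then
G(b) = -kT ln p(b) up to an additive constant.

Per-bin statistical errors follow a blocking procedure: each window's
series is split into ``n_blocks`` contiguous equal-duration blocks, WHAM is
solved once per block, the block profiles are aligned at a reference CV
value, and the error is the sample standard deviation across blocks
divided by sqrt(n_blocks).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .umbrella import CvSeries, bias_energy

__all__ = [
    "KB_KCAL_MOL_K",
    "WhamSettings",
    "PmfProfile",
    "DeltaGResult",
    "HysteresisReport",
    "wham_solve",
    "blocking_errors",
    "wham_with_errors",
    "split_blocks",
    "block_profile_errors",
    "align_profiles",
    "extract_delta_g",
    "hysteresis_report",
]

KB_KCAL_MOL_K = 0.0019872041  # Boltzmann constant, kcal/(mol K)


@dataclass(frozen=True)
class WhamSettings:
    bin_width: float = 0.1
    l_range: tuple[float, float] = (12.0, 34.5)
    tolerance: float = 1e-7
    max_iterations: int = 100_000
    temperature: float = 298.0
    full_k: bool = False

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.tolerance <= 0 or self.temperature <= 0:
            raise ValueError("bin_width, tolerance and temperature must be positive")
        if self.l_range[1] <= self.l_range[0]:
            raise ValueError("l_range must be a non-empty interval")

    @property
    def kt(self) -> float:
        return KB_KCAL_MOL_K * self.temperature

    def bin_edges(self) -> np.ndarray:
        lo, hi = self.l_range
        n_bins = max(1, int(round((hi - lo) / self.bin_width)))
        return lo + self.bin_width * np.arange(n_bins + 1)


@dataclass
class PmfProfile:
    """Free-energy curve G(L) on a bin-center grid (kcal/mol).

    Bins with zero counts carry G = +inf and are excluded from searches.
    """

    grid: np.ndarray
    g: np.ndarray
    counts: np.ndarray
    errors: np.ndarray | None = None
    alignment_ref: float | None = None
    probability: np.ndarray | None = None  # normalized p(b) from WHAM

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.counts = np.asarray(self.counts)
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if self.g.shape != self.grid.shape:
            raise ValueError("g and grid must have the same shape")

    def bin_index(self, l_ref: float) -> int:
        """Index of the bin whose center is nearest to ``l_ref``.

        ``l_ref`` must fall inside the grid span (half a bin beyond the
        outermost centers).
        """
        half = 0.5 * float(np.min(np.diff(self.grid)))
        if not (self.grid[0] - half <= l_ref <= self.grid[-1] + half):
            raise ValueError(
                f"L = {l_ref} is outside the profile grid "
                f"[{self.grid[0]}, {self.grid[-1]}]"
            )
        return int(np.argmin(np.abs(self.grid - l_ref)))

    def aligned_at(self, l_ref: float) -> "PmfProfile":
        """Shift G so the bin containing ``l_ref`` is exactly zero."""
        idx = self.bin_index(l_ref)
        if not np.isfinite(self.g[idx]):
            raise ValueError(f"cannot align at L = {l_ref}: bin has no samples")
        return replace(self, g=self.g - self.g[idx], alignment_ref=l_ref)

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.g)


@dataclass(frozen=True)
class DeltaGResult:
    delta_g: float
    error: float
    l_min: float
    l_ref: float
    mode: str
    minimum_at_edge: bool = False


@dataclass(frozen=True)
class HysteresisReport:
    delta_g_forward: float
    delta_g_backward: float
    error_forward: float
    error_backward: float
    max_profile_gap: float
    delta_delta_g_bounds: tuple[float, float]

    def as_dict(self) -> dict:
        return {
            "delta_g_forward_kcal_mol": self.delta_g_forward,
            "delta_g_backward_kcal_mol": self.delta_g_backward,
            "error_forward_kcal_mol": self.error_forward,
            "error_backward_kcal_mol": self.error_backward,
            "max_profile_gap_kcal_mol": self.max_profile_gap,
            "delta_delta_g_bounds_kcal_mol": list(self.delta_delta_g_bounds),
        }


def _check_overlap(hists: np.ndarray, centers: np.ndarray) -> None:
    """Adjacent windows (by center) must share at least one populated bin."""
    order = np.argsort(centers)
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hists[a] > 0) & (hists[b] > 0)):
            raise ValueError(
                "histogram gap between adjacent windows centered at "
                f"{centers[a]:g} and {centers[b]:g} Å: no shared populated bin"
            )


def wham_solve(series: list[CvSeries], settings: WhamSettings | None = None) -> PmfProfile:
    """Self-consistent WHAM solution over all windows.

    Deterministic given the inputs: f_i = 0 initialization, iteration until
    max |Delta f_i| < tolerance.  Raises on non-overlapping adjacent
    histograms or non-convergence.
    """
    settings = settings if settings is not None else WhamSettings()
    if not series:
        raise ValueError("need at least one CV series")
    kt = settings.kt
    edges = settings.bin_edges()
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_win = len(series)

    hists = np.empty((n_win, len(centers)))
    for i, s in enumerate(series):
        hists[i], _ = np.histogram(s.values, bins=edges)
    window_centers = np.array([s.window.center for s in series])
    if n_win > 1:
        _check_overlap(hists, window_centers)
    n_tot = hists.sum(axis=0)
    n_i = hists.sum(axis=1)  # samples landing inside the grid
    if np.any(n_i == 0):
        empty = [series[i].window.index for i in np.flatnonzero(n_i == 0)]
        raise ValueError(f"windows with no samples inside the grid: {empty}")

    # bias energy of every window at every bin center, in kT units
    u_over_kt = np.stack(
        [np.asarray(bias_energy(centers, s.window, settings.full_k)) / kt
         for s in series]
    )
    populated = n_tot > 0
    log_p = _iterate_wham(u_over_kt, n_i, n_tot, populated, settings)

    g = np.full(len(centers), np.inf)
    g[populated] = -kt * log_p[populated]
    g -= g[populated].min()
    prob = np.where(populated, np.exp(log_p), 0.0)
    return PmfProfile(grid=centers, g=g, counts=n_tot.astype(int),
                      probability=prob)


def _iterate_wham(
    u_over_kt: np.ndarray,
    n_i: np.ndarray,
    n_tot: np.ndarray,
    populated: np.ndarray,
    settings: WhamSettings,
) -> np.ndarray:
    """Fixed-point iteration of the WHAM equations; returns normalized log p.

    The hot loop runs in linear space (bias factors exp(-U/kT) underflow
    harmlessly to zero); if the per-window constants overflow double
    precision it falls back to a logsumexp formulation.
    """
    kt = settings.kt
    f_over_kt = np.zeros(len(n_i))
    exp_neg_u = np.exp(-u_over_kt)
    p = np.zeros(len(n_tot))
    linear = True
    log_n_i = np.log(n_i)
    with np.errstate(divide="ignore"):
        log_n_tot = np.log(n_tot)
    for _ in range(settings.max_iterations):
        if linear:
            weights = n_i * np.exp(f_over_kt)
            denom = weights @ exp_neg_u
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(populated, n_tot / denom, 0.0)
            p /= p.sum()
            z = exp_neg_u @ p
            with np.errstate(divide="ignore"):
                f_new = -np.log(z)
            if not np.all(np.isfinite(f_new)) or not np.all(np.isfinite(weights)):
                linear = False
                continue
        else:
            log_denom = logsumexp(
                log_n_i[:, None] + f_over_kt[:, None] - u_over_kt, axis=0
            )
            log_p = log_n_tot - log_denom
            log_p -= logsumexp(log_p[populated])
            f_new = -logsumexp(
                log_p[None, populated] - u_over_kt[:, populated], axis=1
            )
        delta = np.max(np.abs(f_new - f_over_kt)) * kt
        f_over_kt = f_new
        if delta < settings.tolerance:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {settings.max_iterations} iterations "
            f"(residual {delta:.3g} kcal/mol > tolerance {settings.tolerance:g})"
        )
    if linear:
        with np.errstate(divide="ignore"):
            log_p = np.where(populated, np.log(p, where=populated,
                                               out=np.full_like(p, -np.inf)), -np.inf)
    return log_p


def split_blocks(series: CvSeries, n_blocks: int) -> list[CvSeries]:
    """Split a series into contiguous blocks of equal duration."""
    if n_blocks < 2:
        raise ValueError("need at least 2 blocks")
    t0, t1 = series.times[0], series.times[-1]
    edges = t0 + (t1 - t0) * np.arange(n_blocks + 1) / n_blocks
    blocks = []
    for b in range(n_blocks):
        lo, hi = edges[b], edges[b + 1]
        mask = (series.times >= lo if b == 0 else series.times > lo) & (
            series.times <= hi
        )
        if not np.any(mask):
            raise ValueError(
                f"window {series.window.index}: block {b + 1}/{n_blocks} is empty"
            )
        blocks.append(CvSeries(series.window, series.times[mask],
                               series.values[mask]))
    return blocks


def block_profile_errors(block_g: np.ndarray, align_index: int) -> np.ndarray:
    """Errors from per-block profiles: align, then sample std / sqrt(n).

    ``block_g`` has shape (n_blocks, n_bins).  Each row is shifted to zero
    at ``align_index``; the per-bin error is std(ddof=1) across blocks
    divided by sqrt(n_blocks), so for 4 blocks it equals std/2 exactly.
    """
    block_g = np.asarray(block_g, dtype=float)
    if block_g.ndim != 2:
        raise ValueError("block_g must be 2-D (n_blocks, n_bins)")
    if not np.all(np.isfinite(block_g[:, align_index])):
        raise ValueError("alignment bin is unpopulated in some block")
    aligned = block_g - block_g[:, [align_index]]
    aligned[~np.isfinite(aligned)] = np.nan  # bins unpopulated in some block
    n_blocks = block_g.shape[0]
    errors = np.std(aligned, axis=0, ddof=1) / np.sqrt(n_blocks)
    return errors


def blocking_errors(
    series: list[CvSeries],
    settings: WhamSettings | None = None,
    n_blocks: int = 4,
    align_at: float = 12.1,
) -> tuple[np.ndarray, list[PmfProfile]]:
    """Per-bin blocking errors from ``n_blocks`` independent WHAM solutions.

    Block b of every window forms one WHAM input; the resulting profiles
    are aligned at ``align_at`` and the per-bin error is their sample
    standard deviation divided by sqrt(n_blocks).  Returns the error array
    and the aligned block profiles.
    """
    settings = settings if settings is not None else WhamSettings()
    per_window_blocks = [split_blocks(s, n_blocks) for s in series]
    profiles = []
    for b in range(n_blocks):
        profile = wham_solve([blocks[b] for blocks in per_window_blocks], settings)
        profiles.append(profile.aligned_at(align_at))
    align_index = profiles[0].bin_index(align_at)
    block_g = np.stack([p.g for p in profiles])
    errors = block_profile_errors(block_g, align_index)
    return errors, profiles


def wham_with_errors(
    series: list[CvSeries],
    settings: WhamSettings | None = None,
    n_blocks: int = 4,
    align_at: float = 12.1,
) -> PmfProfile:
    """Full-data WHAM profile with blocking errors attached, aligned at
    ``align_at``."""
    profile = wham_solve(series, settings).aligned_at(align_at)
    errors, _ = blocking_errors(series, settings, n_blocks, align_at)
    return replace(profile, errors=errors)


def align_profiles(
    profile_a: PmfProfile, profile_b: PmfProfile, l_ref: float
) -> tuple[PmfProfile, PmfProfile]:
    """Shift both profiles so G = 0 in the bin containing ``l_ref``."""
    return profile_a.aligned_at(l_ref), profile_b.aligned_at(l_ref)


def extract_delta_g(
    profile: PmfProfile, l_ref: float, mode: str = "undocking"
) -> DeltaGResult:
    """Free-energy difference between the PMF minimum and a reference point.

    undocking: Delta G = G(l_ref) - G(l_min); docking: the negative.  The
    minimum is the bin-center of the global minimum over populated bins
    (ties broken toward smaller L); errors from the two bins combine in
    quadrature when the profile carries them.
    """
    if mode not in ("undocking", "docking"):
        raise ValueError("mode must be 'undocking' or 'docking'")
    finite = profile.finite_mask()
    if not np.any(finite):
        raise ValueError("profile has no populated bins")
    g = np.where(finite, profile.g, np.inf)
    i_min = int(np.argmin(g))
    i_ref = profile.bin_index(l_ref)
    if not np.isfinite(profile.g[i_ref]):
        raise ValueError(f"reference bin at L = {l_ref} has no samples")
    finite_idx = np.flatnonzero(finite)
    at_edge = i_min in (finite_idx[0], finite_idx[-1])
    diff = profile.g[i_ref] - profile.g[i_min]
    delta_g = diff if mode == "undocking" else -diff
    if profile.errors is not None:
        e_ref, e_min = profile.errors[i_ref], profile.errors[i_min]
        error = float(np.hypot(e_ref, e_min))
    else:
        error = float("nan")
    return DeltaGResult(
        delta_g=float(delta_g),
        error=error,
        l_min=float(profile.grid[i_min]),
        l_ref=float(profile.grid[i_ref]),
        mode=mode,
        minimum_at_edge=bool(at_edge),
    )


def hysteresis_report(
    forward: PmfProfile, backward: PmfProfile, l_ref: float
) -> HysteresisReport:
    """Forward/backward comparison after alignment at ``l_ref``.

    Reports both undocking Delta G estimates, the maximum absolute gap
    between the aligned profiles over their shared populated bins, and the
    Delta-Delta-G bounds (min, max) formed from the two estimates.
    """
    fwd, bwd = align_profiles(forward, backward, l_ref)
    if fwd.grid.shape != bwd.grid.shape or not np.allclose(fwd.grid, bwd.grid):
        raise ValueError("forward and backward profiles must share a grid")
    dg_f = extract_delta_g(fwd, l_ref, "undocking")
    dg_b = extract_delta_g(bwd, l_ref, "undocking")
    shared = fwd.finite_mask() & bwd.finite_mask()
    gap = float(np.max(np.abs(fwd.g[shared] - bwd.g[shared]))) if np.any(shared) else float("nan")
    bounds = (min(dg_f.delta_g, dg_b.delta_g), max(dg_f.delta_g, dg_b.delta_g))
    return HysteresisReport(
        delta_g_forward=dg_f.delta_g,
        delta_g_backward=dg_b.delta_g,
        error_forward=dg_f.error,
        error_backward=dg_b.error,
        max_profile_gap=gap,
        delta_delta_g_bounds=bounds,
    )


def profile_to_csv(profile: PmfProfile, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "L": profile.grid,
            "G_kcal_mol": profile.g,
            "err_kcal_mol": profile.errors
            if profile.errors is not None
            else np.full_like(profile.grid, np.nan),
            "counts": profile.counts,
        }
    )
    df.to_csv(path, index=False)


def profile_from_csv(path: str | Path) -> PmfProfile:
    df = pd.read_csv(path)
    errors = df["err_kcal_mol"].to_numpy()
    return PmfProfile(
        grid=df["L"].to_numpy(),
        g=df["G_kcal_mol"].to_numpy(),
        counts=df["counts"].to_numpy(),
        errors=None if np.all(np.isnan(errors)) else errors,
    )
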