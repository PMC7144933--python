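"""1-D umbrella-sampling free-energy reconstruction.

Implements the standard self-consistent weighted-histogram estimator with a
harmonic bias ``w_i(x) = k_i (x - c_i)^2`` (no 1/2 factor, the colvars
convention; a flag restores the 1/2 convention), Monte-Carlo bootstrap
errors with statistical-inefficiency-aware resampling, and cumulative-block
convergence diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

from .errors import (
    BootstrapInstabilityError,
    ConvergenceError,
    CoverageError,
    ParameterError,
)

logger = logging.getLogger("chromkit.wham")

KB_KCAL = 0.0019872041  # kcal / (mol K)


@dataclass
class UmbrellaWindow:
    center: float  # degrees
    force_constant: float  # kcal/mol/deg^2
    samples: np.ndarray  # time-ordered reaction-coordinate values, degrees
    equilibration_cut: int = 0
    g: float | None = None  # statistical inefficiency, filled by analysis

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, float)
        if self.force_constant <= 0:
            raise ParameterError("force_constant must be > 0")
        if self.equilibration_cut < 0:
            raise ParameterError("equilibration_cut must be >= 0")

    @property
    def production(self) -> np.ndarray:
        return self.samples[self.equilibration_cut:]

    def validate(self) -> None:
        if self.production.size < 10:
            raise ParameterError(
                f"window at {self.center}: only {self.production.size} "
                "post-cut samples (need >= 10)"
            )
        if self.g is not None and self.g < 1:
            raise ParameterError("statistical inefficiency must be >= 1")


@dataclass
class WhamConfig:
    n_bins: int = 100
    tolerance: float = 1e-6  # kcal/mol on window free-energy offsets
    max_iterations: int = 100000
    temperature: float = 300.0
    bootstrap_trials: int = 100
    half_factor_bias: bool = False  # True -> w = (k/2)(x-c)^2
    bin_range: tuple[float, float] | None = None  # default: min-max sampled
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ParameterError("tolerance must be > 0")
        if self.bootstrap_trials < 1:
            raise ParameterError("bootstrap_trials must be >= 1")
        if self.n_bins < 2:
            raise ParameterError("n_bins must be >= 2")

    @property
    def kt(self) -> float:
        return KB_KCAL * self.temperature


@dataclass
class PmfProfile:
    bin_centers: np.ndarray
    free_energy: np.ndarray  # kcal/mol, shifted to min 0
    stderr: np.ndarray  # kcal/mol
    temperature: float
    reference_policy: str = "min-zero"
    window_offsets: np.ndarray | None = field(default=None, repr=False)

    def value_at(self, x: float) -> float:
        """Free energy at the bin whose center is closest to x."""
        finite = np.isfinite(self.free_energy)
        centers = self.bin_centers[finite]
        return float(self.free_energy[finite][np.argmin(np.abs(centers - x))])


# ---------------------------------------------------------------------------
# Statistical inefficiency
# ---------------------------------------------------------------------------

def statistical_inefficiency(samples: np.ndarray, min_samples: int = 50) -> float:
    """g = 1 + 2 Σ C(t), summing the normalized autocorrelation until it
    first becomes non-positive; the effective sample size is N/g."""
    x = np.asarray(samples, float)
    n = x.size
    if n < min_samples:
        raise ParameterError(f"need >= {min_samples} samples, got {n}")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var <= 0:
        logger.warning("zero-variance series: statistical inefficiency set to 1")
        return 1.0
    # FFT autocovariance
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(fx * np.conj(fx), nfft)[:n].real / n
    c = acov / acov[0]
    g = 1.0
    for t in range(1, n):
        if c[t] <= 0:
            break
        g += 2.0 * c[t]
    return max(g, 1.0)


# ---------------------------------------------------------------------------
# Core solver
# ---------------------------------------------------------------------------

def _bias_matrix(
    centers: np.ndarray, ks: np.ndarray, x: np.ndarray, half: bool
) -> np.ndarray:
    w = ks[:, None] * (x[None, :] - centers[:, None]) ** 2
    return 0.5 * w if half else w


def _solve_core(
    counts: np.ndarray,  # (n_windows, n_bins) histogram counts
    n_i: np.ndarray,  # (n_windows,) sample counts
    w_over_kt: np.ndarray,  # (n_windows, n_bins) bias / kT
    kt: float,
    tolerance: float,
    max_iterations: int,
    f_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate WHAM equations; returns (log p per bin, f_i per window)."""
    n_tot = counts.sum(axis=0)
    occupied = n_tot > 0
    log_ntot = np.full(n_tot.shape, -np.inf)
    log_ntot[occupied] = np.log(n_tot[occupied])
    with np.errstate(divide="ignore"):
        log_ni = np.log(n_i)
    f = np.zeros(n_i.size) if f_init is None else f_init.copy()
    residual = np.inf
    for _ in range(max_iterations):
        # log denominator per bin: logsumexp_i [ ln N_i + (f_i - w_i(b))/kT ]
        log_denom = logsumexp(log_ni[:, None] + f[:, None] / kt - w_over_kt, axis=0)
        log_p = log_ntot - log_denom
        log_p -= logsumexp(log_p[occupied])
        f_new = -kt * logsumexp(log_p[None, occupied] - w_over_kt[:, occupied], axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < tolerance:
            return log_p, f
    raise ConvergenceError(
        f"WHAM did not converge in {max_iterations} iterations "
        f"(last residual {residual:.3e} kcal/mol)",
        residual=residual,
    )


def _prepare(
    windows: list[UmbrellaWindow], config: WhamConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    all_samples = [w.production for w in windows]
    if config.bin_range is not None:
        lo, hi = config.bin_range
    else:
        lo = min(s.min() for s in all_samples)
        hi = max(s.max() for s in all_samples)
    edges = np.linspace(lo, hi, config.n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts = np.stack([np.histogram(s, bins=edges)[0] for s in all_samples]).astype(float)
    w_centers = np.array([w.center for w in windows])
    ks = np.array([w.force_constant for w in windows])
    w_over_kt = _bias_matrix(w_centers, ks, centers, config.half_factor_bias) / config.kt
    # N_i counts only in-range samples, matching the histogram mass
    return edges, centers, counts, w_over_kt, counts.sum(axis=1)


def _check_coverage(windows: list[UmbrellaWindow], counts: np.ndarray) -> None:
    """Adjacent windows (by center) must share at least one occupied bin."""
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((counts[a] > 0) & (counts[b] > 0)):
            raise CoverageError(
                f"windows at {windows[a].center}° and {windows[b].center}° share "
                "no occupied bin: coverage gap"
            )


def wham_solve(windows: list[UmbrellaWindow], config: WhamConfig) -> PmfProfile:
    """Reconstruct the PMF; free energy shifted so its minimum is 0.

    ``stderr`` is zero-filled; use :func:`bootstrap_pmf` to fill it.
    """
    if not windows:
        raise ParameterError("no umbrella windows supplied")
    for w in windows:
        w.validate()
    edges, centers, counts, w_over_kt, n_i = _prepare(windows, config)
    if len(windows) > 1:
        _check_coverage(windows, counts)
    log_p, f = _solve_core(
        counts, n_i, w_over_kt, config.kt, config.tolerance, config.max_iterations
    )
    free = np.where(np.isneginf(log_p), np.inf, -config.kt * log_p)
    free -= free[np.isfinite(free)].min()
    free = np.where(np.isinf(free), np.nan, free)
    return PmfProfile(
        bin_centers=centers,
        free_energy=free,
        stderr=np.zeros_like(centers),
        temperature=config.temperature,
        window_offsets=f,
    )


# ---------------------------------------------------------------------------
# Bootstrap errors
# ---------------------------------------------------------------------------

def bootstrap_pmf(
    windows: list[UmbrellaWindow],
    config: WhamConfig,
    rng: np.random.Generator | None = None,
) -> PmfProfile:
    """Monte-Carlo bootstrap: each trial resamples ceil(N_i/g_i) points per
    window with replacement, re-solves, and the per-bin standard deviation
    across min-aligned trials is the stderr."""
    for w in windows:
        w.validate()
        if w.g is None:
            w.g = statistical_inefficiency(w.production)
    base = wham_solve(windows, config)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    edges = np.concatenate(
        [base.bin_centers - 0.5 * np.diff(base.bin_centers)[0],
         base.bin_centers[-1:] + 0.5 * np.diff(base.bin_centers)[0]]
    )
    w_centers = np.array([w.center for w in windows])
    ks = np.array([w.force_constant for w in windows])
    w_over_kt = (
        _bias_matrix(w_centers, ks, base.bin_centers, config.half_factor_bias)
        / config.kt
    )
    trials: list[np.ndarray] = []
    failures = 0
    for _ in range(config.bootstrap_trials):
        counts = []
        n_i = []
        for w in windows:
            prod = w.production
            m = int(np.ceil(prod.size / w.g))
            resampled = prod[rng.integers(0, prod.size, size=m)]
            hist = np.histogram(resampled, bins=edges)[0]
            counts.append(hist)
            n_i.append(hist.sum())
        try:
            log_p, _ = _solve_core(
                np.stack(counts).astype(float),
                np.array(n_i, float),
                w_over_kt,
                config.kt,
                config.tolerance,
                config.max_iterations,
                f_init=base.window_offsets,
            )
        except (ConvergenceError, CoverageError):
            failures += 1
            continue
        free = np.where(np.isneginf(log_p), np.nan, -config.kt * log_p)
        if not np.any(np.isfinite(free)):
            failures += 1
            continue
        free = free - np.nanmin(free)
        trials.append(free)
    if failures > 0.2 * config.bootstrap_trials:
        raise BootstrapInstabilityError(
            f"{failures}/{config.bootstrap_trials} bootstrap trials failed"
        )
    stacked = np.stack(trials)
    stderr = (
        np.nanstd(stacked, axis=0, ddof=1)
        if len(trials) > 1
        else np.zeros_like(base.bin_centers)
    )
    stderr = np.nan_to_num(stderr, nan=0.0)
    return replace(base, stderr=stderr)


# ---------------------------------------------------------------------------
# Convergence
# ---------------------------------------------------------------------------

def pmf_convergence(
    windows: list[UmbrellaWindow],
    config: WhamConfig,
    n_blocks: int = 4,
) -> tuple[list[PmfProfile], float]:
    """Re-solve on cumulative time blocks (first 1/n, 2/n, ... of each
    window); returns the profiles and the max pairwise deviation between the
    final two blocks (on bins finite in both)."""
    if n_blocks < 2:
        raise ParameterError("n_blocks must be >= 2")
    # Share one grid across blocks so profiles are comparable.
    shared = config
    if config.bin_range is None:
        lo = min(w.production.min() for w in windows)
        hi = max(w.production.max() for w in windows)
        shared = replace(config, bin_range=(lo, hi))
    profiles = []
    for b in range(1, n_blocks + 1):
        block_windows = []
        for w in windows:
            prod = w.production
            n = max(int(round(prod.size * b / n_blocks)), 10)
            block_windows.append(
                UmbrellaWindow(w.center, w.force_constant, prod[:n], 0, w.g)
            )
        profiles.append(wham_solve(block_windows, shared))
    last, prev = profiles[-1].free_energy, profiles[-2].free_energy
    both = np.isfinite(last) & np.isfinite(prev)
    deviation = float(np.max(np.abs(last[both] - prev[both]))) if both.any() else np.nan
    return profiles, deviation


# ---------------------------------------------------------------------------
# Grossfield-style file I/O
# ---------------------------------------------------------------------------

def read_window_timeseries(path: str, equilibration_cut: int = 0) -> np.ndarray:
    """Two-column (time, value) whitespace/CSV time series."""
    data = np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",")
    values = data[:, 1] if data.ndim == 2 else data
    return values[equilibration_cut:]


def _is_whitespace(path: str) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return "," not in first


def read_window_meta(meta_path: str, equilibration_cut: int = 0) -> list[UmbrellaWindow]:
    """Metadata CSV with columns path, center, force_constant; paths relative
    to the metadata file's directory."""
    import os

    import pandas as pd

    df = pd.read_csv(meta_path)
    for col in ("path", "center", "force_constant"):
        if col not in df.columns:
            raise ParameterError(f"window metadata missing column {col!r}")
    base = os.path.dirname(os.path.abspath(meta_path))
    windows = []
    for _, row in df.iterrows():
        p = row["path"]
        if not os.path.isabs(p):
            p = os.path.join(base, p)
        samples = read_window_timeseries(p)
        windows.append(
            UmbrellaWindow(
                float(row["center"]),
                float(row["force_constant"]),
                samples,
                equilibration_cut,
            )
        )
    return windows
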