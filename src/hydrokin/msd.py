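"""Mean-squared displacement analysis and self-diffusion estimation.

The ensemble MSD of N tracked particles at lag t is

    MSD(t) = (1/N) * sum_n |x_n(t0 + t) - x_n(t0)|^2 ,

averaged by default over all valid time origins t0 (multiple-origin
averaging; a single-origin mode reproduces the literal definition with
t0 = 0).  The directed-motion model

    MSD(t) = 4 D t + (V t)^2

is fitted over a lag window to extract the self-diffusion coefficient D
and drift speed V.  The 4Dt form is a 2-D convention kept as the default
for fidelity with common single-particle-tracking practice; the
dimensionally explicit form 2 * n_dim * D * t is available and is what
the physically grounded recovery analyses use (6Dt in 3-D).

Internally coordinates are Angstrom and times picoseconds; D is converted
to m^2/s exactly once (1 A^2/ps = 1e-8 m^2/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .constants import A2_PER_PS_TO_M2_PER_S
from .errors import (
    ConfigurationError,
    DomainError,
    InsufficientDataError,
)

__all__ = [
    "Trajectory",
    "MSDCurve",
    "DiffusionEstimate",
    "unwrap_pbc",
    "wrap_pbc",
    "compute_msd",
    "fit_msd",
    "estimate_diffusion",
    "diffusion_vs_temperature",
]


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled multi-particle trajectory.

    positions has shape (n_frames, n_particles, 3) in Angstrom; times are
    picoseconds with uniform spacing (relative tolerance 1e-6).  box, when
    present, holds orthorhombic edge lengths; ``wrapped`` records whether
    coordinates are folded into the box.
    """

    times: np.ndarray
    positions: np.ndarray
    box: np.ndarray | None = None
    particle_ids: tuple[str, ...] = ()
    wrapped: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 3 or pos.shape[2] != 3:
            raise DomainError("positions must have shape (frames, particles, 3)")
        if t.ndim != 1 or t.size != pos.shape[0]:
            raise DomainError("times length must equal the number of frames")
        if t.size >= 2:
            dts = np.diff(t)
            if np.any(dts <= 0):
                raise DomainError("frame times must be strictly increasing")
            if (dts.max() - dts.min()) > 1e-6 * dts.mean():
                raise DomainError("frame times must be uniformly spaced")
        box = self.box
        if box is not None:
            box = np.asarray(box, dtype=float)
            if box.shape != (3,) or np.any(box <= 0):
                raise DomainError("box must be 3 positive edge lengths")
        ids = tuple(self.particle_ids) if self.particle_ids else tuple(
            f"p{i}" for i in range(pos.shape[1])
        )
        if len(ids) != pos.shape[1]:
            raise DomainError("particle_ids length must equal particle count")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "box", box)
        object.__setattr__(self, "particle_ids", ids)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise InsufficientDataError("dt undefined for a single-frame trajectory")
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def indices_of(self, selection: Iterable[str] | None) -> np.ndarray:
        """Map particle ids to column indices (all particles when None)."""
        if selection is None:
            return np.arange(self.n_particles)
        wanted = set(selection)
        if not wanted:
            raise DomainError("empty particle selection")
        idx = [i for i, pid in enumerate(self.particle_ids) if pid in wanted]
        missing = wanted - {self.particle_ids[i] for i in idx}
        if missing:
            raise DomainError(f"unknown particle ids: {sorted(missing)}")
        return np.asarray(idx)


@dataclass(frozen=True)
class MSDCurve:
    """Lag-time resolved ensemble MSD with per-lag sample counts."""

    lags: np.ndarray  # ps, strictly increasing, lags[0] == 0
    msd: np.ndarray  # A^2
    n_samples: np.ndarray  # (origin, particle) pairs averaged per lag

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        msd = np.asarray(self.msd, dtype=float)
        ns = np.asarray(self.n_samples)
        # FFT round-off leaves |residuals| ~1e-14 A^2; snap to exact zero
        # far below coordinate precision (files carry 1e-3 A)
        msd = np.where(np.abs(msd) < 1e-9, 0.0, msd)
        if np.any(msd < 0):
            raise DomainError("MSD must be non-negative")
        if lags[0] != 0 or msd[0] != 0:
            raise DomainError("MSD at lag 0 must be exactly 0")
        if np.any(np.diff(lags) <= 0):
            raise DomainError("lags must be strictly increasing")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "msd", msd)
        object.__setattr__(self, "n_samples", ns)


@dataclass(frozen=True)
class DiffusionEstimate:
    """Self-diffusion coefficient from an MSD fit.

    D and stderr_D are m^2/s; V is A/ps.  ``clamped`` flags a negative
    least-squares solution that was clamped to zero.
    """

    D: float
    V: float
    fit_window: tuple[float, float]
    stderr_D: float
    msd_model: str  # "paper_4Dt" | "dim_2nDt"
    n_dim: int = 3
    clamped: bool = False

    @property
    def D_A2_per_ps(self) -> float:
        return self.D / A2_PER_PS_TO_M2_PER_S


def unwrap_pbc(traj: Trajectory) -> Trajectory:
    """Reconstruct continuous paths from box-wrapped coordinates.

    Applies the minimum-image convention to every consecutive-frame
    displacement: each component of the corrected step lies in
    (-L/2, +L/2].  The first frame is unchanged.
    """
    if not traj.wrapped:
        return traj
    if traj.box is None:
        raise ConfigurationError("cannot unwrap without box dimensions")
    pos = traj.positions
    steps = np.diff(pos, axis=0)
    steps -= traj.box * np.round(steps / traj.box)
    unwrapped = np.concatenate(
        [pos[:1], pos[:1] + np.cumsum(steps, axis=0)], axis=0
    )
    return Trajectory(traj.times, unwrapped, traj.box, traj.particle_ids, wrapped=False)


def wrap_pbc(traj: Trajectory) -> Trajectory:
    """Fold coordinates into [0, L) per axis (inverse of unwrapping)."""
    if traj.box is None:
        raise ConfigurationError("cannot wrap without box dimensions")
    pos = np.mod(traj.positions, traj.box)
    return Trajectory(traj.times, pos, traj.box, traj.particle_ids, wrapped=True)


def _autocorr_fft(x: np.ndarray) -> np.ndarray:
    """Column-wise autocorrelation sum_t x[t] x[t+m] via zero-padded FFT."""
    n = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft(f * f.conj(), n=nfft, axis=0)[:n]
    return acf


def _msd_fft_per_particle(pos: np.ndarray, n_lags: int) -> np.ndarray:
    """Multiple-origin MSD per particle, exact, O(F log F) per column.

    Uses the standard decomposition MSD(m) = S1(m) - 2*S2(m) where S2 is
    the positional autocorrelation (computed by FFT) and S1 follows from
    prefix sums of |x|^2.  pos has shape (F, N, 3); returns
    (n_lags+1, N), one multiple-origin curve per particle.
    """
    F, N, _ = pos.shape
    flat = pos.reshape(F, N * 3)
    sq = flat * flat
    total = sq.sum(axis=0)
    # prefix sums of squared coordinates from both ends
    head = np.vstack([np.zeros((1, flat.shape[1])), np.cumsum(sq, axis=0)])
    tail = np.vstack([np.zeros((1, flat.shape[1])), np.cumsum(sq[::-1], axis=0)])
    s2 = _autocorr_fft(flat)
    m = np.arange(n_lags + 1)
    counts = (F - m).astype(float)
    s1 = (2.0 * total - head[m] - tail[m]) / counts[:, None]
    msd_cols = s1 - 2.0 * s2[m] / counts[:, None]
    return msd_cols.reshape(n_lags + 1, N, 3).sum(axis=2)


def _msd_fft(pos: np.ndarray, n_lags: int) -> np.ndarray:
    return _msd_fft_per_particle(pos, n_lags).mean(axis=1)


def _msd_residence(
    pos: np.ndarray, mask: np.ndarray, n_lags: int, min_run: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Multiple-origin MSD restricted to contiguous residence intervals.

    Origin and endpoint must fall inside the same True-run of ``mask``
    (frames x particles); runs shorter than ``min_run`` frames are
    discarded.
    """
    F, N, _ = pos.shape
    sums = np.zeros(n_lags + 1)
    counts = np.zeros(n_lags + 1, dtype=np.int64)
    for j in range(N):
        col = mask[:, j]
        # run boundaries of the residence mask
        edges = np.flatnonzero(np.diff(np.concatenate([[0], col.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            L = stop - start
            if L < min_run:
                continue
            seg = pos[start:stop, j]
            counts[0] += L
            for lag in range(1, min(L - 1, n_lags) + 1):
                d = seg[lag:] - seg[:-lag]
                sums[lag] += np.einsum("ij,ij->", d, d)
                counts[lag] += L - lag
    with np.errstate(invalid="ignore"):
        msd = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    msd[0] = 0.0
    return msd, counts


def compute_msd(
    traj: Trajectory,
    selection: Iterable[str] | None = None,
    max_lag: float | None = None,
    *,
    single_origin: bool = False,
    residence_mask: np.ndarray | None = None,
    min_residence_frames: int = 3,
) -> MSDCurve:
    """Ensemble MSD over all particles in ``selection`` and all time origins.

    max_lag (ps) defaults to half the trajectory duration.  With
    ``single_origin`` only t0 = 0 contributes (the literal textbook
    definition).  ``residence_mask`` (frames x particles, boolean)
    restricts origin/endpoint pairs to the same contiguous True-interval,
    as appropriate for channel-resident waters.
    """
    if traj.wrapped:
        raise ConfigurationError("unwrap the trajectory before computing MSD")
    if traj.n_frames < 2:
        raise InsufficientDataError("need at least 2 frames")
    idx = traj.indices_of(selection)
    dt = traj.dt
    if max_lag is None:
        max_lag = traj.duration / 2.0
    if max_lag > traj.duration:
        raise DomainError(
            f"max_lag {max_lag} ps exceeds trajectory duration {traj.duration} ps"
        )
    n_lags = int(np.floor(max_lag / dt + 1e-9))
    if n_lags < 1:
        raise DomainError("max_lag must cover at least one frame interval")
    pos = traj.positions[:, idx, :]
    lags = np.arange(n_lags + 1) * dt
    if residence_mask is not None:
        mask = np.asarray(residence_mask, dtype=bool)[:, idx]
        msd, counts = _msd_residence(pos, mask, n_lags, min_residence_frames)
        return MSDCurve(lags, msd, counts)
    F, N = pos.shape[:2]
    if single_origin:
        d = pos[: n_lags + 1] - pos[:1]
        msd = np.einsum("fnd,fnd->f", d, d) / N
        counts = np.full(n_lags + 1, N, dtype=np.int64)
    else:
        msd = _msd_fft(pos, n_lags)
        counts = (F - np.arange(n_lags + 1)).astype(np.int64) * N
    msd = msd.copy()
    msd[0] = 0.0
    return MSDCurve(lags, msd, counts)


def _model_slope_factor(model: str, n_dim: int) -> float:
    if model == "paper_4Dt":
        return 4.0
    if model == "dim_2nDt":
        return 2.0 * n_dim
    raise ConfigurationError(f"unknown MSD model {model!r}")


def fit_msd(
    curve: MSDCurve,
    model: str = "paper_4Dt",
    window: tuple[float, float] | None = None,
    *,
    n_dim: int = 3,
    constrain_v: bool = False,
) -> DiffusionEstimate:
    """Least squares of MSD(t) = (slope factor) D t + (V t)^2 over a lag window.

    The default window spans 10-50% of the largest lag, excluding the
    short-time ballistic regime.  Negative solutions are clamped: a
    negative quadratic coefficient refits with V = 0; a negative D is
    reported as 0 with ``clamped`` set.  The standard error is the naive
    OLS value (lag points are treated as independent); for honest
    replicate-level uncertainty use :func:`estimate_diffusion`.
    """
    factor = _model_slope_factor(model, n_dim)
    lag_max = float(curve.lags[-1])
    if window is None:
        window = (0.1 * lag_max, 0.5 * lag_max)
    lo, hi = window
    if not (curve.lags[0] <= lo <= hi <= lag_max):
        raise DomainError(f"fit window {window} outside lag range (0, {lag_max})")
    sel = (curve.lags >= lo) & (curve.lags <= hi) & (curve.lags > 0)
    sel &= np.isfinite(curve.msd)
    t = curve.lags[sel]
    y = curve.msd[sel]
    if t.size < 3:
        raise InsufficientDataError("fit window must contain at least 3 lags")

    def solve(basis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        coef, _, _, _ = np.linalg.lstsq(basis, y, rcond=None)
        resid = y - basis @ coef
        dof = max(t.size - basis.shape[1], 1)
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.inv(basis.T @ basis)
        return coef, cov

    if constrain_v:
        coef, cov = solve(t[:, None])
        slope, quad = float(coef[0]), 0.0
        slope_var = float(cov[0, 0])
    else:
        coef, cov = solve(np.column_stack([t, t * t]))
        slope, quad = float(coef[0]), float(coef[1])
        slope_var = float(cov[0, 0])
        if quad < 0:  # drift term cannot be negative; refit pure diffusion
            coef, cov = solve(t[:, None])
            slope, quad = float(coef[0]), 0.0
            slope_var = float(cov[0, 0])
    clamped = slope < 0
    D_a2ps = max(slope, 0.0) / factor
    V = float(np.sqrt(max(quad, 0.0)))
    return DiffusionEstimate(
        D=D_a2ps * A2_PER_PS_TO_M2_PER_S,
        V=V,
        fit_window=(float(lo), float(hi)),
        stderr_D=np.sqrt(max(slope_var, 0.0)) / factor * A2_PER_PS_TO_M2_PER_S,
        msd_model=model,
        n_dim=n_dim,
        clamped=clamped,
    )


def estimate_diffusion(
    traj: Trajectory,
    selection: Iterable[str] | None = None,
    *,
    model: str = "dim_2nDt",
    n_dim: int = 3,
    max_lag: float | None = None,
    window: tuple[float, float] | None = None,
    n_blocks: int = 10,
    constrain_v: bool = True,
) -> DiffusionEstimate:
    """Diffusion coefficient with a particle-block standard error.

    The point estimate comes from the full-ensemble MSD fit; the standard
    error is the spread of per-block estimates (particles split into
    ``n_blocks`` groups, which are statistically independent for
    non-interacting tracers) divided by sqrt(n_blocks).  This avoids the
    optimistic OLS error that ignores correlation between MSD lags.
    """
    if traj.wrapped:
        raise ConfigurationError("unwrap the trajectory before computing MSD")
    idx = traj.indices_of(selection)
    dt = traj.dt
    if max_lag is None:
        max_lag = traj.duration / 2.0
    n_lags = int(np.floor(max_lag / dt + 1e-9))
    per_particle = _msd_fft_per_particle(traj.positions[:, idx, :], n_lags)
    lags = np.arange(n_lags + 1) * dt
    n_samp = (traj.n_frames - np.arange(n_lags + 1)).astype(np.int64)

    def curve_of(cols: np.ndarray) -> MSDCurve:
        msd = cols.mean(axis=1)
        msd[0] = 0.0
        return MSDCurve(lags, msd, n_samp * cols.shape[1])

    est = fit_msd(
        curve_of(per_particle), model, window, n_dim=n_dim, constrain_v=constrain_v
    )
    n_blocks = min(n_blocks, idx.size)
    if n_blocks >= 2:
        block_D = [
            fit_msd(curve_of(chunk), model, window, n_dim=n_dim,
                    constrain_v=constrain_v).D
            for chunk in np.array_split(per_particle, n_blocks, axis=1)
        ]
        stderr = float(np.std(block_D, ddof=1) / np.sqrt(n_blocks))
    else:
        stderr = est.stderr_D
    return DiffusionEstimate(
        D=est.D, V=est.V, fit_window=est.fit_window, stderr_D=stderr,
        msd_model=est.msd_model, n_dim=est.n_dim, clamped=est.clamped,
    )


def diffusion_vs_temperature(
    runs: Sequence[tuple[float, Trajectory, Iterable[str] | None]],
    *,
    model: str = "dim_2nDt",
    n_dim: int = 3,
    max_lag: float | None = None,
    window: tuple[float, float] | None = None,
    constrain_v: bool = True,
    label: str = "",
):
    """Assemble D(T) from per-temperature trajectories.

    Each run is (temperature K, unwrapped Trajectory, selection).  Returns
    (RateSeries with value_kind='diffusion', list of DiffusionEstimate in
    ascending-temperature order).  Duplicate temperatures are rejected.
    """
    from .kinetics import RateSeries

    if len(runs) < 2:
        raise InsufficientDataError("need runs at >= 2 distinct temperatures")
    temps = [float(T) for T, _, _ in runs]
    if len(set(temps)) != len(temps):
        raise DomainError("duplicate temperatures: one run per temperature")
    order = np.argsort(temps)
    ests, Ts = [], []
    for i in order:
        T, traj, sel = runs[i]
        curve = compute_msd(traj, sel, max_lag)
        ests.append(fit_msd(curve, model, window, n_dim=n_dim, constrain_v=constrain_v))
        Ts.append(float(T))
    series = RateSeries(
        temperatures=np.asarray(Ts),
        values=np.asarray([e.D for e in ests]),
        value_kind="diffusion",
        label=label,
    )
    return series, ests
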