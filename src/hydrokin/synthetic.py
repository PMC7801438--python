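"""Ground-truth generators: Brownian bulk water, channel-confined hopping
tracers, deformed-Arrhenius rate series, and channel-geometry fixtures.

These stand in for molecular-dynamics output so every analysis stage can
be exercised against known truth.  The bulk generator draws independent
Gaussian steps with variance 2*D(T)*dt per axis inside a periodic box.
The channel generator implements barrier-limited site hopping: axial
jumps of one site spacing with per-step probability k0*exp(-Eb/RT)*dt in
each direction, plus bounded radial jitter.  Its ``occupancy_decay``
parameter releases a temperature-growing fraction of tracers to free
bulk-like diffusion: the trapped population thins faster with T than its
own mobility grows, which is what bends ln D(T) vs 1/RT into the
super-Arrhenius (C < 0) shape.  All generators are bit-reproducible
under a fixed seed and share no global random state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .constants import KYTE_DOOLITTLE, R_GAS
from .errors import DomainError, TimestepTooLargeError
from .msd import Trajectory
from .channels import ChannelPath

__all__ = [
    "DiffusionLaw",
    "BulkSimParams",
    "ChannelSimParams",
    "FixtureWaters",
    "simulate_bulk_brownian",
    "simulate_channel_hopping",
    "generate_rate_series",
    "make_channel_fixture",
    "release_fraction",
]

#: Reference temperature window for the occupancy-release ramp (K).
RELEASE_T0 = 260.0
RELEASE_SPAN = 80.0


@dataclass(frozen=True)
class DiffusionLaw:
    """D(T) = exp(ln_pre + B/(RT) + C/(RT)^2) in A^2/ps."""

    ln_pre: float
    B: float
    C: float = 0.0

    def at(self, T: float) -> float:
        x = 1.0 / (R_GAS * T)
        return math.exp(self.ln_pre + self.B * x + self.C * x * x)


@dataclass(frozen=True)
class BulkSimParams:
    """Bulk Brownian tracer ensemble in a periodic box."""

    n_particles: int = 500
    n_frames: int = 2000
    dt: float = 1.0  # ps
    box: float = 50.0  # A, cubic edge
    D_target: float | DiffusionLaw = 0.2  # A^2/ps or a D(T) law
    temperature: float = 300.0  # K
    seed: int = 0


@dataclass(frozen=True)
class ChannelSimParams:
    """Barrier-limited hopping tracers along a channel axis.

    Defaults give channel-water-like mobility: site spacing 3 A (one
    water diameter), barrier 25 kJ/mol, and an effective prefactor such
    that the hop probability stays within the Bernoulli validity bound
    over 260-340 K at dt = 1 ps.  Effective axial diffusion is
    a^2 * k_hop / 2 with k_hop = k0 exp(-Eb/RT), i.e. ~1e-9 m^2/s near
    300 K.  ``free_diffusion`` is the bulk-like coefficient of released
    tracers (only used when occupancy_decay > 0).
    """

    channel_axis_length: float = 90.0  # A
    site_spacing: float = 3.0  # A
    barrier_height: float = 25_000.0  # J/mol
    attempt_rate: float = 500.0  # ps^-1 (effective prefactor)
    radial_sigma: float = 0.3  # A (tight single-file radial confinement)
    occupancy_decay: float = 0.0  # dimensionless release amplitude
    temperature: float = 300.0  # K
    n_particles: int = 200
    n_frames: int = 1500
    dt: float = 1.0  # ps
    seed: int = 0
    free_diffusion: float = 0.5  # A^2/ps for released tracers


@dataclass(frozen=True)
class FixtureWaters:
    """Water positions with exactly known centerline distances and labels."""

    coords: np.ndarray  # (n, 3) A
    distances: np.ndarray  # (n,) true min distance to the centerline
    inside: np.ndarray  # (n,) bool at ``cutoff``
    cutoff: float


def _resolve_D(spec: float | DiffusionLaw, T: float) -> float:
    D = spec.at(T) if isinstance(spec, DiffusionLaw) else float(spec)
    if D < 0:
        raise DomainError(f"diffusion coefficient {D} < 0 at T = {T} K")
    return D


def release_fraction(occupancy_decay: float, T: float) -> float:
    """Fraction of tracers released to bulk-like diffusion at temperature T.

    A quadratic ramp over the 260-340 K study window,
    f(T) = clip(occupancy_decay * ((T - 260)/80)^2, 0, 1): negligible at
    the cold end, of order occupancy_decay at the hot end.  The physical
    mechanism (constrained population thinning with T) fixes only the
    monotonicity; the ramp shape is a package modeling choice.
    """
    if occupancy_decay == 0:
        return 0.0
    u = max(0.0, (T - RELEASE_T0) / RELEASE_SPAN)
    return float(np.clip(occupancy_decay * u * u, 0.0, 1.0))


def simulate_bulk_brownian(params: BulkSimParams) -> Trajectory:
    """Free 3-D Brownian motion in a periodic cubic box, wrapped output."""
    if params.n_particles < 1 or params.n_frames < 1 or params.dt <= 0:
        raise DomainError("counts must be >= 1 and dt > 0")
    D = _resolve_D(params.D_target, params.temperature)
    rng = np.random.default_rng(params.seed)
    box = np.full(3, float(params.box))
    start = rng.uniform(0.0, box, size=(1, params.n_particles, 3))
    sigma = math.sqrt(2.0 * D * params.dt)
    if params.n_frames > 1:
        steps = rng.normal(
            0.0, sigma, size=(params.n_frames - 1, params.n_particles, 3)
        ) if sigma > 0 else np.zeros((params.n_frames - 1, params.n_particles, 3))
        pos = np.concatenate([start, start + np.cumsum(steps, axis=0)], axis=0)
    else:
        pos = start
    times = np.arange(params.n_frames) * params.dt
    return Trajectory(times, np.mod(pos, box), box=box, wrapped=True)


def simulate_channel_hopping(params: ChannelSimParams) -> Trajectory:
    """Site-hopping tracers along z with radial jitter; unwrapped output.

    Per step the total hop probability is p = k0 exp(-Eb/RT) dt, split
    evenly between +a and -a (axial diffusion exactly a^2 k_hop / 2);
    p > 0.5 means the Bernoulli rate model is invalid and an error is
    raised rather than silently saturating.  With
    occupancy_decay > 0, a temperature-growing fraction of tracers
    (chosen per particle at t = 0) instead performs free 3-D Brownian
    motion at ``free_diffusion``.
    """
    if params.site_spacing <= 0 or params.attempt_rate <= 0:
        raise DomainError("site_spacing and attempt_rate must be positive")
    if params.barrier_height < 0:
        raise DomainError("barrier_height must be >= 0")
    T, dt = params.temperature, params.dt
    p = params.attempt_rate * math.exp(-params.barrier_height / (R_GAS * T)) * dt
    if p > 0.5:
        raise TimestepTooLargeError(
            f"hop probability {p:.3f} > 0.5 at T = {T} K; reduce dt or attempt_rate"
        )
    rng = np.random.default_rng(params.seed)
    N, F = params.n_particles, params.n_frames
    f_free = release_fraction(params.occupancy_decay, T)
    is_free = rng.random(N) < f_free

    # axial start sites spread along the channel
    n_sites = max(1, int(params.channel_axis_length / params.site_spacing))
    z0 = rng.integers(0, n_sites, size=N) * params.site_spacing
    # one draw per step: total hop probability p, split evenly between the
    # two directions, so the axial diffusion is exactly a^2 * k_hop / 2
    u = rng.random((F - 1, N))
    hops = (u < p / 2).astype(np.int64) - ((u >= p / 2) & (u < p)).astype(np.int64)
    z = np.vstack([z0, z0 + np.cumsum(hops, axis=0) * params.site_spacing])

    # bounded radial jitter: stationary AR(1) with correlation time 5 ps
    phi = math.exp(-dt / 5.0)
    innov = math.sqrt(1.0 - phi * phi) * params.radial_sigma
    xy = np.empty((F, N, 2))
    xy[0] = rng.normal(0.0, params.radial_sigma, size=(N, 2))
    noise = rng.normal(0.0, innov, size=(F - 1, N, 2))
    for f in range(1, F):
        xy[f] = phi * xy[f - 1] + noise[f - 1]

    pos = np.concatenate([xy, z[:, :, None]], axis=2)

    if is_free.any():
        nf = int(is_free.sum())
        sig = math.sqrt(2.0 * params.free_diffusion * dt)
        start = np.column_stack(
            [rng.normal(0.0, params.radial_sigma, size=(nf, 2)),
             rng.uniform(0.0, params.channel_axis_length, size=nf)]
        )[None]
        steps = rng.normal(0.0, sig, size=(F - 1, nf, 3))
        pos[:, is_free, :] = np.concatenate(
            [start, start + np.cumsum(steps, axis=0)], axis=0
        )

    times = np.arange(F) * dt
    return Trajectory(times, pos, box=None, wrapped=False)


def generate_rate_series(
    ln_pre: float,
    B: float,
    C: float,
    temperatures: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int | None = None,
    value_kind: str = "rate",
    label: str = "",
):
    """Rate/diffusion series from the deformed-Arrhenius forward model.

    values = exp(ln_pre + B/(RT) + C/(RT)^2 + eps), eps ~ N(0, sigma^2)
    i.i.d. on the log scale (multiplicative lognormal noise).
    """
    from .kinetics import RateSeries

    if noise_sigma < 0:
        raise DomainError("noise_sigma must be >= 0")
    T = np.asarray(temperatures, dtype=float)
    x = 1.0 / (R_GAS * T)
    log_v = ln_pre + B * x + C * x * x
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        log_v = log_v + rng.normal(0.0, noise_sigma, size=T.shape)
    return RateSeries(T, np.exp(log_v), value_kind=value_kind, label=label)


def _point_segment_dist(q, a, b) -> float:
    """Plain-Python point-to-segment distance (independent of channels.py)."""
    ab = [b[i] - a[i] for i in range(3)]
    aq = [q[i] - a[i] for i in range(3)]
    L2 = sum(c * c for c in ab)
    t = max(0.0, min(1.0, sum(aq[i] * ab[i] for i in range(3)) / L2))
    d2 = sum((aq[i] - t * ab[i]) ** 2 for i in range(3))
    return math.sqrt(d2)


def _min_dist_polyline(q, pts) -> float:
    if len(pts) == 1:
        return math.dist(q, pts[0])
    return min(
        _point_segment_dist(q, pts[i], pts[i + 1]) for i in range(len(pts) - 1)
    )


def make_channel_fixture(
    n_points: int,
    length: float,
    radius_profile: float | Sequence[float] | Callable[[np.ndarray], np.ndarray] | None = None,
    lining_spec: int | Sequence | None = None,
    seed: int = 0,
    *,
    n_waters: int = 10,
    cutoff: float = 3.0,
    inside_fraction: float = 0.7,
    label: str = "other",
) -> tuple[ChannelPath, FixtureWaters]:
    """Smooth random centerline of exact arc length plus labelled waters.

    Waters are placed at controlled perpendicular offsets from the
    centerline; their true minimum polyline distances are then computed
    by an exhaustive plain-Python check (independent of the vectorized
    analysis code) and returned, so the correct count at the requested
    cutoff is known exactly.  Offsets within 2% of the cutoff are
    redrawn to keep in/out labels unambiguous.
    """
    if n_points < 2:
        raise DomainError("need n_points >= 2")
    if length <= 0 or cutoff <= 0:
        raise DomainError("length and cutoff must be positive")
    rng = np.random.default_rng(seed)

    # gently turning unit directions -> equal-length steps sum to `length`
    step = length / (n_points - 1)
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    dirs = [d]
    for _ in range(n_points - 2):
        d = d + 0.15 * rng.normal(size=3)
        d /= np.linalg.norm(d)
        dirs.append(d)
    pts = np.vstack([np.zeros(3), np.cumsum(np.asarray(dirs) * step, axis=0)])

    s = np.linspace(0.0, 1.0, n_points)
    if radius_profile is None:
        radii = np.full(n_points, 2.0)
    elif callable(radius_profile):
        radii = np.asarray(radius_profile(s), dtype=float)
    elif np.isscalar(radius_profile):
        radii = np.full(n_points, float(radius_profile))
    else:
        radii = np.asarray(radius_profile, dtype=float)

    names = sorted(KYTE_DOOLITTLE)
    if lining_spec is None:
        lining_spec = 10
    if isinstance(lining_spec, int):
        lining = tuple(
            (names[i], k + 1) for k, i in enumerate(rng.integers(0, len(names), lining_spec))
        )
    else:
        lining = tuple(
            (r, i + 1) if isinstance(r, str) else (r[0], int(r[1]))
            for i, r in enumerate(lining_spec)
        )
    path = ChannelPath(points=pts, radii=radii, lining_residues=lining, label=label)

    pts_list = [tuple(p) for p in pts]
    n_in = int(round(inside_fraction * n_waters))
    coords, dists = [], []
    for k in range(n_waters):
        want_inside = k < n_in
        for _attempt in range(200):
            si = int(rng.integers(0, n_points - 1))
            t = float(rng.uniform(0.2, 0.8))
            base = pts[si] + t * (pts[si + 1] - pts[si])
            axis = pts[si + 1] - pts[si]
            perp = rng.normal(size=3)
            perp -= axis * (perp @ axis) / (axis @ axis)
            perp /= np.linalg.norm(perp)
            off = (
                rng.uniform(0.1, 0.85) if want_inside else rng.uniform(1.3, 2.5)
            ) * cutoff
            q = base + off * perp
            dist = _min_dist_polyline(tuple(q), pts_list)
            unambiguous = abs(dist - cutoff) > 0.02 * cutoff
            if unambiguous and (dist <= cutoff) == want_inside:
                coords.append(q)
                dists.append(dist)
                break
        else:  # pragma: no cover - placement failure would be a geometry bug
            raise RuntimeError("could not place fixture water")
    coords = np.asarray(coords)
    dists = np.asarray(dists)
    waters = FixtureWaters(
        coords=coords, distances=dists, inside=dists <= cutoff, cutoff=cutoff
    )
    return path, waters
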