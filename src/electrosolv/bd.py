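"""2D overdamped Brownian dynamics of polydisperse spheres in a periodic box.

Mirrors the protocol used to connect pair potentials to suspension structure:
spheres settled into a plane, periodic x-y boundaries, per-particle
Stokes-Einstein diffusivity D_i = kT / (6 pi eta R_i), Euler-Maruyama updates

    r <- r + (D_i / kT) F dt + sqrt(2 D_i dt) xi,

pairwise forces from the analytic derivative of U(x) at surface separation
x = r_ij - R_i - R_j (force-shifted at the cutoff), and a potential-energy
trace for stationarity detection.  The interaction potential is fixed and
independent of particle size; polydispersity enters only radii and D_i.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import T_DEFAULT, CP, kBT
from .potential import PairPotentialParams

__all__ = [
    "SimulationConfig",
    "ParticleEnsemble",
    "Trajectory",
    "UnstableTimestepError",
    "initialize_ensemble",
    "run",
    "stationarity_reached",
    "frame_potential_energy",
]

# inner repulsive wall keeping contact configurations finite for BD
WALL_X = 5e-9        # m; wall switches on below this surface separation
WALL_EPS_KT = 10.0   # wall scale in kT


class UnstableTimestepError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    """Box geometry, time discretization and thermostat for a BD run.

    Either `density` (particles per m^2) or an explicit `n_particles` sets N.
    `dt=None` selects the largest timestep whose free-flight rms displacement
    for the fastest particle resolves the potential's screening length:
    sqrt(2 D_max dt) = 0.1 / kappa1.  `cutoff=None` defaults to
    10/kappa1 + 2 R_max (interactions beyond are negligible against kT).
    """

    box: tuple[float, float]            # m
    density: float | None = None        # 1/m^2
    n_particles: int | None = None
    dt: float | None = None             # s
    total_time: float = 60.0            # s
    sample_interval: float = 1.0        # s
    temperature: float = T_DEFAULT
    viscosity: float = 0.89 * CP        # Pa.s
    seed: int = 0
    cutoff: float | None = None         # m, centre-distance
    # extra surface-separation margin enforced at placement so runs start
    # outside the steep short-range force region (a few screening lengths
    # is typical); dynamics are unaffected
    placement_buffer: float = 0.0       # m

    def __post_init__(self):
        if self.box[0] <= 0 or self.box[1] <= 0:
            raise ValueError("box sides must be positive")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.density is None and self.n_particles is None:
            raise ValueError("set density or n_particles")

    @property
    def n(self) -> int:
        if self.n_particles is not None:
            return int(self.n_particles)
        return int(round(self.density * self.box[0] * self.box[1]))


@dataclass
class ParticleEnsemble:
    positions: np.ndarray     # (N, 2) m, wrapped into box
    radii: np.ndarray         # (N,) m
    box: tuple[float, float]

    def __post_init__(self):
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    @property
    def n(self) -> int:
        return self.positions.shape[0]


@dataclass
class Trajectory:
    """Time-ordered snapshots of one BD run (constant N)."""

    frames: np.ndarray             # (F, N, 2) m
    radii: np.ndarray              # (N,) m
    times: np.ndarray              # (F,) s
    energy_per_particle: np.ndarray  # (F,) J
    box: tuple[float, float]
    seed: int
    dt: float
    cutoff: float
    params: PairPotentialParams | None = None

    def __post_init__(self):
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.frames.shape[0] != self.times.shape[0]:
            raise ValueError("frames/times length mismatch")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def ensemble(self, i: int) -> ParticleEnsemble:
        return ParticleEnsemble(self.frames[i].copy(), self.radii, self.box)


def initialize_ensemble(config: SimulationConfig, size_distribution,
                        seed: int | None = None) -> ParticleEnsemble:
    """Random non-overlapping placement; radii i.i.d. from size_distribution.

    `size_distribution` is any object with sample(rng, n) -> radii in m
    (see electrosolv.synth.SizeDistribution) or a plain radius (float).
    Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n
    if n < 2:
        raise ValueError("need at least 2 particles")
    Lx, Ly = config.box
    if np.isscalar(size_distribution):
        radii = np.full(n, float(size_distribution))
    else:
        radii = np.asarray(size_distribution.sample(rng, n), dtype=float)
    pos = np.empty((n, 2))
    placed = 0
    attempts = 0
    max_attempts = 10_000 * n
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} non-overlapping particles in the box "
                f"after {max_attempts} attempts; density too high")
        cand = rng.random(2) * (Lx, Ly)
        ok = True
        for j in range(placed):
            dx = cand[0] - pos[j, 0]
            dy = cand[1] - pos[j, 1]
            dx -= Lx * round(dx / Lx)
            dy -= Ly * round(dy / Ly)
            # wall-width margin (plus any configured placement buffer) so
            # initial configurations start outside the steep inner repulsion
            margin = WALL_X + config.placement_buffer
            if dx * dx + dy * dy < (radii[placed] + radii[j] + margin) ** 2:
                ok = False
                break
        attempts += 1
        if ok:
            pos[placed] = cand
            placed += 1
    return ParticleEnsemble(positions=pos, radii=radii, box=(Lx, Ly))


def _auto_dt(config: SimulationConfig, params: PairPotentialParams,
             radii: np.ndarray) -> float:
    kT = kBT(config.temperature)
    d_max = kT / (6 * math.pi * config.viscosity * np.min(radii))
    ell = 0.1 / params.kappa1
    return ell**2 / (2 * d_max)


def run(ensemble: ParticleEnsemble, potential: PairPotentialParams,
        config: SimulationConfig) -> Trajectory:
    """Integrate the ensemble forward; reproducible given config.seed."""
    Lx, Ly = ensemble.box
    kT = kBT(config.temperature)
    radii = ensemble.radii
    dt = config.dt if config.dt is not None else _auto_dt(config, potential, radii)
    cutoff = config.cutoff
    if cutoff is None:
        # 15 screening lengths: the residual force-shift tilt across the
        # potential well is then < 1e-3 kT
        cutoff = 15.0 / potential.kappa1 + 2.0 * float(np.max(radii))
    if cutoff >= min(Lx, Ly) / 2:
        raise ValueError("cutoff must be < half the smallest box side")

    diff = kT / (6 * math.pi * config.viscosity * radii)      # D_i
    mobility = diff / kT
    noise_amp = np.sqrt(2 * diff * dt)

    n_steps = int(round(config.total_time / dt))
    sample_every = max(1, int(round(config.sample_interval / dt)))
    n_frames = 1 + n_steps // sample_every

    frames = np.empty((n_frames, ensemble.n, 2))
    energies = np.empty(n_frames)
    pos = ensemble.positions.copy()
    max_disp = 0.5 / potential.kappa1

    status = _kernels.run_bd(
        pos, radii, Lx, Ly,
        potential.A, potential.B, potential.kappa1, potential.kappa2,
        potential.A_H, potential.include_vdw,
        WALL_EPS_KT * kT, WALL_X, cutoff,
        mobility, noise_amp, dt, n_steps, sample_every,
        config.seed % (2**31), max_disp, frames, energies)
    if status != 0:
        raise UnstableTimestepError(
            f"single-step displacement exceeded half a screening length; "
            f"reduce dt (currently {dt:.3g} s)")

    times = np.arange(n_frames) * (sample_every * dt)
    # strictly increasing times require distinct samples
    return Trajectory(frames=frames, radii=radii.copy(), times=times,
                      energy_per_particle=energies, box=(Lx, Ly),
                      seed=config.seed, dt=dt, cutoff=cutoff, params=potential)


def frame_potential_energy(positions: np.ndarray, radii: np.ndarray,
                           box: tuple[float, float],
                           params: PairPotentialParams, cutoff: float,
                           temperature: float = T_DEFAULT) -> float:
    """From-scratch potential energy per particle of one frame (J).

    Replicates the kernel's force-shifted truncation; used as an independent
    check of the incremental energy trace.
    """
    forces = np.zeros_like(positions, dtype=float)
    wall_forces = np.zeros_like(forces)
    kT = kBT(temperature)
    utot = _kernels.forces_energy(
        np.ascontiguousarray(positions, dtype=float),
        np.ascontiguousarray(radii, dtype=float),
        box[0], box[1], params.A, params.B, params.kappa1, params.kappa2,
        params.A_H, params.include_vdw, WALL_EPS_KT * kT, WALL_X,
        cutoff, forces, wall_forces)
    return utot / positions.shape[0]


def stationarity_reached(trajectory: Trajectory, window: float,
                         rel_tol: float = 0.1) -> tuple[bool, float | None]:
    """Detect a stationary potential-energy-per-particle trace.

    Scans window boundaries from the start; at each candidate onset the
    trailing data must (i) have a linear trend whose total drift over the
    remaining span is within noise (twice the standard error of the fitted
    drift) or within rel_tol of the trailing mean magnitude — attractive
    systems keep coarsening logarithmically, so a small residual drift is
    part of the stationary regime — and (ii) have first- and last-window
    means that agree within noise.  Returns (reached, earliest onset time);
    (False, None) when never reached.
    """
    t = trajectory.times
    e = trajectory.energy_per_particle
    if len(t) < 4:
        raise ValueError("need at least 4 samples")
    dt_s = t[1] - t[0]
    n_w = max(2, int(round(window / dt_s)))
    if len(t) < 2 * n_w:
        raise ValueError("trajectory shorter than two windows")

    for start in range(0, len(t) - 2 * n_w + 1, n_w):
        tt = t[start:]
        ee = e[start:]
        n = len(ee)
        slope, intercept = np.polyfit(tt, ee, 1)
        resid = ee - (slope * tt + intercept)
        noise = float(np.std(resid, ddof=1)) if n > 2 else 0.0
        drift = abs(slope) * (tt[-1] - tt[0])
        # sampling sd of the fitted total drift is ~ noise*sqrt(12/n)
        se = 2.0 * noise * math.sqrt(12.0 / n)
        tol = max(se, rel_tol * abs(float(np.mean(ee[-n_w:]))), 1e-30)
        means_ok = abs(np.mean(ee[:n_w]) - np.mean(ee[-n_w:])) <= max(
            2.0 * noise * math.sqrt(2.0 / n_w),
            rel_tol * abs(float(np.mean(ee[-n_w:]))), 1e-30)
        if drift <= tol and means_ok:
            return True, float(t[start])
    return False, None
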