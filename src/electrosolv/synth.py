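"""Synthetic microscopy-like observations.

Composes Brownian-dynamics trajectories with the statistical imperfections of
video-microscopy particle tracking: isotropic Gaussian localization noise
(default sigma 20 nm), independent missed detections (default efficiency
0.98), manufacturer-like size polydispersity, and a small population of stuck
dimers sitting at contact.  Frames are subsampled at a configurable frame
rate (5-30 frames/s in the experiments, 150-500 frames per movie).  The
provenance (scenario, generating potential, seed) is carried so an
observation set can be regenerated bit-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .bd import SimulationConfig, Trajectory, initialize_ensemble, run, \
    stationarity_reached
from .potential import PairPotentialParams
from .scenarios import Scenario, get_scenario, resolve_potential

__all__ = ["SizeDistribution", "ObservationSet", "ObservationConfig",
           "synthesize_observation", "apply_observation_effects"]


@dataclass(frozen=True)
class SizeDistribution:
    """Truncated-Gaussian particle-diameter distribution (truncation +-4 CV)."""

    mean_diameter: float      # m
    cv: float = 0.03

    def __post_init__(self):
        if self.mean_diameter <= 0:
            raise ValueError("mean diameter must be positive")
        if self.cv < 0:
            raise ValueError("CV must be >= 0")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Draw n radii (m)."""
        if self.cv == 0:
            return np.full(n, self.mean_diameter / 2)
        sd = self.cv * self.mean_diameter
        d = rng.normal(self.mean_diameter, sd, size=n)
        lo, hi = self.mean_diameter - 4 * sd, self.mean_diameter + 4 * sd
        while True:
            bad = (d < lo) | (d > hi)
            if not bad.any():
                break
            d[bad] = rng.normal(self.mean_diameter, sd, size=int(bad.sum()))
        return d / 2


@dataclass
class ObservationSet:
    """Observation-like frames: noisy, incomplete detections of a suspension."""

    frames: list[np.ndarray]          # per frame (N_f, 2) m
    radii_per_frame: list[np.ndarray]
    frame_rate: float                 # 1/s
    noise_sigma: float                # m
    detection_efficiency: float
    dimer_fraction: float
    box: tuple[float, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.detection_efficiency <= 1):
            raise ValueError("efficiency must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class ObservationConfig:
    frame_rate: float = 10.0          # 1/s
    n_frames: int = 200               # 150-500 in the experiments
    noise_sigma: float = 20e-9        # m (<20 nm localization precision)
    detection_efficiency: float = 0.98
    dimer_fraction: float = 0.0       # fraction of particles locked in dimers
    equilibration_window: float = 20.0  # s, stationarity-detection window


def apply_observation_effects(trajectory: Trajectory, cfg: ObservationConfig,
                              seed: int, start_frame: int = 0
                              ) -> ObservationSet:
    """Turn a BD trajectory into observation-like frames (deterministic)."""
    rng = np.random.default_rng(seed)
    Lx, Ly = trajectory.box
    idx_all = np.arange(start_frame, trajectory.n_frames)
    # subsample at the requested frame rate relative to the sample interval
    sample_dt = trajectory.times[1] - trajectory.times[0]
    stride = max(1, int(round(1.0 / (cfg.frame_rate * sample_dt))))
    idx = idx_all[::stride][:cfg.n_frames]

    n = trajectory.frames.shape[1]
    radii = trajectory.radii
    # choose stuck-dimer members once for the whole movie: replace existing
    # particles (density-preserving) with pairs frozen at contact
    n_dimers = int(round(cfg.dimer_fraction * n / 2))
    dimer_members = rng.choice(n, size=2 * n_dimers, replace=False) \
        if n_dimers > 0 else np.empty(0, dtype=int)

    frames_out: list[np.ndarray] = []
    radii_out: list[np.ndarray] = []
    for k in idx:
        pos = trajectory.frames[k].copy()
        for m in range(n_dimers):
            i, j = dimer_members[2 * m], dimer_members[2 * m + 1]
            # place the pair at contact around particle i's location
            theta = rng.uniform(0, 2 * math.pi)
            contact = radii[i] + radii[j]
            pos[j, 0] = (pos[i, 0] + contact * math.cos(theta)) % Lx
            pos[j, 1] = (pos[i, 1] + contact * math.sin(theta)) % Ly
        keep = rng.random(n) < cfg.detection_efficiency
        obs = pos[keep] + rng.normal(0.0, cfg.noise_sigma, size=(int(keep.sum()), 2))
        obs[:, 0] %= Lx
        obs[:, 1] %= Ly
        frames_out.append(obs)
        radii_out.append(radii[keep].copy())
    return ObservationSet(
        frames=frames_out, radii_per_frame=radii_out,
        frame_rate=cfg.frame_rate, noise_sigma=cfg.noise_sigma,
        detection_efficiency=cfg.detection_efficiency,
        dimer_fraction=cfg.dimer_fraction, box=trajectory.box,
        provenance={"seed": seed, "start_frame": int(start_frame),
                    "stride": int(stride)})


def synthesize_observation(scenario: Scenario | str, sim_config: SimulationConfig,
                           seed: int, obs_config: ObservationConfig | None = None,
                           params: PairPotentialParams | None = None
                           ) -> tuple[ObservationSet, Trajectory]:
    """Run a preset scenario to stationarity and observe it.

    Returns the observation set together with the underlying trajectory; the
    provenance records scenario name, seed and generating potential so the
    set can be regenerated exactly.
    """
    if isinstance(scenario, str):
        scenario = get_scenario(scenario)
    if obs_config is None:
        obs_config = ObservationConfig()
    if params is None:
        params, _ = resolve_potential(scenario)
    dist = SizeDistribution(scenario.diameter_mean, scenario.diameter_cv)
    overrides = {"seed": seed}
    if sim_config.placement_buffer == 0.0:
        overrides["placement_buffer"] = 3.0 / params.kappa1
    cfg = SimulationConfig(**{**sim_config.__dict__, **overrides})
    ens = initialize_ensemble(cfg, dist, seed=seed)
    traj = run(ens, params, cfg)
    reached, onset = stationarity_reached(traj, obs_config.equilibration_window)
    start = 0
    if reached and onset is not None:
        start = int(np.searchsorted(traj.times, onset))
    obs = apply_observation_effects(traj, obs_config, seed=seed + 1,
                                    start_frame=start)
    obs.provenance.update({"scenario": scenario.name,
                           "params": {"A": params.A, "B": params.B,
                                      "kappa1": params.kappa1,
                                      "kappa2": params.kappa2},
                           "bd_seed": seed, "stationary": bool(reached)})
    return obs, traj
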