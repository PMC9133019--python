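"""Langevin time integration of the bead chain.

The single-residue equation of motion is

    m r_i'' = -gamma r_i' - dV/dr_i + Gamma(t),

with Gamma a Gaussian white noise whose amplitude is fixed by the
fluctuation-dissipation relation at the configured temperature (k_B = 1).
Two integrators are provided:

* ``underdamped`` — BAOAB splitting (velocity half-kick, drift, exact
  Ornstein-Uhlenbeck friction/noise step, drift, half-kick).  Velocities are
  carried, so equipartition diagnostics apply.
* ``overdamped`` — Euler-Maruyama on gamma r' = F + Gamma, the high-friction
  limit the model is normally run in.  Per-component displacement variance is
  2 (T / gamma) dt.

A single seeded ``numpy.random.Generator`` drives each run; the seed is
recorded in the trajectory so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import ChainTopology, Conformation, GoParameters
from .potentials import PoreParameters, go_energy_forces, pore_energy_forces, drive_force

__all__ = [
    "DynamicsConfig",
    "Trajectory",
    "langevin_step",
    "run_simulation",
    "kinetic_temperature",
    "make_force_field",
]


class IntegrationFailure(RuntimeError):
    pass


@dataclass(frozen=True)
class DynamicsConfig:
    dt: float = 0.002
    n_steps: int = 0
    mode: str = "overdamped"     # "overdamped" | "underdamped"
    seed: int = 0
    record_every: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.mode not in ("overdamped", "underdamped"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class Trajectory:
    frames: list = field(default_factory=list)         # list[Conformation]
    energies: list = field(default_factory=list)       # list[dict], parallel to frames
    seed: int = 0
    mode: str = "overdamped"

    def positions_array(self) -> np.ndarray:
        return np.stack([f.positions for f in self.frames])

    def velocities_array(self) -> np.ndarray:
        if self.frames and self.frames[0].velocities is None:
            raise ValueError("trajectory carries no velocities")
        return np.stack([f.velocities for f in self.frames])

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


def langevin_step(conf: Conformation, force_field, params: GoParameters,
                  cfg: DynamicsConfig, rng: np.random.Generator) -> Conformation:
    """Advance one step.  ``force_field(positions) -> (N, 3) forces``.

    Stability heuristic: dt <= 0.1 sqrt(m / k_h) for the stiffest (bond) term.
    """
    out = conf.copy()
    _step_inplace(out, force_field, params, cfg, rng)
    return out


def _step_inplace(conf, force_field, params, cfg, rng):
    dt = cfg.dt
    pos = conf.positions
    T = params.temperature
    if cfg.mode == "overdamped":
        f = force_field(pos)
        if not np.all(np.isfinite(f)):
            raise IntegrationFailure("non-finite force")
        noise = rng.standard_normal(pos.shape)
        pos += (dt / params.gamma) * f + np.sqrt(2.0 * T * dt / params.gamma) * noise
    else:
        m = params.mass
        v = conf.velocities
        if v is None:
            v = conf.velocities = np.zeros_like(pos)
        f = force_field(pos)
        if not np.all(np.isfinite(f)):
            raise IntegrationFailure("non-finite force")
        v += (0.5 * dt / m) * f                      # B
        pos += 0.5 * dt * v                          # A
        if params.gamma > 0:                         # O: exact OU update
            c1 = np.exp(-params.gamma * dt / m)
            c2 = np.sqrt(T / m * (1.0 - c1 * c1))
            v *= c1
            v += c2 * rng.standard_normal(pos.shape)
        pos += 0.5 * dt * v                          # A
        f = force_field(pos)
        if not np.all(np.isfinite(f)):
            raise IntegrationFailure("non-finite force")
        v += (0.5 * dt / m) * f                      # B
    conf.time += dt


def make_force_field(topo: ChainTopology | None, params: GoParameters,
                     pore: PoreParameters | None = None):
    """Compose the total force callable and a per-term energy reporter.

    ``topo=None`` gives a free (zero chain force) system; a pore adds the
    channel confinement and, if configured, the axial drive on the foremost
    active bead.
    """

    def energies(positions):
        terms = {"bond": 0.0, "angle": 0.0, "dihedral": 0.0,
                 "native": 0.0, "nonnative": 0.0, "pore": 0.0}
        if topo is not None:
            t, _, _ = go_energy_forces(Conformation(positions), topo, params)
            terms.update(t)
        if pore is not None:
            e, _ = pore_energy_forces(positions, pore)
            terms["pore"] = e
        terms["total"] = sum(terms.values())
        return terms

    def forces(positions):
        f = np.zeros_like(positions)
        if topo is not None:
            _, _, fg = go_energy_forces(Conformation(positions), topo, params)
            f += fg
        if pore is not None:
            _, fp = pore_energy_forces(positions, pore)
            f += fp
            if pore.drive_magnitude > 0:
                f += drive_force(positions, pore, pore.drive_magnitude)
        return f

    return forces, energies


def run_simulation(topo: ChainTopology | None, conf0: Conformation,
                   params: GoParameters, pore: PoreParameters | None,
                   cfg: DynamicsConfig) -> Trajectory:
    """Integrate and record every ``record_every`` steps (plus the initial frame)."""
    if topo is not None and conf0.N != topo.N:
        raise ValueError("initial conformation does not match topology")
    forces, energies = make_force_field(topo, params, pore)
    rng = np.random.default_rng(cfg.seed)
    conf = conf0.copy()
    if cfg.mode == "underdamped" and conf.velocities is None:
        conf.velocities = np.zeros_like(conf.positions)
    traj = Trajectory(seed=cfg.seed, mode=cfg.mode)
    traj.frames.append(conf.copy())
    traj.energies.append(energies(conf.positions))
    for step in range(1, cfg.n_steps + 1):
        try:
            _step_inplace(conf, forces, params, cfg, rng)
        except IntegrationFailure as err:
            raise IntegrationFailure(f"step {step}: {err}") from err
        if step % cfg.record_every == 0:
            traj.frames.append(conf.copy())
            traj.energies.append(energies(conf.positions))
    return traj


def kinetic_temperature(traj: Trajectory, masses: np.ndarray | None = None,
                        burn_in: float = 0.1):
    """Equipartition thermometer: mean of 2 KE / (3 N) over post-burn-in frames.

    Returns ``(T_kin, stderr)`` where the standard error comes from block
    averaging (20 blocks) to absorb frame-to-frame correlation.
    """
    if traj.mode != "underdamped":
        raise ValueError("kinetic temperature needs an underdamped trajectory")
    if not 0.0 <= burn_in < 1.0:
        raise ValueError("burn_in must be in [0, 1)")
    vel = traj.velocities_array()
    n = vel.shape[1]
    if masses is None:
        masses = np.ones(n)
    masses = np.asarray(masses, dtype=float)
    start = int(burn_in * len(vel))
    vel = vel[start:]
    ke = 0.5 * np.einsum("j,tjk,tjk->t", masses, vel, vel)
    t_series = 2.0 * ke / (3.0 * n)
    t_kin = float(t_series.mean())
    nblocks = min(20, max(1, len(t_series) // 2))
    blocks = np.array_split(t_series, nblocks)
    bmeans = np.array([b.mean() for b in blocks])
    stderr = float(bmeans.std(ddof=1) / np.sqrt(nblocks)) if nblocks > 1 else 0.0
    return t_kin, stderr
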