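"""Langevin dynamics: unfolded-ensemble generation and folding runs.

The integrator is the BAOAB splitting of Langevin dynamics (half kick, half
drift, Ornstein-Uhlenbeck velocity refresh, half drift, half kick), which is
stable at the default 2 fs timestep and samples the configurational canonical
ensemble accurately.  With friction 0 and the noise disabled it reduces to
velocity Verlet (NVE).

Protocol mirrors the study design: unfolded starts are produced at high
temperature (550–700 K, above tRNA melting) until no native contact remains,
and folding runs are performed at 353 K until more than 80% of the native
contacts have formed (Q > 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .constants import AKMA, KB
from .contacts import ContactMap
from .energy import GoParameters, GoSystem
from .structures import NativeStructure

__all__ = [
    "SimulationState",
    "Trajectory",
    "langevin_run",
    "generate_unfolded_ensemble",
    "run_folding",
    "spawn_seeds",
]


class SimulationFailure(RuntimeError):
    """Raised when the integration produces non-finite coordinates."""


@dataclass
class SimulationState:
    """Positions/velocities plus the seed and temperature that produced them."""

    positions: np.ndarray
    velocities: np.ndarray
    time: float = 0.0
    seed: int | None = None
    temperature: float | None = None


@dataclass
class Trajectory:
    """Frames sampled every ``stride`` steps, with Q series and metadata."""

    frames: np.ndarray          # (n_frames, N, 3)
    times: np.ndarray           # ps, strictly increasing
    q_series: np.ndarray        # Q at each stored frame
    stride: int
    dt: float
    outcome: str                # folded | unfolded_target_reached | max_steps
    metadata: dict = field(default_factory=dict)
    ke_series: np.ndarray | None = None  # kinetic energy (kcal/mol) per frame

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Derive ``n`` independent child seeds (< 2^31) from a master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def _as_system(system) -> GoSystem:
    if isinstance(system, GoSystem):
        return system
    structure, cmap, params = system
    return GoSystem(structure, cmap, params)


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Thermal velocities, Å/ps: each component ~ N(0, kB*T*AKMA/m)."""
    scale = np.sqrt(KB * temperature * AKMA / masses)
    return rng.standard_normal((len(masses), 3)) * scale[:, None]


def _check_timestep(system: GoSystem, dt: float) -> None:
    """Require dt <= 0.2 * (2π/ω_max) for the stiffest harmonic bond."""
    mu = system.masses.min() / 2.0  # lower bound on any pair's reduced mass
    omega_max = np.sqrt(2.0 * system.params.k_bond * AKMA / mu)
    dt_max = 0.2 * 2.0 * np.pi / omega_max
    if dt > dt_max:
        raise ValueError(
            f"dt = {dt} ps unstable for the stiffest bond "
            f"(limit {dt_max:.4f} ps)"
        )


def _integrate(
    system: GoSystem,
    state: SimulationState,
    n_steps: int,
    dt: float,
    friction: float,
    temperature: float,
    seed: int,
    stride: int,
    stop: str | None = None,           # None | "fold" | "unfold"
    q_stop: float = 0.8,
    thermostat: bool = True,
    check_stride: int | None = None,
) -> Trajectory:
    """Shared integration loop.

    Frames (with Q and kinetic energy) are stored every ``stride`` steps;
    the Q termination condition is checked every ``check_stride`` steps
    (default: every ``stride``) so that short-lived threshold crossings
    between stored frames still terminate the run.
    """
    pos = np.ascontiguousarray(state.positions, dtype=float).copy()
    vel = np.ascontiguousarray(state.velocities, dtype=float).copy()
    n = pos.shape[0]
    rng = np.random.default_rng(seed)
    inv_mass = 1.0 / system.masses
    sigma_v = np.sqrt(KB * temperature * AKMA / system.masses)
    if thermostat and friction > 0:
        c1 = float(np.exp(-friction * dt))
        c2 = float(np.sqrt(max(0.0, 1.0 - c1 * c1)))
    else:
        c1, c2 = 1.0, 0.0

    forces = np.zeros_like(pos)
    _kernels.force_kernel(pos, *system._kernel_args(), forces)

    if check_stride is None or stop is None:
        check_stride = stride
    check_stride = min(check_stride, stride)

    frames, times, qs, kes = [], [], [], []
    n_contacts = max(system.cmap.n_contacts, 1)
    masses = system.masses

    def record(t, q):
        frames.append(pos.copy())
        times.append(t)
        qs.append(q)
        kes.append(0.5 * float(np.sum(masses[:, None] * vel**2)) / AKMA)

    record(state.time, system.count_formed(pos) / n_contacts)
    outcome = "max_steps"
    steps_done = 0
    since_frame = 0
    while steps_done < n_steps:
        chunk = min(check_stride, n_steps - steps_done)
        noise = (rng.standard_normal((chunk, n, 3)) if c2 > 0.0
                 else np.zeros((chunk, n, 3)))
        ok = _kernels.baoab_chunk(
            pos, vel, forces, inv_mass, sigma_v,
            chunk, dt, c1, c2, noise,
            *system._kernel_args(),
        )
        steps_done += chunk
        since_frame += chunk
        if not ok:
            raise SimulationFailure(
                f"non-finite coordinates at step {steps_done}"
            )
        q = system.count_formed(pos) / n_contacts
        stopping = (
            (stop == "fold" and q > q_stop)
            or (stop == "unfold" and (q < q_stop or q == 0.0))
        )
        if since_frame >= stride or stopping or steps_done >= n_steps:
            record(state.time + steps_done * dt, q)
            since_frame = 0
        if stopping:
            outcome = ("folded" if stop == "fold"
                       else "unfolded_target_reached")
            break

    state_out = SimulationState(pos, vel, state.time + steps_done * dt,
                                seed=seed, temperature=temperature)
    traj = Trajectory(
        frames=np.array(frames),
        times=np.array(times),
        q_series=np.array(qs),
        stride=stride,
        dt=dt,
        outcome=outcome,
        ke_series=np.array(kes),
        metadata={
            "seed": seed,
            "temperature": temperature,
            "friction": friction,
            "param_hash": system.params.hash(),
            "n_steps": steps_done,
        },
    )
    traj.final_state = state_out
    return traj


def langevin_run(
    state: SimulationState,
    system,
    n_steps: int,
    dt: float = 0.002,
    friction: float = 1.0,
    seed: int = 0,
    temperature: float | None = None,
    stride: int = 100,
) -> Trajectory:
    """Plain Langevin (or NVE, when friction == 0) run of ``n_steps``.

    ``system`` is either a ``GoSystem`` or a (structure, cmap, params) tuple.
    Same (seed, parameters, platform) gives bit-identical trajectories.
    """
    sys_ = _as_system(system)
    _check_timestep(sys_, dt)
    T = temperature if temperature is not None else (state.temperature or 300.0)
    return _integrate(sys_, state, n_steps, dt, friction, T, seed, stride)


def generate_unfolded_ensemble(
    structure: NativeStructure,
    cmap: ContactMap,
    params: GoParameters,
    n_configs: int,
    T_range: tuple[float, float] = (550.0, 700.0),
    seed: int = 0,
    max_steps: int = 500_000,
    dt: float = 0.002,
    friction: float = 1.0,
    stride: int = 100,
) -> list[SimulationState]:
    """High-temperature unfolding from the native state until Q = 0.

    Each configuration is produced by its own seeded run at a temperature
    drawn uniformly from ``T_range`` and is returned only once not a single
    native contact satisfies the formation criterion (r < λσ).
    """
    if n_configs < 1:
        raise ValueError("n_configs must be >= 1")
    system = GoSystem(structure, cmap, params)
    _check_timestep(system, dt)
    seeds = spawn_seeds(seed, n_configs)
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    out: list[SimulationState] = []
    for s in seeds:
        T = float(rng.uniform(*T_range))
        vel_rng = np.random.default_rng(s)
        state = SimulationState(
            positions=structure.coordinates(),
            velocities=maxwell_boltzmann_velocities(system.masses, T, vel_rng),
            seed=s, temperature=T,
        )
        traj = _integrate(system, state, max_steps, dt, friction, T, s, stride,
                          stop="unfold", q_stop=0.0, check_stride=10)
        final = traj.final_state
        if system.count_formed(final.positions) != 0:
            best_q = float(traj.q_series.min())
            raise SimulationFailure(
                f"failed to reach Q = 0 within {max_steps} steps "
                f"(best Q = {best_q:.3f}, T = {T:.0f} K, seed = {s})"
            )
        out.append(final)
    return out


def run_folding(
    start: SimulationState,
    system,
    T: float = 353.0,
    q_stop: float = 0.8,
    max_steps: int = 2_000_000,
    seed: int = 0,
    dt: float = 0.002,
    friction: float = 1.0,
    stride: int = 100,
    check_stride: int = 10,
) -> Trajectory:
    """Fold from an unfolded start until Q > ``q_stop`` (or ``max_steps``).

    The start must be unfolded (Q < 0.2), matching the definition of the
    unfolded basin; outcome is "folded" or "max_steps".  The termination
    condition is evaluated every ``check_stride`` steps (finer than the
    frame ``stride``) so that short-lived crossings are not missed.
    """
    sys_ = _as_system(system)
    _check_timestep(sys_, dt)
    q0 = sys_.q(start.positions)
    if q0 >= 0.2:
        raise ValueError(
            f"start configuration has Q = {q0:.3f}; unfolded starts require Q < 0.2"
        )
    if start.velocities is None or not np.any(start.velocities):
        rng = np.random.default_rng(seed)
        start = SimulationState(
            positions=start.positions,
            velocities=maxwell_boltzmann_velocities(sys_.masses, T, rng),
            time=start.time, seed=seed, temperature=T,
        )
    return _integrate(sys_, start, max_steps, dt, friction, T, seed, stride,
                      stop="fold", q_stop=q_stop, check_stride=check_stride)
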