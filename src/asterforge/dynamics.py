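"""Time evolution: overdamped Langevin dynamics plus the kinetic Monte
Carlo binding/unbinding scheme.

The kMC scheme and detailed balance
-----------------------------------
Each step, every head attempts one event.  An unbound head binds with
the nominal per-step probability ``1 − exp(−k_on·dt)`` times a
Metropolis factor ``min(1, exp(−ΔU/k_BT))`` where ΔU is the mechanical
energy change of moving the head from its current position to the
candidate site (spring stretch change plus any alignment penalty
created).  A bound head unbinds with the nominal probability
``1 − exp(−k_off·dt)`` times ``exp(+E/k_BT)`` (probability capped at 1),
where E is the stretch + alignment energy stored in the bound
configuration relative to a relaxed spring.  At zero strain both rates
reduce to the nominal ones; for a head held at a fixed position the
stationary bound:unbound odds are ``(k_on/k_off)·exp(−E/k_BT)``, i.e.
Boltzmann in the crosslinker potential, and a strained spring unbinds
faster than a relaxed one.

Candidate binding sites are the nearest points on filament links within
the species' capture radius, one chosen uniformly at random; both heads
may attach the same filament only if their attachment points are more
than the occupancy distance ``o_c`` apart along it.
"""
from __future__ import annotations

import numpy as np

from . import _kernels
from .mechanics import species_arrays, system_forces
from .params import SimConfig, SpeciesParams, KBT_ROOM
from .state import SystemState, Trajectory

__all__ = ["langevin_step", "attempt_binding", "attempt_unbinding",
           "run_simulation", "single_site_kmc", "bind_head", "unbind_head"]


def _seed_kmc(seed: int) -> None:
    _kernels.seed_kmc_rng(int(seed) % (2 ** 32))


def bind_head(state: SystemState, i: int, h: int, fil: int, link: int,
              frac: float) -> None:
    """Force-attach head ``h`` of crosslinker ``i`` to a filament link."""
    state.bound[i, h] = 1
    state.bfil[i, h] = fil
    state.blink[i, h] = link
    state.bfrac[i, h] = frac
    state.head_pos[i, h] = state.attachment_point(i, h)


def unbind_head(state: SystemState, i: int, h: int) -> None:
    state.bound[i, h] = 0
    state.bfil[i, h] = -1
    state.blink[i, h] = -1
    state.bfrac[i, h] = 0.0


def langevin_step(state: SystemState, cfg: SimConfig,
                  rng: np.random.Generator, forces=None) -> SystemState:
    """One Euler–Maruyama step of the overdamped dynamics (in place).

    Free coordinates (filament beads and unbound heads) move by
    ``F/γ·dt + sqrt(2·k_BT·dt/γ)·η``; bound heads follow their
    attachment points.  Raises on non-finite forces, naming the
    offending component.
    """
    if forces is None:
        forces = system_forces(state)
    f_bead, f_head = forces
    if not np.all(np.isfinite(f_bead)):
        bad = np.argwhere(~np.isfinite(f_bead))[0]
        raise FloatingPointError(
            f"non-finite force on filament bead {int(bad[0])}")
    if not np.all(np.isfinite(f_head)):
        bad = np.argwhere(~np.isfinite(f_head))[0]
        raise FloatingPointError(
            f"non-finite force on crosslinker {int(bad[0])} head {int(bad[1])}")
    noise_bead = rng.standard_normal(state.bead_pos.shape)
    noise_head = rng.standard_normal(state.head_pos.shape)
    _kernels.apply_langevin(
        state.bead_pos, state.fil_off, state.head_pos, state.bound,
        state.bfil, state.blink, state.bfrac, f_bead, f_head, cfg.dt,
        cfg.filament_params.drag_per_bead, cfg.drag_head, cfg.k_BT,
        noise_bead, noise_head)
    state.time += cfg.dt
    return state


def _sweep(state: SystemState, active: np.ndarray, dt: float,
           k_BT: float) -> int:
    sp = species_arrays(state.species)
    return _kernels.kmc_sweep(
        state.bead_pos, state.fil_off, state.head_pos, state.bound,
        state.bfil, state.blink, state.bfrac, state.species_id, active,
        sp["sp_l"], sp["sp_kappa"], sp["sp_kon"], sp["sp_koff"],
        sp["sp_kalign"], sp["sp_capr"], sp["sp_oc"],
        state.filament_params.link_rest_length, dt, k_BT)


def _attempt(state: SystemState, i: int, h: int, dt: float, k_BT: float,
             seed=None):
    if seed is not None:
        _seed_kmc(seed)
    active = np.zeros_like(state.bound)
    active[i, h] = 1
    before = bool(state.bound[i, h])
    _sweep(state, active, dt, k_BT)
    after = bool(state.bound[i, h])
    if after == before:
        return None
    if after:
        return {"event": "bind", "filament": int(state.bfil[i, h]),
                "link": int(state.blink[i, h]),
                "frac": float(state.bfrac[i, h])}
    return {"event": "unbind"}


def attempt_binding(state: SystemState, i: int, h: int, dt: float,
                    k_BT: float = KBT_ROOM, seed=None):
    """Single kMC binding attempt for an unbound head; returns the event
    dict or None."""
    if state.bound[i, h]:
        raise ValueError("head is already bound")
    return _attempt(state, i, h, dt, k_BT, seed)


def attempt_unbinding(state: SystemState, i: int, h: int, dt: float,
                      k_BT: float = KBT_ROOM, seed=None):
    """Single kMC unbinding attempt for a bound head."""
    if not state.bound[i, h]:
        raise ValueError("head is not bound")
    return _attempt(state, i, h, dt, k_BT, seed)


def run_simulation(cfg: SimConfig, initial: SystemState) -> Trajectory:
    """Alternate force evaluation, Langevin step and a kMC sweep.

    Snapshots are taken every ``cfg.output_interval`` (the first frame is
    the initial condition); the run is reproducible bit-for-bit given
    (config, seed).  Aborts if any coordinate moves farther than one
    link rest length in a single step, which signals a too-large dt.
    """
    state = initial.copy()
    rng = np.random.default_rng(cfg.seed)
    _seed_kmc(cfg.seed)
    sp = species_arrays(state.species)
    fp = cfg.filament_params
    conf = cfg.conf
    active = np.ones_like(state.bound)
    n_steps = cfg.n_steps
    out_every = max(1, int(round(cfg.output_interval / cfg.dt)))
    frames = [state.copy()]
    l0 = fp.link_rest_length
    for step in range(1, n_steps + 1):
        f_bead, f_head = _kernels.compute_forces(
            state.bead_pos, state.fil_off, l0, fp.k_stretch, fp.k_bend,
            conf.r_c, conf.k_c, state.head_pos, state.bound, state.bfil,
            state.blink, state.bfrac, state.species_id,
            sp["sp_l"], sp["sp_kappa"], sp["sp_kalign"])
        noise_bead = rng.standard_normal(state.bead_pos.shape)
        noise_head = rng.standard_normal(state.head_pos.shape)
        max_disp = _kernels.apply_langevin(
            state.bead_pos, state.fil_off, state.head_pos, state.bound,
            state.bfil, state.blink, state.bfrac, f_bead, f_head, cfg.dt,
            fp.drag_per_bead, cfg.drag_head, cfg.k_BT,
            noise_bead, noise_head)
        if not np.isfinite(max_disp):
            # re-raise with a component-level diagnostic
            langevin_step(state, cfg, rng, forces=(f_bead, f_head))
            raise FloatingPointError("non-finite displacement")
        if max_disp > l0:
            raise RuntimeError(
                f"instability at step {step}: displacement {max_disp:.3g} µm "
                f"exceeds the link rest length; reduce dt")
        _kernels.kmc_sweep(
            state.bead_pos, state.fil_off, state.head_pos, state.bound,
            state.bfil, state.blink, state.bfrac, state.species_id, active,
            sp["sp_l"], sp["sp_kappa"], sp["sp_kon"], sp["sp_koff"],
            sp["sp_kalign"], sp["sp_capr"], sp["sp_oc"], l0, cfg.dt,
            cfg.k_BT)
        state.time = step * cfg.dt
        if step % out_every == 0 or step == n_steps:
            frames.append(state.copy())
    return Trajectory(frames, cfg)


def single_site_kmc(species: SpeciesParams, n_steps: int = 10_000_000,
                    dt: float = 1e-4, seed: int = 0,
                    k_BT: float = KBT_ROOM) -> dict:
    """Zero-strain single-head binding/unbinding experiment.

    One head of one crosslinker is held adjacent to a frozen filament so
    that binding and unbinding both occur at zero spring extension and
    zero alignment penalty; only the kMC runs.  The stationary ratio of
    time bound to time unbound estimates k_on/k_off.
    """
    from .state import Filament, Crosslinker
    l = species.rest_length
    fil = Filament(np.array([[0.0, 0.0], [1.0, 0.0]]))
    # head 0 (inactive partner) sits a rest length away from the site so
    # the spring is relaxed whether head 1 is bound at (0.5, 0) or free
    # at the same point.
    xl = Crosslinker(species.name, np.array([[0.5, l], [0.5, 0.0]]))
    state = SystemState.from_components([fil], [xl], [species])
    active = np.zeros_like(state.bound)
    active[0, 1] = 1
    _seed_kmc(seed)
    sp = species_arrays(state.species)
    steps_bound, steps_unbound, n_bind, n_unbind = _kernels.kmc_only_run(
        state.bead_pos, state.fil_off, state.head_pos, state.bound,
        state.bfil, state.blink, state.bfrac, state.species_id, active,
        sp["sp_l"], sp["sp_kappa"], sp["sp_kon"], sp["sp_koff"],
        sp["sp_kalign"], sp["sp_capr"], sp["sp_oc"],
        state.filament_params.link_rest_length, dt, k_BT,
        n_steps, 0, 1)
    time_bound = steps_bound * dt
    time_unbound = steps_unbound * dt
    return {
        "time_bound": time_bound,
        "time_unbound": time_unbound,
        "ratio": time_bound / time_unbound if time_unbound > 0 else np.inf,
        "bound_fraction": steps_bound / n_steps,
        "n_bind": int(n_bind),
        "n_unbind": int(n_unbind),
    }
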