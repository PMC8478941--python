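"""Potential energies of the mechanical model and their forces.

The model: filaments are bead-spring worm-like chains with harmonic
bond-length and bond-angle terms; crosslinkers are linear springs whose
heads can attach to filament links; a harmonic radial potential confines
everything beyond radius ``r_c``; a doubly bound crosslinker of an
orientation-selective species pays ``k_align (1 − cos θ)`` for the angle
θ between the two links it bridges.

Energies here are evaluated in plain NumPy for clarity; the force
evaluation delegates to the compiled kernel, and the two are held
consistent by finite-difference tests.
"""
from __future__ import annotations

import numpy as np

from . import _kernels
from .params import ConfinementParams, FilamentParams, SpeciesParams
from .state import Crosslinker, Filament, SystemState

__all__ = [
    "confinement_energy", "alignment_energy", "filament_energy",
    "crosslinker_energy", "system_energy", "system_forces",
]


def confinement_energy(position, conf: ConfinementParams) -> float:
    """½·k_c·(r − r_c)² beyond the confinement radius, 0 inside."""
    r = float(np.hypot(*np.asarray(position, dtype=float)))
    if r < conf.r_c:
        return 0.0
    return 0.5 * conf.k_c * (r - conf.r_c) ** 2


def alignment_energy(theta: float, species: SpeciesParams) -> float:
    """k_align·(1 − cos θ); identically 0 for orientation-blind species.

    θ is the angle between the two filament links bridged by the
    crosslinker, in [0, π] with parallel = 0.  Antiparallel links pay
    the maximum penalty 2·k_align, which is what makes a fascin-like
    species parallel-selective.
    """
    return species.k_align * (1.0 - np.cos(theta))


def filament_energy(f: Filament, params: FilamentParams,
                    conf: ConfinementParams) -> float:
    """Stretch + bend + confinement energy of a single filament."""
    p = f.bead_positions
    bonds = np.diff(p, axis=0)
    lengths = np.linalg.norm(bonds, axis=1)
    e_stretch = 0.5 * params.k_stretch * np.sum(
        (lengths - params.link_rest_length) ** 2)
    e_bend = 0.0
    if len(bonds) > 1:
        u, v = bonds[:-1], bonds[1:]
        theta = np.arctan2(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0],
                           np.sum(u * v, axis=1))
        e_bend = 0.5 * params.k_bend * np.sum(theta ** 2)
    r = np.linalg.norm(p, axis=1)
    out = r >= conf.r_c
    e_conf = 0.5 * conf.k_c * np.sum((r[out] - conf.r_c) ** 2)
    return float(e_stretch + e_bend + e_conf)


def _effective_head_positions(x: Crosslinker, state: SystemState) -> np.ndarray:
    pos = x.head_positions.copy()
    for h, st in enumerate(x.head_states):
        if st is not None:
            f, j, u = st
            a = state.fil_off[f] + j
            pos[h] = (1.0 - u) * state.bead_pos[a] + u * state.bead_pos[a + 1]
    return pos


def crosslinker_energy(x, state: SystemState) -> float:
    """Spring stretch + per-head confinement + alignment when doubly bound.

    ``x`` may be a :class:`Crosslinker` or an index into ``state``.  The
    constant binding-energy offset per bound head enters the kinetics
    only and is excluded here.
    """
    if not isinstance(x, Crosslinker):
        x = state.crosslinker(int(x))
    sp = state.species[state.species_index(x.species)]
    pos = _effective_head_positions(x, state)
    d = float(np.linalg.norm(pos[1] - pos[0]))
    e = 0.5 * sp.stiffness * (d - sp.rest_length) ** 2
    e += confinement_energy(pos[0], state.confinement)
    e += confinement_energy(pos[1], state.confinement)
    if sp.k_align > 0 and all(st is not None for st in x.head_states):
        links = []
        for f, j, _u in x.head_states:
            a = state.fil_off[f] + j
            links.append(state.bead_pos[a + 1] - state.bead_pos[a])
        u, v = links
        cth = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        e += sp.k_align * (1.0 - np.clip(cth, -1.0, 1.0))
    return float(e)


def system_energy(state: SystemState) -> float:
    """Total potential energy: Σ filament terms + Σ crosslinker terms."""
    e = sum(filament_energy(state.filament(i), state.filament_params,
                            state.confinement)
            for i in range(state.n_filaments))
    e += sum(crosslinker_energy(i, state)
             for i in range(state.n_crosslinkers))
    return float(e)


def species_arrays(species) -> dict:
    """Pack per-species parameters into flat arrays for the kernels."""
    return {
        "sp_l": np.array([s.rest_length for s in species]),
        "sp_kappa": np.array([s.stiffness for s in species]),
        "sp_kon": np.array([s.k_on for s in species]),
        "sp_koff": np.array([s.k_off for s in species]),
        "sp_kalign": np.array([s.k_align for s in species]),
        "sp_capr": np.array([s.capture_radius for s in species]),
        "sp_oc": np.array([s.occupancy_distance for s in species]),
    }


def system_forces(state: SystemState):
    """Analytic forces on every bead and every unbound head.

    Returns ``(f_bead, f_head)`` in pN.  Bound heads are not free
    coordinates: the spring and confinement forces acting at their
    attachment points are distributed onto the two link beads with
    lever-rule weights (1 − u, u), and their ``f_head`` rows are zero.
    """
    sp = species_arrays(state.species)
    fp = state.filament_params
    conf = state.confinement
    return _kernels.compute_forces(
        state.bead_pos, state.fil_off, fp.link_rest_length, fp.k_stretch,
        fp.k_bend, conf.r_c, conf.k_c, state.head_pos, state.bound,
        state.bfil, state.blink, state.bfrac, state.species_id,
        sp["sp_l"], sp["sp_kappa"], sp["sp_kalign"])
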