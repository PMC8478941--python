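"""System state containers and the canonical trajectory text format.

`SystemState` is array-backed for speed: bead positions of all filaments
live in one ``(B, 2)`` array with per-filament offsets, and crosslinkers
in parallel arrays (head positions, bound flags, attachment records).
Small `Filament` / `Crosslinker` dataclasses are provided for
construction and inspection.

Bound-head bookkeeping: a bound head records ``(filament, link, frac)``
where ``frac`` in [0, 1] is the fractional position along the link; its
Cartesian position is kept equal to the attachment point at all times.
"""
from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .params import ConfinementParams, FilamentParams, SimConfig, SpeciesParams

__all__ = ["Filament", "Crosslinker", "SystemState", "Trajectory",
           "write_trajectory", "read_trajectory"]

UNBOUND = -1


@dataclass
class Filament:
    """A single bead-spring filament; ``polarity`` marks the pointed end
    (0 = first bead, 1 = last bead)."""

    bead_positions: np.ndarray  # (n, 2) µm
    polarity: int = 0

    def __post_init__(self):
        self.bead_positions = np.asarray(self.bead_positions, dtype=float)
        if self.bead_positions.ndim != 2 or self.bead_positions.shape[1] != 2:
            raise ValueError("bead_positions must be (n, 2)")
        if len(self.bead_positions) < 2:
            raise ValueError("a filament needs at least 2 beads")
        if not np.all(np.isfinite(self.bead_positions)):
            raise ValueError("bead positions must be finite")

    @property
    def n_beads(self) -> int:
        return len(self.bead_positions)


@dataclass
class Crosslinker:
    """A two-headed crosslinker.

    ``head_states`` holds one entry per head: ``None`` when unbound, or
    a ``(filament_index, link_index, frac)`` tuple when bound.
    """

    species: str
    head_positions: np.ndarray  # (2, 2) µm
    head_states: list = field(default_factory=lambda: [None, None])

    def __post_init__(self):
        self.head_positions = np.asarray(self.head_positions, dtype=float)
        if self.head_positions.shape != (2, 2):
            raise ValueError("head_positions must be (2, 2)")


class SystemState:
    """Array-backed state of filaments + crosslinkers at one time.

    Attributes
    ----------
    time : float
    bead_pos : (B, 2) float array, all filament beads concatenated.
    fil_off : (F+1,) int array, bead-index offsets per filament.
    polarity : (F,) int array.
    head_pos : (X, 2, 2) float array, crosslinker head coordinates.
    bound : (X, 2) uint8, 1 where the head is attached.
    bfil, blink : (X, 2) int32 attachment records (−1 when unbound).
    bfrac : (X, 2) float fractional position along the link.
    species_id : (X,) int32 index into ``species``.
    """

    def __init__(self, time, bead_pos, fil_off, polarity, head_pos, bound,
                 bfil, blink, bfrac, species_id,
                 species: Sequence[SpeciesParams],
                 filament_params: FilamentParams,
                 confinement: ConfinementParams):
        self.time = float(time)
        self.bead_pos = np.ascontiguousarray(bead_pos, dtype=np.float64)
        self.fil_off = np.ascontiguousarray(fil_off, dtype=np.int64)
        self.polarity = np.ascontiguousarray(polarity, dtype=np.int64)
        self.head_pos = np.ascontiguousarray(head_pos, dtype=np.float64)
        self.bound = np.ascontiguousarray(bound, dtype=np.uint8)
        self.bfil = np.ascontiguousarray(bfil, dtype=np.int32)
        self.blink = np.ascontiguousarray(blink, dtype=np.int32)
        self.bfrac = np.ascontiguousarray(bfrac, dtype=np.float64)
        self.species_id = np.ascontiguousarray(species_id, dtype=np.int32)
        self.species = tuple(species)
        self.filament_params = filament_params
        self.confinement = confinement
        if self.time < 0:
            raise ValueError("time must be non-negative")
        self._validate_bindings()

    # -- construction ---------------------------------------------------
    @classmethod
    def from_components(cls, filaments: Sequence[Filament],
                        crosslinkers: Sequence[Crosslinker],
                        species: Sequence[SpeciesParams],
                        filament_params: FilamentParams | None = None,
                        confinement: ConfinementParams | None = None,
                        time: float = 0.0) -> "SystemState":
        filament_params = filament_params or FilamentParams()
        confinement = confinement or ConfinementParams()
        name_to_id = {s.name: i for i, s in enumerate(species)}
        fil_off = np.zeros(len(filaments) + 1, dtype=np.int64)
        for i, f in enumerate(filaments):
            fil_off[i + 1] = fil_off[i] + f.n_beads
        bead_pos = (np.concatenate([f.bead_positions for f in filaments])
                    if filaments else np.zeros((0, 2)))
        polarity = np.array([f.polarity for f in filaments], dtype=np.int64)
        X = len(crosslinkers)
        head_pos = np.zeros((X, 2, 2))
        bound = np.zeros((X, 2), dtype=np.uint8)
        bfil = np.full((X, 2), UNBOUND, dtype=np.int32)
        blink = np.full((X, 2), UNBOUND, dtype=np.int32)
        bfrac = np.zeros((X, 2))
        species_id = np.zeros(X, dtype=np.int32)
        for i, x in enumerate(crosslinkers):
            species_id[i] = name_to_id[x.species]
            head_pos[i] = x.head_positions
            for h, st in enumerate(x.head_states):
                if st is not None:
                    f, j, u = st
                    bound[i, h] = 1
                    bfil[i, h], blink[i, h], bfrac[i, h] = f, j, u
        st = cls(time, bead_pos, fil_off, polarity, head_pos, bound,
                 bfil, blink, bfrac, species_id, species,
                 filament_params, confinement)
        st.refresh_bound_heads()
        return st

    # -- views ----------------------------------------------------------
    @property
    def n_filaments(self) -> int:
        return len(self.fil_off) - 1

    @property
    def n_crosslinkers(self) -> int:
        return len(self.species_id)

    def filament(self, i: int) -> Filament:
        a, b = self.fil_off[i], self.fil_off[i + 1]
        return Filament(self.bead_pos[a:b].copy(), int(self.polarity[i]))

    def crosslinker(self, i: int) -> Crosslinker:
        states = []
        for h in range(2):
            if self.bound[i, h]:
                states.append((int(self.bfil[i, h]), int(self.blink[i, h]),
                               float(self.bfrac[i, h])))
            else:
                states.append(None)
        return Crosslinker(self.species[self.species_id[i]].name,
                           self.head_pos[i].copy(), states)

    def species_index(self, species) -> int:
        """Resolve a species given by name, index or SpeciesParams."""
        if isinstance(species, (int, np.integer)):
            return int(species)
        name = species.name if isinstance(species, SpeciesParams) else str(species)
        for i, s in enumerate(self.species):
            if s.name == name:
                return i
        raise KeyError(f"unknown species {name!r}")

    # -- invariants -----------------------------------------------------
    def attachment_point(self, i: int, h: int) -> np.ndarray:
        f, j, u = self.bfil[i, h], self.blink[i, h], self.bfrac[i, h]
        a = self.fil_off[f] + j
        return (1.0 - u) * self.bead_pos[a] + u * self.bead_pos[a + 1]

    def refresh_bound_heads(self) -> None:
        """Snap bound-head coordinates onto their attachment points."""
        ii, hh = np.nonzero(self.bound)
        for i, h in zip(ii, hh):
            self.head_pos[i, h] = self.attachment_point(i, h)

    def _validate_bindings(self) -> None:
        ii, hh = np.nonzero(self.bound)
        for i, h in zip(ii, hh):
            f, j = self.bfil[i, h], self.blink[i, h]
            if not (0 <= f < self.n_filaments):
                raise ValueError(f"crosslinker {i} head {h}: bad filament {f}")
            n_links = self.fil_off[f + 1] - self.fil_off[f] - 1
            if not (0 <= j < n_links):
                raise ValueError(f"crosslinker {i} head {h}: bad link {j}")
            if not (0.0 <= self.bfrac[i, h] <= 1.0):
                raise ValueError(f"crosslinker {i} head {h}: frac outside [0,1]")

    def copy(self) -> "SystemState":
        return SystemState(self.time, self.bead_pos.copy(), self.fil_off.copy(),
                           self.polarity.copy(), self.head_pos.copy(),
                           self.bound.copy(), self.bfil.copy(), self.blink.copy(),
                           self.bfrac.copy(), self.species_id.copy(),
                           self.species, self.filament_params, self.confinement)


@dataclass
class Trajectory:
    """Ordered snapshots of a run plus its provenance."""

    frames: list  # list[SystemState]
    config: SimConfig | None = None

    def __post_init__(self):
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self):
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def final(self) -> SystemState:
        return self.frames[-1]


# -- canonical text serialization ---------------------------------------
def _state_token(state: SystemState, i: int, h: int) -> str:
    if state.bound[i, h]:
        return f"{state.bfil[i, h]},{state.blink[i, h]},{state.bfrac[i, h]:.6f}"
    return "-"


def write_frame(state: SystemState, fh) -> None:
    fh.write(f"# t={state.time:.6f}\n")
    for f in range(state.n_filaments):
        a, b = state.fil_off[f], state.fil_off[f + 1]
        for k in range(a, b):
            x, y = state.bead_pos[k]
            fh.write(f"F\t{f}\t{k - a}\t{x:.6f}\t{y:.6f}\n")
    for i in range(state.n_crosslinkers):
        sp = state.species[state.species_id[i]].name
        (x0, y0), (x1, y1) = state.head_pos[i]
        fh.write(f"X\t{i}\t{sp}\t{x0:.6f}\t{y0:.6f}\t{_state_token(state, i, 0)}"
                 f"\t{x1:.6f}\t{y1:.6f}\t{_state_token(state, i, 1)}\n")


def write_trajectory(traj: Trajectory, path) -> None:
    """Write in the canonical tab-separated text dialect.

    One block per frame: a ``# t=<seconds>`` header, ``F`` records for
    filament beads and ``X`` records for crosslinkers.
    """
    with open(path, "w") as fh:
        fh.write("# asterforge trajectory v1\n")
        if traj.config is not None:
            c = traj.config
            fh.write(f"# rc={c.conf.r_c} kc={c.conf.k_c} dt={c.dt} "
                     f"kBT={c.k_BT} seed={c.seed}\n")
        for frame in traj.frames:
            write_frame(frame, fh)


def _parse_state_token(tok: str):
    if tok == "-":
        return None
    f, j, u = tok.split(",")
    return int(f), int(j), float(u)


def read_trajectory(path, species: Sequence[SpeciesParams],
                    filament_params: FilamentParams | None = None,
                    confinement: ConfinementParams | None = None) -> Trajectory:
    """Read the canonical text dialect back into a Trajectory.

    The species list supplies the parameter sets for the names found in
    the file; physical parameters are not stored in the file itself.
    """
    filament_params = filament_params or FilamentParams()
    confinement = confinement or ConfinementParams()
    frames = []
    cur_t = None
    fil_pts: dict[int, list] = {}
    xls: list[Crosslinker] = []

    def flush():
        if cur_t is None:
            return
        filaments = [Filament(np.array(fil_pts[f])) for f in sorted(fil_pts)]
        frames.append(SystemState.from_components(
            filaments, xls, species, filament_params, confinement, time=cur_t))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"^#\s*t=([-+0-9.eE]+)$", line)
                if m:
                    flush()
                    cur_t = float(m.group(1))
                    fil_pts, xls = {}, []
                continue
            parts = line.split("\t")
            try:
                if parts[0] == "F":
                    fid = int(parts[1])
                    fil_pts.setdefault(fid, []).append(
                        (float(parts[3]), float(parts[4])))
                elif parts[0] == "X":
                    sp = parts[2]
                    hp = np.array([[float(parts[3]), float(parts[4])],
                                   [float(parts[6]), float(parts[7])]])
                    states = [_parse_state_token(parts[5]),
                              _parse_state_token(parts[8])]
                    xls.append(Crosslinker(sp, hp, states))
                else:
                    raise ValueError(f"unknown record type {parts[0]!r}")
            except (IndexError, ValueError) as e:
                raise ValueError(f"{path}: parse error at line {lineno}: {e}") from e
    flush()
    return Trajectory(frames)


def frame_to_text(state: SystemState) -> str:
    buf = io.StringIO()
    write_frame(state, buf)
    return buf.getvalue()
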