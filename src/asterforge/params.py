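"""Parameter containers for the mechanical model.

Units throughout the package: lengths in µm, forces in pN, energies in
pN·µm, times in s.  Coordinates are 2D Cartesian with the origin at the
center of the confining circle.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "SpeciesParams",
    "FilamentParams",
    "ConfinementParams",
    "SimConfig",
    "KBT_ROOM",
    "FASCIN",
    "ALPHA_ACTININ",
]

#: Thermal energy at room temperature, pN·µm.
KBT_ROOM = 0.0041


@dataclass(frozen=True)
class SpeciesParams:
    """Mechanical and kinetic parameters of one crosslinker species.

    Parameters
    ----------
    name : str
        Species label (used in trajectory files and analysis output).
    rest_length : float
        Rest length ``l`` of the head-to-head spring, µm.
    stiffness : float
        Spring constant ``κ``, pN/µm.
    k_on, k_off : float
        Zero-strain binding / unbinding rates, s⁻¹.
    k_align : float
        Coefficient of the alignment penalty ``k_align (1 − cos θ)``
        applied when both heads are bound, pN·µm.  Zero disables the
        penalty (the α-actinin-like convention).
    capture_radius : float
        Maximum head-to-filament distance at which binding may be
        attempted, µm.  Defaults to the rest length when not given.
    occupancy_distance : float
        Minimum separation ``o_c`` along a single filament at which both
        heads of one crosslinker may attach to it, µm.
    """

    name: str
    rest_length: float
    stiffness: float
    k_on: float
    k_off: float
    k_align: float = 0.0
    capture_radius: float = 0.0
    occupancy_distance: float = 0.5

    def __post_init__(self):
        if self.capture_radius == 0.0:
            object.__setattr__(self, "capture_radius", self.rest_length)
        for attr in ("rest_length", "stiffness", "k_on", "k_off",
                     "capture_radius", "occupancy_distance"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be strictly positive")
        if self.k_align < 0:
            raise ValueError("k_align must be non-negative")

    def with_(self, **kw) -> "SpeciesParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class FilamentParams:
    """Bead-spring worm-like-chain parameters shared by all filaments.

    The bending constant relates to a bare-filament persistence length
    ``L_p`` through ``k_bend = L_p · k_BT / link_rest_length``; the
    default corresponds to L_p ≈ 10 µm at room temperature.
    """

    n_beads: int = 35
    link_rest_length: float = 1.0   # µm
    k_stretch: float = 100.0        # pN/µm
    k_bend: float = 0.041           # pN·µm
    drag_per_bead: float = 0.5      # pN·s/µm

    def __post_init__(self):
        if self.n_beads < 2:
            raise ValueError("n_beads must be at least 2")
        for attr in ("link_rest_length", "k_stretch", "k_bend", "drag_per_bead"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be strictly positive")


@dataclass(frozen=True)
class ConfinementParams:
    """Circular confinement: harmonic beyond radius ``r_c``, zero inside."""

    r_c: float = 15.0   # µm
    k_c: float = 10.0   # pN/µm

    def __post_init__(self):
        if self.r_c <= 0:
            raise ValueError("r_c must be strictly positive")
        if self.k_c < 0:
            raise ValueError("k_c must be non-negative")


# Species parameterization: fascin is short and stiff with fast kinetics
# and a parallel-alignment penalty; alpha-actinin is long, soft, slow and
# orientation-indifferent.  k_off values follow from the on/off ratios of
# 40 and 4 respectively.
FASCIN = SpeciesParams(
    name="fascin",
    rest_length=0.1,
    stiffness=1.0,
    k_on=20.0,
    k_off=0.5,
    k_align=1.0 / 3.0,
)

ALPHA_ACTININ = SpeciesParams(
    name="alpha_actinin",
    rest_length=0.5,
    stiffness=0.1,
    k_on=0.2,
    k_off=0.05,
    k_align=0.0,
)


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of one simulation run."""

    dt: float = 2e-5                # s
    duration: float = 100.0         # s
    k_BT: float = KBT_ROOM          # pN·µm
    seed: int = 0
    output_interval: float = 1.0    # s
    conf: ConfinementParams = field(default_factory=ConfinementParams)
    filament_params: FilamentParams = field(default_factory=FilamentParams)
    species: tuple[SpeciesParams, ...] = (ALPHA_ACTININ, FASCIN)
    n_filaments: int = 50
    crosslinker_density: float = 5.0  # µm⁻² per species
    drag_head: float = 0.5          # pN·s/µm, unbound crosslinker heads

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be strictly positive")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.output_interval < self.dt:
            raise ValueError("output_interval must be >= dt")
        if self.k_BT <= 0:
            raise ValueError("k_BT must be strictly positive")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))
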