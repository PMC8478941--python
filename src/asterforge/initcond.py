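"""Initial conditions: centrally crossing bent filaments and uniformly
scattered crosslinkers.

Each filament is built centered on the origin with its beads at rest
spacing; the half from the center to the pointed end points at an angle
drawn uniformly from [0, 2π), the other half at that angle plus a kink
drawn uniformly from [−π/4, π/4]; the whole filament is then translated
by independent Gaussian offsets in x and y.  Crosslinker centers are
drawn uniformly from the axis-aligned square of side ``r_c`` centered on
the origin — note this square covers only the central part of the
confinement circle of radius ``r_c``; the asymmetry is deliberate and
kept as-is.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ConfinementParams, FilamentParams, SimConfig, SpeciesParams
from .state import Crosslinker, Filament, SystemState

__all__ = ["InitSpec", "generate_filaments", "generate_crosslinkers",
           "build_initial_state", "crosslinker_count", "desk_scale_config"]


@dataclass(frozen=True)
class InitSpec:
    """Parameters of the initial-condition generator."""

    n_filaments: int = 50
    n_beads: int = 35
    center_sd: float = 3.0          # µm
    kink_range: float = np.pi / 4   # radians, half-width
    box_side: float = 15.0          # µm, crosslinker placement square
    counts_per_species: tuple = ()  # crosslinkers per species
    seed: int = 0

    def __post_init__(self):
        if self.n_filaments <= 0 or self.n_beads < 2:
            raise ValueError("counts must be positive")
        if self.center_sd < 0:
            raise ValueError("center_sd must be non-negative")


def crosslinker_count(density: float, r_c: float,
                      convention: str = "circle") -> int:
    """Number of crosslinkers for a given areal density.

    ``circle`` (default) anchors the density to the vesicle area
    π·r_c²; ``square`` to the r_c × r_c placement box.
    """
    if convention == "circle":
        area = np.pi * r_c ** 2
    elif convention == "square":
        area = r_c ** 2
    else:
        raise ValueError("convention must be 'circle' or 'square'")
    return int(round(density * area))


def generate_filaments(spec: InitSpec, rng: np.random.Generator,
                       link_rest_length: float = 1.0) -> list[Filament]:
    """Centrally crossing filaments with a random kink at the middle."""
    filaments = []
    n = spec.n_beads
    mid = n // 2
    for _ in range(spec.n_filaments):
        ang1 = rng.uniform(0.0, 2.0 * np.pi)
        kink = rng.uniform(-spec.kink_range, spec.kink_range)
        pts = np.zeros((n, 2))
        # center -> pointed end at ang1; the other half continues the
        # filament's direction of travel (ang1 + pi) bent by the kink, so
        # the turning angle at the center bead is exactly `kink`
        d1 = np.array([np.cos(ang1), np.sin(ang1)])
        ang2 = ang1 + np.pi + kink
        d2 = np.array([np.cos(ang2), np.sin(ang2)])
        for k in range(mid):
            pts[k] = (mid - k) * link_rest_length * d1
        for k in range(mid + 1, n):
            pts[k] = (k - mid) * link_rest_length * d2
        offset = rng.normal(0.0, spec.center_sd, size=2)
        pts += offset
        filaments.append(Filament(pts, polarity=0))
    return filaments


def generate_crosslinkers(spec: InitSpec, species: list[SpeciesParams],
                          rng: np.random.Generator) -> list[Crosslinker]:
    """Unbound crosslinkers scattered uniformly in the placement square.

    Centers are uniform in the box of side ``box_side``; the two heads
    are placed a rest length apart at a random orientation.
    """
    counts = spec.counts_per_species
    if len(counts) != len(species):
        raise ValueError("need one count per species")
    xls = []
    half = spec.box_side / 2.0
    for sp, count in zip(species, counts):
        centers = rng.uniform(-half, half, size=(count, 2))
        angles = rng.uniform(0.0, 2.0 * np.pi, size=count)
        offs = 0.5 * sp.rest_length * np.column_stack(
            [np.cos(angles), np.sin(angles)])
        for c, o in zip(centers, offs):
            xls.append(Crosslinker(sp.name, np.array([c - o, c + o])))
    return xls


def build_initial_state(cfg: SimConfig, convention: str = "circle",
                        center_sd: float | None = None,
                        n_beads: int | None = None) -> SystemState:
    """Assemble the full initial SystemState for a configuration."""
    count = crosslinker_count(cfg.crosslinker_density, cfg.conf.r_c,
                              convention)
    spec = InitSpec(
        n_filaments=cfg.n_filaments,
        n_beads=n_beads if n_beads is not None else cfg.filament_params.n_beads,
        center_sd=center_sd if center_sd is not None else 3.0,
        box_side=cfg.conf.r_c,
        counts_per_species=tuple(count for _ in cfg.species),
        seed=cfg.seed,
    )
    rng = np.random.default_rng(cfg.seed)
    filaments = generate_filaments(spec, rng,
                                   cfg.filament_params.link_rest_length)
    xls = generate_crosslinkers(spec, list(cfg.species), rng)
    return SystemState.from_components(filaments, xls, cfg.species,
                                       cfg.filament_params, cfg.conf)


def desk_scale_config(seed: int = 0, duration: float = 10.0) -> SimConfig:
    """Reduced-scale mixed-species sorting configuration.

    A 5-µm confinement with 12 eleven-bead filaments and both species at
    5 µm⁻² run for 10 s at dt = 2×10⁻⁴ s; the initial center spread is
    scaled to 1 µm to keep the filaments crossing near the middle of the
    smaller circle.  Small enough for a desktop, large enough to show
    crosslinker sorting.
    """
    from .params import ALPHA_ACTININ, FASCIN
    return SimConfig(
        dt=2e-4,
        duration=duration,
        seed=seed,
        output_interval=1.0,
        conf=ConfinementParams(r_c=5.0, k_c=10.0),
        filament_params=FilamentParams(n_beads=11),
        species=(ALPHA_ACTININ, FASCIN),
        n_filaments=12,
        crosslinker_density=5.0,
    )


def desk_scale_initial(cfg: SimConfig) -> SystemState:
    """Initial state matching :func:`desk_scale_config` (1 µm center sd)."""
    return build_initial_state(cfg, center_sd=1.0)
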