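"""Synthetic-data generators with known ground truth.

Discrete worm-like chains give the persistence-length pipeline inputs
whose true L_p is known; aster-like filament scaffolds give the binding
and density machinery a fixed geometry; multinomial count tables emulate
per-experiment phenotype classification counts.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import FilamentParams, ConfinementParams, SpeciesParams
from .skeleton import Polyline
from .state import Crosslinker, Filament, SystemState

__all__ = ["WLCSpec", "vmf_concentration", "generate_wlc",
           "generate_count_table", "generate_aster_scaffold"]


@dataclass(frozen=True)
class WLCSpec:
    """Specification of a discrete worm-like-chain cohort.

    Successive bond directions decorrelate so that the mean per-step
    cosine is exactly ``exp(−bond_length / lp)``; tangent correlations
    then decay as exp(−s/L_p) and the estimator pipeline can be scored
    against the known ground truth.
    """

    lp: float                        # µm, ground-truth persistence length
    bond_length: float = 0.2         # µm
    contour_range: tuple = (8.0, 20.0)  # µm; (a, a) pins the length
    dimensionality: int = 3
    n_chains: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.lp <= 0 or self.bond_length <= 0:
            raise ValueError("lp and bond_length must be positive")
        if self.dimensionality not in (2, 3):
            raise ValueError("dimensionality must be 2 or 3")
        if self.bond_length > self.lp / 10:
            warnings.warn("bond_length > lp/10: discretization is coarse",
                          stacklevel=2)


def vmf_concentration(mean_cosine: float) -> float:
    """Solve coth(κ) − 1/κ = c for the 3D von Mises–Fisher concentration.

    Exact inversion (no small-angle approximation) keeps the generator
    unbiased even at coarse bond lengths.
    """
    c = float(mean_cosine)
    if not 0 < c < 1:
        raise ValueError("mean cosine must be in (0, 1)")

    def f(k):
        # stable coth for large k
        if k > 20:
            return 1.0 - 1.0 / k - c
        return 1.0 / np.tanh(k) - 1.0 / k - c

    lo, hi = 1e-8, 10.0
    while f(hi) < 0:
        hi *= 10
        if hi > 1e15:
            break
    return brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)


def _sample_vmf_cosines(kappa: float, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Polar cosines w ~ vMF(κ) about the pole (numerically stable)."""
    u = rng.uniform(size=n)
    # w = 1 + log(u + (1-u) e^{-2κ}) / κ
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa


def _propagate_3d(n_bonds: int, kappa: float,
                  rng: np.random.Generator) -> np.ndarray:
    d = np.zeros((n_bonds, 3))
    v = rng.standard_normal(3)
    d[0] = v / np.linalg.norm(v)
    w = _sample_vmf_cosines(kappa, n_bonds - 1, rng)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_bonds - 1)
    for k in range(1, n_bonds):
        prev = d[k - 1]
        # orthonormal frame around prev
        a = np.array([1.0, 0.0, 0.0]) if abs(prev[0]) < 0.9 else \
            np.array([0.0, 1.0, 0.0])
        e1 = np.cross(prev, a)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(prev, e1)
        sw = np.sqrt(max(0.0, 1.0 - w[k - 1] ** 2))
        d[k] = (w[k - 1] * prev
                + sw * (np.cos(phi[k - 1]) * e1 + np.sin(phi[k - 1]) * e2))
        d[k] /= np.linalg.norm(d[k])
    return d


def _propagate_2d(n_bonds: int, sigma: float,
                  rng: np.random.Generator) -> np.ndarray:
    ang = np.empty(n_bonds)
    ang[0] = rng.uniform(0.0, 2.0 * np.pi)
    ang[1:] = rng.normal(0.0, sigma, size=n_bonds - 1)
    ang = np.cumsum(ang)
    d = np.zeros((n_bonds, 3))
    d[:, 0] = np.cos(ang)
    d[:, 1] = np.sin(ang)
    return d


def generate_wlc(spec: WLCSpec, rng: np.random.Generator | None = None
                 ) -> list[Polyline]:
    """Generate discrete worm-like chains as Polylines.

    3D chains step through von Mises–Fisher polar angles about the
    previous bond with concentration solved exactly from
    coth(κ) − 1/κ = exp(−b/L_p); 2D chains use Gaussian turning angles
    with σ² = 2b/L_p.  Either way E[cos θ_step] = exp(−b/L_p) and
    ⟨C(s)⟩ = exp(−s/L_p) in expectation.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    b = spec.bond_length
    c = np.exp(-b / spec.lp)
    if spec.dimensionality == 3:
        kappa = vmf_concentration(c)
    else:
        sigma = np.sqrt(2.0 * b / spec.lp)
    lo, hi = spec.contour_range
    chains = []
    for cid in range(spec.n_chains):
        L = rng.uniform(lo, hi) if hi > lo else lo
        n_bonds = max(2, int(round(L / b)))
        if spec.dimensionality == 3:
            d = _propagate_3d(n_bonds, kappa, rng)
        else:
            d = _propagate_2d(n_bonds, sigma, rng)
        pts = np.vstack([np.zeros(3), np.cumsum(b * d, axis=0)])
        chains.append(Polyline(cid, pts))
    return chains


def generate_count_table(n_experiments: int, categories: list[str],
                         probabilities, totals,
                         rng: np.random.Generator | None = None,
                         seed: int = 0):
    """Multinomial per-experiment category counts (long format).

    ``probabilities`` may sum to less than one; the remainder is an
    implicit uncounted class.  ``totals`` is a scalar or one total per
    experiment.  Returns a :class:`asterforge.stats.CountTable`.
    """
    from .stats import CountTable
    rng = np.random.default_rng(seed) if rng is None else rng
    p = np.asarray(probabilities, dtype=float)
    if np.any(p < 0) or p.sum() > 1 + 1e-12:
        raise ValueError("probabilities must be non-negative and sum <= 1")
    if len(p) != len(categories):
        raise ValueError("need one probability per category")
    totals = np.broadcast_to(np.asarray(totals, dtype=int),
                             (n_experiments,))
    rest = max(0.0, 1.0 - p.sum())
    rows = []
    for e in range(n_experiments):
        draws = rng.multinomial(totals[e], np.append(p, rest))
        for cat, cnt in zip(categories, draws[:len(categories)]):
            rows.append((f"exp{e + 1}", cat, int(cnt), int(totals[e])))
    return CountTable.from_records(rows)


def generate_aster_scaffold(n_bundles: int, r_c: float = 15.0,
                            hub: str = "center",
                            species: tuple = (),
                            rng: np.random.Generator | None = None,
                            seed: int = 0,
                            link_rest_length: float = 1.0) -> SystemState:
    """Straight filaments through a common hub point.

    ``hub='center'`` puts the hub at the origin with filaments radiating
    at random angles; ``hub='periphery'`` puts it on the confinement
    circle.  The scaffold has no crosslinkers — tests attach them with
    :func:`asterforge.dynamics.bind_head` on known geometry.
    """
    if n_bundles < 2:
        raise ValueError("need at least 2 bundles")
    rng = np.random.default_rng(seed) if rng is None else rng
    hub_pt = (np.zeros(2) if hub == "center"
              else np.array([r_c, 0.0]))
    if hub not in ("center", "periphery"):
        raise ValueError("hub must be 'center' or 'periphery'")
    half = int(round(0.4 * r_c / link_rest_length))
    n_beads = max(3, 2 * half + 1)
    filaments = []
    for _ in range(n_bundles):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        d = np.array([np.cos(ang), np.sin(ang)])
        ks = np.arange(n_beads) - n_beads // 2
        pts = hub_pt + np.outer(ks * link_rest_length, d)
        filaments.append(Filament(pts))
    sp = tuple(species) if species else _default_species()
    return SystemState.from_components(
        filaments, [], sp, FilamentParams(n_beads=n_beads),
        ConfinementParams(r_c=r_c))


def _default_species():
    from .params import ALPHA_ACTININ, FASCIN
    return (ALPHA_ACTININ, FASCIN)
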