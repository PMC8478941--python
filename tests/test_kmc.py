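"""Kinetic Monte Carlo binding/unbinding: rates, occupancy rule,
detailed balance and alignment selectivity."""
import numpy as np
import pytest

import asterforge as af
from asterforge.dynamics import _sweep
from asterforge.sim_analysis import bound_crosslinker_pdf


def _head_near_filament(species, head_xy, partner_xy, two_species):
    fil = af.Filament(np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]))
    xl = af.Crosslinker(species, np.array([partner_xy, head_xy]))
    return af.SystemState.from_components([fil], [xl], two_species)


def test_no_filament_within_capture_radius_never_binds(two_species):
    st = _head_near_filament("fascin", [0.5, 5.0], [0.5, 5.1], two_species)
    for seed in range(200):
        ev = af.attempt_binding(st, 0, 1, dt=1.0, seed=seed)
        assert ev is None
    assert not st.bound.any()


def test_binding_occurs_and_reports_site(two_species):
    st = _head_near_filament("fascin", [0.5, 0.05], [0.5, 0.15], two_species)
    events = []
    for seed in range(300):
        if st.bound[0, 1]:
            break
        ev = af.attempt_binding(st, 0, 1, dt=0.05, seed=seed)
        if ev:
            events.append(ev)
    assert events and events[0]["event"] == "bind"
    assert events[0]["filament"] == 0
    assert 0.0 <= events[0]["frac"] <= 1.0
    # bound head sits exactly on its attachment point
    assert np.allclose(st.head_pos[0, 1], st.attachment_point(0, 1))


def test_occupancy_rule_blocks_same_filament_close_sites(two_species):
    """Partner bound to the same filament closer than o_c blocks binding."""
    st = _head_near_filament("alpha_actinin", [0.6, 0.01], [0.0, 0.0],
                             two_species)
    af.bind_head(st, 0, 0, 0, 0, 0.5)   # partner at arc 0.5 µm
    # head at x=0.6: every site within capture radius (0.5) of it lies
    # within o_c = 0.5 µm of the partner's arc position
    for seed in range(300):
        ev = af.attempt_binding(st, 0, 1, dt=0.5, seed=seed)
        assert ev is None


def test_occupancy_rule_allows_distant_sites_on_same_filament(two_species):
    st = _head_near_filament("alpha_actinin", [1.6, 0.01], [0.0, 0.0],
                             two_species)
    af.bind_head(st, 0, 0, 0, 0, 0.2)   # partner at arc 0.2 µm
    bound = False
    for seed in range(300):
        if af.attempt_binding(st, 0, 1, dt=0.5, seed=seed):
            bound = True
            break
    assert bound
    arc = (st.blink[0, 1] + st.bfrac[0, 1]) * 1.0
    assert abs(arc - 0.2) > af.ALPHA_ACTININ.occupancy_distance


def test_zero_strain_unbinding_probability_is_nominal(two_species):
    """1−exp(−k_off·dt) ≈ 1e-5 for k_off=0.5 s⁻¹, dt=2e-5 s."""
    p = 1.0 - np.exp(-af.FASCIN.k_off * 2e-5)
    assert p == pytest.approx(1e-5, rel=1e-4)
    # empirically: a zero-strain bond unbinds at the nominal rate
    st = _head_near_filament("fascin", [0.5, 0.0], [0.5, 0.1], two_species)
    af.bind_head(st, 0, 1, 0, 0, 0.5)
    n_unbind = 0
    trials = 4000
    dt = 0.1     # p_off ≈ 0.0488
    for seed in range(trials):
        st.bound[0, 1] = 1
        st.bfil[0, 1], st.blink[0, 1], st.bfrac[0, 1] = 0, 0, 0.5
        st.head_pos[0, 1] = st.attachment_point(0, 1)
        if af.attempt_unbinding(st, 0, 1, dt=dt, seed=seed):
            n_unbind += 1
    p_exp = 1.0 - np.exp(-af.FASCIN.k_off * dt)
    se = np.sqrt(p_exp * (1 - p_exp) / trials)
    assert abs(n_unbind / trials - p_exp) < 4 * se


def test_stretched_spring_unbinds_faster_than_relaxed(two_species):
    def unbind_rate(partner_y, trials=2000, dt=0.01):
        st = _head_near_filament("fascin", [0.5, 0.0], [0.5, partner_y],
                                 two_species)
        n = 0
        for seed in range(trials):
            st.bound[0, 1] = 1
            st.bfil[0, 1], st.blink[0, 1], st.bfrac[0, 1] = 0, 0, 0.5
            st.head_pos[0, 1] = st.attachment_point(0, 1)
            if af.attempt_unbinding(st, 0, 1, dt=dt, seed=seed):
                n += 1
        return n / trials
    relaxed = unbind_rate(0.1)           # extension 0
    stretched = unbind_rate(0.25)        # extension 0.15 µm
    assert stretched > 2 * relaxed


def test_two_state_occupancy_matches_on_off_ratio(two_species):
    """Zero-strain bound fractions approach k_on/(k_on+k_off):
    ≈0.9756 for the fast species (ratio 40), 0.8 for the slow (ratio 4)."""
    for sp, expected in [(af.FASCIN, 40 / 41), (af.ALPHA_ACTININ, 4 / 5)]:
        res = af.single_site_kmc(sp, n_steps=400_000, dt=1e-3, seed=5)
        n_events = max(res["n_unbind"], 1)
        se = expected * (1 - expected) / np.sqrt(n_events)
        assert res["bound_fraction"] == pytest.approx(expected,
                                                      abs=max(4 * se, 0.02))


def test_frozen_scaffold_occupancy_is_boltzmann(two_species):
    """Held heads at graded spring extensions: stationary bound odds
    follow (k_on/k_off)·exp(−½κ(d−l)²/k_BT)."""
    from asterforge import _kernels
    from asterforge.mechanics import species_arrays

    sp = af.FASCIN
    kBT = af.KBT_ROOM
    extensions = np.array([0.0, 0.04, 0.08, 0.12])
    fil = af.Filament(np.array([[0.0, 0.0], [5.0, 0.0]]))
    xls = []
    for k, ext in enumerate(extensions):
        x = 0.5 + k            # distinct sites along the filament
        # partner pinned above the site so the bound extension is `ext`
        xls.append(af.Crosslinker(sp.name,
                                  np.array([[x, sp.rest_length + ext],
                                            [x, 0.0]])))
    st = af.SystemState.from_components([fil], xls, two_species)
    active = np.zeros_like(st.bound)
    active[:, 1] = 1           # only the lower heads toggle
    _kernels.seed_kmc_rng(31)
    spa = species_arrays(st.species)
    dt = 2e-3
    n_steps = 150_000
    bound_steps = np.zeros(len(extensions))
    for _ in range(n_steps):
        _sweep(st, active, dt, kBT)
        bound_steps += st.bound[:, 1]
    odds = bound_steps / (n_steps - bound_steps)
    ratio0 = sp.k_on / sp.k_off
    expected = ratio0 * np.exp(-0.5 * sp.stiffness * extensions ** 2 / kBT)
    # compare log-odds within a generous Monte Carlo margin
    assert np.allclose(np.log(odds), np.log(expected), atol=0.35)


def test_fascin_binding_suppressed_on_perpendicular_links(two_species):
    """On a hub scaffold, the second fascin head binds a perpendicular
    link far less often than a parallel one (factor exp(−ΔU_align/k_BT)
    is astronomically small at k_align = 1/3, so in practice: never)."""
    f1 = af.Filament(np.array([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]]))
    f2 = af.Filament(np.array([[0.0, -1.0], [0.0, 0.0], [0.0, 1.0]]))
    f3 = af.Filament(np.array([[-1.0, 0.1], [0.0, 0.1], [1.0, 0.1]]))
    st = af.SystemState.from_components([f1, f2, f3],
                                        [af.Crosslinker(
                                            "fascin", np.zeros((2, 2)))],
                                        two_species)
    af.bind_head(st, 0, 0, 0, 1, 0.05)  # first head on horizontal f1
    st.head_pos[0, 1] = [0.05, 0.05]    # near both f2 (⊥) and f3 (∥)
    n_perp = n_par = 0
    for seed in range(500):
        ev = af.attempt_binding(st, 0, 1, dt=0.05, seed=seed)
        if ev:
            if ev["filament"] == 1:
                n_perp += 1
            elif ev["filament"] == 2:
                n_par += 1
            af.unbind_head(st, 0, 1)
            st.head_pos[0, 1] = [0.05, 0.05]
    assert n_par > 20
    assert n_perp == 0


def test_alpha_actinin_binds_regardless_of_angle(two_species):
    f1 = af.Filament(np.array([[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0]]))
    f2 = af.Filament(np.array([[0.3, -1.0], [0.3, 0.0], [0.3, 1.0]]))
    st = af.SystemState.from_components(
        [f1, f2], [af.Crosslinker("alpha_actinin", np.zeros((2, 2)))],
        two_species)
    af.bind_head(st, 0, 0, 0, 1, 0.0)
    st.head_pos[0, 1] = [0.3, 0.3]
    n_perp = 0
    for seed in range(500):
        ev = af.attempt_binding(st, 0, 1, dt=0.5, seed=seed)
        if ev and ev["filament"] == 1:
            n_perp += 1
            af.unbind_head(st, 0, 1)
            st.head_pos[0, 1] = [0.3, 0.3]
    assert n_perp > 20


def test_forced_hub_binding_gives_single_bin_pdf(two_species):
    """Crosslinkers force-bound at a central hub → one-bin spike grid."""
    scaffold = af.generate_aster_scaffold(4, r_c=15.0, hub="center", seed=3)
    xls = [af.Crosslinker("alpha_actinin", np.zeros((2, 2)))
           for _ in range(7)]
    st = af.SystemState.from_components(
        [scaffold.filament(i) for i in range(scaffold.n_filaments)],
        xls, two_species, scaffold.filament_params, scaffold.confinement)
    mid = (st.fil_off[1] - st.fil_off[0]) // 2
    for i in range(7):
        af.bind_head(st, i, 0, 0, mid, 0.01)
        af.bind_head(st, i, 1, 1, mid, 0.01)
    grid = bound_crosslinker_pdf(st, "alpha_actinin", n_bins=20)
    assert grid.n_samples == 7
    assert (grid.values > 0).sum() == 1
    assert grid.values.max() == pytest.approx(1.0 / grid.bin_area)
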