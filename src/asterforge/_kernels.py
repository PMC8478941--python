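"""Numba inner loops: forces, Langevin update, and the kMC sweep.

Everything here operates on the packed arrays owned by
:class:`asterforge.state.SystemState`.  The kMC functions draw their own
random numbers from numba's internal RNG, seeded once per run via
:func:`seed_kmc_rng`; the Langevin update consumes externally generated
Gaussian noise so the integrator remains controllable from Python.
"""
import numpy as np
from numba import njit

# exponent clip for the unbinding rate factor exp(+E/kBT); keeps the
# per-step probability finite, the probability itself is capped at 1.
_EXP_CLIP = 50.0


@njit(cache=True)
def seed_kmc_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def compute_forces(bead_pos, fil_off, l0, ks, kb, rc, kc,
                   head_pos, bound, bfil, blink, bfrac, species_id,
                   sp_l, sp_kappa, sp_kalign):
    """Analytic gradients of the total potential energy.

    Returns ``(f_bead, f_head)``; forces on bound heads are transmitted
    to the beads of their link by lever-rule weights and the ``f_head``
    entry stays zero.
    """
    B = bead_pos.shape[0]
    F = fil_off.shape[0] - 1
    X = head_pos.shape[0]
    f_bead = np.zeros((B, 2))
    f_head = np.zeros((X, 2, 2))

    # filaments: stretch, bend, confinement
    for f in range(F):
        a0, a1 = fil_off[f], fil_off[f + 1]
        for a in range(a0, a1 - 1):
            dx = bead_pos[a + 1, 0] - bead_pos[a, 0]
            dy = bead_pos[a + 1, 1] - bead_pos[a, 1]
            L = np.sqrt(dx * dx + dy * dy)
            if L > 1e-12:
                c = ks * (L - l0) / L
                f_bead[a, 0] += c * dx
                f_bead[a, 1] += c * dy
                f_bead[a + 1, 0] -= c * dx
                f_bead[a + 1, 1] -= c * dy
        for m in range(a0 + 1, a1 - 1):
            ux = bead_pos[m, 0] - bead_pos[m - 1, 0]
            uy = bead_pos[m, 1] - bead_pos[m - 1, 1]
            vx = bead_pos[m + 1, 0] - bead_pos[m, 0]
            vy = bead_pos[m + 1, 1] - bead_pos[m, 1]
            u2 = ux * ux + uy * uy
            v2 = vx * vx + vy * vy
            if u2 < 1e-24 or v2 < 1e-24:
                continue
            theta = np.arctan2(ux * vy - uy * vx, ux * vx + uy * vy)
            # dtheta/dr for the three beads
            g1x, g1y = -uy / u2, ux / u2
            g3x, g3y = -vy / v2, vx / v2
            coef = -kb * theta
            f_bead[m - 1, 0] += coef * g1x
            f_bead[m - 1, 1] += coef * g1y
            f_bead[m + 1, 0] += coef * g3x
            f_bead[m + 1, 1] += coef * g3y
            f_bead[m, 0] += coef * (-(g1x + g3x))
            f_bead[m, 1] += coef * (-(g1y + g3y))
    if kc > 0.0:
        for a in range(B):
            r = np.sqrt(bead_pos[a, 0] ** 2 + bead_pos[a, 1] ** 2)
            if r >= rc and r > 1e-12:
                c = -kc * (r - rc) / r
                f_bead[a, 0] += c * bead_pos[a, 0]
                f_bead[a, 1] += c * bead_pos[a, 1]

    # crosslinkers: spring, head confinement, alignment
    for i in range(X):
        sid = species_id[i]
        l = sp_l[sid]
        kappa = sp_kappa[sid]
        # effective head positions
        hx = np.empty(2)
        hy = np.empty(2)
        for h in range(2):
            if bound[i, h]:
                a = fil_off[bfil[i, h]] + blink[i, h]
                u = bfrac[i, h]
                hx[h] = (1.0 - u) * bead_pos[a, 0] + u * bead_pos[a + 1, 0]
                hy[h] = (1.0 - u) * bead_pos[a, 1] + u * bead_pos[a + 1, 1]
            else:
                hx[h] = head_pos[i, h, 0]
                hy[h] = head_pos[i, h, 1]
        dx = hx[1] - hx[0]
        dy = hy[1] - hy[0]
        d = np.sqrt(dx * dx + dy * dy)
        for h in range(2):
            fx = 0.0
            fy = 0.0
            if d > 1e-12:
                c = kappa * (d - l) / d
                if h == 0:
                    fx += c * dx
                    fy += c * dy
                else:
                    fx -= c * dx
                    fy -= c * dy
            if kc > 0.0:
                r = np.sqrt(hx[h] ** 2 + hy[h] ** 2)
                if r >= rc and r > 1e-12:
                    cc = -kc * (r - rc) / r
                    fx += cc * hx[h]
                    fy += cc * hy[h]
            if bound[i, h]:
                a = fil_off[bfil[i, h]] + blink[i, h]
                u = bfrac[i, h]
                f_bead[a, 0] += (1.0 - u) * fx
                f_bead[a, 1] += (1.0 - u) * fy
                f_bead[a + 1, 0] += u * fx
                f_bead[a + 1, 1] += u * fy
            else:
                f_head[i, h, 0] += fx
                f_head[i, h, 1] += fy
        # alignment between the two bound links
        kal = sp_kalign[sid]
        if kal > 0.0 and bound[i, 0] and bound[i, 1]:
            a = fil_off[bfil[i, 0]] + blink[i, 0]
            b = fil_off[bfil[i, 1]] + blink[i, 1]
            ux = bead_pos[a + 1, 0] - bead_pos[a, 0]
            uy = bead_pos[a + 1, 1] - bead_pos[a, 1]
            vx = bead_pos[b + 1, 0] - bead_pos[b, 0]
            vy = bead_pos[b + 1, 1] - bead_pos[b, 1]
            nu = np.sqrt(ux * ux + uy * uy)
            nv = np.sqrt(vx * vx + vy * vy)
            if nu > 1e-12 and nv > 1e-12:
                cth = (ux * vx + uy * vy) / (nu * nv)
                # dU/du = -kal * dc/du ; F = -dU/dr
                dcdux = vx / (nu * nv) - cth * ux / (nu * nu)
                dcduy = vy / (nu * nv) - cth * uy / (nu * nu)
                dcdvx = ux / (nu * nv) - cth * vx / (nv * nv)
                dcdvy = uy / (nu * nv) - cth * vy / (nv * nv)
                # F_a = -dU/dr_a = -(dU/du)(du/dr_a) = +dU/du = -kal*dc/du... sign:
                # U = kal(1-c) -> dU/du = -kal*dc/du; du/dr_a = -I, du/dr_{a+1} = +I
                f_bead[a, 0] += -kal * dcdux
                f_bead[a, 1] += -kal * dcduy
                f_bead[a + 1, 0] += kal * dcdux
                f_bead[a + 1, 1] += kal * dcduy
                f_bead[b, 0] += -kal * dcdvx
                f_bead[b, 1] += -kal * dcdvy
                f_bead[b + 1, 0] += kal * dcdvx
                f_bead[b + 1, 1] += kal * dcdvy
    return f_bead, f_head


@njit(cache=True)
def apply_langevin(bead_pos, fil_off, head_pos, bound, bfil, blink, bfrac,
                   f_bead, f_head, dt, gamma_bead, gamma_head, kBT,
                   noise_bead, noise_head):
    """Euler–Maruyama overdamped update; returns the max displacement.

    Bound heads are not free coordinates: after the bead update they are
    snapped back onto their (possibly moved) attachment points.
    """
    B = bead_pos.shape[0]
    X = head_pos.shape[0]
    sb = np.sqrt(2.0 * kBT * dt / gamma_bead)
    sh = np.sqrt(2.0 * kBT * dt / gamma_head)
    mb = dt / gamma_bead
    mh = dt / gamma_head
    max_disp = 0.0
    for a in range(B):
        for k in range(2):
            d = f_bead[a, k] * mb + sb * noise_bead[a, k]
            bead_pos[a, k] += d
            if np.abs(d) > max_disp:
                max_disp = np.abs(d)
    for i in range(X):
        for h in range(2):
            if bound[i, h]:
                a = fil_off[bfil[i, h]] + blink[i, h]
                u = bfrac[i, h]
                head_pos[i, h, 0] = ((1.0 - u) * bead_pos[a, 0]
                                     + u * bead_pos[a + 1, 0])
                head_pos[i, h, 1] = ((1.0 - u) * bead_pos[a, 1]
                                     + u * bead_pos[a + 1, 1])
            else:
                for k in range(2):
                    d = f_head[i, h, k] * mh + sh * noise_head[i, h, k]
                    head_pos[i, h, k] += d
                    if np.abs(d) > max_disp:
                        max_disp = np.abs(d)
    return max_disp


@njit(cache=True)
def _partner_effective(i, h, bead_pos, fil_off, head_pos, bound, bfil,
                       blink, bfrac):
    hp = 1 - h
    if bound[i, hp]:
        a = fil_off[bfil[i, hp]] + blink[i, hp]
        u = bfrac[i, hp]
        return ((1.0 - u) * bead_pos[a, 0] + u * bead_pos[a + 1, 0],
                (1.0 - u) * bead_pos[a, 1] + u * bead_pos[a + 1, 1])
    return head_pos[i, hp, 0], head_pos[i, hp, 1]


@njit(cache=True)
def _link_cos(a, b, bead_pos):
    ux = bead_pos[a + 1, 0] - bead_pos[a, 0]
    uy = bead_pos[a + 1, 1] - bead_pos[a, 1]
    vx = bead_pos[b + 1, 0] - bead_pos[b, 0]
    vy = bead_pos[b + 1, 1] - bead_pos[b, 1]
    nu = np.sqrt(ux * ux + uy * uy)
    nv = np.sqrt(vx * vx + vy * vy)
    if nu < 1e-12 or nv < 1e-12:
        return 1.0
    return (ux * vx + uy * vy) / (nu * nv)


@njit(cache=True)
def _kmc_head(i, h, bead_pos, fil_off, head_pos, bound, bfil, blink, bfrac,
              species_id, sp_l, sp_kappa, sp_kon, sp_koff, sp_kalign,
              sp_capr, sp_oc, l0, dt, kBT,
              cand_f, cand_j, cand_u, cand_x, cand_y):
    """Attempt one binding or unbinding event for head (i, h).

    Returns +1 on a binding event, -1 on an unbinding event, 0 otherwise.
    """
    sid = species_id[i]
    l = sp_l[sid]
    kappa = sp_kappa[sid]
    kal = sp_kalign[sid]
    hp = 1 - h

    if bound[i, h]:
        p_off = 1.0 - np.exp(-sp_koff[sid] * dt)
        # stored mechanical energy relative to a relaxed spring
        qx, qy = _partner_effective(i, h, bead_pos, fil_off, head_pos,
                                    bound, bfil, blink, bfrac)
        dx = head_pos[i, h, 0] - qx
        dy = head_pos[i, h, 1] - qy
        d = np.sqrt(dx * dx + dy * dy)
        E = 0.5 * kappa * (d - l) ** 2
        if kal > 0.0 and bound[i, hp]:
            a = fil_off[bfil[i, h]] + blink[i, h]
            b = fil_off[bfil[i, hp]] + blink[i, hp]
            E += kal * (1.0 - _link_cos(a, b, bead_pos))
        ex = E / kBT
        if ex > _EXP_CLIP:
            ex = _EXP_CLIP
        p = p_off * np.exp(ex)
        if p > 1.0:
            p = 1.0
        if np.random.random() < p:
            bound[i, h] = 0
            bfil[i, h] = -1
            blink[i, h] = -1
            bfrac[i, h] = 0.0
            return -1
        return 0

    # unbound: gate on the nominal on-rate first
    if np.random.random() >= 1.0 - np.exp(-sp_kon[sid] * dt):
        return 0
    capr2 = sp_capr[sid] * sp_capr[sid]
    oc = sp_oc[sid]
    px = head_pos[i, h, 0]
    py = head_pos[i, h, 1]
    ncand = 0
    F = fil_off.shape[0] - 1
    for f in range(F):
        a0, a1 = fil_off[f], fil_off[f + 1]
        for a in range(a0, a1 - 1):
            ex_ = bead_pos[a + 1, 0] - bead_pos[a, 0]
            ey_ = bead_pos[a + 1, 1] - bead_pos[a, 1]
            L2 = ex_ * ex_ + ey_ * ey_
            if L2 < 1e-24:
                continue
            u = ((px - bead_pos[a, 0]) * ex_ + (py - bead_pos[a, 1]) * ey_) / L2
            if u < 0.0:
                u = 0.0
            elif u > 1.0:
                u = 1.0
            sx = bead_pos[a, 0] + u * ex_
            sy = bead_pos[a, 1] + u * ey_
            dd = (px - sx) ** 2 + (py - sy) ** 2
            if dd > capr2:
                continue
            j = a - a0
            # occupancy rule: both heads on one filament only if their
            # attachment separation along it exceeds o_c
            if bound[i, hp] and bfil[i, hp] == f:
                arc_here = (j + u) * l0
                arc_partner = (blink[i, hp] + bfrac[i, hp]) * l0
                if np.abs(arc_here - arc_partner) <= oc:
                    continue
            cand_f[ncand] = f
            cand_j[ncand] = j
            cand_u[ncand] = u
            cand_x[ncand] = sx
            cand_y[ncand] = sy
            ncand += 1
    if ncand == 0:
        return 0
    pick = int(np.random.random() * ncand)
    if pick >= ncand:
        pick = ncand - 1
    sx = cand_x[pick]
    sy = cand_y[pick]
    qx, qy = _partner_effective(i, h, bead_pos, fil_off, head_pos,
                                bound, bfil, blink, bfrac)
    d_new = np.sqrt((sx - qx) ** 2 + (sy - qy) ** 2)
    d_old = np.sqrt((px - qx) ** 2 + (py - qy) ** 2)
    dU = 0.5 * kappa * ((d_new - l) ** 2 - (d_old - l) ** 2)
    if kal > 0.0 and bound[i, hp]:
        a = fil_off[cand_f[pick]] + cand_j[pick]
        b = fil_off[bfil[i, hp]] + blink[i, hp]
        dU += kal * (1.0 - _link_cos(a, b, bead_pos))
    if dU > 0.0 and np.random.random() >= np.exp(-dU / kBT):
        return 0
    bound[i, h] = 1
    bfil[i, h] = cand_f[pick]
    blink[i, h] = cand_j[pick]
    bfrac[i, h] = cand_u[pick]
    head_pos[i, h, 0] = sx
    head_pos[i, h, 1] = sy
    return 1


@njit(cache=True)
def kmc_sweep(bead_pos, fil_off, head_pos, bound, bfil, blink, bfrac,
              species_id, active, sp_l, sp_kappa, sp_kon, sp_koff,
              sp_kalign, sp_capr, sp_oc, l0, dt, kBT):
    """One binding/unbinding attempt per active head; returns net events."""
    B = bead_pos.shape[0]
    F = fil_off.shape[0] - 1
    max_links = B - F if B > F else 1
    cand_f = np.empty(max_links, dtype=np.int64)
    cand_j = np.empty(max_links, dtype=np.int64)
    cand_u = np.empty(max_links)
    cand_x = np.empty(max_links)
    cand_y = np.empty(max_links)
    nev = 0
    for i in range(head_pos.shape[0]):
        for h in range(2):
            if active[i, h]:
                nev += _kmc_head(i, h, bead_pos, fil_off, head_pos, bound,
                                 bfil, blink, bfrac, species_id, sp_l,
                                 sp_kappa, sp_kon, sp_koff, sp_kalign,
                                 sp_capr, sp_oc, l0, dt, kBT,
                                 cand_f, cand_j, cand_u, cand_x, cand_y)
    return nev


@njit(cache=True)
def kmc_only_run(bead_pos, fil_off, head_pos, bound, bfil, blink, bfrac,
                 species_id, active, sp_l, sp_kappa, sp_kon, sp_koff,
                 sp_kalign, sp_capr, sp_oc, l0, dt, kBT,
                 n_steps, watch_i, watch_h):
    """Run only the kMC (positions frozen) for ``n_steps`` steps.

    Returns (steps_bound, steps_unbound, n_bind, n_unbind) for the
    watched head, counting the state after each step.
    """
    B = bead_pos.shape[0]
    F = fil_off.shape[0] - 1
    max_links = B - F if B > F else 1
    cand_f = np.empty(max_links, dtype=np.int64)
    cand_j = np.empty(max_links, dtype=np.int64)
    cand_u = np.empty(max_links)
    cand_x = np.empty(max_links)
    cand_y = np.empty(max_links)
    steps_bound = 0
    n_bind = 0
    n_unbind = 0
    for _ in range(n_steps):
        for i in range(head_pos.shape[0]):
            for h in range(2):
                if active[i, h]:
                    ev = _kmc_head(i, h, bead_pos, fil_off, head_pos, bound,
                                   bfil, blink, bfrac, species_id, sp_l,
                                   sp_kappa, sp_kon, sp_koff, sp_kalign,
                                   sp_capr, sp_oc, l0, dt, kBT,
                                   cand_f, cand_j, cand_u, cand_x, cand_y)
                    if ev == 1:
                        n_bind += 1
                    elif ev == -1:
                        n_unbind += 1
        if bound[watch_i, watch_h]:
            steps_bound += 1
    return steps_bound, n_steps - steps_bound, n_bind, n_unbind
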