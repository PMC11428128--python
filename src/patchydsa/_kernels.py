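"""Compiled inner loops for the MC and BD engines (numba).

Everything here operates on plain float64/int64 arrays; the object-level API
in mc.py / bd.py converts to and from the dataclass containers.  Species
codes, bond-rule codes and stop-mode codes match the enums in model.py / mc.py:

  species: 0 = alpha, 1 = beta, 2 = crowder
  rule:    0 = one-state, 1 = two-state
  stop:    0 = fixed budget, 1 = first assembly, 2 = first disassembly

Pair bond counting is pairwise (at most one bond per particle pair).  Under
the default narrow-patch geometry (cos_theta_max = 0.95, lambda_range = 1.1)
the hard core makes it impossible for one patch to satisfy the bonding
criterion with two partners at once, so pairwise counting coincides with the
slot-resolved bond graph built in observables.py.
"""

import numpy as np
from numba import njit

# status codes returned by the kernels
OK = 0
ERR_INITIAL_OVERLAP = 1
ERR_ENERGY_DRIFT = 2
ERR_BAD_INITIAL = 3
ERR_NONFINITE = 4

SP_CROWDER = 2


# ---------------------------------------------------------------------------
# small math helpers
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _mi(x, e):
    """Minimum-image component for box edge e."""
    return x - e * np.floor(x / e + 0.5)


@njit(cache=True)
def _quat_to_mat(q, m):
    """Rotation matrix of a scalar-first unit quaternion into m (3x3)."""
    w, x, y, z = q[0], q[1], q[2], q[3]
    m[0, 0] = 1.0 - 2.0 * (y * y + z * z)
    m[0, 1] = 2.0 * (x * y - w * z)
    m[0, 2] = 2.0 * (x * z + w * y)
    m[1, 0] = 2.0 * (x * y + w * z)
    m[1, 1] = 1.0 - 2.0 * (x * x + z * z)
    m[1, 2] = 2.0 * (y * z - w * x)
    m[2, 0] = 2.0 * (x * z - w * y)
    m[2, 1] = 2.0 * (y * z + w * x)
    m[2, 2] = 1.0 - 2.0 * (x * x + y * y)


@njit(cache=True)
def _quat_mul(a, b, out):
    """out = a * b (scalar-first)."""
    aw, ax, ay, az = a[0], a[1], a[2], a[3]
    bw, bx, by, bz = b[0], b[1], b[2], b[3]
    out[0] = aw * bw - ax * bx - ay * by - az * bz
    out[1] = aw * bx + ax * bw + ay * bz - az * by
    out[2] = aw * by - ax * bz + ay * bw + az * bx
    out[3] = aw * bz + ax * by - ay * bx + az * bw


@njit(cache=True)
def _patch_dirs(q, patches, out):
    """Lab-frame patch directions (2,3) for quaternion q."""
    m = np.empty((3, 3))
    _quat_to_mat(q, m)
    for p in range(2):
        for i in range(3):
            out[p, i] = (
                m[i, 0] * patches[p, 0] + m[i, 1] * patches[p, 1] + m[i, 2] * patches[p, 2]
            )


@njit(cache=True, inline="always")
def _rule_permits(si, sj, rule):
    if si == SP_CROWDER or sj == SP_CROWDER:
        return False
    if rule == 0:
        return si == 0 and sj == 0
    return (si == 0 and sj == 1) or (si == 1 and sj == 0)


@njit(cache=True)
def _pair_status(
    dx, dy, dz, pdi, pdj, si, sj, sigma, lam_sigma, cmax, rule, hard_lower
):
    """-1 overlap, 1 bonded, 0 otherwise.

    pdi/pdj: (2,3) lab-frame patch directions of the two particles.
    hard_lower: require r >= sigma for bonding (square-well MC); the BD
    detector disables it because the soft core allows slight interpenetration.
    """
    r2 = dx * dx + dy * dy + dz * dz
    if hard_lower and r2 < sigma * sigma:
        return -1
    if r2 >= lam_sigma * lam_sigma:
        return 0
    if not _rule_permits(si, sj, rule):
        return 0
    r = np.sqrt(r2)
    if r <= 0.0:
        return 0
    ux, uy, uz = dx / r, dy / r, dz / r
    oki = False
    for p in range(2):
        if pdi[p, 0] * ux + pdi[p, 1] * uy + pdi[p, 2] * uz >= cmax:
            oki = True
            break
    if not oki:
        return 0
    for p in range(2):
        if -(pdj[p, 0] * ux + pdj[p, 1] * uy + pdj[p, 2] * uz) >= cmax:
            return 1
    return 0


@njit(cache=True)
def _env_bonds(
    i, px, py, pz, pos, pdirs, species, edge, sigma, lam_sigma, cmax, rule
):
    """Bond count of particle i at trial position (px,py,pz) against all others.

    Returns (n_bonds, overlap). Uses pdirs[i] as i's (possibly trial) patch
    directions -- the caller swaps them in for rotation trials.  Fully scalar
    inner loop: this is the hot path of the MC kernel.
    """
    n = pos.shape[0]
    nb = 0
    si = species[i]
    ex, ey, ez = edge[0], edge[1], edge[2]
    s2 = sigma * sigma
    l2 = lam_sigma * lam_sigma
    a0x, a0y, a0z = pdirs[i, 0, 0], pdirs[i, 0, 1], pdirs[i, 0, 2]
    a1x, a1y, a1z = pdirs[i, 1, 0], pdirs[i, 1, 1], pdirs[i, 1, 2]
    for j in range(n):
        if j == i:
            continue
        dx = pos[j, 0] - px
        dx -= ex * np.floor(dx / ex + 0.5)
        dy = pos[j, 1] - py
        dy -= ey * np.floor(dy / ey + 0.5)
        dz = pos[j, 2] - pz
        dz -= ez * np.floor(dz / ez + 0.5)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < s2:
            return 0, True
        if r2 >= l2:
            continue
        sj = species[j]
        if not _rule_permits(si, sj, rule):
            continue
        r = np.sqrt(r2)
        ux, uy, uz = dx / r, dy / r, dz / r
        if (a0x * ux + a0y * uy + a0z * uz) < cmax and (
            a1x * ux + a1y * uy + a1z * uz
        ) < cmax:
            continue
        if -(pdirs[j, 0, 0] * ux + pdirs[j, 0, 1] * uy + pdirs[j, 0, 2] * uz) >= cmax or -(
            pdirs[j, 1, 0] * ux + pdirs[j, 1, 1] * uy + pdirs[j, 1, 2] * uz
        ) >= cmax:
            nb += 1
    return nb, False


@njit(cache=True)
def _total_bonds(pos, pdirs, species, edge, sigma, lam_sigma, cmax, rule, hard_lower):
    """Total pairwise bond count; returns (n_bonds, overlap)."""
    n = pos.shape[0]
    nb = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _mi(pos[j, 0] - pos[i, 0], edge[0])
            dy = _mi(pos[j, 1] - pos[i, 1], edge[1])
            dz = _mi(pos[j, 2] - pos[i, 2], edge[2])
            st = _pair_status(
                dx, dy, dz, pdirs[i], pdirs[j], species[i], species[j],
                sigma, lam_sigma, cmax, rule, hard_lower,
            )
            if st == -1 and hard_lower:
                return 0, True
            if st == 1:
                nb += 1
    return nb, False


@njit(cache=True)
def _is_target(pos, pdirs, species, edge, sigma, lam_sigma, cmax, rule, hard_lower, n_target):
    """Single cycle through all patchy particles with all patch slots used.

    Alpha/beta alternation is automatic when rule == two-state, since only
    alpha-beta contacts count as bonds.
    """
    n = pos.shape[0]
    # adjacency limited to degree 2; a third neighbour disqualifies
    nb1 = np.full(n, -1, dtype=np.int64)
    nb2 = np.full(n, -1, dtype=np.int64)
    n_edges = 0
    n_patchy = 0
    for i in range(n):
        if species[i] != SP_CROWDER:
            n_patchy += 1
    for i in range(n):
        if species[i] == SP_CROWDER:
            continue
        for j in range(i + 1, n):
            if species[j] == SP_CROWDER:
                continue
            dx = _mi(pos[j, 0] - pos[i, 0], edge[0])
            dy = _mi(pos[j, 1] - pos[i, 1], edge[1])
            dz = _mi(pos[j, 2] - pos[i, 2], edge[2])
            st = _pair_status(
                dx, dy, dz, pdirs[i], pdirs[j], species[i], species[j],
                sigma, lam_sigma, cmax, rule, hard_lower,
            )
            if st == 1:
                n_edges += 1
                if nb1[i] == -1:
                    nb1[i] = j
                elif nb2[i] == -1:
                    nb2[i] = j
                else:
                    return False
                if nb1[j] == -1:
                    nb1[j] = i
                elif nb2[j] == -1:
                    nb2[j] = i
                else:
                    return False
    if n_edges != n_target or n_patchy != n_target:
        return False
    # every patchy particle must have degree exactly 2
    start = -1
    for i in range(n):
        if species[i] == SP_CROWDER:
            continue
        if nb1[i] == -1 or nb2[i] == -1:
            return False
        if start == -1:
            start = i
    # walk the cycle
    prev = start
    cur = nb1[start]
    count = 1
    while cur != start and count <= n_target:
        nxt = nb1[cur] if nb1[cur] != prev else nb2[cur]
        prev = cur
        cur = nxt
        count += 1
    return cur == start and count == n_target


# ---------------------------------------------------------------------------
# Monte Carlo kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def run_mc_kernel(
    pos,
    quat,
    species,
    patches,
    eps_patch,
    sigma,
    lam_sigma,
    cmax,
    rule,
    kT,
    eps_drive,
    max_tr,
    max_rot,
    p_tr,
    edge,
    budget,
    record_every,
    stop_mode,
    n_target,
    drift_every,
    seed,
):
    """Metropolis MC with the target-bond drive bias on acceptance.

    Mutates pos/quat in place.  Returns
      (status, rec_count, rec_step, rec_nb, rec_S,
       event_step, censored, n_accepted, sum_abs_dn, S_final, nb_final)

    Energy series is -eps_patch * rec_nb (square-well: energy is bond count
    times the well depth).  The drive modifies the acceptance ratio only:
    arg = (dE - eps_drive * dn) / kT with dE = -eps_patch * dn the physical
    energy change of the trial; stored energy stays the undriven energy.
    """
    np.random.seed(seed)
    n = pos.shape[0]
    nrec = budget // record_every + 2
    rec_step = np.empty(nrec, dtype=np.int64)
    rec_nb = np.empty(nrec, dtype=np.int64)
    rec_S = np.empty(nrec)
    # lab-frame patch directions, maintained incrementally
    pdirs = np.zeros((n, 2, 3))
    for i in range(n):
        if species[i] != SP_CROWDER:
            _patch_dirs(quat[i], patches, pdirs[i])

    nb_total, overlap = _total_bonds(
        pos, pdirs, species, edge, sigma, lam_sigma, cmax, rule, True
    )
    if overlap:
        return (ERR_INITIAL_OVERLAP, 0, rec_step, rec_nb, rec_S,
                np.int64(-1), True, np.int64(0), np.int64(0), 0.0, np.int64(0))
    if stop_mode == 2 and nb_total < n_target:
        return (ERR_BAD_INITIAL, 0, rec_step, rec_nb, rec_S,
                np.int64(-1), True, np.int64(0), np.int64(0), 0.0, np.int64(0))

    S = 0.0
    n_accepted = np.int64(0)
    sum_abs_dn = np.int64(0)
    rec_count = 0
    rec_step[0] = 0
    rec_nb[0] = nb_total
    rec_S[0] = 0.0
    rec_count = 1

    event_step = np.int64(-1)
    censored = True
    if stop_mode == 1 and nb_total == n_target:
        if _is_target(pos, pdirs, species, edge, sigma, lam_sigma, cmax, rule, True, n_target):
            event_step = np.int64(0)
            censored = False

    trial_pd = np.zeros((2, 3))
    save_pd = np.zeros((2, 3))
    dq = np.empty(4)
    qnew = np.empty(4)

    step = np.int64(0)
    while step < budget and (censored or stop_mode == 0):
        step += 1
        i = np.random.randint(0, n)
        is_crowder = species[i] == SP_CROWDER
        do_translate = is_crowder or (np.random.random() < p_tr)

        nb_old, _ = _env_bonds(
            i, pos[i, 0], pos[i, 1], pos[i, 2],
            pos, pdirs, species, edge, sigma, lam_sigma, cmax, rule,
        )

        if do_translate:
            px = pos[i, 0] + (2.0 * np.random.random() - 1.0) * max_tr
            py = pos[i, 1] + (2.0 * np.random.random() - 1.0) * max_tr
            pz = pos[i, 2] + (2.0 * np.random.random() - 1.0) * max_tr
            nb_new, ov = _env_bonds(
                i, px, py, pz, pos, pdirs, species, edge, sigma, lam_sigma, cmax, rule
            )
        else:
            # uniform random axis, angle uniform in [0, max_rot)
            ax = np.random.standard_normal()
            ay = np.random.standard_normal()
            az = np.random.standard_normal()
            norm = np.sqrt(ax * ax + ay * ay + az * az)
            if norm < 1e-12:
                ax, ay, az, norm = 1.0, 0.0, 0.0, 1.0
            ang = np.random.random() * max_rot
            s = np.sin(0.5 * ang) / norm
            dq[0] = np.cos(0.5 * ang)
            dq[1] = ax * s
            dq[2] = ay * s
            dq[3] = az * s
            _quat_mul(dq, quat[i], qnew)
            qn = np.sqrt(qnew[0] ** 2 + qnew[1] ** 2 + qnew[2] ** 2 + qnew[3] ** 2)
            for k in range(4):
                qnew[k] /= qn
            _patch_dirs(qnew, patches, trial_pd)
            for p in range(2):
                for k in range(3):
                    save_pd[p, k] = pdirs[i, p, k]
                    pdirs[i, p, k] = trial_pd[p, k]
            px, py, pz = pos[i, 0], pos[i, 1], pos[i, 2]
            nb_new, ov = _env_bonds(
                i, px, py, pz, pos, pdirs, species, edge, sigma, lam_sigma, cmax, rule
            )

        accepted = False
        if not ov:
            dn = nb_new - nb_old
            dE = -eps_patch * dn
            arg = (dE - eps_drive * dn) / kT
            if arg <= 0.0 or np.random.random() < np.exp(-arg):
                accepted = True
                pos[i, 0] = _mi(px - edge[0] * 0.5, edge[0]) + edge[0] * 0.5
                pos[i, 1] = _mi(py - edge[1] * 0.5, edge[1]) + edge[1] * 0.5
                pos[i, 2] = _mi(pz - edge[2] * 0.5, edge[2]) + edge[2] * 0.5
                if not do_translate:
                    for k in range(4):
                        quat[i, k] = qnew[k]
                nb_total += dn
                n_accepted += 1
                if dn != 0:
                    sum_abs_dn += abs(dn)
                    S += eps_drive * abs(dn) / kT
                if stop_mode == 1 and dn > 0 and nb_total == n_target:
                    if _is_target(pos, pdirs, species, edge, sigma, lam_sigma,
                                  cmax, rule, True, n_target):
                        event_step = step
                        censored = False
                elif stop_mode == 2 and nb_total < n_target:
                    event_step = step
                    censored = False
        if not accepted and not do_translate:
            for p in range(2):
                for k in range(3):
                    pdirs[i, p, k] = save_pd[p, k]

        if step % record_every == 0:
            rec_step[rec_count] = step
            rec_nb[rec_count] = nb_total
            rec_S[rec_count] = S
            rec_count += 1

        if step % drift_every == 0:
            nb_check, _ = _total_bonds(
                pos, pdirs, species, edge, sigma, lam_sigma, cmax, rule, True
            )
            if nb_check != nb_total:
                return (ERR_ENERGY_DRIFT, rec_count, rec_step, rec_nb, rec_S,
                        event_step, censored, n_accepted, sum_abs_dn, S, nb_total)

    # final bookkeeping check and final record
    nb_check, _ = _total_bonds(
        pos, pdirs, species, edge, sigma, lam_sigma, cmax, rule, True
    )
    if nb_check != nb_total:
        return (ERR_ENERGY_DRIFT, rec_count, rec_step, rec_nb, rec_S,
                event_step, censored, n_accepted, sum_abs_dn, S, nb_total)
    if rec_count == 0 or rec_step[rec_count - 1] != step:
        rec_step[rec_count] = step
        rec_nb[rec_count] = nb_total
        rec_S[rec_count] = S
        rec_count += 1
    return (OK, rec_count, rec_step, rec_nb, rec_S,
            event_step, censored, n_accepted, sum_abs_dn, S, nb_total)


# ---------------------------------------------------------------------------
# Brownian (Langevin) dynamics kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _bd_forces(
    pos, pdirs, species, edge, eps_t, sigma, rw, aw, eps_core, rule, F, T
):
    """Continuous patchy potential: WCA core + Gaussian-modulated attraction.

    E_pair = core(r) - eps_t * exp(-(r-sigma)^2/(2 rw^2)) * A(th_i) * A(th_j)
    with A(th) = exp(-th^2/(2 aw^2)) over the best patch pairing permitted by
    the bond rule.  Fills forces F (N,3) and torques T (N,3); returns E_total.
    """
    n = pos.shape[0]
    for i in range(n):
        for k in range(3):
            F[i, k] = 0.0
            T[i, k] = 0.0
    rc_core = 2.0 ** (1.0 / 6.0) * sigma
    rc_att = sigma + 5.0 * rw
    E = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = _mi(pos[j, 0] - pos[i, 0], edge[0])
            dy = _mi(pos[j, 1] - pos[i, 1], edge[1])
            dz = _mi(pos[j, 2] - pos[i, 2], edge[2])
            r2 = dx * dx + dy * dy + dz * dz
            if r2 > rc_att * rc_att and r2 > rc_core * rc_core:
                continue
            r = np.sqrt(r2)
            if r < 1e-10:
                return np.nan
            ux, uy, uz = dx / r, dy / r, dz / r
            # WCA core
            if r < rc_core:
                sr6 = (sigma / r) ** 6
                E += 4.0 * eps_core * (sr6 * sr6 - sr6) + eps_core
                fmag = 24.0 * eps_core * (2.0 * sr6 * sr6 - sr6) / r
                # repulsive: force on j along +u
                F[j, 0] += fmag * ux
                F[j, 1] += fmag * uy
                F[j, 2] += fmag * uz
                F[i, 0] -= fmag * ux
                F[i, 1] -= fmag * uy
                F[i, 2] -= fmag * uz
            if eps_t <= 0.0 or r >= rc_att:
                continue
            if not _rule_permits(species[i], species[j], rule):
                continue
            # best patch pairing by product of angular factors
            best = -1.0
            pa = -1
            pb = -1
            for a in range(2):
                ci = pdirs[i, a, 0] * ux + pdirs[i, a, 1] * uy + pdirs[i, a, 2] * uz
                for b in range(2):
                    cj = -(pdirs[j, b, 0] * ux + pdirs[j, b, 1] * uy + pdirs[j, b, 2] * uz)
                    ti = np.arccos(min(1.0, max(-1.0, ci)))
                    tj = np.arccos(min(1.0, max(-1.0, cj)))
                    sc = np.exp(-(ti * ti + tj * tj) / (2.0 * aw * aw))
                    if sc > best:
                        best = sc
                        pa = a
                        pb = b
            ci = pdirs[i, pa, 0] * ux + pdirs[i, pa, 1] * uy + pdirs[i, pa, 2] * uz
            cj = -(pdirs[j, pb, 0] * ux + pdirs[j, pb, 1] * uy + pdirs[j, pb, 2] * uz)
            ci = min(1.0, max(-1.0, ci))
            cj = min(1.0, max(-1.0, cj))
            ti = np.arccos(ci)
            tj = np.arccos(cj)
            Ai = np.exp(-ti * ti / (2.0 * aw * aw))
            Aj = np.exp(-tj * tj / (2.0 * aw * aw))
            g = np.exp(-(r - sigma) ** 2 / (2.0 * rw * rw))
            Eatt = -eps_t * g * Ai * Aj
            E += Eatt
            # radial part: dE/dr along u
            dEdr = -eps_t * Ai * Aj * g * (-(r - sigma) / (rw * rw))
            # angular parts: K(th) = th / (aw^2 sin th), series for small th
            si = np.sin(ti)
            Ki = (ti / si if si > 1e-8 else 1.0) / (aw * aw)
            sj = np.sin(tj)
            Kj = (tj / sj if sj > 1e-8 else 1.0) / (aw * aw)
            # dE/dci, dE/dcj (E = -eps g Ai Aj; dAi/dci = Ai * Ki)
            dEdci = -eps_t * g * Aj * Ai * Ki
            dEdcj = -eps_t * g * Ai * Aj * Kj
            # gradients w.r.t. d = r_j - r_i
            # ci = u_a . u,  dci/dd = (u_a - ci u)/r ; cj = -u_b . u
            dEdd_x = (dEdr * ux + dEdci * (pdirs[i, pa, 0] - ci * ux) / r
                      + dEdcj * (-pdirs[j, pb, 0] - cj * ux) / r)
            dEdd_y = (dEdr * uy + dEdci * (pdirs[i, pa, 1] - ci * uy) / r
                      + dEdcj * (-pdirs[j, pb, 1] - cj * uy) / r)
            dEdd_z = (dEdr * uz + dEdci * (pdirs[i, pa, 2] - ci * uz) / r
                      + dEdcj * (-pdirs[j, pb, 2] - cj * uz) / r)
            F[j, 0] -= dEdd_x
            F[j, 1] -= dEdd_y
            F[j, 2] -= dEdd_z
            F[i, 0] += dEdd_x
            F[i, 1] += dEdd_y
            F[i, 2] += dEdd_z
            # torques: tau = -u_patch x dE/du_patch; dE/du_a = dEdci * u
            tx = -(pdirs[i, pa, 1] * dEdci * uz - pdirs[i, pa, 2] * dEdci * uy)
            ty = -(pdirs[i, pa, 2] * dEdci * ux - pdirs[i, pa, 0] * dEdci * uz)
            tz = -(pdirs[i, pa, 0] * dEdci * uy - pdirs[i, pa, 1] * dEdci * ux)
            T[i, 0] += tx
            T[i, 1] += ty
            T[i, 2] += tz
            # dE/du_b = dEdcj * (-u)
            tx = -(pdirs[j, pb, 1] * (-dEdcj) * uz - pdirs[j, pb, 2] * (-dEdcj) * uy)
            ty = -(pdirs[j, pb, 2] * (-dEdcj) * ux - pdirs[j, pb, 0] * (-dEdcj) * uz)
            tz = -(pdirs[j, pb, 0] * (-dEdcj) * uy - pdirs[j, pb, 1] * (-dEdcj) * ux)
            T[j, 0] += tx
            T[j, 1] += ty
            T[j, 2] += tz
    return E


@njit(cache=True)
def _square_wave(t, baseline, amplitude, period):
    phase = t % period
    eps = baseline + amplitude if phase < 0.5 * period else baseline - amplitude
    return max(eps, 0.0)


@njit(cache=True)
def _advance_quat(quat, omega, dt, dq, qnew):
    """Rotate quaternion by lab-frame angular velocity over dt."""
    n = quat.shape[0]
    for i in range(n):
        wx, wy, wz = omega[i, 0], omega[i, 1], omega[i, 2]
        wnorm = np.sqrt(wx * wx + wy * wy + wz * wz)
        if wnorm < 1e-14:
            continue
        ang = wnorm * dt
        s = np.sin(0.5 * ang) / wnorm
        dq[0] = np.cos(0.5 * ang)
        dq[1] = wx * s
        dq[2] = wy * s
        dq[3] = wz * s
        _quat_mul(dq, quat[i], qnew)
        qn = np.sqrt(qnew[0] ** 2 + qnew[1] ** 2 + qnew[2] ** 2 + qnew[3] ** 2)
        for k in range(4):
            quat[i, k] = qnew[k] / qn


@njit(cache=True)
def run_bd_kernel(
    pos,
    quat,
    vel,
    omega,
    species,
    patches,
    baseline,
    amplitude,
    period,
    sigma,
    rw,
    aw,
    eps_core,
    rule,
    kT,
    mass,
    inertia,
    friction,
    dt,
    edge,
    n_steps,
    record_every,
    check_every,
    stop_mode,
    det_lam_sigma,
    det_cmax,
    n_target,
    seed,
):
    """Langevin dynamics (BAOAB) with a square-wave modulated patch attraction.

    Rotations use a spherical-top rotational Langevin scheme with lab-frame
    angular velocities.  Target detection applies the square-well geometric
    bonding criterion to the instantaneous configuration every ``check_every``
    steps.  Returns
      (status, rec_count, rec_t, rec_E, rec_nb, rec_KE,
       event_time, censored, final_time)
    """
    np.random.seed(seed)
    n = pos.shape[0]
    nrec = n_steps // record_every + 2
    rec_t = np.empty(nrec)
    rec_E = np.empty(nrec)
    rec_nb = np.empty(nrec, dtype=np.int64)
    rec_KE = np.empty(nrec)
    F = np.zeros((n, 3))
    T = np.zeros((n, 3))
    pdirs = np.zeros((n, 2, 3))
    dq = np.empty(4)
    qnew = np.empty(4)

    c1 = np.exp(-friction * dt)
    c2v = np.sqrt((1.0 - c1 * c1) * kT / mass)
    c2w = np.sqrt((1.0 - c1 * c1) * kT / inertia)

    for i in range(n):
        if species[i] != SP_CROWDER:
            _patch_dirs(quat[i], patches, pdirs[i])

    t = 0.0
    eps_t = _square_wave(t, baseline, amplitude, period)
    E = _bd_forces(pos, pdirs, species, edge, eps_t, sigma, rw, aw, eps_core, rule, F, T)
    if not np.isfinite(E):
        return (ERR_NONFINITE, 0, rec_t, rec_E, rec_nb, rec_KE, -1.0, True, 0.0)

    nb, _ = _total_bonds(
        pos, pdirs, species, edge, sigma, det_lam_sigma, det_cmax, rule, False
    )
    rec_t[0] = 0.0
    rec_E[0] = E
    rec_nb[0] = nb
    ke = 0.0
    for i in range(n):
        ke += 0.5 * mass * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
    rec_KE[0] = ke
    rec_count = 1

    event_time = -1.0
    censored = True
    if stop_mode == 1 and nb == n_target:
        if _is_target(pos, pdirs, species, edge, sigma, det_lam_sigma, det_cmax,
                      rule, False, n_target):
            event_time = 0.0
            censored = False
    if stop_mode == 2 and nb < n_target:
        return (ERR_BAD_INITIAL, rec_count, rec_t, rec_E, rec_nb, rec_KE, -1.0, True, 0.0)

    step = 0
    while step < n_steps and (censored or stop_mode == 0):
        step += 1
        half = 0.5 * dt / mass
        halfw = 0.5 * dt / inertia
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * F[i, k]
                omega[i, k] += halfw * T[i, k]
        # A
        for i in range(n):
            for k in range(3):
                pos[i, k] += 0.5 * dt * vel[i, k]
        _advance_quat(quat, omega, 0.5 * dt, dq, qnew)
        # O
        for i in range(n):
            for k in range(3):
                vel[i, k] = c1 * vel[i, k] + c2v * np.random.standard_normal()
                omega[i, k] = c1 * omega[i, k] + c2w * np.random.standard_normal()
        # A
        for i in range(n):
            for k in range(3):
                pos[i, k] += 0.5 * dt * vel[i, k]
                pos[i, k] = pos[i, k] - edge[k] * np.floor(pos[i, k] / edge[k])
        _advance_quat(quat, omega, 0.5 * dt, dq, qnew)
        for i in range(n):
            if species[i] != SP_CROWDER:
                _patch_dirs(quat[i], patches, pdirs[i])
        t = step * dt
        eps_t = _square_wave(t, baseline, amplitude, period)
        E = _bd_forces(pos, pdirs, species, edge, eps_t, sigma, rw, aw, eps_core, rule, F, T)
        if not np.isfinite(E):
            return (ERR_NONFINITE, rec_count, rec_t, rec_E, rec_nb, rec_KE,
                    event_time, censored, t)
        for i in range(n):
            for k in range(3):
                vel[i, k] += half * F[i, k]
                omega[i, k] += halfw * T[i, k]

        if step % check_every == 0 and stop_mode != 0:
            nb, _ = _total_bonds(
                pos, pdirs, species, edge, sigma, det_lam_sigma, det_cmax, rule, False
            )
            if stop_mode == 1 and nb == n_target:
                if _is_target(pos, pdirs, species, edge, sigma, det_lam_sigma,
                              det_cmax, rule, False, n_target):
                    event_time = t
                    censored = False
            elif stop_mode == 2 and nb < n_target:
                event_time = t
                censored = False

        if step % record_every == 0:
            nb, _ = _total_bonds(
                pos, pdirs, species, edge, sigma, det_lam_sigma, det_cmax, rule, False
            )
            ke = 0.0
            for i in range(n):
                ke += 0.5 * mass * (vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
            rec_t[rec_count] = t
            rec_E[rec_count] = E
            rec_nb[rec_count] = nb
            rec_KE[rec_count] = ke
            rec_count += 1

    return (OK, rec_count, rec_t, rec_E, rec_nb, rec_KE, event_time, censored, t)
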