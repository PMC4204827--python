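"""Numba-compiled core: per-step stochastic propagators and the stepping loop.

Everything here works in µm and seconds on flat arrays.  The geometry is
passed as the tuple produced by ``Geometry.arrays()``:

    (R, half, w,
     st_o, st_a, st_n, st_t, st_sp, st_seg0, st_m, st_lo, st_hi,
     seg_stk, seg_j, seg_L, slide_next, slide_prev,
     ist_indptr, ist_indices,
     tg_seg, tg_u, tg_world, s2t_indptr, s2t_indices, tg_lo, tg_hi)

Randomness comes exclusively from the ``numpy.random.Generator`` handed in by
the caller, so a run is fully determined by (config, geometry, placement,
seed).  All rate-to-probability conversions use 1 − exp(−k·dt).

Per-step event order for each TF: (1) complex dissociation, (2) desorption,
(3) motion — a 3D step with crossing-detected adsorption, or a 1D surface
step, (4) intersegmental transfer, (5) end-of-step target-binding test.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

MODE_FREE = 0
MODE_BOUND = 1
MODE_COMPLEXED = 2

EV_ADSORB = 0
EV_DESORB = 1
EV_IST = 2
EV_BIND = 3
EV_UNBIND = 4

STATUS_DONE = 0
STATUS_OVERFLOW = 1
STATUS_STOPPED = 2


@njit(cache=True, inline="always")
def reflect_sphere(x, y, z, R):
    """Mirror a point across the sphere surface (radially); clamp to the
    surface if a pathologically large step leaves it outside even after
    reflection.  Returns the corrected point."""
    r2 = x * x + y * y + z * z
    if r2 <= R * R:
        return x, y, z
    r = math.sqrt(r2)
    rnew = 2.0 * R - r
    if rnew < 0.0:
        rnew = R
    f = rnew / r
    return x * f, y * f, z * f


@njit(cache=True, inline="always")
def uniform_in_sphere(R, rng):
    """Uniform random point inside the sphere of radius R (rejection)."""
    while True:
        x = (2.0 * rng.random() - 1.0) * R
        y = (2.0 * rng.random() - 1.0) * R
        z = (2.0 * rng.random() - 1.0) * R
        if x * x + y * y + z * z <= R * R:
            return x, y, z


@njit(cache=True, inline="always")
def desorb_offset(s3, rng):
    """Distance from the surface at which a desorbed TF re-enters solution.

    The event happens at a uniform time within the step and the TF diffuses
    for the remainder, giving |N(0, 2·D3·dt·U)| with U ~ U(0,1): mean
    ≈ 0.53·√(2·D3·dt), with substantial mass near the surface (this
    near-wall mass is what produces geminate rebinding, i.e. hopping)."""
    g = rng.standard_normal()
    if g < 0.0:
        g = -g
    return s3 * math.sqrt(rng.random()) * g


@njit(cache=True, inline="always")
def free_propose(x, y, z, s3, R, rng):
    """One free-diffusion displacement (per-axis N(0, 2·D3·dt)) with sphere
    reflection.  Returns the proposed end point."""
    x1 = x + s3 * rng.standard_normal()
    y1 = y + s3 * rng.standard_normal()
    z1 = z + s3 * rng.standard_normal()
    return reflect_sphere(x1, y1, z1, R)


@njit(cache=True)
def resolve_free_path(geo, x0, y0, z0, x1, y1, z1, pstick, rng):
    """Trace the straight sub-step from (x0,y0,z0) to (x1,y1,z1) against all
    DNA faces.  Each face crossing sticks with probability ``pstick``
    (adsorption) or reflects the remainder of the path off the face plane.

    Returns (adsorbed, seg, u, v, face, xf, yf, zf): if ``adsorbed`` the
    surface coordinates are valid, otherwise (xf, yf, zf) is the final free
    position after any reflections.
    """
    (R, half, w,
     st_o, st_a, st_n, st_t, st_sp, st_seg0, st_m, st_lo, st_hi,
     seg_stk, seg_j, seg_L, slide_next, slide_prev,
     ist_indptr, ist_indices,
     tg_seg, tg_u, tg_world, s2t_indptr, s2t_indices, tg_lo, tg_hi) = geo
    nstk = st_sp.shape[0]
    for k in range(nstk):
        # quick reject: path box vs stack box
        lox = x0 if x0 < x1 else x1
        hix = x0 if x0 > x1 else x1
        if hix < st_lo[k, 0] or lox > st_hi[k, 0]:
            continue
        loy = y0 if y0 < y1 else y1
        hiy = y0 if y0 > y1 else y1
        if hiy < st_lo[k, 1] or loy > st_hi[k, 1]:
            continue
        loz = z0 if z0 < z1 else z1
        hiz = z0 if z0 > z1 else z1
        if hiz < st_lo[k, 2] or loz > st_hi[k, 2]:
            continue
        ox = st_o[k, 0]; oy = st_o[k, 1]; oz = st_o[k, 2]
        ax = st_a[k, 0]; ay = st_a[k, 1]; az = st_a[k, 2]
        nx = st_n[k, 0]; ny = st_n[k, 1]; nz = st_n[k, 2]
        tx = st_t[k, 0]; ty = st_t[k, 1]; tz = st_t[k, 2]
        sp = st_sp[k]
        m = st_m[k]
        dx0 = x0 - ox; dy0 = y0 - oy; dz0 = z0 - oz
        dx1 = x1 - ox; dy1 = y1 - oy; dz1 = z1 - oz
        ua0 = dx0 * ax + dy0 * ay + dz0 * az
        na0 = dx0 * nx + dy0 * ny + dz0 * nz
        ta0 = dx0 * tx + dy0 * ty + dz0 * tz
        ua1 = dx1 * ax + dy1 * ay + dz1 * az
        na1 = dx1 * nx + dy1 * ny + dz1 * nz
        ta1 = dx1 * tx + dy1 * ty + dz1 * tz
        guard = 0
        while guard < 64:
            guard += 1
            if na1 == na0:
                break
            lo_n = na0 if na0 < na1 else na1
            hi_n = na0 if na0 > na1 else na1
            jlo = int(math.ceil(lo_n / sp))
            jhi = int(math.floor(hi_n / sp))
            if jlo < 0:
                jlo = 0
            if jhi > m - 1:
                jhi = m - 1
            best_s = 2.0
            best_j = -1
            best_q = 0.0
            for j in range(jlo, jhi + 1):
                q = j * sp
                if (q - na0) * (q - na1) < 0.0:
                    s = (q - na0) / (na1 - na0)
                    if 1e-12 < s < best_s:
                        best_s = s
                        best_j = j
                        best_q = q
            if best_j < 0:
                break
            ux = ua0 + best_s * (ua1 - ua0)
            tvx = ta0 + best_s * (ta1 - ta0)
            sidx = st_seg0[k] + best_j
            if 0.0 <= ux <= seg_L[sidx] and (tvx if tvx > 0 else -tvx) <= 0.5 * w:
                if pstick > 0.0 and rng.random() < pstick:
                    # face is the side the TF arrived from
                    fc = 0 if na0 > best_q else 1
                    return True, sidx, ux, tvx + 0.5 * w, fc, x1, y1, z1
                # reflect the remainder off the face plane
                na1 = 2.0 * best_q - na1
                ua0 = ux
                ta0 = tvx
                na0 = best_q
            else:
                # crossed the plane outside this rectangle: pass through
                ua0 = ux
                ta0 = tvx
                na0 = best_q
        # write the (possibly reflected) end point back to world coordinates
        x1 = ox + ua1 * ax + na1 * nx + ta1 * tx
        y1 = oy + ua1 * ay + na1 * ny + ta1 * ty
        z1 = oz + ua1 * az + na1 * nz + ta1 * tz
    return False, -1, 0.0, 0.0, 0, x1, y1, z1


@njit(cache=True, inline="always")
def step_bound_1d(geo, seg, u, v, s1, rng):
    """One on-surface diffusion step: independent N(0, 2·D1·dt) displacements
    along u (axial) and v (transverse).  v reflects at the face edges; u
    reflects at segment ends unless the end is slide-linked, in which case
    the overshoot carries into the linked segment."""
    (R, half, w,
     st_o, st_a, st_n, st_t, st_sp, st_seg0, st_m, st_lo, st_hi,
     seg_stk, seg_j, seg_L, slide_next, slide_prev,
     ist_indptr, ist_indices,
     tg_seg, tg_u, tg_world, s2t_indptr, s2t_indices, tg_lo, tg_hi) = geo
    u = u + s1 * rng.standard_normal()
    v = v + s1 * rng.standard_normal()
    guard = 0
    while (v < 0.0 or v > w) and guard < 64:
        guard += 1
        if v < 0.0:
            v = -v
        else:
            v = 2.0 * w - v
    guard = 0
    while guard < 64:
        guard += 1
        L = seg_L[seg]
        if u < 0.0:
            p = slide_prev[seg]
            if p >= 0:
                seg = p
                u = seg_L[p] + u
            else:
                u = -u
        elif u > L:
            nx = slide_next[seg]
            if nx >= 0:
                seg = nx
                u = u - L
            else:
                u = 2.0 * L - u
        else:
            break
    return seg, u, v


@njit(cache=True, inline="always")
def attempt_ist(geo, seg, u, p_ist, randomize_u, rng):
    """Intersegmental transfer: with probability ``p_ist`` (= 1 − exp(−k·dt))
    move to a uniformly chosen adjacent segment, preserving the axial
    coordinate (clamped to the destination length) unless ``randomize_u``.

    Returns (fired, seg, u)."""
    (R, half, w,
     st_o, st_a, st_n, st_t, st_sp, st_seg0, st_m, st_lo, st_hi,
     seg_stk, seg_j, seg_L, slide_next, slide_prev,
     ist_indptr, ist_indices,
     tg_seg, tg_u, tg_world, s2t_indptr, s2t_indices, tg_lo, tg_hi) = geo
    lo = ist_indptr[seg]
    deg = ist_indptr[seg + 1] - lo
    if deg == 0:
        return False, seg, u
    if rng.random() >= p_ist:
        return False, seg, u
    dest = ist_indices[lo + rng.integers(0, deg)]
    if randomize_u:
        u = rng.random() * seg_L[dest]
    elif u > seg_L[dest]:
        u = seg_L[dest]
    return True, dest, u


@njit(cache=True, inline="always")
def check_tg_bound(geo, seg, u, v, sigb, tg_count, tg_cap):
    """End-of-step specific-binding test for a DNA-bound TF.

    Only TGs on the TF's own segment can be within reach (neighbouring
    segments are farther than the binding radius by construction).  TF and
    TG lie in the same rectangle plane, so the distance to a TG at axial
    offset du is sqrt(du² + (v − w/2)²).  Returns the first eligible TG in
    id order, or −1."""
    (R, half, w,
     st_o, st_a, st_n, st_t, st_sp, st_seg0, st_m, st_lo, st_hi,
     seg_stk, seg_j, seg_L, slide_next, slide_prev,
     ist_indptr, ist_indices,
     tg_seg, tg_u, tg_world, s2t_indptr, s2t_indices, tg_lo, tg_hi) = geo
    sig2 = sigb * sigb
    dv = v - 0.5 * w
    base = dv * dv
    if base > sig2:
        return -1
    for p in range(s2t_indptr[seg], s2t_indptr[seg + 1]):
        tg = s2t_indices[p]
        if tg_count[tg] >= tg_cap:
            continue
        du = u - tg_u[tg]
        if du < 0:
            du = -du
        if du > sigb:
            continue
        if du * du + base <= sig2:
            return tg
    return -1


@njit(cache=True)
def check_tg_free(geo, x, y, z, sigb, tg_count, tg_cap):
    """End-of-step specific-binding test for a freely diffusing TF (only used
    when 3D TG binding is allowed).  Returns the first eligible TG in id
    order within one binding radius, or −1."""
    (R, half, w,
     st_o, st_a, st_n, st_t, st_sp, st_seg0, st_m, st_lo, st_hi,
     seg_stk, seg_j, seg_L, slide_next, slide_prev,
     ist_indptr, ist_indices,
     tg_seg, tg_u, tg_world, s2t_indptr, s2t_indices, tg_lo, tg_hi) = geo
    ntg = tg_seg.shape[0]
    if ntg == 0:
        return -1
    if (x < tg_lo[0] - sigb or x > tg_hi[0] + sigb
            or y < tg_lo[1] - sigb or y > tg_hi[1] + sigb
            or z < tg_lo[2] - sigb or z > tg_hi[2] + sigb):
        return -1
    sig2 = sigb * sigb
    for tg in range(ntg):
        if tg_count[tg] >= tg_cap:
            continue
        dx = x - tg_world[tg, 0]
        if dx > sigb or dx < -sigb:
            continue
        dy = y - tg_world[tg, 1]
        if dy > sigb or dy < -sigb:
            continue
        dz = z - tg_world[tg, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 <= sig2:
            return tg
    return -1


@njit(cache=True, inline="always")
def surface_point(geo, seg, u, v, face, extra):
    """World position of surface coordinates, pushed ``extra`` µm out along
    the face's outward normal (extra = 0 gives the in-plane point itself;
    face 0 is the +normal side of the rectangle, face 1 the −normal side)."""
    (R, half, w,
     st_o, st_a, st_n, st_t, st_sp, st_seg0, st_m, st_lo, st_hi,
     seg_stk, seg_j, seg_L, slide_next, slide_prev,
     ist_indptr, ist_indices,
     tg_seg, tg_u, tg_world, s2t_indptr, s2t_indices, tg_lo, tg_hi) = geo
    k = seg_stk[seg]
    j = seg_j[seg]
    sgn = 1.0 if face == 0 else -1.0
    off = j * st_sp[k] + sgn * extra
    dv = v - 0.5 * w
    x = st_o[k, 0] + u * st_a[k, 0] + off * st_n[k, 0] + dv * st_t[k, 0]
    y = st_o[k, 1] + u * st_a[k, 1] + off * st_n[k, 1] + dv * st_t[k, 1]
    z = st_o[k, 2] + u * st_a[k, 2] + off * st_n[k, 2] + dv * st_t[k, 2]
    return x, y, z


@njit(cache=True, inline="always")
def tg_release_point(geo, tg, delta, rng):
    """Free position "just off the face" at a TG after complex dissociation:
    the TG point pushed ``delta`` along a random face normal."""
    (R, half, w,
     st_o, st_a, st_n, st_t, st_sp, st_seg0, st_m, st_lo, st_hi,
     seg_stk, seg_j, seg_L, slide_next, slide_prev,
     ist_indptr, ist_indices,
     tg_seg, tg_u, tg_world, s2t_indptr, s2t_indices, tg_lo, tg_hi) = geo
    k = seg_stk[tg_seg[tg]]
    sgn = 1.0 if rng.random() < 0.5 else -1.0
    off = sgn * delta
    x = tg_world[tg, 0] + off * st_n[k, 0]
    y = tg_world[tg, 1] + off * st_n[k, 1]
    z = tg_world[tg, 2] + off * st_n[k, 2]
    return reflect_sphere(x, y, z, R)


@njit(cache=True)
def advance(geo,
            D3, D1, pstick, p_desorb, p_ist, p_coff, sigb, dt, nsteps,
            allow3d, tg_cap, ist_rand_u, non_depleting, stop_target,
            mode, pos, seg, uu, vv, face, tgid, tg_count,
            ev_t, ev_tf, ev_kind, ev_a, ev_u, rec,
            sample_every, samp_t, samp_c,
            rng):
    """Advance all TFs by ``nsteps`` time steps, recording events and the
    complex-count time series.  Returns (n_events, n_samples, steps_done,
    status) with status 0 = ran to completion, 1 = event buffer full
    (caller retries with a larger buffer), 2 = stop condition reached.

    ``stop_target`` > 0 stops once that many specific-binding events have
    occurred.  ``non_depleting`` records binding events but immediately
    resets the TF to a uniformly random free position, leaving the TG
    unoccupied (hazard-estimation mode).
    """
    ntf = mode.shape[0]
    cap = ev_t.shape[0]
    s3 = math.sqrt(2.0 * D3 * dt)
    s1 = math.sqrt(2.0 * D1 * dt)
    R = geo[0]
    have_dna = geo[14].shape[0] > 0
    ntg = geo[19].shape[0]
    # scalar bounding boxes hoisted out of the hot loop: the DNA box (union
    # of all stack boxes) and the TG box inflated by the binding radius
    st_lo_all = geo[10]
    st_hi_all = geo[11]
    bx0 = by0 = bz0 = 1e30
    bx1 = by1 = bz1 = -1e30
    for k in range(st_lo_all.shape[0]):
        if st_lo_all[k, 0] < bx0:
            bx0 = st_lo_all[k, 0]
        if st_lo_all[k, 1] < by0:
            by0 = st_lo_all[k, 1]
        if st_lo_all[k, 2] < bz0:
            bz0 = st_lo_all[k, 2]
        if st_hi_all[k, 0] > bx1:
            bx1 = st_hi_all[k, 0]
        if st_hi_all[k, 1] > by1:
            by1 = st_hi_all[k, 1]
        if st_hi_all[k, 2] > bz1:
            bz1 = st_hi_all[k, 2]
    tg_lo_a = geo[24]
    tg_hi_a = geo[25]
    tx0 = tg_lo_a[0] - sigb
    ty0 = tg_lo_a[1] - sigb
    tz0 = tg_lo_a[2] - sigb
    tx1 = tg_hi_a[0] + sigb
    ty1 = tg_hi_a[1] + sigb
    tz1 = tg_hi_a[2] + sigb
    nev = 0
    ncplx = 0
    for i in range(ntf):
        if mode[i] == MODE_COMPLEXED:
            ncplx += 1
    nbinds = 0
    isamp = 0
    if sample_every > 0:
        samp_t[0] = 0.0
        samp_c[0] = ncplx
        isamp = 1
    status = STATUS_DONE
    steps_done = 0
    for step in range(nsteps):
        if nev + 4 * ntf > cap:
            status = STATUS_OVERFLOW
            break
        tnow = (step + 1) * dt
        for i in range(ntf):
            m = mode[i]
            # (1) complex dissociation
            if m == MODE_COMPLEXED:
                if p_coff > 0.0 and rng.random() < p_coff:
                    tg = tgid[i]
                    tg_count[tg] -= 1
                    ncplx -= 1
                    tgid[i] = -1
                    x, y, z = tg_release_point(geo, tg, desorb_offset(s3, rng),
                                               rng)
                    pos[i, 0] = x; pos[i, 1] = y; pos[i, 2] = z
                    m = MODE_FREE
                    mode[i] = MODE_FREE
                    if rec[EV_UNBIND]:
                        ev_t[nev] = tnow; ev_tf[nev] = i
                        ev_kind[nev] = EV_UNBIND; ev_a[nev] = tg
                        ev_u[nev] = -1.0
                        nev += 1
                else:
                    continue
            # (2) desorption
            if m == MODE_BOUND and p_desorb > 0.0 and rng.random() < p_desorb:
                x, y, z = surface_point(geo, seg[i], uu[i], vv[i], face[i],
                                        desorb_offset(s3, rng))
                x, y, z = reflect_sphere(x, y, z, R)
                if rec[EV_DESORB]:
                    ev_t[nev] = tnow; ev_tf[nev] = i
                    ev_kind[nev] = EV_DESORB; ev_a[nev] = seg[i]
                    ev_u[nev] = uu[i]
                    nev += 1
                pos[i, 0] = x; pos[i, 1] = y; pos[i, 2] = z
                m = MODE_FREE
                mode[i] = MODE_FREE
                seg[i] = -1
            # (3) motion
            if m == MODE_FREE:
                if D3 > 0.0:
                    x0 = pos[i, 0]; y0 = pos[i, 1]; z0 = pos[i, 2]
                    x1, y1, z1 = free_propose(x0, y0, z0, s3, R, rng)
                    near_dna = have_dna
                    if near_dna:
                        # path box vs DNA box (scalar fast path)
                        if ((x0 if x0 > x1 else x1) < bx0
                                or (x0 if x0 < x1 else x1) > bx1
                                or (y0 if y0 > y1 else y1) < by0
                                or (y0 if y0 < y1 else y1) > by1
                                or (z0 if z0 > z1 else z1) < bz0
                                or (z0 if z0 < z1 else z1) > bz1):
                            near_dna = False
                    if near_dna:
                        ads, sa, ua, va, fa, x1, y1, z1 = resolve_free_path(
                            geo, x0, y0, z0, x1, y1, z1, pstick, rng)
                        if ads:
                            m = MODE_BOUND
                            mode[i] = MODE_BOUND
                            seg[i] = sa; uu[i] = ua; vv[i] = va; face[i] = fa
                            if rec[EV_ADSORB]:
                                ev_t[nev] = tnow; ev_tf[nev] = i
                                ev_kind[nev] = EV_ADSORB; ev_a[nev] = sa
                                ev_u[nev] = ua
                                nev += 1
                        else:
                            pos[i, 0] = x1; pos[i, 1] = y1; pos[i, 2] = z1
                    else:
                        pos[i, 0] = x1; pos[i, 1] = y1; pos[i, 2] = z1
            elif m == MODE_BOUND:
                if D1 > 0.0:
                    sg, u2, v2 = step_bound_1d(geo, seg[i], uu[i], vv[i], s1, rng)
                    seg[i] = sg; uu[i] = u2; vv[i] = v2
            # (4) intersegmental transfer
            if m == MODE_BOUND and p_ist > 0.0:
                fired, sg, u2 = attempt_ist(geo, seg[i], uu[i], p_ist,
                                            ist_rand_u, rng)
                if fired:
                    seg[i] = sg
                    uu[i] = u2
                    if rec[EV_IST]:
                        ev_t[nev] = tnow; ev_tf[nev] = i
                        ev_kind[nev] = EV_IST; ev_a[nev] = sg
                        ev_u[nev] = u2
                        nev += 1
            # (5) specific-binding test
            if ntg > 0:
                tg = -1
                if m == MODE_BOUND:
                    tg = check_tg_bound(geo, seg[i], uu[i], vv[i], sigb,
                                        tg_count, tg_cap)
                elif m == MODE_FREE and allow3d:
                    px = pos[i, 0]; py = pos[i, 1]; pz = pos[i, 2]
                    if (tx0 <= px <= tx1 and ty0 <= py <= ty1
                            and tz0 <= pz <= tz1):
                        tg = check_tg_free(geo, px, py, pz,
                                           sigb, tg_count, tg_cap)
                if tg >= 0:
                    nbinds += 1
                    if rec[EV_BIND]:
                        ev_t[nev] = tnow; ev_tf[nev] = i
                        ev_kind[nev] = EV_BIND; ev_a[nev] = tg
                        ev_u[nev] = -1.0
                        nev += 1
                    if non_depleting:
                        x, y, z = uniform_in_sphere(R, rng)
                        pos[i, 0] = x; pos[i, 1] = y; pos[i, 2] = z
                        mode[i] = MODE_FREE
                        seg[i] = -1
                    else:
                        mode[i] = MODE_COMPLEXED
                        tgid[i] = tg
                        tg_count[tg] += 1
                        ncplx += 1
        steps_done = step + 1
        if sample_every > 0 and steps_done % sample_every == 0:
            samp_t[isamp] = tnow
            samp_c[isamp] = ncplx
            isamp += 1
        if stop_target > 0 and nbinds >= stop_target:
            status = STATUS_STOPPED
            break
    return nev, isamp, steps_done, status


@njit(cache=True)
def dim_first_passage(ndim, x0, D, dt, sigb, max_steps, box_half, rng):
    """First-passage step count of a single diffusing particle to a point
    target at the origin, tested end-of-step within ``sigb``.

    ndim = 1: reflecting interval [−box_half, box_half];
    ndim = 2: reflecting square; ndim = 3: reflecting sphere of radius
    ``box_half``.  The particle starts at (x0, 0[, 0]).  Returns the step
    index at capture (1-based) or −1 if censored at ``max_steps``."""
    s = math.sqrt(2.0 * D * dt)
    sig2 = sigb * sigb
    x = x0
    y = 0.0
    z = 0.0
    for step in range(max_steps):
        x += s * rng.standard_normal()
        if ndim >= 2:
            y += s * rng.standard_normal()
        if ndim == 3:
            z += s * rng.standard_normal()
            x, y, z = reflect_sphere(x, y, z, box_half)
        else:
            if x < -box_half:
                x = -2.0 * box_half - x
            elif x > box_half:
                x = 2.0 * box_half - x
            if ndim == 2:
                if y < -box_half:
                    y = -2.0 * box_half - y
                elif y > box_half:
                    y = 2.0 * box_half - y
        d2 = x * x + y * y + z * z
        if d2 <= sig2:
            return step + 1
    return -1
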