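"""Numba-compiled hot path for the total pseudo-energy and its gradient.

The modular term functions in :mod:`fcdg.energy` are the reference
implementation and public API; the dynamics inner loops evaluate the same
mathematics through this flattened, JIT-compiled kernel (the two paths are
cross-checked against each other in the test suite).  Restraint data is packed
once per run into plain arrays by :class:`fcdg.energy.CompiledSystem`.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        if a and callable(a[0]):
            return a[0]
        return wrap


@njit(cache=True)
def _etotal_grad(
    coords,          # (n, d) d in {3, 4}
    lower, upper, k_dist,
    chir_quads, chir_targets, chir_ks,          # (mc,4) int, (mc,), (mc,)
    noe_pi, noe_pj, noe_owner,                  # flattened proton pairs
    noe_npairs, noe_dexp, noe_k,                # per NOE restraint
    vp_i, vp_j, vp_gamma, vp_owner,             # RDC vector sub-pairs
    me_c, me_hv, me_gamma, me_owner, me_h,      # methyls: axis + (mm,3) protons
    rdc_dexp, rdc_k, rdc_med,                   # per RDC restraint
    n_media, dmax_coef,
):
    n, d = coords.shape
    grad = np.zeros((n, d))
    e_out = np.zeros(3 + n_media)   # dist, chir, noe, rdc per medium

    # ---- distance bounds (full metric, 3D or 4D) -------------------------
    e_dist = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dij = 0.0
            for a in range(d):
                t = coords[i, a] - coords[j, a]
                dij += t * t
            dij = np.sqrt(dij)
            viol = 0.0
            if dij > upper[i, j]:
                viol = dij - upper[i, j]
            elif dij < lower[i, j]:
                viol = dij - lower[i, j]
            if viol != 0.0:
                e_dist += 0.5 * k_dist * viol * viol
                coef = k_dist * viol / dij
                for a in range(d):
                    g = coef * (coords[i, a] - coords[j, a])
                    grad[i, a] += g
                    grad[j, a] -= g
    e_out[0] = e_dist

    # ---- chiral volumes (3D projection) ----------------------------------
    e_chir = 0.0
    for m in range(chir_quads.shape[0]):
        i1, i2, i3, i4 = chir_quads[m, 0], chir_quads[m, 1], chir_quads[m, 2], chir_quads[m, 3]
        ax = coords[i1, 0] - coords[i4, 0]
        ay = coords[i1, 1] - coords[i4, 1]
        az = coords[i1, 2] - coords[i4, 2]
        bx = coords[i2, 0] - coords[i4, 0]
        by = coords[i2, 1] - coords[i4, 1]
        bz = coords[i2, 2] - coords[i4, 2]
        cx = coords[i3, 0] - coords[i4, 0]
        cy = coords[i3, 1] - coords[i4, 1]
        cz = coords[i3, 2] - coords[i4, 2]
        g1x = by * cz - bz * cy
        g1y = bz * cx - bx * cz
        g1z = bx * cy - by * cx
        v = ax * g1x + ay * g1y + az * g1z
        dev = v - chir_targets[m]
        k = chir_ks[m]
        e_chir += 0.5 * k * dev * dev
        co = k * dev
        g2x = cy * az - cz * ay
        g2y = cz * ax - cx * az
        g2z = cx * ay - cy * ax
        g3x = ay * bz - az * by
        g3y = az * bx - ax * bz
        g3z = ax * by - ay * bx
        grad[i1, 0] += co * g1x
        grad[i1, 1] += co * g1y
        grad[i1, 2] += co * g1z
        grad[i2, 0] += co * g2x
        grad[i2, 1] += co * g2y
        grad[i2, 2] += co * g2z
        grad[i3, 0] += co * g3x
        grad[i3, 1] += co * g3y
        grad[i3, 2] += co * g3z
        grad[i4, 0] -= co * (g1x + g2x + g3x)
        grad[i4, 1] -= co * (g1y + g2y + g3y)
        grad[i4, 2] -= co * (g1z + g2z + g3z)
    e_out[1] = e_chir

    # ---- NOE log-normal with r^-6 group averaging (full metric) ----------
    n_noe = noe_dexp.shape[0]
    e_noe = 0.0
    if n_noe > 0:
        sums = np.zeros(n_noe)
        npair = noe_pi.shape[0]
        dists = np.empty(npair)
        for p in range(npair):
            i, j = noe_pi[p], noe_pj[p]
            dij = 0.0
            for a in range(d):
                t = coords[i, a] - coords[j, a]
                dij += t * t
            dij = np.sqrt(dij)
            dists[p] = dij
            sums[noe_owner[p]] += dij ** (-6.0)
        deff = np.empty(n_noe)
        dcoef = np.empty(n_noe)
        for t in range(n_noe):
            mean6 = sums[t] / noe_npairs[t]
            de = mean6 ** (-1.0 / 6.0)
            deff[t] = de
            lr = np.log(noe_dexp[t] / de)
            e_noe += 0.5 * noe_k[t] * lr * lr
            dcoef[t] = (-noe_k[t] * lr / de) * de ** 7 / noe_npairs[t]
        for p in range(npair):
            t = noe_owner[p]
            i, j = noe_pi[p], noe_pj[p]
            co = dcoef[t] * dists[p] ** (-7.0) / dists[p]
            for a in range(d):
                g = co * (coords[i, a] - coords[j, a])
                grad[i, a] += g
                grad[j, a] -= g
    e_out[2] = e_noe

    # ---- RDC: per-medium tensor refit + quadratic misfit (3D projection) -
    n_res = rdc_dexp.shape[0]
    tensors = np.zeros((n_media, 5))
    dcalc = np.zeros(n_res)
    if n_res > 0:
        nvp = vp_i.shape[0]
        A = np.zeros((n_res, 5))
        vp_u = np.empty((nvp, 3))
        vp_r = np.empty(nvp)
        vp_dm = np.empty(nvp)
        for p in range(nvp):
            i, j = vp_i[p], vp_j[p]
            vx = coords[j, 0] - coords[i, 0]
            vy = coords[j, 1] - coords[i, 1]
            vz = coords[j, 2] - coords[i, 2]
            r = np.sqrt(vx * vx + vy * vy + vz * vz)
            if r < 0.5:
                r = 0.5
            ux, uy, uz = vx / r, vy / r, vz / r
            dm = dmax_coef * vp_gamma[p] / (r * r * r)
            t = vp_owner[p]
            A[t, 0] += dm * (ux * ux - uz * uz)
            A[t, 1] += dm * (uy * uy - uz * uz)
            A[t, 2] += dm * 2.0 * ux * uy
            A[t, 3] += dm * 2.0 * ux * uz
            A[t, 4] += dm * 2.0 * uy * uz
            vp_u[p, 0] = ux
            vp_u[p, 1] = uy
            vp_u[p, 2] = uz
            vp_r[p] = r
            vp_dm[p] = dm
        nme = me_c.shape[0]
        me_u = np.empty((nme, 3))
        me_rax = np.empty(nme)
        me_dm = np.empty(nme)
        me_rbar = np.empty(nme)
        for p in range(nme):
            c, hv = me_c[p], me_hv[p]
            vx = coords[hv, 0] - coords[c, 0]
            vy = coords[hv, 1] - coords[c, 1]
            vz = coords[hv, 2] - coords[c, 2]
            r = np.sqrt(vx * vx + vy * vy + vz * vz)
            if r < 0.5:
                r = 0.5
            ux, uy, uz = vx / r, vy / r, vz / r
            rbar = 0.0
            for hh in range(3):
                h = me_h[p, hh]
                wx = coords[h, 0] - coords[c, 0]
                wy = coords[h, 1] - coords[c, 1]
                wz = coords[h, 2] - coords[c, 2]
                rw = np.sqrt(wx * wx + wy * wy + wz * wz)
                if rw < 0.5:
                    rw = 0.5
                rbar += rw
            rbar /= 3.0
            dm = dmax_coef * me_gamma[p] / (rbar * rbar * rbar)
            t = me_owner[p]
            f = -1.0 / 3.0
            A[t, 0] += f * dm * (ux * ux - uz * uz)
            A[t, 1] += f * dm * (uy * uy - uz * uz)
            A[t, 2] += f * dm * 2.0 * ux * uy
            A[t, 3] += f * dm * 2.0 * ux * uz
            A[t, 4] += f * dm * 2.0 * uy * uz
            me_u[p, 0] = ux
            me_u[p, 1] = uy
            me_u[p, 2] = uz
            me_rax[p] = r
            me_dm[p] = dm
            me_rbar[p] = rbar

        for med in range(n_media):
            # normal equations over this medium's restraints
            ata = np.zeros((5, 5))
            atb = np.zeros(5)
            cnt = 0
            kmax = 0.0
            for t in range(n_res):
                if rdc_med[t] != med:
                    continue
                cnt += 1
                if rdc_k[t] > kmax:
                    kmax = rdc_k[t]
                for a in range(5):
                    atb[a] += A[t, a] * rdc_dexp[t]
                    for b in range(5):
                        ata[a, b] += A[t, a] * A[t, b]
            if cnt == 0 or kmax == 0.0:
                continue
            # Tikhonov floor keeps the solve finite for degenerate geometries
            tr = ata[0, 0] + ata[1, 1] + ata[2, 2] + ata[3, 3] + ata[4, 4]
            eps = 1e-12 * (tr if tr > 0 else 1.0)
            for a in range(5):
                ata[a, a] += eps
            s = np.linalg.solve(ata, atb)
            tensors[med] = s
            Sm = np.empty((3, 3))
            Sm[0, 0] = s[0]
            Sm[1, 1] = s[1]
            Sm[2, 2] = -s[0] - s[1]
            Sm[0, 1] = Sm[1, 0] = s[2]
            Sm[0, 2] = Sm[2, 0] = s[3]
            Sm[1, 2] = Sm[2, 1] = s[4]
            e_med = 0.0
            pref = np.zeros(n_res)
            for t in range(n_res):
                if rdc_med[t] != med:
                    continue
                dc = 0.0
                for a in range(5):
                    dc += A[t, a] * s[a]
                dcalc[t] = dc
                resid = rdc_dexp[t] - dc
                e_med += 0.5 * rdc_k[t] * resid * resid
                pref[t] = -rdc_k[t] * resid
            e_out[3 + med] = e_med
            # gradients, S held fixed (envelope condition)
            for p in range(nvp):
                t = vp_owner[p]
                if rdc_med[t] != med or pref[t] == 0.0:
                    continue
                ux, uy, uz = vp_u[p, 0], vp_u[p, 1], vp_u[p, 2]
                sux = Sm[0, 0] * ux + Sm[0, 1] * uy + Sm[0, 2] * uz
                suy = Sm[1, 0] * ux + Sm[1, 1] * uy + Sm[1, 2] * uz
                suz = Sm[2, 0] * ux + Sm[2, 1] * uy + Sm[2, 2] * uz
                q = ux * sux + uy * suy + uz * suz
                co = pref[t] * vp_dm[p] / vp_r[p]
                gx = co * (2.0 * sux - 5.0 * q * ux)
                gy = co * (2.0 * suy - 5.0 * q * uy)
                gz = co * (2.0 * suz - 5.0 * q * uz)
                i, j = vp_i[p], vp_j[p]
                grad[j, 0] += gx
                grad[j, 1] += gy
                grad[j, 2] += gz
                grad[i, 0] -= gx
                grad[i, 1] -= gy
                grad[i, 2] -= gz
            for p in range(nme):
                t = me_owner[p]
                if rdc_med[t] != med or pref[t] == 0.0:
                    continue
                c, hv = me_c[p], me_hv[p]
                ux, uy, uz = me_u[p, 0], me_u[p, 1], me_u[p, 2]
                sux = Sm[0, 0] * ux + Sm[0, 1] * uy + Sm[0, 2] * uz
                suy = Sm[1, 0] * ux + Sm[1, 1] * uy + Sm[1, 2] * uz
                suz = Sm[2, 0] * ux + Sm[2, 1] * uy + Sm[2, 2] * uz
                q = ux * sux + uy * suy + uz * suz
                co = pref[t] * (-1.0 / 3.0) * me_dm[p] * 2.0 / me_rax[p]
                gx = co * (sux - q * ux)
                gy = co * (suy - q * uy)
                gz = co * (suz - q * uz)
                grad[hv, 0] += gx
                grad[hv, 1] += gy
                grad[hv, 2] += gz
                grad[c, 0] -= gx
                grad[c, 1] -= gy
                grad[c, 2] -= gz
                dD_drbar = q * me_dm[p] / me_rbar[p]
                cohh = pref[t] * dD_drbar / 3.0
                for hh in range(3):
                    h = me_h[p, hh]
                    wx = coords[h, 0] - coords[c, 0]
                    wy = coords[h, 1] - coords[c, 1]
                    wz = coords[h, 2] - coords[c, 2]
                    rw = np.sqrt(wx * wx + wy * wy + wz * wz)
                    if rw < 0.5:
                        rw = 0.5
                    gx = cohh * wx / rw
                    gy = cohh * wy / rw
                    gz = cohh * wz / rw
                    grad[h, 0] += gx
                    grad[h, 1] += gy
                    grad[h, 2] += gz
                    grad[c, 0] -= gx
                    grad[c, 1] -= gy
                    grad[c, 2] -= gz
    return e_out, grad, tensors, dcalc
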