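"""Numba batch kernel for analog photon transport with ring-cell kerma tallies.

Single-threaded and explicitly seeded, so tallies are bit-for-bit reproducible
for a given RNG seed.  The scoring cells are full azimuthal rings bounded by
two spheres (a thin shell around each scoring radius) and two polar cones,
which is exact for an axisymmetric source and replaces the tiny voxels a
general-purpose code would need.

A slower, independently written per-photon implementation lives in
``seedchar.transport``; the two are cross-checked statistically in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# region codes (match seedchar.geometry)
_MARKER = 0
_COATING = 1
_GAP = 2
_WALL = 3
_EXTERIOR = 4

_ELECTRON_REST_KEV = 510.99895
_BIG = 1.0e30
_EPS = 1.0e-7  # cm, boundary crossing push


@njit(cache=True, inline="always")
def _region(g, x, y, z):
    rho2 = x * x + y * y
    az = abs(z)
    mr, mhl, cr, chl, cir, cor, bh, ri, ro = (
        g[0], g[1], g[2], g[3], g[4], g[5], g[6], g[7], g[8],
    )
    if rho2 <= mr * mr and az <= mhl:
        return _MARKER
    if rho2 <= cr * cr and az <= chl:
        return _COATING
    dz = az - bh
    d2 = rho2 + dz * dz
    if (rho2 <= cir * cir and az <= bh) or d2 <= ri * ri:
        return _GAP
    if (rho2 <= cor * cor and az <= bh) or d2 <= ro * ro:
        return _WALL
    return _EXTERIOR


@njit(cache=True, inline="always")
def _push_cyl(ts, n, x, y, ux, uy, radius):
    a = ux * ux + uy * uy
    if a < 1e-16:
        return n
    b = x * ux + y * uy
    c = x * x + y * y - radius * radius
    disc = b * b - a * c
    if disc < 0.0:
        return n
    sq = np.sqrt(disc)
    ts[n] = (-b - sq) / a
    ts[n + 1] = (-b + sq) / a
    return n + 2


@njit(cache=True, inline="always")
def _push_sph(ts, n, x, y, z, ux, uy, uz, zc, radius):
    dz = z - zc
    b = x * ux + y * uy + dz * uz
    c = x * x + y * y + dz * dz - radius * radius
    disc = b * b - c
    if disc < 0.0:
        return n
    sq = np.sqrt(disc)
    ts[n] = -b - sq
    ts[n + 1] = -b + sq
    return n + 2


@njit(cache=True)
def _seed_boundary(g, x, y, z, ux, uy, uz, here):
    """Distance to the first seed-region change along the ray (or _BIG)."""
    # quick reject for exterior rays missing the capsule bounding sphere
    bh = g[6]
    ro = g[8]
    bound = np.sqrt(g[5] * g[5] + (bh + ro) * (bh + ro)) + 1e-4
    if here == _EXTERIOR:
        r2 = x * x + y * y + z * z
        b = x * ux + y * uy + z * uz
        if r2 > bound * bound:
            if b >= 0.0:
                return _BIG
            if r2 - b * b > bound * bound:
                return _BIG

    ts = np.empty(24)
    n = 0
    n = _push_cyl(ts, n, x, y, ux, uy, g[0])
    n = _push_cyl(ts, n, x, y, ux, uy, g[2])
    n = _push_cyl(ts, n, x, y, ux, uy, g[4])
    n = _push_cyl(ts, n, x, y, ux, uy, g[5])
    if abs(uz) > 1e-16:
        for z0 in (g[1], g[3], g[6]):
            ts[n] = (z0 - z) / uz
            ts[n + 1] = (-z0 - z) / uz
            n += 2
    for sgn in (-1.0, 1.0):
        n = _push_sph(ts, n, x, y, z, ux, uy, uz, sgn * bh, g[7])
        n = _push_sph(ts, n, x, y, z, ux, uy, uz, sgn * bh, ro)

    # sort the small candidate list (insertion sort)
    for i in range(1, n):
        key = ts[i]
        j = i - 1
        while j >= 0 and ts[j] > key:
            ts[j + 1] = ts[j]
            j -= 1
        ts[j + 1] = key

    for i in range(n):
        t = ts[i]
        if t <= 1e-10:
            continue
        px = x + (t + 1e-9) * ux
        py = y + (t + 1e-9) * uy
        pz = z + (t + 1e-9) * uz
        if _region(g, px, py, pz) != here:
            return t
    return _BIG


@njit(cache=True, inline="always")
def _interp_log(log_e, log_y, m, energy):
    le = np.log(energy)
    if le <= log_e[0]:
        return np.exp(log_y[0])
    if le >= log_e[m - 1]:
        return np.exp(log_y[m - 1])
    lo = 0
    hi = m - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if log_e[mid] <= le:
            lo = mid
        else:
            hi = mid
    f = (le - log_e[lo]) / (log_e[hi] - log_e[lo])
    return np.exp(log_y[lo] + f * (log_y[hi] - log_y[lo]))


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, cmu, phi):
    """Rotate unit vector u by polar angle acos(cmu) and azimuth phi."""
    smu = np.sqrt(max(0.0, 1.0 - cmu * cmu))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) < 0.99999:
        denom = np.sqrt(1.0 - uz * uz)
        vx = (ux * uz * cp - uy * sp) / denom
        vy = (uy * uz * cp + ux * sp) / denom
        vz = -denom * cp
        nx = ux * cmu + vx * smu
        ny = uy * cmu + vy * smu
        nz = uz * cmu + vz * smu
    else:
        nx = smu * cp
        ny = smu * sp
        nz = cmu if uz > 0.0 else -cmu
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _sample_kn(energy):
    """Klein-Nishina scattering: returns (cos_theta, energy_ratio)."""
    k = energy / _ELECTRON_REST_KEV
    while True:
        c = 1.0 - 2.0 * np.random.random()
        p = 1.0 / (1.0 + k * (1.0 - c))
        w = 0.5 * p * p * (p + 1.0 / p - (1.0 - c * c))
        if np.random.random() < w:
            return c, p


@njit(cache=True, inline="always")
def _sample_rayleigh(alpha):
    """Thomson x squared screened form factor; returns cos_theta."""
    a2 = alpha * alpha
    while True:
        c = 1.0 - 2.0 * np.random.random()
        s2 = 0.5 * (1.0 - c)
        ff = 1.0 / (1.0 + a2 * s2) ** 2
        w = 0.5 * (1.0 + c * c) * ff * ff
        if np.random.random() < w:
            return c


@njit(cache=True)
def run_histories(
    n_histories,
    rng_seed,
    g,                 # geometry params (9,), ignored in point-source mode
    point_source,      # 0 = seed surface emission, 1 = isotropic point source
    coat_end_faces,    # 1 to emit from marker end faces as well
    spec_e,
    spec_cdf,
    region_mat,        # (5,) material index per region code
    phantom_radius,
    densities,         # (nmat,)
    log_e, log_pe, log_inc, log_coh, log_men, xs_len,
    score_mat,         # material index whose mu_en weights the kerma tally
    alpha_coef,        # (nmat,) form-factor screening coefficient per keV
    shell_lo, shell_hi,         # (n_r,)
    cos_th_hi, cos_th_lo,       # (n_th,) cos(theta_edge) hi=cos(lower edge)
    cell_volume,                # (n_r*n_th,)
    cutoff,
    k_edge, k_xray, k_yield,
    substep,
    tally_sum, tally_sumsq,     # (n_cells,) outputs
):
    """Run analog histories; returns (emitted, absorbed, escaped, cutoff) keV."""
    np.random.seed(rng_seed)
    n_r = shell_lo.shape[0]
    n_th = cos_th_hi.shape[0]

    # per-history scoring buffer
    buf_idx = np.empty(1024, dtype=np.int64)
    buf_val = np.empty(1024)

    # emission surface areas (coating mid-surface)
    mr = g[0]
    mhl = g[1]
    rc = 0.5 * (g[0] + g[2])
    lat_area = 2.0 * np.pi * rc * (2.0 * mhl)
    end_area = np.pi * mr * mr * 2.0 if coat_end_faces == 1 else 0.0
    p_lat = lat_area / (lat_area + end_area) if (lat_area + end_area) > 0 else 1.0

    e_emitted = 0.0
    e_absorbed = 0.0
    e_escaped = 0.0
    e_cutoff = 0.0

    for _ in range(n_histories):
        nbuf = 0

        # --- emission ---------------------------------------------------
        u = np.random.random()
        ie = 0
        while spec_cdf[ie] < u:
            ie += 1
        energy = spec_e[ie]

        if point_source == 1:
            x = 0.0
            y = 0.0
            z = 0.0
        else:
            if np.random.random() < p_lat:
                phi = 2.0 * np.pi * np.random.random()
                x = rc * np.cos(phi)
                y = rc * np.sin(phi)
                z = mhl * (2.0 * np.random.random() - 1.0)
            else:
                phi = 2.0 * np.pi * np.random.random()
                rr = mr * np.sqrt(np.random.random())
                x = rr * np.cos(phi)
                y = rr * np.sin(phi)
                z = (mhl + 0.5 * (g[3] - mhl)) if np.random.random() < 0.5 else -(
                    mhl + 0.5 * (g[3] - mhl)
                )
        cmu = 1.0 - 2.0 * np.random.random()
        smu = np.sqrt(max(0.0, 1.0 - cmu * cmu))
        phi = 2.0 * np.pi * np.random.random()
        ux = smu * np.cos(phi)
        uy = smu * np.sin(phi)
        uz = cmu

        e_emitted += energy
        alive = True

        while alive:
            if point_source == 1:
                reg = _EXTERIOR
            else:
                reg = _region(g, x, y, z)
            mat = region_mat[reg]

            # distance to region change / phantom exit
            if point_source == 1:
                t_geo = _BIG
            else:
                t_geo = _seed_boundary(g, x, y, z, ux, uy, uz, reg)
            if reg == _EXTERIOR:
                b = x * ux + y * uy + z * uz
                c = x * x + y * y + z * z - phantom_radius * phantom_radius
                disc = b * b - c
                t_sph = -b + np.sqrt(max(0.0, disc))
                if t_sph < t_geo:
                    t_b = t_sph
                    exits = True
                else:
                    t_b = t_geo
                    exits = False
            else:
                t_b = t_geo
                exits = False

            pe = 0.0
            inc = 0.0
            coh = 0.0
            if mat == 0:
                mu = 0.0
            else:
                m = xs_len[mat]
                pe = _interp_log(log_e[mat], log_pe[mat], m, energy)
                inc = _interp_log(log_e[mat], log_inc[mat], m, energy)
                coh = _interp_log(log_e[mat], log_coh[mat], m, energy)
                mu = (pe + inc + coh) * densities[mat]

            if mu > 0.0:
                s = -np.log(np.random.random()) / mu
            else:
                s = _BIG
            if s >= _BIG and t_b >= _BIG:
                # defensive: no boundary found (grazing ray); drop the photon
                e_escaped += energy
                break
            t = s if s < t_b else t_b

            # --- score the exterior flight segment ----------------------
            if reg == _EXTERIOR and t > 0.0:
                msc = xs_len[score_mat]
                men = _interp_log(log_e[score_mat], log_men[score_mat], msc, energy)
                wseg = energy * men
                r0sq = x * x + y * y + z * z
                ex = x + t * ux
                ey = y + t * uy
                ez = z + t * uz
                r1sq = ex * ex + ey * ey + ez * ez
                tc = -(x * ux + y * uy + z * uz)
                if 0.0 < tc < t:
                    rmin2 = max(0.0, r0sq - tc * tc)
                else:
                    rmin2 = min(r0sq, r1sq)
                rmax2 = max(r0sq, r1sq)
                rmin = np.sqrt(rmin2)
                rmax = np.sqrt(rmax2)
                for ir in range(n_r):
                    if shell_hi[ir] < rmin or shell_lo[ir] > rmax:
                        continue
                    # t-interval(s) inside the shell
                    b2 = x * ux + y * uy + z * uz
                    c_hi = r0sq - shell_hi[ir] * shell_hi[ir]
                    disc_hi = b2 * b2 - c_hi
                    if disc_hi <= 0.0:
                        continue
                    sq_hi = np.sqrt(disc_hi)
                    th1 = -b2 - sq_hi
                    th2 = -b2 + sq_hi
                    c_lo = r0sq - shell_lo[ir] * shell_lo[ir]
                    disc_lo = b2 * b2 - c_lo
                    if disc_lo > 0.0:
                        sq_lo = np.sqrt(disc_lo)
                        tl1 = -b2 - sq_lo
                        tl2 = -b2 + sq_lo
                        n_iv = 2
                    else:
                        tl1 = 0.0
                        tl2 = 0.0
                        n_iv = 1
                    for iv in range(n_iv):
                        if n_iv == 1:
                            a0 = th1
                            b0 = th2
                        elif iv == 0:
                            a0 = th1
                            b0 = tl1
                        else:
                            a0 = tl2
                            b0 = th2
                        if a0 < 0.0:
                            a0 = 0.0
                        if b0 > t:
                            b0 = t
                        seg = b0 - a0
                        if seg <= 0.0:
                            continue
                        nstep = 1 + int(seg / substep)
                        h = seg / nstep
                        for jj in range(nstep):
                            tm = a0 + (jj + 0.5) * h
                            px = x + tm * ux
                            py = y + tm * uy
                            pz = z + tm * uz
                            rr = np.sqrt(px * px + py * py + pz * pz)
                            ct = pz / rr
                            # theta bins: find it with cos_th_hi >= ct >= cos_th_lo
                            it = -1
                            for kk in range(n_th):
                                if cos_th_lo[kk] <= ct <= cos_th_hi[kk]:
                                    it = kk
                                    break
                            if it < 0:
                                continue
                            cell = ir * n_th + it
                            w = h * wseg / cell_volume[cell]
                            found = False
                            for kk in range(nbuf):
                                if buf_idx[kk] == cell:
                                    buf_val[kk] += w
                                    found = True
                                    break
                            if not found and nbuf < 1024:
                                buf_idx[nbuf] = cell
                                buf_val[nbuf] = w
                                nbuf += 1

            # --- advance -------------------------------------------------
            if s < t_b:
                x += s * ux
                y += s * uy
                z += s * uz
                tot = pe + inc + coh
                ui = np.random.random() * tot
                if ui < pe:
                    if mat == 5 and energy > k_edge and np.random.random() < k_yield:
                        e_absorbed += energy - k_xray
                        energy = k_xray
                        cmu = 1.0 - 2.0 * np.random.random()
                        smu = np.sqrt(max(0.0, 1.0 - cmu * cmu))
                        phi = 2.0 * np.pi * np.random.random()
                        ux = smu * np.cos(phi)
                        uy = smu * np.sin(phi)
                        uz = cmu
                    else:
                        e_absorbed += energy
                        alive = False
                elif ui < pe + inc:
                    cmu, ratio = _sample_kn(energy)
                    phi = 2.0 * np.pi * np.random.random()
                    ux, uy, uz = _rotate(ux, uy, uz, cmu, phi)
                    e_absorbed += energy * (1.0 - ratio)
                    energy *= ratio
                    if energy < cutoff:
                        e_cutoff += energy
                        alive = False
                else:
                    cmu = _sample_rayleigh(alpha_coef[mat] * energy)
                    phi = 2.0 * np.pi * np.random.random()
                    ux, uy, uz = _rotate(ux, uy, uz, cmu, phi)
            else:
                x += (t_b + _EPS) * ux
                y += (t_b + _EPS) * uy
                z += (t_b + _EPS) * uz
                if exits:
                    e_escaped += energy
                    alive = False

        # commit the history buffer (history-by-history variance)
        for kk in range(nbuf):
            tally_sum[buf_idx[kk]] += buf_val[kk]
            tally_sumsq[buf_idx[kk]] += buf_val[kk] * buf_val[kk]

    return e_emitted, e_absorbed, e_escaped, e_cutoff
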