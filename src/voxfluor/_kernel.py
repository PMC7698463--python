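"""Numba photon-propagation kernel.

One compiled routine walks a batch of photons through the label grid:
dimensionless-pathlength sampling, DDA voxel traversal, weight deposition
at interaction sites, Henyey-Greenstein direction spin, Fresnel
reflection/refraction at faces where the refractive index changes, Russian
roulette below the weight threshold, and escape scoring.

The pure-Python single-step operations in :mod:`voxfluor.transport` mirror
these formulas exactly; this file only fuses them into a fast loop.

Ledger slot layout (float64[8]):
  0 absorbed   1 escaped   2 roulette_killed   3 roulette_gain
  4 surface_escaped (subset of escaped scored into the surface map)
  5 photons killed by the event cap (count)
  6 interaction-event count   7 boundary-crossing count
"""

import math

import numpy as np
from numba import njit

# ledger indices
L_ABS, L_ESC, L_KILL, L_GAIN, L_SURF, L_CAP, L_NINT, L_NCROSS = range(8)


@njit(cache=True)
def _hg_cos(g: float, u: float) -> float:
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True)
def _fresnel(n1: float, n2: float, ci: float):
    """Unpolarized Fresnel reflectance and transmitted cosine."""
    if n1 == n2:
        return 0.0, ci
    si2 = 1.0 - ci * ci
    st2 = (n1 / n2) * (n1 / n2) * si2
    if st2 >= 1.0:
        return 1.0, 0.0  # total internal reflection
    ct = math.sqrt(1.0 - st2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp), ct


@njit(cache=True)
def propagate(
    labels,          # uint8 (nx, ny, nz)
    mu_a, mu_s, g_arr, n_arr,   # float64[5] per-label properties
    n_ambient,       # float64
    ix0, iy0, iz0,   # int64[N] start voxel
    x0, y0, z0,      # float64[N] start position (cm)
    ux0, uy0, uz0,   # float64[N] start direction (unit)
    w0,              # float64[N] start weight
    h,               # voxel size (cm)
    w_thresh, m_roulette, max_events, seed,
    absorbed,        # float64 (nx, ny, nz) out
    surface,         # float64 (nx, ny) out
    ledger,          # float64[8] out
):
    np.random.seed(seed)
    nx, ny, nz = labels.shape
    inv_m = 1.0 / m_roulette
    n_photons = ix0.shape[0]

    for p in range(n_photons):
        x = x0[p]; y = y0[p]; z = z0[p]
        ux = ux0[p]; uy = uy0[p]; uz = uz0[p]
        w = w0[p]
        ix = ix0[p]; iy = iy0[p]; iz = iz0[p]
        if w <= 0.0:
            continue

        s = -math.log(np.random.random())  # dimensionless pathlength budget
        events = 0
        while True:
            events += 1
            if events > max_events:
                ledger[L_KILL] += w
                ledger[L_CAP] += 1.0
                break

            lab = labels[ix, iy, iz]
            mt = mu_a[lab] + mu_s[lab]

            # distance to the nearest voxel face along the direction
            if ux > 0.0:
                tx = ((ix + 1) * h - x) / ux
            elif ux < 0.0:
                tx = (ix * h - x) / ux
            else:
                tx = 1e30
            if uy > 0.0:
                ty = ((iy + 1) * h - y) / uy
            elif uy < 0.0:
                ty = (iy * h - y) / uy
            else:
                ty = 1e30
            if uz > 0.0:
                tz = ((iz + 1) * h - z) / uz
            elif uz < 0.0:
                tz = (iz * h - z) / uz
            else:
                tz = 1e30

            axis = 0
            db = tx
            if ty < db:
                db = ty; axis = 1
            if tz < db:
                db = tz; axis = 2
            if db < 0.0:
                db = 0.0

            s_geo = s / mt
            if s_geo <= db:
                # interaction inside this voxel
                x += ux * s_geo; y += uy * s_geo; z += uz * s_geo
                dw = w * mu_a[lab] / mt
                absorbed[ix, iy, iz] += dw
                ledger[L_ABS] += dw
                ledger[L_NINT] += 1.0
                w -= dw
                if w <= 0.0:
                    break
                if w < w_thresh:
                    if np.random.random() < inv_m:
                        gain = (m_roulette - 1.0) * w
                        w *= m_roulette
                        ledger[L_GAIN] += gain
                    else:
                        ledger[L_KILL] += w
                        break
                # Henyey-Greenstein spin
                ct = _hg_cos(g_arr[lab], np.random.random())
                st = math.sqrt(max(0.0, 1.0 - ct * ct))
                phi = 2.0 * math.pi * np.random.random()
                cp = math.cos(phi); sp = math.sin(phi)
                if abs(uz) > 0.99999:
                    ux = st * cp
                    uy = st * sp
                    uz = ct if uz >= 0.0 else -ct
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                    nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                    nuz = -st * cp * den + uz * ct
                    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                    ux = nux / norm; uy = nuy / norm; uz = nuz / norm
                s = -math.log(np.random.random())
            else:
                # advance to the face, consume optical depth
                x += ux * db; y += uy * db; z += uz * db
                s -= mt * db
                if s < 0.0:
                    s = 0.0
                ledger[L_NCROSS] += 1.0

                jx = ix; jy = iy; jz = iz
                if axis == 0:
                    if ux > 0.0:
                        jx = ix + 1; x = (ix + 1) * h
                    else:
                        jx = ix - 1; x = ix * h
                elif axis == 1:
                    if uy > 0.0:
                        jy = iy + 1; y = (iy + 1) * h
                    else:
                        jy = iy - 1; y = iy * h
                else:
                    if uz > 0.0:
                        jz = iz + 1; z = (iz + 1) * h
                    else:
                        jz = iz - 1; z = iz * h

                if jx < 0 or jx >= nx or jy < 0 or jy >= ny or jz < 0 or jz >= nz:
                    # left the grid entirely: escaped, not surface-scored
                    ledger[L_ESC] += w
                    break

                lab2 = labels[jx, jy, jz]
                n1 = n_arr[lab] if lab > 0 else n_ambient
                n2 = n_arr[lab2] if lab2 > 0 else n_ambient
                if n1 != n2:
                    if axis == 0:
                        ci = abs(ux)
                    elif axis == 1:
                        ci = abs(uy)
                    else:
                        ci = abs(uz)
                    if ci > 1.0:
                        ci = 1.0
                    R, ct2 = _fresnel(n1, n2, ci)
                    if np.random.random() < R:
                        # reflect: flip the normal component, stay put
                        if axis == 0:
                            ux = -ux
                        elif axis == 1:
                            uy = -uy
                        else:
                            uz = -uz
                        continue
                    # refract (Snell): scale tangentials, rebuild normal comp
                    ratio = n1 / n2
                    if axis == 0:
                        uy *= ratio; uz *= ratio
                        ux = ct2 if ux > 0.0 else -ct2
                    elif axis == 1:
                        ux *= ratio; uz *= ratio
                        uy = ct2 if uy > 0.0 else -ct2
                    else:
                        ux *= ratio; uy *= ratio
                        uz = ct2 if uz > 0.0 else -ct2
                    norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                    ux /= norm; uy /= norm; uz /= norm

                if lab2 == 0:
                    # transmitted into ambient air: escape through the
                    # tissue surface, scored on the (x, y) projection
                    ledger[L_ESC] += w
                    sx = int(x / h)
                    sy = int(y / h)
                    if sx < 0:
                        sx = 0
                    elif sx >= nx:
                        sx = nx - 1
                    if sy < 0:
                        sy = 0
                    elif sy >= ny:
                        sy = ny - 1
                    surface[sx, sy] += w
                    ledger[L_SURF] += w
                    break

                ix = jx; iy = jy; iz = jz
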