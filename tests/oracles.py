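"""Independent reference implementations used only by the test suite.

A vectorized single-medium Monte Carlo (no voxel grid, analytic
semi-infinite geometry) provides the diffuse-reflectance oracle the voxel
engine is checked against; it shares no code with the package.
"""

import numpy as np


def hg_cos_vec(g, u):
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return np.clip((1.0 + g * g - tmp * tmp) / (2.0 * g), -1.0, 1.0)


def diffuse_reflectance_semi_infinite(
    mu_a, mu_s, g, n_photons, seed, w_thresh=1e-4, m=10, max_iter=100_000
):
    """Total diffuse reflectance of a matched-boundary semi-infinite
    homogeneous medium, by direct weighted-photon simulation.

    Photons enter at the origin heading +z; any straight flight whose
    endpoint has z < 0 escapes with its current weight.  Returns
    (mean reflected weight per photon, per-photon std of that weight).
    """
    rng = np.random.default_rng(seed)
    mu_t = mu_a + mu_s
    n = n_photons
    z = np.zeros(n)
    ux = np.zeros(n)
    uy = np.zeros(n)
    uz = np.ones(n)
    w = np.ones(n)
    refl = np.zeros(n)  # per-photon escaped weight
    idx = np.arange(n)  # photon ids still alive

    for _ in range(max_iter):
        if idx.size == 0:
            break
        k = idx.size
        s = -np.log(rng.random(k)) / mu_t
        z_new = z + uz * s
        esc = z_new < 0.0
        refl[idx[esc]] += w[esc]
        keep = ~esc
        idx = idx[keep]
        z = z_new[keep]
        ux, uy, uz, w = ux[keep], uy[keep], uz[keep], w[keep]
        if idx.size == 0:
            break
        # absorb
        dw = w * mu_a / mu_t
        w = w - dw
        # roulette
        low = w < w_thresh
        if low.any():
            u = rng.random(int(low.sum()))
            survive = u < 1.0 / m
            wl = w[low]
            wl[survive] *= m
            wl[~survive] = 0.0
            w[low] = wl
            dead = w <= 0.0
            keep = ~dead
            idx = idx[keep]
            z, ux, uy, uz, w = z[keep], ux[keep], uy[keep], uz[keep], w[keep]
            if idx.size == 0:
                break
        # HG spin
        k = idx.size
        ct = hg_cos_vec(g, rng.random(k))
        st = np.sqrt(np.maximum(0.0, 1.0 - ct * ct))
        phi = 2.0 * np.pi * rng.random(k)
        cp, sp = np.cos(phi), np.sin(phi)
        near_pole = np.abs(uz) > 0.99999
        den = np.sqrt(np.maximum(1e-30, 1.0 - uz * uz))
        nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
        nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nuz = -st * cp * den + uz * ct
        nux = np.where(near_pole, st * cp, nux)
        nuy = np.where(near_pole, st * sp, nuy)
        nuz = np.where(near_pole, np.sign(uz) * ct, nuz)
        norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
        ux, uy, uz = nux / norm, nuy / norm, nuz / norm

    return float(refl.mean()), float(refl.std(ddof=1))


def hg_mean_cos_numeric(g, n_grid=200_001):
    """E[cos theta] under the Henyey-Greenstein density by quadrature."""
    mu = np.linspace(-1.0, 1.0, n_grid)
    p = 0.5 * (1 - g * g) / (1 + g * g - 2 * g * mu) ** 1.5
    return float(np.trapezoid(mu * p, mu) / np.trapezoid(p, mu))
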