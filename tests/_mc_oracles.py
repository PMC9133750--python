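"""Independent oracles for the photon-transport module.

Two routes that share no code with the package walker's bookkeeping:

* ``naive_reflectance`` — an unweighted, unoptimized random walk (photons
  terminate by absorption sampling instead of carrying weights; no roulette,
  no layers, no tallies) for a semi-infinite matched-boundary medium.
* ``isotropic_normal_reflectance`` — the exact Chandrasekhar H-function
  solution for a semi-infinite isotropic-scattering half-space under normal
  incidence: R(µ0=1) = 1 − H(1)·√(1−ω).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def naive_reflectance(n_photons, mua, mus, g, seed):
    np.random.seed(seed)
    mut = mua + mus
    albedo = mus / mut
    n_out = 0
    for _ in range(n_photons):
        z = 0.0
        ux, uy, uz = 0.0, 0.0, 1.0
        while True:
            s = -np.log(np.random.random() + 1e-300) / mut
            z += uz * s
            if z < 0.0:
                n_out += 1
                break
            if np.random.random() > albedo:
                break  # absorbed
            if g != 0.0:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
                ct = min(1.0, max(-1.0, ct))
            else:
                ct = 2.0 * np.random.random() - 1.0
            st = np.sqrt(1.0 - ct * ct)
            phi = 2.0 * np.pi * np.random.random()
            cp, sp = np.cos(phi), np.sin(phi)
            if abs(uz) > 0.99999:
                ux, uy, uz = st * cp, st * sp, ct * (1.0 if uz >= 0 else -1.0)
            else:
                den = np.sqrt(1.0 - uz * uz)
                nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nuz = -st * cp * den + uz * ct
                norm = np.sqrt(nux * nux + nuy * nuy + nuz * nuz)
                ux, uy, uz = nux / norm, nuy / norm, nuz / norm
    return n_out / n_photons


def isotropic_normal_reflectance(omega, n_quad=400, n_iter=400):
    """Exact reflectance of a semi-infinite isotropic half-space, µ0 = 1."""
    x, w = np.polynomial.legendre.leggauss(n_quad)
    mu_q = 0.5 * (x + 1.0)
    w_q = 0.5 * w
    H = np.ones_like(mu_q)
    root = np.sqrt(1.0 - omega)
    for _ in range(n_iter):
        integ = ((w_q * H * mu_q)[None, :]
                 / (mu_q[:, None] + mu_q[None, :])).sum(axis=1)
        H_new = 1.0 / (root + (omega / 2.0) * integ)
        if np.max(np.abs(H_new - H)) < 1e-13:
            H = H_new
            break
        H = H_new
    integ1 = np.sum(w_q * H * mu_q / (1.0 + mu_q))
    H1 = 1.0 / (root + (omega / 2.0) * integ1)
    return 1.0 - H1 * root
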