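"""Independent test oracles.

Deliberately plain, scalar, loop-based reimplementations used to cross-check
the package's vectorised code paths: trapezoid-rule integration for the
photometric/melanopic integrals, an exhaustive nearest-point search on a
1 K Planck table for CCT/Duv, and a from-scratch scalar CIECAM02/CAM02-UCS
plus fidelity scoring loop.  Nothing here imports the implementation being
checked beyond the shared reference tables and sample definitions.
"""

from __future__ import annotations

import math

import numpy as np

from metamel.tables import (
    CMF_2DEG,
    LUMINOUS_EFFICACY_MAX,
    S_MEL,
    V_LAMBDA,
    WAVELENGTHS,
)


def trapz_illuminance(values: np.ndarray) -> float:
    return LUMINOUS_EFFICACY_MAX * float(np.trapezoid(V_LAMBDA * values, WAVELENGTHS))


def trapz_melanopic_irradiance(values: np.ndarray) -> float:
    return float(np.trapezoid(S_MEL * values, WAVELENGTHS))


def brute_force_cct_duv(
    u_prime: float, v_prime: float, step_k: float = 1.0
) -> tuple[float, float]:
    """Exhaustive scan of a dense Planck table in CIE 1960 uv."""
    ccts = np.arange(1500.0, 15000.0 + step_k, step_k)
    lam = WAVELENGTHS * 1e-9
    uv = np.empty((ccts.size, 2))
    for i, cct in enumerate(ccts):
        spd = lam ** -5.0 / np.expm1(1.4388e-2 / (lam * cct))
        x, y, z = CMF_2DEG.T @ spd
        d = x + 15.0 * y + 3.0 * z
        uv[i] = 4.0 * x / d, 6.0 * y / d
    u, v = u_prime, 2.0 / 3.0 * v_prime
    dist = np.hypot(uv[:, 0] - u, uv[:, 1] - v)
    i = int(np.argmin(dist))
    sign = 1.0 if v > uv[i, 1] else -1.0
    return float(ccts[i]), sign * float(dist[i])


# ---------------------------------------------------------------------------
# Scalar CIECAM02 / CAM02-UCS and fidelity scoring
# ---------------------------------------------------------------------------

_CAT02 = (
    (0.7328, 0.4296, -0.1624),
    (-0.7036, 1.6975, 0.0061),
    (0.0030, 0.0136, 0.9834),
)
_HPE = (
    (0.38971, 0.68898, -0.07868),
    (-0.22981, 1.18340, 0.04641),
    (0.0, 0.0, 1.0),
)


def _matvec(m, v):
    return [sum(m[i][j] * v[j] for j in range(3)) for i in range(3)]


def _inv3(m):
    a = np.linalg.inv(np.array(m))
    return tuple(tuple(float(x) for x in row) for row in a)


def scalar_cam02ucs(xyz, white, l_a=100.0, y_b=20.0):
    """Scalar CIECAM02 -> (J', a', b', h) for one sample."""
    f, c, n_c = 1.0, 0.69, 1.0
    y_w = white[1]
    k = 1.0 / (5.0 * l_a + 1.0)
    f_l = 0.2 * k ** 4 * 5.0 * l_a + 0.1 * (1.0 - k ** 4) ** 2 * (
        5.0 * l_a
    ) ** (1.0 / 3.0)
    n = y_b / y_w
    n_bb = 0.725 * (1.0 / n) ** 0.2
    z = 1.48 + math.sqrt(n)
    d = f * (1.0 - (1.0 / 3.6) * math.exp((-l_a - 42.0) / 92.0))
    d = min(max(d, 0.0), 1.0)

    rgb_w = _matvec(_CAT02, white)
    factors = [d * y_w / rgb_w[i] + 1.0 - d for i in range(3)]
    rgb = _matvec(_CAT02, xyz)
    rgb_c = [rgb[i] * factors[i] for i in range(3)]
    rgb_wc = [rgb_w[i] * factors[i] for i in range(3)]

    cat_inv = _inv3(_CAT02)
    rgb_p = _matvec(_HPE, _matvec(cat_inv, rgb_c))
    rgb_wp = _matvec(_HPE, _matvec(cat_inv, rgb_wc))

    def resp(v):
        t = (f_l * abs(v) / 100.0) ** 0.42
        return math.copysign(400.0 * t / (t + 27.13), v) + 0.1

    ra, ga, ba = (resp(v) for v in rgb_p)
    raw, gaw, baw = (resp(v) for v in rgb_wp)

    a = ra - 12.0 * ga / 11.0 + ba / 11.0
    b = (ra + ga - 2.0 * ba) / 9.0
    h = math.degrees(math.atan2(b, a)) % 360.0
    big_a = (2.0 * ra + ga + ba / 20.0 - 0.305) * n_bb
    big_aw = (2.0 * raw + gaw + baw / 20.0 - 0.305) * n_bb
    j = 100.0 * max(big_a / big_aw, 0.0) ** (c * z)
    e_t = 0.25 * (math.cos(math.radians(h) + 2.0) + 3.8)
    t = (
        (50000.0 / 13.0) * n_c * n_bb * e_t * math.hypot(a, b)
        / (ra + ga + 21.0 * ba / 20.0)
    )
    cc = t ** 0.9 * math.sqrt(j / 100.0) * (1.64 - 0.29 ** n) ** 0.73
    m = cc * f_l ** 0.25

    j_u = 1.7 * j / (1.0 + 0.007 * j)
    m_u = math.log(1.0 + 0.0228 * m) / 0.0228
    return (
        j_u,
        m_u * math.cos(math.radians(h)),
        m_u * math.sin(math.radians(h)),
        h,
    )


def scalar_rf(test_values, ref_values, samples) -> float:
    """Loop-based general fidelity index over a reflectance panel."""

    def prepare(values):
        xyz_w = [float(x) for x in CMF_2DEG.T @ values]
        scale = 100.0 / xyz_w[1]
        return values * scale, [v * scale for v in xyz_w]

    test_values, white_t = prepare(np.asarray(test_values, dtype=float))
    ref_values, white_r = prepare(np.asarray(ref_values, dtype=float))
    deltas = []
    for refl in samples:
        xyz_t = [float(x) for x in CMF_2DEG.T @ (refl * test_values)]
        xyz_r = [float(x) for x in CMF_2DEG.T @ (refl * ref_values)]
        jt = scalar_cam02ucs(xyz_t, white_t)
        jr = scalar_cam02ucs(xyz_r, white_r)
        deltas.append(
            math.dist(jt[:3], jr[:3])
        )
    mean = sum(deltas) / len(deltas)
    return 10.0 * math.log(math.exp((100.0 - 6.73 * mean) / 10.0) + 1.0)
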