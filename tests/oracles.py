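"""Independent scalar oracles for the test suite.

Everything here is a deliberately naive, loop-based, pure-Python
re-derivation of the quantities the package computes with vectorized numpy:
single-pixel color conversions, single-pair metric formulas, and two-pass
statistics. Tests compare the package against these; nothing here imports
from chromadiff.
"""

import math

# --- color conversions (single pixel) ---------------------------------------

SRGB_M = (
    (0.4124564, 0.3575761, 0.1804375),
    (0.2126729, 0.7151522, 0.0721750),
    (0.0193339, 0.1191920, 0.9503041),
)
D65 = (0.95047, 1.00000, 1.08883)


def srgb_to_xyz_scalar(r8, g8, b8, wp=D65):
    lin = []
    for v in (r8, g8, b8):
        v = v / 255.0
        lin.append(v / 12.92 if v <= 0.04045 else ((v + 0.055) / 1.055) ** 2.4)
    out = []
    for i in range(3):
        row_sum = sum(SRGB_M[i])
        acc = sum(SRGB_M[i][j] * lin[j] for j in range(3))
        out.append(acc * wp[i] / row_sum)
    return tuple(out)


def _f(t):
    d = 6.0 / 29.0
    return t ** (1.0 / 3.0) if t > d**3 else t / (3 * d * d) + 4.0 / 29.0


def xyz_to_lab_scalar(x, y, z, wp=D65):
    fx, fy, fz = _f(x / wp[0]), _f(y / wp[1]), _f(z / wp[2])
    return (116.0 * fy - 16.0, 500.0 * (fx - fy), 200.0 * (fy - fz))


def xyz_to_luv_scalar(x, y, z, wp=D65):
    denom = x + 15.0 * y + 3.0 * z
    dn = wp[0] + 15.0 * wp[1] + 3.0 * wp[2]
    un, vn = 4.0 * wp[0] / dn, 9.0 * wp[1] / dn
    L = 116.0 * _f(y / wp[1]) - 16.0
    if denom <= 0:
        return (L, 0.0, 0.0)
    up, vp = 4.0 * x / denom, 9.0 * y / denom
    return (L, 13.0 * L * (up - un), 13.0 * L * (vp - vn))


def srgb_to_lab_scalar(r8, g8, b8, wp=D65):
    return xyz_to_lab_scalar(*srgb_to_xyz_scalar(r8, g8, b8, wp), wp=wp)


def srgb_to_luv_scalar(r8, g8, b8, wp=D65):
    return xyz_to_luv_scalar(*srgb_to_xyz_scalar(r8, g8, b8, wp), wp=wp)


# --- metrics (single pair) ---------------------------------------------------


def cie76_scalar(t1, t2):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(t1, t2)))


def cie94_scalar(lab1, lab2, kL=1.0, kC=1.0, kH=1.0, k1=0.045, k2=0.015):
    L1, a1, b1 = lab1
    L2, a2, b2 = lab2
    C1 = math.hypot(a1, b1)
    C2 = math.hypot(a2, b2)
    dC = C1 - C2
    dH2 = max((a1 - a2) ** 2 + (b1 - b2) ** 2 - dC**2, 0.0)
    SC = 1.0 + k1 * C1
    SH = 1.0 + k2 * C2
    return math.sqrt(
        ((L1 - L2) / kL) ** 2 + (dC / (kC * SC)) ** 2 + dH2 / (kH * SH) ** 2
    )


def ciede2000_scalar(lab1, lab2, kL=1.0, kC=1.0, kH=1.0):
    L1, a1, b1 = lab1
    L2, a2, b2 = lab2
    Cb = 0.5 * (math.hypot(a1, b1) + math.hypot(a2, b2))
    G = 0.5 * (1.0 - math.sqrt(Cb**7 / (Cb**7 + 25.0**7)))
    a1p, a2p = (1 + G) * a1, (1 + G) * a2
    C1p, C2p = math.hypot(a1p, b1), math.hypot(a2p, b2)
    h1p = math.degrees(math.atan2(b1, a1p)) % 360.0 if C1p else 0.0
    h2p = math.degrees(math.atan2(b2, a2p)) % 360.0 if C2p else 0.0
    dLp, dCp = L2 - L1, C2p - C1p
    if C1p * C2p == 0:
        dhp = 0.0
    else:
        dhp = h2p - h1p
        if dhp > 180:
            dhp -= 360
        elif dhp < -180:
            dhp += 360
    dHp = 2.0 * math.sqrt(C1p * C2p) * math.sin(math.radians(dhp) / 2.0)
    Lbp, Cbp = 0.5 * (L1 + L2), 0.5 * (C1p + C2p)
    if C1p * C2p == 0:
        hbp = h1p + h2p
    elif abs(h1p - h2p) <= 180:
        hbp = 0.5 * (h1p + h2p)
    elif h1p + h2p < 360:
        hbp = 0.5 * (h1p + h2p + 360)
    else:
        hbp = 0.5 * (h1p + h2p - 360)
    rad = math.radians
    T = (
        1
        - 0.17 * math.cos(rad(hbp - 30))
        + 0.24 * math.cos(rad(2 * hbp))
        + 0.32 * math.cos(rad(3 * hbp + 6))
        - 0.20 * math.cos(rad(4 * hbp - 63))
    )
    dTheta = 30.0 * math.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * math.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    RT = -math.sin(rad(2 * dTheta)) * RC
    SL = 1 + 0.015 * (Lbp - 50) ** 2 / math.sqrt(20 + (Lbp - 50) ** 2)
    SC = 1 + 0.045 * Cbp
    SH = 1 + 0.015 * Cbp * T
    tL, tC, tH = dLp / (kL * SL), dCp / (kC * SC), dHp / (kH * SH)
    return math.sqrt(max(tL**2 + tC**2 + tH**2 + RT * tC * tH, 0.0))


def cmc_scalar(lch1, lch2, l=2.0, c=1.0):
    L1, C1, h1 = lch1
    L2, C2, h2 = lch2
    dL, dC = L2 - L1, C2 - C1
    dH2 = max(2.0 * C1 * C2 * (1.0 - math.cos(math.radians(h2 - h1))), 0.0)
    if 164.0 <= h1 <= 345.0:
        T = 0.56 + abs(0.2 * math.cos(math.radians(h1 + 168.0)))
    else:
        T = 0.36 + abs(0.4 * math.cos(math.radians(h1 + 35.0)))
    F = math.sqrt(C1**4 / (C1**4 + 1900.0))
    SL = 0.511 if L1 < 16.0 else 0.040975 * L1 / (1.0 + 0.01765 * L1)
    SC = 0.0638 * C1 / (1.0 + 0.0131 * C1) + 0.638
    SH = SC * (F * T + 1.0 - F)
    return math.sqrt((dL / (l * SL)) ** 2 + (dC / (c * SC)) ** 2 + dH2 / SH**2)


def lab_to_lch_scalar(lab):
    L, a, b = lab
    C = math.hypot(a, b)
    h = math.degrees(math.atan2(b, a)) % 360.0 if C else 0.0
    return (L, C, h)


# --- statistics --------------------------------------------------------------


def moments_scalar(values):
    """(mean, population variance, skewness, excess kurtosis) by plain loops."""
    n = len(values)
    m = sum(values) / n
    var = sum((v - m) ** 2 for v in values) / n
    if var == 0:
        return m, 0.0, 0.0, 0.0
    m3 = sum((v - m) ** 3 for v in values) / n
    m4 = sum((v - m) ** 4 for v in values) / n
    return m, var, m3 / var**1.5, m4 / var**2 - 3.0


def entropy_scalar(byte_values):
    """Shannon entropy in bits of the 256-bin histogram."""
    n = len(byte_values)
    counts = [0] * 256
    for v in byte_values:
        counts[int(v)] += 1
    h = 0.0
    for c in counts:
        if c:
            p = c / n
            h -= p * math.log2(p)
    return h


def pearson_scalar(xs, ys):
    """Two-pass Pearson correlation."""
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / math.sqrt(sxx * syy)


def ols_scalar(xs, ys):
    """Normal-equation OLS: (slope, intercept, r_squared)."""
    n = len(xs)
    mx, my = sum(xs) / n, sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    slope = sxy / sxx
    intercept = my - slope * mx
    syy = sum((y - my) ** 2 for y in ys)
    ss_res = sum((y - (intercept + slope * x)) ** 2 for x, y in zip(xs, ys))
    r2 = 1.0 - ss_res / syy if syy > 0 else 0.0
    return slope, intercept, r2
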