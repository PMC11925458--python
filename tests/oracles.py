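"""Independent numerical oracles used by the test suite.

These deliberately avoid the package's own intersection/linking code
paths: the segment/triangle oracle rasterises the triangle by dense
barycentric sampling, and the linking oracle integrates the Gauss double
integral over densified polygon edges.
"""

from __future__ import annotations

import numpy as np


def segment_triangle_bruteforce(p0, p1, tri, n_bary=80, tol=0.04):
    """Approximate segment/triangle intersection by rasterisation.

    The triangle is rasterised by dense barycentric sampling; each sample
    point's exact distance to the segment is evaluated in closed form.
    Returns True when some sample lies within ``tol`` of the segment.
    Accurate to the triangle sampling resolution, so callers should avoid
    near-grazing configurations.
    """
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    tri = np.asarray(tri, float)
    us, vs = np.meshgrid(np.linspace(0, 1, n_bary), np.linspace(0, 1, n_bary))
    mask = us + vs <= 1.0
    u = us[mask]
    v = vs[mask]
    pts = (1 - u - v)[:, None] * tri[0] + u[:, None] * tri[1] + v[:, None] * tri[2]
    d = p1 - p0
    denom = float(d @ d)
    t = ((pts - p0) @ d) / denom if denom > 0 else np.zeros(len(pts))
    t = np.clip(t, 0.0, 1.0)
    nearest = p0[None, :] + t[:, None] * d[None, :]
    d2 = ((pts - nearest) ** 2).sum(-1)
    return bool(d2.min() < tol * tol)


def gauss_linking_number(P, Q, sub=24):
    """Gauss double integral over two closed polygons (midpoint rule).

    Returns ``(value, min_distance)``; the value approximates the linking
    number, and ``min_distance`` lets callers discard ill-conditioned
    near-contact pairs.
    """
    def densify(C):
        C = np.asarray(C, float)
        nxt = np.roll(C, -1, axis=0)
        t = np.tile(np.arange(sub) / sub, len(C))[:, None]
        return np.repeat(C, sub, axis=0) * (1 - t) + np.repeat(nxt, sub, axis=0) * t

    A = densify(P)
    B = densify(Q)
    dA = np.roll(A, -1, axis=0) - A
    dB = np.roll(B, -1, axis=0) - B
    RA = A + dA / 2
    RB = B + dB / 2
    diff = RA[:, None, :] - RB[None, :, :]
    r2 = (diff ** 2).sum(-1)
    cross = np.cross(dA[:, None, :], dB[None, :, :])
    integral = ((cross * diff).sum(-1) / r2 ** 1.5).sum() / (4 * np.pi)
    return float(integral), float(np.sqrt(r2.min()))


def smooth_closed_curve(rng, n=40, scale=5.0, harmonics=4):
    """Random smooth closed polygon from a low-order trigonometric series."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.zeros((n, 3))
    for ax in range(3):
        c = rng.normal(0, 1, harmonics) / np.arange(1, harmonics + 1)
        s = rng.normal(0, 1, harmonics) / np.arange(1, harmonics + 1)
        pts[:, ax] = sum(c[k] * np.cos((k + 1) * th) + s[k] * np.sin((k + 1) * th)
                         for k in range(harmonics))
    return pts * scale
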