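"""Shared brute-force ray-quadric oracle: sampling + bisection refinement."""
import numpy as np


def bisection_first_hit(quad, origin, direction, t_max=40.0, n=100_000):
    """First positive ray-surface crossing inside the clip slab.

    Samples the quadric form along the ray, brackets every sign change,
    refines each by bisection, and returns the first refined root whose
    point passes the slab test — independent of the closed-form quadratic
    solve it checks.
    """
    ts = np.linspace(1e-9, t_max, n)
    pts = origin[None] + ts[:, None] * direction[None]
    ph = np.concatenate([pts, np.ones((n, 1))], axis=1)
    vals = np.einsum("ij,jk,ik->i", ph, quad.Q, ph)
    sign = np.sign(vals)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for ci in crossings:
        lo, hi = ts[ci], ts[ci + 1]
        f_lo = vals[ci]
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            pm = np.append(origin + mid * direction, 1.0)
            f_mid = float(pm @ quad.Q @ pm)
            if np.sign(f_mid) == np.sign(f_lo):
                lo, f_lo = mid, f_mid
            else:
                hi = mid
        t = 0.5 * (lo + hi)
        if quad.in_slab(origin + t * direction):
            return t
    return None
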