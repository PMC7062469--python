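import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def star_polygon(rng, center, r_lo=2.0, r_hi=8.0, n_lo=3, n_hi=9):
    """Random star-convex polygon with float vertices (no edge through a
    pixel center, almost surely), as (row, col) vertex array."""
    n = int(rng.integers(n_lo, n_hi))
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    rad = rng.uniform(r_lo, r_hi, n)
    return np.column_stack(
        [center[0] + rad * np.sin(ang), center[1] + rad * np.cos(ang)]
    )


def point_in_polygon(pr, pc, poly):
    """Crossing-number (ray casting) point-in-polygon test, independent of
    any rasterization library; used as the brute-force coverage oracle."""
    n = len(poly)
    inside = False
    j = n - 1
    for i in range(n):
        ri, ci = poly[i]
        rj, cj = poly[j]
        if ((ci > pc) != (cj > pc)) and (pr < (rj - ri) * (pc - ci) / (cj - ci) + ri):
            inside = not inside
        j = i
    return inside
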