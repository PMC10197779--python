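import numpy as np
import pytest

import lifttomo as lt


@pytest.fixture(scope="session")
def small_geom():
    """Non-compressive plan at N=32 spread over 4 views."""
    return lt.build_view_plan(4, 32, image_size_N=32)


@pytest.fixture(scope="session")
def disk_image():
    """Smooth blob supported on the inscribed disk (content never leaves
    the field under rotation), N=32."""
    N = 32
    yy, xx = np.meshgrid(np.arange(N), np.arange(N), indexing="ij")
    c = (N - 1) / 2
    r2 = (yy - c) ** 2 + (xx - c) ** 2
    img = np.exp(-r2 / (2 * 5.0 ** 2))
    img[r2 > (N / 2 - 3) ** 2] = 0.0
    return img


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def brute_force_rotate(img, theta_deg):
    """Independent inverse-mapping bilinear rotation oracle (pure loops)."""
    import math
    N = img.shape[0]
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    ctr = (N - 1) / 2.0
    out = np.zeros_like(img, dtype=float)
    for yo in range(N):
        for xo in range(N):
            dy, dx = yo - ctr, xo - ctr
            # inverse of forward map x' = x c - y s, y' = x s + y c
            sx = c * dx + s * dy + ctr
            sy = -s * dx + c * dy + ctr
            x0, y0 = math.floor(sx), math.floor(sy)
            fx, fy = sx - x0, sy - y0
            acc = 0.0
            for ddy, ddx, w in ((0, 0, (1 - fy) * (1 - fx)),
                                (0, 1, (1 - fy) * fx),
                                (1, 0, fy * (1 - fx)),
                                (1, 1, fy * fx)):
                yy, xx = y0 + ddy, x0 + ddx
                if 0 <= yy < N and 0 <= xx < N:
                    acc += w * img[yy, xx]
            out[yo, xo] = acc
    return out
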