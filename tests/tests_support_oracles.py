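"""Brute-force reference implementations used as independent oracles."""

import numpy as np


def brute_force_lambda(frame, hw, M):
    """Direct double-loop local-contrast sum (out-of-frame contributes 0)."""
    H, W = frame.shape
    out = np.zeros_like(frame)
    for x in range(H):
        for y in range(W):
            s = 0.0
            for i in range(-hw, hw + 1):
                for j in range(-hw, hw + 1):
                    if i == 0 and j == 0:
                        continue
                    xi, yj = x + i, y + j
                    if 0 <= xi < H and 0 <= yj < W:
                        s += abs(frame[x, y] - frame[xi, yj])
            out[x, y] = s / M
    return out


def brute_force_delta(v_cx, p):
    """Direct quadruple-loop motion-discontinuity sum."""
    H, W, N = v_cx.shape
    th = np.deg2rad(np.asarray(p.directions))
    hw = p.surround_halfwidth
    out = np.zeros_like(v_cx)
    for x in range(H):
        for y in range(W):
            for t in range(N):
                s = 0.0
                for i in range(-hw, hw + 1):
                    for j in range(-hw, hw + 1):
                        xi, yj = x + i, y + j
                        if 0 <= xi < H and 0 <= yj < W:
                            for psi in range(N):
                                s += (1.0 - np.cos(th[psi] - th[t])) \
                                     * v_cx[xi, yj, psi]
                out[x, y, t] = s / (10.0 * p.M)
    return np.clip(out, 0.0, 1.0)
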