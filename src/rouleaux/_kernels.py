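"""Numba kernels: cell-list neighbor search, pair forces, time stepping.

The tube is periodic along x and bounded by rigid walls in y, so the cell
list wraps in x only.  Pair interactions are cut off at a center distance
of ``2R + r_cut``; each pair is evaluated once (scan of the 3x3 neighbor
stencil with a ``j < i`` guard) and applied with opposite signs, which makes
Newton's third law exact by construction.

Kernels never raise: a coincident pair poisons the force array with NaN
(or, inside long runs, is resolved deterministically) and the Python layer
turns any remaining non-finite state into a diagnostic error.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# overlap depth (m) past which the Morse repulsion is frozen (overflow guard)
OVERLAP_GUARD = -0.5e-6


@njit(cache=True)
def pair_magnitude(d, R, k, DA, B, delta0, r_cut):
    """Signed magnitude (positive = repulsive) of elastic + Morse pair force."""
    delta = d - 2.0 * R
    mag = 0.0
    if delta < 0.0:
        mag += k * (-delta) ** 1.5
    if delta <= r_cut:
        dd = delta
        if dd < OVERLAP_GUARD:
            dd = OVERLAP_GUARD
        a = B * (delta0 - dd)
        mag += 2.0 * DA * B * (np.exp(2.0 * a) - np.exp(a))
    return mag


@njit(cache=True)
def _build_cells(pos, L, h, ncx, ncy):
    n = pos.shape[0]
    head = np.full(ncx * ncy, -1, np.int64)
    nxt = np.empty(n, np.int64)
    cix = np.empty(n, np.int64)
    ciy = np.empty(n, np.int64)
    for i in range(n):
        cx = int(pos[i, 0] / L * ncx)
        cx = cx % ncx
        if cx < 0:
            cx += ncx
        cy = int((pos[i, 1] + 0.5 * h) / h * ncy)
        if cy < 0:
            cy = 0
        elif cy >= ncy:
            cy = ncy - 1
        c = cy * ncx + cx
        nxt[i] = head[c]
        head[c] = i
        cix[i] = cx
        ciy[i] = cy
    return head, nxt, cix, ciy


@njit(cache=True)
def pairwise_forces(pos, L, h, R, k, DA, B, delta0, r_cut, resolve_coincident=False):
    """Per-particle sum of elastic + aggregation pair forces (N x 2 array).

    A coincident pair (center distance < 1 fm) has no defined direction:
    by default the force array is poisoned with NaN so the caller can raise
    a diagnostic error.  With ``resolve_coincident`` the pair is instead
    pushed apart along +x with the guard-clamped repulsion magnitude — the
    deterministic tie-break used inside long runs, where a hard failure on
    a measure-zero geometry would be worse than an arbitrary direction.
    """
    n = pos.shape[0]
    f = np.zeros((n, 2))
    rmax = 2.0 * R + r_cut
    ncx = int(L / rmax)
    ncy = int(h / rmax)
    if ncx < 3 or ncy < 1 or n < 16:
        # brute force for tiny systems / short tubes
        for i in range(n):
            for j in range(i):
                dx = pos[i, 0] - pos[j, 0]
                if dx > 0.5 * L:
                    dx -= L
                elif dx < -0.5 * L:
                    dx += L
                dy = pos[i, 1] - pos[j, 1]
                d2 = dx * dx + dy * dy
                if d2 < rmax * rmax:
                    d = np.sqrt(d2)
                    if d < 1e-15:
                        if resolve_coincident:
                            mag = pair_magnitude(0.0, R, k, DA, B, delta0, r_cut)
                            f[i, 0] += mag
                            f[j, 0] -= mag
                        else:
                            f[i, 0] = np.nan
                            f[i, 1] = np.nan
                    else:
                        mag = pair_magnitude(d, R, k, DA, B, delta0, r_cut)
                        fx = mag * dx / d
                        fy = mag * dy / d
                        f[i, 0] += fx
                        f[i, 1] += fy
                        f[j, 0] -= fx
                        f[j, 1] -= fy
        return f
    head, nxt, cix, ciy = _build_cells(pos, L, h, ncx, ncy)
    for i in range(n):
        cx = cix[i]
        cy = ciy[i]
        for oy in range(-1, 2):
            yy = cy + oy
            if yy < 0 or yy >= ncy:
                continue
            for ox in range(-1, 2):
                xx = (cx + ox) % ncx
                j = head[yy * ncx + xx]
                while j != -1:
                    if j < i:
                        dx = pos[i, 0] - pos[j, 0]
                        if dx > 0.5 * L:
                            dx -= L
                        elif dx < -0.5 * L:
                            dx += L
                        dy = pos[i, 1] - pos[j, 1]
                        d2 = dx * dx + dy * dy
                        if d2 < rmax * rmax:
                            d = np.sqrt(d2)
                            if d < 1e-15:
                                if resolve_coincident:
                                    mag = pair_magnitude(0.0, R, k, DA, B, delta0, r_cut)
                                    f[i, 0] += mag
                                    f[j, 0] -= mag
                                else:
                                    f[i, 0] = np.nan
                                    f[i, 1] = np.nan
                            else:
                                mag = pair_magnitude(d, R, k, DA, B, delta0, r_cut)
                                fx = mag * dx / d
                                fy = mag * dy / d
                                f[i, 0] += fx
                                f[i, 1] += fy
                                f[j, 0] -= fx
                                f[j, 1] -= fy
                    j = nxt[j]
    return f


@njit(cache=True)
def advance(
    pos, vel, t0, dt, nsteps,
    A_f, B_f, omega, k_f, h, L,
    R, m, k, DA, B, delta0, r_cut, gamma,
):
    """Advance ``nsteps`` of the split integrator, in place.

    Per step: pair + wall forces are frozen, then the linear drag ODE
    ``m v' = F + gamma (u - v)`` is solved exactly over dt (u frozen at the
    particle's start-of-step position); positions move by the exact time
    integral of that velocity.  x wraps periodically, y is clamped to the
    wall-contact limit as a safety net behind the Hertzian wall force.
    """
    n = pos.shape[0]
    tau = m / gamma
    e = np.exp(-dt / tau)
    ylim = 0.5 * h - R
    for s in range(nsteps):
        t = t0 + s * dt
        f = pairwise_forces(pos, L, h, R, k, DA, B, delta0, r_cut, True)
        for i in range(n):
            y = pos[i, 1]
            # virtual Hertzian contact with a mirror particle across the wall
            if y > ylim:
                ov = 2.0 * (y - ylim)
                f[i, 1] -= k * ov**1.5
            elif y < -ylim:
                ov = 2.0 * (-y - ylim)
                f[i, 1] += k * ov**1.5
            env = 1.0 - 4.0 * y * y / (h * h)
            ux = (A_f * np.sin(omega * t - k_f * pos[i, 0]) + B_f) * env
            vinfx = ux + f[i, 0] / gamma
            vinfy = f[i, 1] / gamma
            dvx = vel[i, 0] - vinfx
            dvy = vel[i, 1] - vinfy
            pos[i, 0] += vinfx * dt + dvx * tau * (1.0 - e)
            pos[i, 1] += vinfy * dt + dvy * tau * (1.0 - e)
            vel[i, 0] = vinfx + dvx * e
            vel[i, 1] = vinfy + dvy * e
            if pos[i, 0] >= L or pos[i, 0] < 0.0:
                pos[i, 0] = pos[i, 0] % L
            if pos[i, 1] > ylim:
                pos[i, 1] = ylim
            elif pos[i, 1] < -ylim:
                pos[i, 1] = -ylim
    return t0 + nsteps * dt


@njit(cache=True)
def _count_or_fill_pairs(pos, L, h, thresh, out_i, out_j, fill):
    n = pos.shape[0]
    count = 0
    ncx = int(L / thresh)
    ncy = int(h / thresh)
    if ncx < 3 or ncy < 1 or n < 16:
        for i in range(n):
            for j in range(i):
                dx = pos[i, 0] - pos[j, 0]
                if dx > 0.5 * L:
                    dx -= L
                elif dx < -0.5 * L:
                    dx += L
                dy = pos[i, 1] - pos[j, 1]
                if dx * dx + dy * dy < thresh * thresh:
                    if fill:
                        out_i[count] = i
                        out_j[count] = j
                    count += 1
        return count
    head, nxt, cix, ciy = _build_cells(pos, L, h, ncx, ncy)
    for i in range(n):
        cx = cix[i]
        cy = ciy[i]
        for oy in range(-1, 2):
            yy = cy + oy
            if yy < 0 or yy >= ncy:
                continue
            for ox in range(-1, 2):
                xx = (cx + ox) % ncx
                j = head[yy * ncx + xx]
                while j != -1:
                    if j < i:
                        dx = pos[i, 0] - pos[j, 0]
                        if dx > 0.5 * L:
                            dx -= L
                        elif dx < -0.5 * L:
                            dx += L
                        dy = pos[i, 1] - pos[j, 1]
                        if dx * dx + dy * dy < thresh * thresh:
                            if fill:
                                out_i[count] = i
                                out_j[count] = j
                            count += 1
                    j = nxt[j]
    return count


def close_pairs(pos: np.ndarray, L: float, h: float, thresh: float):
    """All pairs (i, j), i > j, with periodic-x center distance < ``thresh``."""
    pos = np.ascontiguousarray(pos, dtype=np.float64)
    empty = np.empty(0, np.int64)
    count = _count_or_fill_pairs(pos, L, h, thresh, empty, empty, False)
    out_i = np.empty(count, np.int64)
    out_j = np.empty(count, np.int64)
    _count_or_fill_pairs(pos, L, h, thresh, out_i, out_j, True)
    return out_i, out_j


@njit(cache=True)
def place_rsa(N, L, h, R, seed, max_attempts):
    """Random sequential placement of N non-overlapping disks in the tube.

    Centers are uniform over x in [0, L) (periodic) and |y| <= h/2 - R, with
    pairwise center distance >= 2R.  Returns (positions, attempts); attempts
    is -1 on failure (packing too dense for the attempt budget).
    """
    np.random.seed(seed)
    pos = np.empty((N, 2))
    ncx = max(3, int(L / (2.0 * R)))
    ncy = max(1, int(h / (2.0 * R)))
    brute = L / ncx < 2.0 * R  # very short tube: fall back to all-pairs checks
    head = np.full(ncx * ncy, -1, np.int64)
    nxt = np.empty(N, np.int64)
    ylim = 0.5 * h - R
    placed = 0
    attempts = 0
    four_r2 = 4.0 * R * R
    while placed < N:
        attempts += 1
        if attempts > max_attempts:
            return pos[:placed], -1
        x = np.random.uniform(0.0, L)
        y = np.random.uniform(-ylim, ylim)
        ok = True
        if brute:
            for j in range(placed):
                dx = x - pos[j, 0]
                if dx > 0.5 * L:
                    dx -= L
                elif dx < -0.5 * L:
                    dx += L
                dy = y - pos[j, 1]
                if dx * dx + dy * dy < four_r2:
                    ok = False
                    break
        else:
            cx = int(x / L * ncx) % ncx
            cy = int((y + 0.5 * h) / h * ncy)
            if cy < 0:
                cy = 0
            elif cy >= ncy:
                cy = ncy - 1
            for oy in range(-1, 2):
                yy = cy + oy
                if yy < 0 or yy >= ncy:
                    continue
                for ox in range(-1, 2):
                    xx = (cx + ox) % ncx
                    j = head[yy * ncx + xx]
                    while j != -1:
                        dx = x - pos[j, 0]
                        if dx > 0.5 * L:
                            dx -= L
                        elif dx < -0.5 * L:
                            dx += L
                        dy = y - pos[j, 1]
                        if dx * dx + dy * dy < four_r2:
                            ok = False
                            break
                        j = nxt[j]
                    if not ok:
                        break
                if not ok:
                    break
        if ok:
            pos[placed, 0] = x
            pos[placed, 1] = y
            if not brute:
                cx = int(x / L * ncx) % ncx
                cy = int((y + 0.5 * h) / h * ncy)
                if cy < 0:
                    cy = 0
                elif cy >= ncy:
                    cy = ncy - 1
                c = cy * ncx + cx
                nxt[placed] = head[c]
                head[c] = placed
            placed += 1
    return pos, attempts
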