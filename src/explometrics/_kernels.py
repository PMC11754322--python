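"""Numerical inner loops, JIT-compiled when numba is available.

Each kernel has a pure-Python twin so the package degrades gracefully;
the JIT path is selected once at import time.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(func):
            return func

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _rediscretize_core(xy, step):  # pragma: no cover - compiled
    n = xy.shape[0]
    total = 0.0
    for i in range(n - 1):
        dx = xy[i + 1, 0] - xy[i, 0]
        dy = xy[i + 1, 1] - xy[i, 1]
        total += (dx * dx + dy * dy) ** 0.5
    m = int(total / step) + 2
    out = np.empty((m, 2))
    out[0, 0] = xy[0, 0]
    out[0, 1] = xy[0, 1]
    k = 1
    cx = xy[0, 0]
    cy = xy[0, 1]
    seg = 0
    t = 0.0
    while k < m:
        found = False
        j = seg
        lo = t
        while j < n - 1:
            ax = xy[j, 0]
            ay = xy[j, 1]
            dx = xy[j + 1, 0] - ax
            dy = xy[j + 1, 1] - ay
            a = dx * dx + dy * dy
            if a > 0.0:
                fx = ax - cx
                fy = ay - cy
                b = 2.0 * (dx * fx + dy * fy)
                c = fx * fx + fy * fy - step * step
                disc = b * b - 4.0 * a * c
                if disc >= 0.0:
                    u = (-b + disc**0.5) / (2.0 * a)
                    if lo - 1e-12 <= u <= 1.0 + 1e-12:
                        if u < lo:
                            u = lo
                        if u > 1.0:
                            u = 1.0
                        cx = ax + u * dx
                        cy = ay + u * dy
                        out[k, 0] = cx
                        out[k, 1] = cy
                        k += 1
                        seg = j
                        t = u
                        found = True
                        break
            j += 1
            lo = 0.0
        if not found:
            break
    return out[:k]


def _rediscretize_py(xy, step):
    """Reference Python implementation of the constant-step walker."""
    n = xy.shape[0]
    out = [xy[0].copy()]
    cur = xy[0].copy()
    seg, t = 0, 0.0
    while True:
        found = False
        j, lo = seg, t
        while j < n - 1:
            a_pt = xy[j]
            d = xy[j + 1] - a_pt
            a = float(d @ d)
            if a > 0.0:
                f = a_pt - cur
                b = 2.0 * float(d @ f)
                c = float(f @ f) - step * step
                disc = b * b - 4.0 * a * c
                if disc >= 0.0:
                    u = (-b + np.sqrt(disc)) / (2.0 * a)
                    if lo - 1e-12 <= u <= 1.0 + 1e-12:
                        u = min(max(u, lo), 1.0)
                        cur = a_pt + u * d
                        out.append(cur.copy())
                        seg, t = j, u
                        found = True
                        break
            j += 1
            lo = 0.0
        if not found:
            break
    return np.asarray(out)


@njit(cache=True)
def _greedy_centers_core(xy, radius):  # pragma: no cover - compiled
    n = xy.shape[0]
    centers = np.empty((n, 2))
    centers[0, 0] = xy[0, 0]
    centers[0, 1] = xy[0, 1]
    m = 1
    r2 = radius * radius
    for i in range(1, n):
        x = xy[i, 0]
        y = xy[i, 1]
        new = True
        for j in range(m):
            dx = x - centers[j, 0]
            dy = y - centers[j, 1]
            if dx * dx + dy * dy <= r2:
                new = False
                break
        if new:
            centers[m, 0] = x
            centers[m, 1] = y
            m += 1
    return centers[:m]


def _greedy_centers_py(xy, radius):
    centers = [xy[0]]
    r2 = radius * radius
    for p in xy[1:]:
        arr = np.asarray(centers)
        d2 = np.sum((arr - p) ** 2, axis=1)
        if np.all(d2 > r2):
            centers.append(p)
    return np.asarray(centers)


@njit(cache=True)
def _walk_core(  # pragma: no cover - compiled
    n_samples,
    step,
    x0,
    y0,
    h0,
    pause_u,
    rev_u,
    noise,
    step_mult,
    activity,
    turnaround_rate,
    revisit_w,
    landmark_w,
    lmx,
    lmy,
    lm_radius,
    xmin,
    ymin,
    xmax,
    ymax,
    bin_size,
    uturn_steps,
    uturn_angle,
):
    out = np.empty((n_samples, 2))
    out[0, 0] = x0
    out[0, 1] = y0
    ncols = int(np.ceil((xmax - xmin) / bin_size - 1e-12))
    nrows = int(np.ceil((ymax - ymin) / bin_size - 1e-12))
    visited = np.zeros((ncols, nrows), dtype=np.uint8)
    nlm = lmx.shape[0]
    lm_visited = np.zeros(nlm, dtype=np.uint8)
    x, y, h = x0, y0, h0
    r2 = lm_radius * lm_radius
    uturn_left = 0  # remaining steps of an ongoing smooth U-turn
    for s in range(1, n_samples):
        bi = int((x - xmin) / bin_size)
        bj = int((y - ymin) / bin_size)
        if bi < 0:
            bi = 0
        if bi >= ncols:
            bi = ncols - 1
        if bj < 0:
            bj = 0
        if bj >= nrows:
            bj = nrows - 1
        visited[bi, bj] = 1
        for l in range(nlm):
            dx = lmx[l] - x
            dy = lmy[l] - y
            if dx * dx + dy * dy <= r2:
                lm_visited[l] = 1
        # dead-end turnarounds are initiated independently of pausing,
        # so the reversal count tracks the turnaround trait rather than
        # the share of time spent moving
        if uturn_left == 0 and rev_u[s - 1] < turnaround_rate:
            uturn_left = uturn_steps
        if pause_u[s - 1] < activity:
            out[s, 0] = x
            out[s, 1] = y
            continue
        if uturn_left > 0:
            # dead-end reversal: a tight smooth U-turn, invisible at
            # step scale but a full turnaround at flight scale
            h = h + uturn_angle
            uturn_left -= 1
            st = step * step_mult[s - 1]
            nx = x + st * np.cos(h)
            ny = y + st * np.sin(h)
            if nx < xmin:
                nx = 2.0 * xmin - nx
                h = np.pi - h
            if nx > xmax:
                nx = 2.0 * xmax - nx
                h = np.pi - h
            if ny < ymin:
                ny = 2.0 * ymin - ny
                h = -h
            if ny > ymax:
                ny = 2.0 * ymax - ny
                h = -h
            x, y = nx, ny
            out[s, 0] = x
            out[s, 1] = y
            continue
        h = h + noise[s - 1]
        vx = np.cos(h)
        vy = np.sin(h)
        if revisit_w > 0.0:
            best = 1e18
            tx = 0.0
            ty = 0.0
            foundv = False
            for ii in range(ncols):
                for jj in range(nrows):
                    if visited[ii, jj] == 1 and not (ii == bi and jj == bj):
                        cxx = xmin + (ii + 0.5) * bin_size
                        cyy = ymin + (jj + 0.5) * bin_size
                        dx = cxx - x
                        dy = cyy - y
                        d2 = dx * dx + dy * dy
                        if d2 < best:
                            best = d2
                            tx = dx
                            ty = dy
                            foundv = True
            if foundv and best > 1e-12:
                d = best**0.5
                vx += revisit_w * tx / d
                vy += revisit_w * ty / d
        if landmark_w > 0.0 and nlm > 0:
            best = 1e18
            tx = 0.0
            ty = 0.0
            foundl = False
            for l in range(nlm):
                if lm_visited[l] == 0:
                    dx = lmx[l] - x
                    dy = lmy[l] - y
                    d2 = dx * dx + dy * dy
                    if d2 < best:
                        best = d2
                        tx = dx
                        ty = dy
                        foundl = True
            if foundl and best > 1e-12:
                d = best**0.5
                vx += landmark_w * tx / d
                vy += landmark_w * ty / d
        h = np.arctan2(vy, vx)
        st = step * step_mult[s - 1]
        nx = x + st * np.cos(h)
        ny = y + st * np.sin(h)
        if nx < xmin:
            nx = 2.0 * xmin - nx
            h = np.pi - h
        if nx > xmax:
            nx = 2.0 * xmax - nx
            h = np.pi - h
        if ny < ymin:
            ny = 2.0 * ymin - ny
            h = -h
        if ny > ymax:
            ny = 2.0 * ymax - ny
            h = -h
        x, y = nx, ny
        out[s, 0] = x
        out[s, 1] = y
    return out


def _walk_py(*args):
    """Python twin of ``_walk_core`` (identical arithmetic)."""
    (
        n_samples,
        step,
        x0,
        y0,
        h0,
        pause_u,
        rev_u,
        noise,
        step_mult,
        activity,
        turnaround_rate,
        revisit_w,
        landmark_w,
        lmx,
        lmy,
        lm_radius,
        xmin,
        ymin,
        xmax,
        ymax,
        bin_size,
        uturn_steps,
        uturn_angle,
    ) = args
    out = np.empty((n_samples, 2))
    out[0] = (x0, y0)
    ncols = int(np.ceil((xmax - xmin) / bin_size - 1e-12))
    nrows = int(np.ceil((ymax - ymin) / bin_size - 1e-12))
    visited = np.zeros((ncols, nrows), dtype=np.uint8)
    nlm = lmx.shape[0]
    lm_visited = np.zeros(nlm, dtype=np.uint8)
    x, y, h = x0, y0, h0
    r2 = lm_radius * lm_radius
    cell_x = xmin + (np.arange(ncols) + 0.5) * bin_size
    cell_y = ymin + (np.arange(nrows) + 0.5) * bin_size
    uturn_left = 0
    for s in range(1, n_samples):
        bi = min(max(int((x - xmin) / bin_size), 0), ncols - 1)
        bj = min(max(int((y - ymin) / bin_size), 0), nrows - 1)
        visited[bi, bj] = 1
        if nlm:
            lm_visited |= ((lmx - x) ** 2 + (lmy - y) ** 2 <= r2).astype(np.uint8)
        if uturn_left == 0 and rev_u[s - 1] < turnaround_rate:
            uturn_left = uturn_steps
        if pause_u[s - 1] < activity:
            out[s] = (x, y)
            continue
        if uturn_left > 0:
            h = h + uturn_angle
            uturn_left -= 1
            st = step * step_mult[s - 1]
            nx = x + st * np.cos(h)
            ny = y + st * np.sin(h)
            if nx < xmin:
                nx, h = 2.0 * xmin - nx, np.pi - h
            if nx > xmax:
                nx, h = 2.0 * xmax - nx, np.pi - h
            if ny < ymin:
                ny, h = 2.0 * ymin - ny, -h
            if ny > ymax:
                ny, h = 2.0 * ymax - ny, -h
            x, y = nx, ny
            out[s] = (x, y)
            continue
        h = h + noise[s - 1]
        vx, vy = np.cos(h), np.sin(h)
        if revisit_w > 0.0:
            ii, jj = np.nonzero(visited)
            keep = ~((ii == bi) & (jj == bj))
            ii, jj = ii[keep], jj[keep]
            if len(ii):
                dx = cell_x[ii] - x
                dy = cell_y[jj] - y
                d2 = dx * dx + dy * dy
                kbest = int(np.argmin(d2))
                if d2[kbest] > 1e-12:
                    d = np.sqrt(d2[kbest])
                    vx += revisit_w * dx[kbest] / d
                    vy += revisit_w * dy[kbest] / d
        if landmark_w > 0.0 and nlm:
            unv = np.nonzero(lm_visited == 0)[0]
            if len(unv):
                dx = lmx[unv] - x
                dy = lmy[unv] - y
                d2 = dx * dx + dy * dy
                kbest = int(np.argmin(d2))
                if d2[kbest] > 1e-12:
                    d = np.sqrt(d2[kbest])
                    vx += landmark_w * dx[kbest] / d
                    vy += landmark_w * dy[kbest] / d
        h = np.arctan2(vy, vx)
        st = step * step_mult[s - 1]
        nx = x + st * np.cos(h)
        ny = y + st * np.sin(h)
        if nx < xmin:
            nx, h = 2.0 * xmin - nx, np.pi - h
        if nx > xmax:
            nx, h = 2.0 * xmax - nx, np.pi - h
        if ny < ymin:
            ny, h = 2.0 * ymin - ny, -h
        if ny > ymax:
            ny, h = 2.0 * ymax - ny, -h
        x, y = nx, ny
        out[s] = (x, y)
    return out


if HAVE_NUMBA:
    rediscretize_core = _rediscretize_core
    greedy_centers_core = _greedy_centers_core
    walk_core = _walk_core
else:  # pragma: no cover
    rediscretize_core = _rediscretize_py
    greedy_centers_core = _greedy_centers_py
    walk_core = _walk_py
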