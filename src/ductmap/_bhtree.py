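"""Barnes-Hut quadtree for the tSNE repulsive term (numba-compiled).

The 2-D map points are inserted into an adaptive quadtree; each node keeps
its mass (point count) and center-of-mass.  For a query point, a cell is
summarized by its center-of-mass whenever (cell diameter / distance) < theta,
giving the usual O(n log n) approximation of

    F_rep_i = sum_j E_ij^2 (y_i - y_j),   Z = sum_{i != j} E_ij,

with E_ij = 1/(1 + ||y_i - y_j||^2).  Points closer than ~1e-10 (or past the
depth cap) are merged into one leaf; their mutual repulsion is negligible at
that separation.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MAX_DEPTH = 52


@njit(cache=True)
def _build(pos):
    n = pos.shape[0]
    # worst case: one split chain of <= _MAX_DEPTH nodes per insertion
    cap = (_MAX_DEPTH + 4) * n + 64
    children = np.full((cap, 4), -1, dtype=np.int64)
    comx = np.zeros(cap)
    comy = np.zeros(cap)
    mass = np.zeros(cap)
    cx = np.zeros(cap)
    cy = np.zeros(cap)
    half = np.zeros(cap)
    leaf = np.ones(cap, dtype=np.uint8)

    xmin, xmax = pos[:, 0].min(), pos[:, 0].max()
    ymin, ymax = pos[:, 1].min(), pos[:, 1].max()
    cx[0] = 0.5 * (xmin + xmax)
    cy[0] = 0.5 * (ymin + ymax)
    half[0] = 0.5 * max(xmax - xmin, ymax - ymin) + 1e-12
    count = 1

    for k in range(n):
        px, py = pos[k, 0], pos[k, 1]
        node = 0
        depth = 0
        while True:
            mass[node] += 1.0
            comx[node] += px
            comy[node] += py
            if leaf[node] == 1:
                if mass[node] == 1.0:
                    break  # first point in this leaf
                ox = (comx[node] - px) / (mass[node] - 1.0)
                oy = (comy[node] - py) / (mass[node] - 1.0)
                if depth >= _MAX_DEPTH or ((ox - px) ** 2 + (oy - py) ** 2) < 1e-20:
                    break  # merge coincident points
                # split: push the existing occupants into a child
                leaf[node] = 0
                qo = (1 if ox > cx[node] else 0) + (2 if oy > cy[node] else 0)
                c = count
                count += 1
                h = 0.5 * half[node]
                cx[c] = cx[node] + (h if (qo & 1) else -h)
                cy[c] = cy[node] + (h if (qo & 2) else -h)
                half[c] = h
                children[node, qo] = c
                mass[c] = mass[node] - 1.0
                comx[c] = comx[node] - px
                comy[c] = comy[node] - py
                # fall through: node is now internal, descend with p
            q = (1 if px > cx[node] else 0) + (2 if py > cy[node] else 0)
            c = children[node, q]
            if c == -1:
                c = count
                count += 1
                h = 0.5 * half[node]
                cx[c] = cx[node] + (h if (q & 1) else -h)
                cy[c] = cy[node] + (h if (q & 2) else -h)
                half[c] = h
                children[node, q] = c
            node = c
            depth += 1

    return children, comx, comy, mass, half, leaf, count


@njit(cache=True)
def repulsive_forces(pos, theta):
    """Approximate (sum_j E^2 (y_i - y_j)) per point and the global sum of E.

    Returns (forces [n x 2], z_sum) where z_sum includes the n self terms
    (E_ii = 1); the caller subtracts n.
    """
    n = pos.shape[0]
    children, comx, comy, mass, half, leaf, count = _build(pos)
    forces = np.zeros((n, 2))
    z_sum = 0.0
    stack = np.empty(count + 4, dtype=np.int64)
    theta2 = theta * theta

    for i in range(n):
        xi, yi = pos[i, 0], pos[i, 1]
        fx = 0.0
        fy = 0.0
        zi = 0.0
        sp = 0
        stack[sp] = 0
        sp += 1
        while sp > 0:
            sp -= 1
            node = stack[sp]
            m = mass[node]
            if m == 0.0:
                continue
            dx = xi - comx[node] / m
            dy = yi - comy[node] / m
            d2 = dx * dx + dy * dy
            # accept cell if it is a leaf or (2*half)^2 < theta^2 * d2
            if leaf[node] == 1 or 4.0 * half[node] * half[node] < theta2 * d2:
                e = 1.0 / (1.0 + d2)
                zi += m * e
                w = m * e * e
                fx += w * dx
                fy += w * dy
            else:
                for q in range(4):
                    c = children[node, q]
                    if c != -1:
                        stack[sp] = c
                        sp += 1
        forces[i, 0] = fx
        forces[i, 1] = fy
        z_sum += zi

    return forces, z_sum
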