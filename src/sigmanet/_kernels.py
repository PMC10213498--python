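"""Compiled inner loops for the spatial step.

A uniform grid with cells of roughly half the interaction radius
``r = 3*max(sigma_c, sigma_m)`` backs the neighbour queries; scanning the
cell block spanning ``r`` around an individual covers all candidates, so
results are identical to brute-force all-pairs search (tested exactly).

Mate choice consumes one uniform draw per mother: pass A accumulates each
mother's total Gaussian candidate weight, pass B walks the same neighbour
order until the cumulative weight crosses ``u * total``.  Both passes visit
neighbours in the same deterministic (cell-sorted) order, so the selection
is an exact weighted draw given ``u``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["grid_density_and_mates"]


@njit(cache=True, fastmath=True)
def _kernel(x, y, W, r, sigma_c, sigma_m, is_mother, u, dens, mate):
    n = x.size
    # half-radius cells: scanning +-2 cells around an individual covers r
    ncell = max(1, int(2.0 * W / r))
    csize = W / ncell
    span = int(np.ceil(r / csize))
    cix = np.empty(n, np.int64)
    ciy = np.empty(n, np.int64)
    for i in range(n):
        a = int(x[i] / csize)
        b = int(y[i] / csize)
        if a >= ncell:
            a = ncell - 1
        if b >= ncell:
            b = ncell - 1
        cix[i] = a
        ciy[i] = b
    cell = cix * ncell + ciy
    counts = np.zeros(ncell * ncell + 1, np.int64)
    for i in range(n):
        counts[cell[i] + 1] += 1
    for c in range(1, counts.size):
        counts[c] += counts[c - 1]
    order = np.empty(n, np.int64)
    fill = counts[:-1].copy()
    for i in range(n):
        order[fill[cell[i]]] = i
        fill[cell[i]] += 1

    r2c = 9.0 * sigma_c * sigma_c
    r2m = 9.0 * sigma_m * sigma_m
    inv2c = 1.0 / (2.0 * sigma_c * sigma_c)
    inv2m = 1.0 / (2.0 * sigma_m * sigma_m)
    tot = np.zeros(n)

    # pass A: densities and total mate weight
    for i in range(n):
        xi = x[i]
        yi = y[i]
        mi = is_mother[i]
        d_acc = 0.0
        w_acc = 0.0
        for ca in range(max(0, cix[i] - span), min(ncell, cix[i] + span + 1)):
            for cb in range(max(0, ciy[i] - span), min(ncell, ciy[i] + span + 1)):
                c = ca * ncell + cb
                for k in range(counts[c], counts[c + 1]):
                    j = order[k]
                    if j == i:
                        continue
                    dx = xi - x[j]
                    dy = yi - y[j]
                    d2 = dx * dx + dy * dy
                    if d2 <= r2c:
                        d_acc += np.exp(-d2 * inv2c)
                    if mi and d2 <= r2m:
                        w_acc += np.exp(-d2 * inv2m)
        dens[i] = d_acc
        tot[i] = w_acc

    # pass B: weighted mate pick along the identical neighbour order
    for i in range(n):
        mate[i] = -1
        if not is_mother[i] or tot[i] <= 0.0:
            continue
        thresh = u[i] * tot[i]
        acc = 0.0
        xi = x[i]
        yi = y[i]
        done = False
        for ca in range(max(0, cix[i] - span), min(ncell, cix[i] + span + 1)):
            if done:
                break
            for cb in range(max(0, ciy[i] - span), min(ncell, ciy[i] + span + 1)):
                if done:
                    break
                c = ca * ncell + cb
                for k in range(counts[c], counts[c + 1]):
                    j = order[k]
                    if j == i:
                        continue
                    dx = xi - x[j]
                    dy = yi - y[j]
                    d2 = dx * dx + dy * dy
                    if d2 <= r2m:
                        acc += np.exp(-d2 * inv2m)
                        if acc >= thresh:
                            mate[i] = j
                            done = True
                            break
        if mate[i] == -1:
            # numerical guard: assign the last in-range candidate
            for ca in range(max(0, cix[i] - span), min(ncell, cix[i] + span + 1)):
                for cb in range(max(0, ciy[i] - span), min(ncell, ciy[i] + span + 1)):
                    c = ca * ncell + cb
                    for k in range(counts[c], counts[c + 1]):
                        j = order[k]
                        if j != i:
                            dx = xi - x[j]
                            dy = yi - y[j]
                            if dx * dx + dy * dy <= r2m:
                                mate[i] = j


def grid_density_and_mates(x: np.ndarray, y: np.ndarray, W: float,
                           sigma_c: float, sigma_m: float,
                           is_mother: np.ndarray,
                           u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw Gaussian competition weights and chosen mates for all mothers.

    Returns ``(dens, mate)`` where ``dens[i] = sum_j exp(-d_ij^2/(2 sigma_c^2))``
    over neighbours within ``3*sigma_c`` (no normalisation; divide by
    ``sqrt(2*pi)`` for the standard-density convention) and ``mate[i]`` is
    the index of the Gaussian-weighted mate draw for mothers (-1 when no
    candidate is within ``3*sigma_m``).
    """
    n = x.size
    dens = np.empty(n)
    mate = np.empty(n, np.int64)
    r = 3.0 * max(sigma_c, sigma_m)
    _kernel(np.ascontiguousarray(x), np.ascontiguousarray(y), float(W), r,
            float(sigma_c), float(sigma_m),
            np.ascontiguousarray(is_mother), np.ascontiguousarray(u),
            dens, mate)
    return dens, mate
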