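"""Independent brute-force oracles shared by the unit and acceptance tests.

Everything here is deliberately written with explicit python loops and no
code shared with the package implementation paths it checks.
"""

import numpy as np

from petas3d.active_surface import ball_offsets
from petas3d.tissue_sampling import BACKGROUND, BORDER_LINE, LESION


def oracle_prior_at(maps, l, x):
    num_in = num_out = count = 0
    shape = maps.lesion.grid.shape
    for o in ball_offsets(l):
        p = tuple(np.asarray(x) + o)
        if all(0 <= p[a] < shape[a] for a in range(3)):
            count += 1
            num_in += maps.lesion.values[p]
            num_out += maps.background.values[p]
    return num_in / count, num_out / count


def oracle_local_means(phi, suv, x, l):
    ins, outs = [], []
    shape = phi.shape
    for o in ball_offsets(l):
        p = tuple(np.asarray(x) + o)
        if all(0 <= p[a] < shape[a] for a in range(3)):
            (ins if phi[p] < 0 else outs).append(suv[p])
    u = np.mean(ins) if ins else (suv[phi < 0].mean() if (phi < 0).any() else suv.mean())
    v = np.mean(outs) if outs else (suv[phi >= 0].mean() if (phi >= 0).any() else suv.mean())
    return float(u), float(v)


def oracle_total_energy(phi, suv, maps, params):
    """Triple-loop evaluation of the discretized energy, per band voxel."""
    shape = phi.shape
    lam, l, eps = params.lam, params.l, params.epsilon
    offs = ball_offsets(l)
    total, n_band = 0.0, 0
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                if abs(phi[i, j, k]) >= eps:
                    continue
                delta = (0.5 / eps) * (1 + np.cos(np.pi * phi[i, j, k] / eps))
                if delta <= 0:
                    continue
                n_band += 1
                u, v = oracle_local_means(phi, suv, (i, j, k), l)
                prior = intensity = 0.0
                for o in offs:
                    p = (i + o[0], j + o[1], k + o[2])
                    if not all(0 <= p[a] < shape[a] for a in range(3)):
                        continue
                    p_in, p_out = oracle_prior_at(maps, l, p)
                    if phi[p] < 0:
                        prior += p_out
                        intensity += (suv[p] - u) ** 2
                    else:
                        prior += p_in
                        intensity += (suv[p] - v) ** 2
                total += delta * (lam * prior + (1 - lam) * intensity)
    return total / n_band if n_band else 0.0


def brute_force_samples(values, gold):
    """Explicit double/triple-loop window extraction and labelling recount."""
    nx, ny, nz = values.shape
    out = []
    for i in range(1, nx - 1):
        for j in range(1, ny - 1):
            for k in range(1, nz - 1):
                win = values[i - 1 : i + 2, j - 1 : j + 2, k - 1 : k + 2]
                n_lesion = int(gold[i - 1 : i + 2, j - 1 : j + 2, k - 1 : k + 2].sum())
                if n_lesion == 0:
                    lab = BACKGROUND
                elif n_lesion <= 17:
                    lab = BORDER_LINE
                else:
                    lab = LESION
                vec = [win[a, b, c] for c in range(3) for b in range(3) for a in range(3)]
                out.append((vec, lab, (i, j, k)))
    return out


def brute_force_confusion(p, g):
    tp = fp = fn = tn = 0
    for a, b in zip(p.ravel(), g.ravel()):
        if a and b:
            tp += 1
        elif a and not b:
            fp += 1
        elif not a and b:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


def brute_force_hausdorff(a, b, spacing=(1.0, 1.0, 1.0)):
    """O(n^2) all-pairs Hausdorff between surface voxel sets."""

    def surface(m):
        pts = []
        for i in range(m.shape[0]):
            for j in range(m.shape[1]):
                for k in range(m.shape[2]):
                    if not m[i, j, k]:
                        continue
                    nbrs = [(i - 1, j, k), (i + 1, j, k), (i, j - 1, k),
                            (i, j + 1, k), (i, j, k - 1), (i, j, k + 1)]
                    for p in nbrs:
                        if any(p[a] < 0 or p[a] >= m.shape[a] for a in range(3)) or not m[p]:
                            pts.append((i, j, k))
                            break
        return np.array(pts, dtype=float) * np.asarray(spacing)

    pa, pb = surface(a), surface(b)
    d_ab = max(min(np.linalg.norm(x - y) for y in pb) for x in pa)
    d_ba = max(min(np.linalg.norm(x - y) for y in pa) for x in pb)
    return max(d_ab, d_ba)
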