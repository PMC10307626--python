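"""Independent brute-force oracles used only by the test suite."""

import numpy as np


def dbscan_brute_force(xy: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Textbook DBSCAN with O(n^2) neighbourhoods and index-ordered DFS expansion."""
    n = len(xy)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    neighbors = [np.flatnonzero(d[i] <= eps) for i in range(n)]
    is_core = np.array([len(nb) >= min_pts for nb in neighbors])
    label = 0
    for seed in range(n):
        if labels[seed] != -1 or not is_core[seed]:
            continue
        stack = []
        j = seed
        while True:
            if labels[j] == -1:
                labels[j] = label
                if is_core[j]:
                    for v in neighbors[j]:
                        if labels[v] == -1:
                            stack.append(v)
            if not stack:
                break
            j = stack.pop()
        label += 1
    return labels


def min_inter_distance_brute_force(assembly, res_i: int, res_j: int) -> float:
    """Exhaustive cross-subunit CA distance minimum over all ordered pairs."""
    best = np.inf
    for p in range(assembly.n_subunits):
        for q in range(assembly.n_subunits):
            if p == q:
                continue
            sp, sq = assembly.subunit(p), assembly.subunit(q)
            ci = assembly.subunit_ca_coords(p)[sp.res_id[sp.atom_name == "CA"] == res_i]
            cj = assembly.subunit_ca_coords(q)[sq.res_id[sq.atom_name == "CA"] == res_j]
            for a in ci:
                for b in cj:
                    best = min(best, float(np.linalg.norm(a - b)))
    return best


def hydrophobic_moment_brute_force(h_values, delta_deg: float) -> float:
    """Direct evaluation of |sum_k (H_k - mean) exp(i k delta)| / N."""
    h = np.asarray(h_values, float)
    h = h - h.mean()
    total = 0j
    for k, hk in enumerate(h):
        total += hk * np.exp(1j * np.radians(delta_deg) * k)
    return abs(total) / len(h)
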