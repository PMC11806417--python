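"""Independent brute-force oracles used only by the test suite."""

from itertools import combinations

import numpy as np


def _connected(subset, connectivity=26):
    """Union-find connectivity check on a small voxel subset."""
    subset = [tuple(v) for v in subset]
    parent = {v: v for v in subset}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for a, b in combinations(subset, 2):
        d = [abs(x - y) for x, y in zip(a, b)]
        if max(d) > 1:
            continue
        order = sum(d)
        if connectivity == 6 and order > 1:
            continue
        if connectivity == 18 and order > 2:
            continue
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    roots = {find(v) for v in subset}
    return len(roots) == 1


def plant_random_connected_cluster(rng, roi_voxels, n=5):
    """Pick a random connected n-voxel subset of an ROI by random growth."""
    vox = [tuple(v) for v in roi_voxels]
    vox_set = set(vox)
    while True:
        chosen = {vox[rng.integers(len(vox))]}
        for _ in range(200):
            if len(chosen) == n:
                return sorted(chosen)
            frontier = []
            for (i, j, k) in chosen:
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        for dk in (-1, 0, 1):
                            cand = (i + di, j + dj, k + dk)
                            if cand in vox_set and cand not in chosen:
                                frontier.append(cand)
            if not frontier:
                break
            chosen.add(frontier[rng.integers(len(frontier))])
        if len(chosen) == n:
            return sorted(chosen)


def best_connected_subset_mean(volume_data, voxels, n=5, connectivity=26):
    """Maximum mean intensity over ALL connected n-voxel subsets of an ROI.

    Exhaustive enumeration; only feasible for small ROIs (<= ~25 voxels).
    """
    vox = [tuple(v) for v in voxels]
    vals = {v: float(volume_data[v]) for v in vox}
    best = -np.inf
    for subset in combinations(vox, n):
        if not _connected(subset, connectivity):
            continue
        m = sum(vals[v] for v in subset) / n
        if m > best:
            best = m
    return best
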