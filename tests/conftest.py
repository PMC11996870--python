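import numpy as np
import pytest

from se_landscape.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def sim_dir(tmp_path_factory):
    """One default-configuration synthetic study, shared across tests."""
    out = tmp_path_factory.mktemp("sim")
    manifest = simulate_dataset(SimConfig(seed=11), out)
    return out, manifest


# ---- independent brute-force oracles used by several test modules ----

def brute_force_stitch(intervals, window):
    """Transitive closure merge by pairwise closeness; O(n^2) reference."""
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom != b.chrom:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= window:
                union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(intervals[i])
    spans = [
        (g[0].chrom, min(iv.start for iv in g), max(iv.end for iv in g))
        for g in groups.values()
    ]
    return sorted(spans)


def brute_force_hockey_index(signals):
    """Exhaustive argmin scan of the scaled rank-signal gap."""
    s = sorted(signals)
    n = len(s)
    if n < 3 or s[-1] == s[0]:
        return n - 1
    best_i, best_v = 0, float("inf")
    for i in range(n):
        x = i / (n - 1)
        y = (s[i] - s[0]) / (s[-1] - s[0])
        if y - x <= best_v:  # ties toward the largest index
            best_v, best_i = y - x, i
    return best_i


def brute_force_bh(pvals):
    """Direct evaluation of the step-up definition q_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        tail = [p[order[j]] * m / (j + 1) for j in range(rank_pos - 1, m)]
        q[idx] = min(1.0, min(tail))
    return q
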