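"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (enumeration, ray casting, direct
geometry) and shares no code with the package paths it validates.
"""
from collections import deque

import numpy as np


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """Random binary tree with uniform(0.1, 1) branch lengths.

    Returns (leaf distance matrix, labels, canonical non-trivial splits).
    The matrix is exactly additive on the generated topology.
    """
    labels = [f"L{i:02d}" for i in range(n_leaves)]
    adj: dict[int, list[tuple[int, float]]] = {i: [] for i in range(n_leaves)}
    leafsets = {i: frozenset([labels[i]]) for i in range(n_leaves)}
    active = list(range(n_leaves))
    next_id = n_leaves
    splits = []
    while len(active) > 2:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        parent = next_id
        next_id += 1
        adj[parent] = []
        for child in (a, b):
            ln = float(rng.uniform(0.1, 1.0))
            adj[parent].append((child, ln))
            adj[child].append((parent, ln))
        leafsets[parent] = leafsets[a] | leafsets[b]
        active = [x for x in active if x not in (a, b)] + [parent]
    a, b = active
    ln = float(rng.uniform(0.1, 1.0))
    adj[a].append((b, ln))
    adj[b].append((a, ln))

    # splits: one per internal edge = each non-root cluster of size 2..n-2
    all_labels = frozenset(labels)
    ref = min(labels)
    for node, ls in leafsets.items():
        if 2 <= len(ls) <= n_leaves - 2:
            side = all_labels - ls if ref in ls else ls
            splits.append(side)

    d = np.zeros((n_leaves, n_leaves))
    for src in range(n_leaves):
        dist = {src: 0.0}
        q = deque([src])
        while q:
            u = q.popleft()
            for v, ln in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    q.append(v)
        for dst in range(n_leaves):
            d[src, dst] = dist[dst]
    return d, labels, set(splits)


def brute_force_pi(sequences: list[str]) -> float:
    """Mean pairwise mismatch count by direct enumeration of individual pairs."""
    from refugia.sequences import pairwise_differences

    n = len(sequences)
    total = sum(
        pairwise_differences(sequences[i], sequences[j])[0]
        for i in range(n)
        for j in range(i + 1, n)
    )
    return total / (n * (n - 1) / 2)


def brute_force_zi(seqs_a: list[str], seqs_b: list[str]) -> float:
    """Mean cross-population mismatch proportion by direct enumeration."""
    from refugia.sequences import pairwise_differences

    props = [pairwise_differences(a, b)[2] for a in seqs_a for b in seqs_b]
    return float(np.mean(props))


def circumcircle(p1, p2, p3):
    """Center and squared radius of the circle through three points."""
    ax, ay = p1
    bx, by = p2
    cx, cy = p3
    dd = 2 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
    if abs(dd) < 1e-14:
        return None
    ux = ((ax**2 + ay**2) * (by - cy) + (bx**2 + by**2) * (cy - ay) + (cx**2 + cy**2) * (ay - by)) / dd
    uy = ((ax**2 + ay**2) * (cx - bx) + (bx**2 + by**2) * (ax - cx) + (cx**2 + cy**2) * (bx - ax)) / dd
    r2 = (ax - ux) ** 2 + (ay - uy) ** 2
    return (ux, uy), r2


def brute_force_delaunay_edges(points: np.ndarray) -> set[tuple[int, int]]:
    """Delaunay edges by the empty-circumcircle criterion over all triangles."""
    n = len(points)
    edges: set[tuple[int, int]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                cc = circumcircle(points[i], points[j], points[k])
                if cc is None:
                    continue
                (ux, uy), r2 = cc
                empty = True
                for m in range(n):
                    if m in (i, j, k):
                        continue
                    if (points[m][0] - ux) ** 2 + (points[m][1] - uy) ** 2 < r2 - 1e-12:
                        empty = False
                        break
                if empty:
                    edges.update({(i, j), (i, k), (j, k)})
    return edges


def point_in_polygon(x: float, y: float, ring: list[tuple[float, float]]) -> bool:
    """Ray-casting point-in-polygon for a single closed ring."""
    inside = False
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xcross = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x < xcross:
                inside = not inside
    return inside
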