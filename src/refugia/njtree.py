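"""Neighbor-joining trees, bootstrap support, outgroup rooting and
mitochondrial lineage assignment.

The agglomeration is the classical Saitou–Nei algorithm on a p-distance
matrix, made fully deterministic: ties in the Q criterion are broken by the
lexicographically smallest pair of cluster labels (a cluster is labelled by
its smallest member leaf), and negative branch-length estimates are clamped
to zero.  Trees are dendropy objects, so newick IO, rerooting and
bipartition bookkeeping come for free.
"""
from __future__ import annotations

from collections import Counter

import dendropy
import numpy as np

from .sequences import HaplotypeSet, encode, _VALID

__all__ = [
    "nj_tree",
    "tree_bipartitions",
    "bootstrap_support",
    "root_with_outgroup",
    "assign_lineages",
    "flag_introgression",
]


def nj_tree(d: np.ndarray, labels: list[str]) -> dendropy.Tree:
    """Neighbor joining on a symmetric distance matrix.

    Returns an unrooted dendropy tree whose leaves are ``labels``.  Negative
    branch-length estimates are clamped to 0; Q-ties are broken by smallest
    label pair so the result is label-order invariant.
    """
    d = np.asarray(d, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if d.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(d) != 0):
        raise ValueError("distance matrix must have a zero diagonal")

    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)
    # active clusters: (sort key = smallest leaf label, node, row index)
    keys = list(labels)
    active = list(range(n))
    D = d.copy()

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # candidates within numerical tie of the minimum
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12 * max(1.0, abs(qmin))))
        best = None
        for ii, jj in cand:
            if ii >= jj:
                continue
            a, b = active[ii], active[jj]
            pair = tuple(sorted((keys[a], keys[b])))
            if best is None or pair < best[0]:
                best = (pair, ii, jj)
        _, ii, jj = best
        a, b = active[ii], active[jj]
        dij = sub[ii, jj]
        la = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lb = dij - la
        la, lb = max(la, 0.0), max(lb, 0.0)

        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb

        # distances from the new cluster to every other active cluster
        new_row = np.zeros(D.shape[0] + 1)
        for kk in active:
            if kk in (a, b):
                continue
            new_row[kk] = 0.5 * (D[a, kk] + D[b, kk] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[a], keys[b]))
        active = [x for x in active if x not in (a, b)] + [len(keys) - 1]

    # final three clusters join a central node with closed-form lengths
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    center = dendropy.Node()
    for idx, ln in zip((a, b, c), (la, lb, lc)):
        center.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree.seed_node = center
    tree.is_rooted = False
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits as frozensets of leaf labels (side not containing the
    lexicographically smallest leaf, so each split has one canonical form)."""
    leaves = sorted(l.taxon.label for l in tree.leaf_node_iter())
    if not leaves:
        return set()
    ref = leaves[0]
    all_set = frozenset(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) <= 1 or len(side) >= len(all_set) - 1:
            continue
        if ref in side:
            side = all_set - side
        out.add(side)
    return out


def bootstrap_support(
    sequences: list[str],
    labels: list[str],
    reference: dendropy.Tree,
    n_replicates: int = 1000,
    seed: int = 0,
) -> dict[frozenset[str], float]:
    """Percent of site-resampled NJ replicates containing each reference split.

    Sites are resampled with replacement, p-distances recomputed under
    pairwise deletion, and the tree rebuilt per replicate.  Deterministic
    under a fixed seed.
    """
    if n_replicates < 1:
        raise ValueError("need at least 1 replicate")
    enc = np.vstack([encode(s) for s in sequences])
    L = enc.shape[1]
    rng = np.random.default_rng(seed)
    ref_splits = tree_bipartitions(reference)
    counts = Counter()
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        mat = enc[:, cols]
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            valid_i = mat[i] < _VALID
            for j in range(i + 1, n):
                valid = valid_i & (mat[j] < _VALID)
                comp = valid.sum()
                d[i, j] = d[j, i] = ((mat[i] != mat[j]) & valid).sum() / comp if comp else 0.0
        rep = nj_tree(d, labels)
        for split in tree_bipartitions(rep):
            if split in ref_splits:
                counts[split] += 1
    return {split: 100.0 * counts[split] / n_replicates for split in ref_splits}


def root_with_outgroup(tree: dendropy.Tree, outgroup: str) -> dendropy.Tree:
    """Root a copy of the tree at the midpoint of the outgroup's pendant edge."""
    rooted = tree.clone(depth=1)
    node = None
    for leaf in rooted.leaf_node_iter():
        if leaf.taxon is not None and leaf.taxon.label == outgroup:
            node = leaf
            break
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} is not a leaf of the tree")
    edge = node.edge
    half = (edge.length or 0.0) / 2.0
    rooted.reroot_at_edge(edge, length1=half, length2=half, update_bipartitions=False)
    rooted.is_rooted = True
    return rooted


def assign_lineages(
    rooted: dendropy.Tree,
    hap_set: HaplotypeSet,
    individual_species: dict[str, str],
    outgroup: str | None = None,
    distances: tuple[np.ndarray, list[str]] | None = None,
) -> tuple[dict[str, str], dict]:
    """Map each haplotype to the species lineage whose clade contains it.

    For each species, the smallest clade (MRCA) containing all of its *seed*
    haplotypes is found; seeds are haplotypes carried exclusively by that
    species' individuals, falling back to majority carriage when a species
    has no pure haplotype.  A haplotype inside exactly one species clade is
    assigned that lineage.  A haplotype inside several overlapping clades,
    or inside none (it can attach basal to every crown clade), is flagged
    ambiguous and resolved by its nearest unambiguously assigned haplotype
    when ``distances`` (matrix, labels) is given, else by the majority
    species of its own carriers.  The report lists overlapping
    (non-monophyletic) clade pairs and ambiguous haplotypes.
    """
    hap_labels = set(hap_set.haplotype_ids)

    def majority(h: str) -> str:
        tally = Counter(individual_species[ind] for ind in hap_set.members[h])
        top = max(tally.values())
        return sorted(sp for sp, k in tally.items() if k == top)[0]

    carriers = {
        h: {individual_species[ind] for ind in hap_set.members[h]} for h in hap_set.haplotype_ids
    }
    majorities = {h: majority(h) for h in hap_set.haplotype_ids}
    species = sorted({sp for c in carriers.values() for sp in c})

    seeds: dict[str, list[str]] = {}
    for sp in species:
        pure = [h for h in hap_set.haplotype_ids if carriers[h] == {sp}]
        seeds[sp] = pure if pure else [h for h in hap_set.haplotype_ids if majorities[h] == sp]

    if len(rooted.seed_node.child_nodes()) > 2 and len(species) > 1:
        raise ValueError("tree is unresolved (multifurcating) at the root; cannot delimit clades")

    taxa = rooted.taxon_namespace
    clades: dict[str, frozenset[str]] = {}
    for sp in species:
        if not seeds[sp]:
            clades[sp] = frozenset()
            continue
        mrca = rooted.mrca(taxa=[taxa.get_taxon(h) for h in seeds[sp]])
        leafset = frozenset(l.taxon.label for l in mrca.leaf_iter()) & hap_labels
        if outgroup is not None:
            leafset = leafset - {outgroup}
        clades[sp] = leafset

    overlaps = [
        (a, b)
        for i, a in enumerate(species)
        for b in species[i + 1 :]
        if clades[a] & clades[b]
    ]

    lineages: dict[str, str] = {}
    ambiguous: list[str] = []
    for h in hap_set.haplotype_ids:
        containing = [sp for sp in species if h in clades[sp]]
        if len(containing) == 1:
            lineages[h] = containing[0]
        else:
            ambiguous.append(h)
    for h in ambiguous:
        resolved = None
        if distances is not None:
            dmat, dlabels = distances
            pos = {lab: i for i, lab in enumerate(dlabels)}
            candidates = [(dmat[pos[h], pos[g]], g) for g in lineages if g not in ambiguous]
            if candidates:
                resolved = lineages[min(candidates)[1]]
        lineages[h] = resolved if resolved is not None else majorities[h]
    report = {
        "monophyletic": not overlaps,
        "overlapping_pairs": overlaps,
        "ambiguous_haplotypes": ambiguous,
        "clades": {sp: sorted(clades[sp]) for sp in species},
    }
    return lineages, report


def flag_introgression(
    hap_set: HaplotypeSet,
    lineages: dict[str, str],
    individual_species: dict[str, str],
    individual_population: dict[str, str],
):
    """Per-individual introgression status and per-population mtDNA classes.

    An individual is introgressed iff its haplotype's mitochondrial lineage
    differs from its species label.  Populations are classed ``original``
    (all native mtDNA), ``introgressed`` (all foreign) or ``mixed``.
    Returns ``(flags_df, population_classes)`` as a pandas DataFrame and a
    dict.
    """
    import pandas as pd

    rows = []
    for h in hap_set.haplotype_ids:
        lin = lineages[h]
        for ind in hap_set.members[h]:
            sp = individual_species[ind]
            rows.append(
                {
                    "individual": ind,
                    "population": individual_population[ind],
                    "species": sp,
                    "mtdna_lineage": lin,
                    "status": "introgressed" if lin != sp else "original",
                }
            )
    flags = pd.DataFrame(rows).sort_values("individual").reset_index(drop=True)
    classes = {}
    for pop, grp in flags.groupby("population"):
        st = set(grp["status"])
        classes[pop] = "mixed" if len(st) == 2 else ("original" if "original" in st else "introgressed")
    return flags, classes
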