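"""Independent reference computations used to cross-check the package.

These deliberately take different routes than the implementation:
root-path enumeration instead of edge-mask sums for PD, Delaunay
simplex-volume sums instead of a direct hull volume, dendropy bitmask
bipartition tallies for MCC, and a dense slogdet grid search for the
SAR likelihood.
"""

import math

import dendropy
import numpy as np
from scipy.spatial import Delaunay, QhullError


def pd_bruteforce(tree: dendropy.Tree, subset) -> float:
    """Faith's PD by enumerating every root-to-tip path and summing the
    union of the edges encountered."""
    want = set(subset)
    seen = set()
    total = 0.0
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label not in want:
            continue
        node = leaf
        while node.parent_node is not None:
            if id(node.edge) not in seen:
                seen.add(id(node.edge))
                total += float(node.edge.length or 0.0)
            node = node.parent_node
    return total


def hull_volume_delaunay(points: np.ndarray) -> float:
    """Convex-hull volume as the sum of Delaunay simplex volumes
    (|det| / d! per simplex)."""
    pts = np.asarray(points, dtype=float)
    d = pts.shape[1]
    try:
        tri = Delaunay(pts)
    except QhullError:
        return 0.0
    vol = 0.0
    for simplex in tri.simplices:
        mat = pts[simplex[1:]] - pts[simplex[0]]
        vol += abs(np.linalg.det(mat)) / math.factorial(d)
    return vol


def mcc_bruteforce(trees) -> int:
    """Index of the maximum-clade-credibility member, via dendropy's
    bipartition bitmask machinery (rooted clade tally)."""
    ns = trees[0].taxon_namespace
    counts = {}
    per_tree = []
    for t in trees:
        assert t.taxon_namespace is ns
        t.encode_bipartitions()
        masks = [nd.bipartition.leafset_bitmask
                 for nd in t.preorder_node_iter() if not nd.is_leaf()]
        per_tree.append(masks)
        for m in masks:
            counts[m] = counts.get(m, 0) + 1
    n = len(trees)
    scores = [sum(math.log(counts[m] / n) for m in masks) for masks in per_tree]
    return int(np.argmax(scores))


def sar_negloglik_dense(lam, y, X, W, w):
    """Spatial-error negative log-likelihood with a dense slogdet and an
    explicit weighted GLS solve (no concentration shortcuts shared with
    the implementation)."""
    n = len(y)
    A = np.eye(n) - lam * W
    ys, Xs = A @ y, A @ X
    Om = np.diag(w)
    beta = np.linalg.solve(Xs.T @ Om @ Xs, Xs.T @ Om @ ys)
    r = ys - Xs @ beta
    sigma2 = float(r @ Om @ r) / n
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0 or sigma2 <= 0:
        return np.inf
    ll = (-n / 2 * (np.log(2 * np.pi * sigma2) + 1)
          + 0.5 * np.sum(np.log(w)) + logdet)
    return -ll
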