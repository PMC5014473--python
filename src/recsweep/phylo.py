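"""Distance phylogenetics: JC distances, neighbor joining, Robinson–Foulds,
RELL-based tree-comparison support, window compatibility matrices, and
recombination-aware alignment editing.

Neighbor joining is implemented here directly (rather than delegated)
because scan-time callers need strict determinism — ties in the joining
criterion are always broken by the lowest active index pair — and
clamping of negative branch lengths at exactly zero.  Trees are dendropy
objects throughout, so newick serialization and taxon bookkeeping come
for free.
"""

from __future__ import annotations

import numpy as np
import dendropy
from scipy.optimize import minimize_scalar

from .alignment import GAP, Alignment
from .events import RecombinationEvent

__all__ = [
    "SaturationError",
    "jc_distance",
    "jc_from_pdiff",
    "jc_matrix",
    "nj_tree",
    "tree_splits",
    "rf_distance",
    "sh_like_support",
    "compatibility_matrix",
    "strip_recombination",
]


class SaturationError(ValueError):
    """Observed divergence at or beyond the JC saturation bound (p >= 3/4)."""


def jc_from_pdiff(p: float) -> float:
    """Jukes–Cantor distance −(3/4)·ln(1 − 4p/3) for difference fraction *p*."""
    if p < 0 or p >= 0.75:
        raise SaturationError(f"difference proportion {p} outside [0, 0.75)")
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def jc_distance(aln: Alignment, i: int, j: int) -> float:
    x, y = aln.codes[i], aln.codes[j]
    comp = (x < GAP) & (y < GAP)
    n = int(comp.sum())
    if n == 0:
        raise ValueError(f"no comparable columns between {aln.names[i]} and {aln.names[j]}")
    p = np.count_nonzero((x != y) & comp) / n
    if p >= 0.75:
        raise SaturationError(
            f"pair ({aln.names[i]}, {aln.names[j]}) is saturated (p={p:.3f} >= 0.75)"
        )
    return jc_from_pdiff(p)


def jc_matrix(aln: Alignment, columns: tuple[int, int] | None = None,
              cap: float = 0.74) -> np.ndarray:
    """All-pairs JC distance matrix; difference fractions are capped at
    *cap* so that noisy, near-saturated windows still yield finite
    distances (used by window trees, where robustness beats strictness).
    """
    codes = aln.codes if columns is None else aln.codes[:, columns[0]:columns[1]]
    n = aln.n_sequences
    D = np.zeros((n, n))
    comp_all = codes < GAP
    for i in range(n):
        for j in range(i + 1, n):
            comp = comp_all[i] & comp_all[j]
            m = int(comp.sum())
            p = (np.count_nonzero((codes[i] != codes[j]) & comp) / m) if m else cap
            D[i, j] = D[j, i] = jc_from_pdiff(min(p, cap))
    return D


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(D: np.ndarray, names: list[str]) -> dendropy.Tree:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Ties in the Q criterion are broken by the lowest (row, column) pair
    of the current active-node list; negative branch lengths are clamped
    to zero.  Returns an unrooted dendropy tree (trifurcating seed node).
    """
    D = np.array(D, dtype=float)
    n = len(names)
    if D.shape != (n, n):
        raise ValueError("distance matrix shape does not match names")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    taxa = dendropy.TaxonNamespace(list(names))
    active: list[dendropy.Node] = [dendropy.Node(taxon=taxa[i]) for i in range(n)]

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major => lowest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        u = dendropy.Node()
        for child, bl in ((active[i], li), (active[j], lj)):
            u.add_child(child)
            child.edge.length = max(0.0, float(bl))
        du = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([
            np.hstack([D[np.ix_(keep, keep)], du[keep][:, None]]),
            np.hstack([du[keep], [0.0]]),
        ])
        active = [active[k] for k in keep] + [u]

    a, b, c = active
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    root = dendropy.Node()
    for node, bl in (
        (a, (dab + dac - dbc) / 2.0),
        (b, (dab + dbc - dac) / 2.0),
        (c, (dac + dbc - dab) / 2.0),
    ):
        root.add_child(node)
        node.edge.length = max(0.0, float(bl))
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the two leaf-name sides."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(below) <= len(leaves) - 2:
            splits.add(frozenset((below, leaves - below)))
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds distance: |split-set symmetric difference|."""
    l1 = frozenset(lf.taxon.label for lf in t1.leaf_node_iter())
    l2 = frozenset(lf.taxon.label for lf in t2.leaf_node_iter())
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    return len(tree_splits(t1) ^ tree_splits(t2))


# ---------------------------------------------------------------------------
# JC likelihoods and RELL support


def _jc_transition(t: float) -> np.ndarray:
    # floor: zero-length branches (NJ clamping) would make conflicting
    # leaf states impossible and the site likelihood exactly 0
    e = np.exp(-4.0 * max(t, 1e-6) / 3.0)
    P = np.full((4, 4), (1.0 - e) / 4.0)
    np.fill_diagonal(P, 0.25 + 0.75 * e)
    return P


def site_log_likelihoods(
    tree: dendropy.Tree, aln: Alignment, columns: tuple[int, int],
    scale: float = 1.0,
) -> np.ndarray:
    """Per-site JC log-likelihoods of *tree* on the given column window.

    Branch lengths are multiplied by *scale* (used for the coarse
    one-parameter length refit).  Gap/N leaf states contribute a flat
    partial likelihood.  Felsenstein pruning with per-site rescaling.
    """
    s, e = columns
    codes = aln.codes[:, s:e]
    S = e - s
    name_to_row = {nm: i for i, nm in enumerate(aln.names)}
    logscale = np.zeros(S)
    partials: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            row = codes[name_to_row[node.taxon.label]]
            part = np.zeros((4, S))
            ok = row < GAP
            part[:, ~ok] = 1.0
            part[row[ok], np.flatnonzero(ok)] = 1.0
        else:
            part = np.ones((4, S))
            for child in node.child_nodes():
                bl = (child.edge.length or 0.0) * scale
                P = _jc_transition(bl)
                part *= P @ partials.pop(id(child))
            mx = part.max(axis=0)
            mx[mx == 0] = 1.0
            part /= mx
            logscale += np.log(mx)
        partials[id(node)] = part
    root_part = partials[id(tree.seed_node)]
    return np.log(0.25 * root_part.sum(axis=0)) + logscale


def _refit_scale(tree: dendropy.Tree, aln: Alignment, columns: tuple[int, int]) -> float:
    res = minimize_scalar(
        lambda s: -site_log_likelihoods(tree, aln, columns, scale=s).sum(),
        bounds=(0.05, 20.0), method="bounded", options={"xatol": 0.05},
    )
    return float(res.x)


def _ls_refit_lengths(tree: dendropy.Tree, D: np.ndarray, names: list[str]) -> dendropy.Tree:
    """Least-squares branch lengths for *tree*'s topology given a distance
    matrix (clamped at a small positive floor).  A coarse per-window
    refit so that tree *topologies* are compared rather than stale branch
    lengths carried over from another window."""
    tree = tree.clone(depth=1)
    idx = {nm: i for i, nm in enumerate(names)}
    edges = [nd for nd in tree.preorder_node_iter() if nd is not tree.seed_node]
    below = []
    for nd in edges:
        below.append(frozenset(idx[lf.taxon.label] for lf in nd.leaf_iter()))
    n = len(names)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        y[r] = D[i, j]
        for c, bs in enumerate(below):
            if (i in bs) != (j in bs):
                A[r, c] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    for nd, bl in zip(edges, x):
        nd.edge.length = max(float(bl), 1e-6)
    return tree


def _rell_support(ll_own: np.ndarray, ll_other: np.ndarray,
                  n_rell: int, rng: np.random.Generator) -> float:
    """SH-style RELL support for *other* against the window's own tree.

    The observed log-likelihood deficit Δ = Σll_own − Σll_other is
    compared with centred RELL resamples of the same deficit; support is
    the fraction of resamples whose centred deficit is at least Δ — 1.0
    when the trees are indistinguishable, small when *other* is
    significantly worse than the window's own tree.
    """
    S = ll_own.size
    delta_obs = float(ll_own.sum() - ll_other.sum())
    counts = rng.multinomial(S, np.full(S, 1.0 / S), size=n_rell)
    deltas = counts @ (ll_own - ll_other)
    centred = deltas - deltas.mean()
    return float(np.count_nonzero(centred >= delta_obs) / n_rell)


def sh_like_support(
    aln: Alignment,
    window: tuple[int, int],
    tree_other: dendropy.Tree,
    n_rell: int = 200,
    seed: int = 0,
) -> float:
    """RELL/SH-style support in [0, 1] for *tree_other* on one window."""
    if window[1] <= window[0]:
        raise ValueError("zero-length window")
    rng = np.random.default_rng(seed)
    D = jc_matrix(aln, window)
    own = _ls_refit_lengths(nj_tree(D, aln.names), D, aln.names)
    ll_own = site_log_likelihoods(own, aln, window)
    ll_other = site_log_likelihoods(
        _ls_refit_lengths(tree_other, D, aln.names), aln, window)
    return _rell_support(ll_own, ll_other, n_rell, rng)


def compatibility_matrix(
    aln: Alignment,
    window_len: int = 500,
    step: int = 100,
    n_rell: int = 200,
    seed: int = 0,
) -> dict:
    """Window-pair phylogenetic compatibility.

    Builds an NJ tree per window, then fills a matrix whose lower
    triangle holds Robinson–Foulds distances between window trees and
    whose upper triangle holds symmetrized SH-like RELL support
    (1 = indistinguishable, 0 = strongly incompatible).  Diagonal is
    (0, 1).  Windows with fewer than 4 distinct usable rows yield NaN.
    """
    starts = list(range(0, aln.length - window_len + 1, step))
    if len(starts) < 2:
        raise ValueError("need at least 2 windows")
    windows = [(s, s + window_len) for s in starts]
    rng = np.random.default_rng(seed)
    trees: list[dendropy.Tree | None] = []
    dists: list[np.ndarray | None] = []
    for w in windows:
        try:
            D = jc_matrix(aln, w)
            trees.append(nj_tree(D, aln.names))
            dists.append(D)
        except ValueError:
            trees.append(None)
            dists.append(None)
    W = len(windows)
    rf = np.full((W, W), np.nan)
    sh = np.full((W, W), np.nan)
    ll_cache: dict[tuple[int, int], np.ndarray] = {}
    for i, w in enumerate(windows):
        if trees[i] is None:
            continue
        for j in range(W):
            if trees[j] is None:
                continue
            refit = _ls_refit_lengths(trees[j], dists[i], aln.names)
            ll_cache[(i, j)] = site_log_likelihoods(refit, aln, w)
    for i in range(W):
        if trees[i] is None:
            continue
        rf[i, i] = 0.0
        sh[i, i] = 1.0
        for j in range(i + 1, W):
            if trees[j] is None:
                continue
            rf[i, j] = rf[j, i] = rf_distance(trees[i], trees[j])
            sij = _rell_support(ll_cache[(i, i)], ll_cache[(i, j)], n_rell, rng)
            sji = _rell_support(ll_cache[(j, j)], ll_cache[(j, i)], n_rell, rng)
            sh[i, j] = sh[j, i] = 0.5 * (sij + sji)
    combined = np.full((W, W), np.nan)
    for i in range(W):
        combined[i, i] = 0.0
        for j in range(W):
            if i > j:
                combined[i, j] = rf[i, j]
            elif i < j:
                combined[i, j] = sh[i, j]
    combined[np.isnan(rf) & np.isnan(sh)] = np.nan
    return {"windows": windows, "rf": rf, "sh": sh, "matrix": combined, "trees": trees}


# ---------------------------------------------------------------------------
# recombination-aware alignment editing


def strip_recombination(
    aln: Alignment, events: list[RecombinationEvent], mode: str = "remove"
) -> Alignment:
    """Strip detected recombination from an alignment.

    ``remove``: recombinant-region residues are replaced by ``-`` in each
    recombinant row (column count unchanged).  ``split``: each recombinant
    row is replaced by a region-only row (``name_minor``) and a
    complement-only row (``name_major``).
    """
    if mode not in ("remove", "split"):
        raise ValueError(f"unknown mode {mode!r}")
    names = list(aln.names)
    rows = list(aln.rows)
    descs = list(aln.descriptions)
    original = set(names)
    for ev in events:
        b0, e0 = ev.region0
        for rec in ev.recombinants:
            if rec not in names:
                if rec in original:
                    continue  # already split out by an earlier event
                raise KeyError(f"event {ev.event_id}: unknown sequence {rec!r}")
            idx = names.index(rec)
            row = rows[idx]
            if mode == "remove":
                rows[idx] = row[:b0] + "-" * (e0 - b0) + row[e0:]
            else:
                minor = "-" * b0 + row[b0:e0] + "-" * (len(row) - e0)
                major = row[:b0] + "-" * (e0 - b0) + row[e0:]
                names[idx] = f"{rec}_minor"
                rows[idx] = minor
                names.insert(idx + 1, f"{rec}_major")
                rows.insert(idx + 1, major)
                descs.insert(idx + 1, descs[idx])
    return Alignment(names, rows, descs)
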