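"""Hierarchical spherical k-means visual dictionary.

Spherical k-means clusters unit vectors by cosine similarity: vectors are
assigned to the centroid with the largest dot product and each centroid is
recomputed as the renormalised sum of its members.  A fixed number of
iterations is used rather than a convergence test.  The dictionary is a
complete ``n_splits``-ary tree of depth ``n_levels`` whose leaves are the
K = n_splits**n_levels visual words; the hierarchy exists for encoding and
clustering speed, so quantisation is a greedy root-to-leaf descent by
default (exhaustive leaf search is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_KMEANS_ITER = 10


class DictionaryError(ValueError):
    pass


class DegenerateInitError(DictionaryError):
    """Fewer distinct vectors than requested clusters."""


def _unit_rows(x: np.ndarray) -> np.ndarray:
    """L2-normalise rows; zero rows map to the first basis vector.

    Rows that are already unit norm (within 1e-12) are left untouched so
    the operation is idempotent bit-for-bit.
    """
    x = np.asarray(x, dtype=np.float64)
    norms = np.linalg.norm(x, axis=1)
    out = x.copy()
    fix = np.abs(norms - 1.0) > 1e-12
    nz = norms > 0
    sel = fix & nz
    out[sel] = x[sel] / norms[sel, None]
    zero = ~nz
    out[zero] = 0.0
    out[zero, 0] = 1.0
    return out


def spherical_kmeans(
    vectors: np.ndarray,
    k: int,
    n_iter: int = DEFAULT_KMEANS_ITER,
    rng_seed: int | np.random.Generator = 0,
    return_history: bool = False,
):
    """Cluster unit vectors into ``k`` unit-norm centroids by cosine.

    Initialisation samples k distinct input vectors without replacement.
    Each iteration assigns every vector to its max-dot-product centroid
    (ties to the lowest centroid index) and recomputes centroids as
    normalised sums.  A centroid left empty is re-seeded with the vector
    farthest (lowest max-cosine) from all current centroids.

    Returns ``centroids`` of shape (k, d); with ``return_history`` also a
    list of the summed max-cosine objective after each assignment step.
    """
    if k < 1:
        raise DictionaryError(f"k must be >= 1, got {k}")
    x = _unit_rows(np.atleast_2d(vectors))
    distinct = np.unique(x, axis=0)
    if k > distinct.shape[0]:
        raise DegenerateInitError(
            f"k={k} exceeds the {distinct.shape[0]} distinct input vectors"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    init_idx = rng.choice(distinct.shape[0], size=k, replace=False)
    centroids = distinct[init_idx]
    history: list[float] = []
    for _ in range(n_iter):
        sims = x @ centroids.T  # (n, k)
        assign = np.argmax(sims, axis=1)
        history.append(float(np.take_along_axis(sims, assign[:, None], axis=1).sum()))
        new = np.zeros_like(centroids)
        np.add.at(new, assign, x)
        empty = np.flatnonzero(np.linalg.norm(new, axis=1) == 0)
        for j in empty:
            # farthest point from all current centroids, deterministic
            far = int(np.argmin(sims.max(axis=1)))
            new[j] = x[far]
            sims[far] = np.inf  # do not pick the same point twice
        centroids = _unit_rows(new)
    if return_history:
        return centroids, history
    return centroids


@dataclass
class VisualDictionary:
    """Complete n_splits-ary tree of unit-norm centroids.

    ``levels[i]`` holds the centroids of tree level i+1 as an array of
    shape (n_splits**(i+1), d) in level order; the children of node m at
    level i are nodes m*n_splits .. m*n_splits+n_splits-1 at level i+1.
    Leaves (the last level) are the visual words, word id = leaf index.
    """

    levels: list[np.ndarray]
    n_splits: int

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def n_words(self) -> int:
        return int(self.levels[-1].shape[0])

    @property
    def leaves(self) -> np.ndarray:
        return self.levels[-1]

    @property
    def dim(self) -> int:
        return int(self.levels[-1].shape[1])

    def save(self, path) -> None:
        np.savez(
            path,
            n_splits=self.n_splits,
            n_levels=self.n_levels,
            **{f"level_{i}": lvl for i, lvl in enumerate(self.levels)},
        )

    @classmethod
    def load(cls, path) -> "VisualDictionary":
        with np.load(path) as z:
            n_levels = int(z["n_levels"])
            levels = [z[f"level_{i}"] for i in range(n_levels)]
            return cls(levels=levels, n_splits=int(z["n_splits"]))


def _cluster_node(
    x: np.ndarray, k: int, n_iter: int, rng: np.random.Generator, parent: np.ndarray | None
) -> np.ndarray:
    """Cluster one node's patches into k children.

    Under-populated nodes (fewer distinct vectors than k) replicate the
    parent centroid into every child so the tree stays complete and the
    leaf count stays n_splits**n_levels.
    """
    distinct_enough = x.shape[0] >= k and np.unique(x, axis=0).shape[0] >= k
    if not distinct_enough:
        if parent is None:
            raise DegenerateInitError(
                f"root clustering needs at least {k} distinct patches"
            )
        return np.repeat(parent[None, :], k, axis=0)
    return spherical_kmeans(x, k, n_iter=n_iter, rng_seed=rng)


def learn_hierarchical_dictionary(
    whitened_patches: np.ndarray,
    n_levels: int,
    n_splits: int,
    n_iter: int = DEFAULT_KMEANS_ITER,
    rng_seed: int | np.random.Generator = 0,
) -> VisualDictionary:
    """Learn the hierarchical dictionary from whitened patch vectors.

    The root level clusters all patches into ``n_splits`` groups; each
    group is recursively re-clustered until ``n_levels`` levels exist.
    Patches are (re-)L2-normalised before clustering at every level.
    """
    if n_levels < 1:
        raise DictionaryError(f"n_levels must be >= 1, got {n_levels}")
    if n_splits < 2:
        raise DictionaryError(f"n_splits must be >= 2, got {n_splits}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    x = _unit_rows(np.atleast_2d(np.asarray(whitened_patches, dtype=np.float64)))
    levels: list[np.ndarray] = []
    # each entry: (patch subset, parent centroid or None)
    groups: list[tuple[np.ndarray, np.ndarray | None]] = [(x, None)]
    for _ in range(n_levels):
        centroids_this_level: list[np.ndarray] = []
        next_groups: list[tuple[np.ndarray, np.ndarray | None]] = []
        for subset, parent in groups:
            cents = _cluster_node(subset, n_splits, n_iter, rng, parent)
            centroids_this_level.append(cents)
            if subset.shape[0]:
                assign = np.argmax(subset @ cents.T, axis=1)
            else:
                assign = np.zeros(0, dtype=int)
            for j in range(n_splits):
                next_groups.append((subset[assign == j], cents[j]))
        levels.append(np.vstack(centroids_this_level))
        groups = next_groups
    return VisualDictionary(levels=levels, n_splits=n_splits)


def quantize(
    dictionary: VisualDictionary,
    whitened_patches: np.ndarray,
    exhaustive: bool = False,
) -> np.ndarray:
    """Map whitened patches to visual word ids.

    Greedy descent by default: at each level pick the child with the
    largest cosine similarity (ties to the lowest child index); the zero
    patch follows the all-lowest-index path.  With ``exhaustive`` the
    nearest leaf over all K words is returned instead.
    """
    x = np.atleast_2d(np.asarray(whitened_patches, dtype=np.float64))
    single = np.asarray(whitened_patches).ndim == 1
    if x.shape[1] != dictionary.dim:
        raise DictionaryError(
            f"patch dimension {x.shape[1]} does not match dictionary "
            f"dimension {dictionary.dim}"
        )
    if exhaustive:
        ids = np.argmax(x @ dictionary.leaves.T, axis=1)
        return int(ids[0]) if single else ids
    s = dictionary.n_splits
    n = x.shape[0]
    node = np.zeros(n, dtype=np.intp)  # parent node index at the current level
    offsets = np.arange(s)
    for lvl in dictionary.levels:
        # children of parent m are rows m*s .. m*s+s-1 of this level
        if lvl.shape[0] <= 1024:
            sims = x @ lvl.T
            child_cols = node[:, None] * s + offsets
            pick = np.argmax(np.take_along_axis(sims, child_cols, axis=1), axis=1)
        else:
            # large level: one small matmul per occupied parent node
            pick = np.empty(n, dtype=np.intp)
            order = np.argsort(node, kind="stable")
            sorted_node = node[order]
            parents, starts = np.unique(sorted_node, return_index=True)
            bounds = np.append(starts, n)
            for ui, m in enumerate(parents):
                idx = order[bounds[ui] : bounds[ui + 1]]
                children = lvl[m * s : (m + 1) * s]
                pick[idx] = np.argmax(x[idx] @ children.T, axis=1)
        node = node * s + pick
    return int(node[0]) if single else node.astype(np.int64)
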