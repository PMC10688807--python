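"""MinHash sketching, Mash distances and Ward.D2 hierarchical clustering.

A genome (here: a MAG's gene set) is reduced to the `s` smallest distinct
64-bit hashes of its canonical k-mers (bottom-s MinHash, Mash-style defaults
k = 21, s = 1000).  The Jaccard index of two genomes is estimated from the
bottom-s' of the merged hash union, and converted to the Mash distance
d = −(1/k)·ln(2j / (1 + j)), capped at 1 when no hashes are shared.  The
hash is a seeded splitmix64-style 64-bit mixer over 2-bit-encoded k-mers;
bit-compatibility with the Mash binary is not a contract — agreement with
the exact Jaccard index is.

Distance matrices are clustered with the Ward.D2 criterion (Lance-Williams
on squared distances, square-root heights) and exported as dendrograms /
Newick trees for heatmap annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "Sketch",
    "DistanceMatrix",
    "Dendrogram",
    "minhash_sketch",
    "mash_distance",
    "pairwise_mash",
    "ward2_cluster",
    "to_newick",
    "annotate_heatmap_export",
    "canonical_kmer_hashes",
]

_U64 = np.uint64


def _splitmix64(z: np.ndarray, seed: int) -> np.ndarray:
    """Seeded 64-bit finalising mixer (splitmix64 constants)."""
    offset = (int(seed) * 0x9E3779B97F4A7C15) % (1 << 64)
    z = z.astype(_U64) + _U64(offset)
    z = z + _U64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
for i, b in enumerate(b"acgt"):
    _CODE[b] = i


def canonical_kmer_hashes(seq: str, kmer_size: int, hash_seed: int) -> np.ndarray:
    """Distinct hashes of the canonical k-mers of one sequence.

    Canonical = lexicographic minimum of a k-mer and its reverse complement
    (the 2-bit A<C<G<T encoding preserves lexicographic order).  Windows
    containing non-ACGT symbols are skipped.  Raises if the sequence is
    shorter than k.
    """
    k = kmer_size
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k={k}")
    if 2 * k > 63:
        raise ValueError("kmer_size too large for 64-bit packing")
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    L = len(codes) - k + 1
    valid = codes < 4
    ok = np.convolve(valid.astype(np.int32), np.ones(k, dtype=np.int32), mode="valid") == k
    if not ok.any():
        return np.empty(0, dtype=_U64)
    c = np.where(valid, codes, 0).astype(_U64)
    fwd = np.zeros(L, dtype=_U64)
    rev = np.zeros(L, dtype=_U64)
    for j in range(k):
        fwd = (fwd << _U64(2)) | c[j : j + L]
        rev = rev | ((_U64(3) - c[j : j + L]) << _U64(2 * j))
    canon = np.minimum(fwd, rev)[ok]
    return np.unique(_splitmix64(canon, hash_seed))


@dataclass
class Sketch:
    """Bottom-s MinHash sketch of one MAG's sequences."""

    mag_id: str
    kmer_size: int = 21
    sketch_size: int = 1000
    hash_seed: int = 42
    hashes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=_U64))

    def to_dict(self) -> dict:
        return {
            "mag_id": self.mag_id,
            "kmer_size": self.kmer_size,
            "sketch_size": self.sketch_size,
            "hash_seed": self.hash_seed,
            "hashes": [int(h) for h in self.hashes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Sketch":
        return cls(
            mag_id=d["mag_id"],
            kmer_size=d["kmer_size"],
            sketch_size=d["sketch_size"],
            hash_seed=d["hash_seed"],
            hashes=np.asarray(d["hashes"], dtype=_U64),
        )


def minhash_sketch(
    sequences: Mapping[str, str] | Sequence[str] | str,
    mag_id: str = "",
    kmer_size: int = 21,
    sketch_size: int = 1000,
    hash_seed: int = 42,
) -> Sketch:
    """Bottom-`sketch_size` sketch over the canonical k-mers of `sequences`.

    When the genome holds fewer than `sketch_size` distinct k-mers the
    sketch saturates and holds all of them.
    """
    if isinstance(sequences, str):
        seqs = [sequences]
    elif isinstance(sequences, Mapping):
        seqs = [sequences[g] for g in sorted(sequences)]
    else:
        seqs = list(sequences)
    if not seqs:
        raise ValueError("no sequences to sketch")
    all_hashes = np.unique(
        np.concatenate([canonical_kmer_hashes(s, kmer_size, hash_seed) for s in seqs])
    )
    bottom = all_hashes[:sketch_size]
    return Sketch(
        mag_id=mag_id,
        kmer_size=kmer_size,
        sketch_size=sketch_size,
        hash_seed=hash_seed,
        hashes=bottom,
    )


def mash_distance(a: Sketch, b: Sketch) -> float:
    """Mash distance between two sketches of identical parameters.

    The Jaccard index is estimated on the bottom-s' of the merged hash
    union (s' = min(sketch_size, |union|)); d = −ln(2j/(1+j))/k, and d = 1
    when no hashes are shared (the formula diverges at j = 0).
    """
    if (a.kmer_size, a.sketch_size, a.hash_seed) != (b.kmer_size, b.sketch_size, b.hash_seed):
        raise ValueError("sketch parameters differ")
    union = np.union1d(a.hashes, b.hashes)
    s_prime = min(a.sketch_size, union.size)
    if s_prime == 0:
        return 1.0
    bottom = union[:s_prime]
    shared = np.intersect1d(bottom, np.intersect1d(a.hashes, b.hashes, assume_unique=True)).size
    j = shared / s_prime
    if j <= 0:
        return 1.0
    if j >= 1:
        return 0.0
    return float(-np.log(2.0 * j / (1.0 + j)) / a.kmer_size)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path) -> None:
        self.to_frame().rename_axis("id").to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=list(df.index), values=df.to_numpy(dtype=float))


def pairwise_mash(sketches: Sequence[Sketch]) -> DistanceMatrix:
    """All-pairs Mash distances."""
    n = len(sketches)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = mash_distance(sketches[i], sketches[j])
    return DistanceMatrix(ids=[s.mag_id for s in sketches], values=d)


@dataclass
class Dendrogram:
    """A hierarchical clustering result (scipy linkage + leaf order)."""

    linkage: np.ndarray
    ids: list[str]

    @property
    def leaf_order(self) -> list[str]:
        return [self.ids[i] for i in hierarchy.leaves_list(self.linkage)]

    def cut(self, n_clusters: int) -> pd.Series:
        labels = hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")
        return pd.Series(labels, index=self.ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def ward2_cluster(d: DistanceMatrix) -> Dendrogram:
    """Agglomerative clustering under the Ward.D2 criterion.

    Uses the Lance-Williams recurrence on squared dissimilarities with
    square-root merge heights (scipy's ``ward`` on a precomputed condensed
    matrix, which matches R's ``hclust(method="ward.D2")``).
    """
    if len(d.ids) < 2:
        raise ValueError("need at least two observations")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains NaN")
    condensed = squareform(d.values, checks=False)
    Z = hierarchy.ward(condensed)
    return Dendrogram(linkage=Z, ids=list(d.ids))


def to_newick(dend: Dendrogram) -> str:
    """Newick export with branch lengths from merge heights."""
    tree = hierarchy.to_tree(dend.linkage)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0) if np.isfinite(parent_height) else 0.0
        if node.is_leaf():
            length = parent_height
            return f"{dend.ids[node.id]}:{length:.10g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    # root has no parent: emit children with lengths relative to root height
    left = rec(tree.left, tree.dist)
    right = rec(tree.right, tree.dist)
    return f"({left},{right});"


def annotate_heatmap_export(
    d: DistanceMatrix,
    og_flags: pd.DataFrame | None = None,
    partition_classes: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dendrogram-ordered distance matrix with side annotations.

    Rows and columns follow the Ward.D2 leaf order; the annotation frame
    carries per-MAG cassette-OG presence flags and the donor's partition
    class, with ``missing`` for MAGs lacking partition information (the
    blank rows of the published heatmap).
    """
    dend = ward2_cluster(d)
    order = dend.leaf_order
    mat = d.to_frame().loc[order, order]
    ann = pd.DataFrame(index=order)
    if partition_classes is not None:
        ann["partition_class"] = [partition_classes.get(m, "missing") for m in order]
    if og_flags is not None:
        ann = ann.join(og_flags.reindex(order))
    return mat, ann
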