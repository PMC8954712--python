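"""From-scratch SMOTE oversampling, Tomek-link detection, and their hybrid.

SMOTE creates minority-class samples by interpolating between a minority
sample and one of its k minority nearest neighbors; a Tomek link is a
cross-class pair of mutual nearest neighbors, and removing link members
cleans the class boundary.  The hybrid (SMOTE then Tomek removal) is applied
to the training set only — evaluation sets stay imbalanced.

Distances are Euclidean on the raw 0/1 features (= sqrt(Hamming) for binary
fingerprints), with no scaling.  Nearest-neighbor ties break toward the
lower row index, which keeps every step deterministic under a seed.
Synthetic rows are binarized at 0.5 (ties -> 1) so they remain valid
fingerprints for downstream fragment mining.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

ORIGINAL = "original"
SYNTHETIC = "synthetic"


def _sq_dists(matrix: np.ndarray, x: np.ndarray) -> np.ndarray:
    d = matrix.astype(float) - x.astype(float)
    return np.einsum("ij,ij->i", d, d)


def nearest_neighbors(
    matrix: np.ndarray,
    index: int,
    k: int,
    labels: Optional[Sequence] = None,
    restrict_to=None,
) -> List[int]:
    """Indices of the k nearest rows to ``matrix[index]`` (self excluded).

    Euclidean distance, ascending; exact ties broken by lower row index.
    With ``restrict_to``, only rows whose label equals it are eligible.
    Raises if fewer than k eligible rows exist.
    """
    matrix = np.asarray(matrix)
    eligible = np.arange(len(matrix))
    if restrict_to is not None:
        if labels is None:
            raise ValueError("restrict_to requires labels")
        eligible = eligible[np.asarray(labels) == restrict_to]
    eligible = eligible[eligible != index]
    if k > len(eligible):
        raise ValueError(f"k={k} but only {len(eligible)} eligible rows")
    d2 = _sq_dists(matrix[eligible], matrix[index])
    order = np.lexsort((eligible, d2))
    return eligible[order[:k]].tolist()


@dataclass(frozen=True)
class SmoteResult:
    """Synthetic rows plus the (sample, neighbor) parent pair of each row."""

    rows: np.ndarray
    parents: Tuple[Tuple[int, int], ...]


def smote_oversample(
    minority: np.ndarray,
    target_count: int,
    k: int = 5,
    seed: int = 0,
    binarize: bool = True,
) -> SmoteResult:
    """Generate ``target_count`` synthetic minority rows by SMOTE interpolation.

    Each row is x_i + u * (x_nn - x_i) with u ~ Uniform(0,1) and x_nn a
    uniformly chosen one of x_i's k nearest minority neighbors (k capped at
    the available neighbor count).  With ``binarize``, entries are thresholded
    at 0.5, ties to 1.  Requires at least two minority rows.
    """
    minority = np.asarray(minority, dtype=float)
    if minority.ndim != 2 or len(minority) < 2:
        raise ValueError("minority must be a 2-D array with at least 2 rows")
    if target_count < 0:
        raise ValueError("target_count must be non-negative")
    k_eff = min(k, len(minority) - 1)
    neighbor_table = [
        nearest_neighbors(minority, i, k_eff) for i in range(len(minority))
    ]
    rng = np.random.default_rng(seed)
    rows = np.empty((target_count, minority.shape[1]))
    parents = []
    for t in range(target_count):
        i = int(rng.integers(len(minority)))
        nn = neighbor_table[i][int(rng.integers(k_eff))]
        u = rng.random()
        rows[t] = minority[i] + u * (minority[nn] - minority[i])
        parents.append((i, nn))
    if binarize:
        rows = (rows >= 0.5).astype(np.uint8)
    return SmoteResult(rows=rows, parents=tuple(parents))


def find_tomek_links(matrix: np.ndarray, labels: Sequence) -> List[Tuple[int, int]]:
    """All unordered cross-class mutual-nearest-neighbor pairs, sorted.

    Returns an empty list when only one class is present.  Nearest neighbors
    use the same tie-break (lower index) as :func:`nearest_neighbors`.
    """
    matrix = np.asarray(matrix)
    labels = np.asarray(labels)
    n = len(matrix)
    if n < 2 or len(np.unique(labels)) < 2:
        return []
    nn = np.empty(n, dtype=int)
    for i in range(n):
        nn[i] = nearest_neighbors(matrix, i, 1)[0]
    links = set()
    for a in range(n):
        b = nn[a]
        if nn[b] == a and labels[a] != labels[b]:
            links.add((min(a, b), max(a, b)))
    return sorted(links)


@dataclass(frozen=True)
class ResamplingResult:
    """Balanced training data with per-row provenance.

    ``matrix``/``labels`` are the retained rows after Tomek removal;
    ``provenance`` marks each retained row original or synthetic;
    ``removed_ids`` lists the ids of rows deleted as link members.
    """

    matrix: np.ndarray
    labels: List[str]
    provenance: List[str]
    removed_ids: List[str]
    ids: List[str] = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.matrix) == len(self.labels) == len(self.provenance)):
            raise ValueError("matrix, labels and provenance lengths differ")


def smote_tomek(
    matrix: np.ndarray,
    labels: Sequence[str],
    seed: int = 0,
    k: int = 5,
    policy: str = "both",
    binarize: bool = True,
    ids: Optional[Sequence[str]] = None,
) -> ResamplingResult:
    """SMOTE the minority class to parity, then remove Tomek-link members.

    ``policy='both'`` removes both members of each link (the applied hybrid;
    post-balance class counts can differ from parity by at most 2x the link
    count); ``policy='majority-only'`` removes only the majority-class member.
    """
    if policy not in ("both", "majority-only"):
        raise ValueError(f"policy must be 'both' or 'majority-only', got {policy!r}")
    matrix = np.asarray(matrix)
    labels = list(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if ids is None:
        ids = [f"row{i:04d}" for i in range(len(labels))]
    ids = list(ids)

    min_idx = [i for i, l in enumerate(labels) if l == minority]
    synth = smote_oversample(
        matrix[min_idx], target_count=int(n_maj - n_min), k=k, seed=seed,
        binarize=binarize,
    )
    full = np.vstack([matrix, synth.rows]) if len(synth.rows) else matrix.copy()
    full_labels = labels + [str(minority)] * len(synth.rows)
    full_ids = ids + [f"synthetic{t:04d}" for t in range(len(synth.rows))]
    provenance = [ORIGINAL] * len(labels) + [SYNTHETIC] * len(synth.rows)

    links = find_tomek_links(full, full_labels)
    drop = set()
    for a, b in links:
        if policy == "both":
            drop.update((a, b))
        else:
            drop.add(a if full_labels[a] == majority else b)
    keep = [i for i in range(len(full)) if i not in drop]
    return ResamplingResult(
        matrix=full[keep],
        labels=[full_labels[i] for i in keep],
        provenance=[provenance[i] for i in keep],
        removed_ids=[full_ids[i] for i in sorted(drop)],
        ids=[full_ids[i] for i in keep],
    )
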