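"""Privileged-substructure mining over binary fingerprint bits.

Two per-bit statistics identify pharmacophoric fragments:

* **Information gain (IG)** — the reduction in Shannon entropy (base 2) of
  the potency class given the bit's present/absent status.  The higher the
  IG, the more a substructure discriminates potent from non-potent
  compounds.

* **Class frequency** — for class I,
  ``(N_fragment_I * N_total) / (N_fragment_total * N_I)``,
  where N_fragment_I counts class-I compounds containing the fragment,
  N_fragment_total all compounds containing it, N_I the class size and
  N_total the dataset size.  A value above 1 means the fragment is
  over-represented in that class; a bit with potent-class frequency > 1 is a
  candidate privileged substructure.

Both statistics use the modeling dataset's totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np

from .dataset_core import FingerprintMatrix, NON_POTENT, POTENT
from .metrics import UNDEFINED, _Undefined

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class FragmentStats:
    """Occurrence counts and derived statistics for one fingerprint bit."""

    bit_name: str
    n_fragment_P: int
    n_fragment_N: int
    n_P: int
    n_N: int
    ig: Optional[float] = None
    freq_P: Union[float, _Undefined, None] = None
    freq_N: Union[float, _Undefined, None] = None
    polarity: Optional[str] = None

    @property
    def n_fragment_total(self) -> int:
        return self.n_fragment_P + self.n_fragment_N

    @property
    def n_total(self) -> int:
        return self.n_P + self.n_N

    def __post_init__(self):
        if self.n_fragment_P > self.n_P or self.n_fragment_N > self.n_N:
            raise ValueError(f"{self.bit_name}: fragment counts exceed class sizes")


def bit_class_counts(
    matrix: FingerprintMatrix, labels: Sequence[str]
) -> List[FragmentStats]:
    """Per-bit occurrence counts in the potent and non-potent classes."""
    if len(labels) != len(matrix.compound_ids):
        raise ValueError(
            f"{len(labels)} labels for {len(matrix.compound_ids)} compounds"
        )
    is_p = np.asarray(labels) == POTENT
    n_p = int(is_p.sum())
    n_n = int((~is_p).sum())
    counts_p = matrix.values[is_p].sum(axis=0)
    counts_n = matrix.values[~is_p].sum(axis=0)
    return [
        FragmentStats(
            bit_name=b, n_fragment_P=int(cp), n_fragment_N=int(cn), n_P=n_p, n_N=n_n
        )
        for b, cp, cn in zip(matrix.bit_names, counts_p, counts_n)
    ]


def class_frequency(
    n_fragment_class: int, n_fragment_total: int, n_total: int, n_class: int
) -> Union[float, _Undefined]:
    """Over-representation ratio of a fragment in one class.

    ``(n_fragment_class * n_total) / (n_fragment_total * n_class)``; 1 means
    the fragment occurs at the class's base rate.  UNDEFINED when the
    fragment occurs nowhere.
    """
    if n_class <= 0:
        raise ValueError("n_class must be positive")
    if n_fragment_total == 0:
        return UNDEFINED
    return (n_fragment_class * n_total) / (n_fragment_total * n_class)


def _entropy(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        return 0.0
    return -(p * math.log2(p) + (1 - p) * math.log2(1 - p))


def information_gain(
    n_fragment_P: int, n_fragment_N: int, n_P: int, n_N: int
) -> float:
    """H(class) - H(class | bit), Shannon entropy base 2, 0*log0 := 0.

    Always >= 0; exactly 0 when the bit's prevalence is identical in both
    classes (independence in counts).
    """
    if n_P <= 0 or n_N <= 0:
        raise ValueError("both class sizes must be positive")
    if n_fragment_P > n_P or n_fragment_N > n_N:
        raise ValueError("fragment counts exceed class sizes")
    n = n_P + n_N
    present = n_fragment_P + n_fragment_N
    absent = n - present
    h = _entropy(n_P / n)
    h_cond = 0.0
    if present:
        h_cond += (present / n) * _entropy(n_fragment_P / present)
    if absent:
        h_cond += (absent / n) * _entropy((n_P - n_fragment_P) / absent)
    return max(h - h_cond, 0.0)


def annotate(stats: FragmentStats) -> FragmentStats:
    """Fill ig/freq_P/freq_N/polarity from a counts-only record."""
    ig = information_gain(stats.n_fragment_P, stats.n_fragment_N, stats.n_P, stats.n_N)
    fp = class_frequency(stats.n_fragment_P, stats.n_fragment_total, stats.n_total, stats.n_P)
    fn = class_frequency(stats.n_fragment_N, stats.n_fragment_total, stats.n_total, stats.n_N)
    if fp is UNDEFINED or fn is UNDEFINED or fp == fn:
        pol = NEUTRAL
    elif fp > fn:
        pol = POSITIVE
    else:
        pol = NEGATIVE
    return FragmentStats(
        bit_name=stats.bit_name,
        n_fragment_P=stats.n_fragment_P,
        n_fragment_N=stats.n_fragment_N,
        n_P=stats.n_P,
        n_N=stats.n_N,
        ig=ig,
        freq_P=fp,
        freq_N=fn,
        polarity=pol,
    )


def rank_fragments(
    matrix: FingerprintMatrix,
    labels: Sequence[str],
    min_ig: float = 0.0,
    min_support: int = 2,
) -> List[FragmentStats]:
    """Annotated bits with support >= min_support and IG >= min_ig, ranked.

    Sort order: IG descending, then potent-class frequency descending, then
    bit name.  A bit seen in fewer than ``min_support`` compounds cannot be a
    reusable pharmacophore and is dropped.
    """
    uniq = set(labels)
    if not {POTENT, NON_POTENT} <= uniq:
        raise ValueError("both classes must be present to rank fragments")
    out = []
    for st in bit_class_counts(matrix, labels):
        if st.n_fragment_total < min_support:
            continue
        ann = annotate(st)
        if ann.ig < min_ig:
            continue
        out.append(ann)
    def key(s: FragmentStats):
        fp = s.freq_P if not isinstance(s.freq_P, _Undefined) else -math.inf
        return (-s.ig, -fp, s.bit_name)
    out.sort(key=key)
    return out
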