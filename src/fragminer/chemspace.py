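"""Dataset characterization: diversity, descriptor screening, projection, drug-likeness.

A Euclidean distance matrix over fingerprints summarizes chemical diversity
(normalized to [0, 1] for heat-map rendering).  Descriptor tables are
screened before projection: near-constant columns (>80% of compounds sharing
the modal value) and one member of every highly inter-correlated pair
(|Pearson r| > 0.95) are removed; the survivors feed a scaled principal
component projection.  A Lipinski profile (MW, logP, HBD, HBA, RotB)
summarizes drug-likeness for radar rendering.

Descriptor tables are plain pandas DataFrames: compound ids as index, one
named numeric column per descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .dataset_core import FingerprintMatrix

LIPINSKI_COLUMNS = ("MW", "logP", "HBD", "HBA", "RotB")


def distance_heat_matrix(fp: FingerprintMatrix, normalize: bool = True) -> np.ndarray:
    """Pairwise Euclidean distance matrix; scaled by its maximum if ``normalize``."""
    if len(fp.compound_ids) < 2:
        raise ValueError("need at least 2 compounds for a distance matrix")
    d = squareform(pdist(fp.values.astype(float), metric="euclidean"))
    if normalize and d.max() > 0:
        d = d / d.max()
    return d


@dataclass(frozen=True)
class ScreenReport:
    removed_constant: List[str]
    removed_correlated: List[str]
    retained: List[str]

    @property
    def removed(self) -> List[str]:
        return self.removed_constant + self.removed_correlated


def screen_descriptors(
    table: pd.DataFrame,
    constant_fraction: float = 0.80,
    corr_cutoff: float = 0.95,
) -> ScreenReport:
    """Drop near-constant then highly inter-correlated descriptors.

    A descriptor is near-constant when its modal value's frequency strictly
    exceeds ``constant_fraction``.  Among survivors, each pair with
    |Pearson r| > ``corr_cutoff`` loses its later-listed member (greedy,
    keep-first, deterministic).  Row order does not affect the outcome.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows to screen descriptors")
    removed_constant = []
    for col in table.columns:
        modal_freq = table[col].value_counts(dropna=False).iloc[0] / len(table)
        if modal_freq > constant_fraction:
            removed_constant.append(col)
    survivors = [c for c in table.columns if c not in set(removed_constant)]
    removed_correlated: List[str] = []
    if survivors:
        corr = table[survivors].corr().abs().to_numpy()
        dead = np.zeros(len(survivors), dtype=bool)
        for i in range(len(survivors)):
            if dead[i]:
                continue
            for j in range(i + 1, len(survivors)):
                if not dead[j] and corr[i, j] > corr_cutoff:
                    dead[j] = True
        removed_correlated = [c for c, d in zip(survivors, dead) if d]
    retained = [
        c for c in table.columns
        if c not in set(removed_constant) and c not in set(removed_correlated)
    ]
    return ScreenReport(removed_constant, removed_correlated, retained)


def project(
    table: pd.DataFrame, n_components: int = 3
) -> Tuple[np.ndarray, np.ndarray]:
    """Scaled principal-component projection of a screened descriptor table.

    Columns are centered and scaled to unit variance (descriptor units are
    heterogeneous), then projected; returns (coordinates, explained-variance
    fractions, non-increasing).  Constant columns must be screened out first.
    """
    from sklearn.decomposition import PCA

    x = table.to_numpy(dtype=float)
    if x.shape[0] <= n_components:
        raise ValueError("need more rows than components")
    std = x.std(axis=0, ddof=1)
    if (std == 0).any():
        bad = table.columns[np.nonzero(std == 0)[0][0]]
        raise ValueError(f"constant column {bad!r}: run screen_descriptors first")
    z = (x - x.mean(axis=0)) / std
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(z)
    return coords, pca.explained_variance_ratio_


def lipinski_profile(table: pd.DataFrame) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-compound Lipinski 5-tuple plus a min/median/max dataset summary.

    Requires columns MW, logP, HBD, HBA and RotB; raises naming the first
    missing one.
    """
    for col in LIPINSKI_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"missing Lipinski column {col!r}")
    if len(table) == 0:
        raise ValueError("empty descriptor table")
    per_compound = table.loc[:, list(LIPINSKI_COLUMNS)].copy()
    summary = per_compound.agg(["min", "median", "max"])
    return per_compound, summary
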