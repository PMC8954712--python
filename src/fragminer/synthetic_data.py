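"""Synthetic labeled fingerprint datasets with the structure the analysis assumes.

The generator emulates a small, imbalanced kinase-inhibitor SAR dataset:
~117 compounds with a ~3:1 potent:non-potent imbalance, ~881 binary
substructure bits, a handful of bits strongly enriched in the potent class,
near-constant bits, and correlated bit pairs.  Bits are class-conditionally
independent Bernoulli draws — the simplest model consistent with per-bit
frequency analysis — with correlation injected only through explicit
duplicate-with-flip pairs.  Activity values are drawn from two truncated
normals (potent around pIC50 6.9, non-potent around 5.4) so that relabeling
the generated pIC50 values reproduces the generated classes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .dataset_core import (
    DEFAULT_CUTOFF,
    NON_POTENT,
    POTENT,
    ActivityRecord,
    FingerprintMatrix,
    assign_class,
)


@dataclass(frozen=True)
class EnrichmentSpec:
    """A bit with class-dependent prevalence: P(bit=1 | class)."""

    bit_name: str
    p_present_in_P: float
    p_present_in_N: float

    def __post_init__(self):
        for p in (self.p_present_in_P, self.p_present_in_N):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.bit_name}: probability {p} outside [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    n_compounds: int = 117
    n_bits: int = 881
    n_potent: int = 89
    enriched: Tuple[EnrichmentSpec, ...] = ()
    background_p: float = 0.15
    n_constant_bits: int = 0
    n_correlated_pairs: int = 0
    flip_p: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_potent > self.n_compounds:
            raise ValueError("n_potent exceeds n_compounds")
        if not 0.0 <= self.background_p <= 1.0:
            raise ValueError(f"background_p {self.background_p} outside [0, 1]")
        if not 0.0 <= self.flip_p <= 1.0:
            raise ValueError(f"flip_p {self.flip_p} outside [0, 1]")
        if self.n_constant_bits + self.n_correlated_pairs * 2 + len(self.enriched) > self.n_bits:
            raise ValueError("planted bits exceed the bit budget")


def study_enrichment() -> Tuple[EnrichmentSpec, ...]:
    """Enriched-bit prevalences emulating the privileged-substructure pattern
    of the benchmark dataset (e.g. a top bit present in 49/89 potent vs 2/28
    non-potent compounds)."""
    return (
        EnrichmentSpec("PubchemFP691", 49 / 89, 2 / 28),
        EnrichmentSpec("PubchemFP702", 49 / 89, 2 / 28),
        EnrichmentSpec("PubchemFP703", 48 / 89, 2 / 28),
        EnrichmentSpec("PubchemFP499", 32 / 89, 2 / 28),
        EnrichmentSpec("PubchemFP645", 29 / 89, 2 / 28),
        EnrichmentSpec("PubchemFP187", 23 / 89, 1 / 28),
        EnrichmentSpec("PubchemFP629", 41 / 89, 4 / 28),
    )


def study_config(seed: int = 0) -> GeneratorConfig:
    """Default configuration mirroring the benchmark dataset's shape:
    117 compounds (89 potent / 28 non-potent), 881 bits, enriched bits from
    :func:`study_enrichment`, moderate background prevalence, a few constant
    bits and correlated pairs."""
    return GeneratorConfig(
        n_compounds=117,
        n_bits=881,
        n_potent=89,
        enriched=study_enrichment(),
        background_p=0.15,
        n_constant_bits=8,
        n_correlated_pairs=10,
        seed=seed,
    )


def _bit_universe(n_bits: int) -> List[str]:
    return [f"PubchemFP{i}" for i in range(n_bits)]


def generate_fingerprint_dataset(
    config: GeneratorConfig,
) -> Tuple[FingerprintMatrix, List[ActivityRecord]]:
    """Draw a labeled binary fingerprint dataset under ``config``.

    Class counts are exact (``n_potent`` potent).  Enriched bits are Bernoulli
    per class; constant bits are all-1; each correlated pair copies a random
    background bit with ``flip_p`` per-entry flip probability.  Fully
    reproducible under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, m = config.n_compounds, config.n_bits
    bit_names = _bit_universe(m)
    name_to_col = {b: j for j, b in enumerate(bit_names)}
    for spec in config.enriched:
        if spec.bit_name not in name_to_col:
            raise ValueError(f"enriched bit {spec.bit_name!r} outside the bit universe")

    classes = np.array([POTENT] * config.n_potent + [NON_POTENT] * (n - config.n_potent))
    rng.shuffle(classes)
    is_p = classes == POTENT

    values = (rng.random((n, m)) < config.background_p).astype(np.uint8)

    enriched_cols = set()
    for spec in config.enriched:
        j = name_to_col[spec.bit_name]
        enriched_cols.add(j)
        col = np.empty(n, dtype=np.uint8)
        col[is_p] = rng.random(is_p.sum()) < spec.p_present_in_P
        col[~is_p] = rng.random((~is_p).sum()) < spec.p_present_in_N
        values[:, j] = col

    # constant and correlated bits claim the highest-index non-enriched columns
    free = [j for j in range(m - 1, -1, -1) if j not in enriched_cols]
    const_cols = free[: config.n_constant_bits]
    pair_cols = free[config.n_constant_bits : config.n_constant_bits + 2 * config.n_correlated_pairs]
    for j in const_cols:
        values[:, j] = 1
    for k in range(config.n_correlated_pairs):
        src, dst = pair_cols[2 * k], pair_cols[2 * k + 1]
        flips = rng.random(n) < config.flip_p
        values[:, dst] = values[:, src] ^ flips.astype(np.uint8)

    ids = [f"MOL{i + 1:03d}" for i in range(n)]
    pic50s = generate_activity_values(classes.tolist(), seed=int(rng.integers(2**31)))
    records = [
        ActivityRecord(compound_id=cid, pic50=p, potency_class=assign_class(p))
        for cid, p in zip(ids, pic50s)
    ]
    assert [r.potency_class for r in records] == classes.tolist()
    return FingerprintMatrix(ids, bit_names, values), records


#: pIC50 noise model: class-conditional truncated normals.  Potent activities
#: cluster around 6.9 within [6.0, 8.5]; non-potent around 5.4 within
#: [4.5, 6.0).  Truncation at the class cutoff guarantees label round-trip.
_P_MEAN, _N_MEAN, _SD = 6.9, 5.4, 0.5
_P_RANGE = (DEFAULT_CUTOFF, 8.5)
_N_RANGE = (4.5, DEFAULT_CUTOFF)


def generate_activity_values(classes: Sequence[str], seed: int = 0) -> List[float]:
    """Draw one pIC50 per class label; ``assign_class`` round-trips exactly."""
    rng = np.random.default_rng(seed)
    out = np.empty(len(classes))
    idx_p = np.array([c == POTENT for c in classes], dtype=bool)

    def draw(lo, hi, mean, size):
        a, b = (lo - mean) / _SD, (hi - mean) / _SD
        return truncnorm.rvs(a, b, loc=mean, scale=_SD, size=size, random_state=rng)

    out[idx_p] = draw(*_P_RANGE, _P_MEAN, int(idx_p.sum()))
    vals_n = draw(*_N_RANGE, _N_MEAN, int((~idx_p).sum()))
    # open upper bound for the non-potent class: the cutoff itself is potent
    vals_n = np.minimum(vals_n, np.nextafter(DEFAULT_CUTOFF, -np.inf))
    out[~idx_p] = vals_n
    return out.tolist()


def generate_descriptor_table(
    n_rows: int,
    n_descriptors: int,
    n_nearly_constant: int,
    n_high_corr_pairs: int,
    seed: int = 0,
    include_lipinski: bool = False,
) -> pd.DataFrame:
    """Continuous descriptor table with planted screening defects.

    Exactly ``n_nearly_constant`` columns have >80% identical values and
    exactly ``n_high_corr_pairs`` column pairs have |Pearson r| > 0.95 (a
    near-duplicate with small noise); the remaining columns are independent
    standard normals.  With ``include_lipinski``, five drug-likeness columns
    (MW, logP, HBD, HBA, RotB) with realistic ranges are appended.
    """
    if n_nearly_constant + 2 * n_high_corr_pairs > n_descriptors:
        raise ValueError("planted defect columns exceed n_descriptors")
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n_rows, n_descriptors))
    names = [f"D{j + 1:04d}" for j in range(n_descriptors)]
    # near-constant: ~88% of rows share one value
    for j in range(n_nearly_constant):
        col = np.full(n_rows, float(j))
        n_var = max(1, int(round(0.12 * n_rows)))
        var_idx = rng.choice(n_rows, size=n_var, replace=False)
        col[var_idx] = rng.standard_normal(n_var) + j
        data[:, j] = col
    # high-correlation pairs: duplicate + 2% noise
    for k in range(n_high_corr_pairs):
        src = n_nearly_constant + 2 * k
        dst = src + 1
        data[:, dst] = data[:, src] + 0.02 * rng.standard_normal(n_rows)
    df = pd.DataFrame(
        data, index=pd.Index([f"MOL{i + 1:03d}" for i in range(n_rows)], name="Name"),
        columns=names,
    )
    if include_lipinski:
        df["MW"] = np.clip(rng.normal(380, 80, n_rows), 150, 700)
        df["logP"] = rng.normal(3.0, 1.3, n_rows)
        df["HBD"] = rng.poisson(2, n_rows).astype(float)
        df["HBA"] = rng.poisson(5, n_rows).astype(float)
        df["RotB"] = rng.poisson(4, n_rows).astype(float)
    return df
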