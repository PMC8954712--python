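"""Activity tables, potency labeling, fingerprint matrices and train/test splits.

Compounds carry an IC50 (micromolar) or its log transform pIC50 =
-log10(IC50 [M]) = 6 - log10(IC50 [uM]).  The binary potency classes are
potent ("P", pIC50 >= cutoff, default 6.0 i.e. IC50 <= 1 uM) and non-potent
("N").  Fingerprints are fixed-length binary substructure vectors consumed
precomputed as CSV (rows = compounds, columns = named bits), the dialect
common fingerprint calculators emit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

#: pIC50 threshold separating potent from non-potent inhibitors (IC50 = 1 uM).
DEFAULT_CUTOFF = 6.0

POTENT = "P"
NON_POTENT = "N"


def pic50_from_ic50(ic50_uM: float) -> float:
    """Convert a micromolar IC50 to pIC50 = 6 - log10(IC50 [uM]).

    Raises ``ValueError`` for non-positive or non-finite input.
    """
    ic50_uM = float(ic50_uM)
    if not math.isfinite(ic50_uM) or ic50_uM <= 0:
        raise ValueError(f"IC50 must be a positive finite value in uM, got {ic50_uM!r}")
    return 6.0 - math.log10(ic50_uM)


def assign_class(pic50: float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Label a compound potent ("P") iff pIC50 >= cutoff, else non-potent ("N").

    The boundary value (pIC50 exactly at the cutoff, IC50 = 1 uM) counts as
    potent.
    """
    pic50 = float(pic50)
    if not math.isfinite(pic50) or not math.isfinite(float(cutoff)):
        raise ValueError("pIC50 and cutoff must be finite")
    return POTENT if pic50 >= cutoff else NON_POTENT


@dataclass(frozen=True)
class ActivityRecord:
    """One compound: id, optional SMILES, activity and derived potency class.

    At least one of ``ic50_uM``/``pic50`` must be given; when both are, they
    must agree through the log transform to 1e-9.
    """

    compound_id: str
    smiles: Optional[str] = None
    ic50_uM: Optional[float] = None
    pic50: Optional[float] = None
    potency_class: Optional[str] = None

    def __post_init__(self):
        if self.ic50_uM is None and self.pic50 is None:
            raise ValueError(f"{self.compound_id}: need ic50_uM or pic50")
        if self.ic50_uM is not None:
            derived = pic50_from_ic50(self.ic50_uM)
            if self.pic50 is None:
                object.__setattr__(self, "pic50", derived)
            elif abs(self.pic50 - derived) > 1e-9:
                raise ValueError(
                    f"{self.compound_id}: pic50 {self.pic50} inconsistent with "
                    f"ic50_uM {self.ic50_uM} (expected {derived})"
                )
        if self.potency_class is not None and self.potency_class not in (POTENT, NON_POTENT):
            raise ValueError(f"potency_class must be 'P' or 'N', got {self.potency_class!r}")


def label_records(
    records: Sequence[ActivityRecord], cutoff: float = DEFAULT_CUTOFF
) -> List[ActivityRecord]:
    """Return records with ``potency_class`` assigned from pIC50 at ``cutoff``.

    Idempotent and order-independent: relabeling already-labeled records gives
    the same result.
    """
    return [replace(r, potency_class=assign_class(r.pic50, cutoff)) for r in records]


@dataclass(frozen=True)
class FingerprintMatrix:
    """Compounds x named binary bits, rows aligned with ``compound_ids``."""

    compound_ids: List[str]
    bit_names: List[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape != (len(self.compound_ids), len(self.bit_names)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.compound_ids)} ids x {len(self.bit_names)} bits"
            )
        if not np.isin(v, (0, 1)).all():
            raise ValueError("fingerprint entries must be strictly 0/1")
        if len(set(self.bit_names)) != len(self.bit_names):
            raise ValueError("bit names must be unique")
        if len(set(self.compound_ids)) != len(self.compound_ids):
            raise ValueError("compound ids must be unique")
        object.__setattr__(self, "values", v.astype(np.uint8))

    @property
    def shape(self):
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.compound_ids, name="Name"),
            columns=self.bit_names,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FingerprintMatrix":
        return cls(
            compound_ids=[str(i) for i in df.index],
            bit_names=[str(c) for c in df.columns],
            values=df.to_numpy(),
        )

    def subset(self, ids: Sequence[str]) -> "FingerprintMatrix":
        """Rows for ``ids`` in the order given (unknown id -> KeyError)."""
        pos = {cid: i for i, cid in enumerate(self.compound_ids)}
        try:
            rows = [pos[i] for i in ids]
        except KeyError as e:
            raise KeyError(f"compound id not in fingerprint matrix: {e.args[0]!r}")
        return FingerprintMatrix(list(ids), list(self.bit_names), self.values[rows])


def load_fingerprint_table(path, sep: str = ",") -> FingerprintMatrix:
    """Read a fingerprint CSV (first column = compound id, header = bit names).

    Rejects duplicate ids, ragged rows and non-binary cells with the offending
    row/column in the message.  ``sep=';'`` accepts the semicolon dialect.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate compound id {dup!r}")
    if df.isna().any().any():
        r, c = next(zip(*np.nonzero(df.isna().to_numpy())))
        raise ValueError(f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}")
    arr = df.to_numpy()
    bad = ~np.isin(arr, ("0", "1"))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-binary value {arr[r, c]!r} at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return FingerprintMatrix(
        compound_ids=[str(i) for i in df.index],
        bit_names=[str(c) for c in df.columns],
        values=arr.astype(np.uint8),
    )


def write_fingerprint_table(fm: FingerprintMatrix, path, sep: str = ",") -> None:
    fm.to_dataframe().to_csv(path, sep=sep)


_ID_COLS = ("compound_id", "id", "name")


def load_activity_table(path, sep: str = ",") -> List[ActivityRecord]:
    """Read an activity CSV with columns id/compound_id, [smiles], ic50_uM|pic50."""
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    id_col = next((cols[c] for c in _ID_COLS if c in cols), None)
    if id_col is None:
        raise ValueError(f"{path}: no id column (expected one of {_ID_COLS})")
    records = []
    for _, row in df.iterrows():
        records.append(
            ActivityRecord(
                compound_id=str(row[id_col]),
                smiles=str(row[cols["smiles"]]) if "smiles" in cols and pd.notna(row[cols["smiles"]]) else None,
                ic50_uM=float(row[cols["ic50_um"]]) if "ic50_um" in cols and pd.notna(row[cols["ic50_um"]]) else None,
                pic50=float(row[cols["pic50"]]) if "pic50" in cols and pd.notna(row[cols["pic50"]]) else None,
            )
        )
    return records


def write_activity_table(records: Sequence[ActivityRecord], path, sep: str = ",") -> None:
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "smiles": [r.smiles for r in records],
            "ic50_uM": [r.ic50_uM for r in records],
            "pic50": [r.pic50 for r in records],
            "potency_class": [r.potency_class for r in records],
        }
    ).to_csv(path, sep=sep, index=False)


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/test id lists covering the whole modeling set."""

    train_ids: List[str]
    test_ids: List[str]
    stratification_ratio: float

    def __post_init__(self):
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test ids overlap")


def parse_ratio(ratio: Union[float, str]) -> float:
    """Accept a train:test ratio as a float (3.0) or string ('3:1', '1:0')."""
    if isinstance(ratio, str):
        a, _, b = ratio.partition(":")
        a, b = float(a), float(b or 1.0)
        if b == 0:
            return math.inf
        return a / b
    return float(ratio)


def stratified_split(
    records: Sequence[ActivityRecord],
    ratio: Union[float, str] = 3.0,
    seed: int = 0,
    test_counts: Optional[Mapping[str, int]] = None,
) -> DatasetSplit:
    """Seeded stratified train/test split at a train:test ``ratio``.

    Default allocation is proportional per class (largest-remainder on the
    test side).  ``test_counts`` (class -> test size) overrides the per-class
    allocation, e.g. to reproduce a published split layout; the total sizes
    still follow from the ratio.  Refuses to stratify a class with fewer than
    2 members.
    """
    r = parse_ratio(ratio)
    labeled = [rec if rec.potency_class else None for rec in records]
    if any(x is None for x in labeled):
        raise ValueError("all records must be labeled (run label_records first)")
    by_class: dict = {}
    for rec in records:
        by_class.setdefault(rec.potency_class, []).append(rec.compound_id)
    if math.isinf(r):
        return DatasetSplit([rec.compound_id for rec in records], [], float("inf"))
    for cls, ids in by_class.items():
        if len(ids) < 2:
            raise ValueError(f"class {cls!r} has {len(ids)} member(s); cannot stratify")
    n = len(records)
    test_frac = 1.0 / (1.0 + r)
    n_test = round(n * test_frac)
    if test_counts is None:
        # largest-remainder apportionment of n_test over classes
        quotas = {c: len(ids) * n_test / n for c, ids in by_class.items()}
        counts = {c: math.floor(q) for c, q in quotas.items()}
        short = n_test - sum(counts.values())
        for c in sorted(quotas, key=lambda c: quotas[c] - counts[c], reverse=True)[:short]:
            counts[c] += 1
    else:
        counts = dict(test_counts)
        unknown = set(counts) - set(by_class)
        if unknown:
            raise ValueError(f"test_counts for unknown class(es): {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    train_ids: List[str] = []
    test_ids: List[str] = []
    for cls in sorted(by_class):
        ids = by_class[cls]
        k = counts.get(cls, 0)
        if k > len(ids):
            raise ValueError(f"test_counts[{cls!r}]={k} exceeds class size {len(ids)}")
        chosen = set(rng.choice(len(ids), size=k, replace=False).tolist())
        for i, cid in enumerate(ids):
            (test_ids if i in chosen else train_ids).append(cid)
    order = {rec.compound_id: i for i, rec in enumerate(records)}
    train_ids.sort(key=order.__getitem__)
    test_ids.sort(key=order.__getitem__)
    return DatasetSplit(train_ids, test_ids, r)
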