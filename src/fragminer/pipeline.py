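"""End-to-end orchestration: simulate -> split -> (balance) -> train-eval -> mine -> report.

A single YAML/JSON config drives a run; every stage constant (potency cutoff
6.0, split ratio 3:1, 5 CV folds, RF 20 trees / depth 15, descriptor screens
0.80/0.95) is a named default and overridable.  Each run writes a manifest
with the config snapshot, seeds, software versions and SHA-256 digests of
every output file, so deterministic stages can be audited byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from .classify import AlgorithmSpec, run_grid
from .dataset_core import (
    label_records,
    stratified_split,
    write_activity_table,
    write_fingerprint_table,
)
from .fragment_mining import rank_fragments
from .report import render_tables
from .synthetic_data import (
    EnrichmentSpec,
    GeneratorConfig,
    generate_fingerprint_dataset,
    study_enrichment,
)

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "cutoff": 6.0,
    "dataset": {
        "n_compounds": 117,
        "n_potent": 89,
        "n_bits": 881,
        "background_p": 0.15,
        "n_constant_bits": 8,
        "n_correlated_pairs": 10,
        "enriched": "study",  # or a list of [bit, p_P, p_N]
    },
    "split": {"ratio": "3:1"},
    "cv": {"folds": 5},
    "balance": False,
    "balance_within_folds": False,
    "algorithms": ["SVM", "LR", "kNN", "ANN", "NB", "RF", "DT"],
    "mine": {"min_support": 2, "min_ig": 0.0, "top": 30},
    "screen": {"constant_fraction": 0.80, "corr_cutoff": 0.95},
}


def _merge(base: Dict, override: Dict, path: str = "") -> Dict:
    out = dict(base)
    for key, val in override.items():
        if key not in base:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _merge(base[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def load_config(source=None) -> Dict:
    """Defaults, optionally overridden by a YAML/JSON file or dict.

    Unknown keys fail before any computation.
    """
    if source is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    if isinstance(source, dict):
        return _merge(DEFAULT_CONFIG, source)
    with open(source) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {source} must be a mapping")
    return _merge(DEFAULT_CONFIG, data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    config: Dict
    seed: int
    versions: Dict[str, str]
    started: str
    finished: str = ""
    outputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _generator_config(cfg: Dict) -> GeneratorConfig:
    ds = cfg["dataset"]
    enriched = ds["enriched"]
    if enriched == "study":
        specs = study_enrichment()
    else:
        specs = tuple(EnrichmentSpec(b, float(pp), float(pn)) for b, pp, pn in enriched)
    return GeneratorConfig(
        n_compounds=int(ds["n_compounds"]),
        n_bits=int(ds["n_bits"]),
        n_potent=int(ds["n_potent"]),
        enriched=specs,
        background_p=float(ds["background_p"]),
        n_constant_bits=int(ds["n_constant_bits"]),
        n_correlated_pairs=int(ds["n_correlated_pairs"]),
        seed=int(cfg["seed"]),
    )


def run_pipeline(config=None, out_dir="fragminer_run") -> RunManifest:
    """Run the full simulated workflow and write all artifacts + manifest."""
    import numpy as np
    import pandas as pd
    import sklearn

    cfg = load_config(config)
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=cfg,
        seed=seed,
        versions={
            "fragminer": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        started=datetime.now(timezone.utc).isoformat(),
    )

    fm, records = generate_fingerprint_dataset(_generator_config(cfg))
    records = label_records(records, cutoff=float(cfg["cutoff"]))
    write_fingerprint_table(fm, out / "fingerprints.csv")
    write_activity_table(records, out / "activity.csv")

    split = stratified_split(records, ratio=cfg["split"]["ratio"], seed=seed)
    (out / "split.json").write_text(
        json.dumps({"train_ids": split.train_ids, "test_ids": split.test_ids}, indent=2)
    )

    labels = {r.compound_id: r.potency_class for r in records}
    rows = run_grid(
        fingerprints={"SimFP": fm},
        labels=labels,
        split=split,
        specs=[AlgorithmSpec(a) for a in cfg["algorithms"]],
        balance=bool(cfg["balance"]),
        balance_within_folds=bool(cfg["balance_within_folds"]),
        folds=int(cfg["cv"]["folds"]),
        seed=seed,
    )

    train_labels = [labels[i] for i in split.train_ids]
    stats = rank_fragments(
        fm.subset(split.train_ids),
        train_labels,
        min_ig=float(cfg["mine"]["min_ig"]),
        min_support=int(cfg["mine"]["min_support"]),
    )[: int(cfg["mine"]["top"])]

    render_tables(rows, stats, out)

    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest.outputs[p.name] = _sha256(p)
    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out / "manifest.json")
    return manifest
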