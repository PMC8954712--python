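"""Rendering of evaluation and fragment tables in the conventional layout.

Values print half-up to 3 decimals; a metric undefined on its confusion
table renders as ``-``; class frequencies print as ``value (count)``.
Displayed balanced accuracy follows the convention of printed SAR tables:
the mean of the *displayed* (3-decimal) SE and SP, rounded half-up — which
can differ in the last digit from rounding the full-precision mean.
Rendering is a pure function of its inputs.
"""

from __future__ import annotations

from decimal import Decimal
from typing import List, Sequence

import pandas as pd

from .fragment_mining import FragmentStats
from .metrics import UNDEFINED, ConfusionTable, MetricsBundle, _Undefined, round_half_up

EVAL_COLUMNS = ["Model", "AUC", "CA", "MCC", "TP", "TN", "FP", "FN", "SE", "SP", "BA"]


def fmt(value, ndigits: int = 3) -> str:
    """3-decimal half-up string; '-' for undefined/absent."""
    if value is None or isinstance(value, _Undefined):
        return "-"
    return f"{round_half_up(float(value), ndigits):.{ndigits}f}"


def display_ba(se, sp) -> str:
    """BA shown as the half-up-rounded mean of the displayed SE and SP."""
    se_s, sp_s = fmt(se), fmt(sp)
    if "-" in (se_s, sp_s):
        return "-"
    mean = (Decimal(se_s) + Decimal(sp_s)) / 2
    return fmt(float(mean))


def format_metrics_row(model: str, ct: ConfusionTable, mb: MetricsBundle) -> dict:
    return {
        "Model": model,
        "AUC": fmt(mb.auc),
        "CA": fmt(mb.ca),
        "MCC": fmt(mb.mcc),
        "TP": str(ct.tp),
        "TN": str(ct.tn),
        "FP": str(ct.fp),
        "FN": str(ct.fn),
        "SE": fmt(mb.se),
        "SP": fmt(mb.sp),
        "BA": display_ba(mb.se, mb.sp),
    }


def evaluation_frame(rows: Sequence) -> pd.DataFrame:
    """One formatted line per EvaluationRow, with its split."""
    recs = []
    for r in rows:
        d = {"Split": r.split}
        d.update(format_metrics_row(r.model_name, r.confusion, r.metrics))
        recs.append(d)
    return pd.DataFrame(recs, columns=["Split"] + EVAL_COLUMNS)


def frequency_cell(freq, count: int) -> str:
    """Class-frequency display: 'value (count)', e.g. '1.263 (49)'."""
    if isinstance(freq, _Undefined) or freq is None:
        return f"- ({count})"
    return f"{round_half_up(float(freq), 3):.3f} ({count})"


def fragment_frame(stats: Sequence[FragmentStats]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "Fingerprint": s.bit_name,
                "IG": fmt(s.ig),
                "FP": frequency_cell(s.freq_P, s.n_fragment_P),
                "FN": frequency_cell(s.freq_N, s.n_fragment_N),
                "Polarity": s.polarity,
            }
            for s in stats
        ],
        columns=["Fingerprint", "IG", "FP", "FN", "Polarity"],
    )


def render_tables(eval_rows: Sequence, fragment_stats: Sequence[FragmentStats], out_dir) -> List[str]:
    """Write ranked-models and fragment CSVs plus a readable text report."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    ev = evaluation_frame(eval_rows)
    path = out / "ranked_models.csv"
    ev.to_csv(path, index=False)
    written.append(str(path))
    fr = fragment_frame(fragment_stats)
    path = out / "fragments.csv"
    fr.to_csv(path, index=False)
    written.append(str(path))
    path = out / "report.txt"
    with open(path, "w") as fh:
        fh.write("Ranked classification models\n")
        fh.write(ev.to_string(index=False))
        fh.write("\n\nPrivileged-substructure candidates\n")
        fh.write(fr.to_string(index=False))
        fh.write("\n")
    written.append(str(path))
    return written
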