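"""Score stopping rules against the oracle and render comparison reports.

Regret is defined on validation loss: the oracle keeps the model at the
epoch of global minimum validation loss, and a rule's ``regret_loss`` is
how much higher the validation loss of its selected epoch sits. Test
accuracies are reported at the selected epoch but never optimized.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stopping import CeilingSpec
from .trace import StopDecision, TrainingTrace, oracle_epoch

__all__ = ["score_rule", "compare_rules", "overfit_region", "write_report", "format_report"]

REPORT_COLUMNS = [
    "rule_name",
    "params",
    "stop_epoch",
    "selected_epoch",
    "val_loss_at_selected",
    "test_acc_subset",
    "test_acc_novel",
    "regret_loss",
    "regret_epochs",
]


def score_rule(trace: TrainingTrace, decision: StopDecision) -> dict:
    """One report row: the trace's metrics at the rule's selected epoch,
    plus regret against the full-horizon oracle."""
    if not 1 <= decision.selected_epoch <= len(trace):
        raise ValueError(
            f"selected epoch {decision.selected_epoch} outside trace of length {len(trace)}"
        )
    if decision.stop_epoch is not None and not 1 <= decision.stop_epoch <= len(trace):
        raise ValueError(
            f"stop epoch {decision.stop_epoch} outside trace of length {len(trace)}"
        )
    oracle = oracle_epoch(trace)
    rec = trace[decision.selected_epoch - 1]
    oracle_loss = trace[oracle - 1].val_loss
    return {
        "rule_name": decision.rule_name,
        "params": json.dumps(dict(decision.params), sort_keys=True),
        "stop_epoch": decision.stop_epoch if decision.triggered else None,
        "selected_epoch": decision.selected_epoch,
        "val_loss_at_selected": rec.val_loss,
        "test_acc_subset": rec.test_acc_subset,
        "test_acc_novel": rec.test_acc_novel,
        "regret_loss": rec.val_loss - oracle_loss,
        "regret_epochs": abs(decision.selected_epoch - oracle),
    }


def overfit_region(trace: TrainingTrace, ceiling: CeilingSpec, metric: str = "train_acc") -> list[int]:
    """Epochs where the monitored accuracy exceeds the ceiling value —
    accuracy that cannot reflect genuine signal and flags memorization."""
    values = trace.train_acc if metric == "train_acc" else trace.val_acc
    return [int(e) for e in (np.nonzero(values > ceiling.value)[0] + 1)]


def compare_rules(
    trace: TrainingTrace,
    decisions: Sequence[StopDecision],
    ceiling: Optional[CeilingSpec] = None,
) -> pd.DataFrame:
    """Tabulate every rule against the oracle.

    Rows are sorted by stop epoch (never-triggered rules sort last), the
    oracle appended as the final reference row. When a ceiling is given
    the frame's ``attrs`` carry its value/margin/corroboration and the
    overfit-region epochs.
    """
    rows = [score_rule(trace, d) for d in decisions]
    rows.sort(key=lambda r: (r["stop_epoch"] is None, r["stop_epoch"] or 0, r["rule_name"]))
    oracle = oracle_epoch(trace)
    rec = trace[oracle - 1]
    rows.append(
        {
            "rule_name": "oracle",
            "params": "{}",
            "stop_epoch": None,
            "selected_epoch": oracle,
            "val_loss_at_selected": rec.val_loss,
            "test_acc_subset": rec.test_acc_subset,
            "test_acc_novel": rec.test_acc_novel,
            "regret_loss": 0.0,
            "regret_epochs": 0,
        }
    )
    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if ceiling is not None:
        region = overfit_region(trace, ceiling)
        report.attrs["ceiling"] = {
            "value": ceiling.value,
            "margin": ceiling.margin,
            "corroborated": ceiling.corroborated,
            "provenance": ceiling.provenance,
        }
        report.attrs["overfit_region_start"] = region[0] if region else None
        report.attrs["overfit_region_size"] = len(region)
    return report


def format_report(report: pd.DataFrame) -> str:
    """Pretty-printed text table, deterministic for fixed inputs."""
    df = report.copy()
    for col in ("val_loss_at_selected", "regret_loss"):
        df[col] = df[col].map(lambda v: f"{v:.6f}")
    for col in ("test_acc_subset", "test_acc_novel"):
        df[col] = df[col].map(lambda v: "-" if v is None or (isinstance(v, float) and np.isnan(v)) else f"{v:.4f}")
    df["stop_epoch"] = df["stop_epoch"].map(lambda v: "none" if pd.isna(v) else str(int(v)))
    lines = [df.to_string(index=False)]
    if "ceiling" in report.attrs:
        c = report.attrs["ceiling"]
        lines.append(
            f"ceiling: {c['value']:.4f} (margin {c['margin']:.4f}, "
            f"corroborated={c['corroborated']})"
        )
        start = report.attrs.get("overfit_region_start")
        lines.append(
            "overfit region: none"
            if start is None
            else f"overfit region: from epoch {start} "
            f"({report.attrs['overfit_region_size']} epochs)"
        )
    return "\n".join(lines) + "\n"


def write_report(
    report: pd.DataFrame, path: str | Path, ceiling: Optional[CeilingSpec] = None
) -> None:
    """Write the report as CSV plus a JSON sidecar with ceiling metadata."""
    path = Path(path)
    out = report.copy()
    out["stop_epoch"] = out["stop_epoch"].map(lambda v: "none" if pd.isna(v) else str(int(v)))
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(out.to_csv(index=False, float_format=None))
    meta = dict(report.attrs)
    if ceiling is not None and "ceiling" not in meta:
        meta["ceiling"] = {
            "value": ceiling.value,
            "margin": ceiling.margin,
            "corroborated": ceiling.corroborated,
            "provenance": ceiling.provenance,
        }
    if meta:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(meta, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
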