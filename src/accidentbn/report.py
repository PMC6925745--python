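"""Rendering of sensitivity and validation tables.

Percentages are rounded half-up to two decimals at render time only;
no-support cells print an em dash; delimited output can be parsed back
to the same rounded values.
"""

from __future__ import annotations

import io

import pandas as pd

from .sensitivity import SectorSensitivityTable, SensitivityTable
from .survey import round_half_up
from .validation import RocResult

DASH = "—"


def _fmt(value: float | None, signed: bool = False) -> str:
    if value is None:
        return DASH
    v = round_half_up(value, 2)
    return f"{v:+.2f}" if signed else f"{v:.2f}"


def sensitivity_frame(table: SensitivityTable) -> pd.DataFrame:
    """Rendered rows of a sweep: category labels, % ACC, % VAR."""
    recs = []
    for row in table.rows:
        rec = {var: lab for var, lab in row.labels.items()}
        rec["% ACC"] = _fmt(row.p_accident)
        rec["% VAR"] = _fmt(row.delta, signed=True)
        if row.support is not None:
            rec["support"] = row.support
        recs.append(rec)
    return pd.DataFrame(recs)


def render_sensitivity(
    tables: list[SensitivityTable], format: str = "text"
) -> str:
    """Render one or more sweeps as aligned text or delimited CSV."""
    if format not in ("text", "csv"):
        raise ValueError(f"unknown format {format!r}")
    chunks = []
    for table in tables:
        frame = sensitivity_frame(table)
        header = (
            f"target {table.target}={table.positive_label}  "
            f"baseline {_fmt(table.baseline_percent)}%"
        )
        if table.sector:
            header += f"  sector {table.sector[0]}={table.sector[1]}"
        if format == "text":
            chunks.append(header)
            chunks.append(frame.to_string(index=False))
        else:
            buf = io.StringIO()
            frame.insert(0, "sweep", "+".join(table.swept))
            frame.to_csv(buf, index=False)
            chunks.append(buf.getvalue().rstrip("\n"))
        chunks.append("")
    return "\n".join(chunks).rstrip("\n") + ("\n" if chunks else "")


def parse_sensitivity_csv(text: str) -> list[pd.DataFrame]:
    """Parse delimited sweep output back into frames (round-trip aid)."""
    frames = []
    for chunk in text.strip().split("\n\n"):
        frames.append(pd.read_csv(io.StringIO(chunk), dtype=str))
    return frames


def render_sector_table(table: SectorSensitivityTable) -> str:
    """Aligned text for a sector-stratified sweep, with the a-priori
    row on top."""
    cols = list(table.values.columns)
    frame = table.values.map(lambda v: _fmt(v))
    prior_row = pd.DataFrame(
        [[_fmt(table.priors[c]) + "*" for c in cols]],
        index=pd.MultiIndex.from_tuples([("a priori", "")]),
        columns=cols,
    )
    out = pd.concat([prior_row, frame])
    text = out.to_string()
    return (
        f"target {table.target} by {table.sector_var}\n{text}\n"
        "* a-priori accident probability, total and per sector\n"
    )


def render_validation(result: RocResult) -> str:
    lines = ["fold\tAUC"]
    for i, fold_auc in enumerate(result.fold_aucs):
        val = "undefined" if pd.isna(fold_auc) else f"{fold_auc:.4f}"
        lines.append(f"{i}\t{val}")
    lines.append(f"pooled\t{result.auc:.4f}")
    lines.append(f"mean-of-folds\t{result.mean_fold_auc:.4f}")
    return "\n".join(lines) + "\n"


def roc_points_csv(result: RocResult) -> str:
    lines = ["fpr,tpr"]
    for fpr, tpr in result.points:
        lines.append(f"{round_half_up(fpr, 6)},{round_half_up(tpr, 6)}")
    return "\n".join(lines) + "\n"
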