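"""Result formatting: machine-readable TSV and aligned human-readable text.

F- and p-values are printed with 4 decimals, simulated frequencies with 3.
"""

from __future__ import annotations

import sys
from pathlib import Path

import pandas as pd

__all__ = ["results_frame", "write_report"]

_FOUR = ("F", "p", "SS", "rejection")
_THREE = ("boundary_freq", "pr_boundary")


def results_frame(results) -> pd.DataFrame:
    """Normalize a list of TestResult / MixedTestResult (or an existing
    DataFrame) into a flat frame."""
    if isinstance(results, pd.DataFrame):
        return results.reset_index() if results.index.name else results
    rows = []
    for r in results:
        d = r.as_dict()
        strategy = getattr(r, "strategy", None)
        if strategy:
            d["strategy"] = strategy
            d["boundary"] = getattr(r, "at_boundary", False)
            vc = getattr(r, "varcomps", None)
            if vc is not None:
                d.update(vc.as_dict())
        rows.append(d)
    return pd.DataFrame(rows)


def _formatted(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if out[col].dtype.kind != "f":
            continue
        digits = 3 if col in _THREE else 4
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.{digits}f}")
    return out


def write_report(results, path=None, format: str = "tsv") -> str:
    """Write results as TSV (machine) or aligned text (human).

    ``path=None`` or ``"-"`` writes to standard output.  An empty result
    list is an error and no file is written.
    """
    frame = results_frame(results)
    if len(frame) == 0:
        raise ValueError("empty result list; nothing to write")
    frame = _formatted(frame)
    if format == "tsv":
        text = frame.to_csv(sep="\t", index=False)
    elif format == "text":
        text = frame.to_string(index=False) + "\n"
    else:
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'text'")
    if path is None or path == "-":
        sys.stdout.write(text)
    else:
        Path(path).write_text(text)
    return text
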