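"""Report writers: JSON summaries and per-read TSV tables.

Percentages are carried as exact ratios internally and rounded to one
decimal place only at serialization, the precision benchmark tables are
customarily printed at.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional, Sequence, Union

import pandas as pd

from .eval_real import RealEvalSummary, RealReadEvaluation
from .eval_sim import EvalSummary, ReadEvaluation

Summary = Union[EvalSummary, RealEvalSummary]


def _round(x: Optional[float]) -> Optional[float]:
    return None if x is None else round(x, 1)


def summary_to_dict(summary: Summary) -> dict:
    """Fixed-key dict with raw counters and 1-decimal percentages."""
    out = dataclasses.asdict(summary)
    if isinstance(summary, EvalSummary):
        pct_keys = (
            "pct_aligned", "pct_correct", "pct_hit_all", "pct_hit_one",
            "pct_split", "pct_correct_split", "pct_split_hit_all",
            "pct_split_hit_one", "pct_strand_ok",
        )
    else:
        pct_keys = ("pct_aligned", "pct_exon_hit", "pct_contiguous")
    for key in pct_keys:
        out[key] = _round(getattr(summary, key))
    out["mean_match_rate"] = _round(summary.mean_match_rate)
    return out


def write_summary(summary: Summary, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(summary_to_dict(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_per_read_tsv(
    evals: Sequence[Union[ReadEvaluation, RealReadEvaluation]], path: str
) -> None:
    """One row per read; valid header-only TSV when no reads were evaluated."""
    if evals:
        df = pd.DataFrame([dataclasses.asdict(e) for e in evals])
    else:
        df = pd.DataFrame(columns=[f.name for f in dataclasses.fields(ReadEvaluation)])
    df.to_csv(path, sep="\t", index=False)
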