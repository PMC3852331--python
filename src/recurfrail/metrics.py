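"""Model-comparison statistics: %RB and %RW against a reference model.

Two candidate/reference hazard-ratio tables (one row per covariate contrast,
each with a 95% CI) are compared row-wise by

* percent relative bias in the point estimate,
  ``%RB = (HR_other - HR_ref) / HR_ref * 100``, and
* percent relative width difference of the confidence interval,
  ``%RW = ((U_o - L_o) - (U_r - L_r)) / (U_r - L_r) * 100``.

The reference is conventionally the Cox-based conditional frailty model
(label ``CFM``), whose estimates are external inputs here.  Published tables
print both statistics at one decimal, so the rounded values use
round-half-away-from-zero at one decimal; raw values are always retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "relative_bias",
    "relative_width",
    "round_half_away",
    "ComparisonRow",
    "compare_tables",
    "load_reference_tables",
    "REFERENCE_DATASETS",
]

#: Packaged transcriptions of published hazard-ratio tables (six models per
#: dataset).  These are hand-transcribed fixtures, not fitted output.
REFERENCE_DATASETS = {
    "mental_disorders": "hr_table_mental_disorders.csv",
    "neoplasms": "hr_table_neoplasms.csv",
}
MODEL_COLUMNS = ("cfpm", "cpm", "fpm", "cm", "fm", "cfm")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(abs(x)))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d) * (1.0 if x >= 0 else -1.0)


def relative_bias(hr_other: float, hr_ref: float) -> float:
    """Percent relative bias of a candidate HR versus the reference HR (raw)."""
    if hr_ref <= 0:
        raise ValueError(f"reference hazard ratio must be > 0, got {hr_ref}")
    return (hr_other - hr_ref) / hr_ref * 100.0


def relative_width(ci_other, ci_ref) -> float:
    """Percent relative CI-width difference versus the reference CI (raw)."""
    lo_o, hi_o = ci_other
    lo_r, hi_r = ci_ref
    if hi_r <= lo_r:
        raise ValueError(f"reference interval ({lo_r}, {hi_r}) has non-positive width")
    if hi_o < lo_o:
        raise ValueError(f"candidate interval ({lo_o}, {hi_o}) is inverted")
    return ((hi_o - lo_o) - (hi_r - lo_r)) / (hi_r - lo_r) * 100.0


@dataclass(frozen=True)
class ComparisonRow:
    term: str
    level: str
    hr_other: float
    ci_other: tuple[float, float]
    hr_ref: float
    ci_ref: tuple[float, float]
    rb_percent: float
    rw_percent: float


def compare_tables(candidate: pd.DataFrame, reference: pd.DataFrame):
    """Row-wise %RB/%RW of a candidate HR table against a reference table.

    Both tables need columns ``term, level, hr, ci_low, ci_high``; rows are
    matched on (term, level) and must agree exhaustively (reference-category
    rows, which have no HR, are expected to be absent from both).  Returns a
    DataFrame (raw and one-decimal rounded statistics) and a summary dict
    with the min/max absolute %RB and %RW.
    """
    key = ["term", "level"]
    cand = candidate.set_index(key)
    ref = reference.set_index(key)
    only_c = cand.index.difference(ref.index)
    only_r = ref.index.difference(cand.index)
    if len(only_c) or len(only_r):
        msgs = [f"only in candidate: {list(only_c)}"] if len(only_c) else []
        msgs += [f"only in reference: {list(only_r)}"] if len(only_r) else []
        raise ValueError("label mismatch between tables; " + "; ".join(msgs))
    ref = ref.loc[cand.index]

    rb = [relative_bias(o, r) for o, r in zip(cand["hr"], ref["hr"])]
    rw = [relative_width((lo, hi), (lr, hr_))
          for lo, hi, lr, hr_ in zip(cand["ci_low"], cand["ci_high"],
                                     ref["ci_low"], ref["ci_high"])]
    out = pd.DataFrame({
        "term": [t for t, _ in cand.index],
        "level": [l for _, l in cand.index],
        "hr_other": cand["hr"].to_numpy(),
        "l_other": cand["ci_low"].to_numpy(),
        "u_other": cand["ci_high"].to_numpy(),
        "hr_ref": ref["hr"].to_numpy(),
        "l_ref": ref["ci_low"].to_numpy(),
        "u_ref": ref["ci_high"].to_numpy(),
        "rb_percent": rb,
        "rw_percent": rw,
    })
    out["rb_rounded"] = out["rb_percent"].map(round_half_away)
    out["rw_rounded"] = out["rw_percent"].map(round_half_away)
    summary = {
        "min_abs_rb": float(np.min(np.abs(out["rb_percent"]))),
        "max_abs_rb": float(np.max(np.abs(out["rb_percent"]))),
        "min_abs_rw": float(np.min(np.abs(out["rw_percent"]))),
        "max_abs_rw": float(np.max(np.abs(out["rw_percent"]))),
        "n_rows": int(len(out)),
    }
    return out, summary


def load_reference_tables(dataset: str) -> dict[str, pd.DataFrame]:
    """Load a packaged transcription as per-model (term, level, hr, ci) tables.

    ``dataset`` is ``"mental_disorders"`` or ``"neoplasms"``.  Returns a dict
    mapping model label (``cfpm, cpm, fpm, cm, fm, cfm``) to a table usable
    directly with :func:`compare_tables`.
    """
    if dataset not in REFERENCE_DATASETS:
        raise KeyError(f"unknown dataset {dataset!r}; choose from {sorted(REFERENCE_DATASETS)}")
    with resources.files("recurfrail.data").joinpath(
            REFERENCE_DATASETS[dataset]).open("r", encoding="utf-8") as fh:
        wide = pd.read_csv(fh)
    out = {}
    for m in MODEL_COLUMNS:
        out[m] = pd.DataFrame({
            "term": wide["term"],
            "level": wide["level"],
            "hr": wide[f"{m}_hr"],
            "ci_low": wide[f"{m}_lo"],
            "ci_high": wide[f"{m}_hi"],
        })
    return out
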