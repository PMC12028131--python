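"""Cohort comparison of reference vs comparison measurements.

Vertebrae are paired by name, measurement records are differenced
(absolute mm differences per field), and cohorts are summarized the way
the clinical report tables are laid out: median, sample standard
deviation, and 75th/95th percentiles of the per-vertebra absolute
differences, plus Pearson correlation between raw paired values and
condition-tag grouping with a minimum-occurrence threshold.

The unit of aggregation is the vertebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import MEASUREMENT_FIELDS, MorphometryRecord

__all__ = [
    "ComparisonSummary",
    "ConditionTag",
    "pair_vertebrae",
    "diff_records",
    "summarize",
    "pearson",
    "group_summaries",
    "summary_table",
]


@dataclass
class ComparisonSummary:
    """Median/std/p75/p95 of absolute differences per measurement or region."""

    stats: dict[str, dict[str, float]]
    n: dict[str, int]
    direction: str = "ref->cmp"
    condition: str = "all"

    def to_dict(self) -> dict:
        return {
            "direction": self.direction,
            "condition": self.condition,
            "n": self.n,
            "stats": self.stats,
        }


@dataclass(frozen=True)
class ConditionTag:
    """Clinical condition annotation, spine-scope (per subject) or
    vertebra-scope (bound to one vertebra of one subject)."""

    scope: str  # "spine" | "vertebra"
    code: str
    subject: str
    vertebra: str | None = None

    def __post_init__(self) -> None:
        if self.scope not in ("spine", "vertebra"):
            raise ValueError(f"unknown tag scope {self.scope!r}")
        if self.scope == "vertebra" and not self.vertebra:
            raise ValueError("vertebra-scope tags must name a vertebra")


def pair_vertebrae(
    ref: list[MorphometryRecord], cmp: list[MorphometryRecord]
) -> tuple[list[tuple[MorphometryRecord, MorphometryRecord]], list[str]]:
    """Match records by vertebra name.

    Returns (pairs, unmatched names); unmatched vertebrae are reported,
    never silently dropped.  Duplicate names within one scan are an error.
    """
    for side, records in (("reference", ref), ("comparison", cmp)):
        names = [r.name for r in records]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate vertebra names in the {side} scan: {dupes}")
    ref_by = {r.name: r for r in ref}
    cmp_by = {r.name: r for r in cmp}
    pairs = [(ref_by[n], cmp_by[n]) for n in ref_by if n in cmp_by]
    unmatched = sorted(set(ref_by) ^ set(cmp_by))
    return pairs, unmatched


def diff_records(
    pair: tuple[MorphometryRecord, MorphometryRecord]
) -> dict[str, float]:
    """Absolute per-field differences in mm; missing fields stay missing."""
    a, b = pair
    out = {}
    for k in MEASUREMENT_FIELDS:
        va, vb = getattr(a, k), getattr(b, k)
        if va is not None and vb is not None:
            out[k] = abs(va - vb)
    return out


def _summary_row(values: np.ndarray) -> dict[str, float]:
    values = np.asarray(values, dtype=float)
    return {
        "median": float(np.median(values)),
        "std": float(np.std(values, ddof=1)) if len(values) > 1 else 0.0,
        "p75": float(np.percentile(values, 75)),  # linear interpolation
        "p95": float(np.percentile(values, 95)),
    }


def summarize(
    differences: list[dict[str, float]],
    direction: str = "ref->cmp",
    condition: str = "all",
) -> ComparisonSummary:
    """Cohort summary of per-vertebra absolute differences.

    ``differences`` holds one dict per vertebra (measurement name -> mm);
    every field with at least one finite value is summarized.
    """
    if not differences:
        raise ValueError("nothing to summarize")
    by_field: dict[str, list[float]] = {}
    for d in differences:
        for k, v in d.items():
            if v is not None and np.isfinite(v):
                by_field.setdefault(k, []).append(float(v))
    if not by_field:
        raise ValueError("no finite differences to summarize")
    stats_ = {k: _summary_row(np.array(v)) for k, v in by_field.items()}
    n = {k: len(v) for k, v in by_field.items()}
    return ComparisonSummary(stats=stats_, n=n, direction=direction, condition=condition)


def pearson(ref_values, cmp_values) -> float:
    """Pearson product-moment correlation between paired measurements."""
    x = np.asarray(ref_values, dtype=float)
    y = np.asarray(cmp_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1D arrays")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the series")
    return float(stats.pearsonr(x, y).statistic)


def group_summaries(
    differences: list[dict[str, float]],
    keys: list[tuple[str, str]] | None = None,
    tags: list[ConditionTag] | None = None,
    min_count: int = 20,
    direction: str = "ref->cmp",
) -> dict[str, ComparisonSummary]:
    """Per-condition summaries with a minimum-occurrence threshold.

    ``keys[i] = (subject, vertebra_name)`` identifies the vertebra behind
    ``differences[i]``.  Spine-scope tags select every vertebra of the
    tagged subject; vertebra-scope tags select single vertebrae.
    Conditions with fewer than ``min_count`` contributing vertebrae are
    excluded, mirroring the cohort report's exclusion rule.  With no tags
    a single "all" group is returned.
    """
    if not tags:
        return {"all": summarize(differences, direction=direction)}
    if keys is None or len(keys) != len(differences):
        raise ValueError("keys (subject, vertebra) are required, one per difference")
    known = {k[0] for k in keys}
    out: dict[str, ComparisonSummary] = {}
    for code in sorted({t.code for t in tags}):
        sel_subjects = {t.subject for t in tags if t.code == code and t.scope == "spine"}
        sel_vertebrae = {
            (t.subject, t.vertebra) for t in tags if t.code == code and t.scope == "vertebra"
        }
        unknown = {t.subject for t in tags if t.code == code} - known
        if unknown:
            raise ValueError(f"condition {code!r} tags unknown subjects: {sorted(unknown)}")
        idx = [
            i
            for i, (subj, vert) in enumerate(keys)
            if subj in sel_subjects or (subj, vert) in sel_vertebrae
        ]
        if len(idx) < min_count:
            continue
        out[code] = summarize(
            [differences[i] for i in idx], direction=direction, condition=code
        )
    return out


def summary_table(summary: ComparisonSummary) -> pd.DataFrame:
    """Cohort summary as a table with median/std/p75/p95 columns in mm."""
    rows = []
    for name, s in summary.stats.items():
        rows.append(
            {
                "measurement": name,
                "median_mm": s["median"],
                "std_mm": s["std"],
                "p75_mm": s["p75"],
                "p95_mm": s["p95"],
                "n": summary.n[name],
            }
        )
    return pd.DataFrame(rows)
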