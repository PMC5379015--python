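"""SWAN-scale scoring and the predictor-vs-factor correlation report.

The SWAN (Strengths and Weaknesses of ADHD Symptoms and Normal Behavior)
rating scale has 18 items: items 1-9 form the inattention factor, items
10-15 hyperactivity, and items 16-18 impulsivity.  This package uses the
web-administered format in which each item is scored 0-100; factor scores
are item means, which keeps them on the same 0-100 scale (sums differ only
by a constant factor and leave all correlations unchanged).

The validity analysis correlates per-participant CPT summaries (median RT,
median commission index, optionally median CT) with the three factor
scores.  Pearson correlation is the default, with two-sided p-values from
the t transform on n-2 degrees of freedom; Spearman is available as an
option.  Cells are computed pairwise-complete and report their own n; an
optional Holm adjustment is provided for reuse beyond the three-factor
report.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SwanValidationError",
    "SwanRecord",
    "FACTOR_NAMES",
    "FACTOR_SLICES",
    "score_swan",
    "swan_frame",
    "CorrelationReport",
    "correlate",
    "render_report",
]

FACTOR_NAMES = ("inattention", "hyperactivity", "impulsivity")
#: 0-based item slices of the three factors (items 1-9, 10-15, 16-18)
FACTOR_SLICES = {
    "inattention": slice(0, 9),
    "hyperactivity": slice(9, 15),
    "impulsivity": slice(15, 18),
}


class SwanValidationError(ValueError):
    """Wrong item count or out-of-range item score."""


@dataclass(frozen=True)
class SwanRecord:
    """18 item scores plus the three factor means, all on the 0-100 scale."""

    items: tuple[float, ...]
    inattention_score: float
    hyperactivity_score: float
    impulsivity_score: float

    def factor(self, name: str) -> float:
        return getattr(self, f"{name}_score")


def score_swan(items) -> SwanRecord:
    """Validate 18 item scores and compute the three factor means.

    Raises :class:`SwanValidationError` naming the offending item for a
    wrong count or a value outside [0, 100] (items are reported 1-based,
    as on the form).
    """
    arr = np.asarray(list(items), dtype=float)
    if arr.shape != (18,):
        raise SwanValidationError(f"expected exactly 18 item scores, got {arr.size}")
    for i, v in enumerate(arr):
        if not np.isfinite(v) or not 0.0 <= v <= 100.0:
            raise SwanValidationError(f"item {i + 1} out of range [0, 100]: {v}")
    return SwanRecord(
        items=tuple(float(v) for v in arr),
        inattention_score=float(arr[FACTOR_SLICES["inattention"]].mean()),
        hyperactivity_score=float(arr[FACTOR_SLICES["hyperactivity"]].mean()),
        impulsivity_score=float(arr[FACTOR_SLICES["impulsivity"]].mean()),
    )


def swan_frame(records: list[SwanRecord]) -> pd.DataFrame:
    """Factor scores of many records as a DataFrame (one row per record)."""
    return pd.DataFrame(
        {name: [r.factor(name) for r in records] for name in FACTOR_NAMES}
    )


@dataclass
class CorrelationReport:
    """Predictors x SWAN factors: r, two-sided p, and per-cell n.

    ``r``/``p``/``n`` are aligned 2-D arrays (rows = predictors, columns =
    factors); cells with fewer than 3 complete pairs are NaN with n
    recording the pairs available.
    """

    predictors: list[str]
    factors: list[str]
    r: np.ndarray
    p: np.ndarray
    n: np.ndarray
    method: str = "pearson"

    def cell(self, predictor: str, factor: str) -> dict:
        i = self.predictors.index(predictor)
        j = self.factors.index(factor)
        return {"r": float(self.r[i, j]), "p": float(self.p[i, j]), "n": int(self.n[i, j])}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, pred in enumerate(self.predictors):
            for j, fac in enumerate(self.factors):
                rows.append(
                    {
                        "predictor": pred,
                        "factor": fac,
                        "r": self.r[i, j],
                        "p": self.p[i, j],
                        "n": self.n[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "predictors": self.predictors,
            "factors": self.factors,
            "cells": [
                {
                    "predictor": pred,
                    "factor": fac,
                    "r": None if np.isnan(self.r[i, j]) else round(float(self.r[i, j]), 6),
                    "p": None if np.isnan(self.p[i, j]) else round(float(self.p[i, j]), 6),
                    "n": int(self.n[i, j]),
                }
                for i, pred in enumerate(self.predictors)
                for j, fac in enumerate(self.factors)
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationReport":
        preds, facs = list(d["predictors"]), list(d["factors"])
        r = np.full((len(preds), len(facs)), np.nan)
        p = np.full((len(preds), len(facs)), np.nan)
        n = np.zeros((len(preds), len(facs)), dtype=int)
        for cell in d["cells"]:
            i, j = preds.index(cell["predictor"]), facs.index(cell["factor"])
            r[i, j] = np.nan if cell["r"] is None else cell["r"]
            p[i, j] = np.nan if cell["p"] is None else cell["p"]
            n[i, j] = cell["n"]
        return cls(preds, facs, r, p, n, method=d.get("method", "pearson"))


def correlate(
    predictors: pd.DataFrame,
    factors: pd.DataFrame,
    method: str = "pearson",
    holm: bool = False,
) -> CorrelationReport:
    """Correlate each predictor column with each SWAN factor column.

    Rows of the two frames are matched positionally (one participant per
    row).  Each cell uses the pairwise-complete observations for its pair
    of columns; cells with fewer than 3 complete pairs are marked
    not-computable (NaN).  ``method`` is ``"pearson"`` (default) or
    ``"spearman"``.  With ``holm=True`` the p-values are Holm-adjusted
    across the report's computable cells.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if len(predictors) != len(factors):
        raise ValueError("predictor and factor tables must have one row per participant")
    pred_names = list(predictors.columns)
    fac_names = list(factors.columns)
    nr, nc = len(pred_names), len(fac_names)
    r = np.full((nr, nc), np.nan)
    p = np.full((nr, nc), np.nan)
    n = np.zeros((nr, nc), dtype=int)
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i, pred in enumerate(pred_names):
        x_all = predictors[pred].to_numpy(dtype=float)
        for j, fac in enumerate(fac_names):
            y_all = factors[fac].to_numpy(dtype=float)
            mask = np.isfinite(x_all) & np.isfinite(y_all)
            n[i, j] = int(mask.sum())
            if n[i, j] < 3:
                continue
            with warnings.catch_warnings():
                # constant inputs yield a NaN cell, reported as not-computable
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                res = corr(x_all[mask], y_all[mask])
            r[i, j] = res.statistic
            p[i, j] = res.pvalue
    if holm:
        flat = p.ravel()
        ok = np.isfinite(flat)
        if ok.any():
            order = np.argsort(flat[ok])
            m = int(ok.sum())
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * flat[ok][idx])
                adj[idx] = min(1.0, running)
            flat[ok] = adj
            p = flat.reshape(p.shape)
    return CorrelationReport(pred_names, fac_names, r, p, n, method=method)


def _fmt_cell(r: float, p: float) -> str:
    if np.isnan(r):
        return "NA"
    return f"{r:.2f} (P={p:.2f})"


def render_report(report: CorrelationReport, fmt: str = "markdown") -> str:
    """Serialise a report as ``csv``, ``json``, or a ``markdown`` table.

    The markdown layout mirrors the predictors-by-factors validity table:
    one row per predictor, one column per factor, cells as ``r (P=...)``.
    """
    if fmt == "csv":
        return report.to_frame().to_csv(index=False)
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True)
    if fmt == "markdown":
        header = "| Predictor | " + " | ".join(f.capitalize() for f in report.factors) + " |"
        sep = "|" + "---|" * (len(report.factors) + 1)
        lines = [header, sep]
        for i, pred in enumerate(report.predictors):
            cells = [_fmt_cell(report.r[i, j], report.p[i, j]) for j in range(len(report.factors))]
            lines.append("| " + pred + " | " + " | ".join(cells) + " |")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")
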