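"""Benchmark-level success statistics for scoring metrics.

A metric "succeeds" on a case at (N, q) when its ranked cluster
representatives contain a pose of quality >= q within the top N.  The
module computes success counts and rates over a benchmark (top 1 / 10 /
100 by default), the conditional probability of finding a solution of
at least a given quality *given that one exists* among the generated
decoys, and difficulty-stratified variants (rigid-body versus the
pooled medium + difficult "flexible" cases).

Two denominators are reported for rates: all benchmark cases, and only
the cases where a decoy of the required quality exists.  Percentages
are formatted to the nearest integer; raw fractions are always kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .quality import QualityClass
from .ranking import RankedList

logger = logging.getLogger(__name__)

DIFFICULTIES = ("rigid_body", "medium", "difficult")
DEFAULT_TOP_N = (1, 10, 100)
DEFAULT_QUALITIES = (QualityClass.ACCEPTABLE, QualityClass.MEDIUM, QualityClass.HIGH)


@dataclass
class CaseResult:
    """Everything the evaluation needs about one benchmark case."""

    case_id: str
    difficulty: str
    ranked: dict[str, RankedList] = field(default_factory=dict)
    best_available: QualityClass = QualityClass.INCORRECT

    def __post_init__(self) -> None:
        if self.difficulty not in DIFFICULTIES:
            raise ValueError(f"unknown difficulty {self.difficulty!r}")


def _case_success(case: CaseResult, metric: str, n: int, q: QualityClass) -> bool:
    if metric not in case.ranked:
        raise KeyError(f"metric {metric!r} has no ranked list for case {case.case_id}")
    return case.ranked[metric].best_quality(n) >= q


def success_counts(results: Sequence[CaseResult], metric: str,
                   n: int, q: QualityClass) -> int:
    """Number of cases with a >= q representative in the metric's top N."""
    return sum(_case_success(c, metric, n, q) for c in results)


def available_count(results: Sequence[CaseResult], q: QualityClass) -> int:
    """Number of cases for which a decoy of quality >= q was generated at all."""
    return sum(c.best_available >= q for c in results)


def success_table(results: Sequence[CaseResult], metrics: Iterable[str],
                  top_n: Sequence[int] = DEFAULT_TOP_N,
                  qualities: Sequence[QualityClass] = DEFAULT_QUALITIES) -> pd.DataFrame:
    """Counts and rates per (metric, N, quality threshold).

    ``rate_all`` divides by all cases; ``rate_available`` by the cases
    where a solution of the required quality exists.
    """
    n_cases = len(results)
    rows = []
    for metric in metrics:
        for n in top_n:
            for q in qualities:
                count = success_counts(results, metric, n, q)
                avail = available_count(results, q)
                rows.append({
                    "metric": metric, "top_n": n, "quality": str(q),
                    "count": count,
                    "n_cases": n_cases,
                    "n_available": avail,
                    "rate_all": count / n_cases if n_cases else np.nan,
                    "rate_available": count / avail if avail else np.nan,
                })
    return pd.DataFrame(rows)


def conditional_probability(results: Sequence[CaseResult], metric: str,
                            n: int = 10,
                            q: QualityClass = QualityClass.ACCEPTABLE) -> float:
    """P(found at >= q in top N | a decoy of >= q exists).

    The denominator is the number of cases whose best generated decoy
    reaches quality q; NaN with a warning when that is zero.
    """
    eligible = [c for c in results if c.best_available >= q]
    if not eligible:
        logger.warning("no case has a decoy of quality >= %s; conditional undefined", q)
        return float("nan")
    return success_counts(eligible, metric, n, q) / len(eligible)


def conditional_table(results: Sequence[CaseResult], metrics: Iterable[str],
                      n: int = 10,
                      qualities: Sequence[QualityClass] = (QualityClass.ACCEPTABLE,
                                                           QualityClass.MEDIUM)) -> pd.DataFrame:
    rows = []
    for metric in metrics:
        row = {"metric": metric}
        for q in qualities:
            row[f"p_{q}"] = conditional_probability(results, metric, n, q)
        rows.append(row)
    return pd.DataFrame(rows).set_index("metric")


def stratify(results: Sequence[CaseResult]) -> dict[str, list[CaseResult]]:
    """Split cases into rigid-body and pooled flexible (medium + difficult).

    The flexible categories are pooled because individually they contain
    few cases and near-natives are rarer there.
    """
    strata: dict[str, list[CaseResult]] = {"rigid_body": [], "flexible": []}
    for case in results:
        if case.difficulty == "rigid_body":
            strata["rigid_body"].append(case)
        else:
            strata["flexible"].append(case)
    for name, cases in strata.items():
        if not cases:
            logger.warning("stratum %s is empty", name)
    return strata


def stratified_success_tables(results: Sequence[CaseResult], metrics: Iterable[str],
                              **kwargs) -> dict[str, pd.DataFrame]:
    metrics = list(metrics)
    return {name: success_table(cases, metrics, **kwargs)
            for name, cases in stratify(results).items()}


def format_percent(numerator: float, denominator: float) -> int:
    """Percentage rounded to the nearest integer (e.g. 76/115 -> 66)."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return int(round(100.0 * numerator / denominator))
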