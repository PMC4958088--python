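"""Core-marker selection: reduce a marker panel to a small fingerprinting set.

A marker enters the core set when it is discriminating (PID strictly below a
threshold), informative (PIC strictly above a threshold) and manageable (at
most ``na_max`` alleles and ``ng_max`` genotypes, so calls stay easy to score
and tabulate).  The surviving markers are ordered by descending PID — the
order in which the identification diagram consumes them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import isfinite

import pandas as pd

__all__ = ["SelectionCriteria", "select_core_markers", "panel_mean_pid"]


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for core-marker selection.

    PID and PIC bounds are strict (``<`` / ``>``), allele and genotype caps
    non-strict (``<=``).  The default PID ceiling 0.198 is the published panel
    average for the 33-marker tea survey; callers may pass
    :func:`panel_mean_pid` of their own panel instead.
    """

    pid_max: float = 0.198
    pic_min: float = 0.5
    na_max: float = 5
    ng_max: float = 10

    def __post_init__(self) -> None:
        if not (self.pid_max > 0 and self.pic_min >= 0):
            raise ValueError("pid_max must be positive and pic_min non-negative")
        if self.na_max < 2:
            raise ValueError("na_max must be at least 2 (a core marker must be polymorphic)")
        if self.ng_max < 1:
            raise ValueError("ng_max must be at least 1")


def select_core_markers(
    stats: pd.DataFrame, criteria: SelectionCriteria = SelectionCriteria()
) -> list[str]:
    """Markers passing all four criteria, sorted by descending PID.

    ``stats`` needs columns ``marker, na, ng, pic, pid``.  Ties in PID are
    broken by marker name ascending so the order is deterministic.  An empty
    result is legal and returned with a warning.
    """
    if len(stats) == 0:
        raise ValueError("empty statistics table")
    keep = stats[
        (stats["pid"] < criteria.pid_max)
        & (stats["pic"] > criteria.pic_min)
        & (stats["na"] <= criteria.na_max)
        & (stats["ng"] <= criteria.ng_max)
    ]
    ordered = keep.sort_values(
        ["pid", "marker"], ascending=[False, True], kind="mergesort"
    )
    result = list(ordered["marker"])
    if not result:
        warnings.warn("no markers satisfy the selection criteria", stacklevel=2)
    return result


def panel_mean_pid(stats: pd.DataFrame) -> float:
    """Arithmetic mean of the panel's per-locus PID column."""
    if len(stats) == 0:
        raise ValueError("empty statistics table")
    value = float(stats["pid"].mean())
    assert isfinite(value)
    return value
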