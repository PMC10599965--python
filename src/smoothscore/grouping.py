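"""Partitioning cells by annotation columns before graph construction.

Smoothing must never share information across phenotypes, batches or
conditions the user wants kept apart, so the pipeline first splits cells by
the observed combinations of the ``groupby`` columns and every later stage
runs per group.  Each group's computation is independent (no shared mutable
state), which is the contract that makes parallel execution legal; results
are merged back in the original cell order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import ExpressionDataset, MISSING_GROUP_LABEL, ValidationError

__all__ = ["split_by_groupby", "process_groups", "GroupReport", "MIN_SMOOTH_GROUP_SIZE"]

logger = logging.getLogger(__name__)

#: Below this group size smoothing is forced off: K would be clipped to
#: nearly nothing and a neighborhood average over 2-4 cells is noise, not
#: signal.  Such groups are still scored (unsmoothed) and flagged.
MIN_SMOOTH_GROUP_SIZE = 5


def split_by_groupby(
    ds: ExpressionDataset, groupby: list[str] | None
) -> list[tuple[tuple, np.ndarray]]:
    """Disjoint cell-index subsets, one per observed groupby combination.

    Group keys are tuples of column values (missing values become
    ``"(missing)"``); an empty ``groupby`` yields a single all-cells group.
    Subsets are disjoint and cover every cell.
    """
    if not groupby:
        return [((), np.arange(ds.n_cells))]
    ann = ds.cell_annotations
    unknown = [c for c in groupby if c not in ann.columns]
    if unknown:
        raise ValidationError(
            f"unknown groupby column(s) {unknown}; available: {list(ann.columns)}"
        )
    cols = [
        ann[c].astype("string").fillna(MISSING_GROUP_LABEL).to_numpy() for c in groupby
    ]
    keys = pd.DataFrame({c: v for c, v in zip(groupby, cols)})
    groups = []
    for key, sub in keys.groupby(groupby, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        groups.append((tuple(str(k) for k in key), sub.index.to_numpy()))
    return groups


@dataclass
class GroupReport:
    """What happened to one group: its size, smoothing status, and errors."""

    key: tuple
    size: int
    smoothed: bool = True
    K_used: int | None = None
    error: str | None = None
    notes: list = field(default_factory=list)


def process_groups(
    groups: list[tuple[tuple, np.ndarray]],
    per_group_fn,
    n_cells: int,
    columns: list[str],
    min_group_size: int = MIN_SMOOTH_GROUP_SIZE,
) -> tuple[np.ndarray, list[GroupReport]]:
    """Apply ``per_group_fn`` to each group and merge rows in original order.

    ``per_group_fn(key, cell_idx, allow_smoothing, report)`` returns an array
    of shape ``(len(cell_idx), len(columns))``.  Groups smaller than
    ``min_group_size`` are processed with smoothing forced off and flagged;
    a group whose function raises contributes missing values and the error
    is recorded, leaving other groups unaffected.
    """
    out = np.full((n_cells, len(columns)), np.nan)
    reports: list[GroupReport] = []
    for key, idx in groups:
        report = GroupReport(key=key, size=len(idx))
        allow_smoothing = len(idx) >= min_group_size
        if not allow_smoothing:
            report.smoothed = False
            report.notes.append(
                f"group of {len(idx)} cells below minimum {min_group_size}: "
                "smoothing forced off"
            )
            logger.info("group %s: %s", key, report.notes[-1])
        try:
            vals = per_group_fn(key, idx, allow_smoothing, report)
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (len(idx), len(columns)):
                raise ValueError(
                    f"per-group result has shape {vals.shape}, expected "
                    f"({len(idx)}, {len(columns)})"
                )
            out[idx] = vals
        except Exception as exc:  # isolation: one bad group never kills the run
            report.error = f"{type(exc).__name__}: {exc}"
            logger.error("group %s failed: %s", key, report.error)
        reports.append(report)
    return out, reports
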