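"""Regression design construction.

The design follows the case-mix convention: intercept, linear age (centered
at 50 years), age-stratum indicators for nonlinear age effects (default
strata <35, 35-44, 45-54, 55-64, 65-74, >=75 with the mid-distribution
45-54 stratum as reference), a female indicator, and one indicator per
expanded diagnostic group.  Socioeconomic covariates are deliberately out of
scope, matching standard commercial case-mix inputs (age, sex, diagnoses).

Columns that are constant over the sample (a stratum nobody occupies, an
all-male cohort, an empty group) are dropped with a logged warning rather
than erroring, since small synthetic cohorts routinely lack some stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grouper import ExpandedGrouping

logger = logging.getLogger(__name__)

__all__ = ["DesignMatrix", "build_design", "DEFAULT_AGE_BREAKS"]

DEFAULT_AGE_BREAKS: tuple[int, ...] = (35, 45, 55, 65, 75)


@dataclass
class DesignMatrix:
    """Dense design with named columns, row-aligned to ``patient_ids``."""

    values: np.ndarray
    columns: list[str]
    patient_ids: list[str]
    dropped: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.columns,
                            index=pd.Index(self.patient_ids, name="patient_id"))

    def subset(self, mask: np.ndarray) -> "DesignMatrix":
        ids = [p for p, m in zip(self.patient_ids, mask) if m]
        return DesignMatrix(values=self.values[mask], columns=list(self.columns),
                            patient_ids=ids, dropped=list(self.dropped))

    def drop_columns(self, names) -> "DesignMatrix":
        names = set(names)
        keep = [i for i, c in enumerate(self.columns) if c not in names]
        return DesignMatrix(values=self.values[:, keep],
                            columns=[self.columns[i] for i in keep],
                            patient_ids=list(self.patient_ids),
                            dropped=self.dropped + sorted(names))

    def write(self, path) -> None:
        self.frame().to_csv(path, sep="\t")


def _stratum_labels(breaks: tuple[int, ...]) -> list[str]:
    labels = [f"age_lt{breaks[0]}"]
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        labels.append(f"age_{lo}_{hi - 1}")
    labels.append(f"age_ge{breaks[-1]}")
    return labels


def build_design(patients: pd.DataFrame, grouping: ExpandedGrouping,
                 age_breaks: tuple[int, ...] = DEFAULT_AGE_BREAKS,
                 reference_stratum: str | None = None,
                 include_sex: bool = True,
                 center: float = 50.0) -> DesignMatrix:
    """Assemble the case-mix design matrix.

    Every patient must carry at least one group assignment.  The reference
    age stratum (default ``age_45_54``) and male sex are absorbed into the
    intercept.  Row order is the input patient order; the construction is
    deterministic, so rebuilding from identical inputs is bit-identical.
    """
    ids = list(patients["patient_id"])
    missing = [pid for pid in ids if pid not in grouping.assignment
               or not grouping.assignment[pid]]
    if missing:
        raise ValueError(f"{len(missing)} patients have no group assignment "
                         f"(first few: {missing[:5]})")

    ages = patients["age"].to_numpy(dtype=float)
    labels = _stratum_labels(age_breaks)
    if reference_stratum is None:
        reference_stratum = labels[len(labels) // 2]
    if reference_stratum not in labels:
        raise ValueError(f"reference_stratum {reference_stratum!r} not among {labels}")

    stratum_idx = np.digitize(ages, age_breaks, right=False)

    cols: dict[str, np.ndarray] = {}
    cols["intercept"] = np.ones(len(ids))
    cols["age_c"] = ages - center
    for j, lab in enumerate(labels):
        if lab == reference_stratum:
            continue
        cols[lab] = (stratum_idx == j).astype(float)
    if include_sex:
        cols["female"] = (patients["sex"].to_numpy() == "female").astype(float)

    gids = grouping.group_ids()
    pos = {pid: i for i, pid in enumerate(ids)}
    for gid in gids:
        cols[gid] = np.zeros(len(ids))
    for pid, assigned in grouping.assignment.items():
        i = pos.get(pid)
        if i is None:
            continue
        for gid in assigned:
            cols[gid][i] = 1.0

    dropped = []
    for name in list(cols):
        if name == "intercept":
            continue
        v = cols[name]
        if np.all(v == v[0]):
            dropped.append(name)
            del cols[name]
    if dropped:
        logger.warning("design: dropped %d constant columns: %s",
                       len(dropped), dropped[:8])

    names = list(cols)
    values = np.column_stack([cols[c] for c in names])
    return DesignMatrix(values=values, columns=names, patient_ids=ids,
                        dropped=dropped)
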