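"""Diagnostic-category mapping and homogeneity-driven prefix expansion.

Mental-health patients are identified through a CCSR-style code map (ICD-10-CM
code -> diagnostic category).  To sharpen within-group cost homogeneity, each
category is recursively subdivided by successive characters of the normalized
code: a node holding more distinct patients than a threshold T is split on the
next code character, down to a maximum depth (default: the fourth character).
Leaves of this recursion are the "expanded groups" that enter the regression
design as indicators.

The threshold is either an absolute patient count (the full-scale study used
6000, about 0.3% of its population) or a cohort fraction; the fractional form
(default 0.3%) scales the procedure to small synthetic cohorts.

An optional hierarchy step keeps, per patient and parent category, only the
single highest-ranked group (by default the group with the highest development
mean cost), emulating severity hierarchies in condition-category systems.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CodeMap", "Group", "ExpandedGrouping",
    "normalize_code", "load_code_map", "expand_categories",
    "impose_hierarchy", "rank_groups_by_mean_cost",
]


def normalize_code(raw: str) -> str:
    """Normalize an ICD-10-CM code: uppercase, no decimal point, no whitespace."""
    if raw is None:
        raise ValueError("code is empty")
    code = "".join(str(raw).split()).replace(".", "").upper()
    if not code:
        raise ValueError("code is empty")
    return code


@dataclass
class CodeMap:
    """Normalized code -> set of category ids, plus the excluded codes."""

    entries: dict[str, set[str]]
    exclusions: set[str] = field(default_factory=set)

    @property
    def n_codes(self) -> int:
        return len(self.entries)

    def categories(self) -> list[str]:
        return sorted({c for cats in self.entries.values() for c in cats})

    def codes_in_category(self, category: str) -> set[str]:
        return {code for code, cats in self.entries.items() if category in cats}

    def to_frame(self) -> pd.DataFrame:
        rows = [(code, cat) for code in sorted(self.entries)
                for cat in sorted(self.entries[code])]
        return pd.DataFrame(rows, columns=["code", "category"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_code_map(table, exclusion_list=()) -> CodeMap:
    """Build a :class:`CodeMap` from (code, category) rows.

    ``table`` may be a DataFrame with ``code``/``category`` columns, a path to
    a two-column delimited file of that shape, or an iterable of pairs.
    Codes on the exclusion list are dropped from scope; duplicate rows are
    deduplicated with a warning; malformed rows raise with their row number.
    """
    if isinstance(table, (str, bytes)) or hasattr(table, "read_text"):
        table = pd.read_csv(table, sep=None, engine="python", dtype=str)
    if isinstance(table, pd.DataFrame):
        if not {"code", "category"}.issubset(table.columns):
            raise ValueError("code map table needs 'code' and 'category' columns")
        rows = list(table[["code", "category"]].itertuples(index=False, name=None))
    else:
        rows = list(table)

    excluded = set()
    for raw in exclusion_list:
        excluded.add(normalize_code(raw))

    entries: dict[str, set[str]] = {}
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    for i, row in enumerate(rows):
        try:
            code_raw, cat = row
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed code-map row {i}: {row!r}") from exc
        if cat is None or (isinstance(cat, float) and math.isnan(cat)) or str(cat).strip() == "":
            raise ValueError(f"malformed code-map row {i}: empty category")
        try:
            code = normalize_code(code_raw)
        except ValueError as exc:
            raise ValueError(f"malformed code-map row {i}: {exc}") from exc
        cat = str(cat).strip()
        if (code, cat) in seen:
            n_dup += 1
            continue
        seen.add((code, cat))
        if code in excluded:
            continue
        entries.setdefault(code, set()).add(cat)

    if n_dup:
        logger.warning("code map: deduplicated %d duplicate (code, category) rows", n_dup)
    missing = excluded - {normalize_code(c) for c, _ in seen}
    if missing:
        logger.warning("code map: %d excluded codes were absent from the map", len(missing))
    logger.info("code map: retained %d codes across %d categories (%d excluded)",
                len(entries), len({c for s in entries.values() for c in s}), len(excluded))
    return CodeMap(entries=entries, exclusions=excluded)


@dataclass(frozen=True)
class Group:
    """One expanded group: all codes of ``category`` matching ``prefix``.

    ``terminal`` marks an exact-match bucket created when a code is shorter
    than the split position; such a group matches only the code equal to its
    prefix.  (Never arises for fixed-length code universes.)
    """

    group_id: str
    category: str
    prefix: str
    depth: int
    n_patients: int
    terminal: bool = False


@dataclass
class ExpandedGrouping:
    groups: list[Group]
    assignment: dict[str, set[str]]   # patient_id -> set of group_id
    threshold_used: int
    max_depth: int

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def group_ids(self) -> list[str]:
        return [g.group_id for g in self.groups]

    def groups_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(g.group_id, g.category, g.prefix, g.depth, g.n_patients, g.terminal)
             for g in self.groups],
            columns=["group_id", "category", "prefix", "depth", "n_patients", "terminal"],
        )

    def assignment_table(self) -> pd.DataFrame:
        rows = [(pid, gid) for pid in sorted(self.assignment)
                for gid in sorted(self.assignment[pid])]
        return pd.DataFrame(rows, columns=["patient_id", "group_id"])


def _codes_of(patient_row) -> list[str]:
    codes = patient_row
    if isinstance(codes, str):
        return [c for c in codes.split(";") if c]
    return list(codes)


def _patient_code_pairs(patients: pd.DataFrame, code_map: CodeMap):
    """(patient_id, code, category) triples for in-map codes; error if a
    patient has none (the cohort definition requires >= 1 mapped code)."""
    ids, codes, cats = [], [], []
    orphan: list[str] = []
    for pid, code_field in zip(patients["patient_id"], patients["codes"]):
        hit = False
        for raw in _codes_of(code_field):
            code = normalize_code(raw)
            for cat in code_map.entries.get(code, ()):
                ids.append(pid)
                codes.append(code)
                cats.append(cat)
                hit = True
        if not hit:
            orphan.append(pid)
    if orphan:
        raise ValueError(
            f"{len(orphan)} patients have no code in the map "
            f"(first few: {orphan[:5]})"
        )
    return pd.DataFrame({"patient_id": ids, "code": codes, "category": cats})


def resolve_threshold(n_patients: int, threshold: int | None,
                      threshold_fraction: float | None = 0.003) -> int:
    """Absolute distinct-patient threshold T; fractional thresholds get a floor of 1."""
    if threshold is not None:
        if threshold < 1:
            raise ValueError("threshold must be >= 1")
        return int(threshold)
    if threshold_fraction is None or threshold_fraction <= 0:
        raise ValueError("either threshold or a positive threshold_fraction is required")
    return max(1, math.floor(threshold_fraction * n_patients))


def expand_categories(patients: pd.DataFrame, code_map: CodeMap,
                      threshold: int | None = None, max_depth: int = 4,
                      threshold_fraction: float = 0.003) -> ExpandedGrouping:
    """Recursively subdivide each category into prefix-homogeneous groups.

    Starting from the whole category, any node holding more than T distinct
    patients is split on the next character of the normalized code, until the
    count falls to T or ``max_depth`` characters are consumed.  Patients are
    counted once per node however many of their codes fall under it.  Output
    order (category id, then prefix) is deterministic.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    t = resolve_threshold(len(patients), threshold, threshold_fraction)

    pairs = _patient_code_pairs(patients, code_map)
    groups: list[Group] = []
    assignment: dict[str, set[str]] = {}

    for cat in sorted(pairs["category"].unique()):
        sub = pairs[pairs["category"] == cat]
        code_patients: dict[str, set[str]] = {}
        for code, pid in zip(sub["code"], sub["patient_id"]):
            code_patients.setdefault(code, set()).add(pid)
        leaves: list[tuple[str, set[str], set[str], bool]] = []
        _split_node("", code_patients, t, max_depth, leaves)
        for prefix, codes, pats, terminal in sorted(leaves, key=lambda x: x[0]):
            gid = f"{cat}:{prefix if prefix else '*'}"
            groups.append(Group(group_id=gid, category=cat, prefix=prefix,
                                depth=len(prefix), n_patients=len(pats),
                                terminal=terminal))
            for pid in pats:
                assignment.setdefault(pid, set()).add(gid)

    return ExpandedGrouping(groups=groups, assignment=assignment,
                            threshold_used=t, max_depth=max_depth)


def _split_node(prefix: str, code_patients: dict[str, set[str]], t: int,
                max_depth: int, leaves: list) -> None:
    pats: set[str] = set().union(*code_patients.values()) if code_patients else set()
    depth = len(prefix)
    if len(pats) <= t or depth >= max_depth:
        leaves.append((prefix, set(code_patients), pats, False))
        return
    children: dict[str, dict[str, set[str]]] = {}
    exhausted: dict[str, set[str]] = {}
    for code, cp in code_patients.items():
        if len(code) <= depth:
            exhausted[code] = cp     # code ends here; cannot split further
        else:
            children.setdefault(code[depth], {})[code] = cp
    for code, cp in sorted(exhausted.items()):
        leaves.append((code, {code}, set(cp), True))
    for ch in sorted(children):
        _split_node(prefix + ch, children[ch], t, max_depth, leaves)


def rank_groups_by_mean_cost(grouping: ExpandedGrouping,
                             patients: pd.DataFrame) -> dict[str, float]:
    """Default hierarchy ranking: rank = development-sample mean cost of group
    members (higher mean cost wins)."""
    cost = dict(zip(patients["patient_id"], patients["cost"]))
    totals: dict[str, list[float]] = {g.group_id: [] for g in grouping.groups}
    for pid, gids in grouping.assignment.items():
        if pid not in cost:
            continue
        for gid in gids:
            totals[gid].append(cost[pid])
    return {gid: (float(np.mean(v)) if v else 0.0) for gid, v in totals.items()}


def impose_hierarchy(grouping: ExpandedGrouping,
                     ranking: dict[str, float]) -> ExpandedGrouping:
    """Keep, per patient and parent category, only the highest-ranked group.

    Ties break on group id (deterministic).  Idempotent: once each patient
    holds at most one group per category, a second application is a no-op.
    """
    missing = [g.group_id for g in grouping.groups if g.group_id not in ranking]
    if missing:
        raise ValueError(f"ranking is missing {len(missing)} group ids "
                         f"(first few: {missing[:5]})")
    cat_of = {g.group_id: g.category for g in grouping.groups}
    new_assignment: dict[str, set[str]] = {}
    for pid, gids in grouping.assignment.items():
        by_cat: dict[str, list[str]] = {}
        for gid in gids:
            by_cat.setdefault(cat_of[gid], []).append(gid)
        kept = {max(v, key=lambda g: (ranking[g], g)) for v in by_cat.values()}
        new_assignment[pid] = kept

    member_counts: dict[str, int] = {g.group_id: 0 for g in grouping.groups}
    for gids in new_assignment.values():
        for gid in gids:
            member_counts[gid] += 1
    new_groups = [replace(g, n_patients=member_counts[g.group_id])
                  for g in grouping.groups]
    return ExpandedGrouping(groups=new_groups, assignment=new_assignment,
                            threshold_used=grouping.threshold_used,
                            max_depth=grouping.max_depth)
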