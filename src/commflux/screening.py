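"""Combinatorial strain-combination screening across a media panel.

Enumerates member sets from a strain pool (exhaustively, or as a fixed core
plus up to k additions), builds each combination once, solves it under every
medium of a panel, and reports a flat result table plus the classic
presence/absence grid with per-medium biomass columns.  Per-row solver
failures are data, never exceptions: a screen always completes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .community import AbundanceScenario, FREE, build_community, community_fba
from .media import Medium
from .model import StrainModel

DEFAULT_MAX_COMBINATIONS = 4096


class ScreenSizeError(ValueError):
    """The enumeration would exceed the configured hard cap."""


@dataclass
class CombinationSpec:
    pool: List[str]
    core: List[str] = field(default_factory=list)
    mode: str = "exhaustive"
    k: int = 0
    max_subset_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in {"exhaustive", "core_plus_k"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(set(self.pool)) != len(self.pool):
            raise ValueError("pool contains duplicate ids")
        if not set(self.core) <= set(self.pool):
            raise ValueError("core must be a subset of the pool")
        if self.k < 0:
            raise ValueError("k must be >= 0")

    def member_sets(self) -> List[Tuple[str, ...]]:
        """Deterministic (lexicographic) enumeration, empty set excluded."""
        pool = sorted(self.pool)
        sets: List[Tuple[str, ...]] = []
        if self.mode == "exhaustive":
            max_size = self.max_subset_size or len(pool)
            for size in range(1, max_size + 1):
                sets.extend(combinations(pool, size))
        else:
            core = tuple(sorted(self.core))
            extras = [s for s in pool if s not in self.core]
            for size in range(0, self.k + 1):
                for extra in combinations(extras, size):
                    member_set = tuple(sorted(core + extra))
                    if member_set and (
                        self.max_subset_size is None
                        or len(member_set) <= self.max_subset_size
                    ):
                        sets.append(member_set)
        # dedupe preserving order, then sort lexicographically by (size-free)
        # member tuple for a reproducible screen order
        return sorted(set(sets))


@dataclass
class ScreenResult:
    table: pd.DataFrame
    pool: List[str]
    media_names: List[str]
    metadata: Dict[str, object] = field(default_factory=dict)


def enumerate_communities(
    spec: CombinationSpec,
    strains: Dict[str, StrainModel],
    media: Sequence[Medium],
    scenario: AbundanceScenario = FREE,
    max_combinations: int = DEFAULT_MAX_COMBINATIONS,
) -> ScreenResult:
    """Build and solve every enumerated combination under every medium."""
    missing = [sid for sid in spec.pool if sid not in strains]
    if missing:
        raise KeyError(f"pool ids without loaded models: {missing}")
    member_sets = spec.member_sets()
    if len(member_sets) > max_combinations:
        raise ScreenSizeError(
            f"{len(member_sets)} combinations exceed the cap of "
            f"{max_combinations}; use mode='core_plus_k', max_subset_size, or "
            "raise max_combinations explicitly"
        )
    rows = []
    for member_set in member_sets:
        try:
            cm = build_community([strains[sid] for sid in member_set], scenario)
        except Exception as exc:  # per-row failures are data
            for medium in media:
                rows.append(_failure_row(member_set, medium.name, spec.pool,
                                         f"build-error: {exc}"))
            continue
        for medium in media:
            try:
                sol = community_fba(cm, medium)
            except Exception as exc:
                rows.append(_failure_row(member_set, medium.name, spec.pool,
                                         f"solve-error: {exc}"))
                continue
            row = {
                "member_set": ";".join(member_set),
                "medium": medium.name,
                "status": sol.status,
                "community_biomass": (
                    sol.community_objective if sol.optimal else float("nan")
                ),
            }
            for sid in sorted(spec.pool):
                row[f"biomass_{sid}"] = sol.member_biomass.get(sid, float("nan"))
            rows.append(row)
    table = pd.DataFrame(rows)
    return ScreenResult(
        table=table,
        pool=sorted(spec.pool),
        media_names=[m.name for m in media],
        metadata={
            "scenario": scenario.mode,
            "mode": spec.mode,
            "n_combinations": len(member_sets),
            "deterministic": "enumeration and solver are deterministic; "
                             "re-runs bit-reproduce this table",
        },
    )


def _failure_row(member_set, medium_name, pool, status):
    row = {
        "member_set": ";".join(member_set),
        "medium": medium_name,
        "status": status,
        "community_biomass": float("nan"),
    }
    for sid in sorted(pool):
        row[f"biomass_{sid}"] = float("nan")
    return row


def rank_combinations(result: ScreenResult, medium_name: str) -> pd.DataFrame:
    """Rows of one medium ranked by community biomass (descending); ties go
    to the smaller member set, then lexicographic order."""
    if medium_name not in result.media_names:
        raise KeyError(f"medium {medium_name!r} not in screen result")
    sub = result.table[result.table["medium"] == medium_name].copy()
    sub["_size"] = sub["member_set"].str.count(";") + 1
    sub = sub.sort_values(
        by=["community_biomass", "_size", "member_set"],
        ascending=[False, True, True],
        kind="mergesort",
    ).drop(columns="_size")
    return sub.reset_index(drop=True)


def render_grid(result: ScreenResult) -> pd.DataFrame:
    """Presence/absence grid (one row per combination, member columns in
    pool order) plus one community-biomass column per medium."""
    if result.table.empty:
        return pd.DataFrame(
            columns=["member_set"] + result.pool
            + [f"biomass_{m}" for m in result.media_names]
        )
    rows = []
    for member_set, group in result.table.groupby("member_set", sort=False):
        members = set(member_set.split(";"))
        row = {"member_set": member_set}
        for sid in result.pool:
            row[sid] = int(sid in members)
        by_medium = group.set_index("medium")["community_biomass"]
        for name in result.media_names:
            row[f"biomass_{name}"] = by_medium.get(name, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows)


def write_screen_tsv(result: ScreenResult, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def write_grid_tsv(result: ScreenResult, path) -> None:
    render_grid(result).to_csv(path, sep="\t", index=False)
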