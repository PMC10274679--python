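"""Target-decoy FDR control with group-based filtering.

FPOP datasets mix three PSM populations with very different search-space
sizes — unmodified peptides, peptides carrying user-"assigned" common
modifications (by default Met oxidation and protein N-terminal acetylation),
and peptides carrying any other (rare FPOP) modification.  A single pooled
score threshold is appropriate for none of them: the rare-modification
group competes against a far larger candidate space and needs a stricter
threshold.  Group-based FDR therefore computes decoy-derived q-values
independently within each group and applies the nominal threshold (default
1% PSM) per group.

q-values use the standard decoy-count estimator: PSMs sorted by descending
score, FDR-hat = #decoys / max(1, #targets) at each threshold, converted to
q-values by a running minimum from the bottom.  Decoys are excluded from
the reported pass list but drive the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GROUPS = ("unmodified", "assigned", "other")

#: Default assigned-modification list, `--mods M:15.9949,n:42.0106` style:
#: Met oxidation plus protein N-terminal acetylation.
DEFAULT_ASSIGNED_MODS: tuple[tuple[str, float], ...] = (
    ("M", 15.9949),
    ("n", 42.0106),
)

ASSIGNED_MASS_TOL = 0.001


def parse_assigned_mods(text: str) -> list[tuple[str, float]]:
    """Parse an assigned-mods string like ``"M:15.9949,n:42.0106"``."""
    out = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        key, _, massstr = token.partition(":")
        if not key or not massstr:
            raise ValueError(f"malformed assigned-mod token {token!r}")
        out.append((key.strip(), float(massstr)))
    return out


def assign_group(
    mods: "Sequence[tuple[str, float, str]] | object",
    assigned_mods: Sequence[tuple[str, float]] = DEFAULT_ASSIGNED_MODS,
    tol: float = ASSIGNED_MASS_TOL,
) -> str:
    """Classify one PSM as ``unmodified`` / ``assigned`` / ``other``.

    ``mods`` is the PSM's modification list as (site key, mass, label)
    triples — fixed modifications excluded (they carry no information); a
    PSM object with a ``modification_list`` method is also accepted.  A PSM
    is ``unmodified`` iff it carries no variable mod and a zero offset,
    ``assigned`` iff *every* modification matches an entry of
    ``assigned_mods`` (site key and mass within ``tol``), else ``other``.
    For an unlocalized offset the site key holds the offset's eligible
    residue letters; it matches an assigned entry whose key is among them.
    """
    if hasattr(mods, "modification_list"):
        mods = mods.modification_list()
    elif hasattr(mods, "peptidoform"):
        mods = mods.peptidoform.modification_list()
    if not mods:
        return "unmodified"
    for key, mass, _label in mods:
        matched = False
        for akey, amass in assigned_mods:
            if abs(mass - amass) > tol:
                continue
            if akey == key or (akey in key and len(key) > 1) or (
                akey == "n" and key == "n"
            ):
                matched = True
                break
        if not matched:
            return "other"
    return "assigned"


def add_groups(
    psms: pd.DataFrame,
    assigned_mods: Sequence[tuple[str, float]] = DEFAULT_ASSIGNED_MODS,
) -> pd.DataFrame:
    """Return a copy of the PSM table with a ``group`` column."""
    out = psms.copy()
    out["group"] = [assign_group(m, assigned_mods) for m in out["mods"]]
    return out


def compute_qvalues(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """Decoy-count q-values for one group of PSMs.

    Sort by score descending; at each score threshold FDR-hat =
    #decoys / max(1, #targets); q = running minimum from the bottom.  PSMs
    with exactly equal scores share a threshold (both counts include the
    whole tie block).  A group with zero targets gets q = 1 everywhere.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    n = scores.size
    if n == 0:
        return np.empty(0)
    if not np.any(~is_decoy):
        return np.ones(n)
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_sorted = is_decoy[order]
    cum_d = np.cumsum(d_sorted)
    cum_t = np.cumsum(~d_sorted)
    # ties share the counts of the last member of their score block
    block_end = np.arange(n)
    for i in range(n - 2, -1, -1):
        if s_sorted[i] == s_sorted[i + 1]:
            block_end[i] = block_end[i + 1]
    fdr = cum_d[block_end] / np.maximum(1, cum_t[block_end])
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


@dataclass
class FilterReport:
    """Per-group outcome of an FDR filtering pass."""

    threshold: float
    group_min_passing_score: dict[str, float]
    group_counts: dict[str, int]


def group_fdr_filter(
    psms: pd.DataFrame,
    assigned_mods: Sequence[tuple[str, float]] = DEFAULT_ASSIGNED_MODS,
    threshold: float = 0.01,
) -> tuple[pd.DataFrame, FilterReport]:
    """Filter PSMs at ``threshold`` with independent per-group q-values.

    Returns the passing *target* PSMs (decoys dropped) with ``group`` and
    ``q_value`` columns, plus a report carrying each group's minimum passing
    score — the per-group thresholds that pooled filtering cannot provide.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    grouped = add_groups(psms, assigned_mods)
    if grouped.empty:
        grouped["q_value"] = pd.Series(dtype=float)
        grouped["passes"] = pd.Series(dtype=bool)
        return grouped, FilterReport(threshold, {}, {g: 0 for g in GROUPS})
    q = np.ones(len(grouped))
    for g in GROUPS:
        mask = (grouped["group"] == g).to_numpy()
        if mask.any():
            q[mask] = compute_qvalues(
                grouped.loc[mask, "score"].to_numpy(),
                grouped.loc[mask, "is_decoy"].to_numpy(),
            )
    grouped["q_value"] = q
    grouped["passes"] = (grouped["q_value"] <= threshold) & ~grouped["is_decoy"]
    passing = grouped[grouped["passes"]].drop(columns="passes").reset_index(drop=True)
    report = FilterReport(
        threshold=threshold,
        group_min_passing_score={
            g: float(passing.loc[passing["group"] == g, "score"].min())
            for g in GROUPS
            if (passing["group"] == g).any()
        },
        group_counts={g: int((passing["group"] == g).sum()) for g in GROUPS},
    )
    return passing, report


def regular_fdr_filter(
    psms: pd.DataFrame,
    assigned_mods: Sequence[tuple[str, float]] = DEFAULT_ASSIGNED_MODS,
    threshold: float = 0.01,
) -> tuple[pd.DataFrame, FilterReport]:
    """Pooled (single-threshold) FDR filtering over all PSMs together.

    Provided for comparison with :func:`group_fdr_filter`; groups are still
    annotated so the per-group consequences of the pooled threshold can be
    counted.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    grouped = add_groups(psms, assigned_mods)
    if grouped.empty:
        grouped["q_value"] = pd.Series(dtype=float)
        return grouped, FilterReport(threshold, {}, {g: 0 for g in GROUPS})
    grouped["q_value"] = compute_qvalues(
        grouped["score"].to_numpy(), grouped["is_decoy"].to_numpy()
    )
    passing = grouped[
        (grouped["q_value"] <= threshold) & ~grouped["is_decoy"]
    ].reset_index(drop=True)
    report = FilterReport(
        threshold=threshold,
        group_min_passing_score=(
            {"all": float(passing["score"].min())} if len(passing) else {}
        ),
        group_counts={g: int((passing["group"] == g).sum()) for g in GROUPS},
    )
    return passing, report
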