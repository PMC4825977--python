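"""Candidate-marker ranking against a whole-alignment reference tree.

For each candidate region the pipeline builds a bootstrap majority-rule
consensus tree from the region's sub-alignment and scores it against the
reference topology: Robinson-Foulds distance, the fraction of reference
splits recovered with at least moderate support, and monophyly of a
designated taxon group (by default the study's American ingroup).  Regions
are ordered by a composite score

    score = w1 * recovered_split_fraction
          + w2 * (1 - RF / RFmax)
          + w3 * min(pct_total_variability / cap, 1)

with default weights (0.5, 0.3, 0.2) and cap 10%: congruence with the
reference tree and node support dominate, raw divergence is a tie-breaker.
The weights formalize an otherwise visual model-selection step and are fully
configurable.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment
from .errors import LabelError
from .phylo import (
    SupportThresholds,
    bootstrap_trees,
    majority_consensus,
    rf_distance,
    rf_max,
)
from .trees import PhyloTree
from .variability import variability_table
from .windows import CandidateRegion, mean_pairwise_identity

__all__ = ["check_monophyly", "rank_markers", "REPORT_COLUMNS"]

REPORT_COLUMNS = [
    "label",
    "start_1based",
    "end_1based",
    "length",
    "pct_total_variability",
    "pct_informative",
    "mean_identity",
    "rf_distance",
    "recovered_split_fraction",
    "group_monophyletic",
    "score",
    "excluded",
    "note",
]


def check_monophyly(tree: PhyloTree, group: Sequence[str]) -> bool:
    """True iff some edge of the unrooted tree separates exactly ``group``.

    ``group`` must be a proper subset of the leaves with at least two
    members.  A group missing only one leaf is separated by that leaf's
    pendant edge and is therefore trivially monophyletic.
    """
    group_set = frozenset(group)
    if not group_set <= tree.taxa:
        raise LabelError(f"group members {sorted(group_set - tree.taxa)} not in tree")
    if len(group_set) < 2 or len(group_set) >= len(tree.taxa):
        raise LabelError("group must be a proper subset with >= 2 members")
    if len(group_set) == len(tree.taxa) - 1:
        return True
    return tree.canonical_split(group_set) in tree.splits()


def _region_tree_scores(
    region_tree: PhyloTree,
    reference: PhyloTree,
    thresholds: SupportThresholds,
) -> tuple[int, float]:
    """(RF distance, fraction of reference splits recovered with support)."""
    rf = rf_distance(region_tree, reference)
    ref_splits = reference.splits()
    if not ref_splits:
        return rf, 1.0
    supports = region_tree.split_supports()
    recovered = sum(
        1
        for s in ref_splits
        if s in supports
        and (supports[s] is None or supports[s] >= thresholds.moderate)
    )
    return rf, recovered / len(ref_splits)


def rank_markers(
    aln: Alignment,
    candidates: Sequence[CandidateRegion],
    reference: PhyloTree,
    group: Optional[Sequence[str]] = None,
    thresholds: SupportThresholds = SupportThresholds(),
    bootstrap_reps: int = 100,
    seed: int = 0,
    weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
    variability_cap: float = 10.0,
) -> pd.DataFrame:
    """Score and rank candidate marker regions against a reference tree.

    Returns a report DataFrame, one row per candidate, sorted by composite
    score descending with ties broken by lower start coordinate.  Regions in
    which some taxon has no data at all are flagged ``excluded`` (score NaN,
    sorted last) rather than silently dropped.  Coordinates in the report are
    1-based inclusive; everything is deterministic given ``seed``.
    """
    if reference.taxa != frozenset(aln.taxa):
        raise LabelError("reference tree leaves do not match alignment taxa")
    if group is not None and not set(group) <= set(aln.taxa):
        raise LabelError("group contains taxa absent from the alignment")

    rng = np.random.default_rng(seed)
    region_seeds = rng.integers(0, 2**31 - 1, size=max(len(candidates), 1))

    w1, w2, w3 = weights
    rfmax = rf_max(aln.n_taxa)
    rows = []
    for k, cand in enumerate(candidates):
        sub = aln.extract_region(cand.start, cand.end)
        row = {
            "label": cand.label or f"candidate_{k + 1}",
            "start_1based": cand.start + 1,
            "end_1based": cand.end,
            "length": cand.length,
            "excluded": False,
            "note": "",
        }
        vt = variability_table(sub).loc["whole_alignment"]
        row["pct_total_variability"] = float(vt["pct_total_variability"])
        row["pct_informative"] = float(vt["pct_informative"])
        row["mean_identity"] = mean_pairwise_identity(sub)

        empty_taxa = [
            t for t, has in zip(sub.taxa, sub.base_mask().any(axis=1)) if not has
        ]
        if empty_taxa:
            row.update(
                rf_distance=np.nan,
                recovered_split_fraction=np.nan,
                group_monophyletic=pd.NA,
                score=np.nan,
                excluded=True,
                note=f"excluded: insufficient data for {', '.join(empty_taxa)}",
            )
            rows.append(row)
            continue

        trees = bootstrap_trees(sub, bootstrap_reps, int(region_seeds[k]))
        consensus = majority_consensus(trees)
        rf, recovered = _region_tree_scores(consensus, reference, thresholds)
        row["rf_distance"] = rf
        row["recovered_split_fraction"] = recovered
        row["group_monophyletic"] = (
            check_monophyly(consensus, group) if group else pd.NA
        )
        row["score"] = (
            w1 * recovered
            + w2 * (1.0 - rf / rfmax)
            + w3 * min(row["pct_total_variability"] / variability_cap, 1.0)
        )
        rows.append(row)

    report = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if len(report):
        report = report.sort_values(
            ["score", "start_1based"],
            ascending=[False, True],
            na_position="last",
            kind="mergesort",
        ).reset_index(drop=True)
    return report
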