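"""Top-level modelling interface: fit a marker-discovery analysis to data.

:class:`MarkerDiscovery` bundles the full workflow — per-partition
variability, sliding-window identity scan, candidate extraction, reference
tree construction, and congruence-based ranking — behind a model/results
pair.  Construct the model from an alignment and partition (or from files),
call :meth:`MarkerDiscovery.fit`, and inspect the returned
:class:`MarkerDiscoveryResults`.

Example
-------
>>> from plastomarker import simulate, MarkerDiscovery
>>> cfg = simulate.default_config(seed=7, planted_markers=((13000, 14200, 20.0),))
>>> aln, truth = simulate.simulate_alignment(cfg, simulate.default_partition())
>>> res = MarkerDiscovery(aln, simulate.default_partition(),
...                       group=simulate.GIREOUDIA_TAXA).fit(seed=7)
>>> print(res.summary())  # doctest: +SKIP
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .alignment import Alignment, read_alignment
from .partition import PartitionMap, read_partition
from .phylo import SupportThresholds, bootstrap_trees, majority_consensus
from .ranking import rank_markers
from .trees import PhyloTree, read_tree
from .variability import variability_table
from .windows import CandidateRegion, IdentityProfile, extract_candidates, identity_profile

__all__ = ["MarkerDiscovery", "MarkerDiscoveryResults"]


class MarkerDiscovery:
    """Marker-discovery model over a plastome alignment.

    Parameters
    ----------
    alignment, partition:
        The aligned plastome matrix and its quadripartite region map.
    reference_tree:
        Optional externally supplied reference topology; when omitted, the
        reference is the bootstrap majority-rule consensus built from the
        whole alignment at fit time.
    group:
        Taxon group whose monophyly each candidate tree is checked for.
    thresholds:
        Support-interpretation thresholds (default bootstrap 70/85).
    window_size, step, identity_threshold, min_length, max_length,
    max_missing_fraction, merge_gap:
        Identity-scan and candidate-extraction settings.
    weights, variability_cap:
        Composite-score settings of the ranking stage.
    """

    def __init__(
        self,
        alignment: Alignment,
        partition: Optional[PartitionMap] = None,
        *,
        reference_tree: Optional[PhyloTree] = None,
        group: Optional[Sequence[str]] = None,
        thresholds: SupportThresholds = SupportThresholds(),
        window_size: int = 10,
        step: int = 1,
        identity_threshold: float = 0.95,
        min_length: int = 800,
        max_length: int = 2000,
        max_missing_fraction: float = 0.2,
        merge_gap: int = 200,
        weights: tuple[float, float, float] = (0.5, 0.3, 0.2),
        variability_cap: float = 10.0,
    ):
        self.alignment = alignment
        self.partition = partition
        self.reference_tree = reference_tree
        self.group = list(group) if group is not None else None
        self.thresholds = thresholds
        self.window_size = window_size
        self.step = step
        self.identity_threshold = identity_threshold
        self.min_length = min_length
        self.max_length = max_length
        self.max_missing_fraction = max_missing_fraction
        self.merge_gap = merge_gap
        self.weights = weights
        self.variability_cap = variability_cap

    @classmethod
    def from_files(
        cls,
        fasta_path,
        partition_path=None,
        reference_tree_path=None,
        **kwargs,
    ) -> "MarkerDiscovery":
        aln = read_alignment(fasta_path)
        partition = (
            read_partition(partition_path, aln.length) if partition_path else None
        )
        reference = (
            read_tree(reference_tree_path, taxa=aln.taxa)
            if reference_tree_path
            else None
        )
        return cls(aln, partition, reference_tree=reference, **kwargs)

    def fit(self, bootstrap_reps: int = 100, seed: int = 0) -> "MarkerDiscoveryResults":
        """Run the full analysis; deterministic given ``seed``."""
        aln = self.alignment
        variability = variability_table(aln, self.partition)
        profile = identity_profile(aln, self.window_size, self.step)
        candidates = extract_candidates(
            profile,
            aln,
            identity_threshold=self.identity_threshold,
            min_length=self.min_length,
            max_length=self.max_length,
            max_missing_fraction=self.max_missing_fraction,
            merge_gap=self.merge_gap,
        )
        reference = self.reference_tree
        if reference is None:
            trees = bootstrap_trees(aln, bootstrap_reps, seed)
            reference = majority_consensus(trees)
        report = rank_markers(
            aln,
            candidates,
            reference,
            group=self.group,
            thresholds=self.thresholds,
            bootstrap_reps=bootstrap_reps,
            seed=seed + 1,
            weights=self.weights,
            variability_cap=self.variability_cap,
        )
        return MarkerDiscoveryResults(
            model=self,
            variability=variability,
            profile=profile,
            candidates=candidates,
            reference_tree=reference,
            report=report,
            seed=seed,
            bootstrap_reps=bootstrap_reps,
        )


class MarkerDiscoveryResults:
    """Results of a fitted :class:`MarkerDiscovery` analysis.

    Attributes
    ----------
    variability : pandas.DataFrame
        Per-partition site-class counts and percentages.
    profile : IdentityProfile
        Sliding-window mean pairwise identity track.
    candidates : list[CandidateRegion]
        Extracted candidate marker regions (alignment coordinates).
    reference_tree : PhyloTree
        The topology candidates were scored against.
    report : pandas.DataFrame
        Ranked marker report (1-based inclusive coordinates).
    """

    def __init__(
        self,
        model: MarkerDiscovery,
        variability: pd.DataFrame,
        profile: IdentityProfile,
        candidates: list[CandidateRegion],
        reference_tree: PhyloTree,
        report: pd.DataFrame,
        seed: int,
        bootstrap_reps: int,
    ):
        self.model = model
        self.variability = variability
        self.profile = profile
        self.candidates = candidates
        self.reference_tree = reference_tree
        self.report = report
        self.seed = seed
        self.bootstrap_reps = bootstrap_reps

    def summary(self) -> str:
        """Human-readable analysis summary (plain text)."""
        aln = self.model.alignment
        lines = [
            "Marker discovery results",
            "=" * 60,
            f"taxa: {aln.n_taxa}    alignment columns: {aln.length}",
            f"bootstrap replicates: {self.bootstrap_reps}    seed: {self.seed}",
            "",
            "Per-partition variability",
            "-" * 60,
            self.variability.round(2).to_string(),
            "",
            f"Candidate regions ({len(self.candidates)}) "
            f"[window {self.model.window_size}, identity < "
            f"{self.model.identity_threshold}]",
            "-" * 60,
        ]
        if len(self.report):
            cols = [
                "label",
                "start_1based",
                "end_1based",
                "length",
                "pct_total_variability",
                "rf_distance",
                "recovered_split_fraction",
                "group_monophyletic",
                "score",
            ]
            lines.append(self.report[cols].round(3).to_string(index=False))
        else:
            lines.append("(no candidate regions passed the filters)")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<MarkerDiscoveryResults {len(self.candidates)} candidates, "
            f"{self.model.alignment.n_taxa} taxa>"
        )
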