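"""Synthetic plastome-alignment generator with known ground truth.

Emulates the structure of a multi-species plastid-genome alignment: a fixed
16-taxon tree, three partitions (LSC, IR, SSC) with contrasting substitution
rates, optional planted high-divergence marker blocks, and optional missing
data blocks.  Every downstream stage of the package can therefore be tested
against a known generating process without any data download.

Sequences evolve column-by-column under Jukes-Cantor substitution along the
tree; a column's rate is its partition's multiplier, overridden inside
planted marker blocks.  Stationary base frequencies (AT-rich by default, as
in plastid genomes) apply only to the root draw — under JC the substitution
process itself is symmetric.  Indels are modelled only as whole blocks of
missing data (``?``), not as evolutionary events; the statistics under test
treat gaps and missing data uniformly.

Default study conditions: rate multipliers IR=1, LSC=2.5, SSC=5 reproduce
the characteristic ordering of plastome variability (the SSC evolving about
twice as fast as the LSC and about five times as fast as the IR); root base
frequencies give 64.2% AT; the default tree places the nine sect. Gireoudia
species in a clade, with uniform edge lengths of 0.0006 expected
substitutions per site so that realized whole-alignment variability lands
near the few-percent level typical of congeneric plastome alignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from ._util import BASES
from .alignment import Alignment
from .errors import ConfigError
from .partition import PartitionMap, Region
from .trees import PhyloTree

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_alignment",
    "simulate_contigs",
    "default_tree",
    "default_partition",
    "default_config",
    "GIREOUDIA_TAXA",
    "STUDY_TAXA",
]

# The sixteen study species; nine belong to sect. Gireoudia (the American
# ingroup whose monophyly the marker ranking checks by default).
GIREOUDIA_TAXA = (
    "B_conchifolia",
    "B_plebeja",
    "B_carolineifolia",
    "B_stigmosa",
    "B_peltata",
    "B_nelumbiifolia",
    "B_theimei",
    "B_sericoneura",
    "B_involucrata",
)

STUDY_TAXA = GIREOUDIA_TAXA + (
    "B_pustulata",
    "B_solananthera",
    "B_venusta",
    "B_varipeltata",
    "B_dregei",
    "B_socotrana",
    "B_bogneri",
)

_DEFAULT_EDGE = 0.0006  # expected substitutions/site per edge at multiplier 1

_DEFAULT_TOPOLOGY = (
    "(B_bogneri,(B_dregei,B_socotrana),((B_venusta,B_varipeltata),"
    "((B_solananthera,B_pustulata),(B_carolineifolia,((B_conchifolia,"
    "B_plebeja),((B_stigmosa,B_peltata),((B_nelumbiifolia,B_theimei),"
    "(B_sericoneura,B_involucrata))))))));"
)


def default_tree(edge_length: float = _DEFAULT_EDGE) -> PhyloTree:
    """The fixed 16-taxon study tree with uniform branch lengths."""
    tree = PhyloTree.from_newick(_DEFAULT_TOPOLOGY)
    for edge in tree.dendropy_tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = edge_length
    return PhyloTree.from_newick(tree.to_newick())


def default_partition(
    lsc: int = 10_100, ir: int = 2_750, ssc: int = 2_150
) -> PartitionMap:
    """LSC/IR/SSC partition in genome order, scaled to a 15 kb alignment."""
    return PartitionMap(
        [
            Region("LSC", 0, lsc),
            Region("IR", lsc, lsc + ir),
            Region("SSC", lsc + ir, lsc + ir + ssc),
        ],
        lsc + ir + ssc,
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic alignment."""

    tree: PhyloTree
    partition_rates: dict[str, float]
    planted_markers: tuple[tuple[int, int, float], ...] = ()
    missing_blocks: tuple[tuple[str, int, int], ...] = ()
    base_frequencies: tuple[float, float, float, float] = (0.321, 0.179, 0.179, 0.321)
    seed: int = 0

    def __post_init__(self):
        freqs = np.asarray(self.base_frequencies, dtype=float)
        if freqs.shape != (4,) or abs(freqs.sum() - 1.0) > 1e-9 or np.any(freqs < 0):
            raise ConfigError("base_frequencies must be 4 non-negatives summing to 1")
        if any(r < 0 for r in self.partition_rates.values()):
            raise ConfigError("rate multipliers must be >= 0")
        if any(m[2] < 0 for m in self.planted_markers):
            raise ConfigError("planted marker rates must be >= 0")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth accompanying a simulated alignment."""

    rates: np.ndarray  # per-column rate multiplier actually used
    planted_markers: tuple[tuple[int, int, float], ...]
    missing_blocks: tuple[tuple[str, int, int], ...]
    tree_newick: str
    region_rates: dict[str, float] = field(default_factory=dict)


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The study-condition defaults: 16 taxa, IR=1 / LSC=2.5 / SSC=5."""
    kwargs = dict(
        tree=default_tree(),
        partition_rates={"LSC": 2.5, "SSC": 5.0, "IR": 1.0},
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def simulate_alignment(
    config: SimulationConfig, partition: PartitionMap
) -> tuple[Alignment, SimulationTruth]:
    """Evolve one alignment column-independently along the config's tree.

    Each column's Jukes-Cantor rate is its partition's multiplier (overridden
    inside planted marker intervals); missing blocks are overwritten with
    ``?`` after simulation.  Identical config and partition give
    byte-identical output.
    """
    names = set(partition.names)
    unknown = sorted(set(config.partition_rates) - names)
    if unknown:
        raise ConfigError(f"partition_rates name(s) {unknown} not in partition")
    missing_rates = sorted(names - set(config.partition_rates))
    if missing_rates:
        raise ConfigError(f"no rate multiplier for partition(s) {missing_rates}")

    L = partition.alignment_length
    rates = np.zeros(L)
    for region in partition:
        rates[region.start : region.end] = config.partition_rates[region.name]
    for start, end, rate in config.planted_markers:
        if not (0 <= start < end <= L):
            raise ConfigError(f"planted marker [{start}, {end}) outside alignment")
        rates[start:end] = rate
    for taxon, start, end in config.missing_blocks:
        if not (0 <= start < end <= L):
            raise ConfigError(f"missing block [{start}, {end}) outside alignment")

    tree = config.tree.dendropy_tree
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ConfigError("simulation tree needs at least 3 leaves")
    for taxon, _, _ in config.missing_blocks:
        if taxon not in leaves:
            raise ConfigError(f"missing block names unknown taxon {taxon!r}")

    rng = np.random.default_rng(config.seed)
    freqs = np.asarray(config.base_frequencies)
    root_states = rng.choice(4, size=L, p=freqs)

    states: dict[int, np.ndarray] = {}
    rows: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = root_states
        else:
            parent = states[id(node.parent_node)]
            t = node.edge.length or 0.0
            if t < 0:
                raise ConfigError("negative branch length in simulation tree")
            # JC: P(change) = 3/4 (1 - exp(-4/3 rate t)) per column.
            p_change = 0.75 * -np.expm1(-4.0 / 3.0 * rates * t)
            change = rng.random(L) < p_change
            shift = rng.integers(1, 4, size=L)
            child = parent.copy()
            child[change] = (parent[change] + shift[change]) % 4
            states[id(node)] = child
        if node.is_leaf():
            rows[node.taxon.label] = states[id(node)]

    base_codes = np.frombuffer(BASES.encode(), dtype=np.uint8)
    matrix = np.vstack([base_codes[rows[t]] for t in leaves])
    matrix = matrix.copy()
    leaf_index = {t: k for k, t in enumerate(leaves)}
    for taxon, start, end in config.missing_blocks:
        matrix[leaf_index[taxon], start:end] = ord("?")
    aln = Alignment._from_codes(leaves, matrix)

    truth = SimulationTruth(
        rates=rates,
        planted_markers=tuple(config.planted_markers),
        missing_blocks=tuple(config.missing_blocks),
        tree_newick=config.tree.to_newick(),
        region_rates={r.name: config.partition_rates[r.name] for r in partition},
    )
    return aln, truth


def simulate_contigs(
    genome_length: int, n_breaks: int, seed: int
) -> list[int]:
    """Fragment a genome of ``genome_length`` bases into ``n_breaks``+1 contigs.

    Break positions are drawn uniformly without replacement; contig lengths
    are positive and always sum to ``genome_length``.
    """
    if genome_length < 1:
        raise ConfigError("genome_length must be >= 1")
    if not (0 <= n_breaks < genome_length):
        raise ConfigError("need 0 <= n_breaks < genome_length")
    rng = np.random.default_rng(seed)
    cuts = rng.choice(genome_length - 1, size=n_breaks, replace=False) + 1
    bounds = np.concatenate([[0], np.sort(cuts), [genome_length]])
    return [int(x) for x in np.diff(bounds)]
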