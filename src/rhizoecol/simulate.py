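"""Synthetic community generator with known ground truth.

Emulates the data a rhizosphere amplicon survey produces — a metacommunity
pool, neutrally assembled local communities, genotype-structured selection on
designated clades, a birth-death phylogeny over taxa, and 16S-like sequences
evolved along that phylogeny — so that every downstream analysis has a
parameter-recovery oracle without any external dataset.

The neutral generator draws each taxon's latent local relative abundance from
Sloan's stationary beta marginal Beta(N*m*p_i, N*m*(1-p_i)), renormalises
jointly, and then draws sequencing counts as a fixed-depth multinomial.  This
is exactly the distribution the neutral-model fit assumes, which makes Nm
recovery a clean oracle; the joint renormalisation perturbs the marginals
slightly, which recovery tolerances absorb.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from skbio import TreeNode

from .io import FeatureTable, write_feature_table

__all__ = [
    "Metacommunity",
    "SimulationConfig",
    "simulate_metacommunity",
    "simulate_neutral_samples",
    "simulate_tree",
    "simulate_sequences",
    "inject_selection",
    "make_fixture_bundle",
    "simulate_planted_core",
]

DEFAULT_GROUPS = ("MIX", "NSS", "SS", "TST")


@dataclass
class Metacommunity:
    """Source-pool relative abundances the local communities immigrate from."""

    taxon_ids: list[str]
    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if (self.p <= 0).any():
            raise ValueError("metacommunity abundances must be positive")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise ValueError("metacommunity abundances must sum to 1")
        if len(self.taxon_ids) != len(self.p):
            raise ValueError("taxon ids and abundances differ in length")


@dataclass
class SimulationConfig:
    """Parameters of one synthetic survey."""

    S: int = 300
    n_samples: int = 20  # per group
    depth: int = 1000  # reads per sample
    m: float = 0.5  # immigration probability
    groups: tuple[str, ...] = DEFAULT_GROUPS
    selection_effect: float = 1.0  # clade fitness multiplier (1 = neutral)
    logseries_theta: float = 0.999
    birth_rate: float = 1.0
    seq_length: int = 427
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError("need at least 2 taxa")
        if not (0 < self.m <= 1):
            raise ValueError("m must be in (0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


def _taxon_ids(S: int) -> list[str]:
    width = len(str(S))
    return [f"ASV{i + 1:0{width}d}" for i in range(S)]


def simulate_metacommunity(
    S: int, logseries_theta: float = 0.999, seed: int = 0
) -> Metacommunity:
    """Log-series-shaped source pool: few dominant taxa, a long rare tail.

    ``logseries_theta`` is the log-series shape parameter in (0, 1); values
    close to 1 give the heavy tail typical of soil communities.
    """
    if not (0 < logseries_theta < 1):
        raise ValueError("log-series shape must be in (0, 1)")
    from scipy import stats

    rng = np.random.default_rng(seed)
    sizes = stats.logser.rvs(logseries_theta, size=S, random_state=rng).astype(float)
    # break ties so no two taxa are exactly interchangeable
    sizes += rng.uniform(0, 0.5, size=S)
    p = sizes / sizes.sum()
    return Metacommunity(_taxon_ids(S), p)


def simulate_neutral_samples(
    meta: Metacommunity,
    m: float,
    N: int,
    n_samples: int,
    seed: int = 0,
    depth: int | None = None,
) -> FeatureTable:
    """Draw neutrally assembled local communities from the source pool.

    ``N`` is the local community size governing drift (the beta marginal has
    parameters N*m*p and N*m*(1-p)); ``depth`` is the number of sequencing
    reads drawn per sample and defaults to ``N``.  Every sample total equals
    ``depth`` exactly.
    """
    if not (0 < m <= 1):
        raise ValueError("m must be in (0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    depth = N if depth is None else int(depth)
    rng = np.random.default_rng(seed)
    a = N * m * meta.p
    b = N * m * (1.0 - meta.p)
    lam = rng.beta(a[None, :], b[None, :], size=(n_samples, len(meta.p)))
    rowsum = lam.sum(axis=1, keepdims=True)
    # a whole row of exact zeros is essentially impossible; guard anyway
    rowsum[rowsum == 0] = 1.0
    lam /= rowsum
    counts = np.vstack([rng.multinomial(depth, row) for row in lam])
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    return FeatureTable(pd.DataFrame(counts, index=samples, columns=meta.taxon_ids))


def simulate_tree(
    taxon_ids: list[str],
    birth_rate: float = 1.0,
    seed: int = 0,
    height: float | None = 0.3,
) -> TreeNode:
    """Pure-birth (Yule) phylogeny with tips exactly equal to ``taxon_ids``.

    ``height`` rescales branch lengths so the root-to-tip depth matches the
    given value in substitutions per site; the default 0.3 puts patristic
    distances on the scale of a 16S gene tree (tip-tip distances up to
    ~0.6), so that the default phylogenetic-bin ceiling of 0.2 delineates
    genuine clades.  ``height=None`` keeps raw coalescent-time branch
    lengths.
    """
    if len(taxon_ids) < 2:
        raise ValueError("need at least 2 taxa for a tree")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=len(taxon_ids),
        rng=_random.Random(seed),
    )
    for leaf, name in zip(dtree.leaf_node_iter(), taxon_ids):
        leaf.taxon.label = name
    newick = dtree.as_string(schema="newick", suppress_rooting=True)
    tree = TreeNode.read([newick], convert_underscores=False)
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length <= 0:
            node.length = 1e-8  # zero-length edges break patristic distances
    if height is not None:
        depth = max(tip.accumulate_to_ancestor(tree) for tip in tree.tips())
        factor = height / depth
        for node in tree.traverse(include_self=False):
            node.length *= factor
    return tree


_BASES = np.array(list("ACGT"))


def simulate_sequences(
    tree: TreeNode, length: int = 427, rate: float = 0.05, seed: int = 0
) -> dict[str, str]:
    """Evolve 16S-like sequences along the tree by per-site substitution.

    Jukes-Cantor-style: on a branch of length t each site substitutes with
    probability ``0.75 * (1 - exp(-4/3 * rate * t))`` to a uniformly chosen
    different base.  No indels, so all sequences share one alignment length.
    """
    rng = np.random.default_rng(seed)
    root_seq = rng.integers(0, 4, size=length)
    out: dict[str, str] = {}

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            t = child.length or 0.0
            p_sub = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * t))
            child_seq = seq.copy()
            hits = np.nonzero(rng.random(length) < p_sub)[0]
            if len(hits):
                shifts = rng.integers(1, 4, size=len(hits))
                child_seq[hits] = (child_seq[hits] + shifts) % 4
            if child.is_tip():
                out[child.name] = "".join(_BASES[child_seq])
            else:
                descend(child, child_seq)

    descend(tree, root_seq)
    return out


def pick_clade(tree: TreeNode, taxa: list[str] | None = None, target_size: int = 10) -> list[str]:
    """Deterministically pick a monophyletic clade of roughly ``target_size``
    tips whose members all belong to ``taxa`` (useful for planting selection
    inside one phylogenetic bin).  Returns the clade's tip names."""
    allowed = set(taxa) if taxa is not None else {t.name for t in tree.tips()}
    best: tuple[int, list[str]] | None = None
    for node in tree.non_tips(include_self=False):
        tips = [t.name for t in node.tips()]
        if len(tips) < 2 or not set(tips) <= allowed:
            continue
        badness = abs(len(tips) - target_size)
        if best is None or badness < best[0]:
            best = (badness, sorted(tips))
    if best is None:
        raise ValueError("no suitable clade inside the given taxon set")
    return best[1]


def inject_selection(
    table: FeatureTable,
    tree: TreeNode,
    metadata: pd.Series,
    clade_effects: dict[str, tuple[list[str], float]],
    seed: int = 0,
) -> FeatureTable:
    """Apply deterministic selection to designated clades, per sample group.

    ``clade_effects`` maps a group label to ``(clade_tip_names, multiplier)``;
    the clade is the MRCA subtree of the named tips.  Within each group's
    samples the expected counts of clade members are scaled by the multiplier
    and counts are re-drawn as a multinomial of the original sample depth, so
    depth is conserved exactly.
    """
    rng = np.random.default_rng(seed)
    known_samples = set(table.sample_ids)
    new_counts = table.counts.copy()
    for group, (clade_tips, factor) in clade_effects.items():
        if factor < 0:
            raise ValueError("fitness multiplier must be >= 0")
        members = set(metadata[metadata == group].index) & known_samples
        if not members:
            raise ValueError(f"no samples for group {group!r}")
        try:
            mrca = tree.lca(list(clade_tips))
        except Exception as exc:
            raise ValueError(f"clade tips not resolvable in tree: {exc}") from exc
        clade = {t.name for t in mrca.tips()} | {mrca.name}
        mask = np.array([t in clade for t in table.taxon_ids])
        if not mask.any():
            raise ValueError("clade has no members in the table")
        for s in table.sample_ids:
            if s not in members:
                continue
            row = table.counts.loc[s].to_numpy(dtype=float)
            depth = int(row.sum())
            row[mask] *= factor
            tot = row.sum()
            if tot == 0:
                raise ValueError(f"selection zeroed out sample {s!r}")
            new_counts.loc[s] = rng.multinomial(depth, row / tot)
    return FeatureTable(new_counts, taxonomy=table.taxonomy)


def _write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def make_fixture_bundle(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Write a complete synthetic survey: counts TSV, newick, metadata, FASTA.

    When ``selection_effect != 1`` the first group receives a fitness boost on
    one clade (the subtree spanning the first two taxa), creating the
    deterministic-assembly contrast the null models should detect.
    Deterministic: same config -> byte-identical files.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    meta_pool = simulate_metacommunity(config.S, config.logseries_theta, config.seed)
    tree = simulate_tree(meta_pool.taxon_ids, config.birth_rate, config.seed + 1)
    n_total = config.n_samples * len(config.groups)
    table = simulate_neutral_samples(
        meta_pool, config.m, config.depth, n_total, seed=config.seed + 2
    )
    groups = np.repeat(list(config.groups), config.n_samples)
    metadata = pd.Series(groups, index=table.sample_ids, name="group")
    metadata.index.name = "sample_id"
    if config.selection_effect != 1.0:
        clade_tips = meta_pool.taxon_ids[:2]
        table = inject_selection(
            table,
            tree,
            metadata,
            {config.groups[0]: (clade_tips, config.selection_effect)},
            seed=config.seed + 3,
        )
    seqs = simulate_sequences(tree, config.seq_length, seed=config.seed + 4)

    paths = {
        "table": os.path.join(out_dir, "feature_table.tsv"),
        "tree": os.path.join(out_dir, "tree.nwk"),
        "metadata": os.path.join(out_dir, "metadata.tsv"),
        "fasta": os.path.join(out_dir, "asv_sequences.fasta"),
    }
    write_feature_table(table, paths["table"])
    tree.write(paths["tree"], format="newick")
    metadata.to_frame().to_csv(paths["metadata"], sep="\t", lineterminator="\n")
    _write_fasta(seqs, paths["fasta"])
    return paths


def simulate_planted_core(
    n_groups: int = 4,
    n_samples: int = 50,
    n_blocks: int = 3,
    block_size: int = 20,
    n_spokes: int = 28,
    n_noise: int = 80,
    depth: int = 5000,
    seed: int = 0,
) -> tuple[FeatureTable, pd.Series, str]:
    """Latent-factor fixture with one planted ubiquitous hub taxon.

    Each group has ``n_blocks`` group-specific correlated blocks (network
    modules) plus one shared block driven by a common factor.  The planted
    taxon loads strongly on the shared factor in every group, has high base
    abundance everywhere, and therefore should emerge as a keystone in every
    group network, survive the keystone intersection, pass the core
    prevalence/abundance rule, and rank first among candidates.

    Returns (table, metadata, planted_taxon_id).
    """
    rng = np.random.default_rng(seed)
    groups = [f"G{g + 1}" for g in range(n_groups)]
    S = 1 + n_spokes + block_size * n_blocks + n_noise
    taxa = ["ASV_core"] + [f"ASV{i + 1:03d}" for i in range(S - 1)]
    rows, sample_ids, labels = [], [], []
    for gi, g in enumerate(groups):
        # latent factors: one shared-block factor + per-group block factors
        shared = rng.normal(size=n_samples)
        block_f = rng.normal(size=(n_blocks, n_samples))
        log_lam = np.empty((n_samples, S))
        # planted taxon: high base abundance, tight coupling to shared factor
        log_lam[:, 0] = np.log(40.0) + 1.5 * shared + 0.15 * rng.normal(size=n_samples)
        col = 1
        # shared block: spokes of the planted hub — each member tracks the
        # shared factor strongly enough to correlate with the hub (~0.65) but
        # its own noise keeps member-member correlation (~0.45) below the
        # edge threshold, so the hub's within-module degree stands out
        for _ in range(n_spokes):
            log_lam[:, col] = (
                np.log(8.0) + 1.15 * shared + 1.0 * rng.normal(size=n_samples)
            )
            col += 1
        for b in range(n_blocks):
            for _ in range(block_size):
                log_lam[:, col] = (
                    np.log(6.0)
                    + 1.1 * block_f[b]
                    + 0.35 * rng.normal(size=n_samples)
                )
                col += 1
        # a broad, nearly stable background dominates the sequencing
        # denominator so compositional closure does not erode the planted
        # correlation structure
        for _ in range(n_noise):
            log_lam[:, col] = np.log(30.0) + 0.3 * rng.normal(size=n_samples)
            col += 1
        lam = np.exp(log_lam)
        lam /= lam.sum(axis=1, keepdims=True)
        for i in range(n_samples):
            rows.append(rng.multinomial(depth, lam[i]))
            sample_ids.append(f"{g}_S{i + 1:02d}")
            labels.append(g)
    table = FeatureTable(pd.DataFrame(np.array(rows), index=sample_ids, columns=taxa))
    metadata = pd.Series(labels, index=sample_ids, name="group")
    metadata.index.name = "sample_id"
    return table, metadata, "ASV_core"
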