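"""Synthetic barcode-dataset generator.

The generator reproduces the study protocol end to end: an ultrametric
Yule (pure-birth) species tree of fixed depth in generations, a
multispecies-coalescent gene tree over several individuals per species,
additive normal branch-length noise (variance proportional to branch
length, so the gene tree is no longer ultrametric), and HKY sequence
evolution along the noised tree.

Defaults are the study conditions: 10 species at a depth of 1e6
generations, 10 individuals per species, Ne = 10 000 (diploid 2Ne
convention), noise variance 0.7 x branch length, transition/transversion
ratio 3, base frequencies (A, C, G, T) = (0.3, 0.2, 0.2, 0.3), 650 bp,
25 replicates.  Branch lengths in generations are converted to expected
substitutions per site with a rate chosen so that the species-tree depth
corresponds to 0.1 substitutions/site root-to-tip, which puts pairwise
distances in the range typical of COI barcodes.

Everything is deterministic given (master seed, replicate index): each
replicate stage draws from its own child stream of the master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import dendropy
import numpy as np
from scipy.linalg import expm

from barcodecmp.seqdata import Sequence, SequenceSet

__all__ = [
    "SimulationConfig",
    "HKYParams",
    "Replicate",
    "yule_tree",
    "coalescent_gene_tree",
    "add_branch_noise",
    "evolve_sequences",
    "simulate_dataset",
]

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class HKYParams:
    """HKY85 substitution model: stationary frequencies and a
    transition/transversion rate-ratio kappa."""

    kappa: float
    pi: tuple[float, float, float, float]  # A, C, G, T

    def __post_init__(self) -> None:
        if abs(sum(self.pi) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")

    @classmethod
    def from_tstv(cls, tstv: float, pi: TypingSequence[float]) -> "HKYParams":
        """Build from the expected transition/transversion *ratio* R.

        R relates to the rate-ratio kappa through the frequencies:
        R = kappa (pi_A pi_G + pi_C pi_T) / (pi_R pi_Y).
        """
        pa, pc, pg, pt = pi
        pr, py = pa + pg, pc + pt
        kappa = tstv * pr * py / (pa * pg + pc * pt)
        return cls(kappa=kappa, pi=tuple(float(p) for p in pi))

    @property
    def tstv(self) -> float:
        pa, pc, pg, pt = self.pi
        return self.kappa * (pa * pg + pc * pt) / ((pa + pg) * (pc + pt))

    def rate_matrix(self) -> np.ndarray:
        """Generator Q normalised to one expected substitution per unit time."""
        pi = np.asarray(self.pi)
        q = np.tile(pi, (4, 1))
        # transitions: A<->G (0,2) and C<->T (1,3)
        for i, j in ((0, 2), (2, 0), (1, 3), (3, 1)):
            q[i, j] *= self.kappa
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -float(np.dot(pi, np.diag(q)))
        return q / mu

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1."""
        return expm(self.rate_matrix() * t)


@dataclass(frozen=True)
class SimulationConfig:
    """All stochastic-protocol parameters plus the master seed."""

    n_species: int = 10
    tree_depth: float = 1e6  # generations, root to tip
    individuals_per_species: int = 10
    Ne: float = 10_000.0
    noise_variance_factor: float = 0.7
    seq_length: int = 650
    tstv_ratio: float = 3.0
    base_freqs: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    n_replicates: int = 25
    seed: int = 0
    #: expected substitutions/site accumulated root-to-tip over tree_depth
    root_to_tip_subs: float = 0.1
    #: coalescent convention: pair-coalescence rate 1/(ploidy * Ne)
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValueError("base frequencies must sum to 1")
        for name in ("tree_depth", "Ne", "seq_length", "tstv_ratio", "root_to_tip_subs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_variance_factor < 0:
            raise ValueError("noise_variance_factor must be >= 0")

    @property
    def mutation_rate(self) -> float:
        """Substitutions per site per generation."""
        return self.root_to_tip_subs / self.tree_depth

    @property
    def hky(self) -> HKYParams:
        return HKYParams.from_tstv(self.tstv_ratio, self.base_freqs)

    def stage_rng(self, replicate: int, stage: int) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(replicate, stage))
        return np.random.default_rng(ss)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _yule_events(n_species: int, rng: np.random.Generator):
    """Forward-time pure-birth events: (split times, lineage chosen), plus
    the final stopping time.  Waiting time at k lineages ~ Exp(k)."""
    t = 0.0
    events = []
    k = 2
    while k < n_species:
        t += rng.exponential(1.0 / k)
        events.append((t, int(rng.integers(k))))
        k += 1
    t_end = t + rng.exponential(1.0 / n_species)
    return events, t_end


def yule_tree(n_species: int, depth: float, seed) -> dendropy.Tree:
    """Ultrametric pure-birth species tree rescaled to exact *depth*.

    Tips are labelled S01..Snn in order of creation.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = _as_rng(seed)
    events, t_end = _yule_events(n_species, rng)
    scale = depth / t_end

    ns = dendropy.TaxonNamespace()
    root = dendropy.Node()
    # active lineages: (pending node, start time)
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    for t_split, idx in events:
        node, t0 = active[idx]
        node.edge.length = (t_split - t0) * scale
        c1, c2 = dendropy.Node(), dendropy.Node()
        node.add_child(c1)
        node.add_child(c2)
        active[idx] = (c1, t_split)
        active.append((c2, t_split))
    for i, (node, t0) in enumerate(active):
        node.edge.length = (t_end - t0) * scale
        node.taxon = ns.require_taxon(label=f"S{i + 1:02d}")

    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = True
    return tree


def _node_age(node: dendropy.Node, tree_height: float) -> float:
    """Age (time before present) of a node in an ultrametric tree."""
    depth = 0.0
    while node.parent_node is not None:
        depth += node.edge.length or 0.0
        node = node.parent_node
    return tree_height - depth


def _coalesce_in_population(
    lineages: list[tuple[dendropy.Node, float]],
    t_start: float,
    t_end: float,
    pair_rate_denom: float,
    rng: np.random.Generator,
) -> list[tuple[dendropy.Node, float]]:
    """Coalesce (node, age) lineages between ages t_start and t_end
    (t_end may be inf).  Each pair coalesces at rate 1/pair_rate_denom."""
    lineages = list(lineages)
    t = t_start
    while len(lineages) >= 2:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / pair_rate_denom
        t_next = t + rng.exponential(1.0 / rate)
        if t_next >= t_end:
            break
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        i, j = min(i, j), max(i, j)
        ni, ai = lineages[i]
        nj, aj = lineages[j]
        parent = dendropy.Node()
        ni.edge.length = t_next - ai
        nj.edge.length = t_next - aj
        parent.add_child(ni)
        parent.add_child(nj)
        lineages[i] = (parent, t_next)
        del lineages[j]
        t = t_next
    return lineages


def coalescent_gene_tree(
    species_tree: dendropy.Tree,
    k_per_species: int,
    Ne: float,
    seed,
    ploidy: int = 2,
) -> dendropy.Tree:
    """Multispecies-coalescent gene tree over an ultrametric species tree.

    Within every population (species-tree branch) each pair of lineages
    coalesces at rate 1/(ploidy*Ne) per generation; lineages that have not
    coalesced by the top of the branch enter the parent population, and
    coalescence continues above the species-tree root until one lineage
    remains.  Tip labels are ``<species>_I<idx>``.
    """
    rng = _as_rng(seed)
    denom = ploidy * Ne

    def leaf_depth(n):
        d = 0.0
        while n.parent_node is not None:
            d += n.edge.length or 0.0
            n = n.parent_node
        return d

    height = max(leaf_depth(leaf) for leaf in species_tree.leaf_node_iter())
    ns = dendropy.TaxonNamespace()

    pending: dict[int, list[tuple[dendropy.Node, float]]] = {}
    for node in species_tree.postorder_node_iter():
        age_top = (
            float("inf")
            if node.parent_node is None
            else _node_age(node.parent_node, height)
        )
        if node.is_leaf():
            sp = node.taxon.label
            lineages = []
            for i in range(k_per_species):
                tip = dendropy.Node(taxon=ns.require_taxon(label=f"{sp}_I{i + 1:02d}"))
                lineages.append((tip, 0.0))
            age_bottom = 0.0
        else:
            lineages = []
            for ch in node.child_nodes():
                lineages.extend(pending.pop(id(ch)))
            age_bottom = _node_age(node, height)
        pending[id(node)] = _coalesce_in_population(
            lineages, age_bottom, age_top, denom, rng
        )

    (root_node, _root_age), = pending[id(species_tree.seed_node)]
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root_node)
    tree.is_rooted = True
    return tree


def add_branch_noise(tree: dendropy.Tree, factor: float, seed) -> dendropy.Tree:
    """Perturb every branch length by additive N(0, factor * length) noise.

    Results below a floor of 1e-8 x tree height are clamped (count logged
    and attached to the tree as ``noise_clamped_count``); with factor 0
    the tree is returned unchanged apart from a clone.
    """
    if factor < 0:
        raise ValueError("noise variance factor must be >= 0")
    rng = _as_rng(seed)
    out = tree.clone(depth=1)
    depths = []
    for leaf in out.leaf_node_iter():
        d = 0.0
        node = leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths.append(d)
    height = max(depths) if depths else 0.0
    floor = 1e-8 * height
    clamped = 0
    for node in out.preorder_node_iter():
        if node.parent_node is None:
            continue
        ell = node.edge.length or 0.0
        if ell <= 0 or factor == 0:
            continue
        noisy = ell + rng.normal(0.0, np.sqrt(factor * ell))
        if noisy < floor:
            noisy = floor
            clamped += 1
        node.edge.length = float(noisy)
    out.noise_clamped_count = clamped
    if clamped:
        logger.info("branch noise clamped %d branch(es) to the floor", clamped)
    return out


def evolve_sequences(
    tree: dendropy.Tree,
    hky: HKYParams,
    length: int,
    seed,
    rate: float = 1.0,
) -> SequenceSet:
    """Evolve aligned sequences along a tree under the HKY model.

    Branch lengths are multiplied by *rate* to convert them to expected
    substitutions per site (pass rate=1 if they already are).  The root
    sequence is drawn i.i.d. from the stationary frequencies; each branch
    applies P(l) = exp(Q l) independently per site.  Output sequences are
    gap-free and equal-length, i.e. already aligned.
    """
    rng = _as_rng(seed)
    pi = np.asarray(hky.pi)
    q = hky.rate_matrix()

    root_seq = rng.choice(4, size=length, p=pi)
    states: dict[int, np.ndarray] = {id(tree.seed_node): root_seq}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_states = states[id(node.parent_node)]
        ell = (node.edge.length or 0.0) * rate
        if ell <= 0:
            child = parent_states.copy()
        else:
            p = expm(q * ell)
            cum = np.cumsum(p, axis=1)
            u = rng.random(length)
            child = np.empty(length, dtype=np.int64)
            for s in range(4):
                mask = parent_states == s
                if np.any(mask):
                    child[mask] = np.searchsorted(cum[s], u[mask], side="right")
            np.clip(child, 0, 3, out=child)
        states[id(node)] = child
    seqs = []
    for leaf in tree.leaf_node_iter():
        residues = "".join(_BASES[states[id(leaf)]])
        label = leaf.taxon.label
        species = label.split("_")[0] if "_" in label else None
        seqs.append(Sequence(label=label, residues=residues, species=species))
    return SequenceSet(seqs)


@dataclass
class Replicate:
    """One simulated barcode dataset with full provenance."""

    index: int
    species_tree: dendropy.Tree
    gene_tree: dendropy.Tree  # after branch noise, lengths in generations
    sequences: SequenceSet
    seed_info: dict = field(default_factory=dict)


def simulate_dataset(config: SimulationConfig) -> list[Replicate]:
    """Generate ``config.n_replicates`` independent replicates.

    Each replicate draws its own Yule species tree, coalescent gene tree,
    branch noise and HKY sequences from seed streams derived from
    (master seed, replicate index), so any replicate is reproducible in
    isolation.
    """
    out = []
    for rep in range(config.n_replicates):
        sp = yule_tree(config.n_species, config.tree_depth, config.stage_rng(rep, 0))
        gene = coalescent_gene_tree(
            sp,
            config.individuals_per_species,
            config.Ne,
            config.stage_rng(rep, 1),
            ploidy=config.ploidy,
        )
        noised = add_branch_noise(
            gene, config.noise_variance_factor, config.stage_rng(rep, 2)
        )
        seqs = evolve_sequences(
            noised,
            config.hky,
            config.seq_length,
            config.stage_rng(rep, 3),
            rate=config.mutation_rate,
        )
        out.append(
            Replicate(
                index=rep,
                species_tree=sp,
                gene_tree=noised,
                sequences=seqs,
                seed_info={"master_seed": config.seed, "replicate": rep},
            )
        )
    return out
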