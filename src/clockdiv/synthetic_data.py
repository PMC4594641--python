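"""Synthetic gene families with known ground truth.

The generator emulates a seven-taxon insect study design: a focal mosquito
lineage sister to an Aedes/Culex pair, then Anopheles, Drosophila, a
butterfly and a wasp as successive outgroups.  Per gene, the focal terminal
branch is scaled by a rate multiplier m before sequences are simulated, so
the true direction of any rate shift is known; taxon dropout mimics clock
genes that particular lineages have lost.  Alignments are simulated
directly on the tree (no indels), so trimming and tree inference can be
tested against exact truth.

All randomness flows from one integer seed through a single numpy
Generator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .io_formats import Alphabet, Msa, SequenceRecord, read_newick, write_newick
from .phylo_models import (
    AA_ORDER,
    SubstitutionModel,
    _Propagator,
    base_model,
    discrete_gamma_rates,
)

FOCAL = "Wsmithii"

#: Seven-taxon study topology; branch lengths give a mean pairwise distance
#: near 1 substitution/site (deep divergences) with a 0.1 focal terminal.
DEFAULT_SPECIES_TREE = (
    "((((Wsmithii:0.1,(Aedes:0.12,Culex:0.12):0.05):0.12,Anopheles:0.28):0.15,"
    "Drosophila:0.5):0.12,Danaus:0.62,Nasonia:0.75);"
)

#: The 17 study genes: (name, group).  Sites per gene follow the study's
#: transcript lengths (nucleotides / 3).
DEFAULT_GENES: tuple[tuple[str, str, int], ...] = (
    ("CkIIa", "PTM", 150), ("Clk", "TTFL", 621), ("cry2", "TTFL", 211),
    ("Cul3", "PTM", 590), ("cwo", "TTFL", 771), ("cyc", "TTFL", 283),
    ("dbt", "PTM", 175), ("jet", "PTM", 334), ("kaya", "TTFL", 387),
    ("nmo", "PTM", 710), ("Pdp1", "TTFL", 1027), ("per", "TTFL", 890),
    ("PP2A-B'", "PTM", 240), ("sgg", "PTM", 880), ("slimb", "PTM", 785),
    ("tim", "TTFL", 917), ("vri", "TTFL", 821),
)

#: Lineage-specific gene losses: one TTFL gene missing in the fly, a TTFL
#: pair missing in the wasp.
DEFAULT_DROPOUT: Mapping[str, tuple[str, ...]] = {
    "cry2": ("Drosophila", "Nasonia"),
    "tim": ("Nasonia",),
}


@dataclass(frozen=True)
class GeneSpec:
    name: str
    group: str
    n_sites: int
    focal_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.focal_multiplier < 0:
            raise ValueError("focal multiplier must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    species_tree: str = DEFAULT_SPECIES_TREE
    genes: tuple[GeneSpec, ...] = tuple(GeneSpec(n, g, s) for n, g, s in DEFAULT_GENES)
    model_name: str = "JTT"
    alpha: float | None = 1.0
    dropout: Mapping[str, tuple[str, ...]] = field(default_factory=lambda: dict(DEFAULT_DROPOUT))
    focal: str = FOCAL
    seed: int = 0

    def with_multipliers(self, ttfl: float, ptm: float) -> "SimulationConfig":
        genes = tuple(
            replace(g, focal_multiplier=ttfl if g.group == "TTFL" else ptm) for g in self.genes
        )
        return replace(self, genes=genes)

    def model(self) -> SubstitutionModel:
        m = base_model(self.model_name)
        return replace(m, alpha=self.alpha) if self.alpha is not None else m


@dataclass(frozen=True)
class SyntheticGeneFamily:
    name: str
    group: str
    msa: Msa
    true_tree: str  # newick
    focal_multiplier: float


# ---------------------------------------------------------------------------
# Alignment simulation


def simulate_alignment(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sites: int,
    rng: np.random.Generator | int,
) -> Msa:
    """Simulate a gap-free alignment on the tree under the model.

    Root states are drawn from pi; each branch applies exp(Q * t * r_s)
    where r_s is the site's gamma-category rate (all 1 without +G).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    prop = _Propagator.from_model(model)
    pi = model.frequencies
    if model.alpha is not None:
        cat_rates = discrete_gamma_rates(model.alpha, model.n_categories)
        site_rates = rng.choice(cat_rates, size=n_sites)
    else:
        site_rates = np.ones(n_sites)
    unique_rates = np.unique(site_rates)

    root = tree.seed_node
    states: dict[int, np.ndarray] = {id(root): rng.choice(20, size=n_sites, p=pi)}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        parent = states[id(node.parent_node)]
        t = node.edge.length or 0.0
        child = np.empty(n_sites, dtype=np.int64)
        for r in unique_rates:
            mask = site_rates == r
            P = prop.probs(t * float(r))
            # vectorised categorical draw per parent state
            u = rng.random(mask.sum())
            cdf = np.cumsum(P, axis=1)
            child[mask] = (u[:, None] > cdf[parent[mask]]).sum(axis=1)
        states[id(node)] = child

    records = []
    for leaf in tree.leaf_node_iter():
        codes = states[id(leaf)]
        residues = "".join(AA_ORDER[c] for c in codes)
        records.append(SequenceRecord(leaf.taxon.label, residues, Alphabet.aa))
    records.sort(key=lambda r: r.id)
    return Msa(tuple(records))


def _scaled_gene_tree(species_tree_newick: str, focal: str, multiplier: float,
                      drop: Sequence[str] = ()) -> dendropy.Tree:
    tree = read_newick(species_tree_newick)
    focal_leaf = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == focal:
            focal_leaf = leaf
    if focal_leaf is None:
        raise ValueError(f"focal taxon {focal!r} not in species tree")
    focal_leaf.edge.length = (focal_leaf.edge.length or 0.0) * multiplier
    if drop:
        keep = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon.label not in set(drop)]
        tree.retain_taxa_with_labels(keep)
    return tree


def simulate_clock_study(config: SimulationConfig) -> tuple[list[SyntheticGeneFamily], "pd.DataFrame"]:
    """Simulate the full multi-gene study; returns families + truth table.

    Per gene the focal terminal branch is scaled by the gene's multiplier
    before simulation and dropout taxa are pruned.  Dropping the focal
    taxon is an error (the statistic would be undefined for that gene).
    """
    import pandas as pd

    if not config.genes:
        raise ValueError("config lists no genes")
    for gene, taxa in config.dropout.items():
        if config.focal in taxa:
            raise ValueError(f"dropout would remove the focal taxon for gene {gene}")
    rng = np.random.default_rng(config.seed)
    model = config.model()
    families = []
    truth_rows = []
    for spec in config.genes:
        drop = tuple(config.dropout.get(spec.name, ()))
        tree = _scaled_gene_tree(config.species_tree, config.focal, spec.focal_multiplier, drop)
        msa = simulate_alignment(tree, model, spec.n_sites, rng)
        families.append(
            SyntheticGeneFamily(
                name=spec.name,
                group=spec.group,
                msa=msa,
                true_tree=write_newick(tree),
                focal_multiplier=spec.focal_multiplier,
            )
        )
        truth_rows.append(
            {"gene": spec.name, "group": spec.group, "n_sites": spec.n_sites,
             "focal_multiplier": spec.focal_multiplier, "dropped": ",".join(drop)}
        )
    return families, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Paralog families


def simulate_paralog_family(
    species_tree: str | None = None,
    n_paralogs: int = 3,
    duplication_depths: Sequence[float] = (0.6, 1.2),
    seed: int = 0,
    model: SubstitutionModel | None = None,
    n_sites: int = 400,
    paralog_names: Sequence[str] | None = None,
    focal: str = FOCAL,
):
    """A gene family of ``n_paralogs`` copies of the species tree.

    Successive duplications are stacked above the species-tree root with the
    given stem depths (all must be positive), oldest last, so the final
    paralog clade (e.g. a phr6-4-like photolyase) is the natural outgroup
    for rooting.  The focal taxon's leaf in each copy is relabelled
    ``candidate_i`` and the true candidate -> paralog mapping plus the
    reference map (paralog -> non-focal leaf ids) is returned.

    Returns (msa, true_tree_newick, truth: candidate->paralog,
    reference_map: paralog->leaf ids, outgroup paralog name).
    """
    if n_paralogs < 2:
        raise ValueError("need at least 2 paralogs")
    if len(duplication_depths) != n_paralogs - 1:
        raise ValueError("need n_paralogs - 1 duplication depths")
    if any(d <= 0 for d in duplication_depths):
        raise ValueError("duplication depths must be positive")
    species_tree = species_tree or DEFAULT_SPECIES_TREE
    if paralog_names is None:
        if n_paralogs == 3:
            paralog_names = ("cry1", "cry2", "phr6-4")
        elif n_paralogs == 2:
            paralog_names = ("dbt", "Ck1a")
        else:
            paralog_names = tuple(f"P{i+1}" for i in range(n_paralogs))

    def copy_newick(pname: str) -> str:
        tree = read_newick(species_tree)
        for leaf in tree.leaf_node_iter():
            leaf.taxon.label = f"{leaf.taxon.label}_{pname}"
        nwk = write_newick(tree).rstrip(";")
        if nwk.startswith("("):
            return nwk
        return f"({nwk})"

    backbone = copy_newick(paralog_names[0])
    for depth, pname in zip(duplication_depths, paralog_names[1:]):
        backbone = f"({backbone}:{depth},{copy_newick(pname)}:{depth})"
    true_tree = read_newick(backbone + ";")

    truth = {}
    for i, pname in enumerate(paralog_names):
        for leaf in true_tree.leaf_node_iter():
            if leaf.taxon.label == f"{focal}_{pname}":
                cand = f"candidate_{i+1}"
                leaf.taxon.label = cand
                truth[cand] = pname

    reference_map = {
        p: sorted(
            lf.taxon.label
            for lf in true_tree.leaf_node_iter()
            if lf.taxon.label.endswith(f"_{p}") and lf.taxon.label not in truth
        )
        for p in paralog_names
    }
    model = model or replace(base_model("JTT"), alpha=1.0)
    msa = simulate_alignment(true_tree, model, n_sites, np.random.default_rng(seed))
    return msa, write_newick(true_tree), truth, reference_map, paralog_names[-1]
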