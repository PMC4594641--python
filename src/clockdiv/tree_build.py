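"""Gene-tree construction, patristic distances and clade-based assignment.

Topology comes from neighbor joining on maximum-likelihood pairwise
distances; branch lengths can then be re-optimised on the fixed topology by
coordinate-wise likelihood maximisation.  The divergence statistic consumes
only patristic distances, and externally built trees can be dropped in as
Newick at any point, so a full ML topology search is intentionally not
performed here.

Paralog disambiguation roots the gene tree on a designated outgroup clade
and assigns each focal-taxon candidate to the reference gene whose leaves
it nests among.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from .io_formats import Msa, read_newick
from .phylo_models import (
    AA_INDEX,
    LikelihoodResult,
    SubstitutionModel,
    _Propagator,
    encode_alignment,
    prune_loglik,
)

logger = logging.getLogger(__name__)

DISTANCE_BOUNDS = (1e-8, 20.0)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances over an ordered taxon list."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and nonnegative")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def to_tsv(self) -> str:
        header = "\t" + "\t".join(self.taxa)
        lines = [header]
        for i, t in enumerate(self.taxa):
            lines.append(t + "\t" + "\t".join(f"{x:.6f}" for x in self.d[i]))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "DistanceMatrix":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        taxa = tuple(lines[0].split("\t")[1:])
        d = np.array([[float(x) for x in ln.split("\t")[1:]] for ln in lines[1:]])
        return cls(taxa, d)


# ---------------------------------------------------------------------------
# ML pairwise distances


def ml_pairwise_distance(
    a_codes: np.ndarray | str,
    b_codes: np.ndarray | str,
    model: SubstitutionModel,
    prop: _Propagator | None = None,
) -> float:
    """ML distance between two aligned sequences under the model.

    Maximises sum_s log(pi(x_s) P_t(x_s, y_s)) over t in [1e-8, 20] by
    bounded 1-D search; sites where either sequence is missing are skipped.
    Accepts residue strings or pre-encoded integer code arrays.
    """
    if isinstance(a_codes, str):
        a_codes = np.array([AA_INDEX.get(c, -1) for c in a_codes.upper()])
    if isinstance(b_codes, str):
        b_codes = np.array([AA_INDEX.get(c, -1) for c in b_codes.upper()])
    ok = (a_codes >= 0) & (b_codes >= 0)
    if not ok.any():
        raise ValueError("no jointly observed sites between the two sequences")
    counts = np.zeros((20, 20))
    np.add.at(counts, (a_codes[ok], b_codes[ok]), 1.0)
    if prop is None:
        prop = _Propagator.from_model(model)
    logpi = np.log(model.frequencies)

    def neg_loglik(t: float) -> float:
        P = prop.probs(t)
        return -float((counts * (logpi[:, None] + np.log(np.maximum(P, 1e-300)))).sum())

    # identical sequences: optimum is at the lower bound
    if counts.trace() == counts.sum():
        return DISTANCE_BOUNDS[0]
    res = minimize_scalar(neg_loglik, bounds=DISTANCE_BOUNDS, method="bounded", options={"xatol": 1e-7})
    return float(res.x)


def ml_distance_matrix(msa: Msa, model: SubstitutionModel) -> DistanceMatrix:
    codes = encode_alignment(msa)
    prop = _Propagator.from_model(model)
    n = len(msa.records)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = ml_pairwise_distance(codes[i], codes[j], model, prop)
    return DistanceMatrix(tuple(msa.ids), d)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion break toward the lexicographically smallest
    taxon pair (cluster names are compared by their sorted leaf labels).
    Negative branch estimates are clamped to 0 with the deficit moved to the
    sibling branch so patristic path lengths are preserved.
    """
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        half = dm.d[0, 1] / 2
        return read_newick(f"({_quote(dm.taxa[0])}:{half:.10g},{_quote(dm.taxa[1])}:{half:.10g});")

    # working state: list of (sort_key, newick_subtree); distances in a dict
    labels = list(dm.taxa)
    subtrees = {t: _quote(t) for t in labels}
    sortkey = {t: t for t in labels}
    dist = {}
    for i, j in itertools.combinations(range(n), 2):
        dist[frozenset((labels[i], labels[j]))] = float(dm.d[i, j])

    active = sorted(labels)
    counter = itertools.count()
    while len(active) > 3:
        r = len(active)
        totals = {a: sum(dist[frozenset((a, b))] for b in active if b != a) for a in active}
        best = None
        for a, b in itertools.combinations(sorted(active, key=lambda x: sortkey[x]), 2):
            q = (r - 2) * dist[frozenset((a, b))] - totals[a] - totals[b]
            key = (q, tuple(sorted((sortkey[a], sortkey[b]))))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        dab = dist[frozenset((a, b))]
        la = 0.5 * dab + (totals[a] - totals[b]) / (2 * (r - 2))
        lb = dab - la
        la, lb = _clamp_pair(la, lb)
        new = f"__node{next(counter)}"
        subtrees[new] = f"({subtrees[a]}:{la:.10g},{subtrees[b]}:{lb:.10g})"
        sortkey[new] = min(sortkey[a], sortkey[b])
        for c in active:
            if c in (a, b):
                continue
            dist[frozenset((new, c))] = 0.5 * (
                dist[frozenset((a, c))] + dist[frozenset((b, c))] - dab
            )
        active = sorted((x for x in active if x not in (a, b)), key=lambda x: sortkey[x])
        active.append(new)

    a, b, c = sorted(active, key=lambda x: sortkey[x])
    dab = dist[frozenset((a, b))]
    dac = dist[frozenset((a, c))]
    dbc = dist[frozenset((b, c))]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    la, lb, lc = _clamp_triple(la, lb, lc)
    newick = (
        f"({subtrees[a]}:{la:.10g},{subtrees[b]}:{lb:.10g},{subtrees[c]}:{lc:.10g});"
    )
    return read_newick(newick)


def _quote(label: str) -> str:
    if any(ch in label for ch in "()[]:;, '\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def _clamp_pair(la: float, lb: float) -> tuple[float, float]:
    if la < 0:
        lb = max(lb + la, 0.0)
        la = 0.0
    elif lb < 0:
        la = max(la + lb, 0.0)
        lb = 0.0
    return la, lb


def _clamp_triple(la: float, lb: float, lc: float) -> tuple[float, float, float]:
    vals = [la, lb, lc]
    for i in range(3):
        if vals[i] < 0:
            deficit = vals[i]
            vals[i] = 0.0
            j = max((k for k in range(3) if k != i), key=lambda k: vals[k])
            vals[j] = max(vals[j] + deficit, 0.0)
    return tuple(vals)  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# Branch-length optimisation on a fixed topology


def optimize_branch_lengths(
    tree: dendropy.Tree,
    msa: Msa,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_sweeps: int = 20,
) -> tuple[dendropy.Tree, LikelihoodResult]:
    """Coordinate-wise ML branch lengths on the fixed topology.

    Each sweep optimises every branch in turn by bounded 1-D search; sweeps
    stop when the log-likelihood improves by less than ``tol``.  The
    log-likelihood never decreases between sweeps.  Returns (tree, final
    likelihood); warns when the sweep cap is reached.
    """
    tree = tree.clone(depth=1)
    edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    best = prune_loglik(tree, msa, model).loglik
    for sweep in range(max_sweeps):
        sweep_start = best
        for edge in edges:
            old = edge.length or 0.0

            def neg(t: float) -> float:
                edge.length = t
                return -prune_loglik(tree, msa, model).loglik

            res = minimize_scalar(neg, bounds=DISTANCE_BOUNDS, method="bounded", options={"xatol": 1e-6})
            if -res.fun > best:  # accept only improving moves
                edge.length = float(res.x)
                best = float(-res.fun)
            else:
                edge.length = old
        if best - sweep_start < tol:
            break
    else:
        logger.warning("branch-length optimisation hit the sweep cap (%d)", max_sweeps)
    return tree, prune_loglik(tree, msa, model)


# ---------------------------------------------------------------------------
# Patristic distances


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Sum of branch lengths along the path between every leaf pair."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((lf.taxon for lf in tree.leaf_node_iter()), key=lambda t: t.label)
    labels = tuple(t.label for t in taxa)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Rooting and clade assignment


def root_tree(
    tree: dendropy.Tree,
    outgroup_ids: Sequence[str] | str,
    ignore: Sequence[str] = (),
) -> dendropy.Tree:
    """Root on the branch separating the outgroup from everything else.

    The outgroup must be a single leaf or form one side of an edge
    bipartition of the unrooted tree; the root lands at the midpoint of that
    edge.  Patristic distances are unchanged by rooting.

    Leaves named in ``ignore`` (typically unassigned focal-taxon candidates,
    which may legitimately nest inside the outgroup clade) are disregarded
    when checking monophyly; when several edges qualify, the one placing the
    most ignored leaves with the outgroup is used.
    """
    if isinstance(outgroup_ids, str):
        outgroup_ids = [outgroup_ids]
    out = frozenset(outgroup_ids)
    ignored = frozenset(ignore) - out
    tree = tree.clone(depth=1)
    if len(tree.seed_node.child_nodes()) == 2:
        tree.deroot()  # merge the two seed edges into the true unrooted branch
    all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    missing = out - all_leaves
    if missing:
        raise ValueError(f"outgroup leaves not in tree: {sorted(missing)}")
    relevant = all_leaves - ignored
    target = None
    target_size = -1
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        visible = below & relevant
        if visible == out:
            size = len(below)
        elif visible == relevant - out:
            size = len(all_leaves - below)
        else:
            continue
        if size > target_size:
            target, target_size = node, size
    if target is None:
        offenders = _non_monophyly_witness(tree, out)
        raise ValueError(
            f"outgroup {sorted(out)} is not monophyletic; intruding leaves: {offenders}"
        )
    length = target.edge.length or 0.0
    tree.reroot_at_edge(target.edge, length1=length / 2, length2=length / 2, update_bipartitions=False)
    tree.is_rooted = True
    return tree


def _non_monophyly_witness(tree: dendropy.Tree, out: frozenset) -> list[str]:
    tree.is_rooted = True  # mrca() is seed-relative either way; silence the warning
    mrca = tree.mrca(taxon_labels=list(out))
    return sorted(
        lf.taxon.label for lf in mrca.leaf_iter() if lf.taxon.label not in out
    )


def assign_by_clade(
    rooted_tree: dendropy.Tree,
    candidate_ids: Sequence[str],
    reference_map: Mapping[str, Sequence[str]],
) -> dict[str, str]:
    """Assign candidates to reference genes by smallest enclosing clade.

    A candidate is assigned to gene g iff the smallest clade containing the
    candidate and at least one reference leaf contains only g's reference
    leaves among all references; otherwise it is reported as ``ambiguous``.
    Each gene's reference leaves must be mutually monophyletic once
    candidates are ignored (error otherwise, naming the offenders).
    """
    gene_of_ref: dict[str, str] = {}
    for gene, leaves in reference_map.items():
        for leaf in leaves:
            gene_of_ref[leaf] = gene
    ref_leaves = set(gene_of_ref)

    leaf_nodes = {lf.taxon.label: lf for lf in rooted_tree.leaf_node_iter()}
    missing = ref_leaves - set(leaf_nodes)
    if missing:
        raise ValueError(f"reference leaves not in tree: {sorted(missing)}")

    # reference-restricted monophyly check per gene
    for gene, leaves in reference_map.items():
        mrca = rooted_tree.mrca(taxon_labels=list(leaves))
        inside = {
            lf.taxon.label
            for lf in mrca.leaf_iter()
            if lf.taxon.label in ref_leaves
        }
        intruders = inside - set(leaves)
        if intruders:
            raise ValueError(
                f"reference genes are not mutually monophyletic: leaves of "
                f"{sorted({gene_of_ref[x] for x in intruders})} intrude into the "
                f"{gene} clade ({sorted(intruders)})"
            )

    out: dict[str, str] = {}
    for cand in candidate_ids:
        node = leaf_nodes.get(cand)
        if node is None:
            raise ValueError(f"candidate {cand!r} not in tree")
        assignment = "ambiguous"
        anc = node.parent_node
        while anc is not None:
            genes_below = {
                gene_of_ref[lf.taxon.label]
                for lf in anc.leaf_iter()
                if lf.taxon.label in ref_leaves
            }
            if genes_below:
                if len(genes_below) == 1:
                    assignment = genes_below.pop()
                break
            anc = anc.parent_node
        out[cand] = assignment
    return out


# ---------------------------------------------------------------------------
# Convenience: alignment -> tree -> patristic matrix


def gene_tree_from_alignment(
    msa: Msa,
    model: SubstitutionModel,
    refine_branch_lengths: bool = False,
) -> dendropy.Tree:
    """NJ topology on ML pairwise distances, optional ML branch refinement."""
    dm = ml_distance_matrix(msa, model)
    tree = nj_tree(dm)
    if refine_branch_lengths:
        tree, _ = optimize_branch_lengths(tree, msa, model)
    return tree
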