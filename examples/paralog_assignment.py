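"""Disambiguate a cryptochrome-like paralog family by gene-tree clades.

Simulates a three-paralog family (cry1/cry2/phr6-4-like) across the seven
study taxa, rebuilds the gene tree from the sequences, roots it on the
photolyase-like outgroup clade and assigns each focal-taxon candidate
contig to the paralog whose reference sequences it nests among.
"""

from clockdiv.synthetic_data import SimulationConfig, simulate_paralog_family
from clockdiv.tree_build import assign_by_clade, ml_distance_matrix, nj_tree, root_tree

msa, true_tree, truth, reference_map, outgroup = simulate_paralog_family(
    n_paralogs=3, duplication_depths=(0.6, 1.2), seed=7
)
print(f"family of {len(msa.records)} sequences; outgroup paralog: {outgroup}")

model = SimulationConfig().model()
tree = nj_tree(ml_distance_matrix(msa, model))
rooted = root_tree(tree, reference_map[outgroup], ignore=sorted(truth))
assignments = assign_by_clade(rooted, sorted(truth), reference_map)

for cand in sorted(assignments):
    flag = "ok" if assignments[cand] == truth[cand] else "WRONG"
    print(f"  {cand} -> {assignments[cand]:8s} (truth: {truth[cand]:8s}) {flag}")
print(
    "\nEach candidate lands in exactly one reference clade, mirroring how"
    "\nsingle best-hit searches that tie across a multi-gene family are"
    "\nresolved by the gene tree instead."
)
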