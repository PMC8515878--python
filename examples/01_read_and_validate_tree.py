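"""Read a time-calibrated tree and check it is usable for SSE inference.

Builds a small Newick string, parses it, and runs the ultrametricity
check that every downstream likelihood assumes.
"""

from pollendiv import read_tree, validate_ultrametric, write_newick

text = "(((Eucera_a:4,Eucera_b:4):6,Synhalonia_c:10):5,Tetralonia_d:15);"
tree = read_tree(text)
print(f"tips: {tree.n_tips}, internal nodes: {len(tree.postorder)}")
print(f"crown age: {tree.height:.1f} Myr, total branch length: "
      f"{tree.total_branch_length:.1f} Myr")

report = validate_ultrametric(tree, rel_tol=1e-4)
print(f"ultrametric: {report.passed} "
      f"(max relative depth deviation {report.max_relative_deviation:.2e})")
# a passed check means all tips are contemporaneous: the tree is a
# chronogram on which branch lengths are absolute time
print(write_newick(tree).strip())
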