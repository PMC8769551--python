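"""Score one query region at different assignment confidences.

A density map rarely pins every side chain to one residue; positions are
assigned ambiguity categories instead.  A match scores the inverse of the
category size, so a confident singleton is worth 20x a root-level assignment.
"""

from abseek import align_segment, default_tree

tree = default_tree()
subject = "WKDSA"

for label, codes in [
    ("singleton leaves (fully confident)", tuple(subject)),
    ("structural classes (one level up)", ("ARO", "LNB", "MHL", "SML", "SML")),
    ("root everywhere (no information)", (tree.root_code,) * 5),
]:
    aln = align_segment(tree, codes, subject, max_shift=0)
    print(f"{label:38s} match={aln.match_string} score={aln.score:.2f}")

print()
print("All three queries match every position of", subject, "-- the score is")
print("the amount of structural information behind the match: 5.00 means five")
print("uniquely assigned residues, 0.25 means the map only supported 1/20 per")
print("position (5 x 0.05).")
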