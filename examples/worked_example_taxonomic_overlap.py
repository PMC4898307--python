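"""Why drug-class matching matters when comparing guidelines to labels.

A heart-disease guideline recommends the *class* "aldosterone
antagonists" (ATC C03DA) while a product label names the specific drug
eplerenone (C03DA04).  On exact strings the two association sets share
nothing; rolling codes through the ATC hierarchy recovers the overlap.
"""

from guidelink import Association, AssociationSet, compute_overlap

cpg = AssociationSet(associations=(
    Association("aldosterone antagonists", "ischemic heart disease", "CPG",
                frozenset({"guideline-1"}), ("C03DA",)),
    Association("pneumococcal vaccines", "heart failure", "CPG",
                frozenset({"guideline-2"}), ("J07AL",)),
), side="CPG")

spl = AssociationSet(associations=(
    Association("eplerenone", "ischemic heart disease", "SPL",
                frozenset({"label-1"}), ("C03DA04",)),
), side="SPL")

for use_taxonomy in (False, True):
    parts = compute_overlap(cpg, spl, use_taxonomy=use_taxonomy)
    both, cpg_only, spl_only = parts["ALL"].counts
    mode = "with taxonomy" if use_taxonomy else "exact strings"
    print(f"{mode:>14}: both={both}  cpg_only={cpg_only}  spl_only={spl_only}")

group = compute_overlap(cpg, spl, use_taxonomy=True)["ischemic heart disease"].both[0]
print("merged group members:", sorted(m.drug_key for m in group.members))
print("most specific representative:", [r.drug_key for r in group.representatives])
# both goes 0 -> 1: the class association and the drug association are
# the same evidence once the C03DA ancestry links them; the merged
# group is reported by its most specific member, eplerenone.
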