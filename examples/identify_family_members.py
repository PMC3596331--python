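"""Annotate a small synthetic proteome and call family membership.

Builds 9 ground-truthed members (3 per phylogenetic group) and 8 decoys,
runs the full annotation pipeline, and prints the membership table.
A protein is a family member only if it carries >= 2 ankyrin repeats AND
one accepted C3HC4 RING domain; the group column comes from the RING's
ligand 6-7 spacing and signature residues.
"""

from xb3scan import annotate_proteome, summarize_cohort
from xb3scan.synthetic_data import SyntheticProteinSpec, make_decoy, make_member

proteins = []
for i, group in enumerate(["I", "II", "III"] * 3):
    proteins.append(make_member(SyntheticProteinSpec(group=group, n_ank=2 + i % 6, seed=i)))
for i, kind in enumerate(["ring_only", "single_ank", "c3h2c3", "shuffled"] * 2):
    proteins.append(make_decoy(kind, seed=50 + i))

annotations = annotate_proteome([p.record for p in proteins])

print(f"{'protein':<28} {'member':<7} {'ANKs':<5} {'class':<6} {'group':<6} {'pI':<5}")
for ann in annotations:
    print(
        f"{ann.id:<28} {str(ann.is_member).lower():<7} {ann.ank.count:<5} "
        f"{ann.ank.ank_class:<6} {ann.group or '-':<6} {ann.pi:.2f}"
    )

summary = summarize_cohort(annotations)
print(f"\n{summary.n_members}/{summary.n_proteins} proteins are family members")
print("per group:", {k: v for k, v in summary.by_group.items() if v})
print("per ANK class:", {k: v for k, v in summary.by_class.items() if v})
# Every decoy is rejected with a reason (too few ANKs, or no C3HC4 RING);
# members land in the group their RING spacing encodes.
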