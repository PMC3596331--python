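"""Parse a C3HC4 RING region and walk through the group classification.

The 40-residue exemplar below is a minimal group III RING: eight metal
ligands (C,C,C,H,C,C,C,C) with the family's fixed spacings (2 residues
between ligands 1-2 and 7-8, 11 between 2-3, 7 between 3-6) and the
group III hallmarks: 11 residues between ligands 6-7 and Val before
ligand 8.
"""

from xb3scan import GROUP_III_EXEMPLAR, ProteinRecord, classify_group, scan_ring

record = ProteinRecord(id="exemplar", seq=GROUP_III_EXEMPLAR)
print("sequence:", record.seq)

(domain,) = scan_ring(record)
print("ligand positions (1-based):", domain.ligand_pos)
print("ligand residues:", "".join(domain.ligand_res))
print(
    f"spacings: d12={domain.d12} d23={domain.d23} d36={domain.d36} "
    f"d67={domain.d67} d78={domain.d78}"
)

call = classify_group(domain)
print("group:", call.group)
for line in call.trace:
    print("  trace:", line)
# d67=11 is diagnostic for group III; a d67 of 19-20 would force group I,
# 24 group II, and 21-23 is resolved by the residue before ligand 8 (L vs F).
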