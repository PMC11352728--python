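"""Steric fingerprint of a prochiral olefin from its SMILES.

Embeds methyl 2-acetamidoacrylate in 3D, locates the C=C bond, enumerates
the four substituent anchors R1-R4, and prints the 6 buried volumes + 12
sterimol parameters that make up the 18-value fingerprint.
"""

from asymcat import embed_from_smiles, locate_olefin, substrate_fingerprint

smiles = "C=C(NC(C)=O)C(=O)OC"
structure = embed_from_smiles(smiles, seed=0)
site = locate_olefin(structure)
print(f"substrate {smiles}: {structure.n_atoms} atoms")
print(f"olefin carbons C1={site.C1} C2={site.C2}; anchors R1-R4 = {site.R}\n")

fp = substrate_fingerprint(structure, site)
for name, value in fp.as_series().items():
    print(f"{name:>10}  {value:8.3f}")

# vbur_* values are % of a 3.5 A probe sphere buried by the rest of the
# molecule around each position (crowding); the C-R sterimol triples give
# each substituent's minimal width (B1), maximal width (B5) and length (L)
# in Angstrom along its attachment axis.
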