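"""Digest a synthetic proteome and summarise peptide statistics.

Prints, per protease, the median peptide length and the median count of
labelable residues per peptide — the number of same-colour fluorophores a
camera must resolve on one molecule (small medians are good news).
"""

from fluorosim import (
    digest,
    generate_synthetic_proteome,
    human_like_composition,
    labelable_count_stats,
    peptide_length_stats,
)

proteome = generate_synthetic_proteome(
    200, composition=human_like_composition(), seed=0
)

for protease in ["gluc", "cnbr", "trypsin"]:
    peptides = [p for prot in proteome for p in digest(prot, protease)]
    lengths = peptide_length_stats(peptides)
    lysines = labelable_count_stats(peptides, {"K"})
    acidic = labelable_count_stats(peptides, {"D", "E"})
    print(
        f"{protease:8s} {len(peptides):6d} peptides | median length {lengths.median:3d}"
        f" | median K per peptide {lysines.median}"
        f" | median D/E per peptide {acidic.median}"
    )

print()
print("Cleaving after rare residues (Met, via CNBr) gives long peptides; after")
print("common ones (Glu, Lys/Arg) gives short ones with fewer labels each.")
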