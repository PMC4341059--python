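"""Encode toy peptides into their ideal fluorosequences.

Each labeled residue produces a luminosity drop at the Edman cycle equal to its
position, provided it sits before the surface anchor. The printed tuple form
"(K,2)" means "the K channel dropped at cycle 2"; the pattern form "xKxxK" shows
one character per cycle.
"""

from fluorosim import Peptide, encode_ideal, toy_fixtures

peptides = {
    "X": Peptide(toy_fixtures()["X"], "PX", anchor_index=5),       # GKEGC, Cys anchor
    "Y": Peptide(toy_fixtures()["Y"], "PY", anchor_index=6),       # GKGKEC, Cys anchor
    "fig1": Peptide(toy_fixtures()["fig1"], "PF", anchor_index=None),  # WKKAY, free
}

for name, pep in peptides.items():
    scheme = "K" if name != "fig1" else "K+Y+W"
    read = encode_ideal(pep, scheme, 30)
    print(f"{name:5s} {pep.sequence:8s} scheme {scheme:6s} -> "
          f"{read.to_string():22s} pattern {read.pattern(len(pep.sequence))}")

print()
print("Peptide X gives the single-drop read (K,2); Y gives (K,2),(K,4) — the")
print("prefix they share is exactly why a prefix trie stores reads compactly.")
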