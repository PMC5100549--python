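"""Design a peptide microarray library from toxin sequences.

Two short homologous toxins are tiled into overlapping 12-mers (step 2,
with a forced terminal window so the C-terminus is covered), pooled into
a globally unique peptide set, expanded with every single-position
alanine substitution, and laid out at seeded random array positions with
five replicates per wild-type peptide.
"""
from peptarray import build_library, read_toxins

FASTA = """\
>TOX1 species=Example_mamba
RICYNHQSTTRATTKSCEENSCYKKYWRDHRG
>TOX2 species=Example_cobra
RICYNHQSTTPATTKSCEENSCYKKYWRDHRG
"""

toxins = read_toxins(FASTA)
library = build_library(toxins, seed=0)

print(f"toxins:              {len(toxins)}")
print(f"unique 12-mers:      {len(library.unique_wt)}")
print(f"redundant removed:   {library.redundancy_count}")
print(f"alanine variants:    {len(library.variants)}")
print(f"array spots:         {library.n_spots}  "
      f"(= 5 x {len(library.unique_wt)} wt + {len(library.variants)} variants)")

shared = [t for t in library.unique_wt if len(t.occurrences) > 1]
print(f"peptides shared by both toxins: {len(shared)}")
print("\nfirst layout spots (position, peptide, class):")
for spot in library.layout[:5]:
    print(" ", spot)
print("\nThe shared peptides show how homologous toxins are measured by the")
print("same physical spots; the redundancy count is what global")
print("deduplication removed before synthesis.")
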