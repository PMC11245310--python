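"""Motif conservation depth from a pseudocount PSSM and ortholog alignments.

A PSSM built from the experimentally verified binder motifs scores each
ortholog's motif window; scores are normalized to the human reference and
averaged per taxonomic level (Mammalia -> Vertebrata -> Eumetazoa ->
Unicellular eukaryotes). A motif is conserved at a level when the mean
normalized score exceeds 0.5; its depth is the most distal conserved level.
"""

from affinomap import build_pssm, conservation_depth
from affinomap.conservation import LEVELS
from affinomap.synthetic import random_motif_family, simulate_orthologs

# the verified binder set: 15-mer frames, PxxP core at positions 7-10
family = random_motif_family(n=30, seed=1)
pssm = build_pssm(family, B=5)
print(f"PSSM from {pssm.n_motifs} motifs, {pssm.length} positions, pseudocount B=5")

reference = family[0]
print(f"Reference (human) motif: {reference}\n")

for planted in ("Mammalia", "Eumetazoa", "Unicellular"):
    oset = simulate_orthologs(reference, planted_depth=planted, seed=3)
    res = conservation_depth(oset, pssm, min_orthologs=3, threshold=0.5)
    scores = ", ".join(
        f"{lv}: {res.level_scores[lv]:.2f} ({res.level_status[lv]})" for lv in LEVELS
    )
    print(f"motif destroyed beyond {planted}:")
    print(f"  level scores  {scores}")
    print(f"  -> conservation depth: {res.depth}\n")

print("A deeply conserved binding motif (depth Unicellular) has kept its")
print("PSSM-recognizable sequence across ~1 billion years of divergence.")
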