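"""One-off generator for src/twinpzm/data/signatures_30_synthetic.tsv.

Synthetic stand-in for a 30-signature COSMIC v2-style probability
table. Structured analogues:
  - Signature 1: deamination-like, mass concentrated on N[C>T]G;
  - Signature 5: clock-like, T>C dominant with C>T second, flat flanks;
  - Signatures 3 and 16: near-flat (to keep realistic confusability);
  - others: seeded Dirichlet draws with varying sparsity, some zeros.
Deterministic (seed 7).
"""

import sys

sys.path.insert(0, "src")
import numpy as np

from twinpzm.motifs import MOTIFS, split_motif

rng = np.random.default_rng(7)
P = np.zeros((96, 30))

# Signature 1 analogue: C>T at CpG
p = np.full(96, 0.4 / 92)
for i, m in enumerate(MOTIFS):
    sub, five, three = split_motif(m)
    if sub == "C>T" and three == "G":
        p[i] = 0.6 / 4
P[:, 0] = p * rng.uniform(0.9, 1.1, 96)

# Signature 5 analogue: clock-like, T>C then C>T dominant, flat within class
class_mass = {"C>A": 0.07, "C>G": 0.05, "C>T": 0.30, "T>A": 0.07, "T>C": 0.41, "T>G": 0.10}
p = np.array([class_mass[split_motif(m)[0]] / 16 for m in MOTIFS])
P[:, 4] = p * rng.uniform(0.85, 1.15, 96)

# Signatures 3 and 16 analogues: near-flat
for j in (2, 15):
    P[:, j] = rng.dirichlet(np.full(96, 60.0))

# remaining signatures: Dirichlet with varying concentration, some zeros
for j in range(30):
    if P[:, j].sum() > 0:
        continue
    alpha = rng.uniform(0.15, 0.9)
    p = rng.dirichlet(np.full(96, alpha))
    if j % 3 == 0:  # introduce genuine zeros in a third of them
        cut = np.quantile(p, 0.10)
        p = np.where(p <= cut, 0.0, p)
    P[:, j] = p

P /= P.sum(axis=0, keepdims=True)
P = np.round(P, 6)

rows = []
header = ["Substitution Type", "Trinucleotide", "Somatic Mutation Type"] + [
    f"Signature {j + 1}" for j in range(30)
]
for i, m in enumerate(MOTIFS):
    sub, five, three = split_motif(m)
    ref = sub[0]
    tri = five + ref + three
    rows.append([sub, tri, m] + [f"{P[i, j]:.6f}" for j in range(30)])

with open("src/twinpzm/data/signatures_30_synthetic.tsv", "w") as fh:
    fh.write("\t".join(header) + "\n")
    for r in rows:
        fh.write("\t".join(r) + "\n")

print("column sums:", P.sum(axis=0).min(), P.sum(axis=0).max())
print("zeros per signature:", (P == 0).sum(axis=0))
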