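"""Numerator relationship matrices from a toy pedigree.

Builds A, its sparse inverse, and inbreeding coefficients for a pedigree
with a full-sib mating, the classic hand-checkable case.
"""

import numpy as np

from ssgblup import Pedigree, build_A, build_A_inverse, inbreeding

ped = Pedigree.from_records([
    ("SIRE", "0", "0"),
    ("DAM", "0", "0"),
    ("SON", "SIRE", "DAM"),
    ("DAUGHTER", "SIRE", "DAM"),
    ("INBRED", "SON", "DAUGHTER"),  # full-sib mating
])

A = build_A(ped)
F = inbreeding(ped)
Ainv = build_A_inverse(ped)

np.set_printoptions(precision=3, suppress=True)
print("A (additive relationships):")
print(A.dense())
print("\ninbreeding F:", F)
print("\nA^-1 (Henderson's rules, sparse):")
print(Ainv.dense())
print("\nmax |A @ A^-1 - I| =", np.abs(A.dense() @ Ainv.dense() - np.eye(5)).max())

# The INBRED animal's diagonal is 1.25: its parents are full sibs
# (relationship 0.5), so F = 0.25. The product check confirms the sparse
# inverse matches the dense tabular matrix to machine precision.
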