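"""Amino-acid alphabet and the physicochemical residue ordering.

The 20 canonical residues are indexed, throughout the package, by a fixed
ordering derived from the isoelectric point and ionization equilibrium
constants of the amino acids (descending):

    D, E, C, N, M, F, Q, Y, S, P, T, V, L, I, W, H, G, A, R, K

Substitution/contact matrices, adjacency profiles and the dipeptide vector
all use this basis, so a residue's row/column index is its position here.
"""

from __future__ import annotations

#: Physicochemical descending order (isoelectric point / pK based).
PHYSICOCHEMICAL_ORDER: str = "DECNMFQYSPTVLIWHGARK"

#: The canonical residues as a set, for validation.
CANONICAL_AA: frozenset[str] = frozenset(PHYSICOCHEMICAL_ORDER)

#: Residue one-letter code -> index in the physicochemical basis.
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(PHYSICOCHEMICAL_ORDER)}

#: Ambiguity / non-canonical codes commonly seen in FASTA files.
NON_CANONICAL: frozenset[str] = frozenset("XBZUOJ*-.")

N_AA: int = 20
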