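"""Shared alphabets, codon tables and pinned defaults.

The positional amino-acid profiles defined here parametrize the default
"mouse-like" CDR3 background used throughout the package.  They are a
pinned, documented stand-in for a mechanistic V(D)J recombination model:
conserved cysteine at the first junction position, a phenylalanine-rich
last position, germline-flavoured profiles near both ends (including the
hydrophobic anchors contributed by the J segment) and a generic
insertion-like profile in the middle.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

#: Canonical amino-acid alphabet (alphabetical one-letter codes).
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Hydrophobic residues used by the hydrophobicity score and index.
HYDROPHOBIC_AA = frozenset("CFILMWY")

#: Constant-region primer sequences used to anchor raw reads.
ALPHA_CONSTANT_PRIMER = "CAGCAGGTTCTGGGTTCTGGATG"
BETA_CONSTANT_PRIMER = "TGGGTGGAGTCACATTTCTCAGATCCT"

#: Default UMI length (basepairs).
UMI_LENGTH = 12

#: Maturation-stage labels of the seven sorted subsets plus synthetic data.
STAGE_LABELS = (
    "DP pre", "DP pos", "DP dbn",
    "CD4 apo", "CD8 apo", "CD4 spl", "CD8 spl",
    "synthetic",
)

# ---------------------------------------------------------------------------
# Codon machinery (standard genetic code via biopython)
# ---------------------------------------------------------------------------

#: amino acid -> tuple of synonymous codons (standard code).
SYNONYMOUS_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    SYNONYMOUS_CODONS.setdefault(_aa, ())
    SYNONYMOUS_CODONS[_aa] += (_codon,)

STOP_CODONS = tuple(standard_dna_table.stop_codons)

#: codon -> amino acid ('*' for stop).
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _codon in STOP_CODONS:
    CODON_TO_AA[_codon] = "*"


def translate_nt(seq: str) -> str:
    """Translate a nucleotide string (length multiple of 3) to amino acids.

    Stop codons become ``*``; raises ``ValueError`` on a frameshifted input.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    try:
        return "".join(CODON_TO_AA[seq[i:i + 3]] for i in range(0, len(seq), 3))
    except KeyError as exc:  # non-ACGT character
        raise ValueError(f"cannot translate codon {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# Default germline gene labels
# ---------------------------------------------------------------------------
# Reduced single-allele gene sets are configuration; the shipped defaults
# match the reduced mouse sets (76 V / 51 J for the alpha chain and
# 26 V / 14 J for the beta chain, D genes never modelled).

N_ALPHA_V, N_ALPHA_J = 76, 51
N_BETA_V, N_BETA_J = 26, 14


def default_gene_labels(chain: str = "alpha") -> tuple[list[str], list[str]]:
    """Synthetic germline labels matching the reduced mouse set sizes."""
    if chain == "alpha":
        return ([f"TRAV{i}" for i in range(1, N_ALPHA_V + 1)],
                [f"TRAJ{i}" for i in range(1, N_ALPHA_J + 1)])
    if chain == "beta":
        return ([f"TRBV{i}" for i in range(1, N_BETA_V + 1)],
                [f"TRBJ{i}" for i in range(1, N_BETA_J + 1)])
    raise ValueError(f"unknown chain {chain!r}")


# ---------------------------------------------------------------------------
# Pinned default CDR3 amino-acid profiles
# ---------------------------------------------------------------------------

def _profile(weights: dict[str, float]) -> np.ndarray:
    v = np.zeros(len(AA_ALPHABET))
    for aa, w in weights.items():
        v[AA_ALPHABET.index(aa)] = w
    s = v.sum()
    if not 0.7 <= s <= 1.3:
        raise ValueError(f"profile weights sum to {s}")
    return v / s


#: Left-aligned (position-from-start, 1-based) profiles: C..A.. start.
DEFAULT_LEFT_PROFILES: dict[int, np.ndarray] = {
    1: _profile({"C": 1.0}),
    2: _profile({"A": 0.75, "V": 0.1, "I": 0.05, "S": 0.05, "G": 0.05}),
    3: _profile({"V": 0.2, "A": 0.2, "S": 0.2, "L": 0.15, "M": 0.05,
                 "G": 0.1, "E": 0.1}),
    4: _profile({"S": 0.2, "A": 0.15, "G": 0.15, "E": 0.1, "D": 0.1,
                 "P": 0.1, "L": 0.1, "M": 0.05, "R": 0.05}),
    5: _profile({"G": 0.15, "S": 0.15, "R": 0.1, "A": 0.1, "N": 0.1,
                 "D": 0.1, "L": 0.1, "I": 0.05, "Y": 0.05, "E": 0.1}),
}

#: Right-aligned (negative position-from-end) profiles: ..F end, with
#: J-segment hydrophobic anchors at -5 and -7.
DEFAULT_RIGHT_PROFILES: dict[int, np.ndarray] = {
    -1: _profile({"F": 0.85, "W": 0.1, "L": 0.05}),
    -2: _profile({"T": 0.3, "I": 0.2, "V": 0.15, "L": 0.1, "N": 0.1,
                  "A": 0.05, "K": 0.05, "S": 0.05}),
    -3: _profile({"L": 0.4, "I": 0.2, "V": 0.15, "T": 0.1, "M": 0.05,
                  "A": 0.05, "K": 0.05}),
    -4: _profile({"K": 0.2, "T": 0.15, "N": 0.15, "Q": 0.1, "G": 0.1,
                  "L": 0.1, "Y": 0.1, "S": 0.05, "R": 0.05}),
    -5: _profile({"L": 0.3, "I": 0.2, "Y": 0.15, "F": 0.1, "M": 0.05,
                  "V": 0.05, "N": 0.05, "K": 0.05, "T": 0.05}),
    -6: _profile({"G": 0.25, "S": 0.2, "N": 0.15, "K": 0.1, "D": 0.1,
                  "A": 0.05, "Q": 0.05, "Y": 0.05, "L": 0.05}),
    -7: _profile({"L": 0.35, "F": 0.2, "Y": 0.15, "I": 0.1, "S": 0.05,
                  "N": 0.05, "G": 0.05, "T": 0.05}),
}

#: Insertion-like profile reused for untabulated central positions.
DEFAULT_CENTRAL_PROFILE: np.ndarray = _profile({
    "G": 0.14, "S": 0.11, "N": 0.09, "A": 0.07, "R": 0.06, "D": 0.05,
    "T": 0.05, "Q": 0.04, "K": 0.04, "E": 0.03, "V": 0.04, "P": 0.02,
    "H": 0.02,
    # hydrophobic mass 0.24 in the centre
    "L": 0.08, "Y": 0.06, "I": 0.04, "F": 0.03, "M": 0.015, "W": 0.01,
    "C": 0.005,
})
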