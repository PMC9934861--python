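"""Per-sequence hydrophobicity index over the central CDR3 region.

The central region corresponds to IMGT positions 108-114, which in the
positional feature convention of this package are left positions 5..11
(1-based from the conserved cysteine) and right positions -11..-5 (from
the conserved phenylalanine).  A residue belongs to the central region
when it falls in either window; for a junction of 15 amino acids the two
windows coincide.
"""

from __future__ import annotations

import numpy as np

from .constants import HYDROPHOBIC_AA

#: Central-region positional windows (1-based index from either end).
CENTRAL_LEFT_POSITIONS = range(5, 12)
CENTRAL_RIGHT_POSITIONS = range(5, 12)  # i-th from the right, i.e. -i


def central_positions(length: int) -> np.ndarray:
    """1-based junction positions belonging to the central region.

    The union of the two windows, restricted to the trimmed CDR3
    (positions 3..L-1): the conserved leading C/A and the final F never
    count as central, whatever the junction length.
    """
    idx = np.arange(3, length)
    left = (idx >= CENTRAL_LEFT_POSITIONS.start) & (idx < CENTRAL_LEFT_POSITIONS.stop)
    # position i is the (length + 1 - i)-th from the right
    from_right = length + 1 - idx
    right = ((from_right >= CENTRAL_RIGHT_POSITIONS.start)
             & (from_right < CENTRAL_RIGHT_POSITIONS.stop))
    return idx[left | right]


def hydrophobicity_index_u(clonotype_or_seq, region: str = "central") -> float:
    """Number of hydrophobic residues (CFILMWY) in the chosen region,
    normalized by the full CDR3 amino-acid length.

    Accepts a clonotype or a plain amino-acid string.  Always in [0, 1].
    """
    seq = getattr(clonotype_or_seq, "cdr3_aa", clonotype_or_seq)
    if not seq:
        raise ValueError("empty CDR3")
    if region == "full":
        count = sum(1 for a in seq if a in HYDROPHOBIC_AA)
    elif region == "central":
        count = sum(1 for i in central_positions(len(seq))
                    if seq[i - 1] in HYDROPHOBIC_AA)
    else:
        raise ValueError(f"unknown region {region!r}")
    return count / len(seq)
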