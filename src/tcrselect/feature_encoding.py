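"""Sparse binary feature encoding of clonotypes.

Each clonotype maps to a {0,1} vector over: 30 CDR3 amino-acid length
features, 25 left-to-right and 25 right-to-left positional features per
amino acid (500 + 500), independent V and J usage, and optionally the
joint V x J usage.  Positional indices run over the full junction
(conserved C ... F inclusive), left positions 1..25 and right positions
-1..-25; junctions longer than 25 activate both caps.  With the reduced
mouse germline sets this yields 5033 (alpha, joint on), 1434 (beta,
joint on), 1157 (alpha, joint off) and 1070 (beta, joint off) features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .constants import AA_ALPHABET
from .repertoire_io import Clonotype, Repertoire

MAX_LEN = 30
N_POSITIONS = 25


class EncodingError(ValueError):
    """A clonotype cannot be represented in the scheme."""


@dataclass
class FeatureScheme:
    """Bijective feature <-> integer index for one encoding variant."""

    v_genes: list[str]
    j_genes: list[str]
    include_joint_vj: bool
    max_len: int = MAX_LEN
    n_positions: int = N_POSITIONS
    alphabet: str = AA_ALPHABET

    def __post_init__(self) -> None:
        if len(set(self.v_genes)) != len(self.v_genes):
            raise ValueError("duplicate V gene labels")
        if len(set(self.j_genes)) != len(self.j_genes):
            raise ValueError("duplicate J gene labels")
        if not self.v_genes or not self.j_genes:
            raise ValueError("gene lists must be non-empty")
        k = len(self.alphabet)
        names: list[str] = [f"length_{L}" for L in range(1, self.max_len + 1)]
        names += [f"left_{i}_{a}" for i in range(1, self.n_positions + 1)
                  for a in self.alphabet]
        names += [f"right_{i}_{a}" for i in range(1, self.n_positions + 1)
                  for a in self.alphabet]
        names += [f"v_{g}" for g in self.v_genes]
        names += [f"j_{g}" for g in self.j_genes]
        if self.include_joint_vj:
            names += [f"vj_{v}_{j}" for v in self.v_genes for j in self.j_genes]
        self.feature_names: list[str] = names
        self.index: dict[str, int] = {f: i for i, f in enumerate(names)}
        # offsets for fast vectorized encoding
        self._off_left = self.max_len
        self._off_right = self._off_left + self.n_positions * k
        self._off_v = self._off_right + self.n_positions * k
        self._off_j = self._off_v + len(self.v_genes)
        self._off_vj = self._off_j + len(self.j_genes)
        self._v_index = {g: i for i, g in enumerate(self.v_genes)}
        self._j_index = {g: i for i, g in enumerate(self.j_genes)}
        self._aa_index = {a: i for i, a in enumerate(self.alphabet)}

    @property
    def dimension(self) -> int:
        return len(self.feature_names)

    def active_bit_count(self, length: int) -> int:
        """Number of active features for a CDR3 of the given length."""
        return (1 + 2 * min(length, self.n_positions) + 2
                + (1 if self.include_joint_vj else 0))

    # -- single-clonotype encoding ------------------------------------------

    def encode(self, c: Clonotype) -> np.ndarray:
        """Active feature indices for one clonotype (sorted)."""
        L = len(c.cdr3_aa)
        if not 1 <= L <= self.max_len:
            raise EncodingError(f"CDR3 length {L} outside [1, {self.max_len}] "
                                f"for clonotype {c.key}")
        if c.v_gene not in self._v_index or c.j_gene not in self._j_index:
            raise EncodingError(f"unknown gene for clonotype {c.key}")
        k = len(self.alphabet)
        idx = [L - 1]
        try:
            for i in range(min(L, self.n_positions)):
                idx.append(self._off_left + i * k + self._aa_index[c.cdr3_aa[i]])
                idx.append(self._off_right + i * k
                           + self._aa_index[c.cdr3_aa[L - 1 - i]])
        except KeyError as exc:
            raise EncodingError(f"unknown amino acid {exc.args[0]!r} in {c.key}")
        vi, ji = self._v_index[c.v_gene], self._j_index[c.j_gene]
        idx += [self._off_v + vi, self._off_j + ji]
        if self.include_joint_vj:
            idx.append(self._off_vj + vi * len(self.j_genes) + ji)
        return np.array(sorted(idx), dtype=np.int64)

    def decode(self, indices: Iterable[int]) -> dict:
        """Recover (length, v_gene, j_gene, per-position amino acids)."""
        out = {"length": None, "v_gene": None, "j_gene": None,
               "left": {}, "right": {}}
        k = len(self.alphabet)
        for i in indices:
            name = self.feature_names[int(i)]
            kind, _, rest = name.partition("_")
            if kind == "length":
                out["length"] = int(rest)
            elif kind in ("left", "right"):
                pos, aa = rest.rsplit("_", 1)
                out[kind][int(pos)] = aa
            elif kind == "v":
                out["v_gene"] = rest
            elif kind == "j":
                out["j_gene"] = rest
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "v_genes": self.v_genes, "j_genes": self.j_genes,
            "include_joint_vj": self.include_joint_vj,
            "max_len": self.max_len, "n_positions": self.n_positions,
            "alphabet": self.alphabet}, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureScheme":
        return cls(**json.loads(Path(path).read_text()))


def build_scheme(v_genes: Sequence[str], j_genes: Sequence[str],
                 include_joint_vj: bool = True, max_len: int = MAX_LEN,
                 n_positions: int = N_POSITIONS) -> FeatureScheme:
    """Construct a feature scheme; dimension follows the closed form
    ``max_len + 2*n_positions*20 + |V| + |J| (+ |V|*|J| if joint)``."""
    return FeatureScheme(list(v_genes), list(j_genes), include_joint_vj,
                         max_len=max_len, n_positions=n_positions)


def encode(c: Clonotype, scheme: FeatureScheme) -> np.ndarray:
    """Active feature indices of one clonotype under the scheme."""
    return scheme.encode(c)


def encode_matrix(rep: Repertoire | Sequence[Clonotype],
                  scheme: FeatureScheme) -> sp.csr_matrix:
    """Encode a repertoire as a sparse CSR {0,1} matrix (n x dimension).

    Vectorized by CDR3-length group; raises :class:`EncodingError` on
    the first clonotype that cannot be represented.
    """
    clonotypes = list(rep)
    n = len(clonotypes)
    k = len(scheme.alphabet)
    if n == 0:
        return sp.csr_matrix((0, scheme.dimension))

    aa_lookup = np.full(128, -1, dtype=np.int64)
    for a, i in scheme._aa_index.items():
        aa_lookup[ord(a)] = i
    try:
        v_idx = np.array([scheme._v_index[c.v_gene] for c in clonotypes])
        j_idx = np.array([scheme._j_index[c.j_gene] for c in clonotypes])
    except KeyError as exc:
        raise EncodingError(f"unknown gene {exc.args[0]!r}")
    lengths = np.array([len(c.cdr3_aa) for c in clonotypes])
    if lengths.min() < 1 or lengths.max() > scheme.max_len:
        raise EncodingError("CDR3 length outside scheme bounds")

    bits = np.array([scheme.active_bit_count(int(L)) for L in lengths])
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(bits, out=indptr[1:])
    indices = np.empty(indptr[-1], dtype=np.int64)

    seq_codes = {}
    for L in np.unique(lengths):
        sel = np.nonzero(lengths == L)[0]
        arr = np.frombuffer("".join(clonotypes[i].cdr3_aa for i in sel).encode(),
                            dtype=np.uint8).reshape(len(sel), int(L))
        codes = aa_lookup[arr]
        if (codes < 0).any():
            raise EncodingError("unknown amino acid in CDR3")
        seq_codes[int(L)] = (sel, codes)

    joint = scheme.include_joint_vj
    nj = len(scheme.j_genes)
    for L, (sel, codes) in seq_codes.items():
        p = min(L, scheme.n_positions)
        pos = np.arange(p)
        left = scheme._off_left + pos[None, :] * k + codes[:, :p]
        right = scheme._off_right + pos[None, :] * k + codes[:, ::-1][:, :p]
        block = np.concatenate([
            np.full((len(sel), 1), L - 1),
            left, right,
            (scheme._off_v + v_idx[sel])[:, None],
            (scheme._off_j + j_idx[sel])[:, None],
        ] + ([(scheme._off_vj + v_idx[sel] * nj + j_idx[sel])[:, None]]
             if joint else []), axis=1)
        block.sort(axis=1)
        for row, i in enumerate(sel):
            indices[indptr[i]:indptr[i + 1]] = block[row]

    data = np.ones(indptr[-1], dtype=np.float64)
    return sp.csr_matrix((data, indices, indptr), shape=(n, scheme.dimension))


def data_marginals(rep: Repertoire | sp.csr_matrix,
                   scheme: FeatureScheme | None = None) -> np.ndarray:
    """Per-feature empirical frequency p(f): the fraction of clonotypes
    whose vector activates f.  Length-feature marginals sum to one."""
    X = rep if sp.issparse(rep) else encode_matrix(rep, scheme)
    if X.shape[0] == 0:
        raise ValueError("cannot compute marginals of an empty repertoire")
    return np.asarray(X.mean(axis=0)).ravel()
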