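"""Synthetic repertoires with known generative and selective structure.

The generative background is a factorized model: independent V-gene,
J-gene and CDR3-length choices, and independent per-position amino-acid
profiles (left- and right-anchored tables with a central profile reused
in between).  Its virtue is a closed-form generation probability

    Pgen(sigma) = P(V) * P(J) * P(L) * prod_i P(aa_i | position i, L)

for every sequence it emits, which makes every downstream estimator
testable against exact oracles.  Soft-selection filters, energy-based
rejection filters, per-nucleotide sequencing errors and raw-read (UMI)
simulation are layered on top.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from . import constants
from .constants import (AA_ALPHABET, ALPHA_CONSTANT_PRIMER, SYNONYMOUS_CODONS,
                        UMI_LENGTH, translate_nt)
from .hydrophobicity import hydrophobicity_index_u
from .repertoire_io import Clonotype, Repertoire

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)


class ModelValidationError(ValueError):
    """A generation-model field violates its invariants."""


# ---------------------------------------------------------------------------
# Generation model
# ---------------------------------------------------------------------------

@dataclass
class GenerationModel:
    """Factorized V/J/length/positional-amino-acid background model.

    ``aa_left`` maps 1-based positions from the start, ``aa_right``
    negative positions from the end (``aa_right[-1]`` is the last
    position) to probability vectors over ``alphabet``; positions
    tabulated on the right take precedence, then the left table, then
    ``aa_central``.  ``codon_rule`` maps amino
    acid to (codons, probabilities).
    """

    v_probs: pd.Series
    j_probs: pd.Series
    length_probs: pd.Series
    aa_left: dict[int, np.ndarray]
    aa_right: dict[int, np.ndarray]
    aa_central: np.ndarray
    codon_rule: dict[str, tuple[tuple[str, ...], np.ndarray]] = field(default=None)
    alphabet: str = AA_ALPHABET

    def __post_init__(self) -> None:
        if self.codon_rule is None:
            self.codon_rule = uniform_codon_rule()
        self.v_probs = pd.Series(self.v_probs, dtype=float)
        self.j_probs = pd.Series(self.j_probs, dtype=float)
        self.length_probs = pd.Series(self.length_probs, dtype=float).sort_index()
        self.validate()

    def validate(self) -> None:
        for name in ("v_probs", "j_probs", "length_probs"):
            s = getattr(self, name)
            if len(s) == 0 or (s < 0).any():
                raise ModelValidationError(f"{name}: empty or negative entries")
            if abs(float(s.sum()) - 1.0) > 1e-9:
                raise ModelValidationError(f"{name}: probabilities sum to {s.sum()}")
            if s.index.duplicated().any():
                raise ModelValidationError(f"{name}: duplicate labels")
        lengths = self.length_probs.index.to_numpy()
        if lengths.min() < 4:
            raise ModelValidationError("length_probs: minimum length below 4")
        if lengths.max() > 30:
            raise ModelValidationError("length_probs: maximum length above 30")
        k = len(self.alphabet)
        for key, prof in self.position_profiles():
            prof = np.asarray(prof, dtype=float)
            if prof.shape != (k,) or abs(prof.sum() - 1.0) > 1e-9 or (prof < 0).any():
                raise ModelValidationError(f"aa profile {key}: invalid probability vector")

    def position_profiles(self) -> Iterator[tuple[str, np.ndarray]]:
        for i, p in self.aa_left.items():
            yield f"left_{i}", p
        for i, p in self.aa_right.items():
            yield f"right_{i}", p
        yield "central", self.aa_central

    def profile_for(self, position: int, length: int) -> np.ndarray:
        """Profile governing 1-based ``position`` of a CDR3 of ``length``."""
        from_right = position - length - 1   # -1 for the last position
        if from_right in self.aa_right:
            return self.aa_right[from_right]
        if position in self.aa_left:
            return self.aa_left[position]
        return self.aa_central

    def profile_matrix(self, length: int) -> np.ndarray:
        """(length x alphabet) matrix of positional probabilities."""
        return np.stack([self.profile_for(i, length)
                         for i in range(1, length + 1)])

    # -- closed-form generation probabilities -------------------------------

    def log2_pgen(self, v_gene: str, j_gene: str, cdr3_aa: str) -> float:
        L = len(cdr3_aa)
        if L not in self.length_probs.index:
            return -np.inf
        lp = (np.log2(self.v_probs[v_gene]) + np.log2(self.j_probs[j_gene])
              + np.log2(self.length_probs[L]))
        for i, aa in enumerate(cdr3_aa, start=1):
            p = self.profile_for(i, L)[self.alphabet.index(aa)]
            if p == 0.0:
                return -np.inf
            lp += np.log2(p)
        return float(lp)

    def enumerate_support(self) -> Iterator[tuple[str, str, str, float]]:
        """Yield (v, j, cdr3_aa, pgen) over the full support.

        Only feasible for toy models (small alphabet, short lengths).
        """
        from itertools import product
        for L, pL in self.length_probs.items():
            if pL == 0:
                continue
            mats = self.profile_matrix(L)
            for combo in product(range(len(self.alphabet)), repeat=int(L)):
                p_seq = float(np.prod([mats[i, a] for i, a in enumerate(combo)]))
                if p_seq == 0:
                    continue
                seq = "".join(self.alphabet[a] for a in combo)
                for v, pv in self.v_probs.items():
                    for j, pj in self.j_probs.items():
                        p = pv * pj * pL * p_seq
                        if p > 0:
                            yield v, j, seq, p

    # -- serialization -------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alphabet": self.alphabet,
            "v_probs": {str(k): float(v) for k, v in self.v_probs.items()},
            "j_probs": {str(k): float(v) for k, v in self.j_probs.items()},
            "length_probs": {int(k): float(v) for k, v in self.length_probs.items()},
            "aa_left": {int(k): list(map(float, v)) for k, v in self.aa_left.items()},
            "aa_right": {int(k): list(map(float, v)) for k, v in self.aa_right.items()},
            "aa_central": list(map(float, self.aa_central)),
            "codon_rule": {aa: {"codons": list(c), "probs": list(map(float, p))}
                           for aa, (c, p) in self.codon_rule.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GenerationModel":
        d = json.loads(Path(path).read_text())
        return cls(
            v_probs=pd.Series(d["v_probs"]),
            j_probs=pd.Series(d["j_probs"]),
            length_probs=pd.Series({int(k): v for k, v in d["length_probs"].items()}),
            aa_left={int(k): np.array(v) for k, v in d["aa_left"].items()},
            aa_right={int(k): np.array(v) for k, v in d["aa_right"].items()},
            aa_central=np.array(d["aa_central"]),
            codon_rule={aa: (tuple(c["codons"]), np.array(c["probs"]))
                        for aa, c in d["codon_rule"].items()},
            alphabet=d["alphabet"],
        )


def uniform_codon_rule(alphabet: str = AA_ALPHABET
                       ) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    """Synonymous codons assigned uniformly (standard genetic code)."""
    rule = {}
    for aa in alphabet:
        codons = SYNONYMOUS_CODONS[aa]
        rule[aa] = (codons, np.full(len(codons), 1.0 / len(codons)))
    return rule


def _exp_decay_probs(labels: Sequence[str], scale: float) -> pd.Series:
    w = np.exp(-np.arange(len(labels)) / scale)
    return pd.Series(w / w.sum(), index=list(labels))


def default_generation_model(chain: str = "alpha") -> GenerationModel:
    """The pinned default mouse-like background.

    Gene usage decays exponentially with rank (top V gene ~6%), the CDR3
    length distribution is a discretized Gaussian on [8, 22] with mode 14
    and width 1.8, and positional profiles are the pinned tables from
    :mod:`tcrselect.constants` (median central hydrophobicity index
    ~0.2 over background draws).
    """
    v_genes, j_genes = constants.default_gene_labels(chain)
    lengths = np.arange(8, 23)
    lw = np.exp(-((lengths - 14.0) ** 2) / (2 * 1.8 ** 2))
    return GenerationModel(
        v_probs=_exp_decay_probs(v_genes, scale=15.0),
        j_probs=_exp_decay_probs(j_genes, scale=10.0),
        length_probs=pd.Series(lw / lw.sum(), index=lengths),
        aa_left=dict(constants.DEFAULT_LEFT_PROFILES),
        aa_right=dict(constants.DEFAULT_RIGHT_PROFILES),
        aa_central=constants.DEFAULT_CENTRAL_PROFILE.copy(),
    )


# ---------------------------------------------------------------------------
# Repertoire generation
# ---------------------------------------------------------------------------

def generate_repertoire(model: GenerationModel, n: int, seed: int,
                        chain: str = "alpha", stage: str = "synthetic",
                        ) -> Repertoire:
    """Draw ``n`` clonotypes i.i.d. from the background model.

    Each clonotype carries its exact base-2 log generation probability in
    ``Repertoire.log2_pgen``; the nucleotide CDR3 is drawn from the codon
    rule consistently with the amino-acid CDR3.
    """
    if n < 1:
        raise ValueError("n must be >= 1 (empty repertoire requested)")
    model.validate()
    rng = np.random.default_rng(seed)

    v_labels = model.v_probs.index.to_numpy()
    j_labels = model.j_probs.index.to_numpy()
    v_idx = rng.choice(len(v_labels), size=n, p=model.v_probs.to_numpy())
    j_idx = rng.choice(len(j_labels), size=n, p=model.j_probs.to_numpy())
    lengths = rng.choice(model.length_probs.index.to_numpy(), size=n,
                         p=model.length_probs.to_numpy())

    log2_pgen = (np.log2(model.v_probs.to_numpy())[v_idx]
                 + np.log2(model.j_probs.to_numpy())[j_idx])
    lp_len = np.log2(model.length_probs)
    log2_pgen += lp_len.loc[lengths].to_numpy()

    k = len(model.alphabet)
    alpha_bytes = np.frombuffer(model.alphabet.encode(), dtype=np.uint8)
    # codon lookup: (aa index, synonym index) -> 3 bytes
    max_syn = max(len(c) for c, _ in model.codon_rule.values())
    codon_bytes = np.zeros((k, max_syn, 3), dtype=np.uint8)
    syn_counts = np.zeros(k, dtype=np.int64)
    for ai, aa in enumerate(model.alphabet):
        codons, probs = model.codon_rule[aa]
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ModelValidationError(f"codon_rule[{aa}]: probabilities sum to {probs.sum()}")
        syn_counts[ai] = len(codons)
        for ci, codon in enumerate(codons):
            codon_bytes[ai, ci] = np.frombuffer(codon.encode(), dtype=np.uint8)
    aa_strings = [""] * n
    nt_strings = [""] * n
    for L in np.unique(lengths):
        sel = np.nonzero(lengths == L)[0]
        mats = model.profile_matrix(int(L))  # (L, k)
        # cumulative inverse sampling per position
        cum = np.cumsum(mats, axis=1)
        cum[:, -1] = 1.0
        r = rng.random((len(sel), int(L)))
        aa_codes = (r[:, :, None] > cum[None, :, :]).sum(axis=2)  # (m, L)
        log2_pgen[sel] += np.log2(
            mats[np.arange(int(L))[None, :], aa_codes]).sum(axis=1)
        # codons: uniform-index trick over per-aa synonym counts
        syn_idx = np.floor(rng.random(aa_codes.shape)
                           * syn_counts[aa_codes]).astype(np.int64)
        # NOTE: valid for uniform codon probabilities; general rule handled below
        nonuniform = any(len(set(np.round(p, 12))) > 1
                         for _, p in model.codon_rule.values())
        if nonuniform:
            for ai in range(k):
                mask = aa_codes == ai
                if mask.any():
                    _, probs = model.codon_rule[model.alphabet[ai]]
                    syn_idx[mask] = rng.choice(len(probs), size=int(mask.sum()),
                                               p=probs)
        aa_rows = alpha_bytes[aa_codes]
        nt_rows = codon_bytes[aa_codes, syn_idx]  # (m, L, 3)
        for row, i in enumerate(sel):
            aa_strings[i] = aa_rows[row].tobytes().decode()
            nt_strings[i] = nt_rows[row].reshape(-1).tobytes().decode()

    clonotypes = [Clonotype(v_gene=v_labels[v_idx[i]], j_gene=j_labels[j_idx[i]],
                            cdr3_nt=nt_strings[i], cdr3_aa=aa_strings[i],
                            chain=chain, umi_count=1, productive=True)
                  for i in range(n)]
    return Repertoire(clonotypes, stage=stage, chain=chain, log2_pgen=log2_pgen)


# ---------------------------------------------------------------------------
# Toy soft selection
# ---------------------------------------------------------------------------

@dataclass
class ToySelectionConfig:
    """Soft-selection filter acting on CDR3 length or hydrophobicity.

    Acceptance probability is ``x^h / (x^h + x0^h)`` with ``x`` the CDR3
    length (``mode='length'``, midpoint ``L0``) or the hydrophobicity
    index u (``mode='hydrophobicity'``, midpoint ``u0``).
    """

    mode: str
    L0: float = 13.0
    u0: float = 0.2
    h: float = 1.0
    seed: int = 0
    region: str = "central"

    def __post_init__(self) -> None:
        if self.mode not in ("length", "hydrophobicity"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.L0 <= 0 or self.h <= 0 or not 0 <= self.u0 <= 1:
            raise ValueError("invalid soft-selection parameters")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ToySelectionConfig":
        return cls(**json.loads(Path(path).read_text()))


def acceptance_probability(cfg: ToySelectionConfig, rep: Repertoire) -> np.ndarray:
    """Per-clonotype probability of landing in the accepted population."""
    if cfg.mode == "length":
        x = rep.lengths().astype(float)
        x0 = cfg.L0
    else:
        x = np.array([hydrophobicity_index_u(c, region=cfg.region)
                      for c in rep.clonotypes])
        x0 = cfg.u0
    with np.errstate(divide="ignore", invalid="ignore"):
        p = x ** cfg.h / (x ** cfg.h + x0 ** cfg.h)
    return np.where(x == 0, 0.0, p)


def apply_soft_selection(rep: Repertoire, cfg: ToySelectionConfig,
                         ) -> tuple[Repertoire, Repertoire]:
    """Split a repertoire into (accepted, rejected) by the soft filter."""
    if len(rep) == 0:
        raise ValueError("repertoire is empty")
    rng = np.random.default_rng(cfg.seed)
    p = acceptance_probability(cfg, rep)
    accept = rng.random(len(rep)) < p
    names = (("long", "short") if cfg.mode == "length"
             else ("high-hydrophobicity", "low-hydrophobicity"))
    return rep.subset(accept, stage=names[0]), rep.subset(~accept, stage=names[1])


# ---------------------------------------------------------------------------
# Energy-based selection (ground truth for parameter recovery)
# ---------------------------------------------------------------------------

def select_by_energy(rep: Repertoire, true_epsilons: Mapping[str, float],
                     scheme, seed: int) -> Repertoire:
    """Thin a repertoire with retention probability proportional to e^(-E).

    ``E = sum of epsilon(f)`` over the clonotype's active features;
    rejection sampling against the sample maximum of e^(-E) makes the
    retained set an exact draw from P ~ e^(-E) times the empirical input
    distribution.
    """
    from .feature_encoding import encode_matrix  # deferred: avoid cycle

    unknown = [f for f in true_epsilons if f not in scheme.index]
    if unknown:
        raise KeyError(f"features not in scheme: {unknown[:5]}")
    eps = np.zeros(scheme.dimension)
    for f, val in true_epsilons.items():
        eps[scheme.index[f]] = val
    X = encode_matrix(rep, scheme)
    energies = X @ eps
    if not np.isfinite(energies).any():
        raise ValueError("all energies are infinite; empty output")
    p = np.exp(-(energies - energies[np.isfinite(energies)].min()))
    p = np.nan_to_num(p, nan=0.0)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(rep)) < p
    if not keep.any():
        raise ValueError("selection rejected every clonotype")
    return rep.subset(keep)


# ---------------------------------------------------------------------------
# Sequencing errors
# ---------------------------------------------------------------------------

def _substitute(seq_bytes: np.ndarray, error_rate: float,
                rng: np.random.Generator) -> np.ndarray:
    """Independent per-base substitution, uniform among the 3 alternatives."""
    out = seq_bytes.copy()
    hit = np.nonzero(rng.random(out.size) < error_rate)[0]
    if hit.size:
        # index of current base in ACGT
        cur = np.zeros(hit.size, dtype=np.int64)
        for bi, b in enumerate(_NT):
            cur[out[hit] == b] = bi
        shift = rng.integers(1, 4, size=hit.size)
        out[hit] = _NT[(cur + shift) % 4]
    return out


def simulate_sequencing_errors(rep: Repertoire, error_rate: float,
                               seed: int) -> Repertoire:
    """Apply per-nucleotide substitution errors and re-translate.

    Clonotypes whose CDR3 gains a stop codon are flagged nonproductive.
    """
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    if error_rate == 0:
        return rep
    rng = np.random.default_rng(seed)
    out = []
    for c in rep.clonotypes:
        nt = _substitute(np.frombuffer(c.cdr3_nt.encode(), dtype=np.uint8),
                         error_rate, rng).tobytes().decode()
        aa = translate_nt(nt)
        out.append(Clonotype(v_gene=c.v_gene, j_gene=c.j_gene, cdr3_nt=nt,
                             cdr3_aa=aa, chain=c.chain, umi_count=c.umi_count,
                             productive="*" not in aa))
    return Repertoire(out, stage=rep.stage, mouse=rep.mouse, chain=rep.chain,
                      mouse_labels=rep.mouse_labels)


# ---------------------------------------------------------------------------
# Raw-read (UMI) simulation
# ---------------------------------------------------------------------------

def make_raw_reads(rep: Repertoire, reads_per_molecule=1,
                   umi_length: int = UMI_LENGTH, error_rate: float = 0.0,
                   seed: int = 0, primer: str = ALPHA_CONSTANT_PRIMER):
    """Simulate raw reads: per-molecule UMIs, constant-region primer and
    per-base errors on both UMI and insert.

    ``reads_per_molecule`` is either a fixed integer or a probability
    vector over counts 1, 2, ...  Returns ``(reads, truth)`` where reads
    are :class:`tcrselect.umi_preprocessing.RawRead` records and
    ``truth`` is a molecule-level DataFrame for test oracles.
    """
    from .umi_preprocessing import RawRead  # deferred: avoid cycle

    if umi_length < 1:
        raise ValueError("umi_length must be >= 1")
    if not 0 <= error_rate < 0.25:
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)

    reads: list[RawRead] = []
    truth_rows = []
    mol_id = 0
    for ci, c in enumerate(rep.clonotypes):
        for _ in range(max(1, c.umi_count)):
            umi = _NT[rng.integers(0, 4, size=umi_length)].tobytes().decode()
            insert = primer + c.cdr3_nt
            if np.isscalar(reads_per_molecule):
                n_reads = int(reads_per_molecule)
            else:
                pmf = np.asarray(reads_per_molecule, dtype=float)
                n_reads = int(rng.choice(np.arange(1, len(pmf) + 1), p=pmf / pmf.sum()))
            for _ in range(n_reads):
                umi_err = _substitute(np.frombuffer(umi.encode(), np.uint8),
                                      error_rate, rng).tobytes().decode()
                ins_err = _substitute(np.frombuffer(insert.encode(), np.uint8),
                                      error_rate, rng).tobytes().decode()
                reads.append(RawRead(umi=umi_err, insert=ins_err, read_count=1))
            truth_rows.append({"molecule_id": mol_id, "clonotype_index": ci,
                               "umi": umi, "cdr3_nt": c.cdr3_nt,
                               "cdr3_aa": c.cdr3_aa})
            mol_id += 1
    truth = pd.DataFrame(truth_rows)
    return reads, truth
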