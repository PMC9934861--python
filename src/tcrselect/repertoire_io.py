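"""Stage-labelled repertoires: AIRR Rearrangement I/O, clonotype rules,
germline-gene collapsing and gene-usage summaries.

A clonotype is a unique rearrangement identified by (V gene, J gene, CDR3
nucleotide sequence); when several rows of a rearrangement table map to
the same clonotype only the annotation with the highest UMI count is
kept.  The CDR3/junction convention is IMGT: the junction includes the
conserved cysteine and the conserved phenylalanine, amino-acid positions
are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import translate_nt

logger = logging.getLogger(__name__)

AIRR_REQUIRED_COLUMNS = (
    "v_call", "j_call", "junction", "junction_aa", "productive",
    "duplicate_count",
)

_DNA = frozenset("ACGT")


class SchemaError(ValueError):
    """An input table is missing required columns."""


@dataclass(frozen=True)
class Clonotype:
    """One unique rearrangement.

    ``cdr3_nt``/``cdr3_aa`` hold the IMGT junction (conserved C ... F
    inclusive).  For productive clonotypes ``cdr3_aa`` is the standard-code
    translation of ``cdr3_nt``.
    """

    v_gene: str
    j_gene: str
    cdr3_nt: str
    cdr3_aa: str
    chain: str = "alpha"
    umi_count: int = 1
    productive: bool = True

    def __post_init__(self) -> None:
        if self.umi_count < 0:
            raise ValueError("umi_count must be non-negative")
        if self.productive:
            if len(self.cdr3_nt) != 3 * len(self.cdr3_aa):
                raise ValueError(
                    f"productive clonotype with nt length {len(self.cdr3_nt)} "
                    f"!= 3 x aa length {len(self.cdr3_aa)}")
            if "*" in self.cdr3_aa:
                raise ValueError("productive clonotype contains a stop codon")

    @property
    def length(self) -> int:
        """Amino-acid length of the junction."""
        return len(self.cdr3_aa)

    @property
    def key(self) -> tuple[str, str, str]:
        """Clonotype identity: (V gene, J gene, CDR3 nucleotide)."""
        return (self.v_gene, self.j_gene, self.cdr3_nt)


@dataclass
class Repertoire:
    """A stage- and mouse-labelled collection of clonotypes.

    ``mouse_labels``, when present, assigns each clonotype to an animal so
    that per-mouse summaries can be computed from a pooled repertoire.
    ``log2_pgen`` optionally carries per-clonotype generation
    probabilities (base-2 logarithm) for synthetic repertoires.
    """

    clonotypes: list[Clonotype]
    stage: str = "synthetic"
    mouse: str = "pooled"
    chain: str = "alpha"
    mouse_labels: np.ndarray | None = None
    log2_pgen: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.clonotypes = list(self.clonotypes)
        for name in ("mouse_labels", "log2_pgen"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                if len(arr) != len(self.clonotypes):
                    raise ValueError(f"{name} length mismatch")
                setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.clonotypes)

    def __iter__(self) -> Iterator[Clonotype]:
        return iter(self.clonotypes)

    def __getitem__(self, i: int) -> Clonotype:
        return self.clonotypes[i]

    def subset(self, mask: np.ndarray, stage: str | None = None) -> "Repertoire":
        mask = np.asarray(mask)
        idx = np.nonzero(mask)[0] if mask.dtype == bool else mask
        return Repertoire(
            [self.clonotypes[i] for i in idx],
            stage=stage or self.stage, mouse=self.mouse, chain=self.chain,
            mouse_labels=None if self.mouse_labels is None else self.mouse_labels[idx],
            log2_pgen=None if self.log2_pgen is None else self.log2_pgen[idx],
        )

    def productive_partition(self) -> tuple["Repertoire", "Repertoire"]:
        """Split into (productive, nonproductive) repertoires."""
        mask = np.array([c.productive for c in self.clonotypes], dtype=bool)
        return self.subset(mask), self.subset(~mask)

    def lengths(self) -> np.ndarray:
        return np.array([c.length for c in self.clonotypes], dtype=np.int64)

    def dedup(self) -> "Repertoire":
        """Collapse to unique clonotypes, keeping the highest UMI count."""
        best: dict[tuple[str, str, str], int] = {}
        for i, c in enumerate(self.clonotypes):
            j = best.get(c.key)
            if j is None or c.umi_count > self.clonotypes[j].umi_count:
                best[c.key] = i
        return self.subset(np.array(sorted(best.values()), dtype=np.int64))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "v_call": [c.v_gene for c in self.clonotypes],
            "j_call": [c.j_gene for c in self.clonotypes],
            "junction": [c.cdr3_nt for c in self.clonotypes],
            "junction_aa": [c.cdr3_aa for c in self.clonotypes],
            "productive": ["T" if c.productive else "F" for c in self.clonotypes],
            "duplicate_count": [c.umi_count for c in self.clonotypes],
        })
        df["stage"] = self.stage
        df["mouse"] = (self.mouse_labels if self.mouse_labels is not None
                       else self.mouse)
        df["locus"] = "TRA" if self.chain == "alpha" else "TRB"
        return df


def write_airr_repertoire(rep: Repertoire, path: str | Path) -> None:
    """Write a repertoire as an AIRR Rearrangement TSV."""
    rep.to_dataframe().to_csv(path, sep="\t", index=False)


def read_airr_repertoire(path: str | Path, stage: str = "synthetic",
                         mouse: str = "pooled", chain: str = "alpha",
                         ) -> Repertoire:
    """Read an AIRR Rearrangement TSV into a deduplicated :class:`Repertoire`.

    Rows are collapsed to unique clonotypes on (v_call, j_call, junction);
    among duplicates the row with the highest ``duplicate_count`` wins.
    Malformed rows are logged and skipped; the kept/dropped counts are
    reported through the module logger.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in AIRR_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required AIRR columns: {missing}")

    clonotypes: list[Clonotype] = []
    mice: list[str] = []
    n_bad = 0
    for row in df.itertuples(index=False):
        try:
            nt = row.junction.upper()
            aa = row.junction_aa
            productive = str(row.productive).upper() in ("T", "TRUE", "1")
            if not set(nt) <= _DNA:
                raise ValueError("non-ACGT junction")
            if productive and translate_nt(nt) != aa:
                raise ValueError("junction_aa is not the translation of junction")
            clonotypes.append(Clonotype(
                v_gene=row.v_call, j_gene=row.j_call, cdr3_nt=nt, cdr3_aa=aa,
                chain=chain, umi_count=int(row.duplicate_count),
                productive=productive))
            mice.append(getattr(row, "mouse", mouse))
        except (ValueError, TypeError) as exc:
            n_bad += 1
            logger.warning("skipping malformed row: %s", exc)
    logger.info("read %d rows, kept %d, dropped %d",
                len(df), len(clonotypes), n_bad)
    rep = Repertoire(clonotypes, stage=stage, mouse=mouse, chain=chain,
                     mouse_labels=np.array(mice) if mice else None)
    return rep.dedup()


# ---------------------------------------------------------------------------
# Germline-gene collapsing
# ---------------------------------------------------------------------------

def collapse_indistinguishable_v_genes(
        germline: Iterable, offset: int, anchor: int,
        usage: Mapping[str, float]) -> dict[str, str]:
    """Merge V genes that are identical on the annotation window.

    ``germline`` is an iterable of Bio.SeqRecord objects (or any object
    with ``.id`` and ``.seq``).  Two genes are indistinguishable when
    their sub-sequences on ``[offset, anchor]`` (0-based, anchor = index
    of the conserved cysteine codon start, inclusive) are identical
    (Hamming distance 0).  Each cluster maps to its most frequent member
    according to ``usage``; the returned mapping is idempotent.
    """
    windows: dict[str, str] = {}
    for rec in germline:
        seq = str(rec.seq).upper()
        if len(seq) <= anchor:
            logger.warning("gene %s shorter than anchor %d; left unmerged",
                           rec.id, anchor)
            windows[rec.id] = f"__short__{rec.id}"
            continue
        windows[rec.id] = seq[offset:anchor + 1]

    clusters: dict[str, list[str]] = {}
    for gene, window in windows.items():
        clusters.setdefault(window, []).append(gene)

    mapping: dict[str, str] = {}
    for members in clusters.values():
        rep_gene = max(members, key=lambda g: (usage.get(g, 0.0), g))
        for g in members:
            mapping[g] = rep_gene
    return mapping


def apply_gene_collapse(rep: Repertoire, mapping: Mapping[str, str]) -> Repertoire:
    """Rename V genes via a collapse mapping and re-deduplicate."""
    renamed = [replace(c, v_gene=mapping.get(c.v_gene, c.v_gene))
               for c in rep.clonotypes]
    out = Repertoire(renamed, stage=rep.stage, mouse=rep.mouse,
                     chain=rep.chain, mouse_labels=rep.mouse_labels,
                     log2_pgen=rep.log2_pgen)
    return out.dedup()


# ---------------------------------------------------------------------------
# Usage summaries
# ---------------------------------------------------------------------------

def gene_usage(rep: Repertoire, which: str = "V",
               ) -> tuple[pd.Series, pd.DataFrame | None, pd.Series | None]:
    """Gene frequency vector, with per-mouse break-down when available.

    Returns ``(freq, per_mouse, std)`` where ``freq`` sums to one,
    ``per_mouse`` is a genes x mice frequency table and ``std`` the
    empirical standard deviation across mice (both ``None`` for a
    single-mouse repertoire).
    """
    if len(rep) == 0:
        raise ValueError("repertoire is empty")
    if which not in ("V", "J"):
        raise ValueError("which must be 'V' or 'J'")
    genes = pd.Series([c.v_gene if which == "V" else c.j_gene
                       for c in rep.clonotypes])
    freq = genes.value_counts(normalize=True).sort_index()

    if rep.mouse_labels is None or len(set(rep.mouse_labels)) < 2:
        return freq, None, None
    df = pd.DataFrame({"gene": genes, "mouse": rep.mouse_labels})
    per_mouse = (df.groupby("mouse")["gene"].value_counts(normalize=True)
                 .unstack(level="mouse", fill_value=0.0).sort_index())
    std = per_mouse.std(axis=1, ddof=1)
    return freq, per_mouse, std


def gene_pair_fraction(rep: Repertoire, v: str, j: str) -> float:
    """Fraction of clonotypes carrying exactly the (V, J) gene pair."""
    if len(rep) == 0:
        raise ValueError("repertoire is empty")
    hits = sum(1 for c in rep.clonotypes if c.v_gene == v and c.j_gene == j)
    return hits / len(rep)
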