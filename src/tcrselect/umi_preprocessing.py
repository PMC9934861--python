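"""Raw-read error correction: constant-region filtering and two-step
UMI/CDR3 clustering.

The pipeline mirrors a molecular-barcoded TCR-seq protocol: reads carry
a 12-bp unique molecular identifier (UMI); reads matching the
constant-region primer (up to 3 mismatches) are kept; UMIs are greedily
clustered within Levenshtein distance 1 starting from the most frequent;
within each UMI group the CDR3 amino-acid sequences are greedily
absorbed into the most frequent sequence within Hamming distance 4
(equal lengths only); finally distinct UMIs are counted per corrected
CDR3.  Ties in read frequency are broken lexicographically so the
output is independent of input order.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .constants import ALPHA_CONSTANT_PRIMER, UMI_LENGTH, translate_nt

logger = logging.getLogger(__name__)

DEFAULT_UMI_DISTANCE = 1      # Levenshtein threshold for UMI merging
DEFAULT_CDR3_DISTANCE = 4     # Hamming threshold for CDR3 merging
DEFAULT_MAX_MISMATCH = 3      # primer match tolerance


@dataclass(frozen=True)
class RawRead:
    """One sequencing read: UMI plus the CDR3-bearing insert."""

    umi: str
    insert: str
    read_count: int = 1

    def __post_init__(self) -> None:
        if self.read_count < 1:
            raise ValueError("read_count must be >= 1")


# ---------------------------------------------------------------------------
# FASTQ round trip (UMI kept in the header comment)
# ---------------------------------------------------------------------------

def write_fastq(reads: Sequence[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"@read{i} UMI:{r.umi}\n{r.insert}\n+\n"
                     f"{'I' * len(r.insert)}\n")


def read_fastq(path: str | Path) -> list[RawRead]:
    reads = []
    lines = Path(path).read_text().splitlines()
    for i in range(0, len(lines), 4):
        header = lines[i]
        umi = header.split("UMI:")[1].split()[0]
        reads.append(RawRead(umi=umi, insert=lines[i + 1]))
    return reads


# ---------------------------------------------------------------------------
# Constant-region filtering
# ---------------------------------------------------------------------------

def _best_window_distance(read: str, primer: str) -> int:
    """Minimum Hamming distance of the primer over all read windows."""
    n, m = len(read), len(primer)
    if m > n:
        return m + 1
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(r, m)
    return int((windows != p).sum(axis=1).min())


def filter_constant_region(reads: Iterable[RawRead], primer: str,
                           max_mismatch: int = DEFAULT_MAX_MISMATCH,
                           ) -> list[RawRead]:
    """Keep reads with a primer window at Hamming distance <= max_mismatch."""
    if not primer:
        raise ValueError("primer must be non-empty")
    kept, dropped = [], 0
    for r in reads:
        if len(primer) > len(r.insert):
            logger.warning("primer longer than read; read dropped")
            dropped += 1
            continue
        if _best_window_distance(r.insert, primer) <= max_mismatch:
            kept.append(r)
        else:
            dropped += 1
    logger.info("constant-region filter: kept %d, dropped %d",
                len(kept), dropped)
    return kept


def extract_cdr3(reads: Iterable[RawRead], primer: str = ALPHA_CONSTANT_PRIMER,
                 ) -> pd.DataFrame:
    """Locate the primer (best window) and translate the downstream
    insert into a CDR3 amino-acid sequence.

    Returns a DataFrame with columns umi, cdr3_aa, read_count; reads
    whose downstream portion is frameshifted are dropped with a count.
    """
    rows, dropped = [], 0
    p = np.frombuffer(primer.encode(), dtype=np.uint8)
    for r in reads:
        seq = np.frombuffer(r.insert.encode(), dtype=np.uint8)
        if len(p) > len(seq):
            dropped += 1
            continue
        windows = np.lib.stride_tricks.sliding_window_view(seq, len(p))
        start = int((windows != p).sum(axis=1).argmin())
        cdr3_nt = r.insert[start + len(p):]
        if not cdr3_nt or len(cdr3_nt) % 3:
            dropped += 1
            continue
        try:
            aa = translate_nt(cdr3_nt)
        except ValueError:
            dropped += 1
            continue
        rows.append({"umi": r.umi, "cdr3_aa": aa, "read_count": r.read_count})
    if dropped:
        logger.info("extract_cdr3: dropped %d reads", dropped)
    return pd.DataFrame(rows, columns=["umi", "cdr3_aa", "read_count"])


# ---------------------------------------------------------------------------
# Two-step UMI / CDR3 clustering
# ---------------------------------------------------------------------------

def _levenshtein_leq(a: str, b: str, k: int) -> bool:
    res = edlib.align(a, b, task="distance", k=k)
    return res["editDistance"] != -1


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _greedy_umi_clusters(umi_counts: Counter, k: int) -> dict[str, str]:
    """Greedy seeds-by-frequency clustering; returns umi -> seed."""
    order = sorted(umi_counts, key=lambda u: (-umi_counts[u], u))
    seeds: list[str] = []
    assign: dict[str, str] = {}
    for u in order:
        for s in seeds:
            if _levenshtein_leq(u, s, k):
                assign[u] = s
                break
        else:
            seeds.append(u)
            assign[u] = u
    return assign


def correct_and_count(records: pd.DataFrame,
                      umi_distance: int = DEFAULT_UMI_DISTANCE,
                      cdr3_distance: int = DEFAULT_CDR3_DISTANCE,
                      ) -> pd.DataFrame:
    """Cluster UMIs then CDR3s and count distinct UMIs per clonotype.

    ``records`` has columns umi, cdr3_aa, read_count (as produced by
    :func:`extract_cdr3`).  Returns a DataFrame with columns cdr3_aa and
    umi_count, sorted by descending count then sequence.
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["cdr3_aa", "umi_count"])
    grouped = (records.groupby(["umi", "cdr3_aa"], as_index=False)
               ["read_count"].sum())

    umi_counts = Counter()
    for row in grouped.itertuples(index=False):
        umi_counts[row.umi] += int(row.read_count)
    umi_to_seed = _greedy_umi_clusters(umi_counts, umi_distance)

    # per UMI group: greedy CDR3 absorption from the most frequent seed
    by_group: dict[str, Counter] = defaultdict(Counter)
    for row in grouped.itertuples(index=False):
        by_group[umi_to_seed[row.umi]][row.cdr3_aa] += int(row.read_count)

    umis_per_cdr3: dict[str, set] = defaultdict(set)
    for group_umi, cdr3_counts in by_group.items():
        order = sorted(cdr3_counts, key=lambda s: (-cdr3_counts[s], s))
        seeds: list[str] = []
        for seq in order:
            target = None
            for s in seeds:
                if len(s) == len(seq) and _hamming(s, seq) <= cdr3_distance:
                    target = s
                    break
            if target is None:
                seeds.append(seq)
                target = seq
            umis_per_cdr3[target].add(group_umi)

    out = pd.DataFrame(
        [{"cdr3_aa": seq, "umi_count": len(umis)}
         for seq, umis in umis_per_cdr3.items()])
    return (out.sort_values(["umi_count", "cdr3_aa"],
                            ascending=[False, True])
            .reset_index(drop=True))
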