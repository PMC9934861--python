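"""n-gram diversity: distributions, entropy estimators, divergences.

n-grams are overlapping amino-acid windows inside the trimmed CDR3 (the
first two junction positions — usually the conserved cysteine plus an
alanine — and the last one, typically phenylalanine, are excluded).
Each unique clonotype contributes once per window; UMI counts are
deliberately ignored.

Shannon entropies are reported in bits.  Alongside the naive plug-in
estimator, the Nemenman–Shafee–Bialek (NSB) estimator is provided: a
Bayesian posterior mean under a mixture of symmetric Dirichlet priors
chosen so that the implied prior over the entropy itself is nearly
flat, together with the posterior standard deviation.  The mixture is
integrated numerically over the Dirichlet concentration.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.special import gammaln, polygamma, psi

from .repertoire_io import Repertoire
from .synthetic_data import GenerationModel, generate_repertoire, \
    simulate_sequencing_errors

LN2 = math.log(2.0)

MAX_NGRAM = 4  # longer n-grams do not converge at realistic sample sizes


@dataclass
class NgramDistribution:
    """Counts over amino-acid n-grams of a repertoire."""

    n: int
    counts: Counter
    alphabet_size: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        self.counts = Counter({k: int(v) for k, v in dict(self.counts).items()
                               if v > 0})
        if self.alphabet_size is None:
            self.alphabet_size = 20 ** self.n

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def frequencies(self) -> pd.Series:
        t = self.total
        return pd.Series({k: v / t for k, v in self.counts.items()}).sort_index()

    def to_tsv(self, path) -> None:
        pd.Series(self.counts).sort_index().rename("count").to_csv(
            path, sep="\t", header=True, index_label="gram")


@dataclass
class EntropyEstimate:
    value: float          # bits
    std: float            # bits
    estimator: str

    def __post_init__(self) -> None:
        if self.value < -1e-9:
            raise ValueError("negative entropy estimate")


def trim_cdr3(seq: str) -> str:
    """Drop the two conserved leading positions and the final one."""
    return seq[2:-1]


def ngram_distribution(rep: Repertoire, n: int,
                       productive_only: bool = True) -> NgramDistribution:
    """Count overlapping n-grams over trimmed CDR3s of a repertoire.

    Sequences whose trimmed CDR3 is shorter than ``n`` contribute
    nothing; a trimmed CDR3 of length L' yields L'-n+1 windows.
    """
    if not 1 <= n <= MAX_NGRAM:
        raise ValueError(f"n must be in [1, {MAX_NGRAM}]")
    counts: Counter = Counter()
    for c in rep.clonotypes:
        if productive_only and not c.productive:
            continue
        t = trim_cdr3(c.cdr3_aa)
        for i in range(len(t) - n + 1):
            counts[t[i:i + n]] += 1
    return NgramDistribution(n=n, counts=counts)


# ---------------------------------------------------------------------------
# Entropy estimation
# ---------------------------------------------------------------------------

def _plugin_entropy(counts: np.ndarray) -> float:
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _nsb_moments(values: np.ndarray, mult: np.ndarray, k_total: int,
                 beta: float) -> tuple[float, float]:
    """Posterior mean and second moment of the entropy (nats) under a
    symmetric Dirichlet(beta) prior, for grouped counts.

    ``values`` are the distinct observed counts (0 included for the
    unobserved cells), ``mult`` their multiplicities summing to the
    alphabet size ``k_total``.
    """
    n_tot = float((values * mult).sum()) + k_total * beta
    lam = values + beta
    # posterior mean (Wolpert-Wolf)
    s1 = psi(n_tot + 1) - float((mult * lam * psi(lam + 1)).sum()) / n_tot
    # posterior second moment
    a = psi(lam + 1) - psi(n_tot + 2)
    j_term = (psi(lam + 2) - psi(n_tot + 2)) ** 2 \
        + polygamma(1, lam + 2) - polygamma(1, n_tot + 2)
    diag = float((mult * (lam + 1) * lam * j_term).sum())
    sum_la = float((mult * lam * a).sum())
    sum_l2a2 = float((mult * (lam * a) ** 2).sum())
    sum_l = float((mult * lam).sum())
    sum_l2 = float((mult * lam ** 2).sum())
    off = (sum_la ** 2 - sum_l2a2
           - polygamma(1, n_tot + 2) * (sum_l ** 2 - sum_l2))
    s2 = (diag + off) / ((n_tot + 1.0) * n_tot)
    return float(s1), float(s2)


def _nsb_entropy(counts: np.ndarray, k_total: int,
                 grid_size: int = 400) -> tuple[float, float]:
    """NSB posterior mean entropy and standard deviation, in nats.

    Integrates the Dirichlet evidence against the flat-on-entropy prior
    density ``d xi / d beta`` over ``log beta`` on a fixed wide grid.
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    n_obs = int(counts.sum())
    if n_obs < 2:
        raise ValueError("NSB requires a total count of at least 2")
    if k_total < len(counts):
        raise ValueError("alphabet size smaller than observed support")
    vals, mult = np.unique(counts, return_counts=True)
    k0 = k_total - len(counts)
    if k0 > 0:
        vals = np.concatenate([[0], vals])
        mult = np.concatenate([[k0], mult]).astype(float)
    else:
        mult = mult.astype(float)
    vals = vals.astype(float)

    t = np.linspace(-12.0, 12.0, grid_size)
    beta = np.exp(t)
    # log evidence of the Dirichlet-multinomial, dropping count-only terms
    obs_vals = vals[vals > 0]
    obs_mult = mult[vals > 0]
    log_ev = (gammaln(k_total * beta) - gammaln(n_obs + k_total * beta)
              + np.array([float((obs_mult * (gammaln(obs_vals + b)
                                             - gammaln(b))).sum())
                          for b in beta]))
    # flat prior on the expected entropy xi(beta): weight by d xi / d beta,
    # plus the log-grid Jacobian beta
    dxi = k_total * polygamma(1, k_total * beta + 1) - polygamma(1, beta + 1)
    log_w = log_ev + np.log(np.maximum(dxi, 1e-300)) + t
    log_w -= log_w.max()
    w = np.exp(log_w)
    w /= np.trapezoid(w, t)

    s1 = np.empty(grid_size)
    s2 = np.empty(grid_size)
    for i, b in enumerate(beta):
        s1[i], s2[i] = _nsb_moments(vals, mult, k_total, float(b))
    mean = float(np.trapezoid(w * s1, t))
    second = float(np.trapezoid(w * s2, t))
    var = max(second - mean ** 2, 0.0)
    return mean, math.sqrt(var)


def entropy_estimate(dist: NgramDistribution,
                     estimator: str = "NSB") -> EntropyEstimate:
    """Shannon entropy of an n-gram distribution, in bits.

    ``plugin`` is the naive frequency estimate (std reported as 0);
    ``NSB`` is the finite-sampling-corrected Bayesian estimate with its
    posterior standard deviation.
    """
    counts = np.array(sorted(dist.counts.values()), dtype=np.int64)
    if counts.size == 0:
        raise ValueError("empty distribution")
    if estimator == "plugin":
        return EntropyEstimate(_plugin_entropy(counts), 0.0, "plugin")
    if estimator == "NSB":
        mean, std = _nsb_entropy(counts, dist.alphabet_size)
        return EntropyEstimate(max(mean, 0.0) / LN2, std / LN2, "NSB")
    raise ValueError(f"unknown estimator {estimator!r}")


def error_corrected_entropy(dist_data: NgramDistribution,
                            gen_model: GenerationModel, error_rate: float,
                            n: int, n_sim: int = 30_000,
                            seed: int = 0) -> EntropyEstimate:
    """Subtractive sequencing-error correction of the data NSB entropy.

    Synthetic sequences are generated from the background, once clean
    and once with simulated per-nucleotide errors at ``error_rate``; the
    entropy difference (errors only add apparent diversity) is
    subtracted from the data estimate, with errors propagated.
    """
    data_est = entropy_estimate(dist_data, "NSB")
    if error_rate == 0:
        return data_est
    clean = generate_repertoire(gen_model, n_sim, seed)
    noisy = simulate_sequencing_errors(clean, error_rate, seed + 1)
    s_clean = entropy_estimate(ngram_distribution(clean, n), "NSB")
    s_noisy = entropy_estimate(ngram_distribution(noisy, n), "NSB")
    correction = s_noisy.value - s_clean.value
    std = math.sqrt(data_est.std ** 2 + s_noisy.std ** 2 + s_clean.std ** 2)
    return EntropyEstimate(max(data_est.value - correction, 0.0), std,
                           "NSB-corrected")


# ---------------------------------------------------------------------------
# Divergence and clustering
# ---------------------------------------------------------------------------

def ngram_jsd(dist_a: NgramDistribution, dist_b: NgramDistribution) -> float:
    """Jensen-Shannon divergence between two n-gram distributions (bits).

    Symmetric and bounded: 0 for identical distributions, 1 bit for
    disjoint supports.
    """
    if dist_a.n != dist_b.n:
        raise ValueError("distributions have different n")
    support = sorted(set(dist_a.counts) | set(dist_b.counts))
    pa = np.array([dist_a.counts.get(g, 0) for g in support], float)
    pb = np.array([dist_b.counts.get(g, 0) for g in support], float)
    pa /= pa.sum()
    pb /= pb.sum()
    m = pa + pb
    out = 0.0
    for p in (pa, pb):
        nz = p > 0
        out += 0.5 * float((p[nz] * np.log2(2 * p[nz] / m[nz])).sum())
    return out


def jsd_matrix(dists: dict[str, NgramDistribution]) -> pd.DataFrame:
    """Symmetric stage-by-stage JSD matrix from named distributions."""
    labels = list(dists)
    m = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            d = ngram_jsd(dists[a], dists[b])
            m.loc[a, b] = m.loc[b, a] = d
    return m


def cluster_stages(jsd: pd.DataFrame):
    """Ward-linkage hierarchical clustering of a stage divergence matrix.

    Returns ``(linkage, leaf_labels)`` with deterministic optimal leaf
    ordering; raises on an asymmetric matrix or nonzero diagonal.
    """
    m = jsd.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T, atol=1e-12):
        raise ValueError("divergence matrix must be symmetric")
    if not np.allclose(np.diag(m), 0.0, atol=1e-12):
        raise ValueError("divergence matrix must have a zero diagonal")
    cond = squareform(m, checks=False)
    z = hierarchy.linkage(cond, method="ward")
    z = hierarchy.optimal_leaf_ordering(z, cond)
    order = hierarchy.leaves_list(z)
    return z, [jsd.index[i] for i in order]
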