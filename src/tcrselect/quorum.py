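"""Quorum model of self/non-self discrimination.

A random TCR recognizes any given peptide with probability p, so the
number n of recognized self-peptides (out of N) is Poisson with mean
n_bar = p*N.  During thymic development each TCR screens only a
fraction f of the self-peptides (M = f*N), so the probability of
passing negative selection is (1 - n/N)^M ~ exp(-n*f).  Conditioning on
the fate splits the prior into a "spleen" (survivor) and an "apo"
(deleted) posterior over n.  Discrimination quality is summarized by
the AUC between the two discrete distributions, which improves when the
scores of m TCRs are pooled, and is mirrored in the periphery by
discrimination of self vs foreign peptides by R recruited T cells; the
two tasks face identically separated Poisson pairs when p*R = m*n_bar.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

_TAIL = 1e-12


@dataclass
class QuorumParams:
    """Parameters of the Poisson recognition model.

    p: per-peptide recognition probability; N: number of self-peptides;
    f: fraction screened in the thymus (M = f*N).
    """

    p: float
    N: int
    f: float

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p must be in (0, 1)")
        if not 0 < self.f < 1:
            raise ValueError("f must be in (0, 1)")
        if self.N < 1:
            raise ValueError("N must be >= 1")

    @property
    def n_bar(self) -> float:
        """Mean number of recognized self-peptides, p*N."""
        return self.p * self.N

    @property
    def M(self) -> float:
        """Number of screened self-peptides, f*N."""
        return self.f * self.N


def _support(mean: float, shift: int = 0) -> np.ndarray:
    hi = int(stats.poisson.ppf(1 - _TAIL, max(mean, 1e-12))) + shift + 1
    return np.arange(0, hi + 1)


def _poisson_pmf(ns: np.ndarray, mean: float, shift: int = 0) -> np.ndarray:
    return stats.poisson.pmf(ns - shift, mean)


def fate_posterior(params: QuorumParams, fate: str,
                   mode: str = "small_f",
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of n conditioned on the selection fate.

    ``small_f``: spleen ~ Poisson(pN(1-f)); apo ~ the shifted
    Poisson P(n) = Poiss[pN](n-1) (small-f limit).  ``exact_tilt``: the
    exact Bayes update of the Poisson(pN) prior by the survival factor
    exp(-n f) — which is again Poisson with mean pN e^(-f) for spleen —
    and its normalized complement for apo.  Returns ``(ns, probs)``
    with truncated tail mass below 1e-12.
    """
    nb = params.n_bar
    if fate not in ("spleen", "apo"):
        raise ValueError(f"unknown fate {fate!r}")
    if mode == "small_f":
        if fate == "spleen":
            mean = nb * (1 - params.f)
            ns = _support(mean)
            return ns, _poisson_pmf(ns, mean)
        ns = _support(nb, shift=1)
        return ns, _poisson_pmf(ns, nb, shift=1)
    if mode == "exact_tilt":
        ns = _support(nb, shift=1)
        prior = _poisson_pmf(ns, nb)
        surv = np.exp(-ns * params.f)
        if fate == "spleen":
            post = prior * surv
        else:
            post = prior * (1 - surv)
        return ns, post / post.sum()
    raise ValueError(f"unknown mode {mode!r}")


def discrete_auc(dist_x: tuple[np.ndarray, np.ndarray],
                 dist_y: tuple[np.ndarray, np.ndarray]) -> float:
    """AUC = P(X < Y) + 0.5 P(X = Y) for two distributions over the
    non-negative integers, by exact summation."""
    xs, px = dist_x
    ys, py = dist_y
    for p in (px, py):
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError("input distribution is not normalized")
    hi = int(max(xs.max(), ys.max()))
    fx = np.zeros(hi + 1)
    fy = np.zeros(hi + 1)
    fx[xs[xs <= hi]] = px[xs <= hi]
    fy[ys[ys <= hi]] = py[ys <= hi]
    cdf_x = np.cumsum(fx)
    auc = float((fy[1:] * cdf_x[:-1]).sum() + 0.5 * (fy * fx).sum())
    return auc


def thymic_discrimination_auc(params: QuorumParams, m: int = 1) -> float:
    """AUC for telling apo from spleen TCRs from the pooled scores of m
    TCRs: Poisson(m*n_bar*(1-f)) vs m + Poisson(m*n_bar)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    nb = params.n_bar
    mean_s = m * nb * (1 - params.f)
    mean_a = m * nb
    ns_s = _support(mean_s)
    ns_a = _support(mean_a, shift=m)
    return discrete_auc((ns_s, _poisson_pmf(ns_s, mean_s)),
                        (ns_a, _poisson_pmf(ns_a, mean_a, shift=m)))


def peripheral_discrimination_auc(p: float, R: float, f: float) -> float:
    """AUC for telling a self peptide (recognized by Poisson(p(1-f)R)
    recruited T cells) from a foreign one (Poisson(pR))."""
    if p * R <= 0:
        raise ValueError("p*R must be positive")
    if not 0 <= f < 1:
        raise ValueError("f must be in [0, 1)")
    mean_self = p * (1 - f) * R
    mean_foreign = p * R
    ns_s = _support(mean_self)
    ns_f = _support(mean_foreign)
    return discrete_auc((ns_s, _poisson_pmf(ns_s, mean_self)),
                        (ns_f, _poisson_pmf(ns_f, mean_foreign)))


def matched_peripheral_recruitment(params: QuorumParams, m: int) -> float:
    """The recruitment size R with p*R = m*n_bar, at which peripheral
    discrimination faces the same Poisson mean pair (up to the unit
    shift) as the m-TCR thymic task."""
    return m * params.n_bar / params.p
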