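"""Linear selection models over a generative background.

A maturation stage is modelled as

    P_stage(sigma) = (1/Z) * exp(-E_stage(sigma)) * P_gen(sigma),
    E_stage(sigma) = sum of eps(f) over the features f active in sigma,

with Z the mean of exp(-E) over the background ensemble.  The sign
convention follows the energy form above: features *enriched* by
selection carry *negative* eps, and the per-feature enrichment factor is
exp(-eps).  Fitting maximizes the mean log-likelihood of the stage data
over the background with an L2 penalty on eps, which at the optimum
matches model feature marginals (exp(-E)-reweighted background
marginals) to data marginals.

Monte-Carlo estimators for the model entropy and for Jensen-Shannon
divergences between stage models, per-sequence differential-enrichment
comparisons, and the stage-wide hydrophobicity score live here too.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp
from scipy import optimize, stats

from .constants import HYDROPHOBIC_AA
from .feature_encoding import FeatureScheme, data_marginals, encode_matrix
from .hydrophobicity import (CENTRAL_LEFT_POSITIONS, CENTRAL_RIGHT_POSITIONS,
                             hydrophobicity_index_u)
from .repertoire_io import Clonotype, Repertoire
from .synthetic_data import GenerationModel, generate_repertoire

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

__all__ = [
    "BackgroundSample", "SelectionModel", "StageComparison",
    "ConvergenceError", "fit_selection_model", "evaluate", "sample",
    "feature_enrichment_difference", "hydrophobicity_score_U",
    "hydrophobicity_index_u", "model_entropy", "model_jsd",
    "compare_stage_energies", "MonteCarloEstimate",
]


class ConvergenceError(RuntimeError):
    """Optimization stopped before reaching the marginal tolerance."""

    def __init__(self, residual: float, tol: float):
        self.residual = residual
        super().__init__(f"fit did not converge: marginal residual "
                         f"{residual:.2e} > tol {tol:.2e}")


class MonteCarloEstimate(NamedTuple):
    value: float
    std: float
    n: int


@dataclass
class BackgroundSample:
    """A background ensemble: encoded draws plus their Pgen values."""

    repertoire: Repertoire
    X: sp.csr_matrix
    gen_model: GenerationModel | None = None

    @property
    def log2_pgen(self) -> np.ndarray | None:
        return self.repertoire.log2_pgen

    def __len__(self) -> int:
        return self.X.shape[0]

    @classmethod
    def from_model(cls, model: GenerationModel, n: int, seed: int,
                   scheme: FeatureScheme) -> "BackgroundSample":
        rep = generate_repertoire(model, n, seed)
        return cls(rep, encode_matrix(rep, scheme), gen_model=model)

    @classmethod
    def from_repertoire(cls, rep: Repertoire, scheme: FeatureScheme,
                        gen_model: GenerationModel | None = None,
                        ) -> "BackgroundSample":
        return cls(rep, encode_matrix(rep, scheme), gen_model=gen_model)


@dataclass
class SelectionModel:
    """Fitted stage model: per-feature energies and normalization."""

    scheme: FeatureScheme
    epsilons: np.ndarray
    log_z: float
    background: BackgroundSample
    marginals: np.ndarray            # model marginals at the optimum
    stage: str = "stage"

    def __post_init__(self) -> None:
        if len(self.epsilons) != self.scheme.dimension:
            raise ValueError("epsilons length != scheme dimension")

    @property
    def z(self) -> float:
        return math.exp(self.log_z)

    def energies(self, X: sp.csr_matrix | Repertoire) -> np.ndarray:
        """E(sigma) for each row of an encoded matrix or repertoire."""
        if not sp.issparse(X):
            X = encode_matrix(X, self.scheme)
        return X @ self.epsilons

    def enrichment_factors(self) -> np.ndarray:
        """Per-feature multiplicative enrichment exp(-eps)."""
        return np.exp(-self.epsilons)


def zero_selection_model(background: BackgroundSample,
                         scheme: FeatureScheme) -> SelectionModel:
    """The null model E == 0, i.e. P_stage == P_gen (Z = 1)."""
    return SelectionModel(scheme, np.zeros(scheme.dimension), 0.0,
                          background, data_marginals(background.X),
                          stage="pre-selection")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _log_mean_exp_neg(e: np.ndarray) -> tuple[float, np.ndarray]:
    """log(mean(exp(-e))) and the normalized weights, stably."""
    m = e.min()
    w = np.exp(-(e - m))
    s = w.sum()
    return float(-m + np.log(s / e.size)), w / s


def fit_selection_model(data: Repertoire, background, scheme: FeatureScheme,
                        l2: float = 1e-4, tol: float = 1e-4,
                        max_iter: int = 1000, seed: int = 0,
                        background_size: int | None = None,
                        stage: str | None = None) -> SelectionModel:
    """Fit per-feature energies by penalized maximum likelihood.

    ``background`` is a :class:`GenerationModel` (a sample is generated:
    ``background_size`` draws, default ``max(3e5, len(data))``), a
    :class:`Repertoire` of background draws, or a ready
    :class:`BackgroundSample`.  Convergence requires the penalized
    gradient (model-minus-data marginal residual, shifted by the L2
    term) to drop below ``tol`` in the max norm; failure raises
    :class:`ConvergenceError` carrying the residual.  Features absent
    from both data and background are fixed at eps = 0 with a warning.
    """
    if len(data) == 0:
        raise ValueError("data repertoire is empty")
    if isinstance(background, GenerationModel):
        n_bg = background_size or max(300_000, len(data))
        bg = BackgroundSample.from_model(background, n_bg, seed, scheme)
    elif isinstance(background, Repertoire):
        bg = BackgroundSample.from_repertoire(background, scheme)
    elif isinstance(background, BackgroundSample):
        bg = background
    else:
        raise TypeError("background must be a GenerationModel, Repertoire "
                        "or BackgroundSample")

    X_d = encode_matrix(data, scheme)
    X_b = bg.X
    p_data = data_marginals(X_d)
    p_bg = data_marginals(X_b)
    free = (p_data > 0) | (p_bg > 0)
    n_fixed = int((~free).sum())
    if n_fixed:
        logger.warning("%d features absent from data and background; "
                       "their energies are fixed at 0", n_fixed)

    Xd = X_d[:, free].tocsr()
    Xb = X_b[:, free].tocsr()
    pd_free = p_data[free]

    def objective(eps: np.ndarray) -> tuple[float, np.ndarray]:
        e_d = Xd @ eps
        e_b = Xb @ eps
        log_z, w = _log_mean_exp_neg(e_b)
        p_model = Xb.T @ w
        f = float(e_d.mean()) + log_z + 0.5 * l2 * float(eps @ eps)
        grad = pd_free - p_model + l2 * eps
        return f, grad

    res = optimize.minimize(
        objective, np.zeros(int(free.sum())), jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "maxfun": 4 * max_iter,
                 "ftol": 1e-14, "gtol": 0.25 * tol})

    eps_free = res.x
    _, grad = objective(eps_free)
    residual = float(np.abs(grad).max())
    if residual > tol:
        raise ConvergenceError(residual, tol)

    epsilons = np.zeros(scheme.dimension)
    epsilons[free] = eps_free
    e_b = X_b @ epsilons
    log_z, w = _log_mean_exp_neg(e_b)
    marginals = np.asarray(X_b.T @ w).ravel()
    return SelectionModel(scheme, epsilons, log_z, bg, marginals,
                          stage=stage or data.stage)


def gauge_basis(scheme: FeatureScheme) -> np.ndarray:
    """Orthonormal basis of the energy gauge space of a scheme.

    The encoding is over-parametrized: exactly one length, V and J
    feature is active per sequence, and the position-k features are
    active exactly when L >= k.  Shifting all features of such a group
    by a constant (compensated, for positional groups, on the length
    features of the tail L >= k) changes every sequence energy by the
    same constant, which is absorbed by Z — the probability model is
    unchanged.  Energies are therefore only identifiable modulo this
    span; its minimum-norm complement is the canonical representative.
    """
    s = scheme
    k = len(s.alphabet)
    d = s.dimension
    lengths = np.arange(s.max_len)
    vecs = []

    def tail(kpos: int) -> np.ndarray:
        v = np.zeros(d)
        v[lengths[kpos - 1:]] = 1.0  # length features with L >= kpos
        return v

    all_lengths = tail(1)
    for i in range(s.n_positions):
        for off in (s._off_left, s._off_right):
            v = -tail(i + 1)
            v[off + i * k: off + (i + 1) * k] = 1.0
            vecs.append(v)
    for lo, hi in ((s._off_v, s._off_j),
                   (s._off_j, s._off_j + len(s.j_genes))):
        v = -all_lengths.copy()
        v[lo:hi] = 1.0
        vecs.append(v)
    if s.include_joint_vj:
        v = -all_lengths.copy()
        v[s._off_vj:] = 1.0
        vecs.append(v)
    q, _ = np.linalg.qr(np.stack(vecs, axis=1))
    return q


def gauge_fix(epsilons: np.ndarray, scheme: FeatureScheme,
              basis: np.ndarray | None = None) -> np.ndarray:
    """Project energies onto the minimum-norm gauge representative."""
    q = gauge_basis(scheme) if basis is None else basis
    return epsilons - q @ (q.T @ epsilons)


def save_model(model: SelectionModel, path) -> None:
    """Serialize a fitted model (scheme, eps table, Z) as JSON.

    The background sample itself is not stored; reloading requires one.
    """
    import json
    from pathlib import Path
    Path(path).write_text(json.dumps({
        "stage": model.stage,
        "log_z": model.log_z,
        "scheme": {"v_genes": model.scheme.v_genes,
                   "j_genes": model.scheme.j_genes,
                   "include_joint_vj": model.scheme.include_joint_vj,
                   "max_len": model.scheme.max_len,
                   "n_positions": model.scheme.n_positions,
                   "alphabet": model.scheme.alphabet},
        "epsilons": {f: e for f, e in zip(model.scheme.feature_names,
                                          model.epsilons.tolist()) if e != 0.0},
    }, indent=1))


def load_model(path, background: BackgroundSample) -> SelectionModel:
    """Reload a model saved by :func:`save_model` onto a background."""
    import json
    from pathlib import Path
    d = json.loads(Path(path).read_text())
    scheme = FeatureScheme(**d["scheme"])
    eps = np.zeros(scheme.dimension)
    for f, e in d["epsilons"].items():
        eps[scheme.index[f]] = e
    e_b = background.X @ eps
    _, w = _log_mean_exp_neg(e_b)
    marginals = np.asarray(background.X.T @ w).ravel()
    return SelectionModel(scheme, eps, d["log_z"], background, marginals,
                          stage=d["stage"])


# ---------------------------------------------------------------------------
# Evaluation and sampling
# ---------------------------------------------------------------------------

def evaluate(model: SelectionModel, c: Clonotype) -> tuple[float, float]:
    """(energy E, log2 P_stage) for one clonotype.

    ``log2 P_stage = -E/ln2 + log2 Pgen - log2 Z``; requires the
    background to carry a generation model for Pgen.
    """
    idx = model.scheme.encode(c)
    energy = float(model.epsilons[idx].sum())
    if model.background.gen_model is None:
        raise ValueError("background carries no generation model; "
                         "Pgen unavailable")
    log2_pgen = model.background.gen_model.log2_pgen(c.v_gene, c.j_gene,
                                                     c.cdr3_aa)
    return energy, -energy / LN2 + log2_pgen - model.log_z / LN2


def _energy_lower_bound(model: SelectionModel) -> float:
    """A valid lower bound on E over the scheme's support."""
    s, eps = model.scheme, model.epsilons
    k = len(s.alphabet)
    lb = float(eps[:s.max_len].min())          # exactly one length feature
    for i in range(s.n_positions):             # positional features may be absent
        lb += min(0.0, float(eps[s._off_left + i * k:s._off_left + (i + 1) * k].min()))
        lb += min(0.0, float(eps[s._off_right + i * k:s._off_right + (i + 1) * k].min()))
    lb += float(eps[s._off_v:s._off_j].min())
    lb += float(eps[s._off_j:s._off_j + len(s.j_genes)].min())
    if s.include_joint_vj:
        lb += float(eps[s._off_vj:].min())
    return lb


def sample(model: SelectionModel, n: int, seed: int,
           batch: int = 50_000) -> Repertoire:
    """Rejection-sample ``n`` clonotypes from P_stage.

    Background draws are accepted with probability exp(-(E - E_lb)),
    E_lb a per-feature-group lower bound on the energy, making accepted
    draws exact samples from P_stage.  An acceptance rate below 1e-4
    raises with advice to rescale the energies.
    """
    if n == 0:
        return Repertoire([], stage=model.stage)
    gen = model.background.gen_model
    if gen is None:
        raise ValueError("sampling requires a generation-model background")
    e_lb = _energy_lower_bound(model)
    rng = np.random.default_rng(seed)
    kept: list[Clonotype] = []
    kept_lp: list[np.ndarray] = []
    proposed = 0
    while sum(len(x) for x in kept_lp) < n:
        rep = generate_repertoire(gen, batch, int(rng.integers(2 ** 31)),
                                  stage=model.stage)
        e = model.energies(rep)
        acc = rng.random(batch) < np.exp(-(e - e_lb))
        proposed += batch
        sub = rep.subset(acc)
        kept.extend(sub.clonotypes)
        kept_lp.append(sub.log2_pgen)
        n_kept = sum(len(x) for x in kept_lp)
        if proposed >= 2 * batch and n_kept / proposed < 1e-4:
            raise RuntimeError(
                "acceptance rate below 1e-4; rescale the energies or "
                "tighten the energy bound")
    lp = np.concatenate(kept_lp)[:n]
    return Repertoire(kept[:n], stage=model.stage, log2_pgen=lp)


# ---------------------------------------------------------------------------
# Feature-level comparisons
# ---------------------------------------------------------------------------

def feature_enrichment_difference(model_a: SelectionModel,
                                  model_b: SelectionModel) -> np.ndarray:
    """Average weight difference per feature between two stage models:
    ``(p_a(f)+p_b(f))/2 * (eps_a(f) - eps_b(f))`` with model marginals."""
    if model_a.scheme.feature_names != model_b.scheme.feature_names:
        raise ValueError("models use different feature schemes")
    return ((model_a.marginals + model_b.marginals) / 2.0
            * (model_a.epsilons - model_b.epsilons))


def hydrophobicity_score_U(model: SelectionModel,
                           gen_marginals: np.ndarray) -> float:
    """Stage-wide hydrophobicity score: sum over hydrophobic amino acids
    (CFILMWY) and the central positional windows (left 5..11, right
    -11..-5) of eps(a|x) times the background positional marginal.

    Under the e^(-E) sign convention a *more* hydrophobic-enriched stage
    has a *lower* U.
    """
    idx = model.scheme.index
    total = 0.0
    for aa in sorted(HYDROPHOBIC_AA):
        for i in CENTRAL_LEFT_POSITIONS:
            f = idx[f"left_{i}_{aa}"]
            total += model.epsilons[f] * gen_marginals[f]
        for i in CENTRAL_RIGHT_POSITIONS:
            f = idx[f"right_{i}_{aa}"]
            total += model.epsilons[f] * gen_marginals[f]
    return float(total)


# ---------------------------------------------------------------------------
# Entropy and divergence of full models
# ---------------------------------------------------------------------------

def model_entropy(model: SelectionModel, n_samples: int,
                  seed: int) -> MonteCarloEstimate:
    """Shannon entropy of P_stage in bits, by Monte Carlo:
    ``S = -(1/N) sum log2 P_stage(sigma*)`` over draws from P_stage."""
    rep = sample(model, n_samples, seed)
    e = model.energies(rep)
    log2_p = -e / LN2 + rep.log2_pgen - model.log_z / LN2
    return MonteCarloEstimate(float(-log2_p.mean()),
                              float(log2_p.std(ddof=1) / math.sqrt(n_samples)),
                              n_samples)


def _shared_background(a: SelectionModel, b: SelectionModel) -> None:
    if a.background is b.background:
        return
    ga, gb = a.background.gen_model, b.background.gen_model
    if ga is not None and ga is gb:
        return
    raise ValueError("models must share a common background")


def model_jsd(model_a: SelectionModel, model_b: SelectionModel,
              n_samples: int, seed: int) -> MonteCarloEstimate:
    """Jensen-Shannon divergence between two stage models, in bits.

    Because both models share the background Pgen, the log-ratio of the
    stage probabilities reduces to normalized energies
    ``E~ = E + ln Z``; each half is averaged over samples from the
    corresponding model.
    """
    _shared_background(model_a, model_b)
    rng = np.random.default_rng(seed)
    out = []
    for first, second in ((model_a, model_b), (model_b, model_a)):
        rep = sample(first, n_samples, int(rng.integers(2 ** 31)))
        X = encode_matrix(rep, first.scheme)
        d = ((X @ second.epsilons + second.log_z)
             - (X @ first.epsilons + first.log_z))  # E~_other - E~_own
        term = 1.0 - np.logaddexp(0.0, -d) / LN2
        out.append((term.mean(), term.var(ddof=1) / n_samples))
    value = 0.5 * (out[0][0] + out[1][0])
    std = 0.5 * math.sqrt(out[0][1] + out[1][1])
    return MonteCarloEstimate(float(value), float(std), 2 * n_samples)


# ---------------------------------------------------------------------------
# Differential enrichment between stages
# ---------------------------------------------------------------------------

@dataclass
class StageComparison:
    """Per-sequence differential energies of two stages over a common
    background, their Pearson correlation and the principal axis of the
    point cloud (leading eigenvector of the second-moment matrix)."""

    delta_a: np.ndarray
    delta_b: np.ndarray
    pearson_r: float
    principal_axis: np.ndarray


def compare_stage_energies(model_a: SelectionModel, model_b: SelectionModel,
                           model_common: SelectionModel, probe: Repertoire,
                           centered: bool = False) -> StageComparison:
    """Differential enrichment ``E_stage - E_common`` of two stages on a
    probe of background draws, with Pearson r and the major axis."""
    if len(probe) < 100:
        raise ValueError("probe repertoire too small (< 100)")
    if not (model_a.scheme.feature_names == model_b.scheme.feature_names
            == model_common.scheme.feature_names):
        raise ValueError("all models must share the feature scheme")
    X = encode_matrix(probe, model_a.scheme)
    e_c = X @ model_common.epsilons
    da = X @ model_a.epsilons - e_c
    db = X @ model_b.epsilons - e_c
    r = float(stats.pearsonr(da, db).statistic)
    x, y = (da - da.mean(), db - db.mean()) if centered else (da, db)
    m = np.array([[np.mean(x * x), np.mean(x * y)],
                  [np.mean(x * y), np.mean(y * y)]])
    _, vecs = np.linalg.eigh(m)
    axis = vecs[:, -1]
    if axis[0] < 0:
        axis = -axis
    return StageComparison(da, db, r, axis)
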