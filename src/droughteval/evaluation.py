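"""Comprehensive drought-resistance evaluation.

The pipeline turns a stage-mean :class:`~droughteval.data_model.SampleMatrix`
into a genotype ranking:

1.  z-score standardization of each indicator column;
2.  PCA on the indicator correlation matrix (eigenvalues sum to the number
    of indicators p; the variance fraction of component j is lambda_j / p);
3.  retention of the smallest leading set of components whose cumulative
    variance fraction reaches a threshold (default 85%), or a forced count;
4.  membership (min-max) transformation of each retained component's score
    column, pooled over all genotype x stage samples:
    mu(x) = (x - min) / (max - min), or 1 - that for the "anti" orientation
    when larger scores indicate worse stress performance;
5.  weights proportional to the retained components' variance contributions,
    W_j = V_j / sum(V);
6.  composite index D(i) = sum_j mu_j(i) * W_j in [0, 1], averaged over each
    genotype's stages, and a dense rank by descending average D (larger D =
    stronger drought resistance).

Eigenvectors have arbitrary sign; three deterministic orientation rules are
provided (largest-coefficient-positive, direction-tag anchoring, explicit
indicator anchors), plus per-component direct/anti membership overrides.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import Direction, SampleMatrix
from .errors import DegenerateDataError, EvaluationError

__all__ = [
    "PCAResult",
    "EvaluationResult",
    "EvaluationConfig",
    "EvaluationOutcome",
    "standardize",
    "run_pca",
    "select_components",
    "membership",
    "compute_weights",
    "composite_score",
    "evaluate",
]


def standardize(m: SampleMatrix, ddof: int = 1) -> SampleMatrix:
    """Return a copy with each indicator column at mean 0, sd 1.

    The sd denominator convention (``ddof``) does not change the final
    membership or D values — min-max normalization absorbs any positive
    rescaling of a score column — but is configurable for report fidelity.
    """
    x = m.values
    sd = x.std(axis=0, ddof=ddof)
    constant = [m.indicators[j] for j in np.flatnonzero(sd == 0.0)]
    if constant:
        raise DegenerateDataError(f"constant indicator column(s): {constant}")
    z = (x - x.mean(axis=0)) / sd
    return SampleMatrix(
        pd.DataFrame(z, index=m.df.index, columns=m.df.columns), registry=m.registry
    )


@dataclass
class PCAResult:
    """Correlation-matrix PCA decomposition.

    ``eigenvalues`` are descending and sum to the number of indicators p;
    ``loadings`` has orthonormal columns (rows = indicators); per-component
    ``variance_fraction`` = eigenvalue / p; ``scores`` are the standardized
    samples projected onto the loadings (zero-mean columns).
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    variance_fraction: np.ndarray
    scores: pd.DataFrame

    @property
    def components(self) -> list[str]:
        return list(self.loadings.columns)

    @property
    def cumulative_fraction(self) -> np.ndarray:
        return np.cumsum(self.variance_fraction)


def _orient_sign(vec: np.ndarray, indicators, orientation, anchors, registry, pc) -> float:
    if anchors and pc in anchors:
        anchor = anchors[pc]
        if anchor not in indicators:
            raise EvaluationError(f"orientation anchor {anchor!r} is not an indicator")
        coef = vec[indicators.index(anchor)]
        if coef == 0.0:
            raise EvaluationError(f"anchor {anchor!r} has zero loading on {pc}")
        return 1.0 if coef > 0 else -1.0
    if orientation == "direction" and registry is not None:
        # Vote with the higher-is-resistant block only: structural/water
        # indicators decline monotonically under stress, so their net loading
        # sign identifies the "better condition" direction of a component.
        # Stress markers rise both as damage and as active defense, so their
        # loadings are an ambiguous orientation signal and only break ties.
        def _block(direction):
            return sum(
                coef
                for code, coef in zip(indicators, vec)
                if code in registry and registry.direction(code) is direction
            )

        signed = _block(Direction.HIGHER_IS_RESISTANT)
        if signed == 0.0:
            signed = -_block(Direction.HIGHER_IS_STRESSED)
        if signed != 0.0:
            return 1.0 if signed > 0 else -1.0
        # fall through to max-loading rule on a balanced component
    j = int(np.argmax(np.abs(vec)))
    return 1.0 if vec[j] >= 0 else -1.0


def run_pca(
    m: SampleMatrix,
    orientation: str = "max_loading",
    anchors: dict[str, str] | None = None,
    ddof: int = 1,
) -> PCAResult:
    """Eigendecomposition of the indicator correlation matrix.

    Parameters
    ----------
    m
        Sample matrix (raw or standardized; the correlation matrix is
        scale-free).  Needs >= 3 samples and no constant column.
    orientation
        ``"max_loading"``: each eigenvector's largest-magnitude coefficient
        is made positive (deterministic default).  ``"direction"``: each
        component is flipped so that the indicators tagged
        higher-is-resistant load net-positively, making larger scores mean
        better structural/water condition.
    anchors
        Per-component override, e.g. ``{"PC1": "Lth"}`` forces the leaf
        thickness loading on PC1 positive (used to match an external
        loading table).
    """
    if m.n_samples < 3:
        raise EvaluationError(f"need >= 3 samples for PCA, got {m.n_samples}")
    z = standardize(m, ddof=ddof)
    p = len(m.indicators)
    corr = np.corrcoef(m.values, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    pcs = [f"PC{j + 1}" for j in range(p)]
    for j, pc in enumerate(pcs):
        eigvecs[:, j] *= _orient_sign(
            eigvecs[:, j], m.indicators, orientation, anchors, m.registry, pc
        )
    loadings = pd.DataFrame(eigvecs, index=m.indicators, columns=pcs)
    scores = pd.DataFrame(z.values @ eigvecs, index=m.df.index, columns=pcs)
    return PCAResult(eigvals, loadings, eigvals / p, scores)


def select_components(
    pca: PCAResult, threshold: float = 0.85, force_k: int | None = None
) -> list[str]:
    """Leading components kept for the evaluation.

    The rule is the smallest k whose cumulative variance fraction reaches
    ``threshold``; ``force_k`` overrides it (some published analyses retain
    one extra component beyond the threshold).
    """
    if force_k is not None:
        if not 1 <= force_k <= len(pca.components):
            raise EvaluationError(f"forced component count {force_k} out of range")
        return pca.components[:force_k]
    if not 0.0 < threshold <= 1.0:
        raise EvaluationError(f"retention threshold must be in (0, 1], got {threshold}")
    cum = pca.cumulative_fraction
    k = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    k = min(k, len(pca.components))
    return pca.components[:k]


def membership(x, orientation: str = "direct") -> np.ndarray:
    """Min-max membership transform of one score column, pooled over samples.

    ``direct``: mu = (x - min) / (max - min), so the pooled maximum maps to 1.
    ``anti``: 1 - mu, for components where larger scores mean worse stress
    performance.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateDataError("constant score column: membership undefined")
    mu = (x - lo) / (hi - lo)
    if orientation == "anti":
        return 1.0 - mu
    if orientation != "direct":
        raise EvaluationError(f"unknown membership orientation: {orientation}")
    return mu


def compute_weights(variance_contributions) -> np.ndarray:
    """Normalize component variance contributions to weights summing to 1."""
    v = np.asarray(variance_contributions, dtype=float)
    if (v < 0).any():
        raise EvaluationError("variance contributions must be non-negative")
    total = v.sum()
    if total == 0:
        raise DegenerateDataError("all variance contributions are zero")
    return v / total


@dataclass
class EvaluationResult:
    """Per-sample composite index D, genotype averages, and dense ranks."""

    per_sample: pd.DataFrame      # index (genotype, stage); column "D"
    per_genotype: pd.DataFrame    # index genotype; columns "average_D", "rank"
    ties: bool = False

    @property
    def ranking(self) -> list[str]:
        return list(self.per_genotype.sort_values("rank").index)


def composite_score(mu: pd.DataFrame, weights) -> EvaluationResult:
    """Weighted membership sum D(i) = sum_j mu_j(i) * W_j and genotype ranks.

    Genotype average D is the mean of D over that genotype's stages; the
    dense rank is by descending average (rank 1 = most drought resistant).
    Exact ties share a rank and are flagged; ordering within ties follows
    genotype label order.
    """
    w = np.asarray(weights, dtype=float)
    if mu.shape[1] != w.size:
        raise EvaluationError(
            f"membership has {mu.shape[1]} components but {w.size} weights"
        )
    vals = mu.to_numpy(dtype=float)
    if ((vals < -1e-12) | (vals > 1 + 1e-12)).any():
        raise EvaluationError("membership values must lie in [0, 1]")
    d = vals @ w
    per_sample = pd.DataFrame({"D": d}, index=mu.index)
    genotypes = [idx[0] for idx in mu.index]
    avg = per_sample.groupby(genotypes)["D"].mean().sort_index()
    # dense rank by descending average D
    uniq = sorted(set(avg.to_numpy()), reverse=True)
    rank = avg.map(lambda v: uniq.index(v) + 1).astype(int)
    per_genotype = pd.DataFrame({"average_D": avg, "rank": rank})
    per_genotype = per_genotype.sort_values(
        ["rank", "average_D"], ascending=[True, False]
    )
    return EvaluationResult(per_sample, per_genotype, ties=len(uniq) < len(avg))


@dataclass
class EvaluationConfig:
    """Tunables of the evaluation pipeline.

    retention_threshold
        Cumulative variance fraction required of the retained components.
    n_components
        Forced component count overriding the threshold rule.
    orientation / anchors
        Eigenvector sign rule; see :func:`run_pca`.
    membership_orientation
        Per-component {"PC1": "direct" | "anti"} override; default direct.
    ddof
        Standard-deviation denominator (n - ddof) used in standardization.
    """

    retention_threshold: float = 0.85
    n_components: int | None = None
    orientation: str = "max_loading"
    anchors: dict[str, str] | None = None
    membership_orientation: dict[str, str] = field(default_factory=dict)
    ddof: int = 1


@dataclass
class EvaluationOutcome:
    pca: PCAResult
    retained: list[str]
    membership: pd.DataFrame
    weights: np.ndarray
    result: EvaluationResult


def evaluate(m: SampleMatrix, config: EvaluationConfig | None = None) -> EvaluationOutcome:
    """Run the full standardize -> PCA -> membership -> weights -> D pipeline."""
    config = config or EvaluationConfig()
    pca = run_pca(m, orientation=config.orientation, anchors=config.anchors, ddof=config.ddof)
    retained = select_components(pca, config.retention_threshold, config.n_components)
    mu = pd.DataFrame(
        {
            pc: membership(
                pca.scores[pc], config.membership_orientation.get(pc, "direct")
            )
            for pc in retained
        },
        index=pca.scores.index,
    )
    weights = compute_weights(pca.variance_fraction[: len(retained)])
    result = composite_score(mu, weights)
    return EvaluationOutcome(pca, retained, mu, weights, result)
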