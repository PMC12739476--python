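"""Packaged reference tables from a published camellia drought trial.

A drought-resistance study of *Camellia reticulata* and *C. sasanqua*
(five stress stages, 18 leaf-anatomy/stomatal/physiological indicators)
published its PCA loading matrix, eigenvalues and variance contributions,
and the membership values of the three retained components for each
genotype x stage sample — but not the raw replicate data.  These printed
tables are shipped here as regression fixtures: the weights, composite D
values and ranking can be recomputed from them with this package's
evaluation functions and compared against the published summary.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evaluation import EvaluationResult, composite_score, compute_weights

__all__ = [
    "load_loadings",
    "load_pca_summary",
    "load_membership",
    "reference_evaluation",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("droughteval.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_loadings() -> pd.DataFrame:
    """Published loading matrix: 18 indicators x 3 retained components."""
    return _read("camellia_loadings.csv").set_index("indicator")


def load_pca_summary() -> pd.DataFrame:
    """Eigenvalues, variance percentages and cumulative percentages."""
    return _read("camellia_pca_summary.csv").set_index("statistic")


def load_membership() -> pd.DataFrame:
    """Membership values mu(1..3) per species x stage sample."""
    df = _read("camellia_membership.csv")
    return df.set_index(["species", "stage"])


def reference_evaluation() -> tuple[EvaluationResult, pd.Series]:
    """Recompute weights, per-sample D, genotype averages and ranks from the
    packaged membership and variance tables.

    Returns the evaluation result and the weight vector (indexed PC1..PC3).
    """
    summary = load_pca_summary()
    weights = compute_weights(summary.loc["variance_pct"].to_numpy())
    mu = load_membership()
    mu.columns = ["PC1", "PC2", "PC3"]
    result = composite_score(mu, weights)
    return result, pd.Series(weights, index=["PC1", "PC2", "PC3"], name="weight")
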