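"""Publication-style report writers.

All CSV reports round to 3 decimals for readability; a sidecar
``evaluation.json`` carries every intermediate at full precision so the
rounded tables never feed back into computation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import EvaluationOutcome
from .screening import CorrelationMatrix

__all__ = ["write_evaluation_bundle", "loading_table", "membership_table"]

_ROUND = 3


def loading_table(outcome: EvaluationOutcome) -> pd.DataFrame:
    """Loading matrix of the retained components with eigenvalue, variance
    percentage and cumulative percentage summary rows appended."""
    k = len(outcome.retained)
    load = outcome.pca.loadings.iloc[:, :k].copy()
    eig = outcome.pca.eigenvalues[:k]
    var_pct = outcome.pca.variance_fraction[:k] * 100.0
    cum_pct = np.cumsum(var_pct)
    summary = pd.DataFrame(
        [eig, var_pct, cum_pct],
        index=["eigenvalue", "variance_pct", "cumulative_pct"],
        columns=load.columns,
    )
    out = pd.concat([load, summary])
    out.index.name = "indicator"
    return out


def membership_table(outcome: EvaluationOutcome) -> pd.DataFrame:
    """Membership columns with per-sample D, genotype average D and rank."""
    mu = outcome.membership.copy()
    mu.columns = [f"mu_{pc}" for pc in mu.columns]
    mu["D"] = outcome.result.per_sample["D"]
    genotypes = [idx[0] for idx in mu.index]
    mu["average_D"] = [
        outcome.result.per_genotype.loc[g, "average_D"] for g in genotypes
    ]
    mu["rank"] = [int(outcome.result.per_genotype.loc[g, "rank"]) for g in genotypes]
    mu.index = pd.MultiIndex.from_tuples(list(mu.index), names=["genotype", "stage"])
    return mu


def _full_precision_payload(outcome: EvaluationOutcome) -> dict:
    return {
        "eigenvalues": outcome.pca.eigenvalues.tolist(),
        "variance_fraction": outcome.pca.variance_fraction.tolist(),
        "loadings": {
            pc: outcome.pca.loadings[pc].to_dict() for pc in outcome.pca.components
        },
        "scores": {
            pc: outcome.pca.scores[pc].tolist() for pc in outcome.pca.components
        },
        "sample_labels": [list(idx) for idx in outcome.pca.scores.index],
        "retained": outcome.retained,
        "weights": outcome.weights.tolist(),
        "membership": {pc: outcome.membership[pc].tolist() for pc in outcome.retained},
        "per_sample_D": outcome.result.per_sample["D"].tolist(),
        "per_genotype": {
            g: {
                "average_D": float(row["average_D"]),
                "rank": int(row["rank"]),
            }
            for g, row in outcome.result.per_genotype.iterrows()
        },
        "ties": bool(outcome.result.ties),
    }


def write_evaluation_bundle(
    outcome: EvaluationOutcome,
    outdir,
    correlation: CorrelationMatrix | None = None,
    stage_comparisons: pd.DataFrame | None = None,
    anova: pd.DataFrame | None = None,
    heatmap: bool = False,
) -> list[Path]:
    """Write the full report bundle; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    def _csv(df: pd.DataFrame, name: str, index=True):
        path = outdir / name
        df.round(_ROUND).to_csv(path, index=index)
        written.append(path)

    _csv(loading_table(outcome), "loadings.csv")
    _csv(membership_table(outcome), "membership.csv")
    weights = pd.DataFrame({"component": outcome.retained, "weight": outcome.weights})
    _csv(weights, "weights.csv", index=False)
    ranking = outcome.result.per_genotype.reset_index(names="genotype")
    _csv(ranking, "ranking.csv", index=False)
    if correlation is not None:
        _csv(correlation.r, "correlation_r.csv")
        _csv(correlation.p, "correlation_p.csv")
        if heatmap:
            written.append(_heatmap(correlation, outdir / "correlation_heatmap.png"))
    if stage_comparisons is not None and len(stage_comparisons):
        _csv(stage_comparisons, "stage_comparisons.csv", index=False)
    if anova is not None and len(anova):
        _csv(anova, "anova.csv", index=False)
    sidecar = outdir / "evaluation.json"
    sidecar.write_text(
        json.dumps(_full_precision_payload(outcome), indent=1, sort_keys=True)
    )
    written.append(sidecar)
    return written


def _heatmap(correlation: CorrelationMatrix, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(correlation.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(correlation.labels)), correlation.labels, rotation=90)
    ax.set_yticks(range(len(correlation.labels)), correlation.labels)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
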