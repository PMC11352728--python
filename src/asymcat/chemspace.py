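"""PCA maps of the catalyst descriptor space.

A global score plot over all 34 standardized descriptors, plus per-category
(steric / geometric / electronic) first principal components used as
cross-section axes. Component signs follow a fixed rule — the loading with
the largest magnitude is made positive — so reruns and figures are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .schema import SCHEMA

__all__ = ["PCAResult", "pca_scores", "category_cross_sections", "plot_scores"]


@dataclass
class PCAResult:
    scores: pd.DataFrame  # rows = ligands, columns PC1..PCk
    loadings: pd.DataFrame  # rows = descriptors, columns PC1..PCk
    explained_variance_pct: np.ndarray


def _standardize(X: pd.DataFrame) -> pd.DataFrame:
    sd = X.std(ddof=0)
    constant = sd.index[sd < 1e-12].tolist()
    if constant:
        raise ValueError(
            f"constant column(s) {constant}: remove them before PCA"
        )
    return (X - X.mean()) / sd


def pca_scores(
    X: pd.DataFrame, n_components: int = 2, standardize: bool = True
) -> PCAResult:
    """Principal-component scores and explained-variance percentages.

    Columns are standardized to zero mean / unit variance by default (the
    descriptors mix units); components carry the deterministic sign rule.
    """
    Z = _standardize(X) if standardize else X.copy()
    if n_components > min(Z.shape):
        raise ValueError(f"n_components {n_components} exceeds rank bound {min(Z.shape)}")
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Z.to_numpy())
    loadings = pca.components_.T  # (features, components)
    for k in range(n_components):
        lead = np.argmax(np.abs(loadings[:, k]))
        if loadings[lead, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=cols),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=cols),
        explained_variance_pct=100.0 * pca.explained_variance_ratio_,
    )


def category_cross_sections(
    descriptor_table: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-category PC1 coordinates (steric, geometric, electronic).

    Returns a table of the three PC1 vectors plus each one's explained
    variance percent; categories come from the descriptor schema tags.
    """
    by_category: dict[str, list[str]] = {}
    for d in SCHEMA:
        if d.name in descriptor_table.columns:
            by_category.setdefault(d.category, []).append(d.name)
    axes = {}
    ev = {}
    for category, names in by_category.items():
        if len(names) < 2:
            raise ValueError(f"category {category!r} has fewer than 2 columns")
        res = pca_scores(descriptor_table[names], n_components=1)
        axes[f"{category}_PC1"] = res.scores["PC1"]
        ev[category] = float(res.explained_variance_pct[0])
    return pd.DataFrame(axes, index=descriptor_table.index), ev


def plot_scores(
    result: PCAResult, path: str | Path, color: pd.Series | None = None
) -> None:
    """Static score plot of the first two components."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    kwargs = {}
    if color is not None:
        kwargs = {"c": color.loc[result.scores.index], "cmap": "viridis"}
    sc = ax.scatter(result.scores["PC1"], result.scores["PC2"], s=12, **kwargs)
    if color is not None:
        fig.colorbar(sc, ax=ax, label=color.name)
    ax.set_xlabel(f"PC1 ({result.explained_variance_pct[0]:.0f}% EV)")
    ax.set_ylabel(f"PC2 ({result.explained_variance_pct[1]:.0f}% EV)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
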