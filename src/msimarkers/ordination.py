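"""Per-sample marker summaries, PCA biplots and marker correlation groups.

After the screen has fixed a set of passed marker bins, each sample
(patient by default, individual core optionally) is summarized by the mean
normalized intensity of its spots in each marker bin.  A PCA of that small
samples x markers table gives the biplot view: sample scores in the leading
principal plane together with the loading vector of every marker, showing
how the signature separates outcome groups and which markers co-vary.

Markers are additionally grouped by single-linkage on their pairwise
correlations: two markers join a group when |r| reaches the threshold, and
each member carries the sign of its correlation with the group seed, so
anti-correlated members are reported as negative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order, connected_components

from .errors import EmptyDataError, ParameterError
from .markers import MarkerResult, passed_markers
from .peaks import FeatureMatrix


@dataclass
class SampleMarkerMatrix:
    """Samples x marker-bins table of mean normalized intensities.

    ``values`` is indexed by sample id with one column per marker bin
    center; ``sample_meta`` carries the outcome group (and optional
    histotype) per sample.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("marker intensities must be non-negative")
        if not self.values.index.equals(self.sample_meta.index):
            raise ValueError("values and sample_meta must share the sample index")

    @property
    def marker_centers(self) -> np.ndarray:
        return np.asarray([float(c) for c in self.values.columns])


def sample_summary(
    fm: FeatureMatrix,
    markers: list[MarkerResult],
    by: str = "patient",
) -> SampleMarkerMatrix:
    """Mean spot intensity per sample and passed marker bin.

    ``by`` selects the sample unit: ``"patient"`` (mean over all of a
    patient's cores) or ``"roi"`` (one sample per core).
    """
    if by not in ("patient", "roi"):
        raise ParameterError("by must be 'patient' or 'roi'")
    chosen = passed_markers(markers)
    if not chosen:
        raise EmptyDataError(
            "no passed markers; relax the screen cutoffs or check the input data"
        )
    centers = [m.bin_center for m in chosen]
    col_idx = []
    for c in centers:
        j = int(np.argmin(np.abs(fm.bin_centers - c)))
        if abs(fm.bin_centers[j] - c) > 1e-9:
            raise ParameterError(f"marker bin {c} not found in the feature matrix")
        col_idx.append(j)
    df = pd.DataFrame(fm.values[:, col_idx], columns=centers)
    df[by] = fm.spot_index[by].to_numpy()
    grouped = df.groupby(by, sort=True).mean()
    meta = (
        fm.spot_index.groupby(by, sort=True)
        .agg(group=("group", "first"))
        .loc[grouped.index]
    )
    return SampleMarkerMatrix(values=grouped, sample_meta=meta)


def pca_biplot(
    smm: SampleMarkerMatrix, center: bool = True, scale: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of the sample x marker table.

    Returns ``(scores, loadings, explained_variance)``: sample projections,
    marker axes (markers x components) and per-component variances (which
    sum to the total variance of the analyzed table).  Scaling standardizes
    every marker to unit variance (correlation PCA), appropriate when
    marker intensities span different scales.  The sign of each component
    is fixed so its largest-magnitude loading is positive.
    """
    X = smm.values.to_numpy(dtype=np.float64)
    n, m = X.shape
    if n < 2 or m < 2:
        raise ParameterError("PCA needs at least 2 samples and 2 markers")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [smm.values.columns[j] for j in zero]
            raise ParameterError(f"constant marker column(s) cannot be scaled: {names}")
        X = X / sd
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # fixed sign convention: largest-|loading| per component positive
    for k in range(len(s)):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U * s
    explained = s**2 / (n - 1)
    comp_names = [f"PC{k + 1}" for k in range(len(s))]
    return (
        pd.DataFrame(scores, index=smm.values.index, columns=comp_names),
        pd.DataFrame(Vt.T, index=smm.values.columns, columns=comp_names),
        explained,
    )


def marker_correlation_groups(
    smm: SampleMarkerMatrix, threshold: float = 0.8
) -> list[list[tuple[float, int]]]:
    """Single-linkage marker groups on |pairwise correlation| >= threshold.

    Returns one list per group of ``(marker_center, sign)`` pairs; the sign
    is the member's correlation sign relative to the group seed (the first
    member), so a marker tracking the opposite trend of its group is
    reported with sign -1.
    """
    X = smm.values.to_numpy(dtype=np.float64)
    if X.shape[1] < 2:
        raise ParameterError("need at least 2 markers")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    m = corr.shape[0]
    adj = (np.abs(corr) >= threshold) & ~np.eye(m, dtype=bool)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    centers = smm.marker_centers
    groups = []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        seed = members[0]
        signs = {seed: 1}
        order, predecessors = breadth_first_order(
            csr_matrix(adj), seed, directed=False, return_predecessors=True
        )
        for node in order[1:]:
            parent = predecessors[node]
            signs[node] = signs[parent] * (1 if corr[parent, node] >= 0 else -1)
        groups.append([(float(centers[j]), signs.get(j, 1)) for j in members])
    # largest groups first, then by leading marker mass, for stable reporting
    groups.sort(key=lambda g: (-len(g), g[0][0]))
    return groups


def spatial_cv(fm: FeatureMatrix, bin_center: float) -> float:
    """Coefficient of variation of one marker bin across all tissue spots.

    A marker introduced by contamination during sample preparation would be
    spread evenly over the slide (low CV), unlike biology tracking tissue
    structure; this statistic lets users check that argument per marker.
    """
    j = int(np.argmin(np.abs(fm.bin_centers - bin_center)))
    col = fm.values[:, j]
    mean = col.mean()
    if mean == 0:
        return float("nan")
    return float(col.std(ddof=1) / mean)


def plot_biplot(scores: pd.DataFrame, loadings: pd.DataFrame,
                sample_groups: pd.Series | None = None, path=None):
    """Optional SVG/PNG biplot (matplotlib); returns the figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    if sample_groups is not None:
        for g, marker, color in (("+RD", "o", "tab:red"), ("-RD", "s", "tab:blue")):
            rows = sample_groups == g
            ax.scatter(scores.loc[rows, "PC1"], scores.loc[rows, "PC2"],
                       label=g, marker=marker, color=color)
        ax.legend()
    else:
        ax.scatter(scores["PC1"], scores["PC2"])
    span = float(np.abs(scores[["PC1", "PC2"]].to_numpy()).max()) or 1.0
    for name, row in loadings.iterrows():
        ax.annotate("", xy=(row["PC1"] * span, row["PC2"] * span), xytext=(0, 0),
                    arrowprops=dict(arrowstyle="->", color="gray", alpha=0.6))
        ax.annotate(str(name), (row["PC1"] * span, row["PC2"] * span),
                    fontsize=7, color="gray")
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.axhline(0, lw=0.5, color="k")
    ax.axvline(0, lw=0.5, color="k")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
    return fig
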