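"""Probabilistic latent semantic analysis of the feature matrix.

The spots x bins intensity table is treated as a table of co-occurrence
weights and decomposed with the aspect model

    P(spot, bin) = sum_z P(z) P(spot|z) P(bin|z),

fitted by expectation-maximization.  TIC-normalized intensities (scaled by
1e4) enter the EM directly as continuous non-negative weights; no rounding
to integer counts is applied.  Initialization is deterministic: component
profiles are seeded from the k mutually most dissimilar spectra, found by
greedy max-min cosine-distance selection starting from the highest-total
spectrum, so repeated fits of the same matrix are bit-identical.

The module also renders per-component score images on the pixel grid and
offers top-down spatial segmentation by bisecting k-means in cosine
geometry (rows scaled to unit length, largest-inertia cluster split first).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import BisectingKMeans

from .errors import EmptyDataError, ParameterError
from .peaks import FeatureMatrix

DEFAULT_COMPONENTS = 5
COUNT_SCALE = 1e4  # TIC-normalized intensities are ~1/n_bins; rescale for EM weights


@dataclass
class PlsaModel:
    """Fitted aspect model.

    ``spot_scores[d, z]`` is P(z | spot d), rows sum to 1.
    ``component_loadings[z, w]`` is P(bin w | z), rows sum to 1.
    """

    n_components: int
    spot_scores: np.ndarray
    component_loadings: np.ndarray
    component_prior: np.ndarray
    loglik_trace: np.ndarray
    bin_centers: np.ndarray = field(default_factory=lambda: np.empty(0))

    def save(self, prefix: str) -> None:
        """Write scores/loadings CSVs plus a JSON metadata sidecar."""
        pd.DataFrame(
            self.spot_scores, columns=[f"component_{z}" for z in range(self.n_components)]
        ).to_csv(f"{prefix}_scores.csv", index=False)
        pd.DataFrame(
            self.component_loadings,
            columns=[f"{c:.4f}" for c in self.bin_centers]
            if len(self.bin_centers) else None,
        ).to_csv(f"{prefix}_loadings.csv", index=False)
        with open(f"{prefix}_meta.json", "w") as fh:
            json.dump(
                {
                    "n_components": self.n_components,
                    "component_prior": self.component_prior.tolist(),
                    "final_loglik": float(self.loglik_trace[-1]),
                    "n_iterations": int(len(self.loglik_trace)),
                },
                fh,
                indent=2,
            )


def _deterministic_seeds(X: np.ndarray, k: int) -> list[int]:
    """Greedy max-min cosine-distance selection, started at the largest-total row."""
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    U = X / safe[:, None]
    seeds = [int(np.argmax(X.sum(axis=1)))]
    min_dist = 1.0 - U @ U[seeds[0]]
    for _ in range(1, k):
        min_dist[seeds] = -np.inf
        nxt = int(np.argmax(min_dist))
        seeds.append(nxt)
        min_dist = np.minimum(min_dist, 1.0 - U @ U[nxt])
    return seeds


def fit_plsa(
    fm: FeatureMatrix,
    k: int = DEFAULT_COMPONENTS,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> PlsaModel:
    """EM fit of the k-aspect model to the (non-negative) feature matrix.

    ``tol`` is the absolute change in total log-likelihood (in weighted
    units) below which iteration stops.  No randomness is involved.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if k > fm.n_spots:
        raise ParameterError(f"k={k} exceeds the number of spectra ({fm.n_spots})")
    N = fm.values * COUNT_SCALE
    if np.any(N < 0):
        raise ParameterError("feature matrix must be non-negative")
    n, m = N.shape

    seeds = _deterministic_seeds(N, k)
    eps = 1e-12
    p_wz = N[seeds] + N.mean() * 0.01 + eps          # (k, m) seeded profiles
    p_wz /= p_wz.sum(axis=1, keepdims=True)
    p_dz = np.full((n, k), 1.0 / n)
    p_z = np.full(k, 1.0 / k)

    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        # joint[d, w] = sum_z P(z) P(d|z) P(w|z)
        weighted = p_dz * p_z[None, :]               # (n, k)
        joint = weighted @ p_wz                      # (n, m)
        ll = float(np.sum(N * np.log(joint + eps)))
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
        # E+M fused: responsibilities R[d, w, z] = weighted[d,z] p_wz[z,w] / joint
        ratio = N / (joint + eps)                    # (n, m)
        # expected counts per (d, z) and (z, w)
        nz_dz = weighted * (ratio @ p_wz.T)          # (n, k)
        nz_zw = (weighted.T @ ratio) * p_wz          # (k, m)
        total = nz_dz.sum()
        p_z = nz_dz.sum(axis=0) / total
        p_dz = nz_dz / np.maximum(nz_dz.sum(axis=0, keepdims=True), eps)
        p_wz = nz_zw / np.maximum(nz_zw.sum(axis=1, keepdims=True), eps)

    # posterior P(z|d) ~ P(z) P(d|z)
    post = p_dz * p_z[None, :]
    post /= np.maximum(post.sum(axis=1, keepdims=True), eps)
    return PlsaModel(
        n_components=k,
        spot_scores=post,
        component_loadings=p_wz,
        component_prior=p_z,
        loglik_trace=np.asarray(trace),
        bin_centers=fm.bin_centers,
    )


def score_image(model: PlsaModel, fm: FeatureMatrix, component: int) -> np.ndarray:
    """Grid of P(component | spot) at each pixel; off-ROI pixels are NaN."""
    if not 0 <= component < model.n_components:
        raise ParameterError(f"component must be in [0, {model.n_components})")
    xs = fm.spot_index["x"].to_numpy()
    ys = fm.spot_index["y"].to_numpy()
    img = np.full((int(ys.max()), int(xs.max())), np.nan)
    img[ys - 1, xs - 1] = model.spot_scores[:, component]
    return img


def flag_outlier_patients(model: PlsaModel, fm: FeatureMatrix) -> list[str]:
    """Patients whose dominant component matches neither group's majority component.

    This realizes the unsupervised outlier-subclass screen: for each group,
    find the component most often dominant across its spots; a patient whose
    own spots' dominant component differs from both group-majority components
    is flagged for review.
    """
    dom = model.spot_scores.argmax(axis=1)
    groups = fm.spot_index["group"]
    majority = {}
    for g in groups.unique():
        rows = (groups == g).to_numpy()
        majority[g] = np.bincount(dom[rows]).argmax()
    flagged = []
    for pid, sub in fm.spot_index.groupby("patient", sort=True):
        pdom = np.bincount(dom[sub.index.to_numpy()]).argmax()
        if pdom not in majority.values():
            flagged.append(str(pid))
    return flagged


def segment_bisecting_kmeans(fm: FeatureMatrix, k: int, seed: int = 0) -> np.ndarray:
    """Top-down segmentation: repeated 2-means splits of the worst cluster.

    Rows are scaled to unit Euclidean length first, so the splits operate in
    cosine geometry; the cluster with the largest inertia is bisected until
    ``k`` clusters exist.  Returns one integer label per spot.
    """
    if k < 2:
        raise ParameterError("k must be >= 2")
    if k > fm.n_spots:
        raise EmptyDataError(f"cannot form {k} clusters from {fm.n_spots} spots")
    X = fm.values
    norms = np.linalg.norm(X, axis=1)
    U = X / np.where(norms > 0, norms, 1.0)[:, None]
    km = BisectingKMeans(
        n_clusters=k,
        random_state=seed,
        bisecting_strategy="biggest_inertia",
        n_init=1,
    )
    return km.fit_predict(U)
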