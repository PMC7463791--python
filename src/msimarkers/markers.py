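"""Supervised marker discovery: ROC/AUC, Wilcoxon rank-sum, delta intensity.

Every m/z bin of the feature matrix is screened for its ability to separate
recurrent (+RD) from non-recurrent (-RD) spectra:

1. a balanced subsample of spectra is drawn per group (groups should be of
   comparable size; if not, the larger one is randomly capped),
2. the bin's AUC is computed (probability, with tie credit, that a random
   +RD intensity exceeds a random -RD intensity),
3. bins beyond the AUC cutoffs are tested with the two-sided Wilcoxon
   rank-sum test,
4. survivors must show an extreme delta intensity, defined as the +RD share
   of the pooled group means, mean(+RD) / (mean(+RD) + mean(-RD)) — 0.5
   means no difference, so cutoffs like >0.7 / <0.3 demand a >2.3-fold
   change in either direction.

A bin passes only the full chain; every bin is reported with its statistics
and a pass flag, sorted by discriminative strength |AUC - 0.5|.

Two cutoff presets are shipped: ``"methods"`` (AUC >0.65/<0.35, p<0.001,
delta >0.7/<0.3 — the screening chain used to derive the published
signature) and ``"results2020"`` (AUC >0.6/<0.4, p<0.01, no delta filter —
the looser summary cutoffs quoted alongside it).  The two do not agree;
both are exposed rather than silently reconciled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm, rankdata

from .errors import EmptyDataError, ParameterError
from .peaks import FeatureMatrix

DIRECTION_UP = "up-in-+RD"
DIRECTION_DOWN = "up-in--RD"


@dataclass(frozen=True)
class ScreenParams:
    """Cutoffs and subsampling settings of the marker screen."""

    auc_hi: float = 0.65
    auc_lo: float = 0.35
    p_cut: float = 0.001
    delta_hi: float | None = 0.7
    delta_lo: float | None = 0.3
    subsample_n: int = 1500
    seed: int = 0
    fdr: bool = False  # optional Benjamini-Hochberg adjustment of p-values

    def __post_init__(self) -> None:
        if not self.auc_lo < 0.5 < self.auc_hi:
            raise ParameterError("need auc_lo < 0.5 < auc_hi")
        if not 0 < self.p_cut < 1:
            raise ParameterError("p_cut must be in (0, 1)")
        if (self.delta_hi is None) != (self.delta_lo is None):
            raise ParameterError("delta cutoffs must be set together or not at all")


PRESETS: dict[str, ScreenParams] = {
    "methods": ScreenParams(),
    "results2020": ScreenParams(
        auc_hi=0.6, auc_lo=0.4, p_cut=0.01, delta_hi=None, delta_lo=None
    ),
}


@dataclass
class MarkerResult:
    """Screening statistics of one m/z bin."""

    bin_center: float
    auc: float
    p_value: float
    delta: float
    direction: str
    passed: bool


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def roc_auc(a, b) -> float:
    """AUC for separating sample ``a`` (+RD) from ``b`` (-RD).

    Equals [#pairs with x > y + 0.5 * #ties] / (|a| |b|), i.e. the
    Mann-Whitney U statistic of ``a`` divided by |a||b|.  Values above 0.5
    mean higher intensities in ``a``.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise EmptyDataError("roc_auc requires two non-empty samples")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def wilcoxon_ranksum(a, b, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    ``method="auto"`` uses exact enumeration for small tie-free samples
    (both below 20 observations) and the large-sample approximation
    otherwise; ``"exact"``/``"asymptotic"`` force a path.  The large-sample
    approximation is an Edgeworth-corrected normal for tie-free data (the
    rank sum's exact fourth moment under sampling without replacement
    supplies the kurtosis term; its skewness is exactly zero by symmetry),
    falling back to the tie-corrected normal approximation when ties exist.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise EmptyDataError("wilcoxon_ranksum requires two non-empty samples")
    ranks = rankdata(np.concatenate([a, b]))
    has_ties = len(np.unique(ranks)) < a.size + b.size
    if method == "auto":
        method = "asymptotic" if (has_ties or max(a.size, b.size) >= 20) else "exact"
    if method == "exact" or has_ties:
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
        return float(min(res.pvalue, 1.0))
    return _edgeworth_ranksum_p(ranks, a.size)


def _edgeworth_ranksum_p(ranks: np.ndarray, n1: int) -> float:
    """Two-sided rank-sum p: continuity-corrected normal + kurtosis term.

    The rank sum W is the total of a simple random sample of size n1 drawn
    without replacement from the pooled ranks; its exact variance and
    fourth central moment follow from the population power sums, giving the
    one-term Edgeworth refinement of the normal tail.
    """
    N = len(ranks)
    w = float(ranks[:n1].sum())
    y = ranks - (N + 1) / 2.0
    p2 = float((y**2).sum())
    p4 = float((y**4).sum())

    def falling(n: int, r: int) -> float:
        out = 1.0
        for i in range(r):
            out *= n - i
        return out

    pi2 = falling(n1, 2) / falling(N, 2)
    pi3 = falling(n1, 3) / falling(N, 3)
    pi4 = falling(n1, 4) / falling(N, 4)
    mu = n1 * (N + 1) / 2.0
    var = p2 * n1 * (N - n1) / (N * (N - 1))
    mu4 = (
        (n1 / N) * p4
        + 3 * pi2 * (p2**2 - p4)
        - 4 * pi2 * p4
        + 6 * pi3 * (2 * p4 - p2**2)
        + pi4 * (3 * p2**2 - 6 * p4)
    )
    excess_kurtosis = mu4 / var**2 - 3.0
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    tail = norm.sf(z) + norm.pdf(z) * (excess_kurtosis / 24.0) * (z**3 - 3 * z)
    return float(min(1.0, max(0.0, 2.0 * tail)))


def delta_intensity(a, b) -> float:
    """+RD share of the pooled mean intensity: mean(a) / (mean(a) + mean(b)).

    Ranges over [0, 1] with 0.5 meaning no difference.  NaN (marker fails)
    when both group means are zero.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise EmptyDataError("delta_intensity requires two non-empty samples")
    ma, mb = float(a.mean()), float(b.mean())
    if ma + mb == 0:
        return float("nan")
    return ma / (ma + mb)


# ---------------------------------------------------------------------------
# Subsampling and the full screen
# ---------------------------------------------------------------------------

def balanced_subsample(fm: FeatureMatrix, n: int, seed: int = 0) -> FeatureMatrix:
    """Randomly cap each outcome group at ``n`` spectra (reproducible).

    A group smaller than ``n`` is kept whole; only larger groups are
    subsampled, so group sizes end up equal or capped at their natural size.
    """
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    groups = [g for g in fm.spot_index["group"].unique()]
    for g in groups:
        rows = fm.group_rows(g)
        if rows.size == 0:
            raise EmptyDataError(f"group {g!r} has zero spectra")
        if rows.size > n:
            rows = np.sort(rng.choice(rows, size=n, replace=False))
        keep.append(rows)
    return fm.subset_rows(np.sort(np.concatenate(keep)))


def discover_markers(fm: FeatureMatrix, params: ScreenParams | None = None) -> list[MarkerResult]:
    """Run the full AUC -> Wilcoxon -> delta screening chain on every bin.

    Returns one :class:`MarkerResult` per bin (none silently dropped),
    sorted by |AUC - 0.5| descending (ties by bin center).
    """
    params = params or ScreenParams()
    groups = set(fm.spot_index["group"].unique())
    if not {"+RD", "-RD"} <= groups:
        raise EmptyDataError(f"need both +RD and -RD spectra, found {sorted(groups)}")
    sub = balanced_subsample(fm, params.subsample_n, params.seed)
    pos = sub.values[sub.group_rows("+RD")]
    neg = sub.values[sub.group_rows("-RD")]

    results = []
    pvals = np.full(len(fm.bin_centers), np.nan)
    for j, center in enumerate(fm.bin_centers):
        a, b = pos[:, j], neg[:, j]
        auc = roc_auc(a, b)
        auc_pass = auc >= params.auc_hi or auc <= params.auc_lo
        p = wilcoxon_ranksum(a, b) if auc_pass else float("nan")
        pvals[j] = p
        delta = delta_intensity(a, b)
        if params.delta_hi is None:
            delta_pass = True
        else:
            delta_pass = (not np.isnan(delta)) and (
                delta >= params.delta_hi or delta <= params.delta_lo
            )
        passed = bool(auc_pass and not np.isnan(p) and p < params.p_cut and delta_pass)
        results.append(
            MarkerResult(
                bin_center=float(center),
                auc=auc,
                p_value=p,
                delta=delta,
                direction=DIRECTION_UP if auc > 0.5 else DIRECTION_DOWN,
                passed=passed,
            )
        )
    if params.fdr:
        tested = ~np.isnan(pvals)
        adj = _benjamini_hochberg(pvals[tested])
        it = iter(adj)
        for j, r in enumerate(results):
            if tested[j]:
                r.p_value = float(next(it))
                r.passed = bool(r.passed and r.p_value < params.p_cut)
    results.sort(key=lambda r: (-abs(r.auc - 0.5), r.bin_center))
    return results


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        adj[i] = running
    return adj


def passed_markers(results: list[MarkerResult]) -> list[MarkerResult]:
    return [r for r in results if r.passed]


def markers_table(results: list[MarkerResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_center": [r.bin_center for r in results],
            "auc": [r.auc for r in results],
            "p_value": [r.p_value for r in results],
            "delta": [r.delta for r in results],
            "direction": [r.direction for r in results],
            "passed": [r.passed for r in results],
        }
    )


def write_markers(results: list[MarkerResult], path) -> None:
    markers_table(results).to_csv(path, index=False)
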