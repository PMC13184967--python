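"""Time-delayed local similarity analysis (LSA) and association networks.

Local similarity between two taxon trajectories is the maximal-magnitude
contiguous partial sum of aligned products of their normal-score
transformed series, searched over all alignments with time offset up to
``max_delay`` and over all contiguous subintervals, scaled by the series
length.  The signed score captures the strongest positive or negative,
possibly lagged, local association; significance comes from permuting one
series' time order.  Networks are built per treatment from
replicate-averaged trajectories with Benjamini-Hochberg FDR across all
tested pairs, and edges are classified as "global" (significant over the
full series) or "local only" (significant only within sliding temporal
windows).

The subinterval search is carried out on prefix sums, which is both
vectorisable across permutations and exactly equal (same floating-point
operations) to exhaustive enumeration over (delay, start, end) triples.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

from ._util import child_seed
from .core_io import CommunityMatrix, tss_normalize

__all__ = [
    "LocalSimilarity",
    "LSAEdge",
    "NetworkSummary",
    "standardize_series",
    "local_similarity",
    "lsa_permutation",
    "treatment_series",
    "build_network",
    "classify_edge_scope",
]


@dataclass
class LocalSimilarity:
    """Best local alignment: signed score, delay (positive = second series
    lags the first), and the matched subinterval [start, end) in the
    first series' timeline."""

    score: float
    delay: int
    start: int
    end: int


@dataclass
class LSAEdge:
    taxon_a: str
    taxon_b: str
    ls_score: float
    delay: int
    start: int
    end: int
    p_value: float
    q_value: float = np.nan

    @property
    def sign(self) -> str:
        return "positive" if self.ls_score >= 0 else "negative"


@dataclass
class NetworkSummary:
    """Per-treatment signed edge counts (the network topology summary)."""

    treatment: str
    n_positive: int
    n_negative: int

    @property
    def ratio(self) -> float:
        return self.n_positive / self.n_negative if self.n_negative > 0 else np.nan


def standardize_series(x) -> np.ndarray:
    """Rank-based normal-score transform, centred and scaled to unit
    variance.  Rank invariance makes the score robust to monotone marginal
    transforms; ties are mid-ranked.  Constant series map to zeros."""
    x = np.asarray(x, dtype=float)
    if len(x) < 4:
        raise ValueError("series must have length >= 4")
    if np.all(x == x[0]):
        warnings.warn("constant series: normal scores undefined, returning zeros")
        return np.zeros_like(x)
    ranks = rankdata(x, method="average")
    z = norm.ppf(ranks / (len(x) + 1))
    z = z - z.mean()
    return z / z.std(ddof=0)


def _aligned_products(zx: np.ndarray, zy: np.ndarray, d: int) -> tuple[np.ndarray, int]:
    """Products of x_t * y_{t+d}; returns (products, x-offset of index 0)."""
    if d >= 0:
        p = zx[: len(zx) - d] * zy[d:]
        return p, 0
    p = zx[-d:] * zy[: len(zy) + d]
    return p, -d


def local_similarity(zx, zy, max_delay: int = 3) -> LocalSimilarity:
    """Signed local similarity score with its optimal delay and interval.

    Searches every offset |d| <= max_delay and every contiguous run of
    aligned products via prefix sums; the reported score is the signed
    maximal run magnitude divided by the series length.  Ties break toward
    the positive sign, then the smaller |delay|, then the earlier start.
    """
    zx, zy = np.asarray(zx, dtype=float), np.asarray(zy, dtype=float)
    n = len(zx)
    if len(zy) != n:
        raise ValueError("series must have equal length")
    if n <= max_delay:
        raise ValueError("series length must exceed max_delay")
    best: LocalSimilarity | None = None
    best_key = None
    for d in sorted(range(-max_delay, max_delay + 1), key=lambda v: (abs(v), v)):
        p, off = _aligned_products(zx, zy, d)
        s = np.concatenate([[0.0], np.cumsum(p)])
        # max over start <= t < end of s[end] - s[start], both signs
        diff = s[None, 1:] - s[: -1, None]  # diff[i, j] = s[j+1] - s[i], run i..j
        mask = np.tril(np.ones_like(diff, dtype=bool)).T  # j >= i
        for sign in (+1, -1):
            vals = np.where(mask, sign * diff, -np.inf)
            i, j = np.unravel_index(np.argmax(vals), vals.shape)
            mag = vals[i, j]
            score = sign * mag / n
            key = (-mag, 0 if sign > 0 else 1, abs(d), d, i)
            if best_key is None or key < best_key:
                best_key = key
                best = LocalSimilarity(float(score), d, int(i + off), int(j + 1 + off))
    return best


def _batch_best_abs(zx: np.ndarray, y_matrix: np.ndarray, max_delay: int) -> np.ndarray:
    """Best absolute run magnitude (unscaled) per row of *y_matrix*,
    over all delays and subintervals — vectorised across rows."""
    m = y_matrix.shape[0]
    best = np.zeros(m)
    for d in range(-max_delay, max_delay + 1):
        if d >= 0:
            p = zx[None, : len(zx) - d] * y_matrix[:, d:]
        else:
            p = zx[None, -d:] * y_matrix[:, : y_matrix.shape[1] + d]
        s = np.concatenate([np.zeros((m, 1)), np.cumsum(p, axis=1)], axis=1)
        cmin = np.minimum.accumulate(s, axis=1)
        cmax = np.maximum.accumulate(s, axis=1)
        up = (s[:, 1:] - cmin[:, :-1]).max(axis=1)
        down = (cmax[:, :-1] - s[:, 1:]).max(axis=1)
        best = np.maximum(best, np.maximum(up, down))
    return best


def lsa_permutation(
    zx,
    zy,
    max_delay: int = 3,
    n_perm: int = 1000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value for |LS|: one series' time order is shuffled,
    p = (1 + #{perm |ls| >= obs |ls|}) / (1 + n_perm)."""
    zx, zy = np.asarray(zx, dtype=float), np.asarray(zy, dtype=float)
    n = len(zx)
    obs = abs(local_similarity(zx, zy, max_delay).score) * n
    if rng is None:
        rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(zy, (n_perm, 1)), axis=1)
    perm_best = _batch_best_abs(zx, perms, max_delay)
    hits = int(np.sum(perm_best >= obs))
    return (1 + hits) / (1 + n_perm)


def treatment_series(
    cm: CommunityMatrix,
    treatment: str,
    replicate_mode: str = "average",
) -> pd.DataFrame:
    """Per-taxon relative-abundance trajectory for one treatment.

    With ``replicate_mode='average'`` (default) the replicates' relative
    abundances are averaged per timepoint, yielding one trajectory per
    treatment; ``'concatenate'`` chains the replicates end to end.
    """
    meta = cm.metadata
    samples = meta.index[meta["treatment"] == treatment]
    if len(samples) == 0:
        raise ValueError(f"no samples for treatment {treatment!r}")
    rel = tss_normalize(cm.subset_samples(list(samples)))
    sub_meta = rel.metadata
    if replicate_mode == "average":
        tps = np.sort(sub_meta["timepoint"].unique())
        cols = {
            tp: rel.values[sub_meta.index[sub_meta["timepoint"] == tp]].mean(axis=1)
            for tp in tps
        }
        return pd.DataFrame(cols)
    if replicate_mode == "concatenate":
        order = sub_meta.sort_values(["replicate", "timepoint"]).index
        return rel.values[order]
    raise ValueError("replicate_mode must be 'average' or 'concatenate'")


def build_network(
    cm: CommunityMatrix,
    treatment: str,
    max_delay: int = 3,
    n_perm: int = 1000,
    q_max: float = 0.05,
    seed: int = 0,
    prevalence_min: float = 0.25,
    replicate_mode: str = "average",
) -> tuple[list[LSAEdge], NetworkSummary]:
    """LSA network for one treatment: all pairs above the prevalence floor
    tested, BH FDR across pairs, edges kept at q <= q_max.

    Returns the significant edges and the positive/negative count summary
    (ratio reported as NaN when there are no negative edges).
    """
    series = treatment_series(cm, treatment, replicate_mode=replicate_mode)
    n_tp = series.shape[1]
    if n_tp < 8:
        raise ValueError(f"need >= 8 timepoints, got {n_tp}")
    prevalence = (series.to_numpy() > 0).mean(axis=1)
    keep = series.index[prevalence >= prevalence_min]
    z = {t: standardize_series(series.loc[t].to_numpy()) for t in keep}
    rng = np.random.default_rng(child_seed(seed, f"lsa-{treatment}"))
    candidates = []
    for a, b in itertools.combinations(keep, 2):
        ls = local_similarity(z[a], z[b], max_delay)
        p = lsa_permutation(z[a], z[b], max_delay=max_delay, n_perm=n_perm, rng=rng)
        candidates.append(LSAEdge(a, b, ls.score, ls.delay, ls.start, ls.end, p))
    if not candidates:
        return [], NetworkSummary(treatment, 0, 0)
    qvals = multipletests([e.p_value for e in candidates], method="fdr_bh")[1]
    for e, q in zip(candidates, qvals):
        e.q_value = float(q)
    edges = [e for e in candidates if e.q_value <= q_max]
    n_pos = sum(1 for e in edges if e.ls_score >= 0)
    return edges, NetworkSummary(treatment, n_pos, len(edges) - n_pos)


def classify_edge_scope(
    cm: CommunityMatrix,
    treatment: str,
    taxon_a: str,
    taxon_b: str,
    window_length: int = 10,
    step: int = 1,
    max_delay: int = 3,
    n_perm: int = 1000,
    q_max: float = 0.05,
    seed: int = 0,
) -> str | None:
    """Classify one candidate association as 'global', 'local_only' or None.

    Global: significant (p <= q_max) on the full series.  Local only: not
    globally significant, but significant in at least one sliding window
    of ``window_length`` timepoints (BH-corrected within the window
    batch).  Returns None when neither holds (not an edge).
    """
    series = treatment_series(cm, treatment)
    x = series.loc[taxon_a].to_numpy()
    y = series.loc[taxon_b].to_numpy()
    n = len(x)
    if window_length > n:
        raise ValueError("window longer than series")
    rng = np.random.default_rng(child_seed(seed, f"scope-{treatment}-{taxon_a}-{taxon_b}"))
    zx, zy = standardize_series(x), standardize_series(y)
    p_global = lsa_permutation(zx, zy, max_delay=max_delay, n_perm=n_perm, rng=rng)
    if p_global <= q_max:
        return "global"
    window_ps = []
    starts = list(range(0, n - window_length + 1, step))
    for s in starts:
        wx, wy = x[s : s + window_length], y[s : s + window_length]
        if np.all(wx == wx[0]) or np.all(wy == wy[0]):
            window_ps.append(1.0)
            continue
        zwx, zwy = standardize_series(wx), standardize_series(wy)
        d = min(max_delay, window_length - 1)
        window_ps.append(lsa_permutation(zwx, zwy, max_delay=d, n_perm=n_perm, rng=rng))
    window_qs = multipletests(window_ps, method="fdr_bh")[1]
    if np.any(window_qs <= q_max):
        return "local_only"
    return None
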