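"""Dissimilarity, ordination statistics, diversity and subcommunity tools.

Bray-Curtis dissimilarity feeds UPGMA clustering (replicate
reproducibility), nMDS/PCoA ordination (successional trajectories),
PERMDISP (homogeneity of multivariate dispersion around group spatial
medians), ANOSIM (group separation) and Procrustes/PROTEST (congruence of
two ordinations, e.g. abundant vs rare subcommunities).  Diversity is
summarised by inverse Simpson and Margalef richness.  Taxa are split into
main (>1% mean relative abundance over all samples) and rare (<0.1%)
subcommunities with strict thresholds; everything in between is
intermediate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import pdist, squareform
from scipy.stats import f_oneway
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as _skbio_anosim
from skbio.stats.ordination import pcoa as _skbio_pcoa
from sklearn.manifold import MDS

from .core_io import CommunityMatrix, RelativeAbundanceMatrix, tss_normalize

__all__ = [
    "OrdinationResult",
    "SubcommunityPartition",
    "bray_curtis",
    "upgma",
    "UPGMAResult",
    "nmds",
    "pcoa",
    "permdisp",
    "PermdispResult",
    "anosim",
    "procrustes_protest",
    "diversity_indices",
    "partition_subcommunities",
    "trajectory_distance",
    "community_overlap",
]


@dataclass
class OrdinationResult:
    """Sample coordinates from nMDS or PCoA.

    ``stress`` is the normalised Kruskal stress-1 for nMDS (in [0, 1]);
    for PCoA it is 0 and ``eigenvalues`` carries the axis eigenvalues.
    """

    coordinates: pd.DataFrame
    method: str
    stress: float = 0.0
    eigenvalues: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates.to_numpy())):
            raise ValueError("ordination coordinates must be finite")
        if self.method == "nmds" and not 0.0 <= self.stress <= 1.0:
            raise ValueError("nMDS stress must lie in [0, 1]")


@dataclass
class SubcommunityPartition:
    main_taxa: list[str]
    rare_taxa: list[str]
    intermediate_taxa: list[str]


@dataclass
class UPGMAResult:
    """UPGMA dendrogram: scipy linkage matrix plus ultrametric node heights
    (half the between-cluster mean distance) and a newick rendering."""

    linkage: np.ndarray
    heights: np.ndarray
    leaf_ids: list[str]
    newick: str


@dataclass
class PermdispResult:
    f_statistic: float
    p_value: float
    group_dispersion: pd.Series


def bray_curtis(x: CommunityMatrix | RelativeAbundanceMatrix) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between all sample pairs,
    BC(x, y) = 1 - 2 sum(min(x_i, y_i)) / (sum x + sum y).

    The formula is applied to the values as given: pass a
    RelativeAbundanceMatrix (TSS proportions) for the standard
    beta-diversity workflow, or a CommunityMatrix to work on raw counts.
    """
    mat = (x.counts if isinstance(x, CommunityMatrix) else x.values).to_numpy().T
    if np.any(mat.sum(axis=1) <= 0):
        raise ValueError("zero-sum sample")
    ids = x.sample_ids
    return DistanceMatrix(squareform(pdist(mat, metric="braycurtis")), ids=ids)


def _linkage_to_newick(link: np.ndarray, heights: np.ndarray, labels: list[str]) -> str:
    n = len(labels)
    nodes = {i: (labels[i], 0.0) for i in range(n)}
    for k, (i, j, _, _) in enumerate(link):
        hi, hj = nodes[int(i)], nodes[int(j)]
        h = heights[k]
        nodes[n + k] = (f"({hi[0]}:{h - hi[1]:.10g},{hj[0]}:{h - hj[1]:.10g})", h)
    return nodes[n + len(link) - 1][0] + ";"


def upgma(dm: DistanceMatrix) -> UPGMAResult:
    """Size-weighted arithmetic-mean (UPGMA) agglomerative clustering.

    Merge heights are half the inter-cluster mean distance, so the
    dendrogram is ultrametric and reproduces the generating tree exactly
    on ultrametric input.
    """
    d = dm.data
    if d.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    if np.any(np.isnan(d)):
        raise ValueError("NaN in distance matrix")
    link = hierarchy.linkage(squareform(d, checks=False), method="average")
    heights = link[:, 2] / 2.0
    newick = _linkage_to_newick(link, heights, list(dm.ids))
    return UPGMAResult(link, heights, list(dm.ids), newick)


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
) -> OrdinationResult:
    """Non-metric MDS (SMACOF) with random restarts, best stress kept.

    Stress is the normalised Kruskal stress-1; deterministic given the
    seed.  PCoA (:func:`pcoa`) is the deterministic alternative.
    """
    n = dm.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of samples")
    model = MDS(
        n_components=k,
        metric=False,
        dissimilarity="precomputed",
        n_init=n_restarts,
        random_state=seed,
        normalized_stress=True,
        max_iter=500,
        eps=1e-9,
    )
    coords = model.fit_transform(dm.data)
    df = pd.DataFrame(coords, index=list(dm.ids), columns=[f"axis{i + 1}" for i in range(k)])
    return OrdinationResult(df, method="nmds", stress=float(model.stress_), seed=seed)


def pcoa(dm: DistanceMatrix, k: int | None = None) -> OrdinationResult:
    """Principal coordinates analysis (deterministic ordination)."""
    res = _skbio_pcoa(dm, number_of_dimensions=k or 0)
    coords = res.samples
    coords.index = list(dm.ids)
    if k is not None:
        coords = coords.iloc[:, :k]
    eig = res.eigvals.to_numpy()
    return OrdinationResult(coords, method="pcoa", stress=0.0, eigenvalues=eig)


def _spatial_median(points: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Weiszfeld algorithm for the geometric median."""
    y = points.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(points - y, axis=1)
        if np.any(d < 1e-12):
            return y
        w = 1.0 / d
        y_new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def permdisp(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    center: str = "median",
) -> PermdispResult:
    """Homogeneity of multivariate dispersion (betadisper-style).

    Samples are embedded by PCoA (positive-eigenvalue axes); each sample's
    distance to its group's spatial median (or centroid) is the dispersion
    residual, compared across groups with a one-way F statistic and a
    group-label permutation test using p = (1 + #(F_perm >= F)) / (1 + n).
    """
    groups = pd.Series(groups).loc[list(dm.ids)]
    levels = groups.unique()
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError(f"group(s) of size 1: {sizes[sizes < 2].index.tolist()}")
    ord_res = _skbio_pcoa(dm)
    eig = ord_res.eigvals.to_numpy()
    keep = eig > 1e-10
    coords = ord_res.samples.to_numpy()[:, keep]
    labels = groups.to_numpy()

    def _distances(lab: np.ndarray) -> dict:
        dists = {}
        for g in np.unique(lab):
            pts = coords[lab == g]
            ctr = _spatial_median(pts) if center == "median" else pts.mean(axis=0)
            dists[g] = np.linalg.norm(pts - ctr, axis=1)
        return dists

    def _f(lab: np.ndarray) -> float:
        groups_d = list(_distances(lab).values())
        flat = np.concatenate(groups_d)
        if np.allclose(flat.std(), 0):
            return 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat = f_oneway(*groups_d).statistic
        return 0.0 if np.isnan(stat) else float(stat)

    obs_d = _distances(labels)
    f_obs = _f(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _f(rng.permutation(labels)) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    disp = pd.Series({g: d.mean() for g, d in obs_d.items()}, name="mean_dispersion")
    return PermdispResult(f_obs, p, disp)


def anosim(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """ANOSIM R and permutation p-value (rank-based group separation)."""
    groups = pd.Series(groups).loc[list(dm.ids)]
    sizes = groups.value_counts()
    if len(sizes) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    np.random.seed(seed)  # skbio permutes via the global state
    res = _skbio_anosim(dm, groups.to_numpy(), permutations=n_perm)
    return float(res["test statistic"]), float(res["p-value"])


def procrustes_protest(
    ord_a: OrdinationResult,
    ord_b: OrdinationResult,
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Procrustes m2 of b superimposed on a, with PROTEST permutation p.

    m2 is the residual sum of squares after optimal translation, uniform
    scaling and rotation of both configurations to unit norm (in [0, 1]);
    the permutation test shuffles the sample rows of b.
    """
    ids_a, ids_b = list(ord_a.coordinates.index), list(ord_b.coordinates.index)
    if set(ids_a) != set(ids_b):
        raise ValueError("ordinations must cover the same sample set")
    a = ord_a.coordinates.to_numpy()
    b = ord_b.coordinates.loc[ids_a].to_numpy()
    if a.shape[1] != b.shape[1]:
        raise ValueError("ordinations must have the same dimensionality")
    _, _, m2 = _scipy_procrustes(a, b)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, _, m2_perm = _scipy_procrustes(a, b[rng.permutation(len(b))])
        if m2_perm <= m2:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return float(m2), p


def diversity_indices(cm: CommunityMatrix) -> pd.DataFrame:
    """Per-sample inverse Simpson diversity and Margalef richness.

    inverse Simpson = 1 / sum(f_i^2); Margalef = (S - 1) / ln(N) with the
    convention 0 when N = 1.
    """
    counts = cm.counts.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise ValueError("zero-total sample")
    rel = counts / totals
    inv_simpson = 1.0 / (rel**2).sum(axis=0)
    richness = (counts > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        margalef = np.where(totals > 1, (richness - 1) / np.log(totals), 0.0)
    return pd.DataFrame(
        {"inverse_simpson": inv_simpson, "margalef": margalef}, index=cm.sample_ids
    )


def partition_subcommunities(
    cm: CommunityMatrix,
    main_threshold: float = 0.01,
    rare_threshold: float = 0.001,
) -> SubcommunityPartition:
    """Split taxa into main (mean TSS relative abundance strictly > 1%),
    rare (strictly < 0.1%) and intermediate subcommunities."""
    if rare_threshold >= main_threshold:
        raise ValueError("rare threshold must be below main threshold")
    mean_rel = tss_normalize(cm).values.mean(axis=1)
    main = mean_rel.index[mean_rel > main_threshold].tolist()
    rare = mean_rel.index[mean_rel < rare_threshold].tolist()
    inter = [t for t in cm.taxa_ids if t not in set(main) | set(rare)]
    return SubcommunityPartition(main, rare, inter)


def trajectory_distance(
    ord_res: OrdinationResult,
    metadata: pd.DataFrame,
    reference: float | None = None,
) -> pd.DataFrame:
    """Euclidean distance of each treatment's per-timepoint centroid (over
    replicates) from its reference-timepoint centroid (default: the
    treatment's first timepoint)."""
    coords = ord_res.coordinates
    meta = metadata.loc[coords.index]
    rows = []
    for treat, sub in meta.groupby("treatment", sort=True):
        tps = np.sort(sub["timepoint"].unique())
        ref_tp = tps[0] if reference is None else reference
        if ref_tp not in tps:
            raise ValueError(f"reference timepoint {ref_tp} absent for treatment {treat}")
        centroids = {
            tp: coords.loc[sub.index[sub["timepoint"] == tp]].mean(axis=0).to_numpy()
            for tp in tps
        }
        for tp in tps:
            rows.append(
                {
                    "treatment": treat,
                    "timepoint": tp,
                    "distance": float(np.linalg.norm(centroids[tp] - centroids[ref_tp])),
                }
            )
    return pd.DataFrame(rows)


def community_overlap(
    x: CommunityMatrix | RelativeAbundanceMatrix,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.Series:
    """Replicate-pair community overlap, defined as 1 - Bray-Curtis.

    By default all replicate pairs sharing a (treatment, timepoint) cell
    are evaluated; an explicit pair list must respect that pairing.
    Overlap is computed on the values as given (see :func:`bray_curtis`).
    """
    rel = x
    meta = rel.metadata
    if pairs is None:
        pairs = []
        for (_, _), sub in meta.groupby(["treatment", "timepoint"], sort=True):
            pairs.extend(itertools.combinations(sub.index, 2))
        if not pairs:
            raise ValueError("no replicate pairs found")
    else:
        for a, b in pairs:
            ma, mb = meta.loc[a], meta.loc[b]
            if ma["treatment"] != mb["treatment"] or ma["timepoint"] != mb["timepoint"]:
                raise ValueError(f"pair ({a}, {b}) does not share treatment and timepoint")
    dm = bray_curtis(rel)
    return pd.Series({(a, b): 1.0 - dm[a, b] for a, b in pairs}, name="overlap")
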