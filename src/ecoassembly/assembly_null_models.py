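"""Phylogenetic and taxonomic null models for assembly-process partitioning.

The inference follows the Stegen-style two-step framework widely used in
microbial ecology.  For each pair of communities:

1. βMNTD (abundance-weighted beta mean nearest taxon distance) is computed
   on relative abundances, and standardised against a taxa-label-shuffle
   null to give βNTI.  |βNTI| > 2 indicates deterministic selection
   (βNTI < -2 homogeneous, βNTI > +2 variable).
2. Pairs not dominated by selection are passed to a Raup-Crick null built
   on Bray-Curtis dissimilarity of integer count data (RC_bray).
   RC_bray > +0.95 indicates dispersal limitation, < -0.95 homogenizing
   dispersal, and values in between undominated processes (drift).

Per-group fractions of the five process labels produce the familiar
partition table stratified by comparison class (within replicates /
between treatments) and subcommunity (all / main / rare).

SES.MPD (standardised effect size of abundance-weighted mean pairwise
phylogenetic distance; negative = phylogenetic clustering) is provided for
single-sample dispersion screening.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from ._util import child_seed
from .core_io import CommunityMatrix

logger = logging.getLogger(__name__)

PROCESSES = (
    "variable_selection",
    "homogeneous_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "undominated",
)

__all__ = [
    "PROCESSES",
    "PatristicMatrix",
    "patristic_matrix",
    "beta_mntd",
    "beta_mntd_matrix",
    "beta_nti",
    "raup_crick_bray",
    "classify_process",
    "partition_processes",
    "ses_mpd",
    "make_pairs",
    "pair_table",
    "time_resolved_partition",
]


@dataclass
class PatristicMatrix:
    """Symmetric tip-to-tip phylogenetic (branch-length path) distances."""

    taxa_ids: list[str]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.shape != (len(self.taxa_ids), len(self.taxa_ids)):
            raise ValueError("distance matrix shape does not match taxa list")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("patristic matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("patristic matrix diagonal must be exactly zero")
        if np.any(d < 0):
            raise ValueError("patristic distances must be non-negative")
        self.distances = d

    def subset(self, taxa: list[str]) -> "PatristicMatrix":
        idx = [self.taxa_ids.index(t) for t in taxa]
        return PatristicMatrix(list(taxa), self.distances[np.ix_(idx, idx)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.distances, index=self.taxa_ids, columns=self.taxa_ids)


def patristic_matrix(tree: str | dendropy.Tree, taxa_subset: list[str] | None = None) -> PatristicMatrix:
    """Pairwise patristic distances (sum of branch lengths along the
    tip-to-tip path) for the requested tips of a newick tree."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    tip_taxa = {t.label: t for t in tree.taxon_namespace if t.label is not None}
    if taxa_subset is None:
        taxa_subset = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [t for t in taxa_subset if t not in tip_taxa]
    if missing:
        raise ValueError(f"taxa missing from tree: {missing}")
    n = len(taxa_subset)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        dist = pdm.patristic_distance(tip_taxa[taxa_subset[i]], tip_taxa[taxa_subset[j]])
        d[i, j] = d[j, i] = dist
    return PatristicMatrix(list(taxa_subset), d)


def beta_mntd(rel_a: np.ndarray, rel_b: np.ndarray, pd_matrix: PatristicMatrix) -> float:
    """Abundance-weighted beta mean nearest taxon distance between two
    communities given as relative-abundance vectors aligned to the matrix.

    Each taxon present in one community contributes its abundance times
    the patristic distance to its nearest taxon present in the other;
    taxa shared by both communities are their own nearest neighbours at
    distance zero (standard comdistnt behaviour).
    """
    a = np.asarray(rel_a, dtype=float)
    b = np.asarray(rel_b, dtype=float)
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("empty community")
    a, b = a / a.sum(), b / b.sum()
    d = pd_matrix.distances
    pres_a, pres_b = a > 0, b > 0
    dmin_to_b = d[:, pres_b].min(axis=1)
    dmin_to_a = d[:, pres_a].min(axis=1)
    return 0.5 * (float(a[pres_a] @ dmin_to_b[pres_a]) + float(b[pres_b] @ dmin_to_a[pres_b]))


def _rel_abund(cm: CommunityMatrix) -> np.ndarray:
    counts = cm.counts.to_numpy(dtype=float)
    return counts / counts.sum(axis=0)


def beta_mntd_matrix(rel: np.ndarray, d: np.ndarray) -> np.ndarray:
    """All-pairs βMNTD for a taxa x samples relative-abundance matrix.

    Vectorised: ``Dmin[:, s]`` holds each taxon's distance to its nearest
    taxon present in sample ``s``; then
    βMNTD(a, b) = 0.5 (f_a . Dmin_b + f_b . Dmin_a) restricted to present
    taxa, which the masked matmul below computes for all pairs at once.
    """
    n_taxa, n_samp = rel.shape
    present = rel > 0
    dmin = np.empty((n_taxa, n_samp))
    for s in range(n_samp):
        dmin[:, s] = d[:, present[:, s]].min(axis=1)
    m = rel.T @ dmin  # m[a, b] = sum_i rel[i, a] * dmin[i, b]
    return 0.5 * (m + m.T)


def beta_nti(
    cm: CommunityMatrix,
    pd_matrix: PatristicMatrix,
    n_null: int = 999,
    seed: int = 0,
    return_obs: bool = False,
):
    """βNTI z-score matrix over all sample pairs.

    Null replicates shuffle taxon identities across the patristic distance
    matrix (taxa-label randomisation) and recompute βMNTD on the unchanged
    abundances; βNTI = (obs - mean_null) / sd_null.  Pairs whose null
    distribution has zero spread are reported as NaN, never +/-inf.
    """
    if n_null < 99:
        raise ValueError("n_null must be >= 99")
    if pd_matrix.taxa_ids != cm.taxa_ids:
        pd_matrix = pd_matrix.subset(cm.taxa_ids)
    rel = _rel_abund(cm)
    d = pd_matrix.distances
    n_taxa = d.shape[0]
    obs = beta_mntd_matrix(rel, d)
    rng = np.random.default_rng(seed)
    null_sum = np.zeros_like(obs)
    null_sq = np.zeros_like(obs)
    for _ in range(n_null):
        perm = rng.permutation(n_taxa)
        dp = d[np.ix_(perm, perm)]
        nb = beta_mntd_matrix(rel, dp)
        null_sum += nb
        null_sq += nb * nb
    mean = null_sum / n_null
    var = null_sq / n_null - mean**2
    sd = np.sqrt(np.clip(var, 0.0, None) * n_null / max(n_null - 1, 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z[sd <= 1e-12] = np.nan
    np.fill_diagonal(z, 0.0)
    df = pd.DataFrame(z, index=cm.sample_ids, columns=cm.sample_ids)
    if return_obs:
        return df, pd.DataFrame(obs, index=cm.sample_ids, columns=cm.sample_ids)
    return df


def _null_community(
    rng: np.random.Generator,
    richness: int,
    total: int,
    occ_logw: np.ndarray,
    abund_p: np.ndarray,
) -> np.ndarray:
    """One Raup-Crick null community: draw ``richness`` distinct taxa with
    probability proportional to occurrence frequency (Gumbel top-k trick),
    then distribute ``total`` reads multinomially by regional abundance."""
    n = occ_logw.shape[0]
    keys = occ_logw + rng.gumbel(size=n)
    chosen = np.argpartition(-keys, richness - 1)[:richness]
    p = abund_p[chosen]
    counts = np.zeros(n, dtype=np.int64)
    counts[chosen] = rng.multinomial(total, p / p.sum())
    return counts


def _bray_curtis_counts(x: np.ndarray, y: np.ndarray) -> float:
    denom = x.sum() + y.sum()
    return 1.0 - 2.0 * np.minimum(x, y).sum() / denom


def raup_crick_bray(
    cm: CommunityMatrix,
    pairs: list[tuple[str, str]],
    n_null: int = 999,
    seed: int = 0,
) -> pd.Series:
    """RC_bray in [-1, 1] for the requested sample pairs.

    The regional pool is the full analysis set held in *cm* (pass a subset
    CommunityMatrix to change the pool).  Each null replicate rebuilds both
    communities at their observed richness — taxa drawn without
    replacement with probability proportional to occurrence frequency —
    and observed read totals — reads distributed multinomially by regional
    relative abundance over the drawn taxa.  RC ranks the observed
    Bray-Curtis within the null distribution, with ties half-weighted:
    ``RC = 2 ([null < obs] + 0.5 [null == obs]) / n_null - 1``.
    """
    if cm.shape[1] < 2:
        raise ValueError("regional pool undefined: need >= 2 samples")
    counts = cm.counts.to_numpy(dtype=np.int64)
    occ = (counts > 0).mean(axis=1)
    abund = counts.sum(axis=1).astype(float)
    abund_p = abund / abund.sum()
    with np.errstate(divide="ignore"):
        occ_logw = np.log(occ)
    sample_idx = {s: k for k, s in enumerate(cm.sample_ids)}
    rng = np.random.default_rng(seed)
    out = {}
    for a, b in pairs:
        xa, xb = counts[:, sample_idx[a]], counts[:, sample_idx[b]]
        obs = round(_bray_curtis_counts(xa, xb), 12)
        ra, rb = int((xa > 0).sum()), int((xb > 0).sum())
        na, nb = int(xa.sum()), int(xb.sum())
        less = equal = 0
        for _ in range(n_null):
            ya = _null_community(rng, ra, na, occ_logw, abund_p)
            yb = _null_community(rng, rb, nb, occ_logw, abund_p)
            bc = round(_bray_curtis_counts(ya, yb), 12)
            if bc < obs:
                less += 1
            elif bc == obs:
                equal += 1
        out[(a, b)] = 2.0 * (less + 0.5 * equal) / n_null - 1.0
    return pd.Series(out, name="rc_bray")


def classify_process(beta_nti_value: float, rc_bray_value: float | None = None) -> str:
    """Five-way process label from the βNTI / RC_bray decision rule.

    Selection requires strict |βNTI| > 2 (negative homogeneous, positive
    variable); otherwise strict RC > +0.95 is dispersal limitation,
    RC < -0.95 homogenizing dispersal, and anything else undominated.
    βNTI exactly +/-2 falls through to the RC branch.
    """
    if np.isnan(beta_nti_value):
        raise ValueError("undefined betaNTI cannot be classified")
    if beta_nti_value < -2:
        return "homogeneous_selection"
    if beta_nti_value > 2:
        return "variable_selection"
    if rc_bray_value is None or (isinstance(rc_bray_value, float) and np.isnan(rc_bray_value)):
        raise ValueError("RC_bray required when |betaNTI| <= 2")
    if rc_bray_value > 0.95:
        return "dispersal_limitation"
    if rc_bray_value < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def partition_processes(pairs: pd.DataFrame, group_by: list[str] | None = None) -> pd.DataFrame:
    """Percentage of pairs assigned to each process, per group.

    *pairs* needs a ``process`` column; *group_by* names further columns
    (e.g. comparison_class, subcommunity, timepoint).  Fractions within
    each group sum to 100.  Empty groups are simply absent.
    """
    if pairs.empty:
        raise ValueError("no pairs to partition")
    work = pairs.dropna(subset=["process"])
    dropped = len(pairs) - len(work)
    if dropped:
        logger.warning("dropping %d pair(s) with undefined process", dropped)

    def _fractions(sub: pd.DataFrame) -> pd.Series:
        counts = sub["process"].value_counts()
        frac = pd.Series(0.0, index=list(PROCESSES))
        frac[counts.index] = counts.to_numpy()
        return frac / frac.sum() * 100.0

    if not group_by:
        return _fractions(work).to_frame(name="all_pairs").T
    grouped = work.groupby(group_by, sort=True)
    rows = {key: _fractions(sub) for key, sub in grouped}
    out = pd.DataFrame(rows).T
    out.index.names = group_by if len(group_by) > 1 else [group_by[0]]
    return out


def ses_mpd(
    cm: CommunityMatrix,
    pd_matrix: PatristicMatrix,
    n_null: int = 999,
    seed: int = 0,
) -> pd.Series:
    """Per-sample SES.MPD (abundance-weighted; taxa-label-shuffle null).

    MPD = sum_{i != j} f_i f_j d_ij / sum_{i != j} f_i f_j over taxa
    present in the sample.  Negative values indicate phylogenetic
    clustering.  Samples with a single taxon are returned as NaN.
    """
    if pd_matrix.taxa_ids != cm.taxa_ids:
        pd_matrix = pd_matrix.subset(cm.taxa_ids)
    rel = _rel_abund(cm)
    d = pd_matrix.distances
    n_taxa = d.shape[0]
    rng = np.random.default_rng(seed)

    def _mpd_all(dmat: np.ndarray) -> np.ndarray:
        # with zero diagonal: sum_{i!=j} f_i f_j d_ij = f.D.f and the
        # pair-weight total is 1 - sum f_i^2
        num = (rel * (dmat @ rel)).sum(axis=0)
        denom = 1.0 - (rel * rel).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            return num / denom

    obs = _mpd_all(d)
    nulls = np.empty((n_null, rel.shape[1]))
    for k in range(n_null):
        perm = rng.permutation(n_taxa)
        nulls[k] = _mpd_all(d[np.ix_(perm, perm)])
    mean, sd = nulls.mean(axis=0), nulls.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    # a sample containing every taxon is invariant under the label shuffle:
    # obs == null exactly, so the deviation is zero, not undefined
    degenerate = sd <= 1e-12
    z[degenerate & (np.abs(obs - mean) <= 1e-9)] = 0.0
    z[degenerate & (np.abs(obs - mean) > 1e-9)] = np.nan
    single = (rel > 0).sum(axis=0) < 2
    if single.any():
        warnings.warn("single-taxon sample(s): SES.MPD undefined")
        z[single] = np.nan
    return pd.Series(z, index=cm.sample_ids, name="ses_mpd")


def make_pairs(
    metadata: pd.DataFrame,
    comparison_class: str,
    time_matched: bool = True,
) -> list[tuple[str, str]]:
    """Enumerate sample pairs for a comparison class.

    ``within_replicates``: same treatment, different replicate;
    ``between_cs``: different treatment.  With ``time_matched`` (default)
    only pairs sharing a timepoint are compared, matching the paired
    experimental design; disable to pool all timepoint combinations.
    """
    if comparison_class not in ("within_replicates", "between_cs"):
        raise ValueError("comparison_class must be 'within_replicates' or 'between_cs'")
    pairs = []
    for a, b in itertools.combinations(metadata.index, 2):
        ma, mb = metadata.loc[a], metadata.loc[b]
        if time_matched and ma["timepoint"] != mb["timepoint"]:
            continue
        same_treat = ma["treatment"] == mb["treatment"]
        if comparison_class == "within_replicates":
            if same_treat and ma["replicate"] != mb["replicate"]:
                pairs.append((a, b))
        else:
            if not same_treat:
                pairs.append((a, b))
    return pairs


def pair_table(
    cm: CommunityMatrix,
    pd_matrix: PatristicMatrix,
    comparison_class: str,
    n_null: int = 999,
    seed: int = 0,
    time_matched: bool = True,
) -> pd.DataFrame:
    """Run βNTI then RC_bray (on the non-selection pairs) and classify.

    Returns one row per pair: sample ids, class, timepoint (NaN if the
    pair spans timepoints), βMNTD, βNTI, RC_bray (NaN where not needed)
    and the five-way process label.  βNTI and RC use independent child
    seeds derived from *seed*.
    """
    pairs = make_pairs(cm.metadata, comparison_class, time_matched=time_matched)
    if not pairs:
        warnings.warn(f"no pairs for comparison class {comparison_class!r}")
        return pd.DataFrame(
            columns=["sample_a", "sample_b", "comparison_class", "timepoint",
                     "beta_mntd", "beta_nti", "rc_bray", "process"]
        )
    znti, obs_mntd = beta_nti(
        cm, pd_matrix, n_null=n_null, seed=child_seed(seed, "beta-nti"), return_obs=True
    )
    need_rc = [
        (a, b) for a, b in pairs
        if not np.isnan(znti.loc[a, b]) and abs(znti.loc[a, b]) <= 2
    ]
    rc = raup_crick_bray(cm, need_rc, n_null=n_null, seed=child_seed(seed, "raup-crick")) \
        if need_rc else pd.Series(dtype=float)
    rows = []
    for a, b in pairs:
        z = znti.loc[a, b]
        rc_val = rc.get((a, b), np.nan)
        if np.isnan(z):
            proc = np.nan
        else:
            proc = classify_process(float(z), None if abs(z) > 2 else float(rc_val))
        ta, tb = cm.metadata.loc[a, "timepoint"], cm.metadata.loc[b, "timepoint"]
        rows.append(
            {
                "sample_a": a,
                "sample_b": b,
                "comparison_class": comparison_class,
                "timepoint": ta if ta == tb else np.nan,
                "beta_mntd": obs_mntd.loc[a, b],
                "beta_nti": z,
                "rc_bray": rc_val,
                "process": proc,
            }
        )
    return pd.DataFrame(rows)


def time_resolved_partition(
    cm: CommunityMatrix,
    pd_matrix: PatristicMatrix,
    comparison_class: str,
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-timepoint process partition for one comparison class."""
    pairs = pair_table(cm, pd_matrix, comparison_class, n_null=n_null, seed=seed)
    if pairs.empty:
        warnings.warn("no pairs; empty time-resolved partition")
        return pd.DataFrame(columns=list(PROCESSES))
    return partition_processes(pairs, group_by=["timepoint"])
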