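"""Indicator species analysis (IndVal) with permutation significance.

The classic Dufrene-Legendre indicator value of taxon *i* for group *g*
combines specificity A (the group's share of the taxon's mean relative
abundance across groups) and fidelity B (the fraction of the group's
samples where the taxon occurs): IndVal = A x B, reported on the 0-1
scale.  Each taxon is assigned its argmax group and tested by permuting
sample-to-group labels, comparing the permuted maximum IndVal against the
observed one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core_io import CommunityMatrix, tss_normalize

__all__ = ["indval", "significant_indicators"]


def _indval_components(
    rel: np.ndarray, presence: np.ndarray, onehot: np.ndarray, group_sizes: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """A (taxa x groups) and B (taxa x groups) for one label assignment."""
    mean_rel = (rel @ onehot) / group_sizes  # taxa x groups
    denom = mean_rel.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(denom > 0, mean_rel / denom, 0.0)
    b = (presence @ onehot) / group_sizes
    return a, b


def indval(
    cm: CommunityMatrix,
    groups: pd.Series | str = "treatment",
    n_perm: int = 999,
    seed: int = 0,
    all_groups: bool = False,
    presence_floor: float = 0.0,
) -> pd.DataFrame:
    """IndVal per taxon with permutation p-values and BH q-values.

    *groups* is a metadata column name or a Series mapping sample to
    group.  ``presence_floor`` optionally raises the relative-abundance
    threshold for counting a taxon as present (default: any count > 0).
    With ``all_groups`` every (taxon, group) value is returned instead of
    only the argmax group.
    """
    if isinstance(groups, str):
        groups = cm.metadata[groups]
    groups = pd.Series(groups).loc[cm.sample_ids]
    levels = np.array(sorted(groups.unique()))
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    rel = tss_normalize(cm).values.to_numpy()
    presence = (rel > presence_floor).astype(float)
    lab_idx = np.searchsorted(levels, groups.to_numpy())
    n_samples = len(groups)
    onehot = np.zeros((n_samples, len(levels)))
    onehot[np.arange(n_samples), lab_idx] = 1.0
    sizes = onehot.sum(axis=0)

    a, b = _indval_components(rel, presence, onehot, sizes)
    iv = a * b
    best_group = iv.argmax(axis=1)
    obs_max = iv.max(axis=1)

    rng = np.random.default_rng(seed)
    exceed = np.zeros(rel.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(n_samples)
        ap, bp = _indval_components(rel, presence, onehot[perm], sizes)
        exceed += (ap * bp).max(axis=1) >= obs_max - 1e-12
    p = (1 + exceed) / (1 + n_perm)
    # taxa absent everywhere carry no information
    absent = rel.sum(axis=1) == 0
    p[absent] = 1.0
    q = multipletests(p, method="fdr_bh")[1]

    taxa = np.array(cm.taxa_ids)
    if all_groups:
        rows = []
        for gi, g in enumerate(levels):
            rows.append(
                pd.DataFrame(
                    {
                        "taxon": taxa,
                        "group": g,
                        "A": a[:, gi],
                        "B": b[:, gi],
                        "indval": iv[:, gi],
                        "p_value": p,
                        "q_value": q,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)
    return pd.DataFrame(
        {
            "taxon": taxa,
            "group": levels[best_group],
            "A": a[np.arange(len(taxa)), best_group],
            "B": b[np.arange(len(taxa)), best_group],
            "indval": obs_max,
            "p_value": p,
            "q_value": q,
        }
    )


def significant_indicators(
    results: pd.DataFrame, indval_min: float = 0.5, alpha: float = 0.05
) -> pd.DataFrame:
    """Strict screen: IndVal strictly above *indval_min* AND raw p-value
    strictly below *alpha* (both conditions required)."""
    keep = (results["indval"] > indval_min) & (results["p_value"] < alpha)
    return results[keep].reset_index(drop=True)
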