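"""Self-validation benchmarks: oracle equivalence, null calibration and
parameter-recovery runs.

These functions regenerate their own inputs from seeds, run the package's
estimators, and measure agreement with independent references (brute-force
enumeration, the null models' own sampling procedures, or planted ground
truth from :mod:`ecoassembly.synthetic_community`).  They back both the
acceptance-style tests and the reproduction script.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from ._util import child_seed
from .assembly_null_models import (
    PatristicMatrix,
    _null_community,
    beta_mntd,
    beta_nti,
    pair_table,
    raup_crick_bray,
)
from .core_io import CommunityMatrix
from .local_similarity_networks import build_network, local_similarity
from .synthetic_community import (
    PlantedCoupling,
    SyntheticScenario,
    assemble_timeseries,
    generate_truth,
    plant_couplings,
)

__all__ = [
    "beta_mntd_oracle_gap",
    "beta_nti_null_calibration",
    "rc_bray_null_calibration",
    "regime_recovery",
    "lsa_oracle_gap",
    "lsa_planted_recovery",
]


def _brute_force_beta_mntd(rel_a, rel_b, d) -> float:
    """Reference: explicit double loop over all taxon pairs."""
    a = np.asarray(rel_a, float)
    b = np.asarray(rel_b, float)
    a, b = a / a.sum(), b / b.sum()
    pres_a, pres_b = np.where(a > 0)[0], np.where(b > 0)[0]
    total = 0.0
    for i in pres_a:
        total += a[i] * min(d[i, j] for j in pres_b)
    for j in pres_b:
        total += b[j] * min(d[i, j] for i in pres_a)
    return 0.5 * total


def beta_mntd_oracle_gap(n_pairs: int = 200, max_taxa: int = 6, seed: int = 0) -> float:
    """Max |vectorised - brute force| over random small community pairs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        n = int(rng.integers(2, max_taxa + 1))
        d = rng.uniform(0.05, 5.0, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        pm = PatristicMatrix([f"t{i}" for i in range(n)], d)
        a = rng.random(n) * (rng.random(n) > 0.3)
        b = rng.random(n) * (rng.random(n) > 0.3)
        if a.sum() == 0:
            a[int(rng.integers(n))] = 1.0
        if b.sum() == 0:
            b[int(rng.integers(n))] = 1.0
        worst = max(worst, abs(beta_mntd(a, b, pm) - _brute_force_beta_mntd(a, b, d)))
    return worst


def _shuffle_assembled_cm(n_taxa: int, n_samples: int, seed: int):
    """Communities whose taxon identities are themselves random label
    shuffles of a fixed abundance profile — the βNTI null's own world."""
    from .synthetic_community import simulate_tree_and_traits

    newick, traits = simulate_tree_and_traits(n_taxa, 1.0, seed=child_seed(seed, "tree"))
    taxa = list(traits.index)
    rng = np.random.default_rng(child_seed(seed, "profiles"))
    cols = {}
    for j in range(n_samples):
        # independent abundance profile per sample, placed on shuffled taxa
        profile = rng.lognormal(0, 1, n_taxa) * (rng.random(n_taxa) > 0.7)
        if profile.sum() == 0:
            profile[0] = 1.0
        perm = rng.permutation(n_taxa)
        cols[f"s{j}"] = np.round(profile[perm] * 60).astype(int)
    counts = pd.DataFrame(cols, index=taxa)
    counts.iloc[0, counts.sum(axis=0).to_numpy() == 0] = 1
    meta = pd.DataFrame(
        {
            "treatment": ["T1"] * n_samples,
            "replicate": [f"R{j}" for j in range(n_samples)],
            "timepoint": [0] * n_samples,
        },
        index=list(cols),
    )
    return CommunityMatrix(counts, meta), newick, taxa


def beta_nti_null_calibration(
    n_taxa: int = 100,
    n_samples: int = 20,
    n_null: int = 999,
    seed: int = 0,
    n_worlds: int = 8,
) -> dict:
    """Mean, sd and tail fraction of βNTI on null-assembled communities.

    Pairs sharing one tree and one sample set are strongly correlated, so
    a single world gives a noisy grand mean; pooling several independent
    worlds (each its own tree and samples) yields a stable calibration.
    """
    from .assembly_null_models import patristic_matrix

    all_vals = []
    for w in range(n_worlds):
        cm, newick, taxa = _shuffle_assembled_cm(
            n_taxa, n_samples, child_seed(seed, f"world-{w}")
        )
        pdm = patristic_matrix(newick, taxa)
        z = beta_nti(cm, pdm, n_null=n_null, seed=child_seed(seed, f"nti-{w}"))
        vals = z.to_numpy()[np.triu_indices(n_samples, k=1)]
        all_vals.append(vals[~np.isnan(vals)])
    vals = np.concatenate(all_vals)
    return {
        "mean": float(vals.mean()),
        "sd": float(vals.std(ddof=1)),
        "frac_outside_2": float(np.mean(np.abs(vals) > 2)),
        "n_pairs": int(len(vals)),
    }


def rc_bray_null_calibration(
    n_taxa: int = 100,
    n_samples: int = 100,
    n_pairs: int = 60,
    n_null: int = 999,
    seed: int = 0,
) -> dict:
    """Fraction of |RC_bray| > 0.95 for pairs assembled by the RC null's
    own procedure (richness draw by occurrence, reads by abundance).

    A large analysis set keeps the occurrence/abundance weights the test
    derives from the data close to the generating weights.
    """
    rng = np.random.default_rng(child_seed(seed, "rc-pool"))
    pool_abund = rng.lognormal(0, 1, n_taxa)
    pool_abund /= pool_abund.sum()
    occ_logw = np.zeros(n_taxa)  # uniform occurrence weights
    cols = {}
    for j in range(n_samples):
        cols[f"s{j}"] = _null_community(rng, 30, 1000, occ_logw, pool_abund)
    counts = pd.DataFrame(cols, index=[f"t{i}" for i in range(n_taxa)])
    meta = pd.DataFrame(
        {
            "treatment": ["T1"] * n_samples,
            "replicate": [f"R{j}" for j in range(n_samples)],
            "timepoint": [0] * n_samples,
        },
        index=list(cols),
    )
    cm = CommunityMatrix(counts, meta)
    all_pairs = list(itertools.combinations(cm.sample_ids, 2))
    idx = rng.choice(len(all_pairs), size=min(n_pairs, len(all_pairs)), replace=False)
    pairs = [all_pairs[i] for i in idx]
    rc = raup_crick_bray(cm, pairs, n_null=n_null, seed=child_seed(seed, "rc"))
    return {
        "frac_extreme": float(np.mean(np.abs(rc.to_numpy()) > 0.95)),
        "n_pairs": int(len(rc)),
    }


_RECOVERY_SETUP = {
    # regime -> (n_treatments, comparison_class, expected process)
    "homogeneous_selection": (1, "within_replicates", "homogeneous_selection"),
    "variable_selection": (3, "between_cs", "variable_selection"),
    "dispersal_limitation": (1, "within_replicates", "dispersal_limitation"),
    "homogenizing_dispersal": (1, "within_replicates", "homogenizing_dispersal"),
    "drift": (1, "within_replicates", "undominated"),
}


def regime_recovery(
    regime: str,
    seeds=(1, 2, 3, 4, 5),
    n_taxa: int = 150,
    n_timepoints: int = 10,
    n_null: int = 999,
) -> dict:
    """Percent of pairs classified as the regime's expected process,
    pooled over scenario seeds (the parameter-recovery surface)."""
    from .assembly_null_models import patristic_matrix

    n_treat, cls, expected = _RECOVERY_SETUP[regime]
    counts: dict[str, int] = {}
    total = 0
    for seed in seeds:
        sc = SyntheticScenario(
            n_taxa=n_taxa,
            n_treatments=n_treat,
            n_replicates=3,
            n_timepoints=n_timepoints,
            reads_per_sample=2000,
            regime=regime,
            pool_overlap=0.0 if regime == "dispersal_limitation" else 1.0,
            seed=seed,
        )
        truth = generate_truth(sc)
        cm = assemble_timeseries(truth)
        pdm = patristic_matrix(truth.tree_newick, cm.taxa_ids)
        pt = pair_table(cm, pdm, cls, n_null=n_null, seed=child_seed(seed, "recovery"))
        for proc, k in pt["process"].value_counts().items():
            counts[proc] = counts.get(proc, 0) + int(k)
        total += int(pt["process"].notna().sum())
    return {
        "expected_process": expected,
        "recovered_pct": 100.0 * counts.get(expected, 0) / total,
        "n_pairs": total,
    }


def lsa_oracle_gap(n_series: int = 500, max_len: int = 12, seed: int = 0) -> float:
    """Max |scan - exhaustive enumeration| of the local similarity score."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_series):
        n = int(rng.integers(5, max_len + 1))
        zx = rng.normal(size=n)
        zy = rng.normal(size=n)
        d = min(3, n - 1)
        got = local_similarity(zx, zy, max_delay=d).score
        # exhaustive (delay, start, end) enumeration on shared prefix sums
        best = 0.0
        for dd in range(-d, d + 1):
            if dd >= 0:
                p = zx[: n - dd] * zy[dd:]
            else:
                p = zx[-dd:] * zy[: n + dd]
            s = np.concatenate([[0.0], np.cumsum(p)])
            for i in range(len(p)):
                for j in range(i, len(p)):
                    run = s[j + 1] - s[i]
                    if abs(run) > abs(best):
                        best = run
        worst = max(worst, abs(got - best / n))
    return worst


def lsa_planted_recovery(
    seed: int = 0,
    n_taxa: int = 50,
    n_timepoints: int = 29,
    n_couplings: int = 10,
    n_perm: int = 1000,
    q_max: float = 0.05,
) -> dict:
    """Plant lagged couplings in a drift community and measure how many the
    network recovers with the right sign, plus the false-edge rate among
    uncoupled pairs."""
    # iid draws (unselective kernel, no thinning) keep uncoupled taxon
    # trajectories independent; serial-resampling drift would couple every
    # pair through shared compositional history and report genuine
    # (not false) associations.  The pool is two-tiered: 2*n_couplings
    # common taxa carry almost all reads while the rest form a rare tail
    # below the 25% prevalence floor, mirroring real rank-abundance data
    # where only prevalent taxa enter the network.
    sc = SyntheticScenario(
        n_taxa=n_taxa,
        n_treatments=1,
        n_replicates=3,
        n_timepoints=n_timepoints,
        reads_per_sample=500,
        regime="homogeneous_selection",
        selection_sd=1e6,
        colonization_prob=1.0,
        pool_flattening=1.0,
        pool_lognormal_sigma=1.0,
        seed=seed,
    )
    truth = generate_truth(sc)
    rng = np.random.default_rng(child_seed(seed, "pool-tiers"))
    n_common = 2 * n_couplings
    pool = np.full(n_taxa, 1e-4)
    pool[:n_common] = rng.lognormal(0, 0.8, n_common)
    pool[:n_common] *= (1.0 - (n_taxa - n_common) * 1e-4) / pool[:n_common].sum()
    truth.pool_abundances = pd.Series(pool, index=truth.pool_abundances.index)
    cm = assemble_timeseries(truth)
    rng = np.random.default_rng(child_seed(seed, "couplings"))
    abundant = list(truth.pool_abundances.index[:n_common])
    lags = rng.integers(0, 3, n_couplings)
    signs = rng.choice([-1, 1], n_couplings)
    couplings = [
        PlantedCoupling(abundant[2 * k], abundant[2 * k + 1], int(lags[k]), int(signs[k]))
        for k in range(n_couplings)
    ]
    cm2 = plant_couplings(cm, couplings, noise_sd=0.05, seed=child_seed(seed, "noise"))
    edges, _ = build_network(
        cm2, "T1", max_delay=3, n_perm=n_perm, q_max=q_max, seed=child_seed(seed, "net")
    )
    found = {frozenset((e.taxon_a, e.taxon_b)): e for e in edges}
    planted_keys = {frozenset((c.driver, c.follower)): c for c in couplings}
    def _is_recovered(c: PlantedCoupling) -> bool:
        e = found.get(frozenset((c.driver, c.follower)))
        if e is None:
            return False
        sign_ok = (e.ls_score > 0) == (c.sign > 0)
        # positive delay means the second taxon lags the first
        expected = c.lag if e.taxon_a == c.driver else -c.lag
        return sign_ok and e.delay == expected

    recovered = sum(1 for c in couplings if _is_recovered(c))
    # every non-planted pair is uncoupled (a follower copies only its own
    # driver); pairs pruned by the prevalence floor are trivially non-edges
    n_uncoupled = 0
    false_edges = 0
    for a, b in itertools.combinations(cm2.taxa_ids, 2):
        key = frozenset((a, b))
        if key in planted_keys:
            continue
        n_uncoupled += 1
        if key in found:
            false_edges += 1
    return {
        "recovered_pct": 100.0 * recovered / n_couplings,
        "false_edge_pct": 100.0 * false_edges / max(n_uncoupled, 1),
        "n_uncoupled_pairs": n_uncoupled,
    }
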