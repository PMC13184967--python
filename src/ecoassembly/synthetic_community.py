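"""Synthetic communities with known assembly processes.

This module generates phylogenies, phylogenetically conserved traits, and
replicated treatment x replicate x timepoint count tables under one of five
stylised assembly regimes, so that the null-model machinery downstream can
be validated against planted ground truth:

``homogeneous_selection``
    every sample filtered by the same environment through a Gaussian
    trait-matching kernel — compared communities are more phylogenetically
    similar than expected (βNTI << -2 among replicates);
``variable_selection``
    treatments filtered by well-separated environments — between-treatment
    pairs are phylogenetically over-dispersed (βNTI >> +2);

Selection operates at the clade level: the tree is cut into ancestral
clades (lineages crossing a depth where roughly one clade per six tips
exists), each clade carries the mean Brownian trait of its tips, and the
Gaussian kernel on clade traits decides which clades an environment
favours.  Within favoured clades, each sample undergoes an independent
colonisation lottery (Bernoulli thinning) with mild abundance jitter.
This combination — consistent clades, variable membership — is what makes
homogeneous selection detectable by a nearest-taxon null model: replicate
communities share clades but not taxa, so their phylogenetic similarity
exceeds the taxa-shuffle expectation.  Tip-level trait-window selection
does not achieve this (trait convergence across distant clades scatters
the selected set), which is why the clade-level filter is used.

``dispersal_limitation``
    replicates draw from disjoint (or partially overlapping) taxon pools,
    stratified across the phylogeny, then propagate their own history —
    taxonomic divergence (RC_bray -> +1) without phylogenetic divergence;
``homogenizing_dispersal``
    unselective draws with compositional mixing between replicates after
    every timepoint — communities more similar than the taxonomic null
    (RC_bray -> -1);
``drift``
    serial multinomial resampling of each replicate's own previous
    composition (Wright-Fisher style), no selection — neither metric
    deviates systematically (undominated).

The default scenario mirrors a dense succession experiment: 6 treatments x
3 replicates x 29 twice-daily timepoints, with a lognormal rank-abundance
pool providing a long rare tail so that abundant (>1%) and rare (<0.1%)
subcommunities are both populated.

The generator deliberately contains no mechanistic resource chemistry
(no Monod growth or substrate depletion): regimes are statistical
stand-ins whose expected βNTI / RC_bray signatures are known.
"""

from __future__ import annotations

import json
import random as _pyrandom
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from ._util import child_seed
from .core_io import CommunityMatrix, write_community

REGIMES = (
    "homogeneous_selection",
    "variable_selection",
    "dispersal_limitation",
    "homogenizing_dispersal",
    "drift",
)

__all__ = [
    "REGIMES",
    "SyntheticScenario",
    "PlantedCoupling",
    "SyntheticTruth",
    "simulate_tree_and_traits",
    "generate_truth",
    "assemble_timeseries",
    "plant_couplings",
    "write_fixture",
]


@dataclass
class SyntheticScenario:
    """Full parameterisation of one synthetic community experiment.

    ``selection_sd`` (sigma of the Gaussian trait-matching kernel, trait
    units) and ``environment_values`` default to ``None`` meaning
    "auto": sigma is set to 0.3x the standard deviation of the simulated
    traits, and environments are placed at evenly spaced trait quantiles
    (0.1..0.9) for variable selection or all at the trait median for
    homogeneous selection.
    """

    n_taxa: int = 150
    n_treatments: int = 6
    n_replicates: int = 3
    n_timepoints: int = 29
    reads_per_sample: int = 2000
    regime: str = "variable_selection"
    selection_sd: float | None = None
    trait_bm_rate: float = 1.0
    environment_values: tuple[float, ...] | None = None
    pool_overlap: float = 1.0
    mixing_rate: float = 0.7
    pool_lognormal_sigma: float = 1.5
    colonization_prob: float = 0.4
    abundance_jitter_sd: float = 0.5
    pool_flattening: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; choose from {REGIMES}")
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if min(self.n_treatments, self.n_replicates, self.n_timepoints) < 1:
            raise ValueError("design dimensions must be >= 1")
        if self.reads_per_sample < 1:
            raise ValueError("reads_per_sample must be >= 1")
        if not 0.0 <= self.pool_overlap <= 1.0:
            raise ValueError("pool_overlap must be in [0, 1]")
        if self.regime != "dispersal_limitation" and self.pool_overlap != 1.0:
            raise ValueError("pool_overlap < 1 only applies to dispersal_limitation")
        if not 0.0 <= self.mixing_rate <= 1.0:
            raise ValueError("mixing_rate must be in [0, 1]")
        if self.environment_values is not None and len(self.environment_values) != self.n_treatments:
            raise ValueError("environment_values length must equal n_treatments")
        if self.selection_sd is not None and self.selection_sd <= 0:
            raise ValueError("selection_sd must be positive")
        if not 0.0 < self.colonization_prob <= 1.0:
            raise ValueError("colonization_prob must be in (0, 1]")
        if self.abundance_jitter_sd < 0 or self.pool_flattening < 0:
            raise ValueError("abundance_jitter_sd and pool_flattening must be >= 0")


@dataclass
class PlantedCoupling:
    """A known lagged pairwise interaction: follower tracks driver.

    ``lag`` >= 0 timepoints (follower lags driver), ``sign`` +1/-1.
    ``t_start``/``t_end`` optionally restrict the coupling to a temporal
    window (used to plant "local only" associations).
    """

    driver: str
    follower: str
    lag: int = 0
    sign: int = 1
    t_start: int | None = None
    t_end: int | None = None


@dataclass
class SyntheticTruth:
    """Scenario plus everything needed to verify downstream inference."""

    scenario: SyntheticScenario
    tree_newick: str
    traits: pd.Series
    pool_abundances: pd.Series
    environment_values: np.ndarray
    selection_sd: float
    expected_process: dict[str, str]
    clade_of: pd.Series | None = None
    clade_traits: pd.Series | None = None
    planted_couplings: list[PlantedCoupling] = field(default_factory=list)
    replicate_pools: dict[str, list[str]] | None = None


def simulate_tree_and_traits(
    n_taxa: int, trait_bm_rate: float, seed: int
) -> tuple[str, pd.Series]:
    """Pure-birth tree with Brownian-motion trait evolution along branches.

    Returns the newick string and a per-tip trait Series; closely related
    tips have correlated traits (variance of independent increments is
    ``trait_bm_rate x branch length``).  With rate 0 every tip inherits the
    root value exactly.
    """
    if n_taxa < 3:
        raise ValueError("n_taxa must be >= 3")
    from dendropy.simulate import treesim

    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=_pyrandom.Random(int(seed)),
    )
    width = max(4, len(str(n_taxa)))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"OTU_{i + 1:0{width}d}"

    rng = np.random.default_rng(child_seed(int(seed), "bm-traits"))
    tree.seed_node.value = 0.0
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        edge = node.edge.length or 0.0
        step = rng.normal(0.0, np.sqrt(trait_bm_rate * edge)) if trait_bm_rate > 0 else 0.0
        node.value = node.parent_node.value + step
    traits = pd.Series(
        {leaf.taxon.label: leaf.value for leaf in tree.leaf_node_iter()}, name="trait"
    )
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    return newick, traits


_EXPECTED = {
    # regime -> expected dominant process for (within_replicates, between_cs)
    "homogeneous_selection": ("homogeneous_selection", "homogeneous_selection"),
    "variable_selection": ("homogeneous_selection", "variable_selection"),
    "dispersal_limitation": ("dispersal_limitation", "dispersal_limitation"),
    "homogenizing_dispersal": ("homogenizing_dispersal", "homogenizing_dispersal"),
    "drift": ("undominated", "undominated"),
}


def _cut_clades(newick: str, n_taxa: int) -> pd.Series:
    """Cut the tree into roughly one ancestral clade per six tips.

    Starting from the root, the oldest clade is repeatedly split until the
    target number of lineages is reached; each tip is labelled with its
    clade index.  Clade membership is the unit at which the trait-matching
    filter operates.
    """
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.calc_node_ages(ultrametricity_precision=False)
    target = max(4, n_taxa // 6)
    clades = [tree.seed_node]
    while len(clades) < target:
        internal = [c for c in clades if not c.is_leaf()]
        if not internal:
            break
        big = max(internal, key=lambda n: n.age)
        clades.remove(big)
        clades.extend(big.child_nodes())
    clade_of = {}
    for ci, c in enumerate(clades):
        for leaf in ([c] if c.is_leaf() else c.leaf_iter()):
            clade_of[leaf.taxon.label] = ci
    return pd.Series(clade_of, name="clade")


def generate_truth(scenario: SyntheticScenario) -> SyntheticTruth:
    """Simulate the regional species pool: tree, Brownian tip traits,
    lognormal rank abundances, the clade decomposition with its clade-mean
    traits, treatment environments, and expected process labels."""
    newick, traits = simulate_tree_and_traits(
        scenario.n_taxa, scenario.trait_bm_rate, child_seed(scenario.seed, "tree")
    )
    rng = np.random.default_rng(child_seed(scenario.seed, "pool"))
    raw = rng.lognormal(mean=0.0, sigma=scenario.pool_lognormal_sigma, size=scenario.n_taxa)
    pool = pd.Series(raw / raw.sum(), index=traits.index, name="pool")

    clade_of = _cut_clades(newick, scenario.n_taxa).reindex(traits.index)
    clade_traits = traits.groupby(clade_of).mean()

    ct_sd = float(clade_traits.std(ddof=0))
    if scenario.selection_sd is not None:
        sigma = float(scenario.selection_sd)
    else:
        sigma = 0.35 * ct_sd if ct_sd > 0 else 1.0

    ct = clade_traits.to_numpy()
    if scenario.environment_values is not None:
        envs = np.asarray(scenario.environment_values, dtype=float)
    elif scenario.regime == "variable_selection":
        if scenario.n_treatments == 1:
            envs = np.array([float(np.quantile(ct, 0.5))])
        else:
            qs = np.linspace(0.1, 0.9, scenario.n_treatments)
            envs = np.quantile(ct, qs)
    else:
        # homogeneous selection: one shared, moderately extreme optimum;
        # unselective regimes ignore the value entirely
        envs = np.full(scenario.n_treatments, float(np.quantile(ct, 0.8)))

    within, between = _EXPECTED[scenario.regime]
    return SyntheticTruth(
        scenario=scenario,
        tree_newick=newick,
        traits=traits,
        pool_abundances=pool,
        environment_values=envs,
        selection_sd=sigma,
        expected_process={"within_replicates": within, "between_cs": between},
        clade_of=clade_of,
        clade_traits=clade_traits,
    )


def _selection_weights(truth: SyntheticTruth, env: float) -> np.ndarray:
    """Per-taxon base weight for a selective environment.

    The Gaussian kernel is evaluated on clade-mean traits.  Clades are
    admitted in order of trait proximity to the optimum — skipping clades
    of fewer than three tips, which cannot supply the co-occurring close
    relatives that define clade-level filtering — until the admitted pool
    reaches about a quarter of all taxa.  Admitted clades keep their
    kernel weight; the rest are excluded.  The lognormal regional
    abundance enters with exponent ``pool_flattening`` rather than
    linearly: under strong selection the favoured taxa grow toward
    comparable abundances.
    """
    scen = truth.scenario
    pool = truth.pool_abundances.to_numpy()
    if scen.regime in ("dispersal_limitation", "homogenizing_dispersal", "drift"):
        return pool / pool.sum()
    ct = truth.clade_traits
    dist = np.abs(ct.to_numpy() - env)
    kern = np.exp(-(dist**2) / (2.0 * truth.selection_sd**2))
    clade_sizes = truth.clade_of.value_counts().reindex(ct.index).to_numpy()
    if dist.max() <= 2.0 * truth.selection_sd:
        # flat kernel: the filter does not discriminate, nothing is excluded
        selected = np.ones(len(ct), dtype=bool)
    else:
        budget = max(10, int(0.25 * scen.n_taxa))
        selected = np.zeros(len(ct), dtype=bool)
        admitted = 0
        for ci in np.argsort(dist):
            if clade_sizes[ci] < 3 and admitted > 0:
                continue
            selected[ci] = True
            admitted += int(clade_sizes[ci])
            if admitted >= budget:
                break
    clade_w = np.where(selected, kern, 0.0)
    taxon_kern = pd.Series(clade_w, index=ct.index).reindex(truth.clade_of.to_numpy()).to_numpy()
    w = (pool**scen.pool_flattening) * taxon_kern
    if w.sum() <= 0:
        raise ValueError("selection kernel annihilated the pool; increase selection_sd")
    return w / w.sum()


def _replicate_pool_masks(truth: SyntheticTruth, rng: np.random.Generator) -> dict[int, np.ndarray]:
    """Random partition of the pool among replicates for dispersal
    limitation.

    A random partition spreads every replicate's taxa evenly across the
    phylogeny (no clade is private to a replicate), so the divergence it
    creates is taxonomic, not phylogenetic — βNTI stays within +/-2 while
    RC_bray saturates.  A fraction ``pool_overlap`` of taxa (chosen at
    random) is shared by all replicates.
    """
    scen = truth.scenario
    n = scen.n_taxa
    n_shared = int(round(scen.pool_overlap * n))
    shared = rng.choice(n, size=n_shared, replace=False) if n_shared else np.array([], dtype=int)
    shared_set = set(shared.tolist())
    private = np.array([i for i in range(n) if i not in shared_set], dtype=int)
    rng.shuffle(private)
    masks = {r: np.zeros(n, dtype=bool) for r in range(scen.n_replicates)}
    for r in masks:
        masks[r][shared] = True
    for k, i in enumerate(private):
        masks[k % scen.n_replicates][i] = True
    return masks


def assemble_timeseries(truth: SyntheticTruth) -> CommunityMatrix:
    """Draw the full treatment x replicate x timepoint count table.

    Every sample holds exactly ``reads_per_sample`` reads (multinomial
    draws).  Sample ids are ``<treatment>R<rep>_h<hour>`` with timepoints
    spaced 12 h apart; the tip set of the generated tree equals the taxon
    set of the table.  Deterministic given the scenario seed.
    """
    scen = truth.scenario
    rng = np.random.default_rng(child_seed(scen.seed, "assembly"))
    taxa = list(truth.traits.index)
    n = len(taxa)
    reads = scen.reads_per_sample

    rep_masks = None
    if scen.regime == "dispersal_limitation":
        rep_masks = _replicate_pool_masks(truth, rng)
        truth.replicate_pools = {
            f"R{r + 1}": [taxa[i] for i in np.where(m)[0]] for r, m in rep_masks.items()
        }

    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    for t_idx in range(scen.n_treatments):
        treatment = f"T{t_idx + 1}"
        w = _selection_weights(truth, truth.environment_values[t_idx])
        # composition carried forward for history-dependent regimes
        comp = {r: None for r in range(scen.n_replicates)}
        for tp in range(scen.n_timepoints):
            hour = 12 * tp
            drawn = {}
            for r in range(scen.n_replicates):
                if scen.regime in ("homogeneous_selection", "variable_selection"):
                    # per-sample colonisation lottery + mild abundance jitter
                    mask = (rng.random(n) < scen.colonization_prob) & (w > 0)
                    if mask.sum() < 2:
                        mask = w > 0
                    p = w * mask * rng.lognormal(0.0, scen.abundance_jitter_sd, n)
                    p = p / p.sum()
                elif scen.regime == "dispersal_limitation":
                    if comp[r] is None:
                        p = w * rep_masks[r]
                        p = p / p.sum()
                    else:
                        p = comp[r]
                else:  # drift, homogenizing_dispersal
                    p = w if comp[r] is None else comp[r]
                counts = rng.multinomial(reads, p)
                drawn[r] = counts
                comp[r] = counts / reads
            if scen.regime == "homogenizing_dispersal" and scen.n_replicates > 1:
                mean_comp = np.mean([comp[r] for r in comp], axis=0)
                for r in comp:
                    comp[r] = (1 - scen.mixing_rate) * comp[r] + scen.mixing_rate * mean_comp
            for r in range(scen.n_replicates):
                sid = f"{treatment}R{r + 1}_h{hour:03d}"
                columns[sid] = drawn[r]
                meta_rows.append(
                    {"sample": sid, "treatment": treatment, "replicate": f"R{r + 1}", "timepoint": hour}
                )

    counts = pd.DataFrame(columns, index=taxa)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    return CommunityMatrix(counts, meta)


def _largest_remainder_counts(props: np.ndarray, total: int) -> np.ndarray:
    """Deterministically quantise proportions to integers summing to total."""
    target = props / props.sum() * total
    base = np.floor(target).astype(np.int64)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(target - base))
        base[order[:short]] += 1
    return base


def plant_couplings(
    cm: CommunityMatrix,
    couplings: list[PlantedCoupling],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CommunityMatrix:
    """Overwrite follower trajectories with lag-shifted copies of drivers.

    Within each (treatment, replicate) trajectory ordered by timepoint, the
    follower's relative-abundance series becomes the driver's series
    shifted by ``lag`` (held at its first value before the lag), reflected
    as ``(max+min) - x`` when ``sign`` is -1 (an exact negative-linear
    transform), rescaled to the driver's mean abundance, plus Gaussian
    noise of relative magnitude ``noise_sd``.  Columns are re-quantised to
    integers by largest-remainder rounding so each sample keeps its exact
    read total without injecting extra sampling noise that would blur the
    planted signal.
    """
    if not couplings:
        return cm
    n_tp = cm.metadata["timepoint"].nunique()
    for c in couplings:
        if c.lag >= n_tp:
            raise ValueError(f"lag {c.lag} >= number of timepoints {n_tp}")
        if c.lag < 0:
            raise ValueError("lag must be >= 0 (follower lags driver)")
        for tax in (c.driver, c.follower):
            if tax not in cm.counts.index:
                raise ValueError(f"coupled taxon {tax!r} not in matrix")
        if c.sign not in (+1, -1):
            raise ValueError("sign must be +1 or -1")

    rng = np.random.default_rng(seed)
    counts = cm.counts.copy().astype(float)
    meta = cm.metadata
    totals = cm.counts.sum(axis=0)

    for (_, _), group in meta.groupby(["treatment", "replicate"], sort=False):
        order = group.sort_values("timepoint").index.tolist()
        sub = counts[order]
        rel = sub / sub.sum(axis=0)
        for c in couplings:
            drv = rel.loc[c.driver].to_numpy()
            shifted = np.concatenate([np.full(c.lag, drv[0]), drv[: len(drv) - c.lag]])
            if c.sign < 0:
                shifted = (shifted.max() + shifted.min()) - shifted
            target = shifted.copy()
            if target.mean() > 0:
                target = target / target.mean() * max(drv.mean(), 1e-6)
            if noise_sd > 0:
                target = target + rng.normal(0.0, noise_sd * max(target.std(), 1e-12), len(target))
            target = np.clip(target, 1e-9, None)
            lo = 0 if c.t_start is None else c.t_start
            hi = len(order) if c.t_end is None else c.t_end
            follower = rel.loc[c.follower].to_numpy().copy()
            follower[lo:hi] = target[lo:hi]
            rel.loc[c.follower] = follower
        for k, sid in enumerate(order):
            counts[sid] = _largest_remainder_counts(rel[sid].to_numpy(), int(totals[sid]))

    out = CommunityMatrix(counts.round().astype(np.int64), cm.metadata)
    return out


def write_fixture(truth: SyntheticTruth, cm: CommunityMatrix, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture bundle: counts TSV, metadata TSV, newick, truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "metadata": out / "metadata.tsv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.json",
    }
    write_community(cm, paths["counts"], paths["metadata"])
    paths["tree"].write_text(truth.tree_newick + "\n")
    doc = {
        "note": "synthetic ground truth; all generator parameters are artifact choices",
        "scenario": asdict(truth.scenario),
        "selection_sd": truth.selection_sd,
        "environment_values": list(map(float, truth.environment_values)),
        "expected_process": truth.expected_process,
        "planted_couplings": [asdict(c) for c in truth.planted_couplings],
        "replicate_pools": truth.replicate_pools,
    }
    paths["truth"].write_text(json.dumps(doc, indent=2))
    return paths
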