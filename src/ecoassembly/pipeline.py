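"""End-to-end orchestration: load -> normalise -> subcommunity partition ->
null-model process partitioning -> structure statistics -> indicator
species -> association networks -> report bundle.

Every stage draws a named child seed from the master seed (see
:func:`ecoassembly._util.child_seed`), so any stage can be re-run in
isolation reproducibly; all output tables carry the package version,
configuration hash and stage seed in a header comment.  Outputs are
deterministic given the seed: two runs with the same configuration produce
byte-identical numeric tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly_null_models as anm
from . import community_structure as cs
from . import indicator_species as ind
from . import local_similarity_networks as lsa
from ._util import child_seed, config_hash, write_table
from .core_io import CommunityMatrix, read_community, tss_normalize

logger = logging.getLogger(__name__)

ALL_STAGES = ("null_models", "structure", "indicators", "networks")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for a full analysis run.

    Threshold defaults are the standard decision rules of the framework:
    main/rare subcommunity cut-offs 1% / 0.1% mean relative abundance,
    selection at |βNTI| > 2, dispersal at |RC_bray| > 0.95, indicators at
    IndVal > 0.5 with p < 0.05, network FDR q <= 0.05, maximum LSA delay 3,
    999 null-model replicates and 1000 LSA permutations.
    """

    counts: str
    metadata: str
    tree: str
    out_dir: str
    main_threshold: float = 0.01
    rare_threshold: float = 0.001
    bnti_threshold: float = 2.0
    rc_threshold: float = 0.95
    indval_min: float = 0.5
    alpha: float = 0.05
    q_max: float = 0.05
    max_delay: int = 3
    n_null: int = 999
    n_lsa_perm: int = 1000
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    subcommunities: tuple[str, ...] = ("all", "main", "rare")
    ordination: str = "pcoa"

    def __post_init__(self) -> None:
        if self.rare_threshold >= self.main_threshold:
            raise ValueError("rare_threshold must be below main_threshold")
        for val, name in [
            (self.bnti_threshold, "bnti_threshold"),
            (self.rc_threshold, "rc_threshold"),
            (self.indval_min, "indval_min"),
            (self.alpha, "alpha"),
            (self.q_max, "q_max"),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        if "subcommunities" in doc:
            doc["subcommunities"] = tuple(doc["subcommunities"])
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _subcommunity_matrix(cm: CommunityMatrix, part, which: str) -> CommunityMatrix | None:
    if which == "all":
        return cm
    taxa = part.main_taxa if which == "main" else part.rare_taxa
    if len(taxa) < 2:
        logger.warning("subcommunity %s has <2 taxa; skipped", which)
        return None
    sub = cm.subset_taxa(taxa)
    if sub.shape[1] < 4:
        logger.warning("subcommunity %s leaves <4 non-empty samples; skipped", which)
        return None
    return sub


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> dict:
    """Execute the configured stages; returns a summary dict.

    Writes into ``config.out_dir``: pairs.tsv, partition.tsv,
    ordination.tsv, indval.tsv, edges.tsv, network_summary.tsv,
    summary.json and run.log.  Stage failures surface with the stage name.
    """
    out = Path(config.out_dir)
    hashed = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    cfg_hash = config_hash(hashed)
    if dry_run:
        for p in (config.counts, config.metadata, config.tree):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return {"config_hash": cfg_hash, "dry_run": True}

    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    log_lines: list[str] = []

    def _log(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        logger.info(line)
        log_lines.append(line)

    t0 = time.time()
    cm = read_community(config.counts, config.metadata)
    tree_newick = Path(config.tree).read_text()
    pdm = anm.patristic_matrix(tree_newick, cm.taxa_ids)
    part = cs.partition_subcommunities(cm, config.main_threshold, config.rare_threshold)
    _log("load", f"counts {cm.shape}, main={len(part.main_taxa)} rare={len(part.rare_taxa)}")

    summary: dict = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "n_taxa": cm.shape[0],
        "n_samples": cm.shape[1],
        "subcommunity_sizes": {
            "main": len(part.main_taxa),
            "rare": len(part.rare_taxa),
            "intermediate": len(part.intermediate_taxa),
        },
    }

    if "null_models" in config.stages:
        stage_seed = child_seed(config.seed, "null_models")
        all_pairs, partitions = [], []
        for which in config.subcommunities:
            sub = _subcommunity_matrix(cm, part, which)
            if sub is None:
                continue
            sub_pdm = pdm.subset(sub.taxa_ids) if which != "all" else pdm
            for cls in ("within_replicates", "between_cs"):
                pairs = anm.pair_table(
                    sub, sub_pdm, cls,
                    n_null=config.n_null,
                    seed=child_seed(stage_seed, f"{which}-{cls}"),
                )
                if pairs.empty:
                    continue
                pairs.insert(0, "subcommunity", which)
                all_pairs.append(pairs)
                frac = anm.partition_processes(pairs)
                frac.index = pd.MultiIndex.from_tuples(
                    [(cls, which)], names=["comparison_class", "subcommunity"]
                )
                partitions.append(frac)
        pairs_df = pd.concat(all_pairs, ignore_index=True)
        partition_df = pd.concat(partitions)
        write_table(pairs_df, out / "pairs.tsv", seed=stage_seed, cfg_hash=cfg_hash, index=False)
        write_table(partition_df, out / "partition.tsv", seed=stage_seed, cfg_hash=cfg_hash)
        summary["n_pairs"] = int(len(pairs_df))
        summary["partition_row_sums"] = [round(float(v), 6) for v in partition_df.sum(axis=1)]
        _log("null_models", f"{len(pairs_df)} pairs, {len(partition_df)} partition rows")

    if "structure" in config.stages:
        stage_seed = child_seed(config.seed, "structure")
        dm = cs.bray_curtis(tss_normalize(cm))
        if config.ordination == "nmds":
            ordn = cs.nmds(dm, seed=stage_seed)
        else:
            ordn = cs.pcoa(dm, k=2)
        write_table(ordn.coordinates, out / "ordination.tsv", seed=stage_seed, cfg_hash=cfg_hash)
        div = cs.diversity_indices(cm)
        write_table(div, out / "diversity.tsv", seed=stage_seed, cfg_hash=cfg_hash)
        stats: dict = {"ordination_method": ordn.method, "stress": ordn.stress}
        treat = cm.metadata["treatment"]
        if treat.nunique() >= 2 and treat.value_counts().min() >= 2:
            r, p = cs.anosim(dm, treat, seed=child_seed(stage_seed, "anosim"))
            stats["anosim"] = {"R": r, "p": p}
            pdisp = cs.permdisp(dm, treat, seed=child_seed(stage_seed, "permdisp"))
            stats["permdisp"] = {
                "F": pdisp.f_statistic,
                "p": pdisp.p_value,
                "dispersion": {str(k): float(v) for k, v in pdisp.group_dispersion.items()},
            }
        main_cm = _subcommunity_matrix(cm, part, "main")
        rare_cm = _subcommunity_matrix(cm, part, "rare")
        if main_cm is not None and rare_cm is not None:
            shared = [s for s in main_cm.sample_ids if s in set(rare_cm.sample_ids)]
            if len(shared) >= 4:
                ord_main = cs.pcoa(cs.bray_curtis(tss_normalize(main_cm.subset_samples(shared))), k=2)
                ord_rare = cs.pcoa(cs.bray_curtis(tss_normalize(rare_cm.subset_samples(shared))), k=2)
                m2, p = cs.procrustes_protest(
                    ord_main, ord_rare, seed=child_seed(stage_seed, "protest")
                )
                stats["procrustes_main_vs_rare"] = {"m2": m2, "p": p}
        summary["structure"] = stats
        _log("structure", f"ordination={ordn.method} stress={ordn.stress:.4f}")

    if "indicators" in config.stages:
        stage_seed = child_seed(config.seed, "indicators")
        res = ind.indval(cm, "treatment", n_perm=config.n_null, seed=stage_seed)
        write_table(res, out / "indval.tsv", seed=stage_seed, cfg_hash=cfg_hash, index=False)
        sig = ind.significant_indicators(res, config.indval_min, config.alpha)
        summary["n_significant_indicators"] = int(len(sig))
        _log("indicators", f"{len(sig)} significant of {len(res)} taxa")

    if "networks" in config.stages:
        stage_seed = child_seed(config.seed, "networks")
        edge_rows, net_rows = [], []
        for treatment in sorted(cm.metadata["treatment"].unique()):
            edges, net = lsa.build_network(
                cm, treatment,
                max_delay=config.max_delay,
                n_perm=config.n_lsa_perm,
                q_max=config.q_max,
                seed=stage_seed,
            )
            for e in edges:
                edge_rows.append(
                    {
                        "treatment": treatment,
                        "taxon_a": e.taxon_a,
                        "taxon_b": e.taxon_b,
                        "ls": e.ls_score,
                        "delay": e.delay,
                        "p": e.p_value,
                        "q": e.q_value,
                        "sign": e.sign,
                    }
                )
            net_rows.append(
                {
                    "treatment": treatment,
                    "positive": net.n_positive,
                    "negative": net.n_negative,
                    "ratio": net.ratio,
                }
            )
        edges_df = pd.DataFrame(
            edge_rows,
            columns=["treatment", "taxon_a", "taxon_b", "ls", "delay", "p", "q", "sign"],
        )
        nets_df = pd.DataFrame(net_rows)
        write_table(edges_df, out / "edges.tsv", seed=stage_seed, cfg_hash=cfg_hash, index=False)
        write_table(nets_df, out / "network_summary.tsv", seed=stage_seed, cfg_hash=cfg_hash, index=False)
        summary["n_edges"] = int(len(edges_df))
        _log("networks", f"{len(edges_df)} edges across {len(nets_df)} treatments")

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    log_lines.append(f"[done] elapsed {time.time() - t0:.1f}s")
    log_path.write_text("\n".join(log_lines) + "\n")
    return summary
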