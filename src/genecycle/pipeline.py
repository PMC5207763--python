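"""End-to-end orchestration: classify, analyze, report.

``run_pipeline`` drives the full analysis on an input bundle: fit branch
lengths from the distance matrix, infer per-gene gain/loss events and
life stages, detect duplicate families and filter spurious gains,
assemble the feature table, and run the statistical battery (per-stage
medians with bootstrapped SEs, rank tests, TF enrichment, WGD rate
comparison, the logistic local-loss model and the network-integration
ordering test).  All randomness (bootstrap resampling) is seeded.

``crossspecies_view`` re-examines loss locality from the perspective of a
second, distant species using that species' own feature data, both
reclassifying locality relative to the alternate species and projecting
the primary-frame labels onto its orthologs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import duplication, features, stats
from .events import (
    PRE_ROOT,
    GeneEventRecord,
    LifeStage,
    PresenceMatrix,
    build_event_record,
    classify_life_stage,
    event_rate_ratio,
    loss_propensity,
    tabulate_branch_events,
    wgd_gain_loss_fisher,
)
from .phylo import (
    DistanceMatrix,
    LineageConfig,
    ResolvedLineage,
    Tree,
    fit_branch_lengths,
    read_newick,
    resolve_lineage,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "crossspecies_view", "summarize_classification"]

REFERENCE_REWIRING_ORDER = ["regulatory", "kinase", "genetic", "ppi"]

FEATURE_COLUMNS = [
    "ppi_degree",
    "genetic_degree",
    "regulatory_in_degree",
    "mrna_expression",
    "expression_spread",
    "essential",
]


@dataclass
class RunConfig:
    """Paths and options of one pipeline run."""

    indir: Path
    outdir: Path
    focal: str | None = None  # default: read from lineage.tsv
    outgroup: frozenset[str] | None = None
    local_threshold: str | None = None
    wgd_branch: str | None = None
    seed: int = 0
    n_boot: int = 100
    e_threshold: float = 1e-4
    min_conditions: int = 30
    exclude_essential_genetic: bool = True
    wgd_fisher: bool = False
    partial_test: str = "lr"

    def __post_init__(self) -> None:
        self.indir = Path(self.indir)
        self.outdir = Path(self.outdir)

    def path(self, name: str) -> Path:
        p = self.indir / name
        if not p.exists():
            raise FileNotFoundError(f"pipeline input missing: {p}")
        return p

    def read_lineage_file(self) -> dict[str, str]:
        p = self.indir / "lineage.tsv"
        if not p.exists():
            return {}
        df = pd.read_csv(p, sep="\t", dtype=str).fillna("")
        return dict(zip(df["key"], df["value"]))


def _resolve_run_lineage(cfg: RunConfig, tree: Tree) -> tuple[ResolvedLineage, dict[str, str]]:
    meta = cfg.read_lineage_file()
    focal = cfg.focal or meta.get("focal")
    if not focal:
        raise ValueError("no focal species given (flag or lineage.tsv)")
    outgroup = cfg.outgroup
    if outgroup is None and meta.get("outgroup"):
        outgroup = frozenset(meta["outgroup"].split(","))
    lin_cfg = LineageConfig(
        focal=focal,
        outgroup=outgroup,
        local_threshold=cfg.local_threshold or meta.get("local_threshold") or None,
        wgd_branch=cfg.wgd_branch or meta.get("wgd_branch") or None,
    )
    tree.focal = focal
    return resolve_lineage(tree, lin_cfg), meta


def classify_genes(
    tree: Tree,
    pm: PresenceMatrix,
    lineage: ResolvedLineage,
    hits: Sequence[duplication.SimilarityHit],
    e_threshold: float = 1e-4,
    extra_genes: Sequence[str] = (),
) -> tuple[pd.DataFrame, dict[str, GeneEventRecord], list[duplication.DuplicateFamily]]:
    """Per-gene event inference, life stages, duplication annotation.

    ``extra_genes`` are focal genes known from the feature files but
    absent from the orthology map; they are labelled ``excluded``.
    Gained genes with significant similarity to an older gene are
    reclassified as excluded (duplications the orthology map missed).
    """
    focal = lineage.focal
    index = pm.focal_gene_index(focal)
    records: dict[str, GeneEventRecord] = {}
    og_cache: dict[str, GeneEventRecord] = {}
    for gene, og in sorted(index.items()):
        if og in og_cache:
            base = og_cache[og]
            records[gene] = GeneEventRecord(
                gene, base.gain_branch, base.age_class, base.loss_branches,
                base.closest_loss_distance,
            )
        else:
            rec = build_event_record(gene, pm.presence(og), tree, lineage)
            og_cache[og] = rec
            records[gene] = rec

    stages = {g: classify_life_stage(r, tree, lineage) for g, r in records.items()}

    gained = {g for g, r in records.items() if r.age_class != "oldest"}
    older = {g for g, r in records.items() if r.age_class == "oldest"}
    kept, removed = duplication.filter_gained_by_similarity(
        gained, hits, older, e_threshold=e_threshold
    )
    for g in removed:
        stages[g] = LifeStage.EXCLUDED
    logger.info(
        "gained genes: %d initially, %d removed as probable duplications",
        len(gained),
        len(removed),
    )

    families = duplication.annotate_families(
        duplication.find_duplicate_families(pm, focal), hits, pm, tree, lineage
    )

    rows = []
    for gene in sorted(set(records) | set(extra_genes)):
        rec = records.get(gene)
        if rec is None:
            rows.append(
                {
                    "gene": gene,
                    "life_stage": LifeStage.EXCLUDED.value,
                    "gain_branch": "",
                    "age_class": "",
                    "n_losses": 0,
                    "closest_loss_distance": np.nan,
                    "loss_propensity": np.nan,
                }
            )
            continue
        prop = np.nan
        if rec.age_class == "oldest":
            prop = loss_propensity(rec, tree, lineage)
        rows.append(
            {
                "gene": gene,
                "life_stage": stages[gene].value,
                "gain_branch": rec.gain_branch,
                "age_class": rec.age_class,
                "n_losses": len(rec.loss_branches),
                "closest_loss_distance": (
                    rec.closest_loss_distance if rec.closest_loss_distance is not None else np.nan
                ),
                "loss_propensity": prop,
            }
        )
    classification = pd.DataFrame(rows).set_index("gene")
    return classification, records, families


def _off_path_length_split(tree: Tree, lineage: ResolvedLineage) -> tuple[float, float]:
    """Off-path ingroup branch length attaching (pre, post) the WGD node."""
    path = {n.id for n in tree.root_to_focal_path(lineage.focal)}
    wgd = lineage.wgd_node
    pre = post = 0.0
    for node in tree.branches():
        if node.id in path:
            continue
        skip = False
        anc = node
        while anc is not None:
            if anc.id in lineage.outgroup_clade_roots:
                skip = True
                break
            anc = anc.parent
        if skip:
            continue
        length = node.branch_length or 0.0
        if wgd is not None and tree.is_ancestor(wgd, node.id):
            post += length
        else:
            pre += length
    return pre, post


def _wgd_rate_tests(
    tree: Tree,
    lineage: ResolvedLineage,
    records: Sequence[GeneEventRecord],
    use_fisher: bool = False,
) -> pd.DataFrame:
    """Loss- and gain-rate comparison before vs after the WGD branch.

    Loss events are dated by whether the loss branch descends from the
    WGD node; gains by the position of the gain branch on the focal path.
    Rates divide event counts by the relative branch length available in
    each era; undated (pre-root) gains are not compared.  ``records``
    should hold one record per orthogroup so duplicate-family members do
    not double-count events.
    """
    wgd = lineage.wgd_node
    if wgd is None:
        return pd.DataFrame()
    path = tree.root_to_focal_path(lineage.focal)
    loss_pre = loss_post = 0
    for rec in records:
        for b in rec.loss_branches:
            if tree.is_ancestor(wgd, b):
                loss_post += 1
            else:
                loss_pre += 1
    len_pre_off, len_post_off = _off_path_length_split(tree, lineage)

    gains_pre = gains_post = 0
    for rec in records:
        if rec.age_class == "oldest":
            continue
        if tree.is_ancestor(wgd, rec.gain_branch):
            gains_post += 1
        else:
            gains_pre += 1
    widx = [n.id for n in path].index(wgd)
    path_pre = sum(n.branch_length or 0.0 for n in path[1:widx])
    path_post = sum(n.branch_length or 0.0 for n in path[widx:])

    rows = []
    if (loss_pre + loss_post) and len_pre_off > 0 and len_post_off > 0:
        res = event_rate_ratio(loss_post, len_post_off, loss_pre, len_pre_off)
        rows.append(
            {
                "comparison": "loss_rate_post_vs_pre_wgd",
                "fold": res.effect,
                "p_value": res.p_value,
                "n_post": loss_post,
                "n_pre": loss_pre,
                "length_post": len_post_off,
                "length_pre": len_pre_off,
            }
        )
    if (gains_pre + gains_post) and path_pre > 0 and path_post > 0:
        res = event_rate_ratio(gains_pre, path_pre, gains_post, path_post)
        rows.append(
            {
                "comparison": "gain_rate_pre_vs_post_wgd",
                "fold": res.effect,
                "p_value": res.p_value,
                "n_post": gains_post,
                "n_pre": gains_pre,
                "length_post": path_post,
                "length_pre": path_pre,
            }
        )
    if use_fisher and rows:
        fres = wgd_gain_loss_fisher(gains_pre, gains_post, loss_pre, loss_post)
        rows.append(
            {
                "comparison": "gains_vs_losses_x_pre_post_fisher",
                "fold": fres.effect,
                "p_value": fres.p_value,
                "n_post": gains_post + loss_post,
                "n_pre": gains_pre + loss_pre,
                "length_post": np.nan,
                "length_pre": np.nan,
            }
        )
    return pd.DataFrame(rows)


def load_feature_table(
    cfg: RunConfig, classification: pd.DataFrame
) -> pd.DataFrame:
    """Recompute all per-gene features from the raw bundle files."""
    universe = list(classification.index)
    ppi_edges = features.read_edgelist_tsv(cfg.path("ppi.tsv"))
    gen_edges = features.read_edgelist_tsv(cfg.path("genetic.tsv"))
    reg_edges = features.read_edgelist_tsv(cfg.path("regnet.tsv"))
    kinases = set(pd.read_csv(cfg.path("kinases.txt"), sep="\t")["kinase"].astype(str))
    expr = pd.read_csv(cfg.path("expression.tsv"), sep="\t", index_col=0)
    rnaseq = pd.read_csv(cfg.path("rnaseq.tsv"), sep="\t", index_col=0)["reads"]
    flags = pd.read_csv(cfg.path("flags.tsv"), sep="\t", index_col=0).astype(bool)

    feats = {
        "ppi_degree": features.degrees_from_edgelist(ppi_edges, universe, zero_fill=True),
        "genetic_degree": features.degrees_from_edgelist(gen_edges, universe, zero_fill=True),
        "regulatory_in_degree": features.degrees_from_edgelist(
            reg_edges, universe, zero_fill=True, directed_in=True
        ),
        "kinase_degree": features.degrees_from_edgelist(
            ppi_edges, universe, zero_fill=True, partner_subset=kinases
        ),
        "mrna_expression": features.mrna_expression_from_counts(rnaseq.to_dict()),
        "expression_spread": features.expression_spread(
            expr, min_conditions=cfg.min_conditions
        ),
    }
    table = features.assemble_feature_table(
        classification["life_stage"],
        feats,
        flags={"essential": flags["essential"], "is_tf": flags["is_tf"]},
    )
    return table


def _stage_medians(table: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """Median (and bootstrapped SE, 100 resamples) of each feature per stage."""
    rows = []
    numeric = [
        "ppi_degree",
        "genetic_degree",
        "regulatory_in_degree",
        "kinase_degree",
        "mrna_expression",
        "expression_spread",
    ]
    for si, stage in enumerate(s.value for s in LifeStage):
        sub = table[table["life_stage"] == stage]
        for fi, feat in enumerate(numeric):
            vals = sub[feat].dropna()
            if feat == "genetic_degree" and cfg.exclude_essential_genetic:
                vals = sub.loc[~sub["essential"].fillna(False).astype(bool), feat].dropna()
            if len(vals) == 0:
                continue
            se = stats.bootstrap_se_median(
                vals.to_numpy(), n_resamples=cfg.n_boot, seed=cfg.seed + 1000 * si + fi
            )
            rows.append(
                {
                    "life_stage": stage,
                    "feature": feat,
                    "n": len(vals),
                    "median": float(vals.median()),
                    "bootstrap_se": se,
                }
            )
    return pd.DataFrame(rows)


def _group_vals(table: pd.DataFrame, stages: Sequence[str], feat: str, exclude_essential=False) -> np.ndarray:
    sub = table[table["life_stage"].isin(stages)]
    if exclude_essential:
        sub = sub[~sub["essential"].fillna(False).astype(bool)]
    return sub[feat].dropna().to_numpy()


def _comparisons(table: pd.DataFrame, classification: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    """The headline rank-test comparisons between life-stage groups."""
    lost = ["distant_loss", "local_loss"]
    gained = ["ancient_gain", "recent_gain"]
    oldest = ["core"] + lost
    specs: list[tuple[str, Sequence[str], Sequence[str], str, bool]] = [
        ("regulatory_in_degree_lost_vs_core", lost, ["core"], "regulatory_in_degree", False),
        ("regulatory_in_degree_gained_vs_oldest", gained, oldest, "regulatory_in_degree", False),
        ("expression_spread_lost_vs_core", lost, ["core"], "expression_spread", False),
        ("expression_spread_recent_gain_vs_oldest", ["recent_gain"], oldest, "expression_spread", False),
        ("ppi_degree_local_vs_distant_loss", ["local_loss"], ["distant_loss"], "ppi_degree", False),
        (
            "genetic_degree_local_vs_distant_loss",
            ["local_loss"],
            ["distant_loss"],
            "genetic_degree",
            cfg.exclude_essential_genetic,
        ),
        ("mrna_expression_local_vs_distant_loss", ["local_loss"], ["distant_loss"], "mrna_expression", False),
        ("expression_spread_local_vs_distant_loss", ["local_loss"], ["distant_loss"], "expression_spread", False),
        ("regulatory_in_degree_local_vs_distant_loss", ["local_loss"], ["distant_loss"], "regulatory_in_degree", False),
    ]
    rows = []
    for name, ga, gb, feat, excl in specs:
        a = _group_vals(table, ga, feat, excl)
        b = _group_vals(table, gb, feat, excl)
        if len(a) == 0 or len(b) == 0:
            continue
        res = stats.wilcoxon_rank_sum(a, b)
        rows.append(
            {
                "comparison": name,
                "n_a": len(a),
                "n_b": len(b),
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "p_value": res.p_value,
            }
        )
    # loss propensity, local vs distant (tree-wide control)
    cls = classification
    pa = cls.loc[cls["life_stage"] == "local_loss", "loss_propensity"].dropna().to_numpy()
    pb = cls.loc[cls["life_stage"] == "distant_loss", "loss_propensity"].dropna().to_numpy()
    if len(pa) and len(pb):
        res = stats.wilcoxon_rank_sum(pa, pb)
        rows.append(
            {
                "comparison": "loss_propensity_local_vs_distant",
                "n_a": len(pa),
                "n_b": len(pb),
                "median_a": float(np.median(pa)),
                "median_b": float(np.median(pb)),
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def _tf_enrichment(table: pd.DataFrame, dup_members: set[str]) -> pd.DataFrame:
    """TF-enrichment analogue of the published contingency analysis."""
    lost = table[table["life_stage"].isin(["distant_loss", "local_loss"])]
    core = table[table["life_stage"] == "core"]
    gained = table[table["life_stage"].isin(["ancient_gain", "recent_gain"])]
    oldest = table[table["life_stage"].isin(["core", "distant_loss", "local_loss"])]
    dup = table[table.index.isin(dup_members)]
    nondup = table[~table.index.isin(dup_members) & (table["life_stage"] != "excluded")]

    def tf_count(df: pd.DataFrame) -> tuple[int, int]:
        flags = df["is_tf"].fillna(False).astype(bool)
        return int(flags.sum()), int(flags.notna().sum())

    rows = []
    for name, (grp, ref) in {
        "lost_vs_core": (lost, core),
        "gained_vs_oldest": (gained, oldest),
        "duplicated_vs_nonduplicated": (dup, nondup),
    }.items():
        (k1, n1), (k2, n2) = tf_count(grp), tf_count(ref)
        if n1 == 0 or n2 == 0:
            continue
        res = stats.fisher_exact_2x2(k1, n1 - k1, k2, n2 - k2)
        rows.append(
            {
                "comparison": name,
                "tf_group": k1,
                "n_group": n1,
                "percent_group": round(100 * k1 / n1, 1),
                "tf_reference": k2,
                "n_reference": n2,
                "percent_reference": round(100 * k2 / n2, 1),
                "fold": stats.fold_enrichment(k1, n1, k2, n2) if k2 else np.nan,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def _integration(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Degree ratios of anciently gained vs oldest genes, per network type."""
    young = table[table["life_stage"] == "ancient_gain"]
    old = table[table["life_stage"].isin(["core", "distant_loss", "local_loss"])]
    ratios = {}
    for net, col in [
        ("regulatory", "regulatory_in_degree"),
        ("kinase", "kinase_degree"),
        ("genetic", "genetic_degree"),
        ("ppi", "ppi_degree"),
    ]:
        a, b = young[col].dropna(), old[col].dropna()
        if len(a) == 0 or len(b) == 0 or b.mean() <= 0:
            ratios[net] = np.nan
        else:
            ratios[net] = stats.integration_ratio(a, b)
    frame = pd.DataFrame(
        {"network": list(ratios), "degree_ratio_young_over_old": list(ratios.values())}
    )
    observed = [n for n, _ in sorted(ratios.items(), key=lambda kv: -kv[1])]
    p = stats.ordering_pvalue(observed, REFERENCE_REWIRING_ORDER)
    frame["rank"] = frame["network"].map({n: i + 1 for i, n in enumerate(observed)})
    return frame, p


def _loss_model(table: pd.DataFrame, cfg: RunConfig) -> tuple[stats.LossModelFit | None, pd.DataFrame]:
    oldest = table[table["life_stage"].isin(["core", "distant_loss", "local_loss"])]
    X = oldest[FEATURE_COLUMNS].astype(float)
    y = (oldest["life_stage"] == "local_loss").astype(float)
    try:
        fit = stats.fit_local_loss_model(X, y, partial_test=cfg.partial_test)
    except ValueError as exc:
        logger.warning("loss model not fit: %s", exc)
        return None, pd.DataFrame()
    frame = pd.DataFrame(
        {
            "feature": [c for c in FEATURE_COLUMNS if c in fit.partial_pvalues.index],
        }
    )
    frame["coefficient"] = frame["feature"].map(fit.params)
    frame["direction"] = frame["feature"].map(fit.direction())
    frame["partial_p"] = frame["feature"].map(fit.partial_pvalues)
    return fit, frame


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Writes classification.tsv, branch_events.tsv, stage_medians.tsv,
    comparisons.tsv, tf_enrichment.tsv, wgd_rates.tsv, loss_model.tsv,
    integration.tsv, families.tsv and report.txt under ``cfg.outdir``.
    Identical inputs and seed produce byte-identical outputs.
    """
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    tree = read_newick(cfg.path("tree.nwk"))
    lineage, meta = _resolve_run_lineage(cfg, tree)
    dm = DistanceMatrix.from_tsv(cfg.path("distances.tsv"))
    tree = fit_branch_lengths(dm, tree)
    tree.focal = lineage.focal

    pm = PresenceMatrix.from_tsv(cfg.path("orthogroups.tsv"), species=tree.leaf_names)
    hits = duplication.read_hits_tsv(cfg.path("hits.tsv"))
    flags = pd.read_csv(cfg.path("flags.tsv"), sep="\t", index_col=0)
    mapped = set(pm.focal_gene_index(lineage.focal))
    extra = sorted(set(flags.index.astype(str)) - mapped)
    if extra:
        logger.info("%d genes outside the orthology map labelled excluded", len(extra))

    classification, records, families = classify_genes(
        tree, pm, lineage, hits, e_threshold=cfg.e_threshold, extra_genes=extra
    )
    n_classified = int((classification["life_stage"] != "excluded").sum())
    logger.info(
        "classified %d genes (+%d excluded) = %d in",
        n_classified,
        len(classification) - n_classified,
        len(classification),
    )
    branch_events = tabulate_branch_events(
        [records[g] for g in sorted(records)], tree
    )

    table = load_feature_table(cfg, classification)
    dup_members = {m for f in families for m in f.members}

    medians = _stage_medians(table, cfg)
    comparisons = _comparisons(table, classification, cfg)
    tf_table = _tf_enrichment(table, dup_members)
    # one record per orthogroup for event-rate bookkeeping
    gene_to_og = pm.focal_gene_index(lineage.focal)
    og_records = list({gene_to_og[g]: r for g, r in records.items()}.values())
    wgd_table = _wgd_rate_tests(tree, lineage, og_records, use_fisher=cfg.wgd_fisher)
    fit, loss_model = _loss_model(table, cfg)
    integration, ordering_p = _integration(table)
    fam_frame = duplication.families_to_frame(families)

    outputs = {
        "classification": classification,
        "branch_events": branch_events,
        "stage_medians": medians,
        "comparisons": comparisons,
        "tf_enrichment": tf_table,
        "wgd_rates": wgd_table,
        "loss_model": loss_model,
        "integration": integration,
        "families": fam_frame,
    }
    for name, frame in outputs.items():
        frame.round(8).to_csv(
            cfg.outdir / f"{name}.tsv",
            sep="\t",
            index=name in ("classification", "branch_events"),
        )

    counts = classification["life_stage"].value_counts()
    report_lines = [
        "gene life-cycle analysis report",
        "===============================",
        f"focal species: {lineage.focal}",
        f"outgroup: {','.join(sorted(lineage.outgroup))}",
        f"genes in: {len(classification)}  classified: {n_classified}  "
        f"excluded: {len(classification) - n_classified}",
        "life-stage counts: "
        + ", ".join(f"{s}={int(counts.get(s, 0))}" for s in [e.value for e in LifeStage]),
        f"total loss events: {int(branch_events['loss_count'].sum())}",
        f"duplicate families: {len(families)}",
        "",
        "network integration (degree ratio, young/old): "
        + ", ".join(
            f"{r.network}={r.degree_ratio_young_over_old:.3f}"
            for r in integration.itertuples()
        ),
        f"integration ordering p = {ordering_p:.4f}",
    ]
    if fit is not None:
        report_lines += [
            f"local-loss logistic model: n={fit.n}, R^2={fit.r_squared:.4f}, "
            "direction=" + "".join(loss_model["direction"].fillna("?")),
        ]
    for frame, label in ((tf_table, "TF enrichment"), (wgd_table, "WGD rates")):
        if len(frame):
            report_lines.append("")
            report_lines.append(label + ":")
            report_lines.append(frame.round(6).to_string(index=False))
    (cfg.outdir / "report.txt").write_text("\n".join(report_lines) + "\n")

    return {
        **outputs,
        "tree": tree,
        "lineage": lineage,
        "records": records,
        "feature_table": table,
        "loss_model_fit": fit,
        "ordering_p": ordering_p,
        "meta": meta,
    }


def crossspecies_view(
    cfg: RunConfig,
    result: dict,
    alt_focal: str | None = None,
    alt_threshold: str | None = None,
) -> pd.DataFrame:
    """Loss-locality comparisons in the frame of a second species.

    Part 1 reclassifies each lost gene's locality relative to the
    alternate species and compares the alternate species' own expression
    and interaction-degree data between alt-local and alt-distant losses.
    Part 2 projects the primary-frame local/distant labels onto the same
    alternate-species orthologs.  ``alt_focal == focal`` reduces part 2 to
    the primary comparisons.
    """
    tree: Tree = result["tree"]
    lineage: ResolvedLineage = result["lineage"]
    meta = result.get("meta", {})
    alt = alt_focal or meta.get("alt")
    if not alt:
        raise ValueError("no alternate focal species given")
    thr = alt_threshold or meta.get("alt_threshold")
    if thr and tree.has_node(thr) and tree.node(thr).is_leaf and thr != alt:
        thr = tree.mrca(alt, thr).id
    if not thr:
        path = tree.path_to_root(alt)
        thr = path[min(2, len(path) - 1)].id

    pm = PresenceMatrix.from_tsv(cfg.path("orthogroups.tsv"), species=tree.leaf_names)
    alt_expr = pd.read_csv(cfg.path("alt_expression.tsv"), sep="\t", index_col=0)["intensity"]
    alt_gen = features.read_edgelist_tsv(cfg.path("alt_genetic.tsv"))
    alt_ppi = features.read_edgelist_tsv(cfg.path("alt_ppi.tsv"))

    index = pm.focal_gene_index(lineage.focal)
    records: Mapping[str, GeneEventRecord] = result["records"]
    classification: pd.DataFrame = result["classification"]

    rows = []
    for gene, og in index.items():
        rec = records.get(gene)
        if rec is None or rec.age_class != "oldest" or not rec.loss_branches:
            continue
        alt_genes = pm.genes(og, alt)
        if not alt_genes:
            continue
        alt_local = any(
            tree.is_strict_descendant(tree.mrca(alt, b).id, thr) for b in rec.loss_branches
        )
        rows.append(
            {
                "gene": gene,
                "alt_gene": alt_genes[0],
                "alt_local": alt_local,
                "focal_stage": classification.loc[gene, "life_stage"],
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        logger.warning("cross-species view: no lost genes with an ortholog in %s", alt)
        return pd.DataFrame()
    n_skipped = sum(
        1
        for gene, og in index.items()
        if records.get(gene) is not None
        and records[gene].age_class == "oldest"
        and records[gene].loss_branches
        and not pm.genes(og, alt)
    )
    logger.info("cross-species view: %d lost genes without %s ortholog skipped", n_skipped, alt)

    alt_universe = list(frame["alt_gene"])
    gen_deg = features.degrees_from_edgelist(alt_gen, alt_universe, zero_fill=False)
    ppi_deg = features.degrees_from_edgelist(alt_ppi, alt_universe, zero_fill=True)
    frame["alt_expression"] = np.log10(alt_expr.reindex(frame["alt_gene"]).to_numpy())
    frame["alt_genetic_degree"] = frame["alt_gene"].map(gen_deg)
    frame["alt_ppi_degree"] = frame["alt_gene"].map(ppi_deg)

    out_rows = []
    for view, col in [("alt_frame", "alt_local"), ("focal_frame", None)]:
        if col is None:
            sel = frame["focal_stage"] == "local_loss"
            other = frame["focal_stage"] == "distant_loss"
        else:
            sel = frame[col].astype(bool)
            other = ~sel
        for featname in ["alt_expression", "alt_genetic_degree", "alt_ppi_degree"]:
            a = frame.loc[sel, featname].dropna().to_numpy()
            b = frame.loc[other, featname].dropna().to_numpy()
            if len(a) == 0 or len(b) == 0:
                continue
            res = stats.wilcoxon_rank_sum(a, b)
            out_rows.append(
                {
                    "view": view,
                    "feature": featname,
                    "n_local": len(a),
                    "n_other": len(b),
                    "median_local": float(np.median(a)),
                    "median_other": float(np.median(b)),
                    "p_value": res.p_value,
                }
            )
    out = pd.DataFrame(out_rows)
    out.round(8).to_csv(cfg.outdir / "crossspecies.tsv", sep="\t", index=False)
    return out


def summarize_classification(path: str | Path) -> dict[str, int]:
    """Stage counts and total loss events from a classification TSV.

    This is the golden-file entry point: given a per-ORF classification
    table (ours, or an externally curated one with the same columns), it
    recomputes the headline genome-wide counts.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = df["life_stage"].value_counts()
    lost = int(counts.get("distant_loss", 0) + counts.get("local_loss", 0))
    oldest = df[df["life_stage"].isin(["core", "distant_loss", "local_loss"])]
    return {
        "n_core": int(counts.get("core", 0)),
        "n_lost": lost,
        "n_gained": int(
            counts.get("ancient_gain", 0) + counts.get("recent_gain", 0)
        ),
        "n_excluded": int(counts.get("excluded", 0)),
        "n_loss_events": int(oldest["n_losses"].sum()),
    }
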