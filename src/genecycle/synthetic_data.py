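"""Synthetic input bundles with known ground truth.

Generates every input the pipeline consumes — species tree, pairwise
distance matrix, orthogroup membership, network edge lists, expression
matrices, similarity hits — from a single seeded configuration, together
with the true per-gene event records and life stages.

The generator encodes the study conditions as generative effects: a
whole-genome duplication branch with elevated loss and depressed gain
rates downstream, stage-dependent network degrees (lineage-specific genes
have more regulators, fewer physical/genetic partners, lower and more
variable expression), transcription-factor fractions per stage, and a
marginalized gene subset with multiplied loss rate.

Gene histories follow the irreversible single-gain model: a gain branch,
then independent per-branch loss events; a lost lineage stays lost unless
``allow_regain`` is set.  With regain disabled, the generator resamples
the rare gene whose realized history is not parsimony-identifiable (two
sibling lineages lost independently, the gain clade pruned at its root,
or an "oldest" gene wiped from the entire outgroup), so the true event
set is exactly the canonical Dollo reconstruction of the leaf pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import PRE_ROOT, GeneEventRecord, LifeStage, PresenceMatrix, classify_life_stage
from .features import expression_spread, mrna_expression_from_counts
from .phylo import (
    DistanceMatrix,
    Node,
    ResolvedLineage,
    Tree,
    identify_outgroup,
    maximal_clades_within,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StageEffect",
    "SimulationConfig",
    "SyntheticLineage",
    "simulate_tree",
    "default_lineage",
    "simulate_gene_histories",
    "simulate_features",
    "simulate_logistic",
    "simulate_bundle",
]


@dataclass(frozen=True)
class StageEffect:
    """Multiplicative shifts of feature means for one life stage."""

    ppi: float = 1.0
    genetic: float = 1.0
    regulatory: float = 1.0
    kinase: float = 1.0
    expression: float = 1.0
    spread: float = 1.0


# Qualitative stage contrasts: lineage-specific genes carry more regulators
# and more variable, lower expression but fewer physical/genetic partners;
# kinase partnerships of old genes are not deflated by loss propensity, so
# the kinase network integrates new genes faster than PPI/genetic but
# slower than transcriptional regulation.
DEFAULT_STAGE_EFFECTS: dict[str, StageEffect] = {
    "core": StageEffect(),
    "distant_loss": StageEffect(0.70, 0.80, 1.6, 1.0, 0.80, 1.30),
    "local_loss": StageEffect(0.45, 0.55, 2.0, 1.0, 0.55, 1.55),
    "ancient_gain": StageEffect(0.50, 0.60, 1.8, 1.15, 0.70, 1.40),
    "recent_gain": StageEffect(0.30, 0.40, 2.2, 1.2, 0.60, 1.60),
    "focal_specific": StageEffect(0.20, 0.30, 1.0, 0.8, 0.50, 1.60),
    "excluded": StageEffect(0.20, 0.30, 1.0, 0.8, 0.50, 1.60),
}

DEFAULT_TF_FRACTION: dict[str, float] = {
    "core": 0.012,
    "distant_loss": 0.026,
    "local_loss": 0.026,
    "ancient_gain": 0.044,
    "recent_gain": 0.044,
    "focal_specific": 0.044,
    "excluded": 0.020,
}

DEFAULT_ESSENTIAL_FRACTION: dict[str, float] = {
    "core": 0.28,
    "distant_loss": 0.15,
    "local_loss": 0.08,
    "ancient_gain": 0.08,
    "recent_gain": 0.05,
    "focal_specific": 0.03,
    "excluded": 0.03,
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the seed fixes every random draw."""

    seed: int = 0
    n_species: int = 23
    n_genes: int = 4600
    branch_scale: float = 0.12  # mean exponential branch length (subst./site)
    distance_noise: float = 0.0  # sd of noise added to patristic distances
    frac_oldest: float = 0.83  # genes predating the ingroup root
    loss_rate: float = 0.12  # loss events per unit branch length
    allow_regain: bool = False
    regain_rate: float = 0.05  # used only when allow_regain
    loss_rate_multiplier_marginalized: float = 3.0
    marginalized_fraction: float = 0.25
    wgd_loss_multiplier: float = 4.0  # loss-rate boost below the WGD branch
    wgd_gain_factor: float = 1.0 / 5.3  # gain-weight deflation below the WGD branch
    dup_fraction: float = 0.05  # oldest genes with a focal duplicate
    spurious_gain_fraction: float = 84 / 880  # gains that are missed duplications
    benign_hit_fraction: float = 0.05  # gains with an above-threshold hit
    excluded_fraction: float = 0.04  # extra orphan genes outside the orthology map
    n_conditions: int = 300
    mean_ppi: float = 8.0
    mean_genetic: float = 12.0
    mean_regulatory: float = 4.0
    mean_kinase: float = 2.0
    mean_reads: float = 150.0
    base_spread: float = 0.15  # sd of log10 intensity for a core gene
    nb_dispersion: float = 2.0
    identity_noise: float = 3.0  # sd of percent-identity draws for duplicate hits
    stage_effects: Mapping[str, StageEffect] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_EFFECTS)
    )
    tf_fraction: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TF_FRACTION))
    essential_fraction: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ESSENTIAL_FRACTION)
    )

    def __post_init__(self) -> None:
        if self.loss_rate < 0 or self.branch_scale <= 0:
            raise ValueError("rates and scales must be nonnegative")
        if self.loss_rate_multiplier_marginalized < 1:
            raise ValueError("the marginalized loss multiplier must be >= 1")
        for frac in (self.frac_oldest, self.marginalized_fraction, self.dup_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticLineage:
    """Lineage anchors chosen by the generator for a simulated tree."""

    lineage: ResolvedLineage
    alt: str  # distant second focal species (cross-species view)
    alt_threshold: str  # node on the root-to-alt path defining "close to alt"


def simulate_tree(
    n_species: int,
    seed: int = 0,
    branch_scale: float = 0.12,
    distance_noise: float = 0.0,
) -> tuple[Tree, DistanceMatrix]:
    """Random rooted binary tree plus the matching leaf distance matrix.

    Branch lengths are exponential with mean ``branch_scale``; the two
    root-adjacent branches are set to their average so that every branch
    length is identifiable from leaf-pair distances.  With zero noise the
    matrix is exactly additive on the tree.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    width = max(2, len(str(n_species)))
    names = [f"sp{i + 1:0{width}d}" for i in range(n_species)]
    focal_name, side_names = names[0], names[1:]

    def join_random(nodes: list[Node]) -> Node:
        nodes = list(nodes)
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            right = nodes.pop(j)
            left = nodes.pop(i)
            parent = Node("tmp")
            parent.add_child(left)
            parent.add_child(right)
            left.branch_length = float(rng.exponential(branch_scale))
            right.branch_length = float(rng.exponential(branch_scale))
            nodes.append(parent)
        return nodes[0]

    # backbone from root to the focal leaf with one side subtree per node:
    # the shape of the intended application, where the focal species nests
    # deep and the outgroup is the two root-most side clades
    n_side = len(side_names)
    n_back = max(2, min(n_side, int(round(0.6 * n_side))))
    sizes = np.ones(n_back, dtype=int)
    for _ in range(n_side - n_back):
        sizes[rng.integers(n_back)] += 1
    side_trees: list[Node] = []
    pos = 0
    for size in sizes:
        group = [Node(nm) for nm in side_names[pos : pos + size]]
        pos += size
        side_trees.append(join_random(group))

    node = Node(focal_name)  # build upward from the focal leaf
    for side in reversed(side_trees):
        parent = Node("tmp")
        parent.add_child(side)
        parent.add_child(node)
        side.branch_length = float(rng.exponential(branch_scale))
        node.branch_length = float(rng.exponential(branch_scale))
        node = parent
    root = node
    mean_root = (root.children[0].branch_length + root.children[1].branch_length) / 2
    for child in root.children:
        child.branch_length = mean_root

    counter = 0

    def relabel(node: Node) -> None:
        nonlocal counter
        if node.children:
            node.id = f"N{counter}"
            counter += 1
            for c in node.children:
                relabel(c)

    relabel(root)
    tree = Tree(root, focal=f"sp{1:0{width}d}")

    names = tree.leaf_names
    n = len(names)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tree.patristic_distance(names[i], names[j])
            if distance_noise > 0:
                d = max(0.0, d + rng.normal(0.0, distance_noise))
            dm[i, j] = dm[j, i] = d
    return tree, DistanceMatrix(names, dm)


def default_lineage(tree: Tree) -> SyntheticLineage:
    """Choose outgroup, local threshold, WGD branch and alternate focal leaf.

    The local threshold is the deepest root-to-focal path node whose clade
    still holds at least four species (so a "local" neighbourhood exists);
    the WGD branch is the path branch immediately below it.  The alternate
    focal species is the non-outgroup leaf farthest from the focal one.
    """
    focal = tree.focal
    assert focal is not None
    outgroup = identify_outgroup(tree, focal)
    path = tree.root_to_focal_path(focal)
    threshold = path[1] if len(path) > 1 else path[0]
    min_local = max(4, round(0.3 * len(tree.leaf_names)))
    for node in path[1:-1]:
        if len(tree.clade_leaves(node.id)) >= min_local:
            threshold = node
    idx = [n.id for n in path].index(threshold.id)
    wgd = path[idx + 1].id if idx + 1 < len(path) else None
    lineage = ResolvedLineage(
        focal=focal,
        outgroup=outgroup,
        outgroup_clade_roots=maximal_clades_within(tree, outgroup),
        local_threshold=threshold.id,
        wgd_node=wgd,
        ancient_root=None,
    )
    # alternate focal species: a leaf in a distant non-outgroup side clade,
    # preferably one with >= 3 species so a "close to alt" neighbourhood
    # exists; the alt threshold is the attachment node of that clade
    path_ids = {n.id for n in path}
    side_roots = [
        c
        for n in path
        for c in n.children
        if c.id not in path_ids and c.id not in lineage.outgroup_clade_roots
    ]
    if not side_roots:  # degenerate: everything is outgroup
        side_roots = [c for n in path for c in n.children if c.id not in path_ids]
    def clade_dist(c: Node) -> float:
        return max(tree.patristic_distance(focal, l) for l in tree.clade_leaves(c.id))

    # prefer a roomy clade (a real neighbourhood for "close to alt"),
    # then the most distant one
    chosen = max(
        side_roots,
        key=lambda c: (min(len(tree.clade_leaves(c.id)), 4), clade_dist(c), c.id),
    )
    alt = max(
        tree.clade_leaves(chosen.id), key=lambda l: (tree.patristic_distance(focal, l), l)
    )
    alt_threshold = chosen.parent.id if chosen.parent is not None else chosen.id
    return SyntheticLineage(lineage=lineage, alt=alt, alt_threshold=alt_threshold)


def _simulate_one_history(
    tree: Tree,
    lineage: ResolvedLineage,
    gain_node: str,
    rate: float,
    rng: np.random.Generator,
    cfg: SimulationConfig,
    path_ids: frozenset[str],
) -> tuple[set[str], list[str]]:
    """One realization of presence leaves and fired loss branches."""
    present_leaves: set[str] = set()
    fired: list[str] = []
    wgd = lineage.wgd_node

    def branch_rate(node: Node) -> float:
        r = rate
        if wgd is not None and tree.is_ancestor(wgd, node.id):
            r *= cfg.wgd_loss_multiplier
        return r

    def walk(node: Node, present: bool) -> None:
        if node.is_leaf:
            if present:
                present_leaves.add(node.id)
            return
        for child in node.children:
            state = present
            if child.id in path_ids:
                state = True  # condition on survival along the focal path
            elif present:
                p_loss = 1.0 - np.exp(-branch_rate(child) * (child.branch_length or 0.0))
                if rng.random() < p_loss:
                    state = False
                    fired.append(child.id)
            elif cfg.allow_regain:
                p_regain = 1.0 - np.exp(-cfg.regain_rate * (child.branch_length or 0.0))
                if rng.random() < p_regain:
                    state = True
            walk(child, state)

    start = tree.node(gain_node)
    if start.is_leaf:
        present_leaves.add(start.id)
    else:
        walk(start, True)
    return present_leaves, fired


def _is_canonical(
    tree: Tree,
    lineage: ResolvedLineage,
    gain_node: str,
    oldest: bool,
    present: set[str],
    fired: Sequence[str],
) -> bool:
    """True iff the fired event set is the Dollo reconstruction of the pattern."""
    if lineage.focal not in present:
        return False
    outgroup = lineage.outgroup
    if oldest:
        if not (present & outgroup):
            return False
    else:
        if tree.mrca(*sorted(present)).id != gain_node:
            return False
    fired_set = set(fired)
    # every surviving node outside outgroup clades must keep >= 1 child lineage
    alive = {gain_node}
    stack = [tree.node(gain_node)]
    while stack:
        node = stack.pop()
        for child in node.children:
            if child.id not in fired_set:
                alive.add(child.id)
                stack.append(child)
    for nid in alive:
        node = tree.node(nid)
        if node.is_leaf:
            continue
        if tree.clade_leaves(nid) <= outgroup:
            continue
        if all(c.id in fired_set for c in node.children):
            return False
    return True


def simulate_gene_histories(
    tree: Tree,
    cfg: SimulationConfig,
    lineage: ResolvedLineage | None = None,
) -> tuple[PresenceMatrix, list[GeneEventRecord], pd.DataFrame]:
    """Simulate gain/loss histories for ``cfg.n_genes`` focal-present genes.

    Returns the presence matrix, the true event records (one per focal
    gene), and a truth frame with the life stage and the marginalized
    flag of each gene.  Losses fired inside outgroup clades are kept in
    the presence pattern but excluded from the recorded events, matching
    how the reconstruction treats the outgroup.
    """
    rng = np.random.default_rng(cfg.seed)
    if lineage is None:
        lineage = default_lineage(tree).lineage
    focal = lineage.focal
    path = tree.root_to_focal_path(focal)
    path_ids = frozenset(n.id for n in path)
    # gain-branch weights along the focal path (pre-root handled separately);
    # dateable gains can only sit below every outgroup attachment, otherwise
    # the gene would carry outgroup orthologs and count as oldest
    gain_nodes = [
        n for n in path[1:] if not (tree.clade_leaves(n.id) & lineage.outgroup)
    ]
    weights = np.array([n.branch_length or 0.0 for n in gain_nodes], dtype=float)
    if lineage.wgd_node is not None:
        for i, n in enumerate(gain_nodes):
            if tree.is_ancestor(lineage.wgd_node, n.id):
                weights[i] *= cfg.wgd_gain_factor
    if weights.sum() <= 0:
        weights = np.ones(len(gain_nodes))
    weights = weights / weights.sum()

    groups: dict[str, dict[str, tuple[str, ...]]] = {}
    records: list[GeneEventRecord] = []
    truth_rows = []
    attempts = 0
    max_attempts = 200 * cfg.n_genes
    i = 0
    while i < cfg.n_genes:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                "could not generate identifiable gene histories; lower loss_rate"
            )
        oldest = rng.random() < cfg.frac_oldest
        gain_node = (
            tree.root.id if oldest else gain_nodes[rng.choice(len(gain_nodes), p=weights)].id
        )
        marginalized = rng.random() < cfg.marginalized_fraction
        rate = cfg.loss_rate * (
            cfg.loss_rate_multiplier_marginalized if marginalized else 1.0
        )
        present, fired = _simulate_one_history(
            tree, lineage, gain_node, rate, rng, cfg, path_ids
        )
        if not cfg.allow_regain and not _is_canonical(
            tree, lineage, gain_node, oldest, present, fired
        ):
            continue
        if focal not in present:
            continue

        og = f"OG{i:05d}"
        gene = f"{focal}_g{i:05d}"
        groups[og] = {sp: (f"{sp}_g{i:05d}",) for sp in sorted(present)}

        truth_losses = frozenset(
            b for b in fired if not tree.clade_leaves(b) <= lineage.outgroup
        )
        if oldest:
            gain_branch, age = PRE_ROOT, "oldest"
        elif gain_node == focal:
            gain_branch, age = focal, "focal_specific"
        elif lineage.local_threshold is not None and tree.is_strict_descendant(
            gain_node, lineage.local_threshold
        ):
            gain_branch, age = gain_node, "recent_gain"
        else:
            gain_branch, age = gain_node, "ancient_gain"
        closest = (
            min(tree.patristic_distance(focal, b) for b in truth_losses)
            if truth_losses
            else None
        )
        rec = GeneEventRecord(gene, gain_branch, age, truth_losses, closest)
        records.append(rec)
        truth_rows.append(
            {
                "gene": gene,
                "orthogroup": og,
                "life_stage": classify_life_stage(rec, tree, lineage).value,
                "age_class": age,
                "n_losses": len(truth_losses),
                "marginalized": marginalized,
            }
        )
        i += 1

    if not records:
        raise RuntimeError("no focal genes generated; lower loss_rate")
    pm = PresenceMatrix(tuple(tree.leaf_names), groups)
    truth = pd.DataFrame(truth_rows).set_index("gene")
    logger.info(
        "simulated %d genes (%d attempts, %.1f%% resampled)",
        len(records),
        attempts,
        100 * (attempts - len(records)) / attempts,
    )
    return pm, records, truth


def _negbin(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draws with the given means and shape ``dispersion``."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_features(
    stages: Mapping[str, str],
    cfg: SimulationConfig,
    rng: np.random.Generator,
    dup_members: frozenset[str] = frozenset(),
) -> dict[str, pd.DataFrame]:
    """Stage-dependent features plus the raw files they are computed from.

    Returns frames: ``features`` (per-gene table), ``ppi_edges``,
    ``genetic_edges``, ``reg_edges``, ``kinases`` (the kinase-annotated
    partner set), ``expression`` (gene × condition intensities) and
    ``rnaseq`` (read counts).  Degrees in the feature table equal the
    distinct-partner counts of the emitted edge lists by construction;
    expression spread is computed from the emitted matrix.
    """
    genes = sorted(stages)
    n = len(genes)
    eff = [cfg.stage_effects[stages[g]] for g in genes]
    for e in eff:
        if min(e.ppi, e.genetic, e.regulatory, e.kinase, e.expression, e.spread) < 0:
            raise ValueError("stage effects must be nonnegative")

    ppi = _negbin(rng, [cfg.mean_ppi * e.ppi for e in eff], cfg.nb_dispersion)
    genetic = _negbin(rng, [cfg.mean_genetic * e.genetic for e in eff], cfg.nb_dispersion)
    reg = _negbin(rng, [cfg.mean_regulatory * e.regulatory for e in eff], cfg.nb_dispersion)
    kin = np.minimum(
        _negbin(rng, [cfg.mean_kinase * e.kinase for e in eff], cfg.nb_dispersion), ppi
    )
    reads = _negbin(rng, [cfg.mean_reads * e.expression for e in eff], 1.5)

    n_kin_pool = 60
    kin_pool = [f"kin{j:03d}" for j in range(n_kin_pool)]
    n_aux = max(2000, int(3 * max(ppi.max(), genetic.max(), 10)))
    ppi_pool = [f"prt{j:05d}" for j in range(n_aux)]
    gen_pool = [f"gpx{j:05d}" for j in range(n_aux)]
    tf_pool = [f"reg{j:04d}" for j in range(max(400, int(reg.max()) + 10))]

    ppi_rows: list[tuple[str, str]] = []
    gen_rows: list[tuple[str, str]] = []
    reg_rows: list[tuple[str, str]] = []
    for idx, g in enumerate(genes):
        k = int(kin[idx])
        d = int(ppi[idx])
        for partner in rng.choice(n_kin_pool, size=k, replace=False):
            ppi_rows.append((g, kin_pool[partner]))
        for partner in rng.choice(n_aux, size=d - k, replace=False):
            ppi_rows.append((g, ppi_pool[partner]))
        for partner in rng.choice(n_aux, size=int(genetic[idx]), replace=False):
            gen_rows.append((g, gen_pool[partner]))
        for src in rng.choice(len(tf_pool), size=int(reg[idx]), replace=False):
            reg_rows.append((tf_pool[src], g))

    mu = rng.normal(3.0, 0.4, size=n)
    sd = rng.gamma(4.0, np.array([cfg.base_spread * e.spread for e in eff]) / 4.0)
    logvals = rng.standard_normal((n, cfg.n_conditions)) * sd[:, None] + mu[:, None]
    expr = pd.DataFrame(
        np.power(10.0, logvals),
        index=pd.Index(genes, name="gene"),
        columns=[f"c{j:03d}" for j in range(cfg.n_conditions)],
    )

    tf_p = np.array(
        [
            max(cfg.tf_fraction[stages[g]], 0.045) if g in dup_members else cfg.tf_fraction[stages[g]]
            for g in genes
        ]
    )
    is_tf = rng.random(n) < tf_p
    ess_p = np.array([cfg.essential_fraction[stages[g]] for g in genes])
    essential = rng.random(n) < ess_p

    spread = expression_spread(expr, min_conditions=min(30, cfg.n_conditions))
    features = pd.DataFrame(
        {
            "life_stage": [stages[g] for g in genes],
            "ppi_degree": ppi.astype(int),
            "genetic_degree": genetic.astype(int),
            "regulatory_in_degree": reg.astype(int),
            "kinase_degree": kin.astype(int),
            "mrna_expression": mrna_expression_from_counts(dict(zip(genes, reads))).values,
            "expression_spread": spread.reindex(genes).values,
            "essential": essential,
            "is_tf": is_tf,
        },
        index=pd.Index(genes, name="gene"),
    )
    return {
        "features": features,
        "ppi_edges": pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b"]),
        "genetic_edges": pd.DataFrame(gen_rows, columns=["gene_a", "gene_b"]),
        "reg_edges": pd.DataFrame(reg_rows, columns=["tf", "target"]),
        "kinases": pd.DataFrame({"kinase": kin_pool}),
        "expression": expr,
        "rnaseq": pd.DataFrame(
            {"gene": genes, "reads": reads.astype(int)}
        ),
    }


def simulate_logistic(
    n: int,
    coefs: Mapping[str, float],
    seed: int = 0,
    intercept: float = -1.0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Features and binary outcome drawn from a known logistic model."""
    rng = np.random.default_rng(seed)
    names = list(coefs)
    X = pd.DataFrame(rng.standard_normal((n, len(names))), columns=names)
    eta = intercept + X.to_numpy() @ np.array([coefs[c] for c in names])
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(float)
    return X, y


def _add_duplicates(
    pm: PresenceMatrix,
    records: Sequence[GeneEventRecord],
    truth: pd.DataFrame,
    tree: Tree,
    lineage: ResolvedLineage,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[dict]]:
    """Turn a fraction of oldest genes into two-copy focal families.

    Mutates ``pm.groups`` in place: every present species inside the
    duplication clade receives a second gene copy (id suffix ``b``).
    Returns the similarity-hit rows supporting slowest-copy selection and
    the family truth records.
    """
    focal = lineage.focal
    path = tree.root_to_focal_path(focal)
    path_ids = [n.id for n in path]
    wgd = lineage.wgd_node
    oldest_genes = truth.index[truth["age_class"] == "oldest"].tolist()
    n_fam = int(round(cfg.dup_fraction * len(oldest_genes)))
    chosen = list(rng.choice(oldest_genes, size=min(n_fam, len(oldest_genes)), replace=False))
    by_gene = {r.gene: r for r in records}
    og_of = dict(zip(truth.index, truth["orthogroup"]))

    hit_rows: list[dict] = []
    fam_truth: list[dict] = []
    for gene in sorted(chosen):
        og = og_of[gene]
        timing = rng.choice(["pre_wgd", "wgd", "post_wgd"], p=[0.4, 0.2, 0.4])
        if wgd is None:
            timing = "post_wgd"
        widx = path_ids.index(wgd) if wgd is not None else len(path_ids) - 1
        if timing == "pre_wgd":
            candidates = path_ids[1:widx]  # below root, above the WGD branch
            if not candidates:
                timing = "wgd"
        if timing == "pre_wgd":
            dup_node = candidates[rng.integers(len(candidates))]
        elif timing == "wgd":
            dup_node = wgd if wgd is not None else focal
        else:
            post = path_ids[widx + 1 :]
            dup_node = post[rng.integers(len(post))] if post else focal
        clade = tree.clade_leaves(dup_node)
        per = dict(pm.groups[og])
        present_in_clade = [sp for sp in per if sp in clade]
        if not present_in_clade or focal not in present_in_clade:
            continue
        single_copy = [sp for sp in per if sp not in clade]
        if not single_copy:
            continue  # keep at least one unaffected witness species
        for sp in present_in_clade:
            per[sp] = per[sp] + (per[sp][0] + "b",)
        pm.groups[og] = per

        members = sorted(pm.groups[og][focal])
        slowest = members[0]  # the original copy retains ancestral similarity
        for sp in single_copy:
            witness_gene = pm.groups[og][sp][0]
            for member in members:
                base = 75.0 if member == slowest else 60.0
                ident = float(np.clip(rng.normal(base, cfg.identity_noise), 0, 100))
                hit_rows.append(
                    {
                        "query": member,
                        "subject": witness_gene,
                        "e_value": 1e-50,
                        "percent_identity": round(ident, 2),
                    }
                )
        fam_truth.append(
            {
                "orthogroup": og,
                "members": ",".join(members),
                "true_slowest": slowest,
                "true_timing": timing,
                "dup_node": dup_node,
                "any_loss": bool(by_gene[gene].loss_branches),
            }
        )
    return pd.DataFrame(hit_rows), fam_truth


def _alt_frame_frames(
    pm: PresenceMatrix,
    records: Sequence[GeneEventRecord],
    truth: pd.DataFrame,
    tree: Tree,
    syn: SyntheticLineage,
    cfg: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, pd.DataFrame]:
    """Feature files for the alternate focal species (cross-species view).

    Alt-frame features depend only on loss locality *relative to the alt
    species*: genes lost in lineages splitting from the alt lineage below
    its threshold node are marginalized in the alt frame, and genes lost
    close to the primary focal species are not.  This encodes the
    lineage-specificity contrast the cross-species comparison is built to
    detect.
    """
    alt = syn.alt
    og_of = dict(zip(truth.index, truth["orthogroup"]))
    rows_expr = []
    gen_rows: list[tuple[str, str]] = []
    ppi_rows: list[tuple[str, str]] = []
    gen_pool = [f"agx{j:05d}" for j in range(3000)]
    ppi_pool = [f"apx{j:05d}" for j in range(3000)]
    for rec in records:
        og = og_of[rec.gene]
        alt_genes = pm.groups[og].get(alt)
        if not alt_genes:
            continue
        alt_local = any(
            tree.is_strict_descendant(tree.mrca(alt, b).id, syn.alt_threshold)
            for b in rec.loss_branches
        )
        mult = 0.55 if alt_local else 1.0
        for ag in alt_genes:
            intensity = float(np.power(10.0, rng.normal(3.0 + np.log10(mult), 0.35)))
            rows_expr.append({"gene": ag, "intensity": round(intensity, 3)})
            d_gen = int(_negbin(rng, np.array([10.0 * mult]), cfg.nb_dispersion)[0])
            d_ppi = int(_negbin(rng, np.array([6.0 * mult]), cfg.nb_dispersion)[0])
            for partner in rng.choice(len(gen_pool), size=d_gen, replace=False):
                gen_rows.append((ag, gen_pool[partner]))
            for partner in rng.choice(len(ppi_pool), size=d_ppi, replace=False):
                ppi_rows.append((ag, ppi_pool[partner]))
    return {
        "alt_expression": pd.DataFrame(rows_expr),
        "alt_genetic_edges": pd.DataFrame(gen_rows, columns=["gene_a", "gene_b"]),
        "alt_ppi_edges": pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b"]),
    }


def simulate_bundle(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Generate and write a complete input bundle with ground truth.

    Emits: ``tree.nwk``, ``distances.tsv``, ``orthogroups.tsv``,
    ``ppi.tsv``, ``genetic.tsv``, ``regnet.tsv``, ``kinases.txt``,
    ``expression.tsv``, ``rnaseq.tsv``, ``flags.tsv``, ``hits.tsv``,
    ``features.tsv``, ``truth.tsv``, ``truth_families.tsv``, alt-frame
    files and ``lineage.tsv``.  Identical configurations produce
    byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, dm = simulate_tree(
        cfg.n_species, seed=cfg.seed, branch_scale=cfg.branch_scale,
        distance_noise=cfg.distance_noise,
    )
    syn = default_lineage(tree)
    lineage = syn.lineage
    pm, records, truth = simulate_gene_histories(tree, cfg, lineage)
    rng = np.random.default_rng(cfg.seed + 1)

    dup_hits, fam_truth = _add_duplicates(pm, records, truth, tree, lineage, cfg, rng)
    dup_members = frozenset(
        m for f in fam_truth for m in f["members"].split(",")
    )

    # duplicate "b" copies share the history (and stage) of the original gene
    stages = dict(zip(truth.index, truth["life_stage"]))
    records_by_gene = {r.gene: r for r in records}
    extra_records = []
    for member in sorted(dup_members):
        if member not in stages:
            base = member[:-1]
            stages[member] = stages[base]
            r = records_by_gene[base]
            extra_records.append(replace(r, gene=member))
    all_records = records + extra_records

    # orphan genes outside the orthology map (excluded from classification)
    n_orphan = int(round(cfg.excluded_fraction * cfg.n_genes))
    orphans = [f"{lineage.focal}_x{i:04d}" for i in range(n_orphan)]
    for g in orphans:
        stages[g] = "excluded"

    frames = simulate_features(stages, cfg, rng, dup_members=dup_members)

    # similarity hits: duplicate-family witnesses, spurious "gained" genes
    # (missed duplications of older genes) and benign above-threshold hits
    gained = truth.index[truth["age_class"] != "oldest"].tolist()
    oldest = truth.index[truth["age_class"] == "oldest"].tolist()
    n_spur = int(round(cfg.spurious_gain_fraction * len(gained)))
    spurious = sorted(rng.choice(gained, size=min(n_spur, len(gained)), replace=False))
    hit_rows = [dup_hits] if len(dup_hits) else []
    rows = []
    for g in spurious:
        partner = oldest[rng.integers(len(oldest))]
        rows.append(
            {
                "query": g,
                "subject": partner,
                "e_value": float(10.0 ** rng.uniform(-30, -5)),
                "percent_identity": round(float(rng.uniform(30, 60)), 2),
            }
        )
    n_benign = int(round(cfg.benign_hit_fraction * len(gained)))
    for g in sorted(rng.choice(gained, size=min(n_benign, len(gained)), replace=False)):
        partner = oldest[rng.integers(len(oldest))]
        rows.append(
            {
                "query": g,
                "subject": partner,
                "e_value": float(10.0 ** rng.uniform(-3.9, -1.0)),
                "percent_identity": round(float(rng.uniform(20, 35)), 2),
            }
        )
    hit_rows.append(pd.DataFrame(rows, columns=["query", "subject", "e_value", "percent_identity"]))
    hits = pd.concat(hit_rows, ignore_index=True) if hit_rows else pd.DataFrame(
        columns=["query", "subject", "e_value", "percent_identity"]
    )

    alt_frames = _alt_frame_frames(pm, records, truth, tree, syn, cfg, rng)

    # ---- write everything -------------------------------------------
    tree.write(outdir / "tree.nwk")
    dm.to_tsv(outdir / "distances.tsv")
    pm.to_tsv(outdir / "orthogroups.tsv")
    frames["ppi_edges"].to_csv(outdir / "ppi.tsv", sep="\t", index=False)
    frames["genetic_edges"].to_csv(outdir / "genetic.tsv", sep="\t", index=False)
    frames["reg_edges"].to_csv(outdir / "regnet.tsv", sep="\t", index=False)
    frames["kinases"].to_csv(outdir / "kinases.txt", sep="\t", index=False)
    frames["expression"].round(4).to_csv(outdir / "expression.tsv", sep="\t")
    frames["rnaseq"].to_csv(outdir / "rnaseq.tsv", sep="\t", index=False)
    feats = frames["features"]
    feats[["essential", "is_tf"]].astype(int).rename_axis("gene").reset_index().to_csv(
        outdir / "flags.tsv", sep="\t", index=False
    )
    feats.round(6).to_csv(outdir / "features.tsv", sep="\t")
    hits.to_csv(outdir / "hits.tsv", sep="\t", index=False)

    truth_out = truth.copy()
    truth_out["spurious_duplicate"] = truth_out.index.isin(spurious)
    truth_out.round(6).to_csv(outdir / "truth.tsv", sep="\t")
    pd.DataFrame(
        fam_truth,
        columns=["orthogroup", "members", "true_slowest", "true_timing", "dup_node", "any_loss"],
    ).to_csv(outdir / "truth_families.tsv", sep="\t", index=False)

    for name, frame in alt_frames.items():
        frame.to_csv(outdir / f"{name.replace('_edges', '')}.tsv", sep="\t", index=False)

    lineage_rows = [
        ("focal", lineage.focal),
        ("outgroup", ",".join(sorted(lineage.outgroup))),
        ("local_threshold", lineage.local_threshold or ""),
        ("wgd_branch", lineage.wgd_node or ""),
        ("alt", syn.alt),
        ("alt_threshold", syn.alt_threshold),
    ]
    pd.DataFrame(lineage_rows, columns=["key", "value"]).to_csv(
        outdir / "lineage.tsv", sep="\t", index=False
    )

    return {
        "outdir": outdir,
        "tree": tree,
        "distance_matrix": dm,
        "presence": pm,
        "records": all_records,
        "truth": truth_out,
        "family_truth": fam_truth,
        "lineage": lineage,
        "synthetic_lineage": syn,
        "features": feats,
        "spurious": set(spurious),
        "orphans": orphans,
    }
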