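"""Dollo-parsimony gain/loss inference and gene life-stage classification.

A gene (orthogroup) is assumed to be gained at most once; losses are
irreversible.  Under that model, given the presence/absence profile of an
orthogroup across the species tree:

* the gain branch is the branch immediately above the MRCA of the species
  carrying the gene (or "pre-root" when any outgroup species carries it:
  the gene predates the ingroup and is not dated further);
* the loss events are the maximal all-absent clades inside the gain clade.

Losses within outgroup clades are ignored: with only two deep outgroup
lineages, absence there cannot be distinguished from sparse sampling and,
for the oldest genes, does not bear on the focal lineage's history.

Life stages partition the focal species' genes into core, distant-loss,
local-loss, ancient-gain, recent-gain and focal-specific classes, with
"local" meaning the closest loss lineage split from the focal lineage
after a configurable threshold node (the split with K. waltii in the
intended application).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .phylo import Node, ResolvedLineage, Tree, TreeError
from .stats import StatResult, fisher_exact_2x2

logger = logging.getLogger(__name__)

PRE_ROOT = "pre-root"

__all__ = [
    "PRE_ROOT",
    "LifeStage",
    "PresenceMatrix",
    "GeneEventRecord",
    "infer_gain_branch",
    "infer_loss_branches",
    "build_event_record",
    "classify_life_stage",
    "tabulate_branch_events",
    "loss_propensity",
    "event_rate_ratio",
    "wgd_gain_loss_fisher",
]


class LifeStage(str, Enum):
    CORE = "core"
    DISTANT_LOSS = "distant_loss"
    LOCAL_LOSS = "local_loss"
    ANCIENT_GAIN = "ancient_gain"
    RECENT_GAIN = "recent_gain"
    FOCAL_SPECIFIC = "focal_specific"
    EXCLUDED = "excluded"

    def __str__(self) -> str:  # tidy TSV output
        return self.value


@dataclass
class PresenceMatrix:
    """Orthogroup × species gene membership.

    ``groups`` maps orthogroup id → species → tuple of gene ids (empty
    tuple = absent).  Boolean presence is derived as "nonempty list".
    """

    species: tuple[str, ...]
    groups: dict[str, dict[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        seen: dict[str, set[str]] = {s: set() for s in self.species}
        for og, per_species in self.groups.items():
            for sp, genes in per_species.items():
                if sp not in seen:
                    raise ValueError(f"orthogroup {og!r} names unknown species {sp!r}")
                for g in genes:
                    if g in seen[sp]:
                        raise ValueError(f"gene id {g!r} appears twice for species {sp!r}")
                    seen[sp].add(g)

    def orthogroups(self) -> list[str]:
        return sorted(self.groups)

    def genes(self, og: str, species: str) -> tuple[str, ...]:
        return self.groups[og].get(species, ())

    def presence(self, og: str) -> dict[str, bool]:
        per = self.groups[og]
        return {s: bool(per.get(s)) for s in self.species}

    def n_species_present(self, og: str) -> int:
        return sum(1 for s in self.species if self.groups[og].get(s))

    def focal_gene_index(self, focal: str) -> dict[str, str]:
        """Map each focal-species gene id to its orthogroup."""
        index: dict[str, str] = {}
        for og in self.orthogroups():
            for g in self.genes(og, focal):
                index[g] = og
        return index

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            (og, sp, g)
            for og in self.orthogroups()
            for sp in self.species
            for g in self.groups[og].get(sp, ())
        ]
        pd.DataFrame(rows, columns=["orthogroup_id", "species", "gene_id"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path, species: Sequence[str]) -> "PresenceMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"orthogroup_id", "species", "gene_id"}
        if not required <= set(df.columns):
            raise ValueError(f"orthogroup table must have columns {sorted(required)}")
        groups: dict[str, dict[str, list[str]]] = {}
        for og, sp, g in df[["orthogroup_id", "species", "gene_id"]].itertuples(index=False):
            groups.setdefault(og, {}).setdefault(sp, []).append(g)
        frozen = {
            og: {sp: tuple(genes) for sp, genes in per.items()} for og, per in groups.items()
        }
        return cls(tuple(species), frozen)


@dataclass
class GeneEventRecord:
    """Inferred (or simulated) gain/loss history of one focal-species gene."""

    gene: str
    gain_branch: str  # branch id or PRE_ROOT
    age_class: str  # oldest | ancient_gain | recent_gain | focal_specific
    loss_branches: frozenset[str] = field(default_factory=frozenset)
    closest_loss_distance: float | None = None


def infer_gain_branch(
    presence: Mapping[str, bool], tree: Tree, lineage: ResolvedLineage
) -> tuple[str, str]:
    """Locate the gain branch and age class of an orthogroup.

    Presence in any outgroup species makes the gene "oldest" (gain
    pre-root, undated).  Otherwise the gain sits immediately above the
    MRCA of the carrier species; the age class is recent when that MRCA
    falls strictly below the local threshold node, focal-specific when the
    focal species is the only carrier, ancient otherwise.
    """
    focal = lineage.focal
    if not presence.get(focal, False):
        raise ValueError("gene is absent from the focal species; only focal genes are analysed")
    present = {s for s, v in presence.items() if v}
    if present & lineage.outgroup:
        return PRE_ROOT, "oldest"
    if present == {focal}:
        return focal, "focal_specific"
    mrca = tree.mrca(*sorted(present))
    if lineage.local_threshold is not None and tree.is_strict_descendant(
        mrca.id, lineage.local_threshold
    ):
        age = "recent_gain"
    else:
        age = "ancient_gain"
    # a carrier MRCA at the root means the gain predates the root branch
    gain = PRE_ROOT if mrca.parent is None else mrca.id
    return gain, age


def infer_loss_branches(
    presence: Mapping[str, bool],
    tree: Tree,
    gain_branch: str,
    lineage: ResolvedLineage,
) -> frozenset[str]:
    """Maximal all-absent clades within the gain clade (Dollo losses).

    Clades consisting only of outgroup species are dropped.  Branches on
    the root-to-focal path cannot be returned (the focal species carries
    the gene).
    """
    start = tree.root if gain_branch == PRE_ROOT else tree.node(gain_branch)
    outgroup = lineage.outgroup
    losses: list[str] = []

    def visit(node: Node) -> None:
        leaves = tree.clade_leaves(node.id)
        if not any(presence.get(s, False) for s in leaves):
            if not leaves <= outgroup:
                losses.append(node.id)
            return
        for child in node.children:
            visit(child)

    for child in start.children:
        visit(child)
    return frozenset(losses)


def build_event_record(
    gene: str,
    presence: Mapping[str, bool],
    tree: Tree,
    lineage: ResolvedLineage,
) -> GeneEventRecord:
    gain, age = infer_gain_branch(presence, tree, lineage)
    losses = infer_loss_branches(presence, tree, gain, lineage)
    closest = None
    if losses:
        closest = min(tree.patristic_distance(lineage.focal, b) for b in losses)
    return GeneEventRecord(gene, gain, age, losses, closest)


def _is_local_loss(tree: Tree, lineage: ResolvedLineage, loss_branch: str) -> bool:
    if lineage.local_threshold is None:
        return False
    attach = tree.mrca(lineage.focal, loss_branch)
    return tree.is_strict_descendant(attach.id, lineage.local_threshold)


def classify_life_stage(
    rec: GeneEventRecord, tree: Tree, lineage: ResolvedLineage
) -> LifeStage:
    """Assign the life-stage label of a gene from its event record.

    Loss events on gained (non-oldest) genes are ignored for staging, so
    that loss-associated properties are not confounded with gain-associated
    ones; only the oldest genes feed the loss classes.
    """
    if rec.age_class == "focal_specific":
        return LifeStage.FOCAL_SPECIFIC
    if rec.age_class in ("ancient_gain", "recent_gain"):
        if rec.loss_branches:
            logger.debug(
                "gene %s: %d loss event(s) on a gained gene ignored for staging",
                rec.gene,
                len(rec.loss_branches),
            )
        return LifeStage(rec.age_class)
    if rec.age_class != "oldest":
        raise ValueError(f"unknown age class {rec.age_class!r}")
    if not rec.loss_branches:
        return LifeStage.CORE
    if any(_is_local_loss(tree, lineage, b) for b in rec.loss_branches):
        return LifeStage.LOCAL_LOSS
    return LifeStage.DISTANT_LOSS


def tabulate_branch_events(
    records: Iterable[GeneEventRecord], tree: Tree
) -> pd.DataFrame:
    """Per-branch gain and loss event counts.

    Returns a frame indexed by branch id (plus a ``pre-root`` row for
    undated gains) with ``gain_count``, ``loss_count`` and
    ``branch_length`` columns.  Total loss_count equals the number of loss
    events over genes; total gain_count equals the number of genes.
    """
    branch_ids = [n.id for n in tree.branches()]
    table = pd.DataFrame(
        {
            "gain_count": 0,
            "loss_count": 0,
            "branch_length": [np.nan] + [tree.node(b).branch_length for b in branch_ids],
        },
        index=pd.Index([PRE_ROOT] + branch_ids, name="branch"),
    )
    for rec in records:
        if rec.gain_branch not in table.index:
            raise TreeError(f"record for {rec.gene!r} references unknown branch {rec.gain_branch!r}")
        table.loc[rec.gain_branch, "gain_count"] += 1
        for b in rec.loss_branches:
            if b not in table.index:
                raise TreeError(f"record for {rec.gene!r} references unknown branch {b!r}")
            table.loc[b, "loss_count"] += 1
    return table


def loss_propensity(
    rec: GeneEventRecord, tree: Tree, lineage: ResolvedLineage
) -> float:
    """Independent loss events per unit of branch length where loss was possible.

    The opportunity is the summed length of branches off the root-to-focal
    path on which the gene was still present under the reconstruction:
    branches below a loss event are excluded (irreversibility — the gene is
    already gone), the loss branch itself counts as opportunity, and
    outgroup subtrees are excluded because loss events there are never
    counted.
    """
    if rec.age_class != "oldest":
        raise ValueError("loss propensity is defined for the oldest genes only")
    path = {n.id for n in tree.root_to_focal_path(lineage.focal)}
    og_roots = lineage.outgroup_clade_roots
    losses = rec.loss_branches
    total = 0.0

    def visit(node: Node) -> None:
        nonlocal total
        for child in node.children:
            if child.id in path:
                visit(child)
                continue
            if child.id in og_roots:
                continue
            if child.branch_length is None:
                raise TreeError(f"branch above {child.id!r} has no length")
            total += child.branch_length
            if child.id in losses:
                continue
            visit(child)

    visit(tree.root)
    if total <= 0:
        raise ValueError("degenerate tree: zero branch length available for loss")
    return len(losses) / total


def event_rate_ratio(
    count_a: int, length_a: float, count_b: int, length_b: float
) -> StatResult:
    """Ratio of per-branch-length event rates with a two-sided binomial test.

    Under a uniform event rate, the ``count_a + count_b`` events split
    between the two branch-length compartments with probability
    ``length_a / (length_a + length_b)`` each; the p-value is the exact
    two-sided binomial probability of the observed split.
    """
    if length_a <= 0 or length_b <= 0:
        raise ValueError("branch lengths must be positive")
    n = count_a + count_b
    if n == 0:
        raise ValueError("no events in either compartment")
    if count_b == 0:
        logger.warning("zero events in the reference compartment: rate ratio is infinite")
        ratio = float("inf")
    else:
        ratio = (count_a / length_a) / (count_b / length_b)
    p0 = length_a / (length_a + length_b)
    pval = binomtest(count_a, n, p0, alternative="two-sided").pvalue
    return StatResult(
        method="binomial_rate_ratio",
        statistic=float(count_a),
        p_value=float(pval),
        effect=ratio,
        n=(count_a, count_b),
        direction=0 if ratio == 1 else (1 if ratio > 1 else -1),
    )


def wgd_gain_loss_fisher(
    gains_pre: int, gains_post: int, losses_pre: int, losses_post: int
) -> StatResult:
    """Fisher 2×2 variant of the WGD rate comparison (gains vs losses × pre/post)."""
    res = fisher_exact_2x2(gains_post, gains_pre, losses_post, losses_pre)
    return StatResult(
        method="wgd_gain_loss_fisher",
        statistic=res.statistic,
        p_value=res.p_value,
        effect=res.effect,
        n=(gains_pre + gains_post, losses_pre + losses_post),
        direction=res.direction,
    )
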