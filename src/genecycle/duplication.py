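"""Duplicate-family detection and duplication-aware filtering.

A duplicate family is a set of two or more focal-species genes that share
an orthogroup with at least one gene of another species (the witness).
Within each family the slowest-evolving copy is the member most similar to
the ortholog in the closest species not affected by the duplication
(single-copy for the orthogroup).  Duplication timing is read off the tree
as the branch above the MRCA of the species visibly carrying two or more
copies, and placed before / at / after the whole-genome duplication.

Genes called "gained" that nonetheless show significant sequence
similarity (default e < 1e-4) to an older gene are treated as duplications
that the orthology map missed, and removed from the gained set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .events import PresenceMatrix
from .phylo import ResolvedLineage, Tree

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityHit",
    "DuplicateFamily",
    "read_hits_tsv",
    "write_hits_tsv",
    "find_duplicate_families",
    "select_slowest_copy",
    "classify_duplication_timing",
    "filter_gained_by_similarity",
    "annotate_families",
]


@dataclass(frozen=True)
class SimilarityHit:
    """A pairwise sequence-similarity hit (BLAST outfmt-6-compatible subset)."""

    query: str
    subject: str
    e_value: float
    percent_identity: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e-value must be nonnegative")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError("percent identity must lie in [0, 100]")


def read_hits_tsv(path: str | Path) -> list[SimilarityHit]:
    df = pd.read_csv(path, sep="\t", dtype={"query": str, "subject": str})
    return [
        SimilarityHit(q, s, float(e), float(pid))
        for q, s, e, pid in df[["query", "subject", "e_value", "percent_identity"]].itertuples(
            index=False
        )
    ]


def write_hits_tsv(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    pd.DataFrame(
        [(h.query, h.subject, h.e_value, h.percent_identity) for h in hits],
        columns=["query", "subject", "e_value", "percent_identity"],
    ).to_csv(path, sep="\t", index=False)


@dataclass
class DuplicateFamily:
    family_id: str
    orthogroup: str
    members: tuple[str, ...]  # focal-species gene ids, >= 2
    witnesses: tuple[tuple[str, str], ...]  # (species, gene id)
    slowest_copy: str | None = None
    timing: str = "unknown"  # pre_wgd | wgd | post_wgd | unknown

    def __post_init__(self) -> None:
        if len(self.members) < 2 or len(set(self.members)) != len(self.members):
            raise ValueError("a duplicate family needs >= 2 distinct members")
        if self.slowest_copy is not None and self.slowest_copy not in self.members:
            raise ValueError("slowest copy must be a family member")


def find_duplicate_families(pm: PresenceMatrix, focal: str) -> list[DuplicateFamily]:
    """One family per orthogroup with >= 2 focal genes and a non-focal witness.

    All focal genes of the orthogroup form a single family (transitive
    closure over shared witnesses), so families are pairwise disjoint.
    """
    families: list[DuplicateFamily] = []
    for og in pm.orthogroups():
        members = pm.genes(og, focal)
        if len(members) < 2:
            continue
        witnesses = tuple(
            (sp, g) for sp in pm.species if sp != focal for g in pm.genes(og, sp)
        )
        if not witnesses:
            continue
        families.append(
            DuplicateFamily(
                family_id=f"fam{len(families):05d}",
                orthogroup=og,
                members=tuple(sorted(members)),
                witnesses=witnesses,
            )
        )
    return families


def select_slowest_copy(
    family: DuplicateFamily,
    hits: Sequence[SimilarityHit],
    tree: Tree,
    pm: PresenceMatrix,
    focal: str,
) -> str | None:
    """The member most similar to the ortholog in the closest unaffected species.

    "Unaffected" means single-copy for the orthogroup; species lacking the
    orthogroup are skipped.  Closest is by patristic distance to the focal
    species (lexicographic species tie-break); member ties break to the
    lexicographically smaller gene id.
    """
    candidates = [
        sp
        for sp in pm.species
        if sp != focal and len(pm.genes(family.orthogroup, sp)) == 1
    ]
    if not candidates:
        logger.warning(
            "family %s: no single-copy witness species; slowest copy unknown",
            family.family_id,
        )
        return None
    witness_sp = min(candidates, key=lambda sp: (tree.patristic_distance(focal, sp), sp))
    witness_gene = pm.genes(family.orthogroup, witness_sp)[0]

    members = set(family.members)
    best: dict[str, float] = {}
    for h in hits:
        pair = None
        if h.query in members and h.subject == witness_gene:
            pair = h.query
        elif h.subject in members and h.query == witness_gene:
            pair = h.subject
        if pair is not None:
            best[pair] = max(best.get(pair, -1.0), h.percent_identity)
    if not best:
        logger.warning(
            "family %s: no similarity hits between members and witness %s",
            family.family_id,
            witness_gene,
        )
        return None
    top = max(best.values())
    tied = sorted(m for m, v in best.items() if v == top)
    if len(tied) > 1:
        logger.info("family %s: identity tie, choosing %s", family.family_id, tied[0])
    return tied[0]


def classify_duplication_timing(
    family: DuplicateFamily,
    pm: PresenceMatrix,
    tree: Tree,
    lineage: ResolvedLineage,
) -> str:
    """Place the duplication relative to the whole-genome duplication branch.

    The timing branch is the branch above the MRCA of the species whose
    gene list for the orthogroup has two or more members (where the
    duplication is visibly shared).
    """
    dup_species = [
        sp for sp in pm.species if len(pm.genes(family.orthogroup, sp)) >= 2
    ]
    if dup_species == [lineage.focal]:
        logger.debug(
            "family %s: duplication visible only in the focal species; post_wgd by convention",
            family.family_id,
        )
        return "post_wgd"
    if lineage.wgd_node is None:
        return "unknown"
    mrca = tree.mrca(*dup_species)
    if mrca.id == lineage.wgd_node:
        return "wgd"
    if tree.is_strict_descendant(lineage.wgd_node, mrca.id):
        return "pre_wgd"
    if tree.is_strict_descendant(mrca.id, lineage.wgd_node):
        return "post_wgd"
    return "unknown"


def annotate_families(
    families: Iterable[DuplicateFamily],
    hits: Sequence[SimilarityHit],
    pm: PresenceMatrix,
    tree: Tree,
    lineage: ResolvedLineage,
) -> list[DuplicateFamily]:
    """Fill in slowest copy and timing for each family (in place; returns the list)."""
    out = []
    for fam in families:
        fam.slowest_copy = select_slowest_copy(fam, hits, tree, pm, lineage.focal)
        fam.timing = (
            classify_duplication_timing(fam, pm, tree, lineage)
            if fam.slowest_copy is not None
            else "unknown"
        )
        out.append(fam)
    return out


def filter_gained_by_similarity(
    gained: Iterable[str],
    hits: Sequence[SimilarityHit],
    older: Iterable[str],
    e_threshold: float = 1e-4,
    universe: Iterable[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Partition gained genes into (kept, removed) by similarity to older genes.

    A gained gene with any hit to an older gene at ``e_value <
    e_threshold`` is removed as a probable duplication missed by the
    orthology map.  ``|kept| + |removed| == |gained|`` always holds.
    """
    if e_threshold <= 0:
        raise ValueError("e-value threshold must be positive")
    gained_set = set(gained)
    older_set = set(older)
    known = set(universe) if universe is not None else None
    removed: set[str] = set()
    n_unknown = 0
    for h in hits:
        if known is not None and (h.query not in known or h.subject not in known):
            n_unknown += 1
            continue
        if h.e_value >= e_threshold:
            continue
        if h.query in gained_set and h.subject in older_set:
            removed.add(h.query)
        elif h.subject in gained_set and h.query in older_set:
            removed.add(h.subject)
    if n_unknown:
        logger.warning("%d similarity hits referenced unknown genes and were ignored", n_unknown)
    return gained_set - removed, removed


def families_to_frame(families: Sequence[DuplicateFamily]) -> pd.DataFrame:
    """Long-format family table (family_id, member, is_slowest, timing)."""
    rows = [
        (f.family_id, f.orthogroup, m, m == f.slowest_copy, f.timing)
        for f in families
        for m in f.members
    ]
    return pd.DataFrame(
        rows, columns=["family_id", "orthogroup", "member", "is_slowest", "timing"]
    )
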