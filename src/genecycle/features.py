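"""Per-gene network and expression features.

Degrees are counted as distinct interaction partners from plain edge
lists (undirected, or in-degree for the directed regulatory network),
optionally restricted to a partner subset (e.g. PPI partners annotated as
protein kinases).  Expression spread is the per-gene standard deviation of
log10 intensities across conditions.  ``assemble_feature_table`` joins
everything onto the life-stage classification.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "read_edgelist_tsv",
    "degrees_from_edgelist",
    "expression_spread",
    "mrna_expression_from_counts",
    "assemble_feature_table",
]


def read_edgelist_tsv(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    a, b = df.columns[:2]
    return list(df[[a, b]].itertuples(index=False, name=None))


def degrees_from_edgelist(
    edges: Iterable[tuple[str, str]],
    universe: Iterable[str],
    zero_fill: bool = True,
    partner_subset: Iterable[str] | None = None,
    directed_in: bool = False,
) -> dict[str, int]:
    """Distinct-partner degree per gene.

    With ``zero_fill`` every universe gene appears, at 0 if it has no
    edges (the convention for genome-wide S. cerevisiae networks);
    otherwise genes incident to no edge are omitted (the convention for
    screens where only assayed genes are informative).  ``directed_in``
    counts distinct sources per target (regulatory in-degree).
    Self-interactions are not counted as partners.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("universe must be nonempty")
    subset = set(partner_subset) if partner_subset is not None else None
    partners: dict[str, set[str]] = {}
    touched: set[str] = set()
    for src, tgt in edges:
        if directed_in:
            if tgt in uni:
                touched.add(tgt)
                if src != tgt:
                    partners.setdefault(tgt, set()).add(src)
        else:
            for g, p in ((src, tgt), (tgt, src)):
                if g in uni:
                    touched.add(g)
                    if p != g:
                        partners.setdefault(g, set()).add(p)
    genes = uni if zero_fill else (touched & uni)
    out: dict[str, int] = {}
    for g in genes:
        ps = partners.get(g, set())
        if subset is not None:
            ps = ps & subset
        out[g] = len(ps)
    return out


def expression_spread(
    matrix: pd.DataFrame, min_conditions: int = 30
) -> pd.Series:
    """Per-gene sample SD of log10 intensities across observed conditions.

    Nonpositive intensities are dropped with a warning; genes observed in
    fewer than ``min_conditions`` conditions are omitted.
    """
    vals = matrix.astype(float)
    bad = (vals <= 0).sum().sum()
    if bad:
        logger.warning("%d nonpositive intensities dropped before log10", int(bad))
        vals = vals.where(vals > 0)
    logged = np.log10(vals)
    counts = logged.notna().sum(axis=1)
    spread = logged.std(axis=1, ddof=1)
    return spread[counts >= min_conditions].rename("expression_spread")


def mrna_expression_from_counts(counts: Mapping[str, float]) -> pd.Series:
    """Natural-log expression from read counts, with a +1 guard for zeros."""
    s = pd.Series(counts, dtype=float)
    if (s < 0).any():
        raise ValueError("read counts must be nonnegative")
    return np.log(s + 1.0).rename("mrna_expression")


def assemble_feature_table(
    classifications: Mapping[str, str] | pd.Series,
    features: Mapping[str, Mapping[str, float] | pd.Series],
    flags: Mapping[str, Mapping[str, bool] | pd.Series] | None = None,
    synonym_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Join per-gene features and flags onto the life-stage classification.

    The classification defines the row universe; features may cover any
    subset (each downstream comparison uses only rows where the needed
    feature is present).  ``synonym_map`` renames incoming feature gene
    ids before joining.  Duplicate gene rows raise; a disjoint id space
    joins to an all-missing table with a loud warning.
    """
    cls = pd.Series(classifications).rename("life_stage")
    if cls.index.has_duplicates:
        raise ValueError("duplicate gene ids in the classification")
    table = cls.to_frame()

    def _renamed(s: pd.Series) -> pd.Series:
        if synonym_map:
            s = s.rename(index=lambda g: synonym_map.get(g, g))
            if s.index.has_duplicates:
                # synonym collapse: keep the first occurrence deterministically
                s = s.groupby(level=0).first()
        return s

    all_cols: dict[str, pd.Series] = {}
    for name, mapping in features.items():
        all_cols[name] = _renamed(pd.Series(mapping, dtype=float))
    for name, mapping in (flags or {}).items():
        all_cols[name] = _renamed(pd.Series(mapping).astype(bool))

    for name, s in all_cols.items():
        if s.index.has_duplicates:
            raise ValueError(f"duplicate gene rows in feature {name!r}")
        table[name] = s.reindex(table.index)

    n_match = max(
        (table[c].notna().sum() for c in all_cols), default=len(table)
    )
    if all_cols and n_match == 0:
        logger.warning(
            "no feature gene id matched any classified gene: "
            "check identifier spaces / synonym map"
        )
    for name in all_cols:
        miss = int(table[name].isna().sum())
        if miss:
            logger.info("feature %r missing for %d/%d genes", name, miss, len(table))
    logger.info("assembled feature table: %d genes, %d columns", len(table), table.shape[1])
    return table
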