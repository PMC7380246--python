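"""Methylome-transcriptome integration.

Links DMRs to genes within a +/-2 kb flank, cross-classifies DMR direction
(hyper/hypo) with DEG direction (up/down/ns) into quadrant tables, extracts
patterns conserved across two genotypes, computes Pearson correlations
between per-condition methylation enrichment and expression profiles
(retaining anti-correlated links, r <= -0.5), and runs hypergeometric term
enrichment on the resulting gene sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats as sps

from .dmr import bh_adjust

__all__ = [
    "link_dmrs_to_genes",
    "QuadrantTable",
    "quadrant_overlap",
    "conserved_patterns",
    "methylation_expression_correlation",
    "term_enrichment",
]

logger = logging.getLogger(__name__)

QUADRANTS = ("hyper_up", "hyper_down", "hypo_up", "hypo_down", "hyper_ns", "hypo_ns")


def link_dmrs_to_genes(
    dmrs: pd.DataFrame, genes: pd.DataFrame, flank: int = 2000
) -> pd.DataFrame:
    """Assign DMRs to genes whose +/- *flank* extended span they intersect.

    Both inputs are 1-based inclusive (``chrom``/``start``/``end`` plus
    ``window_id`` for DMRs and ``gene_id``/``strand`` for genes).  A DMR
    overlapping the extended spans of several genes links to each.  The
    returned links carry a relative ``position`` (upstream/gene_body/
    downstream, strand-aware) and a signed ``distance`` in bp (negative
    upstream, 0 when overlapping the gene span itself).
    """
    trees: dict[str, IntervalTree] = {}
    for row in genes.itertuples(index=False):
        # half-open interval over the extended span
        lo = max(row.start - flank, 1)
        trees.setdefault(row.chrom, IntervalTree()).addi(
            lo, row.end + flank + 1, row
        )
    rows = []
    id_col = "window_id" if "window_id" in dmrs.columns else "dmr_id"
    for d in dmrs.itertuples(index=False):
        tree = trees.get(d.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(d.start, d.end + 1), key=lambda iv: iv.data.gene_id):
            g = iv.data
            if d.end >= g.start and d.start <= g.end:
                position, dist = "gene_body", 0
            elif d.end < g.start:
                gap = g.start - d.end
                position = "upstream" if g.strand != "-" else "downstream"
                dist = -gap if position == "upstream" else gap
            else:
                gap = d.start - g.end
                position = "downstream" if g.strand != "-" else "upstream"
                dist = -gap if position == "upstream" else gap
            rows.append((g.gene_id, getattr(d, id_col), position, dist))
    return pd.DataFrame(
        rows, columns=["gene_id", "dmr_id", "position", "distance"]
    ).drop_duplicates(["gene_id", "dmr_id"]).reset_index(drop=True)


@dataclass
class QuadrantTable:
    """DMR-direction x DEG-direction cross-classification for one contrast.

    ``counts`` maps quadrant name (e.g. ``hyper_down``) to the number of
    linked genes in it; ``genes`` holds the underlying gene lists.  Genes
    linked to a DMR but absent from the DEG table are tallied in ``no_test``
    rather than dropped, so the cells plus ``no_test`` account for every
    (gene, direction) assignment.
    """

    contrast: str
    counts: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)
    no_test: list = field(default_factory=list)
    ambiguous_genes: list = field(default_factory=list)

    def cell(self, quadrant: str) -> list[str]:
        return self.genes.get(quadrant, [])

    def total(self) -> int:
        return sum(self.counts.values()) + len(self.no_test)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"quadrant": list(QUADRANTS),
             "n": [self.counts.get(qd, 0) for qd in QUADRANTS]}
        )


def quadrant_overlap(
    links: pd.DataFrame,
    dmr_directions: Mapping[str, str],
    deg_table: pd.DataFrame,
    contrast: str,
    deg_contrast: str | None = None,
) -> QuadrantTable:
    """Cross DMR direction with DEG call for one contrast.

    ``dmr_directions`` maps dmr_id -> 'hyper'/'hypo' for *contrast*;
    ``deg_table`` is a :class:`~chillmeth.expression.DEGResults` table (index
    gene_id, ``call`` column) for the same contrast.  A gene with several
    linked DMRs of conflicting direction is counted once per direction and
    flagged.  ``deg_contrast`` (when given) must equal *contrast*.
    """
    if deg_contrast is not None and deg_contrast != contrast:
        raise ValueError(
            f"contrast mismatch: DMR directions for {contrast!r}, "
            f"DEG calls for {deg_contrast!r}"
        )
    table = QuadrantTable(contrast=contrast)
    linked = links[links["dmr_id"].isin(dmr_directions.keys())]
    per_gene: dict[str, set[str]] = {}
    for row in linked.itertuples(index=False):
        per_gene.setdefault(row.gene_id, set()).add(dmr_directions[row.dmr_id])
    calls = deg_table["call"]
    for qd in QUADRANTS:
        table.genes[qd] = []
    for gene in sorted(per_gene):
        dirs = sorted(per_gene[gene])
        if len(dirs) > 1:
            table.ambiguous_genes.append(gene)
        if gene not in calls.index:
            table.no_test.append(gene)
            continue
        call = calls.loc[gene]
        for d in dirs:
            table.genes[f"{d}_{call}"].append(gene)
    table.counts = {qd: len(table.genes[qd]) for qd in QUADRANTS}
    if table.ambiguous_genes:
        logger.warning(
            "%s: %d genes linked to DMRs of conflicting direction "
            "(counted once per direction)",
            contrast, len(table.ambiguous_genes),
        )
    return table


def conserved_patterns(
    tables_a: Sequence[QuadrantTable],
    tables_b: Sequence[QuadrantTable],
    classes: Sequence[str] = ("hyper_down", "hypo_up"),
) -> pd.DataFrame:
    """Genes in the same quadrant class in both genotypes.

    A gene qualifies for a class when it occupies that class in at least one
    contrast of genotype A and at least one contrast of genotype B (the two
    genotypes' chilling time courses differ, so the contrast indices need
    not match).  The output carries per-genotype contrast provenance.
    """
    rows = []
    for cls in classes:
        in_a: dict[str, list[str]] = {}
        in_b: dict[str, list[str]] = {}
        for t in tables_a:
            for g in t.cell(cls):
                in_a.setdefault(g, []).append(t.contrast)
        for t in tables_b:
            for g in t.cell(cls):
                in_b.setdefault(g, []).append(t.contrast)
        for g in sorted(set(in_a) & set(in_b)):
            rows.append(
                (g, cls, ",".join(in_a[g]), ",".join(in_b[g]))
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "class", "contrasts_a", "contrasts_b"]
    )


def methylation_expression_correlation(
    links: pd.DataFrame,
    meth_profiles: pd.DataFrame,
    expr_profiles: pd.DataFrame,
    r_max: float = -0.5,
    closest_only: bool = False,
) -> pd.DataFrame:
    """Pearson r between per-condition methylation and expression profiles.

    ``meth_profiles`` (index dmr_id) and ``expr_profiles`` (index gene_id)
    must share the same ordered condition columns (>= 3).  One record per
    link is produced (or only the closest DMR per gene with
    ``closest_only``); links with a zero-variance profile on either side are
    excluded with a warning.  The ``retained`` column marks r <= *r_max*.
    """
    if list(meth_profiles.columns) != list(expr_profiles.columns):
        raise ValueError("condition axes of methylation and expression differ")
    if meth_profiles.shape[1] < 3:
        raise ValueError("need >= 3 condition points for a defined r")
    use = links[
        links["dmr_id"].isin(meth_profiles.index)
        & links["gene_id"].isin(expr_profiles.index)
    ].copy()
    if closest_only:
        use["absdist"] = use["distance"].abs()
        use = (
            use.sort_values(["gene_id", "absdist", "dmr_id"], kind="stable")
            .drop_duplicates("gene_id")
            .drop(columns="absdist")
        )
    rows = []
    n_points = meth_profiles.shape[1]
    for row in use.itertuples(index=False):
        x = meth_profiles.loc[row.dmr_id].to_numpy(dtype=float)
        y = expr_profiles.loc[row.gene_id].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning(
                "zero-variance profile for link %s-%s; excluded",
                row.gene_id, row.dmr_id,
            )
            continue
        r = float(sps.pearsonr(x, y).statistic)
        rows.append((row.gene_id, row.dmr_id, r, n_points, r <= r_max))
    return pd.DataFrame(
        rows, columns=["gene_id", "dmr_id", "r", "n_points", "retained"]
    )


def term_enrichment(
    selected: Iterable[str],
    universe: Iterable[str],
    gene_terms: pd.DataFrame,
    q_max: float = 0.01,
) -> pd.DataFrame:
    """Hypergeometric term enrichment of *selected* within *universe*.

    ``gene_terms`` is a two-column map (``gene_id``, ``term_id``; optional
    ``term_name``).  Genes not covered by the map are dropped with a warning.
    Per term the upper-tail probability of an overlap at least as large as
    observed is computed and BH-adjusted across terms; ``enriched`` marks
    q < *q_max*.
    """
    universe = sorted(set(universe))
    selected = sorted(set(selected))
    stray = set(selected) - set(universe)
    if stray:
        raise ValueError(f"selected genes outside universe: {sorted(stray)[:5]}")
    covered = set(gene_terms["gene_id"])
    uncovered = [g for g in universe if g not in covered]
    if uncovered:
        logger.warning("term_enrichment: %d universe genes uncovered by map", len(uncovered))
    gt = gene_terms[gene_terms["gene_id"].isin(universe)]
    M = len(universe)
    n_sel = len(selected)
    sel_set = set(selected)
    names = (
        dict(zip(gt["term_id"], gt["term_name"]))
        if "term_name" in gt.columns else {}
    )
    rows = []
    for term, grp in gt.groupby("term_id"):
        term_genes = set(grp["gene_id"])
        K = len(term_genes)
        k = len(term_genes & sel_set)
        p = float(sps.hypergeom.sf(k - 1, M, K, n_sel)) if n_sel else 1.0
        rows.append((term, names.get(term, ""), k, K, n_sel, M, p))
    out = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "n_overlap", "n_term",
                 "n_selected", "n_universe", "p"],
    )
    if out.empty or not selected:
        out["q"] = pd.Series(dtype=float)
        out["enriched"] = pd.Series(dtype=bool)
        return out
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = out["q"] < q_max
    return out.sort_values(["q", "term_id"], kind="stable").reset_index(drop=True)
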