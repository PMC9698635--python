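"""Genomic context of miRNA loci: gene overlap, TSS/TTS proximity, host expression.

Overlap is strand-agnostic (a hairpin inside a gene on either strand counts
as intragenic).  Distances are measured from the hairpin midpoint to the
nearest gene's transcription start/termination site in the *gene's*
orientation: negative = upstream of the TSS, positive = downstream of the
TTS, and both are 0 when the midpoint lies inside the gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core_io import GeneRecord, MiRNALocus


@dataclass
class GenomicContext:
    locus_id: str
    overlaps_gene: bool
    host_gene_id: str | None
    signed_tss_distance: float
    signed_tts_distance: float
    nearest_gene_id: str | None


def _gene_trees(genes: list[GeneRecord]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        # 1-based inclusive -> half-open for the tree
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    return trees


def intersect_with_genes(loci: list[MiRNALocus],
                         genes: list[GeneRecord]) -> list[GenomicContext]:
    """Gene overlap + boundary distances for every locus.

    Overlap means the 1-based inclusive hairpin and gene intervals share at
    least one bp; ties among overlapping genes are broken by largest
    overlap, then smallest gene id.  Loci on chromosomes absent from the
    annotation get ``overlaps_gene=False`` and unbounded distances.
    """
    trees = _gene_trees(genes)
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for locus in loci:
        tree = trees.get(locus.chrom)
        if tree is None:
            out.append(GenomicContext(locus.locus_id, False, None,
                                      float("inf"), float("inf"), None))
            continue
        overlapping = [iv.data for iv in tree.overlap(locus.start, locus.end + 1)]
        if overlapping:
            def overlap_len(g: GeneRecord) -> int:
                return min(locus.end, g.end) - max(locus.start, g.start) + 1
            host = sorted(overlapping, key=lambda g: (-overlap_len(g), g.gene_id))[0]
            out.append(GenomicContext(locus.locus_id, True, host.gene_id,
                                      0.0, 0.0, host.gene_id))
        else:
            tss, tts, nearest = distance_to_gene_boundaries(locus, by_chrom[locus.chrom])
            out.append(GenomicContext(locus.locus_id, False, None, tss, tts, nearest))
    return out


def distance_to_gene_boundaries(locus: MiRNALocus,
                                genes: list[GeneRecord]) -> tuple[float, float, str | None]:
    """Signed midpoint distances to the nearest gene's TSS and TTS.

    The nearest gene minimizes the unsigned midpoint-to-gene-interval
    distance (ties: smallest gene id).  Signs follow the gene orientation:
    for a + strand gene the TSS is its start; for a - strand gene its end.
    Negative values lie upstream of the TSS, positive downstream of the
    TTS; a midpoint inside the gene gives (0, 0).
    """
    chrom_genes = [g for g in genes if g.chrom == locus.chrom]
    if not chrom_genes:
        return float("inf"), float("inf"), None
    mid = (locus.start + locus.end) / 2

    def interval_dist(g: GeneRecord) -> float:
        if g.start <= mid <= g.end:
            return 0.0
        return min(abs(mid - g.start), abs(mid - g.end))

    nearest = sorted(chrom_genes, key=lambda g: (interval_dist(g), g.gene_id))[0]
    if nearest.start <= mid <= nearest.end:
        return 0.0, 0.0, nearest.gene_id
    sign = 1 if nearest.strand == "+" else -1
    tss = (mid - nearest.tss) * sign
    tts = (mid - nearest.tts) * sign
    return float(tss), float(tts), nearest.gene_id


def proximity_profile(contexts: list[GenomicContext], calls,
                      window: int = 10_000, bins: int = 50) -> dict[str, pd.DataFrame]:
    """Per-class binned densities of TSS and TTS distances in [-window, window].

    Returns one DataFrame per anchor ("tss", "tts") with bin midpoints as
    index and one normalized (sum 1 over in-window loci) column per class.
    """
    label_of = {c.subject: c.label for c in calls if c.level == "locus"}
    edges = np.linspace(-window, window, bins + 1)
    mids = (edges[:-1] + edges[1:]) / 2
    out = {}
    for anchor, attr in (("tss", "signed_tss_distance"), ("tts", "signed_tts_distance")):
        cols = {}
        for cls in ("SS", "NSS"):
            vals = [getattr(c, attr) for c in contexts
                    if label_of.get(c.locus_id) == cls and np.isfinite(getattr(c, attr))]
            vals = [v for v in vals if -window <= v <= window]
            hist, _ = np.histogram(vals, bins=edges)
            total = hist.sum()
            cols[cls] = hist / total if total else hist.astype(float)
        out[anchor] = pd.DataFrame(cols, index=mids)
    return out


def intragenic_proportions(contexts: list[GenomicContext], calls,
                           loci: list[MiRNALocus]) -> pd.DataFrame:
    """Per-species proportion of intragenic loci per class (box-plot semantics)."""
    label_of = {c.subject: c.label for c in calls if c.level == "locus"}
    species_of = {l.locus_id: l.species for l in loci}
    rows = []
    df = pd.DataFrame([{
        "species": species_of[c.locus_id],
        "label": label_of.get(c.locus_id),
        "intragenic": c.overlaps_gene,
    } for c in contexts if c.locus_id in species_of])
    for (sp, cls), grp in df.groupby(["species", "label"]):
        rows.append({"species": sp, "label": cls,
                     "n": len(grp), "prop_intragenic": grp.intragenic.mean()})
    return pd.DataFrame(rows)


def expression_concordance(mirna_expr: pd.DataFrame, host_expr: pd.DataFrame,
                           pairs: list[tuple[str, str]]) -> dict:
    """Tissue-expression concordance between miRNAs and their host genes.

    Per pair: does the most highly expressed tissue match?  Across pairs:
    Pearson correlation of all (miRNA, host) expression values after
    per-row max normalization.  Constant rows are excluded from the
    correlation with a warning entry.
    """
    if mirna_expr.shape[1] < 3:
        raise ValueError("at least 3 tissues required")
    matches = {}
    xs, ys = [], []
    excluded = []
    for mirna_id, gene_id in pairs:
        mv = mirna_expr.loc[mirna_id]
        gv = host_expr.loc[gene_id]
        matches[(mirna_id, gene_id)] = bool(mv.idxmax() == gv.idxmax())
        if mv.max() == mv.min() or gv.max() == gv.min():
            excluded.append((mirna_id, gene_id))
            continue
        xs.extend((mv / mv.max()).tolist())
        ys.extend((gv / gv.max()).tolist())
    if len(xs) < 3:
        raise ValueError("fewer than 3 usable pairs for correlation")
    r, p = stats.pearsonr(xs, ys)
    return {
        "argmax_match": matches,
        "n_match": sum(matches.values()),
        "n_pairs": len(pairs),
        "pearson_r": float(r),
        "p": float(p),
        "excluded_pairs": excluded,
    }
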