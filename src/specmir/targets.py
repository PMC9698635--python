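"""Plant miRNA target prediction and GO-term enrichment.

Target sites are scored with an expectation penalty summed over the
miRNA/target duplex: Watson-Crick pair 0, G:U wobble 0.5, mismatch 1.0,
gap 2.0, with every penalty doubled at miRNA positions 2-13 from the 5'
end (the core region).  A transcript is scanned antiparallel (the miRNA 5'
end pairs the 3' end of the site); at most one gap is allowed per duplex
and only the best site per (miRNA, transcript) is kept.  Sites with
expectation <= 3 count as predicted targets.

Enrichment of GO terms among target genes uses a one-sided Fisher exact
test per term with Benjamini-Hochberg correction at adjusted p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import MiRNALocus

MISMATCH = 1.0
WOBBLE = 0.5
GAP = 2.0
CORE = (2, 13)  # 1-based miRNA positions with doubled penalties

_PAIR = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class TargetHit:
    mirna_id: str
    transcript_id: str
    site_start: int  # 1-based start of the site on the transcript
    duplex: tuple[str, str]  # (miRNA 5'->3', site 3'->5'), aligned
    expectation: float


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    fg_count: int
    fg_total: int
    bg_count: int
    bg_total: int
    p: float
    adjusted_p: float
    enriched: bool


def _core_weight(pos_1based: int) -> float:
    return 2.0 if CORE[0] <= pos_1based <= CORE[1] else 1.0


def _column_penalty(m: str, s: str) -> float:
    if (m, s) in _PAIR:
        return 0.0
    if (m, s) in _WOBBLE:
        return WOBBLE
    return MISMATCH


def score_target_site(mirna: str, site: str) -> float:
    """Expectation of an aligned miRNA/site duplex.

    ``mirna`` is written 5'->3' and ``site`` 3'->5' so that column i of the
    two equal-length strings is one duplex position; '-' marks a gap on
    either side.  A gap column takes the core weight of the miRNA position
    it interrupts (for a transcript bulge, the next miRNA base).
    """
    if not mirna or not site:
        raise ValueError("empty duplex string")
    if len(mirna) != len(site):
        raise ValueError("duplex strings must be aligned to equal length")
    total = 0.0
    pos = 0  # 1-based miRNA position of the last miRNA base seen
    for m, s in zip(mirna, site):
        if m == "-" and s == "-":
            raise ValueError("double-gap column")
        if m == "-":
            total += GAP * _core_weight(pos + 1)
        elif s == "-":
            pos += 1
            total += GAP * _core_weight(pos)
        else:
            pos += 1
            total += _column_penalty(m, s) * _core_weight(pos)
    return total


# ---------------------------------------------------------------------------
# Scanner
# ---------------------------------------------------------------------------

_BASE_INDEX = {b: i for i, b in enumerate("ACGU")}


def _penalty_matrix(mirna: str, transcript: str) -> np.ndarray:
    """M[i, j] = core-weighted penalty of miRNA base i paired with transcript base j."""
    pair_pen = np.full((4, 4), MISMATCH)
    for a, b in _PAIR:
        pair_pen[_BASE_INDEX[a], _BASE_INDEX[b]] = 0.0
    for a, b in _WOBBLE:
        pair_pen[_BASE_INDEX[a], _BASE_INDEX[b]] = WOBBLE
    mi = np.array([_BASE_INDEX[c] for c in mirna])
    ti = np.array([_BASE_INDEX[c] for c in transcript])
    M = pair_pen[np.ix_(mi, ti)]
    w = np.array([_core_weight(i + 1) for i in range(len(mirna))])
    return M * w[:, None]


def _best_site(mirna: str, transcript: str) -> tuple[float, int, tuple[str, str]] | None:
    """Best duplex over all site positions with <= 1 gap.

    Returns ``(expectation, site_start_0based, duplex)`` or None when the
    transcript is shorter than any admissible site.
    """
    L, n = len(mirna), len(transcript)
    if n < L - 1:
        return None
    M = _penalty_matrix(mirna, transcript)
    w = np.array([_core_weight(i + 1) for i in range(L)])
    candidates: list[tuple[float, int, int, int]] = []  # (score, case, s, g)

    # ungapped: miRNA i pairs transcript s + L-1-i
    if n >= L:
        ns = n - L + 1
        U = np.zeros(ns)
        for i in range(L):
            U += M[i, L - 1 - i: L - 1 - i + ns]
        s = int(np.argmin(U))
        candidates.append((float(U[s]), 0, s, -1))

    # one transcript base bulged (gap in miRNA), site length L+1, interior only
    if n >= L + 1:
        ns = n - L
        pre = np.zeros(ns)   # sum_{i<g} M[i, s+L-i]
        suf = np.zeros((L + 1, ns))
        for g in range(L - 1, -1, -1):
            suf[g] = suf[g + 1] + M[g, L - 1 - g: L - 1 - g + ns]
        best = None
        for g in range(1, L):
            pre += M[g - 1, L - (g - 1): L - (g - 1) + ns]
            gap_pen = GAP * w[g]  # bulge interrupts before miRNA base g+1 (1-based)
            total = pre + gap_pen + suf[g]
            s = int(np.argmin(total))
            if best is None or total[s] < best[0]:
                best = (float(total[s]), 1, s, g)
        if best is not None:
            candidates.append(best)

    # one miRNA base unpaired (gap in site), site length L-1
    if n >= L - 1:
        ns = n - (L - 1) + 1
        pre = np.zeros(ns)   # sum_{i<g} M[i, s+L-2-i]
        suf = np.zeros((L + 1, ns))
        # suf[0] (i >= 0 all paired on the suffix frame) is never used:
        # when miRNA base 0 is the gap, the suffix starts at i = 1
        for g in range(L - 1, 0, -1):
            suf[g] = suf[g + 1] + M[g, L - 1 - g: L - 1 - g + ns]
        best = None
        for g in range(L):
            gap_pen = GAP * w[g]
            total = pre + gap_pen + suf[g + 1]
            s = int(np.argmin(total))
            if best is None or total[s] < best[0]:
                best = (float(total[s]), 2, s, g)
            if g < L - 1:
                pre += M[g, L - 2 - g: L - 2 - g + ns]
        if best is not None:
            candidates.append(best)

    if not candidates:
        return None
    score, case, s, g = min(candidates, key=lambda c: (c[0], c[1], c[2]))
    duplex = _build_duplex(mirna, transcript, case, s, g)
    return score, s, duplex


def _build_duplex(mirna: str, transcript: str, case: int, s: int, g: int) -> tuple[str, str]:
    """Aligned (miRNA 5'->3', site 3'->5') strings for a scanner candidate."""
    L = len(mirna)
    if case == 0:
        site = transcript[s: s + L][::-1]
        return mirna, site
    if case == 1:  # transcript bulge between miRNA bases g-1 and g
        site = transcript[s: s + L + 1][::-1]
        return mirna[:g] + "-" + mirna[g:], site
    # case 2: miRNA base g unpaired
    site = transcript[s: s + L - 1][::-1]
    return mirna, site[:g] + "-" + site[g:]


def scan_targets(mirna_id: str, mirna: str, transcripts: dict[str, str],
                 expectation_max: float = 3.0) -> list[TargetHit]:
    """All best-per-transcript sites with expectation <= ``expectation_max``.

    The reported expectation is recomputed from the reconstructed duplex
    with :func:`score_target_site`, which doubles as an internal
    consistency check on the vectorized scanner.
    """
    hits = []
    for tid in sorted(transcripts):
        found = _best_site(mirna, transcripts[tid])
        if found is None:
            continue
        score, s, duplex = found
        expectation = score_target_site(*duplex)
        if abs(expectation - score) > 1e-9:
            raise AssertionError("scanner/duplex score mismatch")
        if expectation <= expectation_max:
            hits.append(TargetHit(mirna_id, tid, s + 1, duplex, expectation))
    return hits


def scan_all_targets(loci: list[MiRNALocus],
                     transcripts_by_species: dict[str, dict[str, str]],
                     expectation_max: float = 3.0) -> list[TargetHit]:
    """Scan every miRNA against its own species' transcriptome."""
    hits = []
    for locus in loci:
        transcripts = transcripts_by_species.get(locus.species, {})
        hits.extend(scan_targets(locus.locus_id, locus.mature_seq,
                                 transcripts, expectation_max))
    return hits


# ---------------------------------------------------------------------------
# Target-spectrum statistics and GO enrichment
# ---------------------------------------------------------------------------

def target_spectrum_stats(hits: list[TargetHit], calls,
                          loci: list[MiRNALocus]) -> dict:
    """Per-species, per-class target-spectrum summaries.

    For every species and class: the fraction of miRNAs with zero
    predicted targets and the mean number of target genes per miRNA; the
    SS-vs-NSS contrasts are Welch t-tests across the per-species values
    (box-plot semantics).
    """
    from .features import compare_groups

    label_of = {c.subject: c.label for c in calls if c.level == "locus"}
    n_targets = {l.locus_id: 0 for l in loci}
    for h in hits:
        if h.mirna_id in n_targets:
            n_targets[h.mirna_id] += 1
    df = pd.DataFrame([{
        "species": l.species, "label": label_of.get(l.locus_id),
        "n_targets": n_targets[l.locus_id],
    } for l in loci if l.locus_id in label_of])
    per_species = df.groupby(["species", "label"]).agg(
        n_mirnas=("n_targets", "size"),
        zero_target_frac=("n_targets", lambda v: float((v == 0).mean())),
        mean_targets=("n_targets", "mean"),
    ).reset_index()
    out = {"per_species": per_species}
    for metric in ("zero_target_frac", "mean_targets"):
        ss = per_species.loc[per_species.label == "SS", metric]
        nss = per_species.loc[per_species.label == "NSS", metric]
        if len(ss) >= 2 and len(nss) >= 2:
            t, p, (m_ss, m_nss) = compare_groups(ss, nss)
            out[metric] = {"mean_ss": m_ss, "mean_nss": m_nss, "t": t, "p": p}
    return out


def go_enrichment(fg_genes: set[str], bg_genes: set[str],
                  go_table: dict[str, set[str]], alpha: float = 0.05) -> list[EnrichmentRow]:
    """One-sided Fisher enrichment per GO term with BH correction.

    ``fg_genes`` must be a subset of ``bg_genes``.  Terms with at least one
    foreground gene are tested; rows with BH-adjusted p < ``alpha`` are
    flagged enriched.
    """
    fg = set(fg_genes)
    bg = set(bg_genes)
    if not fg <= bg:
        raise ValueError("foreground genes must be a subset of the background")
    annotated_fg: dict[str, int] = {}
    annotated_bg: dict[str, int] = {}
    for gene in bg:
        for term in go_table.get(gene, ()):
            annotated_bg[term] = annotated_bg.get(term, 0) + 1
            if gene in fg:
                annotated_fg[term] = annotated_fg.get(term, 0) + 1
    terms = sorted(annotated_fg)  # fg_count >= 1
    if not terms:
        return []
    fg_total, bg_total = len(fg), len(bg)
    pvals = []
    for term in terms:
        a = annotated_fg[term]
        k = annotated_bg[term]
        table = [[a, fg_total - a], [k - a, (bg_total - fg_total) - (k - a)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        pvals.append(p)
    reject, adj, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return [
        EnrichmentRow(term=t, fg_count=annotated_fg[t], fg_total=fg_total,
                      bg_count=annotated_bg[t], bg_total=bg_total,
                      p=float(p), adjusted_p=float(q), enriched=bool(r))
        for t, p, q, r in zip(terms, pvals, adj, reject)
    ]


def classify_term_overlap(enriched_ss: set[str], enriched_nss: set[str]) -> dict:
    """Partition enriched terms into SS-only / NSS-only / both."""
    ss_only = set(enriched_ss) - set(enriched_nss)
    nss_only = set(enriched_nss) - set(enriched_ss)
    both = set(enriched_ss) & set(enriched_nss)
    total = len(ss_only) + len(nss_only) + len(both)
    return {
        "ss_only": sorted(ss_only), "nss_only": sorted(nss_only),
        "both": sorted(both),
        "counts": {"ss_only": len(ss_only), "nss_only": len(nss_only),
                   "both": len(both), "total": total},
    }
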