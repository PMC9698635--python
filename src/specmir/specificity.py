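"""Species-specific miRNA calling: the seq-based strategy and the homology baseline.

The seq-based strategy labels a miRNA family species-specific (SS) when

(i)   no mature miRNA in any other species lies within 2 edits of any of
      its members' matures,
(ii)  every member hairpin folds into a stable secondary structure, and
(iii) every member shows the canonical sRNA-seq read-distribution profile
      (>75% of reads in the mature+star regions, <=20% boundary-straddling
      reads).

The homology baseline instead BLAST-style aligns each hairpin against every
other species' genome and labels the locus SS only when no alignment
survives an e-value < 1e-10 and >=70% query-coverage filter.  The two
strategies disagree in two characteristic ways: the homology caller misses
SS loci whose hairpin happens to have a silent genomic copy elsewhere
(false negatives of SS), and over-calls SS where a conserved mature sits in
a diverged hairpin that no longer aligns at 70% coverage (false positives).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp, log

import numpy as np

from .core_io import MiRNALocus, ReadProfile, rna_to_dna, revcomp_dna
from .families import FamilyAssignment, mature_distance
from . import folding

# Karlin-Altschul parameters for the blastn-default scoring used below
# (match +2, mismatch -3, gap open -5, extend -2).
_KA_LAMBDA = 0.625
_KA_K = 0.41


@dataclass
class SpecificityCall:
    """SS/NSS verdict for one family or locus, with the evidence trail."""

    subject: str
    level: str  # "family" or "locus"
    label: str  # "SS" or "NSS"
    species: str | None = None
    evidence: dict = field(default_factory=dict)


@dataclass(frozen=True)
class HomologyHit:
    query_locus: str
    subject_species: str
    subject_chrom: str
    start: int  # 1-based inclusive, on the forward strand of the subject
    end: int
    strand: str
    score: int
    e_value: float
    query_coverage: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.query_coverage <= 1.0:
            raise ValueError("query_coverage outside [0, 1]")
        if self.e_value < 0:
            raise ValueError("negative e-value")


# ---------------------------------------------------------------------------
# Requirement (iii): canonical read-distribution profile
# ---------------------------------------------------------------------------

def validate_read_profile(p: ReadProfile) -> tuple[bool, list[str]]:
    """Check the canonical read-distribution criterion.

    Pass iff (mature+star)/total > 0.75 (strict) and overlap/total <= 0.20
    (non-strict).  Returns ``(flag, reasons)`` with one reason per violated
    condition.
    """
    if p.total_reads == 0:
        raise ValueError("no reads")
    reasons = []
    precise = (p.mature_reads + p.star_reads) / p.total_reads
    overlap = p.overlap_reads / p.total_reads
    if not precise > 0.75:
        reasons.append(f"mature+star {precise:.1%} not > 75%")
    if not overlap <= 0.20:
        reasons.append(f"overlap {overlap:.1%} > 20%")
    return not reasons, reasons


# ---------------------------------------------------------------------------
# Requirement (ii): stable hairpin structure
# ---------------------------------------------------------------------------

def validate_structure(locus: MiRNALocus, nmfe_max: float = -0.20,
                       min_paired_frac: float = 0.60) -> tuple[bool, list[str]]:
    """Check hairpin folding stability.

    Pass iff the normalized MFE (kcal/mol per nt) is at most ``nmfe_max``
    and at least ``min_paired_frac`` of the mature positions are paired in
    the MFE structure.
    """
    structure, mfe = folding.fold(locus.hairpin_seq)
    nmfe = mfe / len(locus.hairpin_seq)
    mask = folding.paired_mask(structure)
    m0, m1 = locus.mature_span_in_hairpin
    paired_frac = sum(mask[m0:m1]) / (m1 - m0)
    reasons = []
    if not nmfe <= nmfe_max:
        reasons.append(f"NMFE {nmfe:.3f} above {nmfe_max}")
    if not paired_frac >= min_paired_frac:
        reasons.append(f"mature paired fraction {paired_frac:.2f} below {min_paired_frac}")
    return not reasons, reasons


# ---------------------------------------------------------------------------
# Seq-based caller
# ---------------------------------------------------------------------------

def call_species_specific_seq(matrix, families: list[FamilyAssignment],
                              loci: list[MiRNALocus],
                              require_structure: bool = True,
                              require_profile: bool = True,
                              max_dist: int = 2) -> list[SpecificityCall]:
    """Seq-based SS/NSS calls at family level, inherited by loci.

    A family is SS iff (a) it is present in exactly one species column of
    the conservation matrix, (b) none of its members' matures is within
    ``max_dist`` edits of ANY mature in another species (an explicit
    all-pairs post-check — founder linkage can place two <=2-edit matures
    in different families), and (c) when the corresponding flags are on,
    every member passes the structure and read-profile validators.
    """
    by_id = {l.locus_id: l for l in loci}
    fam_ids = set(matrix.index)
    for fam in families:
        if fam.family_id not in fam_ids:
            raise ValueError(f"family {fam.family_id} missing from conservation matrix")
        for lid in fam.member_loci:
            if lid not in by_id:
                raise ValueError(f"locus {lid} missing from locus set")

    # all matures per species, for the cross-species post-check
    matures_by_species: dict[str, list[str]] = {}
    for l in loci:
        matures_by_species.setdefault(l.species, []).append(l.mature_seq)

    def nearest_cross_species(member_ids: list[str], own_species: str) -> int | None:
        best = None
        for lid in member_ids:
            mat = by_id[lid].mature_seq
            for sp, matures in matures_by_species.items():
                if sp == own_species:
                    continue
                for other in matures:
                    d = mature_distance(mat, other)
                    if best is None or d < best:
                        best = d
        return best

    calls: list[SpecificityCall] = []
    locus_calls: list[SpecificityCall] = []
    for fam in families:
        row = matrix.loc[fam.family_id]
        n_species = int((row > 0).sum())
        evidence: dict = {"n_species": n_species}
        label = "SS"
        if n_species != 1:
            label = "NSS"
            evidence["reason"] = "present in multiple species"
        else:
            own_species = row[row > 0].index[0]
            d = nearest_cross_species(fam.member_loci, own_species)
            evidence["nearest_cross_species_distance"] = d
            if d is not None and d <= max_dist:
                label = "NSS"
                evidence["reason"] = "cross-species mature within mismatch threshold"
            if label == "SS" and require_structure:
                for lid in fam.member_loci:
                    ok, reasons = validate_structure(by_id[lid])
                    if not ok:
                        label = "NSS"
                        evidence["reason"] = f"structure check failed for {lid}: {reasons}"
                        break
                else:
                    evidence["structure_check"] = "pass"
            if label == "SS" and require_profile:
                for lid in fam.member_loci:
                    p = by_id[lid].read_profile
                    if p is None:
                        continue  # star/profile unknown: not evidence against
                    ok, reasons = validate_read_profile(p)
                    if not ok:
                        label = "NSS"
                        evidence["reason"] = f"read profile failed for {lid}: {reasons}"
                        break
                else:
                    evidence["profile_check"] = "pass"
        calls.append(SpecificityCall(fam.family_id, "family", label, evidence=evidence))
        for lid in fam.member_loci:
            locus_calls.append(SpecificityCall(
                lid, "locus", label, species=by_id[lid].species,
                evidence={"family": fam.family_id}))
    return calls + locus_calls


# ---------------------------------------------------------------------------
# Homology baseline
# ---------------------------------------------------------------------------

def _local_align(query_dna: str, subject_dna: str) -> tuple[int, int, int, int, int]:
    """Best local alignment (score, q0, q1, s0, s1; 0-based half-open)."""
    from biotite.sequence import NucleotideSequence
    from biotite.sequence.align import SubstitutionMatrix, align_optimal

    alph = NucleotideSequence.unambiguous_alphabet()
    scores = np.where(np.eye(4, dtype=bool), 2, -3).astype(np.int32)
    matrix = SubstitutionMatrix(alph, alph, scores)
    alns = align_optimal(NucleotideSequence(query_dna), NucleotideSequence(subject_dna),
                         matrix, gap_penalty=(-5, -2), local=True, max_number=1)
    aln = alns[0]
    q = aln.trace[:, 0]
    s = aln.trace[:, 1]
    q = q[q >= 0]
    s = s[s >= 0]
    return aln.score, int(q.min()), int(q.max()) + 1, int(s.min()), int(s.max()) + 1


def _evalue(score: int, query_len: int, subject_len: int) -> float:
    # Karlin-Altschul: E = K * m * n * exp(-lambda * S)
    return _KA_K * query_len * subject_len * exp(-_KA_LAMBDA * score)


def homology_search(hairpin: str, genome: dict[str, str], *,
                    query_locus: str = "query", subject_species: str = "subject",
                    evalue_max: float = 1e-10,
                    min_coverage: float = 0.70) -> list[HomologyHit]:
    """Gapped local alignment of one hairpin against one genome.

    The hairpin (RNA) is searched as DNA against both strands of every
    genome record with a Smith-Waterman aligner (match +2, mismatch -3,
    gap open -5, extend -2) and Karlin-Altschul e-values sized by the
    genome length.  Hits with e-value >= ``evalue_max`` are discarded;
    surviving regions whose aligned query span covers less than
    ``min_coverage`` of the hairpin are filtered out.  Because hairpins
    are near-palindromic, both strands usually align to the same genomic
    region; overlapping hits on one chromosome are merged into a single
    region keeping the best-scoring strand.
    """
    if not genome:
        raise ValueError("empty genome")
    query = rna_to_dna(hairpin)
    total_len = sum(len(s) for s in genome.values())
    hits: list[HomologyHit] = []
    for chrom, seq in genome.items():
        if not seq:
            continue
        for strand in "+-":
            subject = seq if strand == "+" else revcomp_dna(seq)
            score, q0, q1, s0, s1 = _local_align(query, subject)
            e = _evalue(score, len(query), total_len)
            if e >= evalue_max:
                continue
            coverage = (q1 - q0) / len(query)
            if coverage < min_coverage:
                continue
            if strand == "-":
                s0, s1 = len(seq) - s1, len(seq) - s0
            hits.append(HomologyHit(
                query_locus=query_locus, subject_species=subject_species,
                subject_chrom=chrom, start=s0 + 1, end=s1, strand=strand,
                score=score, e_value=e, query_coverage=coverage))
    return _merge_regions(hits)


def _merge_regions(hits: list[HomologyHit]) -> list[HomologyHit]:
    """One hit per subject region: best score among overlapping intervals."""
    kept: list[HomologyHit] = []
    for h in sorted(hits, key=lambda h: (h.subject_chrom, -h.score, h.start)):
        clash = any(k.subject_chrom == h.subject_chrom
                    and k.start <= h.end and h.start <= k.end for k in kept)
        if not clash:
            kept.append(h)
    return sorted(kept, key=lambda h: (h.subject_chrom, h.start))


def call_species_specific_homology(loci: list[MiRNALocus],
                                   other_genomes: dict[str, dict[str, str]],
                                   evalue_max: float = 1e-10,
                                   min_coverage: float = 0.70) -> list[SpecificityCall]:
    """Homology-based SS calls: SS iff no surviving hit in ANY other genome."""
    if not other_genomes:
        raise ValueError("at least one other genome is required")
    calls = []
    for locus in loci:
        all_hits: list[HomologyHit] = []
        for species, genome in other_genomes.items():
            all_hits.extend(homology_search(
                locus.hairpin_seq, genome, query_locus=locus.locus_id,
                subject_species=species, evalue_max=evalue_max,
                min_coverage=min_coverage))
        label = "SS" if not all_hits else "NSS"
        calls.append(SpecificityCall(
            locus.locus_id, "locus", label, species=locus.species,
            evidence={"n_hits": len(all_hits),
                      "hit_species": sorted({h.subject_species for h in all_hits})}))
    return calls


# ---------------------------------------------------------------------------
# Strategy comparison and summaries
# ---------------------------------------------------------------------------

def compare_strategies(seq_calls: list[SpecificityCall],
                       homology_calls: list[SpecificityCall],
                       families: list[FamilyAssignment] | None = None) -> dict:
    """Partition loci by seq-based vs homology-based agreement.

    ``homology_fn_corrected``: loci the homology caller labels NSS
    (conserved) but the seq-based caller labels SS — the false negatives of
    SS the seq-based strategy corrects.  ``homology_fp_corrected``: loci
    homology labels SS but seq-based labels NSS.  Family-level counts use
    the family of each disagreeing locus.
    """
    seq = {c.subject: c.label for c in seq_calls if c.level == "locus"}
    hom = {c.subject: c.label for c in homology_calls if c.level == "locus"}
    if set(seq) != set(hom):
        raise ValueError("seq-based and homology call sets cover different loci")
    agree = [l for l in seq if seq[l] == hom[l]]
    fn = sorted(l for l in seq if seq[l] == "SS" and hom[l] == "NSS")
    fp = sorted(l for l in seq if seq[l] == "NSS" and hom[l] == "SS")
    out = {
        "n_loci": len(seq),
        "agree": len(agree),
        "homology_fn_corrected": len(fn),
        "homology_fp_corrected": len(fp),
        "fn_loci": fn,
        "fp_loci": fp,
    }
    if families is not None:
        fam_of = {lid: f.family_id for f in families for lid in f.member_loci}
        out["fn_families"] = sorted({fam_of[l] for l in fn})
        out["fp_families"] = sorted({fam_of[l] for l in fp})
    return out


def taxon_summary(family_calls: list[SpecificityCall],
                  families: list[FamilyAssignment],
                  taxonomy: dict[str, set[str] | list[str]]) -> dict[str, dict]:
    """Per-clade SS/NSS family proportions.

    ``taxonomy`` maps species -> clade labels.  For each clade, the SS
    proportion is the number of SS families whose single species lies in
    the clade divided by the number of families with any member species in
    the clade; families spanning clades count once per clade where present.
    """
    label_of = {c.subject: c.label for c in family_calls if c.level == "family"}
    unmapped = sorted({sp for f in families for sp in f.species_set} - set(taxonomy))
    if unmapped:
        raise ValueError(f"species not mapped to clades: {unmapped}")
    clades = sorted({c for v in taxonomy.values() for c in v})
    out: dict[str, dict] = {}
    for clade in clades:
        present = [f for f in families
                   if any(clade in taxonomy[sp] for sp in f.species_set)]
        ss = [f for f in present if label_of[f.family_id] == "SS"]
        out[clade] = {
            "n_families": len(present),
            "n_ss": len(ss),
            "ss_proportion": len(ss) / len(present) if present else float("nan"),
        }
    return out


def filter_species(loci: list[MiRNALocus], families: list[FamilyAssignment],
                   required_families: list[str], min_mirnas: int = 100,
                   allowlist: set[str] | None = None) -> list[str]:
    """Retain species with all required families and more than ``min_mirnas`` loci.

    ``required_families`` names family ids (e.g. the highly conserved land
    plant families after clustering); it has no default.  Allowlisted
    species (e.g. chlorophyte outgroups) are kept unconditionally.
    """
    allowlist = allowlist or set()
    counts: dict[str, int] = {}
    for l in loci:
        counts[l.species] = counts.get(l.species, 0) + 1
    fams_by_species: dict[str, set[str]] = {sp: set() for sp in counts}
    for f in families:
        for sp in f.species_set:
            fams_by_species.setdefault(sp, set()).add(f.family_id)
    kept = []
    for sp in sorted(counts):
        if sp in allowlist:
            kept.append(sp)
            continue
        if counts[sp] > min_mirnas and set(required_families) <= fams_by_species[sp]:
            kept.append(sp)
    return kept
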