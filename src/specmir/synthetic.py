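"""Multi-species miRNA datasets with planted ground truth.

The generator emulates what a curated multi-species miRNA annotation
resource provides — per-species locus tables, genomes with gene
annotation, transcriptomes, GO labels and tissue expression — while
planting every truth the pipeline is meant to recover:

* family structure: conserved families appear in >=2 species with members
  within ``intra_family_max_mismatch`` substitutions of a planted founder;
  species-specific (SS) loci are singleton families rejection-sampled to
  stay >= ``cross_family_min_mismatch`` edits from every other mature;
* hairpins built as long foldable stems containing mature and star;
* read profiles drawn to pass or fail the 75%/20% rule on demand;
* genomic placement: SS and NSS loci become intragenic at separate
  configured rates, the rest sit at controlled TSS/TTS offsets;
* target sites complementary to chosen miRNAs planted into transcripts;
* GO terms enriched among SS- or NSS-target genes by construction;
* miRNA/host-gene tissue expression with a configurable concordance.

The planted founder of each conserved family always carries the highest
read count of its family.  Together with the founder separation this makes
greedy founder-linkage clustering recover the planted partition exactly,
so label-recovery tests are sharp rather than probabilistic.

Determinism: one integer seed; each stage derives a child generator from
``(seed, stage_index)``, so stages are individually reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (GeneRecord, MiRNALocus, ReadProfile, revcomp_dna,
                      revcomp_rna, rna_to_dna, write_fasta, write_gff3,
                      write_go_table, write_locus_table,
                      write_expression_matrix)

BASES = np.array(list("ACGU"))


class InfeasibleConfigError(ValueError):
    """The requested repertoire cannot be sampled (e.g. separation too tight)."""


@dataclass(frozen=True)
class SimConfig:
    n_species: int = 5
    n_conserved_families: int = 30
    n_specific_per_species: int = 10
    mature_len_range: tuple[int, int] = (20, 24)
    hairpin_len_range: tuple[int, int] = (80, 200)
    intra_family_max_mismatch: int = 2
    cross_family_min_mismatch: int = 5
    frac_valid_profiles: float = 1.0
    frac_intragenic_ss: float = 0.5
    frac_intragenic_nss: float = 0.2
    au_shift_ss: float = 0.10
    mean_targets_ss: float = 1.6
    mean_targets_nss: float = 2.3
    expression_concordance: float = 0.5
    n_go_terms: int = 30
    n_enriched_terms_ss: int = 2
    n_enriched_terms_nss: int = 1
    n_enriched_terms_both: int = 1
    n_extra_genes_per_species: int = 40
    tss_tts_offset_range: tuple[int, int] = (300, 4000)
    tissues: tuple[str, ...] = ("root", "stem", "leaf", "flower")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.cross_family_min_mismatch <= self.intra_family_max_mismatch:
            raise ValueError("cross_family_min_mismatch must exceed "
                             "intra_family_max_mismatch (separability)")
        for name in ("frac_valid_profiles", "frac_intragenic_ss",
                     "frac_intragenic_nss", "expression_concordance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class PlantedTruth:
    """Per-locus and per-term ground truth of one simulated dataset."""

    family_of: dict[str, str] = field(default_factory=dict)
    label_of: dict[str, str] = field(default_factory=dict)       # locus -> SS/NSS
    family_label: dict[str, str] = field(default_factory=dict)   # family -> SS/NSS
    family_members: dict[str, list[str]] = field(default_factory=dict)
    profile_valid: dict[str, bool] = field(default_factory=dict)
    intragenic: dict[str, bool] = field(default_factory=dict)
    host_gene: dict[str, str | None] = field(default_factory=dict)
    targets: dict[str, list[str]] = field(default_factory=dict)  # locus -> gene ids
    go_class: dict[str, str] = field(default_factory=dict)       # term -> SS/NSS/both/none

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class SimulatedDataset:
    config: SimConfig
    loci: list[MiRNALocus]
    genomes: dict[str, dict[str, str]]          # species -> chrom -> DNA
    genes: dict[str, list[GeneRecord]]          # species -> gene records
    transcripts: dict[str, dict[str, str]]      # species -> transcript id -> RNA
    go_table: dict[str, set[str]]               # gene -> GO terms
    mirna_expression: pd.DataFrame
    gene_expression: pd.DataFrame
    truth: PlantedTruth


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stage])


def _base_probs(au: float) -> np.ndarray:
    return np.array([au / 2, (1 - au) / 2, (1 - au) / 2, au / 2])


def _sample_seq(rng: np.random.Generator, length: int, au: float = 0.5) -> str:
    return "".join(rng.choice(BASES, size=length, p=_base_probs(au)))


def _sample_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=length))


def _substitute(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply n distinct random substitutions (always to a different base)."""
    chars = list(seq)
    for pos in rng.choice(len(chars), size=n_subs, replace=False):
        options = [b for b in "ACGU" if b != chars[pos]]
        chars[pos] = options[rng.integers(0, 3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Hairpins and read profiles
# ---------------------------------------------------------------------------

def simulate_hairpin(mature: str, rng: np.random.Generator,
                     target_len: int = 120, au: float = 0.5) -> tuple[str, str]:
    """Build a foldable hairpin around a mature sequence.

    Layout: 5' stem extension + mature + loop + star + 3' stem extension,
    where the star is the reverse complement of the mature carrying 1-3
    randomized bulge substitutions and the extensions are mutually
    complementary, giving a long continuous stem.  The 2-nt duplex
    overhangs of the biological mature/star duplex are absorbed into the
    loop and extension boundaries.  Returns ``(hairpin, star)``.
    """
    if not 18 <= len(mature) <= 26:
        raise ValueError("mature length must be within 18-26 nt")
    loop_len = int(rng.integers(8, 16))
    ext_len = max(10, (target_len - 2 * len(mature) - loop_len) // 2)
    ext5 = _sample_seq(rng, ext_len, au)
    loop = _sample_seq(rng, loop_len, au)
    n_bulges = int(rng.integers(1, 4))
    star = revcomp_rna(mature)
    # keep bulges off the star ends so the stem stays anchored
    chars = list(star)
    for pos in rng.choice(np.arange(2, len(star) - 2), size=n_bulges, replace=False):
        options = [b for b in "ACGU" if b != chars[pos]]
        chars[pos] = options[rng.integers(0, 3)]
    star = "".join(chars)
    hairpin = ext5 + mature + loop + star + revcomp_rna(ext5)
    return hairpin, star


def simulate_read_profile(valid: bool, rng: np.random.Generator) -> ReadProfile:
    """Draw per-region read counts that pass (or fail) the 75%/20% rule."""
    total = int(rng.integers(50, 500))
    if valid:
        precise = rng.uniform(0.80, 0.98)
        overlap = int(rng.uniform(0.0, 0.15) * total)
        mature = int(precise * total * 0.8)
        star = int(precise * total * 0.2)
    else:
        if rng.random() < 0.5:  # too few precise reads
            precise = rng.uniform(0.30, 0.70)
            mature = int(precise * total * 0.8)
            star = int(precise * total * 0.2)
            overlap = int(rng.uniform(0.0, 0.15) * total)
        else:                   # too many boundary-straddling reads
            precise = rng.uniform(0.80, 0.95)
            mature = int(precise * total * 0.8)
            star = int(precise * total * 0.2)
            overlap = int(np.ceil(0.25 * total))
    return ReadProfile(total_reads=total, mature_reads=mature,
                       star_reads=star, overlap_reads=overlap)


# ---------------------------------------------------------------------------
# Repertoires
# ---------------------------------------------------------------------------

def _min_distance(seq: str, others: list[str]) -> int | None:
    from .families import mature_distance
    if not others:
        return None
    return min(mature_distance(seq, o) for o in others)


def _sample_separated(rng: np.random.Generator, length_range: tuple[int, int],
                      au: float, others: list[str], min_dist: int,
                      max_tries: int = 2000) -> str:
    for _ in range(max_tries):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = _sample_seq(rng, length, au)
        d = _min_distance(seq, others)
        if d is None or d >= min_dist:
            return seq
    raise InfeasibleConfigError(
        f"could not sample a mature >= {min_dist} edits from "
        f"{len(others)} existing sequences; the configuration is too tight")


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one full multi-species dataset with planted truth."""
    truth = PlantedTruth()
    species = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    au_nss = 0.5
    au_ss = min(1.0, 0.5 + config.au_shift_ss)

    rng_fam = _rng(config, 1)
    all_matures: list[str] = []
    loci: list[MiRNALocus] = []

    # conserved (NSS) families: founder + one member per chosen species
    founders: list[str] = []
    for f in range(config.n_conserved_families):
        founder = _sample_separated(rng_fam, config.mature_len_range, au_nss,
                                    founders, config.cross_family_min_mismatch)
        founders.append(founder)
    all_matures.extend(founders)

    fam_specs: list[dict] = []
    for f, founder in enumerate(founders):
        fam_id = f"PF{f + 1:04d}"
        k = int(rng_fam.integers(2, config.n_species + 1))
        members_sp = list(rng_fam.choice(species, size=k, replace=False))
        fam_specs.append({"fam_id": fam_id, "founder": founder,
                          "species": members_sp})
        truth.family_label[fam_id] = "NSS"

    # member matures (founder copy goes to the first species, highest reads)
    for spec in fam_specs:
        member_matures = []
        for j, sp in enumerate(spec["species"]):
            if j == 0:
                member_matures.append(spec["founder"])
            else:
                n_subs = int(rng_fam.integers(0, config.intra_family_max_mismatch + 1))
                member_matures.append(_substitute(rng_fam, spec["founder"], n_subs)
                                      if n_subs else spec["founder"])
        spec["member_matures"] = member_matures
        all_matures.extend(m for m in member_matures if m != spec["founder"])

    # species-specific singleton families
    ss_specs: list[dict] = []
    for sp in species:
        for j in range(config.n_specific_per_species):
            mature = _sample_separated(rng_fam, config.mature_len_range, au_ss,
                                       all_matures, config.cross_family_min_mismatch)
            all_matures.append(mature)
            fam_id = f"PS_{sp}_{j + 1:03d}"
            ss_specs.append({"fam_id": fam_id, "founder": mature, "species": [sp],
                             "member_matures": [mature]})
            truth.family_label[fam_id] = "SS"

    # build loci: hairpins, read profiles, read counts
    rng_hp = _rng(config, 2)
    rng_prof = _rng(config, 3)
    counter = 0
    for spec, label in ([(s, "NSS") for s in fam_specs] + [(s, "SS") for s in ss_specs]):
        au = au_ss if label == "SS" else au_nss
        members = []
        for j, (sp, mature) in enumerate(zip(spec["species"], spec["member_matures"])):
            counter += 1
            locus_id = f"{sp}_mir{counter:05d}"
            target_len = int(rng_hp.integers(*config.hairpin_len_range))
            hairpin, star = simulate_hairpin(mature, rng_hp, target_len, au)
            valid = bool(rng_prof.random() < config.frac_valid_profiles)
            profile = simulate_read_profile(valid, rng_prof)
            loci.append(MiRNALocus(
                locus_id=locus_id, species=sp, mature_seq=mature,
                star_seq=star, hairpin_seq=hairpin,
                read_profile=_with_total_rank(profile, j == 0)))
            members.append(locus_id)
            truth.family_of[locus_id] = spec["fam_id"]
            truth.label_of[locus_id] = label
            truth.profile_valid[locus_id] = valid
        truth.family_members[spec["fam_id"]] = members

    # genomes + gene annotation + placement
    genomes, genes = simulate_genome_annotation(loci, config, _rng(config, 4), truth)

    # transcripts, GO labels, expression
    transcripts, go_table, mirna_expr, gene_expr = simulate_targets_and_go(
        loci, genes, config, _rng(config, 5), truth)

    return SimulatedDataset(config=config, loci=loci, genomes=genomes,
                            genes=genes, transcripts=transcripts,
                            go_table=go_table, mirna_expression=mirna_expr,
                            gene_expression=gene_expr, truth=truth)


def _with_total_rank(profile: ReadProfile, is_founder: bool) -> ReadProfile:
    """Rescale a profile's total reads into the founder/member abundance band.

    The founder factor (16x on a 50-500 base total) puts every founder
    strictly above the member band, so abundance-ranked clustering always
    visits the planted founder first.  Region fractions (and hence 75%/20%
    validity) are preserved exactly by scaling all four counts with one
    integer factor.
    """
    scale = 16 if is_founder else 1
    return ReadProfile(total_reads=profile.total_reads * scale,
                       mature_reads=profile.mature_reads * scale,
                       star_reads=profile.star_reads * scale,
                       overlap_reads=profile.overlap_reads * scale)


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

def simulate_genome_annotation(loci: list[MiRNALocus], config: SimConfig,
                               rng: np.random.Generator,
                               truth: PlantedTruth) -> tuple[dict, dict]:
    """Assemble per-species genomes embedding every hairpin.

    Each locus gets its own block: a gene plus the hairpin either inside
    the gene (intragenic, per-class rate) or at a signed TSS/TTS offset
    drawn from ``tss_tts_offset_range``.  Extra genes without miRNAs pad
    the annotation so downstream backgrounds are non-trivial.  The
    placement coordinates are written back onto the loci (which are
    replaced — records are frozen) and into ``truth``.
    """
    offset_lo, offset_hi = config.tss_tts_offset_range
    genomes: dict[str, dict[str, str]] = {}
    genes: dict[str, list[GeneRecord]] = {}
    by_species: dict[str, list[int]] = {}
    for i, l in enumerate(loci):
        by_species.setdefault(l.species, []).append(i)

    for sp in sorted(by_species):
        parts: list[str] = []
        cursor = 0  # length so far (0-based); 1-based coord of next char = cursor+1
        sp_genes: list[GeneRecord] = []
        chrom = f"{sp}_chr1"  # species-qualified: loci of all species may be pooled

        def emit(seq: str) -> tuple[int, int]:
            nonlocal cursor
            parts.append(seq)
            start = cursor + 1
            cursor += len(seq)
            return start, cursor

        for idx in by_species[sp]:
            locus = loci[idx]
            label = truth.label_of[locus.locus_id]
            frac = config.frac_intragenic_ss if label == "SS" else config.frac_intragenic_nss
            intragenic = bool(rng.random() < frac)
            strand = "+" if rng.random() < 0.5 else "-"
            hp_dna = rna_to_dna(locus.hairpin_seq)
            embedded = hp_dna if strand == "+" else revcomp_dna(hp_dna)
            gene_id = f"{sp}_g{len(sp_genes) + 1:04d}"
            gene_strand = "+" if rng.random() < 0.5 else "-"
            gene_len = int(rng.integers(800, 2000))
            emit(_sample_dna(rng, int(rng.integers(500, 1500))))  # spacer

            if intragenic:
                pad5 = int(rng.integers(50, max(51, gene_len - len(embedded) - 50)))
                g_start, _ = emit(_sample_dna(rng, pad5))
                h_start, h_end = emit(embedded)
                _, g_end = emit(_sample_dna(rng, max(50, gene_len - pad5 - len(embedded))))
                sp_genes.append(GeneRecord(gene_id, chrom, g_start, g_end, gene_strand))
                host = gene_id
            else:
                upstream = bool(rng.random() < 0.5)  # genome-coordinate side
                offset = int(rng.integers(offset_lo, offset_hi + 1))
                if upstream:
                    h_start, h_end = emit(embedded)
                    emit(_sample_dna(rng, offset))
                    g_start, g_end = emit(_sample_dna(rng, gene_len))
                else:
                    g_start, g_end = emit(_sample_dna(rng, gene_len))
                    emit(_sample_dna(rng, offset))
                    h_start, h_end = emit(embedded)
                sp_genes.append(GeneRecord(gene_id, chrom, g_start, g_end, gene_strand))
                host = None
            loci[idx] = dataclasses.replace(locus, chrom=chrom, start=h_start,
                                            end=h_end, strand=strand)
            truth.intragenic[locus.locus_id] = intragenic
            truth.host_gene[locus.locus_id] = host

        for _ in range(config.n_extra_genes_per_species):
            emit(_sample_dna(rng, int(rng.integers(300, 800))))
            g_start, g_end = emit(_sample_dna(rng, int(rng.integers(800, 2000))))
            gene_strand = "+" if rng.random() < 0.5 else "-"
            sp_genes.append(GeneRecord(f"{sp}_g{len(sp_genes) + 1:04d}", chrom,
                                       g_start, g_end, gene_strand))
        emit(_sample_dna(rng, 500))
        genomes[sp] = {chrom: "".join(parts)}
        genes[sp] = sp_genes
    return genomes, genes


# ---------------------------------------------------------------------------
# Transcripts, GO, expression
# ---------------------------------------------------------------------------

def _plant_site(rng: np.random.Generator, mature: str) -> str:
    """A target site (transcript 5'->3') scoring 0 or 0.5 against the miRNA."""
    site = revcomp_rna(mature)  # site position j pairs miRNA position L-1-j
    if rng.random() < 0.5:
        return site
    # one G:U wobble at a non-core miRNA position (>= 14, 1-based)
    L = len(mature)
    wobblable = [p for p in range(14, L + 1) if mature[p - 1] in "GU"]
    if not wobblable:
        return site
    p = int(rng.choice(wobblable))
    j = L - p  # site index pairing miRNA position p (1-based)
    chars = list(site)
    chars[j] = "U" if mature[p - 1] == "G" else "G"
    return "".join(chars)


def simulate_targets_and_go(loci: list[MiRNALocus], genes: dict[str, list[GeneRecord]],
                            config: SimConfig, rng: np.random.Generator,
                            truth: PlantedTruth):
    """Transcripts with planted target sites, GO labels, tissue expression."""
    transcripts: dict[str, dict[str, str]] = {}
    used: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for sp, sp_genes in genes.items():
        transcripts[sp] = {
            g.gene_id: _sample_seq(rng, int(rng.integers(300, 600)))
            for g in sp_genes
        }

    # plant complementary sites
    for locus in loci:
        label = truth.label_of[locus.locus_id]
        mean = config.mean_targets_ss if label == "SS" else config.mean_targets_nss
        k = int(rng.poisson(mean))
        sp_transcripts = transcripts[locus.species]
        tids = sorted(sp_transcripts)
        k = min(k, len(tids))
        chosen = list(rng.choice(tids, size=k, replace=False)) if k else []
        planted = []
        for tid in chosen:
            site = _plant_site(rng, locus.mature_seq)
            seq = sp_transcripts[tid]
            intervals = used.setdefault((locus.species, tid), [])
            pos = _free_position(rng, len(seq), len(site), intervals)
            if pos is None:
                continue
            sp_transcripts[tid] = seq[:pos] + site + seq[pos + len(site):]
            intervals.append((pos, pos + len(site)))
            planted.append(tid)
        truth.targets[locus.locus_id] = planted

    # GO labels: base rate everywhere, planted enrichment among target genes
    terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    go_table: dict[str, set[str]] = {}
    all_genes = [g.gene_id for sp_genes in genes.values() for g in sp_genes]
    for gene in all_genes:
        n = int(rng.integers(1, 5))
        go_table[gene] = set(rng.choice(terms, size=n, replace=False))

    ss_targets = {g for l, gs in truth.targets.items()
                  for g in gs if truth.label_of[l] == "SS"}
    nss_targets = {g for l, gs in truth.targets.items()
                   for g in gs if truth.label_of[l] == "NSS"}
    for term in terms:
        truth.go_class[term] = "none"
    pool = list(terms)
    picks = rng.choice(len(pool),
                       size=(config.n_enriched_terms_ss + config.n_enriched_terms_nss
                             + config.n_enriched_terms_both),
                       replace=False)
    cut1 = config.n_enriched_terms_ss
    cut2 = cut1 + config.n_enriched_terms_nss
    enriched_ss = [pool[i] for i in picks[:cut1]]
    enriched_nss = [pool[i] for i in picks[cut1:cut2]]
    enriched_both = [pool[i] for i in picks[cut2:]]
    for term, gene_sets, cls in (
            [(t, [ss_targets], "SS") for t in enriched_ss]
            + [(t, [nss_targets], "NSS") for t in enriched_nss]
            + [(t, [ss_targets, nss_targets], "both") for t in enriched_both]):
        truth.go_class[term] = cls
        for gene_set in gene_sets:
            for gene in sorted(gene_set):
                if rng.random() < 0.8:
                    go_table[gene].add(term)

    # tissue expression with host concordance
    tissues = list(config.tissues)
    nt = len(tissues)
    mirna_rows, gene_rows = {}, {}
    for locus in loci:
        vec = rng.uniform(1, 5, nt)
        top = int(rng.integers(0, nt))
        vec[top] += 10 + rng.uniform(0, 5)
        mirna_rows[locus.locus_id] = vec
        host = truth.host_gene.get(locus.locus_id)
        if host is not None:
            gvec = rng.uniform(1, 5, nt)
            gtop = top if rng.random() < config.expression_concordance \
                else int(rng.integers(0, nt))
            gvec[gtop] += 10 + rng.uniform(0, 5)
            gene_rows[host] = gvec
    for gene in all_genes:
        if gene not in gene_rows:
            vec = rng.uniform(1, 5, nt)
            vec[int(rng.integers(0, nt))] += 10 + rng.uniform(0, 5)
            gene_rows[gene] = vec

    mirna_expr = pd.DataFrame.from_dict(mirna_rows, orient="index", columns=tissues)
    gene_expr = pd.DataFrame.from_dict(gene_rows, orient="index", columns=tissues)
    return transcripts, go_table, mirna_expr, gene_expr


def _free_position(rng: np.random.Generator, seq_len: int, site_len: int,
                   occupied: list[tuple[int, int]], tries: int = 50) -> int | None:
    for _ in range(tries):
        pos = int(rng.integers(0, seq_len - site_len + 1))
        if all(pos + site_len <= a or pos >= b for a, b in occupied):
            return pos
    return None


# ---------------------------------------------------------------------------
# On-disk form (the same formats core_io reads)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_locus_table(out / "loci.tsv", dataset.loci)
    for sp, chroms in dataset.genomes.items():
        write_fasta(out / f"{sp}.genome.fa", sorted(chroms.items()))
        write_gff3(out / f"{sp}.genes.gff3", dataset.genes[sp])
        write_fasta(out / f"{sp}.transcripts.fa", sorted(dataset.transcripts[sp].items()))
    write_go_table(out / "go.tsv", dataset.go_table)
    write_expression_matrix(out / "mirna_expression.tsv", dataset.mirna_expression)
    write_expression_matrix(out / "gene_expression.tsv", dataset.gene_expression)
    (out / "truth.json").write_text(dataset.truth.to_json())


# ---------------------------------------------------------------------------
# Two-species strategy-divergence fixture
# ---------------------------------------------------------------------------

@dataclass
class StrategyFixture:
    """A two-species fixture exhibiting both homology-caller failure modes.

    ``fn_locus``: a genuinely species-specific locus whose hairpin has a
    silent, highly similar genomic copy in the other species — the
    homology caller labels it conserved (a false negative of SS).
    ``fp_locus``: a locus whose mature is conserved in the other species
    but whose hairpin has diverged below the coverage threshold — the
    homology caller labels it SS (a false positive).  ``control_locus``
    is a clean SS locus both strategies agree on.
    """

    loci: list[MiRNALocus]              # pooled, both species
    genomes: dict[str, dict[str, str]]  # species -> chrom -> DNA
    fn_locus: str
    fp_locus: str
    control_locus: str


def strategy_divergence_fixture(seed: int = 0) -> StrategyFixture:
    rng = np.random.default_rng([seed, 99])
    sp_a, sp_b = "spA", "spB"

    def make_locus(locus_id, species, mature):
        hairpin, star = simulate_hairpin(mature, rng, target_len=120)
        return MiRNALocus(locus_id=locus_id, species=species, mature_seq=mature,
                          star_seq=star, hairpin_seq=hairpin,
                          read_profile=simulate_read_profile(True, rng))

    # three well-separated matures
    matures: list[str] = []
    for _ in range(3):
        matures.append(_sample_separated(rng, (20, 24), 0.5, matures, 6))
    fn = make_locus("spA_fn", sp_a, matures[0])
    fp = make_locus("spA_fp", sp_a, matures[1])
    ctrl = make_locus("spA_ctrl", sp_a, matures[2])

    # spB carries a 1-mismatch homolog of fp's mature in an unrelated hairpin
    b_mature = _substitute(rng, fp.mature_seq, 1)
    b_homolog = make_locus("spB_hom", sp_b, b_mature)

    def assemble(chunks):
        parts, coords, cursor = [], {}, 0
        for name, seq in chunks:
            parts.append(seq)
            if name:
                coords[name] = (cursor + 1, cursor + len(seq))
            cursor += len(seq)
        return "".join(parts), coords

    genome_a, _ = assemble([
        (None, _sample_dna(rng, 5000)),
        ("fn", rna_to_dna(fn.hairpin_seq)),
        (None, _sample_dna(rng, 5000)),
        ("fp", rna_to_dna(fp.hairpin_seq)),
        (None, _sample_dna(rng, 5000)),
        ("ctrl", rna_to_dna(ctrl.hairpin_seq)),
        (None, _sample_dna(rng, 5000)),
    ])
    # silent near-copy (~97% identity) of the fn hairpin in spB
    fn_copy = rna_to_dna(_substitute(rng, fn.hairpin_seq,
                                     max(1, int(0.03 * len(fn.hairpin_seq)))))
    genome_b, _ = assemble([
        (None, _sample_dna(rng, 5000)),
        ("fn_copy", fn_copy),
        (None, _sample_dna(rng, 5000)),
        ("b_hom", rna_to_dna(b_homolog.hairpin_seq)),
        (None, _sample_dna(rng, 5000)),
    ])
    return StrategyFixture(
        loci=[fn, fp, ctrl, b_homolog],
        genomes={sp_a: {"chr1": genome_a}, sp_b: {"chr1": genome_b}},
        fn_locus=fn.locus_id, fp_locus=fp.locus_id, control_locus=ctrl.locus_id)


# ---------------------------------------------------------------------------
# Labeled locus / feature-vector samples for feature studies
# ---------------------------------------------------------------------------

def simulate_labeled_loci(n_per_class: int, config: SimConfig | None = None,
                          seed: int = 0) -> tuple[list[MiRNALocus], list]:
    """Equal-sized SS and NSS locus samples for intrinsic-feature studies.

    Matures, loops and stem extensions of SS loci are sampled with the
    configured AU shift; the weaker A:U pairing shifts the hairpin NMFE
    upward (less stable) as a thermodynamic consequence, so the AU and
    NMFE contrasts are planted by one mechanism.  Returns ``(loci,
    locus-level calls)`` ready for :func:`specmir.features.compute_features`.
    """
    from .specificity import SpecificityCall

    config = config or SimConfig()
    rng = np.random.default_rng([seed, 7])
    au = {"SS": min(1.0, 0.5 + config.au_shift_ss), "NSS": 0.5}
    loci, calls = [], []
    for label in ("SS", "NSS"):
        for i in range(n_per_class):
            L = int(rng.integers(config.mature_len_range[0],
                                 config.mature_len_range[1] + 1))
            mature = _sample_seq(rng, L, au[label])
            target_len = int(rng.integers(*config.hairpin_len_range))
            hairpin, star = simulate_hairpin(mature, rng, target_len, au[label])
            lid = f"{label.lower()}_{i + 1:05d}"
            loci.append(MiRNALocus(locus_id=lid, species="simsp", mature_seq=mature,
                                   star_seq=star, hairpin_seq=hairpin))
            calls.append(SpecificityCall(lid, "locus", label))
    return loci, calls


def simulate_feature_vectors(n_per_class: int, au_mature_shift: float = 0.10,
                             seed: int = 0) -> list:
    """Feature vectors where ONLY au_mature separates the classes.

    All other columns (nmfe, au_hairpin, lengths, first base) are drawn
    iid from the same distributions for both classes, isolating au_mature
    as the single discriminative feature for importance-model checks.
    """
    from .features import FeatureVector

    rng = np.random.default_rng([seed, 8])
    vectors = []
    for label, au_mu in (("SS", 0.5 + au_mature_shift), ("NSS", 0.5)):
        for i in range(n_per_class):
            vectors.append(FeatureVector(
                locus_id=f"{label.lower()}{i}",
                nmfe=float(-np.clip(rng.normal(0.40, 0.08), 0.05, None)),
                au_mature=float(np.clip(rng.normal(au_mu, 0.10), 0, 1)),
                au_hairpin=float(np.clip(rng.normal(0.5, 0.08), 0, 1)),
                first_base=str(rng.choice(list("ACGU"))),
                len_mature=int(rng.integers(20, 25)),
                len_hairpin=int(rng.integers(80, 201)),
                label=label,
            ))
    return vectors
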