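import numpy as np
import pytest
from scipy.special import comb

from specmir.core_io import revcomp_rna
from specmir.targets import (classify_term_overlap, go_enrichment, scan_targets,
                             score_target_site, target_spectrum_stats, TargetHit)

MIR = "UGACAGAAGAGAGUGAGCAC"  # 20 nt


def brute_force_best_site(mirna: str, transcript: str):
    """Independent oracle: enumerate every site and every single-gap
    placement, scoring each duplex with the stated penalty scheme."""
    L, n = len(mirna), len(transcript)

    def duplexes():
        for s in range(n - L + 1):                   # ungapped
            yield mirna, transcript[s:s + L][::-1]
        for s in range(n - L):                       # transcript bulge, interior
            site = transcript[s:s + L + 1][::-1]
            for g in range(1, L):
                yield mirna[:g] + "-" + mirna[g:], site
        for s in range(n - (L - 1) + 1):             # unpaired miRNA base
            site = transcript[s:s + L - 1][::-1]
            for g in range(L):
                yield mirna, site[:g] + "-" + site[g:]

    best = None
    for m_aln, s_aln in duplexes():
        score = score_target_site(m_aln, s_aln)
        if best is None or score < best:
            best = score
    return best


class TestScoreTargetSite:
    def test_perfect_complement_is_zero(self):
        assert score_target_site(MIR, revcomp_rna(MIR)[::-1]) == 0.0

    def test_single_noncore_wobble(self):
        # miRNA position 17 (1-based, outside the 2-13 core) is G; pairing
        # it with U instead of C forms a G:U wobble at half penalty
        site = list(revcomp_rna(MIR)[::-1])
        assert MIR[16] == "G"
        site[16] = "U"
        assert score_target_site(MIR, "".join(site)) == 0.5

    def test_core_mismatch_doubled(self):
        site = list(revcomp_rna(MIR)[::-1])
        pos = 5  # 1-based, inside the 2-13 core
        site[pos - 1] = MIR[pos - 1]  # same base cannot pair
        assert score_target_site(MIR, "".join(site)) == 2.0

    def test_gap_penalties(self):
        site = revcomp_rna(MIR)[::-1]  # column i pairs MIR[i]
        # unpaired miRNA base at position 20 (non-core): plain gap penalty
        assert score_target_site(MIR, site[:19] + "-") == 2.0
        # transcript bulge interrupting the core (before miRNA base 6): doubled
        m_aln = MIR[:5] + "-" + MIR[5:]
        s_aln = site[:5] + "A" + site[5:]
        assert score_target_site(m_aln, s_aln) == 4.0

    def test_expectation_monotone_in_penalties(self):
        site = list(revcomp_rna(MIR)[::-1])
        base = score_target_site(MIR, "".join(site))
        site[0] = MIR[0]
        one = score_target_site(MIR, "".join(site))
        site[14] = MIR[14]
        two = score_target_site(MIR, "".join(site))
        assert base <= one <= two

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            score_target_site("ACGU", "ACG")


class TestScanner:
    def test_exact_reverse_complement_found(self):
        rng = np.random.default_rng(0)
        t = "".join(rng.choice(list("ACGU"), 400))
        t = t[:150] + revcomp_rna(MIR) + t[150 + len(MIR):]
        (hit,) = scan_targets("mir", MIR, {"tx": t})
        assert hit.expectation == 0.0
        assert hit.site_start == 151

    def test_planted_wobble_site(self):
        rng = np.random.default_rng(1)
        site = list(revcomp_rna(MIR))
        # miRNA position 17 is G; its partner sits at site index L-17
        site[len(MIR) - 17] = "U"
        t = "".join(rng.choice(list("ACGU"), 300))
        t = t[:100] + "".join(site) + t[100 + len(MIR):]
        (hit,) = scan_targets("mir", MIR, {"tx": t})
        assert hit.expectation == 0.5

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for i in range(20):
            L = int(rng.integers(19, 23))
            mirna = "".join(rng.choice(list("ACGU"), L))
            t = "".join(rng.choice(list("ACGU"), 160))
            if i % 3 == 0:  # sometimes plant a near-perfect site
                site = revcomp_rna(mirna)
                pos = int(rng.integers(0, len(t) - len(site)))
                t = t[:pos] + site + t[pos + len(site):]
            from specmir.targets import _best_site
            found = _best_site(mirna, t)
            assert found is not None
            assert found[0] == pytest.approx(brute_force_best_site(mirna, t))

    def test_only_best_site_per_transcript(self):
        t = revcomp_rna(MIR) + "AAAA" + revcomp_rna(MIR)
        hits = scan_targets("mir", MIR, {"tx": t})
        assert len(hits) == 1

    def test_threshold_excludes_weak_sites(self):
        site = list(revcomp_rna(MIR)[::-1])
        for pos in (3, 6, 9):  # three core mismatches: expectation 6
            site[pos - 1] = MIR[pos - 1]
        t = "".join(site)[::-1]
        assert scan_targets("mir", MIR, {"tx": t}, expectation_max=3.0) == []
        assert scan_targets("mir", MIR, {"tx": t}, expectation_max=6.0) != []


class TestSpectrumStats:
    def _hits(self, pairs):
        return [TargetHit(m, t, 1, (MIR, revcomp_rna(MIR)[::-1]), 0.0)
                for m, t in pairs]

    def test_all_with_hits_zero_fraction(self):
        from conftest import make_locus
        from specmir.specificity import SpecificityCall
        loci = [make_locus(f"m{i}", f"sp{i % 2}", MIR, seed=i) for i in range(4)]
        calls = [SpecificityCall(l.locus_id, "locus", "SS" if i % 2 else "NSS")
                 for i, l in enumerate(loci)]
        hits = self._hits([(l.locus_id, "tx1") for l in loci])
        res = target_spectrum_stats(hits, calls, loci)
        assert (res["per_species"]["zero_target_frac"] == 0).all()

    def test_fractions_in_unit_interval(self, tiny_dataset):
        from specmir.families import build_conservation_matrix, cluster_families
        from specmir.specificity import call_species_specific_seq
        from specmir.targets import scan_all_targets
        fams = cluster_families(tiny_dataset.loci)
        m = build_conservation_matrix(fams, tiny_dataset.loci)
        calls = [c for c in call_species_specific_seq(m, fams, tiny_dataset.loci)
                 if c.level == "locus"]
        hits = scan_all_targets(tiny_dataset.loci, tiny_dataset.transcripts)
        res = target_spectrum_stats(hits, calls, tiny_dataset.loci)
        fracs = res["per_species"]["zero_target_frac"]
        assert ((fracs >= 0) & (fracs <= 1)).all()

    def test_planted_targets_all_recovered(self, tiny_dataset):
        from specmir.targets import scan_all_targets
        hits = scan_all_targets(tiny_dataset.loci, tiny_dataset.transcripts)
        found = {}
        for h in hits:
            found.setdefault(h.mirna_id, set()).add(h.transcript_id)
        for lid, planted in tiny_dataset.truth.targets.items():
            assert set(planted) <= found.get(lid, set())


def hypergeom_tail(a, fg_total, k, bg_total):
    """Oracle: exhaustive hypergeometric upper tail P(X >= a)."""
    total = comb(bg_total, fg_total, exact=True)
    num = sum(comb(k, x, exact=True) * comb(bg_total - k, fg_total - x, exact=True)
              for x in range(a, min(k, fg_total) + 1))
    return num / total


class TestEnrichment:
    def test_fisher_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            bg_total = int(rng.integers(20, 80))
            fg_total = int(rng.integers(5, bg_total // 2))
            k = int(rng.integers(1, bg_total))
            a = int(rng.integers(max(1, k + fg_total - bg_total),
                                 min(k, fg_total) + 1))
            bg = {f"g{i}" for i in range(bg_total)}
            fg = {f"g{i}" for i in range(fg_total)}
            annotated = ({f"g{i}" for i in range(a)}
                         | {f"g{i}" for i in range(fg_total, fg_total + k - a)})
            table = {g: {"T"} for g in annotated}
            rows = go_enrichment(fg, bg, table, alpha=0.05)
            row = next(r for r in rows if r.term == "T")
            assert row.p == pytest.approx(hypergeom_tail(a, fg_total, k, bg_total),
                                          rel=1e-9)

    def test_saturated_term(self):
        bg = {f"g{i}" for i in range(100)}
        fg = {f"g{i}" for i in range(10)}
        table = {f"g{i}": {"T"} for i in range(50)}
        (row,) = go_enrichment(fg, bg, table)
        assert row.fg_count == 10 and row.bg_count == 50
        assert row.p == pytest.approx(hypergeom_tail(10, 10, 50, 100), rel=1e-9)

    def test_no_signal_not_enriched(self):
        bg = {f"g{i}" for i in range(200)}
        fg = {f"g{i}" for i in range(50)}
        table = {f"g{i}": {"T"} for i in range(0, 200, 4)}  # 25% everywhere
        (row,) = go_enrichment(fg, bg, table)
        assert not row.enriched

    def test_bh_adjustment_closed_form(self):
        # independent check of the BH path: 3 designed tables
        bg = {f"g{i}" for i in range(40)}
        fg = {f"g{i}" for i in range(10)}
        table = {}
        for g in range(8):
            table.setdefault(f"g{g}", set()).add("T1")
        for g in list(range(6)) + [12, 13]:
            table.setdefault(f"g{g}", set()).add("T2")
        for g in list(range(4)) + [14, 15, 16, 17]:
            table.setdefault(f"g{g}", set()).add("T3")
        rows = {r.term: r for r in go_enrichment(fg, bg, table)}
        ps = sorted((r.term, r.p) for r in rows.values())
        ranked = sorted(rows.values(), key=lambda r: r.p)
        m = len(ranked)
        expected = [r.p * m / (i + 1) for i, r in enumerate(ranked)]
        for i in range(m - 2, -1, -1):
            expected[i] = min(expected[i], expected[i + 1])
        for r, e in zip(ranked, expected):
            assert r.adjusted_p == pytest.approx(min(e, 1.0), rel=1e-9)
            assert r.adjusted_p >= r.p

    def test_fg_outside_bg_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            go_enrichment({"a"}, {"b"}, {"a": {"T"}})

    def test_planted_enrichment_recovered(self, tiny_dataset):
        truth = tiny_dataset.truth
        fg = {g for l, gs in truth.targets.items()
              for g in gs if truth.label_of[l] == "SS"}
        bg = set(tiny_dataset.go_table)
        rows = go_enrichment(fg & bg, bg, tiny_dataset.go_table)
        enriched = {r.term for r in rows if r.enriched}
        for term, cls in truth.go_class.items():
            if cls in {"SS", "both"}:
                assert term in enriched


class TestTermOverlap:
    def test_disjoint_sets(self):
        res = classify_term_overlap({"a"}, {"b"})
        assert res["counts"] == {"ss_only": 1, "nss_only": 1, "both": 0, "total": 2}

    def test_identical_sets(self):
        res = classify_term_overlap({"a", "b"}, {"a", "b"})
        assert res["counts"]["both"] == 2 and res["counts"]["total"] == 2

    def test_counts_sum_to_union(self):
        rng = np.random.default_rng(5)
        universe = [f"t{i}" for i in range(30)]
        a = set(rng.choice(universe, 12, replace=False))
        b = set(rng.choice(universe, 9, replace=False))
        res = classify_term_overlap(a, b)
        assert res["counts"]["total"] == len(a | b)
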