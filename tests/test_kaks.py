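import math

import numpy as np
import pytest

from conftest import random_cds
from oracles import ng86_differences, ng86_sites
from wgdkit import kaks
from wgdkit.codonaln import CodonAlignment, align_codons
from wgdkit.kaks import (
    KAPPA_FALLBACK,
    SiteCounts,
    count_sites_ng86,
    estimate_kappa,
    estimates_to_frame,
    kaks_lpb,
    kaks_ng86,
)
from wgdkit.seqio import SENSE_CODONS
from wgdkit.synthio import evolve_pair


def aln_of(nt1, nt2):
    return CodonAlignment("a", "b", nt1, nt2)


class TestCountSitesNG86:
    def test_single_codon_lysine_example(self):
        # AAA: of 8 non-stop changes only AAA->AAG is synonymous
        c = count_sites_ng86(aln_of("AAA", "AAA"))
        assert c.S == pytest.approx(1 / 3)
        assert c.N == pytest.approx(8 / 3)
        assert c.Sd == c.Nd == 0.0

    def test_identical_alignment_no_differences(self, rng):
        cds = random_cds(rng, 30)
        c = count_sites_ng86(aln_of(cds.nt, cds.nt))
        assert c.Sd == c.Nd == 0.0

    def test_random_codon_pairs_match_pathway_oracle(self, rng):
        for _ in range(150):
            c1 = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
            c2 = SENSE_CODONS[rng.integers(len(SENSE_CODONS))]
            got = count_sites_ng86(aln_of(c1, c2))
            sd, nd = ng86_differences(c1, c2)
            assert got.Sd == pytest.approx(sd, abs=1e-12)
            assert got.Nd == pytest.approx(nd, abs=1e-12)
            assert got.S == pytest.approx(
                0.5 * (ng86_sites(c1) + ng86_sites(c2)), abs=1e-12
            )

    def test_counts_additive_over_codon_columns(self, rng):
        c1 = random_cds(rng, 12, "a")
        c2 = random_cds(rng, 12, "b")
        whole = count_sites_ng86(aln_of(c1.nt, c2.nt))
        parts = [
            count_sites_ng86(aln_of(c1.nt[i : i + 3], c2.nt[i : i + 3]))
            for i in range(0, 36, 3)
        ]
        assert whole.S == pytest.approx(sum(p.S for p in parts))
        assert whole.Sd == pytest.approx(sum(p.Sd for p in parts))
        assert whole.Nd == pytest.approx(sum(p.Nd for p in parts))

    def test_site_conservation(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 30))
            c1, c2 = random_cds(rng, n, "a"), random_cds(rng, n, "b")
            c = count_sites_ng86(aln_of(c1.nt, c2.nt))
            assert c.S + c.N == pytest.approx(3 * n, abs=1e-9)

    def test_gapped_columns_dropped(self):
        c = count_sites_ng86(aln_of("ATG---AAA", "ATGGGGAAA"))
        assert c.S + c.N == pytest.approx(6.0)


class TestKaksNG86:
    def test_no_differences_gives_zero_rates_missing_omega(self):
        est = kaks_ng86(SiteCounts(100.0, 200.0, 0.0, 0.0))
        assert est.ka == est.ks == 0.0
        assert est.omega is None
        assert est.status == "ok"

    def test_jukes_cantor_closed_form(self):
        est = kaks_ng86(SiteCounts(100.0, 200.0, 30.0, 0.0))
        # ps = 0.3 -> ks = -0.75 ln(0.6)
        assert est.ks == pytest.approx(-0.75 * math.log(0.6), abs=1e-12)
        assert round(est.ks, 3) == 0.383

    def test_correction_boundary_is_undefined(self):
        est = kaks_ng86(SiteCounts(100.0, 200.0, 75.0, 0.0))
        assert est.status == "undefined"
        assert est.omega is None

    def test_role_swap_invariance(self, rng):
        c1 = random_cds(rng, 40, "a")
        c2 = random_cds(rng, 40, "b")
        e1 = kaks_ng86(count_sites_ng86(aln_of(c1.nt, c2.nt)))
        e2 = kaks_ng86(count_sites_ng86(aln_of(c2.nt, c1.nt)))
        assert e1.ka == pytest.approx(e2.ka)
        assert e1.ks == pytest.approx(e2.ks)


class TestEstimateKappa:
    def test_recovers_k2p_from_constructed_fourfold_counts(self):
        # 100 glycine codons (GGN: third position fourfold); plant 10
        # transitions and 10 transversions at the third position
        base = ["GGT"] * 100
        other = ["GGC"] * 10 + ["GGA"] * 10 + ["GGT"] * 80
        aln = aln_of("".join(base), "".join(other))
        P, Q = 0.10, 0.10
        alpha = -0.5 * math.log(1 - 2 * P - Q) + 0.25 * math.log(1 - 2 * Q)
        beta = -0.25 * math.log(1 - 2 * Q)
        assert estimate_kappa(aln) == pytest.approx(alpha / beta)

    def test_no_fourfold_sites_falls_back(self):
        # AAA/TGG have no fourfold-degenerate positions
        aln = aln_of("AAATGG" * 3, "AAATGG" * 3)
        assert estimate_kappa(aln) == KAPPA_FALLBACK

    def test_recovery_from_simulated_pairs(self, rng):
        # generator kappa = 3; mean K2P estimate within 15% at 500 codons
        anc = random_cds(rng, 500, "anc")
        vals = []
        for s in range(30):
            a, b = evolve_pair(anc, target_ks=0.8, omega=0.2, kappa=3.0, seed=s)
            vals.append(estimate_kappa(align_codons(a, b)))
        assert np.mean(vals) == pytest.approx(3.0, rel=0.15)


class TestKaksLPB:
    def test_identical_sequences_zero(self, rng):
        cds = random_cds(rng, 50)
        est = kaks_lpb(aln_of(cds.nt, cds.nt))
        assert est.ka == 0.0 and est.ks == 0.0
        assert est.status == "ok"

    def test_pure_fourfold_transitions_equal_k2p(self):
        # glycine-only fixture: positions 1+2 are 0-fold, position 3 is
        # 4-fold and L2 = 0, so Ks = A4 + B4 = K2P at the fourfold sites
        s1 = "GGT" * 50
        s2 = "GGC" * 10 + "GGT" * 40  # 10 transitions among 50 fourfold sites
        P = 10 / 50
        k2p = -0.5 * math.log(1 - 2 * P)
        est = kaks_lpb(aln_of(s1, s2), kappa=2.0)
        assert est.ks == pytest.approx(k2p, abs=1e-12)
        assert est.ka == 0.0

    def test_role_swap_invariance(self, rng):
        c1 = random_cds(rng, 60, "a")
        c2 = random_cds(rng, 60, "b")
        e1 = kaks_lpb(aln_of(c1.nt, c2.nt), kappa=2.0)
        e2 = kaks_lpb(aln_of(c2.nt, c1.nt), kappa=2.0)
        if e1.status == "ok":
            assert e1.ka == pytest.approx(e2.ka)
            assert e1.ks == pytest.approx(e2.ks)

    def test_planted_omega_recovery(self, rng):
        # median estimated omega within 20% of planted at 500 codons;
        # simulated without transition bias, where the degeneracy-class
        # and NG86 site normalisations coincide
        anc = random_cds(rng, 500, "anc")
        for target in (0.2, 1.5):
            oms = []
            for s in range(25):
                a, b = evolve_pair(anc, target_ks=0.5, omega=target, kappa=1.0,
                                   seed=1000 + s)
                est = kaks_lpb(align_codons(a, b))
                if est.omega is not None:
                    oms.append(est.omega)
            assert np.median(oms) == pytest.approx(target, rel=0.2)


class TestDivergenceMonotonicity:
    def test_estimated_ks_increases_with_planted_ks(self, rng):
        anc = random_cds(rng, 300, "anc")
        medians = []
        for target in (0.2, 0.6, 1.2):
            vals = []
            for s in range(10):
                a, b = evolve_pair(anc, target, omega=0.1, kappa=2.0, seed=7000 + s)
                est = kaks.estimate_pair(align_codons(a, b), "NG86")
                vals.append(est.ks)
            medians.append(np.median(vals))
        assert medians == sorted(medians)


class TestFrame:
    def test_tsv_layout_and_missing_encoding(self, rng):
        cds = random_cds(rng, 30)
        est = kaks.estimate_pair(aln_of(cds.nt, cds.nt), "NG86")
        df = estimates_to_frame([est])
        assert list(df.columns) == [
            "id_1", "id_2", "method", "S", "N", "Sd", "Nd",
            "kappa", "ka", "ks", "omega", "status",
        ]
        assert np.isnan(df.loc[0, "omega"])  # ks = 0 -> omega missing
        with pytest.raises(ValueError, match="unknown method"):
            kaks.estimate_pair(aln_of(cds.nt, cds.nt), "GY94")
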