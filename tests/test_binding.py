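"""Sequence-level binding: enrichment, energy model, site pairing."""

import numpy as np
import pandas as pd
import pytest

import spliceproof as sp
from spliceproof.binding import VALIDATED_AFFINITY_FLOOR


def small_model(k=4, u_pen=1.0):
    """U-favouring additive model over 4-mers (consensus UUUU)."""
    pen = np.tile([u_pen, u_pen * 0.5, u_pen, 0.0], (k, 1))
    return sp.EnergyModel(penalties=pen)


class TestEnrichment:
    def test_identical_tables_give_unit_enrichment(self):
        t = sp.KmerCountTable(k=4, counts={"AAAA": 50.0, "UUUU": 50.0})
        enr = sp.compute_enrichment(t, t, pseudocount=0.0)
        np.testing.assert_allclose(enr.table["r"], 1.0)

    def test_forced_arithmetic(self):
        inp = sp.KmerCountTable(k=4, counts={"AAAA": 50.0, "UUUU": 50.0})
        ip = sp.KmerCountTable(k=4, counts={"AAAA": 10.0, "UUUU": 90.0}, library_label="ip")
        enr = sp.compute_enrichment(ip, inp, pseudocount=0.0)
        assert enr.r("UUUU") == pytest.approx(1.8)
        assert enr.r("AAAA") == pytest.approx(0.2)

    def test_scale_invariance(self):
        inp = sp.KmerCountTable(k=4, counts={"AAAA": 30.0, "UUUU": 70.0, "ACGU": 10.0})
        ip = sp.KmerCountTable(k=4, counts={"AAAA": 5.0, "UUUU": 100.0, "ACGU": 10.0})
        r1 = sp.compute_enrichment(ip, inp, pseudocount=0.0).table["r"]
        ip10 = sp.KmerCountTable(k=4, counts={k: 10 * v for k, v in ip.counts.items()})
        inp10 = sp.KmerCountTable(k=4, counts={k: 10 * v for k, v in inp.counts.items()})
        r2 = sp.compute_enrichment(ip10, inp10, pseudocount=0.0).table["r"]
        np.testing.assert_allclose(r1, r2)

    def test_k_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sp.compute_enrichment(
                sp.KmerCountTable(k=4, counts={"AAAA": 1.0}),
                sp.KmerCountTable(k=5, counts={"AAAAA": 1.0}),
            )

    def test_significance_flags_planted_enrichment(self):
        rng = np.random.default_rng(0)
        kmers = ["".join(rng.choice(list("ACGU"), 4)) for _ in range(50)]
        kmers = sorted(set(kmers))
        inp = sp.KmerCountTable(k=4, counts={km: 200.0 for km in kmers})
        ip_counts = {km: 200.0 for km in kmers}
        ip_counts[kmers[0]] = 600.0  # strongly enriched
        ip = sp.KmerCountTable(k=4, counts=ip_counts)
        enr = sp.compute_enrichment(ip, inp)
        assert kmers[0] in enr.significant_kmers()

    def test_uridine_count_predicts_enrichment_on_simulated_pool(self):
        # a U-favouring model must produce monotone median R in the number of
        # uridines, the dominant trend in the selected pools
        model = small_model()
        pool, ip = sp.simulate_rbns_reads(model, conc=20.0, n_reads=4000, read_len=20, seed=1)
        enr = sp.compute_enrichment(
            sp.KmerCountTable.from_reads(ip, 4, "ip"),
            sp.KmerCountTable.from_reads(pool, 4, "input"),
        )
        tab = enr.table.assign(n_u=enr.table["kmer"].str.count("U"))
        med = tab.groupby("n_u")["r"].median()
        assert np.all(np.diff(med.to_numpy()) > 0)


class TestAgPositionalPreference:
    def _uniform_table(self, k=4):
        from itertools import product

        kmers = ["".join(p) for p in product("ACGU", repeat=k)]
        return sp.EnrichmentTable(
            k=k,
            table=pd.DataFrame(
                {"kmer": kmers, "r": 1.0, "pvalue": 1.0, "qvalue": 1.0, "significant": False}
            ),
        )

    def test_uniform_enrichment_gives_unit_ratios(self):
        res = sp.ag_positional_preference(self._uniform_table())
        np.testing.assert_allclose(res["mean_ratio"], 1.0)

    def test_terminal_ag_bonus_detected_only_at_the_3prime_end(self):
        from itertools import product

        k = 6
        model = sp.u2af_like_model(k=k, ag_bonus=2.0)
        kmers = ["".join(p) for p in product("ACGU", repeat=k)]
        r = [model.relative_affinity(km) for km in kmers]
        enr = sp.EnrichmentTable(
            k=k,
            table=pd.DataFrame(
                {"kmer": kmers, "r": r, "pvalue": 1.0, "qvalue": 1.0, "significant": False}
            ),
        )
        res = sp.ag_positional_preference(enr).set_index("position")["mean_ratio"]
        assert res.loc[k - 2] > 1.5  # AG in the terminal dinucleotide position
        assert np.all(res.drop(index=k - 2) < 1.2)

    def test_swapping_ag_and_ga_inverts_the_ratio(self):
        def table(r_ag, r_ga):
            return sp.EnrichmentTable(
                k=4,
                table=pd.DataFrame(
                    {
                        "kmer": ["CAGC", "CGAC"],  # AG/GA pair at position 1, no other AG or GA
                        "r": [r_ag, r_ga],
                        "pvalue": 1.0,
                        "qvalue": 1.0,
                        "significant": False,
                    }
                ),
            )

        fwd = sp.ag_positional_preference(table(2.0, 1.0)).set_index("position")["mean_ratio"]
        rev = sp.ag_positional_preference(table(1.0, 2.0)).set_index("position")["mean_ratio"]
        assert fwd.loc[1] == pytest.approx(1.0 / rev.loc[1])

    def test_no_pairs_error(self):
        empty = sp.EnrichmentTable(
            k=4,
            table=pd.DataFrame(
                {"kmer": ["CCCC"], "r": [1.0], "pvalue": [1.0], "qvalue": [1.0], "significant": [False]}
            ),
        )
        with pytest.raises(ValueError):
            sp.ag_positional_preference(empty)


class TestScoreSequence:
    def test_consensus_scores_one(self):
        model = sp.u2af_like_model()
        assert model.relative_affinity(model.consensus) == pytest.approx(1.0)

    def test_penalty_definition(self):
        model = small_model(k=4, u_pen=np.log(100) / 4)
        # AAAA carries four full penalties summing to ln(100)
        assert model.relative_affinity("AAAA") == pytest.approx(0.01, rel=1e-9)

    def test_embedded_consensus_is_located(self):
        model = sp.u2af_like_model()
        rng = np.random.default_rng(3)
        flank1 = "".join(rng.choice(list("ACG"), 20))  # U-free flanks score poorly
        flank2 = "".join(rng.choice(list("ACG"), 18))
        seq = flank1 + model.consensus + flank2
        scores = sp.score_sequence(model, seq)
        assert scores.best_start == 20
        assert scores.best_kmer == model.consensus
        assert scores.best_affinity == pytest.approx(1.0)

    def test_translation_consistency(self):
        model = small_model()
        window = "UUCU"
        embedded = sp.score_sequence(model, "AAAA" + window + "GGGG")
        assert embedded.affinities[4] == pytest.approx(model.relative_affinity(window))

    def test_dna_alphabet_mapped(self):
        model = small_model()
        assert sp.score_sequence(model, "TTTT").best_affinity == pytest.approx(1.0)

    def test_input_validation(self):
        model = small_model()
        with pytest.raises(ValueError):
            sp.score_sequence(model, "UU")
        with pytest.raises(ValueError):
            sp.score_sequence(model, "UUNXUU")

    def test_json_round_trip(self, tmp_path):
        model = sp.u2af_like_model()
        path = tmp_path / "model.json"
        model.to_json(path)
        back = sp.EnergyModel.from_json(path)
        np.testing.assert_allclose(back.penalties, model.penalties)


class TestDdgBetweenSites:
    def test_equal_affinities(self):
        assert sp.ddg_between_sites(0.5, 0.5).ddG == pytest.approx(0.0)

    def test_e_fold_affinity_is_one_rt(self):
        pair = sp.ddg_between_sites(0.2, 0.2 * np.e)
        assert pair.ddG == pytest.approx(1.0, rel=1e-12)  # S3 tighter by one RT

    def test_antisymmetric_under_swap(self):
        a = sp.ddg_between_sites(0.3, 0.7).ddG
        b = sp.ddg_between_sites(0.7, 0.3).ddG
        assert a == pytest.approx(-b)

    def test_round_trip_to_boltzmann_squared_discrimination(self):
        # at vanishing Kf, Ks the PSI of the pair is the two-site Boltzmann
        # occupancy ratio with the exponent doubled (both checkpoints read it)
        a2, a3 = 0.2, 0.5
        pair = sp.ddg_between_sites(a2, a3)
        expected = a3**2 / (a3**2 + a2**2)
        assert sp.psi_full_proofreading(pair.ddG) == pytest.approx(expected, rel=1e-12)

    def test_invalid_affinity(self):
        with pytest.raises(ValueError):
            sp.ddg_between_sites(0.0, 0.5)


class TestFindDownstreamCompetitor:
    def mk(self, start, end, strand="+", aff=0.5, name="site", chrom="tx1"):
        return sp.BindingSiteRecord(
            chrom=chrom, start=start, end=end, strand=strand, relative_affinity=aff, name=name
        )

    def test_no_candidate_in_window(self):
        site = self.mk(100, 112, name="3ss")
        assert sp.find_downstream_competitor(site, [self.mk(300, 312)]) is None

    def test_nearest_rule(self):
        site = self.mk(100, 112, name="3ss", aff=0.8)
        near = self.mk(132, 144, name="plus20", aff=0.4)
        far = self.mk(152, 164, name="plus40", aff=0.4)
        pair = sp.find_downstream_competitor(site, [far, near])
        assert pair is not None and pair.label_s2 == "plus20"
        assert pair.ddG == pytest.approx(np.log(0.8 / 0.4))

    def test_negative_strand_mirrors_positive(self):
        plus = sp.find_downstream_competitor(
            self.mk(100, 112, aff=0.8), [self.mk(132, 144, aff=0.4)]
        )
        minus = sp.find_downstream_competitor(
            self.mk(132, 144, strand="-", aff=0.8), [self.mk(100, 112, strand="-", aff=0.4)]
        )
        assert minus is not None and minus.ddG == pytest.approx(plus.ddG)

    def test_affinity_floor_excludes_unvalidated_sites(self):
        site = self.mk(100, 112, aff=0.9)
        weak = self.mk(132, 144, aff=VALIDATED_AFFINITY_FLOOR / 10)
        assert sp.find_downstream_competitor(site, [weak]) is None

    def test_matches_brute_force_window_scan(self):
        rng = np.random.default_rng(5)
        sites = [
            self.mk(int(s), int(s) + 12, aff=float(a), name=f"c{i}")
            for i, (s, a) in enumerate(zip(rng.integers(0, 400, 40), rng.uniform(0.01, 1, 40)))
        ]
        anchor = self.mk(200, 212, aff=0.7, name="3ss")
        got = sp.find_downstream_competitor(anchor, sites)
        valid = [
            c
            for c in sites
            if 10 <= c.start - anchor.end <= 50 and c.relative_affinity >= 1e-3
        ]
        if not valid:
            assert got is None
        else:
            best = min(valid, key=lambda c: c.start - anchor.end)
            assert got is not None and got.label_s2 == best.name
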