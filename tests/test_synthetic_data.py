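"""Simulator: reference generation, variant planting, count sampling,
recovery evaluation."""

import numpy as np
import pytest

import linediff as ld
from linediff.io_formats import write_fasta, write_gff3
from linediff.synthetic_data import CODON_TABLE, Genotypes, plant_variants


class TestGenerateReference:
    def test_deterministic_under_seed(self, tmp_path):
        cfg = ld.SimConfig(seed=1)
        ref1, models1 = ld.generate_reference(cfg)
        ref2, models2 = ld.generate_reference(cfg)
        assert ref1 == ref2 and models1 == models2
        a, b = tmp_path / "a", tmp_path / "b"
        for d, (r, m) in ((a, (ref1, models1)), (b, (ref2, models2))):
            d.mkdir()
            write_fasta(r, d / "ref.fa")
            write_gff3(m, d / "models.gff3")
        assert (a / "ref.fa").read_bytes() == (b / "ref.fa").read_bytes()
        assert (a / "models.gff3").read_bytes() == (b / "models.gff3").read_bytes()

    def test_every_cds_translates_cleanly(self):
        """Translate-and-scan oracle: ATG start, stop only at terminus."""
        from linediff.consequence import cds_sequence
        for seed in (0, 1, 2):
            ref, models = ld.generate_reference(ld.SimConfig(seed=seed))
            assert models
            for m in models:
                cds = cds_sequence(m, ref)
                assert len(cds) % 3 == 0
                codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
                aas = [CODON_TABLE[c] for c in codons]
                assert codons[0] == "ATG"
                assert aas[-1] == "."
                assert "." not in aas[:-1]

    def test_zero_genes(self):
        ref, models = ld.generate_reference(ld.SimConfig(seed=0, n_genes=0))
        assert len(ref) == 2 and models == []

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            ld.generate_reference(ld.SimConfig(seed=0, contig_length=5000,
                                               n_genes=20))

    def test_gc_fraction_respected(self):
        ref, _ = ld.generate_reference(ld.SimConfig(seed=0, n_genes=0,
                                                    gc_fraction=0.6))
        seq = "".join(ref.values())
        gc = sum(b in "GC" for b in seq) / len(seq)
        assert gc == pytest.approx(0.6, abs=0.01)


class TestPlantVariants:
    def test_fixed_case_only_genotypes(self):
        cfg = ld.SimConfig(seed=2)
        ref, models = ld.generate_reference(cfg)
        truth, geno = plant_variants(ref, models, cfg)
        case_only = [i for i, t in enumerate(truth)
                     if t.line_specificity == "case_only"]
        assert len(case_only) == cfg.n_case_only
        assert np.all(geno.case[case_only] == 2)
        assert np.all(geno.control[case_only] == 0)

    def test_shared_frequency_binomial(self):
        cfg = ld.SimConfig(seed=3, n_shared=200, n_case_only=0, n_control_only=0)
        ref, models = ld.generate_reference(cfg)
        truth, geno = plant_variants(ref, models, cfg)
        mean_freq = geno.case.mean() / 2
        # Binomial(2*pool*200, 0.5): SE ~ 0.008
        assert mean_freq == pytest.approx(0.5, abs=0.03)

    def test_planted_coding_variants_change_protein(self):
        cfg = ld.SimConfig(seed=4)
        ref, models = ld.generate_reference(cfg)
        truth, _ = plant_variants(ref, models, cfg)
        coding = [t for t in truth if t.impact != "noncoding"]
        assert coding
        assert all(t.impact in {"non_synonymous", "nonsense", "no_start",
                                "frameshift"} for t in coding)

    def test_truth_impact_by_direct_translation(self):
        """A planted CAA->TAA first-position change is truth-labelled
        nonsense by the simulator's own codon table."""
        from linediff.synthetic_data import _truth_impact_substitution
        cds = "ATG" + "CAA" + "TAA"
        assert _truth_impact_substitution(cds, 4, "T") == "nonsense"
        assert _truth_impact_substitution(cds, 6, "G") == "synonymous"
        assert _truth_impact_substitution(cds, 2, "A") == "no_start"

    def test_infeasible_coding_demand_rejected(self):
        cfg = ld.SimConfig(seed=0, n_genes=1, n_shared=4000, n_case_only=0,
                           n_control_only=0, coding_fraction=1.0)
        ref, models = ld.generate_reference(cfg)
        with pytest.raises(ValueError, match="CDS space"):
            plant_variants(ref, models, cfg)


class TestSimulateCounts:
    def test_noiseless_fixed_variant_reads_all_alt(self):
        cfg = ld.SimConfig(seed=5, error_rate=0.0, depth_mean=20)
        study = ld.simulate_study(cfg)
        by_pos = study.counts_by_pos("case")
        for t in study.truth:
            if t.line_specificity != "case_only" or t.variant_type != "substitution":
                continue
            c = by_pos.get(t.key)
            if c is None:
                continue
            assert c.base_count(t.alt) == c.depth

    def test_mean_rate_matches_planted_frequency(self):
        """Across 1000 replicate sites at frequency f (error 0), the mean
        observed rate is within 3 standard errors of f."""
        f = 0.7
        cfg = ld.SimConfig(seed=6, pool_size=10, depth_mean=30, error_rate=0.0)
        rng = np.random.default_rng(99)
        truth = [
            ld.TruthRecord(contig="c1", pos=i + 1, ref="C", alt="T",
                           variant_type="substitution", line_specificity="shared",
                           allele_freq_case=f, allele_freq_control=f,
                           impact="noncoding")
            for i in range(1000)
        ]
        geno = rng.binomial(2, f, size=(1000, cfg.pool_size))
        counts = ld.simulate_counts(truth, geno, cfg, rng)
        rates = [ld.snp_rate(c) for c in counts if c.depth > 0]
        # sites share genotype draws, so SE includes the genotype level too
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert np.mean(rates) == pytest.approx(f, abs=3 * max(se, 0.01))

    def test_sparse_depth_yields_no_calls(self):
        cfg = ld.SimConfig(seed=7, depth_mean=0.01)
        study = ld.simulate_study(cfg)
        calls = ld.call_all_sites(study.case_counts)
        assert len(study.case_counts) < 20  # most sites uncovered
        assert len(calls) <= len(study.case_counts)


class TestEvaluateRecovery:
    def test_perfect_run_scores_unity(self, noiseless_study):
        res = ld.run_discovery(
            noiseless_study.case_counts, noiseless_study.control_counts,
            noiseless_study.reference, noiseless_study.models,
        )
        rep = ld.evaluate_recovery(res.markers, noiseless_study.truth,
                                   noiseless_study.counts_by_pos("case"))
        assert rep.precision == 1.0 and rep.recall == 1.0

    def test_shared_contamination_lowers_precision(self, noiseless_study):
        markers = ld.run_discovery(
            noiseless_study.case_counts, noiseless_study.control_counts,
            noiseless_study.reference, noiseless_study.models,
        ).markers
        shared = next(t for t in noiseless_study.truth
                      if t.line_specificity == "shared")
        fake = ld.MarkerSNP(
            contig=shared.contig, chrom="1", pos=shared.pos, ref_base="C",
            called_base="T", impact=ld.Impact.NON_SYNONYMOUS, snp_rate=0.9,
            gene_symbol="X", dna_change=".", aa_change=".", depth=10,
            counts=ld.SiteCounts(contig=shared.contig, pos=shared.pos,
                                 ref_base="C", count_t=9, count_c=1, depth=10),
        )
        rep = ld.evaluate_recovery(list(markers) + [fake], noiseless_study.truth,
                                   noiseless_study.counts_by_pos("case"))
        assert rep.precision < 1.0
        assert (shared.contig, shared.pos) in rep.false_positives

    def test_confusion_diagonal_on_noiseless_run(self, noiseless_study):
        res = ld.run_discovery(
            noiseless_study.case_counts, noiseless_study.control_counts,
            noiseless_study.reference, noiseless_study.models,
        )
        rep = ld.evaluate_recovery(res.markers, noiseless_study.truth,
                                   noiseless_study.counts_by_pos("case"))
        assert all(t == c for t, c in rep.confusion)


class TestEndToEndInvariants:
    def test_fixed_shared_variants_never_in_unique_set(self):
        """Variants fixed in both pools are always subtracted (deep,
        noiseless libraries, several seeds)."""
        for seed in (1, 2, 3):
            study = ld.simulate_study(
                ld.SimConfig(seed=seed, depth_mean=20, error_rate=0.0,
                             shared_allele_freq=1.0)
            )
            res = ld.run_discovery(study.case_counts, study.control_counts,
                                   study.reference, study.models)
            shared = {t.key for t in study.truth
                      if t.line_specificity == "shared"}
            reported = {(m.contig, m.pos) for m in res.markers}
            assert not shared & reported

    def test_panel_simulation_matches_truth_frequencies(self, small_study):
        panel = ld.simulate_panel(small_study.truth, small_study.config,
                                  rng=np.random.default_rng(5))
        from linediff.validation_panel import tally_line
        by_key = {}
        for o in panel:
            by_key.setdefault((o.contig, o.pos, o.line_label), []).append(o)
        for t in small_study.truth[:30]:
            if t.variant_type != "substitution":
                continue
            obs = by_key[(t.contig, t.pos, "SL")]
            ref_n, alt_n, _ = tally_line(obs, t.ref, t.alt)
            freq = alt_n / (ref_n + alt_n)
            assert freq == pytest.approx(t.allele_freq_case, abs=0.2)
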