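import math

import numpy as np
import pandas as pd
import pytest

from polyhybrid.cnv import (
    allelic_cnv_call,
    allelic_thresholds,
    call_allelic_cnvs,
    call_gene_cnvs,
    cnv_subgenome_summary,
    cnv_thresholds,
    detect_allele_loss,
    gene_cnv_call,
    segment_cnv,
)
from polyhybrid.config import GENOTYPES, CnvEvent, SimulationConfig, VarietySpec
from polyhybrid.quantify import gpm
from polyhybrid.simulate import catalog_agps, simulate_all


class TestThresholds:
    def test_band_is_expected_plus_minus_one(self):
        """For any B the gain/loss bounds are log2(B/C) +/- 1 (2-fold band)."""
        for b in (1 / 3, 1 / 2, 2 / 3, 0.9):
            gain, loss = cnv_thresholds(b)
            expected = math.log2(b / 0.5)
            assert gain == pytest.approx(expected + 1.0)
            assert loss == pytest.approx(expected - 1.0)

    @pytest.mark.parametrize(
        "name, upper, lower",
        [
            ("2nRC", math.log10(2), math.log10(0.5)),
            ("2nCR", math.log10(2), math.log10(0.5)),
            ("3nR2C", math.log10(4), math.log10(1)),
            ("3nCR2", math.log10(4), math.log10(1)),
            ("3nC2R", math.log10(1), math.log10(0.25)),
            ("3nRC2", math.log10(1), math.log10(0.25)),
        ],
    )
    def test_published_allelic_bounds_reproduced_exactly(self, name, upper, lower):
        got_upper, got_lower = allelic_thresholds(GENOTYPES[name])
        assert got_upper == pytest.approx(upper, abs=1e-12)
        assert got_lower == pytest.approx(lower, abs=1e-12)

    def test_gene_band_implies_allelic_bounds(self):
        """The gene-level 2-fold band around log2(B_R/B_C) reproduces each
        genotype's allelic bounds when mapped to the log10 scale."""
        for g in GENOTYPES.values():
            expected = g.allelic_ratio("R") / g.allelic_ratio("C")
            upper, lower = allelic_thresholds(g)
            assert upper == pytest.approx(math.log10(2 * expected))
            assert lower == pytest.approx(math.log10(expected / 2))


class TestGeneCnvCall:
    def test_f1_balanced_is_none(self):
        call = gene_cnv_call(100.0, 100.0, GENOTYPES["2nRC"], "R")
        assert call.call == "none"
        assert call.log2_ratio == pytest.approx(0.0, abs=0.01)
        assert call.expected_log2 == pytest.approx(0.0)

    def test_triploid_expected_dosage_is_none(self):
        # 3nR2C allele R (B=2/3): ratio exactly 4/3 sits at the expectation
        call = gene_cnv_call(400.0, 300.0, GENOTYPES["3nR2C"], "R")
        assert call.call == "none"
        assert call.expected_log2 == pytest.approx(math.log2(4 / 3))

    def test_absent_allele_rejected(self):
        from polyhybrid.config import ConfigError, GenotypeSpec

        rr_like = GenotypeSpec("2nR2", 2, 0, "R")
        with pytest.raises(ValueError):
            gene_cnv_call(10.0, 10.0, rr_like, "C")

    def test_negative_gpm_rejected(self):
        with pytest.raises(ValueError):
            gene_cnv_call(-1.0, 10.0, GENOTYPES["2nRC"], "R")

    @pytest.mark.parametrize("genotype", list(GENOTYPES.values()))
    @pytest.mark.parametrize("allele", ["R", "C"])
    @pytest.mark.parametrize("copies", [0, 1, 2, 3, 4])
    def test_oracle_equivalence_on_integer_copies(self, genotype, allele, copies):
        """Noise-free calls match a direct integer copy-number comparator.

        With GPM constructed from the dosage model
        (gpm_h = gpm_m * (B/C) * copies / expected_copies), the call must be
        gain iff fold > 2, loss iff fold < 0.5 (strict; boundary folds stay
        'none' because the pseudocount pulls ratios toward zero).
        """
        expected_copies = genotype.copies(allele)
        if expected_copies == 0:
            return
        b = genotype.allelic_ratio(allele)
        gpm_m = 100.0
        gpm_h = gpm_m * (b / 0.5) * copies / expected_copies
        call = gene_cnv_call(gpm_h, gpm_m, genotype, allele)
        fold = copies / expected_copies
        oracle = "gain" if fold > 2 else ("loss" if fold < 0.5 else "none")
        assert call.call == oracle


class TestAllelicCnvCall:
    def test_f1_balanced_none(self):
        call = allelic_cnv_call(100.0, 100.0, 100.0, 100.0, GENOTYPES["2nRC"])
        assert call.call == "none"
        assert call.log10_ratio == pytest.approx(0.0, abs=0.01)

    def test_triploid_c_loss_crosses_upper_bound(self):
        """3nRC2 expects R:C = 1:2 (upper bound log10(1) = 0); a C-allele loss
        making the observed ratio 1:1 pushes the statistic above 0."""
        upper, lower = allelic_thresholds(GENOTYPES["3nRC2"])
        assert upper == pytest.approx(0.0, abs=1e-12)
        # no-CNV sample sits below the bound
        ok = allelic_cnv_call(100.0, 200.0, 100.0, 100.0, GENOTYPES["3nRC2"])
        assert ok.call == "none"
        # C loss: observed hybrid ratio 1:1 -> statistic ~ 0+, must cross
        lost = allelic_cnv_call(100.0, 33.0, 100.0, 100.0, GENOTYPES["3nRC2"])
        assert lost.log10_ratio > 0
        assert lost.call == "R_gain_or_C_loss"

    def test_both_alleles_zero_undetermined(self):
        call = allelic_cnv_call(0.0, 0.0, 100.0, 100.0, GENOTYPES["2nRC"])
        assert call.call == "undetermined"
        assert math.isnan(call.log10_ratio)

    def test_no_event_triploids_low_false_positive_rate(self):
        cfg = SimulationConfig(
            seed=31, n_chromosomes=2, genes_per_chromosome=100, agp_fraction=1.0,
            varieties=(
                VarietySpec("3nR2C", 2, 1, "R", 3),
                VarietySpec("3nRC2", 1, 2, "C", 3),
            ),
            sequencing_depth=1e6,
        )
        ds = simulate_all(cfg)
        g = gpm(ds.genomic_counts, ds.catalog["length_bp"]).values
        m = gpm(ds.mixed_control.to_frame(), ds.catalog["length_bp"]).values.iloc[:, 0]
        calls = call_allelic_cnvs(g, m, catalog_agps(ds.catalog), ds.metadata)
        fp = calls["call"].isin(["R_gain_or_C_loss", "C_gain_or_R_loss"]).mean()
        assert fp <= 0.05


@pytest.fixture(scope="module")
def planted():
    events = [
        CnvEvent("3nR2C", 0, 1, 5, 25, "C", -1),   # 20-gene loss run
        CnvEvent("2nRC", 1, 2, 10, 20, "R", 2),    # 10-gene dup run (1->3)
    ]
    for i in range(10):  # scattered single-gene events
        events.append(CnvEvent("3nRC2", 1, 1, 30 + i, 31 + i, "R", -1))
    cfg = SimulationConfig(
        seed=33, n_chromosomes=2, genes_per_chromosome=60, agp_fraction=0.9,
        varieties=(
            VarietySpec("2nRC", 1, 1, "R", 2),
            VarietySpec("3nR2C", 2, 1, "R", 2),
            VarietySpec("3nRC2", 1, 2, "C", 2),
        ),
        sequencing_depth=1e6,
        cnv_events=tuple(events),
    )
    ds = simulate_all(cfg)
    g = gpm(ds.genomic_counts, ds.catalog["length_bp"]).values
    m = gpm(ds.mixed_control.to_frame(), ds.catalog["length_bp"]).values.iloc[:, 0]
    calls = call_gene_cnvs(g, m, ds.metadata, ds.catalog)
    return ds, g, calls


class TestPlantedRecovery:
    def test_gene_level_precision_recall(self, planted):
        ds, _, calls = planted
        truth = ds.truth.cnv_gene_sample_pairs(ds.catalog)
        called = calls[calls["call"] != "none"]
        found = set(zip(called["gene"], called["sample"]))
        tp = len(found & truth)
        assert tp / len(found) >= 0.95
        assert tp / len(truth) >= 0.95

    def test_call_signs_match_planted_deltas(self, planted):
        ds, _, calls = planted
        indexed = calls.set_index(["gene", "sample"])["call"]
        assert indexed.loc[("C01g0005", "3nR2C-1")] == "loss"
        assert indexed.loc[("R02g0010", "2nRC-2")] == "gain"

    def test_segments_recovered(self, planted):
        ds, _, calls = planted
        segments, _ = segment_cnv(calls, ds.catalog, min_run=10)
        runs = {(s.chromosome, s.sample, s.call): s for s in segments}
        loss = runs[("C01", "3nR2C-1", "loss")]
        assert (loss.start, loss.end, loss.n_genes) == (5, 25, 20)
        gain = runs[("R02", "2nRC-2", "gain")]
        assert (gain.start, gain.end, gain.n_genes) == (10, 20, 10)

    def test_allele_loss_detection(self, planted):
        ds, g, _ = planted
        losses = detect_allele_loss(ds.genomic_counts, g, ds.metadata, ds.catalog)
        truth = {(r["gene"], r["sample"]) for r in ds.truth.lost_alleles}
        found = {
            (losses.index[i], losses.columns[j])
            for i, j in zip(*np.where(losses.to_numpy()))
        }
        tp = len(found & truth)
        assert tp / len(found) >= 0.95
        assert tp / len(truth) >= 0.95

    def test_no_losses_called_in_f1(self, planted):
        ds, g, _ = planted
        losses = detect_allele_loss(ds.genomic_counts, g, ds.metadata, ds.catalog)
        f1_cols = [c for c in losses.columns if c.startswith("2nRC")]
        assert losses[f1_cols].to_numpy().sum() == 0


class TestAlleleLossBasics:
    def _setup(self):
        catalog = pd.DataFrame(
            {"subgenome": ["R", "R"], "chrom": ["R01", "R01"],
             "pos_index": [0, 1], "length_bp": [1000, 1000],
             "agp_partner": ["", ""]},
            index=["gA", "gB"],
        )
        metadata = pd.DataFrame(
            {"variety": ["v"] * 4, "r_copies": [1] * 4, "c_copies": [1] * 4,
             "mito_origin": ["R"] * 4},
            index=[f"s{i}" for i in range(4)],
        )
        return catalog, metadata

    def test_zero_reads_with_covered_cohort_is_loss(self):
        catalog, metadata = self._setup()
        counts = pd.DataFrame(
            [[0, 500, 500, 500], [480, 510, 490, 505]],
            index=catalog.index, columns=metadata.index,
        )
        gpm_values = gpm(counts, catalog["length_bp"]).values
        lost = detect_allele_loss(counts, gpm_values, metadata, catalog)
        assert bool(lost.loc["gA", "s0"])
        assert not lost.drop(columns="s0").to_numpy().any()

    def test_expected_depth_not_loss(self):
        catalog, metadata = self._setup()
        counts = pd.DataFrame(
            [[500, 500, 500, 500], [500, 500, 500, 500]],
            index=catalog.index, columns=metadata.index,
        )
        gpm_values = gpm(counts, catalog["length_bp"]).values
        lost = detect_allele_loss(counts, gpm_values, metadata, catalog)
        assert not lost.to_numpy().any()


class TestSegments:
    def _calls(self, call_seq, chrom="R01", sample="s1"):
        catalog = pd.DataFrame(
            {
                "subgenome": ["R"] * len(call_seq),
                "chrom": [chrom] * len(call_seq),
                "pos_index": range(len(call_seq)),
                "length_bp": [1000] * len(call_seq),
                "agp_partner": [""] * len(call_seq),
            },
            index=[f"{chrom}g{i:04d}" for i in range(len(call_seq))],
        )
        calls = pd.DataFrame(
            {"gene": catalog.index, "sample": sample, "call": call_seq}
        )
        return calls, catalog

    def test_planted_92_gene_run(self):
        seq = ["none"] * 3 + ["loss"] * 92 + ["none"] * 5
        calls, catalog = self._calls(seq)
        segments, _ = segment_cnv(calls, catalog, min_run=10)
        assert len(segments) == 1
        seg = segments[0]
        assert (seg.start, seg.end, seg.n_genes, seg.call) == (3, 95, 92, "loss")

    def test_alternating_calls_yield_no_segment(self):
        seq = ["gain", "none"] * 20
        calls, catalog = self._calls(seq)
        segments, short = segment_cnv(calls, catalog, min_run=10)
        assert segments == []
        assert all(s.n_genes == 1 for s in short)

    def test_whole_chromosome_event(self):
        seq = ["loss"] * 40
        calls, catalog = self._calls(seq)
        segments, _ = segment_cnv(calls, catalog, min_run=10)
        assert len(segments) == 1
        assert segments[0].n_genes == 40
        assert (segments[0].start, segments[0].end) == (0, 40)

    def test_n_genes_equals_end_minus_start(self):
        seq = ["none"] * 2 + ["gain"] * 15 + ["none"] * 2 + ["loss"] * 12
        calls, catalog = self._calls(seq)
        segments, _ = segment_cnv(calls, catalog, min_run=10)
        for seg in segments:
            assert seg.n_genes == seg.end - seg.start


class TestSummary:
    def _catalog(self):
        return pd.DataFrame(
            {
                "subgenome": ["R", "R", "C", "C"],
                "chrom": ["R01", "R01", "C01", "C01"],
                "pos_index": [0, 1, 0, 1],
                "length_bp": [1000] * 4,
                "agp_partner": ["C01g0000", "", "R01g0000", ""],
            },
            index=["R01g0000", "R01g0001", "C01g0000", "C01g0001"],
        )

    def test_all_r_calls(self):
        calls = pd.DataFrame(
            {"gene": ["R01g0000", "R01g0001"], "sample": ["s1", "s1"],
             "call": ["gain", "loss"]}
        )
        out = cnv_subgenome_summary(calls, self._catalog())
        assert out.loc[0, "frac_r"] == 1.0
        assert out.loc[0, "frac_c"] == 0.0

    def test_fractions_sum_to_one(self):
        calls = pd.DataFrame(
            {
                "gene": ["R01g0000", "C01g0000", "C01g0001"],
                "sample": ["s1"] * 3,
                "call": ["gain", "gain", "loss"],
            }
        )
        out = cnv_subgenome_summary(calls, self._catalog())
        assert out.loc[0, "frac_r"] + out.loc[0, "frac_c"] == pytest.approx(1.0)
        assert out.loc[0, "frac_agp"] + out.loc[0, "frac_ssg"] == pytest.approx(1.0)

    def test_zero_calls_absent(self):
        calls = pd.DataFrame(
            {"gene": ["R01g0000"], "sample": ["s1"], "call": ["none"]}
        )
        out = cnv_subgenome_summary(calls, self._catalog())
        assert out.empty

    def test_planted_r_c_split_recovered(self):
        rng = np.random.default_rng(0)
        genes = ["R01g0000", "R01g0001", "C01g0000", "C01g0001"]
        picks = rng.choice(["R01g0000", "R01g0001", "C01g0000"], size=200,
                           p=[0.35, 0.35, 0.30])
        calls = pd.DataFrame(
            {"gene": picks, "sample": "s1", "call": "gain"}
        )
        out = cnv_subgenome_summary(calls, self._catalog())
        assert out.loc[0, "frac_r"] == pytest.approx(0.7, abs=0.1)
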