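"""Tests of the synthetic hybrid-embryo data generator."""

import numpy as np
import pandas as pd
import pytest

from hybridzga._seq import encode, revcomp
from hybridzga.config import LINEAGE_CELL_COUNTS, ConfigError, SimConfig
from hybridzga.simulate import (
    generate_coverage_tracks,
    generate_expression_program,
    generate_genome_pair,
    generate_stiffness_table,
    simulate_bulk_reads,
    simulate_cells,
)
from hybridzga.simulate.genomes import _apportion, _mutate


# --------------------------------------------------------------- genome pair

class TestGenomePair:
    def test_mean_divergence_matches_configured_distribution(self, cfg_default,
                                                             gp_default):
        """Observed pairwise mismatch fraction approximates 14.3%."""
        fracs = []
        for pair_id in gp_default.pair_ids:
            a = encode(gp_default.transcript(pair_id, "A"))
            model = gp_default.model_for_pair(pair_id, "B")
            b_seq = gp_default.species_b[model.chrom]
            b = encode(model.spliced_transcript(b_seq))
            # strand correction applied identically, so positions align
            fracs.append(np.mean(a != b))
        assert abs(np.mean(fracs) - cfg_default.divergence_mean) < 0.02
        assert all(0.01 <= gp_default.truth_divergence[p] <= 0.5
                   for p in gp_default.pair_ids)

    def test_zero_rate_substitution_leaves_sequence_identical(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 4, 500, dtype=np.uint8)
        copy = codes.copy()
        _mutate(copy, 0.0, rng)
        assert np.array_equal(codes, copy)

    def test_single_pair_mismatch_count_near_expectation(self):
        """d=0.2 on a 1000-bp transcript: site-by-site mismatch oracle."""
        cfg = SimConfig(seed=5, n_gene_pairs=1, divergence_mean=0.2,
                        divergence_sd=0.0, gene_length=1000, n_exons=1)
        gp = generate_genome_pair(cfg)
        a = encode(gp.transcript("g0000", "A"))
        b = encode(gp.transcript("g0000", "B"))
        mismatches = int((a != b).sum())
        assert abs(mismatches - 200) <= 3 * np.sqrt(1000 * 0.2 * 0.8)

    def test_deterministic_under_seed(self, cfg_small, gp_small):
        again = generate_genome_pair(cfg_small)
        assert again.species_a == gp_small.species_a
        assert again.species_b == gp_small.species_b
        assert again.truth_divergence == gp_small.truth_divergence
        pd.testing.assert_frame_equal(again.classes, gp_small.classes)

    def test_empty_config_gives_empty_pair_set(self):
        gp = generate_genome_pair(SimConfig(seed=0, n_gene_pairs=0))
        assert gp.pair_ids == []

    def test_negative_lengths_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(gene_length=-10)

    def test_gene_models_identical_across_species(self, gp_small):
        for pair_id in gp_small.pair_ids:
            ma = gp_small.model_for_pair(pair_id, "A")
            mb = gp_small.model_for_pair(pair_id, "B")
            assert ma.exons == mb.exons
            assert ma.strand == mb.strand
            lo, hi = ma.upstream_interval(1000)
            assert lo >= 0
            assert hi <= len(gp_small.species_a[ma.chrom])

    def test_minus_strand_transcript_is_reverse_complement(self, gp_small):
        minus = [p for p in gp_small.pair_ids
                 if gp_small.model_for_pair(p, "A").strand == "-"]
        model = gp_small.model_for_pair(minus[0], "A")
        chrom = gp_small.species_a[model.chrom]
        plus_concat = "".join(chrom[s:e] for s, e in model.exons)
        assert gp_small.transcript(minus[0], "A") == revcomp(plus_concat)

    def test_apportion_preserves_total_and_tracks_weights(self):
        counts = _apportion({"a": 0.5, "b": 0.3, "c": 0.2}, 7)
        assert sum(counts.values()) == 7
        assert counts["a"] >= counts["b"] >= counts["c"]


# --------------------------------------------------------- expression program

class TestExpressionProgram:
    def test_no_paternal_signal_before_eight_cell(self, prog_small):
        for cross in ("forward", "reverse"):
            frac = prog_small.truth_paternal_fraction(cross)
            for stage in ("1-cell", "2-cell", "4-cell"):
                assert frac[stage] == 0.0

    def test_conservation_without_decay_or_transcription(self, gp_small,
                                                         cfg_small):
        cfg = cfg_small.with_(decay_rate=0.0, zygotic_init=0.0,
                              zygotic_level=0.0)
        prog = generate_expression_program(cfg, gp_small)
        for pair_id, row in prog.truth.iterrows():
            ab = prog.abundance["forward"]["A"].loc[pair_id]
            assert (ab == row["deposit"]).all()

    def test_paternal_fraction_increases_at_both_waves(self, gp_small,
                                                       cfg_small):
        """Hand-summed abundance oracle on a 10-gene configuration."""
        cfg = cfg_small.with_(n_gene_pairs=10)
        gp = generate_genome_pair(cfg)
        prog = generate_expression_program(cfg, gp)
        # independent summation straight from the truth table
        def hand_fraction(stage):
            s = cfg.stage_idx(stage)
            pat = mat = 0.0
            for pair_id, row in prog.truth.iterrows():
                onset = row["onset_stage"]
                zyg = 0.0
                if onset is not None:
                    o = cfg.stage_idx(onset)
                    if s == o:
                        zyg = cfg.zygotic_init
                    elif s > o:
                        zyg = cfg.zygotic_level
                pat += zyg * row["cis_B_forward"]
                mat += (zyg * row["cis_A_forward"]
                        + row["deposit"] * (1 - cfg.decay_rate) ** s)
            return pat / (pat + mat)

        frac = prog.truth_paternal_fraction("forward")
        for stage in cfg.stages:
            assert frac[stage] == pytest.approx(hand_fraction(stage))
        assert frac["32-cell"] > frac["16-cell"]
        assert frac["112-cell"] > frac["64-cell"]

    def test_maternal_allele_at_one_cell_equals_deposit(self, prog_small):
        for pair_id, row in prog_small.truth.iterrows():
            assert prog_small.get(pair_id, "A", "forward", "1-cell") == \
                pytest.approx(row["deposit"])
            assert prog_small.get(pair_id, "B", "reverse", "1-cell") == \
                pytest.approx(row["deposit"])

    def test_abundance_non_negative_and_zero_pre_onset(self, prog_small,
                                                       cfg_small):
        for cross in ("forward", "reverse"):
            for allele in "AB":
                ab = prog_small.abundance[cross][allele]
                assert (ab.to_numpy() >= 0).all()
        zygotic = prog_small.truth["onset_stage"].dropna()
        for pair_id, onset in zygotic.items():
            o = cfg_small.stage_idx(onset)
            pat = prog_small.abundance["forward"]["B"].loc[pair_id]
            assert (pat.iloc[:o] == 0).all()

    def test_unknown_onset_stage_rejected(self, gp_small, cfg_small):
        with pytest.raises(ConfigError):
            cfg_small.with_(onset_stage_by_class={
                **cfg_small.onset_stage_by_class, "minor_wave": "13-cell"})


# ----------------------------------------------------------------- bulk reads

class TestBulkReads:
    def test_zero_reads_gives_empty_set_and_sidecar(self, prog_small, gp_small):
        rs = simulate_bulk_reads(prog_small, gp_small, "forward", "1-cell", 0)
        assert len(rs) == 0
        assert rs.sidecar.empty

    def test_read_shares_follow_abundance(self, gp_small, cfg_small):
        """Two sources at 3:1 abundance: multinomial expectation oracle."""
        cfg = cfg_small.with_(n_gene_pairs=2, class_fractions={
            "maternal_only": 1.0, "early_zygotic": 0.0, "minor_wave": 0.0,
            "housekeeping": 0.0, "zygotic_only_ase": 0.0})
        gp = generate_genome_pair(cfg)
        prog = generate_expression_program(cfg, gp)
        p0, p1 = prog.pair_ids
        for cross in ("forward", "reverse"):
            for allele in "AB":
                prog.abundance[cross][allele].loc[p0] = 0.0
                prog.abundance[cross][allele].loc[p1] = 0.0
        prog.abundance["forward"]["A"].loc[p0, "1-cell"] = 3.0
        prog.abundance["forward"]["A"].loc[p1, "1-cell"] = 1.0
        n = 100_000
        rs = simulate_bulk_reads(prog, gp, "forward", "1-cell", n,
                                 error_rate=0.0)
        share = (rs.sidecar["pair_id"] == p0).mean()
        se = np.sqrt(0.75 * 0.25 / n)
        assert abs(share - 0.75) <= 3 * se

    def test_pre_zga_sample_is_purely_maternal(self, prog_small, gp_small):
        rs = simulate_bulk_reads(prog_small, gp_small, "forward", "1-cell",
                                 5000)
        assert (rs.sidecar["allele"] == "A").all()
        rs_rev = simulate_bulk_reads(prog_small, gp_small, "reverse", "4-cell",
                                     5000)
        assert (rs_rev.sidecar["allele"] == "B").all()

    def test_conservation_and_support(self, prog_small, gp_small):
        rs = simulate_bulk_reads(prog_small, gp_small, "forward", "112-cell",
                                 20_000)
        assert len(rs.sidecar) == 20_000
        ab = prog_small.abundance["forward"]
        for (pair_id, allele), _ in rs.sidecar.groupby(["pair_id", "allele"]):
            assert ab[allele].loc[pair_id, "112-cell"] > 0

    def test_sidecar_paternal_fraction_calibrated(self, prog_small, gp_small):
        n = 100_000
        rs = simulate_bulk_reads(prog_small, gp_small, "forward", "112-cell", n)
        p = prog_small.truth_paternal_fraction("forward")["112-cell"]
        est = (rs.sidecar["allele"] == "B").mean()
        se = np.sqrt(p * (1 - p) / n)
        assert abs(est - p) <= 3 * se

    def test_deterministic_under_seed(self, prog_small, gp_small):
        a = simulate_bulk_reads(prog_small, gp_small, "forward", "64-cell", 500)
        b = simulate_bulk_reads(prog_small, gp_small, "forward", "64-cell", 500)
        assert np.array_equal(a.seqs, b.seqs)
        pd.testing.assert_frame_equal(a.sidecar, b.sidecar)

    def test_unknown_stage_rejected(self, prog_small, gp_small):
        with pytest.raises(ValueError, match="stage"):
            simulate_bulk_reads(prog_small, gp_small, "forward", "3-cell", 10)


# --------------------------------------------------------------- single cells

class TestSimulateCells:
    def test_endoderm_leads_at_64_cell(self, prog_small, cfg_small):
        _, truth = simulate_cells(prog_small, cfg_small, "64-cell")
        means = truth.groupby("lineage", observed=True)[
            "expected_paternal_hk_ratio"].mean()
        assert means.idxmax() == "endoderm"
        others = means.drop(["endoderm", "notochord"])
        assert means["notochord"] > others.max()

    def test_pre_onset_lineage_has_zero_paternal_housekeeping(self, prog_small,
                                                              cfg_small):
        adata, _ = simulate_cells(prog_small, cfg_small, "64-cell")
        hk = set(prog_small.truth.index[
            prog_small.truth["klass"] == "housekeeping"])
        pat_cols = (adata.var["pair_id"].isin(hk)
                    & (adata.var["species"] == "B")).to_numpy()
        late = (adata.obs["lineage"] == "epidermis").to_numpy()  # onset earN
        assert np.asarray(adata.X)[late][:, pat_cols].sum() == 0

    def test_published_celltype_counts_reproduced_exactly(self, prog_small, cfg_small):
        adata, _ = simulate_cells(prog_small, cfg_small, "64-cell", n_cells=844)
        observed = adata.obs["lineage"].value_counts().to_dict()
        assert observed == LINEAGE_CELL_COUNTS

    def test_unknown_stage_rejected(self, prog_small, cfg_small):
        with pytest.raises(ValueError, match="stage"):
            simulate_cells(prog_small, cfg_small, "8-cell")

    def test_markers_exclusive_to_their_lineage(self, prog_small, cfg_small):
        adata, _ = simulate_cells(prog_small, cfg_small, "112-cell")
        X = np.asarray(adata.X)
        for lineage in cfg_small.lineage_onsets:
            col = (adata.var["marker_lineage"] == lineage).to_numpy()
            outside = (adata.obs["lineage"] != lineage).to_numpy()
            assert X[outside][:, col].sum() == 0


# ------------------------------------------------------- tracks and stiffness

class TestTracksAndStiffness:
    def test_housekeeping_signal_rises_between_waves(self, prog_small,
                                                     gp_small):
        t64 = generate_coverage_tracks(prog_small, gp_small, "64-cell")
        t112 = generate_coverage_tracks(prog_small, gp_small, "112-cell")
        hk = prog_small.truth.index[prog_small.truth["klass"] == "housekeeping"]
        for pair_id in hk:
            model = gp_small.model_for_pair(pair_id, "B")
            for stage_track, other in ((t112["B"], t64["B"]),):
                body = stage_track[(stage_track["chrom"] == model.chrom)
                                   & (stage_track["start"] == model.start)]
                body64 = other[(other["chrom"] == model.chrom)
                               & (other["start"] == model.start)]
                assert float(body["value"].iloc[0]) > float(body64["value"].iloc[0])

    def test_background_only_gene_is_flat(self, prog_small, gp_small):
        track = generate_coverage_tracks(prog_small, gp_small, "1-cell",
                                         background=1.5)["A"]
        maternal_only = prog_small.truth.index[
            prog_small.truth["klass"] == "maternal_only"][0]
        chrom = gp_small.model_for_pair(maternal_only, "A").chrom
        assert (track.loc[track["chrom"] == chrom, "value"] == 1.5).all()

    def test_track_integral_matches_summation_oracle(self, prog_small,
                                                     gp_small):
        from hybridzga.simulate.tracks import _zygotic_activity

        track = generate_coverage_tracks(prog_small, gp_small, "112-cell")["A"]
        for pair_id in gp_small.pair_ids[:5]:
            model = gp_small.model_for_pair(pair_id, "A")
            sub = track[(track["chrom"] == model.chrom)
                        & (track["start"] >= model.start)
                        & (track["end"] <= model.end)]
            integral = float(((sub["end"] - sub["start"]) * sub["value"]).sum())
            activity = _zygotic_activity(prog_small, pair_id, "A", "forward",
                                         "112-cell")
            length = model.end - model.start
            assert integral == pytest.approx((activity + 1.0) * length)

    def test_stiffness_ranks_and_onset_correlation(self, cfg_small):
        from scipy.stats import spearmanr

        table = generate_stiffness_table(cfg_small).set_index("lineage")
        ranked = table["stiffness"].rank(ascending=False)
        assert ranked["endoderm"] == 1
        assert ranked["notochord"] == 2
        onsets = [cfg_small.stage_idx(cfg_small.lineage_onsets[lin])
                  for lin in table.index]
        rho, _ = spearmanr(table["stiffness"], [-o for o in onsets])
        assert rho > 0

    def test_single_lineage_single_row(self, cfg_small):
        cfg = cfg_small.with_(lineage_onsets={"endoderm": "32-cell"},
                              lineage_proportions={"endoderm": 10})
        assert len(generate_stiffness_table(cfg)) == 1
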