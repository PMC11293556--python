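import numpy as np
import pandas as pd
import pytest

from dartcall import simulate as sim
from dartcall.annotation_io import load_transcript_models
from dartcall.metagene import map_sites


@pytest.fixture(scope="module")
def small_scenario():
    ts, genome = sim.generate_transcriptome(
        sim.TranscriptomeParams(n_genes=12), seed=3)
    truth = sim.plant_truth(ts, genome, n_m6a=30, n_snps=10, n_artifacts=5,
                            seed=3)
    return sim.SyntheticScenario(ts, genome, truth,
                                 sim.enumerate_c_sites(ts, genome))


def test_determinism_of_transcriptome_and_samples(small_scenario, tmp_path):
    ts1, g1 = sim.generate_transcriptome(
        sim.TranscriptomeParams(n_genes=10), seed=1)
    ts2, g2 = sim.generate_transcriptome(
        sim.TranscriptomeParams(n_genes=10), seed=1)
    assert g1 == g2
    assert {t.transcript_id: t.exons for t in ts1} == \
           {t.transcript_id: t.exons for t in ts2}
    a = sim.simulate_bulk_sample(small_scenario, "YTH", 1)
    b = sim.simulate_bulk_sample(small_scenario, "YTH", 1)
    pd.testing.assert_frame_equal(a.df, b.df)
    c = sim.simulate_bulk_sample(small_scenario, "YTH", 2)
    assert not a.df.equals(c.df)


def test_generated_gtf_reloads_with_valid_models(tmp_path):
    ts, genome = sim.generate_transcriptome(
        sim.TranscriptomeParams(n_genes=6, isoforms_per_gene=3), seed=5)
    from dartcall.annotation_io import write_gtf
    path = tmp_path / "t.gtf"
    write_gtf(ts, path)
    back = load_transcript_models(path)
    assert set(back.transcripts) == set(ts.transcripts)
    for tid, tm in back.transcripts.items():
        orig = ts[tid]
        assert tm.exons == orig.exons
        assert (tm.cds_start, tm.cds_end) == (orig.cds_start, orig.cds_end)
        assert tm.mature_length == orig.mature_length
    for gene in back.genes:
        assert back.longest_isoform(gene).gene_id == gene


def test_generated_tables_satisfy_schema(small_scenario):
    for cond in ("YTH", "WT"):
        table = sim.simulate_bulk_sample(small_scenario, cond, 1)
        table.validate()   # raises on any invariant violation
        assert (table.df.k > 0).all()


def test_planted_offsets_rederive_through_metagene(small_scenario):
    truth = small_scenario.truth
    keys = [(r.chrom, int(r.pos), r.strand) for r in truth.m6a.itertuples()]
    mapped = {p.key: p for p in map_sites(keys, small_scenario.ts)}
    for r in truth.m6a.itertuples():
        mp = mapped[(r.chrom, int(r.pos), r.strand)]
        assert mp.offset_from_stop == r.offset
        assert mp.gene_id == r.gene_id


def test_planted_sites_are_transcript_strand_cytidines(small_scenario):
    truth, genome = small_scenario.truth, small_scenario.genome
    for df in (truth.m6a, truth.snps, truth.artifacts):
        for r in df.itertuples():
            assert sim.transcript_strand_base(
                genome, r.chrom, int(r.pos), r.strand) == "C"


def test_snp_sites_look_saturated_in_every_condition(small_scenario):
    snp_keys = small_scenario.truth.snp_keys()
    for cond in ("YTH", "YTHmut", "WT"):
        table = sim.simulate_bulk_sample(small_scenario, cond, 1)
        df = table.df
        snp = df[[(c, p, s) in snp_keys for c, p, s in
                  zip(df.chrom, df.pos, df.strand)]]
        deep = snp[snp.k >= 20]
        assert (deep.m / deep.k >= 0.95).all()


def test_degenerate_rates_give_exact_saturation():
    ts, genome = sim.generate_transcriptome(
        sim.TranscriptomeParams(n_genes=6), seed=11)
    truth = sim.plant_truth(ts, genome, n_m6a=20, n_snps=0, n_artifacts=0,
                            pi_dist=lambda r, n: np.ones(n), seed=11,
                            e=0.0, b_cond={c: 0.0 for c in
                                           ("YTH", "YTHmut", "APOBEC1", "WT")})
    scen = sim.SyntheticScenario(ts, genome, truth,
                                 truth.m6a[["chrom", "pos", "strand"]])
    table = sim.simulate_bulk_sample(scen, "YTH", 1)
    assert (table.df.m == table.df.k).all()


def test_wt_sample_carries_no_signal_at_planted_sites(small_scenario):
    m6a = small_scenario.truth.m6a_keys()
    table = sim.simulate_bulk_sample(small_scenario, "WT", 1)
    df = table.df
    at = df[[(c, p, s) in m6a for c, p, s in
             zip(df.chrom, df.pos, df.strand)]]
    # mean WT ratio at planted sites is at the sequencing-error scale
    assert (at.m / at.k).mean() < 0.01


def test_law_of_large_numbers_at_planted_sites(small_scenario):
    """Pooled observed ratio converges to the planted editing probability
    p = e + b + pi within 3 binomial standard errors."""
    truth = small_scenario.truth
    tables = [sim.simulate_bulk_sample(small_scenario, "YTH", r)
              for r in (1, 2, 3)]
    lookup = truth.m6a.set_index(["chrom", "pos", "strand"]).pi
    m_tot = k_tot = 0
    expected = 0.0
    for t in tables:
        df = t.df.join(lookup, on=["chrom", "pos", "strand"], how="inner")
        m_tot += df.m.sum()
        k_tot += df.k.sum()
        expected += (df.k * (truth.e + truth.b_cond["YTH"] + df.pi)).sum()
    p_hat = m_tot / k_tot
    p_bar = expected / k_tot
    se = np.sqrt(p_bar * (1 - p_bar) / k_tot)
    assert abs(p_hat - p_bar) <= 3 * se


def test_cells_determinism_and_homogeneous_mimics():
    scenario, cells, plan, controls = sim.sc_clusters(seed=7)
    cells2 = sim.simulate_cells(scenario, plan)
    pd.testing.assert_frame_equal(cells.counts, cells2.counts)
    # an h=1 site is saturated in every covering YTH cell
    truth = scenario.truth
    mimics = truth.m6a[truth.m6a.h == 1.0]
    key = (mimics.iloc[0].chrom, int(mimics.iloc[0].pos), mimics.iloc[0].strand)
    yth = cells.subset("YTH").counts
    at = yth[(yth.chrom == key[0]) & (yth.pos == key[1]) &
             (yth.strand == key[2]) & (yth.k >= 20)]
    assert len(at) > 10
    assert (at.m / at.k >= 0.95).all()


def test_lambda_zero_and_no_error_gives_zero_mutant_edits():
    ts, genome = sim.generate_transcriptome(
        sim.TranscriptomeParams(n_genes=6), seed=13)
    truth = sim.plant_truth(ts, genome, n_m6a=10, n_snps=0, n_artifacts=0,
                            seed=13, e=0.0,
                            b_cond={c: 5e-3 for c in
                                    ("YTH", "YTHmut", "APOBEC1", "WT")})
    scen = sim.SyntheticScenario(ts, genome, truth,
                                 sim.enumerate_c_sites(ts, genome))
    plan = sim.ClusterPlan([sim.ClusterSpec("z", lam=0.0, n_yth=2, n_mut=3)],
                           n_null_sites=50)
    cells = sim.simulate_cells(scen, plan)
    mut = cells.subset("YTHmut")
    assert mut.counts.m.sum() == 0


def test_window_radius_plants_neighboring_cytidines():
    ts, genome = sim.generate_transcriptome(
        sim.TranscriptomeParams(n_genes=6), seed=17)
    t0 = sim.plant_truth(ts, genome, n_m6a=5, n_snps=0, n_artifacts=0, seed=17)
    t1 = sim.plant_truth(ts, genome, n_m6a=5, n_snps=0, n_artifacts=0,
                         seed=17, window_radius=3)
    assert len(t1.m6a) >= len(t0.m6a)


def test_placement_exhaustion_raises():
    ts, genome = sim.generate_transcriptome(
        sim.TranscriptomeParams(n_genes=1), seed=19)
    with pytest.raises(RuntimeError):
        sim.plant_truth(ts, genome, n_m6a=10_000, n_snps=0, n_artifacts=0,
                        seed=19)
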