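import numpy as np
import pandas as pd
import pytest

from dartcall import simulate as sim
from dartcall.annotation_io import SiteCountTable, SnpMask, TranscriptModel, TranscriptSet
from dartcall.pipeline import RunConfig, run_bulk_from_tables, run_sc_from_data

SEED = 42


def random_count_table(rng, n=200, sample_id="s1", condition="YTH",
                       replicate=1, chroms=("chr1", "chr2")):
    """A random but schema-valid site-count table."""
    pos = rng.choice(50_000, size=n, replace=False)
    k = rng.integers(1, 120, size=n)
    m = rng.binomial(k, rng.uniform(0, 0.4, size=n))
    df = pd.DataFrame({
        "chrom": rng.choice(chroms, size=n),
        "pos": pos,
        "strand": rng.choice(["+", "-"], size=n),
        "ref": "C",
        "m": m,
        "k": k,
    }).drop_duplicates(["chrom", "pos", "strand"])
    return SiteCountTable(sample_id, condition, replicate, df)


@pytest.fixture(scope="session")
def toy_transcripts():
    """Mirror-image +/- strand two-exon coding transcripts with identical
    mature geometry (mature length 500, 5'UTR 100, CDS 300, 3'UTR 100)."""
    plus = TranscriptModel("tp.1", "gplus", "chr1", "+",
                           ((1000, 1200), (1500, 1800)),
                           cds_start=1100, cds_end=1700)
    minus = TranscriptModel("tm.1", "gminus", "chr2", "-",
                            ((1000, 1300), (1600, 1800)),
                            cds_start=1100, cds_end=1700)
    return TranscriptSet([plus, minus])


@pytest.fixture(scope="session")
def bulk_run():
    """The bulk study conditions at the reference seed, run end to end."""
    scenario, samples = sim.bulk_basic(seed=SEED)
    mask = SnpMask([(r.chrom, int(r.pos))
                    for r in scenario.truth.snps.itertuples()])
    result = run_bulk_from_tables(samples["YTH"], samples["YTHmut"],
                                  samples["WT"], samples["APOBEC1"],
                                  RunConfig(), mask, scenario.ts)
    return {"scenario": scenario, "samples": samples, "mask": mask,
            "result": result}


@pytest.fixture(scope="session")
def sc_run():
    """The single-cell study conditions at the reference seed."""
    scenario, cells, plan, controls = sim.sc_clusters(seed=SEED)
    mask = SnpMask([(r.chrom, int(r.pos))
                    for r in scenario.truth.snps.itertuples()])
    yth = cells.subset("YTH")
    mut = cells.subset("YTHmut")
    result = run_sc_from_data(yth, mut, controls["YTHmut"], controls["WT"],
                              controls["APOBEC1"], RunConfig(), mask)
    return {"scenario": scenario, "cells": cells, "plan": plan,
            "controls": controls, "yth": yth, "mut": mut, "mask": mask,
            "result": result}


@pytest.fixture(scope="session")
def ko_run():
    wt, ko, wt_samples, ko_samples = sim.ko_contrast(seed=SEED)
    return {"wt": wt, "ko": ko, "wt_samples": wt_samples,
            "ko_samples": ko_samples}
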