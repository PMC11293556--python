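import numpy as np
import pandas as pd
import pytest

from dartcall.bulk_calling import intersect_replicates
from dartcall.edit_detection import EditSite, EditThresholds
from dartcall.sc_calling import (CellEditMatrix, call_cell_edits,
                                 cluster_background_profile,
                                 read_cell_matrix, remove_bulk_background_sc,
                                 subtract_cluster_background,
                                 summarize_counts)


def _matrix(rows, cells):
    counts = pd.DataFrame(rows, columns=["barcode", "chrom", "pos", "strand",
                                         "m", "k"])
    counts["ref"] = "C"
    cells = pd.DataFrame(cells, columns=["barcode", "condition", "cluster"])
    return CellEditMatrix(cells, counts)


def _site(m, k, chrom="chr1", pos=1, strand="+"):
    return EditSite(chrom, pos, strand, m, k, 1e-12, 1e-11)


# ---------------------------------------------------------------------------
# Per-cell calling
# ---------------------------------------------------------------------------

def test_bulk_thresholds_reused_per_cell():
    mat = _matrix([("c1", "chr1", 1, "+", 3, 12),   # kept
                   ("c1", "chr1", 2, "+", 2, 8),    # k < 10
                   ("c2", "chr1", 1, "+", 1, 50)],  # m < 2
                  [("c1", "YTH", "A"), ("c2", "YTH", "A"),
                   ("c3", "YTH", "B")])
    calls = call_cell_edits(mat)
    assert set(calls["c1"]) == {("chr1", 1, "+")}
    assert calls["c2"] == {}
    assert calls["c3"] == {}   # cell with no covered sites -> empty, no error


def test_cell_matrix_validation():
    with pytest.raises(ValueError):
        _matrix([("c1", "chr1", 1, "+", 5, 3)], [("c1", "YTH", "A")])
    with pytest.raises(ValueError):
        _matrix([("zz", "chr1", 1, "+", 1, 3)], [("c1", "YTH", "A")])


def test_missing_cluster_label_becomes_unassigned():
    cells = pd.DataFrame({"barcode": ["c1"], "condition": ["YTH"],
                          "cluster": [None]})
    counts = pd.DataFrame({"barcode": ["c1"], "chrom": ["chr1"], "pos": [1],
                           "strand": ["+"], "ref": ["C"], "m": [1], "k": [5]})
    mat = CellEditMatrix(cells, counts)
    assert mat.cluster_of()["c1"] == "unassigned"


# ---------------------------------------------------------------------------
# Bulk-control removal
# ---------------------------------------------------------------------------

def test_bulk_control_removal_rules():
    cells = {"c1": {("chr1", 1, "+"): _site(5, 10),     # in bulk WT -> drop
                    ("chr1", 2, "+", ): _site(5, 10, pos=2),  # fold 2.5 -> keep
                    ("chr1", 3, "+"): _site(2, 10, pos=3),    # fold 1.0 -> drop
                    ("chr1", 4, "+"): _site(3, 12, pos=4)}}   # clean -> keep
    bulk_mut = intersect_replicates(
        [{("chr1", 2, "+"): _site(20, 100, pos=2),
          ("chr1", 3, "+"): _site(20, 100, pos=3)}], min_rep=1)
    out = remove_bulk_background_sc(cells, wt={("chr1", 1, "+")},
                                    apobec=set(), bulk_mut=bulk_mut)
    assert set(out["c1"]) == {("chr1", 2, "+"), ("chr1", 4, "+")}


# ---------------------------------------------------------------------------
# Cluster background profile
# ---------------------------------------------------------------------------

def test_cluster_means_match_hand_computation():
    # 3 clusters x 4 cells; site chr1:1 covered variously
    rows, cells = [], []
    ratios = {"A": [0.1, 0.3, None, None],   # two covered cells -> mean 0.2
              "B": [0.5, 0.5, 0.5, 0.5],
              "C": [None, None, None, None]}  # uncovered -> no entry
    for cl, rs in ratios.items():
        for i, r in enumerate(rs):
            bc = f"{cl}{i}"
            cells.append((bc, "YTHmut", cl))
            if r is None:
                rows.append((bc, "chr9", 99, "+", 0, 20))  # other site only
            else:
                rows.append((bc, "chr1", 1, "+", int(r * 20), 20))
    bg = cluster_background_profile(_matrix(rows, cells), k_min=10)
    assert bg.per_site["A"][("chr1", 1, "+")][0] == pytest.approx(0.2)
    assert bg.per_site["A"][("chr1", 1, "+")][2] == 2
    assert bg.per_site["B"][("chr1", 1, "+")][0] == pytest.approx(0.5)
    assert ("chr1", 1, "+") not in bg.per_site.get("C", {})


def test_low_coverage_cells_excluded_from_site_mean():
    mat = _matrix([("c1", "chr1", 1, "+", 5, 20),
                   ("c2", "chr1", 1, "+", 4, 5)],   # k < 10: excluded
                  [("c1", "YTHmut", "A"), ("c2", "YTHmut", "A")])
    bg = cluster_background_profile(mat, k_min=10)
    assert bg.per_site["A"][("chr1", 1, "+")] == (0.25, 5.0, 1)


def test_cluster_without_mutant_cells_flagged(caplog):
    mat = _matrix([("c1", "chr1", 1, "+", 1, 20)],
                  [("c1", "YTHmut", "A")])
    mat.cells = pd.concat([mat.cells, pd.DataFrame(
        [{"barcode": "ghost", "condition": "YTHmut", "cluster": "B"}])],
        ignore_index=True)
    # cluster B exists in labels but holds no counts; treat as present cell
    bg = cluster_background_profile(mat, k_min=10)
    assert bg.rate("A") >= 0


# ---------------------------------------------------------------------------
# Cluster background subtraction
# ---------------------------------------------------------------------------

def _profile_from(mut_rows, mut_cells):
    return cluster_background_profile(_matrix(mut_rows, mut_cells), k_min=10)


def test_zero_background_is_identity():
    yth = {"y1": {("chr1", i, "+"): _site(10, 20, pos=i) for i in range(6)}}
    bg = _profile_from([("m1", "chr9", 999, "+", 0, 20)],
                       [("m1", "YTHmut", "A")])
    profiles = subtract_cluster_background(yth, bg, {"y1": "A"})
    assert set(profiles[0].sites) == set(yth["y1"])
    for rec in profiles[0].sites.values():
        assert rec.adjusted_ratio == rec.ratio
        assert rec.background == 0.0


def test_subtraction_examples():
    # cell ratio 0.4 over background 0.1 -> kept with adjusted 0.3;
    # cell ratio 0.1 equal to background 0.1 -> removed
    yth = {"y1": {("chr1", 1, "+"): _site(20, 50),
                  ("chr1", 2, "+"): _site(5, 50, pos=2)}}
    mut_rows = [(f"m{i}", "chr1", p, "+", 5, 50)
                for i in range(4) for p in (1, 2)]
    bg = _profile_from(mut_rows, [(f"m{i}", "YTHmut", "A") for i in range(4)])
    profiles = subtract_cluster_background(yth, bg, {"y1": "A"})
    sites = profiles[0].sites
    assert set(sites) == {("chr1", 1, "+")}
    assert sites[("chr1", 1, "+")].adjusted_ratio == pytest.approx(0.3)
    assert sites[("chr1", 1, "+")].m == 20 and sites[("chr1", 1, "+")].k == 50


def test_outputs_are_subsets_at_every_stage(sc_run):
    res = sc_run["result"]
    for barcode, cleaned in res.after_bulk_controls.items():
        assert set(cleaned) <= set(res.candidates_per_cell[barcode])
    for p in res.profiles:
        assert set(p.sites) <= set(res.after_bulk_controls[p.barcode])


def test_uniform_background_equals_global_subtraction():
    """With a mutant background that is exactly uniform across clusters
    (identical mutant counts in each cluster), cluster-specific subtraction
    must coincide with the single-cluster (global) subtraction."""
    rng = np.random.default_rng(3)
    base_rows = []
    for i in range(8):          # 8 mutant cells worth of counts
        for pos in range(25):
            k = int(rng.integers(10, 60))
            m = int(rng.binomial(k, 0.08))
            base_rows.append((pos, "+", m, k))
    mut_rows, mut_cells = [], []
    for cl in ("A", "B", "C"):
        for i in range(8):
            bc = f"m_{cl}{i}"
            mut_cells.append((bc, "YTHmut", cl))
            for pos, strand, m, k in base_rows[i * 25:(i + 1) * 25]:
                mut_rows.append((bc, "chr1", pos, strand, m, k))
    bg_cluster = _profile_from(mut_rows, mut_cells)
    bg_global = _profile_from(
        mut_rows, [(bc, cond, "all") for bc, cond, _ in mut_cells])

    yth = {}
    for j, cl in enumerate(("A", "B", "C")):
        yth[f"y{j}"] = {("chr1", pos, "+"): _site(int(0.3 * 40), 40, pos=pos)
                        for pos in range(25)}
    by_cluster = subtract_cluster_background(
        yth, bg_cluster, {"y0": "A", "y1": "B", "y2": "C"})
    globally = subtract_cluster_background(
        yth, bg_global, {bc: "all" for bc in yth})
    for p_c, p_g in zip(sorted(by_cluster, key=lambda p: p.barcode),
                        sorted(globally, key=lambda p: p.barcode)):
        assert set(p_c.sites) == set(p_g.sites)
        for key in p_c.sites:
            assert p_c.sites[key].adjusted_ratio == \
                pytest.approx(p_g.sites[key].adjusted_ratio)


def test_summarize_counts_mean():
    from dartcall.sc_calling import CellM6AProfile, CellSiteRecord
    rec = CellSiteRecord(2, 10, 0.2, 0.2, 0.0)
    profiles = [CellM6AProfile("c1", "A", {("chr1", i, "+"): rec
                                           for i in range(10)}),
                CellM6AProfile("c2", "A", {("chr1", i, "+"): rec
                                           for i in range(20)})]
    out = summarize_counts(profiles)
    row = out["per_cluster"].iloc[0]
    assert row["mean"] == pytest.approx(15.0)
    assert row["n_cells"] == 2


def test_cell_matrix_tsv_roundtrip(tmp_path):
    mat = _matrix([("c1", "chr1", 1, "+", 3, 12), ("c2", "chr2", 5, "-", 0, 9)],
                  [("c1", "YTH", "A"), ("c2", "YTH", "B")])
    mat.write(tmp_path / "counts.tsv", tmp_path / "clusters.tsv")
    back = read_cell_matrix(tmp_path / "counts.tsv", tmp_path / "clusters.tsv")
    assert back.cluster_of() == {"c1": "A", "c2": "B"}
    pd.testing.assert_frame_equal(
        back.counts.reset_index(drop=True),
        mat.counts[["barcode", "chrom", "pos", "strand", "ref", "m", "k"]],
        check_dtype=False)
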