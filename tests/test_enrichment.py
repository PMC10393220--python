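import numpy as np
import pandas as pd
import pytest

from phipkit import enrichment
from phipkit.errors import ConsistencyError, LookupError_, PreconditionError


def _loo_z_oracle(fc: pd.DataFrame, ref_cols, other_cols, ddof=1):
    """From-scratch recomputation: per held-out reference sample, recompute
    mean/sd over the remaining reference columns; others use the full set."""
    z = pd.DataFrame(np.nan, index=fc.index, columns=fc.columns)
    for s in other_cols:
        for g in fc.index:
            vals = fc.loc[g, ref_cols].to_numpy(dtype=float)
            sd = vals.std(ddof=ddof)
            if sd > 0:
                z.loc[g, s] = (fc.loc[g, s] - vals.mean()) / sd
    for r in ref_cols:
        rest = [c for c in ref_cols if c != r]
        for g in fc.index:
            vals = fc.loc[g, rest].to_numpy(dtype=float)
            sd = vals.std(ddof=ddof)
            if sd > 0:
                z.loc[g, r] = (fc.loc[g, r] - vals.mean()) / sd
    return z


@pytest.fixture
def small_chain(tiny_counts, tiny_library, tiny_sheet):
    genes = enrichment.collapse_to_genes(tiny_counts, tiny_library)
    percent = enrichment.percent_normalize(genes)
    fc = enrichment.fold_change(percent, tiny_sheet)
    z = enrichment.zscore_vs_reference(fc, tiny_sheet)
    return genes, percent, fc, z


def test_collapse_sums_and_pseudocount(tiny_library):
    counts = pd.DataFrame(
        {"s1": [10, 5, 0, 0]}, index=tiny_library.index.copy()
    )
    genes = enrichment.collapse_to_genes(counts, tiny_library)
    assert genes.loc["GA", "s1"] == 15.5
    assert genes.loc["GB", "s1"] == 0.5  # all-zero gene kept, 0.5


def test_collapse_single_peptide_gene_is_elementwise():
    lib = pd.DataFrame(
        {"gene_id": ["g1", "g2"], "protein_name": ["p", "q"],
         "start_pos": [0, 0], "aa_seq": ["A" * 49, "C" * 49]},
        index=pd.Index(["pep1", "pep2"], name="peptide_id"),
    )
    counts = pd.DataFrame({"s": [7, 3]}, index=lib.index.copy())
    genes = enrichment.collapse_to_genes(counts, lib)
    assert genes["s"].tolist() == [7.5, 3.5]


def test_collapse_orphan_peptide_errors(tiny_library):
    counts = pd.DataFrame({"s1": [1]}, index=pd.Index(["nope"], name="peptide_id"))
    with pytest.raises(ConsistencyError):
        enrichment.collapse_to_genes(counts, tiny_library)


@pytest.mark.parametrize(
    "column, expected",
    [([0.5, 0.5], [50.0, 50.0]), ([1.5, 0.5], [75.0, 25.0])],
)
def test_percent_normalize_arithmetic(column, expected):
    genes = pd.DataFrame({"s": column}, index=["g1", "g2"])
    pct = enrichment.percent_normalize(genes)
    assert pct["s"].tolist() == expected


def test_percent_columns_sum_to_100(small_chain):
    _, percent, _, _ = small_chain
    assert np.allclose(percent.sum(axis=0), 100.0, atol=1e-9)


def test_fold_change_arithmetic():
    percent = pd.DataFrame({"samp": [0.4], "mock1": [0.1]}, index=["g"])
    sheet = pd.DataFrame(
        {"role": ["case", "mock_ip"]},
        index=pd.Index(["samp", "mock1"], name="sample_id"),
    )
    fc = enrichment.fold_change(percent, sheet)
    assert fc.loc["g", "samp"] == pytest.approx(4.0)
    assert fc.loc["g", "mock1"] == pytest.approx(1.0)


def test_fold_change_identical_to_single_mock_is_one():
    percent = pd.DataFrame(
        {"samp": [30.0, 70.0], "mock1": [30.0, 70.0]}, index=["g1", "g2"]
    )
    sheet = pd.DataFrame(
        {"role": ["case", "mock_ip"]},
        index=pd.Index(["samp", "mock1"], name="sample_id"),
    )
    fc = enrichment.fold_change(percent, sheet)
    assert np.allclose(fc["samp"], 1.0)


def test_fold_change_requires_mock(tiny_sheet):
    percent = pd.DataFrame({"s0": [100.0]}, index=["g"])
    no_mock = tiny_sheet[tiny_sheet["role"] != "mock_ip"]
    with pytest.raises(PreconditionError):
        enrichment.fold_change(percent, no_mock)


def test_fold_change_mock_columns_recompute(small_chain, tiny_sheet):
    """FC restricted to the mock-IP columns equals each mock percentage over
    the arithmetic mean of mock percentages, recomputed directly."""
    _, percent, fc, _ = small_chain
    mocks = tiny_sheet.index[tiny_sheet["role"] == "mock_ip"]
    expected = percent[mocks].div(percent[mocks].mean(axis=1), axis=0)
    pd.testing.assert_frame_equal(fc[mocks], expected)


def test_zscore_matches_leave_one_out_oracle():
    rng = np.random.default_rng(0)
    fc = pd.DataFrame(
        rng.lognormal(0, 1, size=(6, 8)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{j}" for j in range(8)],
    )
    sheet = pd.DataFrame(
        {"role": ["pre_control"] * 5 + ["case"] * 3},
        index=fc.columns.rename("sample_id"),
    )
    z = enrichment.zscore_vs_reference(fc, sheet)
    oracle = _loo_z_oracle(fc, list(fc.columns[:5]), list(fc.columns[5:]))
    assert np.allclose(z.to_numpy(), oracle.to_numpy(), rtol=1e-10, equal_nan=True)


def test_zscore_centering_and_degenerate_sd():
    fc = pd.DataFrame(
        {"r1": [1.0, 2.0], "r2": [1.0, 3.0], "r3": [1.0, 4.0], "c": [11.0, 3.0]},
        index=["flat", "var"],
    )
    sheet = pd.DataFrame(
        {"role": ["pre_control"] * 3 + ["case"]},
        index=pd.Index(["r1", "r2", "r3", "c"], name="sample_id"),
    )
    z = enrichment.zscore_vs_reference(fc, sheet)
    # reference sd of "flat" is 0: undefined, flagged as NaN (never inf)
    assert np.isnan(z.loc["flat", "c"])
    assert not np.isinf(z.to_numpy()).any()
    # FC equal to the reference mean -> z = 0
    assert z.loc["var", "c"] == pytest.approx(0.0)


def test_zscore_requires_three_reference_samples():
    fc = pd.DataFrame({"r1": [1.0], "r2": [2.0], "c": [3.0]}, index=["g"])
    sheet = pd.DataFrame(
        {"role": ["pre_control", "pre_control", "case"]},
        index=pd.Index(["r1", "r2", "c"], name="sample_id"),
    )
    with pytest.raises(PreconditionError):
        enrichment.zscore_vs_reference(fc, sheet)


def test_call_boundaries_and_independence():
    fc = pd.DataFrame({"s1": [5.0], "s2": [4.999], "s3": [2.0]}, index=["g"])
    z = pd.DataFrame({"s1": [0.0], "s2": [7.0], "s3": [np.nan]}, index=["g"])
    calls = enrichment.call(fc, z)
    assert bool(calls.enriched.loc["g", "s1"])          # FC = 5.0 inclusive
    assert not bool(calls.positive.loc["g", "s1"])
    assert not bool(calls.enriched.loc["g", "s2"])      # calls are independent
    assert bool(calls.positive.loc["g", "s2"])
    assert not bool(calls.positive.loc["g", "s3"])      # undefined z never positive
    assert not bool(calls.z_defined.loc["g", "s3"])
    assert calls.threshold_fc == 5.0 and calls.threshold_z == 6.0


def test_call_table_long_form():
    fc = pd.DataFrame({"s1": [6.0]}, index=["g"])
    z = pd.DataFrame({"s1": [7.0]}, index=["g"])
    df = enrichment.call(fc, z).to_frame()
    assert list(df.columns) == ["gene_id", "sample_id", "enriched", "positive", "z_defined"]
    assert df.iloc[0].tolist() == ["g", "s1", True, True, True]


def test_peptide_profile_focality_limits(tiny_library):
    # all reads on one peptide -> focality 1.0
    counts = pd.DataFrame(
        {"s1": [40, 0, 10, 10]}, index=tiny_library.index.copy()
    )
    prof = enrichment.peptide_profile(counts, tiny_library, "GA", ["s1"])
    assert prof.focality == pytest.approx(1.0)
    # uniform over k peptides -> 1/k
    prof_b = enrichment.peptide_profile(counts, tiny_library, "GB", ["s1"])
    assert prof_b.focality == pytest.approx(0.5)
    # ordered by start position, normalized per 100,000 total reads
    assert prof.per_peptide["start_pos"].is_monotonic_increasing
    assert prof.per_peptide["mean_rp100k"].iloc[0] == pytest.approx(1e5 * 40 / 60)


def test_peptide_profile_unknown_gene(tiny_counts, tiny_library):
    with pytest.raises(LookupError_):
        enrichment.peptide_profile(tiny_counts, tiny_library, "nope", ["s0"])


def test_positivity_fraction_counting(tiny_sheet):
    fc = pd.DataFrame(
        {s: [10.0] for s in tiny_sheet.index}, index=["g"]
    )
    z = pd.DataFrame(
        {s: [8.0 if s in ("s0",) else 1.0] for s in tiny_sheet.index}, index=["g"]
    )
    calls = enrichment.call(fc, z)
    assert enrichment.positivity_fraction(calls, tiny_sheet, "g", {"case"}) == 0.5
    assert enrichment.positivity_fraction(calls, tiny_sheet, "g", {"pre_control"}) == 0.0
    with pytest.raises(PreconditionError):
        enrichment.positivity_fraction(calls, tiny_sheet, "g", {"comparator"})


def test_depth_scale_invariance(tiny_counts, tiny_library, tiny_sheet):
    """Multiplying one sample's counts by a constant leaves its percent and
    FC columns essentially unchanged (exactly, up to the 0.5 pseudocount)."""
    scaled = tiny_counts.copy()
    scaled["s0"] = scaled["s0"] * 10
    def chain(c):
        genes = enrichment.collapse_to_genes(c, tiny_library)
        pct = enrichment.percent_normalize(genes)
        return pct, enrichment.fold_change(pct, tiny_sheet)
    pct_a, fc_a = chain(tiny_counts)
    pct_b, fc_b = chain(scaled)
    assert np.allclose(pct_a["s0"], pct_b["s0"], rtol=5e-3)
    assert np.allclose(fc_a["s0"], fc_b["s0"], rtol=5e-3)
    # untouched columns are bit-identical
    pd.testing.assert_series_equal(fc_a["s1"], fc_b["s1"])


def test_null_cohort_false_positive_rate_below_one_per_thousand():
    """With a realistically sized reference cohort (57 pre-exposure
    controls, as a typical study carries), the null rate of z >= 6 among
    non-reference samples stays below 1e-3 across seeds."""
    from phipkit import generate_library, simulate_cohort
    from phipkit.simulate import SimulationConfig

    for seed in range(3):
        cfg = SimulationConfig(
            n_genes=100, peptides_per_gene=3, n_pre_controls=57,
            n_comparators=30, n_cases=30, n_mock_ip=8,
            depth_mean=300_000.0, seed=seed,
        )
        lib = generate_library(cfg)
        counts, sheet, _ = simulate_cohort(cfg, lib)
        genes = enrichment.collapse_to_genes(counts, lib)
        fc = enrichment.fold_change(enrichment.percent_normalize(genes), sheet)
        z = enrichment.zscore_vs_reference(fc, sheet)
        non_ref = sheet.index[sheet["role"] != "pre_control"]
        zz = z[non_ref].to_numpy()
        assert (zz >= 6).sum() / zz.size < 1e-3
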