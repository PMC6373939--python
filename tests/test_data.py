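"""Containers, readers, filtering rules and metadata encoding."""

import numpy as np
import pandas as pd
import pytest

from rcmord import (
    CountTable,
    encode_metadata,
    filter_taxa,
    read_counts,
    write_counts,
)


@pytest.fixture()
def tiny_tsv(tmp_path):
    path = tmp_path / "counts.tsv"
    df = pd.DataFrame(
        [[1, 0, 3, 2], [0, 5, 1, 0], [2, 2, 2, 2]],
        index=["sampleA", "sampleB", "sampleC"],
        columns=["taxon1", "taxon2", "taxon3", "taxon4"],
    )
    df.to_csv(path, sep="\t")
    return path


class TestReadWrite:
    def test_tsv_reader_shape_and_ids(self, tiny_tsv):
        ct = read_counts(tiny_tsv)
        assert (ct.n, ct.p) == (3, 4)
        assert ct.sample_ids == ["sampleA", "sampleB", "sampleC"]
        assert ct.lib_sizes.tolist() == [6, 6, 8]

    def test_taxa_in_rows_orientation(self, tiny_tsv, tmp_path):
        df = pd.read_csv(tiny_tsv, sep="\t", index_col=0).T
        path = tmp_path / "transposed.tsv"
        df.to_csv(path, sep="\t")
        ct = read_counts(path, orientation="taxa-in-rows")
        assert ct.sample_ids == ["sampleA", "sampleB", "sampleC"]

    def test_biom_equivalence(self, tiny_tsv, tmp_path):
        biom = pytest.importorskip("biom")
        ct = read_counts(tiny_tsv)
        table = biom.Table(
            ct.X.T.astype(float), observation_ids=ct.taxon_ids,
            sample_ids=ct.sample_ids,
        )
        path = tmp_path / "counts.biom"
        with biom.util.biom_open(str(path), "w") as fh:
            table.to_hdf5(fh, "test")
        ct2 = read_counts(path, format="biom")
        df1 = ct.to_frame()
        df2 = ct2.to_frame().loc[df1.index, df1.columns].astype(int)
        pd.testing.assert_frame_equal(df1, df2)

    def test_roundtrip_bit_identical(self, tiny_tsv, tmp_path):
        ct = read_counts(tiny_tsv)
        out = tmp_path / "again.tsv"
        write_counts(ct, out)
        ct2 = read_counts(out)
        assert np.array_equal(ct.X, ct2.X)
        assert ct.sample_ids == ct2.sample_ids
        assert ct.taxon_ids == ct2.taxon_ids

    def test_negative_entry_names_the_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame([[1, -1]], index=["s1"], columns=["t1", "t2"]).to_csv(
            path, sep="\t")
        with pytest.raises(ValueError, match="t2"):
            read_counts(path)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            CountTable(np.ones((2, 2), dtype=int), ["s", "s"], ["a", "b"])


class TestFilterTaxa:
    def _table(self, cols):
        X = np.column_stack(cols)
        return CountTable(
            X, [f"s{i}" for i in range(X.shape[0])],
            [f"t{j}" for j in range(X.shape[1])],
        )

    def test_prevalence_rule_at_default_5pct(self):
        # present in 2 of 60 samples (3.3%) -> removed at the 5% threshold
        rare = np.zeros(60, dtype=int)
        rare[:2] = 50
        keep = np.ones(60, dtype=int) * 3
        ct = filter_taxa(self._table([rare, keep]))
        assert ct.taxon_ids == ["t1"]

    def test_total_count_rule_at_default_10pct_of_n(self):
        # total 5 < 0.10 * 60 = 6 -> removed even though prevalence is fine
        low = np.zeros(60, dtype=int)
        low[:5] = 1
        keep = np.ones(60, dtype=int) * 3
        ct = filter_taxa(self._table([low, keep]))
        assert ct.taxon_ids == ["t1"]

    def test_abundant_taxon_retained(self):
        tax = np.zeros(60, dtype=int)
        tax[:30] = 4  # prevalence 50%, total 120
        ct = filter_taxa(self._table([tax, np.ones(60, dtype=int)]))
        assert "t0" in ct.taxon_ids

    def test_idempotent(self, filtered_nb_sim):
        _, ct, _, _ = filtered_nb_sim
        again = filter_taxa(ct)
        assert np.array_equal(ct.X, again.X)

    def test_empty_samples_dropped_after_taxa(self):
        X = np.array([[5, 1], [0, 0], [3, 2]])
        ct = filter_taxa(CountTable(X, ["a", "b", "c"], ["t1", "t2"]),
                         prevalence_min=0.0, totalcount_min_frac=0.0)
        assert ct.sample_ids == ["a", "c"]

    def test_everything_removed_is_an_error(self):
        X = np.zeros((30, 2), dtype=int)
        X[0, 0] = 1  # prevalence 1/30 < 5%; the other taxon is empty
        with pytest.raises(ValueError, match="every taxon"):
            filter_taxa(CountTable(X, [f"s{i}" for i in range(30)], ["t1", "t2"]))


class TestEncodeMetadata:
    def test_factor_expands_to_full_dummies(self):
        raw = pd.DataFrame({"grp": ["a", "b", "c", "a", "b", "c"]},
                           index=[f"s{i}" for i in range(6)])
        sd = encode_metadata(raw, constraining=["grp"])
        dummies = sd.Q[[c for c in sd.Q.columns if c.startswith("grp")]]
        assert dummies.shape[1] == 3
        np.testing.assert_allclose(dummies.sum(axis=1), 1.0)
        # the block used for fitting is centred
        np.testing.assert_allclose(sd.C.mean(axis=0), 0.0, atol=1e-12)

    def test_confounder_factor_uses_reference_coding(self):
        raw = pd.DataFrame({"batch": ["x", "y", "x", "y"]},
                           index=[f"s{i}" for i in range(4)])
        sd = encode_metadata(raw, confounders=["batch"])
        assert sd.G.shape[1] == 1  # one dummy for a 2-level factor

    def test_numeric_column_standardised(self):
        raw = pd.DataFrame({"age": [1.0, 2.0, 3.0, 4.0]},
                           index=[f"s{i}" for i in range(4)])
        sd = encode_metadata(raw, constraining=["age"])
        col = sd.Q["age"].to_numpy()
        assert col.mean() == pytest.approx(0.0, abs=1e-12)
        assert col.var() == pytest.approx(1.0, rel=1e-12)

    def test_role_overlap_rejected(self):
        raw = pd.DataFrame({"v": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="both"):
            encode_metadata(raw, confounders=["v"], constraining=["v"])

    def test_missing_values_name_the_samples(self):
        raw = pd.DataFrame({"v": [1.0, np.nan, 3.0]}, index=["a", "b", "c"])
        with pytest.raises(ValueError, match="b"):
            encode_metadata(raw, constraining=["v"])

    def test_coding_map_records_levels(self):
        raw = pd.DataFrame({"grp": ["ctl", "trt", "ctl"]},
                           index=["a", "b", "c"])
        sd = encode_metadata(raw, constraining=["grp"])
        assert sd.coding_map["grp"]["levels"] == ["ctl", "trt"]
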