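"""Quantile normalization, probe collapse and batch adjustment."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from instascore import collapse_probes, combat_adjust, log2_if_needed, quantile_normalize


def frame(values, prefix="s"):
    values = np.asarray(values, float)
    return pd.DataFrame(
        values,
        index=[f"g{i}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j}" for j in range(values.shape[1])],
    )


class TestQuantileNormalize:
    def test_two_by_two_example(self):
        out = quantile_normalize(frame([[1, 2], [3, 4]]))
        assert np.allclose(out.to_numpy(), [[1.5, 1.5], [3.5, 3.5]])

    def test_identical_columns_are_a_fixed_point(self):
        X = frame(np.tile(np.arange(6.0)[:, None], (1, 4)))
        pd.testing.assert_frame_equal(quantile_normalize(X), X)

    def test_columns_share_sorted_values(self, rng):
        X = frame(rng.normal(size=(50, 10)))
        out = quantile_normalize(X).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 10):
            assert np.allclose(np.sort(out[:, j]), ref)

    def test_idempotent(self, rng):
        X = frame(rng.normal(size=(40, 6)))
        once = quantile_normalize(X)
        twice = quantile_normalize(once)
        assert np.abs(once.to_numpy() - twice.to_numpy()).max() < 1e-10

    def test_ties_get_mean_of_reference_block(self):
        # column 0 has a tie at its two lowest entries
        X = frame([[1, 5], [1, 2], [4, 8]])
        out = quantile_normalize(X)
        ref = np.sort(X.to_numpy(), axis=0).mean(axis=1)
        assert out.iloc[0, 0] == out.iloc[1, 0] == pytest.approx(ref[:2].mean())

    def test_rejects_single_sample_and_nans(self):
        with pytest.raises(ValueError, match="2 samples"):
            quantile_normalize(frame([[1.0], [2.0]]))
        bad = frame([[1, 2], [np.nan, 4]])
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize(bad)


class TestCollapseProbes:
    def test_max_mean_probe_wins(self):
        X = frame([[5, 5], [7, 7]], prefix="a")
        X.index = ["p1", "p2"]
        out = collapse_probes(X, {"p1": "G", "p2": "G"})
        assert list(out.index) == ["G"]
        assert np.allclose(out.loc["G"], [7, 7])

    def test_identity_map_preserves_rows(self, rng):
        X = frame(rng.normal(size=(5, 3)))
        out = collapse_probes(X, {g: g for g in X.index})
        pd.testing.assert_frame_equal(out.sort_index(), X.sort_index(), check_names=False)

    def test_matches_bruteforce_groupby_oracle(self, rng):
        X = frame(rng.normal(size=(10, 4)))
        genes = ["A", "B", "C", "D"]
        pmap = {p: genes[i % 4] for i, p in enumerate(X.index)}
        out = collapse_probes(X, pmap)
        for gene in genes:
            probes = [p for p, g in pmap.items() if g == gene]
            best = max(probes, key=lambda p: X.loc[p].mean())
            assert np.allclose(out.loc[gene], X.loc[best])

    def test_no_mapped_probes_errors(self):
        with pytest.raises(ValueError, match="maps"):
            collapse_probes(frame([[1.0, 2.0]]), {"nope": "G"})


class TestCombat:
    def test_single_batch_is_identity(self, rng):
        X = frame(rng.normal(size=(30, 8)))
        batch = pd.Series(["b1"] * 8, index=X.columns)
        out = combat_adjust(X, batch)
        assert np.abs(out.to_numpy() - X.to_numpy()).max() < 1e-8

    def test_pure_additive_offset_removed_exactly(self, rng):
        mu = rng.normal(7, 1, 25)
        off = rng.normal(0, 1, 25)
        X = np.empty((25, 10))
        X[:, :5] = mu[:, None]
        X[:, 5:] = (mu + off)[:, None]
        Xdf = frame(X)
        batch = pd.Series(["A"] * 5 + ["B"] * 5, index=Xdf.columns)
        out = combat_adjust(Xdf, batch)
        diff = out.iloc[:, :5].mean(axis=1) - out.iloc[:, 5:].mean(axis=1)
        assert np.abs(diff).max() < 1e-6

    def test_location_scale_batches_mostly_corrected(self, rng):
        G, per = 80, 50
        mu = rng.normal(7, 1, G)
        batches = ["A"] * per + ["B"] * per
        gamma = {"A": rng.normal(0, 1.0, G), "B": rng.normal(0, 1.0, G)}
        scale = {"A": np.exp(rng.normal(0, 0.3, G)), "B": np.exp(rng.normal(0, 0.3, G))}
        X = np.empty((G, 2 * per))
        for j, b in enumerate(batches):
            X[:, j] = mu + gamma[b] + scale[b] * rng.normal(0, 1, G)
        Xdf = frame(X)
        bser = pd.Series(batches, index=Xdf.columns)
        out = combat_adjust(Xdf, bser)

        def gap(M):
            return np.abs(
                M.iloc[:, :per].mean(axis=1) - M.iloc[:, per:].mean(axis=1)
            ).mean()

        assert gap(out) < 0.1 * gap(Xdf)

    def test_grand_mean_roughly_preserved_with_equal_batches(self, rng):
        X = frame(rng.normal(7, 1, size=(100, 20)) + np.repeat([0.0, 1.0], 10)[None, :])
        batch = pd.Series(["A"] * 10 + ["B"] * 10, index=X.columns)
        out = combat_adjust(X, batch)
        shift = np.abs(out.mean(axis=1) - X.mean(axis=1))
        assert shift.max() < 0.05

    def test_singleton_batch_named_in_error(self, rng):
        X = frame(rng.normal(size=(10, 5)))
        batch = pd.Series(["A"] * 4 + ["lonely"], index=X.columns)
        with pytest.raises(ValueError, match="lonely"):
            combat_adjust(X, batch)

    def test_matches_bioconductor_sva(self, rng, tmp_path):
        """Independent oracle: Bioconductor's reference EB implementation."""
        G, n = 40, 24
        batch = ["A"] * 10 + ["B"] * 14
        mu = rng.normal(7, 1, G)
        X = np.empty((G, n))
        for j, b in enumerate(batch):
            g = rng.normal(0, 0.8, G) if b == "A" else rng.normal(0.5, 0.8, G)
            X[:, j] = mu + g + rng.normal(0, 1, G)
        Xdf = frame(X)
        bser = pd.Series(batch, index=Xdf.columns)
        ours = combat_adjust(Xdf, bser)

        Xdf.to_csv(tmp_path / "in.tsv", sep="\t")
        script = textwrap.dedent(
            """
            suppressMessages(library(sva))
            X <- as.matrix(read.table(file.path("{d}", "in.tsv"), sep="\\t",
                                      header=TRUE, row.names=1))
            b <- c(rep("A", 10), rep("B", 14))
            out <- ComBat(dat=X, batch=b, par.prior=TRUE)
            write.table(out, file.path("{d}", "out.tsv"), sep="\\t", quote=FALSE)
            """
        ).format(d=tmp_path)
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        theirs = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        assert np.abs(ours.to_numpy() - theirs.to_numpy()).max() < 1e-3


def test_log2_detection_and_transform():
    linear = frame([[100.0, 400.0], [1000.0, 40.0]])
    out = log2_if_needed(linear)
    assert np.allclose(out.to_numpy(), np.log2(linear.to_numpy() + 1))
    logged = frame([[7.0, 8.0], [6.0, 9.0]])
    pd.testing.assert_frame_equal(log2_if_needed(logged), logged)
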