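import numpy as np
import pandas as pd
import pytest

from funnorm.controls import (OOB_MEASURE_NAMES, STANDARD_CONTROL_SCHEME,
                              batch_association_report, control_covariates,
                              summarize_controls)
from funnorm.data_model import ChannelData, ProbeManifest, SampleSheet
from funnorm.errors import ValidationError
from funnorm.simulate import (DEFAULT_CONTROL_COUNTS, SimulationConfig,
                              simulate_dataset)
from tests.conftest import SMALL_PROBES


def constant_control_setup(value: float):
    """A manifest with one probe per standard control category and constant
    channel intensities."""
    rows = []
    addr = 0
    for cat in DEFAULT_CONTROL_COUNTS:
        addr += 1
        rows.append((f"c_{cat}", "II", "", True, cat, f"a{addr}", ""))
    manifest = ProbeManifest.from_frame(pd.DataFrame(
        rows, columns=["probe_id", "design_type", "chromosome", "is_control",
                       "control_category", "address_a", "address_b"]))
    addresses = [f"a{i}" for i in range(1, addr + 1)]
    green = pd.DataFrame({"s1": value, "s2": value}, index=pd.Index(addresses),
                         dtype=float)
    red = green.copy()
    oob = np.full((10, 2), value)
    return manifest, ChannelData(green, red), oob


class TestSummarizeControls:
    def test_full_scheme_emits_42_columns(self, small_dataset, small_raw):
        summary = summarize_controls(small_dataset.channels,
                                     small_dataset.manifest,
                                     small_raw.oob_green, small_raw.oob_red)
        assert summary.values.shape[1] == 42
        assert summary.measures[-4:] == OOB_MEASURE_NAMES

    def test_constant_intensities_give_log2_of_constant(self):
        c = 255.0
        manifest, channels, oob = constant_control_setup(c)
        summary = summarize_controls(channels, manifest, oob, oob)
        assert np.allclose(summary.values.to_numpy(), np.log2(1 + c))

    def test_norm_c_column_is_mean_of_log_green(self):
        """Two 'C' normalization probes at 100 and 300 summarize to the mean
        of log2(101) and log2(301)."""
        rows = [("c1", "II", "", True, "NORM_C", "a1", ""),
                ("c2", "II", "", True, "NORM_C", "a2", "")]
        manifest = ProbeManifest.from_frame(pd.DataFrame(
            rows, columns=["probe_id", "design_type", "chromosome",
                           "is_control", "control_category", "address_a",
                           "address_b"]))
        green = pd.DataFrame({"s1": [100.0, 300.0]}, index=pd.Index(["a1", "a2"]))
        red = green * 0 + 50.0
        oob = np.full((5, 1), 10.0)
        summary = summarize_controls(ChannelData(green, red), manifest, oob, oob)
        expected = np.mean([np.log2(101.0), np.log2(301.0)])
        assert summary.values.loc["s1", "norm_c.green"] == pytest.approx(expected)

    def test_dropping_a_category_drops_exactly_its_columns(self, small_dataset,
                                                           small_raw):
        manifest = small_dataset.manifest
        keep = manifest.table["control_category"] != "STAINING"
        trimmed = ProbeManifest.from_frame(manifest.table[keep])
        summary = summarize_controls(small_dataset.channels, trimmed,
                                     small_raw.oob_green, small_raw.oob_red)
        staining_cols = [m.name for m in STANDARD_CONTROL_SCHEME
                        if m.category == "STAINING"]
        assert summary.values.shape[1] == 42 - len(staining_cols)
        assert not set(staining_cols) & set(summary.measures)

    def test_invariant_to_sample_order(self, small_dataset, small_raw):
        channels = small_dataset.channels
        rev = list(reversed(channels.samples))
        flipped = channels.subset_samples(rev)
        pos = [channels.samples.index(s) for s in rev]
        s1 = summarize_controls(channels, small_dataset.manifest,
                                small_raw.oob_green, small_raw.oob_red)
        s2 = summarize_controls(flipped, small_dataset.manifest,
                                small_raw.oob_green[:, pos],
                                small_raw.oob_red[:, pos])
        pd.testing.assert_frame_equal(s1.values.loc[rev], s2.values)


class TestControlCovariates:
    def test_m_zero_gives_empty_projection(self, small_dataset, small_raw):
        summary = summarize_controls(small_dataset.channels,
                                     small_dataset.manifest,
                                     small_raw.oob_green, small_raw.oob_red)
        cov = control_covariates(summary, m=0)
        assert cov.Z.shape == (12, 0)

    def test_identical_summary_rows_rejected(self):
        """With identical samples every column is zero-variance and no PCA
        direction is defined."""
        manifest, channels, oob = constant_control_setup(100.0)
        summary = summarize_controls(channels, manifest, oob, oob)
        with pytest.raises(ValidationError, match="zero variance"):
            control_covariates(summary, m=1)

    def test_scores_match_svd_oracle(self, rng):
        from funnorm.controls import ControlSummaryMatrix

        X = rng.normal(size=(10, 6))
        summary = ControlSummaryMatrix(pd.DataFrame(
            X, index=[f"s{i}" for i in range(10)],
            columns=[f"m{j}" for j in range(6)]))
        cov = control_covariates(summary, m=2)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        oracle = U[:, :2] * S[:2]
        for j in range(2):
            assert (np.allclose(cov.Z[:, j], oracle[:, j], atol=1e-8)
                    or np.allclose(cov.Z[:, j], -oracle[:, j], atol=1e-8))

    def test_scores_match_sklearn_pca_up_to_sign(self, rng):
        from sklearn.decomposition import PCA

        from funnorm.controls import ControlSummaryMatrix

        X = rng.normal(size=(12, 5))
        summary = ControlSummaryMatrix(pd.DataFrame(
            X, index=[f"s{i}" for i in range(12)],
            columns=[f"m{j}" for j in range(5)]))
        cov = control_covariates(summary, m=3)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        ref = PCA(n_components=3).fit_transform(Xs)
        for j in range(3):
            assert min(np.abs(cov.Z[:, j] - ref[:, j]).max(),
                       np.abs(cov.Z[:, j] + ref[:, j]).max()) < 1e-8

    def test_m_at_least_n_rejected(self, small_dataset, small_raw):
        summary = summarize_controls(small_dataset.channels,
                                     small_dataset.manifest,
                                     small_raw.oob_green, small_raw.oob_red)
        with pytest.raises(ValidationError, match="smaller than"):
            control_covariates(summary, m=12)

    def test_reconstruction_error_nonincreasing_in_m(self, rng):
        from funnorm.controls import ControlSummaryMatrix

        X = rng.normal(size=(15, 8))
        summary = ControlSummaryMatrix(pd.DataFrame(
            X, index=[f"s{i}" for i in range(15)],
            columns=[f"m{j}" for j in range(8)]))
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        errors = []
        for m in range(1, 6):
            Z = control_covariates(summary, m=m).Z
            # projection residual of the standardized matrix on the scores
            coef, *_ = np.linalg.lstsq(Z, Xs, rcond=None)
            errors.append(np.linalg.norm(Xs - Z @ coef))
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))


class TestBatchAssociation:
    def test_plate_shift_appears_in_plate_means(self):
        manifest, channels, oob = constant_control_setup(100.0)
        delta = 50.0
        shifted = ChannelData(channels.green + delta, channels.red + delta)
        # sample s2 on plate B gets the shifted intensities
        merged = ChannelData(
            pd.concat([channels.green[["s1"]], shifted.green[["s2"]]], axis=1),
            pd.concat([channels.red[["s1"]], shifted.red[["s2"]]], axis=1))
        summary = summarize_controls(merged, manifest,
                                     np.column_stack([oob[:, 0], oob[:, 0] + delta]),
                                     np.column_stack([oob[:, 0], oob[:, 0] + delta]))
        sheet = SampleSheet.from_frame(pd.DataFrame({
            "sample_id": ["s1", "s2"], "sex": ["MALE", "MALE"],
            "plate": ["A", "B"], "slide": ["sl1", "sl1"], "row": [1, 2],
            "column": [1, 1], "group": ["g", "g"], "replicate_of": ["", ""]}))
        report = batch_association_report(summary, sheet)
        diff = report.plate_means.loc["B"] - report.plate_means.loc["A"]
        expected = np.log2(151.0) - np.log2(101.0)
        assert np.allclose(diff.to_numpy(), expected, atol=1e-9)

    def test_plate_background_shift_drives_pc1(self):
        cfg = SimulationConfig(seed=5, n_samples=40, probe_counts=SMALL_PROBES,
                               n_dmp=0)
        ds = simulate_dataset(cfg)
        from funnorm.data_model import preprocess_raw

        raw = preprocess_raw(ds.channels, ds.manifest)
        summary = summarize_controls(ds.channels, ds.manifest,
                                     raw.oob_green, raw.oob_red)
        report = batch_association_report(summary, ds.samplesheet)
        plates = ds.samplesheet.table["plate"].to_numpy()
        indicator = (plates == plates[0]).astype(float)
        corr = np.corrcoef(report.pc_scores["PC1"], indicator)[0, 1]
        assert abs(corr) > 0.8
        assert report.pc1_plate_r2 > 0.6

    def test_permuted_plate_labels_remove_association(self):
        cfg = SimulationConfig(seed=5, n_samples=40, probe_counts=SMALL_PROBES,
                               n_dmp=0)
        ds = simulate_dataset(cfg)
        from funnorm.data_model import preprocess_raw

        raw = preprocess_raw(ds.channels, ds.manifest)
        summary = summarize_controls(ds.channels, ds.manifest,
                                     raw.oob_green, raw.oob_red)
        sheet = ds.samplesheet.table.copy()
        perm = np.random.default_rng(0).permutation(len(sheet))
        sheet["plate"] = sheet["plate"].to_numpy()[perm]
        report = batch_association_report(summary, SampleSheet.from_frame(sheet))
        assert report.pc1_plate_r2 < 0.3
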