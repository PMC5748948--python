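import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from gfpquant import (
    EmbryoImageRecord,
    ManifestError,
    load_gfp_image,
    proliferation_index,
    render_pair,
    run_batch,
    run_group_analysis,
    validate_manifest,
)
from gfpquant.cli import main as cli_main
from gfpquant.phantoms import Ellipse, EmbryoPhantomSpec, MassDisk


def _phantom_spec(seed=0):
    return EmbryoPhantomSpec(
        image_size=(96, 96),
        yolk=Ellipse(center=(30, 30), semi_axes=(10, 12), plateau=10, falloff_power=16),
        masses=(MassDisk(center=(55, 55), radius=16, intensity=200),),
        seed=seed,
    )


def _write_png(path, image):
    import imageio.v3 as iio

    iio.imwrite(path, np.clip(np.rint(image.pixels), 0, 255).astype(np.uint8))
    return str(path)


@pytest.fixture
def manifest_dir(tmp_path):
    """Two phantom embryos (PI ~2.4 and ~0.5) plus their manifest CSV."""
    rows = []
    for eid, (ar, ir), group in [("e1", (2.0, 1.2), "warm"), ("e2", (0.5, 1.0), "cold")]:
        (img0, img72), _ = render_pair(_phantom_spec(seed=hash(eid) % 100), ar, ir)
        p0 = _write_png(tmp_path / f"{eid}_0.png", img0)
        p72 = _write_png(tmp_path / f"{eid}_72.png", img72)
        rows.append({"embryo_id": eid, "timepoint": "0hpi", "image_path": p0, "temp": group})
        rows.append({"embryo_id": eid, "timepoint": "72hpi", "image_path": p72, "temp": group})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(tmp_path / "manifest.csv", index=False)
    return tmp_path, manifest


class TestValidateManifest:
    def test_extra_columns_are_group_labels(self, manifest_dir):
        _, manifest = manifest_dir
        assert validate_manifest(manifest) == ["temp"]

    def test_missing_column(self):
        with pytest.raises(ManifestError, match="image_path"):
            validate_manifest(pd.DataFrame({"embryo_id": [], "timepoint": []}))

    def test_unpaired_embryo_named(self, manifest_dir):
        _, manifest = manifest_dir
        bad = manifest.iloc[:-1]  # drop e2's 72hpi row
        with pytest.raises(ManifestError, match="e2"):
            validate_manifest(bad)

    def test_duplicate_timepoint_rejected(self, manifest_dir):
        _, manifest = manifest_dir
        dup = manifest.copy()
        dup.loc[dup.index[-1], "timepoint"] = "0hpi"
        with pytest.raises(ManifestError):
            validate_manifest(dup)

    def test_unknown_timepoint_rejected(self, manifest_dir):
        _, manifest = manifest_dir
        bad = manifest.copy()
        bad.loc[bad.index[0], "timepoint"] = "48hpi"
        with pytest.raises(ManifestError, match="48hpi"):
            validate_manifest(bad)


class TestRunBatch:
    def test_batch_matches_single_pair_runs(self, manifest_dir):
        tmp_path, manifest = manifest_dir
        results, discards = run_batch(manifest)
        assert len(results) == 2 and len(discards) == 0
        for _, row in results.iterrows():
            sub = manifest[manifest.embryo_id == row.embryo_id]
            recs = {
                r.timepoint: EmbryoImageRecord(
                    r.embryo_id, r.timepoint, load_gfp_image(r.image_path)
                )
                for r in sub.itertuples()
            }
            single = proliferation_index(recs["0hpi"], recs["72hpi"])
            assert row.PI == pytest.approx(single.PI)
            assert row.shared_threshold == single.shared_threshold

    def test_row_order_independence(self, manifest_dir):
        _, manifest = manifest_dir
        shuffled = manifest.sample(frac=1, random_state=1).reset_index(drop=True)
        r1, _ = run_batch(manifest)
        r2, _ = run_batch(shuffled)
        pd.testing.assert_frame_equal(r1, r2)

    def test_blank_baseline_goes_to_discards(self, manifest_dir, tmp_path):
        _, manifest = manifest_dir
        blank = _write_png(
            tmp_path / "blank.png",
            type("I", (), {"pixels": np.zeros((96, 96))})(),
        )
        manifest = manifest.copy()
        manifest.loc[manifest.embryo_id == "e1", "image_path"] = blank
        results, discards = run_batch(manifest)
        assert list(discards.embryo_id) == ["e1"]
        assert "signal" in discards.reason.iloc[0]
        assert list(results.embryo_id) == ["e2"]  # others still processed

    def test_group_labels_carried(self, manifest_dir):
        _, manifest = manifest_dir
        results, _ = run_batch(manifest)
        assert set(results.temp) == {"warm", "cold"}


class TestRunGroupAnalysis:
    @staticmethod
    def _results(groups):
        rows = []
        for name, pis in groups.items():
            rows += [{"embryo_id": f"{name}{i}", "temp": name, "PI": pi}
                     for i, pi in enumerate(pis)]
        return pd.DataFrame(rows)

    def test_separated_groups_significant(self, rng):
        res = self._results({
            "cold": rng.normal(0.6, 0.05, 20),
            "warm": rng.normal(2.4, 0.05, 20),
        })
        summary, pairwise = run_group_analysis(res, "temp")
        means = dict(zip(summary.group, summary.mean_PI))
        assert means["cold"] == pytest.approx(0.6, abs=0.1)
        assert means["warm"] == pytest.approx(2.4, abs=0.1)
        assert pairwise.significant.all()

    def test_identical_groups_not_significant(self, rng):
        vals = rng.normal(1.0, 0.2, 15)
        res = self._results({"a": vals, "b": vals.copy()})
        _, pairwise = run_group_analysis(res, "temp")
        assert not pairwise.significant.any()

    def test_single_group_raises(self):
        res = self._results({"only": [1.0, 1.1, 0.9, 1.2]})
        with pytest.raises(ValueError, match="2 groups"):
            run_group_analysis(res, "temp")

    def test_outliers_removed_before_comparison(self, rng):
        a = list(rng.normal(1.0, 0.05, 12)) + [50.0]
        b = list(rng.normal(1.05, 0.05, 12))
        res = self._results({"a": a, "b": b})
        summary, _ = run_group_analysis(res, "temp")
        row = summary[summary.group == "a"].iloc[0]
        assert row.n_outliers == 1
        assert row.mean_PI == pytest.approx(1.0, abs=0.1)


class TestCli:
    def test_measure_command(self, manifest_dir):
        tmp_path, manifest = manifest_dir
        sub = manifest[manifest.embryo_id == "e1"].sort_values("timepoint")
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["measure", sub.iloc[0].image_path, sub.iloc[1].image_path,
             "--sweep-csv", str(tmp_path / "sweeps.csv")],
        )
        assert result.exit_code == 0, result.output
        assert '"PI"' in result.output
        sweeps = pd.read_csv(tmp_path / "sweeps.csv")
        assert set(sweeps.timepoint) == {"0hpi", "72hpi"}
        assert sweeps.t.max() == 50

    def test_batch_command(self, manifest_dir):
        tmp_path, _ = manifest_dir
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["batch", str(tmp_path / "manifest.csv"), "--output-dir", str(tmp_path / "out")],
        )
        assert result.exit_code == 0, result.output
        results = pd.read_csv(tmp_path / "out" / "results.csv")
        assert len(results) == 2

    def test_count_command(self, tmp_path):
        from gfpquant import render_cell_drop

        img, _ = render_cell_drop(25, (6, 6), 20, seed=1, image_size=(300, 300))
        p = _write_png(tmp_path / "drop.png", img)
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["count", p, "--r-min", "4", "--r-max", "8",
             "--detections-csv", str(tmp_path / "det.csv")],
        )
        assert result.exit_code == 0, result.output
        assert result.output.strip().splitlines()[-1] == "25"
        assert len(pd.read_csv(tmp_path / "det.csv")) == 25

    def test_simulate_command(self, tmp_path):
        import yaml

        spec = [{
            "name": "ph0",
            "image_size": [64, 64],
            "yolk": {"center": [32, 32], "semi_axes": [20, 24], "plateau": 15},
            "masses": [{"center": [32, 32], "radius": 6, "intensity": 150}],
        }]
        specfile = tmp_path / "specs.yaml"
        specfile.write_text(yaml.safe_dump(spec))
        runner = CliRunner()
        result = runner.invoke(
            cli_main, ["simulate", str(specfile), "--output-dir", str(tmp_path / "sim")]
        )
        assert result.exit_code == 0, result.output
        assert (tmp_path / "sim" / "ph0.png").exists()
        gt = pd.read_csv(tmp_path / "sim" / "ground_truth.csv")
        assert gt.mass_area.iloc[0] > 0

    def test_stats_command(self, tmp_path, rng):
        res = TestRunGroupAnalysis._results({
            "cold": rng.normal(0.6, 0.05, 10),
            "warm": rng.normal(2.4, 0.05, 10),
        })
        res.to_csv(tmp_path / "results.csv", index=False)
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["stats", str(tmp_path / "results.csv"), "--group-by", "temp",
             "--output-dir", str(tmp_path / "st")],
        )
        assert result.exit_code == 0, result.output
        pw = pd.read_csv(tmp_path / "st" / "pairwise_tests.csv")
        assert pw.significant.all()

    def test_config_file_defaults(self, manifest_dir, tmp_path):
        tmp_path_m, manifest = manifest_dir
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("tolerance: 0.2\n")
        sub = manifest[manifest.embryo_id == "e1"].sort_values("timepoint")
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            ["--config", str(cfg), "measure", sub.iloc[0].image_path, sub.iloc[1].image_path],
        )
        assert result.exit_code == 0, result.output

    def test_config_unknown_key_rejected(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("bogus: 1\n")
        runner = CliRunner()
        result = runner.invoke(cli_main, ["--config", str(cfg), "measure", "a", "b"])
        assert result.exit_code != 0
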