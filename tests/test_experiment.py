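import dataclasses
import json

import numpy as np
import pytest
from click.testing import CliRunner

from mwdetect.cli import main as cli_main
from mwdetect.experiment import ExperimentConfig, run_study
from mwdetect.surrogate import TOY_PROFILE


def _tiny_config(out_dir, **overrides) -> ExperimentConfig:
    base = dict(
        name="tiny",
        cohort=dict(n_subjects=60, effect_amplitude=2.0, **TOY_PROFILE),
        noise_floors_db=(-100.0,),
        subset_sizes=(30,),
        repeats=3,
        seed=123,
        output_dir=str(out_dir),
    )
    base.update(overrides)
    return ExperimentConfig(**base)


def test_config_yaml_round_trip(tmp_path):
    cfg = _tiny_config(tmp_path / "out")
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    assert ExperimentConfig.from_yaml(path) == cfg


def test_config_rejects_unknown_keys():
    with pytest.raises(ValueError):
        ExperimentConfig.from_dict({"name": "x", "bogus": 1})


def test_config_rejects_reserved_cohort_overrides():
    with pytest.raises(ValueError):
        ExperimentConfig(cohort={"seed": 3})
    with pytest.raises(ValueError):
        ExperimentConfig(source="tarot")


def test_run_study_outputs_and_manifest(tmp_path):
    cfg = _tiny_config(tmp_path / "out")
    result = run_study(cfg)
    out = result.output_dir
    for name in ("config.yaml", "manifest.json", "summary.json",
                 "learning_curve_nf-100.csv", "summary_nf-100.csv",
                 "auc_vs_size.png", "cohort_nf-100.h5"):
        assert (out / name).exists(), name
    manifest = json.loads((out / "manifest.json").read_text())
    assert manifest["master_seed"] == 123
    assert manifest["config_hash"] == cfg.content_hash()
    assert "cohort_nf-100" in manifest["stage_seeds"]
    assert all(0 <= s < 2 ** 31 for s in manifest["stage_seeds"].values())
    assert set(manifest["outputs"]) <= {p.name for p in out.iterdir()}
    assert -100.0 in result.curves


def test_run_study_reruns_are_byte_identical(tmp_path):
    cfg_a = _tiny_config(tmp_path / "a")
    cfg_b = _tiny_config(tmp_path / "b")
    res_a = run_study(cfg_a)
    res_b = run_study(cfg_b)
    csv_a = (res_a.output_dir / "learning_curve_nf-100.csv").read_bytes()
    csv_b = (res_b.output_dir / "learning_curve_nf-100.csv").read_bytes()
    assert csv_a == csv_b


def test_run_study_refuses_nonempty_dir(tmp_path):
    out = tmp_path / "out"
    out.mkdir()
    (out / "stale.txt").write_text("prior results")
    cfg = _tiny_config(out)
    with pytest.raises(FileExistsError):
        run_study(cfg)
    run_study(dataclasses.replace(cfg, overwrite=True))  # now allowed


def test_cli_cohort_classify_pipeline(tmp_path):
    runner = CliRunner()
    rec_path = str(tmp_path / "cohort.h5")
    r = runner.invoke(cli_main, ["cohort", "--n", "40", "--toy",
                                 "--effect", "3", "--seed", "2",
                                 "--out", rec_path])
    assert r.exit_code == 0, r.output
    assert json.loads(r.output)["n_subjects"] == 40

    r = runner.invoke(cli_main, ["classify", "--records", rec_path,
                                 "--dimension", "2", "--seed", "0"])
    assert r.exit_code == 0, r.output
    payload = json.loads(r.output)
    assert 0.0 <= payload["auc"] <= 1.0


def test_cli_study_from_yaml(tmp_path):
    cfg = _tiny_config(tmp_path / "out", repeats=3)
    path = tmp_path / "study.yaml"
    cfg.to_yaml(path)
    runner = CliRunner()
    r = runner.invoke(cli_main, ["study", "--config", str(path)])
    assert r.exit_code == 0, r.output
    assert (tmp_path / "out" / "manifest.json").exists()


def test_cli_phantom_and_noise(tmp_path):
    runner = CliRunner()
    ph = str(tmp_path / "p.h5")
    r = runner.invoke(cli_main, ["phantom", "--out", ph, "--bleeding",
                                 "--seed", "4"])
    assert r.exit_code == 0, r.output
    assert "volume_ml" in json.loads(r.output)

    rec = str(tmp_path / "c.h5")
    runner.invoke(cli_main, ["cohort", "--n", "4", "--toy", "--out", rec])
    r = runner.invoke(cli_main, ["noise", "--records", rec, "--out",
                                 str(tmp_path / "cn.h5"), "--nf", "-70"])
    assert r.exit_code == 0, r.output
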