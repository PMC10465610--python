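"""Presets, output writers, parameter round trips and the CLI surface."""

import json
import os

import numpy as np
import pandas as pd
import pytest

from rodenergy import (
    ExperimentConfig, StimulusProtocol, default_parameters, load_parameters,
    run_simulation, save_parameters, write_outputs,
)
from rodenergy.protocols import FIG_FLASH_INTENSITIES, run_energy_budget


def test_flash_intensity_preset_matches_publication():
    assert FIG_FLASH_INTENSITIES == (1.7, 4.8, 15.2, 39.4, 125.0, 444.0, 1406.0, 4630.0)


def test_parameter_yaml_round_trip(tmp_path, params):
    path = os.path.join(tmp_path, "params.yaml")
    save_parameters(params, path)
    p2 = load_parameters(path)
    assert p2 == params


def test_config_validation(tmp_path):
    with pytest.raises(ValueError):
        ExperimentConfig(dt=-1.0)
    with pytest.raises(FileNotFoundError):
        ExperimentConfig(params_path=os.path.join(tmp_path, "missing.yaml"))


def test_flash_family_amplitudes_monotone(flash_family):
    _, summary = flash_family
    amps = [r["amplitude_pA"] for r in summary["rows"]]
    assert amps == sorted(amps)
    # intensity 0 would yield zero amplitude by construction of the metric
    assert amps[0] > 0.0


def test_energy_budget_report_consistent(params):
    report = run_energy_budget(params, dt=5e-5)
    for block in (report["darkness"], report["light"]):
        assert block["atp_total"] == pytest.approx(
            block["atp_nak_total"] + block["atp_pmca"] + block["atp_cascade"],
            rel=1e-9,
        )
    assert report["darkness"]["atp_total"] > report["light"]["atp_total"]


def test_write_outputs_round_trip(tmp_path, params):
    """The written CSV re-parses to the in-memory series at 9 significant
    digits, and the JSON report echoes the configuration."""
    proto = StimulusProtocol("flash", 125.0, onset=0.05, duration=0.02)
    series = run_simulation(params, proto, dt=1e-4, t_end=0.2, stride=50)
    cfg = ExperimentConfig(protocol=proto, dt=1e-4, t_end=0.2, stride=50,
                           out_dir=str(tmp_path))
    written = write_outputs(series, {"answer": 42.0}, cfg, basename="trip")
    csv_path = [w for w in written if w.endswith(".csv")][0]
    df = pd.read_csv(csv_path)
    ref = series.to_dataframe()
    assert list(df.columns) == list(ref.columns)
    for col in ("t", "Vm", "Na_i", "ATP_total"):
        np.testing.assert_allclose(df[col].values, ref[col].values, rtol=1e-8)
    with open([w for w in written if w.endswith(".json")][0]) as fh:
        echo = json.load(fh)
    assert echo["config"]["dt"] == 1e-4
    assert echo["report"]["answer"] == 42.0
    assert echo["config"]["protocol"]["intensity"] == 125.0


def test_cli_steady_state_and_validate(tmp_path):
    from rodenergy.cli import main
    rc = main(["steady-state", "--out", str(tmp_path)])
    assert rc == 0
    with open(os.path.join(tmp_path, "steady_state.json")) as fh:
        out = json.load(fh)
    assert out["vm_mV"] == pytest.approx(-36.2, abs=0.01)
    assert os.path.exists(os.path.join(tmp_path, "parameters.yaml"))
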