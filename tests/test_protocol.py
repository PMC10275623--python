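import numpy as np
import pandas as pd
import pytest

from revcorr.protocol import (
    ExperimentConfig,
    build_session_stimuli,
    ingest_responses,
    run_full_pipeline,
    simulate_cohort,
)


@pytest.fixture()
def small_config():
    # scaled-down session so WAV export stays fast in tests
    return ExperimentConfig(
        trials_per_block=5, blocks_per_target=2,
        targets=["buzzing-like", "roaring-like"], master_seed=11,
    )


def _answer_all(manifest, token="yes"):
    return pd.DataFrame(
        {"stimulus_id": manifest["stimulus_id"], "response": token}
    )


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = ExperimentConfig(master_seed=42, trials_per_block=50)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert ExperimentConfig.from_yaml(tmp_path / "cfg.yaml") == cfg

    def test_default_session_accounting_matches_protocol(self):
        cfg = ExperimentConfig()
        assert cfg.trials_per_target == 200  # 2 blocks x 100 trials
        assert cfg.b == 8
        assert (cfg.f_lo, cfg.f_hi) == (100.0, 13000.0)

    def test_config_hash_tracks_content(self):
        assert (
            ExperimentConfig(master_seed=1).config_hash()
            != ExperimentConfig(master_seed=2).config_hash()
        )


class TestBuildSessionStimuli:
    def test_stimulus_count_and_files(self, small_config, tmp_path):
        manifest = build_session_stimuli(small_config, "S01", tmp_path)
        # 2 targets x 2 blocks x 5 trials
        assert len(manifest) == 20
        assert all((tmp_path / f"{sid}.wav").exists()
                   for sid in manifest["stimulus_id"])

    def test_single_block_single_target_scaling(self, tmp_path):
        cfg = ExperimentConfig(trials_per_block=10, blocks_per_target=1,
                               targets=["buzzing-like"])
        manifest = build_session_stimuli(cfg, "S01", tmp_path, write_wavs=False)
        assert len(manifest) == 10

    def test_same_seed_gives_identical_manifest(self, small_config, tmp_path):
        a = build_session_stimuli(small_config, "S01", tmp_path / "a",
                                  write_wavs=False)
        b = build_session_stimuli(small_config, "S01", tmp_path / "b",
                                  write_wavs=False)
        assert a.drop(columns="wav_path").equals(b.drop(columns="wav_path"))

    def test_different_subjects_get_different_stimuli(self, small_config, tmp_path):
        a = build_session_stimuli(small_config, "S01", tmp_path / "a",
                                  write_wavs=False)
        b = build_session_stimuli(small_config, "S02", tmp_path / "b",
                                  write_wavs=False)
        assert not a["mask"].equals(b["mask"])


class TestIngestResponses:
    def test_complete_session_round_trip(self, small_config, tmp_path):
        manifest = build_session_stimuli(small_config, "S01", tmp_path,
                                         write_wavs=False)
        session = ingest_responses(manifest, _answer_all(manifest))
        for target in small_config.targets:
            assert session.psi[target].shape == (10, 8)
            assert np.all(session.y[target] == 1)

    def test_shuffled_rows_join_identically(self, small_config, tmp_path):
        manifest = build_session_stimuli(small_config, "S01", tmp_path,
                                         write_wavs=False)
        rng = np.random.default_rng(0)
        responses = _answer_all(manifest)
        responses["response"] = rng.choice(["yes", "no"], len(responses))
        shuffled = responses.sample(frac=1, random_state=1)
        a = ingest_responses(manifest, responses)
        b = ingest_responses(manifest, shuffled)
        for target in small_config.targets:
            assert np.array_equal(a.y[target], b.y[target])
            assert np.array_equal(a.psi[target], b.psi[target])

    def test_token_spellings_coerced_case_insensitively(self, small_config,
                                                        tmp_path):
        manifest = build_session_stimuli(small_config, "S01", tmp_path,
                                         write_wavs=False)
        tokens = ["YES", "y", "1", "No", "N", "-1"] * 4
        responses = pd.DataFrame({
            "stimulus_id": manifest["stimulus_id"],
            "response": tokens[: len(manifest)],
        })
        session = ingest_responses(manifest, responses)
        joined = np.concatenate([session.y[t] for t in small_config.targets])
        assert set(np.unique(joined)) == {-1, 1}

    @pytest.mark.parametrize(
        "mutate,match",
        [
            (lambda r: r.iloc[0:0], "empty"),
            (lambda r: r.assign(response="maybe"), "token"),
            (lambda r: pd.concat([r, r.iloc[[0]]]), "duplicate"),
            (lambda r: r.iloc[:-3], "incomplete"),
            (
                lambda r: r.assign(
                    stimulus_id=["ghost"] + list(r["stimulus_id"][1:])
                ),
                "unknown",
            ),
        ],
    )
    def test_malformed_logs_rejected(self, small_config, tmp_path, mutate, match):
        manifest = build_session_stimuli(small_config, "S01", tmp_path,
                                         write_wavs=False)
        with pytest.raises(ValueError, match=match):
            ingest_responses(manifest, mutate(_answer_all(manifest)))


class TestFullPipeline:
    def test_ideal_cohort_reconstructs_targets(self, small_config):
        cfg = ExperimentConfig(trials_per_block=100, blocks_per_target=2,
                               master_seed=3)
        sessions = simulate_cohort(cfg, "ideal", n_subjects=10, rng=1)
        out = run_full_pipeline(cfg, sessions)
        assert len(out["accuracies"]) == 20
        for label, test in out["group_tests"].items():
            assert test.mean_r > 0.8
            assert test.p_value < 1e-3

    def test_random_cohort_centers_on_zero(self):
        cfg = ExperimentConfig(master_seed=4)
        sessions = simulate_cohort(cfg, "random", n_subjects=10, rng=2)
        out = run_full_pipeline(cfg, sessions)
        assert abs(out["group_tests"]["combined"].mean_r) < 0.3

    def test_single_subject_single_target_notice(self):
        cfg = ExperimentConfig(targets=["buzzing-like"], trials_per_block=20,
                               blocks_per_target=1)
        sessions = simulate_cohort(cfg, "ideal", n_subjects=1, rng=3)
        out = run_full_pipeline(cfg, sessions)
        assert len(out["accuracies"]) == 1
        assert out["group_tests"] == {}
        assert any("n=1" in note for note in out["notices"])

    def test_end_to_end_determinism(self):
        cfg = ExperimentConfig(trials_per_block=20, master_seed=9)
        outs = []
        for _ in range(2):
            sessions = simulate_cohort(cfg, "ideal", n_subjects=3, rng=7)
            out = run_full_pipeline(cfg, sessions)
            outs.append([a.r for a in out["accuracies"]])
        assert outs[0] == outs[1]

    def test_simulated_session_runtime_is_negligible(self):
        # a full simulated session (generate + respond + reconstruct)
        # must be effectively instantaneous next to the human protocol
        import time

        cfg = ExperimentConfig(master_seed=5)
        t0 = time.perf_counter()
        sessions = simulate_cohort(cfg, "ideal", n_subjects=1, rng=0)
        run_full_pipeline(cfg, sessions)
        assert time.perf_counter() - t0 < 10.0
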