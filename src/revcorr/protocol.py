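"""A-X experiment orchestration: configuration, stimulus export, response
ingestion, and the end-to-end pipeline.

A session presents A-X trials: a fixed target sound A per block followed
by a freshly drawn random stimulus X; the subject answers "yes" if X
seems to contain A.  Each subject completes ``blocks_per_target`` blocks
of ``trials_per_block`` trials per target (defaults 2 x 100, so p = 200
trials per target).  For human runs the package exports WAV stimuli plus
a manifest CSV and later joins a response log back into (Psi, y); for
simulated runs the observers answer directly in the bin domain.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .binning import BinnedSpectrum, BinPartition, make_mel_partition
from .reconstruction import Reconstruction, reconstruct
from .observers import ideal_responses, random_responses
from .stats import AccuracyResult, GroupTestResult, one_sample_t, pearson_r
from .stimulus import (
    StimulusSpec,
    export_stimulus_wav,
    generate_stimulus,
    synthesize_waveform,
)
from .targets import TargetSound, synthesize_target

__all__ = [
    "ExperimentConfig",
    "ExperimentSession",
    "build_session_stimuli",
    "ingest_responses",
    "run_full_pipeline",
    "simulate_cohort",
]

#: Accepted response spellings (case-insensitive); anything else is an error.
RESPONSE_TOKENS = {"yes": 1, "y": 1, "1": 1, "no": -1, "n": -1, "-1": -1}


@dataclass
class ExperimentConfig:
    """Full description of an experiment; serializable to YAML."""

    f_lo: float = 100.0
    f_hi: float = 13000.0
    b: int = 8
    duration: float = 0.5
    sample_rate: float = 44100.0
    min_filled: int = 2
    max_filled: int = 7
    filled_db: float = 0.0
    unfilled_db: float = -100.0
    trials_per_block: int = 100
    blocks_per_target: int = 2
    targets: list[str] = field(default_factory=lambda: ["buzzing-like", "roaring-like"])
    master_seed: int = 0

    @property
    def partition(self) -> BinPartition:
        return make_mel_partition(self.f_lo, self.f_hi, self.b)

    @property
    def trials_per_target(self) -> int:
        """p used in the estimator: the per-target session length."""
        return self.trials_per_block * self.blocks_per_target

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


@dataclass
class ExperimentSession:
    """Joined stimuli and responses for one subject, keyed by target."""

    subject_id: str
    psi: dict[str, np.ndarray]        # target -> (p, b)
    y: dict[str, np.ndarray]          # target -> (p,)
    block_of_trial: dict[str, np.ndarray]
    config_hash: str | None = None

    def __post_init__(self):
        for target, psi in self.psi.items():
            if psi.shape[0] != self.y[target].size:
                raise ValueError(f"stimulus/response length mismatch for {target!r}")


def _subject_entropy(subject_id: str) -> int:
    """Stable (cross-run) integer derived from the subject label."""
    digest = hashlib.sha256(subject_id.encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _stimulus_rng(config: ExperimentConfig, subject_id: str,
                  target_idx: int, block: int, trial: int) -> np.random.Generator:
    seq = np.random.SeedSequence(
        [config.master_seed, _subject_entropy(subject_id), target_idx, block, trial]
    )
    return np.random.default_rng(seq)


def build_session_stimuli(
    config: ExperimentConfig,
    subject_id: str,
    out_dir: str | Path,
    write_wavs: bool = True,
) -> pd.DataFrame:
    """Generate and export the full stimulus set for one subject.

    For every target and block, ``trials_per_block`` stimuli are drawn,
    synthesized, and written as WAV files; the returned (and saved)
    manifest CSV records stimulus_id, target, block, trial, the filled
    mask as a 0/1 string, per-bin dB levels, and the file path.  Fully
    deterministic given (master seed, subject_id).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    partition = config.partition
    rows = []
    for t_idx, target in enumerate(config.targets):
        for block in range(config.blocks_per_target):
            for trial in range(config.trials_per_block):
                rng = _stimulus_rng(config, subject_id, t_idx, block, trial)
                sid = f"{subject_id}_{target}_b{block:02d}_t{trial:03d}"
                spec = generate_stimulus(
                    partition,
                    rng,
                    min_filled=config.min_filled,
                    max_filled=config.max_filled,
                    filled_db=config.filled_db,
                    unfilled_db=config.unfilled_db,
                    stimulus_id=sid,
                    seed_state={
                        "master_seed": config.master_seed,
                        "subject_id": subject_id,
                        "target_idx": t_idx,
                        "block": block,
                        "trial": trial,
                    },
                )
                wav_path = out_dir / f"{sid}.wav"
                if write_wavs:
                    wave = synthesize_waveform(
                        spec, config.sample_rate, config.duration, rng
                    )
                    export_stimulus_wav(wave, wav_path)
                rows.append(
                    {
                        "stimulus_id": sid,
                        "subject_id": subject_id,
                        "target": target,
                        "block": block,
                        "trial": trial,
                        "mask": spec.mask_string,
                        "power_db": " ".join(f"{v:g}" for v in spec.binned.power_db),
                        "wav_path": str(wav_path),
                        "config_hash": config.config_hash(),
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / f"{subject_id}_manifest.csv", index=False)
    return manifest


def _parse_response_token(token) -> int:
    key = str(token).strip().lower()
    if key not in RESPONSE_TOKENS:
        raise ValueError(f"unrecognized response token {token!r}")
    return RESPONSE_TOKENS[key]


def ingest_responses(
    manifest: pd.DataFrame | str | Path,
    responses: pd.DataFrame | str | Path,
) -> ExperimentSession:
    """Join a response log onto a stimulus manifest into (Psi, y).

    Responses are matched by ``stimulus_id`` (row order in the log is
    irrelevant); Psi rows keep presentation order.  Unknown stimulus ids,
    duplicate responses, invalid tokens, and incomplete sessions raise.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if not isinstance(responses, pd.DataFrame):
        responses = pd.read_csv(responses)
    if responses.empty:
        raise ValueError("empty response file: no trials to ingest")
    unknown = set(responses["stimulus_id"]) - set(manifest["stimulus_id"])
    if unknown:
        raise ValueError(f"responses reference unknown stimulus ids: {sorted(unknown)[:5]}")
    dupes = responses["stimulus_id"][responses["stimulus_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"duplicate responses for: {sorted(set(dupes))[:5]}")
    coded = {
        sid: _parse_response_token(tok)
        for sid, tok in zip(responses["stimulus_id"], responses["response"])
    }
    missing = set(manifest["stimulus_id"]) - set(coded)
    if missing:
        by_block = manifest[manifest["stimulus_id"].isin(missing)]
        summary = by_block.groupby(["target", "block"]).size().to_dict()
        raise ValueError(f"incomplete session; missing responses per (target, block): {summary}")

    psi: dict[str, np.ndarray] = {}
    y: dict[str, np.ndarray] = {}
    blocks: dict[str, np.ndarray] = {}
    for target, group in manifest.groupby("target", sort=False):
        group = group.sort_values(["block", "trial"])
        psi[target] = np.array(
            [[float(v) for v in row.split()] for row in group["power_db"]]
        )
        y[target] = np.array([coded[sid] for sid in group["stimulus_id"]])
        blocks[target] = group["block"].to_numpy()
    subject_id = str(manifest["subject_id"].iloc[0])
    chash = (
        str(manifest["config_hash"].iloc[0]) if "config_hash" in manifest else None
    )
    return ExperimentSession(
        subject_id=subject_id, psi=psi, y=y, block_of_trial=blocks, config_hash=chash
    )


def _fixture_target(label: str, config: ExperimentConfig) -> TargetSound:
    rng = np.random.default_rng(
        np.random.SeedSequence([config.master_seed, _subject_entropy(label)])
    )
    return synthesize_target(
        label, config.partition, config.sample_rate, config.duration, rng=rng
    )


def simulate_cohort(
    config: ExperimentConfig,
    subject_kind: str,
    n_subjects: int = 10,
    rng: np.random.Generator | int | None = None,
    targets: dict[str, TargetSound] | None = None,
) -> list[ExperimentSession]:
    """Simulate sessions for a cohort of identical-policy observers."""
    if subject_kind not in ("ideal", "random"):
        raise ValueError(f"unknown subject kind {subject_kind!r}")
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if targets is None:
        targets = {t: _fixture_target(t, config) for t in config.targets}
    from .stimulus import generate_stimulus_batch

    sessions = []
    p = config.trials_per_target
    for i in range(n_subjects):
        psi, y, blocks = {}, {}, {}
        for label in config.targets:
            stim, _ = generate_stimulus_batch(
                config.partition, p, rng,
                min_filled=config.min_filled, max_filled=config.max_filled,
                filled_db=config.filled_db, unfilled_db=config.unfilled_db,
            )
            if subject_kind == "ideal":
                resp = ideal_responses(stim, targets[label].binned.power_db)
            else:
                resp = random_responses(p, rng)
            psi[label], y[label] = stim, resp
            blocks[label] = np.repeat(
                np.arange(config.blocks_per_target), config.trials_per_block
            )
        sessions.append(
            ExperimentSession(
                subject_id=f"sim-{subject_kind}-{i:02d}",
                psi=psi, y=y, block_of_trial=blocks,
                config_hash=config.config_hash(),
            )
        )
    return sessions


def run_full_pipeline(
    config: ExperimentConfig,
    sessions: list[ExperimentSession],
    targets: dict[str, TargetSound] | None = None,
) -> dict:
    """Reconstruct, score, and summarize a set of sessions.

    Per subject x target: the reverse-correlation estimate and its
    Pearson r against the binned target; per target (and combined): a
    one-sample t-test on Fisher-z accuracies when the cohort has n >= 2,
    otherwise an explicit notice.  Returns a dict with keys
    ``reconstructions``, ``accuracies``, ``group_tests``, ``notices``.
    """
    if targets is None:
        targets = {t: _fixture_target(t, config) for t in config.targets}
    reconstructions: list[Reconstruction] = []
    accuracies: list[AccuracyResult] = []
    notices: list[str] = []
    for session in sessions:
        for label in config.targets:
            if label not in session.psi:
                raise ValueError(
                    f"session {session.subject_id!r} lacks target {label!r}"
                )
            rec = reconstruct(
                session.psi[label], session.y[label],
                subject_id=session.subject_id, target_label=label,
            )
            reconstructions.append(rec)
            accuracies.append(
                AccuracyResult(
                    r=pearson_r(rec.x_hat, targets[label].binned.power_db),
                    subject_id=session.subject_id,
                    target_label=label,
                )
            )
    group_tests: dict[str, GroupTestResult] = {}
    by_target: dict[str, list[float]] = {}
    for acc in accuracies:
        by_target.setdefault(acc.target_label, []).append(acc.r)
    all_r = [acc.r for acc in accuracies]
    for label, rs in list(by_target.items()) + [("combined", all_r)]:
        if len(rs) >= 2:
            group_tests[label] = one_sample_t(rs)
        else:
            notices.append(f"{label}: n={len(rs)} < 2, no group test performed")
    return {
        "reconstructions": reconstructions,
        "accuracies": accuracies,
        "group_tests": group_tests,
        "notices": notices,
        "config_hash": config.config_hash(),
    }
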