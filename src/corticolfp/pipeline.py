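"""End-to-end orchestration: simulate -> preprocess -> features -> stats.

Every stage writes plain-format outputs (HDF5 recordings, CSV tables,
JSON summaries) plus a manifest carrying the full configuration, its
hash and the package version, so a re-run with the same config is
byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import h5py
import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    CohortTable,
    compare_real_vs_null,
    permutation_null,
    single_feature_importance,
)
from .config import PipelineConfig, validate_config
from .phenotype import (
    average_last_sessions,
    median_split,
    mixed_anova_2x2,
    two_sample_t,
)
from .preprocessing import preprocess
from .recording import RawRecording, load_recording, save_recording
from .spectral import FeatureVector, combine_sessions, extract_features
from .synthetic import (
    CohortSpec,
    build_subject_specs,
    generate_drinking_table,
    generate_recording,
    inject_artifacts,
)

__all__ = [
    "run_pipeline",
    "simulate_cohort",
    "cohort_feature_table",
    "subject_features",
]

logger = logging.getLogger(__name__)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def cohort_spec_from_config(config: PipelineConfig) -> CohortSpec:
    return CohortSpec(
        n_subjects=config.n_subjects,
        n_sessions_recording=config.n_sessions_recording,
        recording_duration=config.recording_duration,
        sampling_rate=config.sampling_rate,
        n_drinking_sessions=config.n_drinking_sessions,
        n_stim_sessions=config.n_stim_sessions,
        group_effect=dict(config.group_effect),
        seed=config.seed,
        band_scheme=config.band_scheme,
    )


def simulate_cohort(
    config: PipelineConfig,
    artifact_rate: float = 0.0,
    artifact_amplitude: float = 3.0,
) -> Tuple[Dict[Tuple[str, str], RawRecording], pd.DataFrame]:
    """Generate all recordings and the drinking table for a cohort.

    Returns ``(recordings, drinking)`` where recordings are keyed by
    ``(subject_id, session_id)``. Seeds are derived deterministically
    from ``config.seed`` per subject and session.
    """
    spec = cohort_spec_from_config(config)
    subjects = build_subject_specs(spec)
    rng = np.random.default_rng(config.seed)
    recordings: Dict[Tuple[str, str], RawRecording] = {}
    for subj in subjects:
        for s in range(1, config.n_sessions_recording + 1):
            session_id = f"session{s:02d}"
            rec_seed = int(rng.integers(0, 2**31 - 1))
            rec = generate_recording(
                subj,
                duration=config.recording_duration,
                fs=config.sampling_rate,
                seed=rec_seed,
                session_id=session_id,
                scheme=config.band_scheme,
            )
            if artifact_rate > 0:
                art_seed = int(rng.integers(0, 2**31 - 1))
                rec = inject_artifacts(
                    rec, rate=artifact_rate, amplitude=artifact_amplitude, seed=art_seed
                )
            recordings[(subj.subject_id, session_id)] = rec
    drink_seed = int(rng.integers(0, 2**31 - 1))
    drinking = generate_drinking_table(spec, seed=drink_seed)
    return recordings, drinking


def subject_features(
    sessions: List[RawRecording], config: PipelineConfig
) -> FeatureVector:
    """Preprocess each session, extract 60 features, average across sessions."""
    vectors = []
    for rec in sessions:
        epochs = preprocess(
            rec,
            notch_center=config.notch_center,
            notch_order=config.notch_order,
            notch_bandwidth=config.notch_bandwidth,
            notch_ripple_db=config.notch_ripple_db,
            decimation_factor=config.decimation_factor,
            threshold=config.artifact_threshold_mv,
            pre_window=config.artifact_pre_window_s,
            post_window=config.artifact_post_window_s,
            epoch_length=config.epoch_length_s,
        )
        vectors.append(
            extract_features(
                epochs,
                scheme=config.band_scheme,
                window_length=config.welch_window_s,
                overlap_fraction=config.welch_overlap,
                power_domain=config.power_domain,
            )
        )
    return combine_sessions(vectors)


def cohort_feature_table(
    recordings: Dict[Tuple[str, str], RawRecording], config: PipelineConfig
) -> pd.DataFrame:
    """Feature matrix (subjects x features) from a cohort's recordings."""
    by_subject: Dict[str, List[RawRecording]] = {}
    for (subject_id, _), rec in sorted(recordings.items()):
        by_subject.setdefault(subject_id, []).append(rec)
    rows = {}
    for subject_id, recs in by_subject.items():
        vec = subject_features(recs, config)
        rows[subject_id] = vec.values
    return pd.DataFrame(rows).T.rename_axis("subject_id")


def run_pipeline(config: PipelineConfig, outdir: Path) -> Dict[str, object]:
    """Execute the full analysis and write artifacts under ``outdir``.

    Stages: simulate, preprocess+features, phenotype, classify,
    stimulation stats. Outputs: ``recordings.h5``, ``drinking.csv``,
    ``features.csv``, ``labels.csv``, ``classification.json``,
    ``stimulation_anova.csv`` and ``manifest.json``.
    """
    errors = validate_config(config)
    if errors:
        raise ValueError("invalid configuration:\n- " + "\n- ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: Dict[str, object] = {}

    def stage(name):
        logger.info("stage %s starting", name)
        return time.time()

    # -- simulate -------------------------------------------------------
    t0 = stage("simulate")
    recordings, drinking = simulate_cohort(config)
    with h5py.File(outdir / "recordings.h5", "w") as f:
        for (subject_id, session_id), rec in sorted(recordings.items()):
            g = f.create_group(f"{subject_id}/{session_id}")
            save_recording(rec, g)
    drinking.to_csv(outdir / "drinking.csv", index=False)
    logger.info("stage simulate done in %.1fs", time.time() - t0)

    # -- features -------------------------------------------------------
    t0 = stage("features")
    features = cohort_feature_table(recordings, config)
    features.to_csv(outdir / "features.csv")
    logger.info(
        "stage features done in %.1fs (%d subjects x %d features)",
        time.time() - t0,
        *features.shape,
    )

    # -- phenotype ------------------------------------------------------
    t0 = stage("phenotype")
    training_avg = average_last_sessions(drinking, k=config.last_k_sessions)
    labels = median_split(training_avg)
    lab_series = labels.to_series().rename_axis("subject_id")
    pd.DataFrame(
        {"group": lab_series, "training_avg_g_per_kg": pd.Series(training_avg)}
    ).rename_axis("subject_id").to_csv(outdir / "labels.csv")
    hd = [training_avg[s] for s in labels.subjects("HD")]
    ld = [training_avg[s] for s in labels.subjects("LD")]
    ttest = two_sample_t(hd, ld)
    summary["phenotype"] = {
        "split_value_g_per_kg": labels.split_value,
        "n_hd": len(hd),
        "n_ld": len(ld),
        "t": ttest.t,
        "df": ttest.df,
        "p": ttest.p,
    }
    logger.info("stage phenotype done in %.1fs", time.time() - t0)

    # -- classify -------------------------------------------------------
    t0 = stage("classify")
    table = CohortTable(features=features, labels=lab_series)
    perm = permutation_null(
        table,
        n_permutations=config.permutations,
        folds=config.folds,
        repetitions=config.repetitions,
        seed=config.seed,
    )
    decision = compare_real_vs_null(perm)
    summary["classification"] = decision
    with open(outdir / "classification.json", "w") as f:
        json.dump(
            {
                **decision,
                "per_repetition_accuracies": perm.real.per_repetition_accuracies.tolist(),
                "null_accuracies": perm.null_accuracies.tolist(),
                "seed": config.seed,
                "folds": config.folds,
                "repetitions": config.repetitions,
                "permutations": config.permutations,
            },
            f,
            indent=2,
        )
    if config.run_feature_importance and decision["outperforms_chance"]:
        importance = single_feature_importance(
            table,
            folds=config.folds,
            repetitions=min(config.repetitions, 20),
            n_permutations=min(config.permutations, 50),
            seed=config.seed,
        )
        importance.to_csv(outdir / "feature_importance.csv")
        summary["top_features"] = importance.head(5).index.tolist()
    logger.info("stage classify done in %.1fs", time.time() - t0)

    # -- stimulation response -------------------------------------------
    t0 = stage("stim-stats")
    stim_avg = {
        s: float(v)
        for s, v in drinking[drinking["session_type"] == "stimulation"]
        .groupby("subject_id")["g_per_kg"]
        .mean()
        .items()
    }
    anova = mixed_anova_2x2(training_avg, stim_avg, labels)
    anova.to_frame().to_csv(outdir / "stimulation_anova.csv")
    summary["stimulation_anova"] = anova.effects
    logger.info("stage stim-stats done in %.1fs", time.time() - t0)

    manifest = {
        "config": config.to_dict(),
        "config_sha256": _config_hash(config),
        "package_version": __version__,
        "seed": config.seed,
    }
    with open(outdir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    summary["manifest"] = manifest
    return summary
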