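"""End-to-end orchestration: ingest -> resample -> formant tracks -> replicas
-> features -> site/formant ranking -> window-length sweep -> LDA/LOO.

Every stage's output is persisted as delimited text under the run directory,
and a manifest (config echo, input hashes, library versions) makes a run
reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassificationResult, loo_evaluate
from .cohort_stats import (
    TestResult,
    assign_groups,
    optimal_window,
    rank_sites_formants,
    sweep_window_lengths,
)
from .errors import CardioformantError
from .features import (
    SpectrogramParams,
    compute_spectrogram,
    frame_feature_profile,
    profile_segment_mean,
)
from .formants import track_formants
from .pcg_io import PcgRecording, load_cohort_metadata, read_wav, resample
from .replica import synthesize_replica

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run, echoed into the run manifest."""

    analysis_rate: float = 8000.0
    frame_duration: float = 0.032
    lpc_order: int = 8
    taper: str = "hamming"
    min_pole_radius: float = 0.7
    spectrogram: SpectrogramParams = field(default_factory=SpectrogramParams)
    feature: str = "entropy"
    window_lengths: tuple = tuple(float(L) for L in range(1, 21))
    ranking_window: float | None = None  # None: whole framed recording
    alpha: float = 0.05
    lda_priors: str = "empirical"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["window_lengths"] = list(self.window_lengths)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spec = raw.pop("spectrogram", None)
        cfg = cls(**raw)
        if spec:
            cfg.spectrogram = SpectrogramParams(**spec)
        if isinstance(cfg.window_lengths, list):
            cfg.window_lengths = tuple(float(L) for L in cfg.window_lengths)
        return cfg


@dataclass
class RecordingProfiles:
    """Cached per-formant feature profiles for one (subject, site) recording."""

    subject_id: str
    site: str
    frame_times: np.ndarray
    profiles: np.ndarray  # (4, n_spectrogram_frames)
    duration: float  # framed duration at the analysis rate
    n_degenerate: int
    sha256: str


def process_recording(rec: PcgRecording, config: PipelineConfig) -> RecordingProfiles:
    """Run one recording through tracking, replica synthesis and STFT.

    Returns the per-formant per-frame feature contributions from which any
    window-length feature can be assembled by summation.
    """
    digest = hashlib.sha256(np.ascontiguousarray(rec.samples).tobytes()).hexdigest()
    work = resample(rec.normalized(), config.analysis_rate)
    track = track_formants(
        work,
        frame_duration=config.frame_duration,
        order=config.lpc_order,
        taper=config.taper,
        min_pole_radius=config.min_pole_radius,
    )
    rep = synthesize_replica(track)
    profiles = []
    frame_times = None
    for f in range(4):
        spec = compute_spectrogram(rep.waveforms[f], rep.rate, config.spectrogram)
        profiles.append(frame_feature_profile(spec, config.feature))
        frame_times = spec.frame_times
    return RecordingProfiles(
        subject_id=rec.subject_id,
        site=rec.site,
        frame_times=frame_times,
        profiles=np.vstack(profiles),
        duration=rep.n_samples / rep.rate,
        n_degenerate=track.n_degenerate,
        sha256=digest,
    )


def feature_table(
    processed: dict,
    groups: dict,
    window_lengths,
    kind: str,
    sites=None,
    formants=(1, 2, 3, 4),
) -> pd.DataFrame:
    """Tidy feature table from cached profiles.

    ``processed`` maps (subject_id, site) -> RecordingProfiles and ``groups``
    maps subject_id -> group label.
    """
    rows = []
    for (subject_id, site), prof in processed.items():
        if sites is not None and site not in sites:
            continue
        for f in formants:
            for L in window_lengths:
                eff_L = prof.duration if L is None else float(L)
                value, n_seg = profile_segment_mean(
                    prof.profiles[f - 1], prof.frame_times, eff_L, prof.duration
                )
                rows.append(
                    {
                        "subject_id": subject_id,
                        "group": groups[subject_id],
                        "site": site,
                        "formant": f,
                        "feature": kind,
                        "window_length_s": eff_L,
                        "n_segments": n_seg,
                        "value": value,
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class PipelineResult:
    selected_site: str
    selected_formant: int
    ranking: list
    sweep: list
    optimal_window_length: float
    classification: ClassificationResult
    run_dir: Path | None = None
    n_failed_recordings: int = 0


def _results_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "site": r.site,
                "formant": r.formant,
                "window_length_s": r.window_length,
                "t": r.t,
                "df": r.df,
                "p_raw": r.p_raw,
                "p_corrected": r.p_corrected,
            }
            for r in results
        ]
    )


def run_pipeline(
    metadata: pd.DataFrame | str | Path,
    config: PipelineConfig | None = None,
    outdir=None,
    recordings: dict | None = None,
) -> PipelineResult:
    """Execute the full detection pipeline on a cohort.

    ``metadata`` is the cohort table (or a path to one); WAV paths resolve
    relative to the metadata file's directory.  ``recordings`` may supply
    in-memory PcgRecording objects keyed by (subject_id, site), bypassing
    file I/O (used with synthetic cohorts).
    """
    config = config or PipelineConfig()
    base_dir = Path(".")
    if not isinstance(metadata, pd.DataFrame):
        base_dir = Path(metadata).parent
        metadata = load_cohort_metadata(metadata)
    labeled = assign_groups(metadata)
    groups = dict(zip(labeled["subject_id"], labeled["group"]))

    processed: dict = {}
    failures = []
    for row in labeled.itertuples(index=False):
        key = (row.subject_id, row.site)
        try:
            if recordings is not None and key in recordings:
                rec = recordings[key]
                rec = PcgRecording(rec.samples, rec.sampling_rate, row.site, row.subject_id)
            else:
                rec = read_wav(base_dir / row.wav_path, site=row.site, subject_id=row.subject_id)
            processed[key] = process_recording(rec, config)
        except (CardioformantError, FileNotFoundError, OSError) as exc:
            failures.append((key, str(exc)))
            logger.warning("skipping %s/%s: %s", row.subject_id, row.site, exc)
    if not processed:
        raise CardioformantError("ingest stage failed: no recording could be processed")
    if failures:
        logger.warning("%d recording(s) failed and were skipped", len(failures))

    # stage: site/formant ranking at the ranking window
    ranking_features = feature_table(
        processed, groups, [config.ranking_window], config.feature
    )
    ranking = rank_sites_formants(ranking_features, alpha=config.alpha)
    best = ranking[0]

    # stage: window-length sweep at the selected (site, formant)
    sweep_features = feature_table(
        processed,
        groups,
        config.window_lengths,
        config.feature,
        sites=(best.site,),
        formants=(best.formant,),
    )
    sweep = sweep_window_lengths(sweep_features)
    opt = optimal_window(sweep)

    # stage: LDA with leave-one-out at the optimal window length
    cls_rows = sweep_features[sweep_features["window_length_s"] == opt.window_length]
    cls_rows = cls_rows.sort_values("subject_id").reset_index(drop=True)
    result = loo_evaluate(
        cls_rows["value"].to_numpy(), cls_rows["group"].to_numpy(), priors=config.lda_priors
    )

    out = PipelineResult(
        selected_site=best.site,
        selected_formant=best.formant,
        ranking=ranking,
        sweep=sweep,
        optimal_window_length=opt.window_length,
        classification=result,
        n_failed_recordings=len(failures),
    )
    if outdir is not None:
        out.run_dir = _persist(
            Path(outdir), config, labeled, processed, ranking_features, sweep_features,
            ranking, sweep, cls_rows, result, failures,
        )
    return out


def _persist(
    outdir: Path,
    config: PipelineConfig,
    labeled: pd.DataFrame,
    processed: dict,
    ranking_features: pd.DataFrame,
    sweep_features: pd.DataFrame,
    ranking: list,
    sweep: list,
    cls_rows: pd.DataFrame,
    result: ClassificationResult,
    failures: list,
) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.concat([ranking_features, sweep_features]).to_csv(
        outdir / "features.tsv", sep="\t", index=False
    )
    _results_frame(ranking).to_csv(outdir / "site_formant_tests.tsv", sep="\t", index=False)
    _results_frame(sweep).to_csv(outdir / "window_sweep.tsv", sep="\t", index=False)
    preds = cls_rows.copy()
    preds["predicted"] = [p for _, _, p in result.predictions]
    preds["split_index"] = [i for i, _, _ in result.predictions]
    preds.to_csv(outdir / "predictions.tsv", sep="\t", index=False)
    best, opt = ranking[0], optimal_window(sweep)
    summary = {
        "selected_site": best.site,
        "selected_formant": best.formant,
        "selection_p_raw": best.p_raw,
        "selection_p_corrected": best.p_corrected,
        "optimal_window_length_s": opt.window_length,
        "optimal_p_raw": opt.p_raw,
        "optimal_p_corrected": opt.p_corrected,
        "confusion": {"TP": result.tp, "FP": result.fp, "TN": result.tn, "FN": result.fn},
        "sensitivity_pct": result.sensitivity,
        "specificity_pct": result.specificity,
        "n_failed_recordings": len(failures),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "config": config.to_dict(),
        "n_subjects": int(labeled["subject_id"].nunique()),
        "inputs": {
            f"{sid}/{site}": prof.sha256 for (sid, site), prof in sorted(processed.items())
        },
        "failed": [f"{sid}/{site}: {msg}" for (sid, site), msg in failures],
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return outdir
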