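"""End-to-end orchestration: simulate → align → segment → QC → features
→ reference targets → train → validate.

The pipeline is a pure function of a :class:`PipelineConfig` (including
its seeds): two runs with the same config produce bit-identical
artifacts.  Every beat dropped at any stage appears exactly once in the
drop log with a reason code.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import acquisition as acq
from . import qc as qcmod
from .features import (FEATURE_CODES, FeatureIncompleteError,
                       extract_feature_vector, locate_rois)
from .reference import (BinningScheme, IncompleteSystoleError, bin_value,
                        extract_pressure_targets)
from .simulate import (GroundTruth, MultiChannelRecording, PacingConfig,
                       default_configs, default_subjects, simulate_dataset)

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "process_recording",
    "build_feature_table",
    "simulate_and_extract",
    "run_pipeline",
]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Every tunable of the end-to-end run, with reproducible seeds."""

    seed: int
    # simulator
    n_subjects: int = 5
    duration_s: float = 60.0
    heart_rate_bpm: float = 100.0
    locations: tuple[str, ...] = ("mitral_valve",)
    artifact_rate: float = 0.02
    gain_spread: float = 0.15
    noise_sd: float = 0.005
    # QC
    coherence_threshold: float = 0.95
    lag_frac: float = 0.05
    # binning
    lvp_bin_widths: tuple[float, ...] = (20.0, 10.0, 5.0)
    dpdt_bin_widths: tuple[float, ...] = (200.0, 100.0, 50.0)
    lvp_range: tuple[float, float] = (60.0, 130.0)
    dpdt_range: tuple[float, float] = (600.0, 1600.0)
    # model
    n_trees: int = 50
    search_n_trees: int = 10
    max_splits_factor: int = 4
    # validation
    k: int = 10
    search_k: int = 5
    repeats: int = 1
    holdout_fraction: float = 0.05
    min_train_per_class: int = 10
    run_loso: bool = False
    metric: str = "accuracy"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("config must carry a seed")
        if not 0 <= self.artifact_rate < 1:
            raise ConfigError("artifact_rate must lie in [0, 1)")
        if not 0 < self.coherence_threshold <= 1:
            raise ConfigError("coherence_threshold must lie in (0, 1]")
        if self.k < 2 or self.search_k < 2:
            raise ConfigError("k and search_k must be >= 2")
        if not 0 < self.holdout_fraction < 1:
            raise ConfigError("holdout_fraction must lie in (0, 1)")
        if self.metric not in ("accuracy", "loss"):
            raise ConfigError("metric must be 'accuracy' or 'loss'")
        if any(w <= 0 for w in
               tuple(self.lvp_bin_widths) + tuple(self.dpdt_bin_widths)):
            raise ConfigError("bin widths must be positive")
        self.locations = tuple(self.locations)
        self.lvp_bin_widths = tuple(float(w) for w in self.lvp_bin_widths)
        self.dpdt_bin_widths = tuple(float(w) for w in self.dpdt_bin_widths)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a mapping")
        if "seed" not in raw:
            raise ConfigError("config file must define 'seed'")
        known = {f.name for f in
                 cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def schemes(self) -> list[BinningScheme]:
        lvp = [BinningScheme(*self.lvp_range, w, "lvpmax")
               for w in self.lvp_bin_widths]
        dpdt = [BinningScheme(*self.dpdt_range, w, "dpdtmax")
                for w in self.dpdt_bin_widths]
        return lvp + dpdt

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Recording -> feature/target rows
# ---------------------------------------------------------------------------

@dataclass
class SettingResult:
    rows: list[dict]
    drops: list[dict]
    qc_summary: dict
    kept_cycles: list[int]


def process_recording(
    recording: MultiChannelRecording,
    pacing: PacingConfig,
    locations: tuple[str, ...],
    coherence_threshold: float = 0.95,
    lag_frac: float = 0.05,
    truth: GroundTruth | None = None,
) -> SettingResult:
    """Full per-recording chain: align, filter, segment, QC, extract.

    Returns one feature/target row per beat that survives segmentation,
    three-way coherence QC and feature extraction, for every requested
    sensor location.  When the simulator ground truth is supplied its
    per-beat values and artifact flags are joined onto the rows (oracle
    columns, never used by the models).
    """
    setting = recording.metadata.get("setting", "recording")
    drops: list[dict] = []

    aligned = acq.align_and_resample(recording)
    fs = aligned.fs_common
    ecg_f = acq.bandpass_filter(aligned.channels["ecg"], fs, "ecg")
    a_rel, v_rel = acq.detect_pacing_spikes(ecg_f, fs, pacing)
    a_abs, v_abs = a_rel + aligned.t0, v_rel + aligned.t0
    if len(a_abs) < 2:
        raise acq.AlignmentError(f"{setting}: no pacing spikes found")

    filtered = dict(aligned.channels)
    filtered["ecg"] = ecg_f
    z_channels = {}
    for loc in locations:
        label = f"accel_{loc}_z"
        filtered[label] = acq.bandpass_filter(
            aligned.channels[label], fs, "accel")
        z_channels[loc] = label
    aligned_f = acq.AlignedRecording(
        channels=filtered, fs_common=fs, t0=aligned.t0,
        offset_applied=aligned.offset_applied, repairs=aligned.repairs,
        metadata=aligned.metadata,
    )

    chan_map = {"ecg": "ecg"}
    chan_map.update({f"accel_{loc}": lab for loc, lab in z_channels.items()})
    beats = acq.segment_beats(aligned_f, a_abs, v_abs, chan_map, pacing)
    pressure_beats = acq.segment_pressure_beats(aligned, a_abs)

    segmented = {b.beat_index for b in beats["ecg"]}
    for k in range(len(a_abs) - 1):
        if k not in segmented:
            drops.append({"setting": setting, "beat": k,
                          "stage": "segmentation",
                          "reason": "implausible_spacing_or_span"})
    p_indices = {b.beat_index for b in pressure_beats}

    # --- coherence QC per signal kind -------------------------------------
    kept_sets: dict[str, set[int]] = {}
    qc_summary: dict = {"setting": setting, "kinds": {}}
    kind_beats: dict[str, list] = dict(beats)
    kind_beats["pressure"] = pressure_beats
    for kind, blist in kind_beats.items():
        if len(blist) < 2:
            kept_sets[kind] = {b.beat_index for b in blist}
            continue
        resampled = qcmod.resample_beats_to_modal_length(blist)
        kept_pos, report = qcmod.coherence_group(
            resampled, coherence_threshold, lag_frac=lag_frac,
            setting=setting, signal_kind=kind,
        )
        kept_sets[kind] = {resampled[i].beat_index for i in kept_pos}
        for i in report.rejected:
            drops.append({"setting": setting,
                          "beat": resampled[i].beat_index,
                          "stage": f"qc_{kind}", "reason": "incoherent"})
        qc_summary["kinds"][kind] = {
            "n": len(blist), "kept": len(kept_pos),
            "rejected": len(report.rejected),
        }

    accel_kept: set[int] = set.intersection(
        *[kept_sets[f"accel_{loc}"] for loc in locations]
    )
    try:
        final = qcmod.cross_confirm(kept_sets["ecg"], accel_kept,
                                    kept_sets["pressure"] & p_indices)
    except qcmod.EmptyIntersectionError:
        qc_summary["unusable"] = True
        return SettingResult([], drops, qc_summary, [])
    qc_summary["final_kept"] = len(final)

    # --- reference targets ------------------------------------------------
    targets: dict[int, tuple[float, float]] = {}
    for b in pressure_beats:
        if b.beat_index not in final:
            continue
        try:
            targets[b.beat_index] = extract_pressure_targets(b)
        except IncompleteSystoleError as exc:
            drops.append({"setting": setting, "beat": b.beat_index,
                          "stage": "reference", "reason": str(exc)})

    # --- acceleration features (Z axis only) ------------------------------
    meta = recording.metadata
    # Detected-spike beat indices need not equal the generator's cycle
    # numbers (leading beats can fall outside the aligned span), so the
    # oracle is joined by nearest atrial-spike time.
    truth_map = {}
    if truth is not None:
        for k in range(len(a_abs) - 1):
            j = int(np.argmin(np.abs(truth.beat_times - a_abs[k])))
            if abs(truth.beat_times[j] - a_abs[k]) < 0.05:
                truth_map[k] = (truth.lvpmax[j], truth.dpdtmax[j],
                                bool(truth.artifact_flags[j]))
    rows: list[dict] = []
    for loc in locations:
        loc_beats = [b for b in beats[f"accel_{loc}"]
                     if b.beat_index in final]
        if not loc_beats:
            continue
        norm_scale = max(float(np.max(np.abs(b.samples)))
                         for b in loc_beats)
        for b in loc_beats:
            if b.beat_index not in targets:
                continue
            if b.v_spike_time is None:
                drops.append({"setting": setting, "beat": b.beat_index,
                              "stage": f"features_{loc}",
                              "reason": "missing_v_spike"})
                continue
            try:
                rois = locate_rois(b, norm_scale=norm_scale)
                fv = extract_feature_vector(
                    b, rois, norm_scale=norm_scale,
                    sensor_location=loc, setting=setting,
                )
            except FeatureIncompleteError as exc:
                drops.append({"setting": setting, "beat": b.beat_index,
                              "stage": f"features_{loc}",
                              "reason": str(exc)})
                continue
            lvp, dpdt = targets[b.beat_index]
            row = {
                "subject": meta.get("subject", "unknown"),
                "setting": setting,
                "location": loc,
                "beat_index": b.beat_index,
                "mode": pacing.mode,
                "av_delay_ms": pacing.av_delay_ms,
                "vv_delay_ms": pacing.vv_delay_ms,
                "state": pacing.state,
                **fv.values,
                "lvpmax": lvp,
                "dpdtmax": dpdt,
            }
            if b.beat_index in truth_map:
                t_lvp, t_dpdt, t_art = truth_map[b.beat_index]
                row.update(true_lvpmax=float(t_lvp),
                           true_dpdtmax=float(t_dpdt),
                           true_artifact=t_art)
            rows.append(row)
    return SettingResult(rows, drops, qc_summary, final)


def build_feature_table(
    recordings: list[MultiChannelRecording],
    pacings: list[PacingConfig],
    locations: tuple[str, ...],
    schemes: list[BinningScheme],
    coherence_threshold: float = 0.95,
    lag_frac: float = 0.05,
    truths: list[GroundTruth] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Process every recording and assemble the training table.

    Returns ``(table, drop_log, qc_summaries)``; the table carries the
    17 feature columns, the physical targets, and one bin column per
    scheme (named ``bin_<scheme>``).
    """
    all_rows, all_drops, summaries = [], [], []
    for i, (rec, pacing) in enumerate(zip(recordings, pacings)):
        truth = truths[i] if truths is not None else None
        result = process_recording(
            rec, pacing, locations, coherence_threshold, lag_frac, truth)
        all_rows.extend(result.rows)
        all_drops.extend(result.drops)
        summaries.append(result.qc_summary)
    table = pd.DataFrame(all_rows)
    if not table.empty:
        for scheme in schemes:
            src = table[scheme.target]
            table[f"bin_{scheme.name}"] = [
                bin_value(v, scheme) for v in src
            ]
    drop_log = pd.DataFrame(
        all_drops, columns=["setting", "beat", "stage", "reason"])
    return table, drop_log, summaries


def simulate_and_extract(
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Simulate the cohort under ``config`` and run it through the
    acquisition/QC/feature chain."""
    subjects = default_subjects(
        config.n_subjects, seed=config.seed,
        locations=tuple(config.locations), gain_spread=config.gain_spread,
        noise_sd=config.noise_sd,
    )
    configs = default_configs(config.duration_s, config.heart_rate_bpm)
    recordings, truths = simulate_dataset(
        subjects, configs, config.locations,
        artifact_rate=config.artifact_rate, seed=config.seed + 1,
    )
    pacings = [PacingConfig(**r.metadata["pacing"]) for r in recordings]
    return build_feature_table(
        recordings, pacings, config.locations, config.schemes(),
        config.coherence_threshold, config.lag_frac, truths,
    )


# ---------------------------------------------------------------------------
# Full run with artifacts on disk
# ---------------------------------------------------------------------------

def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the whole study on synthetic data and write all artifacts.

    Per sensor location and per binning scheme: the greedy-selected
    feature subset, the repeated-k-fold validation report, a stratified
    holdout confusion matrix, and the serialized ensemble.  A manifest
    records the config, its hash and the package version; no wall-clock
    information enters any artifact, so reruns are bit-identical.
    """
    from . import __version__
    from .evaluation import (anova_one_way, greedy_feature_search,
                             holdout_validate, kfold_validate,
                             stratified_holdout_split)
    from .trees import ensemble_to_json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    log.info("stage=simulate+extract subjects=%d locations=%s",
             config.n_subjects, config.locations)
    table, drop_log, qc_summaries = simulate_and_extract(config)
    if table.empty:
        raise RuntimeError("pipeline produced no usable beats")
    table.to_csv(outdir / "features.csv", index=False, float_format="%.8g")
    drop_log.to_csv(outdir / "drop_log.csv", index=False)
    _write_json(outdir / "qc_summary.json", qc_summaries)

    rng = np.random.default_rng(config.seed + 2)
    summary: dict = {"locations": {}, "n_beats": int(
        table.groupby(["setting", "beat_index"]).ngroups)}
    schemes = config.schemes()
    for loc in config.locations:
        sub = table[table["location"] == loc].reset_index(drop=True)
        loc_dir = outdir / loc
        loc_dir.mkdir(exist_ok=True)
        loc_summary: dict = {}
        for scheme in schemes:
            label = f"bin_{scheme.name}"
            seed_search = int(rng.integers(0, 2**31 - 1))
            seed_val = int(rng.integers(0, 2**31 - 1))
            seed_hold = int(rng.integers(0, 2**31 - 1))
            max_splits = config.max_splits_factor * scheme.n_bins
            subset, trace = greedy_feature_search(
                sub, FEATURE_CODES, label, scheme.n_bins,
                metric=config.metric, k=config.search_k, seed=seed_search,
                n_trees=config.search_n_trees, max_splits=max_splits,
            )
            report = kfold_validate(
                sub, subset, label, scheme.n_bins, k=config.k,
                repeats=config.repeats, seed=seed_val,
                n_trees=config.n_trees, max_splits=max_splits,
                scheme_name=scheme.name,
            )
            train, hold = stratified_holdout_split(
                sub, label, config.holdout_fraction,
                config.min_train_per_class, seed=seed_hold,
            )
            hold_report = None
            ens = None
            if not hold.empty:
                hold_report, ens = holdout_validate(
                    train, hold, subset, label, scheme.n_bins,
                    seed=seed_hold, n_trees=config.n_trees,
                    max_splits=max_splits, scheme_name=scheme.name,
                )
            trace.to_frame().to_csv(
                loc_dir / f"search_{scheme.name}.csv", index=False)
            _write_json(loc_dir / f"validation_{scheme.name}.json",
                        report.to_dict())
            pd.DataFrame(report.confusion).to_csv(
                loc_dir / f"confusion_kfold_{scheme.name}.csv", index=False)
            if hold_report is not None:
                _write_json(loc_dir / f"holdout_{scheme.name}.json",
                            hold_report.to_dict())
                pd.DataFrame(hold_report.confusion).to_csv(
                    loc_dir / f"confusion_holdout_{scheme.name}.csv",
                    index=False)
            if ens is not None:
                (loc_dir / f"model_{scheme.name}.json").write_text(
                    ensemble_to_json(ens))
            loc_summary[scheme.name] = {
                "features": list(subset),
                "cv_accuracy": report.accuracy,
                "cv_loss": report.loss,
                "n_bins": scheme.n_bins,
                "holdout_accuracy": (hold_report.accuracy
                                     if hold_report else None),
            }
            log.info("stage=model location=%s scheme=%s features=%s "
                     "cv_acc=%.3f", loc, scheme.name, subset,
                     report.accuracy)

        # Bin-size effect: one-way ANOVA over per-fold accuracies.
        for target, widths in (("lvpmax", config.lvp_bin_widths),
                               ("dpdtmax", config.dpdt_bin_widths)):
            names = [s.name for s in schemes
                     if s.target == target]
            groups = []
            for name in names:
                rep = json.loads(
                    (loc_dir / f"validation_{name}.json").read_text())
                groups.append(rep["fold_accuracies"])
            if len(groups) >= 2 and all(len(g) >= 2 for g in groups):
                try:
                    f_stat, p = anova_one_way(groups)
                    loc_summary[f"anova_{target}"] = {
                        "F": f_stat, "p": p, "schemes": names}
                except ValueError:
                    pass

        if config.run_loso and config.n_subjects >= 2:
            from .evaluation import leave_one_subject_out

            scheme = schemes[0]
            label = f"bin_{scheme.name}"
            reports = leave_one_subject_out(
                sub, FEATURE_CODES, label, scheme.n_bins,
                metric=config.metric, k=config.search_k,
                seed=int(rng.integers(0, 2**31 - 1)),
                n_trees=config.n_trees,
                search_n_trees=config.search_n_trees,
                max_splits=config.max_splits_factor * scheme.n_bins,
                scheme_name=scheme.name,
            )
            accs = [r.accuracy for r in reports]
            _write_json(loc_dir / "loso.json", {
                "scheme": scheme.name,
                "per_subject": [r.to_dict() for r in reports],
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs, ddof=1)),
            })
            loc_summary["loso_mean_accuracy"] = float(np.mean(accs))
        summary["locations"][loc] = loc_summary

    manifest = {
        "package": "epibeat",
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
    }
    _write_json(outdir / "manifest.json", manifest)
    _write_json(outdir / "summary.json", summary)
    return summary
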