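"""End-to-end runs: spontaneous, paired, pharmacology, evoked, benchmark.

Each ``run_*`` function takes a :class:`RunConfig`, simulates (or loads) the
traces, pushes them through the full preprocessing → detection → measurement
→ statistics chain, and returns machine-readable results; with an output
directory set, result tables land on disk as CSV/JSON stamped with the seed
and a hash of the configuration so any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ca_spikes, eap, preprocess, stats, synth
from .trace import Trace, write_trace_matrix, write_ground_truth_csv

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_spontaneous",
    "run_paired",
    "run_pharmacology",
    "run_benchmark",
    "match_event_times",
    "score_detection",
]


@dataclass
class RunConfig:
    """Scenario configuration; exactly one of input_dir / synthetic scenario.

    With ``input_dir`` unset the run is synthetic and fully described by the
    generator parameters below, all of which default to the study conditions.
    """

    scenario: str = "spontaneous"
    seed: int = 0
    out_dir: str | None = None
    input_dir: str | None = None

    # synthetic-population parameters
    n_cells: int = 127
    n_animals: int = 15
    duration: float = 300.0              # s per cell
    rate_median: float = synth.DEFAULT_RATE_HZ
    rate_sigma: float = 0.5              # log-normal spread of per-cell rates
    classes: synth.SpikeClassParams = field(default_factory=synth.SpikeClassParams)
    kernel: synth.KernelParams = field(default_factory=synth.KernelParams)
    template: synth.EapTemplateParams = field(default_factory=synth.EapTemplateParams)
    f0_baseline: float = 100.0           # raw-fluorescence baseline (a.u.)

    # analysis parameters
    detection: ca_spikes.DetectionConfig = field(default_factory=ca_spikes.DetectionConfig)
    eap_cfg: eap.EapConfig = field(default_factory=eap.EapConfig)
    null_alpha: float = 0.05
    null_replicates: int = 100_000
    match_tolerance: float | None = None  # s; default one imaging frame
    condition: str = "TTx"
    effect: synth.EffectConfig = field(default_factory=synth.EffectConfig)
    noise_sweep: tuple[float, ...] = (0.0125, 0.025, 0.05, 0.1, 0.2)
    persist_intermediates: bool = True

    def __post_init__(self) -> None:
        if self.input_dir is not None and self.scenario == "":
            raise ValueError("scenario name required")
        if self.n_cells < 0 or self.duration <= 0:
            raise ValueError("n_cells must be >= 0 and duration > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sub = {
            "classes": synth.SpikeClassParams,
            "kernel": synth.KernelParams,
            "template": synth.EapTemplateParams,
            "detection": ca_spikes.DetectionConfig,
            "eap_cfg": eap.EapConfig,
            "effect": synth.EffectConfig,
        }
        for key, typ in sub.items():
            if key in d and isinstance(d[key], dict):
                try:
                    d[key] = typ(**d[key])
                except TypeError as exc:
                    raise ValueError(f"bad config section {key!r}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path} must hold a mapping at top level")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("out_dir", None)  # where results land does not change them
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _stamp(cfg: RunConfig) -> dict:
    return {"seed": cfg.seed, "config_hash": cfg.config_hash(), "scenario": cfg.scenario}


def _write_json(path: Path, obj: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float) + "\n")


def _write_csv(path: Path, frame: pd.DataFrame) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.9g")


def match_event_times(
    true_times: np.ndarray, detected_times: np.ndarray, tolerance: float
) -> tuple[list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Greedy nearest-neighbour matching within ``tolerance`` seconds.

    Returns matched index pairs plus the unmatched indices on each side.
    Each event matches at most once; candidate pairs are taken closest-first.
    """
    a = np.asarray(true_times, dtype=float)
    b = np.asarray(detected_times, dtype=float)
    pairs: list[tuple[int, int]] = []
    if a.size and b.size:
        cand = [
            (abs(a[i] - b[j]), i, j)
            for i in range(a.size)
            for j in np.nonzero(np.abs(b - a[i]) <= tolerance)[0]
        ]
        cand.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, i, j in cand:
            if i in used_a or j in used_b:
                continue
            pairs.append((i, int(j)))
            used_a.add(i)
            used_b.add(int(j))
    matched_a = {i for i, _ in pairs}
    matched_b = {j for _, j in pairs}
    return (
        pairs,
        np.array([i for i in range(a.size) if i not in matched_a], dtype=int),
        np.array([j for j in range(b.size) if j not in matched_b], dtype=int),
    )


def score_detection(
    true_times: np.ndarray,
    detected_times: np.ndarray,
    tolerance: float,
    true_amplitudes: np.ndarray | None = None,
    min_amplitude: float | None = None,
) -> dict:
    """Sensitivity and precision of a detection against ground truth.

    Scoring is attribution-based and symmetric: a qualifying true event
    (``true_amplitudes >= min_amplitude``, or every event when no floor is
    given) counts as recovered when any detection falls within ``tolerance``
    of it, and a detection counts as genuine when any true event —
    qualifying or not — falls within ``tolerance`` of it.  Sensitivity is
    the recovered fraction of qualifying events; precision the genuine
    fraction of detections.  ``pairs`` additionally carries a one-to-one
    greedy matching for amplitude comparisons.
    """
    a = np.asarray(true_times, dtype=float)
    b = np.asarray(detected_times, dtype=float)
    pairs, _, _ = match_event_times(a, b, tolerance)
    if min_amplitude is not None and true_amplitudes is not None:
        amp = np.asarray(true_amplitudes, dtype=float)
        qualifying = np.nonzero(amp >= min_amplitude)[0]
    else:
        qualifying = np.arange(a.size)
    n_qual = qualifying.size
    if b.size:
        n_hit = int(sum(np.min(np.abs(b - a[i])) <= tolerance for i in qualifying))
    else:
        n_hit = 0
    if a.size:
        attributable = np.array([np.min(np.abs(a - t)) <= tolerance for t in b], dtype=bool)
    else:
        attributable = np.zeros(b.size, dtype=bool)
    n_fp = int((~attributable).sum())
    return {
        "n_true": n_qual,
        "n_detected": int(b.size),
        "n_matched": n_hit,
        "n_false_positive": n_fp,
        "sensitivity": n_hit / n_qual if n_qual else float("nan"),
        "precision": (b.size - n_fp) / b.size if b.size else float("nan"),
        "pairs": pairs,
    }


def _simulate_cell(cfg: RunConfig, cell: int, rate: float, seed_key: int = 0):
    """One synthetic cell: ground truth + raw fluorescence trace."""
    rng = synth.spawn_rng(cfg.seed, seed_key, cell)
    times = synth.generate_spike_train(rate, cfg.duration, rng)
    truth = synth.assign_amplitudes(times, cfg.classes, rng, rate=rate, duration=cfg.duration)
    sig = synth.render_ca_trace(truth, cfg.kernel, cfg.duration, seed=rng)
    raw = sig.with_samples(cfg.f0_baseline * (1.0 + sig.samples), units="au")
    return truth, raw


def _analyze_ca_trace(raw: Trace, cfg: RunConfig):
    """ΔF/F → conditioned derivative → detection → per-event measurements."""
    d = preprocess.dff(raw)
    deriv, det_times, thresh = ca_spikes.detect(d, cfg.detection)
    events = ca_spikes.measure_events(d, deriv, det_times, cfg.detection, threshold=thresh)
    return d, deriv, det_times, events


def _cell_rates(cfg: RunConfig) -> np.ndarray:
    rng = synth.spawn_rng(cfg.seed, 999)
    return rng.lognormal(math.log(cfg.rate_median), cfg.rate_sigma, size=cfg.n_cells)


def run_spontaneous(cfg: RunConfig) -> dict:
    """Spontaneous-activity survey: per-cell rates, ISI CV, JB multimodality.

    Simulates ``n_cells`` cells (assigned round-robin to ``n_animals``
    animals), runs the full detection chain on each, and summarises the
    population with medians ± IQR.  Returns ``{"cells": DataFrame,
    "events": DataFrame, "summary": dict}``.
    """
    t0 = time.time()
    null = stats.NullTable(alpha=cfg.null_alpha, replicates=cfg.null_replicates, seed=cfg.seed)
    rates = _cell_rates(cfg)
    cell_rows = []
    event_rows = []
    if cfg.n_cells == 0:
        logger.warning("empty cell set: spontaneous run produces empty results")
    for c in range(cfg.n_cells):
        truth, raw = _simulate_cell(cfg, c, rates[c])
        d, deriv, det_times, events = _analyze_ca_trace(raw, cfg)
        rate, cv = stats.rate_and_cv(det_times, d.duration)
        amps = np.array([e.amplitude for e in events])
        snrs = np.array([e.snr for e in events])
        finite_snr = snrs[np.isfinite(snrs)]
        jb = float("nan")
        crit = float("nan")
        multi = None
        if amps.size >= 8 and np.var(amps) > 0:
            jb = stats.jarque_bera(amps)
            crit = null.critical(amps.size)
            multi = bool(jb > crit)
        cell_id = f"cell{c:04d}"
        cell_rows.append(
            {
                "cell_id": cell_id,
                "animal_id": f"animal{c % cfg.n_animals:03d}",
                "n_events": int(det_times.size),
                "rate_hz": rate,
                "isi_cv": cv,
                "jb_stat": jb,
                "jb_crit": crit,
                "multimodal": multi,
                "mean_snr": float(np.mean(finite_snr)) if finite_snr.size else float("nan"),
                "activity_index": stats.activity_index(amps, d.duration),
                "true_rate_hz": rates[c],
                "true_n_events": truth.n_events,
            }
        )
        for e in events:
            event_rows.append(
                {
                    "cell_id": cell_id,
                    "time_s": e.time,
                    "amplitude_dff": e.amplitude,
                    "snr": e.snr,
                    "edge_flag": e.edge,
                }
            )
        logger.info("spontaneous cell=%s events=%d elapsed=%.1fs", cell_id,
                    det_times.size, time.time() - t0)
    cells = pd.DataFrame(cell_rows)
    events_df = pd.DataFrame(event_rows)

    def _med_iqr(x):
        x = np.asarray(x, dtype=float)
        x = x[np.isfinite(x)]
        if x.size == 0:
            return {"median": float("nan"), "iqr": float("nan"), "n": 0}
        return {
            "median": float(np.median(x)),
            "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
            "n": int(x.size),
        }

    flags = [r["multimodal"] for r in cell_rows if r["multimodal"] is not None]
    summary = {
        **_stamp(cfg),
        "n_cells": cfg.n_cells,
        "rate_hz": _med_iqr(cells["rate_hz"]) if len(cells) else _med_iqr([]),
        "isi_cv": _med_iqr(cells["isi_cv"]) if len(cells) else _med_iqr([]),
        "mean_snr": _med_iqr(cells["mean_snr"]) if len(cells) else _med_iqr([]),
        "n_multimodal": int(sum(flags)),
        "n_flagged": len(flags),
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        _write_csv(out / "cells.csv", cells)
        _write_csv(out / "events.csv", events_df)
        _write_json(out / "summary.json", summary)
    return {"cells": cells, "events": events_df, "summary": summary}


def run_paired(cfg: RunConfig) -> dict:
    """Paired Ca²⁺-imaging + EAP runs with event matching and regression.

    Ca and EAP events are matched when they fall within the matching
    tolerance (default: one imaging frame); matched pairs feed an OLS of Ca
    amplitude on ∫EAP peak per cell.
    """
    tol = cfg.match_tolerance or 2.0 / cfg.kernel.frame_rate
    matched_rows = []
    reg_rows = []
    for c in range(cfg.n_cells):
        pc = synth.PairedConfig(
            duration=cfg.duration,
            classes=cfg.classes,
            kernel=cfg.kernel,
            template=cfg.template,
            seed=int(synth.spawn_rng(cfg.seed, 7, c).integers(2**31)),
        )
        ca_tr, eap_tr, truth = synth.generate_paired_recording(pc)
        raw = ca_tr.with_samples(cfg.f0_baseline * (1.0 + ca_tr.samples), units="au")
        d, deriv, ca_times, ca_events = _analyze_ca_trace(raw, cfg)
        bp = preprocess.bandpass(eap_tr)
        eap_times = eap.detect_eaps(bp, cfg.eap_cfg)
        eap_events = eap.measure_eap_events(bp, eap_times, cfg.eap_cfg)
        # The Ca timestamp (derivative peak) lags the electrical event by a
        # systematic, cell-constant amount (plus any acquisition clock
        # offset); estimate it with a wide pass, then match within tolerance.
        wide, _, _ = match_event_times(ca_times, eap_times, 6.0 / cfg.kernel.frame_rate)
        lag = (
            float(np.median([ca_times[i] - eap_times[j] for i, j in wide])) if wide else 0.0
        )
        pairs, un_ca, un_eap = match_event_times(ca_times - lag, eap_times, tol)
        cell_id = f"cell{c:04d}"
        for i, j in pairs:
            matched_rows.append(
                {
                    "cell_id": cell_id,
                    "ca_time_s": ca_times[i],
                    "eap_time_s": eap_times[j],
                    "ca_amplitude_dff": ca_events[i].amplitude,
                    "integral_peak_pas": eap_events[j].integral_peak,
                    "secondary_rel": eap_events[j].secondary_rel,
                }
            )
        snrs = np.array([e.snr for e in ca_events])
        snrs = snrs[np.isfinite(snrs)]
        row = {
            "cell_id": cell_id,
            "n_ca": int(ca_times.size),
            "n_eap": int(eap_times.size),
            "n_matched": len(pairs),
            "n_unmatched_ca": int(un_ca.size),
            "n_unmatched_eap": int(un_eap.size),
            "mean_snr": float(np.mean(snrs)) if snrs.size else float("nan"),
            "slope": float("nan"),
            "intercept": float("nan"),
            "r_squared": float("nan"),
        }
        if len(pairs) >= 3:
            x = np.array([eap_events[j].integral_peak for _, j in pairs])
            y = np.array([ca_events[i].amplitude for i, _ in pairs])
            if np.var(x) > 0 and np.var(y) > 0:
                row["slope"], row["intercept"], row["r_squared"] = stats.paired_regression(x, y)
        reg_rows.append(row)
    matched = pd.DataFrame(matched_rows)
    regs = pd.DataFrame(reg_rows)
    summary = {
        **_stamp(cfg),
        "match_tolerance_s": tol,
        "mean_r_squared": float(np.nanmean(regs["r_squared"])) if len(regs) else float("nan"),
        "total_matched": int(regs["n_matched"].sum()) if len(regs) else 0,
        "total_unmatched": int((regs["n_unmatched_ca"] + regs["n_unmatched_eap"]).sum())
        if len(regs) else 0,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        _write_csv(out / "matched_events.csv", matched)
        _write_csv(out / "regressions.csv", regs)
        _write_json(out / "summary.json", summary)
    return {"matched": matched, "regressions": regs, "summary": summary}


def simulate_condition_recording(
    cfg: RunConfig, cell: int, rate: float, drug_time: float | None = None
) -> tuple[synth.GroundTruth, Trace, float]:
    """One continuous recording with the condition applied at ``drug_time``.

    The control epoch runs to ``drug_time`` (default: half the recording);
    events after it come from an independent train of the same rate with
    :func:`gradespike.synth.apply_condition` applied — the drug washes into
    an ongoing recording, exactly how the threshold-per-cell analysis sees
    it.  Returns (full ground truth, raw fluorescence, drug time).
    """
    total = cfg.duration
    if drug_time is None:
        drug_time = total / 2.0
    if not 0 < drug_time < total:
        raise ValueError(
            f"drug_time {drug_time} s outside the recording (0, {total} s)"
        )
    rng = synth.spawn_rng(cfg.seed, 11, cell)
    t_pre = synth.generate_spike_train(rate, drug_time, rng)
    truth_pre = synth.assign_amplitudes(t_pre, cfg.classes, rng, rate=rate,
                                        duration=drug_time)
    post_dur = total - drug_time
    t_post = synth.generate_spike_train(rate, post_dur, rng)
    truth_post = synth.assign_amplitudes(t_post, cfg.classes, rng, rate=rate,
                                         duration=post_dur)
    truth_post = synth.apply_condition(truth_post, cfg.condition, cfg.effect, rng)
    full = synth.GroundTruth(
        np.concatenate([truth_pre.event_times, truth_post.event_times + drug_time]),
        np.concatenate([truth_pre.class_labels, truth_post.class_labels]),
        np.concatenate([truth_pre.true_amplitudes, truth_post.true_amplitudes]),
        np.concatenate(
            [truth_pre.true_secondary_scales, truth_post.true_secondary_scales]
        ),
        rate=rate,
        duration=total,
    )
    sig = synth.render_ca_trace(full, cfg.kernel, total, seed=rng)
    raw = sig.with_samples(cfg.f0_baseline * (1.0 + sig.samples), units="au")
    return full, raw, drug_time


def run_pharmacology(cfg: RunConfig) -> dict:
    """Pre/post condition comparison through the full detection chain.

    Each cell is one continuous recording whose second half has
    :func:`gradespike.synth.apply_condition` applied to the generating
    process (the drug washes in mid-recording, so the per-cell detection
    threshold spans both epochs).  Reports per-cell rates/amplitudes, the
    paired rate test, pooled mean-normalized amplitude histograms with a KS
    test, and (for Cd²⁺) the secondary-peak shift measured on synthetic EAP
    trains.
    """
    cond = cfg.condition
    rates = _cell_rates(cfg)
    rows = []
    amp_cells: dict[str, dict[str, np.ndarray]] = {}
    for c in range(cfg.n_cells):
        full, raw, drug_time = simulate_condition_recording(cfg, c, rates[c])
        d = preprocess.dff(raw)
        deriv = ca_spikes.condition_derivative(d, cfg.detection)
        # per-cell threshold from the control epoch only: the drug changes
        # the very statistics the threshold is estimated from
        ctrl = d.with_samples(d.samples[: d.index_of(drug_time)])
        thresh = ca_spikes.detection_threshold(ctrl, cfg.detection)
        det_times = ca_spikes.detect_spikes(deriv, cfg.detection, threshold=thresh)
        events = ca_spikes.measure_events(d, deriv, det_times, cfg.detection,
                                          threshold=thresh)
        pre_mask = det_times < drug_time
        t_pre = det_times[pre_mask]
        t_post = det_times[~pre_mask]
        ev_pre = [e for e, m in zip(events, pre_mask) if m]
        ev_post = [e for e, m in zip(events, pre_mask) if not m]
        r_pre, _ = stats.rate_and_cv(t_pre, drug_time)
        r_post, _ = stats.rate_and_cv(t_post - drug_time, cfg.duration - drug_time)
        cell_id = f"cell{c:04d}"
        amp_cells[cell_id] = {
            "control": np.array([e.amplitude for e in ev_pre]),
            cond: np.array([e.amplitude for e in ev_post]),
        }
        rows.append(
            {
                "cell_id": cell_id,
                "rate_pre_hz": r_pre,
                "rate_post_hz": r_post,
                "mean_amp_pre": float(np.mean(amp_cells[cell_id]["control"]))
                if t_pre.size else float("nan"),
                "mean_amp_post": float(np.mean(amp_cells[cell_id][cond]))
                if t_post.size else float("nan"),
            }
        )
    cells = pd.DataFrame(rows)
    rate_test = stats.compare_conditions(
        cells["rate_pre_hz"].to_numpy(), cells["rate_post_hz"].to_numpy(), "paired"
    )
    pooled = stats.normalize_amplitudes(
        {cid: d for cid, d in amp_cells.items() if d["control"].size and d[cond].size}
    )
    ks = None
    if cond in pooled and "control" in pooled and pooled[cond].size:
        ks = stats.compare_conditions(pooled["control"], pooled[cond], "distribution")
    report = {
        **_stamp(cfg),
        "condition": cond,
        "rate_test": rate_test,
        "amplitude_ks": ks,
        "mean_rate_reduction": float(
            1.0 - np.mean(cells["rate_post_hz"]) / np.mean(cells["rate_pre_hz"])
        )
        if len(cells) and np.mean(cells["rate_pre_hz"]) > 0 else float("nan"),
    }

    if cond == "Cd":
        report["secondary_shift_pa"] = _cd_secondary_shift(cfg)

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        _write_csv(out / f"pharmacology_{cond}_cells.csv", cells)
        _write_json(out / f"pharmacology_{cond}_report.json", report)
    return {"cells": cells, "pooled": pooled, "report": report}


def _cd_secondary_shift(cfg: RunConfig, n_cells: int = 4, n_events: int = 50) -> dict:
    """Per-cell secondary-peak shift from synthetic EAP trains under Cd²⁺."""
    shifts = []
    for c in range(n_cells):
        rng = synth.spawn_rng(cfg.seed, 23, c)
        times = np.arange(1, n_events + 1) * 0.1
        scales = synth.draw_secondary_scales(
            n_events, rng, median=cfg.template.secondary_rel_median,
            iqr=cfg.template.secondary_rel_iqr,
        )
        pre = synth.render_eap_train(times, cfg.template, scales, rng,
                                     duration=times[-1] + 0.05)
        post = synth.render_eap_train(times, cfg.template, np.zeros(n_events), rng,
                                      duration=times[-1] + 0.05)
        bp_pre = preprocess.bandpass(pre)
        bp_post = preprocess.bandpass(post)
        shifts.append(eap.condition_shift(bp_pre, times, bp_post, times, cfg.eap_cfg))
    return {
        "per_cell_pa": [float(s) for s in shifts],
        "mean_pa": float(np.mean(shifts)),
        "sd_pa": float(np.std(shifts, ddof=1)) if len(shifts) > 1 else float("nan"),
    }


def run_benchmark(cfg: RunConfig) -> dict:
    """Detector performance over an imaging-noise sweep.

    For each noise level: sensitivity, precision and relative amplitude bias
    of the Ca²⁺ spike detector against ground truth, plus the per-cell
    Ca↔∫EAP regression R² at that noise level.  R² should fall (and miss
    rates rise) as noise grows; the report carries every seed needed for an
    exact rerun.
    """
    tol_frames = 3
    rows = []
    # Deterministic Ca↔∫EAP coupling: the benchmark scores the measurement
    # chain, so the generator must not add its own coupling scatter.
    bench_classes = dataclasses.replace(cfg.classes, coupling_noise_sd=0.0)
    for k, noise in enumerate(cfg.noise_sweep):
        kernel = dataclasses.replace(cfg.kernel, noise_sd=noise)
        sens, prec, biases, r2s, snrs = [], [], [], [], []
        for c in range(cfg.n_cells):
            # common random numbers across the sweep: each noise level sees
            # the same cells, so the noise effect is not confounded with
            # cell-to-cell sampling variation
            pc = synth.PairedConfig(
                duration=cfg.duration,
                classes=bench_classes,
                kernel=kernel,
                template=cfg.template,
                seed=int(synth.spawn_rng(cfg.seed, 31, c).integers(2**31)),
            )
            ca_tr, eap_tr, truth = synth.generate_paired_recording(pc)
            raw = ca_tr.with_samples(cfg.f0_baseline * (1.0 + ca_tr.samples), units="au")
            d, deriv, det_times, events = _analyze_ca_trace(raw, cfg)
            score = score_detection(
                truth.event_times, det_times, tol_frames / kernel.frame_rate,
                true_amplitudes=truth.true_amplitudes,
                min_amplitude=5.0 * noise if noise > 0 else None,
            )
            sens.append(score["sensitivity"])
            prec.append(score["precision"])
            # Amplitude fidelity and coupling R² are scored on isolated
            # events: an undetected neighbour inside the measurement window
            # contaminates the amplitude, and that failure mode is already
            # captured by sensitivity.
            tt = truth.event_times
            gap_next = cfg.detection.amp_window + 2.0 / kernel.frame_rate
            gap_prev = 3.0 * kernel.decay_tau  # the baseline must outlive the tail
            isolated = np.ones(tt.size, dtype=bool)
            if tt.size > 1:
                gaps = np.diff(tt)
                isolated[1:] &= gaps > gap_prev
                isolated[:-1] &= gaps > gap_next
            iso_pairs = [(i, j) for i, j in score["pairs"] if isolated[i]]
            if iso_pairs:
                est = np.array([events[j].amplitude for _, j in iso_pairs])
                tru = np.array([truth.true_amplitudes[i] for i, _ in iso_pairs])
                if tru.size and np.mean(tru) > 0:
                    biases.append((np.mean(est) - np.mean(tru)) / np.mean(tru))
            ev_snr = np.array([e.snr for e in events])
            ev_snr = ev_snr[np.isfinite(ev_snr)]
            if ev_snr.size:
                snrs.append(float(np.mean(ev_snr)))
            if len(iso_pairs) >= 3:
                ipk = np.array(
                    [synth.template_integral_peak(cfg.template, s)
                     for s in truth.true_secondary_scales]
                )
                x = np.array([ipk[i] for i, _ in iso_pairs])
                y = np.array([events[j].amplitude for _, j in iso_pairs])
                if np.var(x) > 0 and np.var(y) > 0:
                    r2s.append(stats.paired_regression(x, y)[2])
        rows.append(
            {
                "noise_sd": noise,
                "sensitivity": float(np.mean(sens)) if sens else float("nan"),
                "precision": float(np.mean(prec)) if prec else float("nan"),
                "amplitude_bias": float(np.mean(biases)) if biases else float("nan"),
                "mean_snr": float(np.mean(snrs)) if snrs else float("nan"),
                "mean_r_squared": float(np.mean(r2s)) if r2s else float("nan"),
            }
        )
    table = pd.DataFrame(rows)
    report = {
        **_stamp(cfg),
        "match_tolerance_frames": tol_frames,
        "sweep": rows,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        _write_csv(out / "benchmark.csv", table)
        _write_json(out / "benchmark.json", report)
    return {"table": table, "report": report}


def simulate_to_dir(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Write a synthetic dataset (traces + sidecars + ground truth) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.scenario in ("spontaneous", "pharmacology", "evoked"):
        rates = _cell_rates(cfg)
        for c in range(cfg.n_cells):
            truth, raw = _simulate_cell(cfg, c, rates[c])
            write_trace_matrix(
                out / f"cell{c:04d}", {"fluorescence": raw},
                seed=cfg.seed, scenario=cfg.scenario,
            )
            write_ground_truth_csv(out / f"cell{c:04d}_truth.csv", truth)
    elif cfg.scenario == "paired":
        for c in range(cfg.n_cells):
            pc = synth.PairedConfig(
                duration=cfg.duration, classes=cfg.classes, kernel=cfg.kernel,
                template=cfg.template,
                seed=int(synth.spawn_rng(cfg.seed, 7, c).integers(2**31)),
            )
            ca_tr, eap_tr, truth = synth.generate_paired_recording(pc)
            write_trace_matrix(out / f"cell{c:04d}_ca", {"dff": ca_tr},
                               seed=cfg.seed, scenario=cfg.scenario)
            write_trace_matrix(out / f"cell{c:04d}_eap", {"current": eap_tr},
                               seed=cfg.seed, scenario=cfg.scenario)
            write_ground_truth_csv(out / f"cell{c:04d}_truth.csv", truth)
    else:
        raise ValueError(f"unknown scenario {cfg.scenario!r}")
    _write_json(out / "run.json", _stamp(cfg))
    return out
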