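"""End-to-end orchestration: simulate/load -> detect -> spectrogram -> slow-gamma
power -> PAC -> group report, with a provenance manifest.

A run is described by a single JSON-serializable :class:`RunConfig` holding
either real input files (recording + immobility mask per subject) or a
synthetic block (group profiles and subject counts), plus the parameters of
every stage.  Outputs land in ``out_dir``; a ``manifest.json`` written last
records the resolved parameters, per-stage outputs and SHA-256 checksums, so
a seeded run can be re-executed bit-identically.  A stage failure stops
downstream stages, preserves completed outputs and flags the manifest
incomplete.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .io import IntervalMask, read_lfp, read_mask, write_events, write_lfp, write_mask
from .pac import PacParams, pac_mi
from .signal import Band
from .stats import GroupTable, compare_groups, group_summary
from .swr import (
    SwrDetectionParams,
    detect_swr,
    duration_stats,
    slow_gamma_power,
    swr_triggered_spectrogram,
)
from .synthetic import make_group_fixtures

__all__ = ["RunConfig", "RunManifest", "run"]

logger = logging.getLogger("ripplepac")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    inputs: list[dict[str, str]] | None = None
    """Real data: [{'recording': path, 'mask': path, 'group': label}, ...]."""
    synthetic: dict[str, Any] | None = None
    """Synthetic block: {'profiles': {label: n_subjects}, 'duration_s': float}."""
    detection: dict[str, Any] = field(default_factory=dict)
    spectrogram: dict[str, Any] = field(default_factory=dict)
    pac: dict[str, Any] = field(default_factory=dict)
    stats: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'inputs' or 'synthetic' must be given")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def detection_params(self) -> SwrDetectionParams:
        d = self.detection
        band = d.get("band", [150.0, 250.0])
        return SwrDetectionParams(
            band=Band(*band),
            threshold_sd=d.get("threshold_sd", 5.0),
            min_duration_ms=d.get("min_duration_ms", 15.0),
        )

    def pac_params(self) -> PacParams:
        d = self.pac
        return PacParams(
            phase_band=Band(*d.get("phase_band", [4.0, 12.0])),
            amp_band=Band(*d.get("amp_band", [30.0, 50.0])),
            n_bins=d.get("n_bins", 18),
        )


@dataclass
class RunManifest:
    version: str
    config: dict
    outputs: list[str] = field(default_factory=list)
    checksums: dict[str, str] = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0
    complete: bool = False
    error: str | None = None

    def record(self, path: Path) -> None:
        self.outputs.append(str(path))
        self.checksums[str(path)] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def _load_subjects(config: RunConfig, out_dir: Path, manifest: RunManifest):
    """Yield (subject_id, group, recording, mask) tuples."""
    subjects = []
    if config.synthetic is not None:
        profiles = config.synthetic.get("profiles", {"WT-like": 1})
        duration_s = config.synthetic.get("duration_s", 120.0)
        for group, n in profiles.items():
            fixtures = make_group_fixtures(group, int(n), seed=config.seed, duration_s=duration_s)
            for i, (rec, truth) in enumerate(fixtures):
                sid = f"{group}-{i:02d}"
                rec_path = out_dir / f"{sid}.f32bin"
                write_lfp(rec, rec_path, format="f32bin")
                manifest.record(rec_path)
                mask_path = out_dir / f"{sid}.mask.csv"
                write_mask(truth.immobility_mask, mask_path)
                manifest.record(mask_path)
                subjects.append((sid, group, rec, truth.immobility_mask))
    else:
        for i, item in enumerate(config.inputs):
            rec = read_lfp(item["recording"])
            if "mask" in item and item["mask"]:
                mask = read_mask(item["mask"])
            else:
                mask = IntervalMask(((rec.start_time, rec.start_time + rec.duration),))
            subjects.append((item.get("id", f"subject-{i:02d}"), item.get("group", "all"), rec, mask))
    return subjects


def run(config: RunConfig) -> RunManifest:
    """Execute the full pipeline described by ``config``.

    Returns the manifest; raises after writing an incomplete manifest if any
    stage fails.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config=asdict(config), started=time.time())
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    spec_cfg = config.spectrogram
    metrics_rows: list[tuple[str, str, str, float]] = []
    try:
        subjects = _load_subjects(config, out_dir, manifest)
        det_params = config.detection_params()
        pac_params = config.pac_params()
        for sid, group, rec, mask in subjects:
            logger.info("subject %s (%s): detecting ripples", sid, group)
            result = detect_swr(rec, det_params, mask)
            ev_path = out_dir / f"{sid}.events.csv"
            write_events(result, ev_path)
            manifest.record(ev_path)
            manifest.record(Path(str(ev_path) + ".json"))

            dstats = duration_stats(result, seed=config.seed)
            zspec = swr_triggered_spectrogram(
                rec,
                result,
                window_s=spec_cfg.get("window_s", 0.4),
                spec_window_s=spec_cfg.get("spec_window_s", 0.1),
                spec_step_s=spec_cfg.get("spec_step_s", 0.01),
                nw=spec_cfg.get("nw", 3.0),
                k=spec_cfg.get("k", 5),
            )
            sg_z = float("nan")
            if zspec is not None:
                zs_path = out_dir / f"{sid}.zspec.csv"
                mat = np.zeros((zspec.freqs.size + 1, zspec.times.size + 1))
                mat[0, 1:] = zspec.times
                mat[1:, 0] = zspec.freqs
                mat[1:, 1:] = zspec.zpower
                np.savetxt(zs_path, mat, delimiter=",")
                nw_, k_, win_, step_ = zspec.taper_params
                Path(str(zs_path) + ".json").write_text(
                    json.dumps({"NW": nw_, "K": k_, "window_s": win_, "step_s": step_,
                                "n_events": zspec.n_events, "norm": "event_window"})
                )
                manifest.record(zs_path)
                sg_z = slow_gamma_power(zspec)

            pres = pac_mi(rec, PacParams(pac_params.phase_band, pac_params.amp_band,
                                         pac_params.n_bins, mask))
            pac_path = out_dir / f"{sid}.pac.json"
            pac_path.write_text(
                json.dumps(
                    {
                        "mi": pres.mi,
                        "n_bins": pres.n_bins,
                        "n_samples": pres.n_samples,
                        "bin_centers_rad": pres.bin_centers.tolist(),
                        "p": pres.p.tolist(),
                    },
                    indent=2,
                )
            )
            manifest.record(pac_path)

            metrics_rows += [
                (sid, group, "incidence_hz", result.incidence_hz),
                (sid, group, "median_duration_ms", dstats.median_ms),
                (sid, group, "sg_zpower", sg_z),
                (sid, group, "pac_mi", pres.mi),
            ]

        # metrics table + group report
        metrics_path = out_dir / "metrics.csv"
        with open(metrics_path, "w") as fh:
            fh.write("subject_id,group,metric,value\n")
            for sid, group, metric, value in metrics_rows:
                fh.write(f"{sid},{group},{metric},{value!r}\n")
        manifest.record(metrics_path)

        groups_present = {g for _, g, _, _ in metrics_rows}
        report: dict[str, Any] = {}
        if len(groups_present) >= 2:
            for metric in ("incidence_hz", "median_duration_ms", "sg_zpower", "pac_mi"):
                by_group: dict[str, list[float]] = {}
                for sid, group, m, value in metrics_rows:
                    if m == metric and np.isfinite(value):
                        by_group.setdefault(group, []).append(value)
                if len(by_group) < 2 or min(len(v) for v in by_group.values()) < 2:
                    continue
                table = GroupTable(
                    {g: np.asarray(v) for g, v in by_group.items()}, metric=metric
                )
                cmp = compare_groups(table, alpha_route=config.stats.get("alpha", 0.05))
                report[metric] = {
                    "summary": {g: {"mean": m_, "sem": s_, "n": n_}
                                for g, (m_, s_, n_) in group_summary(table).items()},
                    "route": cmp["route"],
                    "levene_p": cmp["levene"].p_value,
                    "omnibus": {
                        "test": cmp["omnibus"].test,
                        "statistic": cmp["omnibus"].statistic,
                        "df": cmp["omnibus"].df,
                        "p_value": cmp["omnibus"].p_value,
                    },
                    "pairwise": [
                        {"pair": list(pr.pair), "statistic": pr.statistic,
                         "p_adjusted": pr.p_adjusted, "method": pr.method}
                        for pr in cmp["omnibus"].pairwise
                    ],
                }
            report_path = out_dir / "report.json"
            report_path.write_text(json.dumps(report, indent=2, default=str))
            manifest.record(report_path)

        manifest.complete = True
    except Exception as exc:  # flag, persist, re-raise
        manifest.error = f"{type(exc).__name__}: {exc}"
        manifest.complete = False
        manifest.finished = time.time()
        manifest.write(out_dir / "manifest.json")
        logger.removeHandler(handler)
        handler.close()
        raise
    manifest.finished = time.time()
    manifest.write(out_dir / "manifest.json")
    logger.removeHandler(handler)
    handler.close()
    return manifest
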