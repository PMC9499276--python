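"""End-to-end orchestration: signals → events → features → reliability.

A *manifest* is a table (DataFrame, list of dicts, or CSV path) with one
row per trial and columns ``subject, limb, task, trial`` plus the file
paths the task needs: ``tibia``/``foot`` for SLS and CHT, ``grf`` and
``body_mass`` for CMJ.  Per-trial failures are recorded and skipped; the
run fails only if every trial fails.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import features as feat
from . import io as kio
from . import preprocessing as prep
from . import segmentation as seg
from .config import PipelineConfig
from .errors import EmptyInputError, KneestabError
from .reliability import CohortSummary, summarize_cohort

logger = logging.getLogger("kneestab")

__all__ = ["run_pipeline", "process_trial", "PipelineReport"]


@dataclass
class PipelineReport:
    """Everything one pipeline run produced."""

    config: PipelineConfig
    records: list
    events: dict                 # (subject, limb, task, trial) -> TaskEvents
    failures: list = field(default_factory=list)
    cohort: CohortSummary | None = None

    def tidy_features(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.extend(r.as_rows())
        return pd.DataFrame(rows)

    def wide_features(self) -> pd.DataFrame:
        tidy = self.tidy_features()
        if tidy.empty:
            return tidy
        return tidy.pivot_table(
            index=["subject", "limb", "task", "trial"],
            columns="parameter", values="value").reset_index()

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.config.to_json(out / "config.json")
        self.tidy_features().to_csv(out / "features_tidy.csv", index=False)
        self.wide_features().to_csv(out / "features_wide.csv", index=False)
        with open(out / "events.json", "w") as fh:
            json.dump({"/".join(map(str, key)): ev.to_dict()
                       for key, ev in self.events.items()}, fh, indent=2)
        if self.cohort is not None:
            self.cohort.summary.to_csv(out / "cohort_summary.csv",
                                       index=False)
            self.cohort.reliability.to_csv(out / "reliability.csv",
                                           index=False)
            with open(out / "reliability.json", "w") as fh:
                json.dump({
                    "config": self.config.model_dump(),
                    "reliability": self.cohort.reliability.to_dict(
                        orient="records"),
                    "lsi": self.cohort.lsi.to_dict(orient="records"),
                    "failures": self.failures,
                }, fh, indent=2, default=float)
        if self.failures:
            with open(out / "failures.json", "w") as fh:
                json.dump(self.failures, fh, indent=2)


def process_trial(row: dict, config: PipelineConfig):
    """Process one manifest row into (FeatureRecord, TaskEvents)."""
    task = str(row["task"]).upper()
    meta = dict(subject=str(row["subject"]), limb=str(row["limb"]),
                trial=int(row["trial"]))
    if task == "CMJ":
        grf = kio.read_grf_csv(row["grf"], float(row["body_mass"]))
        ev, _net = seg.segment_cmj(
            grf, flight_threshold=config.flight_force_threshold,
            onset_band=config.cmj_onset_band,
            d2_window=config.cmj_d2_window)
        rec = feat.extract_cmj_features(grf, ev, **meta)
        return rec, ev

    tibia = kio.read_imu_csv(row["tibia"], "tibia")
    foot = kio.read_imu_csv(row["foot"], "foot")
    still = (0, config.sls_static_samples)
    tibia = prep.remove_gyro_bias(tibia, still,
                                  stillness_threshold=config.still_threshold)
    foot = prep.remove_gyro_bias(foot, still,
                                 stillness_threshold=config.still_threshold)
    if task == "SLS":
        orient = prep.estimate_orientation(tibia, k1=config.k1, k2=config.k2)
        pitch = prep.tibia_pitch(orient)
        ev = seg.segment_sls(
            pitch, tibia.fs, window=config.sls_window,
            static_samples=config.sls_static_samples,
            start_factor=config.sls_start_factor, scale=config.sls_scale)
        rec = feat.extract_sls_features(
            tibia, foot, orient, ev,
            ellipse_coverage=config.ellipse_coverage, **meta)
        return rec, ev
    if task == "CHT":
        ev = seg.segment_cht(
            foot, to_threshold=config.to_threshold,
            la_threshold=config.la_threshold, refractory=config.refractory,
            t_risk=config.t_risk, gyro_smooth=config.gyro_smooth,
            acc_smooth=config.acc_smooth)
        hop = row.get("hop_distance")
        if hop is None or pd.isna(hop):
            hop = None
        else:
            hop = float(hop)
        rec = feat.extract_cht_features(foot, tibia, None, ev,
                                        hop_distance=hop, **meta)
        return rec, ev
    raise EmptyInputError(f"unknown task {task!r}")


def run_pipeline(config: PipelineConfig, manifest,
                 outdir=None) -> PipelineReport:
    """Run preprocessing → segmentation → features → reliability.

    ``manifest`` may be a DataFrame, a list of dicts, or a CSV path.
    """
    if isinstance(manifest, (str, Path)):
        manifest = pd.read_csv(manifest)
    if isinstance(manifest, pd.DataFrame):
        rows = manifest.to_dict(orient="records")
    else:
        rows = list(manifest)
    if not rows:
        raise EmptyInputError("empty manifest: no trials to process")

    records, events, failures = [], {}, []
    for row in rows:
        key = (str(row.get("subject")), str(row.get("limb")),
               str(row.get("task")), int(row.get("trial", 0)))
        try:
            rec, ev = process_trial(row, config)
            records.append(rec)
            events[key] = ev
            logger.info("processed %s", "/".join(map(str, key)))
        except (KneestabError, OSError, KeyError, ValueError) as e:
            failures.append({"trial": list(key), "error": type(e).__name__,
                             "message": str(e)})
            logger.warning("failed %s: %s", "/".join(map(str, key)), e)
    if not records:
        raise EmptyInputError(
            f"all {len(rows)} trial(s) failed; first error: "
            f"{failures[0]['message']}")

    cohort = None
    try:
        cohort = summarize_cohort(records, lsi_band=config.lsi_band)
    except (KneestabError, ValueError) as e:
        failures.append({"trial": None, "error": type(e).__name__,
                         "message": f"cohort summary failed: {e}"})
    report = PipelineReport(config=config, records=records, events=events,
                            failures=failures, cohort=cohort)
    if outdir is not None:
        report.write(outdir)
    return report
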