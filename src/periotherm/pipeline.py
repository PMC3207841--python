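"""Study orchestration: simulate -> track -> extract -> detect -> analyse.

:func:`run_study` executes the full imaging chain for every trial of a
simulated study — rendering the phantom video, tracking both inner-canthus
regions, extracting the trimmed/filtered mean-temperature series, cutting
pre/post-stimulus windows, testing stationarity, flagging unusable and
formal-startle trials — then assembles the long-format study table, the
trial accounting, the six per-measure mixed ANOVAs (for all usable stimulus
trials and for the formal-startle subset) and a report.

:func:`run_series_study` is the series-level fast path for statistical
experiments: it skips rendering and tracking and models the extracted mean
series directly (see :func:`periotherm.phantom.simulate_mean_series`).

A failing trial is quarantined (logged, marked unusable), never fatal to
the study.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

from . import detection, extraction, stats, tracking
from .phantom import (
    PhantomConfig,
    TrialRecord,
    participant_offsets,
    render_trial,
    simulate_mean_series,
    simulate_study,
    trial_rng,
    trial_seed_key,
)

logger = logging.getLogger("periotherm")


@dataclass
class StudyConfig:
    """Phantom + study shape + analysis parameters, JSON round-trippable."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    n_participants: int = 11
    n_sessions: int = 10
    n_trials: int = 10
    roi_height: int = 27
    roi_width: int = 38
    window_width: float = 2.0
    n_bins: int = 1000
    alpha: float = 0.05
    max_step: int = 8
    fail_ratio: float = 25.0
    fail_consecutive: int = 5
    z_threshold: float = 3.0

    def __post_init__(self) -> None:
        if self.n_trials % 2 != 0:
            from .phantom import InvalidConfigError

            raise InvalidConfigError("n_trials must be even (half stimulus)")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["phantom"] = self.phantom.to_dict()
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        d = json.loads(text)
        d["phantom"] = PhantomConfig.from_dict(d["phantom"])
        return cls(**d)

    def reference_rois(self) -> dict:
        """ROIs centred on the phantom's canthus positions (the automated
        stand-in for the study's manual per-trial ROI placement)."""
        rois = {}
        for side, (r, c) in zip(("left", "right"), self.phantom.canthus_centers):
            rois[side] = tracking.ROI(
                top=int(r - self.roi_height // 2),
                left=int(c - self.roi_width // 2),
                height=self.roi_height,
                width=self.roi_width,
            )
        return rois


@dataclass
class AccountingSummary:
    """Trial tallies mirroring the study's accounting."""

    total: int
    stimulus: int
    non_stimulus: int
    unusable_stimulus: int
    unusable_non_stimulus: int
    unusable_total: int
    usable_stimulus: int
    usable_non_stimulus: int
    formal_startle: int

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def account_trials(records) -> AccountingSummary:
    """Tally trial flags; enforces the additivity invariants.

    Accepts an iterable of :class:`TrialRecord` or any objects exposing
    ``stimulus_flag``, ``usable_flag`` and ``formal_startle_flag``.
    """
    total = stimulus = unus_s = unus_n = startle = 0
    for rec in records:
        total += 1
        stim = bool(rec.stimulus_flag)
        usable = rec.usable_flag
        usable = True if usable is None else bool(usable)
        fs = bool(rec.formal_startle_flag) if rec.formal_startle_flag is not None else False
        if fs and not stim:
            raise ValueError(
                f"inconsistent flags: formal startle on non-stimulus trial "
                f"{getattr(rec, 'key', '?')}"
            )
        if stim:
            stimulus += 1
            if not usable:
                unus_s += 1
            elif fs:
                startle += 1
        else:
            if not usable:
                unus_n += 1
    non_stimulus = total - stimulus
    summary = AccountingSummary(
        total=total,
        stimulus=stimulus,
        non_stimulus=non_stimulus,
        unusable_stimulus=unus_s,
        unusable_non_stimulus=unus_n,
        unusable_total=unus_s + unus_n,
        usable_stimulus=stimulus - unus_s,
        usable_non_stimulus=non_stimulus - unus_n,
        formal_startle=startle,
    )
    assert summary.usable_stimulus == summary.stimulus - summary.unusable_stimulus
    assert summary.unusable_total == summary.unusable_stimulus + summary.unusable_non_stimulus
    return summary


@dataclass
class StudyResult:
    config: StudyConfig
    accounting: AccountingSummary
    study_table: pd.DataFrame
    stationarity: pd.DataFrame  # per trial+side runs-test outcomes
    anovas: Dict[str, Dict[str, stats.PeriorbitalAnovaResults]]
    report: stats.StudyReport
    trials: list
    errors: list = field(default_factory=list)

    def report_markdown(self) -> str:
        head = [
            "# Periorbital temperature study report",
            "",
            "Configuration:",
            "```json",
            self.config.to_json(),
            "```",
            "",
            "## Trial accounting",
            "",
            json.dumps(self.accounting.as_dict(), indent=1),
            "",
        ]
        return "\n".join(head) + "\n" + self.report.to_markdown()

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.study_table.to_csv(out / "window_stats.csv", index=False)
        self.stationarity.to_csv(out / "stationarity.csv", index=False)
        rows = []
        for subset, per_measure in self.anovas.items():
            for measure, res in per_measure.items():
                for effect in ("window", "side", "participant", "window:side"):
                    r = res.anova_table.loc[effect]
                    rows.append(
                        {
                            "subset": subset,
                            "measure": measure,
                            "effect": effect,
                            "df1": r["df"],
                            "df2": r["df_denom"],
                            "F": r["F"],
                            "p": r["p"],
                        }
                    )
        pd.DataFrame(rows).to_csv(out / "anova.csv", index=False)
        flags = pd.DataFrame(
            [
                {
                    "participant": rec.participant_id,
                    "session": rec.session_index,
                    "trial": rec.trial_index,
                    "stimulus": rec.stimulus_flag,
                    "t_stim": rec.t_stim,
                    "usable": rec.usable_flag,
                    "formal_startle": rec.formal_startle_flag,
                }
                for rec in self.trials
            ]
        )
        flags.to_csv(out / "trials.csv", index=False)
        (out / "report.md").write_text(self.report_markdown())
        (out / "accounting.json").write_text(json.dumps(self.accounting.as_dict(), indent=1))
        return out


def _window_rows(config: StudyConfig, rec: TrialRecord, side: str, series_filtered):
    pair = extraction.extract_windows(series_filtered, rec.t_stim, config.window_width)
    rows = []
    for window, vals in (("pre", pair.pre), ("post", pair.post)):
        ws = stats.summary_stats(vals)
        ws.entropy = stats.shannon_entropy(vals, config.n_bins)
        rows.append(
            {
                "participant": rec.participant_id,
                "session": rec.session_index,
                "trial": rec.trial_index,
                "side": side,
                "window": window,
                **ws.as_dict(),
            }
        )
    return rows


def _finalize(config: StudyConfig, records, table_rows, stat_rows, errors) -> StudyResult:
    accounting = account_trials(records)
    study_table = pd.DataFrame(table_rows, columns=list(stats.STUDY_TABLE_COLUMNS))
    stationarity = pd.DataFrame(
        stat_rows,
        columns=["participant", "session", "trial", "side", "stimulus_flag",
                 "n_runs", "p", "nonstationary"],
    )
    anovas: Dict[str, Dict[str, stats.PeriorbitalAnovaResults]] = {}
    report = stats.build_report(study_table, alpha=config.alpha)
    anovas = report.anovas
    return StudyResult(
        config=config,
        accounting=accounting,
        study_table=study_table,
        stationarity=stationarity,
        anovas=anovas,
        report=report,
        trials=records,
        errors=errors,
    )


def run_study(config: StudyConfig) -> StudyResult:
    """Execute the full imaging pipeline over a simulated study.

    Every trial is rendered, tracked on both sides, extracted, filtered and
    tested; per-trial errors quarantine the trial (marked unusable) rather
    than aborting the study.  Deterministic given ``config.phantom.seed``.
    """
    records = simulate_study(
        config.phantom, config.n_participants, config.n_sessions, config.n_trials,
        render_frames=False,
    )
    rois = config.reference_rois()
    table_rows, stat_rows, errors = [], [], []
    for rec in records:
        try:
            full = render_trial(config.phantom, rec)
            rec.ground_truth = full.ground_truth
            tracks = {
                side: tracking.track_region(
                    full.stack, rois[side], side=side, max_step=config.max_step,
                    fail_ratio=config.fail_ratio, fail_consecutive=config.fail_consecutive,
                )
                for side in ("left", "right")
            }
            rec.usable_flag = not detection.flag_unusable(tracks["left"], tracks["right"])
            if rec.stimulus_flag and rec.usable_flag:
                rec.formal_startle_flag = detection.detect_formal_startle(
                    full.stack, rec.t_stim, z_threshold=config.z_threshold
                )
            elif rec.stimulus_flag:
                rec.formal_startle_flag = None
            if rec.usable_flag:
                for side in ("left", "right"):
                    raw = extraction.series_from_track(full.stack, tracks[side])
                    filt = extraction.lowpass(raw)
                    rt = stats.runs_test(filt.values, alpha=config.alpha)
                    stat_rows.append(
                        {
                            "participant": rec.participant_id,
                            "session": rec.session_index,
                            "trial": rec.trial_index,
                            "side": side,
                            "stimulus_flag": rec.stimulus_flag,
                            "n_runs": rt.n_runs,
                            "p": rt.p,
                            "nonstationary": rt.nonstationary,
                        }
                    )
                    if rec.stimulus_flag:
                        for row in _window_rows(config, rec, side, filt):
                            row.update(
                                stimulus_flag=rec.stimulus_flag,
                                formal_startle_flag=rec.formal_startle_flag,
                                usable_flag=rec.usable_flag,
                            )
                            table_rows.append(row)
            logger.info(
                "trial %s/%s/%s: usable=%s startle=%s",
                rec.participant_id, rec.session_index, rec.trial_index,
                rec.usable_flag, rec.formal_startle_flag,
            )
        except Exception as exc:  # quarantine, never abort the study
            rec.usable_flag = False
            rec.formal_startle_flag = None
            errors.append({"trial": rec.key, "error": repr(exc)})
            logger.warning("trial %s quarantined: %r", rec.key, exc)
    return _finalize(config, records, table_rows, stat_rows, errors)


def run_series_study(config: StudyConfig) -> StudyResult:
    """Series-level study: model the extracted series directly (no video).

    Usability is taken as given (no tracking is exercised) and the
    formal-startle flag comes from the generator's ground truth.  Used for
    statistical calibration experiments where only the series model matters.
    """
    phant = config.phantom
    offsets = participant_offsets(phant, config.n_participants)
    records, table_rows, stat_rows, errors = [], [], [], []
    for p in range(1, config.n_participants + 1):
        pid = f"P{p:02d}"
        for s in range(1, config.n_sessions + 1):
            sched_rng = np.random.default_rng(
                np.random.SeedSequence((phant.seed, p, s))
            )
            flags = np.array(
                [True] * (config.n_trials // 2) + [False] * (config.n_trials // 2)
            )
            sched_rng.shuffle(flags)
            for t in range(1, config.n_trials + 1):
                rng = trial_rng(phant.seed, p, s, t)
                stim = bool(flags[t - 1])
                values, t_stim, gt = simulate_mean_series(
                    phant, stim, rng=rng, participant_offset=float(offsets[p - 1])
                )
                rec = TrialRecord(
                    participant_id=pid, session_index=s, trial_index=t,
                    stimulus_flag=stim, t_stim=t_stim,
                    trial_duration=phant.trial_duration,
                    ground_truth=gt, usable_flag=True,
                    formal_startle_flag=(gt["startle_occurred"] if stim else None),
                    seed_key=trial_seed_key(phant.seed, p, s, t),
                )
                records.append(rec)
                # sides share the physiological state but not measurement noise
                base = (
                    phant.canthus_peak_temp
                    + float(offsets[p - 1])
                    + gt["drift"]
                    + gt["effect"]
                )
                for side in ("left", "right"):
                    vals = values if side == "left" else (
                        base + rng.normal(0.0, phant.series_noise_sd, len(values))
                    )
                    ser = extraction.TemperatureSeries(vals, phant.fs_video, side=side)
                    filt = extraction.lowpass(ser)
                    rt = stats.runs_test(filt.values, alpha=config.alpha)
                    stat_rows.append(
                        {
                            "participant": pid, "session": s, "trial": t,
                            "side": side, "stimulus_flag": stim,
                            "n_runs": rt.n_runs, "p": rt.p,
                            "nonstationary": rt.nonstationary,
                        }
                    )
                    if stim:
                        for row in _window_rows(config, rec, side, filt):
                            row.update(
                                stimulus_flag=stim,
                                formal_startle_flag=rec.formal_startle_flag,
                                usable_flag=True,
                            )
                            table_rows.append(row)
    return _finalize(config, records, table_rows, stat_rows, errors)
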