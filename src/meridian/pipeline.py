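"""End-to-end study pipeline: cohort -> staircases -> CSF -> ssVEP -> statistics.

One seeded configuration drives the whole simulated study: a cohort of
two 16-observer groups, contrast sensitivity measured by two 3-down-1-up
staircases per condition (5 spatial frequencies x 2 orientations), CSF
parabola fits with AULCSF and cutoff per observer and orientation,
30 ssVEP trials per observer (3 per condition, 4 segments each) pushed
through the filtering/DFT/SNR chain, and finally the mixed
repeated-measures analyses, simple main effects, planned comparisons and
CS-ssVEP correlations.  Rerunning with the same seed reproduces every
table bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import math
import time
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import cohort as _cohort
from . import csf as _csf
from . import ssvep as _ssvep
from . import staircase as _staircase
from . import stats as _stats
from .cohort import Cohort, CohortSpec, ORIENTATIONS, SPATIAL_FREQUENCIES
from .staircase import StaircaseConfig

__all__ = ["StudyConfig", "StudyReport", "run_study", "summarize_demographics"]

log = logging.getLogger("meridian.pipeline")


@dataclass(frozen=True)
class StudyConfig:
    """Complete configuration of one simulated study run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    n_staircase_runs: int = 2
    n_ssvep_trials: int = 3
    n_ssvep_segments: int = 4
    csf_domain: Tuple[float, float] = (0.6, 12.0)
    snr_threshold: float = 3.0
    seed: int = 0

    def trials_per_subject(self) -> int:
        """ssVEP trial count per observer over the 5 x 2 condition grid."""
        return (
            len(SPATIAL_FREQUENCIES) * len(ORIENTATIONS) * self.n_ssvep_trials
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cohort_kwargs = raw.pop("cohort", {})
        staircase_kwargs = raw.pop("staircase", {})
        seed = raw.pop("seed", 0)
        cohort_kwargs.setdefault("seed", seed)
        if "csf_domain" in raw:
            raw["csf_domain"] = tuple(raw["csf_domain"])
        return cls(
            cohort=CohortSpec(**cohort_kwargs),
            staircase=StaircaseConfig(**staircase_kwargs),
            seed=seed,
            **raw,
        )

    def with_seed(self, seed: int) -> "StudyConfig":
        return dataclasses.replace(
            self,
            seed=seed,
            cohort=dataclasses.replace(self.cohort, seed=seed),
        )


@dataclass
class StudyReport:
    """All persisted outputs of one study run."""

    demographics: pd.DataFrame
    demographic_tests: pd.DataFrame
    cs_long: pd.DataFrame
    csf_table: pd.DataFrame
    ssvep_trials: pd.DataFrame
    ssvep_long: pd.DataFrame
    anovas: Dict[str, pd.DataFrame]
    cs_simple_effects: pd.DataFrame
    ssvep_group_effects: pd.DataFrame
    aulcsf_ttests: pd.DataFrame
    correlations: pd.DataFrame
    rejection_rate: float
    config: StudyConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "demographics.csv": self.demographics,
            "demographic_tests.csv": self.demographic_tests,
            "cs_long.csv": self.cs_long,
            "csf_table.csv": self.csf_table,
            "ssvep_trials.csv": self.ssvep_trials,
            "ssvep_long.csv": self.ssvep_long,
            "cs_simple_effects.csv": self.cs_simple_effects,
            "ssvep_group_effects.csv": self.ssvep_group_effects,
            "aulcsf_ttests.csv": self.aulcsf_ttests,
            "correlations.csv": self.correlations,
        }
        for name, df in tables.items():
            df.to_csv(out / name, index=False)
        for name, df in self.anovas.items():
            df.to_csv(out / f"anova_{name}.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {
                    "n_participants": int(self.demographics.loc[
                        self.demographics["group"] == "Overall", "n"
                    ].iloc[0]),
                    "ssvep_rejection_rate": self.rejection_rate,
                    "seed": self.config.seed,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def summarize_demographics(observers) -> pd.DataFrame:
    """Per-group and overall mean, SEM (SD/sqrt(n)), min, max of
    age/sphere/cylinder.  SEM is NaN for a single participant."""
    if not observers:
        raise ValueError("empty cohort")
    df = pd.DataFrame(
        [
            {
                "group": o.group,
                "age": o.age,
                "sphere": o.sphere,
                "cylinder": o.cylinder,
            }
            for o in observers
        ]
    )
    rows = []
    groups = [(g, sub) for g, sub in df.groupby("group", sort=True)]
    groups.append(("Overall", df))
    for gname, sub in groups:
        row = {"group": gname, "n": len(sub)}
        for var in ("age", "sphere", "cylinder"):
            v = sub[var]
            row[f"{var}_mean"] = v.mean()
            row[f"{var}_sem"] = (
                v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else math.nan
            )
            row[f"{var}_min"] = v.min()
            row[f"{var}_max"] = v.max()
        rows.append(row)
    return pd.DataFrame(rows)


def _measure_cs(cohort: Cohort, config: StudyConfig, rng) -> pd.DataFrame:
    rows = []
    for obs in cohort.observers:
        for sf in SPATIAL_FREQUENCIES:
            for orientation in ORIENTATIONS:
                log_cs = _staircase.run_condition(
                    obs, sf, orientation, rng,
                    n_runs=config.n_staircase_runs,
                    config=config.staircase,
                )
                rows.append(
                    {
                        "participant": obs.participant_id,
                        "group": obs.group,
                        "sf": sf,
                        "orientation": orientation,
                        "log_cs": log_cs,
                    }
                )
    return pd.DataFrame(rows)


def _fit_csfs(cs_long: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    lo, hi = config.csf_domain
    rows = []
    for (pid, group, orientation), sub in cs_long.groupby(
        ["participant", "group", "orientation"], sort=True
    ):
        fit = _csf.fit_csf(
            sub["sf"].to_numpy(), sub["log_cs"].to_numpy(), lo, hi
        )
        rows.append(
            {
                "participant": pid,
                "group": group,
                "orientation": orientation,
                "a": fit.a,
                "b": fit.b,
                "c": fit.c,
                "aulcsf": fit.aulcsf,
                "cutoff": fit.cutoff,
            }
        )
    return pd.DataFrame(rows)


def _measure_ssvep(cohort: Cohort, config: StudyConfig, rng):
    model = cohort.signal_model
    trial_rows = []
    for obs in cohort.observers:
        offset = cohort.log_amp_offsets[obs.participant_id]
        for sf in SPATIAL_FREQUENCIES:
            for orientation in ORIENTATIONS:
                for trial in range(config.n_ssvep_trials):
                    segments = _cohort.synthesize_trial(
                        model, obs.group, orientation, sf, rng,
                        n_segments=config.n_ssvep_segments,
                        log_amp_offset=offset,
                    )
                    res = _ssvep.analyze_trial(
                        segments, fs=model.fs, threshold=config.snr_threshold
                    )
                    trial_rows.append(
                        {
                            "participant": obs.participant_id,
                            "group": obs.group,
                            "sf": sf,
                            "orientation": orientation,
                            "trial": trial,
                            "signal_amp": res.signal_amp,
                            "noise_amp": res.noise_amp,
                            "snr": res.snr,
                            "reliable": res.reliable,
                        }
                    )
    trials = pd.DataFrame(trial_rows)
    summaries = []
    for (pid, group, sf, orientation), sub in trials.groupby(
        ["participant", "group", "sf", "orientation"], sort=True
    ):
        kept = sub.loc[sub["reliable"], "signal_amp"]
        summary = _ssvep.summarize_condition(kept.to_numpy(), len(sub))
        summaries.append(
            {
                "participant": pid,
                "group": group,
                "sf": sf,
                "orientation": orientation,
                "mean_log_amp": summary.mean_log_amp,
                "n_kept": summary.n_kept,
                "n_total": summary.n_total,
            }
        )
    return trials, pd.DataFrame(summaries)


def _complete_participants(table: pd.DataFrame, dv: str) -> pd.DataFrame:
    """Listwise-drop participants with any missing cell (logged)."""
    bad = table.loc[table[dv].isna(), "participant"].unique()
    if len(bad):
        log.info("dropping %d participant(s) with incomplete %s cells: %s",
                 len(bad), dv, ", ".join(map(str, bad)))
        table = table[~table["participant"].isin(bad)]
    return table


def run_study(config: StudyConfig, out_dir=None) -> StudyReport:
    """Run the whole simulated study and (optionally) persist all tables."""
    t0 = time.perf_counter()
    seeds = np.random.SeedSequence(config.seed).spawn(3)
    cohort = _cohort.make_cohort(
        dataclasses.replace(config.cohort, seed=config.seed)
    )
    log.info("cohort: %d observers (%.2fs)", len(cohort.observers),
             time.perf_counter() - t0)

    cs_rng = np.random.default_rng(seeds[0])
    cs_long = _measure_cs(cohort, config, cs_rng)
    log.info("staircases: %d conditions (%.2fs)", len(cs_long),
             time.perf_counter() - t0)

    csf_table = _fit_csfs(cs_long, config)

    ssvep_rng = np.random.default_rng(seeds[1])
    ssvep_trials, ssvep_long = _measure_ssvep(cohort, config, ssvep_rng)
    rej = _ssvep.rejection_rate(
        _ssvep.SNRResult(0, 0, 0, bool(r)) for r in ssvep_trials["reliable"]
    )
    log.info("ssvep: %d trials, rejection rate %.4f (%.2fs)",
             len(ssvep_trials), rej, time.perf_counter() - t0)

    # ---- statistics -------------------------------------------------------
    anovas: Dict[str, pd.DataFrame] = {}
    anovas["cs"] = _stats.mixed_anova(
        cs_long, dv="log_cs", within=["sf", "orientation"]
    )
    for dv_name in ("aulcsf", "cutoff"):
        tab = csf_table.rename(columns={dv_name: "value"})[
            ["participant", "group", "orientation", "value"]
        ]
        tab = _complete_participants(tab, "value")
        anovas[dv_name] = _stats.mixed_anova(
            tab, dv="value", within=["orientation"]
        )
    ssvep_complete = _complete_participants(ssvep_long, "mean_log_amp")
    anovas["ssvep"] = _stats.mixed_anova(
        ssvep_complete, dv="mean_log_amp", within=["sf", "orientation"]
    )

    # orientation effect inside each group x spatial frequency (family = 5 sf
    # per group, Holm-adjusted within group)
    cs_se = []
    for group, sub in cs_long.groupby("group", sort=True):
        se = _stats.simple_main_effects(
            sub, stratify_by=["sf"], test_factor="orientation", dv="log_cs"
        )
        se.insert(0, "group", group)
        cs_se.append(se)
    cs_simple = pd.concat(cs_se, ignore_index=True)

    # group effect per spatial frequency on ssVEP amplitude (family = 5)
    ssvep_group = _stats.simple_main_effects(
        ssvep_complete, stratify_by=["sf"], test_factor="group",
        dv="mean_log_amp",
    )

    # planned paired comparisons of AULCSF orientation within each group
    # (plain Bonferroni over the two groups)
    rows = []
    for group, sub in csf_table.groupby("group", sort=True):
        wide = sub.pivot(index="participant", columns="orientation",
                         values="aulcsf").dropna()
        res = _stats.paired_t(wide["H"], wide["V"])
        rows.append({"group": group, "t": res.statistic, "df": res.df,
                     "p": res.p_raw, "n": len(wide)})
    aulcsf_t = pd.DataFrame(rows)
    aulcsf_t["p_adjusted"] = _stats.bonferroni(aulcsf_t["p"].to_numpy())

    # CS vs ssVEP amplitude correlations per condition within each group
    # (Holm over the 10 conditions of a group)
    merged = cs_long.merge(
        ssvep_long[["participant", "sf", "orientation", "mean_log_amp"]],
        on=["participant", "sf", "orientation"],
    )
    corr_rows = []
    for (group, sf, orientation), sub in merged.groupby(
        ["group", "sf", "orientation"], sort=True
    ):
        sub = sub.dropna(subset=["log_cs", "mean_log_amp"])
        if len(sub) < 3:
            continue
        res = _stats.pearson(sub["log_cs"], sub["mean_log_amp"])
        corr_rows.append({"group": group, "sf": sf, "orientation": orientation,
                          "r": res.statistic, "p": res.p_raw, "n": len(sub)})
    correlations = pd.DataFrame(corr_rows)
    if not correlations.empty:
        adjusted = []
        for group, sub in correlations.groupby("group", sort=True):
            adj = _stats.holm(sub["p"].to_numpy())
            adjusted.append(pd.Series(adj, index=sub.index))
        correlations["p_adjusted"] = pd.concat(adjusted).sort_index()

    demographics = summarize_demographics(cohort.observers)
    demo_tests = _demographic_tests(cohort)

    report = StudyReport(
        demographics=demographics,
        demographic_tests=demo_tests,
        cs_long=cs_long,
        csf_table=csf_table,
        ssvep_trials=ssvep_trials,
        ssvep_long=ssvep_long,
        anovas=anovas,
        cs_simple_effects=cs_simple,
        ssvep_group_effects=ssvep_group,
        aulcsf_ttests=aulcsf_t,
        correlations=correlations,
        rejection_rate=rej,
        config=config,
    )
    if out_dir is not None:
        report.write(out_dir)
        _cohort.write_cohort_tables(cohort, out_dir)
    log.info("study complete (%.2fs)", time.perf_counter() - t0)
    return report


def _demographic_tests(cohort: Cohort) -> pd.DataFrame:
    has = cohort.by_group("HAS")
    nas = cohort.by_group("NAS")
    rows = []
    for var in ("age", "sphere", "cylinder"):
        res = _stats.unpaired_t(
            [getattr(o, var) for o in has], [getattr(o, var) for o in nas]
        )
        rows.append({"variable": var, "t": res.statistic, "df": res.df,
                     "p": res.p_raw})
    return pd.DataFrame(rows)
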