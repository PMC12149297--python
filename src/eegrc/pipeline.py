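"""Pipeline orchestration: ingest -> preprocess -> metrics -> statistics.

A single :class:`PipelineConfig` drives the whole analysis: read (or
synthesise) a cohort, band-pass 1-45 Hz, re-reference to the common
average, select a 15 s artifact-free epoch, compute relative band power
and both fractal-dimension estimates on the epoch, run alpha-band DFA on
the first 300 s of the recording, then summarise regionally and compare
groups.  Outputs are tidy TSV tables plus a JSON run manifest with
per-subject logs and output checksums; runs are deterministic for a fixed
config, seed and inputs.

The ``dataset2_128hz`` dialect (128 Hz, 8 s records) forbids DFA — those
recordings are far shorter than the 300 s the fluctuation analysis needs —
and defaults kmax to 32 instead of 126.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .complexity import (DEFAULT_KMAX, box_counting_table, kmax_scan,
                         windowed_hfd)
from .dfa import alpha_lrtc_pipeline
from .io import Recording, read_cohort, standard_montage
from .preprocess import (BROADBAND, EpochSelectionError, FilterSpec, bandpass,
                         common_average_reference, select_epoch)
from .spectral import BAND_NAMES, relative_band_power
from .stats import (channelwise_t_map, mann_whitney_u, normality_diagnostic,
                    one_way_anova, pillai_manova, regional_summary, tukey_hsd)
from .synth import CohortSpec, gen_cohort

DIALECTS = ("dataset1_500hz", "dataset2_128hz", "custom")


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Run configuration; defaults mirror the 500 Hz dataset-1 settings."""

    input_dir: str | None = None          # None -> synthetic cohort
    input_format: str = "auto"
    dialect: str = "dataset1_500hz"
    filter_low_hz: float = 1.0
    filter_high_hz: float = 45.0
    epoch_duration_s: float = 15.0
    epoch_amp_limit_uv: float = 100.0
    kmax: int | str | None = None         # None -> by fs; "scan" -> cohort scan
    kmax_scan_values: list | None = None
    run_dfa: bool | None = None           # None -> dialect default
    dfa_duration_s: float = 300.0
    dfa_fit_interval_s: tuple = (2.0, 25.0)
    dfa_calc_interval_s: tuple = (0.8, 30.0)
    dfa_overlap: float = 0.5
    dfa_n_windows: int = 10
    stats_alpha: float = 0.05
    use_mann_whitney: bool = False
    output_dir: str = "results"
    seed: int = 0
    synth: CohortSpec | None = None

    def __post_init__(self):
        if self.dialect not in DIALECTS:
            raise ConfigError(f"unknown dialect {self.dialect!r}")
        if self.dialect == "dataset2_128hz":
            if self.run_dfa:
                raise ConfigError(
                    "the dataset2_128hz dialect forbids DFA: its recordings "
                    "are too short for the fluctuation analysis"
                )
            self.run_dfa = False
        elif self.run_dfa is None:
            self.run_dfa = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw: dict = {}
        flat_map = {
            "input": {"dir": "input_dir", "format": "input_format",
                      "dialect": "dialect"},
            "filter": {"low_hz": "filter_low_hz", "high_hz": "filter_high_hz"},
            "epoch": {"duration_s": "epoch_duration_s",
                      "amp_limit_uv": "epoch_amp_limit_uv"},
            "hfd": {"kmax": "kmax", "scan_values": "kmax_scan_values"},
            "dfa": {"enabled": "run_dfa", "duration_s": "dfa_duration_s",
                    "fit_interval_s": "dfa_fit_interval_s",
                    "calc_interval_s": "dfa_calc_interval_s",
                    "overlap": "dfa_overlap", "n_windows": "dfa_n_windows"},
            "stats": {"alpha": "stats_alpha",
                      "mann_whitney": "use_mann_whitney"},
        }
        for section, mapping in flat_map.items():
            for k, v in (raw.get(section) or {}).items():
                if k not in mapping:
                    raise ConfigError(f"unknown key {section}.{k}")
                kw[mapping[k]] = tuple(v) if isinstance(v, list) and \
                    mapping[k].endswith("interval_s") else v
        for k in ("output_dir", "seed", "dialect"):
            if k in raw:
                kw[k] = raw[k]
        if "synth" in raw and raw["synth"] is not None:
            kw["synth"] = CohortSpec(**raw["synth"])
        return cls(**kw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synth is not None:
            d["synth"] = dataclasses.asdict(self.synth)
        return d


@dataclass
class RunManifest:
    """Audit record of one pipeline run."""

    config: dict
    version: str = __version__
    subjects: dict = field(default_factory=dict)   # id -> per-stage log
    outputs: dict = field(default_factory=dict)    # filename -> sha256
    started: str = ""
    finished: str = ""
    n_failures: int = 0

    def log(self, subject: str, **entries) -> None:
        self.subjects.setdefault(subject, {}).update(entries)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, default=str)


@dataclass
class PipelineResult:
    manifest: RunManifest
    tables: dict  # name -> DataFrame

    @property
    def ok(self) -> bool:
        return self.manifest.n_failures == 0


def exclude_subjects(cohort, min_duration_s: float = 0.0,
                     epoch_duration_s: float = 15.0,
                     amp_limit_uv: float = 100.0):
    """Drop subjects with no clean epoch or insufficient duration.

    Returns ``(kept, exclusion_log)``; raises if every subject is excluded.
    """
    kept, log = [], {}
    for rec in cohort:
        if rec.duration_s < max(min_duration_s, epoch_duration_s):
            log[rec.subject_id] = (
                f"recording {rec.duration_s:g} s shorter than required")
            continue
        try:
            select_epoch(rec, epoch_duration_s, amp_limit_uv)
        except EpochSelectionError as exc:
            log[rec.subject_id] = str(exc)
            continue
        kept.append(rec)
    if not kept:
        raise RuntimeError("all subjects excluded: " + "; ".join(log.values()))
    return kept, log


_REGIONS = ("global", "rostral", "caudal", "asymmetry")


def _region_value(summary, region: str) -> float:
    return {"global": summary.global_mean, "rostral": summary.rostral_mean,
            "caudal": summary.caudal_mean,
            "asymmetry": summary.asymmetry}[region]


def run_pipeline(config: PipelineConfig,
                 recordings: list[Recording] | None = None) -> PipelineResult:
    """Execute the full analysis and write TSV tables plus a manifest.

    Per-subject stage failures are recorded in the manifest and the
    remaining subjects are processed; ``result.ok`` is False if anything
    failed.
    """
    manifest = RunManifest(config=config.snapshot(),
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"))
    if recordings is None:
        if config.input_dir is not None:
            recordings = read_cohort(config.input_dir, config.input_format)
        else:
            spec = config.synth or CohortSpec(master_seed=config.seed)
            recordings = gen_cohort(spec)
    montage = standard_montage()
    bb = FilterSpec(config.filter_low_hz, config.filter_high_hz, "broadband")

    epochs, processed = [], []
    for rec in recordings:
        sid = rec.subject_id
        try:
            clean = common_average_reference(bandpass(rec, bb))
            ep = select_epoch(clean, config.epoch_duration_s,
                              config.epoch_amp_limit_uv)
            manifest.log(sid, group=rec.group,
                         epoch_offset_s=ep.source_offset_s)
            epochs.append(ep)
            processed.append(rec)
        except Exception as exc:
            manifest.log(sid, group=rec.group, failure=f"preprocess: {exc}")
            manifest.n_failures += 1
    if not epochs:
        raise RuntimeError("no subject survived preprocessing")

    kmax = config.kmax
    tables: dict[str, pd.DataFrame] = {}
    if kmax == "scan":
        values = config.kmax_scan_values or [
            int(k) for k in np.unique(np.round(np.logspace(
                np.log10(2), np.log10(epochs[0].fs / 2), 25)))]
        scan = kmax_scan(epochs, values)
        tables["kmax_scan"] = scan.to_frame()
        kmax = scan.selected_kmax
        manifest.log("_cohort", selected_kmax=kmax,
                     kmax_rule=scan.selection_rule)
    elif kmax is None:
        kmax = DEFAULT_KMAX.get(int(round(epochs[0].fs)), 126)

    bp_rows, fd_rows, hfd_rows, dfa_rows, reg_rows = [], [], [], [], []
    metric_maps: dict[str, dict[str, dict[str, float]]] = {}

    def store(metric: str, sid: str, per_channel: dict):
        metric_maps.setdefault(metric, {})[sid] = per_channel

    for rec, ep in zip(processed, epochs):
        sid = ep.subject_id
        try:
            bpt = relative_band_power(ep)
            for ch in bpt.table.index:
                bp_rows.append({"subject": sid, "group": ep.group,
                                "channel": ch,
                                **bpt.table.loc[ch].to_dict()})
            for band in BAND_NAMES:
                store(f"relpower_{band}", sid, bpt.table[band].to_dict())
            fdt = box_counting_table(ep)
            for ch, v in fdt.values.items():
                fd_rows.append({"subject": sid, "group": ep.group,
                                "channel": ch, "fd": v})
            store("fd_box", sid, fdt.values.to_dict())
            hft = windowed_hfd(ep, kmax=kmax)
            for ch, v in hft.values.items():
                hfd_rows.append({"subject": sid, "group": ep.group,
                                 "channel": ch, "fd": v})
            store("fd_higuchi", sid, hft.values.to_dict())
        except Exception as exc:
            manifest.log(sid, failure=f"metrics: {exc}")
            manifest.n_failures += 1
            continue
        if config.run_dfa:
            if rec.duration_s >= config.dfa_duration_s:
                try:
                    dres = alpha_lrtc_pipeline(
                        rec, config.dfa_duration_s,
                        calc_interval_s=config.dfa_calc_interval_s,
                        fit_interval_s=config.dfa_fit_interval_s,
                        overlap=config.dfa_overlap,
                        n_sizes=config.dfa_n_windows)
                    for ch, a, r in zip(dres.channels, dres.exponents,
                                        dres.residuals):
                        dfa_rows.append({"subject": sid, "group": ep.group,
                                         "channel": ch, "exponent": a,
                                         "residual": r})
                    store("dfa_alpha", sid, dres.as_dict())
                except Exception as exc:
                    manifest.log(sid, failure=f"dfa: {exc}")
                    manifest.n_failures += 1
            else:
                manifest.log(sid, dfa_skipped=(
                    f"recording {rec.duration_s:g} s < "
                    f"{config.dfa_duration_s:g} s"))

    groups_by_sid = {ep.subject_id: ep.group for ep in epochs}
    for metric, by_sid in metric_maps.items():
        for sid, chvals in by_sid.items():
            rs = regional_summary(chvals, montage, subject_id=sid,
                                  metric=metric)
            reg_rows.append({"subject": sid, "group": groups_by_sid[sid],
                             "metric": metric, "global": rs.global_mean,
                             "rostral": rs.rostral_mean,
                             "caudal": rs.caudal_mean,
                             "asymmetry": rs.asymmetry})

    tables["band_power"] = pd.DataFrame(bp_rows)
    tables["complexity_box"] = pd.DataFrame(fd_rows)
    tables["complexity_higuchi"] = pd.DataFrame(hfd_rows)
    if dfa_rows:
        tables["dfa"] = pd.DataFrame(dfa_rows)
    tables["regional"] = pd.DataFrame(reg_rows)

    reg = tables["regional"]
    glabels = sorted(reg["group"].unique())
    stat_rows, tmap_rows = [], []
    sizable = [g for g in glabels
               if (reg["group"] == g).sum() // max(len(metric_maps), 1) >= 2]
    if len(sizable) >= 2:
        _group_statistics(config, reg, metric_maps, groups_by_sid, montage,
                          stat_rows, tmap_rows, sizable)
    tables["group_stats"] = pd.DataFrame(stat_rows)
    tables["tmaps"] = pd.DataFrame(tmap_rows)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.6g")
        manifest.outputs[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(manifest.to_json())
    return PipelineResult(manifest=manifest, tables=tables)


def _group_statistics(config, reg, metric_maps, groups_by_sid, montage,
                      stat_rows, tmap_rows, glabels) -> None:
    pairs = [(glabels[i], glabels[j]) for i in range(len(glabels))
             for j in range(i + 1, len(glabels))]
    for metric in metric_maps:
        piv = reg[reg["metric"] == metric]
        for region in _REGIONS:
            groups = {g: piv.loc[piv["group"] == g, region].to_numpy()
                      for g in glabels}
            try:
                an = one_way_anova(groups)
            except ValueError:
                continue
            stat_rows.append({"metric": metric, "region": region,
                              **an.as_row()})
            for tk in tukey_hsd(groups):
                stat_rows.append({"metric": metric, "region": region,
                                  **tk.as_row()})
            if config.use_mann_whitney:
                for a, b in pairs:
                    mw = mann_whitney_u(groups[a], groups[b])
                    row = mw.as_row()
                    row["comparison"] = f"{a}:{b}"
                    stat_rows.append({"metric": metric, "region": region,
                                      **row})
            for g in glabels:
                nd = normality_diagnostic(groups[g]) if len(groups[g]) >= 8 \
                    else None
                if nd is not None:
                    stat_rows.append({"metric": metric, "region": region,
                                      "test": nd.test, "comparison": g,
                                      "statistic": nd.statistic,
                                      "p": nd.p_value})
        # channelwise t-maps, FDR within each metric x comparison family
        mat = pd.DataFrame(metric_maps[metric]).T[list(montage.all19)]
        labels = pd.Series({s: groups_by_sid[s] for s in mat.index})
        for pair in pairs:
            if min((labels == g).sum() for g in pair) < 2:
                continue
            tm = channelwise_t_map(mat, labels, pair, config.stats_alpha,
                                   metric)
            for _, r in tm.to_frame().iterrows():
                tmap_rows.append({"metric": metric,
                                  "comparison": f"{pair[0]}:{pair[1]}",
                                  **r.to_dict()})
    # joint band-power profile (gamma dropped: the five ratios sum to 1)
    prof = reg[(reg["metric"].str.startswith("relpower_"))
               & (reg["metric"] != "relpower_gamma")]
    wide = prof.pivot_table(index="subject", columns="metric",
                            values="global")
    labels = reg.drop_duplicates("subject").set_index("subject")["group"]
    try:
        mv = pillai_manova({g: wide.loc[labels[labels == g].index].to_numpy()
                            for g in glabels})
        stat_rows.append({"metric": "relpower_profile", "region": "global",
                          **mv.as_row()})
    except (ValueError, np.linalg.LinAlgError):
        pass
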