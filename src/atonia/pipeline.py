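"""End-to-end orchestration: simulate → stage → REM-A → architecture /
spectral → statistics, written as a reproducible report bundle.

A run is described by a single :class:`RunConfig` (YAML-loadable); the same
config and master seed always produce byte-identical CSV outputs. The report
bundle contains per-animal hypnograms, a REM-A table, state-proportion /
bout / transition / latency tables, group-level mean spectra, a statistics
report, and a manifest recording the config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import architecture, io_formats, spectral, staging, stats, synthetic
from .core import ARTIFACT, REMS, STATES, WAKE, Hypnogram
from .errors import ConfigError, UndefinedResultError
from .rema import RemaConfig, analyze_rema
from .staging import StagingConfig
from .synthetic import CohortConfig


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    staging: StagingConfig = field(default_factory=StagingConfig)
    rema: RemaConfig = field(default_factory=RemaConfig)
    bin_s: float = 7200.0
    n_boot: int = 10_000
    seed: int | None = None  # overrides cohort.seed when given

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        out = {}
        for name, sub_cls in [
            ("cohort", CohortConfig),
            ("staging", StagingConfig),
            ("rema", RemaConfig),
        ]:
            if name in d:
                sub = d.pop(name)
                sub_known = {f.name for f in dataclasses.fields(sub_cls)}
                bad = set(sub) - sub_known
                if bad:
                    raise ConfigError(
                        f"unknown keys in {name!r} block: {sorted(bad)}"
                    )
                # YAML gives tuples back as lists
                sub = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()
                }
                out[name] = sub_cls(**sub)
        out.update(d)
        return cls(**out)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def analyze_animal(
    rec, cfg: RunConfig, truth: Hypnogram | None = None, hypnogram: Hypnogram | None = None
) -> dict:
    """Stage one animal (unless a pre-staged hypnogram is supplied), run the
    REM-A pass and collect all per-animal tables."""
    features = staging.compute_features(rec, cfg.staging)
    if hypnogram is None:
        th = staging.calibrate_thresholds(features, cfg.staging)
        raw = staging.classify_epochs(features, th, cfg.staging.epoch_len)
        hyp = staging.enforce_min_bout(raw, cfg.staging.min_bout_epochs)
    else:
        hyp = hypnogram.copy()
    emg_rms = features["emg_rms"].to_numpy()
    try:
        hyp, rema_res, atonia_th = analyze_rema(hyp, emg_rms, features, cfg.rema)
    except UndefinedResultError:
        rema_res, atonia_th = None, np.nan

    lights_off = rec.lights_off_at
    props = architecture.state_proportions(hyp, cfg.bin_s)
    bouts = architecture.extract_bouts(hyp, lights_off)
    transitions = {
        period: architecture.transition_profile(hyp, period, lights_off)
        for period in architecture.PERIODS
    }
    latency = architecture.rems_latency(
        hyp, lights_off, cfg.staging.min_bout_epochs
    )
    out = {
        "recording": rec,
        "hypnogram": hyp,
        "features": features,
        "rema": rema_res,
        "atonia_threshold": atonia_th,
        "proportions": props,
        "bouts": bouts,
        "transitions": transitions,
        "rems_latency_active": latency,
    }
    if truth is not None:
        n = min(truth.n_epochs, hyp.n_epochs)
        agree = truth.states[:n] == hyp.states[:n]
        out["staging_agreement"] = float(np.mean(agree))
        out["state_recall"] = {
            s: float(np.mean(agree[truth.states[:n] == s]))
            if np.any(truth.states[:n] == s)
            else np.nan
            for s in STATES
        }
    return out


def _rems_percent(result: dict, period: str) -> float:
    hyp = result["hypnogram"]
    lights_off = result["recording"].lights_off_at
    periods = architecture.epoch_periods(hyp, lights_off)
    sel = (periods == period) & ~hyp.flags[ARTIFACT]
    if not sel.any():
        return np.nan
    return 100.0 * np.mean(hyp.states[sel] == REMS)


def group_statistics(results: list[dict], cfg: RunConfig) -> dict:
    """The study-level comparisons: AUC of inactive-period REMS% between
    young MSA and young controls, AUC of REM-A proportions of adult MSA vs
    both control groups, a strain×time mixed ANOVA on the young pair's
    per-bin REMS%, and KS tests on active-period WAKE bout lengths."""
    by_group: dict[str, list[dict]] = {}
    for r in results:
        by_group.setdefault(r["recording"].group, []).append(r)
    seed = cfg.seed if cfg.seed is not None else cfg.cohort.seed
    out: dict = {"groups": {g: len(v) for g, v in by_group.items()}}

    def rems_inactive(group):
        return np.array([_rems_percent(r, "inactive") for r in by_group[group]])

    def rema_props(group):
        return np.array(
            [
                r["rema"].proportion if r["rema"] is not None else 0.0
                for r in by_group[group]
            ]
        )

    if {"msa_young", "control_young"} <= by_group.keys():
        res = stats.auc_analysis(
            rems_inactive("control_young"),
            rems_inactive("msa_young"),
            n_boot=cfg.n_boot,
            seed=seed,
        )
        out["auc_rems_inactive_msa_young_vs_control_young"] = dataclasses.asdict(res)

        # strain x time ANOVA on per-bin REMS% (needs >=2 time bins,
        # i.e. a session at least twice the bin width)
        bins = min(len(r["proportions"]) for g in ("msa_young", "control_young")
                   for r in by_group[g])
        if bins >= 2:
            table, labels = [], []
            for g in ("control_young", "msa_young"):
                for r in by_group[g]:
                    table.append(r["proportions"][REMS].to_numpy()[:bins])
                    labels.append(g)
            anova = stats.mixed_anova(np.vstack(table), np.array(labels))
            out["anova_rems_young"] = {
                "effects": anova.effects.reset_index(names="effect").to_dict("records"),
                "sphericity_correction": anova.sphericity_correction,
            }

        # KS on pooled active-period WAKE bout lengths
        def wake_bouts(group):
            pooled = []
            for r in by_group[group]:
                b = r["bouts"]
                sel = (b["state"] == WAKE) & (b["period"] == "active")
                pooled.extend(b.loc[sel, "length"].tolist())
            return np.array(pooled, dtype=float)

        xw, yw = wake_bouts("control_young"), wake_bouts("msa_young")
        if xw.size and yw.size:
            ks = stats.ks_two_sample(xw, yw, m_comparisons=1)
            out["ks_wake_bouts_active_young"] = dataclasses.asdict(ks)

    for ctrl in ("control_young", "control_adult"):
        if {"msa_adult", ctrl} <= by_group.keys():
            res = stats.auc_analysis(
                rema_props(ctrl), rema_props("msa_adult"), n_boot=cfg.n_boot, seed=seed
            )
            out[f"auc_rema_msa_adult_vs_{ctrl}"] = dataclasses.asdict(res)
    return out


def run_full_analysis(
    cfg: RunConfig,
    outdir=None,
    animals=None,
    prestaged: dict[str, Hypnogram] | None = None,
) -> dict:
    """Run the full pipeline and (optionally) write the report bundle.

    ``animals`` may supply an iterable of :class:`synthetic.CohortAnimal`
    (or objects with ``recording``/``truth`` attributes) to analyze instead
    of generating the configured cohort; ``prestaged`` maps animal ids to
    hypnograms that skip the staging step for those animals.
    """
    if cfg.seed is not None:
        cfg.cohort.seed = cfg.seed
    if animals is None:
        animals = synthetic.generate_cohort(cfg.cohort)
    prestaged = prestaged or {}

    results = []
    for animal in animals:
        rec = animal.recording
        res = analyze_animal(
            rec,
            cfg,
            truth=getattr(animal, "truth", None),
            hypnogram=prestaged.get(rec.animal_id),
        )
        results.append(res)

    group_stats = group_statistics(results, cfg)
    bundle = {"results": results, "stats": group_stats, "config": cfg}
    if outdir is not None:
        write_report(bundle, cfg, Path(outdir))
    return bundle


def _rema_table(results: list[dict]) -> pd.DataFrame:
    rows = []
    for r in results:
        rec = r["recording"]
        rema_res = r["rema"]
        rows.append(
            {
                "animal_id": rec.animal_id,
                "group": rec.group,
                "rema_epochs": rema_res.rema_epochs if rema_res else np.nan,
                "total_rems": rema_res.total_rems_epochs if rema_res else 0,
                "proportion_percent": rema_res.proportion if rema_res else np.nan,
            }
        )
    return pd.DataFrame(rows)


def write_report(bundle: dict, cfg: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "hypnograms").mkdir(exist_ok=True)
    results = bundle["results"]

    prop_rows, bout_rows, trans_rows, lat_rows, spec_pairs = [], [], [], [], {}
    for r in results:
        rec = r["recording"]
        io_formats.write_hypnogram(
            r["hypnogram"], outdir / "hypnograms" / f"{rec.animal_id}.csv"
        )
        props = r["proportions"].reset_index()
        props.insert(0, "animal_id", rec.animal_id)
        props.insert(1, "group", rec.group)
        prop_rows.append(props)
        bouts = r["bouts"].copy()
        bouts.insert(0, "animal_id", rec.animal_id)
        bouts.insert(1, "group", rec.group)
        bout_rows.append(bouts)
        for period, profile in r["transitions"].items():
            for key, count in profile.counts.items():
                trans_rows.append(
                    {
                        "animal_id": rec.animal_id,
                        "group": rec.group,
                        "period": period,
                        "transition": key,
                        "count": count,
                        "probability": profile.probabilities()[key],
                    }
                )
            trans_rows.append(
                {
                    "animal_id": rec.animal_id,
                    "group": rec.group,
                    "period": period,
                    "transition": "WAKE->REMS (anomaly)",
                    "count": profile.anomalies,
                    "probability": np.nan,
                }
            )
        lat_rows.append(
            {
                "animal_id": rec.animal_id,
                "group": rec.group,
                "rems_latency_active_epochs": r["rems_latency_active"],
            }
        )
        spec_pairs.setdefault(rec.group, []).append((rec, r["hypnogram"]))

    pd.concat(prop_rows, ignore_index=True).to_csv(
        outdir / "state_proportions.csv", index=False
    )
    pd.concat(bout_rows, ignore_index=True).to_csv(outdir / "bouts.csv", index=False)
    pd.DataFrame(trans_rows).to_csv(outdir / "transitions.csv", index=False)
    pd.DataFrame(lat_rows).to_csv(outdir / "rems_latency.csv", index=False)
    _rema_table(results).to_csv(outdir / "rema_report.csv", index=False)

    spec_rows = []
    for group, pairs in spec_pairs.items():
        for state in STATES:
            for period in architecture.PERIODS:
                try:
                    freqs, mean, sem, n = spectral.cohort_state_spectrum(
                        pairs, state, period
                    )
                except UndefinedResultError:
                    continue
                spec_rows.append(
                    pd.DataFrame(
                        {
                            "group": group,
                            "state": state,
                            "period": period,
                            "freq_hz": freqs,
                            "psd_mean": mean,
                            "psd_sem": sem,
                            "n_animals": n,
                        }
                    )
                )
    if spec_rows:
        pd.concat(spec_rows, ignore_index=True).to_csv(
            outdir / "group_spectra.csv", index=False
        )

    with open(outdir / "stats.json", "w", encoding="utf-8") as fh:
        json.dump(bundle["stats"], fh, indent=2, default=float)

    cfg_dict = cfg.to_dict()
    manifest = {
        "config": cfg_dict,
        "seed": cfg.seed if cfg.seed is not None else cfg.cohort.seed,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "package_version": __import__("atonia").__version__,
        "n_animals": len(results),
    }
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
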