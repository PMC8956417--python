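"""End-to-end orchestration: generate or load a cohort, preprocess, extract
features, run the group statistics, cluster, and write a structured report.

Outputs under the configured directory:

* ``features.csv`` — long feature table (subject, stage, band, measure, location, value)
* ``statmap_<contrast>_<band>.csv`` — per-electrode paired-t maps
* ``coherence_group_tests.csv`` — per-pair between-group ANOVA
* ``ancova.csv`` — group x age ANCOVA per headline feature
* ``anova_band_group_stage.csv`` — factorial ANOVA table
* ``dfa_surrogate_test.json`` — envelope-nonlinearity test summary
* ``clustering_report.json`` — per-preset confusion, accuracy, PPV, test p values
* ``assignments_<preset>.csv`` and ``manifest.json``

Reruns with the same configuration are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import __version__
from .clustering import (
    FEATURE_PRESETS,
    assemble_features,
    centroid_identity_test,
    dispersion_test,
    evaluate_against_selfreport,
    kmeans_cluster,
)
from .features import extract_features, pair_key
from .groupstats import ancova_group_age, factorial_anova, paired_t_map
from .lrtc import DFAConfig, surrogate_nonlinearity_test
from .protocol import FRONTAL_CENTRAL, SCALP_19, STANDARD_BANDS, CohortSpec
from .recordings import Recording, band_filter, broadband_filter, read_recording, stage_segment
from .synth import generate_cohort

log = logging.getLogger("neuromark")

__all__ = ["RunConfig", "run_pipeline"]

#: Electrode pairs whose coherence the study found group-discriminative,
#: plus an untargeted control pair.
TARGET_PAIRS = (("Cz", "Pz"), ("Cz", "Fp2"))
CONTROL_PAIR = ("Cz", "C3")


@dataclass(frozen=True)
class RunConfig:
    mode: str = "synthetic"                      # or "files"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    input_dir: str | None = None                 # files mode: EDFs + events + self_report.csv
    out_dir: str = "neuromark_out"
    psd_bands: tuple[str, ...] = ("alpha", "theta", "whole")
    presets: tuple[str, ...] = tuple(FEATURE_PRESETS)
    distance: str = "euclidean"
    seed: int = 0
    surrogate_test: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "files" and not self.input_dir:
            raise ValueError("files mode requires input_dir")
        unknown = [p for p in self.presets if p not in FEATURE_PRESETS]
        if unknown:
            raise ValueError(f"unknown feature presets: {unknown}")


def _load_files(input_dir: str) -> tuple[list[Recording], pd.DataFrame]:
    d = Path(input_dir)
    recs = []
    for edf in sorted(d.glob("*.edf")):
        events = d / f"{edf.stem}_events.tsv"
        recs.append(read_recording(edf, events if events.exists() else None))
    if not recs:
        raise ValueError(f"no EDF files under {input_dir}")
    sr_path = d / "self_report.csv"
    self_report = pd.read_csv(sr_path) if sr_path.exists() else pd.DataFrame(
        {"subject_id": [r.subject_id for r in recs]})
    return recs, self_report


def _pivot(features: pd.DataFrame, measure: str, band: str, stage: str,
           locations: list[str], subjects: list[str]) -> np.ndarray:
    sub = features[(features.measure == measure) & (features.band == band)
                   & (features.stage == stage)]
    wide = sub.pivot(index="subject_id", columns="location", values="value")
    return wide.loc[subjects, locations].to_numpy()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and return the manifest dictionary."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- data -------------------------------------------------------------
    if config.mode == "synthetic":
        spec = config.cohort.with_seed(config.seed)
        log.info("generating synthetic cohort: %d + %d subjects",
                 spec.n_group_a, spec.n_group_b)
        recordings, self_report = generate_cohort(spec)
        self_report.to_csv(out / "self_report.csv", index=False)
    else:
        recordings, self_report = _load_files(config.input_dir)
    subjects = [r.subject_id for r in recordings]
    groups = (self_report.set_index("subject_id")["group"].reindex(subjects)
              if "group" in self_report.columns else pd.Series(index=subjects, dtype=object))
    have_groups = groups.notna().all() and groups.nunique() == 2
    log.info("cohort loaded: %d subjects (group stats %s)", len(subjects),
             "enabled" if have_groups else "skipped")

    # --- preprocessing + features -----------------------------------------
    t = time.time()
    feats = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # expected degenerate-epoch warnings on 5 s stages
        for rec in recordings:
            filtered = broadband_filter(rec)
            feats.append(extract_features(filtered, psd_bands=config.psd_bands))
    features = pd.concat(feats, ignore_index=True)
    features.to_csv(out / "features.csv", index=False)
    log.info("feature extraction: %.1f s", time.time() - t)

    # --- stage-contrast statistical maps ----------------------------------
    if len(subjects) >= 3:
        for band in config.psd_bands:
            for hi, lo, name in (("S2", "S1", "S2_gt_S1"), ("D2", "D1", "D2_gt_D1")):
                a = _pivot(features, "psd", band, hi, list(SCALP_19), subjects)
                b = _pivot(features, "psd", band, lo, list(SCALP_19), subjects)
                smap = paired_t_map(a, b, list(SCALP_19), contrast=name, band=band)
                smap.to_frame().to_csv(out / f"statmap_{name}_{band}.csv", index=False)
    else:
        warnings.warn("fewer than 3 subjects: stage-contrast maps skipped")

    # --- group-level tests --------------------------------------------------
    if have_groups:
        y = groups.loc[subjects].to_numpy()
        mask_a = y == "A"
        # coherence: between-group one-way ANOVA per targeted pair (+ control)
        rows = []
        for pair in (*TARGET_PAIRS, CONTROL_PAIR):
            loc = pair_key(*pair)
            for stage in ("S1", "D1", "S2", "D2"):
                sub = features[(features.measure == "coherence")
                               & (features.band == "alpha")
                               & (features.stage == stage)
                               & (features.location == loc)]
                v = sub.set_index("subject_id")["value"].loc[subjects].to_numpy()
                f, p = sstats.f_oneway(v[mask_a], v[~mask_a])
                rows.append(dict(pair=loc, stage=stage, F=float(f), p=float(p),
                                 mean_a=float(v[mask_a].mean()),
                                 mean_b=float(v[~mask_a].mean())))
        pd.DataFrame(rows).to_csv(out / "coherence_group_tests.csv", index=False)

        # ANCOVA (group + age + group:age) per headline feature
        age = self_report.set_index("subject_id")["age"].loc[subjects].to_numpy()
        headline = {
            "frontal_alpha_power_stimulation": ("psd", ("S1", "S2"), FRONTAL_CENTRAL),
            "targeted_coherence": ("coherence", ("S1", "D1", "S2", "D2"),
                                   tuple(pair_key(*p) for p in TARGET_PAIRS)),
            "frontal_alpha_dfa_decision": ("dfa", ("D2",), FRONTAL_CENTRAL),
        }
        arows = []
        for name, (measure, stages, locs) in headline.items():
            sub = features[(features.measure == measure) & (features.band == "alpha")
                           & features.stage.isin(stages) & features.location.isin(locs)]
            v = sub.groupby("subject_id")["value"].mean().loc[subjects].to_numpy()
            res = ancova_group_age(v, y, age)
            for term in res.terms:
                arows.append(dict(feature=name, term=term, F=res.f(term),
                                  p=res.p(term), partial_eta_sq=res.partial_eta_sq(term)))
        pd.DataFrame(arows).to_csv(out / "ancova.csv", index=False)

        # factorial ANOVA: band x group x stage on per-subject mean band power
        psd = features[features.measure == "psd"]
        agg = (psd.groupby(["subject_id", "band", "stage"])["value"].mean()
               .reset_index())
        agg["group"] = agg["subject_id"].map(groups)
        table = factorial_anova(agg, "value", ["band", "group", "stage"])
        table.to_csv(out / "anova_band_group_stage.csv")
    else:
        warnings.warn("fewer than two self-report groups: group statistics skipped")

    # --- envelope nonlinearity (surrogate) test ----------------------------
    if config.surrogate_test:
        rec = broadband_filter(recordings[0])
        seg = stage_segment(rec, "S2")
        alpha = STANDARD_BANDS["alpha"]
        sigs = [band_filter(seg.channel(ch), alpha, fs=seg.fs) for ch in SCALP_19]
        res = surrogate_nonlinearity_test(sigs, fs=seg.fs, seed=config.seed)
        with open(out / "dfa_surrogate_test.json", "w") as fh:
            json.dump({"subject_id": rec.subject_id, "stage": "S2", "band": "alpha",
                       "p_value": res.p_value,
                       "alpha_original_mean": float(res.alpha_original.mean()),
                       "alpha_surrogate_mean": float(res.alpha_surrogate_mean.mean())},
                      fh, indent=2, sort_keys=True)

    # --- clustering ---------------------------------------------------------
    report: dict = {}
    for preset in config.presets:
        X, subj, cols = assemble_features(features, FEATURE_PRESETS[preset])
        result = kmeans_cluster(X, k=2, distance=config.distance,
                                seed=np.random.default_rng(config.seed))
        entry = {"n_features": len(cols), "objective": result.objective}
        if have_groups:
            result = evaluate_against_selfreport(result, groups.loc[subj].to_numpy())
            f1, p1 = centroid_identity_test(X, result.assignments,
                                            distance=config.distance,
                                            seed=np.random.default_rng(config.seed))
            f2, p2 = dispersion_test(X, result.assignments, distance=config.distance)
            entry.update(confusion=result.confusion.tolist(),
                         accuracy_pct=result.accuracy, ppv_pct=result.ppv,
                         centroid_test_p=p1, dispersion_test_p=p2)
        report[preset] = entry
        pd.DataFrame({"subject_id": subj, "cluster": result.assignments}).to_csv(
            out / f"assignments_{preset}.csv", index=False)
    with open(out / "clustering_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    # --- manifest -----------------------------------------------------------
    manifest = {
        "neuromark_version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "n_subjects": len(subjects),
        "subjects": subjects,
        "presets": list(config.presets),
        "distance": config.distance,
        "group_stats": bool(have_groups),
    }
    if config.mode == "synthetic":
        manifest["cohort"] = {
            "n_group_a": config.cohort.n_group_a,
            "n_group_b": config.cohort.n_group_b,
            "protocol": dataclasses.asdict(config.cohort.protocol),
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("pipeline done in %.1f s -> %s", time.time() - t0, out)
    return manifest
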