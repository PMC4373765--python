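"""Subject- and cohort-level orchestration.

``run_subject`` drives the full single-subject chain: orient the bundle,
classify fibers against the lesion mask, split into compartments, build
50-node weighted-core profiles for AD/RD/MD/FA per compartment, compute
asymmetry profiles and lesion node extents, and (optionally) write the CSV
outputs. ``run_cohort`` aggregates subject reports into group mean
profiles, node-wise t profiles against a control group, lesion-frequency
and Wallerian-degeneration histograms, topographic correlations and a
subject-means table, with an optional backward-elimination regression of
non-lesional diffusivity on metadata covariates.
"""

from __future__ import annotations

import json
import logging
import os

import numpy as np
import pandas as pd

from . import compartments as comp
from . import topography as topo
from .io import ScalarVolume, StreamlineBundle, write_profile_table
from .metrics import metrics_from_eigen_volumes
from .phantom import eigenvalue_volumes
from .profile import (N_NODES, TractProfile, resample_bundle, tract_profile,
                      valid_node_mask)
from .stats import nodewise_two_sample_t, ols_backward

__all__ = ["run_subject", "run_cohort", "cohort_regression"]

log = logging.getLogger(__name__)

METRICS = ("AD", "RD", "MD", "FA")


def _metric_volumes(ad: ScalarVolume, rd: ScalarVolume,
                    md: ScalarVolume | None,
                    fa: ScalarVolume | None) -> dict:
    """Fill in MD/FA maps from AD/RD via the axially symmetric tensor."""
    if md is None or fa is None:
        derived = metrics_from_eigen_volumes(*eigenvalue_volumes(ad, rd))
        md = md if md is not None else derived["MD"]
        fa = fa if fa is not None else derived["FA"]
    return {"AD": ad, "RD": rd, "MD": md, "FA": fa}


def _profiles_frame(subject_id: str, compartment: str,
                    profiles: dict) -> pd.DataFrame:
    rows = []
    for metric, prof in profiles.items():
        for node in range(1, len(prof.values) + 1):
            rows.append((subject_id, compartment, metric, node,
                         prof.values[node - 1]))
    return pd.DataFrame(rows, columns=["subject", "compartment", "metric",
                                       "node", "value"])


def _compartment_profiles(bundle: StreamlineBundle, volumes: dict,
                          interpolation: str) -> dict:
    resampled = resample_bundle(bundle)
    return {m: tract_profile(resampled, volumes[m], m,
                             interpolation=interpolation)
            for m in METRICS}, resampled


def run_subject(bundle: StreamlineBundle, ad: ScalarVolume, rd: ScalarVolume,
                lesion_mask: ScalarVolume, subject_id: str = "subject",
                md: ScalarVolume | None = None, fa: ScalarVolume | None = None,
                out_dir: str | os.PathLike | None = None,
                interpolation: str = "trilinear") -> dict:
    """Full single-subject compartment analysis; returns the report dict."""
    if bundle.anchor is None:
        raise ValueError(f"{subject_id}: bundle needs an anchor (seed end)")
    volumes = _metric_volumes(ad, rd, md, fa)

    labeling = comp.classify_fibers(bundle, lesion_mask)
    lesional_b, non_lesional_b = comp.split_bundle(bundle, labeling)
    tmask = comp.tract_mask(bundle, lesion_mask)
    inventory = comp.lesion_volumes(lesion_mask, tmask)

    frames = []
    all_profiles, _ = _compartment_profiles(bundle, volumes, interpolation)
    frames.append(_profiles_frame(subject_id, "all", all_profiles))

    extents: list = []
    if labeling.category == comp.CATEGORY_PARTIAL:
        les_profiles, les_resampled = _compartment_profiles(
            lesional_b, volumes, interpolation)
        non_profiles, _ = _compartment_profiles(
            non_lesional_b, volumes, interpolation)
        frames.append(_profiles_frame(subject_id, "lesional", les_profiles))
        frames.append(_profiles_frame(subject_id, "non_lesional", non_profiles))
        deltas = {m: topo.asymmetry_profile(les_profiles[m], non_profiles[m])
                  for m in METRICS}
        drows = []
        for metric, d in deltas.items():
            for node in range(1, N_NODES + 1):
                drows.append((subject_id, "delta", metric, node,
                              d.delta[node - 1]))
        frames.append(pd.DataFrame(
            drows, columns=["subject", "compartment", "metric", "node",
                            "value"]))
        extents = topo.lesion_node_extent(les_resampled, inventory, lesion_mask)
    elif labeling.category == comp.CATEGORY_COMPLETE:
        resampled = resample_bundle(bundle)
        extents = topo.lesion_node_extent(resampled, inventory, lesion_mask)

    profiles = pd.concat(frames, ignore_index=True)
    log.info("%s: %d fibers (%d lesional, %d non-lesional), category=%s",
             subject_id, len(bundle), labeling.n_lesional,
             labeling.n_non_lesional, labeling.category)

    report = {
        "subject": subject_id,
        "category": labeling.category,
        "n_fibers": len(bundle),
        "n_lesional": labeling.n_lesional,
        "n_non_lesional": labeling.n_non_lesional,
        "profiles": profiles,
        "extents": extents,
        "lesion_volume_inside_mm3": inventory.volume_inside_mm3,
        "lesion_volume_outside_mm3": inventory.volume_outside_mm3,
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        write_profile_table(profiles,
                            os.path.join(out_dir, f"{subject_id}_profiles.csv"))
        summary = {k: v for k, v in report.items()
                   if k not in ("profiles", "extents")}
        summary["extents"] = [[e.start, e.end] for e in extents]
        with open(os.path.join(out_dir, f"{subject_id}_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=1)
    return report


def _profile_matrix(reports: list, compartment: str, metric: str) -> np.ndarray:
    """Stack (n_subjects, 50) node values for one compartment x metric."""
    rows = []
    for rep in reports:
        df = rep["profiles"]
        sel = df[(df["compartment"] == compartment) & (df["metric"] == metric)]
        if len(sel):
            rows.append(sel.sort_values("node")["value"].to_numpy())
    return np.array(rows) if rows else np.empty((0, N_NODES))


def _subject_means(reports: list) -> pd.DataFrame:
    """Per-subject metric means over valid nodes, per compartment."""
    valid = valid_node_mask()
    rows = []
    for rep in reports:
        df = rep["profiles"]
        for compartment in df["compartment"].unique():
            row = {"subject": rep["subject"], "category": rep["category"],
                   "compartment": compartment}
            for metric in METRICS:
                sel = df[(df["compartment"] == compartment) &
                         (df["metric"] == metric)].sort_values("node")
                vals = sel["value"].to_numpy()[valid]
                row[metric] = float(np.nanmean(vals))
            rows.append(row)
    return pd.DataFrame(rows)


def run_cohort(reports: list, groups: dict | None = None,
               control: str | None = None, alpha: float = 0.05,
               wd_within_lesion: str = "ramp",
               out_dir: str | os.PathLike | None = None) -> dict:
    """Aggregate subject reports into the cohort-level analysis.

    ``groups`` maps subject id -> group label and ``control`` names the
    reference group for node-wise t profiles (skipped when absent). The
    topographic block (histograms, mean asymmetry profiles, correlations)
    uses every subject with a partial lesion.
    """
    if not reports:
        raise ValueError("no subject reports")
    valid = valid_node_mask()

    all_extents = [e for rep in reports for e in rep["extents"]]
    freq = topo.lesion_frequency_histogram(all_extents)
    wd = topo.wd_cumulative_histogram(all_extents,
                                      within_lesion=wd_within_lesion)

    partial = [r for r in reports if r["category"] == comp.CATEGORY_PARTIAL]
    mean_delta = {}
    correlations = {}
    for metric in ("RD", "AD"):
        mat = _profile_matrix(partial, "delta", metric)
        if len(mat):
            mean = np.full(mat.shape[1], np.nan)
            has_data = ~np.isnan(mat).all(axis=0)
            mean[has_data] = np.nanmean(mat[:, has_data], axis=0)
            mean_delta[metric] = mean
    if "RD" in mean_delta and len(all_extents):
        asym = topo.AsymmetryProfile("RD", mean_delta["RD"], valid)
        correlations["lesion_freq_vs_delta_rd"] = \
            topo.topographic_correlation(freq, asym)
    if "AD" in mean_delta and len(all_extents):
        asym = topo.AsymmetryProfile("AD", mean_delta["AD"], valid)
        correlations["wd_load_vs_delta_ad"] = \
            topo.topographic_correlation(wd, asym)

    node_tests = {}
    if groups is not None and control is not None:
        if control not in set(groups.values()):
            raise ValueError(f"control group '{control}' not in groups")
        by_group: dict = {}
        for rep in reports:
            by_group.setdefault(groups.get(rep["subject"]), []).append(rep)
        ctrl_reports = by_group.pop(control, [])
        for gname, greports in by_group.items():
            if gname is None or len(greports) < 2 or len(ctrl_reports) < 2:
                continue
            node_tests[gname] = {
                metric: nodewise_two_sample_t(
                    _profile_matrix(greports, "all", metric),
                    _profile_matrix(ctrl_reports, "all", metric),
                    valid=valid, alpha=alpha)
                for metric in METRICS}

    means = _subject_means(reports)
    result = {
        "n_subjects": len(reports),
        "subject_means": means,
        "lesion_frequency": freq,
        "wd_load": wd,
        "mean_delta": mean_delta,
        "correlations": correlations,
        "node_tests": node_tests,
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        means.to_csv(os.path.join(out_dir, "subject_means.csv"), index=False)
        hist_rows = []
        for name, h in (("lesion_freq", freq), ("wd_load", wd)):
            for node in range(1, N_NODES + 1):
                hist_rows.append(("cohort", name, "count", node,
                                  h.counts[node - 1]))
        for metric, delta in mean_delta.items():
            for node in range(1, N_NODES + 1):
                hist_rows.append(("cohort", "delta", metric, node,
                                  delta[node - 1]))
        write_profile_table(
            pd.DataFrame(hist_rows, columns=["subject", "compartment",
                                             "metric", "node", "value"]),
            os.path.join(out_dir, "cohort_topography.csv"))
        with open(os.path.join(out_dir, "cohort_correlations.json"), "w") as fh:
            json.dump(correlations, fh, indent=1)
    return result


def cohort_regression(subject_means: pd.DataFrame, metadata: pd.DataFrame,
                      outcome_metric: str = "RD",
                      compartment: str = "non_lesional",
                      p_out: float = 0.05) -> dict:
    """Backward-elimination OLS of a compartment metric mean on covariates.

    ``metadata`` columns: subject, age, sex, duration, on_history,
    t2lv_in, t2lv_out (sex/on_history coded 0/1). Standardized coefficients
    are reported, mirroring common neurology reporting practice.
    """
    sel = subject_means[subject_means["compartment"] == compartment]
    merged = sel.merge(metadata, on="subject", how="inner")
    covars = ["age", "sex", "duration", "on_history", "t2lv_in", "t2lv_out"]
    missing = [c for c in covars if c not in merged.columns]
    if missing:
        raise ValueError(f"metadata missing columns {missing}")
    return ols_backward(merged[outcome_metric].to_numpy(),
                        merged[covars], p_out=p_out)
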