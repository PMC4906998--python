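"""End-to-end orchestration: generate/load data, fit, assess, summarise.

Reproduces the computational designs of the interaction studies on one
dataset: per-drug CRC fits with subject-level pEC50/E_max summaries, Bliss
assessments across the isoeffective effect-level grid, and the EFS
synergism time course with its metrics. All outputs are deterministic given
the configuration seed; every written file is accompanied by a plain-text
run log carrying the configuration hash.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import bliss as _bliss
from . import crc as _crc
from . import io as _io
from . import synthetic as _syn
from . import timecourse as _tc
from .errors import PipelineError

__all__ = ["run_pipeline", "fit_crc_table", "assess_combination_table",
           "analyze_efs_table"]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("fit-crc")
def fit_crc_table(table: pd.DataFrame, *, constrained: bool = True) -> pd.DataFrame:
    """Per-subject 4PL fits of every single-agent CRC in a bath table.

    Returns one row per (drug, subject) with the fitted parameters; curves
    with fewer than five distinct concentrations are skipped (they belong to
    the isoeffective combination design, not to a full CRC).
    """
    norm = _io.normalize_table(table)
    rows = []
    crc_rows = norm[norm["mode"] == "crc"]
    for (drug, subj), grp in crc_rows.groupby(["drug_labels", "subject_id"]):
        conc = grp["concentration_molar"].map(
            lambda v: _io.parse_concentrations(v)[0]
        ).to_numpy(float)
        if np.unique(conc).size < 5:
            continue
        fit = _crc.fit_4pl(
            np.log10(conc),
            grp["response"].to_numpy(float),
            constrained=constrained,
            drug_label=drug,
            subject_id=subj,
        )
        rows.append(fit.to_dict())
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.drop(columns=["standard_errors"])
    return out


def summarize_fits(fits: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of pEC50 and E_max over subjects, per drug."""
    def sem(x):
        return x.std(ddof=1) / np.sqrt(len(x))

    return fits.groupby("drug_label").agg(
        pec50_mean=("pec50", "mean"),
        pec50_sem=("pec50", sem),
        e_max_mean=("e_max", "mean"),
        e_max_sem=("e_max", sem),
        n=("pec50", "size"),
    ).reset_index()


@_stage("bliss")
def assess_combination_table(
    table: pd.DataFrame, *, alpha: float = 0.05, pairing: str = "by_subject"
) -> pd.DataFrame:
    """Bliss assessment at every isoeffective condition of a combination table.

    Combination rows are matched with the single-agent rows measured at the
    same concentrations within the same subjects; one assessment per
    condition (keyed by the combination's concentration set).
    """
    norm = _io.normalize_table(table)
    singles = norm[norm["mode"] == "crc"]
    combos = norm[norm["mode"] == "combination_crc"]
    results = []
    for conc_key, grp in combos.groupby("concentration_molar"):
        labels = grp["drug_labels"].iloc[0].split(";")
        concs = _io.parse_concentrations(conc_key)
        grp = grp.sort_values("subject_id")
        subjects = grp["subject_id"].to_list()
        observed = grp["response"].to_numpy(float)
        reps = {}
        for lab, c in zip(labels, concs):
            m = singles[
                (singles["drug_labels"] == lab)
                & np.isclose(
                    singles["concentration_molar"].map(
                        lambda v: _io.parse_concentrations(v)[0]
                    ).to_numpy(float),
                    c,
                    rtol=1e-9,
                    atol=0.0,  # molar values span decades; no absolute floor
                )
            ].sort_values("subject_id")
            m = m[m["subject_id"].isin(subjects)]
            reps[lab] = m["response"].to_numpy(float)
        expected = _bliss.expected_with_uncertainty(reps, pairing=pairing)
        assessment = _bliss.assess_interaction(
            observed, expected, alpha=alpha,
            condition=float(expected.mean),
        )
        rec = assessment.to_dict()
        rec["concentration_molar"] = conc_key
        rec["drug_labels"] = ";".join(labels)
        results.append(rec)
    out = pd.DataFrame(results)
    return out.sort_values("expected_mean").reset_index(drop=True)


@_stage("timecourse")
def analyze_efs_table(
    table: pd.DataFrame,
    *,
    alpha: float = 0.05,
    intervals=_tc.DEFAULT_INTERVALS,
) -> dict:
    """Synergism curve, metrics and duration from an EFS bath table."""
    norm = _io.normalize_table(table)
    efs = norm[norm["mode"] == "efs"]
    traces = {}
    for label, grp in efs.groupby("drug_labels"):
        wide = grp.pivot_table(
            index="subject_id", columns="time_min", values="response"
        ).sort_index()
        traces[label] = wide
    combo_label = next(lab for lab in traces if ";" in lab)
    single_labels = [lab for lab in traces if ";" not in lab]
    times = traces[combo_label].columns.to_numpy(float)
    observed = traces[combo_label].to_numpy(float)
    singles = {lab: traces[lab].to_numpy(float) for lab in single_labels}

    delta_curve = _tc.synergism_curve(
        observed, singles, times, alpha=alpha, test="welch"
    )
    trend = _tc.fit_trend(times, observed.mean(axis=0))
    metrics = _tc.compute_metrics(trend, times, observed.mean(axis=0))
    usable = [iv for iv in intervals if iv[1] * 60.0 <= times.max() + 1e-9]
    metrics.auc = _tc.auc_intervals(delta_curve, intervals=usable)
    metrics.duration_of_synergism = _tc.duration_of_synergism(
        delta_curve, alpha=alpha
    )
    # summaries of the synergism curve itself (max delta and when it occurs)
    delta_trend = _tc.fit_trend(times, delta_curve.delta_percent)
    dense = np.linspace(times.min(), times.max(), 4 * times.size)
    dvals = delta_trend.predict(dense)
    return {
        "delta_curve": delta_curve,
        "trend_degree": trend.degree,
        "metrics": metrics,
        "delta_max_percent": float(dvals.max()),
        "delta_max_time_min": float(dense[int(np.argmax(dvals))]),
    }


def run_pipeline(config: _io.RunConfig, table: pd.DataFrame | None = None) -> dict:
    """Run the full analysis; optionally write a report bundle to disk.

    With no ``table``, synthetic data are generated from
    ``config.synthetic`` (CRCs and combination design for the configured
    drugs, plus the EFS time course). Returns a dict with fits, summaries,
    Bliss assessments, time-course metrics and the delta curve; when
    ``config.out_dir`` is set, CSV/JSON outputs and a run log (with the
    config hash) are written there. Deterministic given the seed.
    """
    cfg = config.synthetic
    bundle: dict = {"config_hash": config.config_hash()}

    if table is None:
        try:
            drugs = cfg.drugs
            crc_tables = [_syn.simulate_crc(t, cfg) for t in drugs[:2]]
            combo_table, unattainable = _syn.simulate_combination_crc(
                drugs[0], drugs[1], *drugs[2:3] or [None],
                cfg=cfg, levels=config.ec_levels,
            )
            efs_table = _syn.simulate_efs_timecourse(drugs[:2], cfg=cfg)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        crc_table = pd.concat(crc_tables + [combo_table], ignore_index=True)
        bundle["unattainable_levels"] = unattainable
    else:
        crc_table = table[table["mode"].isin(["crc", "combination_crc"])]
        efs_table = table[table["mode"].isin(["efs", "time_control"])]

    fits = fit_crc_table(crc_table)
    bundle["fits"] = fits
    bundle["fit_summary"] = summarize_fits(fits) if not fits.empty else fits

    if (crc_table["mode"] == "combination_crc").any():
        bundle["bliss"] = assess_combination_table(crc_table, alpha=config.alpha)

    if not efs_table.empty and (efs_table["mode"] == "efs").any():
        efs = analyze_efs_table(
            efs_table, alpha=config.alpha, intervals=config.intervals
        )
        bundle["timecourse_metrics"] = efs["metrics"]
        bundle["delta_curve"] = efs["delta_curve"]
        bundle["trend_degree"] = efs["trend_degree"]
        bundle["delta_max_percent"] = efs["delta_max_percent"]
        bundle["delta_max_time_min"] = efs["delta_max_time_min"]

    if config.out_dir:
        _write_bundle(config, bundle)
    return bundle


def _write_bundle(config: _io.RunConfig, bundle: dict) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    if "fits" in bundle and not bundle["fits"].empty:
        bundle["fits"].to_csv(out / "fits.csv", index=False)
        bundle["fit_summary"].to_csv(out / "fit_summary.csv", index=False)
    if "bliss" in bundle:
        bundle["bliss"].to_csv(out / "bliss_assessments.csv", index=False)
    if "delta_curve" in bundle:
        bundle["delta_curve"].to_frame().to_csv(out / "delta_curve.csv", index=False)
    if "timecourse_metrics" in bundle:
        (out / "timecourse_metrics.json").write_text(
            json.dumps(bundle["timecourse_metrics"].to_dict(), indent=2)
        )
    lines = [
        f"config_hash: {bundle['config_hash']}",
        f"seed: {config.seed}",
        f"alpha: {config.alpha}",
        f"stages: {', '.join(k for k in bundle if k != 'config_hash')}",
    ]
    (out / "run_log.txt").write_text("\n".join(lines) + "\n")
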