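"""End-to-end orchestration over a subject manifest.

``analyze_cohort`` runs the full chain in memory: band decomposition,
per-subject GFP-peak clustering, two-level group templates, re-ordering
against the reference cell (young-adult broadband by default),
backfitting, temporal parameters, and the sensor-type GEV contrast.
``run_pipeline`` wraps it with file IO for the command line.

Subjects whose processing fails at any stage are skipped and reported;
a run aborts if more than ``config.max_skip_fraction`` of subjects drop.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as osio
from .bands import get_band
from .config import GROUP_ORDER, RunConfig
from .containers import SensorRecording
from .microstate import MicrostateModel, fit_microstates
from .pipeline import (
    GroupTemplates,
    apply_reorder,
    backfit,
    gev_by_sensor_type,
    microstate_parameters,
    reorder_to_template,
    smooth_labels,
    two_level_global_maps,
)
from .preprocess import bandpass, resample_250
from .stats import (
    age_correlation,
    anova_with_posthoc,
    bonferroni,
    paired_t,
)

logger = logging.getLogger("oscistate")

__all__ = ["CohortResults", "analyze_cohort", "cohort_stats_table", "run_pipeline"]


@dataclass
class CohortResults:
    """Bundle emitted by a cohort run."""

    templates: dict[tuple[str, str], GroupTemplates]
    subject_models: dict[tuple[str, str], MicrostateModel]
    params: pd.DataFrame
    gev_by_type: pd.DataFrame
    labels: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)


def _sub_seed(base: int, *parts: str) -> int:
    """Stable per-(subject, band) seed below 2**31."""
    tag = zlib.crc32("|".join(parts).encode())
    return int((base * 1_000_003 + tag) % (2**31))


def _check_channels(recordings: dict[str, SensorRecording]) -> None:
    ref_names = None
    for sid, rec in recordings.items():
        names = rec.channels["name"].tolist()
        if ref_names is None:
            ref_names = names
        elif names != ref_names:
            raise ValueError(
                f"subject {sid!r} channel set differs from the first subject; "
                "recordings must share an identical, ordered channel set"
            )


def analyze_cohort(
    recordings: dict[str, SensorRecording],
    manifest: pd.DataFrame,
    config: RunConfig | None = None,
) -> CohortResults:
    """Run the full microstate pipeline over in-memory recordings.

    ``recordings`` maps subject id to a recording; a recording whose band
    tag already equals the analysis band is used as-is, otherwise it is
    band-filtered on the fly.  Group structure comes exclusively from the
    manifest.
    """
    config = config or RunConfig()
    manifest = manifest.set_index("subject", drop=False)
    missing = [s for s in manifest["subject"] if s not in recordings]
    if missing:
        raise ValueError(f"recordings missing for subjects: {missing}")
    _check_channels(recordings)

    subject_models: dict[tuple[str, str], MicrostateModel] = {}
    templates: dict[tuple[str, str], GroupTemplates] = {}
    labels_out: dict[tuple[str, str], np.ndarray] = {}
    skipped: list[tuple[str, str, str]] = []
    band_data: dict[tuple[str, str], SensorRecording] = {}

    for band_name in config.bands:
        band = get_band(band_name)
        for sid in manifest["subject"]:
            rec = recordings[sid]
            try:
                rec_b = rec if rec.band == band_name else bandpass(
                    rec, band, order=config.filter_order
                )
                band_data[(sid, band_name)] = rec_b
                subject_models[(sid, band_name)] = fit_microstates(
                    rec_b,
                    K=config.K,
                    n_restarts=config.n_restarts,
                    seed=_sub_seed(config.seed, sid, band_name, "subject"),
                )
            except Exception as exc:  # noqa: BLE001 - skip-and-report contract
                logger.warning("subject %s band %s: clustering failed: %s", sid, band_name, exc)
                skipped.append((sid, band_name, str(exc)))

    if len(skipped) > config.max_skip_fraction * len(manifest) * len(config.bands):
        raise RuntimeError(
            f"{len(skipped)} subject x band cells failed "
            f"(> {config.max_skip_fraction:.0%} allowed); aborting"
        )

    groups_present = [g for g in GROUP_ORDER if g in set(manifest["group"])]
    groups_present += [g for g in manifest["group"].unique() if g not in groups_present]

    for band_name in config.bands:
        for group in groups_present:
            members = manifest.loc[manifest["group"] == group, "subject"]
            models = [
                subject_models[(s, band_name)]
                for s in members
                if (s, band_name) in subject_models
            ]
            if not models:
                continue
            level2 = two_level_global_maps(
                models,
                K=config.K,
                n_restarts=config.n_restarts,
                seed=_sub_seed(config.seed, group, band_name, "group"),
            )
            templates[(group, band_name)] = GroupTemplates(
                group=group,
                band=band_name,
                maps=level2.maps,
                reorder_perm=np.arange(config.K),
                reorder_corrs=np.ones(config.K),
                gev=level2.gev,
            )

    ref_key = (config.reference_group, config.reference_band)
    if ref_key not in templates:
        ref_key = next(iter(templates))
        logger.warning("reference cell %s unavailable; using %s",
                       (config.reference_group, config.reference_band), ref_key)
    reference = templates[ref_key].maps.copy()
    for key, tpl in templates.items():
        perm, corrs, signs = reorder_to_template(tpl.maps, reference)
        tpl.maps = apply_reorder(tpl.maps, perm, signs)
        tpl.reorder_perm = perm
        tpl.reorder_corrs = corrs

    param_rows = []
    gev_rows = []
    failed_fits = set((s, b) for s, b, _ in skipped)
    for band_name in config.bands:
        for sid in manifest["subject"]:
            if (sid, band_name) in failed_fits:
                continue
            group = manifest.at[sid, "group"]
            tpl = templates.get((group, band_name))
            if tpl is None:
                continue
            rec_b = band_data[(sid, band_name)]
            seq = backfit(tpl.maps, rec_b, mode=config.backfit_mode, subject=sid)
            if config.smooth_min_dur_s > 0:
                seq = smooth_labels(seq, config.smooth_min_dur_s)
            labels_out[(sid, band_name)] = seq.labels
            pars = microstate_parameters(seq, K=config.K)
            pars.insert(0, "band", band_name)
            pars.insert(0, "group", group)
            pars.insert(0, "subject", sid)
            param_rows.append(pars)

            kinds = set(rec_b.channels["kind"])
            if {"MAG", "COMB"} <= kinds:
                gev_rows.append(
                    {
                        "subject": sid,
                        "band": band_name,
                        "gev_com": gev_by_sensor_type(
                            rec_b, tpl.maps, "COMB", mode=config.backfit_mode
                        ),
                        "gev_mag": gev_by_sensor_type(
                            rec_b, tpl.maps, "MAG", mode=config.backfit_mode
                        ),
                    }
                )

    params = (
        pd.concat(param_rows, ignore_index=True)
        if param_rows
        else pd.DataFrame(
            columns=["subject", "group", "band", "state", "duration_s", "occurrence_hz", "coverage"]
        )
    )
    gev_by_type = pd.DataFrame(gev_rows, columns=["subject", "band", "gev_com", "gev_mag"])
    return CohortResults(
        templates=templates,
        subject_models=subject_models,
        params=params,
        gev_by_type=gev_by_type,
        labels=labels_out,
        skipped=skipped,
    )


PARAMETERS = ("duration_s", "occurrence_hz", "coverage")


def cohort_stats_table(
    params: pd.DataFrame,
    manifest: pd.DataFrame,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-cell ANOVA + gated post hoc + age correlation grid.

    One row per (band, state, parameter): group means and SEs, the F test
    with its Bonferroni-adjusted p, the homogeneity gate's choice, and
    the Pearson age correlation (raw and Bonferroni-adjusted).
    """
    config = config or RunConfig()
    ages = manifest.set_index("subject")["age"]
    groups_present = [g for g in GROUP_ORDER if g in set(manifest["group"])]
    rows = []
    for band in sorted(params["band"].unique()):
        for state in sorted(params["state"].unique()):
            cell = params[(params["band"] == band) & (params["state"] == state)]
            for parameter in PARAMETERS:
                by_group = [
                    cell.loc[cell["group"] == g, parameter].to_numpy()
                    for g in groups_present
                ]
                by_group = [g for g in by_group if g.size >= 2]
                row: dict = {"band": band, "state": state, "parameter": parameter}
                for g in groups_present:
                    vals = cell.loc[cell["group"] == g, parameter]
                    row[f"mean_{g}"] = vals.mean()
                    row[f"se_{g}"] = vals.sem(ddof=1) if len(vals) > 1 else np.nan
                if len(by_group) >= 2:
                    res = anova_with_posthoc(by_group, config.alpha_homog)
                    row.update(
                        F=res.F,
                        df1=res.df1,
                        df2=res.df2,
                        p=res.p,
                        p_bonferroni=float(bonferroni([res.p], config.bonferroni_m)[0]),
                        homogeneity_p=res.homogeneity_p,
                        posthoc=res.posthoc_method,
                        n_posthoc_significant=sum(
                            c.p_adjusted < config.alpha for c in res.pairwise
                        ),
                    )
                vals = cell.groupby("subject")[parameter].mean()
                age_vec = ages.reindex(vals.index)
                if (
                    len(vals) >= 3
                    and np.ptp(vals.to_numpy()) > 0
                    and np.ptp(age_vec.to_numpy()) > 0
                ):
                    corr = age_correlation(age_vec.to_numpy(), vals.to_numpy())
                    row.update(
                        r_age=corr.r,
                        r_squared=corr.r_squared,
                        p_corr=corr.p,
                        p_corr_bonferroni=float(
                            bonferroni([corr.p], config.bonferroni_m)[0]
                        ),
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def gev_contrast_table(gev_by_type: pd.DataFrame) -> pd.DataFrame:
    """Paired t of COM vs MAG GEV per band (the sensor-type contrast)."""
    rows = []
    for band, sub in gev_by_type.groupby("band"):
        t, df, p = paired_t(sub["gev_com"], sub["gev_mag"])
        rows.append(
            {
                "band": band,
                "mean_gev_com": sub["gev_com"].mean(),
                "mean_gev_mag": sub["gev_mag"].mean(),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def _load_recording(path: Path) -> SensorRecording:
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        return osio.read_recording_h5(path)
    if suffix == ".fif":
        return osio.read_fif(path)
    if suffix == ".csv":
        sidecar = path.with_name(path.stem + "_channels.csv")
        return osio.read_recording_csv(path, sidecar)
    raise ValueError(f"unrecognized recording format: {path}")


def run_pipeline(config: RunConfig, manifest: pd.DataFrame) -> CohortResults:
    """File-based entry point: load recordings named in the manifest,
    resample to 250 Hz if needed, run the cohort analysis, and write the
    results bundle under ``config.output_dir``."""
    recordings = {}
    for _, row in manifest.iterrows():
        rec = _load_recording(Path(config.input_dir) / row["path"])
        if rec.fs > 250:
            rec = resample_250(rec)
        recordings[row["subject"]] = rec

    results = analyze_cohort(recordings, manifest, config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (group, band), tpl in results.templates.items():
        names = next(iter(recordings.values())).channels["name"]
        osio.write_templates_csv(tpl.maps, names, out / f"templates_{group}_{band}.csv")
    osio.write_params_csv(results.params, out / "microstate_parameters.csv")
    results.gev_by_type.to_csv(out / "gev_by_sensor_type.csv", index=False)
    if len(results.gev_by_type):
        gev_contrast_table(results.gev_by_type).to_csv(
            out / "gev_contrast.csv", index=False
        )
    if len(results.params):
        cohort_stats_table(results.params, manifest, config).to_csv(
            out / "cohort_stats.csv", index=False
        )
    return results
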