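"""End-to-end orchestration: simulate → ERP → inverse methods → statistics.

A run consumes a :class:`~mmnloc.config.RunConfig` and produces, per
subject, matched-trial ERPs and the mismatch wave; per inverse method,
deviant/standard ratio maps (LCMV on the full grid, eLORETA on the
grey-matter grid) or fixed-dipole mean powers; and per method a group
statistics table plus a cross-method concordance table giving the sign of
the patient-vs-control difference per region.  Every stage is seeded from
the single master seed and a rerun with the same config hash and seed
reproduces the output bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .forward import (
    build_source_grid,
    compute_leadfield,
    default_head_model,
    load_region_table,
    make_standard_montage,
    normalize_leadfield,
)
from .synth import CohortSpec, OddballParadigm, default_components, iter_cohort
from .erp import average_erp, compute_mmn, gfp_peak_window, match_trials
from .lcmv import LCMVBeamformer
from .eloreta import Eloreta
from .dipole import DIPOLE_SEEDS_MM, dipole_group_table, fit_fixed_dipoles
from .stats import assemble_stats, bonferroni_threshold, spearman_partial

__all__ = ["PipelineResult", "run_pipeline", "StageError"]

log = logging.getLogger("mmnloc")

ROI_DECREASE = ("IFG-L", "IFG-R", "STG-L")
ROI_INCREASE = ("PPC-L", "M1-L", "DLPFC-L")


class StageError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"[{stage}] {exc}")
        self.stage = stage


@dataclass
class PipelineResult:
    """In-memory result bundle of one pipeline run."""

    config: RunConfig
    config_hash: str
    manifest: pd.DataFrame
    stats: dict  # method -> GroupStatsResults
    dipole_table: pd.DataFrame | None
    region_ratio: dict  # method -> DataFrame (subjects × regions, dB)
    concordance: pd.DataFrame
    cwit: pd.DataFrame | None
    summaries: dict = field(default_factory=dict)

    def sign_recovery(self) -> dict:
        """Direction of the recovered group differences in the key regions.

        Returns booleans: reduced patient dipole power in IFG-L/IFG-R/STG-L
        and increased patient LCMV region power in PPC-L/M1-L/DLPFC-L.
        """
        out = {}
        if self.dipole_table is not None:
            med = self.dipole_table.pivot_table(
                index="dipole", columns="group", values="power", aggfunc="median"
            )
            for r in ROI_DECREASE:
                out[f"dipole_down_{r}"] = bool(
                    med.loc[r, "patient"] < med.loc[r, "control"]
                )
        if "lcmv" in self.region_ratio:
            rr = self.region_ratio["lcmv"]
            for r in ROI_INCREASE:
                med = rr.groupby(self.manifest["group"].values)[r].median()
                out[f"lcmv_up_{r}"] = bool(med["patient"] > med["control"])
        return out


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*a, **kw)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
            log.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


@_stage("forward")
def _build_forward(cfg: RunConfig):
    head = default_head_model()
    montage = make_standard_montage(cfg.forward.n_sensors, head)
    grid_full = build_source_grid(head, cfg.forward.spacing_mm, exclude_white=False)
    grid_grey = build_source_grid(head, cfg.forward.spacing_mm, exclude_white=True)
    L_full = compute_leadfield(head, montage, grid_full, cfg.forward.n_terms)
    L_grey = compute_leadfield(head, montage, grid_grey, cfg.forward.n_terms)
    L_lcmv = normalize_leadfield(L_full) if cfg.forward.normalise else L_full
    return head, montage, grid_full, grid_grey, L_full, L_grey, L_lcmv


def _region_means(grid, values, defined, regions):
    out = {}
    for r in regions:
        idx = grid.region_indices(r)
        idx = idx[defined[idx]] if idx.size else idx
        out[r] = float(np.nanmean(values[idx])) if idx.size else np.nan
    return out


def run_pipeline(config: RunConfig, out_dir=None) -> PipelineResult:
    """Run the full simulate → localise → statistics pipeline.

    With ``out_dir`` the bundle (stats and concordance TSVs, manifest, run
    summary JSON, optionally per-subject ERP exports) is written to disk.
    """
    cfg = config
    chash = cfg.hash()
    log.info("pipeline run: seed=%d config=%s methods=%s", cfg.seed, chash, cfg.methods)
    head, montage, grid_full, grid_grey, L_full, L_grey, L_lcmv = _build_forward(cfg)
    region_table, _ = load_region_table()
    regions = list(region_table)

    eloreta_res = None
    if "eloreta" in cfg.methods:
        try:
            eloreta_res = Eloreta(
                L_grey,
                grid_grey,
                snr=cfg.eloreta.snr,
                tol=cfg.eloreta.tol,
                max_iter=cfg.eloreta.max_iter,
                window=tuple(cfg.eloreta.window),
            ).fit()
        except Exception as exc:
            raise StageError("eloreta-weights", exc) from exc

    L4 = None
    if "dipole" in cfg.methods:
        pos = np.asarray(list(DIPOLE_SEEDS_MM.values()))
        L4 = compute_leadfield(head, montage, pos, cfg.forward.n_terms).gain

    spec = CohortSpec(
        n_controls=cfg.cohort.n_controls,
        n_patients=cfg.cohort.n_patients,
        gain_multipliers={
            "control": dict(cfg.cohort.control_multipliers),
            "patient": dict(cfg.cohort.patient_multipliers),
        },
        gain_jitter_sd=cfg.cohort.gain_jitter_sd,
        noise_sd=cfg.cohort.noise_sd,
        seed=cfg.seed,
    )
    paradigm = OddballParadigm(
        n_sessions=cfg.paradigm.n_sessions,
        trials_per_session=cfg.paradigm.trials_per_session,
        deviant_fraction=cfg.paradigm.deviant_fraction,
        min_standards_between_deviants=cfg.paradigm.min_standards_between_deviants,
    )
    n_sub = spec.n_controls + spec.n_patients
    match_seeds = [
        int(s.generate_state(1)[0] & 0x7FFFFFFF)
        for s in np.random.SeedSequence([cfg.seed, 11]).spawn(n_sub)
    ]

    rows, erp_exports = [], []
    lcmv_maps, eloreta_maps, dipole_fits = [], [], []
    lcmv_region_rows, eloreta_region_rows = [], []
    t0 = time.perf_counter()
    try:
        for i, rec in enumerate(
            iter_cohort(spec, L_full, grid_full, default_components(), paradigm)
        ):
            matched = match_trials(rec.epochs, seed=match_seeds[i])
            erp = average_erp(matched)
            mmn = compute_mmn(erp)
            if "lcmv" in cfg.methods:
                res = LCMVBeamformer(
                    matched,
                    L_lcmv,
                    grid_full,
                    window=tuple(cfg.lcmv.window),
                    reg_fraction=cfg.lcmv.reg_fraction,
                    cov_mode=cfg.lcmv.cov_mode,
                ).fit()
                lcmv_maps.append(res.ratio.ratio_db)
                lcmv_region_rows.append(
                    _region_means(grid_full, res.ratio.ratio_db, res.ratio.defined, regions)
                )
            if eloreta_res is not None:
                rmap = eloreta_res.ratio_map(erp)
                eloreta_maps.append(rmap.ratio_db)
                eloreta_region_rows.append(
                    _region_means(grid_grey, rmap.ratio_db, rmap.defined, regions)
                )
            if L4 is not None:
                win = gfp_peak_window(
                    mmn,
                    search=tuple(cfg.dipole.search_window),
                    half_width=cfg.dipole.half_width_ms,
                )
                dipole_fits.append(
                    fit_fixed_dipoles(mmn, win, leadfield_gain=L4)
                )
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    **rec.covariates,
                }
            )
            if cfg.save_subjects:
                erp_exports.append((rec.subject_id, rec.group, erp, mmn))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("cohort", exc) from exc
    log.info("stage cohort     done in %.2fs (%d subjects)", time.perf_counter() - t0, n_sub)

    manifest = pd.DataFrame(rows)
    groups = manifest["group"].to_numpy()

    stats, region_ratio, summaries = {}, {}, {}
    try:
        if "lcmv" in cfg.methods:
            meta = pd.DataFrame(
                {
                    "x_mm": grid_full.points[:, 0],
                    "y_mm": grid_full.points[:, 1],
                    "z_mm": grid_full.points[:, 2],
                    "region": grid_full.region,
                }
            )
            stats["lcmv"] = assemble_stats(
                np.vstack(lcmv_maps),
                groups,
                unit_meta=meta,
                q=cfg.stats.q,
                group_order=tuple(cfg.stats.orientation),
            )
            region_ratio["lcmv"] = pd.DataFrame(lcmv_region_rows)
        if eloreta_res is not None:
            meta = pd.DataFrame(
                {
                    "x_mm": grid_grey.points[:, 0],
                    "y_mm": grid_grey.points[:, 1],
                    "z_mm": grid_grey.points[:, 2],
                    "region": grid_grey.region,
                }
            )
            stats["eloreta"] = assemble_stats(
                np.vstack(eloreta_maps),
                groups,
                unit_meta=meta,
                q=cfg.stats.q,
                group_order=tuple(cfg.stats.orientation),
            )
            region_ratio["eloreta"] = pd.DataFrame(eloreta_region_rows)
        dipole_table = None
        if L4 is not None:
            dipole_table = dipole_group_table(
                dipole_fits, list(groups), list(manifest["subject_id"])
            )
            wide = dipole_table.pivot(
                index="subject_id", columns="dipole", values="power"
            ).loc[manifest["subject_id"]]
            stats["dipole"] = assemble_stats(
                wide,
                groups,
                q=cfg.stats.q,
                group_order=tuple(cfg.stats.orientation),
                use_ebi=False,
                n_boot=cfg.stats.n_boot,
                seed=cfg.seed,
            )
            summaries["bonferroni_threshold"] = bonferroni_threshold(
                cfg.stats.alpha, cfg.stats.bonferroni_m
            )
    except StageError:
        raise
    except Exception as exc:
        raise StageError("stats", exc) from exc

    concordance = _concordance(cfg, stats, region_ratio, dipole_table, manifest)
    cwit = _cwit_correlations(region_ratio, manifest) if "lcmv" in cfg.methods else None

    result = PipelineResult(
        config=cfg,
        config_hash=chash,
        manifest=manifest,
        stats=stats,
        dipole_table=dipole_table,
        region_ratio=region_ratio,
        concordance=concordance,
        cwit=cwit,
        summaries=summaries,
    )
    if out_dir is not None:
        _write_bundle(result, out_dir, erp_exports, montage)
    return result


def _concordance(cfg, stats, region_ratio, dipole_table, manifest) -> pd.DataFrame:
    """Sign of the patient-vs-control difference per region per method."""
    groups = manifest["group"].to_numpy()
    rows = []
    thr = bonferroni_threshold(cfg.stats.alpha, cfg.stats.bonferroni_m)
    if dipole_table is not None:
        med = dipole_table.pivot_table(
            index="dipole", columns="group", values="power", aggfunc="median"
        )
        ptab = stats["dipole"].table.set_index("unit_id")
        for r in med.index:
            diff = med.loc[r, "patient"] - med.loc[r, "control"]
            rows.append(
                {
                    "method": "dipole",
                    "region": r,
                    "direction": "up" if diff > 0 else "down",
                    "median_diff": diff,
                    "significant": bool(ptab.loc[r, "p"] < thr),
                }
            )
    for method in ("lcmv", "eloreta"):
        if method not in region_ratio:
            continue
        rr = region_ratio[method]
        flagged = (
            stats[method]
            .table.loc[lambda t: t["fdr_flag"], "region"]
            .value_counts()
            if "region" in stats[method].table
            else pd.Series(dtype=int)
        )
        for r in rr.columns:
            med = rr.groupby(groups)[r].median()
            diff = float(med.get("patient", np.nan) - med.get("control", np.nan))
            rows.append(
                {
                    "method": method,
                    "region": r,
                    "direction": "up" if diff > 0 else "down",
                    "median_diff": diff,
                    "significant": bool(flagged.get(r, 0) > 0),
                }
            )
    return pd.DataFrame(rows)


def _cwit_correlations(region_ratio, manifest) -> pd.DataFrame | None:
    """Partial Spearman of patient region power vs inhibition-switching time,
    controlling age and speech score."""
    pat = manifest["group"].to_numpy() == "patient"
    cw = manifest.loc[pat, "cwit_inhib_switch_s"].to_numpy(float)
    ok = np.isfinite(cw)
    if ok.sum() < 6:
        return None
    rows = []
    rr = region_ratio["lcmv"].loc[pat].reset_index(drop=True)
    cov = manifest.loc[pat, ["age", "speech_score"]].to_numpy(float)
    for r in ("PPC-L", "M1-L", "DLPFC-L"):
        x = rr[r].to_numpy(float)
        sel = ok & np.isfinite(x)
        try:
            res = spearman_partial(x[sel], cw[sel], cov[sel])
        except ValueError:
            continue
        rows.append({"region": r, "rho": res.rho, "p": res.p, "n": res.n})
    return pd.DataFrame(rows) if rows else None


def _write_bundle(result: PipelineResult, out_dir, erp_exports, montage) -> None:
    from .io import erp_to_tsv

    os.makedirs(out_dir, exist_ok=True)
    tag = f"{result.config_hash}_seed{result.config.seed}"
    result.manifest.to_csv(
        os.path.join(out_dir, f"manifest_{tag}.tsv"),
        sep="\t",
        index=False,
        float_format="%.6g",
    )
    for method, res in result.stats.items():
        res.to_tsv(os.path.join(out_dir, f"stats_{method}_{tag}.tsv"))
    if result.dipole_table is not None:
        result.dipole_table.to_csv(
            os.path.join(out_dir, f"dipole_powers_{tag}.tsv"),
            sep="\t",
            index=False,
            float_format="%.6g",
        )
    result.concordance.to_csv(
        os.path.join(out_dir, f"concordance_{tag}.tsv"),
        sep="\t",
        index=False,
        float_format="%.6g",
    )
    if result.cwit is not None:
        result.cwit.to_csv(
            os.path.join(out_dir, f"cwit_correlations_{tag}.tsv"),
            sep="\t",
            index=False,
            float_format="%.6g",
        )
    for sid, group, erp, mmn in erp_exports:
        erp_to_tsv(
            os.path.join(out_dir, f"mmn_{sid}_{tag}.tsv"),
            mmn.waveform,
            mmn.times,
            montage.labels,
        )
    summary = {
        "package_version": __version__,
        "config_hash": result.config_hash,
        "seed": result.config.seed,
        "config": result.config.to_dict(),
        "n_subjects": int(len(result.manifest)),
        "fdr_discoveries": {
            m: int(res.n_discoveries) for m, res in result.stats.items()
        },
        **result.summaries,
    }
    with open(os.path.join(out_dir, f"summary_{tag}.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
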