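"""End-to-end simulate-then-analyze pipeline orchestration."""

from __future__ import annotations

import logging
import traceback
from pathlib import Path

import numpy as np

from . import counts as counts_mod
from . import scoring, spatial, spiketrain, synthetic, vep
from .config import RunConfig
from .io import write_results

log = logging.getLogger("fosmap")

STAGES = ("spikes", "spatial", "counts", "vep", "gad")


def _stage_spikes(config: RunConfig, rng_seed: int) -> dict:
    protocol = spiketrain.StimulusProtocol(
        pulse_onset=config.pulse_onset_s,
        pulse_duration=config.pulse_duration_s,
        inter_pulse_interval=config.inter_pulse_interval_s,
        n_sweeps=config.n_sweeps,
    )
    cells = synthetic.make_spike_trains(protocol=protocol, seed=rng_seed)
    per_cell = []
    for c in cells:
        acg = spiketrain.autocorrelogram(
            c.ap4_spont, config.lag_window_s, config.acg_bin_s
        )
        ps = spiketrain.power_spectrum(acg)
        pr = spiketrain.periodicity_index(
            ps, config.peak_threshold, config.index_threshold
        )
        mode = spiketrain.classify_firing_mode(acg, ps, pr)
        d_ctrl = spiketrain.discrimination_index(c.control_stim, protocol)
        d_4ap = spiketrain.discrimination_index(c.ap4_stim, protocol)
        per_cell.append(
            {
                "cell_id": c.cell_id,
                "rat_id": c.rat_id,
                "classification": mode.classification,
                "predominant_frequency_hz": mode.predominant_frequency,
                "periodicity_index": mode.periodicity_index,
                "D_control": d_ctrl.discrimination_index,
                "D_4ap": d_4ap.discrimination_index,
                "Hs_control": spiketrain.isi_standardized_entropy(
                    c.control_stim, protocol
                ),
                "Hs_4ap": spiketrain.isi_standardized_entropy(c.ap4_stim, protocol),
            }
        )
    trials = spiketrain.discrimination_trials(
        [c.control_stim for c in cells] + [c.ap4_stim for c in cells], protocol
    )
    glmm = spiketrain.fit_discrimination_glmm(trials)
    d_ctrl = [abs(r["D_control"]) for r in per_cell if r["D_control"] is not None]
    d_4ap = [abs(r["D_4ap"]) for r in per_cell if r["D_4ap"] is not None]
    return {
        "cells": per_cell,
        "mean_abs_D_control": float(np.mean(d_ctrl)),
        "mean_abs_D_4ap": float(np.mean(d_4ap)),
        "glmm_condition_coef": None if glmm.separation else glmm.coef[1],
        "glmm_condition_p": glmm.p_condition,
        "units": {"frequency": "Hz", "D": "dimensionless", "Hs": "dimensionless"},
    }


def _stage_spatial(config: RunConfig, rng_seed: int) -> dict:
    rng = np.random.default_rng(rng_seed)
    sections = []
    for i in range(3):
        params = synthetic.SectionParams(
            section_id=f"S{i + 1}",
            lateral_bias_scale=180.0,
            outer_radius=450.0,
            inner_radius=550.0,
            inner_offset=750.0,
        )
        sections.append(synthetic.make_section(params, seed=int(rng.integers(2**31))))
    per_section = []
    pvals = []
    for s in sections:
        ent = spatial.mc_entropy_test(
            s, N_sim=config.n_sim_entropy, seed=int(rng.integers(2**31))
        )
        med = spatial.median_lateralization_test(
            s, N_sim=config.n_sim_median, seed=int(rng.integers(2**31))
        )
        part = spatial.stripe_partition(s, marker="neun")
        g = spatial.gtest_uniform(part)
        pvals.append(med.p_value)
        per_section.append(
            {
                "section_id": s.section_id,
                "H_obs_nats": ent.H_obs,
                "entropy_p": ent.p_value,
                "entropy_p_label": ent.p_label,
                "median_lateral_um": med.median_obs,
                "median_p": med.p_value,
                "neun_G": g.G,
                "neun_G_p": g.p_value,
                "n_stripes": part.k,
            }
        )
    adjusted = spatial.holm_adjust(pvals)
    for rec, adj in zip(per_section, adjusted):
        rec["median_p_holm"] = float(adj)
    return {"sections": per_section, "units": {"H_obs": "nats", "median": "um"}}


def _stage_counts(config: RunConfig, rng_seed: int) -> dict:
    records = synthetic.make_count_records(seed=rng_seed)
    res = counts_mod.bootstrap_lrt(records, B=config.bootstrap_B, seed=rng_seed + 1)
    return {
        "alpha": res.full.alpha.tolist(),
        "sigma_rat": res.full.sigma_rat,
        "lrt": res.lrt,
        "bootstrap_p": res.p_value,
        "B": res.B,
        "units": {"alpha": "log cells per section vs mm^2", "lrt": "deviance"},
    }


def _stage_vep(config: RunConfig, rng_seed: int) -> dict:
    ctrl, _ = synthetic.make_vep_sweeps(seed=rng_seed)
    ap4, _ = synthetic.make_vep_sweeps(
        on_amplitude=0.0, off_amplitude=0.0, condition="4AP", seed=rng_seed + 1
    )
    on_ctrl = [vep.vep_metrics(s).on_rms_integral for s in ctrl]
    on_ap4 = [vep.vep_metrics(s).on_rms_integral for s in ap4]
    perm = vep.permutation_test(on_ctrl, on_ap4, n_perm=config.n_perm, seed=rng_seed)
    return {
        "on_rms_integral_control_Vs": float(np.mean(on_ctrl)),
        "on_rms_integral_4ap_Vs": float(np.mean(on_ap4)),
        "t_obs": perm.t_obs,
        "permutation_p": perm.p_value,
        "units": {"rms_integral": "V*s"},
    }


def _stage_gad(config: RunConfig, rng_seed: int) -> dict:
    field = synthetic.make_field(
        n_gad=12, gad_effects=[5.0] * 6 + [0.0] * 6, seed=rng_seed
    )
    bg = scoring.sample_background(
        field, n=config.n_background, radius=config.roi_radius_px, seed=rng_seed + 1
    )
    records = scoring.classify_gad_cfos(field, bg)
    n_pos = int(records["cfos_positive"].sum())
    return {
        "background_mean": bg.mean,
        "background_sd": bg.sd,
        "threshold": bg.threshold,
        "n_gad": len(records),
        "n_cfos_positive": n_pos,
        "percent_positive": scoring.gad_activation_summary(n_pos, len(records)),
        "units": {"intensity": "arbitrary fluorescence"},
    }


def run_pipeline(
    config: RunConfig,
    out_dir,
    stages: tuple[str, ...] = STAGES,
) -> dict:
    """Run the requested stages on synthetic inputs and write result JSON.

    Each stage simulates its inputs from the run seed, executes the
    corresponding analyses, and writes ``<stage>.json`` with provenance.
    Stage failures are caught, logged, and marked in the returned bundle;
    the bundle's ``ok`` flag is False if any stage failed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runners = {
        "spikes": _stage_spikes,
        "spatial": _stage_spatial,
        "counts": _stage_counts,
        "vep": _stage_vep,
        "gad": _stage_gad,
    }
    unknown = set(stages) - set(runners)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    bundle = {"stages": {}, "ok": True}
    for i, name in enumerate(stages):
        log.info("running stage %s", name)
        try:
            payload = runners[name](config, config.seed + 1000 * i)
            write_results(
                payload, out_dir / f"{name}.json", config.to_dict(), config.seed
            )
            bundle["stages"][name] = {"status": "ok", "results": payload}
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            log.error("stage %s failed: %s", name, exc)
            bundle["stages"][name] = {
                "status": "failed",
                "error": str(exc),
                "traceback": traceback.format_exc(),
            }
            bundle["ok"] = False
    return bundle
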