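"""End-to-end orchestration of a seeded synthetic study.

``run_demo`` chains every stage — synthetic generation, photometry
conditioning, EPM metrics, peri-event statistics, layer clustering and CRACM
quantification — writing tidy outputs plus a JSON manifest with per-stage
seeds and checksums.  All per-stage seeds derive from one global seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cracm, epm, io, layers, perievent, photometry, synthgen

__all__ = ["RunConfig", "run_demo", "validate_io"]

# re-exported here because input validation is a pipeline responsibility
validate_io = io.validate_io

#: per-stage offsets added to the global seed so stages draw independent streams
_STAGE_SEEDS = {"photometry": 101, "cellmap": 211, "cracm": 307, "epm": 401, "pattern": 503}


@dataclass
class RunConfig:
    """Configuration of a demo run (desk-scale defaults, < 5 min on one CPU)."""

    seed: int = 0
    out_dir: str = "demo_out"
    photometry_duration: float = 120.0
    photometry_fs_raw: float = 10_000.0
    n_cells: int = 500
    epm_duration: float = 540.0
    make_figures: bool = True

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + _STAGE_SEEDS[stage]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_df(path: Path, df: pd.DataFrame) -> str:
    df.to_csv(path, index=False, float_format="%.10g")
    return _checksum(path)


def run_demo(config: RunConfig | None = None) -> dict:
    """Run the full synthetic study; returns the manifest dict.

    Any stage failure aborts with the stage name attached to the exception.
    """
    cfg = config or RunConfig()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "config": asdict(cfg), "stages": {}, "checksums": {}}
    stage = "init"
    try:
        # --- synthetic photometry + conditioning -------------------------
        stage = "photometry"
        pcfg = synthgen.SynthPhotometryConfig(
            duration=cfg.photometry_duration,
            fs_raw=cfg.photometry_fs_raw,
            noise_sd=0.005,
            seed=cfg.stage_seed("photometry"),
        )
        rec, _ptruth = synthgen.gen_photometry_session(pcfg)
        session = photometry.process_session(rec, photometry.PhotometryConfig())
        for role in ("green", "red"):
            tr = session.channel(role)
            pth = out / f"photometry_{role}_z.csv"
            manifest["checksums"][pth.name] = _write_df(
                pth, pd.DataFrame({"time": tr.times, "z": tr.values})
            )
        manifest["stages"]["photometry"] = {
            "fs_raw": pcfg.fs_raw, "duration": pcfg.duration,
            "log": session.log, "seed": pcfg.seed,
        }

        # --- EPM ----------------------------------------------------------
        stage = "epm"
        ecfg = synthgen.SynthEPMConfig(duration=cfg.epm_duration, seed=cfg.stage_seed("epm"))
        track, _ev_truth, etruth = synthgen.gen_epm_track(ecfg)
        zones = epm.classify_zone(track)
        events = epm.detect_arm_entries(track, zones)
        epochs = epm.default_epochs(cfg.epm_duration)
        open_time = epm.open_arm_time_per_epoch(zones, epochs, track.frame_dt)
        p_entry = epm.entry_probability(events, epochs)
        gate = epm.closed_loop_gate(zones, epochs, stim_epoch=1, mode="latched")
        manifest["checksums"]["epm_events.tsv"] = _write_events(out / "epm_events.tsv", events)
        manifest["checksums"]["epm_gate.csv"] = _write_df(
            out / "epm_gate.csv", pd.DataFrame({"time": gate.t, "on": gate.on.astype(int)})
        )
        manifest["stages"]["epm"] = {
            "seed": ecfg.seed,
            "open_arm_time_per_epoch_s": open_time,
            "entry_probability_per_epoch": p_entry,
            "n_open_entries": int((events["event_type"] == "open_entry").sum()),
            "n_closed_entries": int((events["event_type"] == "closed_entry").sum()),
        }

        # --- peri-event on a programmed pattern session ------------------
        stage = "perievent"
        pat = synthgen.PatternSessionConfig(
            duration=cfg.epm_duration, seed=cfg.stage_seed("pattern")
        )
        sup, deep, pev, _truth = synthgen.gen_pattern_session(pat)
        spec = perievent.WindowSpec()
        stats_rows = []
        for et in ("open_entry", "closed_entry"):
            for name, tr in (("superficial", sup), ("deep", deep)):
                tensor = perievent.extract_epochs(tr, pev, event_type=et)
                tensor = perievent.baseline_subtract(tensor, spec.bl)
                st = perievent.window_stats(tensor, spec, et)
                st["channel"] = name
                stats_rows.append(st)
        stats = pd.concat(stats_rows, ignore_index=True)
        manifest["checksums"]["window_stats.csv"] = _write_df(out / "window_stats.csv", stats)
        summary = (
            stats.groupby(["channel", "event_type", "window"])["value"].mean().to_dict()
        )
        manifest["stages"]["perievent"] = {
            "seed": pat.seed,
            "window_means": {"/".join(k): float(v) for k, v in summary.items()},
            "sign_pattern": {
                "sup_post_open_up": summary[("superficial", "open_entry", "post")] > 0,
                "deep_pre_open_up": summary[("deep", "open_entry", "pre")] > 0,
                "deep_post_open_down": summary[("deep", "open_entry", "post")] < 0,
                "deep_post_closed_up": summary[("deep", "closed_entry", "post")] > 0,
            },
        }

        # --- cell map + layers -------------------------------------------
        stage = "layers"
        ccfg = synthgen.SynthCellMapConfig(n_cells=cfg.n_cells, seed=cfg.stage_seed("cellmap"))
        cellmap, ctruth = synthgen.gen_cellmap(ccfg)
        model = layers.fit_layer_gmm(cellmap, seed=cfg.stage_seed("cellmap"))
        assignments = layers.assign_layers(model, cellmap)
        fractions = layers.subset_layer_fractions(assignments, "rabies")
        manifest["checksums"]["cellmap.tsv"] = _write_cellmap(out / "cellmap.tsv", cellmap)
        manifest["stages"]["layers"] = {
            "seed": ccfg.seed,
            "selected_k": model.selected_k,
            "bic": {str(k): model.bics[k] for k in model.ks},
            "rabies_fractions": {k: float(v) for k, v in fractions["pooled"].items()},
        }

        # --- CRACM --------------------------------------------------------
        stage = "cracm"
        scfg = synthgen.SynthCracmConfig(seed=cfg.stage_seed("cracm"))
        sweeps, struth = synthgen.gen_cracm_sweeps(scfg)
        results = cracm.analyze_connectivity(sweeps)
        res_df = pd.DataFrame(
            {
                "pulse_ms": [r.pulse_ms for r in results],
                "amplitude": [r.amplitude for r in results],
                "baseline_sd": [r.baseline_sd for r in results],
                "connected": [r.connected for r in results],
            }
        )
        manifest["checksums"]["cracm_results.csv"] = _write_df(out / "cracm_results.csv", res_df)
        manifest["stages"]["cracm"] = {
            "seed": scfg.seed,
            "n_connected": int(res_df["connected"].sum()),
            "truth_connected": bool(struth.connectivity_truth["connected"]),
        }

        if cfg.make_figures:
            stage = "figures"
            _make_figures(out, session, stats, cellmap, assignments)
    except Exception as e:
        raise RuntimeError(f"demo stage {stage!r} failed: {e}") from e

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def _write_events(path: Path, events: pd.DataFrame) -> str:
    io.write_events_tsv(path, events)
    return _checksum(path)


def _write_cellmap(path: Path, cellmap) -> str:
    io.write_cellmap_tsv(path, cellmap)
    return _checksum(path)


def _make_figures(out: Path, session, stats: pd.DataFrame, cellmap, assignments) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
    for ax, role, color in zip(axes, ("red", "green"), ("tab:red", "tab:green")):
        tr = session.channel(role)
        ax.plot(tr.times, tr.values, lw=0.5, color=color)
        ax.set_ylabel(f"{role} (z)")
    axes[-1].set_xlabel("time (s)")
    fig.tight_layout()
    fig.savefig(out / "photometry_traces.png", dpi=100)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    for layer, grp in assignments.groupby("layer"):
        ax.scatter(grp["longitudinal"], grp["radial"], s=6, label=layer)
    ax.set_xlabel("longitudinal")
    ax.set_ylabel("radial (0 = alveus)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "cellmap_layers.png", dpi=100)
    plt.close(fig)
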