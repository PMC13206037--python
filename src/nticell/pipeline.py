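"""Pipeline stages tying the modules together behind the CLI.

Each stage reads/writes plain CSV/JSON artifacts in a run directory and
drops a manifest with the resolved configuration, so identical configs
yield identical artifacts.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .inheritance import (
    fidelity_by_regime,
    generation_fidelity,
    jsd,
    ke_distribution,
    pairwise_jsd_cluster,
    shared_bin_edges,
)
from .kinematics import log_resample, read_ke_csv, segment_phases
from .lineage import LineageTable
from .pid import pid_fingerprint
from .regimes import classify_bundle
from .scaling import sweep_scales
from .synthetic import RegimeSpec, SeriesBundle, simulate_community, simulate_lineage

__all__ = ["run_pipeline", "simulate_stage", "classify_stage", "inherit_stage", "sweep_stage"]

_SPEC_BUILDERS = {
    "coupled": RegimeSpec.coupled,
    "information_closed": RegimeSpec.information_closed,
    "independent": RegimeSpec.independent,
}


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing {what}: {path}")
    return path


def load_bundle(rundir: str | Path) -> SeriesBundle:
    """Rebuild a SeriesBundle from a simulate-stage run directory."""
    rundir = Path(rundir)
    lineage = LineageTable.from_csv(_require(rundir / "lineage.csv", "lineage table"))
    series = read_ke_csv(_require(rundir / "series.csv", "KE series"))
    sidecar_path = rundir / "bundle.json"
    truth, seed, dt = {}, 0, 0.5
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        truth = {int(k): v for k, v in sidecar.get("truth", {}).items()}
        seed = sidecar.get("seed", 0)
        dt = sidecar.get("dt", 0.5)
    for s in series.values():
        s.dt = dt
    return SeriesBundle(lineage=lineage, series=series, truth=truth, seed=seed, dt=dt)


def simulate_stage(config: PipelineConfig, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    lineage = simulate_lineage(
        config.generations, config.frames_per_generation, seed=config.seed
    )
    specs = {}
    for g in range(config.generations + 1):
        label = config.regimes_by_generation.get(g, config.default_regime)
        specs[g] = _SPEC_BUILDERS[label]()
    bundle = simulate_community(lineage, specs, seed=config.seed)
    bundle.write(outdir)
    config.write_manifest(outdir, "simulate")
    return outdir


def classify_stage(
    config: PipelineConfig,
    rundir: str | Path,
    phases: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    rundir = Path(rundir)
    bundle = load_bundle(rundir)
    results = classify_bundle(
        bundle,
        config.estimator(),
        phases=phases or config.phases,
        n_perm=config.n_perm,
        seed=config.seed,
        stride=config.stride,
    )
    # append the PID fingerprint columns, with each cell's approximate-
    # equality tolerance tied to its surrogate interval half-width
    fps = [
        pid_fingerprint(
            _triple_from_row(r),
            tolerance=max(1e-6, (r["ntic_upper"] - r["ntic_lower"]) / 2),
        )
        for _, r in results.iterrows()
    ]
    results["redundancy"] = [f.redundancy for f in fps]
    results["synergy"] = [f.synergy for f in fps]
    results["dominance_holds"] = [f.dominance_holds for f in fps]
    results["fingerprint"] = [f.regime_fingerprint for f in fps]
    results.to_csv(rundir / "classification.csv", index=False)
    config.write_manifest(rundir, "classify", {"n_rows": len(results)})
    return results


def _triple_from_row(r):
    from .estimators import InfoTriple

    return InfoTriple(
        mi_self=r["mi_self"],
        mi_ctx=r["mi_ctx"],
        cmi_self_given_ctx=r["cmi_self_given_ctx"],
        cmi_ctx_given_self=r["cmi_ctx_given_self"],
        ntic=r["ntic"],
    )


def middle_phase_distributions(
    bundle: SeriesBundle,
    config: PipelineConfig,
) -> dict[int, "object"]:
    """Central-window log-KE distribution for every cell, on shared bins."""
    transformed = {
        cid: log_resample(s, stride=config.stride) for cid, s in bundle.series.items()
    }
    windows = {}
    samples = []
    for cid, s in transformed.items():
        seg = segment_phases(s, window_samples=min(len(s), config.window_samples))
        windows[cid] = seg.central_window
        m = (s.frames >= seg.central_window[0]) & (s.frames < seg.central_window[1])
        samples.append(s.values[m])
    edges = shared_bin_edges(samples, config.n_bins)
    return {
        cid: ke_distribution(s, windows[cid], config.n_bins, shared_range=edges)
        for cid, s in transformed.items()
    }


def parent_daughter_fidelity(
    bundle: SeriesBundle,
    classification: pd.DataFrame,
    config: PipelineConfig,
    series_label: str = "run",
) -> pd.DataFrame:
    """Parent–daughter JSD table with the daughter's middle-phase category."""
    dists = middle_phase_distributions(bundle, config)
    mid = classification[classification["phase"] == "middle"]
    cat = dict(zip(mid["cell_id"], mid["category"]))
    rows = []
    for parent, daughter in bundle.lineage.parent_daughter_pairs():
        if parent not in dists or daughter not in dists:
            continue
        rows.append(
            dict(
                series=series_label,
                parent_id=parent,
                daughter_id=daughter,
                generation=bundle.lineage.generation_of(daughter),
                category=cat.get(daughter),
                truth=bundle.truth.get(daughter),
                jsd=jsd(dists[parent], dists[daughter]),
            )
        )
    return pd.DataFrame(rows)


def inherit_stage(config: PipelineConfig, rundir: str | Path) -> dict:
    rundir = Path(rundir)
    bundle = load_bundle(rundir)
    cls_path = _require(rundir / "classification.csv", "classification table")
    classification = pd.read_csv(cls_path)
    pairs = parent_daughter_fidelity(bundle, classification, config)
    pairs.to_csv(rundir / "fidelity.csv", index=False)

    dists = middle_phase_distributions(bundle, config)
    ordered = [dists[cid] for cid in sorted(dists)]
    mat, labels = pairwise_jsd_cluster(ordered)
    pd.DataFrame(
        mat, index=sorted(dists), columns=sorted(dists)
    ).to_csv(rundir / "jsd_matrix.csv")

    stats: dict = {"clusters": {str(cid): int(l) for cid, l in zip(sorted(dists), labels)}}
    try:
        fs = fidelity_by_regime(pairs)
        stats["by_regime"] = dict(
            group_means=fs.group_means,
            group_sds=fs.group_sds,
            group_sizes=fs.group_sizes,
            kruskal_h=fs.kruskal_h,
            kruskal_p=fs.kruskal_p,
            pairwise={f"{a}|{b}": v for (a, b), v in fs.pairwise.items()},
        )
    except ValueError:
        stats["by_regime"] = None  # too few categories in this run
    stats["by_generation"] = generation_fidelity(pairs)
    (rundir / "fidelity_stats.json").write_text(json.dumps(stats, indent=2, default=str))
    config.write_manifest(rundir, "inherit", {"n_pairs": len(pairs)})
    return stats


def sweep_stage(config: PipelineConfig, rundir: str | Path) -> pd.DataFrame:
    rundir = Path(rundir)
    bundle = load_bundle(rundir)
    sweep = sweep_scales(
        bundle,
        config.estimator(),
        blocks=config.blocks,
        phases=config.phases,
        n_perm=config.n_perm,
        seed=config.seed,
        stride=config.stride,
    )
    sweep.table.to_csv(rundir / "scale_sweep.csv", index=False)
    sweep.cells.to_csv(rundir / "scale_sweep_cells.csv", index=False)
    config.write_manifest(rundir, "sweep")
    return sweep.table


def report_stage(rundir: str | Path) -> dict:
    """Collect the run's headline numbers into one JSON report."""
    rundir = Path(rundir)
    report: dict = {}
    cls_path = rundir / "classification.csv"
    if cls_path.exists():
        from .regimes import phase_regime_table

        results = pd.read_csv(cls_path)
        report["phase_table"] = phase_regime_table(results).to_dict()
        report["dominance_fraction"] = float(results["dominance_holds"].mean())
    stats_path = rundir / "fidelity_stats.json"
    if stats_path.exists():
        report["fidelity"] = json.loads(stats_path.read_text())
    sweep_path = rundir / "scale_sweep.csv"
    if sweep_path.exists():
        report["scale_sweep"] = pd.read_csv(sweep_path).to_dict("records")
    (rundir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def run_pipeline(config: PipelineConfig, command: str, rundir: str | Path) -> int:
    """Dispatch one stage; returns a process exit status."""
    stages = {
        "simulate": lambda: simulate_stage(config, rundir),
        "classify": lambda: classify_stage(config, rundir),
        "inherit": lambda: inherit_stage(config, rundir),
        "sweep": lambda: sweep_stage(config, rundir),
        "report": lambda: report_stage(rundir),
    }
    if command not in stages:
        raise ValueError(f"unknown command {command!r}")
    stages[command]()
    return 0
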