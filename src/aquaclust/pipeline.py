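"""Full-pipeline orchestration and run reporting.

``run_pipeline`` drives the hierarchy on every frame — hydrogen bonds →
SP rings → cage fragments → fragment network → Louvain communities →
water clusters — then the per-cluster measurements (alpha-shape
morphology, SPC/E energy) and the cross-frame dynamics, and collects
everything in a :class:`RunReport`.

Frames are processed independently; the dynamics stage consumes the
per-frame entity decompositions afterwards.  Re-running with identical
inputs and seed reproduces the report exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .clusters import (WaterCluster, assemble_clusters, build_fragment_network,
                       coverage_fraction, debris_molecules, isolated_rings,
                       louvain_partition)
from .dynamics import FrameState, lifetime_stats
from .energetics import cluster_energy, energy_size_fit
from .fragments import detect_fragments
from .frames import TrajectorySettings, WaterFrame
from .hbonds import detect_hbonds
from .morphology import (cluster_shape, powerlaw_exponent, radius_scaling_fit,
                         surface_volume_fit)
from .rings import enumerate_sp_rings

ALL_STAGES = ("hbonds", "rings", "fragments", "clusters", "morphology",
              "energy", "dynamics")


class StageError(RuntimeError):
    def __init__(self, stage: str, frame_index: int, cause: Exception):
        super().__init__(f"stage {stage!r} failed on frame {frame_index}: {cause}")
        self.stage = stage
        self.frame_index = frame_index


@dataclasses.dataclass
class FrameResult:
    """Everything computed for one frame."""

    frame: WaterFrame
    graph: object = None
    rings: set = dataclasses.field(default_factory=set)
    fragments: set = dataclasses.field(default_factory=set)
    clusters: list = dataclasses.field(default_factory=list)
    coverage: float = float("nan")
    shapes: dict = dataclasses.field(default_factory=dict)   # cluster_id -> ClusterShape
    energies: dict = dataclasses.field(default_factory=dict)  # cluster_id -> kJ/mol

    def state(self) -> FrameState:
        iso = isolated_rings(self.rings, self.fragments)
        debris = debris_molecules(self.frame, self.rings, self.clusters)
        return FrameState.build([c.molecules for c in self.clusters],
                                [frozenset(r.members) for r in iso], debris)


@dataclasses.dataclass
class RunReport:
    """Aggregated counts, distributions and fits for one run."""

    settings: TrajectorySettings
    frames: list[FrameResult]
    per_frame: pd.DataFrame          # molecules, hbonds, rings, fragments, clusters, coverage
    cluster_table: pd.DataFrame      # frame, cluster_id, S, V, A, L, E_S, signature
    size_histogram: dict[int, int]
    fits: dict
    lifetime: object = None          # LifetimeStats
    provenance: dict = dataclasses.field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "settings": {k: (sorted(v) if isinstance(v, frozenset) else v)
                         for k, v in dataclasses.asdict(self.settings).items()},
            "per_frame": self.per_frame.to_dict(orient="records"),
            "size_histogram": {str(k): v for k, v in
                               sorted(self.size_histogram.items())},
            "fits": self.fits,
            "lifetime": (None if self.lifetime is None else {
                "mean_lifetime": self.lifetime.mean_lifetime,
                "rates": self.lifetime.rates,
                "n_events": self.lifetime.n_events}),
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, default=float)


def _settings_hash(settings: TrajectorySettings) -> str:
    blob = json.dumps(
        {k: (sorted(v) if isinstance(v, frozenset) else v)
         for k, v in dataclasses.asdict(settings).items()}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def analyze_frame(frame: WaterFrame, settings: TrajectorySettings,
                  stages: Sequence[str] = ALL_STAGES) -> FrameResult:
    """Run the per-frame stages in hierarchy order.

    Later stages are skipped when their prerequisites are not requested;
    disabling a stage never changes upstream outputs.
    """
    result = FrameResult(frame)
    want = set(stages)

    def run(stage, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - annotate failing stage
            raise StageError(stage, frame.frame_index, exc) from exc

    if "hbonds" not in want:
        return result
    result.graph = run("hbonds", lambda: detect_hbonds(frame, settings.hb_cutoff))
    if "rings" not in want:
        return result
    result.rings = run("rings", lambda: enumerate_sp_rings(
        result.graph, settings.max_ring_size))
    if "fragments" not in want:
        return result
    result.fragments = run("fragments", lambda: detect_fragments(
        result.rings, result.graph, settings.fragment_ring_counts))
    if "clusters" not in want:
        return result

    def cluster_stage():
        network = build_fragment_network(result.fragments)
        partition = louvain_partition(network, seed=settings.rng_seed)
        return assemble_clusters(partition, result.fragments)

    result.clusters = run("clusters", cluster_stage)
    result.coverage = coverage_fraction(result.clusters, frame)
    if "morphology" in want:
        for c in result.clusters:
            try:
                result.shapes[c.cluster_id] = cluster_shape(
                    frame, c.molecules, result.graph, settings.alpha_radius)
            except Exception:  # noqa: BLE001 - per-cluster geometry downgraded
                pass
    if "energy" in want:
        for c in result.clusters:
            result.energies[c.cluster_id] = run("energy", lambda c=c: cluster_energy(
                c.molecules, frame, settings.energy_cutoff))
    return result


def run_pipeline(frames: Iterable[WaterFrame],
                 settings: TrajectorySettings | None = None,
                 stages: Sequence[str] = ALL_STAGES,
                 powerlaw_min_size: int = 3) -> RunReport:
    """Analyze a trajectory and aggregate the summary report."""
    settings = settings or TrajectorySettings()
    results = [analyze_frame(f, settings, stages) for f in frames]

    per_frame_rows = []
    cluster_rows = []
    size_hist: dict[int, int] = {}
    for res in results:
        f = res.frame
        per_frame_rows.append({
            "frame": f.frame_index,
            "molecules": f.n_molecules,
            "hbonds": res.graph.number_of_edges() if res.graph is not None else 0,
            "rings": len(res.rings),
            "fragments": len(res.fragments),
            "clusters": len(res.clusters),
            "coverage": res.coverage,
        })
        for c in res.clusters:
            size_hist[c.size] = size_hist.get(c.size, 0) + 1
            shape = res.shapes.get(c.cluster_id)
            sig = "+".join(",".join(map(str, fr.signature))
                           for fr in sorted(c.fragments,
                                            key=lambda fr: fr.signature))
            cluster_rows.append({
                "frame": f.frame_index, "cluster_id": c.cluster_id,
                "S": c.size,
                "V": shape.volume if shape else np.nan,
                "A": shape.area if shape else np.nan,
                "L": shape.max_diameter if shape else np.nan,
                "E_S": res.energies.get(c.cluster_id, np.nan),
                "signature": sig,
            })
    per_frame = pd.DataFrame(per_frame_rows)
    cluster_table = pd.DataFrame(
        cluster_rows, columns=["frame", "cluster_id", "S", "V", "A", "L",
                               "E_S", "signature"])

    fits: dict = {}
    if len(cluster_table) >= 3 and "morphology" in stages:
        from .morphology import ClusterShape
        shapes = [ClusterShape(r.V, r.A, r.L, settings.alpha_radius)
                  for r in cluster_table.itertuples()
                  if np.isfinite(r.V) and np.isfinite(r.A) and r.L > 0]
        try:
            dv, ds = radius_scaling_fit(shapes)
            fits["d_V"] = dv.slope
            fits["d_S"] = ds.slope
        except ValueError:
            pass
        sv = surface_volume_fit(shapes)
        for regime, fit in sv.items():
            if fit is not None:
                fits[f"surface_volume_{regime}"] = {
                    "a": fit.slope, "b": fit.intercept, "n": fit.n_points}
    try:
        fits["tau"] = powerlaw_exponent(size_hist, fit_min_size=powerlaw_min_size)
    except ValueError:
        pass
    if "energy" in stages:
        es = cluster_table.dropna(subset=["E_S"])
        try:
            fit = energy_size_fit(es["S"].to_numpy(), es["E_S"].to_numpy())
            fits["energy"] = {"a": fit.slope, "b": fit.intercept}
        except ValueError:
            pass

    lifetime = None
    if "dynamics" in stages and len(results) >= 2:
        lifetime = lifetime_stats([r.state() for r in results])

    provenance = {
        "package_version": __version__,
        "settings_hash": _settings_hash(settings),
        "seed": settings.rng_seed,
        "n_frames": len(results),
    }
    return RunReport(settings, results, per_frame, cluster_table, size_hist,
                     fits, lifetime, provenance)


def write_report(report: RunReport, outdir: str | Path) -> None:
    """Write report.json plus per-stage TSV tables under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json())
    report.per_frame.to_csv(outdir / "per_frame.tsv", sep="\t", index=False)
    report.cluster_table.to_csv(outdir / "clusters.tsv", sep="\t", index=False)
    hist = pd.DataFrame(sorted(report.size_histogram.items()),
                        columns=["S", "n_S"])
    hist.to_csv(outdir / "size_distribution.tsv", sep="\t", index=False)
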