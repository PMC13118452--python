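"""End-to-end pipeline wiring with a validated run configuration.

Stages chain through files on disk rather than in-memory handoff, so
every stage is independently re-runnable on its predecessor's outputs:

    simulate -> screen -> tracer filter/export -> network -> annotate

``RunConfig`` validates eagerly and rejects unknown keys, and the whole
run is reproducible from its seed: two runs with the same configuration
produce identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

from . import __version__
from .annotate import annotate_precursor, ch2_cluster, assign_core
from .msio import read_feature_table, read_mgf
from .screen import ScreenRuleSet, default_rule_set, screen
from .simulate import SpectrumParams, synth_feature_bundle, synth_library
from .tracer import TracerRuleSet, build_network, export_gnps_bundle, network_metrics, tracer_filter

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str
    seed: int = 0
    n_gsl: int = 100
    n_decoy: int = 100
    mgf_path: str | None = None  # when set, simulation is skipped
    features_path: str | None = None
    merge_tol_ppm: float = 5.0
    annotation_tol_ppm: float = 5.0
    min_cosine: float = 0.7
    min_matched_peaks: int = 6
    top_k: int = 10
    verbosity: str = "info"

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.n_gsl < 0 or self.n_decoy < 0:
            raise ValueError("compound counts must be non-negative")
        if self.merge_tol_ppm <= 0 or self.annotation_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if not 0 <= self.min_cosine <= 1:
            raise ValueError("min_cosine must lie in [0, 1]")
        if self.verbosity not in ("debug", "info", "warning"):
            raise ValueError(f"unknown verbosity {self.verbosity!r}")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)


def run_all(config: RunConfig,
            screen_rules: ScreenRuleSet | None = None,
            tracer_rules: TracerRuleSet | None = None) -> dict[str, Any]:
    """Execute every stage, writing outputs and a run log under
    ``config.out_dir``; returns a summary dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.verbosity.upper()))
    summary: dict[str, Any] = {"version": __version__, "seed": config.seed}

    # stage 1: inputs (simulated unless provided)
    if config.mgf_path is None:
        library = synth_library(config.n_gsl, config.n_decoy, seed=config.seed)
        bundle = synth_feature_bundle(library, out / "simulated", SpectrumParams(),
                                      seed=config.seed)
        mgf_path, features_path = bundle["mgf"], bundle["features"]
        summary["n_compounds"] = len(library)
    else:
        mgf_path = Path(config.mgf_path)
        features_path = Path(config.features_path) if config.features_path else None

    # stage 2: diagnostic-ion screening
    rules = screen_rules or default_rule_set()
    rules = dataclasses.replace(rules, merge_tol_ppm=config.merge_tol_ppm)
    rows, screen_summary = screen(mgf_path, rules, out / "screen_report.csv")
    summary["screen"] = screen_summary

    # stage 3: tracer filtering + GNPS-compatible export
    spectra = [s.normalize() for s in read_mgf(mgf_path) if s.peaks]
    features = read_feature_table(features_path) if features_path else []
    retained, kept_features = tracer_filter(spectra, features, tracer_rules)
    export_gnps_bundle(retained, kept_features, out / "tracer")
    summary["tracer"] = {"n_input": len(spectra), "n_retained": len(retained)}

    # stage 4: local molecular network over the retained spectra
    if retained:
        net = build_network(retained, config.min_cosine, config.min_matched_peaks,
                            config.top_k)
        metrics = network_metrics(net, unfiltered_node_count=len(spectra))
        edge_path = out / "network_edges.csv"
        with edge_path.open("w") as fh:
            fh.write("source,target,cosine,matched_peaks\n")
            for u, v, d in sorted(net.edges):
                fh.write(f"{u},{v},{d['cosine']:.4f},{d['matched_peaks']}\n")
        summary["network"] = metrics
    else:
        summary["network"] = {"nodes": 0, "edges": 0, "connected_components": 0,
                              "redundancy_reduction": 0.0}

    # stage 5: annotation + CH2 homolog series of the screened precursors
    ann_path = out / "annotations.csv"
    residuals: list[float] = []
    with ann_path.open("w") as fh:
        fh.write("spectrum_id,precursor_mz,core,substituents,formula,theoretical_mz,ppm\n")
        for row in rows:
            mz = float(row["precursor_mz"])
            for cand in annotate_precursor(mz, tol_ppm=config.annotation_tol_ppm)[:3]:
                subs = ";".join(f"{n}x{k}" for n, k in cand.substituents) or "-"
                fh.write(
                    f"{row['spectrum_id']},{mz:.4f},{cand.core},{subs},"
                    f"{cand.formula.hill()},{cand.theoretical_mz:.4f},{cand.ppm:.2f}\n"
                )
            fits = assign_core(mz)
            if fits:
                residuals.append(min(fits, key=lambda cr: cr[1])[1])
    series = ch2_cluster(residuals) if residuals else []
    series_path = out / "homolog_series.csv"
    with series_path.open("w") as fh:
        fh.write("series_id,n_members,residuals\n")
        for s in series:
            fh.write(f"{s.series_id},{len(s.members)},{';'.join(f'{m:.4f}' for m in s.members)}\n")
    summary["annotation"] = {"n_screened": len(rows), "n_homolog_series": len(series)}

    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    logger.info("run complete: %s", summary)
    return summary
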