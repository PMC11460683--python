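"""One-call pipeline: standardize → enumerate → patterns → compare → report.

`run_pipeline` drives the full analysis for one model: it enumerates the
requested pathway definitions, reduces them to unique exchange patterns,
filters for growth, extracts EFPs, verifies the pattern hierarchy,
computes exchange (and, for communities, interaction) frequencies, and
optionally samples fluxes.  The report bundle is a plain dict of counts,
pandas tables, and a manifest of every seed and tolerance used; with an
output directory the tables are also written as CSV/JSON with
deterministic ordering.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .ecm import enumerate_ecms
from .efm import enumerate_efms, pattern_vectors
from .frequencies import exchange_frequency, frequency_difference, interaction_frequency
from .network import MetabolicNetwork, standardize
from .patterns import (
    compare_collections,
    enumerate_mps,
    extract_efps,
    filter_growth,
    to_patterns,
)
from .sampling import sample_fluxes

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    model: MetabolicNetwork
    label: str = "model"
    subnetwork_mode: str = "boundary"
    definitions: tuple[str, ...] = ("ecm", "efp", "mp")
    efp_source: str = "auto"  # efm | ecm | auto (prefer ECM tier)
    growth_floor_enumeration: float = 1e-4
    growth_floor_sampling: float = 0.1
    mp_use_bounds: bool = False
    ray_ceiling: int = 2_000_000
    n_samples: int = 0
    seed: int = 0
    out_dir: str | None = None
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        defs = {d.lower() for d in self.definitions}
        unknown = defs - {"efm", "ecm", "efp", "mp"}
        if unknown:
            raise ValueError(f"unknown definitions: {sorted(unknown)}")
        if not defs:
            raise ValueError("at least one pathway definition must be requested")
        if "efp" in defs and not defs & {"efm", "ecm"}:
            raise ValueError("the EFP tier requires the EFM or ECM tier")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline and return the report bundle."""
    config.validate()
    defs = {d.lower() for d in config.definitions}
    timings: dict[str, float] = {}
    report: dict = {"label": config.label, "counts": {}, "tables": {}}

    t0 = time.perf_counter()
    std = standardize(config.model, subnetwork_mode=config.subnetwork_mode)
    timings["standardize"] = time.perf_counter() - t0
    prov = f"{config.label}:{config.subnetwork_mode}"

    collections = {}
    growth_collections = {}

    if "efm" in defs:
        t0 = time.perf_counter()
        efms = enumerate_efms(std, max_rays=config.ray_ceiling)
        timings["efm"] = time.perf_counter() - t0
        report["counts"]["efms"] = efms.count
        vecs, bio = pattern_vectors(efms, std)
        coll = to_patterns(
            vecs, std, definition="EFM", biomass_fluxes=bio, provenance=prov
        )
        collections["EFM"] = coll
        report["counts"]["efm_patterns"] = coll.count

    if "ecm" in defs:
        t0 = time.perf_counter()
        ecms = enumerate_ecms(std, max_rays=config.ray_ceiling)
        timings["ecm"] = time.perf_counter() - t0
        report["counts"]["ecms"] = ecms.count
        coll = to_patterns(
            ecms.subnetwork_vectors(),
            std,
            definition="ECM",
            biomass_fluxes=[1 if g else 0 for g in ecms.growth],
            provenance=prov,
        )
        collections["ECM"] = coll
        report["counts"]["ecm_patterns"] = coll.count
        report["conversions"] = ecms.conversions

    if "efp" in defs:
        source = config.efp_source
        if source == "auto":
            source = "ecm" if "ECM" in collections else "efm"
        src = collections[source.upper()]
        t0 = time.perf_counter()
        coll = extract_efps(src)
        timings["efp"] = time.perf_counter() - t0
        collections["EFP"] = coll
        report["counts"]["efps"] = coll.count

    if "mp" in defs:
        t0 = time.perf_counter()
        coll = enumerate_mps(
            std,
            growth_floor=config.growth_floor_enumeration,
            use_bounds=config.mp_use_bounds,
            provenance=prov,
        )
        timings["mp"] = time.perf_counter() - t0
        collections["MP"] = coll
        report["counts"]["mps"] = coll.count

    for name, coll in collections.items():
        g = filter_growth(coll)
        growth_collections[name] = g
        report["counts"][f"{name.lower()}_growth_patterns"] = g.count

    comparison = compare_collections(list(growth_collections.values()))
    report["hierarchy_holds"] = comparison.hierarchy_holds
    report["hierarchy_equal"] = comparison.hierarchy_equal
    report["comparison"] = comparison

    freqs = {}
    for name, coll in growth_collections.items():
        if coll.count:
            freqs[name] = exchange_frequency(coll)
    report["frequencies"] = freqs
    if "MP" in freqs:
        report["frequency_differences"] = {
            f"{name}-MP": frequency_difference(freqs[name], freqs["MP"])
            for name in freqs
            if name != "MP"
        }
    if config.model.intermicrobial:
        report["interactions"] = {
            name: interaction_frequency(coll)
            for name, coll in growth_collections.items()
            if coll.count
        }

    if config.n_samples:
        t0 = time.perf_counter()
        report["samples"] = sample_fluxes(
            config.model,
            config.n_samples,
            growth_floor=config.growth_floor_sampling,
            seed=config.seed,
        )
        timings["sampling"] = time.perf_counter() - t0

    report["collections"] = collections
    report["growth_collections"] = growth_collections
    report["manifest"] = {
        "version": __version__,
        "seed": config.seed,
        "growth_floor_enumeration": config.growth_floor_enumeration,
        "growth_floor_sampling": config.growth_floor_sampling,
        "mp_use_bounds": config.mp_use_bounds,
        "ray_ceiling": config.ray_ceiling,
        "subnetwork_mode": config.subnetwork_mode,
        "definitions": sorted(defs),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }

    if config.out_dir:
        _write_bundle(report, growth_collections, Path(config.out_dir))
    return report


def _write_bundle(report, growth_collections, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(report["manifest"], fh, indent=1, sort_keys=True)
    with open(out / "counts.json", "w") as fh:
        json.dump(report["counts"], fh, indent=1, sort_keys=True)
    for name, coll in growth_collections.items():
        rows = []
        for i, p in enumerate(coll.patterns):
            for entity, direction in p.sorted_items():
                rows.append(f"{i}\t{entity}\t{direction}")
        (out / f"patterns_{name.lower()}.tsv").write_text(
            "pattern\tentity\tdirection\n" + "\n".join(rows) + "\n"
        )
    for name, ft in report.get("frequencies", {}).items():
        ft.table.to_csv(out / f"frequencies_{name.lower()}.csv", index=False)
    for name, df in report.get("frequency_differences", {}).items():
        df.to_csv(out / f"frequency_difference_{name.lower()}.csv", index=False)
    for name, df in report.get("interactions", {}).items():
        df.to_csv(out / f"interactions_{name.lower()}.csv", index=False)
    comparison = report.get("comparison")
    if comparison is not None:
        comparison.lengths.to_csv(out / "pattern_lengths.csv", index=False)
        if len(comparison.mp_subset_counts):
            comparison.mp_subset_counts.to_csv(out / "mp_subset_counts.csv", index=False)
        if len(comparison.superset_counts):
            comparison.superset_counts.to_csv(out / "superset_counts.csv", index=False)
        comparison.venn.to_csv(out / "venn_overlaps.csv", index=False)
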