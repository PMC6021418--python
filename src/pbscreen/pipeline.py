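"""End-to-end orchestration: simulate -> splink -> map -> assign -> screen
-> somatic -> enrich -> diststats, with a reproducible JSON report.

The report carries every cross-stage count (reads, sites, assignments,
candidates, filter trace, enrichment) plus the config hash and a report
hash, so a rerun under the same configuration can be verified
byte-for-byte.  Stage failures are recorded in the report (written even
on partial completion) and re-raised naming the failing stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from ._util import PbscreenError
from . import assign, mapping, screen as screen_mod, splink, stats, variants
from .simulate import SimConfig, simulate_all

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat parameter block for one full screen run."""

    outdir: str
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    window: int = 50_000
    min_support: int = 5
    snap_window: int = 4
    map_max_mismatches: int = 4
    index_k: int = 12
    min_depth: int = 20
    min_alt: int = 4
    universe: int = stats.DEFAULT_UNIVERSE
    control_condition: str = "scramble"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):  # loaded from JSON
            from .simulate import VariantCounts

            raw = dict(self.sim)
            vc = raw.pop("variant_counts", None)
            self.sim = SimConfig(**raw)
            if vc:
                self.sim.variant_counts = VariantCounts(**vc)
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


class StageError(PbscreenError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline on synthetic data and return the report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("splink", _stage_splink),
        ("map_sites", _stage_map),
        ("assign", _stage_assign),
        ("screen", _stage_screen),
        ("somatic", _stage_somatic),
        ("enrich", _stage_enrich),
        ("diststats", _stage_diststats),
    ]
    try:
        for name, fn in stages:
            logger.info("running stage %s", name)
            try:
                report["stages"][name] = {"status": "ok"}
                report[name] = fn(config, state, outdir)
            except Exception as exc:
                report["stages"][name] = {"status": "failed", "error": str(exc)}
                raise StageError(name, exc) from exc
    finally:
        payload = json.dumps(report, sort_keys=True, default=str)
        report["report_hash"] = hashlib.sha256(payload.encode()).hexdigest()[:16]
        (outdir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=str)
        )
    return report


def _stage_simulate(config: RunConfig, state: dict, outdir: Path) -> dict:
    state["sim"] = simulate_all(config.sim, outdir)
    sim = state["sim"]
    return {
        "n_reads": {pool: len(r) for pool, r in sim["reads"].items()},
        "skipped_reads": sim["skipped_reads"],
        "n_variants": len(sim["channel_a"]) + len(sim["channel_b"]),
        "driver_genes": sim["roles"]["driver_genes"],
        "shared_genes": sim["roles"]["shared_genes"],
    }


def _stage_splink(config: RunConfig, state: dict, outdir: Path) -> dict:
    sim = state["sim"]
    out = {}
    state["fragments"] = {}
    for pool in ("ectopic", "cortical"):
        table, summary = splink.batch_classify(sim["reads"][pool])
        table.to_csv(outdir / f"fragments_{pool}.tsv", sep="\t", index=False)
        state["fragments"][pool] = table
        out[pool] = summary
    return out


def _stage_map(config: RunConfig, state: dict, outdir: Path) -> dict:
    sim = state["sim"]
    index = mapping.build_index(sim["genome"].sequences, k=config.index_k)
    hits = []
    n_unmapped = 0
    for pool, table in state["fragments"].items():
        for row in table.itertuples():
            if not row.readable:
                continue
            hit = mapping.map_flank(row.read_id, row.flank, index,
                                    max_mismatches=config.map_max_mismatches)
            if hit is None:
                n_unmapped += 1
                continue
            hits.append((hit, pool))
    sites, drops = mapping.call_sites(
        hits, sim["genome"], min_support=config.min_support, snap_window=config.snap_window
    )
    mapping.write_sites_bed(sites, outdir / "sites.bed")
    sites.to_csv(outdir / "sites.tsv", sep="\t", index=False)
    state["sites"] = sites
    return {
        "n_mapped_reads": len(hits),
        "n_unmapped": n_unmapped,
        "drops": drops,
        "n_sites": len(sites),
        "n_major_sites": int(sites["major"].sum()) if len(sites) else 0,
    }


def _stage_assign(config: RunConfig, state: dict, outdir: Path) -> dict:
    sim = state["sim"]
    index = assign.AnnotationIndex(sim["genes"], window=config.window)
    major = state["sites"][state["sites"]["major"]]
    assignments = assign.classify_sites(major, index)
    state["assignments"] = assignments
    assign.assignments_frame(assignments).to_csv(
        outdir / "assignments.tsv", sep="\t", index=False
    )
    total_readable = sum(
        int(t["readable"].sum()) for t in state["fragments"].values()
    )
    report = assign.breakdown_report(assignments, total_readable)
    (outdir / "summary.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def _stage_screen(config: RunConfig, state: dict, outdir: Path) -> dict:
    pools = {}
    for pool in ("ectopic", "cortical"):
        pool_assign = [a for a in state["assignments"]
                       if a.pool == pool and a.category != "unassigned"]
        pools[pool] = screen_mod.pool_gene_sets(pool_assign, pool)
    result = screen_mod.differential_exclude(pools["ectopic"], pools["cortical"])
    state["candidates"] = sorted(result.table["gene_id"]) if len(result.table) else []
    out_tbl = result.table.drop(columns=["sites"]) if len(result.table) else result.table
    out_tbl.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    (outdir / "screen_provenance.json").write_text(
        json.dumps(result.provenance, indent=1, sort_keys=True)
    )
    return {"candidates": state["candidates"], **result.provenance}


def _stage_somatic(config: RunConfig, state: dict, outdir: Path) -> dict:
    sim = state["sim"]
    merged, info = variants.merge_callers(sim["channel_a"], sim["channel_b"])
    res = variants.apply_filters(
        merged,
        set(sim["known_snps"]),
        sim["genes"],
        sim["genome"],
        min_depth=config.min_depth,
        min_alt=config.min_alt,
        n_input=info["n_input"],
    )
    state["filter_result"] = res
    return {
        "merge": info,
        "trace": list(res.trace.as_tuple()),
        "n_survivors": len(res.survivors),
    }


def _stage_enrich(config: RunConfig, state: dict, outdir: Path) -> dict:
    res = state["filter_result"]
    panel = set(state["candidates"])
    overlap, k = variants.candidate_intersection(res.survivors, res.annotations, panel)
    mutated = {res.annotations[r.key].gene_id for r in res.survivors
               if res.annotations[r.key].gene_id}
    inp = stats.EnrichmentInput(N=config.universe, K=len(mutated), n=len(panel), k=k)
    exact = stats.hypergeom_upper_tail(inp)
    out = {
        "overlap_genes": sorted(overlap),
        "k": k,
        "K_mutated_genes": len(mutated),
        "n_panel": len(panel),
        "N_universe": config.universe,
        "p_upper": exact.p_upper,
        "expected_overlap": exact.expected_overlap,
    }
    (outdir / "enrichment.json").write_text(json.dumps(out, indent=1, sort_keys=True))
    return out


def _stage_diststats(config: RunConfig, state: dict, outdir: Path) -> dict:
    cells = state["sim"]["cells"]
    fracs = stats.bin_fractions(cells)
    comp = stats.compare_conditions(fracs, control=config.control_condition)
    comp.to_csv(outdir / "distribution_stats.tsv", sep="\t", index=False)
    return {
        "n_animals": len(fracs),
        "comparisons": comp.to_dict(orient="records"),
    }
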