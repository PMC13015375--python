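"""End-to-end orchestration: panel -> blocks -> components -> cores.

Stages communicate only through TSV files in the output directory, so any
stage can be replayed from disk; outputs carry no timestamps and every
tie-break upstream is deterministic, making re-runs byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
from collections import Counter
from pathlib import Path

from . import blocks as blocks_mod
from .cores import SweepStats, find_block_core
from .local_cores import build_core_graph, enumerate_local_cores
from .overlap import build_overlap_graph, connected_components
from .panel import attach_genetic_map, read_genetic_map, read_panel
from .pbwt import build_pbwt


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration.

    Thresholds: (L_block, W_block) define blocks, (L_overlap, W_overlap)
    define overlap-graph edges, and (min_core_length, min_core_width)
    constrain cores; each length threshold carries its own unit.  'cm'
    units require a genetic map.
    """

    panel: str
    panel_format: str = "auto"
    genetic_map: str | None = None
    blocks: str | None = None  # precomputed block TSV; skips block finding
    L_block: float = 3.0
    W_block: int = 2
    unit_block: str = "sites"
    L_overlap: float = 1.0
    W_overlap: int = 1
    unit_overlap: str = "sites"
    min_core_length: float | None = None
    unit_core: str = "sites"
    min_core_width: int = 1
    local_cores: bool = True
    outdir: str = "hapcores_out"
    verbosity: int = 1

    def validate(self) -> None:
        for name in ("L_block", "L_overlap"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.W_block < 2:
            raise ConfigError("W_block must be >= 2")
        if self.W_overlap < 1 or self.min_core_width < 1:
            raise ConfigError("width thresholds must be >= 1")
        if self.min_core_length is not None and self.min_core_length <= 0:
            raise ConfigError("min_core_length must be positive")
        for name in ("unit_block", "unit_overlap", "unit_core"):
            if getattr(self, name) not in ("sites", "bp", "cm"):
                raise ConfigError(f"{name} must be one of sites/bp/cm")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "panel" not in data:
            raise ConfigError("config must set 'panel'")
        return cls(**data)


def _write_components(comps, path) -> None:
    with open(path, "w") as fh:
        fh.write("#component_id\tblock_ids\n")
        for i, comp in enumerate(comps):
            fh.write(f"{i}\t{','.join(map(str, comp.block_ids))}\n")


def _core_row(panel, core) -> list[str]:
    hap_ids = ",".join(panel.sample_ids[h] for h in sorted(core.H_star))
    fields = [
        str(core.size),
        str(core.S_star),
        str(core.E_star),
        str(int(panel.site_bp[core.S_star])),
        str(int(panel.site_bp[core.E_star - 1])),
    ]
    if panel.site_cm is not None:
        fields += [
            format(panel.site_cm[core.S_star], "g"),
            format(panel.site_cm[core.E_star - 1], "g"),
        ]
    else:
        fields += ["NA", "NA"]
    fields += [
        str(len(core.H_star)),
        ",".join(map(str, sorted(core.member_blocks))),
        hap_ids,
    ]
    return fields


_CORE_HEADER = (
    "#component_id\tcore_size\tstart_site\tend_site\tstart_bp\tend_bp"
    "\tstart_cm\tend_cm\tn_haplotypes\tblock_ids\thaplotype_ids\n"
)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline, writing TSVs and a JSON report.

    Returns the report dict.  On a stage failure the exception propagates
    after a MANIFEST naming the failed stage is written; outputs of earlier
    stages are retained.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": dataclasses.asdict(config), "stages": {}}
    stage = "load_panel"
    try:
        panel = read_panel(config.panel, format=config.panel_format)
        if config.genetic_map is not None:
            panel = attach_genetic_map(panel, read_genetic_map(config.genetic_map))
        if "cm" in (config.unit_block, config.unit_overlap, config.unit_core):
            if panel.site_cm is None:
                raise ConfigError("a 'cm' threshold requires a genetic map")
        report["stages"]["load_panel"] = {"M": panel.M, "N": panel.N}

        stage = "pbwt"
        index = build_pbwt(panel)

        stage = "blocks"
        if config.blocks is not None:
            blockset = blocks_mod.read_blocks(config.blocks)
        else:
            blockset = blocks_mod.find_width_maximal_blocks(
                panel,
                index,
                L=config.L_block,
                unit=config.unit_block,
                W=config.W_block,
            )
        blocks_mod.write_blocks(blockset, outdir / "blocks.tsv", panel)
        report["stages"]["blocks"] = {"n_blocks": len(blockset)}

        stage = "components"
        graph = build_overlap_graph(
            blockset,
            L=config.L_overlap,
            W=config.W_overlap,
            panel=panel,
            unit=config.unit_overlap,
        )
        comps = connected_components(graph)
        _write_components(comps, outdir / "components.tsv")
        report["stages"]["components"] = {
            "n_components": len(comps),
            "n_edges": graph.n_edges,
        }

        stage = "cores"
        stats_total = SweepStats()
        cores = []
        for comp in comps:
            core, stats = find_block_core(
                comp,
                blockset,
                index,
                min_core_length=config.min_core_length,
                unit=config.unit_core,
                min_core_width=config.min_core_width,
                panel=panel,
                with_stats=True,
            )
            cores.append(core)
            stats_total.events += stats.events
            stats_total.end_events += stats.end_events
            stats_total.max_active = max(stats_total.max_active, stats.max_active)
            stats_total.max_runs = max(stats_total.max_runs, stats.max_runs)
        with open(outdir / "cores.tsv", "w") as fh:
            fh.write(_CORE_HEADER)
            for i, core in enumerate(cores):
                if core.size == 0:
                    continue
                fh.write("\t".join([str(i)] + _core_row(panel, core)) + "\n")
        sizes = [c.size for c in cores if c.size > 0]
        report["stages"]["cores"] = {
            "n_cores": len(sizes),
            "max_core_size": max(sizes, default=0),
            "mean_core_size": (sum(sizes) / len(sizes)) if sizes else 0.0,
            "core_size_histogram": {
                str(k): v for k, v in sorted(Counter(sizes).items())
            },
            "sweep": dataclasses.asdict(stats_total),
        }

        if config.local_cores:
            stage = "local_cores"
            all_local = []
            with open(outdir / "local_cores.tsv", "w") as fh:
                fh.write("#core_id\tcomponent_id" + _CORE_HEADER[len("#component_id") :])
                cid = 0
                for comp_id, comp in enumerate(comps):
                    lcs = enumerate_local_cores(
                        comp,
                        blockset,
                        index,
                        min_core_length=config.min_core_length,
                        unit=config.unit_core,
                        panel=panel,
                    )
                    for lc in lcs:
                        fh.write(
                            "\t".join([str(cid), str(comp_id)] + _core_row(panel, lc))
                            + "\n"
                        )
                        cid += 1
                    all_local.extend(lcs)
            core_graph = build_core_graph(all_local, blockset)
            with open(outdir / "core_graph.tsv", "w") as fh:
                fh.write("#core_i\tcore_j\tshared_blocks\tiou_w\tiou_l\n")
                for edge in core_graph.edges:
                    fh.write(
                        f"{edge.core_i}\t{edge.core_j}\t{edge.shared_blocks}"
                        f"\t{edge.iou_w:.6g}\t{edge.iou_l:.6g}\n"
                    )
            lsizes = [lc.size for lc in all_local]
            report["stages"]["local_cores"] = {
                "n_local_cores": len(all_local),
                "mean_local_core_size": (sum(lsizes) / len(lsizes)) if lsizes else 0.0,
                "n_core_graph_edges": len(core_graph.edges),
            }
    except Exception as exc:
        with open(outdir / "MANIFEST", "w") as fh:
            fh.write(f"FAILED at stage: {stage}\nerror: {exc}\n")
        raise
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
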