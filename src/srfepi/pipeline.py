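"""End-to-end orchestration: simulate inputs, run every stage, emit a report.

A run is fully determined by its configuration (seed included): the manifest
records the configuration hash, seeds and package version, and a stage's
outputs are reused on rerun only when the recorded hash still matches.  The
report cross-links the classified SRF-dependent genes with their promoter
CArG sites and ChIP binding calls, mirroring how expression tiers, motif
scanning and ChIP validation feed one another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from . import cargscan, eeg, expression, qpcr, simdata

log = logging.getLogger("srfepi.pipeline")


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "srfepi_run"
    stages: dict = field(
        default_factory=lambda: {
            "expression": True,
            "promoters": True,
            "eeg": True,
            "qpcr": True,
        }
    )
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    thresholds: dict = field(default_factory=dict)  # ClassificationThresholds overrides
    #: per-group EEG overrides (rate, duration mean/sd, latency)
    eeg_groups: dict = field(
        default_factory=lambda: {
            "KO": {"seizure_rate_per_day": 3.13, "seizure_duration_mean": 35.7},
            "CTR": {"seizure_rate_per_day": 0.81, "seizure_duration_mean": 30.0},
        }
    )
    detection: dict = field(
        default_factory=lambda: {"threshold_ratio": 2.0, "min_duration": 5.0, "merge_gap": 1.0}
    )
    chip_threshold: float = 2.0
    qpcr_case: str = "CTR_KA"
    qpcr_control: str = "CTR_saline"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sim_config(config: RunConfig, **overrides) -> simdata.SimConfig:
    kwargs: dict[str, Any] = {"seed": config.seed}
    kwargs.update(config.sim)
    kwargs.update(overrides)
    return simdata.SimConfig(**kwargs)


def _stage_cached(stage_dir: Path, cfg_hash: str) -> bool:
    marker = stage_dir / ".done.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("config_hash") == cfg_hash
    except json.JSONDecodeError:
        return False


def _finish_stage(stage_dir: Path, cfg_hash: str, summary: Mapping) -> None:
    (stage_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
    (stage_dir / ".done.json").write_text(json.dumps({"config_hash": cfg_hash}))


def _load_summary(stage_dir: Path) -> dict:
    return json.loads((stage_dir / "summary.json").read_text())


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    report: dict[str, Any] = {}
    srf_genes: list[str] = []
    panel: list[str] = []

    if config.stages.get("expression", True):
        stage = out / "expression"
        stage.mkdir(exist_ok=True)
        if _stage_cached(stage, cfg_hash):
            log.info("expression: reusing cached outputs")
            summary = _load_summary(stage)
        else:
            log.info("expression: simulate + classify")
            try:
                sim = simdata.simulate_expression(_sim_config(config))
                normalized = expression.quantile_normalize(sim.matrix)
                logged = expression.log2_transform(normalized)
                stats = expression.fit_two_way_anova(logged, sim.sample_sheet)
                th = expression.ClassificationThresholds(**config.thresholds)
                cls = expression.classify(stats, sim.probe_gene_map, th)
                tiers = expression.tier_report(cls)
            except Exception:
                log.exception("stage 'expression' failed")
                raise
            expression.write_matrix_tsv(sim.matrix, stage / "matrix.tsv")
            sim.sample_sheet.to_csv(stage / "samples.tsv", sep="\t", index=False)
            sim.truth.to_csv(stage / "truth.tsv", sep="\t")
            stats.to_csv(stage / "probe_stats.tsv", sep="\t")
            cls.probes.to_csv(stage / "classification_probes.tsv", sep="\t")
            cls.genes.to_csv(stage / "classification_genes.tsv", sep="\t")
            up = cls.genes.index[cls.genes["srf_dependent_up"]].tolist()
            down = cls.genes.index[cls.genes["srf_dependent_down"]].tolist()
            summary = {"tiers": tiers, "srf_dependent_up": up, "srf_dependent_down": down}
            _finish_stage(stage, cfg_hash, summary)
        report["expression"] = summary["tiers"]
        srf_genes = summary["srf_dependent_up"] + summary["srf_dependent_down"]

    if config.stages.get("promoters", True):
        stage = out / "promoters"
        stage.mkdir(exist_ok=True)
        sim_cfg = _sim_config(config)
        if _stage_cached(stage, cfg_hash):
            log.info("promoters: reusing cached outputs")
            summary = _load_summary(stage)
        else:
            log.info("promoters: simulate + scan")
            try:
                panel_genes = (
                    sorted(srf_genes)[: sim_cfg.promoter_count] if srf_genes else None
                )
                psim = simdata.simulate_promoters(sim_cfg, gene_ids=panel_genes)
                hits = []
                for rec in psim.records:
                    hits.extend(cargscan.scan_promoter(rec))
                hits = cargscan.flag_conserved(hits, psim.blocks)
                summary_df = cargscan.summarize_genes(
                    hits, gene_ids=[r.gene_id for r in psim.records]
                )
            except Exception:
                log.exception("stage 'promoters' failed")
                raise
            cargscan.write_promoters(psim.records, stage / "promoters.fa")
            by_gene = {r.gene_id: r for r in psim.records}
            cargscan.write_blocks_bed(psim.blocks, by_gene, stage / "blocks.bed")
            psim.truth.to_csv(stage / "truth_sites.tsv", sep="\t", index=False)
            cargscan.hits_to_frame(hits).to_csv(stage / "hits.tsv", sep="\t", index=False)
            summary_df.to_csv(stage / "gene_summary.tsv", sep="\t", index=False)
            summary = {
                "n_hits": len(hits),
                "genes": summary_df.to_dict(orient="records"),
            }
            _finish_stage(stage, cfg_hash, summary)
        report["promoters"] = {"n_hits": summary["n_hits"]}
        report["promoter_genes"] = summary["genes"]

    if config.stages.get("eeg", True):
        stage = out / "eeg"
        stage.mkdir(exist_ok=True)
        if _stage_cached(stage, cfg_hash):
            log.info("eeg: reusing cached outputs")
            summary = _load_summary(stage)
        else:
            log.info("eeg: simulate + detect")
            try:
                summaries = []
                for group, overrides in config.eeg_groups.items():
                    sim_cfg = _sim_config(config, **overrides)
                    esim = simdata.simulate_eeg(sim_cfg, group=group)
                    for rec in esim.recordings:
                        events = eeg.detect_seizures(rec, **config.detection)
                        summaries.append(
                            eeg.summarize_animal(
                                events,
                                recording_days=sim_cfg.eeg_days,
                                animal_id=rec.animal_id,
                                group=group,
                            )
                        )
                comparisons = []
                for metric, test in (
                    ("frequency", "mann_whitney"),
                    ("duration", "t"),
                    ("latency", "t"),
                ):
                    try:
                        comparisons.append(eeg.compare_groups(summaries, metric, test=test))
                    except ValueError as exc:  # too few animals with events
                        comparisons.append(
                            {"metric": metric, "test": test, "skipped": str(exc)}
                        )
            except Exception:
                log.exception("stage 'eeg' failed")
                raise
            per_animal = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
            per_animal.to_csv(stage / "animal_summaries.tsv", sep="\t", index=False)
            summary = {
                "animals": per_animal.to_dict(orient="records"),
                "comparisons": comparisons,
            }
            _finish_stage(stage, cfg_hash, summary)
        report["eeg"] = {
            "group_means": _group_means(summary["animals"]),
            "comparisons": summary["comparisons"],
        }

    if config.stages.get("qpcr", True):
        stage = out / "qpcr"
        stage.mkdir(exist_ok=True)
        if _stage_cached(stage, cfg_hash):
            log.info("qpcr: reusing cached outputs")
            summary = _load_summary(stage)
        else:
            log.info("qpcr: simulate + quantify")
            try:
                csim = simdata.simulate_ct_tables(_sim_config(config))
                folds = qpcr.ddct_fold_change(
                    csim.ct_table, config.qpcr_case, config.qpcr_control
                )
                calls = qpcr.call_binding(csim.chip_table, threshold=config.chip_threshold)
            except Exception:
                log.exception("stage 'qpcr' failed")
                raise
            csim.ct_table.to_csv(stage / "ct_table.tsv", sep="\t", index=False)
            csim.chip_table.to_csv(stage / "chip_table.tsv", sep="\t", index=False)
            folds.to_frame().to_csv(stage / "fold_changes.tsv", sep="\t")
            calls.to_csv(stage / "binding_calls.tsv", sep="\t", index=False)
            summary = {
                "fold_changes": folds.to_dict(),
                "binding_calls": calls.to_dict(orient="records"),
            }
            _finish_stage(stage, cfg_hash, summary)
        report["qpcr"] = summary

    report["srf_dependent_cross_links"] = _cross_link(report, srf_genes)
    manifest = {
        "config_hash": cfg_hash,
        "seed": config.seed,
        "version": __version__,
        "stages": [s for s, on in config.stages.items() if on],
        "config": dataclasses.asdict(config),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report


def _group_means(animals: list[dict]) -> dict:
    df = pd.DataFrame(animals)
    out = {}
    for group, sub in df.groupby("group"):
        out[group] = {
            "frequency_per_day": float(sub["frequency_per_day"].mean()),
            "mean_duration_s": float(sub["mean_duration_s"].dropna().mean()),
            "latency_first_spontaneous_h": float(
                sub["latency_first_spontaneous_h"].dropna().mean()
            ),
        }
    return out


def _cross_link(report: dict, srf_genes: list[str]) -> list[dict]:
    """Join classified SRF-dependent genes to motif and binding evidence."""
    sites = {
        row["gene_id"]: row for row in report.get("promoter_genes", [])
    }
    bound = {
        row["amplicon_id"]: row
        for row in report.get("qpcr", {}).get("binding_calls", [])
    }
    links = []
    for gene in sorted(srf_genes):
        site = sites.get(gene)
        call = bound.get(gene)
        links.append(
            {
                "gene_id": gene,
                "n_conserved_sites": None if site is None else site["n_conserved_sites"],
                "passes_min_sites": None if site is None else bool(site["passes_min_sites"]),
                "srf_bound": None if call is None else bool(call["bound"]),
            }
        )
    return links
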