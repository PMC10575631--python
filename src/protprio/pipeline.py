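"""End-to-end pipeline: ingest -> normalize -> differential abundance ->
absolute GSEA -> frequency prioritization -> reporting data products.

A single :class:`PipelineConfig` drives the run. All randomness flows from
one root seed through named per-stage substreams, so any stage can be
re-run independently yet reproducibly, and two runs with the same config
are identical. The run manifest (written last, as the completion marker)
records the config snapshot, per-stage row counts, the chosen ROTS
statistic per contrast, and timestamps.
"""

from __future__ import annotations

import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .containers import SimTruth, StudyDesign, ValidationError
from .genesets import GeneSetCollection, read_gmt, write_gmt
from .gsea import build_ranked_list, enrich_collection
from .normalize import aggregate_proteins, glog_normalize, variation_filter
from .prioritize import (
    disease_frequency,
    filter_cascade,
    frequency_table,
    term_overrepresentation,
)
from .report import pca_scores, reproducibility_plot_data, volcano_data, ward_clustering
from .rots import RotsParams, run_differential
from .simulate import SimConfig, simulate_counts, simulate_genesets

__version__ = "0.1.0"


def stage_seed(root_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic per-stage child seed derived from the root seed."""
    h = np.random.SeedSequence(
        [root_seed, zlib.crc32(stage.encode()) % (2**31), index]
    ).generate_state(1)[0]
    return int(h % (2**31))


@dataclass
class Thresholds:
    min_peptides: int = 2
    min_detected_samples: int = 4
    p_cut: float = 0.05
    fdr_cut: float = 0.25
    percentile: float = 90.0
    fc_cut: float = 3.0
    spectra_cut: int = 10
    weight_p: float = 1.0
    gsea_min_overlap: int = 3
    B: int = 500
    P: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.p_cut < 1 or not 0 <= self.fdr_cut <= 1:
            raise ValidationError("p_cut must be in (0,1) and fdr_cut in [0,1]")
        if not 0 < self.percentile < 100:
            raise ValidationError("percentile must lie in (0, 100)")
        if self.fc_cut < 1 or self.spectra_cut < 0:
            raise ValidationError("fc_cut must be >= 1 and spectra_cut >= 0")
        if self.min_peptides < 1 or self.min_detected_samples < 1:
            raise ValidationError("min_peptides and min_detected_samples must be >= 1")


@dataclass
class InputPaths:
    counts: str | None = None
    peptides: str | None = None
    design: str | None = None
    genesets: list[str] = field(default_factory=list)
    disease_libraries: list[str] = field(default_factory=list)


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    simulate: SimConfig | None = None
    inputs: InputPaths | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValidationError(
                "config must contain exactly one of a 'simulate' or an 'inputs' block"
            )
        if self.inputs is not None:
            if (self.inputs.counts is None) == (self.inputs.peptides is None):
                raise ValidationError("inputs need exactly one of counts/peptides")
            if self.inputs.design is None:
                raise ValidationError("inputs.design is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim = SimConfig(**raw["simulate"]) if "simulate" in raw else None
        if sim is not None and "seed" in raw and "seed" not in raw["simulate"]:
            sim = replace(sim, seed=stage_seed(raw["seed"], "simulate"))
        inputs = InputPaths(**raw["inputs"]) if "inputs" in raw else None
        thr = Thresholds(**raw.get("thresholds", {}))
        return cls(
            outdir=raw["outdir"],
            seed=int(raw.get("seed", 0)),
            simulate=sim,
            inputs=inputs,
            thresholds=thr,
        )


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    stage_counts: dict
    rots_choice: dict
    started: str
    finished: str = ""

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "seed": self.seed,
            "stage_counts": self.stage_counts,
            "rots_choice": self.rots_choice,
            "started": self.started,
            "finished": self.finished,
        }


def _log(stage: str, t0: float, **counts) -> None:
    msg = " ".join(f"{k}={v}" for k, v in counts.items())
    print(f"[protprio] {stage}: {msg} elapsed={time.perf_counter() - t0:.1f}s")


def _simulated_disease_libraries(
    cfg: SimConfig, truth: SimTruth, protein_ids: list[str]
) -> list[GeneSetCollection]:
    """Two small synthetic disease-annotation libraries over the universe.

    Terms are drawn like gene sets, with a planted share biased toward the
    differential proteins so the disease-frequency stage has recoverable
    signal; names mimic external library labels but are synthetic.
    """
    libs = []
    for i, label in enumerate(("synthetic_disease_A", "synthetic_disease_B")):
        sub_cfg = replace(
            cfg,
            n_sets=40,
            set_size_range=(10, min(40, len(protein_ids))),
            planted_set_fraction=0.25,
            seed=cfg.seed + 101 + i,
        )
        sub_truth = SimTruth(de_proteins=set(truth.de_proteins))
        lib = simulate_genesets(protein_ids, sub_cfg, sub_truth)
        lib.label = label
        libs.append(lib)
    return libs


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order and write all data products.

    Any stage failure raises with the stage name in the message. Returns
    the manifest (also written as ``manifest.json``, last).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    stage_counts: dict = {}
    rots_choice: dict = {}
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    t0 = time.perf_counter()
    truth: SimTruth | None = None

    # --- ingest ---------------------------------------------------------
    try:
        if config.simulate is not None:
            counts, design, truth = simulate_counts(config.simulate)
            collections = [simulate_genesets(list(counts.index), config.simulate, truth)]
            disease_libs = _simulated_disease_libraries(
                config.simulate, truth, list(counts.index)
            )
            io.write_matrix(counts, out / "counts.tsv")
            io.write_design(design, out / "design.tsv")
            write_gmt(collections[0], out / "genesets_simulated.gmt")
            for lib in disease_libs:
                write_gmt(lib, out / f"library_{lib.label}.gmt")
            io.write_json(truth.to_dict(), out / "truth.json")
        else:
            inp = config.inputs
            design = io.read_design(inp.design)
            if inp.peptides is not None:
                evidence = io.read_peptide_table(inp.peptides)
                counts = aggregate_proteins(evidence, thr.min_peptides)
                stage_counts["peptide_rows"] = int(len(evidence))
            else:
                counts = io.read_count_matrix(inp.counts)
            collections = [read_gmt(p) for p in inp.genesets]
            disease_libs = [read_gmt(p) for p in inp.disease_libraries]
        design.check_matrix(counts)
        stage_counts["proteins_ingested"] = int(counts.shape[0])
        stage_counts["samples"] = int(counts.shape[1])
        _log("ingest", t0, proteins=counts.shape[0], samples=counts.shape[1])
    except Exception as e:
        raise ValidationError(f"stage ingest failed: {e}") from e

    # --- normalize ------------------------------------------------------
    try:
        filtered = variation_filter(counts, thr.min_detected_samples)
        normalized = glog_normalize(filtered)
        stage_counts["proteins_after_detection_filter"] = int(filtered.shape[0])
        io.write_matrix(filtered, out / "filtered_counts.tsv")
        io.write_matrix(normalized.values, out / "normalized.tsv")
        io.write_json(normalized.transform_params, out / "transform_params.json")
        _log("normalize", t0, proteins=filtered.shape[0])
    except Exception as e:
        raise ValidationError(f"stage normalize failed: {e}") from e

    # --- QC data products ----------------------------------------------
    scores, explained = pca_scores(normalized.values)
    scores["explained_fraction"] = list(explained) + [np.nan] * (
        len(scores) - len(explained)
    )
    io.write_table(scores.reset_index(names="sample"), out / "pca_scores.tsv")
    _link, sample_order = ward_clustering(normalized.values, axis="samples")
    _linkp, protein_order = ward_clustering(normalized.values, axis="proteins")
    io.write_json(
        {"sample_order": sample_order, "protein_order": protein_order},
        out / "cluster_orders.json",
    )

    # --- differential abundance + GSEA per contrast ---------------------
    freq_inputs = []
    de_tables: dict[str, pd.DataFrame] = {}
    for ci, contrast in enumerate(design.contrasts):
        label = f"{contrast[0]}_vs_{contrast[1]}"
        try:
            params = RotsParams(
                B=thr.B, P=thr.P, seed=stage_seed(config.seed, "rots", ci)
            )
            run = run_differential(
                normalized.values, design, params, contrast=contrast,
                counts=filtered, p_cut=thr.p_cut, fdr_cut=thr.fdr_cut,
            )
            de_tables[label] = run.table
            rots_choice[label] = {
                "alpha1": run.optimum.alpha1,
                "alpha2": run.optimum.alpha2,
                "k": run.optimum.k,
                "z": run.optimum.z,
            }
            stage_counts[f"de_selected_{label}"] = int(run.table["selected"].sum())
            io.write_table(
                run.table.reset_index(names="protein_id"), out / f"de_{label}.tsv"
            )
            io.write_table(
                volcano_data(run.table).reset_index(names="protein_id"),
                out / f"volcano_{label}.tsv",
            )
            io.write_table(
                reproducibility_plot_data(run.optimum), out / f"reproducibility_{label}.tsv"
            )
            _log("de", t0, contrast=label, selected=int(run.table["selected"].sum()))
        except Exception as e:
            raise ValidationError(f"stage de ({label}) failed: {e}") from e

        try:
            ranked = build_ranked_list(
                run.table, tie_seed=stage_seed(config.seed, "ranking", ci)
            )
            for gi, coll in enumerate(collections):
                enr = enrich_collection(
                    ranked, coll, P=thr.P,
                    seed=stage_seed(config.seed, "gsea", ci * 1000 + gi),
                    weight_p=thr.weight_p, min_overlap=thr.gsea_min_overlap,
                    p_cut=thr.p_cut,
                )
                freq_inputs.append(enr)
                tag = coll.label or f"collection{gi}"
                stage_counts[f"enriched_{label}_{tag}"] = int(enr["significant"].sum())
                io.write_table(enr, out / f"enrichment_{label}_{tag}.tsv")
            _log("gsea", t0, contrast=label, collections=len(collections))
        except Exception as e:
            raise ValidationError(f"stage gsea ({label}) failed: {e}") from e

    # --- prioritize ------------------------------------------------------
    try:
        freq = frequency_table(freq_inputs)
        stage_counts["proteins_in_frequency_table"] = int(len(freq))
        if len(freq) == 0:
            raise ValidationError("no significant pathways; frequency table empty")
        # pool fold change / spectra over contrasts: largest |fc|, total spectra
        fc_pool = pd.concat(
            [t["fold_change"] for t in de_tables.values()], axis=1
        )
        fc = fc_pool.apply(lambda row: row.loc[row.abs().idxmax()], axis=1)
        spectra = filtered.sum(axis=1)
        cand_table = filter_cascade(
            freq, fc, spectra,
            percentile=thr.percentile, fc_cut=thr.fc_cut, spectra_cut=thr.spectra_cut,
        )
        candidates = set(cand_table.index[cand_table["candidate"]])
        io.write_table(
            freq.rename_axis("protein_id").reset_index(), out / "frequency.tsv"
        )
        io.write_table(
            cand_table.reset_index(), out / "candidates.tsv"
        )
        stage_counts["proteins_top_percentile"] = int(
            cand_table["passed_percentile"].sum()
        )
        stage_counts["candidates_final"] = int(len(candidates))
        _log("prioritize", t0, candidates=len(candidates))
    except Exception as e:
        raise ValidationError(f"stage prioritize failed: {e}") from e

    # --- disease over-representation ------------------------------------
    try:
        disease_rows = None
        if disease_libs and candidates:
            universe = set(filtered.index)
            tables = [
                term_overrepresentation(candidates, lib, universe, p_cut=thr.p_cut)
                for lib in disease_libs
            ]
            for lib, tab in zip(disease_libs, tables):
                io.write_table(tab, out / f"overrep_{lib.label}.tsv")
            disease_rows = disease_frequency(candidates, disease_libs, tables)
            io.write_table(disease_rows, out / "disease_frequency.tsv")
            stage_counts["candidates_clinically_related"] = int(
                disease_rows["clinically_related"].sum()
            )
        _log("disease", t0, libraries=len(disease_libs))
    except Exception as e:
        raise ValidationError(f"stage disease failed: {e}") from e

    summary = {
        "candidates": sorted(candidates),
        "n_candidates": len(candidates),
        "up": sorted(cand_table.index[cand_table["candidate"] & (cand_table["direction"] == "up")]),
        "down": sorted(cand_table.index[cand_table["candidate"] & (cand_table["direction"] == "down")]),
    }
    if truth is not None:
        summary["n_planted_de"] = len(truth.de_proteins)
        summary["candidates_planted"] = len(candidates & truth.de_proteins)
    io.write_json(summary, out / "summary.json")

    manifest = RunManifest(
        config={"outdir": str(config.outdir), "seed": config.seed,
                "thresholds": vars(thr),
                "simulate": (vars(config.simulate) if config.simulate else None),
                "inputs": (vars(config.inputs) if config.inputs else None)},
        version=__version__,
        seed=config.seed,
        stage_counts=stage_counts,
        rots_choice=rots_choice,
        started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    io.write_json(manifest.to_dict(), out / "manifest.json")
    return manifest
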