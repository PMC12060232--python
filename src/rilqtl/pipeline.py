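"""End-to-end pipeline driver: scan -> peaks -> epistasis -> meta.

``run_pipeline`` executes the full analysis for one or more traits from
files on disk and writes every stage's output plus a manifest (versions,
seeds, input checksums, stage timings) sufficient to rerun the analysis.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import ConfigurationError
from .epistasis import interaction_null, interaction_p, interaction_scan
from .io import (
    read_ancestry_matrix,
    read_phenotypes,
    read_window_map,
    write_null,
    write_qtl_calls,
    write_scan_table,
)
from .meta import fisher_combined, median_removal_count
from .scan import call_qtl_peaks, genomewide_p, permutation_null, scan_additive
from .windows import flag_skewed

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    matrix_path: str
    window_map_path: str
    phenotype_path: str
    out_dir: str
    traits: list = field(default_factory=list)  # empty = all non-ril columns
    n_perm: int = 10_000
    n_perm_epistasis: int = 10_000
    alpha: float = 0.10
    lod_drop: float = 1.5
    min_sep_cM: float = 10.0
    skew_threshold: float = 0.9
    seed: int = 0
    run_epistasis: bool = True
    run_meta: bool = True

    def validate(self) -> None:
        for p in (self.matrix_path, self.window_map_path, self.phenotype_path):
            if not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")
        if self.n_perm < 1 or self.n_perm_epistasis < 1:
            raise ConfigurationError("permutation counts must be >= 1")


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run scan, peak calling, per-QTL epistasis and meta-analysis.

    Returns the manifest dict (also written to ``<out_dir>/manifest.json``).
    Stage failures raise with a stage-scoped message; outputs written
    before the failure are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "rilqtl_version": __version__,
        "numpy_version": np.__version__,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "n_perm_epistasis": config.n_perm_epistasis,
        "alpha": config.alpha,
        "lod_drop": config.lod_drop,
        "min_sep_cM": config.min_sep_cM,
        "skew_threshold": config.skew_threshold,
        "inputs": {
            "matrix": {"path": config.matrix_path, "sha256": _sha256(config.matrix_path)},
            "window_map": {
                "path": config.window_map_path,
                "sha256": _sha256(config.window_map_path),
            },
            "phenotypes": {
                "path": config.phenotype_path,
                "sha256": _sha256(config.phenotype_path),
            },
        },
        "traits": {},
        "timings_s": {},
    }

    t0 = time.perf_counter()
    matrix = read_ancestry_matrix(config.matrix_path)
    wmap = read_window_map(config.window_map_path)
    pheno = read_phenotypes(config.phenotype_path)
    if "ril" not in pheno.columns:
        raise ConfigurationError("phenotype table must have a 'ril' column")
    pheno = pheno.set_index("ril")
    traits = config.traits or [c for c in pheno.columns if c != "env"]
    manifest["timings_s"]["load"] = time.perf_counter() - t0

    summary = flag_skewed(matrix, threshold=config.skew_threshold)
    summary.to_csv(out / "window_summary.tsv", sep="\t", index=False)
    logger.info(
        "windows: %d total, %d excluded for skew",
        len(summary),
        int(summary["skew_excluded"].sum()),
    )

    all_interaction = []
    for ti, trait in enumerate(traits):
        t0 = time.perf_counter()
        y = pheno[trait].reindex(matrix.rils).to_numpy(dtype=float)
        scan = scan_additive(matrix, y, summary)
        null = permutation_null(
            matrix, y, summary, n_perm=config.n_perm, seed=config.seed + ti
        )
        scan = genomewide_p(scan, null)
        write_scan_table(scan, wmap, out / f"scan_{trait}.tsv")
        write_null(null, out / f"null_{trait}.tsv")
        calls = call_qtl_peaks(
            scan,
            wmap,
            alpha=config.alpha,
            lod_drop=config.lod_drop,
            min_sep_cM=config.min_sep_cM,
        )
        write_qtl_calls(
            calls, out / f"qtls_{trait}.tsv", out / f"qtls_{trait}.json"
        )
        trait_entry = {
            "n_qtls": len(calls),
            "qtls": [c.to_dict() for c in calls],
            "null_seed": config.seed + ti,
            "epistasis": [],
        }
        manifest["timings_s"][f"scan_{trait}"] = time.perf_counter() - t0

        if config.run_epistasis and calls:
            t0 = time.perf_counter()
            for qi, call in enumerate(calls):
                escan = interaction_scan(matrix, y, call, summary)
                enull = interaction_null(
                    matrix,
                    y,
                    call,
                    summary,
                    n_perm=config.n_perm_epistasis,
                    seed=config.seed + 1000 * (ti + 1) + qi,
                )
                p = interaction_p(escan, enull)
                escan.to_frame().to_csv(
                    out / f"epistasis_{trait}_{call.peak_window}.tsv",
                    sep="\t",
                    index=False,
                )
                rec = {
                    "focal": str(call.peak_window),
                    "max_interaction_lod": escan.max_lod,
                    "max_partner": str(escan.max_partner),
                    "p": p,
                }
                trait_entry["epistasis"].append(rec)
                all_interaction.append({"trait": trait, **rec})
            manifest["timings_s"][f"epistasis_{trait}"] = time.perf_counter() - t0
        manifest["traits"][trait] = trait_entry

    if config.run_meta and all_interaction:
        ps = [r["p"] for r in all_interaction]
        fisher = fisher_combined(ps, n_perm=config.n_perm_epistasis)
        med = median_removal_count(ps)
        manifest["meta"] = {
            "k": fisher.k,
            "fisher_statistic": fisher.statistic,
            "fisher_df": fisher.df,
            "fisher_p": fisher.p,
            "min_p": float(min(ps)),
            "median_removal_m": med.m,
            "median_trajectory": list(med.trajectory),
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
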