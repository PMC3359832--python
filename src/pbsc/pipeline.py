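"""End-to-end orchestration: preprocess, rank, gate, score, report.

For each patient pair the pipeline computes the differential ranking and
tag signature, selects treatment-affected pathways, scores every bank
instance in every selected pathway with the signed KS statistic plus a
permutation p-value, counts significantly positive/negative pathways per
instance, and writes a top-k report. A JSON manifest records the config
hash, seed and per-stage counts; identical config + seed reproduce every
output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pbsc_io
from .connectivity import PermutationNullCache, pathway_connectivity
from .containers import ExpressionMatrix, PathwayCollection, ReferenceBank
from .differential import paired_log2fc, tag_signature
from .enrichment import (
    hypergeometric_enrichment,
    ks_permutation_enrichment,
    select_pathways,
)
from .preprocessing import PreprocessConfig, preprocess
from .ranking import count_pathways, shared_hits_report, top_k_report

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PatientResult", "analyze_patient", "run_pbsc", "validate_inputs"]


@dataclass
class RunConfig:
    expression: str = ""
    pairs: str = ""
    gmt: str = ""
    bank: str = ""
    out_dir: str = "pbsc_out"
    preprocess: dict = field(default_factory=dict)
    fold_threshold: float = 2.0
    enrichment_mode: str = "ks_permutation"  # or "hypergeometric"
    enrichment_alpha: float = 0.05
    enrichment_fdr: bool = False
    n_perm: int = 1000
    seed: int = 0
    connectivity_mode: str = "combined"  # or "single_set"
    halve_combined: bool = True
    count_alpha: float = 0.05
    min_abs_score: float = 0.0
    rank_by: str = "total"
    k: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PatientResult:
    patient_id: str
    ranking: pd.DataFrame
    up_genes: list[str]
    down_genes: list[str]
    enrichment: pd.DataFrame
    selected_pathways: list[str]
    cells: pd.DataFrame
    report: pd.DataFrame
    status: str  # "ok" | "no pathways selected" | "empty tag signature"
    counts: dict


def analyze_patient(
    expr: ExpressionMatrix,
    patient: str,
    pathways: PathwayCollection,
    bank: ReferenceBank,
    cfg: RunConfig,
) -> PatientResult:
    """Run differential -> enrichment -> connectivity -> ranking for one patient.

    ``expr`` must already be preprocessed (log2 scale). The measured/bank
    gene-universe intersection defines the universe for enrichment and the
    pathway restriction for scoring.
    """
    universe = sorted(set(expr.gene_ids) & set(bank.gene_universe))
    if not universe:
        raise ValueError(
            "expression matrix and reference bank share no gene identifiers; "
            "check identifier mapping"
        )

    ranking = paired_log2fc(expr, patient)
    keep = set(universe)
    mask = [g in keep for g in ranking.genes]
    from .containers import DifferentialRanking

    ranking = DifferentialRanking(
        genes=ranking.genes[mask], log2fc=ranking.log2fc[mask]
    )
    sig = tag_signature(ranking, fold_threshold=cfg.fold_threshold)

    if cfg.enrichment_mode == "ks_permutation":
        logger.warning(
            "enrichment mode: rank-KS with gene-label permutation "
            "(single pre/post pair admits no sample permutation)"
        )
        enr = ks_permutation_enrichment(
            ranking, pathways, n_perm=cfg.n_perm, seed=cfg.seed
        )
    elif cfg.enrichment_mode == "hypergeometric":
        enr = hypergeometric_enrichment(sig, pathways, universe)
    else:
        raise ValueError(f"unknown enrichment_mode {cfg.enrichment_mode!r}")
    selected = select_pathways(
        enr, pathways, alpha=cfg.enrichment_alpha, fdr=cfg.enrichment_fdr
    )
    enr_df = pd.DataFrame(
        {
            "pathway": [e.pathway for e in enr],
            "method": [e.method for e in enr],
            "statistic": [e.statistic for e in enr],
            "p_value": [e.p_value for e in enr],
            "selected": [e.pathway in selected for e in enr],
        }
    )

    counts = {
        "n_measured_genes": len(expr.gene_ids),
        "n_universe": len(universe),
        "n_up_tags": len(sig.up_genes),
        "n_down_tags": len(sig.down_genes),
        "n_pathways": len(pathways),
        "n_selected_pathways": len(selected),
    }

    empty_cols = [
        "patient",
        "instance_id",
        "compound",
        "dose",
        "pathway",
        "ks_up",
        "ks_down",
        "score",
        "p_value",
    ]
    report_cols = [
        "instance_id",
        "compound",
        "dose",
        "positive_count",
        "negative_count",
        "pathway_counts",
        "sum_abs_score",
    ]
    if sig.is_empty():
        logger.warning("patient %s: empty tag signature; nothing to score", patient)
        return PatientResult(
            patient, ranking.to_frame(), [], [], enr_df, [],
            pd.DataFrame(columns=empty_cols), pd.DataFrame(columns=report_cols),
            "empty tag signature", counts | {"n_cells": 0},
        )
    if len(selected) == 0:
        return PatientResult(
            patient, ranking.to_frame(), sig.up_genes, sig.down_genes, enr_df, [],
            pd.DataFrame(columns=empty_cols), pd.DataFrame(columns=report_cols),
            "no pathways selected", counts | {"n_cells": 0},
        )

    cache = PermutationNullCache(
        seed=cfg.seed, n_perm=cfg.n_perm, halve=cfg.halve_combined
    )
    meta = {i.instance_id: i for i in bank}
    cells = []
    for name, genes in selected.items():
        genes = genes & keep
        if not genes:
            continue
        for inst in bank:
            cell = pathway_connectivity(
                sig,
                inst,
                genes,
                pathway_name=name,
                mode=cfg.connectivity_mode,
                halve=cfg.halve_combined,
            )
            if cell is None:
                continue
            cell.p_value = cache.p_value(cell, mode=cfg.connectivity_mode)
            cells.append(cell)

    cells_df = pd.DataFrame(
        {
            "patient": [patient] * len(cells),
            "instance_id": [c.instance_id for c in cells],
            "compound": [meta[c.instance_id].compound for c in cells],
            "dose": [meta[c.instance_id].dose for c in cells],
            "pathway": [c.pathway for c in cells],
            "ks_up": [c.ks_up for c in cells],
            "ks_down": [c.ks_down for c in cells],
            "score": [c.score for c in cells],
            "p_value": [c.p_value for c in cells],
        }
    )
    summaries = count_pathways(
        cells, bank, alpha=cfg.count_alpha, min_abs_score=cfg.min_abs_score
    )
    report = top_k_report(summaries, k=cfg.k, rank_by=cfg.rank_by)
    return PatientResult(
        patient, ranking.to_frame(), sig.up_genes, sig.down_genes, enr_df,
        selected.names(), cells_df, report, "ok",
        counts | {"n_cells": len(cells)},
    )


def _write_patient(result: PatientResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.ranking.to_csv(out / "ranking.csv", index=False)
    (out / "signature.up.txt").write_text("".join(g + "\n" for g in result.up_genes))
    (out / "signature.dn.txt").write_text("".join(g + "\n" for g in result.down_genes))
    result.enrichment.to_csv(out / "enrichment.csv", index=False)
    result.cells.to_csv(out / "connectivity.csv", index=False)
    result.report.to_csv(out / "topk.csv", index=False)
    with open(out / "topk.txt", "w") as fh:
        fh.write(f"# patient {result.patient_id} — status: {result.status}\n")
        fh.write("instance_id\tcompound\tdose\tpathway_counts\n")
        for row in result.report.itertuples(index=False):
            fh.write(
                f"{row.instance_id}\t{row.compound}\t{row.dose}\t{row.pathway_counts}\n"
            )


def run_pbsc(cfg: RunConfig) -> dict:
    """Run the full pipeline from files on disk; returns the manifest."""
    expr = pbsc_io.read_expression_matrix(cfg.expression)
    expr.pair_map.update(pbsc_io.read_pair_map(cfg.pairs))
    expr = ExpressionMatrix(expr.data, expr.pair_map)  # re-validate pairs
    pathways = pbsc_io.read_gmt(cfg.gmt)
    bank = pbsc_io.read_reference_bank(cfg.bank)

    pp = PreprocessConfig(**(cfg.preprocess or {"quantile": False}))
    expr = preprocess(expr, pp)

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "patients": {},
    }
    reports: dict[str, pd.DataFrame] = {}
    for patient in sorted(expr.pair_map):
        result = analyze_patient(expr, patient, pathways, bank, cfg)
        _write_patient(result, out / patient)
        reports[patient] = result.report
        manifest["patients"][patient] = {"status": result.status, **result.counts}
    if len(reports) > 1:
        shared_hits_report(reports).to_csv(out / "shared_topk.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def validate_inputs(cfg: RunConfig) -> dict:
    """Diagnostic identifier-overlap report; never raises on bad overlap."""
    expr = pbsc_io.read_expression_matrix(cfg.expression)
    pair_map = pbsc_io.read_pair_map(cfg.pairs) if cfg.pairs else {}
    pathways = pbsc_io.read_gmt(cfg.gmt)
    bank = pbsc_io.read_reference_bank(cfg.bank)

    expr_genes = set(expr.gene_ids)
    bank_genes = set(bank.gene_universe)
    gmt_genes = set().union(*(g for _, g in pathways.items())) if len(pathways) else set()
    diag = {
        "n_expression_genes": len(expr_genes),
        "n_bank_genes": len(bank_genes),
        "n_gmt_genes": len(gmt_genes),
        "expression_bank_overlap_pct": round(
            100 * len(expr_genes & bank_genes) / max(len(expr_genes), 1), 2
        ),
        "expression_gmt_overlap_pct": round(
            100 * len(expr_genes & gmt_genes) / max(len(expr_genes), 1), 2
        ),
        "missing_pair_samples": sorted(
            p
            for p, (pre, post) in pair_map.items()
            if pre not in expr.data.columns or post not in expr.data.columns
        ),
        "fatal_on_run": len(expr_genes & bank_genes) == 0,
    }
    return diag
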