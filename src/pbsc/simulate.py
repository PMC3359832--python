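"""Synthetic reference banks and patient pairs with planted drug effects.

Real inputs to this tool — patient microarrays and a licensed
perturbation bank — cannot ship with the package, so this module builds
statistically analogous stand-ins with a known ground truth:

* a pathway collection of random gene sets;
* a reference bank whose instances each carry an up/down signature
  concentrated inside a few "affected" pathways, embedded in Gaussian
  rank noise;
* patient pre/post pairs whose post sample carries one instance's
  signature (optionally sign-flipped), so the pipeline's ability to
  recover the planted instance is measurable.

Defaults approximate a desk-scale study: 2,000 genes, 50 instances,
100 pathways of 10-80 genes, 50 tag genes per direction, a 4-fold
(2 log2 units) planted effect and 0.5 log2 units of noise. Baseline
intensities are Normal(8, 1), typical of log2 microarray data; the exact
baseline is immaterial to rank-based scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    PathwayCollection,
    ReferenceBank,
    ReferenceInstance,
)

__all__ = [
    "SimulationConfig",
    "simulate_pathways",
    "simulate_bank",
    "simulate_patient_pair",
    "simulate_scenario",
]


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_instances: int = 50
    n_pathways: int = 100
    pathway_size_range: tuple[int, int] = (10, 80)
    signature_size: int = 50  # tag genes per direction
    affected_pathways_per_instance: int = 5
    effect_size: float = 2.0  # log2 units
    noise_sd: float = 0.5  # log2 units
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_genes",
            "n_instances",
            "n_pathways",
            "signature_size",
            "affected_pathways_per_instance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.signature_size > self.n_genes // 4:
            raise ValueError("signature_size must be <= n_genes / 4")
        lo, hi = self.pathway_size_range
        if not (0 < lo <= hi <= self.n_genes):
            raise ValueError("invalid pathway_size_range")

    @property
    def gene_ids(self) -> np.ndarray:
        width = len(str(self.n_genes))
        return np.array([f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)])


def simulate_pathways(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> PathwayCollection:
    """Random gene sets with sizes uniform over ``pathway_size_range``."""
    rng = rng or np.random.default_rng(cfg.seed)
    genes = cfg.gene_ids
    lo, hi = cfg.pathway_size_range
    width = len(str(cfg.n_pathways))
    collection = PathwayCollection()
    for i in range(1, cfg.n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        collection.add(f"pw{i:0{width}d}", members, "synthetic pathway")
    return collection


def _sample_signature(
    rng: np.random.Generator,
    pathways: PathwayCollection,
    cfg: SimulationConfig,
    max_tries: int = 100,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Pick affected pathways and disjoint up/down tag genes inside them.

    Pathway sets whose union is too small for the signature are redrawn;
    sampling fails only if no feasible set exists within ``max_tries``.
    """
    names = pathways.names()
    need = 2 * cfg.signature_size
    for _ in range(max_tries):
        chosen = list(rng.choice(names, size=cfg.affected_pathways_per_instance, replace=False))
        union = sorted(set().union(*(pathways[n] for n in chosen)))
        if len(union) >= need:
            picked = rng.choice(union, size=need, replace=False)
            return chosen, picked[: cfg.signature_size], picked[cfg.signature_size :]
    raise ValueError(
        "infeasible sampling: no affected-pathway union large enough for "
        f"{need} signature genes after {max_tries} draws"
    )


def simulate_bank(
    cfg: SimulationConfig,
    pathways: PathwayCollection | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ReferenceBank, pd.DataFrame]:
    """Build a reference bank with planted per-instance signatures.

    Each instance's ranked profile is the descending order of a latent
    effect vector: +effect_size on its up genes, -effect_size on its down
    genes, zero elsewhere, plus Normal(0, noise_sd); ties (e.g. at
    noise_sd = 0) break by gene id. The truth table records each
    instance's signature genes and affected pathways.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    if pathways is None:
        pathways = simulate_pathways(cfg, rng)
    genes = cfg.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    width = len(str(cfg.n_instances))

    instances, truth_rows = [], []
    for i in range(1, cfg.n_instances + 1):
        affected, up, down = _sample_signature(rng, pathways, cfg)
        latent = np.zeros(cfg.n_genes)
        latent[[gene_pos[g] for g in up]] = cfg.effect_size
        latent[[gene_pos[g] for g in down]] = -cfg.effect_size
        if cfg.noise_sd > 0:
            latent = latent + rng.normal(0.0, cfg.noise_sd, cfg.n_genes)
        order = genes[np.lexsort((genes, -latent))]
        iid = f"inst{i:0{width}d}"
        instances.append(
            ReferenceInstance(
                instance_id=iid,
                compound=f"compound_{i:0{width}d}",
                dose="10 uM",
                cell_line="SYN1",
                order=order,
            )
        )
        truth_rows.append(
            {
                "instance_id": iid,
                "up_genes": ";".join(up),
                "down_genes": ";".join(down),
                "affected_pathways": ";".join(affected),
            }
        )
    return ReferenceBank(instances), pd.DataFrame(truth_rows)


def simulate_patient_pair(
    cfg: SimulationConfig,
    truth: pd.DataFrame,
    mimic_instance: str,
    reverse: bool = False,
    patient_id: str = "patientA",
    rng: np.random.Generator | None = None,
) -> ExpressionMatrix:
    """A pre/post pair whose post sample carries one instance's effect.

    The pre column is a Normal(baseline_mean, baseline_sd) log2 baseline;
    the post column adds ±effect_size on the instance's signature genes
    (sign flipped when ``reverse``) plus Normal(0, noise_sd) noise.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    rows = truth[truth["instance_id"] == mimic_instance]
    if rows.empty:
        raise KeyError(f"unknown instance {mimic_instance!r} in truth table")
    row = rows.iloc[0]
    genes = cfg.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    delta = np.zeros(cfg.n_genes)
    delta[[gene_pos[g] for g in row.up_genes.split(";")]] = cfg.effect_size
    delta[[gene_pos[g] for g in row.down_genes.split(";")]] = -cfg.effect_size
    if reverse:
        delta = -delta
    pre = rng.normal(cfg.baseline_mean, cfg.baseline_sd, cfg.n_genes)
    noise = rng.normal(0.0, cfg.noise_sd, cfg.n_genes) if cfg.noise_sd > 0 else 0.0
    post = pre + delta + noise
    df = pd.DataFrame(
        {f"{patient_id}_pre": pre, f"{patient_id}_post": post}, index=pd.Index(genes, name="gene")
    )
    return ExpressionMatrix(
        data=df, pair_map={patient_id: (f"{patient_id}_pre", f"{patient_id}_post")}
    )


@dataclass
class Scenario:
    """One fully specified synthetic study: inputs plus ground truth."""

    config: SimulationConfig
    pathways: PathwayCollection
    bank: ReferenceBank
    truth: pd.DataFrame
    expression: ExpressionMatrix
    mimic_instance: str
    reverse: bool = False
    patient_id: str = "patientA"


def simulate_scenario(
    cfg: SimulationConfig | None = None,
    mimic_instance: str | None = None,
    reverse: bool = False,
    patient_id: str = "patientA",
) -> Scenario:
    """Generate pathways, bank and one patient pair in one call.

    ``mimic_instance`` defaults to the first bank instance. All randomness
    derives from ``cfg.seed``.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    pathways = simulate_pathways(cfg, rng)
    bank, truth = simulate_bank(cfg, pathways, rng)
    mimic = mimic_instance or bank.instance_ids[0]
    expr = simulate_patient_pair(
        cfg, truth, mimic, reverse=reverse, patient_id=patient_id, rng=rng
    )
    return Scenario(
        config=cfg,
        pathways=pathways,
        bank=bank,
        truth=truth,
        expression=expr,
        mimic_instance=mimic,
        reverse=reverse,
        patient_id=patient_id,
    )
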