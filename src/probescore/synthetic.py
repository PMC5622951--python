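"""Synthetic data with known ground truth for every pipeline stage.

The probe-level generator emulates a PM-only transcriptome array experiment:
two age groups × two sexes × ethanol/control with a handful of biological
replicates per cell, several thousand transcript clusters each interrogated
by a few probes.  The noise model is multiplicative-plus-additive,

    I_{j,c} = a_j · x_{g,c} · exp(η) + max(0-truncated additive background),
    η ~ Normal(0, mult_noise_sd²),  a_j ~ logNormal(0, affinity_sd²),

with per-probe affinities ``a_j`` fixed across samples, which is exactly the
structure under which an intensity-proportional error term is the correct
standardization for between-chip probe differences.  Differential clusters
carry a multiplicative fold change in ethanol-treated samples.

Companion generators produce Gaussian behavioral cohorts, triplicate-well
qPCR Ct tables with multiple reference genes, and linear-response ELISA
plates.  All generators are pure functions of their (spec, seed) arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assays import DEFAULT_REFERENCE_GENES, ElisaPlate
from .probe_io import DesignTable, ProbeMatrix, ValidationError


def make_study_design(
    ages: Sequence[str] = ("adolescent_PND43", "adult_PND66"),
    pairs_per_sex: Mapping[str, int] | int = None,
) -> DesignTable:
    """Design template mirroring the study scale: per age, 5 male and 4 female
    ethanol/control pairs (9 pairwise replicates per age)."""
    if pairs_per_sex is None:
        pairs_per_sex = {"M": 5, "F": 4}
    elif isinstance(pairs_per_sex, int):
        pairs_per_sex = {"M": pairs_per_sex, "F": pairs_per_sex}
    rows = []
    for age in ages:
        tag = "adol" if "adolescent" in age else "adult"
        for sex, npairs in pairs_per_sex.items():
            for i in range(1, npairs + 1):
                pid = f"{tag}_{sex}{i}"
                for trt in ("ethanol", "control"):
                    rows.append(
                        dict(
                            sample_id=f"{pid}_{trt[0].upper()}",
                            age_group=age, sex=sex, treatment=trt, pair_id=pid,
                        )
                    )
    return DesignTable(pd.DataFrame(rows))


@dataclass
class SimulationSpec:
    """Parameters of the probe-level generator; defaults are the desk-scale
    stand-in for the study's arrays (5,000 clusters × 4 probes)."""

    n_clusters: int = 5000
    probes_per_cluster: int = 4
    design: DesignTable | None = None
    n_de: int = 0
    effect_size: float = 2.0
    affinity_sd: float = 0.5
    mult_noise_sd: float = 0.15
    add_noise_sd: float = 10.0
    background: float = 50.0
    base_log_mean: float = 5.5
    base_log_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_de > self.n_clusters:
            raise ValidationError("n_de exceeds n_clusters")
        for name in ("affinity_sd", "mult_noise_sd", "add_noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be > 0")


@dataclass
class GroundTruth:
    """What the generator actually planted, retrievable by id."""

    de_clusters: dict[str, float] = field(default_factory=dict)
    group_means: dict[tuple, float] = field(default_factory=dict)
    qpcr_ratios: dict[tuple, float] = field(default_factory=dict)
    elisa_conc: dict[str, float] = field(default_factory=dict)


def simulate_probe_data(spec: SimulationSpec) -> tuple[ProbeMatrix, DesignTable, GroundTruth]:
    """Generate a probe-intensity matrix, its design, and the planted truth."""
    spec.validate()
    design = spec.design if spec.design is not None else make_study_design()
    rng = np.random.default_rng(spec.seed)

    n_probes = spec.n_clusters * spec.probes_per_cluster
    cluster_ids = np.array([f"TC{g:05d}" for g in range(spec.n_clusters)])
    probe_ids = [
        f"TC{g:05d}_p{j}" for g in range(spec.n_clusters) for j in range(spec.probes_per_cluster)
    ]
    probe_cluster = np.repeat(np.arange(spec.n_clusters), spec.probes_per_cluster)

    base = np.exp(rng.normal(spec.base_log_mean, spec.base_log_sd, size=spec.n_clusters))
    affinity = np.exp(rng.normal(0.0, spec.affinity_sd, size=n_probes))
    de_idx = rng.choice(spec.n_clusters, size=spec.n_de, replace=False)
    fold = np.ones(spec.n_clusters)
    fold[de_idx] = spec.effect_size

    samples = design.table["sample_id"].to_numpy()
    treated = (design.table["treatment"] == "ethanol").to_numpy()
    data = np.empty((n_probes, len(samples)))
    for c, (sid, is_trt) in enumerate(zip(samples, treated)):
        x = base * (fold if is_trt else 1.0)
        mu = affinity * x[probe_cluster]
        eta = rng.normal(0.0, spec.mult_noise_sd, size=n_probes) if spec.mult_noise_sd > 0 else 0.0
        add = rng.normal(spec.background, spec.add_noise_sd, size=n_probes) if (
            spec.add_noise_sd > 0 or spec.background != 0
        ) else 0.0
        data[:, c] = np.maximum(mu * np.exp(eta) + add, 0.0)

    pm = ProbeMatrix(
        pd.DataFrame(data, index=pd.Index(probe_ids, name="probe_id"), columns=samples),
        pd.Series(cluster_ids[probe_cluster], index=probe_ids, name="cluster_id"),
    )
    truth = GroundTruth(de_clusters={cluster_ids[g]: spec.effect_size for g in sorted(de_idx)})
    return pm, design, truth


def simulate_behavior_cohort(
    groups: Sequence[tuple[str, str, int, float, float]],
    measure: str,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Gaussian per-animal draws for (sex, treatment, n, mean, sd) groups.

    Returns a long behavior table (animal_id, sex, adolescent_treatment,
    measure, value) and the planted group means.
    """
    rng = np.random.default_rng(seed)
    rows = []
    truth = GroundTruth()
    for sex, trt, n, mean, sd in groups:
        if sd < 0:
            raise ValidationError("group sd must be >= 0")
        if n < 2:
            raise ValidationError("need n >= 2 per group")
        vals = mean + (rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n))
        truth.group_means[(sex, trt, measure)] = mean
        for i, v in enumerate(vals, start=1):
            rows.append(
                dict(animal_id=f"{sex}_{trt}_{i}", sex=sex, adolescent_treatment=trt,
                     measure=measure, value=v)
            )
    return pd.DataFrame(rows), truth


def simulate_qpcr(
    targets: Sequence[str],
    design: pd.DataFrame,
    true_ratios: Mapping[str, Mapping[str, float]],
    refs: Sequence[str] = DEFAULT_REFERENCE_GENES,
    base_ct: Mapping[str, float] | None = None,
    ct_sd: float = 0.15,
    n_wells: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Triplicate-well Ct tables with Ct = base_Ct − log2(expression) + noise.

    ``design`` needs columns sample_id and group; ``true_ratios`` maps group →
    {target: expression ratio relative to the baseline group}.  Reference
    genes have expression 1 everywhere.
    """
    rng = np.random.default_rng(seed)
    genes = list(targets) + [r for r in refs if r not in targets]
    if base_ct is None:
        base_ct = {g: 20.0 + 1.5 * i for i, g in enumerate(genes)}
    truth = GroundTruth()
    rows = []
    for _, srow in design.iterrows():
        sid, group = srow["sample_id"], srow["group"]
        for gene in genes:
            if gene in refs:
                expr = 1.0
            else:
                expr = float(true_ratios.get(group, {}).get(gene, 1.0))
                if expr <= 0:
                    raise ValidationError("true expression ratios must be > 0")
                truth.qpcr_ratios[(group, gene)] = expr
            ct0 = base_ct[gene] - np.log2(expr)
            for w in range(1, n_wells + 1):
                noise = rng.normal(0.0, ct_sd) if ct_sd > 0 else 0.0
                rows.append(dict(sample_id=sid, target=gene, well=w, ct=ct0 + noise))
    return pd.DataFrame(rows), truth


def simulate_elisa_plate(
    standard_conc: Sequence[float],
    true_conc: Mapping[str, float],
    slope: float = 0.1,
    intercept: float = 0.05,
    od_sd: float = 0.0,
    protein_ug: float | Mapping[str, float] = 5.0,
    seed: int = 0,
) -> tuple[ElisaPlate, GroundTruth]:
    """Linear-response plate: OD = intercept + slope·conc + Normal(0, od_sd²)."""
    standard_conc = np.asarray(standard_conc, dtype=float)
    if len(standard_conc) < 3:
        raise ValidationError("at least 3 standards required")
    rng = np.random.default_rng(seed)
    ids = list(true_conc)
    concs = np.array([true_conc[i] for i in ids], dtype=float)
    if isinstance(protein_ug, Mapping):
        prot = np.array([protein_ug[i] for i in ids], dtype=float)
    else:
        prot = np.full(len(ids), float(protein_ug))

    def od(c: np.ndarray) -> np.ndarray:
        noise = rng.normal(0.0, od_sd, size=np.shape(c)) if od_sd > 0 else 0.0
        return intercept + slope * np.asarray(c, dtype=float) + noise

    plate = ElisaPlate(standard_conc, od(standard_conc), ids, od(concs), prot)
    truth = GroundTruth(elisa_conc=dict(zip(ids, concs / prot)))
    return plate, truth
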