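"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: paired tumor miRNA
counts with spiked differential miRNAs, mRNA profiles anti-correlated with a
planted miRNA -> target map, partially overlapping target-prediction
resources, gene-set collections with one planted enriched pathway, survival
cohorts with expression-dependent proportional hazards, a non-malignant
reference expression matrix, and replicate Ct measurements.  The planted
truth is returned alongside the data so each downstream stage has a
parameter-recovery test.

Count model
-----------
miRNA counts are negative binomial, parameterized by mean ``m`` and
dispersion ``phi`` (variance ``m + phi * m**2``), with a log-normal
per-patient baseline shared by the primary/relapse pair so that a paired
test has genuine within-patient correlation to exploit.  Differential
miRNAs multiply the relapse mean by ``2**effect`` with a random sign per
miRNA.  mRNA expression is generated directly on the log2 scale: the
integration stage consumes normalized expression, so count-level realism
adds nothing there.

Reproducibility: the same seed and parameters give bit-identical output.
Pipelines derive per-component sub-seeds with :func:`component_seed` so
adding one generator never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import COUNTS, LOG2, ExpressionMatrix, PairingTable

# log2-scale sd of the shared per-patient baseline (natural-log sigma 0.5)
PATIENT_SIGMA_LN = 0.5
# baseline hazard: exponential with 36-month median survival
BASELINE_HAZARD = np.log(2.0) / 36.0


@dataclass
class SimulationTruth:
    """Ground truth planted by the generators.

    ``de_mirnas`` maps miRNA id -> signed log2 effect size; ``target_map``
    maps miRNA id -> {gene id: regulation slope on the log2 scale}, with
    slope <= 0 for repressive targets.
    """

    seed: int
    mirna_universe: list[str] = field(default_factory=list)
    gene_universe: list[str] = field(default_factory=list)
    de_mirnas: dict[str, float] = field(default_factory=dict)
    target_map: dict[str, dict[str, float]] = field(default_factory=dict)
    enriched_set_id: str | None = None
    true_cutpoint: float | None = None
    true_hazard_ratio: float | None = None

    def validate(self) -> None:
        if not set(self.de_mirnas) <= set(self.mirna_universe):
            raise ValueError("de_mirnas outside simulated miRNA universe")
        genes = {g for t in self.target_map.values() for g in t}
        if self.gene_universe and not genes <= set(self.gene_universe):
            raise ValueError("target_map genes outside simulated gene universe")
        if self.true_hazard_ratio is not None and self.true_hazard_ratio <= 0:
            raise ValueError("true_hazard_ratio must be > 0")

    def true_edges(self) -> set[tuple[str, str]]:
        return {(m, g) for m, t in self.target_map.items() for g in t}

    def to_flat_dict(self) -> dict[str, str]:
        """Flat key/value serialization for test harnesses."""
        out = {"seed": str(self.seed)}
        for m, e in sorted(self.de_mirnas.items()):
            out[f"de.{m}"] = repr(e)
        for m, targets in sorted(self.target_map.items()):
            for g, s in sorted(targets.items()):
                out[f"target.{m}.{g}"] = repr(s)
        if self.enriched_set_id is not None:
            out["enriched_set_id"] = self.enriched_set_id
        if self.true_cutpoint is not None:
            out["true_cutpoint"] = repr(self.true_cutpoint)
        if self.true_hazard_ratio is not None:
            out["true_hazard_ratio"] = repr(self.true_hazard_ratio)
        return out


def component_seed(seed: int, component: str) -> int:
    """Stable sub-seed for a named pipeline component (< 2**31)."""
    mix = np.random.SeedSequence([int(seed), zlib.crc32(component.encode())])
    return int(mix.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draw with variance mean + dispersion * mean**2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_paired_mirna_counts(
    n_mirnas: int = 500,
    n_pairs: int = 7,
    de_fraction: float = 0.026,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.1,
    depth: float = 1e6,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth, PairingTable]:
    """Paired primary/relapse miRNA count matrix with spiked DE miRNAs.

    ``round(n_mirnas * de_fraction)`` miRNAs get a signed log2 effect of
    magnitude ``effect_log2fc`` applied to the relapse mean, so in
    expectation the paired log2 fold change of a planted miRNA equals its
    signed effect; all other miRNAs have effect 0.
    """
    if n_pairs < 2:
        raise ValueError("n_pairs must be >= 2 (paired test undefined)")
    if not 0 <= de_fraction <= 1:
        raise ValueError("de_fraction must be in [0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if int(n_mirnas) != n_mirnas or int(n_pairs) != n_pairs:
        raise ValueError("n_mirnas and n_pairs must be integers")
    rng = np.random.default_rng(seed)

    mirnas = [f"miR-{i + 1:04d}" for i in range(n_mirnas)]
    patients = [f"P{i + 1:02d}" for i in range(n_pairs)]

    # relative abundances (log-normal, heavy-tailed like small-RNA libraries)
    rel = rng.lognormal(mean=0.0, sigma=1.5, size=n_mirnas)
    rel /= rel.sum()

    n_de = int(round(n_mirnas * de_fraction))
    de_idx = rng.choice(n_mirnas, size=n_de, replace=False)
    effects = np.zeros(n_mirnas)
    if effect_log2fc != 0 and n_de:
        signs = rng.choice([-1.0, 1.0], size=n_de)
        effects[de_idx] = signs * effect_log2fc

    # unit-mean log-normal so library sizes stay centered on the requested depth
    patient_effect = rng.lognormal(
        -PATIENT_SIGMA_LN**2 / 2.0, PATIENT_SIGMA_LN, size=(n_mirnas, n_pairs)
    )

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    for j, pat in enumerate(patients):
        base = depth * rel * patient_effect[:, j]
        for phase in ("primary", "relapse"):
            m = base * (2.0**effects if phase == "relapse" else 1.0)
            sid = f"{pat}_{phase}"
            cols[sid] = _nb_counts(rng, m, dispersion)
            meta_rows.append({"sample": sid, "patient": pat, "phase": phase})

    values = pd.DataFrame(cols, index=mirnas)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    truth = SimulationTruth(
        seed=seed,
        mirna_universe=mirnas,
        de_mirnas={mirnas[i]: float(effects[i]) for i in de_idx},
    )
    truth.validate()
    pairing = PairingTable(
        pd.DataFrame(
            {
                "patient": patients,
                "primary_sample": [f"{p}_primary" for p in patients],
                "relapse_sample": [f"{p}_relapse" for p in patients],
            }
        )
    )
    return ExpressionMatrix(values, meta, COUNTS), truth, pairing


def generate_mrna_expression(
    mirna_expr: ExpressionMatrix,
    truth: SimulationTruth,
    noise_sd: float = 0.2,
    n_genes: int = 2000,
    seed: int = 0,
    targets_per_mirna: int = 30,
    strength: float = -1.5,
) -> ExpressionMatrix:
    """Matched mRNA log2 expression with planted repressive targets.

    Each DE miRNA in ``truth`` is assigned ``targets_per_mirna`` distinct
    genes; a planted target's log2 expression is
    ``baseline + strength * regulator_log2 + N(0, noise_sd)``, so
    ``strength <= 0`` yields anti-correlation.  Non-target genes are
    independent of every miRNA.  ``truth.target_map`` and
    ``truth.gene_universe`` are filled in.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]

    if mirna_expr.scale == COUNTS:
        from .profiling import normalize_counts

        mirna_log2 = normalize_counts(mirna_expr)
    else:
        mirna_log2 = mirna_expr
    n_samples = len(mirna_log2.sample_ids)

    expr = rng.normal(8.0, 1.0, size=(n_genes, 1)) + rng.normal(
        0.0, 1.0, size=(n_genes, n_samples)
    )
    values = pd.DataFrame(expr, index=genes, columns=mirna_log2.sample_ids)

    pool = rng.permutation(n_genes)
    truth.gene_universe = genes
    truth.target_map = {}
    cursor = 0
    for m in sorted(truth.de_mirnas):
        if cursor + targets_per_mirna > n_genes:
            raise ValueError("not enough genes for the requested target map")
        take = pool[cursor : cursor + targets_per_mirna]
        cursor += targets_per_mirna
        reg = mirna_log2.values.loc[m].to_numpy(dtype=float)
        reg = reg - reg.mean()
        targets = {}
        for gi in take:
            noise = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
            values.iloc[gi] = 8.0 + strength * reg + noise
            targets[genes[gi]] = float(strength)
        truth.target_map[m] = targets
    truth.validate()
    return ExpressionMatrix(values, mirna_log2.sample_meta.copy(), LOG2)


@dataclass
class TargetResource:
    """One target-prediction database: a named set of (miRNA, gene) edges."""

    name: str
    edges: set[tuple[str, str]]


def generate_target_resources(
    truth: SimulationTruth,
    n_resources: int = 5,
    sensitivity: float = 0.8,
    fp_rate: float = 0.001,
    seed: int = 0,
) -> list[TargetResource]:
    """Partially overlapping prediction resources around the true target map.

    Each resource contains each true (miRNA, gene) edge with probability
    ``sensitivity`` and each false edge with probability ``fp_rate``,
    independently per resource.
    """
    if not (0 <= sensitivity <= 1 and 0 <= fp_rate <= 1):
        raise ValueError("sensitivity and fp_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    true_edges = sorted(truth.true_edges())
    mirnas = truth.mirna_universe or sorted({m for m, _ in true_edges})
    genes = truth.gene_universe or sorted({g for _, g in true_edges})
    n_false_universe = len(mirnas) * len(genes) - len(true_edges)
    true_set = set(true_edges)

    resources = []
    for r in range(n_resources):
        edges = {e for e in true_edges if rng.random() < sensitivity}
        if fp_rate > 0 and n_false_universe > 0:
            n_fp = rng.binomial(n_false_universe, fp_rate)
            n_false = 0
            while n_false < n_fp:
                m = mirnas[rng.integers(len(mirnas))]
                g = genes[rng.integers(len(genes))]
                if (m, g) not in true_set and (m, g) not in edges:
                    edges.add((m, g))
                    n_false += 1
        resources.append(TargetResource(name=f"resource_{r + 1}", edges=edges))
    return resources


def generate_survival_cohort(
    n: int = 233,
    biomarker_dist: tuple = ("normal", 0.0, 1.0),
    true_cutpoint: float = 0.6745,
    hazard_ratio: float = 4.0,
    censor_rate: float = 0.3,
    covariates: dict | None = None,
    seed: int = 0,
    baseline_hazard: float = BASELINE_HAZARD,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Survival cohort with a proportional-hazards biomarker effect.

    Event times are exponential; the hazard is multiplied by
    ``hazard_ratio`` when the biomarker exceeds ``true_cutpoint`` and by a
    per-level hazard ratio for an optional categorical covariate, e.g.
    ``{"name": "IPI", "levels": ["0-2", "3-5"], "probs": [0.6, 0.4],
    "hazard_ratios": [1.0, 2.0]}``.  Censoring is independent with
    per-subject probability ``censor_rate``.  Times are in months.
    """
    if not 0 <= censor_rate <= 1:
        raise ValueError("censor_rate must be in [0, 1]")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    rng = np.random.default_rng(seed)

    kind, *params = biomarker_dist
    if kind == "normal":
        biomarker = rng.normal(params[0], params[1], size=n)
    elif kind == "lognormal":
        biomarker = rng.lognormal(params[0], params[1], size=n)
    elif kind == "uniform":
        biomarker = rng.uniform(params[0], params[1], size=n)
    else:
        raise ValueError(f"unknown biomarker distribution {kind!r}")

    hazard = np.full(n, baseline_hazard)
    hazard[biomarker > true_cutpoint] *= hazard_ratio

    table = pd.DataFrame(
        {
            "patient": [f"PT{i + 1:04d}" for i in range(n)],
            "biomarker": biomarker,
        }
    )
    if covariates:
        levels = covariates["levels"]
        probs = covariates.get("probs", [1.0 / len(levels)] * len(levels))
        hrs = covariates.get("hazard_ratios", [1.0] * len(levels))
        idx = rng.choice(len(levels), size=n, p=probs)
        table[covariates.get("name", "covariate")] = [levels[i] for i in idx]
        hazard = hazard * np.asarray(hrs)[idx]

    event_time = rng.exponential(1.0 / hazard)
    if censor_rate >= 1.0:
        time, event = event_time, np.zeros(n, dtype=int)
    elif censor_rate <= 0.0:
        time, event = event_time, np.ones(n, dtype=int)
    else:
        # exponential censoring racing the event at matched per-subject rate:
        # P(censor first) = censor_rate exactly
        c_rate = hazard * censor_rate / (1.0 - censor_rate)
        censor_time = rng.exponential(1.0 / c_rate)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    table["time_months"] = time
    table["event"] = event
    table["endpoint"] = "OS"

    truth = SimulationTruth(
        seed=seed,
        true_cutpoint=float(true_cutpoint),
        true_hazard_ratio=float(hazard_ratio),
    )
    truth.validate()
    return table, truth


def generate_ct_replicates(
    true_rq: float,
    control_ct: float = 20.0,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    calibrator_delta_ct: float = 2.0,
    sample_id: str = "sample",
    calibrator_id: str = "calibrator",
    assay: str = "target_assay",
    control_assay: str = "control_assay",
) -> pd.DataFrame:
    """Replicate Ct table for one sample/calibrator pair of specimens.

    The sample's target Ct is ``control_ct + calibrator_delta_ct -
    log2(true_rq)`` plus Gaussian replicate noise, so the recovered
    ``2**-ddCt`` equals ``true_rq`` in expectation.
    """
    if true_rq <= 0:
        raise ValueError("true_rq must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []

    def _add(sample: str, a: str, role: str, base: float) -> None:
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {"sample": sample, "assay": a, "role": role, "replicate": rep,
                 "ct": base + noise}
            )

    _add(sample_id, control_assay, "endogenous_control", control_ct)
    _add(sample_id, assay, "target",
         control_ct + calibrator_delta_ct - np.log2(true_rq))
    _add(calibrator_id, control_assay, "endogenous_control", control_ct)
    _add(calibrator_id, assay, "target", control_ct + calibrator_delta_ct)
    return pd.DataFrame(rows)


def generate_reference_expression(
    tumor: ExpressionMatrix,
    offsets: dict[str, float],
    n_samples: int = 6,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> ExpressionMatrix:
    """Non-malignant reference matrix for the high/low classifier.

    A positive offset for a miRNA means the tumor mean exceeds the
    reference mean by that many log2 units (the miRNA is "high" in tumor);
    a negative offset makes it "low".  Unlisted miRNAs get offset 0.
    """
    if tumor.scale != LOG2:
        raise ValueError("reference generation expects a log2-scale tumor matrix")
    rng = np.random.default_rng(seed)
    tumor_mean = tumor.values.mean(axis=1).to_numpy()
    off = np.array([offsets.get(f, 0.0) for f in tumor.feature_ids])
    base = tumor_mean - off
    expr = base[:, None] + rng.normal(0.0, noise_sd, size=(len(base), n_samples))
    sample_ids = [f"REF{i + 1:02d}" for i in range(n_samples)]
    values = pd.DataFrame(expr, index=tumor.feature_ids, columns=sample_ids)
    meta = pd.DataFrame(
        {"patient": sample_ids, "phase": "reference"}, index=pd.Index(sample_ids)
    )
    return ExpressionMatrix(values, meta, LOG2)


def generate_gene_sets(
    truth: SimulationTruth,
    n_sets: int = 50,
    set_size: tuple[int, int] = (20, 80),
    target_fraction: float = 0.7,
    seed: int = 0,
    enriched_set_id: str = "PLANTED_PATHWAY",
):
    """Gene-set collection with one set enriched in planted target genes.

    The planted set draws ``target_fraction`` of its members from
    ``truth.target_map`` genes; decoy sets are uniform over the gene
    universe.  Records ``truth.enriched_set_id``.
    """
    from .enrichment import GeneSetCollection

    rng = np.random.default_rng(seed)
    universe = list(truth.gene_universe)
    if not universe:
        raise ValueError("truth has no gene universe; generate mRNA data first")
    target_genes = sorted({g for t in truth.target_map.values() for g in t})
    if not target_genes:
        raise ValueError("truth has no target map; generate mRNA data first")

    sets: dict[str, set[str]] = {}
    lo, hi = set_size
    size = int(rng.integers(lo, hi + 1))
    n_from_targets = min(int(round(size * target_fraction)), len(target_genes))
    planted = set(rng.choice(target_genes, size=n_from_targets, replace=False))
    others = [g for g in universe if g not in planted]
    planted |= set(rng.choice(others, size=size - n_from_targets, replace=False))
    sets[enriched_set_id] = planted

    for i in range(n_sets - 1):
        size = int(rng.integers(lo, hi + 1))
        sets[f"DECOY_SET_{i + 1:03d}"] = set(
            rng.choice(universe, size=size, replace=False)
        )
    truth.enriched_set_id = enriched_set_id
    return GeneSetCollection(sets=sets, universe=set(universe))
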