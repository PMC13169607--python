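"""Synthetic tumor/normal cohorts with planted miRNA-mRNA regulatory axes.

The generator emulates the statistical structure of paired bulk expression
studies: negative-binomial counts around gene-wise log-normal baseline
means, planted tumor log2 fold changes, a small set of regulator miRNA
archetypes (one downregulated tumor-suppressor, the rest upregulated
oncomiRs), true targets whose expression across tumors is negatively
coupled to the regulator's latent abundance, decoy predicted targets,
exponential survival with hazards tied to a known linear predictor of the
eight axis features, and a batch-shifted external validation cohort that
carries only miRNA expression and survival.

Every quantity needed to score recovery downstream is returned in a
:class:`GroundTruth` record, including the latent per-tumor regulator
deviations and the noiseless target-set activities they induce.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, MiraxError, TargetPredictionPair

__all__ = ["SimulationConfig", "GroundTruth", "generate_cohort",
           "generate_validation_cohort", "simulate_screen_cohort"]

MONTHS_MEDIAN_BASELINE = 24.0  # baseline median survival, months
ADMIN_CENSOR_MONTHS = 240.0


@dataclass
class SimulationConfig:
    """Parameters of the synthetic discovery/validation cohorts.

    Defaults define the standard study conditions used throughout the test
    suite: 2000 genes, 300 miRNAs, 120 tumors vs 50 normals, planted
    |log2FC| centred on 2 for DE genes, four axis miRNAs (1 down-archetype,
    3 up-archetypes) with 12 true targets and 12 shared decoys each, and an
    8-coefficient log-hazard vector on the standardized latent axis
    features.
    """

    n_genes: int = 2000
    n_mirnas: int = 300
    n_tumor: int = 120
    n_normal: int = 50
    paired_fraction: float = 0.4
    de_fraction_up: float = 0.10
    de_fraction_down: float = 0.10
    mirna_de_fraction_up: float = 0.08    # background (non-axis) miRNA effects
    mirna_de_fraction_down: float = 0.08
    lfc_mean: float = 2.0       # centre of planted |log2FC|
    lfc_scale: float = 0.25     # SD of planted |log2FC| around the centre
    nb_dispersion: float = 0.15
    lib_size_range: tuple[float, float] = (8e5, 1.2e6)
    n_axis_mirnas: int = 4
    targets_per_mirna: int = 12
    decoys_per_mirna: int = 12
    repression_strength: float = 0.15
    mirna_archetype_shift: float = 1.5   # |log2FC| of the planted axis miRNAs
    mirna_bio_sd: float = 1.0            # latent log2 SD of miRNA abundance
    gene_bio_sd: float = 0.6             # latent log2 SD of gene expression
    patient_shared_fraction: float = 0.4  # share of latent variance common to a
                                          # patient's tumor and matched normal
    surv_beta: tuple[float, ...] = (0.52, -0.46, 0.46, 0.40, -0.40, 0.35, 0.35, 0.29)
    clinical_age_beta: float = 0.30      # per decade of age
    clinical_stage_beta: float = 0.30    # per stage unit
    censor_rate: float = 0.35
    batch_shift: float | tuple[float, ...] = 0.75
    n_validation: int = 160
    missing_stage_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(n_genes=self.n_genes, n_mirnas=self.n_mirnas,
                      n_tumor=self.n_tumor, n_normal=self.n_normal,
                      n_axis_mirnas=self.n_axis_mirnas,
                      targets_per_mirna=self.targets_per_mirna,
                      n_validation=self.n_validation)
        for name, v in counts.items():
            if v <= 0:
                raise MiraxError(f"{name} must be positive, got {v}")
        for name in ("paired_fraction", "de_fraction_up", "de_fraction_down",
                     "mirna_de_fraction_up", "mirna_de_fraction_down",
                     "censor_rate", "missing_stage_fraction",
                     "patient_shared_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise MiraxError(f"{name} must be in [0,1], got {v}")
        if self.nb_dispersion <= 0:
            raise MiraxError("nb_dispersion must be > 0")
        if len(self.surv_beta) != 8:
            raise MiraxError("surv_beta must have length 8")
        if self.targets_per_mirna + self.decoys_per_mirna > self.n_genes:
            raise MiraxError("targets_per_mirna + decoys_per_mirna exceeds n_genes")
        if self.lib_size_range[0] <= 0 or self.lib_size_range[0] > self.lib_size_range[1]:
            raise MiraxError("lib_size_range must be positive and ordered")

    @property
    def expected_lfc_mean(self) -> float:
        """Mean of the folded normal |N(lfc_mean, lfc_scale)|."""
        m, s = self.lfc_mean, self.lfc_scale
        if s == 0:
            return abs(m)
        return float(s * np.sqrt(2 / np.pi) * np.exp(-m**2 / (2 * s**2))
                     + m * (1 - 2 * stats.norm.cdf(-m / s)))


@dataclass
class GroundTruth:
    """Planted signal of one simulation: DE sets, axes, targets and risk."""

    de_genes_up: frozenset[str]
    de_genes_down: frozenset[str]
    axis_mirnas: list[tuple[str, str]]  # (mirna_id, direction)
    true_targets: dict[str, frozenset[str]]
    predicted_targets_sourceA: dict[str, frozenset[str]]
    predicted_targets_sourceB: dict[str, frozenset[str]]
    true_risk: pd.Series  # latent linear predictor per tumor sample
    regulator_z: pd.DataFrame = None  # tumors x axis miRNAs, latent z-deviations
    true_activity: pd.DataFrame = None  # tumors x axis miRNAs, noiseless activity
    gene_lfc: pd.Series = None
    mirna_lfc: pd.Series = None
    # baselines kept so replicate/validation cohorts share the generative law
    gene_baseline: pd.Series = None
    mirna_baseline: pd.Series = None
    validation_risk: pd.Series = None  # latent linear predictor of the validation cohort

    def to_dict(self) -> dict:
        return {
            "de_genes_up": sorted(self.de_genes_up),
            "de_genes_down": sorted(self.de_genes_down),
            "axis_mirnas": [list(x) for x in self.axis_mirnas],
            "true_targets": {m: sorted(s) for m, s in self.true_targets.items()},
            "predicted_targets_sourceA": {m: sorted(s) for m, s in self.predicted_targets_sourceA.items()},
            "predicted_targets_sourceB": {m: sorted(s) for m, s in self.predicted_targets_sourceB.items()},
            "true_risk": self.true_risk.to_dict(),
        }


# ---------------------------------------------------------------------------
# Truth construction
# ---------------------------------------------------------------------------

def _build_truth(cfg: SimulationConfig) -> GroundTruth:
    rng = np.random.default_rng([cfg.seed, 11])
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    mirnas = [f"M{i:04d}" for i in range(cfg.n_mirnas)]

    gene_baseline = pd.Series(rng.normal(5.0, 1.8, cfg.n_genes), index=genes)
    mirna_baseline = pd.Series(rng.normal(7.0, 1.5, cfg.n_mirnas), index=mirnas)

    n_up = int(round(cfg.de_fraction_up * cfg.n_genes))
    n_down = int(round(cfg.de_fraction_down * cfg.n_genes))
    perm = rng.permutation(cfg.n_genes)
    up_genes = [genes[i] for i in perm[:n_up]]
    down_genes = [genes[i] for i in perm[n_up:n_up + n_down]]
    null_genes = [genes[i] for i in perm[n_up + n_down:]]

    gene_lfc = pd.Series(0.0, index=genes)
    mag_up = np.abs(rng.normal(cfg.lfc_mean, cfg.lfc_scale, n_up))
    mag_dn = np.abs(rng.normal(cfg.lfc_mean, cfg.lfc_scale, n_down))
    gene_lfc[up_genes] = mag_up
    gene_lfc[down_genes] = -mag_dn

    # axis archetypes: first miRNA down, remainder up
    axis_ids = mirnas[: cfg.n_axis_mirnas]
    directions = ["down"] + ["up"] * (cfg.n_axis_mirnas - 1)
    axis_mirnas = list(zip(axis_ids, directions))
    mirna_lfc = pd.Series(0.0, index=mirnas)
    for mid, direction in axis_mirnas:
        mirna_lfc[mid] = -cfg.mirna_archetype_shift if direction == "down" else cfg.mirna_archetype_shift
    _plant_background_mirna_de(cfg, mirna_lfc, mirnas[cfg.n_axis_mirnas:], rng)

    # true targets: DE direction opposite to the regulator's
    n_up_axes = sum(1 for _, d in axis_mirnas if d == "up")
    n_dn_axes = cfg.n_axis_mirnas - n_up_axes
    up_pool = list(rng.permutation(up_genes))
    down_pool = list(rng.permutation(down_genes))
    decoy_pool = list(rng.permutation(null_genes))
    # under a null design (no planted DE) targets are drawn from null genes;
    # with planted DE there must be enough opposite-direction genes
    if n_up and n_dn_axes * cfg.targets_per_mirna > n_up:
        raise MiraxError("not enough planted up-genes for the requested targets per miRNA")
    if n_down and n_up_axes * cfg.targets_per_mirna > n_down:
        raise MiraxError("not enough planted down-genes for the requested targets per miRNA")
    if not n_up:
        up_pool = decoy_pool[: n_dn_axes * cfg.targets_per_mirna]
        del decoy_pool[: n_dn_axes * cfg.targets_per_mirna]
    if not n_down:
        down_pool = decoy_pool[: n_up_axes * cfg.targets_per_mirna]
        del decoy_pool[: n_up_axes * cfg.targets_per_mirna]
    true_targets: dict[str, frozenset[str]] = {}
    srcA: dict[str, frozenset[str]] = {}
    srcB: dict[str, frozenset[str]] = {}
    n_extra = max(3, cfg.decoys_per_mirna // 2)
    for mid, direction in axis_mirnas:
        pool = up_pool if direction == "down" else down_pool
        targets = frozenset(pool[: cfg.targets_per_mirna])
        del pool[: cfg.targets_per_mirna]
        shared = frozenset(decoy_pool[: cfg.decoys_per_mirna])
        del decoy_pool[: cfg.decoys_per_mirna]
        extraA = frozenset(decoy_pool[:n_extra]); del decoy_pool[:n_extra]
        extraB = frozenset(decoy_pool[:n_extra]); del decoy_pool[:n_extra]
        true_targets[mid] = targets
        srcA[mid] = targets | shared | extraA
        srcB[mid] = targets | shared | extraB

    return GroundTruth(
        de_genes_up=frozenset(up_genes),
        de_genes_down=frozenset(down_genes),
        axis_mirnas=axis_mirnas,
        true_targets=true_targets,
        predicted_targets_sourceA=srcA,
        predicted_targets_sourceB=srcB,
        true_risk=pd.Series(dtype=float),
        gene_lfc=gene_lfc,
        mirna_lfc=mirna_lfc,
        gene_baseline=gene_baseline,
        mirna_baseline=mirna_baseline,
    )


def _plant_background_mirna_de(cfg: SimulationConfig, mirna_lfc: pd.Series,
                               others: list[str], rng: np.random.Generator) -> None:
    """Plant cohort-level background effects on the non-axis miRNAs in place."""
    n_up_m = int(round(cfg.mirna_de_fraction_up * len(others)))
    n_dn_m = int(round(cfg.mirna_de_fraction_down * len(others)))
    perm_m = rng.permutation(len(others))
    for i in perm_m[:n_up_m]:
        mirna_lfc[others[i]] = abs(rng.normal(cfg.lfc_mean, cfg.lfc_scale))
    for i in perm_m[n_up_m:n_up_m + n_dn_m]:
        mirna_lfc[others[i]] = -abs(rng.normal(cfg.lfc_mean, cfg.lfc_scale))


# ---------------------------------------------------------------------------
# Count sampling
# ---------------------------------------------------------------------------

def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and variance ``mean + phi*mean^2``."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _counts_from_latent(rng: np.random.Generator, latent_log2: np.ndarray,
                        lib_sizes: np.ndarray, dispersion: float) -> np.ndarray:
    """Convert latent per-sample log2 abundances to NB counts at given depths."""
    rel = 2.0 ** latent_log2
    props = rel / rel.sum(axis=0, keepdims=True)
    mean = props * lib_sizes[None, :]
    return _nb_sample(rng, mean, dispersion)


def _survival_from_risk(rng: np.random.Generator, risk: np.ndarray,
                        censor_rate: float) -> tuple[np.ndarray, np.ndarray]:
    lam0 = np.log(2.0) / MONTHS_MEDIAN_BASELINE
    t = rng.exponential(1.0 / (lam0 * np.exp(risk)))
    if censor_rate > 0:
        mu = lam0 * censor_rate / (1.0 - censor_rate)
        c = rng.exponential(1.0 / mu, size=len(risk))
    else:
        c = np.full(len(risk), np.inf)
    c = np.minimum(c, ADMIN_CENSOR_MONTHS)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    time = np.maximum(time, 1e-3)
    return time, event


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    cohort_id: str = "discovery",
    noise_seed: int | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, TargetPredictionPair, pd.DataFrame, GroundTruth]:
    """Generate a tumor/normal cohort with planted axes and survival.

    Passing a ``truth`` from a previous call draws a replicate cohort under
    the same planted effects (new sampling noise, controlled by
    ``noise_seed``), which is how multi-cohort consensus is exercised.

    Returns (mrna_counts, mirna_counts, target_predictions, clinical_survival,
    truth).  The survival table covers the tumor samples and carries
    ``time_months``, ``event``, ``age``, ``sex`` and ``stage``.
    """
    fresh = truth is None
    if fresh:
        truth = _build_truth(config)
    rng = np.random.default_rng([config.seed if noise_seed is None else noise_seed,
                                 zlib.crc32(cohort_id.encode()) % (2**31)])
    mirna_lfc = truth.mirna_lfc
    if not fresh:
        # replicate cohorts keep the planted axis archetypes but redraw the
        # background miRNA effects (cohort-specific platform artifacts)
        axis_set = {m for m, _ in truth.axis_mirnas}
        mirna_lfc = mirna_lfc.copy()
        others = [m for m in mirna_lfc.index if m not in axis_set]
        mirna_lfc[others] = 0.0
        _plant_background_mirna_de(config, mirna_lfc, others, rng)

    n_t, n_n = config.n_tumor, config.n_normal
    tumors = [f"{cohort_id}-T{i:03d}" for i in range(n_t)]
    normals = [f"{cohort_id}-N{i:03d}" for i in range(n_n)]
    n_paired = min(n_n, int(round(config.paired_fraction * n_t)))
    patient_t = [f"{cohort_id}-P{i:03d}" for i in range(n_t)]
    patient_n = [f"{cohort_id}-P{i:03d}" for i in range(n_paired)] + [
        f"{cohort_id}-PN{i:03d}" for i in range(n_n - n_paired)
    ]
    samples = tumors + normals
    is_tumor = np.array([1] * n_t + [0] * n_n)

    genes = list(truth.gene_baseline.index)
    mirnas = list(truth.mirna_baseline.index)
    axis_ids = [m for m, _ in truth.axis_mirnas]

    def _with_patient_effects(noise: np.ndarray, sd: float) -> np.ndarray:
        """Mix a patient-shared component into the tumor/normal pair columns,
        keeping the marginal variance at sd^2."""
        rho = config.patient_shared_fraction
        if rho <= 0 or n_paired == 0:
            return noise
        shared = rng.normal(0.0, sd, size=(noise.shape[0], n_paired))
        for i in range(n_paired):
            for col in (i, n_t + i):  # tumor i and its matched normal
                noise[:, col] = np.sqrt(rho) * shared[:, i] + np.sqrt(1 - rho) * noise[:, col]
        return noise

    # latent miRNA log2 abundances
    eta = rng.normal(0.0, config.mirna_bio_sd, size=(len(mirnas), len(samples)))
    eta = _with_patient_effects(eta, config.mirna_bio_sd)
    mirna_latent = (
        truth.mirna_baseline.to_numpy()[:, None]
        + mirna_lfc.to_numpy()[:, None] * is_tumor[None, :]
        + eta
    )
    axis_rows = [mirnas.index(m) for m in axis_ids]
    # standardized latent deviations of the regulators (tumor columns)
    z_reg = eta[axis_rows][:, :n_t] / config.mirna_bio_sd

    # latent gene log2 abundances with tumor-only repression coupling
    eps = rng.normal(0.0, config.gene_bio_sd, size=(len(genes), len(samples)))
    eps = _with_patient_effects(eps, config.gene_bio_sd)
    gene_latent = (
        truth.gene_baseline.to_numpy()[:, None]
        + truth.gene_lfc.to_numpy()[:, None] * is_tumor[None, :]
        + eps
    )
    gene_index = {g: i for i, g in enumerate(genes)}
    for k, mid in enumerate(axis_ids):
        rows = [gene_index[g] for g in truth.true_targets[mid]]
        gene_latent[np.ix_(rows, range(n_t))] -= config.repression_strength * z_reg[k][None, :]

    lib_g = rng.uniform(*config.lib_size_range, size=len(samples))
    lib_m = rng.uniform(*config.lib_size_range, size=len(samples))
    mrna_counts = _counts_from_latent(rng, gene_latent, lib_g, config.nb_dispersion)
    mirna_counts = _counts_from_latent(rng, mirna_latent, lib_m, config.nb_dispersion)

    meta = pd.DataFrame(
        {
            "group": ["tumor"] * n_t + ["normal"] * n_n,
            "patient_id": patient_t + patient_n,
            "cohort": cohort_id,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    mrna = ExpressionMatrix(pd.DataFrame(mrna_counts, index=genes, columns=samples),
                            meta, assay="mrna", scale="counts")
    mirna = ExpressionMatrix(pd.DataFrame(mirna_counts, index=mirnas, columns=samples),
                             meta, assay="mirna", scale="counts")

    # latent axis features of the tumors: 4 abundances (z) + 4 activities (-c*z,
    # standardized => -z up to sign), combined through surv_beta
    beta = np.asarray(config.surv_beta, dtype=float)
    feats = np.vstack([z_reg, -z_reg])  # 8 x n_tumor, already unit-SD latents
    mol_risk = beta @ feats

    age = rng.normal(60.0, 10.0, n_t)
    sex = rng.integers(0, 2, n_t)
    stage = rng.choice([1, 2, 3, 4], size=n_t, p=[0.35, 0.30, 0.25, 0.10]).astype(float)
    clin_risk = (config.clinical_age_beta * (age - 60.0) / 10.0
                 + config.clinical_stage_beta * (stage - 2.5))
    time, event = _survival_from_risk(rng, mol_risk + clin_risk, config.censor_rate)
    if config.missing_stage_fraction > 0:
        n_missing = int(round(config.missing_stage_fraction * n_t))
        miss = rng.choice(n_t, size=n_missing, replace=False)
        stage[miss] = np.nan
    surv = pd.DataFrame(
        {"time_months": time, "event": event, "age": age, "sex": sex, "stage": stage},
        index=pd.Index(tumors, name="sample_id"),
    )

    targets = TargetPredictionPair(
        sourceA=dict(truth.predicted_targets_sourceA),
        sourceB=dict(truth.predicted_targets_sourceB),
    )
    if fresh or cohort_id == "discovery":
        truth.true_risk = pd.Series(mol_risk, index=tumors)
        truth.regulator_z = pd.DataFrame(z_reg.T, index=tumors, columns=axis_ids)
        truth.true_activity = pd.DataFrame(
            (-config.repression_strength * z_reg).T, index=tumors, columns=axis_ids
        )
    return mrna, mirna, targets, surv, truth


def generate_validation_cohort(
    config: SimulationConfig, truth: GroundTruth, cohort_id: str = "validation"
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """External cohort: miRNA counts (batch-shifted) plus survival only.

    Samples follow the same tumor generative law; ``config.batch_shift``
    (scalar or per-miRNA vector) is added to the latent log2 means.
    Survival is driven by ``surv_beta`` restricted to the four miRNA
    abundance features, mirroring a validation design in which only the
    miRNA component of the model is transferable.
    """
    rng = np.random.default_rng([config.seed, 777])
    n = config.n_validation
    samples = [f"{cohort_id}-T{i:03d}" for i in range(n)]
    mirnas = list(truth.mirna_baseline.index)
    axis_ids = [m for m, _ in truth.axis_mirnas]

    shift = np.asarray(config.batch_shift, dtype=float)
    if shift.ndim == 0:
        # a uniform log2 offset cancels under library-size normalization, so a
        # scalar is interpreted as the SD of heterogeneous per-feature offsets
        rng_batch = np.random.default_rng([config.seed, 888])
        shift = rng_batch.normal(0.0, float(shift), len(mirnas)) if float(shift) > 0 \
            else np.zeros(len(mirnas))
    if len(shift) != len(mirnas):
        raise MiraxError("batch_shift vector length must equal n_mirnas")

    eta = rng.normal(0.0, config.mirna_bio_sd, size=(len(mirnas), n))
    latent = (truth.mirna_baseline.to_numpy()[:, None]
              + truth.mirna_lfc.to_numpy()[:, None]  # all-tumor cohort
              + shift[:, None]
              + eta)
    lib = rng.uniform(*config.lib_size_range, size=n)
    counts = _counts_from_latent(rng, latent, lib, config.nb_dispersion)

    axis_rows = [mirnas.index(m) for m in axis_ids]
    z_reg = eta[axis_rows] / config.mirna_bio_sd
    beta = np.asarray(config.surv_beta, dtype=float)[: len(axis_ids)]
    risk = beta @ z_reg
    time, event = _survival_from_risk(rng, risk, config.censor_rate)
    truth.validation_risk = pd.Series(risk, index=samples)

    meta = pd.DataFrame(
        {"group": "tumor", "patient_id": samples, "cohort": cohort_id},
        index=pd.Index(samples, name="sample_id"),
    )
    mirna = ExpressionMatrix(pd.DataFrame(counts, index=mirnas, columns=samples),
                             meta, assay="mirna", scale="counts")
    surv = pd.DataFrame({"time_months": time, "event": event},
                        index=pd.Index(samples, name="sample_id"))
    return mirna, surv


# ---------------------------------------------------------------------------
# Dedicated survival-screen cohort
# ---------------------------------------------------------------------------

def simulate_screen_cohort(
    n_genes: int = 25,
    n_effect: int = 7,
    effect_size: float = 1.0,
    n_samples: int = 400,
    censor_rate: float = 0.30,
    n_risk: int = 1,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Expression panel plus survival for exercising the univariable screen.

    ``n_effect`` genes carry log-hazard coefficients of magnitude
    ``effect_size`` per SD of expression (the first ``n_risk`` adverse, the
    rest protective); the remaining genes are null.  Returns (gene-by-sample
    expression, survival table, planted gene list).
    """
    if n_effect > n_genes:
        raise MiraxError("n_effect cannot exceed n_genes")
    rng = np.random.default_rng([seed, 555])
    genes = [f"SG{i:03d}" for i in range(n_genes)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    expr = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    betas = np.zeros(n_genes)
    signs = np.array([1.0] * n_risk + [-1.0] * (n_effect - n_risk))
    betas[:n_effect] = signs * effect_size
    risk = betas @ expr
    time, event = _survival_from_risk(rng, risk, censor_rate)
    genes_df = pd.DataFrame(expr, index=genes, columns=samples)
    surv = pd.DataFrame({"time_months": time, "event": event},
                        index=pd.Index(samples, name="sample_id"))
    return genes_df, surv, genes[:n_effect]
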