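"""Synthetic glioma cohorts with planted microenvironment ground truth.

Each simulated sample is a convex mixture of cell-type reference profiles
plus a tumor component.  A latent "BBB alteration" factor u ~ Uniform(0, 1)
per sample tilts the Dirichlet composition: the three blood-brain-barrier
constituent cells (endothelial cells, astrocytes, pericytes) are tilted up
together with u (producing their hallmark collinearity), neural-lineage
cells (neurons, oligodendrocytes) and the tumor component are tilted down,
and any remaining stromal/immune type (e.g. microglia) is tilted up at half
strength.  Tumor purity is the tumor mixing fraction, so it falls as the
stromal content rises.  WHO grade comes from u tertiles; survival times are
exponential with log-hazard ``hazard_beta * (u - 0.5)`` plus independent
exponential censoring, so the planted log-hazard ratio is exactly the Cox
estimand.  Age and KPS are drawn from a Gaussian copula with a mild
positive rank correlation with u.

The tilt is implemented by scaling the per-component Gamma draws of the
Dirichlet:

    f_c  proportional to  G_c * exp(lambda_c * bbb_link * tilt_scale * (2u - 1)),
    G_c ~ Gamma(alpha_c),

with lambda_c in {+1 (BBB cells), -1 (neural lineage), +1/2 (other stroma),
-1/2 (tumor)}; a single knob (``bbb_link``) therefore controls the
collinearity of the BBB cell fractions and their coupling to purity, grade
and hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .io_formats import ExpressionMatrix, write_clinical_table, write_expression_matrix
from .signatures import GeneSet, SignatureCollection, write_gmt

TUMOR = "tumor"
DEFAULT_CELL_TYPES = (
    "endothelial cells",
    "astrocytes",
    "pericytes",
    "microglia",
    "neurons",
    "oligodendrocytes",
)
BBB_PREFIXES = ("endothelial", "astrocyte", "pericyte")
NEURAL_PREFIXES = ("neuron", "oligodendrocyte")


def _tilt_weight(cell_type: str) -> float:
    name = cell_type.strip().lower()
    if any(name.startswith(p) for p in BBB_PREFIXES):
        return 1.0
    if any(name.startswith(p) for p in NEURAL_PREFIXES):
        return -1.0
    if name == TUMOR:
        return -0.5
    return 0.5  # other stromal/immune residents follow the stroma, weakly


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults give a pan-glioma-scale
    cohort (685 samples) with realistic purity spread and ~20% censoring."""

    n_genes: int = 2000
    n_samples: int = 685
    cell_types: tuple = DEFAULT_CELL_TYPES
    signature_size: int = 50
    signature_effect: float = 2.0  # log2 FC of a marker in its own cell type
    bbb_link: float = 0.8  # strength of the shared latent BBB factor
    tilt_scale: float = 2.5  # converts bbb_link into a log-composition tilt
    dirichlet_base: dict = field(default_factory=dict)  # component -> alpha
    noise_sd: float = 0.5  # log2-scale Gaussian expression noise
    hazard_beta: float = 1.0  # log-HR per unit latent BBB factor
    baseline_hazard: float = 1.0 / 1000.0  # events per day at u = 0.5
    censor_rate: float = 0.00025  # independent exponential censoring (~20%)
    grade_labels: tuple = ("II", "III", "IV")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_samples <= 0 or self.signature_size <= 0:
            raise ValueError("sizes must be positive")
        if self.signature_size * len(self.cell_types) > self.n_genes:
            raise ValueError("signature blocks exceed the gene universe")
        if not self.dirichlet_base:
            # tumor-dominated composition with a wide purity spread; BBB
            # cells get larger concentrations so the shared latent factor
            # (not Dirichlet noise) dominates their variation
            base = {TUMOR: 20.0}
            for ct in self.cell_types:
                base[ct] = 5.0 if _tilt_weight(ct) == 1.0 else 2.0
            self.dirichlet_base = base
        missing = [c for c in (*self.cell_types, TUMOR) if c not in self.dirichlet_base]
        if missing:
            raise ValueError(f"dirichlet_base missing components: {missing!r}")
        if any(a <= 0 for a in self.dirichlet_base.values()):
            raise ValueError("Dirichlet concentrations must be positive")

    @property
    def components(self) -> tuple:
        return (*self.cell_types, TUMOR)


@dataclass
class SyntheticTruth:
    """Planted ground truth used by recovery tests.

    ``fractions`` holds the per-sample simplex over cell types plus tumor;
    ``bbb_factor`` the latent u; ``purity`` the tumor fraction;
    ``linear_predictor`` the planted log-hazard ``hazard_beta * (u - 0.5)``;
    ``gene_ownership`` maps each gene to its owning signature ('' if
    background).
    """

    fractions: pd.DataFrame
    bbb_factor: pd.Series
    purity: pd.Series
    grade: pd.Series
    linear_predictor: pd.Series
    gene_ownership: pd.Series
    signatures: SignatureCollection
    stromal_set: GeneSet
    immune_set: GeneSet
    config: GeneratorConfig
    seed: int


def make_reference_profiles(
    cfg: GeneratorConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, SignatureCollection, pd.Series]:
    """Log2 reference profile per component plus the planted signature GMT.

    Marker blocks are disjoint by construction: the first
    ``signature_size * n_cell_types`` genes are partitioned among the cell
    types; each marker is elevated by ``signature_effect`` (log2) in its own
    type only.  The tumor profile is pure background.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:05d}" for i in range(1, cfg.n_genes + 1)]
    background = rng.uniform(2.0, 8.0, size=cfg.n_genes)
    profiles = pd.DataFrame(
        np.tile(background[:, None], (1, len(cfg.components))),
        index=pd.Index(genes, name="gene_id"),
        columns=list(cfg.components),
    )
    ownership = pd.Series("", index=profiles.index, name="signature")
    sets = []
    for i, ct in enumerate(cfg.cell_types):
        block = genes[i * cfg.signature_size : (i + 1) * cfg.signature_size]
        profiles.loc[block, ct] += cfg.signature_effect
        ownership.loc[block] = ct
        sets.append(GeneSet(ct, tuple(block), "cell_type", "planted marker block"))
    return profiles, SignatureCollection(sets, source="planted"), ownership


def _stromal_immune_sets(
    cfg: GeneratorConfig, signatures: SignatureCollection
) -> tuple[GeneSet, GeneSet]:
    """Derive stromal/immune compartment sets from the planted blocks.

    Stromal = markers of every positively tilted resident (BBB constituent
    cells plus microglia-like types), mirroring a general stromal signature;
    immune = markers of the non-neural immune-like residents only.  Falls
    back to the stromal genes if the catalog has no immune-like resident.
    """
    stromal_genes: list[str] = []
    immune_genes: list[str] = []
    for s in signatures:
        w = _tilt_weight(s.name)
        if w > 0:
            stromal_genes.extend(s.genes)
        if w == 0.5:
            immune_genes.extend(s.genes)
    if not immune_genes:
        immune_genes = list(stromal_genes)
    return (
        GeneSet("stromal", tuple(stromal_genes), "stromal", "planted stromal set"),
        GeneSet("immune", tuple(immune_genes), "immune", "planted immune set"),
    )


def simulate_cohort(
    cfg: GeneratorConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Draw a full synthetic cohort: expression, clinical table, truth.

    All randomness flows from ``cfg.seed`` through a single generator in a
    fixed order, so reruns with the same config are bit-identical.
    """
    rng = np.random.default_rng(cfg.seed)
    profiles, signatures, ownership = make_reference_profiles(cfg, rng)
    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]

    u = rng.uniform(0.0, 1.0, size=cfg.n_samples)
    kappa = cfg.bbb_link * cfg.tilt_scale
    alphas = np.array([cfg.dirichlet_base[c] for c in cfg.components])
    lambdas = np.array([_tilt_weight(c) for c in cfg.components])
    gammas = rng.gamma(shape=alphas, size=(cfg.n_samples, len(alphas)))
    weights = gammas * np.exp(np.outer(2.0 * u - 1.0, lambdas) * kappa)
    fractions = weights / weights.sum(axis=1, keepdims=True)
    frac_df = pd.DataFrame(
        fractions, index=pd.Index(samples, name="sample_id"), columns=list(cfg.components)
    )
    purity = frac_df[TUMOR].rename("purity")

    # linear-scale mixture of reference profiles with log-normal noise
    linear_profiles = np.exp2(profiles.to_numpy())
    mean_expr = linear_profiles @ fractions.T
    noise = rng.normal(0.0, cfg.noise_sd, size=mean_expr.shape)
    expr = pd.DataFrame(
        mean_expr * np.exp2(noise), index=profiles.index, columns=samples
    )
    matrix = ExpressionMatrix(expr, log_transformed=False)

    # grade: tertiles of the latent factor (rank-based, deterministic)
    ranks = pd.Series(u, index=samples).rank(method="first")
    tertile = np.ceil(ranks / len(ranks) * 3).astype(int).clip(1, 3)
    grade = tertile.map(dict(enumerate(cfg.grade_labels, start=1))).rename("grade")

    # age / KPS: Gaussian copula, mild positive rank link with u (target ~0.3)
    z_u = (pd.Series(u, index=samples).rank() - 0.5) / len(u)
    z_u = pd.Series(np.clip(np.vectorize(_probit)(z_u), -4, 4), index=samples)
    rho_cov = 0.3
    z_age = rho_cov * z_u + np.sqrt(1 - rho_cov**2) * rng.standard_normal(len(u))
    z_kps = rho_cov * z_u + np.sqrt(1 - rho_cov**2) * rng.standard_normal(len(u))
    age = np.clip(np.round(46 + 13 * z_age), 18, 89).astype(int)
    kps = np.clip(np.round((75 + 12 * z_kps) / 10) * 10, 40, 100).astype(int)

    histology = np.where(
        grade == cfg.grade_labels[-1],
        "glioblastoma",
        np.where(rng.uniform(size=len(u)) < 0.5, "astrocytoma", "oligodendroglioma"),
    )
    idh = np.where(rng.uniform(size=len(u)) < np.clip(0.9 - 0.8 * u, 0, 1),
                   "mutant", "wildtype")
    codel = np.where(rng.uniform(size=len(u)) < np.clip(0.5 - 0.4 * u, 0, 1),
                     "codel", "non-codel")

    lp = cfg.hazard_beta * (u - 0.5)
    rate = cfg.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    t_censor = rng.exponential(1.0 / cfg.censor_rate, size=len(u))
    os_time = np.minimum(t_event, t_censor)
    os_event = (t_event <= t_censor).astype(int)
    recurrence = rng.exponential(1.0 / ((1.0 / 600.0) * np.exp(lp)))

    clinical = pd.DataFrame(
        {
            "sample_id": samples,
            "grade": grade.to_numpy(),
            "histology": histology,
            "age": age,
            "kps": kps,
            "idh_status": idh,
            "codel_1p19q": codel,
            "os_time": np.maximum(np.round(os_time, 1), 0.1),
            "os_event": os_event,
            "days_to_recurrence": np.maximum(np.round(recurrence, 1), 0.1),
        }
    )

    stromal_set, immune_set = _stromal_immune_sets(cfg, signatures)
    truth = SyntheticTruth(
        fractions=frac_df,
        bbb_factor=pd.Series(u, index=samples, name="bbb_factor"),
        purity=purity,
        grade=grade,
        linear_predictor=pd.Series(lp, index=samples, name="linear_predictor"),
        gene_ownership=ownership,
        signatures=signatures,
        stromal_set=stromal_set,
        immune_set=immune_set,
        config=cfg,
        seed=cfg.seed,
    )
    return matrix, clinical, truth


def _probit(q: float) -> float:
    from scipy.special import ndtri

    return float(ndtri(q))


def evaluate_recovery(
    truth: SyntheticTruth,
    scores,
    bbb: pd.Series,
    cell_rho_threshold: float = 0.6,
    bbb_rho_threshold: float = 0.7,
) -> dict:
    """Spearman recovery of planted fractions and of the latent BBB factor.

    Returns per-cell-type rho (planted fraction vs recovered score), the rho
    between the latent factor u and the BBB score, and a pass flag against
    the configured thresholds.
    """
    from scipy.stats import spearmanr

    shared = truth.fractions.index.intersection(bbb.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    cell_rho = {}
    for ct in truth.config.cell_types:
        if ct in scores.score_names:
            rho, _ = spearmanr(
                truth.fractions.loc[shared, ct], scores.scores.loc[shared, ct]
            )
            cell_rho[ct] = float(rho)
    rho_u, _ = spearmanr(truth.bbb_factor.loc[shared], bbb.loc[shared])
    passed = bool(
        all(r >= cell_rho_threshold for r in cell_rho.values())
        and float(rho_u) >= bbb_rho_threshold
    )
    return {
        "cell_rho": cell_rho,
        "bbb_factor_rho": float(rho_u),
        "passed": passed,
        "thresholds": {
            "cell_rho": cell_rho_threshold,
            "bbb_factor_rho": bbb_rho_threshold,
        },
    }


def write_cohort(outdir, matrix, clinical, truth: SyntheticTruth) -> None:
    """Write expression/clinical/truth TSVs, planted GMTs and the config."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_expression_matrix(matrix, os.path.join(outdir, "expression.tsv"))
    write_clinical_table(clinical, os.path.join(outdir, "clinical.tsv"))
    truth_table = pd.concat(
        [
            truth.fractions,
            truth.bbb_factor,
            truth.purity.rename("purity"),
            truth.grade.rename("grade"),
            truth.linear_predictor,
        ],
        axis=1,
    )
    truth_table.index.name = "sample_id"
    truth_table.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t")
    write_gmt(truth.signatures, os.path.join(outdir, "planted_signatures.gmt"))
    write_gmt(
        SignatureCollection([truth.stromal_set, truth.immune_set]),
        os.path.join(outdir, "stromal_immune.gmt"),
    )
    cfg = truth.config
    cfg_dict = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(cfg).items()
    }
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
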