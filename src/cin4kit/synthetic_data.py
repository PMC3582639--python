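"""Seeded synthetic cohorts with a planted chromosomal-instability factor.

Each simulated tumor carries a latent instability level ``L`` drawn around
a grade-specific mean (grade 3 tumors carry more instability, but grade is
a noisy label for ``L`` — the overlap is deliberate, mirroring the
imperfect relationship between histological grade and ploidy).  Everything
downstream hangs off ``L``:

- signature genes load linearly on ``L`` (background genes do not);
- qPCR Ct values are built on the log2 scale with expression entering
  negatively (one cycle = two-fold), with a gene-specific offset, a
  per-sample loading offset, well noise, and duplicated wells;
- recurrence-free survival is exponential with hazard
  ``baseline * exp(log_hr_per_cin_unit * L)`` under independent uniform
  censoring (the simplest proportional-hazards mechanism), reported at
  month resolution so tied event times occur as they do in clinical data;
- aneuploidy probability is logistic in ``L``; aneuploid tumors receive a
  DNA index above the 1.10 calling threshold and a Gaussian-mixture
  DNA-content histogram with diploid and tumor G1/G2 peaks plus debris;
- proliferation markers (Ki67, mitotic index), receptor negativity and
  tumor size shift with ``L``.

The per-sample truth (latent value, true DNA index, true risk group) is
kept alongside the observables so recovery can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .ploidy_facs import DnaHistogram
from .qpcr_scoring import TARGET_GENES, REFERENCE_GENES
from .signature_reduction import ExpressionCohort

__all__ = [
    "SimConfig",
    "SyntheticCohort",
    "ConfigError",
    "generate_cohort",
    "generate_histogram",
]


class ConfigError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults reproduce the design of the motivating study: 63/62/60 tumors
    in grades 1/2/3, a 70-gene instability signature containing the four
    qPCR target genes, duplicate-well qPCR for 4 target + 3 reference
    genes, a planted per-unit hazard ratio of 2, and ~120 months of
    follow-up.
    """

    n_per_grade: tuple = (63, 62, 60)
    n_signature_genes: int = 70
    n_background_genes: int = 130

    # latent instability factor
    cin_grade_means: tuple = (-1.0, 0.0, 1.0)
    cin_sd: float = 0.8

    # expression model
    loading_range: tuple = (0.5, 1.5)
    expr_noise_sd: float = 1.0
    n_boosted_genes: int = 0       # planted-loading studies: first k genes
    boost_factor: float = 3.0

    # qPCR model (cycles)
    ct_noise_sd: float = 0.25
    replicate_sd: float = 0.15
    sample_ct_offset_sd: float = 0.0

    # survival model (months)
    baseline_hazard: float = 0.012
    log_hr_per_cin_unit: float = float(np.log(2.0))
    censor_time_max: float = 120.0

    # ploidy model
    aneuploidy_logistic: tuple = (-0.1, 1.0)   # (intercept, slope) on L
    histogram_channels: int = 1024
    n_events_per_histogram: int = 20000
    reference_g1_channel: float = 200.0
    histogram_cv: float = 0.012

    seed: int = 0

    def validate(self) -> "SimConfig":
        for name in ("n_signature_genes", "n_background_genes",
                     "histogram_channels", "n_events_per_histogram"):
            if getattr(self, name) < 0 or (
                name in ("n_signature_genes", "histogram_channels")
                and getattr(self, name) <= 0
            ):
                raise ConfigError(f"{name} must be positive")
        if len(self.n_per_grade) != 3 or any(n <= 0 for n in self.n_per_grade):
            raise ConfigError("n_per_grade must be three positive counts")
        if len(self.cin_grade_means) != 3 or not (
            self.cin_grade_means[0] < self.cin_grade_means[1] < self.cin_grade_means[2]
        ):
            raise ConfigError("cin_grade_means must be strictly increasing")
        for name in ("cin_sd", "expr_noise_sd", "ct_noise_sd", "replicate_sd"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.sample_ct_offset_sd < 0:
            raise ConfigError("sample_ct_offset_sd must be >= 0")
        if self.censor_time_max <= 0:
            raise ConfigError("censor_time_max must be > 0")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.loading_range[0] > self.loading_range[1] or self.loading_range[0] < 0:
            raise ConfigError("loading_range must be 0 <= low <= high")
        if self.n_boosted_genes < 0 or self.n_boosted_genes > self.n_signature_genes:
            raise ConfigError("n_boosted_genes must lie in [0, n_signature_genes]")
        if len(self.aneuploidy_logistic) != 2:
            raise ConfigError("aneuploidy_logistic must be (intercept, slope)")
        if self.n_signature_genes < len(TARGET_GENES):
            raise ConfigError(
                f"n_signature_genes must be >= {len(TARGET_GENES)} "
                "(the qPCR target genes head the signature)"
            )
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticCohort:
    expression: ExpressionCohort
    qpcr: pd.DataFrame                 # long table: sample, gene, replicate, ct
    histograms: dict                   # sample -> DnaHistogram
    clinical: pd.DataFrame             # indexed by sample
    truth: pd.DataFrame                # indexed by sample
    config: SimConfig = field(repr=False, default=None)

    def __post_init__(self):
        ids = list(self.expression.sample_ids)
        for name, other in (
            ("clinical", list(self.clinical.index)),
            ("truth", list(self.truth.index)),
            ("histograms", list(self.histograms.keys())),
            ("qpcr", sorted(self.qpcr["sample"].unique())),
        ):
            if sorted(other) != sorted(ids):
                raise ValueError(f"{name} does not index the same samples as expression")

    @property
    def sample_ids(self) -> list:
        return list(self.expression.sample_ids)


def _signature_gene_ids(n: int) -> list:
    ids = list(TARGET_GENES)
    ids += [f"CIN_G{i:03d}" for i in range(len(ids) + 1, n + 1)]
    return ids[:n]


def generate_histogram(
    dna_index: float,
    n_events: int,
    channels: int = 1024,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    reference_channel: float = 200.0,
    cv: float = 0.012,
    aneuploid_fraction: float = 0.35,
    g2_fraction: float = 0.12,
    debris_fraction: float = 0.03,
) -> DnaHistogram:
    """Multinomial draw from a Gaussian-mixture DNA-content model.

    Diploid G1 at the reference channel with a G2/M companion at twice the
    channel; if ``dna_index > 1`` an aneuploid G1 (and its G2/M) is added at
    ``dna_index`` times the reference; a small uniform debris floor covers
    the full range.  Peak widths scale with position (constant CV).
    ``n_events = 0`` yields an empty (unusable) histogram.
    """
    if dna_index < 1.0:
        raise ValueError("dna_index must be >= 1.0 (hypo-diploid not modeled)")
    if rng is None:
        rng = np.random.default_rng(seed)
    centers = np.arange(1, channels + 1, dtype=float)

    def peak(pos, mass):
        sd = cv * pos
        return mass * np.exp(-0.5 * ((centers - pos) / sd) ** 2) / (
            sd * np.sqrt(2 * np.pi)
        )

    c0 = reference_channel
    signal = 1.0 - debris_fraction
    if dna_index > 1.0:
        dip = signal * (1.0 - aneuploid_fraction)
        ane = signal * aneuploid_fraction
        dens = (
            peak(c0, dip * (1 - g2_fraction))
            + peak(2 * c0, dip * g2_fraction)
            + peak(dna_index * c0, ane * (1 - g2_fraction))
            + peak(2 * dna_index * c0, ane * g2_fraction)
        )
    else:
        dens = peak(c0, signal * (1 - g2_fraction)) + peak(2 * c0, signal * g2_fraction)
    dens = dens + debris_fraction / channels
    prob = dens / dens.sum()
    counts = rng.multinomial(int(n_events), prob) if n_events > 0 else np.zeros(
        channels, dtype=int
    )
    return DnaHistogram(channels=centers, counts=counts)


def _simulate_survival(latent, cfg: SimConfig, rng: np.random.Generator):
    """Exponential event times under proportional hazards, uniform censoring.

    Times are reported at month resolution (minimum one month), so tied
    event times occur; the event indicator is 1 when the event precedes
    censoring.
    """
    rate = cfg.baseline_hazard * np.exp(cfg.log_hr_per_cin_unit * latent)
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0.0, cfg.censor_time_max, size=latent.size)
    observed = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    months = np.maximum(1.0, np.round(observed))
    return months, event


def generate_cohort(config: SimConfig) -> SyntheticCohort:
    """Generate a full seeded cohort (expression, qPCR, histograms, clinical).

    Identical configs (including the seed) give bit-identical cohorts: all
    sub-generators derive child seeds deterministically from ``config.seed``.
    """
    cfg = config.validate()
    ss = np.random.SeedSequence(cfg.seed)
    (ss_latent, ss_load, ss_expr, ss_qpcr, ss_surv,
     ss_clin, ss_ploidy, ss_hist) = ss.spawn(8)

    n1, n2, n3 = cfg.n_per_grade
    n = n1 + n2 + n3
    grade = np.array([1] * n1 + [2] * n2 + [3] * n3)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    rng_latent = np.random.default_rng(ss_latent)
    means = np.array(cfg.cin_grade_means)[grade - 1]
    latent = rng_latent.normal(means, cfg.cin_sd)

    # --- expression -------------------------------------------------------
    rng_load = np.random.default_rng(ss_load)
    rng_expr = np.random.default_rng(ss_expr)
    sig_ids = _signature_gene_ids(cfg.n_signature_genes)
    bg_ids = [f"BG_{i:04d}" for i in range(1, cfg.n_background_genes + 1)]
    loadings = rng_load.uniform(*cfg.loading_range, size=cfg.n_signature_genes)
    if cfg.n_boosted_genes:
        loadings[: cfg.n_boosted_genes] *= cfg.boost_factor
    sig = loadings[:, None] * latent[None, :] + rng_expr.normal(
        0.0, cfg.expr_noise_sd, size=(cfg.n_signature_genes, n)
    )
    bg = rng_expr.normal(0.0, 1.0, size=(cfg.n_background_genes, n))
    matrix = pd.DataFrame(
        np.vstack([sig, bg]), index=sig_ids + bg_ids, columns=sample_ids
    )

    # --- survival ---------------------------------------------------------
    rng_surv = np.random.default_rng(ss_surv)
    months, event = _simulate_survival(latent, cfg, rng_surv)

    # --- clinical covariates ---------------------------------------------
    rng_clin = np.random.default_rng(ss_clin)
    ki67 = np.clip(20.0 + 12.0 * latent + rng_clin.normal(0, 8, n), 1.0, 95.0)
    mitotic = np.clip(
        np.round(10.0 + 6.0 * latent + rng_clin.normal(0, 4, n)), 0, 60
    ).astype(int)
    size_mm = np.round(
        np.clip(15.0 + 4.0 * grade + 3.0 * latent + rng_clin.normal(0, 6, n), 5.0, 90.0),
        1,
    )
    u = _sigmoid(0.4 * latent + rng_clin.normal(0, 1, n))
    node_stage = 1 + (u > 0.45).astype(int) + (u > 0.75).astype(int)
    er_pos = rng_clin.uniform(size=n) > _sigmoid(-1.5 + 0.8 * latent)
    pgr_pos = rng_clin.uniform(size=n) > _sigmoid(-1.2 + 0.8 * latent)
    her2_pos = rng_clin.uniform(size=n) < _sigmoid(-2.2 + 0.6 * latent)
    her2_amp = her2_pos & (rng_clin.uniform(size=n) < 0.8)
    vascular = rng_clin.uniform(size=n) < _sigmoid(-0.3 + 0.6 * latent)
    necrosis = rng_clin.uniform(size=n) < _sigmoid(-1.0 + 0.8 * latent)
    age = np.round(np.clip(rng_clin.normal(58.8, 12.8, n), 23, 95), 1)
    npi = 0.2 * (size_mm / 10.0) + node_stage + grade

    clinical = pd.DataFrame(
        {
            "grade": grade,
            "age": age,
            "tumor_size_mm": size_mm,
            "node_stage": node_stage,
            "vascular_invasion": vascular.astype(int),
            "necrosis": necrosis.astype(int),
            "er_positive": er_pos.astype(int),
            "pgr_positive": pgr_pos.astype(int),
            "her2_positive": her2_pos.astype(int),
            "her2_amplified": her2_amp.astype(int),
            "ki67": np.round(ki67, 1),
            "mitotic_index": mitotic,
            "npi": np.round(npi, 2),
            "survival_months": months,
            "event": event,
        },
        index=pd.Index(sample_ids, name="sample"),
    )

    # --- qPCR plate -------------------------------------------------------
    rng_qpcr = np.random.default_rng(ss_qpcr)
    qpcr_genes = list(TARGET_GENES) + list(REFERENCE_GENES)
    offsets = {g: rng_qpcr.uniform(22.0, 30.0) for g in qpcr_genes}
    sample_offset = rng_qpcr.normal(0.0, cfg.sample_ct_offset_sd, size=n)
    records = []
    for gi, g in enumerate(qpcr_genes):
        if g in TARGET_GENES:
            expr = matrix.loc[g].to_numpy()
        else:
            expr = np.zeros(n)  # housekeeping: no biological variation
        ct_true = offsets[g] - expr + sample_offset + rng_qpcr.normal(
            0.0, cfg.ct_noise_sd, size=n
        )
        for rep in (1, 2):
            ct_rep = ct_true + rng_qpcr.normal(0.0, cfg.replicate_sd, size=n)
            for si, s in enumerate(sample_ids):
                records.append(
                    {"sample": s, "gene": g, "replicate": rep,
                     "ct": float(np.clip(ct_rep[si], 5.0, 45.0))}
                )
    qpcr = pd.DataFrame.from_records(records)

    # --- ploidy truth and histograms -------------------------------------
    rng_ploidy = np.random.default_rng(ss_ploidy)
    a, b = cfg.aneuploidy_logistic
    p_aneu = _sigmoid(a + b * latent)
    aneuploid = rng_ploidy.uniform(size=n) < p_aneu
    di_true = np.ones(n)
    di_true[aneuploid] = np.clip(
        1.2 + 0.15 * latent[aneuploid] + rng_ploidy.normal(0, 0.12, aneuploid.sum()),
        1.12,
        1.85,
    )
    hist_seeds = ss_hist.spawn(n)
    histograms = {
        s: generate_histogram(
            di_true[i],
            cfg.n_events_per_histogram,
            channels=cfg.histogram_channels,
            rng=np.random.default_rng(hist_seeds[i]),
            reference_channel=cfg.reference_g1_channel,
            cv=cfg.histogram_cv,
        )
        for i, s in enumerate(sample_ids)
    }

    mid = 0.5 * (cfg.cin_grade_means[0] + cfg.cin_grade_means[2])
    truth = pd.DataFrame(
        {
            "latent_cin": latent,
            "true_dna_index": di_true,
            "true_ploidy": np.where(aneuploid, "aneuploid", "diploid"),
            "true_risk_group": np.where(latent > mid, "high", "low"),
            "aneuploidy_prob": p_aneu,
        },
        index=pd.Index(sample_ids, name="sample"),
    )

    expression = ExpressionCohort(matrix=matrix, annotations=clinical, name="synthetic")
    return SyntheticCohort(
        expression=expression,
        qpcr=qpcr,
        histograms=histograms,
        clinical=clinical,
        truth=truth,
        config=cfg,
    )
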