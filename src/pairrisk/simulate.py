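"""Synthetic tumor/normal cohorts with the structure the pipeline assumes.

The generator emulates a two-registry ovarian-cancer design: a tumor cohort
with survival follow-up and a smaller normal-tissue cohort, expression on
the log2(FPKM+1) scale, a block of lncRNAs differentially expressed in
tumor (mostly up), each differentially expressed lncRNA coexpressed with at
least one immune gene, survival driven by a small set of latent lncRNA-pair
indicators through a proportional-hazards law with constant baseline
hazard, and immune-infiltration fractions that increase monotonically with
the latent risk while checkpoint genes shift between risk groups.

Every generator is a pure function of (scenario, seed): the scenario's
``rng_seed`` is split into independent streams for expression, survival and
infiltration, so regenerating any piece is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix
from .pairs import pair_id

# checkpoint genes reported to differ between risk groups; the last two
# move up in high-risk samples, the rest down
CHECKPOINT_DOWN = ("CD244", "LAG3", "ICOS", "CTLA4", "CD48", "TNFRSF4",
                   "CD80", "TMIGD2", "IDO1", "TNFRSF18", "CD274", "CD40")
CHECKPOINT_UP = ("CD276", "TNFRSF25")

CELL_TYPES = ("neutrophil", "endothelial_cell", "macrophage",
              "cancer_associated_fibroblast", "t_cell", "mast_cell")

DAYS_PER_YEAR = 365.25


@dataclass
class SimScenario:
    """Parameters of one synthetic cohort.

    Defaults mirror the reference study design: 379 tumor vs 88 normal
    samples, 171 up- and 7 down-regulated lncRNAs, a 7-pair causal
    signature with coefficient magnitudes in the 0.4-0.7 range, an
    exponential baseline with ~3-year median survival for an average-risk
    patient, and 40% censoring.
    """

    n_tumor: int = 379
    n_normal: int = 88
    n_lncrna: int = 300
    n_immune_gene: int = 150
    n_de_up: int = 171
    n_de_down: int = 7
    de_effect: float = 1.5          # log2-fold shift in tumor
    corr_block_rho: float = 0.6     # planted lncRNA/immune-gene correlation
    n_causal_pairs: int = 7
    causal_betas: tuple = (-0.37, -0.39, 0.51, -0.52, -0.73, -0.54, 0.40)
    baseline_hazard: float = np.log(2) / (3 * DAYS_PER_YEAR)  # per day
    censor_rate: float = 0.4
    age_risk_link: bool = True
    age_risk_coef: float = 3.0      # years of age per SD of linear predictor
    infil_noise_sd: float = 0.05
    checkpoint_shift: float = 1.0   # log2 units between risk groups
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_de_up + self.n_de_down > self.n_lncrna:
            raise ValueError("n_de_up + n_de_down exceeds n_lncrna")
        self.causal_betas = tuple(float(b) for b in self.causal_betas)
        if len(self.causal_betas) != self.n_causal_pairs:
            raise ValueError("causal_betas length must equal n_causal_pairs")
        if not 0 < self.corr_block_rho < 1:
            raise ValueError("corr_block_rho must lie in (0, 1)")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.n_tumor < 1 or self.n_normal < 0:
            raise ValueError("degenerate scenario: need tumor samples")
        if 2 * self.n_causal_pairs > max(self.n_de_up, 1):
            raise ValueError("not enough upregulated lncRNAs to host the "
                             "causal pairs")

    def _streams(self):
        ss = np.random.SeedSequence(self.rng_seed)
        return [np.random.default_rng(c) for c in ss.spawn(3)]

    # deterministic gene naming so downstream stages can find the truth
    def lncrna_ids(self):
        up = [f"LNCU{i:04d}" for i in range(self.n_de_up)]
        down = [f"LNCD{i:04d}" for i in range(self.n_de_down)]
        null = [f"LNCN{i:04d}" for i in
                range(self.n_lncrna - self.n_de_up - self.n_de_down)]
        return up, down, null

    def immune_ids(self):
        return [f"IMM{i:04d}" for i in range(self.n_immune_gene)]

    def causal_pair_ids(self):
        """The planted pairs: consecutive upregulated lncRNAs (2k, 2k+1)."""
        up, _, _ = self.lncrna_ids()
        return [pair_id(up[2 * k], up[2 * k + 1])
                for k in range(self.n_causal_pairs)]


def simulate_expression(s: SimScenario):
    """Draw the expression matrix and its gene annotation.

    Returns ``(ExpressionMatrix, annotation DataFrame)``. lncRNA values are
    Gaussian on the log2 scale around gene-specific means (clipped at 0, as
    log2(FPKM+1) demands); differentially expressed lncRNAs are shifted by
    +/- ``de_effect`` in tumor samples; every DE lncRNA and half of the
    null lncRNAs share a latent factor with one immune gene at population
    correlation ``corr_block_rho``. The two members of each causal pair get
    equal base means so their ordering indicator is informative (near 50/50)
    rather than frozen by a mean offset.
    """
    rng = s._streams()[0]
    up, down, null = s.lncrna_ids()
    lnc_ids = up + down + null
    imm_ids = s.immune_ids()
    pc_ids = [f"PC{i:03d}" for i in range(10)]
    other_ids = [f"OTH{i:02d}" for i in range(5)]
    n = s.n_tumor + s.n_normal
    tumor_ids = [f"TUMOR{i:04d}" for i in range(s.n_tumor)]
    normal_ids = [f"NORM{i:04d}" for i in range(s.n_normal)]
    samples = tumor_ids + normal_ids
    is_tumor = np.array([1] * s.n_tumor + [0] * s.n_normal, float)

    mu_l = rng.uniform(2.0, 6.0, size=s.n_lncrna)
    # equal means within each causal pair keep the pair indicator balanced
    for k in range(s.n_causal_pairs):
        mu_l[2 * k + 1] = mu_l[2 * k]
    z_own = rng.standard_normal((s.n_lncrna, n))

    # immune genes carry the latent factors; each partnered lncRNA mixes its
    # partner's factor in at weight rho, giving population correlation rho
    mu_m = rng.uniform(2.0, 6.0, size=s.n_immune_gene)
    f = rng.standard_normal((s.n_immune_gene, n))
    M = mu_m[:, None] + f
    rho = s.corr_block_rho
    n_de = s.n_de_up + s.n_de_down
    # DE lncRNAs all get a partner; null lncRNAs alternate (half of them)
    partnered = list(range(n_de)) + [i for i in range(n_de, s.n_lncrna)
                                     if (i - n_de) % 2 == 0]
    partner_of = {}
    z_l = z_own.copy()
    for rank, i in enumerate(partnered):
        j = rank % s.n_immune_gene
        partner_of[lnc_ids[i]] = imm_ids[j]
        z_l[i] = rho * f[j] + np.sqrt(1 - rho ** 2) * z_own[i]

    shift = np.zeros(s.n_lncrna)
    shift[:s.n_de_up] = s.de_effect
    shift[s.n_de_up:s.n_de_up + s.n_de_down] = -s.de_effect
    L = mu_l[:, None] + z_l + shift[:, None] * is_tumor[None, :]

    PC = rng.uniform(2.0, 6.0, size=(10, 1)) + rng.standard_normal((10, n))
    OTH = rng.uniform(1.0, 4.0, size=(5, 1)) + rng.standard_normal((5, n))

    values = np.vstack([L, M, PC, OTH])
    values = np.maximum(values, 0.0)
    gene_ids = lnc_ids + imm_ids + pc_ids + other_ids
    df = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                      columns=samples)
    group = pd.Series(["tumor"] * s.n_tumor + ["normal"] * s.n_normal,
                      index=samples)
    ann = pd.DataFrame({
        "biotype": (["lncRNA"] * s.n_lncrna
                    + ["protein_coding"] * (s.n_immune_gene + 10)
                    + ["other"] * 5),
        "is_immune": ([False] * s.n_lncrna + [True] * s.n_immune_gene
                      + [False] * 15),
    }, index=pd.Index(gene_ids, name="gene_id"))
    expr = ExpressionMatrix(df, group)
    expr.immune_partner = partner_of  # planted blocks, for tests
    return expr, ann


def _pair_indicators(expr: ExpressionMatrix, pair_ids_, samples):
    ind = np.empty((len(pair_ids_), len(samples)))
    for r, pid in enumerate(pair_ids_):
        a, b = pid.split("|")
        ind[r] = (expr.values.loc[a, samples].to_numpy()
                  > expr.values.loc[b, samples].to_numpy()).astype(float)
    return ind


def simulate_survival(expr: ExpressionMatrix, s: SimScenario):
    """Exponential event times driven by the planted pair indicators.

    hazard = baseline_hazard * exp(sum of causal_betas * indicators); a
    fraction ``censor_rate`` of subjects is censored at a uniform fraction
    of their event time. Age is linked to the linear predictor when
    ``age_risk_link`` is set; grade and stage are drawn independently of
    risk. Returns ``(clinical DataFrame, truth dict)`` where truth carries
    the causal pair ids and each tumor sample's linear predictor.
    """
    rng = s._streams()[1]
    tumor = expr.samples_in_group("tumor")
    if not tumor:
        raise ValueError("no tumor samples present")
    causal = s.causal_pair_ids()
    ind = _pair_indicators(expr, causal, tumor)
    lp = np.asarray(s.causal_betas) @ ind
    hazard = s.baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(len(tumor)) < s.censor_rate
    u = rng.uniform(0.0, 1.0, len(tumor))
    time = np.where(censored, u * t_event, t_event)
    event = (~censored).astype(int)

    lp_sd = lp.std() if lp.std() > 0 else 1.0
    age = 60.0 + rng.normal(0.0, 8.0, len(tumor))
    if s.age_risk_link:
        age = age + s.age_risk_coef * (lp - lp.mean()) / lp_sd
    grade = rng.choice([1, 2, 3], size=len(tumor), p=[0.1, 0.3, 0.6])
    stage = rng.choice([1, 2, 3, 4], size=len(tumor), p=[0.05, 0.1, 0.35, 0.5])

    clinical = pd.DataFrame({
        "time": time, "event": event, "age": np.round(age, 1),
        "grade": grade, "stage": stage,
    }, index=pd.Index(tumor, name="sample_id"))
    truth = {"causal_pairs": causal, "linear_predictor":
             pd.Series(lp, index=tumor, name="lp")}
    return clinical, truth


def simulate_infiltration(risk: pd.Series, s: SimScenario):
    """Infiltration fractions and checkpoint expression tied to risk.

    Six cell types get fractions that are a strictly increasing function of
    the risk rank plus Gaussian noise of sd ``infil_noise_sd``; with zero
    noise each cell type is a perfect monotone transform of risk. Checkpoint
    genes are shifted by ``checkpoint_shift`` log2 units between the
    above/below-median risk halves (down for most, up for CD276/TNFRSF25).
    Returns ``(infiltration DataFrame, checkpoint DataFrame)``, both
    features x samples. A constant risk vector yields risk-independent
    tables (with a flag attribute ``degenerate_risk``).
    """
    rng = s._streams()[2]
    risk = pd.Series(risk)
    nsamp = len(risk)
    degenerate = np.ptp(risk.to_numpy(float)) == 0
    if degenerate:
        u = np.full(nsamp, 0.5)
    else:
        ranks = risk.rank(method="average").to_numpy()
        u = (ranks - 1) / max(nsamp - 1, 1)  # in [0, 1], monotone in risk
    base = np.linspace(0.08, 0.25, len(CELL_TYPES))
    slope = np.linspace(0.10, 0.30, len(CELL_TYPES))
    frac = (base[:, None] + slope[:, None] * u[None, :]
            + s.infil_noise_sd * rng.standard_normal((len(CELL_TYPES), nsamp)))
    frac = np.maximum(frac, 0.0)
    infil = pd.DataFrame(frac, index=pd.Index(CELL_TYPES, name="cell_type"),
                         columns=risk.index)

    genes = list(CHECKPOINT_DOWN) + list(CHECKPOINT_UP)
    mu = rng.uniform(2.0, 5.0, len(genes))
    high = (risk > risk.median()).to_numpy() if not degenerate else \
        np.zeros(nsamp, bool)
    sign = np.array([-1.0] * len(CHECKPOINT_DOWN) + [1.0] * len(CHECKPOINT_UP))
    expr = (mu[:, None] + rng.standard_normal((len(genes), nsamp))
            + s.checkpoint_shift * sign[:, None] * high[None, :])
    expr = np.maximum(expr, 0.0)
    checkpoint = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"),
                              columns=risk.index)
    infil.degenerate_risk = degenerate
    return infil, checkpoint


def simulate_cohort(s: SimScenario):
    """One full cohort: expression, annotation, clinical, truth,
    infiltration and checkpoint tables keyed by the true latent risk."""
    expr, ann = simulate_expression(s)
    clinical, truth = simulate_survival(expr, s)
    true_risk = np.exp(truth["linear_predictor"])
    infil, checkpoint = simulate_infiltration(true_risk, s)
    return {"expression": expr, "annotation": ann, "clinical": clinical,
            "truth": truth, "infiltration": infil, "checkpoint": checkpoint}
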