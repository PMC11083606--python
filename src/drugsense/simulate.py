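"""Synthetic study generator with known causal ground truth.

Emulates the inputs of the drug-repurposing pipeline: a cancer cell-line
panel (gene expression plus a partially missing drug screen whose AUC values
depend linearly on a few *parent* genes), patient cohorts (GBM vs control or
NPC) in which the parent genes of sensitive drugs are mean-shifted so that
GBM imputes as more drug-sensitive, optional cross-platform distortions, and
replicated dose-response (relative ATP) plates.

Every generated gene has a known role per drug:

* parent  -- causally drives the latent drug response (gene -> response),
* child   -- generated from the latent (noise-free) response
             (response -> gene), so it correlates without causing,
* confounded -- coupled to one parent gene only, hence correlated with the
             response but conditionally independent of it given that parent,
* bystander -- independent standard-normal noise.

AUC values are affinely rescaled per drug into the 10-20 band conventional
for large screening portals (lower = more sensitive); the affine parameters
are recorded in the truth object so that noise-free "true" AUCs can be
computed for any sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve

__all__ = [
    "SimulationConfig",
    "DrugTruth",
    "SyntheticTruth",
    "Cohort",
    "StudyData",
    "generate_cell_line_panel",
    "generate_patient_cohorts",
    "generate_study",
    "apply_platform_effect",
    "generate_dose_response",
]

GROUP_GBM = "GBM"
GROUP_CONTROL = "control"
GROUP_NPC = "NPC"

# rng substream tags so each stage draws from an independent stream of the
# single study seed
_STREAM_PANEL = 1
_STREAM_COHORT = 2
_STREAM_PLATFORM = 3
_STREAM_DOSE = 4


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pipeline inputs.

    Parameters
    ----------
    n_genes, n_cell_lines, n_drugs
        Dimensions of the cell-line panel.
    n_parents_per_drug, n_children_per_drug, n_confounded_per_drug
        Causal-role gene counts per drug; role sets are disjoint across all
        drugs, so ``n_drugs * (parents + children + confounded)`` must fit
        within ``n_genes``.
    effect_size
        Magnitude of every parent weight (gene -> AUC), child weight
        (response -> gene) and confounder coupling; signs are random.
    noise_sd
        SD of the additive noise on the latent response, on child genes and
        on confounded genes, relative to unit-variance gene expression.
    missing_fraction
        Fraction of cell-line x drug screens masked completely at random.
    n_gbm, n_control
        Cohort sizes for patient datasets.
    sensitivity_shift
        Mean shift applied to parent genes in GBM samples, directed so GBM
        imputes as *more* sensitive (lower AUC).
    n_sensitive_drugs
        How many drugs are truly more effective in GBM (their parents get
        the shift). ``None`` means all drugs.
    platform_distortion
        ``"none"`` or ``"monotone"`` (per-gene strictly increasing map).
    block_rho, block_size
        Optional equicorrelation among blocks of bystander genes
        (``block_rho == 0`` keeps them independent).
    """

    n_genes: int = 210
    n_cell_lines: int = 500
    n_drugs: int = 1
    n_parents_per_drug: int = 3
    n_children_per_drug: int = 3
    n_confounded_per_drug: int = 4
    effect_size: float = 1.0
    noise_sd: float = 1.0
    missing_fraction: float = 0.2
    n_gbm: int = 100
    n_control: int = 100
    sensitivity_shift: float = 1.0
    platform_distortion: str = "none"
    seed: int = 0
    n_sensitive_drugs: Optional[int] = None
    block_rho: float = 0.0
    block_size: int = 10

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cell_lines", "n_drugs", "n_gbm", "n_control"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in ("n_parents_per_drug", "n_children_per_drug", "n_confounded_per_drug"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        per_drug = (self.n_parents_per_drug + self.n_children_per_drug
                    + self.n_confounded_per_drug)
        if per_drug > self.n_genes:
            raise ConfigurationError(
                f"role genes per drug ({per_drug}) exceed n_genes ({self.n_genes})")
        if self.n_drugs * per_drug > self.n_genes:
            raise ConfigurationError(
                f"{self.n_drugs} drugs x {per_drug} role genes need more than "
                f"n_genes={self.n_genes}; role sets are disjoint across drugs")
        if self.n_confounded_per_drug > 0 and self.n_parents_per_drug == 0:
            raise ConfigurationError("confounded genes require at least one parent gene")
        if not 0 <= self.missing_fraction < 1:
            raise ConfigurationError("missing_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.platform_distortion not in ("none", "monotone"):
            raise ConfigurationError(
                f"platform_distortion must be 'none' or 'monotone', "
                f"got {self.platform_distortion!r}")
        if self.n_sensitive_drugs is not None and not 0 <= self.n_sensitive_drugs <= self.n_drugs:
            raise ConfigurationError("n_sensitive_drugs must be in [0, n_drugs]")
        if not 0 <= self.block_rho < 1:
            raise ConfigurationError("block_rho must be in [0, 1)")


@dataclass
class DrugTruth:
    """Ground-truth generative parameters for one drug."""

    parents: dict[str, float]                    # gene -> weight on latent response
    children: dict[str, float]                   # gene -> weight of response on gene
    confounded: dict[str, tuple[str, float]]     # gene -> (shared parent, coupling)
    scale_a: float                               # AUC = scale_a + scale_b * latent + noise
    scale_b: float
    sensitive: bool                              # parents shifted in GBM cohorts?

    @property
    def pc_genes(self) -> set[str]:
        """True parents-children set (direct causes and direct effects)."""
        return set(self.parents) | set(self.children)

    @property
    def confounded_genes(self) -> set[str]:
        return set(self.confounded)


@dataclass
class SyntheticTruth:
    """Full generative ground truth for one simulated study."""

    config: SimulationConfig
    drugs: dict[str, DrugTruth]

    def latent_response(self, expr: pd.DataFrame, drug: str) -> pd.Series:
        """Noise-free latent response (raw scale) of each sample/column."""
        t = self.drugs[drug]
        out = pd.Series(0.0, index=expr.columns)
        for gene, w in t.parents.items():
            out += w * expr.loc[gene]
        return out

    def true_auc(self, expr: pd.DataFrame, drug: str) -> pd.Series:
        """Noise-free AUC on the rescaled 10-20 screen scale."""
        t = self.drugs[drug]
        return t.scale_a + t.scale_b * self.latent_response(expr, drug)

    def to_json(self) -> str:
        payload = {
            "config": asdict(self.config),
            "drugs": {
                d: {
                    "parents": t.parents,
                    "children": t.children,
                    "confounded": {g: list(pc) for g, pc in t.confounded.items()},
                    "scale_a": t.scale_a,
                    "scale_b": t.scale_b,
                    "sensitive": t.sensitive,
                }
                for d, t in self.drugs.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        payload = json.loads(text)
        cfg = SimulationConfig(**payload["config"])
        drugs = {
            d: DrugTruth(
                parents=rec["parents"],
                children=rec["children"],
                confounded={g: (p, float(c)) for g, (p, c) in rec["confounded"].items()},
                scale_a=rec["scale_a"],
                scale_b=rec["scale_b"],
                sensitive=rec["sensitive"],
            )
            for d, rec in payload["drugs"].items()
        }
        return cls(config=cfg, drugs=drugs)


@dataclass
class Cohort:
    """One patient (or avatar) dataset: expression, labels, true response."""

    dataset_id: str
    expression: pd.DataFrame       # genes x samples
    labels: pd.Series              # sample -> group
    true_auc: pd.DataFrame         # samples x drugs, noise-free screen scale
    kind: str = "clinical"         # "clinical" or "avatar"
    observed_auc: pd.DataFrame = field(default_factory=pd.DataFrame)
    # samples x drugs: the response realization (noise included) each
    # sample's child genes were generated from, on the screen scale


@dataclass
class StudyData:
    """A full multi-dataset synthetic study."""

    panel_expression: pd.DataFrame
    screen: pd.DataFrame
    truth: SyntheticTruth
    cohorts: list[Cohort] = field(default_factory=list)

    @property
    def clinical(self) -> list[Cohort]:
        return [c for c in self.cohorts if c.kind == "clinical"]

    @property
    def avatar(self) -> Optional[Cohort]:
        av = [c for c in self.cohorts if c.kind == "avatar"]
        return av[0] if av else None


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def _signed(rng: np.random.Generator, magnitude: float, size: int) -> np.ndarray:
    return magnitude * rng.choice([-1.0, 1.0], size=size)


def _assign_roles(config: SimulationConfig, rng: np.random.Generator,
                  genes: list[str]) -> dict[str, DrugTruth]:
    """Draw disjoint parent/child/confounded gene sets and weights per drug."""
    per_drug = (config.n_parents_per_drug + config.n_children_per_drug
                + config.n_confounded_per_drug)
    pool = rng.permutation(config.n_genes)[: config.n_drugs * per_drug]
    n_sens = config.n_drugs if config.n_sensitive_drugs is None else config.n_sensitive_drugs
    drugs: dict[str, DrugTruth] = {}
    for d in range(config.n_drugs):
        chunk = pool[d * per_drug: (d + 1) * per_drug]
        p, c = config.n_parents_per_drug, config.n_children_per_drug
        parent_g = [genes[i] for i in chunk[:p]]
        child_g = [genes[i] for i in chunk[p: p + c]]
        conf_g = [genes[i] for i in chunk[p + c:]]
        parents = dict(zip(parent_g, _signed(rng, config.effect_size, p)))
        children = dict(zip(child_g, _signed(rng, config.effect_size, c)))
        confounded = {
            g: (parent_g[i % max(p, 1)], float(s))
            for i, (g, s) in enumerate(
                zip(conf_g, _signed(rng, config.effect_size, len(conf_g))))
        }
        drugs[f"D{d:02d}"] = DrugTruth(
            parents=parents, children=children, confounded=confounded,
            scale_a=15.0, scale_b=1.0, sensitive=d < n_sens)
    return drugs


def _base_expression(config: SimulationConfig, rng: np.random.Generator,
                     n_samples: int, role_rows: set[int]) -> np.ndarray:
    """Standard-normal expression; optional block correlation on bystanders."""
    expr = rng.standard_normal((config.n_genes, n_samples))
    if config.block_rho > 0:
        bystanders = [i for i in range(config.n_genes) if i not in role_rows]
        rho = config.block_rho
        for start in range(0, len(bystanders), config.block_size):
            block = bystanders[start: start + config.block_size]
            shared = rng.standard_normal(n_samples)
            expr[block] = (np.sqrt(rho) * shared
                           + np.sqrt(1 - rho) * expr[block])
    return expr


def _fill_role_genes(expr: pd.DataFrame, truth: SyntheticTruth,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Overwrite child/confounded gene rows; return raw responses per drug.

    The drug response realization is ``latent + noise`` where
    ``latent = sum_parents w * expression``. Child genes load linearly on
    the standardized response realization (so the response -> child edge is
    genuine: children carry the response's intrinsic noise, not just the
    parents' signal), confounded genes load on their single shared parent.
    Both are rescaled to unit variance so all gene marginals stay
    comparable. Iteration over drugs is in sorted key order for
    reproducibility.
    """
    cfg = truth.config
    sd = cfg.noise_sd
    n = expr.shape[1]
    responses: dict[str, np.ndarray] = {}
    for drug in sorted(truth.drugs):
        t = truth.drugs[drug]
        latent = np.zeros(n)
        for gene, w in t.parents.items():
            latent = latent + w * expr.loc[gene].to_numpy()
        resp = latent + sd * rng.standard_normal(n)
        responses[drug] = resp
        resp_sd = np.sqrt(cfg.effect_size**2 * len(t.parents) + sd * sd)
        z = resp / resp_sd if resp_sd > 0 else np.zeros(n)
        for gene, w in t.children.items():
            norm = np.sqrt(w * w + sd * sd)
            raw = w * z + sd * rng.standard_normal(n)
            expr.loc[gene] = raw / norm if norm > 0 else raw
        for gene, (parent, coupling) in t.confounded.items():
            norm = np.sqrt(coupling * coupling + sd * sd)
            raw = coupling * expr.loc[parent].to_numpy() + sd * rng.standard_normal(n)
            expr.loc[gene] = raw / norm if norm > 0 else raw
    return responses


def generate_cell_line_panel(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate the training panel: expression, drug screen and ground truth.

    Returns
    -------
    expression : DataFrame, genes x cell lines, ~standard normal per gene.
    screen : DataFrame, cell lines x drugs; AUC in the 10-20 band with
        ``missing_fraction`` of entries NaN (missing completely at random).
    truth : SyntheticTruth carrying all causal roles, weights and the
        per-drug affine AUC rescaling.
    """
    rng = np.random.default_rng([config.seed, _STREAM_PANEL])
    genes = _gene_ids(config.n_genes)
    lines = [f"CL{i:04d}" for i in range(config.n_cell_lines)]
    drug_truth = _assign_roles(config, rng, genes)
    truth = SyntheticTruth(config=config, drugs=drug_truth)

    role_rows = {genes.index(g) for t in drug_truth.values()
                 for g in (t.pc_genes | t.confounded_genes)}
    expr = pd.DataFrame(
        _base_expression(config, rng, config.n_cell_lines, role_rows),
        index=genes, columns=lines)
    responses = _fill_role_genes(expr, truth, rng)

    screen = pd.DataFrame(index=lines, columns=list(drug_truth), dtype=float)
    for drug, t in drug_truth.items():
        raw = responses[drug]
        lo, hi = raw.min(), raw.max()
        if hi > lo:
            b = 10.0 / (hi - lo)
            a = 10.0 - b * lo
        else:                          # degenerate flat response
            a, b = 15.0, 0.0
        t.scale_a, t.scale_b = float(a), float(b)
        screen[drug] = a + b * raw
    if config.missing_fraction > 0:
        mask = rng.random(screen.shape) < config.missing_fraction
        screen = screen.mask(mask)
    return expr, screen, truth


def generate_patient_cohorts(
    config: SimulationConfig,
    truth: SyntheticTruth,
    dataset_id: str = "cohort0",
    dataset_index: int = 0,
    control_label: str = GROUP_CONTROL,
    kind: str = "clinical",
) -> Cohort:
    """Simulate one patient/avatar dataset of ``n_gbm + n_control`` samples.

    GBM samples have each sensitive drug's parent genes mean-shifted by
    ``-sensitivity_shift * sign(weight)``, which lowers the latent response
    and hence the (true and imputed) AUC: GBM looks more sensitive. Control
    samples (label ``control`` or ``NPC``) are unshifted. Child and
    confounded genes are regenerated from the cohort's own latent responses
    and parent values, preserving the correlate-but-not-cause structure.
    """
    if control_label not in (GROUP_CONTROL, GROUP_NPC):
        raise ValueError(f"unknown group label {control_label!r}; "
                         f"expected {GROUP_CONTROL!r} or {GROUP_NPC!r}")
    rng = np.random.default_rng([config.seed, _STREAM_COHORT, dataset_index])
    n = config.n_gbm + config.n_control
    samples = [f"{dataset_id}_S{i:04d}" for i in range(n)]
    labels = pd.Series([GROUP_GBM] * config.n_gbm + [control_label] * config.n_control,
                       index=samples, name="group")
    gene_ids = _gene_ids(config.n_genes)
    rows = {gene_ids.index(g) for t in truth.drugs.values()
            for g in (t.pc_genes | t.confounded_genes)}
    expr = pd.DataFrame(_base_expression(config, rng, n, rows),
                        index=gene_ids, columns=samples)

    gbm_cols = labels.index[labels == GROUP_GBM]
    for t in truth.drugs.values():
        if not t.sensitive:
            continue
        for gene, w in t.parents.items():
            expr.loc[gene, gbm_cols] -= config.sensitivity_shift * np.sign(w)
    responses = _fill_role_genes(expr, truth, rng)

    true_auc = pd.DataFrame(
        {drug: truth.true_auc(expr, drug) for drug in truth.drugs},
        index=samples)
    observed_auc = pd.DataFrame(
        {drug: truth.drugs[drug].scale_a + truth.drugs[drug].scale_b * responses[drug]
         for drug in truth.drugs},
        index=samples)
    return Cohort(dataset_id=dataset_id, expression=expr, labels=labels,
                  true_auc=true_auc, kind=kind, observed_auc=observed_auc)


def generate_study(config: SimulationConfig, n_clinical: int = 5,
                   include_avatar: bool = True) -> StudyData:
    """Simulate a full study: one training panel plus independent cohorts.

    Clinical cohorts compare GBM against ``control`` (the low-grade-glioma
    stand-in); the avatar cohort compares GBM against ``NPC``.
    """
    expr, screen, truth = generate_cell_line_panel(config)
    cohorts = [
        generate_patient_cohorts(
            config, truth, dataset_id=f"clinical{i}", dataset_index=i,
            control_label=GROUP_CONTROL, kind="clinical")
        for i in range(n_clinical)
    ]
    if include_avatar:
        cohorts.append(generate_patient_cohorts(
            config, truth, dataset_id="avatar", dataset_index=n_clinical,
            control_label=GROUP_NPC, kind="avatar"))
    return StudyData(panel_expression=expr, screen=screen, truth=truth,
                     cohorts=cohorts)


def apply_platform_effect(expr: pd.DataFrame, distortion: str = "monotone",
                          seed: int = 0) -> pd.DataFrame:
    """Apply a per-gene platform effect; ``monotone`` preserves rank order.

    The monotone map is a random strictly increasing cubic,
    ``a + b*x + c*x**3`` with ``b, c > 0``, emulating the cross-platform
    distortions rank-based harmonization is meant to undo.
    """
    if distortion == "none":
        return expr.copy()
    if distortion != "monotone":
        raise ValueError(f"unknown distortion {distortion!r}")
    rng = np.random.default_rng([seed, _STREAM_PLATFORM])
    n_genes = expr.shape[0]
    a = rng.normal(0.0, 0.5, n_genes)[:, None]
    b = rng.uniform(0.5, 2.0, n_genes)[:, None]
    c = rng.uniform(0.1, 0.5, n_genes)[:, None]
    x = expr.to_numpy()
    return pd.DataFrame(a + b * x + c * x**3, index=expr.index,
                        columns=expr.columns)


def generate_dose_response(
    config: SimulationConfig,
    n_gbm: int = 4,
    n_npc: int = 2,
    drug: str = "D00",
    gbm_emax: float = 80.0,
    npc_emax: float = 15.0,
    hill: float = 1.2,
    rep_noise_sd: float = 4.0,
    n_doses: int = 9,
    n_replicates: int = 6,
) -> tuple[list[DoseResponseCurve], pd.Series, pd.Series]:
    """Simulate replicated relative-ATP dose-response plates.

    Nine doses log-spaced over 0.015-100 nM, six technical replicates per
    dose by default. Each sample follows a four-parameter logistic in
    log-dose (top fixed at 100% ATP, bottom ``100 - emax``) with per-sample
    EC50 jitter; GBM samples get the large maximal effect, NPC samples a
    small one. Returns the curves, sample group labels, and the noise-free
    trapezoidal AUC (log10-dose axis) of each underlying logistic.
    """
    rng = np.random.default_rng([config.seed, _STREAM_DOSE])
    doses = np.logspace(np.log10(0.015), np.log10(100.0), n_doses)
    log_d = np.log10(doses)
    curves: list[DoseResponseCurve] = []
    labels = {}
    true_auc = {}
    groups = [(GROUP_GBM, n_gbm, gbm_emax), (GROUP_NPC, n_npc, npc_emax)]
    for group, count, emax in groups:
        for i in range(count):
            sample = f"{group}_{i}"
            ec50 = 10 ** rng.uniform(np.log10(1.0), np.log10(30.0))
            # multiplicative jitter: a drug with zero maximal effect stays flat
            emax_i = float(np.clip(emax * rng.uniform(0.85, 1.15), 0.0, 100.0))
            clean = 100.0 - emax_i / (1.0 + (ec50 / doses) ** hill)
            atp = clean[None, :] + rng.normal(0.0, rep_noise_sd,
                                              (n_replicates, n_doses))
            curves.append(DoseResponseCurve(
                doses=doses, atp=atp, sample_id=sample, drug_id=drug))
            labels[sample] = group
            true_auc[sample] = float(np.trapezoid(clean, log_d))
    return curves, pd.Series(labels, name="group"), pd.Series(true_auc, name="true_auc")
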