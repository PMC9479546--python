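"""Synthetic multi-omics data with the statistical structure the pipeline
assumes, plus ground truth for recovery tests.

The generator emulates a two-sex staged floral development study: 8
conditions (M1..M4, F1..F4) x 3 replicate RNA-seq libraries, a 12-hormone +
4-sugar concentration panel on the same samples, and Ct tables consistent
with expression. It provides:

* negative-binomial fragment counts (variance = mu + phi * mu^2) with
  planted per-contrast log2 effects,
* a hub block: a set of genes whose stage-level expression follows a shared
  latent profile (high in late male stages, low in female stages), so that
  the co-expression network contains a recoverable module, together with
  designated background genes whose fold changes are null,
* hormone/sugar panels with log-normal replicate noise; analytes named in
  the hub spec track the same latent profile so planted transcript-compound
  correlations exist,
* Ct values Ct = a_ct - b_ct * log2(FPKM + 1) + N(0, sigma_ct), with a
  stage-constant reference gene,
* a gene -> pathway annotation in which each contrast's planted genes are
  concentrated in one designated pathway.

All randomness flows from a single integer seed through deterministically
spawned sub-streams, so identical configurations are bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import DEFAULT_STAGES, SampleDesign
from .diffexpr import CountMatrix, FpkmMatrix
from .groupstats import DEFAULT_HORMONES, DEFAULT_SUGARS, CompoundTable
from .qpcr import CtTable


class SimConfigError(ValueError):
    pass


#: Stage-indexed latent profile driving the hub block: high in the late male
#: stages, low/negative in female stages — mirroring a male-biased module.
DEFAULT_LATENT: dict[str, float] = {
    "M1": 0.0, "M2": 0.5, "M3": 1.0, "M4": 1.0,
    "F1": 0.0, "F2": -0.5, "F3": -1.0, "F4": -1.0,
}


@dataclass(frozen=True)
class DESpec:
    """Planted differential effect: in ``contrast`` ("AvsB"), a ``fraction``
    of eligible genes get a multiplicative log2 effect on the first-named
    stage, magnitude ~ Uniform(lfc_low, lfc_high), sign +-1 equiprobable."""

    contrast: str
    fraction: float
    lfc_low: float = 1.0
    lfc_high: float = 3.0


@dataclass(frozen=True)
class HubSpec:
    """Planted co-expression module.

    n_hub_features hub genes share the latent stage profile with mixing
    weight ``loading`` (1 = pure latent, 0 = pure gene-private wobble) and
    log2 amplitude ``gain``; ``n_background`` further genes are designated
    null-fold-change candidates for the network. ``linked_analytes`` from
    the compound panel track the same latent profile.
    """

    n_hub_features: int = 10
    loading: float = 0.9
    n_background: int = 90
    gain: float = 2.0
    linked_analytes: tuple[str, ...] = ("ZT", "TZR", "sucrose")


@dataclass(frozen=True)
class CompoundSpec:
    """One analyte of the concentration panel.

    ``stage_means`` fixes the per-stage expected concentration explicitly;
    when None, a smooth random stage profile around ``base`` is drawn (or
    the latent profile, for analytes named in the hub spec).
    """

    analyte: str
    kind: str  # 'hormone' | 'sugar'
    base: float | None = None  # stage-mean scale; drawn if None
    cv: float = 0.15           # log-normal replicate coefficient of variation
    stage_means: tuple[tuple[str, float], ...] | None = None


@dataclass(frozen=True)
class CtModel:
    """Ct = a_ct - b_ct * log2(FPKM + 1) + Normal(0, sigma_ct)."""

    a_ct: float = 35.0
    b_ct: float = 1.0
    sigma_ct: float = 0.2
    reference_fpkm: float = 500.0  # stage-constant expression of the reference
    tech_replicates: int = 3


def default_de_spec() -> tuple[DESpec, ...]:
    from .diffexpr import CONTRAST_NAMES

    return tuple(DESpec(name, 0.02, 1.0, 3.0) for name in CONTRAST_NAMES)


def default_compound_panel() -> tuple[CompoundSpec, ...]:
    hormones = tuple(CompoundSpec(a, "hormone") for a in DEFAULT_HORMONES)
    sugars = tuple(CompoundSpec(a, "sugar") for a in DEFAULT_SUGARS)
    return hormones + sugars


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated study."""

    n_genes: int = 5000
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 3
    dispersion: float = 0.05                       # NB: var = mu + phi mu^2
    library_size_range: tuple[float, float] = (4e6, 6e6)
    gene_length_range: tuple[int, int] = (500, 3000)
    baseline_log_mean: float = np.log(150.0)       # log-normal baseline counts
    baseline_log_sd: float = 1.2
    de_spec: tuple[DESpec, ...] = field(default_factory=default_de_spec)
    hub_spec: HubSpec = field(default_factory=HubSpec)
    compound_panel: tuple[CompoundSpec, ...] = field(default_factory=default_compound_panel)
    ct_model: CtModel = field(default_factory=CtModel)
    latent_profile: tuple[tuple[str, float], ...] = tuple(DEFAULT_LATENT.items())
    latent_wobble_sd: float = 0.75                 # sd of the gene-private stage term
    n_pathways: int = 20
    annotated_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise SimConfigError("n_genes must be positive")
        if self.replicates_per_stage < 2:
            raise SimConfigError("need >= 2 replicates per stage")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        if self.ct_model.sigma_ct < 0:
            raise SimConfigError("sigma_ct must be >= 0")
        if self.library_size_range[0] <= 0 or self.library_size_range[0] > self.library_size_range[1]:
            raise SimConfigError("invalid library_size_range")
        stage_set = set(self.stages)
        for spec in self.de_spec:
            if not 0 <= spec.fraction <= 1:
                raise SimConfigError(f"DE fraction outside [0,1] for {spec.contrast}")
            a, sep, b = spec.contrast.partition("vs")
            if not sep or a not in stage_set or b not in stage_set:
                raise SimConfigError(
                    f"de_spec contrast {spec.contrast!r} does not name two known stages"
                )
        for spec in self.compound_panel:
            if spec.kind not in ("hormone", "sugar"):
                raise SimConfigError(f"unknown analyte kind {spec.kind!r} for {spec.analyte}")
            if spec.cv < 0:
                raise SimConfigError("compound CV must be >= 0")
        n_candidates = self.hub_spec.n_hub_features + self.hub_spec.n_background
        if n_candidates > self.n_genes:
            raise SimConfigError("hub + background candidates exceed n_genes")

    @property
    def latent(self) -> dict[str, float]:
        return dict(self.latent_profile)

    def sample_ids(self) -> list[str]:
        return [f"{s}_{r}" for s in self.stages for r in range(1, self.replicates_per_stage + 1)]

    def design(self) -> SampleDesign:
        return SampleDesign.from_sample_ids(self.sample_ids(), allowed_stages=self.stages)


@dataclass
class GroundTruth:
    """Planted structure emitted alongside each simulated dataset."""

    de_genes: dict[str, dict[str, float]]      # contrast -> {gene: planted lfc}
    hub_features: set[str]
    background_features: set[str]
    latent_profiles: dict[str, float]          # stage -> latent value
    stage_log2_effect: pd.DataFrame            # genes x stages planted log2 shifts
    linked_analytes: set[str] = field(default_factory=set)
    pathway_of_contrast: dict[str, str] = field(default_factory=dict)

    def true_lfc(self, contrast: str) -> pd.Series:
        """Planted log2FC of every gene for a contrast (0 for null genes)."""
        a, _, b = contrast.partition("vs")
        return self.stage_log2_effect[a] - self.stage_log2_effect[b]

    @property
    def candidate_features(self) -> list[str]:
        feats = sorted(self.hub_features) + sorted(self.background_features)
        return feats + sorted(self.linked_analytes)


def negative_binomial(
    rng: np.random.Generator, mu: np.ndarray, phi: float, size=None
) -> np.ndarray:
    """NB draws parameterized by mean and dispersion: var = mu + phi * mu^2.

    phi = 0 degenerates to Poisson.
    """
    mu = np.asarray(mu, dtype=float)
    if phi == 0.0:
        return rng.poisson(mu, size=size)
    return rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu), size=size)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _rng_for(config: SimConfig, component: int) -> np.random.Generator:
    # one fixed sub-stream per pipeline component, all derived from config.seed
    return _streams(config.seed, 6)[component]


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the count matrix and record the planted truth.

    Counts for gene g, sample i of stage c are NB with mean
    mu_gic = N_i * q_gc / sum_g q_gc, where q_gc = b_g * 2^E_gc combines a
    log-normal baseline with the planted log2 effect matrix E (differential
    effects on the first-named stage of each contrast, plus the latent hub
    block), and variance mu + phi mu^2.
    """
    rng = _rng_for(config, 0)
    n = config.n_genes
    genes = [f"gene_{i:05d}" for i in range(n)]
    stages = list(config.stages)
    lengths = pd.Series(
        rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1, size=n),
        index=pd.Index(genes, name="gene_id"),
        name="length",
    )
    baseline = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)

    hub = config.hub_spec
    n_candidates = hub.n_hub_features + hub.n_background
    candidate_idx = rng.choice(n, size=n_candidates, replace=False) if n_candidates else np.array([], dtype=int)
    hub_idx = candidate_idx[: hub.n_hub_features]
    background_idx = candidate_idx[hub.n_hub_features:]
    # candidates are curated, well-expressed genes: keep their baselines off
    # the noisy low end so network profiles are not dominated by shot noise
    if n_candidates:
        baseline[candidate_idx] = np.exp(
            rng.uniform(np.log(200.0), np.log(2000.0), size=n_candidates)
        )

    effects = pd.DataFrame(0.0, index=genes, columns=stages)
    candidate_set = set(candidate_idx.tolist())
    eligible = np.array([i for i in range(n) if i not in candidate_set], dtype=int)

    de_genes: dict[str, dict[str, float]] = {}
    for spec in config.de_spec:
        stage_a = spec.contrast.partition("vs")[0]
        n_planted = int(round(spec.fraction * n))
        de_genes[spec.contrast] = {}
        if n_planted == 0:
            continue
        if n_planted > eligible.size:
            raise SimConfigError("not enough non-candidate genes to plant effects")
        chosen = rng.choice(eligible, size=n_planted, replace=False)
        mags = rng.uniform(spec.lfc_low, spec.lfc_high, size=n_planted)
        signs = rng.choice([-1.0, 1.0], size=n_planted)
        for idx, mag, sign in zip(chosen, mags, signs):
            lfc = float(sign * mag)
            effects.iloc[idx, effects.columns.get_loc(stage_a)] += lfc
            de_genes[spec.contrast][genes[idx]] = lfc

    latent = config.latent
    missing_latent = [s for s in stages if s not in latent]
    if missing_latent:
        raise SimConfigError(f"latent profile lacks stage(s) {missing_latent}")
    for idx in hub_idx:
        wobble = rng.normal(0.0, config.latent_wobble_sd, size=len(stages))
        for j, stage in enumerate(stages):
            effects.iloc[idx, j] += hub.gain * (
                hub.loading * latent[stage] + (1.0 - hub.loading) * wobble[j]
            )

    q = baseline[:, None] * np.power(2.0, effects.to_numpy())
    rel = q / q.sum(axis=0, keepdims=True)  # per-stage relative abundance

    sample_ids = config.sample_ids()
    counts = np.empty((n, len(sample_ids)), dtype=np.int64)
    phi = config.dispersion
    for i, sid in enumerate(sample_ids):
        stage = sid.rpartition("_")[0]
        target = rng.uniform(*config.library_size_range)
        mu = target * rel[:, stages.index(stage)]
        counts[:, i] = negative_binomial(rng, mu, phi)

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=sample_ids),
        lengths=lengths,
    )
    truth = GroundTruth(
        de_genes=de_genes,
        hub_features={genes[i] for i in hub_idx},
        background_features={genes[i] for i in background_idx},
        latent_profiles=dict(latent),
        stage_log2_effect=effects,
        linked_analytes=set(hub.linked_analytes),
    )
    return matrix, truth


def simulate_compounds(config: SimConfig, truth: GroundTruth) -> CompoundTable:
    """Hormone/sugar panel with log-normal replicate noise around stage means.

    Analytes named in the hub spec follow the latent stage profile (log2
    amplitude = hub gain), planting real correlations with the hub genes;
    the rest get smooth random stage profiles.
    """
    rng = _rng_for(config, 1)
    stages = list(config.stages)
    sample_ids = config.sample_ids()
    latent = truth.latent_profiles
    rows, kinds = {}, {}
    for spec in config.compound_panel:
        if spec.analyte in rows:
            raise SimConfigError(f"duplicate analyte {spec.analyte!r} in panel")
        base = spec.base if spec.base is not None else float(np.exp(rng.uniform(np.log(10), np.log(1000))))
        if spec.stage_means is not None:
            stage_means = dict(spec.stage_means)
            missing = [s for s in stages if s not in stage_means]
            if missing:
                raise SimConfigError(
                    f"analyte {spec.analyte!r}: stage_means lacks stage(s) {missing}"
                )
        elif spec.analyte in truth.linked_analytes:
            stage_means = {s: base * 2.0 ** (config.hub_spec.gain * latent[s]) for s in stages}
        else:
            shifts = rng.normal(0.0, 0.5, size=len(stages))
            stage_means = {s: base * 2.0**shift for s, shift in zip(stages, shifts)}
        sigma = float(np.sqrt(np.log1p(spec.cv**2)))  # mean-preserving log-normal
        values = []
        for sid in sample_ids:
            m = stage_means[sid.rpartition("_")[0]]
            if sigma == 0.0:
                values.append(m)
            else:
                values.append(float(m * np.exp(rng.normal(-sigma**2 / 2.0, sigma))))
        rows[spec.analyte] = values
        kinds[spec.analyte] = spec.kind
    table = pd.DataFrame(rows, index=sample_ids).T
    table.index.name = "analyte"
    return CompoundTable(values=table, kinds=pd.Series(kinds))


def simulate_ct(
    fpkm: FpkmMatrix,
    config: SimConfig,
    gene_ids,
    reference_gene: str = "ZaUBQ",
    calibrator_sample: str | None = None,
) -> CtTable:
    """Ct tables consistent with expression, plus a stage-constant reference.

    Ct = a_ct - b_ct * log2(FPKM + 1) + N(0, sigma_ct) per technical
    replicate. The reference gene is generated at a fixed expected Ct in
    every sample. The default calibrator is the first female sample.
    """
    rng = _rng_for(config, 2)
    model = config.ct_model
    missing = [g for g in gene_ids if g not in fpkm.gene_ids]
    if missing:
        raise KeyError(f"gene(s) absent from expression matrix: {missing}")
    samples = list(fpkm.sample_ids)
    if calibrator_sample is None:
        females = [s for s in samples if s.startswith("F")]
        calibrator_sample = females[0] if females else samples[0]
    ref_expected = model.a_ct - model.b_ct * np.log2(model.reference_fpkm + 1.0)
    records = []
    for sid in samples:
        for gene in list(gene_ids) + [reference_gene]:
            if gene == reference_gene:
                expected = ref_expected
            else:
                expected = model.a_ct - model.b_ct * np.log2(fpkm.fpkm.loc[gene, sid] + 1.0)
            for _ in range(model.tech_replicates):
                noise = rng.normal(0.0, model.sigma_ct) if model.sigma_ct > 0 else 0.0
                records.append({"sample": sid, "gene": gene, "ct": expected + noise})
    return CtTable(
        table=pd.DataFrame.from_records(records),
        reference_gene=reference_gene,
        calibrator_sample=calibrator_sample,
    )


def simulate_annotation(config: SimConfig, truth: GroundTruth):
    """Gene -> pathway annotation with contrast-linked planted pathways.

    About ``annotated_fraction`` of genes receive 1-3 of ``n_pathways``
    pathways uniformly; the genes planted for each contrast additionally
    join a pathway designated for that contrast with probability 0.5, so
    enrichment of a recovered DEG set is detectable.
    """
    from .enrich import PathwayAnnotation

    rng = _rng_for(config, 3)
    pathways = [f"pw{i:03d}" for i in range(1, config.n_pathways + 1)]
    names = {p: f"Pathway {i:03d}" for i, p in enumerate(pathways, start=1)}
    genes = list(truth.stage_log2_effect.index)
    gene_pathways: dict[str, set[str]] = {}
    for gene in genes:
        if rng.random() < config.annotated_fraction:
            k = int(rng.integers(1, 4))
            gene_pathways[gene] = set(rng.choice(pathways, size=k, replace=False).tolist())
    contrasts = sorted(truth.de_genes)
    for i, contrast in enumerate(contrasts):
        linked = pathways[i % len(pathways)]
        truth.pathway_of_contrast[contrast] = linked
        for gene in truth.de_genes[contrast]:
            if rng.random() < 0.5:
                gene_pathways.setdefault(gene, set()).add(linked)
    return PathwayAnnotation(gene_pathways=gene_pathways, pathway_names=names)
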