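"""Seeded synthetic multiplexed proteomics generator with planted structure.

Emulates the statistical shape of a TMT-multiplexed, cerebrovascular-enriched
brain proteome so every downstream stage has ground truth: proteins organised
into latent-factor co-expression modules, one pooled global-internal-standard
(GIS) channel per batch, additive log2 batch offsets, covariate effects
(age, PMI, endothelial cell proportion), abundance-dependent (MNAR)
missingness, and clinical traits generated from the planted module factors
through ordinal (proportional-odds), binary (logistic) and continuous
(linear) links.

Generative model, per protein g and sample s::

    log2(A_gs) = base_g + lambda_g * f_{m(g),s} + b_{batch(s)}
                 + sum_c beta_gc (c_s - mean c) + eps_gs,   eps ~ N(0, noise_sd^2)

with intensities 2**log2(A).  Module factors f are iid N(0,1) per sample,
standardised to exactly zero mean / unit variance.  GIS channels carry the
within-batch per-protein mean of subject-channel intensities plus small noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import AbundanceMatrix, SampleManifest

#: links supported for trait generation
TRAIT_LINKS = ("ordinal4", "binary", "linear")

#: equally spaced cumulative-logit cutpoints for the 4-level ordinal link
ORDINAL4_CUTPOINTS = (-1.1, 0.0, 1.1)


@dataclass(frozen=True)
class TraitLink:
    """A trait generated from one planted module's latent factor."""

    name: str
    module: int           # planted module index (0-based)
    link: str             # ordinal4 | binary | linear
    beta: float           # effect size on the standardised factor scale

    def __post_init__(self):
        if self.link not in TRAIT_LINKS:
            raise ValueError(f"unknown trait link {self.link!r}")


def default_trait_links() -> list[TraitLink]:
    return [
        TraitLink("caa_severity", 0, "ordinal4", 0.8),
        TraitLink("microbleeds", 1, "binary", 0.8),
        TraitLink("infarcts", 2, "binary", 0.6),
        TraitLink("wmh", 3, "linear", 0.5),
    ]


def default_covariate_effects() -> dict[str, tuple[float, float]]:
    # per-protein effect ~ N(mean, sd^2); units: log2 per covariate unit
    return {"age": (0.0, 0.01), "pmi": (0.0, 0.01), "cell_proportion": (0.0, 0.3)}


@dataclass
class SynthConfig:
    """Study conditions for the generator.

    Defaults emulate the cohort structure the pipeline targets: 6 planted
    modules of 50 proteins within 400 measured proteins, 120 subject channels
    spread over 7 multiplexed batches each carrying one GIS channel, with
    noise calibrated so planted within-module |bicor| averages >= 0.5.
    """

    n_proteins: int = 400
    n_modules: int = 6
    module_sizes: list[int] = field(default_factory=lambda: [50] * 6)
    n_samples: int = 120
    n_batches: int = 7
    gis_per_batch: int = 1
    loading_mean: float = 1.0
    loading_sd: float = 0.3
    #: residual log2 noise, calibrated together with batch_protein_sd so the
    #: planted within-module |bicor| averages >= 0.5 at the default loadings
    noise_sd: float = 0.7
    batch_effect_sd: float = 0.5
    #: sd of per-protein deviations around each batch offset (log2).  TMT
    #: batch effects are largely protein-specific (digestion, labeling and
    #: co-isolation differ per protein per plex); None -> 0.8*batch_effect_sd
    batch_protein_sd: float | None = None
    base_abundance_range: tuple[float, float] = (10.0, 20.0)
    missing_steepness: float = 1.0
    missing_midpoint: float = 9.0
    trait_links: list[TraitLink] = field(default_factory=default_trait_links)
    covariate_effects: dict[str, tuple[float, float]] = field(
        default_factory=default_covariate_effects)
    seed: int = 0

    def validate(self) -> None:
        if len(self.module_sizes) != self.n_modules:
            raise ValueError("module_sizes length must equal n_modules")
        if sum(self.module_sizes) > self.n_proteins:
            raise ValueError("sum(module_sizes) exceeds n_proteins")
        if any(m < 3 for m in self.module_sizes):
            raise ValueError("module sizes must all be >= 3")
        for name in ("loading_sd", "noise_sd", "batch_effect_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.batch_protein_sd is not None and self.batch_protein_sd < 0:
            raise ValueError("batch_protein_sd must be >= 0")
        if self.gis_per_batch < 1:
            raise ValueError("gis_per_batch must be >= 1")
        for tl in self.trait_links:
            if not (0 <= tl.module < self.n_modules):
                raise ValueError(
                    f"trait {tl.name!r} references nonexistent module {tl.module}")


@dataclass
class SyntheticTruth:
    """Ground truth for a generated dataset.

    ``planted_labels`` maps each protein to a 1-based module id (0 =
    background); ``latent_factors`` is modules x samples with exactly zero
    mean and unit variance per module over subject channels.
    """

    planted_labels: pd.Series
    latent_factors: pd.DataFrame
    batch_offsets: pd.Series
    covariate_betas: pd.DataFrame
    trait_betas: dict[str, float]
    loadings: pd.Series

    def to_jsonable(self) -> dict:
        return {
            "planted_labels": self.planted_labels.to_dict(),
            "latent_factors": {m: list(map(float, row))
                               for m, row in self.latent_factors.iterrows()},
            "batch_offsets": {str(k): float(v) for k, v in self.batch_offsets.items()},
            "covariate_betas": {c: self.covariate_betas[c].to_dict()
                                for c in self.covariate_betas.columns},
            "trait_betas": self.trait_betas,
            "loadings": self.loadings.to_dict(),
        }


# ---------------------------------------------------------------------------
# trait links

def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def ordinal4_probabilities(eta: np.ndarray,
                           cutpoints=ORDINAL4_CUTPOINTS) -> np.ndarray:
    """Category probabilities of the proportional-odds model
    P(Y <= k) = logistic(alpha_k - eta); returns shape (len(eta), 4)."""
    eta = np.asarray(eta, dtype=float)
    # cum[:, k] = logistic(alpha_k - eta)
    cum = _logistic(np.asarray(cutpoints)[None, :] - eta[:, None])
    cum = np.hstack([cum, np.ones((len(eta), 1))])
    probs = np.diff(cum, prepend=0.0, axis=1)
    return probs


def _draw_ordinal4(rng, eta):
    probs = ordinal4_probabilities(eta)
    u = rng.random(len(eta))
    return (u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1)


# ---------------------------------------------------------------------------
# generator

def generate_dataset(config: SynthConfig
                     ) -> tuple[AbundanceMatrix, SampleManifest, SyntheticTruth]:
    """Generate one seeded dataset: raw intensities, manifest, ground truth.

    Deterministic: the same config (including seed) produces bit-identical
    output.  Missing cells are explicit NaN — zeros are never emitted.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    P, S, K = config.n_proteins, config.n_samples, config.n_modules
    protein_ids = pd.Index([f"P{i:05d}" for i in range(P)], name="protein")
    sample_ids = [f"S{i:03d}" for i in range(S)]

    # planted membership: first sum(module_sizes) proteins in module blocks,
    # remainder background (label 0)
    labels = np.zeros(P, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[pos:pos + size] = m
        pos += size
    planted = pd.Series(labels, index=protein_ids, name="module")

    # latent factors, standardised exactly per module over subject channels
    F = rng.standard_normal((K, S))
    F = (F - F.mean(axis=1, keepdims=True)) / F.std(axis=1, keepdims=True)
    latent = pd.DataFrame(F, index=[f"M{m}" for m in range(1, K + 1)],
                          columns=sample_ids)

    # loadings ~ N(mean, sd), resampled away from zero so planted membership
    # is recoverable
    lam = rng.normal(config.loading_mean, config.loading_sd, size=P)
    floor = 0.25
    bad = np.abs(lam) < floor
    while bad.any():
        lam[bad] = rng.normal(config.loading_mean, config.loading_sd, size=bad.sum())
        bad = np.abs(lam) < floor
    lam[labels == 0] = 0.0
    loadings = pd.Series(lam, index=protein_ids, name="loading")

    base = rng.uniform(*config.base_abundance_range, size=P)

    # batches: subject channels dealt round-robin
    batch_names = [f"b{j + 1:02d}" for j in range(config.n_batches)]
    batch_of = np.array([j % config.n_batches for j in range(S)])
    b_off = rng.normal(0.0, config.batch_effect_sd, size=config.n_batches)
    batch_offsets = pd.Series(b_off, index=batch_names, name="log2_offset")
    # per-protein deviations around the batch offset; the GIS channel of a
    # batch experiences the same deviation, so the sample/GIS ratio removes it
    bp_sd = (0.8 * config.batch_effect_sd if config.batch_protein_sd is None
             else config.batch_protein_sd)
    d_batch = rng.normal(0.0, bp_sd, size=(P, config.n_batches))

    # covariates
    cov = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    cov["age"] = rng.normal(75.0, 8.0, size=S)
    cov["pmi"] = np.clip(rng.normal(8.0, 3.0, size=S), 1.0, None)
    cov["sex"] = np.where(rng.random(S) < 0.5, "F", "M")
    cov["apoe4"] = rng.choice([0, 1, 2], size=S, p=[0.60, 0.33, 0.07])
    cov["cell_proportion"] = rng.beta(2.0, 8.0, size=S)

    cov_betas = pd.DataFrame(0.0, index=protein_ids,
                             columns=list(config.covariate_effects))
    for c, (mu, sd) in config.covariate_effects.items():
        cov_betas[c] = rng.normal(mu, sd, size=P)

    # assemble log2 abundance for subject channels
    log2A = base[:, None] + lam[:, None] * np.where(
        labels[:, None] > 0, F[np.maximum(labels - 1, 0), :], 0.0)
    log2A = log2A + b_off[batch_of][None, :] + d_batch[:, batch_of]
    for c in cov_betas.columns:
        vals = pd.to_numeric(cov[c], errors="coerce").to_numpy(dtype=float)
        log2A = log2A + np.outer(cov_betas[c].to_numpy(), vals - np.nanmean(vals))
    log2A = log2A + rng.normal(0.0, config.noise_sd, size=(P, S))

    intens = np.power(2.0, log2A)

    # MNAR mask on subject channels: P(missing) = logistic(k * (mid - log2A))
    p_miss = _logistic(config.missing_steepness
                       * (config.missing_midpoint - log2A))
    miss = rng.random((P, S)) < p_miss
    intens_masked = np.where(miss, np.nan, intens)

    # GIS channels: one pooled all-sample mixture (global per-protein mean of
    # present subject intensities) measured once per batch, so it carries the
    # batch's offset plus small measurement noise (sd noise_sd/4 in log2).
    # A GIS cell is missing only where the protein is missing in every
    # subject channel (the pool cannot contain what was never measured).
    with np.errstate(invalid="ignore"):
        pool = np.nanmean(intens_masked, axis=1)
    gis_cols = {}
    gis_rows = []
    for j, bname in enumerate(batch_names):
        for r in range(config.gis_per_batch):
            gid = f"GIS_{bname}" if config.gis_per_batch == 1 else f"GIS_{bname}_{r + 1}"
            jitter = np.power(2.0, rng.normal(0.0, config.noise_sd / 4.0, size=P))
            gis_cols[gid] = pool * np.power(2.0, b_off[j] + d_batch[:, j]) * jitter
            gis_rows.append((gid, bname))

    values = pd.DataFrame(intens_masked, index=protein_ids, columns=sample_ids)
    for gid, col in gis_cols.items():
        values[gid] = col

    # traits from planted factors
    traits = pd.DataFrame(index=cov.index)
    trait_betas: dict[str, float] = {}
    for tl in config.trait_links:
        eta = tl.beta * F[tl.module, :]
        if tl.link == "ordinal4":
            traits[tl.name] = _draw_ordinal4(rng, eta)
        elif tl.link == "binary":
            traits[tl.name] = (rng.random(S) < _logistic(eta)).astype(int)
        else:  # linear, unit residual sd on the standardised factor scale
            traits[tl.name] = eta + rng.normal(0.0, 1.0, size=S)
        trait_betas[tl.name] = tl.beta

    # diagnosis and staging tied to the first planted module's factor
    traits["group"] = np.where(rng.random(S) < _logistic(1.0 * F[0, :]),
                               "AD", "control")
    traits["cerad"] = _draw_ordinal4(rng, 0.8 * F[0, :])
    traits["braak"] = _draw_ordinal4(rng, 0.8 * F[0, :]) + \
        _draw_ordinal4(rng, 0.8 * F[0, :])  # 0..6 staging

    manifest_rows = pd.DataFrame(index=pd.Index(list(values.columns),
                                                name="sample_id"))
    manifest_rows["batch"] = [batch_names[batch_of[i]] for i in range(S)] + \
        [b for _, b in gis_rows]
    manifest_rows["is_gis"] = [False] * S + [True] * len(gis_rows)
    for c in list(cov.columns) + list(traits.columns):
        src = cov[c] if c in cov.columns else traits[c]
        manifest_rows[c] = src.reindex(manifest_rows.index)

    X = AbundanceMatrix(values=values, scale_tag="raw")
    manifest = SampleManifest(manifest_rows)
    truth = SyntheticTruth(planted_labels=planted, latent_factors=latent,
                           batch_offsets=batch_offsets, covariate_betas=cov_betas,
                           trait_betas=trait_betas, loadings=loadings)
    return X, manifest, truth
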