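"""Synthetic exome-like case-control data generator.

Emulates the structure of a mini-exome association study of unrelated
individuals: three continental subpopulations with Balding-Nichols allele
frequency divergence at common variants, a MAF spectrum in which ~74% of
variants are rare (MAF < 1%), synonymous/nonsynonymous labels, a binary
environmental exposure (smoking), and a logistic disease model with
optional marginal genetic, gene-environment and SNP-SNP interaction
effects.  Case/control totals can be held fixed across replicates by
rejection sampling, and genotypes are shared between the two members of a
screening/testing replicate pair.

Defaults mirror the emulated study: 697 individuals, 209 affected / 488
unaffected, ~30% disease prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .data_model import (
    Dataset,
    GenotypeMatrix,
    SnpSet,
    ValidationError,
    classify_variant_frequency,
    compute_maf,
    standardize_columns,
)


@dataclass
class EffectSpec:
    """Disease-model contribution of one causal gene (log-odds scale).

    beta_common  — effect per standardized common-variant dosage (summed
                   over the gene's common variants);
    beta_rare    — effect of the standardized rare-allele burden;
    gamma_ge     — exposure x rare-burden interaction;
    eta_snp_snp  — product interaction of the gene's first two common
                   variants (standardized dosages).
    """

    gene: str
    beta_common: float = 0.0
    beta_rare: float = 0.0
    gamma_ge: float = 0.0
    eta_snp_snp: float = 0.0


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic cohort."""

    n_samples: int = 697
    subpop_proportions: tuple[float, ...] = (0.40, 0.35, 0.25)
    subpop_names: tuple[str, ...] = ("EUR", "ASN", "AFR")
    n_genes: int = 50
    mean_variants_per_gene: float = 7.6  # ~24.5k variants over ~3.2k genes in the emulated study
    rare_fraction: float = 0.74
    nonsyn_fraction: float = 0.65
    fst: float = 0.05
    common_maf_range: tuple[float, float] = (0.01, 0.5)
    env_prevalence: float = 0.30
    disease_prevalence: float = 0.30
    fixed_totals: tuple[int, int] | None = None  # (affected, unaffected)
    age_mean: float = 50.0
    age_sd: float = 10.0
    sex_prob: float = 0.5
    age_effect: float = 0.01  # per year, age centered at age_mean
    sex_effect: float = 0.2
    env_effect: float = 0.4
    effects: list[EffectSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(sum(self.subpop_proportions) - 1.0) > 1e-9:
            raise ValidationError("subpopulation proportions must sum to 1")
        for name, val in (
            ("rare_fraction", self.rare_fraction),
            ("nonsyn_fraction", self.nonsyn_fraction),
            ("env_prevalence", self.env_prevalence),
            ("disease_prevalence", self.disease_prevalence),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.fixed_totals is not None and sum(self.fixed_totals) != self.n_samples:
            raise ValidationError("fixed_totals must sum to n_samples")


@dataclass
class Replicate(Dataset):
    """One simulated dataset plus its ground-truth effect record."""

    truth: pd.DataFrame


def _subpop_labels(cfg: SimConfig) -> np.ndarray:
    counts = np.floor(np.asarray(cfg.subpop_proportions) * cfg.n_samples).astype(int)
    counts[0] += cfg.n_samples - counts.sum()
    return np.repeat(np.asarray(cfg.subpop_names), counts)


def simulate_genotypes(
    cfg: SimConfig, seed: int | None = None, rng: np.random.Generator | None = None
) -> tuple[GenotypeMatrix, pd.DataFrame, list[SnpSet]]:
    """Draw genotypes, annotations and gene->variant sets for one cohort.

    Common-variant frequencies diverge between subpopulations under the
    Balding-Nichols model with the configured Fst; rare variants share one
    frequency across subpopulations.  Genotypes are binomial(2, f).  The
    annotation table is returned with realized ``maf`` and
    ``frequency_class`` already filled.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = cfg.n_samples
    rare_floor = 1.0 / (2 * n)
    if rare_floor >= 0.01:
        raise ValidationError(
            f"n_samples={n} too small for the rare-MAF floor 1/(2n) < 1%"
        )
    subpop = _subpop_labels(cfg)
    n_variants_per_gene = 2 + rng.poisson(max(cfg.mean_variants_per_gene - 2, 0.0), cfg.n_genes)
    genes = [f"G{g + 1:04d}" for g in range(cfg.n_genes)]
    records = []
    columns = []
    pos = 0
    vid_counter = 0
    a_bn = (1.0 - cfg.fst) / cfg.fst if cfg.fst > 0 else None
    for gene, n_var in zip(genes, n_variants_per_gene):
        for _ in range(n_var):
            vid_counter += 1
            vid = f"V{vid_counter:05d}"
            pos += int(rng.integers(500, 5000))
            is_rare = rng.random() < cfg.rare_fraction
            # redraw on realized-class mismatch so the configured rare
            # fraction is the fraction of rare variants in the data, not
            # just the sampling probability (frequencies near the 1%
            # boundary otherwise leak across it)
            for _attempt in range(20):
                if is_rare:
                    # log-uniform on [1/(2n), 0.01)
                    f = np.exp(rng.uniform(np.log(rare_floor), np.log(0.01)))
                    freqs = {s: f for s in cfg.subpop_names}
                else:
                    f = rng.uniform(*cfg.common_maf_range)
                    if a_bn is None:
                        freqs = {s: f for s in cfg.subpop_names}
                    else:
                        freqs = {
                            s: float(
                                np.clip(rng.beta(f * a_bn, (1 - f) * a_bn), 1e-4, 1 - 1e-4)
                            )
                            for s in cfg.subpop_names
                        }
                col = np.empty(n)
                for s in cfg.subpop_names:
                    mask = subpop == s
                    col[mask] = rng.binomial(2, freqs[s], mask.sum())
                raw = col.sum() / (2 * n)
                realized_rare = min(raw, 1 - raw) < 0.01
                if realized_rare == is_rare:
                    break
            columns.append(col)
            records.append(
                {
                    "variant_id": vid,
                    "gene": gene,
                    "functional_class": (
                        "nonsynonymous" if rng.random() < cfg.nonsyn_fraction else "synonymous"
                    ),
                    "chrom": "1",
                    "pos": pos,
                }
            )
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    geno = GenotypeMatrix(np.column_stack(columns), sample_ids, [r["variant_id"] for r in records])
    ann = pd.DataFrame(records)
    ann = classify_variant_frequency(compute_maf(geno, ann))
    sets = [
        SnpSet(gene, ann.loc[ann["gene"] == gene, "variant_id"].tolist()) for gene in genes
    ]
    return geno, ann, sets


def _genetic_predictor(
    geno: GenotypeMatrix,
    ann: pd.DataFrame,
    sets: list[SnpSet],
    env: np.ndarray,
    effects: list[EffectSpec],
) -> np.ndarray:
    by_gene = {s.gene: s for s in sets}
    ann_idx = ann.set_index("variant_id")
    lp = np.zeros(geno.n_samples)
    for eff in effects:
        if eff.gene not in by_gene:
            raise ValidationError(f"causal gene {eff.gene!r} not in the SNP sets")
        vids = by_gene[eff.gene].variant_ids
        common = [v for v in vids if ann_idx.at[v, "frequency_class"] == "common"]
        rare = [v for v in vids if ann_idx.at[v, "frequency_class"] == "rare"]
        if eff.beta_common and common:
            zc, const = standardize_columns(geno.dosages(common))
            lp += eff.beta_common * zc[:, ~const].sum(axis=1)
        if (eff.beta_rare or eff.gamma_ge) and rare:
            burden = geno.dosages(rare).sum(axis=1)
            sd = burden.std(ddof=1)
            if sd > 0:
                b = (burden - burden.mean()) / sd
                lp += eff.beta_rare * b + eff.gamma_ge * env * b
        if eff.eta_snp_snp and len(common) >= 2:
            zc, const = standardize_columns(geno.dosages(common[:2]))
            if not const.any():
                lp += eff.eta_snp_snp * zc[:, 0] * zc[:, 1]
    return lp


def simulate_phenotypes(
    geno: GenotypeMatrix,
    ann: pd.DataFrame,
    sets: list[SnpSet],
    cfg: SimConfig,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_attempts: int = 10_000,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw exposure, covariates and disease status under the logistic model.

    The intercept is calibrated so the mean fitted probability matches the
    target prevalence.  With ``fixed_totals`` the status vector is redrawn
    until the affected/unaffected counts match exactly.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = geno.n_samples
    env = rng.binomial(1, cfg.env_prevalence, n).astype(int)
    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    sex = rng.binomial(1, cfg.sex_prob, n).astype(int)
    lp = (
        cfg.age_effect * (age - cfg.age_mean)
        + cfg.sex_effect * sex
        + cfg.env_effect * env
        + _genetic_predictor(geno, ann, sets, env.astype(float), cfg.effects)
    )

    def prevalence_gap(c: float) -> float:
        return float(expit(c + lp).mean() - cfg.disease_prevalence)

    intercept = brentq(prevalence_gap, -30.0, 30.0)
    probs = expit(intercept + lp)
    if cfg.fixed_totals is None:
        y = rng.binomial(1, probs).astype(int)
    else:
        target_cases = cfg.fixed_totals[0]
        for attempt in range(max_attempts):
            y = rng.binomial(1, probs).astype(int)
            if y.sum() == target_cases:
                break
        else:
            raise ValidationError(
                f"could not hit fixed totals {cfg.fixed_totals} in {max_attempts} draws"
            )
    samples = pd.DataFrame(
        {
            "sample_id": geno.sample_ids,
            "status": y,
            "age": age,
            "sex": sex,
            "environment": env,
            "subpopulation": _subpop_labels(cfg),
        }
    )
    truth_rows = []
    for eff in cfg.effects:
        for name in ("beta_common", "beta_rare", "gamma_ge", "eta_snp_snp"):
            val = getattr(eff, name)
            if val:
                truth_rows.append({"gene": eff.gene, "effect_type": name, "coefficient": val})
    truth = pd.DataFrame(truth_rows, columns=["gene", "effect_type", "coefficient"])
    return samples, truth


def simulate_replicate(
    cfg: SimConfig, seed: int | None = None, rng: np.random.Generator | None = None
) -> Replicate:
    """Genotypes and phenotypes for a single standalone replicate."""
    if rng is None:
        rng = np.random.default_rng(seed)
    geno, ann, sets = simulate_genotypes(cfg, rng=rng)
    samples, truth = simulate_phenotypes(geno, ann, sets, cfg, rng=rng)
    return Replicate(geno, ann, sets, samples, truth)


def generate_replicates(
    cfg: SimConfig, n_pairs: int, seed: int | None = None
) -> list[tuple[Replicate, Replicate]]:
    """Screening/testing replicate pairs sharing one fixed genotype panel.

    As in the emulated study design, genotypes (and hence annotations and
    SNP sets) are generated once and held fixed across every replicate;
    exposure, covariates and disease status are re-simulated per replicate
    with seeds derived deterministically from the master seed.
    """
    ss = np.random.SeedSequence(seed)
    geno_rng = np.random.default_rng(ss.spawn(1)[0])
    geno, ann, sets = simulate_genotypes(cfg, rng=geno_rng)
    pairs = []
    children = ss.spawn(2 * n_pairs + 1)[1:]
    for i in range(n_pairs):
        members = []
        for j in range(2):
            rng = np.random.default_rng(children[2 * i + j])
            samples, truth = simulate_phenotypes(geno, ann, sets, cfg, rng=rng)
            members.append(Replicate(geno, ann, sets, samples, truth))
        pairs.append(tuple(members))
    return pairs


# ---------------------------------------------------------------------------
# disk output for the CLI


def write_replicate(rep: Replicate, out_dir: str | Path, write_geno: bool = True) -> None:
    from .data_model import write_genotypes

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if write_geno:
        write_genotypes(rep.genotypes, out / "genotypes.tsv")
    rep.annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    rep.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    rep.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def write_pairs(
    pairs: list[tuple[Replicate, Replicate]], out_dir: str | Path
) -> Path:
    """Emit pair directories plus a manifest.tsv consumed by the two-stage CLI."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # genotypes/annotations identical across replicates: write once
    from .data_model import write_genotypes

    write_genotypes(pairs[0][0].genotypes, out / "genotypes.tsv")
    pairs[0][0].annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    rows = []
    for i, (screen, test) in enumerate(pairs, start=1):
        sdir = out / f"pair{i:03d}_screen"
        tdir = out / f"pair{i:03d}_test"
        for rep, d in ((screen, sdir), (test, tdir)):
            d.mkdir(exist_ok=True)
            rep.samples.to_csv(d / "samples.tsv", sep="\t", index=False)
            rep.truth.to_csv(d / "truth.tsv", sep="\t", index=False)
        rows.append(
            {
                "pair": i,
                "genotypes": "genotypes.tsv",
                "annotations": "annotations.tsv",
                "screen_samples": f"{sdir.name}/samples.tsv",
                "test_samples": f"{tdir.name}/samples.tsv",
            }
        )
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def config_from_dict(d: dict) -> SimConfig:
    """Build a SimConfig from a plain dict (YAML/JSON config files)."""
    d = dict(d)
    effects = [EffectSpec(**e) for e in d.pop("effects", [])]
    for key in ("subpop_proportions", "subpop_names", "common_maf_range"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    if "fixed_totals" in d and isinstance(d["fixed_totals"], list):
        d["fixed_totals"] = tuple(d["fixed_totals"])
    return SimConfig(effects=effects, **d)
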