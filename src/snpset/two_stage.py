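"""Two-stage screening/testing pipeline with Holm adjustment.

Stage 1 (screening) filters genes on one replicate using permutation tests:
Hotelling T^2 on common-variant genotypes within each subpopulation,
a two-dimensional Hotelling T^2 on (WS_syn, WS_nonsyn) over the whole
population, and Fisher-z gene-environment correlation contrasts for the
common summary score and WS_nonsyn.  A gene passes when any available test
has p below the screening threshold (default 0.1).

Stage 2 (testing) applies five methods to the genes that passed, on the
paired testing replicate, with Madsen-Browning weights and summary-score
coefficients estimated on the screening replicate:

    logistic_regression        logistic score test, raw common genotypes + WS_combined
    logistic_common_score      logistic score test, common summary score + WS_combined
    linear_rare_ws_combined    kernel machine, linear kernel, genotypes + WS_combined
    linear_rare_ws_nonsyn      kernel machine, linear kernel, genotypes + WS_nonsyn
    quadratic_rare_ws_combined kernel machine, quadratic kernel, genotypes + WS_combined

Per method, p-values are Holm-adjusted across the passed genes and a gene
is selected when its adjusted p falls below ``alpha_select`` (default 0.1).
Selections are tallied across replicate pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assoc_tests, collapse, kernel_machine
from .assoc_tests import TestResult
from .data_model import (
    Dataset,
    GenotypeMatrix,
    SnpSet,
    ValidationError,
    add_population_pcs,
    compute_population_pcs,
)

logger = logging.getLogger(__name__)

COVARIATE_COLUMNS = ("age", "sex", "pc1", "pc2", "environment")


@dataclass
class MethodConfig:
    """One row of the testing-stage method table."""

    name: str
    model: str  # 'logistic' or 'kernel'
    kernel: str | None  # main-effect kernel for kernel-machine methods
    common: str  # 'genotypes' or 'score'
    rare: str  # 'ws_combined' or 'ws_nonsyn'


TESTING_METHODS: dict[str, MethodConfig] = {
    m.name: m
    for m in (
        MethodConfig("logistic_regression", "logistic", None, "genotypes", "ws_combined"),
        MethodConfig("logistic_common_score", "logistic", None, "score", "ws_combined"),
        MethodConfig("linear_rare_ws_combined", "kernel", "linear", "genotypes", "ws_combined"),
        MethodConfig("linear_rare_ws_nonsyn", "kernel", "linear", "genotypes", "ws_nonsyn"),
        MethodConfig("quadratic_rare_ws_combined", "kernel", "quadratic", "genotypes", "ws_combined"),
    )
}


@dataclass
class ScreenReport:
    """Screening p-values for one gene; None marks an unavailable test."""

    gene: str
    p_common: dict[str, float | None]  # per subpopulation
    p_rare_2d: float | None
    p_ge_common: float | None
    p_ge_rare: float | None
    passed: bool

    def available_pvalues(self) -> list[float]:
        ps = [p for p in self.p_common.values() if p is not None]
        ps += [p for p in (self.p_rare_2d, self.p_ge_common, self.p_ge_rare) if p is not None]
        return ps


def _aligned_samples(ds: Dataset) -> pd.DataFrame:
    df = ds.samples.set_index("sample_id").reindex(ds.genotypes.sample_ids)
    if df["status"].isna().any():
        raise ValidationError("sample table does not cover every genotyped sample")
    return df.reset_index(names="sample_id")


def _gene_partition(ds: Dataset, snp_set: SnpSet) -> tuple[list[str], list[str]]:
    ann = ds.annotations.set_index("variant_id")
    present = set(ds.genotypes.variant_ids)
    common, rare = [], []
    for v in snp_set.variant_ids:
        if v not in present or v not in ann.index:
            continue
        (common if ann.at[v, "frequency_class"] == "common" else rare).append(v)
    return common, rare


def assign_subpopulations(samples: pd.DataFrame, geno: GenotypeMatrix, k: int = 3) -> pd.Series:
    """Subpopulation labels: from the table if present, else k-means on 2 PCs."""
    if "subpopulation" in samples.columns and samples["subpopulation"].notna().all():
        return samples["subpopulation"].astype(str)
    from sklearn.cluster import KMeans

    if {"pc1", "pc2"}.issubset(samples.columns) and samples[["pc1", "pc2"]].notna().all().all():
        scores = samples[["pc1", "pc2"]].to_numpy()
    else:
        scores = compute_population_pcs(geno, k=2)
    km = KMeans(n_clusters=k, n_init=10, random_state=0).fit(scores)
    return pd.Series([f"cluster{c}" for c in km.labels_], index=samples.index)


def screen_gene(
    ds: Dataset,
    snp_set: SnpSet | str,
    threshold: float = 0.1,
    B: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    labels: np.ndarray | None = None,
    subpop_labels: dict[str, np.ndarray] | None = None,
) -> ScreenReport:
    """Run all screening permutation tests for one gene.

    ``labels`` / ``subpop_labels`` may supply precomputed permuted status
    matrices (whole population / per subpopulation) so a replicate's label
    draws are shared across genes.  Tests whose preconditions fail (no
    common variants, constant scores, tiny groups) are recorded as
    unavailable rather than as p = 1.
    """
    if isinstance(snp_set, str):
        snp_set = ds.snp_set(snp_set)
    if rng is None:
        rng = np.random.default_rng(seed)
    samples = _aligned_samples(ds)
    status = samples["status"].to_numpy()
    env = samples["environment"].to_numpy(dtype=float)
    subpop = assign_subpopulations(samples, ds.genotypes)
    common_ids, _rare_ids = _gene_partition(ds, snp_set)
    affected = status == 1

    if labels is None:
        labels = assoc_tests.permuted_label_matrix(status, B, rng)

    # (a) common variants: Hotelling per subpopulation
    p_common: dict[str, float | None] = {}
    for name in sorted(subpop.unique()):
        mask = (subpop == name).to_numpy()
        p_common[name] = None
        if not common_ids:
            continue
        sub_status = status[mask]
        if sub_status.sum() < 2 or (1 - sub_status).sum() < 2:
            continue
        M = ds.genotypes.dosages(common_ids)[mask]
        sub_labels = None
        if subpop_labels is not None and name in subpop_labels:
            sub_labels = subpop_labels[name]
        try:
            res = assoc_tests.hotelling_permutation_test(
                M, sub_status, B=B, rng=rng, labels=sub_labels
            )
            p_common[name] = res.p_value
        except ValidationError:
            pass

    # (b) rare variants: 2-D Hotelling on (WS_syn, WS_nonsyn), whole population
    ws_syn, ws_nonsyn = collapse.weighted_sum_scores(
        ds.genotypes, ds.annotations, affected, snp_set
    )
    p_rare_2d = None
    W = np.column_stack([ws_syn, ws_nonsyn])
    if np.ptp(W, axis=0).max() > 0:
        try:
            res = assoc_tests.hotelling_permutation_test(W, status, B=B, rng=rng, labels=labels)
            p_rare_2d = res.p_value
        except ValidationError:
            pass

    # (c) gene-environment correlation contrasts
    p_ge_common = None
    if common_ids:
        try:
            cscore, _ = collapse.common_summary_score(ds.genotypes, affected, common_ids)
            res = assoc_tests.ge_correlation_permutation_test(
                cscore, env, status, B=B, rng=rng, labels=labels
            )
            p_ge_common = res.p_value
        except ValidationError:
            pass
    p_ge_rare = None
    try:
        res = assoc_tests.ge_correlation_permutation_test(
            ws_nonsyn, env, status, B=B, rng=rng, labels=labels
        )
        p_ge_rare = res.p_value
    except ValidationError:
        pass

    report = ScreenReport(
        gene=snp_set.gene,
        p_common=p_common,
        p_rare_2d=p_rare_2d,
        p_ge_common=p_ge_common,
        p_ge_rare=p_ge_rare,
        passed=False,
    )
    report.passed = any(p < threshold for p in report.available_pvalues())
    return report


def test_gene(
    screen_ds: Dataset,
    test_ds: Dataset,
    snp_set: SnpSet | str,
    config: MethodConfig | str,
) -> TestResult:
    """Run one testing-stage method on one gene.

    Covariates are intercept, age, sex, two principal-component scores and
    the exposure; the exposure also drives the interaction design.
    Madsen-Browning weights and summary-score coefficients are estimated on
    ``screen_ds`` and applied to ``test_ds``.
    """
    if isinstance(config, str):
        if config not in TESTING_METHODS:
            raise ValidationError(
                f"unknown method {config!r}; known: {sorted(TESTING_METHODS)}"
            )
        config = TESTING_METHODS[config]
    if isinstance(snp_set, str):
        snp_set = test_ds.snp_set(snp_set)
    samples = _aligned_samples(test_ds)
    missing = [c for c in COVARIATE_COLUMNS if c not in samples.columns or samples[c].isna().any()]
    if missing:
        raise ValidationError(
            f"testing covariates missing or incomplete: {missing}; run add_population_pcs first"
        )
    y = samples["status"].to_numpy(dtype=float)
    s = samples["environment"].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(samples))] + [samples[c].to_numpy(dtype=float) for c in COVARIATE_COLUMNS]
    )
    screen_samples = _aligned_samples(screen_ds)
    screen_affected = screen_samples["status"].to_numpy() == 1
    affected = y == 1

    common_ids, _ = _gene_partition(test_ds, snp_set)
    ws_syn, ws_nonsyn = collapse.weighted_sum_scores(
        test_ds.genotypes, test_ds.annotations, affected, snp_set,
        weight_geno=screen_ds.genotypes, weight_affected=screen_affected,
    )
    rare_col = (
        collapse.combined_ws(ws_syn, ws_nonsyn) if config.rare == "ws_combined" else ws_nonsyn
    )

    if config.common == "score" and common_ids:
        cscore, _ = collapse.common_summary_score(
            test_ds.genotypes, affected, common_ids,
            source_geno=screen_ds.genotypes, source_affected=screen_affected,
        )
        common_part = cscore[:, None]
    elif common_ids:
        common_part = test_ds.genotypes.dosages(common_ids)
    else:
        common_part = np.empty((len(y), 0))

    Z = np.hstack([common_part, rare_col[:, None]])
    if config.model == "logistic":
        return assoc_tests.logistic_score_test(y, X, Z, s, method=config.name)
    return kernel_machine.kernel_machine_test(
        y, X, Z, s, main_kernel=config.kernel, method=config.name
    )


def holm_adjust(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values, mapped back to input order.

    adjusted_(i) = max_{j<=i} min(1, (m - j + 1) p_(j)) over the ascending
    sort; controls the family-wise error rate.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = (m - np.arange(m)) * p[order]
    adjusted_sorted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def _ensure_pcs(ds: Dataset) -> Dataset:
    cols = set(ds.samples.columns)
    if {"pc1", "pc2"}.issubset(cols) and ds.samples[["pc1", "pc2"]].notna().all().all():
        return ds
    samples = add_population_pcs(ds.samples, ds.genotypes, ds.annotations)
    return Dataset(ds.genotypes, ds.annotations, ds.snp_sets, samples)


def run_two_stage(
    pairs: list[tuple[Dataset, Dataset]],
    threshold: float = 0.1,
    methods: list[str] | None = None,
    alpha_select: float = 0.1,
    B_screen: int = 1000,
    seed: int | None = None,
    no_screening: bool = False,
) -> pd.DataFrame:
    """Screen and test every gene across replicate pairs; tally selections.

    Returns a table with one row per (gene, method): ``times_selected``
    (Holm-adjusted p < alpha_select on the testing replicate) and
    ``times_screened_in`` (the gene passed screening; with
    ``no_screening=True`` every gene counts as screened in).
    """
    method_names = list(methods) if methods is not None else list(TESTING_METHODS)
    for m in method_names:
        if m not in TESTING_METHODS:
            raise ValidationError(f"unknown method {m!r}")
    ss = np.random.SeedSequence(seed)
    pair_seeds = ss.spawn(len(pairs))
    selected: dict[tuple[str, str], int] = {}
    screened_in: dict[str, int] = {}
    genes_ref: list[str] | None = None

    for pair_idx, (screen_ds, test_ds) in enumerate(pairs):
        genes = [s.gene for s in screen_ds.snp_sets]
        if [s.gene for s in test_ds.snp_sets] != genes:
            raise ValidationError(f"pair {pair_idx}: gene sets differ between replicates")
        if genes_ref is None:
            genes_ref = genes
        rng = np.random.default_rng(pair_seeds[pair_idx])
        screen_ds = _ensure_pcs(screen_ds)
        test_ds = _ensure_pcs(test_ds)

        if no_screening:
            passed = list(genes)
        else:
            samples = _aligned_samples(screen_ds)
            status = samples["status"].to_numpy()
            subpop = assign_subpopulations(samples, screen_ds.genotypes)
            labels = assoc_tests.permuted_label_matrix(status, B_screen, rng)
            subpop_labels = {
                name: assoc_tests.permuted_label_matrix(
                    status[(subpop == name).to_numpy()], B_screen, rng
                )
                for name in sorted(subpop.unique())
            }
            passed = []
            for g in genes:
                report = screen_gene(
                    screen_ds, g, threshold=threshold, B=B_screen, rng=rng,
                    labels=labels, subpop_labels=subpop_labels,
                )
                if report.passed:
                    passed.append(g)
        for g in passed:
            screened_in[g] = screened_in.get(g, 0) + 1

        for method in method_names:
            tested_genes: list[str] = []
            pvals: list[float] = []
            for g in passed:
                try:
                    res = test_gene(screen_ds, test_ds, g, method)
                except (ValidationError, kernel_machine.ConvergenceError) as exc:
                    logger.debug("pair %d gene %s method %s skipped: %s", pair_idx, g, method, exc)
                    continue
                if np.isfinite(res.p_value):
                    tested_genes.append(g)
                    pvals.append(res.p_value)
            if not pvals:
                continue
            adj = holm_adjust(np.array(pvals))
            for g, a in zip(tested_genes, adj):
                if a < alpha_select:
                    selected[(g, method)] = selected.get((g, method), 0) + 1

    rows = []
    for g in genes_ref or []:
        for method in method_names:
            rows.append(
                {
                    "gene": g,
                    "method": method,
                    "times_selected": selected.get((g, method), 0),
                    "times_screened_in": screened_in.get(g, 0),
                }
            )
    tally = pd.DataFrame(rows, columns=["gene", "method", "times_selected", "times_screened_in"])
    bad = tally["times_selected"] > tally["times_screened_in"]
    if bad.any():  # defensive: selection implies screened in
        raise RuntimeError("tally invariant violated: selected > screened_in")
    return tally
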