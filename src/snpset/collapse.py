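"""Per-SNP-set collapsing scores.

Rare variants are summarized by Madsen-Browning weighted sums computed
separately for synonymous and nonsynonymous variants, with the combined
score ``WS_combined = WS_syn + 2 * WS_nonsyn`` giving nonsynonymous
variants double weight.  Common variants are reduced to a one-dimensional
summary score with per-variant coefficients derived from the case/control
allele-frequency contrast (the principal-fitted-components direction for a
binary response).

Weight and coefficient estimation accept an explicit source dataset so the
two-stage pipeline can estimate them on a screening replicate and apply
them to a testing replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_model import GenotypeMatrix, SnpSet, ValidationError


@dataclass
class CollapsedScores:
    """All collapsing scores for one gene, aligned to the target samples."""

    gene: str
    ws_syn: np.ndarray
    ws_nonsyn: np.ndarray
    ws_combined: np.ndarray
    common_score: np.ndarray | None
    weights_rare: dict[str, np.ndarray]
    coeffs_common: np.ndarray | None


def madsen_browning_weights(geno: GenotypeMatrix, affected: np.ndarray) -> np.ndarray:
    """Inverse-standard-deviation weights estimated from the unaffected group.

    For variant k let ``m_U`` be its minor-allele count among unaffected
    samples with non-missing genotype, ``n_U`` that group's non-missing
    count and ``n`` the total non-missing count.  Then::

        q_k = (m_U + 1) / (2 n_U + 2)
        w_k = sqrt(n * q_k * (1 - q_k))

    The +1/+2 pseudocount keeps weights finite for control-absent variants.
    """
    affected = np.asarray(affected, dtype=bool)
    if affected.shape[0] != geno.n_samples:
        raise ValidationError("affected mask length does not match sample count")
    unaff = ~affected
    if unaff.sum() == 0:
        raise ValidationError("no unaffected samples: weights undefined")
    vals = geno.values
    with np.errstate(invalid="ignore"):
        m_u = np.nansum(vals[unaff], axis=0)
        n_u = (~np.isnan(vals[unaff])).sum(axis=0)
        n_tot = (~np.isnan(vals)).sum(axis=0)
    q = (m_u + 1.0) / (2.0 * n_u + 2.0)
    return np.sqrt(n_tot * q * (1.0 - q))


def weighted_sum_scores(
    geno: GenotypeMatrix,
    annotations: pd.DataFrame,
    affected: np.ndarray,
    snp_set: SnpSet,
    weight_geno: GenotypeMatrix | None = None,
    weight_affected: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample weighted sums over a gene's rare variants, by class.

    ``score_i = sum_k I_ik / w_k`` over the rare variants of the class,
    with dosages ``I_ik`` mean-imputed.  Weights come from ``weight_geno``
    (default: the same data), so a screening replicate can drive the
    weighting for a testing replicate.  An empty class scores identically 0.
    """
    if weight_geno is None:
        weight_geno = geno
        weight_affected = affected
    if weight_affected is None:
        raise ValidationError("weight_affected must accompany weight_geno")
    ann = annotations.set_index("variant_id")
    out = []
    for cls in ("synonymous", "nonsynonymous"):
        ids = [
            v
            for v in snp_set.variant_ids
            if v in ann.index
            and ann.at[v, "functional_class"] == cls
            and ann.at[v, "frequency_class"] == "rare"
            and v in geno.variant_ids
        ]
        if not ids:
            out.append(np.zeros(geno.n_samples))
            continue
        w = madsen_browning_weights(weight_geno.subset_variants(ids), weight_affected)
        dos = geno.dosages(ids)
        out.append(dos @ (1.0 / w))
    return out[0], out[1]


def combined_ws(ws_syn: np.ndarray, ws_nonsyn: np.ndarray) -> np.ndarray:
    """WS_combined = WS_syn + 2 WS_nonsyn (nonsynonymous doubly weighted)."""
    ws_syn = np.asarray(ws_syn, dtype=float)
    ws_nonsyn = np.asarray(ws_nonsyn, dtype=float)
    if ws_syn.shape != ws_nonsyn.shape:
        raise ValidationError(
            f"score length mismatch: {ws_syn.shape} vs {ws_nonsyn.shape}"
        )
    return ws_syn + 2.0 * ws_nonsyn


def allele_frequency_contrast(geno: GenotypeMatrix, affected: np.ndarray) -> np.ndarray:
    """Default summary-score coefficients: case minus control allele frequency.

    ``c_k = m_k^A / (2 n^A) - m_k^U / (2 n^U)`` with counts over non-missing
    genotypes.  This is the fitted-component direction for a binary response
    without covariance rescaling.
    """
    affected = np.asarray(affected, dtype=bool)
    if affected.sum() == 0 or (~affected).sum() == 0:
        raise ValidationError("both affected and unaffected samples are required")
    vals = geno.values
    with np.errstate(invalid="ignore"):
        m_a = np.nansum(vals[affected], axis=0)
        n_a = (~np.isnan(vals[affected])).sum(axis=0)
        m_u = np.nansum(vals[~affected], axis=0)
        n_u = (~np.isnan(vals[~affected])).sum(axis=0)
    if (n_a == 0).any() or (n_u == 0).any():
        raise ValidationError("a variant has no non-missing genotypes in one status group")
    return m_a / (2.0 * n_a) - m_u / (2.0 * n_u)


CoefficientFn = Callable[[GenotypeMatrix, np.ndarray], np.ndarray]


def common_summary_score(
    geno: GenotypeMatrix,
    affected: np.ndarray,
    variant_ids: Sequence[str] | None = None,
    source_geno: GenotypeMatrix | None = None,
    source_affected: np.ndarray | None = None,
    coeff_fn: CoefficientFn = allele_frequency_contrast,
) -> tuple[np.ndarray, np.ndarray]:
    """One-dimensional reduction of a gene's common variants.

    ``score_i = sum_k c_k I_ik`` with coefficients from ``coeff_fn``
    estimated on ``source_geno`` (default: the same data) and applied to
    the mean-imputed dosages of ``geno``.  Returns ``(scores, coeffs)``.
    """
    if variant_ids is not None:
        geno = geno.subset_variants(variant_ids)
    if geno.n_variants == 0:
        raise ValidationError("no common variants to summarize")
    if source_geno is None:
        src, src_aff = geno, affected
    else:
        src = source_geno.subset_variants(geno.variant_ids)
        if source_affected is None:
            raise ValidationError("source_affected must accompany source_geno")
        src_aff = source_affected
    coeffs = np.asarray(coeff_fn(src, np.asarray(src_aff, dtype=bool)), dtype=float)
    scores = geno.dosages() @ coeffs
    return scores, coeffs


def collapse_gene(
    geno: GenotypeMatrix,
    annotations: pd.DataFrame,
    affected: np.ndarray,
    snp_set: SnpSet,
    source_geno: GenotypeMatrix | None = None,
    source_affected: np.ndarray | None = None,
) -> CollapsedScores:
    """All collapsing scores for one gene in a single call."""
    ws_syn, ws_nonsyn = weighted_sum_scores(
        geno, annotations, affected, snp_set,
        weight_geno=source_geno, weight_affected=source_affected,
    )
    ann = annotations.set_index("variant_id")
    common_ids = [
        v
        for v in snp_set.variant_ids
        if v in ann.index and ann.at[v, "frequency_class"] == "common" and v in geno.variant_ids
    ]
    common_score = coeffs = None
    if common_ids:
        common_score, coeffs = common_summary_score(
            geno, affected, common_ids,
            source_geno=source_geno, source_affected=source_affected,
        )
    weights = {}
    for cls in ("synonymous", "nonsynonymous"):
        ids = [
            v
            for v in snp_set.variant_ids
            if v in ann.index
            and ann.at[v, "functional_class"] == cls
            and ann.at[v, "frequency_class"] == "rare"
            and v in geno.variant_ids
        ]
        if ids:
            wg = source_geno if source_geno is not None else geno
            wa = source_affected if source_affected is not None else affected
            weights[cls] = madsen_browning_weights(wg.subset_variants(ids), wa)
    return CollapsedScores(
        gene=snp_set.gene,
        ws_syn=ws_syn,
        ws_nonsyn=ws_nonsyn,
        ws_combined=combined_ws(ws_syn, ws_nonsyn),
        common_score=common_score,
        weights_rare=weights,
        coeffs_common=coeffs,
    )


def scores_to_frame(scores: CollapsedScores, sample_ids: Sequence[str]) -> pd.DataFrame:
    """Tabular export: sample_id, gene, ws_syn, ws_nonsyn, ws_combined, common_score."""
    return pd.DataFrame(
        {
            "sample_id": list(sample_ids),
            "gene": scores.gene,
            "ws_syn": scores.ws_syn,
            "ws_nonsyn": scores.ws_nonsyn,
            "ws_combined": scores.ws_combined,
            "common_score": (
                scores.common_score if scores.common_score is not None else np.nan
            ),
        }
    )
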