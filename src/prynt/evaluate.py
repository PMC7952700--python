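"""Precision and specificity evaluation of a candidate ranking.

Precision at ``k`` is the fraction of the top-``k`` ranked candidates that
appear in a disease's reference candidate list; the precision curve runs
over ``k = 1..K`` (default ``K = 100``) and is summarized by its
trapezoidal area (AUC). Specificity is probed two ways: the cross delta
(AUC against the matching disease's reference list minus AUC against a
different disease's list, positive for a specific method) and the overall
rank of the matching AUC among many decoy diseases' AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .prioritize import PrioritizationResult
from .string_io import DPSet, ReferenceCandidates

DEFAULT_K_MAX = 100


@dataclass
class PrecisionCurve:
    k_values: np.ndarray
    precision_at_k: np.ndarray
    auc: float
    auc_normalized: float        # auc / (K - 1): mean-height readability aid
    reference_name: str

    def precision_at(self, k: int) -> float:
        return float(self.precision_at_k[k - 1])


@dataclass
class SpecificityReport:
    specific_auc: float
    nonspecific_auc: float | None = None
    cross_delta: float | None = None
    decoy_aucs: tuple = ()
    specific_rank: int | None = None
    metadata: dict = field(default_factory=dict)


def _ranked_nodes(ranking) -> list:
    if isinstance(ranking, PrioritizationResult):
        return ranking.nodes()
    return list(ranking)


def precision_curve(ranking, reference: ReferenceCandidates,
                    k_max: int = DEFAULT_K_MAX) -> PrecisionCurve:
    """Precision at each cutoff k = 1..min(k_max, |ranking|) and its AUC.

    ``ranking`` may be a :class:`PrioritizationResult` or any ordered
    sequence of identifiers. Matching is by exact identifier; an empty
    reference yields an all-zero curve with a warning.
    """
    nodes = _ranked_nodes(ranking)
    if not nodes:
        raise ValueError("cannot evaluate an empty ranking")
    members = reference.members
    if not members:
        warnings.warn(
            f"reference {reference.disease_name!r} is empty; precision is 0",
            stacklevel=2,
        )
    limit = min(k_max, len(nodes))
    hits = np.cumsum([1 if node in members else 0 for node in nodes[:limit]])
    k_values = np.arange(1, limit + 1)
    precision = hits / k_values
    auc = float(np.trapezoid(precision, k_values)) if limit > 1 else 0.0
    normalized = auc / (limit - 1) if limit > 1 else 0.0
    return PrecisionCurve(
        k_values=k_values,
        precision_at_k=precision,
        auc=auc,
        auc_normalized=normalized,
        reference_name=reference.disease_name,
    )


def cross_specificity(ranking, specific_ref: ReferenceCandidates,
                      nonspecific_ref: ReferenceCandidates,
                      k_max: int = DEFAULT_K_MAX) -> SpecificityReport:
    """AUC difference between the matching and a mismatched reference list.

    A positive ``cross_delta`` indicates the ranking favours candidates of
    the disease under study over those of the other disease.
    """
    specific = precision_curve(ranking, specific_ref, k_max=k_max)
    nonspecific = precision_curve(ranking, nonspecific_ref, k_max=k_max)
    return SpecificityReport(
        specific_auc=specific.auc,
        nonspecific_auc=nonspecific.auc,
        cross_delta=specific.auc - nonspecific.auc,
        metadata={
            "specific_reference": specific_ref.disease_name,
            "nonspecific_reference": nonspecific_ref.disease_name,
            "k_max": k_max,
        },
    )


def overall_specificity(ranking, specific_ref: ReferenceCandidates,
                        decoy_refs: Sequence[ReferenceCandidates],
                        k_max: int = DEFAULT_K_MAX) -> SpecificityReport:
    """Rank of the matching disease's AUC among decoy diseases' AUCs.

    Competition ranking: ``specific_rank = 1 + #{decoy AUC > specific
    AUC}``, so ties share the better rank. A specific method places the
    matching AUC near rank 1 of ``len(decoys) + 1``.
    """
    if not decoy_refs:
        raise ValueError("overall specificity needs at least one decoy list")
    specific = precision_curve(ranking, specific_ref, k_max=k_max)
    decoy_aucs = tuple(
        precision_curve(ranking, decoy, k_max=k_max).auc
        for decoy in decoy_refs
    )
    rank = 1 + sum(1 for auc in decoy_aucs if auc > specific.auc)
    return SpecificityReport(
        specific_auc=specific.auc,
        decoy_aucs=decoy_aucs,
        specific_rank=rank,
        metadata={
            "specific_reference": specific_ref.disease_name,
            "n_decoys": len(decoy_refs),
            "k_max": k_max,
        },
    )


def experimental_ranking(dps: DPSet) -> list:
    """P-value baseline: the seeds themselves, most significant first.

    Mirrors ranking deregulated proteins directly by their experimental
    p-value (ascending); members without a p-value go last, in
    lexicographic order.
    """
    pvalues = dps.pvalues or {}
    return sorted(dps.members, key=lambda m: (pvalues.get(m, 2.0), m))
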