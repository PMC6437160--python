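"""Tissue-enrichment gene prioritization.

Promoters are scored as log10(max expression in any target-group sample + 1)
minus log10(median expression across the collection + 1); a strict score
threshold of 3 corresponds to >1000-fold enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class EnrichmentResult:
    promoter: str
    score: float
    passes: bool


@dataclass(frozen=True)
class CandidateSelection:
    enriched: tuple[str, ...]
    known: tuple[str, ...]
    novel: tuple[str, ...]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "enriched": len(self.enriched),
            "known": len(self.known),
            "novel": len(self.novel),
        }


def enrichment_score(
    matrix: pd.DataFrame,
    groups: pd.Series,
    target_group: str,
    threshold: float = 3.0,
    include_target_in_median: bool = True,
) -> pd.DataFrame:
    """Score every promoter for target-group enrichment.

    Parameters
    ----------
    matrix : DataFrame
        Promoters (rows) x samples (columns) of non-negative expression.
    groups : Series
        Sample -> group label, covering every column of ``matrix``.
    target_group : str
        Group whose maximum is compared with the collection median.
    include_target_in_median : bool
        The default reads "median of the collection" as the median over all
        samples including the target group; set False to exclude it.

    Returns
    -------
    DataFrame indexed by promoter with ``score`` and ``passes`` (strict
    ``score > threshold``) columns, sorted by descending score.
    """
    if not set(matrix.columns).issubset(set(groups.index)):
        raise ValueError("group labels must cover all samples")
    if (matrix.to_numpy() < 0).any():
        raise ValueError("expression values must be non-negative")
    labels = groups.loc[matrix.columns]
    target_cols = matrix.columns[labels == target_group]
    if len(target_cols) == 0:
        raise ValueError(f"target group {target_group!r} has no samples")
    if len(target_cols) == len(matrix.columns):
        raise ValueError("target group must be a proper subset of samples")
    target_max = matrix[target_cols].max(axis=1)
    median_cols = matrix.columns if include_target_in_median else matrix.columns.difference(target_cols)
    overall_median = matrix[median_cols].median(axis=1)
    score = np.log10(target_max + 1.0) - np.log10(overall_median + 1.0)
    out = pd.DataFrame({"score": score, "passes": score > threshold})
    return out.sort_values("score", ascending=False)


def select_candidates(
    results: pd.DataFrame,
    known_disease_genes: set[str],
    threshold: float = 3.0,
) -> CandidateSelection:
    """Partition promoters passing the strict threshold by prior association.

    ``enriched`` is every promoter with score strictly greater than
    ``threshold``; ``known``/``novel`` split it by membership in
    ``known_disease_genes``.
    """
    passing = results.index[results["score"] > threshold]
    known = tuple(p for p in passing if p in known_disease_genes)
    novel = tuple(p for p in passing if p not in known_disease_genes)
    return CandidateSelection(enriched=tuple(passing), known=known, novel=novel)


def matrix_to_tsv(matrix: pd.DataFrame, groups: pd.Series) -> str:
    """Promoters x samples TSV whose first header row carries group labels."""
    lines = ["group\t" + "\t".join(str(groups[c]) for c in matrix.columns)]
    lines.append("promoter\t" + "\t".join(map(str, matrix.columns)))
    for promoter, row in matrix.iterrows():
        lines.append(str(promoter) + "\t" + "\t".join(f"{v:.6g}" for v in row))
    return "\n".join(lines) + "\n"


def matrix_from_tsv(text: str) -> tuple[pd.DataFrame, pd.Series]:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    group_row = lines[0].split("\t")[1:]
    samples = lines[1].split("\t")[1:]
    promoters, values = [], []
    for ln in lines[2:]:
        parts = ln.split("\t")
        promoters.append(parts[0])
        values.append([float(x) for x in parts[1:]])
    matrix = pd.DataFrame(values, index=promoters, columns=samples)
    groups = pd.Series(group_row, index=samples)
    return matrix, groups
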