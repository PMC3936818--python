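"""Singular enrichment analysis (SEA) of gene sets over GO annotations.

Tests each GO term for over-representation in a study gene list against a
background, by the upper-tail hypergeometric test: with N background genes
of which K carry the term, and a study of n genes of which k carry it,

    p = P[X >= k],   X ~ Hypergeometric(N, K, n).

P-values are corrected by the Benjamini–Hochberg step-up FDR procedure by
default; Hochberg's step-up FWER correction is available behind a flag,
since "FDR" and "Hochberg" name different procedures and either may be
meant when both words appear together.  Terms with fewer than
``min_mapping`` study hits are not tested; study lists smaller than
``min_class_size`` are gated out entirely (small gene classes give the
hypergeometric test no power and are conventionally excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

#: Defaults mirroring a conventional SEA setup.
DEFAULT_ALPHA = 0.05
DEFAULT_MIN_MAPPING = 1
DEFAULT_MIN_CLASS_SIZE = 20


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    study_hits: int      # k
    study_size: int      # n
    background_hits: int  # K
    background_size: int  # N
    p_value: float
    adjusted_p: float
    enriched: bool


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K) and k <= n <= N and K <= N):
        raise ValidationError(
            f"invalid hypergeometric bounds k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values.

    Sorted p(i) become p(i)*m/i, repaired to be monotone by a cumulative
    minimum from the largest p down, and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(m)
    out[order] = ranked
    return out.tolist()


def hochberg_adjust(p_values: Sequence[float]) -> list[float]:
    """Hochberg's step-up FWER-adjusted p-values: p(i)*(m-i+1), monotone."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * (m - np.arange(1, m + 1) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(m)
    out[order] = ranked
    return out.tolist()


def read_go_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a gene -> GO term TSV (columns gene, term[, namespace])."""
    mapping: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValidationError(f"bad GO annotation line: {line!r}")
            mapping.setdefault(fields[0], set()).add(fields[1])
    return mapping


def run_sea(
    study_genes: Iterable[str],
    background_genes: Iterable[str],
    go_annotation: Mapping[str, set[str]],
    alpha: float = DEFAULT_ALPHA,
    min_mapping: int = DEFAULT_MIN_MAPPING,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
    method: str = "bh",
) -> list[EnrichmentResult]:
    """Test every GO term with at least ``min_mapping`` study hits.

    ``method`` selects the multiple-testing correction: ``"bh"``
    (Benjamini–Hochberg FDR, default) or ``"hochberg"`` (step-up FWER).
    A study list smaller than ``min_class_size`` returns an empty result.
    Raises when a study gene is missing from the background.
    """
    study = set(study_genes)
    background = set(background_genes)
    stray = study - background
    if stray:
        raise ValidationError(
            f"{len(stray)} study gene(s) absent from the background, "
            f"e.g. {sorted(stray)[:3]}"
        )
    if len(study) < min_class_size:
        return []

    n = len(study)
    N = len(background)
    term_background: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in background:
        for term in go_annotation.get(gene, ()):
            term_background[term] = term_background.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1

    tested = sorted(t for t, k in term_study.items() if k >= min_mapping)
    p_values = [
        hypergeom_upper_tail(term_study[t], term_background[t], n, N)
        for t in tested
    ]
    if method == "bh":
        adjusted = bh_adjust(p_values)
    elif method == "hochberg":
        adjusted = hochberg_adjust(p_values)
    else:
        raise ValidationError(f"unknown correction method {method!r}")

    results = [
        EnrichmentResult(
            term=t,
            study_hits=term_study[t],
            study_size=n,
            background_hits=term_background[t],
            background_size=N,
            p_value=p,
            adjusted_p=q,
            enriched=q <= alpha,
        )
        for t, p, q in zip(tested, p_values, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.term))
    return results


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term": r.term,
                "study_hits": r.study_hits,
                "study_size": r.study_size,
                "background_hits": r.background_hits,
                "background_size": r.background_size,
                "p_value": r.p_value,
                "adjusted_p": r.adjusted_p,
                "enriched": r.enriched,
            }
            for r in results
        ],
        columns=[
            "term", "study_hits", "study_size", "background_hits",
            "background_size", "p_value", "adjusted_p", "enriched",
        ],
    )
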