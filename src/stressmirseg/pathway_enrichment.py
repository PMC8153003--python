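"""Pathway over-representation analysis of miRNA target genes.

One-sided Fisher exact test (upper-tail hypergeometric) per pathway
against a background universe, Benjamini-Hochberg step-up FDR across all
pathways tested, and -log10(FDR) for display. Pathway collections are
consumed in GMT format; the default background is the union of all
pathway genes (configurable, since web-tool backgrounds are not
reproducible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class EnrichmentError(ValueError):
    """Invalid enrichment input."""


@dataclass(frozen=True)
class AnnotationCollection:
    pathways: Mapping[str, frozenset[str]]
    background: frozenset[str]

    def __post_init__(self):
        if not self.background:
            raise EnrichmentError("background universe is empty")
        for name, genes in self.pathways.items():
            extra = genes - self.background
            if extra:
                raise EnrichmentError(
                    f"pathway {name!r} has genes outside the background: "
                    f"{sorted(extra)[:5]}"
                )


def read_gmt(path: str | Path,
             background: Iterable[str] | None = None) -> AnnotationCollection:
    """Parse a GMT file (name <tab> description <tab> gene ...).

    Duplicate genes within a set are collapsed with a warning. If no
    background is given, the union of all pathway genes is used.
    """
    pathways: dict[str, frozenset[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise EnrichmentError(
                f"{path}, line {line_no}: expected name, description and at "
                "least one gene"
            )
        name, genes = parts[0], [g.strip() for g in parts[2:] if g.strip()]
        if len(genes) != len(set(genes)):
            logger.warning("%s line %d: duplicate genes in %s collapsed",
                           path, line_no, name)
        if name in pathways:
            raise EnrichmentError(f"{path}: duplicate pathway name {name!r}")
        pathways[name] = frozenset(genes)
    bg = (frozenset(background) if background is not None
          else frozenset().union(*pathways.values()))
    return AnnotationCollection(pathways, bg)


def fisher_overrep(k: int, list_size: int, pathway_size: int,
                   background_size: int) -> float:
    """One-sided upper-tail hypergeometric probability P(X >= k)."""
    for name, v in (("k", k), ("list_size", list_size),
                    ("pathway_size", pathway_size),
                    ("background_size", background_size)):
        if v < 0:
            raise EnrichmentError(f"{name} must be nonnegative, got {v}")
    if k > list_size or k > pathway_size:
        raise EnrichmentError(
            f"inconsistent table: k={k} exceeds list ({list_size}) or "
            f"pathway ({pathway_size}) size"
        )
    if list_size > background_size or pathway_size > background_size:
        raise EnrichmentError("list/pathway larger than background")
    if list_size + pathway_size - k > background_size:
        raise EnrichmentError(
            "inconsistent table: list + pathway - k exceeds background"
        )
    return float(stats.hypergeom.sf(k - 1, background_size, pathway_size,
                                    list_size))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise EnrichmentError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(targets: Iterable[str], collection: AnnotationCollection,
           fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Fisher over-representation of ``targets`` in every pathway.

    Target genes outside the background are dropped with a warning. The
    result is sorted by FDR (then raw p, then name), with a significance
    flag at ``fdr_threshold`` and -log10(FDR) for bar-plot style display.
    """
    if not collection.pathways:
        raise EnrichmentError("empty pathway collection")
    targets = set(targets)
    outside = targets - collection.background
    if outside:
        logger.warning("%d target genes outside the background dropped: %s",
                       len(outside), sorted(outside)[:5])
        targets -= outside
    list_size = len(targets)
    bg_size = len(collection.background)
    rows = []
    for name in sorted(collection.pathways):
        genes = collection.pathways[name]
        k = len(targets & genes)
        p = fisher_overrep(k, list_size, len(genes), bg_size)
        rows.append((name, k, list_size, len(genes), bg_size, p))
    out = pd.DataFrame(rows, columns=["pathway", "k", "list_size",
                                      "pathway_size", "background_size", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["neg_log10_fdr"] = -np.log10(out["fdr"])
    out["significant"] = out["fdr"] < fdr_threshold
    out = out.sort_values(["fdr", "p", "pathway"], kind="mergesort")
    return out.reset_index(drop=True)
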