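"""Hypergeometric over-representation analysis and gene-list overlap.

The signal set (e.g. up-regulated circle-producing genes) is tested
against user-supplied gene-set collections over an explicit background
universe; the p-value is the hypergeometric upper tail P[X >= k].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .model import EccdiffError, GeneSet

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["term_id", "term_name", "k", "K", "n", "N", "p_value", "member_genes"]


def _normalize(genes: Iterable[str]) -> set[str]:
    return {g.upper() for g in genes}


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(population N, successes K, draws n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    signal: Iterable[str],
    background: Iterable[str],
    sets: Sequence[GeneSet],
    bh: bool = False,
) -> pd.DataFrame:
    """Over-representation of the signal set in each gene set.

    Signal genes absent from the background are dropped with a warning.
    Terms with no background members (K == 0) are skipped. Results are
    ordered by ascending p-value, then term_id. With ``bh=True`` a
    ``p_adjusted`` Benjamini-Hochberg column is appended.
    """
    background_set = _normalize(background)
    signal_set = _normalize(signal)
    stray = signal_set - background_set
    if stray:
        warnings.warn(
            f"{len(stray)} signal gene(s) absent from background dropped: "
            f"{sorted(stray)[:5]}...",
            stacklevel=2,
        )
        signal_set &= background_set
    if not signal_set:
        raise EccdiffError("signal set is empty after intersecting with background")
    if not sets:
        raise EccdiffError("no gene sets supplied")

    N = len(background_set)
    n = len(signal_set)
    rows = []
    for gs in sets:
        members = _normalize(gs.members)
        K = len(members & background_set)
        if K == 0:
            continue
        hit = sorted(members & signal_set)
        k = len(hit)
        rows.append(
            {
                "term_id": gs.term_id,
                "term_name": gs.term_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeom_upper_tail(k, N, K, n),
                "member_genes": ",".join(hit),
            }
        )
    table = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    table = table.sort_values(["p_value", "term_id"]).reset_index(drop=True)
    if bh:
        table["p_adjusted"] = _bh(table["p_value"].to_numpy())
    return table


def _bh(p):
    import numpy as np

    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * n / (rank_idx + 1))
        adj[i] = running
    return adj


@dataclass
class OverlapResult:
    overlap: list[str]
    n_overlap: int
    n_signal: int
    n_catalog: int


def overlap_catalog(signal: Iterable[str], catalog: Iterable[str]) -> OverlapResult:
    """Case-insensitive intersection of the signal list with a gene list."""
    signal_set = _normalize(signal)
    catalog_set = _normalize(catalog)
    if not signal_set or not catalog_set:
        raise EccdiffError("overlap_catalog needs two non-empty gene lists")
    inter = sorted(signal_set & catalog_set)
    return OverlapResult(
        overlap=inter,
        n_overlap=len(inter),
        n_signal=len(signal_set),
        n_catalog=len(catalog_set),
    )
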