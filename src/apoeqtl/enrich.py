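"""Hypergeometric over-representation analysis of metabolite hit lists.

A pathway library (GMT format) defines metabolite sets over a reference
background metabolome of size N; for a hit list of size n, a pathway of
size K containing k of the hits gets the upper-tail probability
P(X >= k) under Hypergeometric(N, K, n), and q-values are BH-adjusted
over the tested pathways.  The background size is an explicit parameter
(defaulting to the union of library members), since enrichment p-values
are only meaningful conditional on it.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import bh_fdr

__all__ = ["PathwayLibrary", "load_gmt", "ora_hypergeom", "enrich_table"]


class EnrichError(ValueError):
    pass


def _norm(name: str) -> str:
    return " ".join(str(name).lower().split())


@dataclass
class PathwayLibrary:
    """name -> member set, plus the reference background size."""

    pathways: dict[str, set[str]]
    background_size: int

    def __post_init__(self):
        if not self.pathways:
            raise EnrichError("pathway library is empty")
        for name, members in self.pathways.items():
            if not members:
                raise EnrichError(f"pathway {name!r} has no members")
        union = set().union(*self.pathways.values())
        biggest = max(len(m) for m in self.pathways.values())
        if self.background_size < max(len(union), biggest):
            raise EnrichError(
                f"background_size {self.background_size} smaller than the "
                f"library union ({len(union)})"
            )


def load_gmt(path: str | os.PathLike,
             background_size: int | None = None) -> PathwayLibrary:
    """Read a GMT file (name, description, members; tab-delimited).

    Members are case/whitespace-normalized and de-duplicated; empty lines
    and pathways without members are skipped with a warning.  The
    background defaults to the size of the union of all members.
    """
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0].strip():
                if line.strip():
                    warnings.warn(f"{path}:{ln}: skipping malformed GMT line")
                continue
            members = {_norm(m) for m in parts[2:] if m.strip()}
            if not members:
                warnings.warn(f"{path}:{ln}: pathway {parts[0]!r} has no members")
                continue
            pathways[parts[0].strip()] = members
    if not pathways:
        raise EnrichError(f"{path}: no valid pathways")
    if background_size is None:
        background_size = len(set().union(*pathways.values()))
    return PathwayLibrary(pathways, background_size)


def ora_hypergeom(hits: int, input_size: int, pathway_size: int,
                  background: int) -> float:
    """P(X >= hits) with X ~ Hypergeometric(background, pathway_size,
    input_size)."""
    k, n, K, N = hits, input_size, pathway_size, background
    if min(k, n, K, N) < 0 or k > min(n, K) or n > N or K > N:
        raise EnrichError(
            f"inconsistent counts: hits={k}, input={n}, pathway={K}, background={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_table(hit_list, library: PathwayLibrary) -> pd.DataFrame:
    """One row per pathway with >= 1 hit: Total, Hits, P and BH q.

    Hit identifiers are matched after lower-casing and whitespace
    normalization; unmatched ones are reported in
    ``.attrs["unmapped"]``.  An empty hit list warns and yields an empty
    table.  q is BH over all pathways tested (those with >= 1 hit), and
    rows are sorted by p.
    """
    hits = {_norm(h) for h in hit_list}
    cols = ["pathway", "total", "hits", "p", "q"]
    if not hits:
        warnings.warn("empty hit list; nothing to enrich")
        return pd.DataFrame(columns=cols)
    vocab = set().union(*library.pathways.values())
    mapped = hits & vocab
    unmapped = sorted(hits - vocab)
    n = len(mapped)
    rows = []
    for name, members in library.pathways.items():
        k = len(mapped & members)
        if k == 0:
            continue
        p = ora_hypergeom(k, n, len(members), library.background_size)
        rows.append((name, len(members), k, p))
    out = pd.DataFrame(rows, columns=cols[:4])
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    out = out.sort_values(["p", "pathway"]).reset_index(drop=True)
    out.attrs["unmapped"] = unmapped
    out.attrs["input_size"] = n
    return out
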