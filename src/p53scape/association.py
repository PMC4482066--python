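"""Guilt-by-association inference for noncoding RNAs.

A query lincRNA's function is inferred from protein-coding genes with
similar expression profiles across a compendium of cell/tissue types.
Profiles are compared with the Jensen-Shannon distance (square root of the
Jensen-Shannon divergence in log base 2, so it is a metric bounded by 1),
genes are ranked most-similar first, and curated gene sets are scored on
the ranked list with a weighted running-sum enrichment statistic (the
standard preranked enrichment score) with a gene-label permutation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon


class ExpressionCompendium:
    """Gene x tissue non-negative expression matrix; all-zero rows are
    excluded at load."""

    def __init__(self, values: pd.DataFrame):
        if (values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        keep = values.sum(axis=1) > 0
        self.values = values.loc[keep]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.values.columns)

    def profile(self, gene_id: str) -> np.ndarray:
        return self.values.loc[gene_id].to_numpy(dtype=float)

    @classmethod
    def read(cls, path: str | Path) -> "ExpressionCompendium":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass
class RankedGeneList:
    """Genes ordered by similarity to the query (most similar first)."""

    query_id: str
    entries: pd.DataFrame  # columns: gene_id, distance; strictly ordered

    def genes(self) -> list[str]:
        return list(self.entries["gene_id"])

    def distances(self) -> np.ndarray:
        return self.entries["distance"].to_numpy(dtype=float)


def js_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Jensen-Shannon distance between two expression profiles.

    Profiles are normalized to probability vectors; the divergence uses log
    base 2 so the distance is in [0, 1], with 1 attained for disjoint
    supports. Symmetric; 0 iff the normalized profiles coincide; invariant
    under uniform rescaling of either profile.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("profiles must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("profiles must be non-negative")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("profiles must have positive sums")
    d = float(jensenshannon(p, q, base=2))
    # guard the sqrt against tiny negative round-off inside scipy
    return min(max(d, 0.0), 1.0)


def rank_by_association(
    query_profile: Sequence[float],
    compendium: ExpressionCompendium,
) -> RankedGeneList:
    """Rank compendium genes by ascending JS distance from the query.

    Ties are broken by gene id, so the order is strict and reproducible.
    Invariant under any permutation of the tissue axis applied to both the
    query and the compendium.
    """
    query = np.asarray(query_profile, dtype=float)
    mat = compendium.values.to_numpy(dtype=float)
    dists = [js_distance(query, row) for row in mat]
    frame = pd.DataFrame({"gene_id": compendium.genes, "distance": dists})
    frame = frame.sort_values(["distance", "gene_id"], kind="mergesort")
    return RankedGeneList(query_id="query", entries=frame.reset_index(drop=True))


def preranked_set_score(
    ranked: RankedGeneList,
    gene_set: Iterable[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Weighted running-sum enrichment score of a gene set on a ranked list.

    Hits increment the running sum proportionally to their similarity
    weight |1 - distance| (weighting exponent 1); misses decrement it
    uniformly. The enrichment score is the maximal deviation of the running
    sum from zero (signed). The p-value permutes gene labels n_perm times
    and uses the (1 + b) / (1 + n) convention, one-sided in the direction of
    the observed score.
    """
    genes = ranked.genes()
    dists = ranked.distances()
    hits = np.isin(genes, list(set(gene_set)))
    n_hit = int(hits.sum())
    n = len(genes)
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    weights = np.abs(1.0 - dists)
    obs = _running_sum_es(hits, weights)
    if n_hit == n:
        # every gene is a hit: the running sum can only rise; degenerate
        return obs, 1.0
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        null_hits = np.zeros(n, dtype=bool)
        null_hits[rng.permutation(n)[:n_hit]] = True
        es = _running_sum_es(null_hits, weights)
        if (obs >= 0 and es >= obs) or (obs < 0 and es <= obs):
            b += 1
    return obs, (1 + b) / (1 + n_perm)


def _running_sum_es(hits: np.ndarray, weights: np.ndarray) -> float:
    n = len(hits)
    n_hit = int(hits.sum())
    w_hit = weights[hits]
    total_w = w_hit.sum()
    steps = np.zeros(n, dtype=float)
    if total_w > 0:
        steps[hits] = weights[hits] / total_w
    else:  # all weights zero: fall back to unweighted hits
        steps[hits] = 1.0 / n_hit
    if n_hit < n:
        steps[~hits] = -1.0 / (n - n_hit)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx])


# -- GMT gene sets ----------------------------------------------------------------


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT: one set per line, tab-separated name, description, members."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            members = sorted(sets[name])
            fh.write("\t".join([name, "na"] + members) + "\n")
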