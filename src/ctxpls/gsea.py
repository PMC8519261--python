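"""Preranked gene-set enrichment on PLS gene weights.

Genes are ranked by descending signed weight (ties broken by gene id)
and each set is scored with the weighted Kolmogorov-Smirnov running
sum: member genes ("hits") increment the sum by ``|w|^exponent``
normalized over the set, non-members decrement it by ``1 / (N - N_H)``.
The enrichment score (ES) is the signed maximum deviation of the sum,
so ES lies in [-1, 1].

Because the ranking statistic is a per-gene weight with no sample-level
phenotype behind it, the null model permutes gene labels: for each set
the null ES distribution comes from random same-size gene draws from
the universe. P-values are two-sided tail frequencies with a +1
pseudo-count, NES divides the ES by the mean |null ES| of matching
sign, and FDR control is Benjamini-Hochberg over all tested sets. A
set's direction is the sign of the median weight of its member genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str]

    def __len__(self) -> int:
        return len(self.sets)

    @classmethod
    def from_dict(cls, sets: dict[str, list[str]]) -> "GeneSetCollection":
        return cls(sets=dict(sets), descriptions={k: "" for k in sets})


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a set are collapsed (order preserved), empty
    lines are skipped, and a line with fewer than three fields raises a
    parse error naming the line number.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected name, description and "
                    f"at least one gene, got {len(parts)} field(s)"
                )
            name, desc, *genes = parts
            sets[name] = list(dict.fromkeys(g for g in genes if g))
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def rank_genes(weights: pd.Series) -> pd.Series:
    """Descending-weight ordering with lexicographic gene-id tie-break."""
    if not np.all(np.isfinite(weights.to_numpy(dtype=float))):
        raise ValueError("non-finite gene weights")
    frame = weights.rename("w").rename_axis("gene").reset_index()
    frame = frame.sort_values(["w", "gene"], ascending=[False, True], kind="mergesort")
    return pd.Series(frame["w"].to_numpy(), index=frame["gene"].to_numpy())


def _es_from_positions(
    abs_w_pow: np.ndarray, positions: np.ndarray
) -> np.ndarray:
    """ES for one or many hit-position vectors against a fixed ranking.

    ``abs_w_pow`` is ``|w|^exponent`` in rank order (length N);
    ``positions`` is (B, s) of 0-based rank positions, unsorted is
    fine. The running sum is piecewise linear between hits, so its
    extrema occur just before or at each hit; both candidates are
    evaluated in closed form.
    """
    positions = np.sort(np.atleast_2d(positions), axis=1)
    B, s = positions.shape
    N = abs_w_pow.shape[0]
    if s >= N:
        raise ValueError("set size must be smaller than the universe")
    hitw = abs_w_pow[positions]
    csum = np.cumsum(hitw, axis=1)
    total = csum[:, -1:]
    miss = 1.0 / (N - s)
    j = np.arange(s)[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, csum / total, (j + 1.0) / s)
        frac_before = np.where(
            total > 0, (csum - hitw) / total, j.astype(float) / s
        )
    at_hit = frac - (positions - j) * miss
    before_hit = frac_before - (positions - j) * miss
    cand = np.concatenate([at_hit, before_hit], axis=1)
    best = np.take_along_axis(
        cand, np.argmax(np.abs(cand), axis=1)[:, None], axis=1
    )[:, 0]
    return best


def enrichment_score(
    ranked: pd.Series, gene_set, exponent: float = 1.0
) -> tuple[float, np.ndarray]:
    """ES and full running-sum trace of one set against a ranking.

    ``ranked`` must already be in rank order (see :func:`rank_genes`).
    Returns ``(ES, trace)`` where ``trace[i]`` is the running sum after
    the gene at rank position i.
    """
    genes = np.asarray(ranked.index)
    members = set(gene_set) & set(genes)
    if not members:
        raise ValueError("gene set has empty intersection with the universe")
    ishit = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    aw = np.abs(ranked.to_numpy(dtype=float)) ** exponent
    hit_total = aw[ishit].sum()
    n, nh = len(genes), int(ishit.sum())
    if nh >= n:
        raise ValueError("gene set covers the whole universe")
    steps = np.where(
        ishit,
        (aw / hit_total) if hit_total > 0 else (1.0 / nh),
        -1.0 / (n - nh),
    )
    trace = np.cumsum(steps)
    es = float(trace[np.argmax(np.abs(trace))])
    return es, trace


def pathway_direction(gene_set, weights: pd.Series) -> str:
    """Sign of the median weight of member genes: '+', '-' or '0'."""
    members = [g for g in set(gene_set) if g in weights.index]
    if not members:
        raise ValueError("gene set has empty intersection with the weights")
    med = float(np.median(weights.loc[members].to_numpy(dtype=float)))
    if med > 0:
        return "+"
    if med < 0:
        return "-"
    return "0"


def gsea_preranked(
    weights: pd.Series,
    collection: GeneSetCollection,
    n_perm: int = 10_000,
    seed: int = 0,
    min_size: int = 10,
    max_size: int = 500,
    exponent: float = 1.0,
) -> pd.DataFrame:
    """Permutation GSEA of every set against a per-gene weight vector.

    Sets are intersected with the weight universe and filtered to
    ``[min_size, max_size]``. The null for a set of size s is the ES of
    ``n_perm`` uniform random draws of s genes; draws are shared across
    sets of equal size. Returns one row per tested set with ES, NES,
    permutation p, BH q, median member weight and direction; the frame
    is sorted by p then set name. Empty after filtering -> empty frame.
    """
    if isinstance(collection, dict):
        collection = GeneSetCollection.from_dict(collection)
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ranked = rank_genes(weights)
    universe = list(ranked.index)
    pos_of = {g: i for i, g in enumerate(universe)}
    N = len(universe)
    aw = np.abs(ranked.to_numpy(dtype=float)) ** exponent

    tested = {}
    for name, genes in collection.sets.items():
        members = sorted({g for g in genes if g in pos_of})
        if min_size <= len(members) <= max_size and len(members) < N:
            tested[name] = members
    if not tested:
        return pd.DataFrame(
            columns=[
                "set", "size", "es", "nes", "p", "q", "median_weight", "direction",
            ]
        )

    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}
    rows = []
    for name in sorted(tested):
        members = tested[name]
        s = len(members)
        positions = np.asarray([pos_of[g] for g in members])
        es = float(_es_from_positions(aw, positions[None, :])[0])
        if s not in null_cache:
            draws = np.empty((n_perm, s), dtype=int)
            for b in range(n_perm):
                draws[b] = rng.choice(N, size=s, replace=False)
            null_cache[s] = _es_from_positions(aw, draws)
        null = null_cache[s]
        p = (1.0 + np.count_nonzero(np.abs(null) >= abs(es) - 1e-12)) / (n_perm + 1.0)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        nes = es / np.mean(np.abs(same_sign)) if same_sign.size else np.nan
        direction = pathway_direction(members, weights)
        med = float(np.median(weights.loc[members].to_numpy(dtype=float)))
        rows.append(
            {
                "set": name,
                "size": s,
                "es": es,
                "nes": float(nes),
                "p": float(p),
                "median_weight": med,
                "direction": direction,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return out[["set", "size", "es", "nes", "p", "q", "median_weight", "direction"]]
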