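"""Preranked gene-set enrichment with a gene-set permutation null.

Genes ranked by a score (here, correlation with a marker gene) are walked in
the classic weighted GSEA fashion: hits contribute ``|score|^w`` normalised
over hits, misses a constant penalty, and the enrichment score (ES) is the
walk deviation of largest magnitude.  Significance comes from permuted gene
sets of the same size; normalised enrichment scores (NES) divide ES by the
mean magnitude of same-sign null ES, nominal p uses the add-one permutation
convention, and the FDR q is the pooled null-ratio estimate of the original
GSEA procedure.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "make_ranked_list",
    "read_rnk",
    "write_rnk",
    "preranked_es",
    "permutation_null",
    "gsea_preranked",
]


def make_ranked_list(scores: pd.Series, source: str = "") -> pd.Series:
    """Sort scores descending with deterministic gene-id tie-breaking.

    Drops non-finite scores; raises on duplicate gene ids.
    """
    s = scores[np.isfinite(scores.astype(float))].astype(float)
    if s.index.duplicated().any():
        raise ValueError("ranked list has duplicate gene ids")
    s = s.sort_index(kind="mergesort")          # secondary key: gene id
    s = s.sort_values(ascending=False, kind="mergesort")  # primary: score
    s.attrs["source"] = source
    return s


def read_rnk(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: RNK needs two columns (gene, score)")
    s = pd.Series(df[1].astype(float).to_numpy(), index=df[0].str.strip())
    return make_ranked_list(s, source=str(path))


def write_rnk(scores: pd.Series, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for gene, val in scores.items():
            fh.write(f"{gene}\t{val:.10g}\n")


def _walk_es(scores: np.ndarray, hit_mask: np.ndarray, weight_exponent: float) -> float:
    n = scores.size
    m = int(hit_mask.sum())
    wm = np.abs(scores[hit_mask]) ** weight_exponent
    total = wm.sum()
    steps = np.full(n, -1.0 / (n - m))
    steps[hit_mask] = wm / total if total > 0 else 1.0 / m
    path = np.cumsum(steps)
    hi, lo = float(path.max()), float(path.min())
    return hi if hi >= -lo else lo


def preranked_es(
    ranked: pd.Series,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> float:
    """Weighted KS enrichment score of one set in a ranked list (signed).

    A set covering the whole list is the degenerate all-hit walk, which
    peaks at exactly 1.
    """
    genes = set(gene_set)
    hit_mask = ranked.index.isin(genes)
    m = int(hit_mask.sum())
    if m < 2:
        raise ValueError(f"gene set matches only {m} gene(s); need >= 2")
    if m == ranked.size:
        return 1.0
    return _walk_es(ranked.to_numpy(dtype=float), hit_mask, weight_exponent)


def permutation_null(
    ranked: pd.Series,
    set_size: int,
    n_perm: int,
    seed: int | np.random.Generator = 0,
    weight_exponent: float = 1.0,
    _chunk: int = 256,
) -> np.ndarray:
    """ES values of ``n_perm`` uniformly random same-size gene sets.

    Seeded and reproducible; used as the gene-set permutation null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null")
    n = ranked.size
    if not 2 <= set_size < n:
        raise ValueError("set_size must satisfy 2 <= set_size < list size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scores = ranked.to_numpy(dtype=float)
    absw = np.abs(scores) ** weight_exponent
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(_chunk, n_perm - done)
        # random distinct positions per permutation via random-key argpartition
        keys = rng.random((b, n))
        idx = np.argpartition(keys, set_size, axis=1)[:, :set_size]
        steps = np.full((b, n), -1.0 / (n - set_size))
        rows = np.arange(b)[:, None]
        hit_w = absw[idx]
        totals = hit_w.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        steps[rows, idx] = hit_w / totals
        path = np.cumsum(steps, axis=1)
        hi, lo = path.max(axis=1), path.min(axis=1)
        out[done : done + b] = np.where(hi >= -lo, hi, lo)
        done += b
    return out


def _normalise(es: float, nulls: np.ndarray) -> tuple[float, float]:
    """(NES, nominal p) against a same-size null ES sample."""
    if es >= 0:
        same = nulls[nulls >= 0]
    else:
        same = nulls[nulls < 0]
    if same.size == 0:
        return np.nan, np.nan
    denom = np.abs(same).mean()
    nes = es / denom if denom > 0 else np.nan
    p = (1.0 + float((np.abs(same) >= abs(es)).sum())) / (1.0 + same.size)
    return nes, p


def gsea_preranked(
    ranked: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
) -> pd.DataFrame:
    """Full preranked GSEA: ES, NES, nominal p and FDR q per gene set.

    Sets outside ``[min_size, max_size]`` matched genes are filtered (the
    conventional preranked defaults).  FDR: for a set with NES*, q is the
    ratio of the null fraction of NES at least as extreme (same sign) to the
    observed fraction at least as extreme, pooled over sets, clipped to
    [0, 1] and monotonised in |NES|.  Null ES are shared across sets of the
    same matched size.
    """
    rng = np.random.default_rng(seed)
    records = []
    null_nes_pool: list[np.ndarray] = []
    nulls_by_size: dict[int, np.ndarray] = {}

    for gs in sets:
        m = int(ranked.index.isin(set(gs.genes)).sum())
        if not min_size <= m <= max_size or m >= ranked.size:
            logger.info("set %r: %d matched genes outside [%d, %d]; filtered",
                        gs.name, m, min_size, max_size)
            continue
        es = preranked_es(ranked, gs.genes, weight_exponent)
        if m not in nulls_by_size:
            nulls_by_size[m] = permutation_null(
                ranked, m, n_perm, rng, weight_exponent
            )
        nulls = nulls_by_size[m]
        nes, p = _normalise(es, nulls)
        records.append({"name": gs.name, "size": m, "es": es, "nes": nes, "p": p})
        # normalise this set's null sample into NES units for the pooled FDR
        pos, neg = nulls[nulls >= 0], nulls[nulls < 0]
        nn = np.concatenate([
            pos / pos.mean() if pos.size else pos,
            neg / np.abs(neg).mean() if neg.size else neg,
        ])
        null_nes_pool.append(nn)

    if not records:
        raise ValueError("no gene set passed the size filter")
    res = pd.DataFrame(records).set_index("name")
    pool = np.concatenate(null_nes_pool)
    obs = res["nes"].to_numpy()

    q = np.full(obs.size, np.nan)
    for sign in (1, -1):
        sel = np.where((obs >= 0) if sign > 0 else (obs < 0))[0]
        if sel.size == 0:
            continue
        pool_side = pool[pool >= 0] if sign > 0 else pool[pool < 0]
        obs_side = obs[(obs >= 0)] if sign > 0 else obs[obs < 0]
        for i in sel:
            v = obs[i]
            null_frac = (
                float((pool_side >= v).sum()) / pool_side.size if pool_side.size else np.nan
            ) if sign > 0 else (
                float((pool_side <= v).sum()) / pool_side.size if pool_side.size else np.nan
            )
            obs_frac = (
                float((obs_side >= v).sum()) / obs_side.size
                if sign > 0
                else float((obs_side <= v).sum()) / obs_side.size
            )
            q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan
        # monotonise: a more extreme |NES| never has a larger q
        order = sel[np.argsort(-np.abs(obs[sel]))]  # most extreme first
        best = np.inf
        for i in order:
            if np.isfinite(q[i]):
                best = min(best, q[i])
                q[i] = best
    res["q"] = q
    return res.sort_values("nes", ascending=False)
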