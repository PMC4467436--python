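"""Seed-gene correlation profiling and coexpression-module selection.

The signature-discovery stage: correlate every gene in the matrix with a seed
(marker) gene, attach a t-distribution p-value and a Benjamini–Hochberg q,
and select the module as the genes whose correlation exceeds the profile mean
by ``sd_mult`` standard deviations with q below ``fdr_max`` (positively
correlated genes only, by default — genes must be co-detected with the marker
to be usable as a signature).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import stdtr

from .association_stats import bh_fdr, hypergeom_overlap_test

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationProfile",
    "CoexpressionModule",
    "correlate_with_seed",
    "select_module",
    "module_overlap",
    "write_modules",
    "read_modules",
]


@dataclass
class CorrelationProfile:
    """Per-gene correlation of the matrix with one seed gene.

    ``table`` is indexed by gene (seed excluded) with columns ``r``,
    ``n_used``, ``p``, ``q``; genes with fewer than 3 pairwise-complete
    observations or zero variance carry NaN throughout.
    """

    seed: str
    method: str
    table: pd.DataFrame

    @property
    def finite(self) -> pd.DataFrame:
        return self.table[np.isfinite(self.table["r"])]


@dataclass
class CoexpressionModule:
    marker: str
    genes: list[str]
    cutoff_params: dict = field(default_factory=dict)
    threshold: float = math.nan      # r cutoff: mean + sd_mult * sd
    percentile: float = math.nan     # percentile of the threshold in the r profile
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.genes)


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Average ranks along axis 1 (ties share the mean rank)."""
    order = np.argsort(x, axis=1, kind="mergesort")
    n = x.shape[1]
    ranks = np.empty_like(x, dtype=float)
    rows = np.arange(x.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, n + 1, dtype=float)
    # average ties
    sx = np.take_along_axis(x, order, axis=1)
    for i in range(x.shape[0]):
        row, srow = ranks[i], sx[i]
        j = 0
        while j < n:
            k = j
            while k + 1 < n and srow[k + 1] == srow[j]:
                k += 1
            if k > j:
                idx = order[i, j : k + 1]
                row[idx] = row[idx].mean()
            j = k + 1
    return ranks


def correlate_with_seed(
    matrix: pd.DataFrame, seed: str, method: str = "pearson"
) -> CorrelationProfile:
    """Correlate all genes with a seed gene over pairwise-complete samples.

    ``method`` is ``"pearson"`` or ``"spearman"`` (Pearson on average ranks,
    computed within each gene's pairwise-complete sample subset).  The
    p-value is two-sided from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom — the correlation-test statistic under the null of zero
    correlation — and q is BH over all finite p.  The seed itself is excluded
    from the profile.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    if seed not in matrix.index:
        raise KeyError(f"seed gene {seed!r} not present in the expression matrix")

    x = np.asarray(matrix, dtype=float)
    seed_pos = matrix.index.get_loc(seed)
    if not isinstance(seed_pos, (int, np.integer)):
        raise ValueError(f"seed gene {seed!r} is duplicated in the matrix")
    s = x[seed_pos]

    genes = matrix.index
    n_genes = x.shape[0]
    r = np.full(n_genes, np.nan)
    n_used = np.zeros(n_genes, dtype=int)

    seed_ok = np.isfinite(s)
    complete = np.isfinite(x) & seed_ok  # per-gene pairwise-complete mask
    n_used = complete.sum(axis=1)

    if method == "pearson" and complete.all():
        r = _pearson_rows(x, s)
    else:
        for i in range(n_genes):
            m = complete[i]
            if n_used[i] < 3:
                continue
            gi, si = x[i, m], s[m]
            if method == "spearman":
                both = _rank_rows(np.vstack([gi, si]))
                gi, si = both[0], both[1]
            r[i] = _pearson_rows(gi[None, :], si)[0]

    with np.errstate(divide="ignore", invalid="ignore"):
        df = n_used - 2.0
        t = r * np.sqrt(df / (1.0 - r**2))
        p = np.where(np.isfinite(r), 2.0 * stdtr(np.maximum(df, 1.0), -np.abs(t)), np.nan)
        p = np.where(np.isfinite(r) & (np.abs(r) >= 1.0), 0.0, p)

    table = pd.DataFrame({"r": r, "n_used": n_used, "p": p}, index=genes)
    table = table.drop(index=seed)
    table["q"] = bh_fdr(table["p"].to_numpy())
    return CorrelationProfile(seed=seed, method=method, table=table)


def _pearson_rows(x: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``x`` against the vector ``s`` (no NaN)."""
    xc = x - x.mean(axis=1, keepdims=True)
    sc = s - s.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (sc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ sc) / denom
    r[denom == 0] = np.nan  # zero-variance gene (or seed): undefined
    return np.clip(r, -1.0, 1.0, out=r, where=np.isfinite(r))


def select_module(
    profile: CorrelationProfile,
    sd_mult: float = 2.0,
    fdr_max: float = 0.05,
    positive_only: bool = True,
) -> CoexpressionModule:
    """Select the coexpression module from a correlation profile.

    Members are the genes with finite r exceeding ``mean(r) + sd_mult*sd(r)``
    (mean and SD over the signed finite correlations of the whole profile,
    seed excluded) and ``q < fdr_max``; with ``positive_only`` also r > 0.
    An empty selection is legal and logged, not an error.  The empirical
    percentile of the r-threshold within the profile is reported so the
    selection can be compared against a "top x%" description.
    """
    fin = profile.finite
    if len(fin) < 10:
        raise ValueError(
            f"profile for {profile.seed!r} has only {len(fin)} finite correlations; need >= 10"
        )
    r = fin["r"].to_numpy()
    threshold = float(r.mean() + sd_mult * r.std(ddof=1))
    keep = (fin["r"] > threshold) & (fin["q"] < fdr_max)
    if positive_only:
        keep &= fin["r"] > 0
    genes = fin.index[keep].tolist()
    percentile = float((r < threshold).mean() * 100.0)
    if not genes:
        logger.warning("module for seed %r is empty at the chosen cutoff", profile.seed)
    return CoexpressionModule(
        marker=profile.seed,
        genes=genes,
        cutoff_params={
            "sd_mult": sd_mult,
            "fdr_max": fdr_max,
            "positive_only": positive_only,
            "method": profile.method,
        },
        threshold=threshold,
        percentile=percentile,
    )


def module_overlap(
    a: Iterable[str], b: Iterable[str], universe: int
) -> dict[str, float]:
    """Overlap size and upper-tail hypergeometric p of two gene sets.

    ``universe`` is the number of genes the two sets were drawn from (the
    post-collapse platform gene count).
    """
    sa, sb = set(a), set(b)
    if universe < max(len(sa), len(sb)):
        raise ValueError("universe smaller than one of the sets")
    k = len(sa & sb)
    p = hypergeom_overlap_test(k, len(sa), len(sb), universe)
    return {"k": k, "p": p}


def write_modules(modules: Sequence[CoexpressionModule], path: str | Path) -> None:
    """Write modules as two-column TSV (module, gene) plus a JSON sidecar.

    The sidecar ``<path>.json`` records cutoff parameters, the r-threshold
    and its percentile for each module.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("module\tgene\n")
        for mod in modules:
            for g in mod.genes:
                fh.write(f"{mod.marker}\t{g}\n")
    sidecar = {
        mod.marker: {
            "cutoff_params": mod.cutoff_params,
            "threshold": mod.threshold,
            "percentile": mod.percentile,
            "n_genes": len(mod.genes),
        }
        for mod in modules
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2), encoding="utf-8")


def read_modules(path: str | Path) -> list[CoexpressionModule]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["module", "gene"]:
        raise ValueError(f"{path}: expected columns 'module' and 'gene'")
    sidecar_path = Path(str(path) + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    out = []
    for marker, grp in df.groupby("module", sort=False):
        info = meta.get(marker, {})
        out.append(
            CoexpressionModule(
                marker=marker,
                genes=grp["gene"].tolist(),
                cutoff_params=info.get("cutoff_params", {}),
                threshold=info.get("threshold", math.nan),
                percentile=info.get("percentile", math.nan),
            )
        )
    return out
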