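"""Windowed r²-based LD pruning (indep-pairwise style, on unphased dosages).

r² is the squared Pearson correlation of dosage vectors over pairwise-
complete observations (the composite-LD convention).  Pruning scans sliding
marker windows, removing the later-indexed member of any pair above the
threshold, and re-scans to convergence.  Windows never span chromosomes.
Monomorphic markers (undefined r²) are kept: undefined is not high LD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix

__all__ = ["PruneParams", "genotype_r2", "prune", "prune_brute_force"]


@dataclass(frozen=True)
class PruneParams:
    window_size: int = 200
    step: int = 25
    r2_threshold: float = 0.4

    def __post_init__(self) -> None:
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")
        if self.step < 1 or self.window_size < 1:
            raise ValueError("window_size and step must be >= 1")
        if not (0.0 < self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must lie in (0, 1]")


def genotype_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation over complete pairs; NaN if undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = (x != MISSING) & (y != MISSING) & ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return math.nan
    xs, ys = x[ok], y[ok]
    xd = xs - xs.mean()
    yd = ys - ys.mean()
    vx = (xd * xd).sum()
    vy = (yd * yd).sum()
    if vx == 0.0 or vy == 0.0:
        return math.nan
    c = (xd * yd).sum()
    return float((c * c) / (vx * vy))


def _prune_chromosome(
    dosages: np.ndarray, offset: int, params: PruneParams
) -> list[int]:
    """Prune markers of one chromosome; returns kept global indices."""
    L = dosages.shape[1]
    kept = list(range(L))
    changed = True
    while changed:
        changed = False
        n_kept = len(kept)
        start = 0
        while start < n_kept:
            window = kept[start : start + params.window_size]
            removed: set[int] = set()
            for a_pos in range(len(window)):
                ia = window[a_pos]
                if ia in removed:
                    continue
                for b_pos in range(a_pos + 1, len(window)):
                    ib = window[b_pos]
                    if ib in removed:
                        continue
                    r2 = genotype_r2(dosages[:, ia], dosages[:, ib])
                    if not math.isnan(r2) and r2 > params.r2_threshold:
                        removed.add(ib)  # drop the later-indexed member
            if removed:
                changed = True
                kept = [i for i in kept if i not in removed]
                n_kept = len(kept)
            if start + params.window_size >= n_kept:
                break
            start += params.step
    return [offset + i for i in kept]


def prune(G: GenotypeMatrix, params: PruneParams | None = None) -> list[int]:
    """Return the sorted list of surviving marker indices."""
    if params is None:
        params = PruneParams()
    if G.n_markers == 0:
        return []
    kept: list[int] = []
    for _chrom, start, end in G.chromosome_spans():
        kept.extend(_prune_chromosome(G.dosages[:, start:end], start, params))
    return sorted(kept)


def prune_brute_force(G: GenotypeMatrix, r2_threshold: float = 0.4) -> list[int]:
    """Oracle: exhaustive all-pairs pruning with the same removal rule.

    Scans every within-chromosome pair in index order and removes the
    later-indexed member of any pair above the threshold, repeating to
    convergence.  Equivalent to `prune` whenever the window covers the whole
    chromosome.
    """
    kept: list[int] = []
    for _chrom, start, end in G.chromosome_spans():
        local = list(range(start, end))
        changed = True
        while changed:
            changed = False
            removed: set[int] = set()
            for ai in range(len(local)):
                a = local[ai]
                if a in removed:
                    continue
                for bi in range(ai + 1, len(local)):
                    b = local[bi]
                    if b in removed:
                        continue
                    r2 = genotype_r2(G.dosages[:, a], G.dosages[:, b])
                    if not math.isnan(r2) and r2 > r2_threshold:
                        removed.add(b)
            if removed:
                changed = True
                local = [i for i in local if i not in removed]
        kept.extend(local)
    return sorted(kept)
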