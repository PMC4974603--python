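"""Blinding of the simulated cohort and scoring of submissions.

`blind` selects the release cohort (terminal offspring by default), applies
a seeded identity permutation, and strips sex, pedigree links, and labels
from the public files; the hidden answer key stays with the private map.
`score` compares a {blinded_id -> bool} submission with the key for one
rule, reporting the confusion counts plus accuracy, sensitivity, and
specificity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .descent_rules import DEFAULT_RULES, DescentRule, label_pedigree
from .genotype_io import GenotypeMatrix, SampleMeta
from .pedigree_sim import Pedigree, pedigree_genotypes

__all__ = ["BenchmarkBundle", "ScoreReport", "blind", "score", "read_submission"]


@dataclass
class BenchmarkBundle:
    public_genotypes: GenotypeMatrix  # blinded ids, shuffled rows
    public_meta: list[SampleMeta]  # sex stripped unless retained
    blinding_map: dict[str, str]  # blinded_id -> original id (private)
    manifest: dict

    def unblind(self, blinded_id: str) -> str:
        return self.blinding_map[blinded_id]


@dataclass(frozen=True)
class ScoreReport:
    rule: str
    tp: int
    fp: int
    tn: int
    fn: int
    n_missing: int = 0

    @property
    def n_scored(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_scored if self.n_scored else float("nan")

    @property
    def sensitivity(self) -> float:
        pos = self.tp + self.fn
        return self.tp / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn + self.fp
        return self.tn / neg if neg else float("nan")

    def to_row(self) -> dict:
        return {
            "rule": self.rule,
            "n_scored": self.n_scored,
            "n_missing": self.n_missing,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }


def blind(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix | None,
    seed: int,
    mode: str = "terminal_only",
    rules: Sequence[DescentRule] = DEFAULT_RULES,
    retain_sex: bool = False,
) -> tuple[BenchmarkBundle, dict[str, dict[str, bool]]]:
    """Blind the release cohort and return (bundle, hidden answer key).

    ``genotypes`` may be None, in which case dosages are collapsed from the
    pedigree haplotypes.  Blinded ids are sequential under a seeded
    permutation; genotype rows are only permuted and relabeled, never
    modified.
    """
    if mode not in ("terminal_only", "all_generations"):
        raise ValueError(f"unknown blinding mode {mode!r}")
    cohort = (
        pedigree.terminal_members()
        if mode == "terminal_only"
        else list(pedigree.members.values())
    )
    scope = "terminal" if mode == "terminal_only" else "all"
    key_by_original = label_pedigree(
        pedigree,
        rules,
        scope=scope,
        include_nonterminal_grandparent_rule=(scope == "all"),
    )
    if not key_by_original:
        raise ValueError("pedigree produced an empty answer key; cannot blind")

    original_ids = [ind.id for ind in cohort]
    if genotypes is None:
        genotypes = pedigree_genotypes(pedigree, cohort)
    missing = set(original_ids) - set(genotypes.samples)
    if missing:
        raise ValueError(f"genotypes missing release individuals: {sorted(missing)}")
    G = genotypes.subset_samples(original_ids)

    rng = substream(seed, "blind")
    perm = rng.permutation(len(original_ids))
    width = max(4, len(str(len(original_ids))))
    blinded_ids = [f"B{i + 1:0{width}d}" for i in range(len(original_ids))]
    # blinded_ids[j] names the original individual original_ids[perm[j]]
    blinding_map = {
        blinded_ids[j]: original_ids[perm[j]] for j in range(len(original_ids))
    }
    public = GenotypeMatrix(
        samples=blinded_ids,
        markers=list(G.markers),
        dosages=G.dosages[perm, :],
    )
    sex_by_id = {ind.id: ind.sex for ind in cohort}
    public_meta = [
        SampleMeta(
            sample_id=bid,
            sex=sex_by_id[blinding_map[bid]] if retain_sex else "unknown",
        )
        for bid in blinded_ids
    ]
    key = {
        bid: dict(key_by_original[blinding_map[bid]])
        for bid in blinded_ids
        if blinding_map[bid] in key_by_original
    }
    manifest = {
        "n_samples": public.n_samples,
        "n_markers": public.n_markers,
        "mode": mode,
        "rules": [r.name for r in rules],
        "seed_hash": hashlib.sha256(str(seed).encode()).hexdigest()[:16],
    }
    return BenchmarkBundle(public, public_meta, blinding_map, manifest), key


def score(
    submission: Mapping[str, bool],
    key: Mapping[str, Mapping[str, bool]],
    rule: str,
) -> ScoreReport:
    """Confusion counts of a submission against the key for one rule.

    Individuals in the key but absent from the submission are excluded and
    reported as ``n_missing``; submission ids outside the key are an error.
    """
    unknown = sorted(set(submission) - set(key))
    if unknown:
        raise ValueError(f"submission contains unknown blinded ids: {unknown}")
    tp = fp = tn = fn = 0
    n_missing = 0
    for bid, labels in key.items():
        if rule not in labels:
            raise KeyError(f"rule {rule!r} absent from key entry {bid!r}")
        if bid not in submission:
            n_missing += 1
            continue
        truth = bool(labels[rule])
        pred = bool(submission[bid])
        if truth and pred:
            tp += 1
        elif truth:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    return ScoreReport(rule=rule, tp=tp, fp=fp, tn=tn, fn=fn, n_missing=n_missing)


def read_submission(path) -> dict[str, bool]:
    """Read a (blinded_id, prediction in {0,1}) TSV."""
    df = pd.read_csv(path, sep="\t")
    preds: dict[str, bool] = {}
    for bid, val in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if val not in (0, 1, "0", "1", True, False):
            raise ValueError(f"prediction for {bid!r} not in {{0,1}}")
        preds[str(bid)] = bool(int(val))
    return preds
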