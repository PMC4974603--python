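"""Forward-in-time pedigree simulation with block recombination.

Founders are randomly paired male-female; offspring are built by choosing,
independently for each recombination block, one of the parent's two
haplotypes (no within-block crossover).  Blocks are half-open marker-index
ranges of fixed spacing, restarting at every chromosome boundary.  Each pair
has a fixed number of offspring with fair-coin sex; a sex-balanced cohort is
sampled from each offspring generation and paired for the next round.

Haplotype row convention: for non-founders, row 0 is the maternal gamete and
row 1 the paternal gamete.  This makes the Mendelian block oracle (every
offspring block equals one of the parent-of-origin's two blocks)
exhaustively checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._rng import substream
from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    MarkerInfo,
    MetadataError,
    SampleMeta,
)

__all__ = [
    "Individual",
    "Pedigree",
    "SimConfig",
    "PedigreeIntegrityError",
    "CohortBalanceError",
    "block_bounds",
    "phase_founders",
    "impute_missing",
    "make_gamete",
    "mate",
    "founders_from_genotypes",
    "run_benchmark_sim",
    "pedigree_genotypes",
]


class PedigreeIntegrityError(ValueError):
    pass


class CohortBalanceError(RuntimeError):
    """The offspring pool cannot supply a sex-balanced cohort."""


@dataclass
class Individual:
    id: str
    sex: str  # {male, female}
    generation: int
    mother_id: str | None = None
    father_id: str | None = None
    haplotypes: np.ndarray | None = None  # 2 x L; row 0 maternal for non-founders
    founder_label: str | None = None  # {labeled, unlabeled}; founders only

    @property
    def is_founder(self) -> bool:
        return self.mother_id is None and self.father_id is None

    @property
    def dosages(self) -> np.ndarray:
        return self.haplotypes.sum(axis=0).astype(np.int16)


@dataclass
class Pedigree:
    """Directed acyclic pedigree; insertion order is deterministic."""

    members: dict[str, Individual] = field(default_factory=dict)
    markers: list[MarkerInfo] = field(default_factory=list)

    def add(self, ind: Individual) -> None:
        if ind.id in self.members:
            raise PedigreeIntegrityError(f"duplicate individual id {ind.id!r}")
        for pid, want_sex in ((ind.mother_id, "female"), (ind.father_id, "male")):
            if pid is not None:
                parent = self.members.get(pid)
                if parent is None:
                    raise PedigreeIntegrityError(
                        f"{ind.id}: parent {pid!r} not in pedigree"
                    )
                if parent.sex != want_sex:
                    raise PedigreeIntegrityError(
                        f"{ind.id}: parent {pid!r} has sex {parent.sex}, "
                        f"expected {want_sex}"
                    )
        if ind.is_founder and ind.founder_label not in ("labeled", "unlabeled"):
            raise PedigreeIntegrityError(
                f"founder {ind.id!r} lacks a founder_label"
            )
        self.members[ind.id] = ind

    def __getitem__(self, ind_id: str) -> Individual:
        return self.members[ind_id]

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self.members

    def __len__(self) -> int:
        return len(self.members)

    def generation_members(self, generation: int) -> list[Individual]:
        return [m for m in self.members.values() if m.generation == generation]

    @property
    def max_generation(self) -> int:
        return max(m.generation for m in self.members.values())

    def terminal_members(self) -> list[Individual]:
        return self.generation_members(self.max_generation)

    def founders(self) -> list[Individual]:
        return self.generation_members(0)

    def to_table(self, path: str | Path) -> None:
        """Serialize topology as TSV (no genotypes)."""
        with open(path, "w") as fh:
            fh.write("id\tsex\tmother\tfather\tgeneration\tfounder_label\n")
            for m in self.members.values():
                fh.write(
                    f"{m.id}\t{m.sex}\t{m.mother_id or '0'}\t{m.father_id or '0'}"
                    f"\t{m.generation}\t{m.founder_label or '-'}\n"
                )


@dataclass(frozen=True)
class SimConfig:
    n_founders: int = 30  # sex-balanced; half labeled
    hotspot_spacing: int = 10_000
    offspring_per_pair: int = 4
    generations: int = 2
    cohort_size_per_generation: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders % 2:
            raise ValueError("n_founders must be even (sex-balanced pairing)")
        if self.hotspot_spacing < 1:
            raise ValueError("hotspot_spacing must be >= 1")
        if self.cohort_size_per_generation % 2:
            raise ValueError("cohort size must be even")
        n_pairs = self.cohort_size_per_generation // 2
        if self.generations > 0 and (
            self.cohort_size_per_generation
            > (self.n_founders // 2) * self.offspring_per_pair
        ):
            raise ValueError("cohort size exceeds offspring produced per round")
        _ = n_pairs


def block_bounds(
    markers: Sequence[MarkerInfo] | GenotypeMatrix, spacing: int
) -> list[tuple[int, int]]:
    """Half-open [start, end) recombination blocks, restarting per chromosome."""
    if spacing < 1:
        raise ValueError("spacing must be >= 1")
    if isinstance(markers, GenotypeMatrix):
        spans = markers.chromosome_spans()
    else:
        spans = GenotypeMatrix(
            samples=[], markers=list(markers), dosages=np.empty((0, len(markers)))
        ).chromosome_spans()
    blocks: list[tuple[int, int]] = []
    for _chrom, start, end in spans:
        pos = start
        while pos < end:
            blocks.append((pos, min(pos + spacing, end)))
            pos += spacing
    return blocks


def impute_missing(dosages: np.ndarray, seed: int) -> np.ndarray:
    """Fill missing cells with Bernoulli(pooled allele frequency) allele pairs."""
    out = np.array(dosages, dtype=np.int16, copy=True)
    miss = out == MISSING
    if not miss.any():
        return out
    rng = substream(seed, "impute_missing")
    n, L = out.shape
    for l in np.flatnonzero(miss.any(axis=0)):
        col = out[:, l]
        obs = col[col != MISSING]
        freq = obs.sum() / (2 * len(obs)) if len(obs) else 0.5
        rows = np.flatnonzero(col == MISSING)
        out[rows, l] = rng.binomial(2, freq, size=len(rows))
    return out


def phase_founders(G: GenotypeMatrix, seed: int) -> np.ndarray:
    """Split dosages into haplotype pairs (n x 2 x L).

    Homozygous cells phase uniquely; each heterozygous cell assigns the
    counted allele to haplotype 0 or 1 by an independent fair seeded coin.
    Haplotype sums reproduce dosages exactly.
    """
    d = np.asarray(G.dosages)
    if (d == MISSING).any():
        raise ValueError("missing dosages must be imputed before phasing")
    rng = substream(seed, "phase_founders")
    n, L = d.shape
    coin = rng.integers(0, 2, size=(n, L))
    hap = np.zeros((n, 2, L), dtype=np.int16)
    hap[:, 0, :] = np.where(d == 2, 1, np.where(d == 1, coin, 0))
    hap[:, 1, :] = d - hap[:, 0, :]
    return hap


def make_gamete(
    parent: Individual,
    blocks: Sequence[tuple[int, int]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Copy one parental haplotype per block, chosen uniformly and independently."""
    if parent.haplotypes is None:
        raise ValueError(f"{parent.id}: no haplotypes")
    L = parent.haplotypes.shape[1]
    gamete = np.empty(L, dtype=np.int16)
    choices = rng.integers(0, 2, size=len(blocks))
    for (start, end), which in zip(blocks, choices):
        gamete[start:end] = parent.haplotypes[which, start:end]
    return gamete


def mate(
    mother: Individual,
    father: Individual,
    n_offspring: int,
    blocks: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    generation: int,
    id_prefix: str,
) -> list[Individual]:
    """Produce offspring, each from one maternal and one paternal gamete."""
    if mother.sex != "female" or father.sex != "male":
        raise PedigreeIntegrityError(
            f"pair ({mother.id}, {father.id}) is not a female-male pair"
        )
    kids = []
    for j in range(n_offspring):
        maternal = make_gamete(mother, blocks, rng)
        paternal = make_gamete(father, blocks, rng)
        sex = "female" if rng.integers(0, 2) else "male"
        kids.append(
            Individual(
                id=f"{id_prefix}_{j + 1}",
                sex=sex,
                generation=generation,
                mother_id=mother.id,
                father_id=father.id,
                haplotypes=np.stack([maternal, paternal]),
            )
        )
    return kids


def _pair_randomly(
    cohort: list[Individual], rng: np.random.Generator
) -> list[tuple[Individual, Individual]]:
    females = [m for m in cohort if m.sex == "female"]
    males = [m for m in cohort if m.sex == "male"]
    if len(females) != len(males):
        raise CohortBalanceError(
            f"cannot pair {len(females)} females with {len(males)} males"
        )
    rng.shuffle(females)
    rng.shuffle(males)
    return list(zip(females, males))


def _sample_balanced_cohort(
    pool: list[Individual], size: int, rng: np.random.Generator
) -> list[Individual]:
    half = size // 2
    females = [m for m in pool if m.sex == "female"]
    males = [m for m in pool if m.sex == "male"]
    if len(females) < half or len(males) < half:
        # sexes are fixed at birth; no resampling is attempted
        raise CohortBalanceError(
            f"offspring pool has {len(females)} females / {len(males)} males; "
            f"need {half} of each"
        )
    pick_f = rng.choice(len(females), size=half, replace=False)
    pick_m = rng.choice(len(males), size=half, replace=False)
    return [females[i] for i in sorted(pick_f)] + [males[i] for i in sorted(pick_m)]


def founders_from_genotypes(
    G: GenotypeMatrix, meta: Sequence[SampleMeta], seed: int
) -> list[Individual]:
    """Phase (imputing missing cells first) and wrap founders as individuals."""
    by_id = {m.sample_id: m for m in meta}
    for sid in G.samples:
        sm = by_id.get(sid)
        if sm is None or sm.sex not in ("male", "female"):
            raise MetadataError(f"founder {sid!r}: sex must be male or female")
        if sm.label not in ("labeled", "unlabeled"):
            raise MetadataError(f"founder {sid!r}: label must be labeled/unlabeled")
    complete = GenotypeMatrix(
        samples=G.samples, markers=G.markers, dosages=impute_missing(G.dosages, seed)
    )
    haps = phase_founders(complete, seed)
    return [
        Individual(
            id=sid,
            sex=by_id[sid].sex,
            generation=0,
            haplotypes=haps[i],
            founder_label=by_id[sid].label,
        )
        for i, sid in enumerate(G.samples)
    ]


def run_benchmark_sim(
    founders: Sequence[Individual],
    config: SimConfig,
    markers: Sequence[MarkerInfo],
) -> Pedigree:
    """Run the full forward simulation and return the complete pedigree.

    Generation 0 founders are randomly paired male-female (monogamous); each
    pair yields ``offspring_per_pair`` children; a sex-balanced cohort of
    ``cohort_size_per_generation`` is sampled uniformly without replacement
    from each offspring generation and paired for the next round.
    Non-selected offspring remain in the pedigree.
    """
    ped = Pedigree(markers=list(markers))
    for f in founders:
        if f.generation != 0:
            raise PedigreeIntegrityError("all founders must have generation 0")
        ped.add(f)
    blocks = block_bounds(markers, config.hotspot_spacing)
    rng = substream(config.seed, "run_benchmark_sim")

    cohort = list(founders)
    for gen in range(1, config.generations + 1):
        pairs = _pair_randomly(cohort, rng)
        offspring: list[Individual] = []
        for p, (mo, fa) in enumerate(pairs):
            kids = mate(
                mo,
                fa,
                config.offspring_per_pair,
                blocks,
                rng,
                generation=gen,
                id_prefix=f"G{gen}P{p + 1:02d}",
            )
            offspring.extend(kids)
        for kid in offspring:
            ped.add(kid)
        if gen < config.generations:
            cohort = _sample_balanced_cohort(
                offspring, config.cohort_size_per_generation, rng
            )
    return ped


def pedigree_genotypes(
    ped: Pedigree, individuals: Sequence[Individual] | None = None
) -> GenotypeMatrix:
    """Collapse haplotypes of the given individuals (default: terminal) to dosages."""
    if individuals is None:
        individuals = ped.terminal_members()
    dosages = np.stack([ind.dosages for ind in individuals]) if individuals else (
        np.empty((0, len(ped.markers)), dtype=np.int16)
    )
    return GenotypeMatrix(
        samples=[ind.id for ind in individuals],
        markers=list(ped.markers),
        dosages=dosages,
    )
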