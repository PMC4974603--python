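"""Synthetic inputs: ancestral allele-frequency panels, admixed founders,
and simulated reference admixture cohorts.

This module stands in for the real genotype panels: founders are drawn from
K ancestral allele-frequency profiles (a Balding–Nichols construction)
mixed by per-individual admixture vectors, and the reference cohort
generator reproduces the published 9-component profile of the simulated
"Israelite" population by sampling each component from a configurable
family and renormalizing to the simplex.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ._rng import substream
from .genotype_io import GenotypeMatrix, MarkerInfo, SampleMeta

__all__ = [
    "AncestralFrequencies",
    "ComponentSpec",
    "CohortSpec",
    "DEFAULT_COMPONENT_NAMES",
    "default_israelite_spec",
    "sample_ancestral_frequencies",
    "generate_founders",
    "sample_reference_cohort",
    "random_admixture_vectors",
]

#: the nine ancestry components used throughout; the first four carry the
#: published means, the remainder are minor components of the same panel.
DEFAULT_COMPONENT_NAMES: tuple[str, ...] = (
    "Mediterranean",
    "South West Asian",
    "Sub-Saharan African",
    "Northern European",
    "South East Asian",
    "North East Asian",
    "Native American",
    "Oceanian",
    "Southern African",
)

_IDENTIFIABILITY_TOL = 1e-12


class ParameterError(ValueError):
    pass


@dataclass
class AncestralFrequencies:
    """L markers x K components allele-frequency table."""

    F: np.ndarray
    component_names: list[str]

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.ndim != 2:
            raise ValueError("F must be 2-D (L x K)")
        L, K = self.F.shape
        if K < 1:
            raise ValueError("need K >= 1 components")
        if len(self.component_names) != K:
            raise ValueError("component_names length != K")
        if (self.F < 0).any() or (self.F > 1).any():
            raise ValueError("allele frequencies must lie in [0, 1]")
        for a in range(K):
            for b in range(a + 1, K):
                if np.linalg.norm(self.F[:, a] - self.F[:, b]) < _IDENTIFIABILITY_TOL:
                    raise ValueError(
                        f"components {self.component_names[a]!r} and "
                        f"{self.component_names[b]!r} are identical (unidentifiable)"
                    )

    @property
    def n_markers(self) -> int:
        return self.F.shape[0]

    @property
    def n_components(self) -> int:
        return self.F.shape[1]


def validate_admixture_vector(q: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if (q < 0).any():
        raise ValueError("admixture proportions must be nonnegative")
    if abs(q.sum() - 1.0) > atol:
        raise ValueError(f"admixture proportions sum to {q.sum()!r}, not 1")
    return q


@dataclass(frozen=True)
class ComponentSpec:
    """Sampling spec for one admixture component, in percent units."""

    name: str
    location: float
    scale: float
    family: str = "truncated_normal"  # or "uniform_range"

    def __post_init__(self) -> None:
        if self.scale < 0:
            raise ParameterError(f"{self.name}: scale must be >= 0")
        if self.location < 0:
            raise ParameterError(f"{self.name}: location must be >= 0")
        if self.family not in ("truncated_normal", "uniform_range"):
            raise ParameterError(f"{self.name}: unknown family {self.family!r}")


@dataclass
class CohortSpec:
    components: list[ComponentSpec]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "components": [
                {
                    "name": c.name,
                    "location": c.location,
                    "scale": c.scale,
                    "family": c.family,
                }
                for c in self.components
            ]
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            components=[ComponentSpec(**entry) for entry in payload["components"]]
        )


# Published major-component means +/- SD (percent) of the simulated
# Israelite cohort; the five minor components are unpublished and default to
# equal shares of the residual mass.  Their SD defaults to 0.25 rather than
# a larger value: with location ~1.16 a bigger SD puts non-trivial mass at
# the zero-truncation boundary, which inflates the component-sum mean and
# drags the renormalized major-component means off their configured
# locations.
_MAJOR = (
    ("Mediterranean", 57.7, 1.2),
    ("South West Asian", 23.9, 0.6),
    ("Sub-Saharan African", 9.4, 0.5),
    ("Northern European", 3.2, 1.3),
)
_MINOR_SD = 0.25


def default_israelite_spec(
    family: str = "truncated_normal", minor_sd: float = _MINOR_SD
) -> CohortSpec:
    """Default 9-component cohort spec built from the published means."""
    residual = 100.0 - sum(m for _, m, _ in _MAJOR)
    minors = [n for n in DEFAULT_COMPONENT_NAMES if n not in {m[0] for m in _MAJOR}]
    comps = [
        ComponentSpec(name=n, location=loc, scale=sd, family=family)
        for n, loc, sd in _MAJOR
    ]
    comps += [
        ComponentSpec(
            name=n, location=residual / len(minors), scale=minor_sd, family=family
        )
        for n in minors
    ]
    return CohortSpec(components=comps)


# ---------------------------------------------------------------------------
# ancestral frequencies (Balding–Nichols)


def sample_ancestral_frequencies(
    K: int,
    L: int,
    fst: float,
    seed: int,
    component_names: Sequence[str] | None = None,
) -> AncestralFrequencies:
    """Draw a K-component allele-frequency panel for L markers.

    Per marker an ancestral frequency p ~ Uniform(0.05, 0.95) is drawn, then
    each component frequency ~ Beta(p(1-fst)/fst, (1-p)(1-fst)/fst), so that
    E[f|p] = p and Var[f|p] = p(1-p)*fst.
    """
    if not (0.0 < fst < 1.0):
        raise ParameterError(f"fst must lie in (0, 1), got {fst}")
    if L < 1 or K < 1:
        raise ParameterError("need L >= 1 and K >= 1")
    rng = substream(seed, "sample_ancestral_frequencies")
    p = rng.uniform(0.05, 0.95, size=L)
    c = (1.0 - fst) / fst
    F = rng.beta(np.outer(p, np.ones(K)) * c, np.outer(1.0 - p, np.ones(K)) * c)
    if component_names is None:
        if K <= len(DEFAULT_COMPONENT_NAMES):
            component_names = list(DEFAULT_COMPONENT_NAMES[:K])
        else:
            component_names = [f"component_{k + 1}" for k in range(K)]
    return AncestralFrequencies(F=F, component_names=list(component_names))


# ---------------------------------------------------------------------------
# founders


def _default_markers(L: int) -> list[MarkerInfo]:
    return [
        MarkerInfo(chromosome="1", marker_id=f"snp{l + 1}", position=l + 1)
        for l in range(L)
    ]


def generate_founders(
    F: AncestralFrequencies,
    q_assignments: Sequence[np.ndarray],
    seed: int,
    sexes: Sequence[str] | None = None,
    labels: Sequence[str] | None = None,
    markers: Sequence[MarkerInfo] | None = None,
    id_prefix: str = "F",
) -> tuple[GenotypeMatrix, np.ndarray, list[SampleMeta]]:
    """Draw phased founder genotypes from per-individual admixture vectors.

    For individual i at marker l each of the two haplotype alleles is an
    independent Bernoulli(sum_k q_ik F_lk) draw; the dosage is the haplotype
    sum, so founders are born phased.  Returns (genotypes, haplotypes of
    shape (n, 2, L), metadata).  Sexes and labels alternate male/female and
    labeled/unlabeled when not supplied.
    """
    n = len(q_assignments)
    L, K = F.F.shape
    Q = np.empty((n, K))
    for i, q in enumerate(q_assignments):
        q = validate_admixture_vector(q)
        if q.shape != (K,):
            raise ValueError(f"q_assignments[{i}] has length {q.shape}, F has K={K}")
        Q[i] = q
    rng = substream(seed, "generate_founders")
    # per-individual, per-marker expected allele frequency
    P = Q @ F.F.T  # n x L
    haplos = (rng.random((n, 2, L)) < P[:, None, :]).astype(np.int16)
    dosages = haplos.sum(axis=1)
    if markers is None:
        markers = _default_markers(L)
    if sexes is None:
        sexes = ["male" if i % 2 == 0 else "female" for i in range(n)]
    if labels is None:
        labels = ["labeled" if i < n // 2 else "unlabeled" for i in range(n)]
    ids = [f"{id_prefix}{i + 1:03d}" for i in range(n)]
    meta = [
        SampleMeta(sample_id=ids[i], sex=sexes[i], label=labels[i], population="founder")
        for i in range(n)
    ]
    G = GenotypeMatrix(samples=ids, markers=list(markers), dosages=dosages)
    return G, haplos, meta


def random_admixture_vectors(n: int, K: int, seed: int) -> list[np.ndarray]:
    """Uniform (flat Dirichlet) admixture vectors, handy for simulations."""
    rng = substream(seed, "random_admixture_vectors")
    return list(rng.dirichlet(np.ones(K), size=n))


# ---------------------------------------------------------------------------
# reference cohort


def sample_reference_cohort(
    n: int, spec: CohortSpec, seed: int, max_attempts: int = 100
) -> list[np.ndarray]:
    """Sample n admixture vectors from a component spec and renormalize.

    Each component is drawn from its configured family truncated at zero
    (truncated normal by rejection; uniform over
    [max(0, location-scale), location+scale]), then the vector is divided by
    its sum.  Returns proportions (0-1 scale).
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    rng = substream(seed, "sample_reference_cohort")
    K = len(spec.components)
    out: list[np.ndarray] = []
    for _ in range(n):
        for _attempt in range(max_attempts):
            v = np.empty(K)
            for k, comp in enumerate(spec.components):
                if comp.family == "truncated_normal":
                    if comp.scale == 0.0:
                        v[k] = comp.location
                    else:
                        while True:  # rejection = truncation at 0
                            draw = rng.normal(comp.location, comp.scale)
                            if draw >= 0.0:
                                v[k] = draw
                                break
                else:  # uniform_range
                    lo = max(0.0, comp.location - comp.scale)
                    hi = comp.location + comp.scale
                    v[k] = rng.uniform(lo, hi) if hi > lo else lo
            total = v.sum()
            if total > 0.0:
                out.append(v / total)
                break
        else:
            raise RuntimeError(
                f"all-zero admixture draw {max_attempts} times in a row"
            )
    return out
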