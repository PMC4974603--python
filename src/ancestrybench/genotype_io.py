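"""PLINK text genotype I/O, sample metadata tables, answer keys and matrices.

Text formats are canonical throughout the package: whitespace-delimited
.ped/.map pairs for genotypes, TSV sidecars for sex/label metadata and for
Q/F matrices, and a JSON answer key.  Dosages are counted against
``allele_a``, defined as the first non-missing allele observed for the
marker in file order (a deterministic convention that needs no allele
frequencies at parse time; PLINK's minor-allele convention is *not*
assumed).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: sentinel for a missing dosage cell
MISSING: int = -1

_VALID_ALLELES = set("ACGT12")


class PlinkParseError(ValueError):
    """Malformed .ped/.map content (ragged rows, bad allele codes...)."""


class DimensionError(ValueError):
    """Marker/sample dimensions disagree between inputs."""


class MetadataError(ValueError):
    """Invalid or missing sample metadata."""


@dataclass(frozen=True)
class MarkerInfo:
    """A single biallelic marker.

    ``position`` is 1-based, as in .map files; all internal marker
    *indexing* is 0-based with half-open [start, end) block ranges.
    """

    chromosome: str
    marker_id: str
    position: int
    allele_a: str = "A"  # counted allele
    allele_b: str = "G"

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError(f"marker {self.marker_id}: allele_a == allele_b")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    sex: str = "unknown"  # {male, female, unknown}
    label: str = "unknown"  # {labeled, unlabeled, unknown}
    population: str = ""


@dataclass
class GenotypeMatrix:
    """Unphased dosage matrix: ``dosages[i, l]`` counts copies of allele_a.

    Missing cells hold :data:`MISSING`.
    """

    samples: list[str]
    markers: list[MarkerInfo]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        n, L = self.dosages.shape
        if n != len(self.samples):
            raise DimensionError(
                f"{len(self.samples)} samples but {n} dosage rows"
            )
        if L != len(self.markers):
            raise DimensionError(
                f"{len(self.markers)} markers but {L} dosage columns"
            )
        bad = ~np.isin(self.dosages, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2} or MISSING")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chromosome_spans(self) -> list[tuple[str, int, int]]:
        """Half-open [start, end) marker-index runs, one per chromosome."""
        spans: list[tuple[str, int, int]] = []
        start = 0
        for i, m in enumerate(self.markers):
            if i and m.chromosome != self.markers[i - 1].chromosome:
                spans.append((self.markers[start].chromosome, start, i))
                start = i
        if self.markers:
            spans.append((self.markers[start].chromosome, start, len(self.markers)))
        return spans

    def subset_markers(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=[self.markers[i] for i in idx],
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        rows = [pos[s] for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            markers=list(self.markers),
            dosages=self.dosages[rows, :],
        )


_SEX_FROM_CODE = {"1": "male", "2": "female"}
_CODE_FROM_SEX = {"male": "1", "female": "2"}


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    missing_cap: float = 0.10,
) -> tuple[GenotypeMatrix, list[SampleMeta]]:
    """Read a whitespace-delimited .ped/.map pair.

    Markers whose missing rate exceeds ``missing_cap`` are dropped with a
    warning.  Sex is parsed from .ped column 5 (1=male, 2=female); any other
    code yields ``sex="unknown"`` (rejected later by the simulator, which
    requires sexed founders).
    """
    ped_path, map_path = Path(ped_path), Path(map_path)
    markers_raw: list[tuple[str, str, int]] = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkParseError(
                    f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, mid, _gdist, pos = parts
            markers_raw.append((chrom, mid, int(pos)))
    L = len(markers_raw)

    samples: list[str] = []
    meta: list[SampleMeta] = []
    allele_pairs: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * L:
                raise PlinkParseError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * L} columns "
                    f"({L} markers), got {len(parts)}"
                )
            _fid, iid, _pat, _mat, sex_code, _pheno = parts[:6]
            alleles = parts[6:]
            for a in alleles:
                if a != "0" and a not in _VALID_ALLELES:
                    raise PlinkParseError(
                        f"{ped_path}:{lineno}: invalid allele code {a!r}"
                    )
            samples.append(iid)
            meta.append(
                SampleMeta(sample_id=iid, sex=_SEX_FROM_CODE.get(sex_code, "unknown"))
            )
            allele_pairs.append(alleles)

    n = len(samples)
    dosages = np.full((n, L), MISSING, dtype=np.int16)
    markers: list[MarkerInfo] = []
    for l, (chrom, mid, pos) in enumerate(markers_raw):
        a_allele: str | None = None
        b_allele: str | None = None
        col = np.full(n, MISSING, dtype=np.int16)
        for i in range(n):
            a1 = allele_pairs[i][2 * l]
            a2 = allele_pairs[i][2 * l + 1]
            if a1 == "0" or a2 == "0":
                continue  # either allele missing -> cell missing
            for a in (a1, a2):
                if a_allele is None:
                    a_allele = a
                elif b_allele is None and a != a_allele:
                    b_allele = a
            col[i] = (a1 == a_allele) + (a2 == a_allele)
        if a_allele is None:
            a_allele, b_allele = "A", "G"  # fully missing marker
        if b_allele is None:
            b_allele = "0" if a_allele != "0" else "N"  # monomorphic placeholder
        markers.append(
            MarkerInfo(
                chromosome=chrom,
                marker_id=mid,
                position=pos,
                allele_a=a_allele,
                allele_b=b_allele,
            )
        )
        dosages[:, l] = col

    G = GenotypeMatrix(samples=samples, markers=markers, dosages=dosages)
    if n:
        miss_rate = (G.dosages == MISSING).mean(axis=0)
        keep = np.flatnonzero(miss_rate <= missing_cap)
        if len(keep) < L:
            dropped = [G.markers[i].marker_id for i in np.flatnonzero(miss_rate > missing_cap)]
            warnings.warn(
                f"dropping {len(dropped)} marker(s) above missing-rate cap "
                f"{missing_cap:g}: {dropped[:5]}{'...' if len(dropped) > 5 else ''}"
            )
            log.warning("dropped %d markers above missing cap", len(dropped))
            G = G.subset_markers(keep.tolist())
    return G, meta


def write_plink_text(
    G: GenotypeMatrix,
    meta: Sequence[SampleMeta] | None,
    ped_path: str | Path,
    map_path: str | Path,
) -> None:
    """Write a .ped/.map pair; heterozygotes are written counted-allele first."""
    meta_by_id: dict[str, SampleMeta] = {}
    if meta is not None:
        for m in meta:
            meta_by_id[m.sample_id] = m

    with open(map_path, "w") as fh:
        for m in G.markers:
            fh.write(f"{m.chromosome}\t{m.marker_id}\t0\t{m.position}\n")

    het_needs_b = [
        m.allele_b in ("0", "N") for m in G.markers
    ]
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(G.samples):
            sm = meta_by_id.get(sid)
            sex_code = _CODE_FROM_SEX.get(sm.sex, "0") if sm else "0"
            row = [sid, sid, "0", "0", sex_code, "-9"]
            for l, m in enumerate(G.markers):
                d = G.dosages[i, l]
                if d == MISSING:
                    row += ["0", "0"]
                elif d == 2:
                    row += [m.allele_a, m.allele_a]
                elif d == 0:
                    if het_needs_b[l]:
                        raise ValueError(
                            f"marker {m.marker_id}: dosage {d} but no valid allele_b"
                        )
                    row += [m.allele_b, m.allele_b]
                else:
                    if het_needs_b[l]:
                        raise ValueError(
                            f"marker {m.marker_id}: dosage 1 but no valid allele_b"
                        )
                    row += [m.allele_a, m.allele_b]
            fh.write(" ".join(row) + "\n")


# ---------------------------------------------------------------------------
# sample metadata sidecar


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read the sex/label sidecar TSV (sample_id, sex, label, population)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "sex", "label"}
    missing = required - set(df.columns)
    if missing:
        raise MetadataError(f"sidecar missing columns: {sorted(missing)}")
    out = []
    for rec in df.itertuples(index=False):
        out.append(
            SampleMeta(
                sample_id=rec.sample_id,
                sex=rec.sex or "unknown",
                label=rec.label or "unknown",
                population=getattr(rec, "population", "") or "",
            )
        )
    return out


def write_sample_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        [(m.sample_id, m.sex, m.label, m.population) for m in meta],
        columns=["sample_id", "sex", "label", "population"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# answer keys

AnswerKey = dict  # blinded_id -> {rule_name: bool}


def write_answer_key(key: Mapping[str, Mapping[str, bool]], path: str | Path) -> None:
    """Write the hidden per-individual labels as UTF-8 JSON, one record each."""
    ids = list(key)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate blinded ids in answer key")
    records = [
        {"id": bid, **{rule: bool(v) for rule, v in sorted(labels.items())}}
        for bid, labels in key.items()
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"records": records}, fh, indent=1)
        fh.write("\n")


def read_answer_key(path: str | Path) -> dict[str, dict[str, bool]]:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    key: dict[str, dict[str, bool]] = {}
    for rec in payload["records"]:
        bid = rec["id"]
        if bid in key:
            raise ValueError(f"duplicate blinded id {bid!r} in answer key")
        key[bid] = {k: bool(v) for k, v in rec.items() if k != "id"}
    return key


# ---------------------------------------------------------------------------
# Q / F matrices and edge lists


def write_q_matrix(
    ids: Sequence[str], Q: np.ndarray, component_names: Sequence[str], path: str | Path
) -> None:
    df = pd.DataFrame(np.asarray(Q, dtype=float), columns=list(component_names))
    df.insert(0, "sample_id", list(ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_q_matrix(path: str | Path) -> tuple[list[str], np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    ids = df["sample_id"].astype(str).tolist()
    names = [c for c in df.columns if c != "sample_id"]
    return ids, df[names].to_numpy(dtype=float), names


def write_f_matrix(
    marker_ids: Sequence[str], F: np.ndarray, component_names: Sequence[str], path: str | Path
) -> None:
    df = pd.DataFrame(np.asarray(F, dtype=float), columns=list(component_names))
    df.insert(0, "marker_id", list(marker_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_f_matrix(path: str | Path) -> tuple[list[str], np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    mids = df["marker_id"].astype(str).tolist()
    names = [c for c in df.columns if c != "marker_id"]
    return mids, df[names].to_numpy(dtype=float), names


def write_edge_list(
    edges: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for a, b, w in edges:
            fh.write(f"{a}\t{b}\t{w:.8g}\n")
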