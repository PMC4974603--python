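"""Descent-rule label propagation over a pedigree.

Two rules ship by default:

* ``halacha`` — matrilineal: an individual is labeled iff its strict
  maternal-line founder is labeled (a founder returns its own label).
* ``law_of_return`` — grandparent threshold: labeled iff at least
  ``threshold`` (default 1) of its four grandparents are labeled.

The grandparent rule needs a basis for what makes a *grandparent* labeled:
``recursive_matrilineal`` applies the matrilineal definition to each
grandparent (the default), ``founder_self_report`` uses the grandparent's
own founder label and requires all four grandparents to be founders.  On
two-generation pedigrees with founder grandparents the bases agree on the
maternal side and the published worked example holds under both.

Rule outputs depend only on pedigree topology and founder labels, never on
genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .pedigree_sim import Individual, Pedigree, PedigreeIntegrityError

__all__ = [
    "DescentRule",
    "HALACHA",
    "LAW_OF_RETURN",
    "DEFAULT_RULES",
    "matrilineal_label",
    "patrilineal_label",
    "grandparent_label",
    "label_pedigree",
]


@dataclass(frozen=True)
class DescentRule:
    name: str
    kind: str  # {matrilineal, patrilineal, grandparent_threshold}
    threshold: int = 1
    grandparent_label_basis: str = "recursive_matrilineal"

    def __post_init__(self) -> None:
        if self.kind not in ("matrilineal", "patrilineal", "grandparent_threshold"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "grandparent_threshold" and not (1 <= self.threshold <= 4):
            raise ValueError("grandparent threshold must lie in 1..4")
        if self.grandparent_label_basis not in (
            "founder_self_report",
            "recursive_matrilineal",
        ):
            raise ValueError(
                f"unknown grandparent basis {self.grandparent_label_basis!r}"
            )


HALACHA = DescentRule(name="halacha", kind="matrilineal")
LAW_OF_RETURN = DescentRule(
    name="law_of_return", kind="grandparent_threshold", threshold=1
)
DEFAULT_RULES: tuple[DescentRule, ...] = (HALACHA, LAW_OF_RETURN)


def _lineal_label(ped: Pedigree, individual: Individual, parent_attr: str) -> bool:
    node = individual
    seen: set[str] = set()
    while True:
        if node.id in seen:
            raise PedigreeIntegrityError(f"cycle in lineage at {node.id!r}")
        seen.add(node.id)
        if node.is_founder:
            return node.founder_label == "labeled"
        pid = getattr(node, parent_attr)
        if pid is None or pid not in ped:
            raise PedigreeIntegrityError(
                f"{individual.id}: broken lineage chain at {node.id!r}"
            )
        node = ped[pid]


def matrilineal_label(ped: Pedigree, individual: Individual) -> bool:
    """Label of the strict maternal-line founder (mother of mother of ...)."""
    return _lineal_label(ped, individual, "mother_id")


def patrilineal_label(ped: Pedigree, individual: Individual) -> bool:
    return _lineal_label(ped, individual, "father_id")


def _grandparents(ped: Pedigree, individual: Individual) -> list[Individual]:
    gps = []
    for pid in (individual.mother_id, individual.father_id):
        if pid is None or pid not in ped:
            raise PedigreeIntegrityError(
                f"{individual.id}: parent {pid!r} unresolvable"
            )
        parent = ped[pid]
        for gid in (parent.mother_id, parent.father_id):
            if gid is None or gid not in ped:
                raise PedigreeIntegrityError(
                    f"{individual.id}: grandparent via {pid!r} unresolvable"
                )
            gps.append(ped[gid])
    return gps


def grandparent_label(
    ped: Pedigree, individual: Individual, rule: DescentRule
) -> bool:
    """True iff >= rule.threshold grandparents are labeled under the basis."""
    if rule.kind != "grandparent_threshold":
        raise ValueError("rule is not a grandparent_threshold rule")
    gps = _grandparents(ped, individual)
    if rule.grandparent_label_basis == "founder_self_report":
        for gp in gps:
            if not gp.is_founder:
                raise PedigreeIntegrityError(
                    f"{individual.id}: grandparent {gp.id!r} is not a founder; "
                    "founder_self_report basis is undefined"
                )
        count = sum(gp.founder_label == "labeled" for gp in gps)
    else:
        count = sum(matrilineal_label(ped, gp) for gp in gps)
    return count >= rule.threshold


def apply_rule(ped: Pedigree, individual: Individual, rule: DescentRule) -> bool:
    if rule.kind == "matrilineal":
        return matrilineal_label(ped, individual)
    if rule.kind == "patrilineal":
        return patrilineal_label(ped, individual)
    return grandparent_label(ped, individual, rule)


def label_pedigree(
    ped: Pedigree,
    rules: Sequence[DescentRule] = DEFAULT_RULES,
    scope: str = "terminal",
    include_nonterminal_grandparent_rule: bool = False,
) -> dict[str, dict[str, bool]]:
    """Assign one boolean per rule to every in-scope individual.

    ``scope`` is ``terminal`` (default: only the last generation, the cohort
    the benchmark scores) or ``all``.  The grandparent rule is defined only
    for generation >= 2; for earlier generations it falls back to the
    matrilineal label, and such individuals are emitted only when
    ``include_nonterminal_grandparent_rule`` is set (with scope="all").
    """
    if scope not in ("terminal", "all"):
        raise ValueError(f"unknown scope {scope!r}")
    targets = ped.terminal_members() if scope == "terminal" else list(
        ped.members.values()
    )
    key: dict[str, dict[str, bool]] = {}
    for ind in targets:
        labels: dict[str, bool] = {}
        for rule in rules:
            if rule.kind == "grandparent_threshold" and ind.generation < 2:
                if not include_nonterminal_grandparent_rule:
                    continue
                labels[rule.name] = matrilineal_label(ped, ind)
            else:
                labels[rule.name] = apply_rule(ped, ind, rule)
        if labels:
            key[ind.id] = labels
    return key
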