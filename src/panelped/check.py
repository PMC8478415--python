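"""Pedigree validation, harmonization and repair.

``check_pedigree`` validates and repairs a user pedigree so the peeling
engine can accept it, applying in order: value-range checks, sex-cancer
compatibility, germline-column resolution to default variant labels,
heredity harmonization of race/ancestry, twin consistency, loop
detection, disconnected-member removal and pseudo-parent insertion.
Every automatic change is reported back through a :class:`CheckReport`;
unresolvable inconsistencies raise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import networkx as nx

from .core import (
    DEFAULT_ANCESTRY, DEFAULT_RACE, MAX_AGE, CancerHistory, Individual,
    LoopError, ParameterDatabase, Pedigree, PedigreeError,
)
from .params import ModelDatabase, build_model_database


@dataclass
class CheckReport:
    """Record of everything the pedigree check changed or observed."""

    messages: List[str] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    changed_ids: Dict[str, List[int]] = field(default_factory=dict)

    def note_change(self, kind: str, ids, message: str) -> None:
        ids = [ids] if isinstance(ids, int) else list(ids)
        self.changed_ids.setdefault(kind, []).extend(
            i for i in ids if i not in self.changed_ids.get(kind, []))
        self.messages.append(message)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        warnings.warn(message)


def detect_loops(ped: Pedigree) -> List[List[int]]:
    """Find loops in the marriage-node graph.

    Nodes are individuals plus one node per mating unit (unordered parent
    pair); edges join each parent and each child to the mating unit.  The
    pedigree is loop-free iff this graph is acyclic.  Returns one id list
    per independent cycle (mating-unit nodes expanded to their parents).
    """
    g = nx.Graph()
    for m in ped:
        g.add_node(("i", m.id))
        if m.mother_id is not None or m.father_id is not None:
            unit = ("u", (m.mother_id, m.father_id))
            g.add_node(unit)
            g.add_edge(("i", m.id), unit)
            for pid in (m.mother_id, m.father_id):
                if pid is not None and pid in ped.individuals:
                    g.add_edge(("i", pid), unit)
    loops = []
    for cycle in nx.cycle_basis(g):
        ids: List[int] = []
        for kind, payload in cycle:
            if kind == "i":
                ids.append(payload)
            else:
                ids.extend(p for p in payload if p is not None and p not in ids)
        loops.append(sorted(set(ids)))
    return loops


def remove_disconnected(ped: Pedigree) -> Tuple[Pedigree, List[int]]:
    """Drop members with no parent-child path to any proband.

    Mating-only links with no shared children carry no genotype
    information about the counselee, so connectivity is judged on the
    parent-child relationship graph only.
    """
    g = nx.Graph()
    g.add_nodes_from(ped.individuals)
    for m in ped:
        for pid in (m.mother_id, m.father_id):
            if pid is not None and pid in ped.individuals:
                g.add_edge(m.id, pid)
    keep = set()
    for p in ped.probands():
        keep |= nx.node_connected_component(g, p.id)
    removed = [iid for iid in ped.individuals if iid not in keep]
    if not removed:
        return ped, []
    out = ped.copy()
    for iid in removed:
        del out.individuals[iid]
    for m in out:
        if m.mother_id in removed:
            m.mother_id = None
        if m.father_id in removed:
            m.father_id = None
    return out, removed


def add_pseudo_parents(ped: Pedigree) -> Tuple[Pedigree, List[int]]:
    """Complete single-parent links with synthetic founders.

    Children listed with the same known single parent share one
    pseudo-parent, so sibships stay intact.  The pseudo-parent is a
    founder of the opposite sex with no phenotype and no censoring age;
    its ancestry and race copy the known parent so its founder prior
    matches.
    """
    out = ped.copy()
    next_id = max(out.individuals) + 1 if out.individuals else 1
    added: List[int] = []
    # group children by (known parent id, missing role)
    groups: Dict[Tuple[int, str], List[int]] = {}
    for m in out:
        if m.mother_id is None and m.father_id is not None:
            groups.setdefault((m.father_id, "mother"), []).append(m.id)
        elif m.father_id is None and m.mother_id is not None:
            groups.setdefault((m.mother_id, "father"), []).append(m.id)
    for (known_id, role), child_ids in sorted(groups.items()):
        known = out.individuals[known_id]
        pseudo = Individual(
            id=next_id,
            sex=0 if role == "mother" else 1,
            cancers={tag: CancerHistory() for tag in out.cancers},
            race=known.race,
            ancestry=known.ancestry,
            pseudo=True,
        )
        out.individuals[next_id] = pseudo
        for cid in child_ids:
            child = out.individuals[cid]
            if role == "mother":
                child.mother_id = next_id
            else:
                child.father_id = next_id
        added.append(next_id)
        next_id += 1
    return out, added


def _merge_value(a: Optional[str], b: Optional[str], neutral: str) -> Optional[str]:
    known = [v for v in (a, b) if v is not None]
    if not known:
        return None
    if len(known) == 2 and known[0] != known[1]:
        return neutral
    return known[0]


def _harmonize_heredity(ped: Pedigree, report: CheckReport) -> None:
    """Reset child race/ancestry that conflicts with both parents.

    A child's value is consistent when it matches either parent's
    recorded value (or the parents are unrecorded).  Conflicts reset the
    child to the neutral category; processing in generation order
    propagates the reset downward.
    """
    order = _topological_ids(ped)
    for attr, neutral, word in (("ancestry", DEFAULT_ANCESTRY, "Ancestry"),
                                ("race", DEFAULT_RACE, "race")):
        for iid in order:
            m = ped.individuals[iid]
            if m.mother_id is None and m.father_id is None:
                continue
            parents = [ped.individuals[p] for p in (m.mother_id, m.father_id)
                       if p is not None and p in ped.individuals]
            parent_vals = [getattr(p, attr) for p in parents]
            known = [v for v in parent_vals if v is not None]
            val = getattr(m, attr)
            if val is None or not known:
                continue
            if val not in known and val != neutral:
                setattr(m, attr, neutral)
                report.note_change(
                    f"heredity_{attr}", iid,
                    f"ID {iid} 's {word} has been changed to {neutral} "
                    "to meet heredity consistency")


def _topological_ids(ped: Pedigree) -> List[int]:
    depth: Dict[int, int] = {}

    def d(iid: int) -> int:
        if iid in depth:
            return depth[iid]
        m = ped.individuals[iid]
        parents = [p for p in (m.mother_id, m.father_id)
                   if p is not None and p in ped.individuals]
        depth[iid] = 0 if not parents else 1 + max(d(p) for p in parents)
        return depth[iid]

    return sorted(ped.individuals, key=lambda i: (d(i), i))


def generation_index(ped: Pedigree) -> Dict[int, int]:
    """Pedigree depth per member (founders 0, child = 1 + max parent)."""
    order = _topological_ids(ped)
    depth: Dict[int, int] = {}
    for iid in order:
        m = ped.individuals[iid]
        parents = [p for p in (m.mother_id, m.father_id)
                   if p is not None and p in ped.individuals]
        depth[iid] = 0 if not parents else 1 + max(depth[p] for p in parents)
    return depth


def _check_twins(ped: Pedigree) -> None:
    groups: Dict[int, List[Individual]] = {}
    for m in ped:
        if m.twin_group > 0:
            groups.setdefault(m.twin_group, []).append(m)
    for gid, members in groups.items():
        if len(members) < 2:
            continue
        first = members[0]
        for m in members[1:]:
            if (m.mother_id, m.father_id) != (first.mother_id, first.father_id):
                raise PedigreeError(
                    f"twin set {gid}: members {first.id} and {m.id} have different parents")
            if m.sex != first.sex:
                raise PedigreeError(
                    f"twin set {gid}: members {first.id} and {m.id} differ in sex")
            if m.race != first.race or m.ancestry != first.ancestry:
                raise PedigreeError(
                    f"twin set {gid}: members {first.id} and {m.id} differ in race/ancestry")


def _check_sex_cancer(ped: Pedigree, mdb: ModelDatabase) -> None:
    name_by_tag = mdb.cancer_tags
    for m in ped:
        for tag in m.affected_cancers():
            name = name_by_tag.get(tag, tag)
            if name not in mdb.cancers:
                continue
            r = mdb.cancer_index(name)
            sex_slice = mdb.pen[r, :, :, m.sex, :, :]
            if (sex_slice == 0).all():
                sexname = ("female", "male")[m.sex]
                raise PedigreeError(
                    f"ID {m.id}: {sexname} individual diagnosed with {name}, "
                    "which has zero penetrance for that sex")


def _range_fixes(ped: Pedigree, report: CheckReport) -> None:
    for m in ped:
        if m.cur_age is not None and m.cur_age > MAX_AGE:
            report.note_change("age_clamped", m.id,
                               f"ID {m.id} 's CurAge {m.cur_age} has been clamped to {MAX_AGE}")
            report.warn(f"ID {m.id}: CurAge above {MAX_AGE} clamped")
            m.cur_age = MAX_AGE
        for tag, hist in m.cancers.items():
            if hist.diagnosis_age is not None and hist.diagnosis_age > MAX_AGE:
                report.note_change(
                    "age_clamped", m.id,
                    f"ID {m.id} 's Age{tag} {hist.diagnosis_age} has been clamped to {MAX_AGE}")
                hist.diagnosis_age = MAX_AGE
            if hist.affected == 0 and hist.diagnosis_age is not None:
                report.note_change(
                    "age_dropped", m.id,
                    f"ID {m.id} 's Age{tag} has been dropped because isAff{tag}=0")
                hist.diagnosis_age = None


def check_pedigree(ped: Pedigree, db: ParameterDatabase,
                   cancers=None, genes=None) -> Tuple[Pedigree, CheckReport]:
    """Validate, harmonize and repair a pedigree against a database.

    Returns the repaired pedigree and a report of changes.  Raises
    :class:`PedigreeError` for unresolvable inconsistencies and
    :class:`LoopError` for pedigree loops.  Idempotent: running the check
    on its own output changes nothing further.
    """
    report = CheckReport()
    out = ped.copy()
    if not out.probands():
        raise PedigreeError("pedigree has no proband (isProband=1)")

    mdb = build_model_database(db, cancers=cancers, genes=genes, ped=out)
    report.messages.append(
        f"Your model has {len(mdb.cancers)} cancers - {', '.join(mdb.cancers)} "
        f"and {len(mdb.genes)} genes - {', '.join(mdb.gene_variants)}")

    _range_fixes(out, report)
    out.validate()
    _check_sex_cancer(out, mdb)

    tested = sorted({g for m in out for g in m.germline if g in mdb.genes})
    for g in tested:
        variant = mdb.gene_variants[mdb.genes.index(g)]
        report.messages.append(
            f"Germline testing results for {g} are assumed to be for "
            f"default variant {variant}.")

    _harmonize_heredity(out, report)
    _check_twins(out)

    loops = detect_loops(out)
    if loops:
        raise LoopError(
            "pedigree contains loop(s) through ids: "
            + "; ".join(str(loop) for loop in loops))

    out, removed = remove_disconnected(out)
    if removed:
        report.note_change(
            "removed_disconnected", removed,
            f"IDs {','.join(map(str, removed))} are disconnected from every "
            "proband and have been removed")
    if len(out) == 1:
        report.warn("proband has no connected relatives; singleton pedigree")

    out, added = add_pseudo_parents(out)
    if added:
        report.note_change(
            "added_pseudo_parents", added,
            f"IDs {','.join(map(str, added))} have been added as pseudo-parents "
            "to complete single-parent links")

    out.validate(require_both_parents=True)
    return out, report
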