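"""Core domain types for multi-gene, multi-cancer Mendelian risk modeling.

The central objects are:

* :class:`Individual` / :class:`Pedigree` — a validated family graph with
  per-member cancer histories, in the standard pedigree column schema
  (``ID``/``MotherID``/``FatherID``/``Sex``/``isAff*``/``Age*``/...).
* :class:`PenetranceTable` / :class:`AlleleFrequencyTable` /
  :class:`ParameterDatabase` — age-specific cancer penetrances indexed by
  cancer x gene-variant x race x sex x age x penetrance-type, and pathogenic
  allele frequencies indexed by gene x ancestry.
* :class:`ModelOptions` — run-time options (paring parameter, imputation
  count, net-vs-crude risk, age grid step, seed).
* :class:`PosteriorResult` / :class:`RiskEstimate` — per-counselee posterior
  carrier probabilities over the pared genotype space and future cancer
  risks on an age grid, each with lower/upper bounds from multiple
  imputation.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

#: Last age on the penetrance age axis; ages beyond this are clamped.
MAX_AGE = 94

SEXES = ("Female", "Male")  # sex code 0 = Female, 1 = Male
PENETRANCE_TYPES = ("Net", "Crude")
RACES = ("All_Races", "AIAN", "Asian", "Black", "White", "Hispanic", "WH", "WNH")
ANCESTRIES = ("AJ", "nonAJ", "Italian")
DEFAULT_RACE = "All_Races"
DEFAULT_ANCESTRY = "nonAJ"
MARKER_TYPES = ("CK14", "CK5.6", "ER", "PR", "HER2", "MSI")
INTERVENTION_TYPES = ("mastectomy", "hysterectomy", "oophorectomy")

#: Genes recognised as germline-result columns in pedigree files.
GENE_TYPES = (
    "APC", "ATM", "BARD1", "BMPR1A", "BRCA1", "BRCA2", "BRIP1", "CDH1",
    "CDK4", "CDKN2A", "CHEK2", "EPCAM", "MLH1", "MSH2", "MSH6", "MUTYH",
    "NBN", "PALB2", "PMS2", "PTEN", "RAD51C", "RAD51D", "STK11", "TP53",
)

#: Default short-tag -> full-name dictionary for cancer column suffixes.
DEFAULT_CANCER_TAGS = {
    "BRA": "Brain", "BC": "Breast", "CER": "Cervical", "COL": "Colorectal",
    "ENDO": "Endometrial", "GAS": "Gastric", "KID": "Kidney",
    "LEUK": "Leukemia", "MELA": "Melanoma", "OC": "Ovarian",
    "OST": "Osteosarcoma", "PANC": "Pancreatic", "SI": "Small Intestine",
    "STS": "Soft Tissue Sarcoma", "THY": "Thyroid", "UB": "Urinary Bladder",
    "HEP": "Hepatobiliary",
}

NONCARRIER = "noncarrier"


class PanelPedError(Exception):
    """Base class for all package errors."""


class SchemaError(PanelPedError):
    """Pedigree file does not follow the expected column schema."""


class PedigreeError(PanelPedError):
    """Pedigree content is invalid or cannot be repaired."""


class LoopError(PedigreeError):
    """Pedigree contains a loop in the marriage-node graph."""


class DatabaseError(PanelPedError):
    """Parameter database is malformed or fails validation."""


class ResolutionError(PanelPedError):
    """A requested cancer/gene/preset label cannot be resolved."""


# ---------------------------------------------------------------------------
# Pedigree types
# ---------------------------------------------------------------------------

@dataclass
class CancerHistory:
    """Affection status and diagnosis age for one cancer."""

    affected: int = 0
    diagnosis_age: Optional[int] = None


@dataclass
class Individual:
    """One pedigree member.

    ``cur_age`` is the censoring age (current age, or death age when
    ``is_dead`` is 1).  ``twin_group`` equals 0 for non-twins; identical
    twins share a positive group number.  ``pseudo`` marks synthetic
    founders inserted to complete single-parent links; they carry the
    population prior and no phenotype.
    """

    id: int
    mother_id: Optional[int] = None
    father_id: Optional[int] = None
    sex: int = 0
    is_proband: int = 0
    cur_age: Optional[int] = None
    is_dead: Optional[int] = None
    cancers: Dict[str, CancerHistory] = field(default_factory=dict)
    race: Optional[str] = None
    ancestry: Optional[str] = None
    twin_group: int = 0
    interventions: List[Tuple[str, int]] = field(default_factory=list)
    germline: Dict[str, int] = field(default_factory=dict)
    markers: Dict[str, int] = field(default_factory=dict)
    pseudo: bool = False

    def validate(self) -> None:
        if not (isinstance(self.id, int) and self.id > 0):
            raise PedigreeError(f"individual id must be a positive integer, got {self.id!r}")
        if self.sex not in (0, 1):
            raise PedigreeError(f"ID {self.id}: Sex must be 0 or 1, got {self.sex!r}")
        if self.cur_age is not None and not 1 <= self.cur_age <= MAX_AGE:
            raise PedigreeError(f"ID {self.id}: CurAge {self.cur_age} outside [1, {MAX_AGE}]")
        for tag, hist in self.cancers.items():
            if hist.affected not in (0, 1):
                raise PedigreeError(f"ID {self.id}: isAff{tag} must be 0 or 1")
            if hist.affected == 0 and hist.diagnosis_age is not None:
                raise PedigreeError(f"ID {self.id}: Age{tag} present but isAff{tag}=0")
            if hist.diagnosis_age is not None:
                if not 1 <= hist.diagnosis_age <= MAX_AGE:
                    raise PedigreeError(
                        f"ID {self.id}: Age{tag} {hist.diagnosis_age} outside [1, {MAX_AGE}]")
                if self.cur_age is not None and hist.diagnosis_age > self.cur_age:
                    raise PedigreeError(
                        f"ID {self.id}: Age{tag} {hist.diagnosis_age} exceeds CurAge {self.cur_age}")
        seen = set()
        for kind, age in self.interventions:
            if kind not in INTERVENTION_TYPES:
                raise PedigreeError(f"ID {self.id}: unknown intervention {kind!r}")
            if kind in seen:
                raise PedigreeError(f"ID {self.id}: duplicate intervention {kind!r}")
            seen.add(kind)
            if not 1 <= age <= MAX_AGE:
                raise PedigreeError(f"ID {self.id}: intervention age {age} outside [1, {MAX_AGE}]")
        if self.twin_group < 0:
            raise PedigreeError(f"ID {self.id}: Twins group must be non-negative")

    def is_founder(self) -> bool:
        return self.mother_id is None and self.father_id is None

    def affected_cancers(self) -> List[str]:
        return [tag for tag, h in self.cancers.items() if h.affected == 1]


@dataclass
class Pedigree:
    """Ordered collection of individuals plus the cancer tags observed."""

    individuals: Dict[int, Individual]
    cancers: List[str] = field(default_factory=list)

    @classmethod
    def from_members(cls, members: Sequence[Individual],
                     cancers: Optional[Sequence[str]] = None) -> "Pedigree":
        if cancers is None:
            tags: List[str] = []
            for m in members:
                for tag in m.cancers:
                    if tag not in tags:
                        tags.append(tag)
            cancers = tags
        return cls({m.id: m for m in members}, list(cancers))

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals.values())

    def __getitem__(self, iid: int) -> Individual:
        return self.individuals[iid]

    def copy(self) -> "Pedigree":
        return _copy.deepcopy(self)

    def probands(self) -> List[Individual]:
        return [m for m in self if m.is_proband == 1]

    def children_of(self, iid: int) -> List[Individual]:
        return [m for m in self if iid in (m.mother_id, m.father_id)]

    def validate(self, require_both_parents: bool = False) -> None:
        ids = list(self.individuals)
        if len(ids) != len(set(ids)):
            raise PedigreeError("duplicate individual ids")
        for m in self:
            m.validate()
            for tag in m.cancers:
                if tag not in self.cancers:
                    raise PedigreeError(f"ID {m.id}: cancer tag {tag} not declared in pedigree")
            for pid, want_sex, role in ((m.mother_id, 0, "mother"), (m.father_id, 1, "father")):
                if pid is None:
                    continue
                if pid not in self.individuals:
                    raise PedigreeError(f"ID {m.id}: {role} {pid} not in pedigree")
                if self.individuals[pid].sex != want_sex:
                    raise PedigreeError(
                        f"ID {m.id}: {role} {pid} has sex {self.individuals[pid].sex}")
            if require_both_parents and (m.mother_id is None) != (m.father_id is None):
                raise PedigreeError(f"ID {m.id}: has exactly one recorded parent")
        if not self.probands():
            raise PedigreeError("pedigree has no proband (isProband=1)")
        self._check_no_ancestor_cycle()

    def _check_no_ancestor_cycle(self) -> None:
        state: Dict[int, int] = {}  # 0 in-progress, 1 done

        def visit(iid: int, stack: tuple) -> None:
            if iid in stack:
                raise PedigreeError(f"ID {iid} is its own ancestor")
            if state.get(iid) == 1:
                return
            m = self.individuals[iid]
            for pid in (m.mother_id, m.father_id):
                if pid is not None and pid in self.individuals:
                    visit(pid, stack + (iid,))
            state[iid] = 1

        for iid in self.individuals:
            visit(iid, ())


# ---------------------------------------------------------------------------
# Parameter database types
# ---------------------------------------------------------------------------

@dataclass
class PenetranceTable:
    """Age-specific cancer penetrances with named axes.

    ``values`` has shape ``(cancer, gene_variant, race, sex, age, type)``
    with the age axis covering 1..:data:`MAX_AGE` and the type axis
    ``("Net", "Crude")``.  Each fixed (cancer, variant, race, sex, type)
    slice is a sub-distribution over age of diagnosis: values in [0, 1]
    summing to at most 1.
    """

    values: np.ndarray
    cancers: List[str]
    gene_variants: List[str]
    races: List[str]
    sexes: Tuple[str, ...] = SEXES
    types: Tuple[str, ...] = PENETRANCE_TYPES

    def validate(self) -> None:
        expect = (len(self.cancers), len(self.gene_variants), len(self.races),
                  len(self.sexes), MAX_AGE, len(self.types))
        if self.values.shape != expect:
            raise DatabaseError(
                f"penetrance array has shape {self.values.shape}, expected {expect}")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise DatabaseError("penetrance values outside [0, 1]")
        sums = self.values.sum(axis=4)
        if np.any(sums > 1 + 1e-12):
            idx = np.unravel_index(np.argmax(sums), sums.shape)
            c, v, r, s, t = idx
            raise DatabaseError(
                "penetrance age-sum exceeds 1 for slice "
                f"(cancer={self.cancers[c]}, variant={self.gene_variants[v]}, "
                f"race={self.races[r]}, sex={self.sexes[s]}, type={self.types[t]})")


@dataclass
class AlleleFrequencyTable:
    """Pathogenic variant allele frequencies by gene and ancestry."""

    values: np.ndarray
    genes: List[str]
    ancestries: Tuple[str, ...] = ANCESTRIES

    def validate(self) -> None:
        expect = (len(self.genes), len(self.ancestries))
        if self.values.shape != expect:
            raise DatabaseError(
                f"allele-frequency array has shape {self.values.shape}, expected {expect}")
        if np.any(self.values <= 0) or np.any(self.values > 0.5):
            raise DatabaseError("allele frequencies must lie in (0, 0.5]")


@dataclass
class ParameterDatabase:
    """Penetrance + allele-frequency tables plus label dictionaries.

    ``gene_variant_map`` maps plain gene names (BRCA1) to the default
    variant label used on the penetrance axis (BRCA1_hetero_anyPV).  The
    noncarrier baseline is stored as its own penetrance row labelled
    ``"noncarrier"``.  ``cancer_tags`` maps short column-suffix tags (BC)
    to the full cancer names on the penetrance axis (Breast).
    ``risk_modifiers`` maps (intervention, cancer) to a hazard-reduction
    factor in [0, 1] applied from the intervention age onward; pairs not
    listed default to the neutral factor 1.
    """

    penetrance: PenetranceTable
    allele_frequency: AlleleFrequencyTable
    gene_variant_map: Dict[str, str]
    cancer_tags: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_CANCER_TAGS))
    risk_modifiers: Dict[Tuple[str, str], float] = field(default_factory=dict)
    marker_tables: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        self.penetrance.validate()
        self.allele_frequency.validate()
        if NONCARRIER not in self.penetrance.gene_variants:
            raise DatabaseError("penetrance table must include a 'noncarrier' row")
        for gene, variant in self.gene_variant_map.items():
            if gene not in self.allele_frequency.genes:
                raise DatabaseError(f"mapped gene {gene} missing from allele-frequency table")
            if variant not in self.penetrance.gene_variants:
                raise DatabaseError(f"variant {variant} missing from penetrance table")
        variants = [v for v in self.gene_variant_map.values()]
        if len(set(variants)) != len(variants):
            raise DatabaseError("gene_variant_map is not one-to-one")

    @property
    def genes(self) -> List[str]:
        return list(self.gene_variant_map)


# ---------------------------------------------------------------------------
# Options and results
# ---------------------------------------------------------------------------

@dataclass
class ModelOptions:
    """Run-time options.

    ``max_mut`` is the paring parameter: the maximum number of simultaneous
    mutations a genotype may carry.  Unset resolves to 2 (clamped to the
    number of model genes).  ``net`` switches future risk from crude
    (competing mortality accounted for) to net penetrances.  ``age_by`` is
    the future-risk grid step in years.  ``germline_sensitivity`` /
    ``germline_specificity`` parameterise germline test accuracy (1.0 =
    perfect test).
    """

    max_mut: Optional[int] = None
    iterations: int = 20
    parallel: bool = True
    net: bool = False
    age_by: int = 5
    seed: Optional[int] = None
    germline_sensitivity: float = 1.0
    germline_specificity: float = 1.0

    def resolved_max_mut(self, n_genes: int) -> int:
        m = 2 if self.max_mut is None else int(self.max_mut)
        return max(1, min(m, n_genes))


@dataclass
class PosteriorResult:
    """Posterior carrier probabilities per proband over the pared space.

    ``probands`` maps proband id -> dict with 'estimate', 'lower', 'upper'
    arrays aligned to ``labels``.
    """

    labels: List[str]
    probands: Dict[int, Dict[str, np.ndarray]]

    def entries(self, proband_id: int) -> List[Tuple[str, float, float, float]]:
        d = self.probands[proband_id]
        return [(lab, float(d["estimate"][i]), float(d["lower"][i]), float(d["upper"][i]))
                for i, lab in enumerate(self.labels)]

    def carrier_probability(self, proband_id: int) -> float:
        """Total probability of carrying at least one mutation."""
        d = self.probands[proband_id]
        nc = self.labels.index(NONCARRIER)
        return float(1.0 - d["estimate"][nc])

    def validate(self) -> None:
        for pid, d in self.probands.items():
            est = d["estimate"]
            if abs(est.sum() - 1.0) > 1e-9:
                raise PanelPedError(f"proband {pid}: posterior sums to {est.sum()}")
            if np.any(d["lower"] > est + 1e-12) or np.any(d["upper"] < est - 1e-12):
                raise PanelPedError(f"proband {pid}: bounds do not bracket estimate")


@dataclass
class RiskEstimate:
    """Future cancer risk per proband per cancer on an age grid."""

    #: proband id -> cancer name -> dict with 'by_age', 'estimate', 'lower', 'upper'
    probands: Dict[int, Dict[str, Dict[str, np.ndarray]]]

    def entries(self, proband_id: int, cancer: str) -> List[Tuple[int, float, float, float]]:
        d = self.probands[proband_id][cancer]
        return [(int(a), float(e), float(lo), float(hi)) for a, e, lo, hi in
                zip(d["by_age"], d["estimate"], d["lower"], d["upper"])]

    def validate(self) -> None:
        for pid, per_cancer in self.probands.items():
            for cancer, d in per_cancer.items():
                est = d["estimate"]
                if np.any(np.diff(est) < -1e-12):
                    raise PanelPedError(
                        f"proband {pid} / {cancer}: risk not monotone in age")
                if np.any(est < -1e-12) or np.any(est > 1 + 1e-12):
                    raise PanelPedError(f"proband {pid} / {cancer}: risk outside [0, 1]")
                if np.any(d["lower"] > est + 1e-12) or np.any(d["upper"] < est - 1e-12):
                    raise PanelPedError(f"proband {pid} / {cancer}: bounds invalid")
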