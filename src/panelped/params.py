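"""Model database construction: resolve cancers/genes, subset, look up.

``build_model_database`` mirrors the pre-processing step that subsets
the full parameter database to the cancers and genes requested for one
model run.  Unset genes default to every gene in the database; unset
cancers default to the cancers present in the pedigree.  Lookups fall
back to ``All_Races`` when race is missing and to ``nonAJ`` when
ancestry is missing.

Presets reproduce the classic single-syndrome models: BRCAPRO (breast/
ovarian, BRCA1/2), MMRPRO (colorectal/endometrial, MLH1/MSH2/MSH6) and
the extended BRCAPRO5/BRCAPRO6 gene panels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    DEFAULT_ANCESTRY, DEFAULT_RACE, MAX_AGE, NONCARRIER,
    ParameterDatabase, Pedigree, ResolutionError,
)

PRESETS: Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...]]] = {
    "BRCAPRO": (("Breast", "Ovarian"), ("BRCA1", "BRCA2")),
    "BRCAPRO5": (("Breast", "Ovarian"), ("BRCA1", "BRCA2", "MLH1", "MSH2", "MSH6")),
    "BRCAPRO6": (("Breast", "Ovarian"),
                 ("BRCA1", "BRCA2", "MLH1", "MSH2", "MSH6", "CDKN2A")),
    "MMRPRO": (("Colorectal", "Endometrial"), ("MLH1", "MSH2", "MSH6")),
}


def preset_model(name: str) -> Tuple[List[str], List[str]]:
    """Return the (cancers, genes) specification of a named preset model."""
    if name not in PRESETS:
        raise ResolutionError(
            f"unknown preset {name!r}; supported presets: {', '.join(sorted(PRESETS))}")
    cancers, genes = PRESETS[name]
    return list(cancers), list(genes)


@dataclass
class ModelDatabase:
    """Database subset restricted to the model's cancers and genes.

    Arrays are plain numpy for fast access in the inference hot path:
    ``pen`` has shape (R, V, n_race, 2, 94, 2) where the variant axis V
    covers the K model gene variants followed by the noncarrier baseline
    at index ``noncarrier_index``; ``cum`` is its cumulative sum over the
    age axis.  ``freq`` has shape (K, n_ancestry).
    """

    cancers: List[str]
    cancer_tags: Dict[str, str]
    genes: List[str]
    gene_variants: List[str]
    races: List[str]
    ancestries: List[str]
    pen: np.ndarray
    cum: np.ndarray
    freq: np.ndarray
    risk_modifiers: Dict[Tuple[str, str], float] = field(default_factory=dict)
    marker_tables: Dict[str, Dict[str, float]] = field(default_factory=dict)

    TYPE_INDEX = {"Net": 0, "Crude": 1}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def noncarrier_index(self) -> int:
        return len(self.gene_variants)

    def cancer_index(self, cancer: str) -> int:
        if cancer not in self.cancers:
            raise ResolutionError(
                f"cancer {cancer!r} not in model; valid: {', '.join(self.cancers)}")
        return self.cancers.index(cancer)

    def variant_index(self, label: str) -> int:
        if label == NONCARRIER:
            return self.noncarrier_index
        if label in self.gene_variants:
            return self.gene_variants.index(label)
        if label in self.genes:
            return self.genes.index(label)
        raise ResolutionError(
            f"gene variant {label!r} not in model; valid: "
            f"{', '.join(self.gene_variants + [NONCARRIER])}")

    def race_index(self, race: Optional[str]) -> int:
        if race is None or race not in self.races:
            return self.races.index(DEFAULT_RACE)
        return self.races.index(race)

    def ancestry_index(self, ancestry: Optional[str]) -> int:
        if ancestry is None:
            return self.ancestries.index(DEFAULT_ANCESTRY)
        if ancestry not in self.ancestries:
            raise ResolutionError(
                f"ancestry {ancestry!r} not on axis; valid: {', '.join(self.ancestries)}")
        return self.ancestries.index(ancestry)

    def female_only(self, cancer: str) -> bool:
        """True when the male penetrance slice is identically zero."""
        r = self.cancer_index(cancer)
        return bool(np.all(self.pen[r, :, :, 1, :, :] == 0))

    def frequencies(self, ancestry: Optional[str]) -> np.ndarray:
        """Allele frequency per model gene for an ancestry (fallback nonAJ)."""
        return self.freq[:, self.ancestry_index(ancestry)]

    def dominant_variant_table(self) -> np.ndarray:
        """(K, R, 2) lifetime Net cumulative penetrance at All_Races.

        Used to pick the dominant carried variant for multi-mutation
        genotypes: per cancer and sex, the carried gene with the largest
        lifetime cumulative penetrance supplies the curve.
        """
        ri = self.races.index(DEFAULT_RACE)
        K, R = self.n_genes, len(self.cancers)
        out = np.empty((K, R, 2))
        for k in range(K):
            out[k] = self.cum[:, k, ri, :, MAX_AGE - 1, 0]
        return out


def _resolve_genes(db: ParameterDatabase, genes: Optional[Sequence[str]]) -> List[str]:
    if genes is None:
        return list(db.gene_variant_map)
    resolved = []
    variant_to_gene = {v: g for g, v in db.gene_variant_map.items()}
    for g in genes:
        if g in db.gene_variant_map:
            resolved.append(g)
        elif g in variant_to_gene:
            resolved.append(variant_to_gene[g])
        else:
            raise ResolutionError(
                f"unknown gene {g!r}; valid genes: {', '.join(db.gene_variant_map)}")
    return resolved


def _resolve_cancers(db: ParameterDatabase, cancers: Optional[Sequence[str]],
                     ped: Optional[Pedigree]) -> List[str]:
    axis = db.penetrance.cancers
    if cancers is None:
        if ped is None:
            return [c for c in axis]
        out = []
        for tag in ped.cancers:
            name = db.cancer_tags.get(tag, tag)
            if name in axis:
                out.append(name)
        # a pedigree without cancer columns carries no phenotype data:
        # default to the full axis so the model is still well-formed
        return out if out else [c for c in axis]
    out = []
    for c in cancers:
        name = db.cancer_tags.get(c, c)
        if name not in axis:
            raise ResolutionError(
                f"unknown cancer {c!r}; valid cancers: {', '.join(axis)}")
        out.append(name)
    return out


def build_model_database(db: ParameterDatabase,
                         cancers: Optional[Sequence[str]] = None,
                         genes: Optional[Sequence[str]] = None,
                         ped: Optional[Pedigree] = None) -> ModelDatabase:
    """Subset the database to the requested cancers and genes.

    ``cancers`` accepts full names or short tags; ``genes`` accepts plain
    gene names or variant labels.  Unset arguments follow the defaults
    described in the module docstring.
    """
    db.validate()
    sel_genes = _resolve_genes(db, genes)
    sel_cancers = _resolve_cancers(db, cancers, ped)
    variants = [db.gene_variant_map[g] for g in sel_genes]

    pen_t = db.penetrance
    c_idx = [pen_t.cancers.index(c) for c in sel_cancers]
    v_idx = [pen_t.gene_variants.index(v) for v in variants]
    v_idx.append(pen_t.gene_variants.index(NONCARRIER))
    pen = pen_t.values[np.ix_(c_idx, v_idx)]

    freq_t = db.allele_frequency
    g_idx = [freq_t.genes.index(g) for g in sel_genes]
    freq = freq_t.values[g_idx, :]

    tags = {tag: name for tag, name in db.cancer_tags.items() if name in sel_cancers}
    return ModelDatabase(
        cancers=sel_cancers,
        cancer_tags=tags,
        genes=sel_genes,
        gene_variants=variants,
        races=list(pen_t.races),
        ancestries=list(freq_t.ancestries),
        pen=pen,
        cum=np.cumsum(pen, axis=4),
        freq=freq,
        risk_modifiers=dict(db.risk_modifiers),
        marker_tables={k: dict(v) for k, v in db.marker_tables.items()},
    )


def lookup_penetrance(mdb: ModelDatabase, cancer: str, gene_variant: str,
                      race: Optional[str], sex: str, age: int,
                      ptype: str = "Net") -> float:
    """Stored penetrance P(T = age | variant, sex), with race fallback."""
    if not 1 <= age <= MAX_AGE:
        raise ResolutionError(f"age {age} outside 1..{MAX_AGE}")
    if sex not in ("Female", "Male"):
        raise ResolutionError("sex must be 'Female' or 'Male'")
    if ptype not in mdb.TYPE_INDEX:
        raise ResolutionError("penetrance type must be 'Net' or 'Crude'")
    r = mdb.cancer_index(cancer)
    v = mdb.variant_index(gene_variant)
    return float(mdb.pen[r, v, mdb.race_index(race), ("Female", "Male").index(sex),
                         age - 1, mdb.TYPE_INDEX[ptype]])


def lookup_allele_frequency(mdb: ModelDatabase, gene: str,
                            ancestry: Optional[str] = None) -> float:
    """Allele frequency for a model gene, ancestry fallback nonAJ."""
    if gene in mdb.genes:
        k = mdb.genes.index(gene)
    elif gene in mdb.gene_variants:
        k = mdb.gene_variants.index(gene)
    else:
        raise ResolutionError(
            f"unknown gene {gene!r}; valid genes: {', '.join(mdb.genes)}")
    return float(mdb.freq[k, mdb.ancestry_index(ancestry)])
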