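"""Forward simulation: toy parameter databases and pedigrees with known
true genotypes.

``make_toy_database`` builds a fully valid parameter database with
smooth unimodal per-age penetrance curves, carrier curves elevated over
the noncarrier baseline, crude penetrances equal to net times a fixed
other-cause survival curve, and rare allele frequencies — the study
conditions for every simulation-based test in the package.

``simulate_family`` draws founder genotypes from Hardy-Weinberg (true
allele counts 0/1/2), transmits alleles by Mendelian coin flips, and
generates each member's cancer history from the genotype-, sex- and
age-specific penetrances, censored at a generation-dependent current
age.  The hidden truth is returned separately from the observable
pedigree, so inference can be scored against it.

``calibration_experiment`` closes the loop: simulate many families, run
the risk engine on each observable pedigree, and compare predicted
carrier probabilities with observed carrier fractions by decile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    ANCESTRIES, MAX_AGE, AlleleFrequencyTable, CancerHistory, Individual,
    ModelOptions, ParameterDatabase, Pedigree, PenetranceTable,
)
from .params import ModelDatabase, build_model_database

_GENE_POOL = ("BRCA1", "BRCA2", "ATM", "MSH2", "MLH1", "MSH6", "CDKN2A",
              "PALB2", "CHEK2", "PMS2", "APC", "BARD1", "BMPR1A", "BRIP1",
              "CDH1", "CDK4", "EPCAM", "MUTYH", "NBN", "PTEN", "RAD51C",
              "RAD51D", "STK11", "TP53")
_CANCER_POOL = (("Breast", "BC", False), ("Ovarian", "OC", True),
                ("Colorectal", "COL", False), ("Endometrial", "ENDO", True),
                ("Pancreatic", "PANC", False), ("Melanoma", "MELA", False))


def _bump(mode: float, sd: float, mass: float) -> np.ndarray:
    """Discretized unimodal curve over ages 1..94 with total mass ``mass``."""
    ages = np.arange(1, MAX_AGE + 1)
    shape = np.exp(-0.5 * ((ages - mode) / sd) ** 2)
    return mass * shape / shape.sum()


def other_cause_survival() -> np.ndarray:
    """Fixed survival-from-other-causes curve S_d(age), Gompertz-like."""
    ages = np.arange(1, MAX_AGE + 1)
    hazard = 2e-5 * np.exp(0.075 * ages)
    return np.exp(-np.cumsum(hazard))


def make_toy_database(K: int = 3, R: int = 2, seed: int = 0,
                      races: Sequence[str] = ("All_Races",),
                      freq_range: Tuple[float, float] = (1e-4, 1e-2),
                      carrier_mass_range: Tuple[float, float] = (0.25, 0.55),
                      ) -> ParameterDatabase:
    """Small, valid parameter database for K genes and R cancers.

    Carrier lifetime penetrances are drawn in ``carrier_mass_range``
    (default [0.25, 0.55]) with gene-specific onset ages; the noncarrier
    baseline has lifetime mass 0.06 with late onset.  Female-only
    cancers (Ovarian, Endometrial) have identically zero male
    penetrance.  Crude = net x other-cause survival.  Allele frequencies
    are drawn from ``freq_range`` (default [1e-4, 1e-2]).
    """
    if K < 1 or R < 1:
        raise ValueError("K and R must be at least 1")
    if K > len(_GENE_POOL):
        raise ValueError(f"at most {len(_GENE_POOL)} genes supported")
    rng = np.random.default_rng(seed)
    genes = list(_GENE_POOL[:K])
    variants = [f"{g}_hetero_anyPV" for g in genes]
    pool = list(_CANCER_POOL) * (R // len(_CANCER_POOL) + 1)
    cancers = [c[0] if i < len(_CANCER_POOL) else f"{c[0]}{i}"
               for i, c in enumerate(pool[:R])]
    tags = {(_CANCER_POOL[i % len(_CANCER_POOL)][1] if i < len(_CANCER_POOL)
             else f"C{i}"): name for i, name in enumerate(cancers)}
    female_only = [pool[i][2] for i in range(R)]

    V = K + 1  # variants + noncarrier
    pen = np.zeros((R, V, len(races), 2, MAX_AGE, 2))
    S_d = other_cause_survival()
    for r in range(R):
        base = _bump(mode=68.0, sd=13.0, mass=0.06)
        for v in range(V):
            if v < K:
                mass = rng.uniform(*carrier_mass_range)
                mode = rng.uniform(40.0, 55.0)
                net = _bump(mode=mode, sd=12.0, mass=mass)
            else:
                net = base
            for s in range(2):
                if female_only[r] and s == 1:
                    continue
                scale = 1.0 if s == 0 else (0.01 if cancers[r].startswith("Breast")
                                            else 0.8)
                curve = net * scale
                for race_i in range(len(races)):
                    pen[r, v, race_i, s, :, 0] = curve
                    pen[r, v, race_i, s, :, 1] = curve * S_d

    freq = rng.uniform(*freq_range, size=(K, len(ANCESTRIES)))
    db = ParameterDatabase(
        penetrance=PenetranceTable(
            values=pen, cancers=cancers,
            gene_variants=variants + ["noncarrier"], races=list(races)),
        allele_frequency=AlleleFrequencyTable(values=freq, genes=genes),
        gene_variant_map=dict(zip(genes, variants)),
        cancer_tags=tags,
    )
    db.validate()
    return db


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------

GENERATION_AGE_MEANS = (75.0, 50.0, 25.0)
GENERATION_AGE_SD = 8.0


def _draw_current_age(generation: int, rng: np.random.Generator) -> int:
    mean = (GENERATION_AGE_MEANS[generation]
            if generation < len(GENERATION_AGE_MEANS)
            else max(5.0, GENERATION_AGE_MEANS[-1] - 25.0 * (generation - 2)))
    return int(np.clip(round(rng.normal(mean, GENERATION_AGE_SD)), 1, MAX_AGE))


def _founder_counts(freqs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """True allele counts per gene under Hardy-Weinberg."""
    return rng.binomial(2, freqs)


def _transmit(counts_m: np.ndarray, counts_f: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """One allele drawn from each parent per gene."""
    from_m = rng.random(counts_m.shape) < counts_m / 2.0
    from_f = rng.random(counts_f.shape) < counts_f / 2.0
    return from_m.astype(int) + from_f.astype(int)


def _phenotype(counts: np.ndarray, sex: int, cur_age: int, mdb: ModelDatabase,
               dom_life: np.ndarray, rng: np.random.Generator) -> Dict[str, CancerHistory]:
    """Draw censored cancer histories from the net penetrance curves."""
    tag_by_cancer = {name: tag for tag, name in mdb.cancer_tags.items()}
    carried = np.flatnonzero(counts >= 1)
    out: Dict[str, CancerHistory] = {}
    for r, cancer in enumerate(mdb.cancers):
        if carried.size:
            k = carried[np.argmax(dom_life[carried, r, sex])]
            v = int(k)
        else:
            v = mdb.noncarrier_index
        curve = mdb.pen[r, v, mdb.race_index(None), sex, :, 0]
        never = max(0.0, 1.0 - curve.sum())
        probs = np.append(curve, never)
        probs = probs / probs.sum()
        draw = rng.choice(MAX_AGE + 1, p=probs)
        tag = tag_by_cancer.get(cancer, cancer)
        if draw < MAX_AGE and (draw + 1) <= cur_age:
            out[tag] = CancerHistory(affected=1, diagnosis_age=int(draw + 1))
        else:
            out[tag] = CancerHistory(affected=0)
    return out


@dataclass
class SimulatedFamily:
    pedigree: Pedigree
    true_genotypes: Dict[int, Tuple[int, ...]]  # id -> carrier flags per gene


def simulate_family(structure: Sequence[int], db: ParameterDatabase,
                    seed: Optional[int] = None,
                    ancestry: str = "nonAJ",
                    genes: Optional[Sequence[str]] = None,
                    cancers: Optional[Sequence[str]] = None,
                    proband_generation: Optional[int] = None) -> SimulatedFamily:
    """Simulate one pedigree with hidden true genotypes.

    ``structure[g]`` is the sibship size produced by the generation-g
    couple; one child per generation marries a new founder spouse and
    produces the next sibship.  The proband is the first child of the
    last generation (or of ``proband_generation``).
    """
    if not structure or any(s < 1 for s in structure):
        raise ValueError("structure must list at least one positive sibship size")
    rng = np.random.default_rng(seed)
    mdb = build_model_database(db, cancers=cancers, genes=genes)
    dom_life = mdb.dominant_variant_table()
    freqs = mdb.frequencies(ancestry)

    members: List[Individual] = []
    counts: Dict[int, np.ndarray] = {}
    next_id = 1

    def add(sex, mother, father, generation, cnt) -> int:
        nonlocal next_id
        iid = next_id
        next_id += 1
        cur_age = _draw_current_age(generation, rng)
        ind = Individual(id=iid, mother_id=mother, father_id=father, sex=sex,
                         cur_age=cur_age, is_dead=0, ancestry=ancestry,
                         cancers=_phenotype(cnt, sex, cur_age, mdb, dom_life, rng))
        members.append(ind)
        counts[iid] = cnt
        return iid

    mother = add(0, None, None, 0, _founder_counts(freqs, rng))
    father = add(1, None, None, 0, _founder_counts(freqs, rng))
    last_children: List[int] = []
    for g, sibs in enumerate(structure):
        children = []
        for _ in range(sibs):
            cnt = _transmit(counts[mother], counts[father], rng)
            children.append(add(int(rng.integers(0, 2)), mother, father, g + 1, cnt))
        last_children = children
        if g + 1 < len(structure):
            heir = children[0]
            spouse_sex = 1 - members[heir - 1].sex
            spouse = add(spouse_sex, None, None, g + 1, _founder_counts(freqs, rng))
            mother = heir if members[heir - 1].sex == 0 else spouse
            father = spouse if members[heir - 1].sex == 0 else heir

    target_gen = (len(structure) if proband_generation is None
                  else proband_generation)
    proband_id = last_children[0] if target_gen >= len(structure) else 1
    for m in members:
        if m.id == proband_id:
            m.is_proband = 1
    ped = Pedigree.from_members(members)
    truth = {iid: tuple((c >= 1).astype(int)) for iid, c in counts.items()}
    return SimulatedFamily(pedigree=ped, true_genotypes=truth)


def mask_ages(ped: Pedigree, probability: float = 0.2,
              seed: Optional[int] = None,
              protect_probands: bool = True) -> Pedigree:
    """Independently blank each age with the given probability."""
    rng = np.random.default_rng(seed)
    out = ped.copy()
    for m in out:
        if protect_probands and m.is_proband:
            continue
        if m.cur_age is not None and rng.random() < probability:
            m.cur_age = None
        for hist in m.cancers.values():
            if hist.diagnosis_age is not None and rng.random() < probability:
                hist.diagnosis_age = None
    return out


def calibration_experiment(n_families: int, db: ParameterDatabase,
                           options: Optional[ModelOptions] = None,
                           seed: Optional[int] = None,
                           structure: Sequence[int] = (2, 2),
                           n_bins: int = 10,
                           engine: str = "peel",
                           level: float = 0.99) -> pd.DataFrame:
    """Simulate families, predict carrier probability, bin, and compare
    the observed true-carrier fraction against the binomial interval
    implied by the mean prediction in each bin.

    Returns a table with one row per occupied bin: n, mean predicted
    probability, observed carrier fraction, the ``level`` binomial
    interval around the mean prediction, and a within-interval flag.
    """
    from .engine import run_model  # late import: engine sits above this module

    opts = options or ModelOptions()
    ss = np.random.SeedSequence(seed).spawn(n_families)
    preds, truths = [], []
    for fam_seed in ss:
        child = np.random.default_rng(fam_seed)
        sim = simulate_family(structure, db, seed=child.integers(2 ** 31))
        res = run_model(sim.pedigree, db, options=opts, engine=engine)
        post = res["posterior"]
        pid = sim.pedigree.probands()[0].id
        preds.append(post.carrier_probability(pid))
        truths.append(int(any(sim.true_genotypes[pid])))
    preds = np.asarray(preds)
    truths = np.asarray(truths)

    edges = np.quantile(preds, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    bins = np.clip(np.searchsorted(edges, preds, side="right") - 1,
                   0, len(edges) - 2)
    rows = []
    alpha = 1.0 - level
    for b in range(len(edges) - 1):
        mask = bins == b
        n = int(mask.sum())
        if n == 0:
            continue
        mean_pred = float(preds[mask].mean())
        k = int(truths[mask].sum())
        lo_k, hi_k = stats.binom.ppf([alpha / 2, 1 - alpha / 2], n, mean_pred)
        rows.append({
            "bin": b, "n": n, "mean_predicted": mean_pred,
            "observed_fraction": k / n, "observed_carriers": k,
            "interval_low": lo_k / n, "interval_high": hi_k / n,
            "within_interval": bool(lo_k <= k <= hi_k),
        })
    return pd.DataFrame(rows)
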