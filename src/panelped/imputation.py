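"""Multiple imputation of missing ages and min/mean/max aggregation.

Missing censoring ages are sampled from the ages of same-generation
relatives (generation = pedigree depth): the sampled value is the
generation mean plus Normal(0, 10) noise, clamped to [1, 94] and to
plausible parent/child gaps (at least 15 years older than any known
child, at least 15 years younger than any known parent).  Generations
with no known ages borrow the nearest informative generation's mean
shifted by 25 years per generation step.

Missing diagnosis ages for affected members are sampled from the
model-averaged net penetrance (mixture over the founder genotype prior)
truncated at the member's censoring age.

Each imputation pass yields one completed pedigree; downstream results
are aggregated elementwise as estimate = mean, lower = min, upper = max.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Optional, Sequence, Union

import numpy as np

from .core import MAX_AGE, Pedigree, PosteriorResult, RiskEstimate
from .check import generation_index
from .genotypes import enumerate_genotypes, founder_prior_vector
from .inference import dominant_variant_indices
from .params import ModelDatabase

AGE_NOISE_SD = 10.0
GENERATION_GAP = 25
MIN_PARENT_CHILD_GAP = 15


def _has_missing(ped: Pedigree) -> bool:
    for m in ped:
        if m.pseudo:
            continue
        if m.cur_age is None:
            return True
        for hist in m.cancers.values():
            if hist.affected == 1 and hist.diagnosis_age is None:
                return True
    return False


def _mean_penetrance(mdb: ModelDatabase, sex: int, race_idx: int,
                     ancestry: Optional[str]) -> np.ndarray:
    """Genotype-prior-averaged net penetrance curve per cancer, (R, 94)."""
    space = enumerate_genotypes(mdb.gene_variants, min(2, max(1, mdb.n_genes)))
    prior = founder_prior_vector(space, mdb.frequencies(ancestry))
    dom = dominant_variant_indices(mdb, space)
    R = len(mdb.cancers)
    out = np.zeros((R, MAX_AGE))
    for r in range(R):
        curves = mdb.pen[r, dom[:, r, sex], race_idx, sex, :, 0]  # (N, 94)
        out[r] = prior @ curves
    return out


def _sample_current_ages(ped: Pedigree, rng: np.random.Generator) -> None:
    gen = generation_index(ped)
    known: Dict[int, List[int]] = {}
    for m in ped:
        if m.cur_age is not None:
            known.setdefault(gen[m.id], []).append(m.cur_age)
    gen_mean: Dict[int, float] = {g: float(np.mean(a)) for g, a in known.items()}
    if not gen_mean and any(m.cur_age is None and not m.pseudo for m in ped):
        warnings.warn("no relative has a known age; sampling missing ages "
                      "around the fallback prior mean of 50")

    def reference_mean(g: int) -> float:
        if g in gen_mean:
            return gen_mean[g]
        if not gen_mean:
            return 50.0
        nearest = min(gen_mean, key=lambda k: abs(k - g))
        return gen_mean[nearest] - GENERATION_GAP * (g - nearest)

    for m in ped:
        if m.pseudo or m.cur_age is not None:
            continue
        age = reference_mean(gen[m.id]) + rng.normal(0.0, AGE_NOISE_SD)
        lo, hi = 1.0, float(MAX_AGE)
        for child in ped.children_of(m.id):
            if child.cur_age is not None:
                lo = max(lo, child.cur_age + MIN_PARENT_CHILD_GAP)
        for pid in (m.mother_id, m.father_id):
            if pid is not None and ped.individuals[pid].cur_age is not None:
                hi = min(hi, ped.individuals[pid].cur_age - MIN_PARENT_CHILD_GAP)
        if lo > hi:
            lo, hi = min(lo, hi), max(lo, hi)
        m.cur_age = int(round(min(max(age, lo), hi)))
        for hist in m.cancers.values():
            if hist.diagnosis_age is not None and hist.diagnosis_age > m.cur_age:
                m.cur_age = hist.diagnosis_age


def _sample_diagnosis_ages(ped: Pedigree, mdb: ModelDatabase,
                           rng: np.random.Generator) -> None:
    tag_by_cancer = {name: tag for tag, name in mdb.cancer_tags.items()}
    cache: Dict[tuple, np.ndarray] = {}
    for m in ped:
        if m.pseudo:
            continue
        for r, cancer in enumerate(mdb.cancers):
            tag = tag_by_cancer.get(cancer, cancer)
            hist = m.cancers.get(tag)
            if hist is None or hist.affected != 1 or hist.diagnosis_age is not None:
                continue
            upper = m.cur_age if m.cur_age is not None else MAX_AGE
            key = (m.sex, mdb.race_index(m.race), m.ancestry)
            if key not in cache:
                cache[key] = _mean_penetrance(mdb, key[0], key[1], key[2])
            weights = cache[key][r, :upper].copy()
            if weights.sum() <= 0:
                weights = np.ones(upper)
            weights /= weights.sum()
            hist.diagnosis_age = int(rng.choice(np.arange(1, upper + 1), p=weights))


def impute_ages(ped: Pedigree, mdb: ModelDatabase, iterations: int = 20,
                seed: Optional[int] = None) -> List[Pedigree]:
    """Return completed pedigrees: one per imputation, or a single copy
    of the input when nothing is missing.

    Deterministic for a fixed seed; per-iteration random substreams are
    spawned from the master seed, so results do not depend on execution
    order (the sequential/parallel contract).
    """
    if iterations < 1:
        raise ValueError("iterations must be at least 1")
    if not _has_missing(ped):
        return [ped.copy()]
    seeds = np.random.SeedSequence(seed).spawn(iterations)
    completed = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        out = ped.copy()
        _sample_current_ages(out, rng)
        _sample_diagnosis_ages(out, mdb, rng)
        completed.append(out)
    return completed


def aggregate(results: Sequence[Union[PosteriorResult, RiskEstimate]]
              ) -> Union[PosteriorResult, RiskEstimate]:
    """Combine per-imputation results: mean estimate, min lower, max upper."""
    if not results:
        raise ValueError("nothing to aggregate")
    first = results[0]
    if isinstance(first, PosteriorResult):
        for r in results[1:]:
            if not isinstance(r, PosteriorResult) or r.labels != first.labels \
                    or set(r.probands) != set(first.probands):
                raise ValueError("posterior results have incongruent shapes")
        probands = {}
        for pid in first.probands:
            stack = np.stack([r.probands[pid]["estimate"] for r in results])
            stack = np.sort(stack, axis=0)  # exact permutation invariance
            probands[pid] = {"estimate": stack.mean(axis=0),
                             "lower": stack.min(axis=0),
                             "upper": stack.max(axis=0)}
        return PosteriorResult(labels=list(first.labels), probands=probands)
    if isinstance(first, RiskEstimate):
        probands = {}
        for pid, per_cancer in first.probands.items():
            probands[pid] = {}
            for cancer, d in per_cancer.items():
                stacks = []
                for r in results:
                    if not isinstance(r, RiskEstimate) or pid not in r.probands \
                            or cancer not in r.probands[pid] \
                            or len(r.probands[pid][cancer]["by_age"]) != len(d["by_age"]):
                        raise ValueError("risk results have incongruent shapes")
                    stacks.append(r.probands[pid][cancer]["estimate"])
                stack = np.sort(np.stack(stacks), axis=0)
                probands[pid][cancer] = {"by_age": np.asarray(d["by_age"]).copy(),
                                         "estimate": stack.mean(axis=0),
                                         "lower": stack.min(axis=0),
                                         "upper": stack.max(axis=0)}
        return RiskEstimate(probands=probands)
    raise TypeError(f"cannot aggregate objects of type {type(first).__name__}")
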