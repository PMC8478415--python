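"""Phenotype likelihoods and the pedigree posterior engine.

The posterior over a counselee's genotype is proportional to

    P(G_1) * sum_{G_2..G_I} prod_i P(H_i | G_i, U_i) * P(G_2..G_I | G_1),

with founder genotypes drawn from Hardy-Weinberg priors and non-founder
genotypes from Mendelian transmission.  The per-member likelihood
P(H_ri | G_i, U_i) is the net penetrance at the observed diagnosis age
for an affected member, and the survival term 1 - sum_{s<=C_i} P(T=s)
for a member unaffected at censoring age C_i; germline-test and tumour-
marker results multiply in as additional factors.

``peel`` evaluates the sum exactly on loop-free pedigrees by sum-product
message passing over the tree of nuclear families (Elston-Stewart
peeling in its anterior/posterior factorisation), with every message
renormalized to guard against floating-point underflow.  Identical-twin
sets are collapsed into a single genotype variable.
``brute_force_posterior`` enumerates every genotype configuration and is
the independent oracle used in testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import networkx as nx
import numpy as np

from .core import (
    MAX_AGE, NONCARRIER, Individual, LoopError, ModelOptions, PanelPedError,
    Pedigree, PedigreeError, PosteriorResult,
)
from .genotypes import GenotypeSpace, GenotypeVector, founder_prior_vector, transmission_matrix
from .params import ModelDatabase

_NET = 0  # penetrance-type axis index used for genotype probabilities


def dominant_variant_indices(mdb: ModelDatabase, space: GenotypeSpace) -> np.ndarray:
    """(N, R, 2) variant index supplying the penetrance curve per genotype.

    For a multi-carrier genotype the carried variant with the largest
    lifetime net cumulative penetrance (for that cancer and sex) is
    used; the noncarrier genotype maps to the noncarrier baseline row.
    """
    life = mdb.dominant_variant_table()  # (K, R, 2)
    M = space.carrier_matrix  # (N, K)
    N, K = M.shape
    R = len(mdb.cancers)
    out = np.full((N, R, 2), mdb.noncarrier_index, dtype=np.int64)
    for i in range(N):
        carried = np.flatnonzero(M[i])
        if carried.size == 0:
            continue
        sub = life[carried]  # (n_carried, R, 2)
        out[i] = carried[np.argmax(sub, axis=0)]
    return out


def _riskmod_factor_curves(ind: Individual, mdb: ModelDatabase) -> Optional[np.ndarray]:
    """(R, MAX_AGE) multiplicative hazard factors from interventions."""
    if not ind.interventions or not mdb.risk_modifiers:
        return None
    fac = np.ones((len(mdb.cancers), MAX_AGE))
    any_change = False
    ages = np.arange(1, MAX_AGE + 1)
    for kind, age in ind.interventions:
        for r, cancer in enumerate(mdb.cancers):
            factor = mdb.risk_modifiers.get((kind, cancer), 1.0)
            if factor != 1.0:
                fac[r, ages >= age] *= factor
                any_change = True
    return fac if any_change else None


def likelihood_vector(ind: Individual, mdb: ModelDatabase, space: GenotypeSpace,
                      options: Optional[ModelOptions] = None,
                      dom: Optional[np.ndarray] = None,
                      tag_by_cancer: Optional[Dict[str, str]] = None) -> np.ndarray:
    """P(H_i | G, U_i) over the genotype space for one individual."""
    opts = options or ModelOptions()
    N = len(space)
    if ind.pseudo:
        return np.ones(N)
    if dom is None:
        dom = dominant_variant_indices(mdb, space)
    if tag_by_cancer is None:
        tag_by_cancer = {name: tag for tag, name in mdb.cancer_tags.items()}

    ri = mdb.race_index(ind.race)
    s = ind.sex
    fac = _riskmod_factor_curves(ind, mdb)
    log_lik = np.zeros(N)
    for r, cancer in enumerate(mdb.cancers):
        tag = tag_by_cancer.get(cancer, cancer)
        hist = ind.cancers.get(tag)
        if hist is None:
            continue  # cancer not observed in this pedigree
        pen_curves = mdb.pen[r, :, ri, s, :, _NET]  # (V, 94)
        if fac is not None:
            pen_curves = pen_curves * fac[r][None, :]
        cum_curves = np.cumsum(pen_curves, axis=1)
        v_idx = dom[:, r, s]
        if hist.affected == 1:
            t = hist.diagnosis_age
            if t is not None:
                vals = pen_curves[v_idx, t - 1]
            elif ind.cur_age is not None:
                vals = cum_curves[v_idx, ind.cur_age - 1]  # P(T <= C), defensive
            else:
                continue
        else:
            if ind.cur_age is None:
                continue  # no phenotype information without a censoring age
            vals = 1.0 - cum_curves[v_idx, ind.cur_age - 1]
        with np.errstate(divide="ignore"):
            log_lik += np.log(np.clip(vals, 0.0, None))

    lik = np.exp(log_lik)
    lik[~np.isfinite(log_lik)] = 0.0

    # germline test results (perfect test by default)
    sens, spec = opts.germline_sensitivity, opts.germline_specificity
    M = space.carrier_matrix
    for gene, result in ind.germline.items():
        if gene not in mdb.genes:
            continue
        k = mdb.genes.index(gene)
        carrier = M[:, k] == 1
        if result == 1:
            lik *= np.where(carrier, sens, 1.0 - spec)
        else:
            lik *= np.where(carrier, 1.0 - sens, spec)

    # tumour-marker results through pluggable per-variant tables
    for marker, result in ind.markers.items():
        table = mdb.marker_tables.get(marker)
        if not table:
            continue
        p = np.empty(N)
        for i in range(N):
            carried = [mdb.gene_variants[k] for k in np.flatnonzero(M[i])]
            key = next((v for v in carried if v in table), NONCARRIER)
            p[i] = table.get(key, np.nan)
        if np.any(np.isnan(p)):
            continue
        lik *= p if result == 1 else 1.0 - p
    return lik


def phenotype_likelihood(ind: Individual, g: GenotypeVector, mdb: ModelDatabase,
                         options: Optional[ModelOptions] = None) -> float:
    """Scalar P(H_i | G_i = g, U_i); see :func:`likelihood_vector`."""
    space1 = GenotypeSpace([g], list(mdb.gene_variants), max(1, sum(g.flags)))
    return float(likelihood_vector(ind, mdb, space1, options)[0])


# ---------------------------------------------------------------------------
# Pedigree structure shared by peel and the brute-force oracle
# ---------------------------------------------------------------------------

@dataclass
class _Structures:
    var_of: Dict[int, int]            # individual id -> variable id
    members: Dict[int, List[int]]     # variable id -> member ids
    local: Dict[int, np.ndarray]      # variable id -> local factor (lik x prior)
    founder_vars: List[int]
    families: List[Tuple[int, int, List[int]]]  # (mother var, father var, child vars)
    T: np.ndarray                     # transmission tensor


def _build_structures(ped: Pedigree, mdb: ModelDatabase, space: GenotypeSpace,
                      options: Optional[ModelOptions]) -> _Structures:
    var_of: Dict[int, int] = {m.id: m.id for m in ped}
    twin_groups: Dict[int, List[int]] = {}
    for m in ped:
        if m.twin_group > 0:
            twin_groups.setdefault(m.twin_group, []).append(m.id)
    for ids in twin_groups.values():
        rep = min(ids)
        for i in ids:
            var_of[i] = rep
    members: Dict[int, List[int]] = {}
    for iid, v in var_of.items():
        members.setdefault(v, []).append(iid)

    dom = dominant_variant_indices(mdb, space)
    tag_by_cancer = {name: tag for tag, name in mdb.cancer_tags.items()}
    local: Dict[int, np.ndarray] = {}
    founder_vars: List[int] = []
    fam_children: Dict[Tuple[int, int], List[int]] = {}
    for v, ids in members.items():
        first = ped.individuals[ids[0]]
        vec = np.ones(len(space))
        for iid in ids:
            vec = vec * likelihood_vector(ped.individuals[iid], mdb, space,
                                          options, dom, tag_by_cancer)
        if first.is_founder():
            freqs = mdb.frequencies(first.ancestry)
            vec = vec * founder_prior_vector(space, freqs)
            founder_vars.append(v)
        elif (first.mother_id is None) != (first.father_id is None):
            raise PedigreeError(
                f"ID {first.id}: has exactly one recorded parent; run the "
                "pedigree check to insert pseudo-parents")
        else:
            fam_children.setdefault(
                (var_of[first.mother_id], var_of[first.father_id]), []).append(v)
        local[v] = vec
    families = [(pm, pf, children) for (pm, pf), children in fam_children.items()]
    return _Structures(var_of, members, local, founder_vars, families,
                       transmission_matrix(space))


def _result_from_marginals(ped: Pedigree, space: GenotypeSpace,
                           var_of: Dict[int, int],
                           marginals: Dict[int, np.ndarray]) -> PosteriorResult:
    probands = {}
    for p in ped.probands():
        est = marginals[var_of[p.id]]
        probands[p.id] = {"estimate": est.copy(), "lower": est.copy(),
                          "upper": est.copy()}
    return PosteriorResult(labels=space.labels, probands=probands)


def peel(ped: Pedigree, mdb: ModelDatabase, space: GenotypeSpace,
         options: Optional[ModelOptions] = None) -> PosteriorResult:
    """Posterior genotype probabilities for every proband (single pass).

    Exact on loop-free pedigrees; supports any number of probands in one
    message-passing sweep.  Raises :class:`LoopError` if the family
    graph is not a forest.
    """
    st = _build_structures(ped, mdb, space, options)
    g = nx.Graph()
    for v in st.local:
        g.add_node(("v", v))
    for i, (pm, pf, children) in enumerate(st.families):
        fnode = ("f", i)
        g.add_node(fnode)
        g.add_edge(("v", pm), fnode)
        g.add_edge(("v", pf), fnode)
        for c in children:
            g.add_edge(("v", c), fnode)
    if nx.cycle_basis(g):
        raise LoopError("pedigree family graph contains a cycle; peeling requires "
                        "a loop-free pedigree")

    msgs: Dict[Tuple[tuple, tuple], np.ndarray] = {}

    def norm(vec: np.ndarray) -> np.ndarray:
        s = vec.sum()
        if s <= 0:
            raise PanelPedError("pedigree has zero likelihood under the model "
                                "(contradictory phenotypes or test results)")
        return vec / s

    def message(src: tuple, dst: tuple) -> np.ndarray:
        if src[0] == "v":
            out = st.local[src[1]].copy()
            for nb in g.neighbors(src):
                if nb != dst:
                    out = out * msgs[(nb, src)]
            return norm(out)
        pm, pf, children = st.families[src[1]]
        s_list = {}
        for c in children:
            if ("v", c) != dst:
                s_list[c] = np.einsum("cmf,c->mf", st.T, msgs[(("v", c), src)])
        if dst[0] == "v" and dst[1] in children:
            W = np.outer(msgs[(("v", pm), src)], msgs[(("v", pf), src)])
            for s_c in s_list.values():
                W = W * s_c
            return norm(np.einsum("cmf,mf->c", st.T, W))
        W = np.ones_like(st.T[0])
        for s_c in s_list.values():
            W = W * s_c
        if dst == ("v", pm):
            return norm(W @ msgs[(("v", pf), src)])
        if dst == ("v", pf):
            return norm(msgs[(("v", pm), src)] @ W)
        raise AssertionError("unreachable")

    for component in nx.connected_components(g):
        root = next(iter(sorted(component)))
        tree = nx.bfs_tree(g, root)
        order = list(nx.topological_sort(tree))
        parent = {child: par for par, child in tree.edges()}
        for node in reversed(order):
            if node in parent:
                msgs[(node, parent[node])] = message(node, parent[node])
        for node in order:
            for child in tree.successors(node):
                msgs[(node, child)] = message(node, child)

    marginals = {}
    for v in st.local:
        belief = st.local[v].copy()
        for nb in g.neighbors(("v", v)):
            belief = belief * msgs[(nb, ("v", v))]
        marginals[v] = belief / belief.sum()
    return _result_from_marginals(ped, space, st.var_of, marginals)


BRUTE_FORCE_GUARD = 10_000_000


def brute_force_posterior(ped: Pedigree, mdb: ModelDatabase, space: GenotypeSpace,
                          options: Optional[ModelOptions] = None) -> PosteriorResult:
    """Exact posterior by enumerating every genotype configuration.

    Independent oracle for :func:`peel`: sums founder priors x
    transmissions x likelihoods over all |space|^(n variables)
    configurations.  Guarded at 10^7 configurations.
    """
    st = _build_structures(ped, mdb, space, options)
    var_list = sorted(st.local)
    n, N = len(var_list), len(space)
    total = N ** n
    if total > BRUTE_FORCE_GUARD:
        raise PanelPedError(
            f"{total} genotype configurations exceed the enumeration guard "
            f"({BRUTE_FORCE_GUARD})")
    col = {v: i for i, v in enumerate(var_list)}
    posts = {v: np.zeros(N) for v in var_list}
    radix = N ** np.arange(n - 1, -1, -1, dtype=np.int64)
    chunk = 1 << 18
    for start in range(0, total, chunk):
        idx = np.arange(start, min(start + chunk, total), dtype=np.int64)
        conf = (idx[:, None] // radix[None, :]) % N
        w = np.ones(len(idx))
        for v in var_list:
            w *= st.local[v][conf[:, col[v]]]
        for pm, pf, children in st.families:
            for c in children:
                w *= st.T[conf[:, col[c]], conf[:, col[pm]], conf[:, col[pf]]]
        for v in var_list:
            posts[v] += np.bincount(conf[:, col[v]], weights=w, minlength=N)
    marginals = {}
    for v in var_list:
        s = posts[v].sum()
        if s <= 0:
            raise PanelPedError("pedigree has zero likelihood under the model")
        marginals[v] = posts[v] / s
    return _result_from_marginals(ped, space, st.var_of, marginals)
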