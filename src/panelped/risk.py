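"""Future cancer risk from the posterior genotype distribution.

For a counselee free of cancer r at censoring age C, the risk of
developing it by age C + t0 is the posterior-weighted mixture of the
genotype-specific conditional penetrances:

    risk(a) = sum_G P(G | H, U) * [F_G(a) - F_G(C)] / [1 - F_G(C)]

where F_G is the cumulative penetrance of genotype G — crude by default
(competing mortality accounted for), net on request.  Division by
1 - F_G(C) conditions each genotype-specific term on being cancer-free
at the current age, making the reported risk a proper conditional
probability.  Risks are reported on the grid C + age_by * k up to 94.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional

import numpy as np

from .core import MAX_AGE, ModelOptions, Pedigree, PosteriorResult, RiskEstimate
from .genotypes import GenotypeSpace
from .inference import _riskmod_factor_curves, dominant_variant_indices
from .params import ModelDatabase


def risk_grid(cur_age: int, age_by: int) -> np.ndarray:
    """Report ages cur_age + age_by*k, k >= 1, capped at 94."""
    return np.arange(cur_age + age_by, MAX_AGE + 1, age_by, dtype=int)


def future_risk(posterior: PosteriorResult, ped: Pedigree, mdb: ModelDatabase,
                space: GenotypeSpace,
                options: Optional[ModelOptions] = None,
                include: Optional[set] = None) -> RiskEstimate:
    """Project future risk for every proband and every cancer they have
    not had (single imputation pass: lower = estimate = upper).

    ``include`` optionally restricts projection to a subset of proband
    ids (others get an empty risk section); used when a proband's
    censoring age had to be imputed, since risk grids anchored at
    sampled ages would not be congruent across imputations.
    """
    opts = options or ModelOptions()
    ptype = 0 if opts.net else 1  # Net / Crude axis
    dom = dominant_variant_indices(mdb, space)
    tag_by_cancer = {name: tag for tag, name in mdb.cancer_tags.items()}
    out: Dict[int, Dict[str, Dict[str, np.ndarray]]] = {}
    for proband in ped.probands():
        post = posterior.probands[proband.id]["estimate"]
        per_cancer: Dict[str, Dict[str, np.ndarray]] = {}
        if include is not None and proband.id not in include:
            out[proband.id] = per_cancer
            continue
        if proband.cur_age is None:
            warnings.warn(f"proband {proband.id} has no censoring age; "
                          "future risk omitted")
            out[proband.id] = per_cancer
            continue
        C = proband.cur_age
        ri = mdb.race_index(proband.race)
        s = proband.sex
        fac = _riskmod_factor_curves(proband, mdb)
        for r, cancer in enumerate(mdb.cancers):
            tag = tag_by_cancer.get(cancer, cancer)
            hist = proband.cancers.get(tag)
            if hist is not None and hist.affected == 1:
                continue  # already diagnosed: no future-risk projection
            grid = risk_grid(C, opts.age_by)
            if grid.size == 0:
                per_cancer[cancer] = {"by_age": grid,
                                      "estimate": np.zeros(0),
                                      "lower": np.zeros(0), "upper": np.zeros(0)}
                continue
            pen_curves = mdb.pen[r, :, ri, s, :, ptype]  # (V, 94)
            if fac is not None:
                pen_curves = pen_curves * fac[r][None, :]
            cum = np.cumsum(pen_curves, axis=1)
            v_idx = dom[:, r, s]
            F_C = cum[v_idx, C - 1]  # (N,)
            denom = np.clip(1.0 - F_C, 1e-300, None)
            est = np.empty(grid.size)
            for j, a in enumerate(grid):
                F_a = cum[v_idx, a - 1]
                est[j] = float(post @ ((F_a - F_C) / denom))
            est = np.clip(est, 0.0, 1.0)
            per_cancer[cancer] = {"by_age": grid, "estimate": est,
                                  "lower": est.copy(), "upper": est.copy()}
        out[proband.id] = per_cancer
    return RiskEstimate(probands=out)
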