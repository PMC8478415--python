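"""Top-level orchestration: check -> build -> impute -> peel -> risk.

``run_model`` is the main entry point.  It validates and repairs the
pedigree, subsets the parameter database to the requested cancers and
genes, imputes missing ages (one pass per imputation), runs the peeling
engine and the future-risk projection on each completed pedigree, and
aggregates the per-imputation results into estimate/lower/upper.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence, Union

import numpy as np

from .core import (
    ModelOptions, ParameterDatabase, Pedigree, PosteriorResult, RiskEstimate,
)
from .check import check_pedigree
from .genotypes import enumerate_genotypes
from .imputation import aggregate, impute_ages
from .inference import brute_force_posterior, peel
from .io import read_pedigree
from .params import build_model_database, preset_model
from .risk import future_risk


def run_model(ped: Union[Pedigree, str, Path], db: ParameterDatabase,
              cancers: Optional[Sequence[str]] = None,
              genes: Optional[Sequence[str]] = None,
              options: Optional[ModelOptions] = None,
              preset: Optional[str] = None,
              engine: str = "peel") -> Dict[str, object]:
    """Run the full pipeline; returns posterior, future risk and report.

    ``preset`` overrides ``cancers``/``genes`` with a named classic model
    specification.  ``engine`` selects the posterior engine: ``"peel"``
    (default) or ``"brute"`` (exhaustive enumeration; small inputs only).
    Deterministic for a fixed ``options.seed``.
    """
    opts = options or ModelOptions()
    if preset is not None:
        cancers, genes = preset_model(preset)
    if not isinstance(ped, Pedigree):
        ped = read_pedigree(ped)

    checked, report = check_pedigree(ped, db, cancers=cancers, genes=genes)
    mdb = build_model_database(db, cancers=cancers, genes=genes, ped=checked)
    space = enumerate_genotypes(mdb.gene_variants,
                                opts.resolved_max_mut(mdb.n_genes))
    completed = impute_ages(checked, mdb, iterations=opts.iterations,
                            seed=opts.seed)
    # probands whose censoring age had to be imputed get no risk grid
    risk_probands = {p.id for p in checked.probands() if p.cur_age is not None}
    solver = brute_force_posterior if engine == "brute" else peel
    posteriors, risks = [], []
    for cped in completed:
        post = solver(cped, mdb, space, opts)
        posteriors.append(post)
        risks.append(future_risk(post, cped, mdb, space, opts,
                                 include=risk_probands))
    posterior = aggregate(posteriors)
    risk = aggregate(risks)
    posterior.validate()
    risk.validate()
    return {"posterior": posterior, "future_risk": risk, "report": report}


def serialize_output(result: Dict[str, object]) -> Dict[str, object]:
    """Render a run_model result as a JSON-ready nested document.

    Field names mirror the engine's printed output structure:
    ``posterior.prob`` keyed by proband id with genes/estimate/lower/
    upper rows, and ``future.risk`` keyed by proband id and cancer with
    ByAge/estimate/lower/upper rows.
    """
    posterior: PosteriorResult = result["posterior"]
    risk: RiskEstimate = result["future_risk"]
    doc: Dict[str, object] = {"posterior.prob": {}, "future.risk": {}}
    for pid in posterior.probands:
        doc["posterior.prob"][str(pid)] = [
            {"genes": lab, "estimate": est, "lower": lo, "upper": hi}
            for lab, est, lo, hi in posterior.entries(pid)]
    for pid, per_cancer in risk.probands.items():
        doc["future.risk"][str(pid)] = {
            cancer: [{"ByAge": a, "estimate": e, "lower": lo, "upper": hi}
                     for a, e, lo, hi in risk.entries(pid, cancer)]
            for cancer in per_cancer}
    return doc


def parse_output(doc: Dict[str, object]) -> Dict[str, object]:
    """Inverse of :func:`serialize_output` (posterior and risk only)."""
    post_doc = doc["posterior.prob"]
    labels = None
    probands = {}
    for pid, rows in post_doc.items():
        if labels is None:
            labels = [row["genes"] for row in rows]
        probands[int(pid)] = {
            "estimate": np.array([row["estimate"] for row in rows]),
            "lower": np.array([row["lower"] for row in rows]),
            "upper": np.array([row["upper"] for row in rows]),
        }
    risk_probands = {}
    for pid, per_cancer in doc["future.risk"].items():
        risk_probands[int(pid)] = {
            cancer: {
                "by_age": np.array([row["ByAge"] for row in rows], dtype=int),
                "estimate": np.array([row["estimate"] for row in rows]),
                "lower": np.array([row["lower"] for row in rows]),
                "upper": np.array([row["upper"] for row in rows]),
            } for cancer, rows in per_cancer.items()}
    return {"posterior": PosteriorResult(labels=labels or [], probands=probands),
            "future_risk": RiskEstimate(probands=risk_probands)}


def write_output(result: Dict[str, object], path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(serialize_output(result), indent=2))


def plot_risk(result: Dict[str, object], path: Union[str, Path]) -> None:
    """Static chart: posterior bars plus risk curves with bounds, one
    panel row per proband."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    posterior: PosteriorResult = result["posterior"]
    risk: RiskEstimate = result["future_risk"]
    pids = list(posterior.probands)
    fig, axes = plt.subplots(len(pids), 2, figsize=(11, 3.5 * len(pids)),
                             squeeze=False)
    for row, pid in enumerate(pids):
        ax = axes[row][0]
        entries = posterior.entries(pid)
        labels = [e[0] for e in entries]
        est = np.array([e[1] for e in entries])
        lo = np.array([e[2] for e in entries])
        hi = np.array([e[3] for e in entries])
        x = np.arange(len(labels))
        ax.bar(x, est, yerr=[est - lo, hi - est], capsize=2, color="#4878d0")
        ax.set_xticks(x)
        ax.set_xticklabels(labels, rotation=90, fontsize=6)
        ax.set_ylabel("posterior probability")
        ax.set_title(f"proband {pid}")
        ax = axes[row][1]
        for cancer in risk.probands.get(pid, {}):
            rows = risk.entries(pid, cancer)
            if not rows:
                continue
            ages = [r[0] for r in rows]
            est_r = [r[1] for r in rows]
            ax.plot(ages, est_r, marker="o", label=cancer)
            ax.fill_between(ages, [r[2] for r in rows], [r[3] for r in rows],
                            alpha=0.25)
        ax.set_xlabel("age")
        ax.set_ylabel("future risk")
        if risk.probands.get(pid):
            ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
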